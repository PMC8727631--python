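"""Readers and writers for the plain-text interchange formats.

BED (3-6 columns), fixed-step bedGraph, and the TSV tables used for TSS
annotation, expression matrices, survival records and limiting-dilution
designs. All parsers raise :class:`ParseError` with a line number on
malformed records; nothing is silently coerced. Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .intervals import GenomicInterval, TSS
from .lda import LDAExperiment
from .survival import SurvivalRecord
from .tracks import BinnedTrack


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _is_header_line(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6. Track/browser/comment lines are skipped; strand '.'
    maps to absent; the score column '.' likewise."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ParseError(path, lineno, f"non-integer coordinates: {err}") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative start {start}")
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {fields[4]!r}") from None
            strand = None
            if len(fields) > 5 and fields[5] != ".":
                if fields[5] not in ("+", "-"):
                    raise ParseError(path, lineno, f"bad strand {fields[5]!r}")
                strand = fields[5]
            out.append(GenomicInterval(chrom, start, end, strand=strand, score=score, name=name))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, bin_size: int | None = None) -> BinnedTrack:
    """Read a single-chromosome fixed-step bedGraph into a binned track.

    Every record must span exactly one bin; bins must tile the chromosome
    contiguously from 0 (the writer's convention).
    """
    chrom = None
    values: list[float] = []
    expected_start = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as err:
                raise ParseError(path, lineno, str(err)) from None
            if chrom is None:
                chrom = fields[0]
                if bin_size is None:
                    bin_size = end - start
            elif fields[0] != chrom:
                raise ParseError(path, lineno, "multiple chromosomes in one bedGraph track")
            if start != expected_start:
                raise ParseError(path, lineno, f"non-contiguous bin at {start}")
            if end - start != bin_size:
                raise ParseError(path, lineno, f"bin width {end - start} != {bin_size}")
            values.append(value)
            expected_start = end
    if chrom is None:
        raise ParseError(path, 0, "empty bedGraph")
    return BinnedTrack(chrom=chrom, bin_size=int(bin_size), values=np.asarray(values))


def write_bedgraph(path: str | Path, track: BinnedTrack) -> None:
    bs = track.bin_size
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{i * bs}\t{(i + 1) * bs}\t{format(v, 'g')}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_tss(path: str | Path) -> list[TSS]:
    """TSV with header: gene_id, chrom, pos, strand."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["gene_id", "chrom", "pos", "strand"]:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 columns")
            try:
                out.append(TSS(fields[0], fields[1], int(fields[2]), fields[3]))
            except ValueError as err:
                raise ParseError(path, lineno, str(err)) from None
    return out


def write_tss(path: str | Path, tss_table: Sequence[TSS]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tpos\tstrand\n")
        for t in tss_table:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.pos}\t{t.strand}\n")


def read_expression(values_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Genes x samples TSV (first column gene_id) plus a two-column label file."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t", index_col=0)
    labels = labels_df.iloc[:, 0]
    return ExpressionMatrix(values=values, group_labels=labels)


def write_expression(values_path: str | Path, labels_path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    matrix.group_labels.rename("group").to_csv(labels_path, sep="\t", index_label="sample")


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """TSV with header: time, event, marker, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"time", "event", "marker"}
    if not required.issubset(df.columns):
        raise ParseError(path, 1, f"missing columns {sorted(required - set(df.columns))}")
    covs = [c for c in df.columns if c not in required]
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SurvivalRecord(
                    time=float(row["time"]),
                    event=int(row["event"]),
                    marker=float(row["marker"]),
                    covariates={c: float(row[c]) for c in covs},
                )
            )
        except ValueError as err:
            raise ParseError(path, i + 2, str(err)) from None
    return out


def write_survival(path: str | Path, records: Sequence[SurvivalRecord]) -> None:
    covs = sorted({c for r in records for c in r.covariates})
    rows = [
        {"time": r.time, "event": r.event, "marker": r.marker, **r.covariates}
        for r in records
    ]
    pd.DataFrame(rows, columns=["time", "event", "marker", *covs]).to_csv(
        path, sep="\t", index=False
    )


def read_lda(path: str | Path) -> list[LDAExperiment]:
    """TSV with header: dose, n_injected, n_positive, group. One experiment per group."""
    df = pd.read_csv(path, sep="\t")
    required = {"dose", "n_injected", "n_positive", "group"}
    if not required.issubset(df.columns):
        raise ParseError(path, 1, f"missing columns {sorted(required - set(df.columns))}")
    out = []
    for group, sub in df.groupby("group", sort=False):
        out.append(
            LDAExperiment(
                dose=sub["dose"].to_numpy(float),
                n_injected=sub["n_injected"].to_numpy(int),
                n_positive=sub["n_positive"].to_numpy(int),
                group=str(group),
            )
        )
    return out


def write_lda(path: str | Path, experiments: Sequence[LDAExperiment]) -> None:
    rows = []
    for exp in experiments:
        for d, n, r in zip(exp.dose, exp.n_injected, exp.n_positive):
            rows.append({"dose": d, "n_injected": n, "n_positive": r, "group": exp.group})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to {id: sequence} via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
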