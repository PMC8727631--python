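"""End-to-end pipeline: tracks -> enhancers -> subtype SEs -> gene pairs.

Stages, in order: binarize + HMM segmentation per track; promoter filter;
super-enhancer call per track; subtype-specific SE loci; differential
expression; SE-gene pairing. Each stage writes its output under the run
directory and contributes counts to a JSON summary. Given identical inputs
and seed the whole run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from . import io as sio
from .expression import differential_expression, de_table
from .hmm import decode_regions, fit_hmm
from .pairing import pair_se_genes, subtype_specific_ses
from .secall import call_super_enhancers, filter_promoters
from .simulate import SimulationConfig, make_truth, simulate_chip_track, simulate_expression
from .tracks import binarize_track

log = logging.getLogger("sescope")


@dataclass
class PipelineConfig:
    track_paths: dict[str, str]          # label -> bedGraph path
    track_subtypes: dict[str, str]       # label -> TNBC | nonTNBC
    tss_path: str
    expression_path: str
    labels_path: str
    dnase_peaks_path: str | None = None
    outdir: str = "sescope_out"
    seed: int = 0
    # segmentation
    p_threshold: float = 1e-4
    hmm_restarts: int = 3
    # enhancer catalogue
    promoter_window: int = 2500
    loess_span: float = 0.3
    ranking: str = "size"
    # subtype specificity
    k_min_subtype: int = 2
    k_max_other: int = 0
    min_reciprocal: float = 0.5
    # differential expression / pairing
    prior_weight: float = 4.0
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    max_distance: int = 500_000

    def validate(self) -> None:
        for label, p in self.track_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"track {label}: {p}")
            if label not in self.track_subtypes:
                raise ValueError(f"track {label} has no subtype label")
        for p in (self.tss_path, self.expression_path, self.labels_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all six stages; returns (and writes) the summary report."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("track_paths", "track_subtypes", "outdir")
        },
        "counts": {},
    }

    def stage(name):
        log.info("[%s] starting", name)
        return name

    # 1. segmentation
    s = stage("segment")
    enrichment = {}
    try:
        for i, (label, path) in enumerate(sorted(config.track_paths.items())):
            track = sio.read_bedgraph(path)
            binarized = binarize_track(track, p_threshold=config.p_threshold)
            model = fit_hmm(
                binarized, seed=config.seed * 1000 + i, n_restarts=config.hmm_restarts
            )
            regions = decode_regions(model, binarized)
            enrichment[label] = regions
            sio.write_bed(out / f"enrichment_{label}.bed", regions)
            log.info("[segment] %s: %d regions", label, len(regions))
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["enrichment_regions"] = {k: len(v) for k, v in sorted(enrichment.items())}

    # 2. promoter filter
    s = stage("promoter_filter")
    try:
        tss_table = sio.read_tss(config.tss_path)
        enhancers = {
            label: filter_promoters(regs, tss_table, window=config.promoter_window)
            for label, regs in enrichment.items()
        }
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["enhancers_after_promoter_filter"] = {
        k: len(v) for k, v in sorted(enhancers.items())
    }

    # 3. super-enhancer call per track
    s = stage("se_call")
    se_calls = {}
    try:
        for label, regs in enhancers.items():
            result = call_super_enhancers(
                regs, ranking=config.ranking, loess_span=config.loess_span
            )
            se_calls[label] = result
            sio.write_bed(
                out / f"se_call_{label}.bed",
                [
                    r.interval.with_name(f"{r.enh_class}_rank{r.rank}")
                    for r in result.regions
                ],
            )
            log.info("[se_call] %s: %d super / %d total", label, len(result.supers), len(result.regions))
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["super_enhancers"] = {
        k: len(v.supers) for k, v in sorted(se_calls.items())
    }

    # 4. subtype-specific SE loci
    s = stage("subtype_specific")
    try:
        specific = subtype_specific_ses(
            se_calls,
            labels=config.track_subtypes,
            k_min_subtype=config.k_min_subtype,
            k_max_other=config.k_max_other,
            min_reciprocal=config.min_reciprocal,
        )
        sio.write_bed(
            out / "specific_ses.bed",
            [loc.interval.with_name(loc.se_id) for loc in specific],
        )
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["subtype_specific_ses"] = len(specific)

    # 5. differential expression
    s = stage("differential_expression")
    try:
        matrix = sio.read_expression(config.expression_path, config.labels_path)
        de = differential_expression(
            matrix,
            prior_weight=config.prior_weight,
            lfc_threshold=config.lfc_threshold,
            alpha=config.alpha,
        )
        de_table(de).to_csv(out / "de_results.tsv", sep="\t")
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["upregulated_genes"] = sum(r.upregulated for r in de)

    # 6. pairing
    s = stage("pairing")
    try:
        pairs = pair_se_genes(
            specific, tss_table, de, max_distance=config.max_distance
        )
        with open(out / "pairs.tsv", "w") as fh:
            fh.write("se_id\tgene_id\tdistance\n")
            for p in pairs:
                fh.write(f"{p.se_id}\t{p.gene_id}\t{p.distance}\n")
    except Exception as err:
        raise StageError(s, err) from err
    summary["counts"]["se_gene_pairs"] = len(pairs)
    summary["pairs"] = [
        {"se_id": p.se_id, "gene_id": p.gene_id, "distance": p.distance} for p in pairs
    ]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline finished: %d pairs", len(pairs))
    return summary


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic input bundle (with its planted truth).

    Returns a manifest mapping logical names to paths, plus the truth
    object under key "truth". The bundle is everything run_pipeline and the
    survival/LDA verbs consume.
    """
    from .simulate import simulate_lda, simulate_survival

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    manifest: dict = {"truth": truth, "track_paths": {}, "track_subtypes": {}}
    for label in config.track_labels:
        track = simulate_chip_track(truth, config, label)
        path = out / f"track_{label}.bedgraph"
        sio.write_bedgraph(path, track)
        manifest["track_paths"][label] = str(path)
        manifest["track_subtypes"][label] = config.track_subtype(label)
    sio.write_bed(
        out / "planted_enhancers.bed",
        [
            e.interval.with_name(
                f"{e.enh_class}{'_specific' if e.subtype_specific else ''}"
            )
            for e in truth.planted_enhancers
        ],
    )
    sio.write_bed(out / "dnase_peaks.bed", truth.dnase_peaks)
    sio.write_tss(out / "tss.tsv", truth.tss)
    matrix = simulate_expression(truth, config)
    sio.write_expression(out / "expression.tsv", out / "labels.tsv", matrix)
    sio.write_survival(out / "survival.tsv", simulate_survival(config))
    sio.write_lda(out / "lda.tsv", simulate_lda(config))
    manifest.update(
        {
            "dnase_peaks_path": str(out / "dnase_peaks.bed"),
            "tss_path": str(out / "tss.tsv"),
            "expression_path": str(out / "expression.tsv"),
            "labels_path": str(out / "labels.tsv"),
            "survival_path": str(out / "survival.tsv"),
            "lda_path": str(out / "lda.tsv"),
        }
    )
    return manifest


def pipeline_config_from_bundle(
    manifest: Mapping, outdir: str | Path, seed: int = 0, **params
) -> PipelineConfig:
    return PipelineConfig(
        track_paths=dict(manifest["track_paths"]),
        track_subtypes=dict(manifest["track_subtypes"]),
        tss_path=manifest["tss_path"],
        expression_path=manifest["expression_path"],
        labels_path=manifest["labels_path"],
        dnase_peaks_path=manifest.get("dnase_peaks_path"),
        outdir=str(outdir),
        seed=seed,
        **params,
    )
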