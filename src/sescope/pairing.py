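"""Subtype-specific super-enhancers and enhancer-gene pairing.

Super-enhancer calls from several tracks are merged into loci (connected
components under >= 50% reciprocal overlap); a locus is subtype-specific
when enough tracks of the target subtype and few enough other tracks
support it. A specific locus is paired with a gene when the gene is
upregulated, the locus lies strand-aware upstream of the gene's TSS and
the gap from the TSS to the nearest locus edge is at most a maximum
distance (default 500 kb). A locus containing the TSS counts as distance
0 and is still paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .expression import DEResult
from .intervals import GenomicInterval, TSS, reciprocal_overlap
from .secall import SECallResult


@dataclass(frozen=True)
class SELocus:
    """A reciprocal-overlap-merged super-enhancer locus across tracks."""

    se_id: str
    interval: GenomicInterval
    supporting_tracks: tuple[str, ...]


@dataclass(frozen=True)
class SEGenePair:
    se_id: str
    gene_id: str
    distance: int            # bp from nearest SE edge to the TSS; 0 if inside
    upstream: bool = True


def _super_intervals(call: SECallResult | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    if isinstance(call, SECallResult):
        return [r.interval for r in call.supers]
    return list(call)


def merge_se_loci(
    se_calls: Mapping[str, SECallResult | Sequence[GenomicInterval]],
    min_reciprocal: float = 0.5,
) -> list[SELocus]:
    """Cluster per-track super-enhancers into loci.

    Two SEs are linked when their reciprocal overlap is at least
    ``min_reciprocal``; connected components become loci spanning the union
    of their members. Loci are labelled SE1, SE2, ... in genomic order.
    """
    members: list[tuple[str, GenomicInterval]] = []
    for track, call in se_calls.items():
        for iv in _super_intervals(call):
            members.append((track, iv))
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if reciprocal_overlap(members[i][1], members[j][1]) >= min_reciprocal:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    loci = []
    for idxs in groups.values():
        ivs = [members[i][1] for i in idxs]
        chrom = ivs[0].chrom
        if any(iv.chrom != chrom for iv in ivs):
            raise ValueError("inconsistent chromosomes inside one merged locus")
        span = GenomicInterval(chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))
        tracks = tuple(sorted({members[i][0] for i in idxs}))
        loci.append((span, tracks))
    loci.sort(key=lambda x: (x[0].chrom, x[0].start, x[0].end))
    return [
        SELocus(se_id=f"SE{i + 1}", interval=span, supporting_tracks=tracks)
        for i, (span, tracks) in enumerate(loci)
    ]


def subtype_specific_ses(
    se_calls: Mapping[str, SECallResult | Sequence[GenomicInterval]],
    labels: Mapping[str, str],
    target_subtype: str = "TNBC",
    k_min_subtype: int = 2,
    k_max_other: int = 0,
    min_reciprocal: float = 0.5,
) -> list[SELocus]:
    """Loci called super in >= k_min_subtype target tracks and <= k_max_other others."""
    unknown = set(se_calls) - set(labels)
    if unknown:
        raise ValueError(f"tracks without subtype label: {sorted(unknown)}")
    loci = merge_se_loci(se_calls, min_reciprocal=min_reciprocal)
    out = []
    for locus in loci:
        n_target = sum(1 for t in locus.supporting_tracks if labels[t] == target_subtype)
        n_other = len(locus.supporting_tracks) - n_target
        if n_target >= k_min_subtype and n_other <= k_max_other:
            out.append(locus)
    return out


def upstream_gap(se: GenomicInterval, tss: TSS) -> int | None:
    """Strand-aware gap from the TSS to the nearest SE edge.

    Returns 0 when the TSS falls inside the SE, the non-negative gap when
    the SE lies entirely upstream of the TSS (lower coordinates for '+'
    genes, higher for '-'), and None when the SE is on the downstream side
    or another chromosome.
    """
    if se.chrom != tss.chrom:
        return None
    if se.contains(tss.chrom, tss.pos):
        return 0
    if tss.strand == "+":
        if se.end <= tss.pos:
            return tss.pos - se.end
        return None
    if se.start > tss.pos:
        return se.start - tss.pos
    return None


def pair_se_genes(
    specific_ses: Sequence[SELocus],
    tss_table: Sequence[TSS],
    de_results: Sequence[DEResult],
    max_distance: int = 500_000,
) -> list[SEGenePair]:
    """Pair each subtype-specific SE locus with nearby upregulated genes.

    A pair (SE, gene) is emitted iff the gene is upregulated, the SE lies
    strand-aware upstream of the gene's TSS (or contains it), and the gap
    is at most ``max_distance`` bp.
    """
    up_genes = {r.gene_id for r in de_results if r.upregulated}
    pairs: list[SEGenePair] = []
    for locus in specific_ses:
        for tss in tss_table:
            if tss.gene_id not in up_genes:
                continue
            gap = upstream_gap(locus.interval, tss)
            if gap is not None and gap <= max_distance:
                pairs.append(SEGenePair(se_id=locus.se_id, gene_id=tss.gene_id, distance=gap))
    pairs.sort(key=lambda p: (p.se_id, p.gene_id))
    return pairs
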