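"""Enhancer catalogue construction.

From HMM enrichment regions to a ranked enhancer list: regions overlapping
promoters (a fixed window around any TSS) are removed; the survivors are
ranked by size (or summed signal) and split into typical and super
enhancers at the slope-1 inflection of a LOESS fit to the rescaled ranked
curve — the standard "hockey stick" construction. DNase-hypersensitive
peaks falling inside a super-enhancer are its constituent (nucleosome-free)
elements, labelled e1, e2, ... in decreasing order of importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .intervals import GenomicInterval, TSS


class DegenerateDistributionError(ValueError):
    """Raised when all ranking values coincide and no inflection exists."""


@dataclass
class EnhancerRegion:
    interval: GenomicInterval
    signal: float | None = None
    rank: int | None = None                      # 1-based after sorting
    enh_class: Literal["typical", "super"] | None = None

    @property
    def size(self) -> int:
        return self.interval.length


@dataclass
class SECallResult:
    """Outcome of the super/typical split.

    ``fitted_curve`` holds (scaled_rank, scaled_value, fitted_value) triples
    for the ascending ranked curve; ``cutoff_value`` is in the original
    ranking units (bp for size ranking). Every region with ranking value
    >= ``cutoff_value`` — equivalently rank > ``cutoff_rank`` — is super.
    """

    regions: list[EnhancerRegion]
    fitted_curve: np.ndarray          # (n, 3) columns: scaled rank, scaled value, fit
    cutoff_rank: int
    cutoff_value: float
    loess_span: float
    ranking: str = "size"

    @property
    def supers(self) -> list[EnhancerRegion]:
        return [r for r in self.regions if r.enh_class == "super"]

    @property
    def typicals(self) -> list[EnhancerRegion]:
        return [r for r in self.regions if r.enh_class == "typical"]


def filter_promoters(
    regions: Sequence[EnhancerRegion | GenomicInterval],
    tss_table: Sequence[TSS],
    window: int = 2500,
) -> list[EnhancerRegion]:
    """Drop regions overlapping any promoter window ``[tss-window, tss+window)``.

    Overlap is half-open any-overlap; surviving regions pass through
    unchanged. The default window mirrors the +/-2.5 kb promoter definition
    used when retaining H3K27ac regions as predicted enhancers.
    """
    if window < 0:
        raise ValueError("promoter window must be non-negative")
    regs = [r if isinstance(r, EnhancerRegion) else EnhancerRegion(r) for r in regions]
    # promoter windows per chromosome, sorted by start for bisection
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tss_table:
        by_chrom.setdefault(t.chrom, []).append((max(0, t.pos - window), t.pos + window))
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, wins in by_chrom.items():
        wins.sort()
        s = np.array([w[0] for w in wins])
        e = np.maximum.accumulate(np.array([w[1] for w in wins]))
        starts[chrom], ends[chrom] = s, e
    kept = []
    for r in regs:
        iv = r.interval
        if iv.chrom not in starts:
            kept.append(r)
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        # windows with start < iv.end could overlap; among those, the max
        # running end decides (sorted starts + cumulative-max ends)
        i = int(np.searchsorted(s, iv.end, side="left"))
        if i == 0 or e[i - 1] <= iv.start:
            kept.append(r)
    return kept


def call_super_enhancers(
    regions: Sequence[EnhancerRegion | GenomicInterval],
    ranking: Literal["size", "signal"] = "size",
    loess_span: float = 0.3,
) -> SECallResult:
    """Split enhancers into typical and super at the LOESS slope-1 inflection.

    Regions are sorted ascending by the ranking value (region size by
    default, summed signal optionally); both rank and value axes are
    min-max rescaled to [0, 1]; a degree-1 LOESS is fitted to the rescaled
    curve and its numerical derivative (central finite differences) is
    scanned from low to high rank. The cutoff is the fitted value at the
    first point where the derivative reaches 1; every region whose ranking
    value is at least that cutoff (mapped back to original units) is super.
    """
    regs = [r if isinstance(r, EnhancerRegion) else EnhancerRegion(r) for r in regions]
    if len(regs) < 10:
        raise ValueError("super-enhancer calling requires at least 10 regions")
    if ranking == "size":
        values = np.array([float(r.size) for r in regs])
    elif ranking == "signal":
        if any(r.signal is None for r in regs):
            raise ValueError("signal ranking requested but some regions lack signal")
        values = np.array([float(r.signal) for r in regs])
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    if np.any(values <= 0):
        raise ValueError("ranking values must be positive")
    if np.ptp(values) == 0:
        raise DegenerateDistributionError(
            "all ranking values are equal; the ranked curve has no inflection"
        )

    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    n = len(regs)
    x = np.arange(n) / (n - 1)
    y = (v_sorted - v_sorted[0]) / (v_sorted[-1] - v_sorted[0])
    fit = lowess(y, x, frac=loess_span, it=0, return_sorted=False)
    deriv = np.gradient(fit, x)
    crossing = np.nonzero(deriv >= 1.0)[0]
    if crossing.size == 0:
        raise DegenerateDistributionError(
            "LOESS fit never reaches slope 1; no super/typical inflection found"
        )
    i0 = int(crossing[0])
    cut_scaled = float(fit[i0])
    cutoff_value = cut_scaled * (v_sorted[-1] - v_sorted[0]) + v_sorted[0]

    is_super_sorted = v_sorted >= cutoff_value
    cutoff_rank = int(np.sum(~is_super_sorted))  # rank of the last typical
    ranked: list[EnhancerRegion] = []
    for rank0, idx in enumerate(order):
        ranked.append(
            replace(
                regs[idx],
                rank=rank0 + 1,
                enh_class="super" if is_super_sorted[rank0] else "typical",
            )
        )
    curve = np.column_stack([x, y, fit])
    return SECallResult(
        regions=ranked,
        fitted_curve=curve,
        cutoff_rank=cutoff_rank,
        cutoff_value=float(cutoff_value),
        loess_span=loess_span,
        ranking=ranking,
    )


def constituent_enhancers(
    se: EnhancerRegion,
    dnase_peaks: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Nominate nucleosome-free constituents of a super-enhancer.

    DNase peaks overlapping the SE interval are returned sorted by
    descending score (ties: wider first, then leftmost) and labelled
    e1, e2, ...; e1 is the major peak. Non-super regions are rejected.
    """
    if se.enh_class != "super":
        raise ValueError("constituent nomination applies to super-enhancers only")
    hits = [p for p in dnase_peaks if p.overlaps(se.interval)]
    hits.sort(key=lambda p: (-(p.score if p.score is not None else 0.0), -p.length, p.start))
    return [p.with_name(f"e{i + 1}") for i, p in enumerate(hits)]
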