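"""Binned signal tracks and their binarization.

A :class:`BinnedTrack` holds fixed-width per-chromosome bin values (raw
counts or CPM-scaled). Binarization thresholds raw counts against a global
Poisson background: a bin is called enriched when its count is improbably
large under ``Poisson(lambda_bg)`` with ``lambda_bg`` the genome-wide mean
count per bin. This is the conventional preprocessing in front of a
Bernoulli-emission chromatin HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class BinnedTrack:
    chrom: str
    bin_size: int
    values: np.ndarray
    total_mapped: int | None = None
    cpm_scaled: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)


@dataclass
class BinarizedTrack:
    chrom: str
    bin_size: int
    calls: np.ndarray
    lambda_bg: float
    p_threshold: float

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be 0/1")
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be positive")


def cpm_normalize(track: BinnedTrack, total_mapped: int) -> BinnedTrack:
    """Scale bin values to counts per million mapped reads.

    Each value is multiplied by ``1e6 / total_mapped``; the returned track
    records the library size and that scaling was applied.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be a positive count")
    return BinnedTrack(
        chrom=track.chrom,
        bin_size=track.bin_size,
        values=track.values * (1e6 / total_mapped),
        total_mapped=total_mapped,
        cpm_scaled=True,
    )


def binarize_track(track: BinnedTrack, p_threshold: float = 1e-4) -> BinarizedTrack:
    """Call bins enriched by a Poisson upper-tail test against the track mean.

    ``lambda_bg`` is the global mean count per bin. A bin with count ``c``
    is called 1 iff ``P(X >= c | X ~ Poisson(lambda_bg)) <= p_threshold``.
    Binarization operates on raw counts and therefore precedes any CPM
    display scaling.
    """
    if track.n_bins == 0:
        raise ValueError("cannot binarize an empty track")
    if track.cpm_scaled:
        raise ValueError("binarization requires raw counts, not CPM-scaled values")
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    counts = track.values
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("binarization expects integer counts per bin")
    lam = float(counts.mean())
    if lam <= 0:
        raise ValueError("track has zero mean count; background is undefined")
    # P(X >= c) = sf(c - 1); vectorized over bins.
    upper_tail = stats.poisson.sf(np.round(counts) - 1, lam)
    calls = (upper_tail <= p_threshold).astype(np.int8)
    return BinarizedTrack(
        chrom=track.chrom,
        bin_size=track.bin_size,
        calls=calls,
        lambda_bg=lam,
        p_threshold=p_threshold,
    )
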