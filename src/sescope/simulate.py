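"""Synthetic data with planted ground truth.

Every pipeline input can be generated here with a known answer: a genome
layout with planted typical and super enhancers (a subset of supers being
TNBC-specific, each with one target gene), Poisson ChIP count tracks per
cell-line label, log-normal (normal on the log2 scale) expression with the
target genes shifted up in the TNBC group, exponential survival with a
marker-threshold hazard effect, and single-hit limiting-dilution outcome
tables.

Determinism: every generator draws from an independent substream derived
from the master seed (seeded as ``[seed, stream_id, index]``), so adding
one generator call never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, NON_TNBC, TNBC
from .intervals import GenomicInterval, TSS
from .lda import LDAExperiment
from .survival import SurvivalRecord
from .tracks import BinnedTrack

# substream identifiers
_TRUTH, _TRACK, _EXPR, _SURV, _LDA = 0, 1, 2, 3, 4


class SizingError(ValueError):
    """The chromosome cannot host the requested enhancer layout."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults defining it.

    ChIP model: mean Poisson counts per 200-bp bin of 1 (background) vs 10
    (enriched), i.e. a 10x enrichment typical of a strong H3K27ac mark.
    Three tracks per subtype. Expression: 500 genes, 20 samples per group,
    planted targets shifted by 2 log2 units. Survival: marker normally
    distributed around 5.39 with a hazard stepping up by exp(0.7) above a
    cutpoint of 5.35, 30% independent censoring. Limiting dilution: the
    three-dose design {300, 1200, 4800} with 6 injections per dose and a
    true frequency of 1/2000 (control) vs 1/20000 (knockout).
    """

    # genome / enhancer layout
    chrom: str = "chr1"
    chrom_length: int = 5_000_000
    bin_size: int = 200
    n_super: int = 5
    n_typical: int = 95
    n_subtype_specific: int = 3
    n_promoter_decoys: int = 5        # genes planted inside typical enhancers
    super_width: tuple[int, int] = (40_000, 80_000)
    typical_width: tuple[int, int] = (1_000, 8_000)
    # ChIP counts
    lambda_bg: float = 1.0
    lambda_fg: float = 10.0
    n_tnbc_tracks: int = 3
    n_nontnbc_tracks: int = 3
    # expression
    n_genes: int = 500
    n_tnbc_samples: int = 20
    n_nontnbc_samples: int = 20
    effect_size: float = 2.0          # log2 shift of target genes in TNBC
    expr_noise_sd: float = 0.5        # within-group sd on the log2 scale
    # survival
    n_patients: int = 300
    baseline_hazard: float = 0.01     # events per month below the cutpoint
    log_hazard_ratio: float = 0.7
    censor_rate: float = 0.3
    marker_mean: float = 5.39
    marker_sd: float = 1.0
    marker_cutpoint: float = 5.35
    # limiting dilution
    lda_doses: tuple[int, ...] = (300, 1200, 4800)
    lda_replicates: int = 6
    lda_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1 / 2000, "knockout": 1 / 20000}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_fg > self.lambda_bg > 0):
            raise ValueError("need lambda_fg > lambda_bg > 0")
        for f in self.lda_frequencies.values():
            if not (0 < f < 1):
                raise ValueError("limiting-dilution frequencies must lie in (0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("expression effect size must be non-negative")
        if self.n_subtype_specific > self.n_super:
            raise ValueError("cannot have more subtype-specific supers than supers")
        if min(self.super_width) <= max(self.typical_width):
            raise ValueError("super widths must strictly exceed typical widths")

    @property
    def tnbc_track_labels(self) -> list[str]:
        return [f"TNBC_{i + 1}" for i in range(self.n_tnbc_tracks)]

    @property
    def nontnbc_track_labels(self) -> list[str]:
        return [f"nonTNBC_{i + 1}" for i in range(self.n_nontnbc_tracks)]

    @property
    def track_labels(self) -> list[str]:
        return self.tnbc_track_labels + self.nontnbc_track_labels

    def track_subtype(self, label: str) -> str:
        if label in self.tnbc_track_labels:
            return TNBC
        if label in self.nontnbc_track_labels:
            return NON_TNBC
        raise ValueError(f"unknown track label {label!r}")


@dataclass
class PlantedEnhancer:
    interval: GenomicInterval
    enh_class: str                 # "typical" | "super"
    subtype_specific: bool = False


@dataclass
class GenomeTruth:
    chrom_lengths: dict[str, int]
    tss: list[TSS]
    planted_enhancers: list[PlantedEnhancer]
    dnase_peaks: list[GenomicInterval]
    target_genes: list[str]        # gene_id per subtype-specific super, in order
    seed: int

    def validate(self) -> None:
        for e in self.planted_enhancers:
            L = self.chrom_lengths[e.interval.chrom]
            if e.interval.end > L:
                raise SizingError(f"enhancer {e.interval} exceeds chromosome length {L}")
        widths_t = [e.interval.length for e in self.planted_enhancers if e.enh_class == "typical"]
        widths_s = [e.interval.length for e in self.planted_enhancers if e.enh_class == "super"]
        if widths_t and widths_s and min(widths_s) <= max(widths_t):
            raise ValueError("planted super widths must strictly exceed typical widths")

    @property
    def supers(self) -> list[PlantedEnhancer]:
        return [e for e in self.planted_enhancers if e.enh_class == "super"]

    @property
    def specific_supers(self) -> list[PlantedEnhancer]:
        return [e for e in self.supers if e.subtype_specific]


def _rng(config_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream, index])


def make_truth(config: SimulationConfig) -> GenomeTruth:
    """Lay out the planted genome.

    Supers (with their DNase constituents and, for subtype-specific ones,
    a target gene 20-60 kb strand-aware downstream) come first along the
    chromosome, then the typicals; decoy genes are placed beyond the
    enhancer region. TSSs are kept more than 2.5 kb away from every planted
    enhancer so the promoter filter does not erase the ground truth.
    """
    rng = _rng(config.seed, _TRUTH)
    chrom = config.chrom
    cursor = 50_000
    enhancers: list[PlantedEnhancer] = []
    dnase: list[GenomicInterval] = []
    tss: list[TSS] = []
    target_genes: list[str] = []

    for i in range(config.n_super):
        specific = i < config.n_subtype_specific
        width = int(rng.integers(*config.super_width))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_gap = int(rng.integers(20_000, 60_000))
        if specific and strand == "-":
            # '-' strand gene: upstream is the higher-coordinate side, so
            # the TSS sits to the left of its SE
            gene_pos = cursor + 10_000
            cursor = gene_pos + 4_000 + gene_gap
        start = cursor
        end = start + width
        enhancers.append(PlantedEnhancer(GenomicInterval(chrom, start, end), "super", specific))
        # two nucleosome-free constituents: e1 major (higher score, wider)
        e1_w = int(rng.integers(800, 1500))
        e2_w = int(rng.integers(300, 700))
        e1_s = start + int(rng.integers(0, max(1, width - e1_w - e2_w - 2000)))
        e2_s = e1_s + e1_w + 1000
        dnase.append(GenomicInterval(chrom, e1_s, e1_s + e1_w, score=float(rng.uniform(80, 120))))
        dnase.append(GenomicInterval(chrom, e2_s, e2_s + e2_w, score=float(rng.uniform(20, 60))))
        cursor = end
        if specific:
            gid = f"TARGET_{len(target_genes) + 1}"
            if strand == "-":
                tss.append(TSS(gid, chrom, gene_pos, "-"))
            else:
                gene_pos = end + gene_gap
                tss.append(TSS(gid, chrom, gene_pos, "+"))
                cursor = gene_pos + 4_000
            target_genes.append(gid)
        if specific:
            # keep subtype-specific supers > 500 kb apart so the upstream
            # pairing window of each target gene contains exactly one of them
            cursor += 520_000
        else:
            cursor += int(rng.integers(30_000, 50_000))

    promoter_decoys = min(config.n_promoter_decoys, config.n_typical)
    for j in range(config.n_typical):
        width = int(rng.integers(*config.typical_width))
        start = cursor
        enhancers.append(
            PlantedEnhancer(GenomicInterval(chrom, start, start + width), "typical", False)
        )
        if j < promoter_decoys:
            # a gene whose TSS sits inside this typical enhancer, so the
            # promoter filter has real work to do downstream
            tss.append(TSS(f"PGENE_{j + 1}", chrom, start + width // 2, "+"))
        cursor = start + width + int(rng.integers(4_000, 12_000))

    # decoy genes downstream of the enhancer region
    gene_region_start = cursor + 10_000
    n_decoys = config.n_genes - len(target_genes) - promoter_decoys
    if n_decoys < 0:
        raise ValueError("n_genes smaller than the number of target genes")
    span = config.chrom_length - gene_region_start - 10_000
    if span <= 0 or n_decoys > span // 500:
        raise SizingError(
            f"chromosome of {config.chrom_length} bp too short for the requested layout"
        )
    positions = np.sort(rng.choice(span // 500, size=n_decoys, replace=False)) * 500
    for k, off in enumerate(positions):
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TSS(f"GENE_{k + 1}", chrom, int(gene_region_start + off), strand))

    truth = GenomeTruth(
        chrom_lengths={chrom: config.chrom_length},
        tss=tss,
        planted_enhancers=enhancers,
        dnase_peaks=dnase,
        target_genes=target_genes,
        seed=config.seed,
    )
    truth.validate()
    # each target gene must sit <= 500 kb strand-aware downstream of its SE
    from .pairing import upstream_gap

    tss_by_id = {t.gene_id: t for t in truth.tss}
    for se, gid in zip(truth.specific_supers, target_genes):
        gap = upstream_gap(se.interval, tss_by_id[gid])
        if gap is None or gap > 500_000:
            raise SizingError(f"target gene {gid} is not within 500 kb downstream of its SE")
    return truth


def enhancer_bins(truth: GenomeTruth, config: SimulationConfig, subtype: str) -> np.ndarray:
    """Boolean mask over bins covered by enhancers active in ``subtype`` tracks."""
    n_bins = -(-config.chrom_length // config.bin_size)
    mask = np.zeros(n_bins, dtype=bool)
    for e in truth.planted_enhancers:
        if e.subtype_specific and subtype != TNBC:
            continue
        b0 = e.interval.start // config.bin_size
        b1 = -(-e.interval.end // config.bin_size)
        mask[b0:b1] = True
    return mask


def simulate_chip_track(
    truth: GenomeTruth, config: SimulationConfig, track_label: str
) -> BinnedTrack:
    """Poisson counts per bin: lambda_fg over active enhancers, lambda_bg elsewhere.

    TNBC-specific enhancers are enriched only in TNBC-labelled tracks.
    """
    subtype = config.track_subtype(track_label)
    idx = config.track_labels.index(track_label)
    rng = _rng(config.seed, _TRACK, idx)
    mask = enhancer_bins(truth, config, subtype)
    lam = np.where(mask, config.lambda_fg, config.lambda_bg)
    counts = rng.poisson(lam).astype(float)
    return BinnedTrack(chrom=config.chrom, bin_size=config.bin_size, values=counts)


def simulate_expression(truth: GenomeTruth, config: SimulationConfig) -> ExpressionMatrix:
    """log2-scale expression; target genes shifted by the effect size in TNBC."""
    if config.n_tnbc_samples < 2 or config.n_nontnbc_samples < 2:
        raise ValueError("need at least 2 samples per group")
    rng = _rng(config.seed, _EXPR)
    gene_ids = [t.gene_id for t in truth.tss]
    n_genes = len(gene_ids)
    samples = [f"TNBC_s{i + 1}" for i in range(config.n_tnbc_samples)] + [
        f"nonTNBC_s{i + 1}" for i in range(config.n_nontnbc_samples)
    ]
    labels = pd.Series(
        [TNBC] * config.n_tnbc_samples + [NON_TNBC] * config.n_nontnbc_samples,
        index=samples,
    )
    base = rng.uniform(3, 12, size=n_genes)
    values = base[:, None] + rng.normal(0, config.expr_noise_sd, size=(n_genes, len(samples)))
    target_rows = [i for i, g in enumerate(gene_ids) if g in set(truth.target_genes)]
    values[np.ix_(target_rows, np.arange(config.n_tnbc_samples))] += config.effect_size
    frame = pd.DataFrame(values, index=gene_ids, columns=samples)
    return ExpressionMatrix(values=frame, group_labels=labels)


def simulate_survival(config: SimulationConfig) -> list[SurvivalRecord]:
    """Exponential survival with a marker-threshold hazard step.

    Hazard is ``baseline_hazard`` below the cutpoint and
    ``baseline_hazard * exp(log_hazard_ratio)`` above it. Censoring is
    random at the configured rate: a censored subject reports a uniform
    fraction of its latent event time.
    """
    if config.n_patients < 10:
        raise ValueError("need at least 10 patients")
    rng = _rng(config.seed, _SURV)
    n = config.n_patients
    marker = rng.normal(config.marker_mean, config.marker_sd, size=n)
    high = marker > config.marker_cutpoint
    hazard = config.baseline_hazard * np.exp(config.log_hazard_ratio * high)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    t_obs = np.where(censored, t_event * rng.random(n), t_event)
    grade = rng.integers(1, 4, size=n)
    age = rng.normal(60, 10, size=n)
    return [
        SurvivalRecord(
            time=float(t_obs[i]),
            event=int(not censored[i]),
            marker=float(marker[i]),
            covariates={"age": float(age[i]), "grade": float(grade[i])},
        )
        for i in range(n)
    ]


def simulate_lda(config: SimulationConfig) -> list[LDAExperiment]:
    """Single-hit dilution outcomes per group: P(positive) = 1 - exp(-f * dose)."""
    out = []
    for g, (group, f) in enumerate(config.lda_frequencies.items()):
        rng = _rng(config.seed, _LDA, g)
        doses = np.asarray(config.lda_doses, float)
        n_inj = np.full(doses.size, config.lda_replicates, int)
        p_pos = 1.0 - np.exp(-f * doses)
        n_pos = rng.binomial(n_inj, p_pos)
        out.append(LDAExperiment(dose=doses, n_injected=n_inj, n_positive=n_pos, group=group))
    return out
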