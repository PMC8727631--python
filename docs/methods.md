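# Methods

This note records the models implemented in `sescope`, the defaults and
why they were chosen, the design decisions taken where the design was
genuinely open, and what the synthetic benchmark does and does not
demonstrate about real data.

## Chromatin segmentation

ChIP signal enters as fixed-width bins of read counts per chromosome
(default 200 bp, the usual resolution for histone-mark segmentation).
Display tracks may be scaled to counts per million mapped reads (CPM);
segmentation itself always operates on raw counts.

**Binarization.** The genome-wide mean count per bin estimates a Poisson
background rate λ_bg. A bin with count *c* is called enriched when
P(X ≥ c | X ~ Poisson(λ_bg)) ≤ p, default p = 1e-4. This follows the
standard convention for preparing histone-mark counts for a
Bernoulli-emission chromatin HMM. The threshold is deliberately
conservative: with a genome of ~10^4–10^7 bins, 1e-4 keeps the expected
number of false 1-calls per genome small. Over regions of genuine
enrichment only a fraction of bins individually clears the threshold;
recovering the full region is the HMM's job, not the binarizer's.

**Two-state HMM.** Observations are the 0/1 calls; each state emits 1
with its own probability; transitions are a 2×2 row-stochastic matrix.
Fitting is Baum–Welch with scaled forward–backward recursions. Because EM
is a local optimizer, the fit runs several seeded random restarts
(default 3) and keeps the best final likelihood; initializations use
sticky transitions (stay probability 0.6–0.99) since segmentation
problems live in that basin. Convergence is declared when the
log-likelihood gain per sweep drops below 1e-6 (default) and the trace is
guaranteed non-decreasing by EM; the invariant is asserted to 1e-8 to
allow floating-point jitter. The state with the larger emit-1 probability
is labelled *enriched* after fitting. An all-identical observation
sequence converges trivially and is flagged non-identifiable rather than
rejected.

**Decoding.** Regions are defined by the Viterbi path (not posterior
thresholding), which gives a deterministic segmentation with a simple
contract. Back-pointer ties resolve to the lower-indexed state. Maximal
runs of the enriched state become half-open intervals in bp. The inner
recursions are compiled with numba (a pure-NumPy fallback with identical
arithmetic runs when numba is unavailable), which keeps chromosome-scale
fitting at ~1 ms per EM sweep per 10^5 bins.

## Enhancer catalogue

**Promoter filter.** Enrichment regions overlapping ±2.5 kb of any
annotated TSS are discarded (half-open, any-overlap). The filter never
enlarges the set and is idempotent.

**Super-enhancer call.** Surviving enhancers are ranked ascending by size
(signal ranking is available; size is the default because the ranked
*size* distribution is what the slope-1 construction here is fitted to).
Both rank and value axes are min–max rescaled to [0, 1]; a degree-1 LOESS
(default span 0.3) is fitted to the rescaled curve; its derivative is
taken by central finite differences and scanned from low to high rank.
The cutoff is the **fitted value** at the first point where the
derivative reaches 1, mapped back to original units: every region whose
ranking value is at least that cutoff is a super-enhancer. Anchoring the
classification on the fitted value rather than on the rank index at the
crossing matters: LOESS smears the sharp typical/super transition over a
window of ranks, so the derivative crosses 1 somewhat before the
transition, and a rank-anchored cut systematically drags top typicals
into the super class. The value-anchored cut is also exactly scale
invariant. A catalogue whose ranking values are all equal (or whose fit
never reaches slope 1) has no inflection and raises a degenerate-
distribution error. At least 10 regions are required.

**Constituents.** DNase-hypersensitive peaks overlapping a
super-enhancer are its nucleosome-free constituent elements, labelled
e1, e2, … by descending peak score (ties: wider first, then leftmost);
e1 is the major peak.

**Motif scanning.** JASPAR-style position frequency matrices are
pseudocount-normalized (default 0.1) into PWMs. Windows are scored by the
log2 likelihood ratio against a 0-order background (uniform by default).
Significance is exact: scores are discretized to 1/1000 of the achievable
score range, the full distribution of the discretized window score under
the background is built by convolution DP, and the p-value of a hit is
the exact tail probability of its discretized score — the convention of
standard PWM scanners, which makes DP p-values exactly equal to
enumeration over all 4^w words. Both strands are scanned (the reverse
strand with the reverse-complement matrix and its own score
distribution, since the background need not be strand-symmetric); windows
containing non-ACGT characters are skipped rather than scored; hits with
p below the threshold (default 1e-4) are reported sorted by position.

## Subtype specificity and gene pairing

Per-track super-enhancer calls are merged into loci: two SEs are linked
when their reciprocal overlap is ≥ 50%, and connected components span
their members' union. A locus is subtype-specific when it is called super
in at least `k_min_subtype` tracks of the target subtype (default 2) and
at most `k_max_other` other tracks (default 0). The k-of-n rule and the
50% reciprocal threshold are declared defaults — reasonable for
replicate-supported specificity — not a canonical standard.

A specific locus is paired with a gene when (i) the gene is upregulated,
(ii) the locus lies strand-aware **upstream** of the gene's TSS — lower
coordinates for + genes, higher for − genes, with a locus containing the
TSS counting as distance 0 — and (iii) the gap from the TSS to the
nearest locus edge is at most 500 kb. The window is anchored at the locus
edge (not midpoint): with loci tens of kb wide, edge anchoring is the
conservative reading of an upstream-distance rule.

## Differential expression

Expression is analysed on the log2 scale. The per-gene statistic is a
two-sample t with empirical-Bayes variance moderation: the pooled gene
variance s² (df = n1+n2−2) is shrunk toward the grand mean variance s0²
with a prior weight d0 expressed in pseudo-observations,

    s²_mod = (d0·s0² + df·s²) / (d0 + df),   df_mod = df + d0.

Default d0 = 4: enough to stabilize small-sample variances without
importing a full hierarchical variance model; d0 = 0 recovers the
ordinary pooled t exactly, which is the tested contract. p-values are
two-sided from t(df_mod) and adjusted by Benjamini–Hochberg step-up. A
gene is *upregulated* when log2FC > 0.5 and adjusted p < 0.05. A gene
with zero variance in both groups is flagged unevaluable (p set to 1)
rather than being rescued by the prior. Per-sample upregulation can also
be summarized as the percentage of samples with expression z-score
strictly above 1.5 (per-gene z across all samples).

## Limiting-dilution analysis

The single-hit model: an injection of *d* cells is positive with
probability 1 − exp(−f·d), where f is the active-cell frequency. The MLE
of θ = log f maximizes the exact binomial log-likelihood (equivalently a
complementary log-log binomial regression with offset log d); the
implementation is Newton iteration with analytic first/second derivatives
and step-halving, started from the pooled response fraction. The 95% CI
is Wald on the log scale, exp(θ̂ ± 1.96·SE), with SE from observed
information — the convention of the standard limiting-dilution tools; a
profile-likelihood interval was considered and not implemented, recorded
here as a limitation for very small designs. Degenerate tables return
exact one-sided binomial bounds instead of failing: all-negative gives
the f at which "no tumours anywhere" has probability 0.025; all-positive
the analogous lower bound. Frequencies are displayed as "1 in N" with N
rounded for display only. Two experiments are compared by a 1-df
likelihood-ratio test of a shared frequency versus separate frequencies;
a boundary group contributes its supremum log-likelihood (zero).

Also here: the mammosphere self-renewal ratio (second- over
first-generation sphere count) and the calliper volume V = W²·L/2 (mm³).

## Survival analysis

**Kaplan–Meier** is the product-limit estimator, right-continuous, with
censoring decrementing the risk set without a step.

**Log-rank** accumulates observed-minus-expected deaths over pooled event
times with the hypergeometric variance. Two-sided inference is
chi-square (1 df); the one-sided alternative is *higher hazard in the
marker-high group* (matching the directional question "does high marker
expression shorten survival"), reported as a signed normal deviate.

**Maximally selected cutpoint.** Each subject carries a log-rank score
a_i = δ_i − Λ̂(t_i) (Nelson–Aalen cumulative hazard at the subject's
time). Splitting at marker value c gives the linear statistic
T(c) = Σ_{marker ≤ c} a_i, which is identical to the log-rank O−E of the
low-marker group. T(c) is standardized by its exact permutation moments
(mean m·ā, variance m(n−m)/(n−1)·σ²_a for a low group of size m) — the
classic maximally-selected rank-statistic construction. Candidates are
the distinct marker values whose split keeps both groups inside the
ε-quantile band (default (0.1, 0.9); the band is a declared default).
The cutpoint is the maximizing candidate. Its p-value is obtained by
permuting markers against (time, event) pairs (seeded, default 10,000
permutations) and taking the exceedance fraction of the permutation
maximum with add-one correction — a reference distribution that accounts
for the selection over cutpoints exactly, at the cost of simulation
rather than an analytic improved-Bonferroni approximation. Note the
standardization uses the permutation variance of the score sum, not the
hypergeometric log-rank variance; the two agree asymptotically, and the
permutation p is exact for the statistic actually maximized.

**Cox regression** maximizes the Breslow partial likelihood by
Newton–Raphson with step-halving (the partial likelihood is
non-decreasing across iterations); covariates are centred for numerical
stability; Wald CIs are exp(β̂ ± 1.96·SE) from the inverse information.
Breslow (not Efron) tie handling is the simplest correct choice and is a
documented limitation: with continuous simulated times ties are absent
and the two coincide (the test suite cross-checks coefficients against an
independent Efron-based implementation on tie-free data). The score
statistic at β = 0 is reported; for a binary covariate without ties it
equals the log-rank chi-square, which is asserted to 1e-8. Monotone
likelihood (perfect separation) surfaces as a non-convergence flag once
coefficients diverge; a singular information matrix is an error.

## Synthetic data generator

The generator emulates the structure of a subtype-specific
super-enhancer study with planted ground truth; its defaults define the
benchmark conditions.

| parameter | default | rationale |
| --- | --- | --- |
| chromosome | 5 Mb, 200 bp bins | hosts the full layout at chromosome-arm scale |
| background / enriched Poisson mean | 1 / 10 per bin | 10× enrichment, a strong activating mark |
| tracks | 3 TNBC + 3 non-TNBC | replicate-supported specificity calls |
| planted enhancers | 95 typical (1–8 kb), 5 super (40–80 kb) | the canonical hockey-stick geometry; supers strictly wider than typicals |
| subtype-specific supers | 3 of 5, each with one target gene 20–60 kb strand-aware downstream | specific SEs are spaced > 500 kb apart so each target's upstream window contains exactly one of them |
| promoter decoys | 5 genes planted inside typical enhancers | exercises the promoter filter in-pipeline |
| expression | 500 genes, 20 samples/group, log2 noise sd 0.5, target shift +2 log2 | sd 0.5 is typical residual spread for expressed genes on the log2 scale; +2 is a strongly SE-driven effect |
| survival | n = 300, marker ~ N(5.39, 1), hazard ×e^0.7 above 5.35, 30% censoring | mirrors a normalized-expression marker with a threshold effect and realistic censoring |
| limiting dilution | doses {300, 1200, 4800}, 6 injections each; f = 1/2000 (control) vs 1/20000 (knockout) | the three-dose, six-replicate in-vivo design |

Counts are Poisson rather than negative binomial: the binarization model
downstream is a Poisson tail test, and Poisson is the simplest generator
consistent with it. Super-enhancers are single wide enriched blocks with
internal DNase constituents; sub-bin internal gaps are not modelled (the
HMM merges at bin resolution regardless). Censoring is random at the
configured rate (a censored subject reports a uniform fraction of its
latent event time), which pins the event proportion exactly at
1 − censor_rate. Every generator draws from an independent substream of
the master seed (`default_rng([seed, stream, index])`), so adding one
generator call never perturbs another's draws, and everything is a pure
function of (config, seed).

**What passing the benchmark does not show.** Real ChIP data are
overdispersed, GC- and mappability-biased, and have fragment-level
autocorrelation; real expression has correlated genes and batch effects;
real survival has informative censoring and time-varying effects; real
limiting-dilution assays can violate the single-hit assumption. Recovery
of the planted truth here validates the *algorithms* under their own
model assumptions, not robustness to these violations.

## Problem sizes and numerical choices

The test and acceptance runs use one 5 Mb chromosome (25,000 bins) per
track, six tracks, 500 genes × 40 samples, n = 300–2,000 survival
records, and 500–1,000 replicate simulations for the calibration checks
(limiting-dilution CI coverage and LRT type-I error; maximally-selected
cutpoint type-I error with 199 permutations per dataset, giving p-value
granularity 1/200 at level 0.05). These sizes were chosen so each
calibration has enough replicates for a ±2% band while the whole suite
stays interactive.

Fixed numerical conventions: genomic intervals are 0-based half-open
with any-overlap semantics everywhere; Viterbi ties go to the lower
state index; constituent ties go to the higher score, then width, then
leftmost; motif scores are discretized to 1/1000 of the score range;
Baum–Welch tolerance 1e-6, Newton tolerances 1e-9–1e-10; BH adjustment
caps at 1; the maximally-selected p uses the add-one permutation
estimator, so its smallest attainable value is 1/(n_perm + 1).

## Known limitations

* Single-mark, two-state segmentation only; no multi-mark multivariate
  chromatin states.
* Size- or signal-ranked SE calling without a peak-stitching step; the
  catalogue must already be region-level.
* The subtype-specificity k-of-n rule and the 50% reciprocal-overlap
  merge are declared defaults, not inferred from data.
* Wald (not profile) intervals for limiting-dilution frequencies;
  Breslow (not Efron) ties in Cox.
* The SE-call inflection needs a genuinely two-regime size distribution;
  near-degenerate catalogues (e.g. only marginally wide supers) can
  misplace the cutoff by a region or two.
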