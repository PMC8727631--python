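"""Two-state Bernoulli-emission hidden Markov model for chromatin calls.

The model segments a binarized signal track into "background" and
"enriched" runs. Fitting is Baum-Welch (EM) on the 0/1 call sequence with
scaled forward-backward recursions; decoding is Viterbi. The state with the
higher emit-1 probability after fitting is labelled enriched.

Conventions:
  * multiple seeded random restarts, best final likelihood wins;
  * Viterbi back-pointer ties resolve to the lower-indexed state;
  * an all-identical observation sequence converges trivially and is
    flagged non-identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hmm_kernels import forward_backward, viterbi_kernel
from .intervals import GenomicInterval
from .tracks import BinarizedTrack

_EPS = 1e-300


@dataclass
class HMMModel:
    initial: np.ndarray            # (2,) state probabilities at position 0
    transition: np.ndarray         # (2, 2) row-stochastic
    emission: np.ndarray           # (2,) per-state P(emit 1)
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = False
    non_identifiable: bool = False
    n_states: int = 2

    @property
    def enriched_state(self) -> int:
        return int(np.argmax(self.emission))

    def validate(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        for arr in (self.initial, self.transition, self.emission):
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise ValueError("probabilities must lie in [0, 1]")


def _as_obs(binarized: BinarizedTrack | np.ndarray) -> np.ndarray:
    obs = binarized.calls if isinstance(binarized, BinarizedTrack) else binarized
    return np.ascontiguousarray(np.asarray(obs, dtype=np.int8))


def forward_log_likelihood(model: HMMModel, obs: np.ndarray) -> float:
    """log P(obs | model) via the scaled forward recursion."""
    _, _, ll = forward_backward(
        np.asarray(model.initial, float),
        np.asarray(model.transition, float),
        np.asarray(model.emission, float),
        _as_obs(obs),
    )
    return float(ll)


def posterior_probabilities(model: HMMModel, obs: np.ndarray) -> np.ndarray:
    """(T, 2) smoothed state posteriors; rows sum to 1."""
    gamma, _, _ = forward_backward(
        np.asarray(model.initial, float),
        np.asarray(model.transition, float),
        np.asarray(model.emission, float),
        _as_obs(obs),
    )
    return gamma


def _random_init(rng: np.random.Generator):
    pi = rng.dirichlet([1.0, 1.0])
    # Sticky-ish transitions, spread-out emissions: a sensible basin for
    # segmentation problems without prejudging which state is enriched.
    stay = rng.uniform(0.6, 0.99, size=2)
    A = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
    e = rng.uniform(0.05, 0.95, size=2)
    return pi, A, e


def fit_hmm(
    binarized: BinarizedTrack | np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
) -> HMMModel:
    """Baum-Welch fit of the two-state Bernoulli HMM to a 0/1 sequence.

    Runs ``n_restarts`` seeded random initializations and keeps the fit with
    the best final log-likelihood. Iteration stops when the per-iteration
    log-likelihood gain falls below ``tol`` or after ``max_iter`` sweeps.
    The log-likelihood trace of the winning restart is stored on the model;
    EM guarantees it is non-decreasing up to floating-point jitter.
    """
    obs = _as_obs(binarized)
    if obs.size < 2:
        raise ValueError("HMM fitting requires a sequence of length >= 2")
    uniform_obs = bool((obs == obs[0]).all())

    best: HMMModel | None = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        pi, A, e = _random_init(rng)
        trace: list[float] = []
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            gamma, xi_sum, ll = forward_backward(pi, A, e, obs)
            trace.append(float(ll))
            if np.isfinite(prev_ll) and ll - prev_ll < tol:
                converged = True
                break
            prev_ll = ll
            # M step
            pi = gamma[0] / gamma[0].sum()
            denom = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(denom > 0, xi_sum / np.maximum(denom, _EPS), A)
            A = A / A.sum(axis=1, keepdims=True)
            e = (gamma * (obs[:, None] == 1)).sum(axis=0) / gamma.sum(axis=0)
            e = np.clip(e, 1e-12, 1 - 1e-12)
        model = HMMModel(
            initial=np.asarray(pi, float),
            transition=np.asarray(A, float),
            emission=np.asarray(e, float),
            log_likelihood_trace=trace,
            converged=converged,
            non_identifiable=uniform_obs,
        )
        if best is None or trace[-1] > best.log_likelihood_trace[-1]:
            best = model
    assert best is not None
    best.validate(atol=1e-8)
    return best


def viterbi_path(model: HMMModel, obs: np.ndarray) -> np.ndarray:
    """Most probable state path; back-pointer ties go to state 0."""
    obs = _as_obs(obs)
    e = np.asarray(model.emission, float)
    b = np.where(obs[:, None] == 1, e[None, :], 1.0 - e[None, :])
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(model.initial, float) + _EPS)
        log_A = np.log(np.asarray(model.transition, float) + _EPS)
        log_b = np.log(b + _EPS)
    return viterbi_kernel(log_pi, log_A, np.ascontiguousarray(log_b))


def decode_regions(model: HMMModel, binarized: BinarizedTrack) -> list[GenomicInterval]:
    """Viterbi-decode and convert maximal enriched-state runs to intervals.

    A run of enriched bins ``[i, j]`` (inclusive) becomes the interval
    ``[i * bin_size, (j + 1) * bin_size)`` on the track's chromosome.
    """
    path = viterbi_path(model, binarized.calls)
    enriched = np.asarray(path) == model.enriched_state
    regions: list[GenomicInterval] = []
    bs = binarized.bin_size
    # run-length encode the boolean mask
    padded = np.diff(np.concatenate([[0], enriched.astype(np.int8), [0]]))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    for s, t in zip(starts, ends):
        regions.append(GenomicInterval(binarized.chrom, int(s) * bs, int(t) * bs))
    return regions
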