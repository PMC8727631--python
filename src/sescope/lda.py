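"""Limiting-dilution analysis under the single-hit Poisson model.

An injection of ``dose`` cells forms a tumour with probability
``1 - exp(-f * dose)`` where ``f`` is the tumour-initiating (active) cell
frequency. The MLE of ``log f`` is found by Newton iteration on the exact
binomial log-likelihood (equivalently a complementary log-log binomial
regression with offset ``log dose`` and intercept ``log f``); the 95% CI is
Wald on the log scale, ``exp(log_f +/- 1.96 SE)``, from observed
information. Degenerate tables (all positive or all negative) return
one-sided exact binomial bounds instead of a point estimate. Two
experiments are compared by a 1-df likelihood-ratio test of a shared
frequency against separate frequencies.

Also here: the mammosphere self-renewal ratio and the calliper
tumour-volume formula V = W^2 * L / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass
class LDAExperiment:
    """Dose/response table: cells per injection, injections, tumours formed."""

    dose: np.ndarray
    n_injected: np.ndarray
    n_positive: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, float)
        self.n_injected = np.asarray(self.n_injected, int)
        self.n_positive = np.asarray(self.n_positive, int)
        if not (self.dose.shape == self.n_injected.shape == self.n_positive.shape):
            raise ValueError("dose, n_injected, n_positive must have equal length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if np.any(self.n_injected <= 0):
            raise ValueError("n_injected must be positive")
        if np.any(self.n_positive < 0) or np.any(self.n_positive > self.n_injected):
            raise ValueError("need 0 <= n_positive <= n_injected")

    @property
    def all_negative(self) -> bool:
        return int(self.n_positive.sum()) == 0

    @property
    def all_positive(self) -> bool:
        return int(self.n_positive.sum()) == int(self.n_injected.sum())

    @staticmethod
    def concat(a: "LDAExperiment", b: "LDAExperiment") -> "LDAExperiment":
        return LDAExperiment(
            dose=np.concatenate([a.dose, b.dose]),
            n_injected=np.concatenate([a.n_injected, b.n_injected]),
            n_positive=np.concatenate([a.n_positive, b.n_positive]),
            group=f"{a.group}+{b.group}",
        )


@dataclass
class LDAFit:
    log_f: float | None
    frequency: float | None               # active cells per cell; reported as 1/N
    ci95: tuple[float, float]             # on the frequency scale
    se_log_f: float | None = None
    log_likelihood: float = np.nan
    converged: bool = False
    boundary: bool = False
    group: str = ""

    @property
    def one_in(self) -> float | None:
        """Frequency expressed as '1 in N cells' (N, full precision)."""
        return None if self.frequency is None else 1.0 / self.frequency

    def display(self) -> str:
        if self.frequency is None:
            lo, hi = self.ci95
            return f"boundary (CI {1/hi:.0f}..{'inf' if lo == 0 else f'{1/lo:.0f}'})"
        lo, hi = self.ci95
        return f"1/{round(self.one_in)} (95% CI 1/{round(1/lo)} - 1/{round(1/hi)})"


def log_likelihood(exp: LDAExperiment, log_f: float) -> float:
    """Exact binomial log-likelihood at log-frequency ``log_f`` (constants dropped)."""
    mu = np.exp(log_f) * exp.dose
    # log(1 - exp(-mu)) computed stably
    log_p = np.log(-np.expm1(-mu))
    return float(np.sum(exp.n_positive * log_p - (exp.n_injected - exp.n_positive) * mu))


def _score_info(exp: LDAExperiment, theta: float) -> tuple[float, float]:
    """First and second derivative of the log-likelihood in theta = log f."""
    mu = np.exp(theta) * exp.dose
    q = np.exp(-mu)
    p = -np.expm1(-mu)
    r, n = exp.n_positive, exp.n_injected
    score = np.sum(r * mu * q / p - (n - r) * mu)
    curv = np.sum(
        r * (mu * q / p - mu**2 * q / p - mu**2 * q**2 / p**2) - (n - r) * mu
    )
    return float(score), float(curv)


def fit_lda(exp: LDAExperiment, max_iter: int = 50, tol: float = 1e-10) -> LDAFit:
    """MLE of the single-hit frequency with Wald CI on the log scale.

    Boundary tables get one-sided exact binomial bounds: all-negative
    yields an upper bound (the f at which seeing no tumour at all has
    probability 0.025), all-positive the analogous lower bound.
    """
    if exp.all_negative:
        total = float(np.sum(exp.n_injected * exp.dose))
        upper = -np.log(0.025) / total
        return LDAFit(
            log_f=None, frequency=None, ci95=(0.0, upper),
            boundary=True, converged=True, group=exp.group,
        )
    if exp.all_positive:
        def prob_all_pos(f: float) -> float:
            return float(np.sum(exp.n_injected * np.log(-np.expm1(-f * exp.dose))))
        target = np.log(0.025)
        lo = optimize.brentq(lambda f: prob_all_pos(f) - target, 1e-14, 1.0, xtol=1e-16)
        return LDAFit(
            log_f=None, frequency=None, ci95=(lo, 1.0),
            boundary=True, converged=True, group=exp.group,
        )

    # initial value from the pooled response fraction at the mean dose
    p_tot = exp.n_positive.sum() / exp.n_injected.sum()
    p_tot = min(max(p_tot, 1e-6), 1 - 1e-6)
    theta = float(np.log(-np.log1p(-p_tot) / exp.dose.mean()))
    ll = log_likelihood(exp, theta)
    converged = False
    for _ in range(max_iter):
        score, curv = _score_info(exp, theta)
        if curv >= 0:  # fall back to a gradient step if curvature degenerates
            step = np.sign(score) * 0.5
        else:
            step = -score / curv
        # step-halving to guarantee likelihood ascent
        new_theta, new_ll = theta, ll
        s = step
        for _ in range(40):
            cand = theta + s
            cand_ll = log_likelihood(exp, cand)
            if cand_ll >= ll - 1e-12:
                new_theta, new_ll = cand, cand_ll
                break
            s *= 0.5
        if abs(new_theta - theta) < tol:
            theta, ll = new_theta, new_ll
            converged = True
            break
        theta, ll = new_theta, new_ll
    _, curv = _score_info(exp, theta)
    se = float(np.sqrt(-1.0 / curv)) if curv < 0 else np.inf
    f = float(np.exp(theta))
    ci = (float(np.exp(theta - 1.96 * se)), float(np.exp(theta + 1.96 * se)))
    return LDAFit(
        log_f=theta, frequency=f, ci95=ci, se_log_f=se,
        log_likelihood=ll, converged=converged, group=exp.group,
    )


def compare_lda(a: LDAExperiment, b: LDAExperiment) -> tuple[float, float]:
    """1-df likelihood-ratio test of equal frequencies in two experiments.

    Returns (chi2, p). Boundary groups contribute their boundary-profile
    likelihood only when at least one group is fittable; two degenerate
    groups make the test unavailable.
    """
    if (a.all_negative or a.all_positive) and (b.all_negative or b.all_positive):
        raise ValueError("both groups are boundary-degenerate; LRT unavailable")

    def max_ll(exp: LDAExperiment) -> float:
        if exp.all_negative:
            return 0.0  # likelihood maximized as f -> 0; sup log-lik = 0
        if exp.all_positive:
            return 0.0  # f -> 1 upper boundary; binomial term -> 0
        return fit_lda(exp).log_likelihood

    joint = fit_lda(LDAExperiment.concat(a, b)).log_likelihood
    chi2 = 2.0 * (max_ll(a) + max_ll(b) - joint)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def self_renewal_ratio(n_secondary: float, n_primary: float) -> float:
    """Second- over first-generation sphere count; the self-renewal readout."""
    if n_primary <= 0:
        raise ValueError("primary sphere count must be positive")
    if n_secondary < 0:
        raise ValueError("sphere counts must be non-negative")
    return n_secondary / n_primary


def tumour_volume(width: float, length: float) -> float:
    """Calliper tumour volume V = W^2 * L / 2 (mm^3 for mm inputs)."""
    if width < 0 or length < 0:
        raise ValueError("measurements must be non-negative")
    return width**2 * length / 2.0


@dataclass
class TumourMeasurement:
    width: float
    length: float
    volume: float = field(init=False)

    def __post_init__(self) -> None:
        if self.width > self.length:
            raise ValueError("by convention W <= L")
        self.volume = tumour_volume(self.width, self.length)
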