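"""Marker-based survival analysis.

Kaplan-Meier product-limit curves, the (one- or two-sided) log-rank test,
maximally selected log-rank cutpoints with a permutation reference
distribution, and a Cox proportional-hazards fit (Newton-Raphson on the
Breslow partial likelihood with step-halving, Wald confidence intervals).

The maximally selected statistic uses the classic rank-score construction:
each subject carries a log-rank (martingale-residual) score
``a_i = delta_i - Lambda(t_i)`` with ``Lambda`` the Nelson-Aalen cumulative
hazard; splitting at marker value c gives the linear statistic
``T(c) = sum_{marker_i <= c} a_i`` whose exact permutation mean and
variance standardize it. The sum ``T(c)`` is identical to the log-rank
observed-minus-expected for the low-marker group, and permuting markers
against (time, event) pairs yields the selection-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class SurvivalRecord:
    time: float
    event: int
    marker: float = np.nan
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


def records_to_arrays(
    records: Sequence[SurvivalRecord],
    covariate_names: Sequence[str] = (),
):
    time = np.array([r.time for r in records], float)
    event = np.array([r.event for r in records], int)
    marker = np.array([r.marker for r in records], float)
    X = np.array([[r.covariates[c] for c in covariate_names] for r in records], float)
    if not covariate_names:
        X = X.reshape(len(records), 0)
    return time, event, marker, X


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Right-continuous product-limit step function."""

    event_times: np.ndarray     # distinct times with >= 1 event, ascending
    survival: np.ndarray        # S just after each event time

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) else out


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMEstimate:
    """Product-limit estimator; censored subjects leave the risk set silently."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("at least one record required")
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    n = time.size
    s = 1.0
    ev_times, surv = [], []
    for u, i0 in zip(uniq, first):
        at_risk = n - i0
        d = int(e_sorted[(t_sorted == u)].sum())
        if d > 0:
            s *= 1.0 - d / at_risk
            ev_times.append(u)
            surv.append(s)
    return KMEstimate(event_times=np.asarray(ev_times), survival=np.asarray(surv))


# ---------------------------------------------------------------------------
# Log-rank


def _logrank_oev(time_a, event_a, time_b, event_b):
    """Observed-minus-expected and hypergeometric variance for group b."""
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b]).astype(int)
    grp = np.concatenate([np.zeros(len(time_a), int), np.ones(len(time_b), int)])
    order = np.argsort(time, kind="stable")
    time, event, grp = time[order], event[order], grp[order]
    n = time.size
    oe = 0.0
    var = 0.0
    uniq, first = np.unique(time, return_index=True)
    for u, i0 in zip(uniq, first):
        mask = time == u
        d = int(event[mask].sum())
        if d == 0:
            continue
        n_at = n - i0
        nb = int(grp[i0:].sum())
        db = int(event[mask & (grp == 1)].sum())
        oe += db - d * nb / n_at
        if n_at > 1:
            var += d * (nb / n_at) * (1 - nb / n_at) * (n_at - d) / (n_at - 1)
    return oe, var


def logrank_test(
    group_a: tuple[np.ndarray, np.ndarray],
    group_b: tuple[np.ndarray, np.ndarray],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Log-rank test between two samples of (time, event) arrays.

    ``alternative='two_sided'`` returns the chi-square statistic and its
    1-df p. ``alternative='high_risk_b'`` tests the one-sided alternative
    that group b has the higher hazard (more deaths than expected in b):
    returns the signed normal deviate Z and P(N(0,1) >= Z).
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in the pooled sample; log-rank unavailable")
    oe, var = _logrank_oev(ta, ea, tb, eb)
    if var <= 0:
        raise ValueError("log-rank variance is zero")
    if alternative == "two_sided":
        chi2 = oe * oe / var
        return float(chi2), float(stats.chi2.sf(chi2, df=1))
    if alternative == "high_risk_b":
        z = oe / np.sqrt(var)
        return float(z), float(stats.norm.sf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# Maximally selected log-rank cutpoint


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores a_i = event_i - NelsonAalen(time_i)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    n = time.size
    t_s, e_s = time[order], event[order]
    uniq, first = np.unique(t_s, return_index=True)
    # cumulative hazard increment d_j / n_j at each distinct time
    cumhaz_at = {}
    ch = 0.0
    for u, i0 in zip(uniq, first):
        d = int(e_s[t_s == u].sum())
        ch += d / (n - i0)
        cumhaz_at[u] = ch
    return event - np.array([cumhaz_at[t] for t in time])


@dataclass
class MaxstatResult:
    cutpoint: float
    max_statistic: float
    p_value: float
    candidates: list[tuple[float, float]]    # (cutpoint value, standardized stat)
    epsilon: tuple[float, float]
    n_perm: int
    seed: int


def _standardized_cut_stats(a_marker_sorted: np.ndarray, ms: np.ndarray) -> np.ndarray:
    """|T(m) - m*abar| / sd for low-group sizes ``ms`` (vectorized).

    ``a_marker_sorted`` is the score vector ordered by ascending marker;
    sampling m scores without replacement gives mean m*abar and variance
    m(n-m)/(n-1) * sigma^2 with sigma^2 the population variance of a.
    """
    n = a_marker_sorted.size
    abar = a_marker_sorted.mean()
    sigma2 = np.mean((a_marker_sorted - abar) ** 2)
    csum = np.cumsum(a_marker_sorted)
    T = csum[ms - 1]
    var = ms * (n - ms) / (n - 1) * sigma2
    return np.abs(T - ms * abar) / np.sqrt(var)


def maxstat_cutpoint(
    time: np.ndarray,
    event: np.ndarray,
    marker: np.ndarray,
    epsilon: tuple[float, float] = (0.1, 0.9),
    n_perm: int = 10_000,
    seed: int = 0,
) -> MaxstatResult:
    """Best-separating marker cutpoint by the maximally selected log-rank statistic.

    Candidate cutpoints are the distinct marker values whose induced split
    keeps both groups inside the ``epsilon`` quantile band. The cutpoint is
    the candidate maximizing the standardized statistic; its p-value is the
    exceedance fraction of the permutation max (markers permuted against
    (time, event) pairs, seeded, with add-one correction).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    marker = np.asarray(marker, float)
    n = time.size
    if n < 10:
        raise ValueError("maxstat requires at least 10 records")
    if event.sum() < 1:
        raise ValueError("maxstat requires at least one event")
    a = logrank_scores(time, event)
    order = np.argsort(marker, kind="stable")
    a_sorted = a[order]
    m_sorted = marker[order]
    # distinct marker values and the low-group size they induce
    uniq, counts = np.unique(m_sorted, return_counts=True)
    m_sizes = np.cumsum(counts)
    lo = int(np.ceil(epsilon[0] * n))
    hi = int(np.floor(epsilon[1] * n))
    keep = (m_sizes >= max(lo, 1)) & (m_sizes <= min(hi, n - 1))
    if keep.sum() < 2:
        raise ValueError("epsilon band too narrow: fewer than 2 candidate cutpoints")
    cand_values = uniq[keep]
    cand_ms = m_sizes[keep]

    obs = _standardized_cut_stats(a_sorted, cand_ms)
    best = int(np.argmax(obs))
    max_obs = float(obs[best])

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(a, (b, n)).copy(), axis=1)
        csum = np.cumsum(perm, axis=1)
        T = csum[:, cand_ms - 1]
        abar = a.mean()
        sigma2 = np.mean((a - abar) ** 2)
        var = cand_ms * (n - cand_ms) / (n - 1) * sigma2
        Z = np.abs(T - cand_ms * abar) / np.sqrt(var)
        exceed += int(np.sum(Z.max(axis=1) >= max_obs))
        done += b
    p = (1 + exceed) / (n_perm + 1)

    return MaxstatResult(
        cutpoint=float(cand_values[best]),
        max_statistic=max_obs,
        p_value=float(p),
        candidates=list(zip(cand_values.tolist(), obs.tolist())),
        epsilon=epsilon,
        n_perm=n_perm,
        seed=seed,
    )


def cut_statistic(time, event, marker, cutpoint: float) -> float:
    """Standardized log-rank score statistic at one prespecified cutpoint."""
    a = logrank_scores(np.asarray(time, float), np.asarray(event, int))
    marker = np.asarray(marker, float)
    order = np.argsort(marker, kind="stable")
    m = int(np.sum(marker <= cutpoint))
    if m == 0 or m == marker.size:
        raise ValueError("cutpoint leaves one group empty")
    return float(_standardized_cut_stats(a[order], np.array([m]))[0])


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


@dataclass
class CoxFit:
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    standard_errors: dict[str, float]
    score_statistic: float
    log_likelihood: float
    converged: bool


def _breslow_ll_grad_hess(beta, time, event, X):
    """Breslow partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time; tied event times share the risk
    set of everyone still under observation at that time.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix sums over the risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * X[:, :, None] * X[:, None, :])[::-1], axis=0)[::-1]
    # map each row to the first index of its time value (risk-set anchor)
    uniq, first_idx = np.unique(time, return_index=True)
    anchor = first_idx[np.searchsorted(uniq, time)]
    ev = event == 1
    ll = float(np.sum(eta[ev] - np.log(S0[anchor[ev]])))
    s0 = S0[anchor[ev]][:, None]
    xbar = S1[anchor[ev]] / s0
    grad = (X[ev] - xbar).sum(axis=0)
    hess = -(S2[anchor[ev]] / s0[:, :, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    covariate_names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Newton-Raphson Cox fit with Breslow tie handling and Wald CIs.

    The partial log-likelihood is guaranteed non-decreasing across
    iterations by step-halving. Monotone likelihood (perfect separation)
    surfaces as a non-convergence flag when coefficients diverge.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (n, p)")
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(p)]
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate; Cox model unidentifiable")
    if event.sum() < p:
        raise ValueError("fewer events than covariates")
    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]
    # centre covariates for numerical stability; slopes are unchanged
    centre = X.mean(axis=0)
    Xc = X - centre

    beta = np.zeros(p)
    ll, grad, hess = _breslow_ll_grad_hess(beta, time, event, Xc)
    info0 = -hess
    try:
        score_stat = float(grad @ np.linalg.solve(info0, grad))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular information matrix at beta = 0") from err

    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular information matrix") from err
        s = 1.0
        for _ in range(30):
            cand = beta + s * step
            cand_ll, cand_grad, cand_hess = _breslow_ll_grad_hess(cand, time, event, Xc)
            if cand_ll >= ll - 1e-12:
                break
            s *= 0.5
        improved = cand_ll - ll
        beta, ll, grad, hess = cand, cand_ll, cand_grad, cand_hess
        if np.max(np.abs(beta)) > 30:
            converged = False
            break
        if improved < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular information matrix at optimum") from err
    se = np.sqrt(np.diag(cov))
    names = list(covariate_names)
    return CoxFit(
        coefficients={c: float(b) for c, b in zip(names, beta)},
        hazard_ratios={c: float(np.exp(b)) for c, b in zip(names, beta)},
        ci95={
            c: (float(np.exp(b - 1.96 * s_)), float(np.exp(b + 1.96 * s_)))
            for c, b, s_ in zip(names, beta, se)
        },
        standard_errors={c: float(s_) for c, s_ in zip(names, se)},
        score_statistic=score_stat,
        log_likelihood=float(ll),
        converged=converged,
    )
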