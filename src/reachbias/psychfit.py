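"""Maximum-likelihood psychometric fitting.

The model is an equal-asymptote cumulative Gaussian,

    psi(x) = lambda + (1 - 2*lambda) * Phi((x - m) / sigma),

parameterized by the *threshold* m (the level of 50% rightward choice), the
*width* w (distance between the 5% and 95% points of the unscaled sigmoid,
w = 2 * Phi^-1(0.95) * sigma ~= 3.2897 * sigma) and a single *guess/lapse
rate* lambda that compresses both asymptotes symmetrically.  Trials are
weighted equally via the Bernoulli likelihood.  Confidence intervals come
from a parametric bootstrap (binomial resampling from the fitted curve at
the observed levels, percentile intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

#: width / sigma conversion: the unscaled sigmoid spans its 5%..95% points
#: over 2 * Phi^-1(0.95) standard deviations.
WIDTH_PER_SIGMA = float(2.0 * ndtri(0.95))  # 3.2897072539...

LAPSE_MAX = 0.49
_EPS = 1e-10
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

AggData = Tuple[np.ndarray, np.ndarray, np.ndarray]


@dataclass(frozen=True)
class PsychometricFit:
    """One fitted curve: point estimates, optional bootstrap CIs, diagnostics."""

    threshold: float
    width: float
    lapse: float
    n_trials: int
    converged: bool
    nll: float
    ci95: Optional[Dict[str, Tuple[float, float]]] = None
    ci_unreliable: bool = False

    def predict(self, x) -> np.ndarray:
        """psi(x) at the fitted parameters."""
        return psi(np.asarray(x, dtype=float), self.threshold, self.width, self.lapse)


def sigma_from_width(width: float) -> float:
    return width / WIDTH_PER_SIGMA


def psi(x: np.ndarray, threshold: float, width: float, lapse: float) -> np.ndarray:
    """The equal-asymptote cumulative-Gaussian psychometric function."""
    z = (x - threshold) / sigma_from_width(width)
    return lapse + (1.0 - 2.0 * lapse) * ndtr(z)


def aggregate_trials(
    levels: Union[pd.DataFrame, Sequence[float]], responses: Optional[Sequence[str]] = None
) -> AggData:
    """Aggregate trial-level data to (level, n_right, n_total) arrays.

    Accepts either a trial-log DataFrame (columns ``stimulus_level`` and
    ``response``; misses are dropped) or parallel level/response sequences.
    """
    if isinstance(levels, pd.DataFrame):
        df = levels
        lv = df["stimulus_level"].to_numpy(float)
        resp = df["response"].to_numpy()
    else:
        lv = np.asarray(levels, dtype=float)
        resp = np.asarray(responses)
    keep = resp != "miss"
    lv, resp = lv[keep], resp[keep]
    uniq, inv = np.unique(lv, return_inverse=True)
    n_total = np.bincount(inv, minlength=uniq.size)
    n_right = np.bincount(inv, weights=(resp == "right").astype(float), minlength=uniq.size)
    return uniq, n_right.astype(float), n_total.astype(float)


def _coerce(data) -> AggData:
    if isinstance(data, pd.DataFrame):
        return aggregate_trials(data)
    levels, n_right, n_total = (np.asarray(a, dtype=float) for a in data)
    if not (levels.shape == n_right.shape == n_total.shape):
        raise ValueError("levels, n_right, n_total must have equal shapes")
    if np.any(n_right > n_total) or np.any(n_right < 0):
        raise ValueError("need 0 <= n_right <= n_total at every level")
    return levels, n_right, n_total


def nll(threshold: float, width: float, lapse: float, data) -> float:
    """Negative Bernoulli log-likelihood of the model on aggregated data.

    ``data`` is a DataFrame of trials or a (levels, n_right, n_total) triple.
    Predicted probabilities are clamped away from 0/1 before the logs.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not 0.0 <= lapse < 0.5:
        raise ValueError("lapse must be in [0, 0.5)")
    levels, n_right, n_total = _coerce(data)
    p = np.clip(psi(levels, threshold, width, lapse), _EPS, 1.0 - _EPS)
    return float(-(n_right * np.log(p) + (n_total - n_right) * np.log(1.0 - p)).sum())


def _nll_grad(theta, levels, n_right, n_total):
    m, w, lam = theta
    sigma = w / WIDTH_PER_SIGMA
    z = (levels - m) / sigma
    F = ndtr(z)
    phi = np.exp(-0.5 * z * z) * _INV_SQRT_2PI
    p = lam + (1.0 - 2.0 * lam) * F
    p = np.clip(p, _EPS, 1.0 - _EPS)
    n_left = n_total - n_right
    val = float(-(n_right * np.log(p) + n_left * np.log(1.0 - p)).sum())
    dldp = -(n_right / p) + n_left / (1.0 - p)
    a = (1.0 - 2.0 * lam) * phi
    g = np.array(
        [
            float((dldp * (-a / sigma)).sum()),
            float((dldp * (-a * z / w)).sum()),
            float((dldp * (1.0 - 2.0 * F)).sum()),
        ]
    )
    return val, g


def _degenerate_fit(levels: np.ndarray, n_total: np.ndarray, all_right: bool) -> PsychometricFit:
    span = float(levels.max() - levels.min()) or 1.0
    pinned = float(levels.min() - span) if all_right else float(levels.max() + span)
    return PsychometricFit(
        threshold=pinned, width=span, lapse=0.0,
        n_trials=int(n_total.sum()), converged=False, nll=float("nan"),
    )


def _start_grid(levels: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    span = float(levels.max() - levels.min())
    rep = np.repeat(levels, n_total.astype(int))
    ms = np.quantile(rep, [0.25, 0.5, 0.75])
    ws = np.array([span / 4.0, span / 2.0, span])
    lams = np.array([0.01, 0.05])
    grid = np.array([(m, w, l) for m in ms for w in ws for l in lams])
    return grid


def fit_psychometric(data, n_local_starts: int = 6) -> PsychometricFit:
    """Constrained MLE of (threshold, width, lapse) with a deterministic multi-start.

    The start grid crosses observed-level quantiles {0.25, 0.5, 0.75} for the
    threshold, {span/4, span/2, span} for the width and {0.01, 0.05} for the
    lapse; local optimization (L-BFGS-B with analytic gradients) runs from
    the ``n_local_starts`` grid points with the best likelihood.  Degenerate
    data (all responses to one side) yield an unconverged fit with the
    threshold pinned just outside the observed range.
    """
    levels, n_right, n_total = _coerce(data)
    if levels.size < 2:
        raise ValueError("need at least 2 distinct stimulus levels to fit")
    total_r, total = float(n_right.sum()), float(n_total.sum())
    if total_r == 0.0 or total_r == total:
        return _degenerate_fit(levels, n_total, all_right=(total_r == total))

    span = float(levels.max() - levels.min())
    bounds = [
        (float(levels.min() - span), float(levels.max() + span)),
        (span / 20.0, 5.0 * span),
        (0.0, LAPSE_MAX),
    ]
    grid = _start_grid(levels, n_total)
    scores = [_nll_grad(g, levels, n_right, n_total)[0] for g in grid]
    order = np.argsort(scores)[:n_local_starts]

    best = None
    for idx in order:
        res = minimize(
            _nll_grad,
            grid[idx],
            args=(levels, n_right, n_total),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    m, w, lam = best.x
    return PsychometricFit(
        threshold=float(m), width=float(w), lapse=float(lam),
        n_trials=int(total), converged=bool(best.success), nll=float(best.fun),
    )


@dataclass(frozen=True)
class BootstrapCI:
    ci95: Optional[Dict[str, Tuple[float, float]]]
    n_boot: int
    n_failed: int
    unreliable: bool


def bootstrap_ci(
    fit: PsychometricFit,
    data,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
) -> BootstrapCI:
    """Parametric-bootstrap 95% CIs for threshold, width and lapse.

    Responses are resampled binomially from the fitted curve at the observed
    levels and refit (seeded from the original estimates); the 2.5/97.5
    percentiles of the refits form the intervals.  Refit failures are
    dropped; if more than 10% fail — or ``n_boot`` is 0 — the result is
    flagged unreliable.
    """
    if not fit.converged:
        raise ValueError("bootstrap_ci requires a converged fit")
    if n_boot <= 0:
        return BootstrapCI(None, 0, 0, True)
    levels, _, n_total = _coerce(data)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_hat = np.clip(fit.predict(levels), _EPS, 1.0 - _EPS)
    span = float(levels.max() - levels.min())
    bounds = [
        (float(levels.min() - span), float(levels.max() + span)),
        (span / 20.0, 5.0 * span),
        (0.0, LAPSE_MAX),
    ]
    x0 = np.array([fit.threshold, fit.width, fit.lapse])
    x0[1] = min(max(x0[1], bounds[1][0]), bounds[1][1])
    draws = []
    n_failed = 0
    counts = n_total.astype(int)
    for _ in range(n_boot):
        nr = rng.binomial(counts, p_hat).astype(float)
        if nr.sum() == 0.0 or nr.sum() == n_total.sum():
            n_failed += 1
            continue
        res = minimize(
            _nll_grad, x0, args=(levels, nr, n_total),
            jac=True, method="L-BFGS-B", bounds=bounds,
        )
        if not res.success:
            n_failed += 1
            continue
        draws.append(res.x)
    if not draws:
        return BootstrapCI(None, n_boot, n_failed, True)
    arr = np.array(draws)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    ci = {
        "threshold": (float(lo[0]), float(hi[0])),
        "width": (float(lo[1]), float(hi[1])),
        "lapse": (float(lo[2]), float(hi[2])),
    }
    return BootstrapCI(ci, n_boot, n_failed, n_failed > 0.1 * n_boot)


def fit_with_ci(
    data, n_boot: int = 999, seed: int | np.random.Generator = 0
) -> PsychometricFit:
    """Fit and attach bootstrap CIs in one call (CIs omitted for failed fits)."""
    fit = fit_psychometric(data)
    if not fit.converged or n_boot <= 0:
        return fit
    bs = bootstrap_ci(fit, data, n_boot=n_boot, seed=seed)
    return replace(fit, ci95=bs.ci95, ci_unreliable=bs.unreliable)


def lapse_exclusion_flags(
    fits: pd.DataFrame, criterion: float = 0.05, participant_col: str = "participant_id"
) -> pd.Series:
    """Flag participants with any curve whose lapse rate exceeds the criterion.

    The comparison is strict (> criterion), so a lapse of exactly 0.05 is not
    flagged.  Flagging marks candidates for exclusion; the exclusion decision
    itself is left to the caller.
    """
    return fits.groupby(participant_col)["lapse"].apply(
        lambda s: bool((s > criterion).any())
    )
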