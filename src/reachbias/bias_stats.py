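"""Decision-bias statistics.

The decision bias of a participant is the difference between the fitted
threshold when the right response button is closer and the fitted threshold
when the left one is closer; negative values mean attraction towards the
nearer button.  Its 95% CI combines the two threshold CIs by
root-sum-of-squares of the per-side half-widths.  Group-level inference uses
the Wilcoxon signed-rank test (W reported as the smaller rank sum, exact
two-tailed p for tie-free samples up to n = 25 via the rank-sum distribution
recursion, a tie-corrected normal approximation otherwise) with the signed
rank-biserial correlation r_rb = (W+ - W-) / (W+ + W-) as effect size, plus
a permutation-based Spearman correlation of biases across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata, spearmanr

from .psychfit import PsychometricFit

EXACT_N_MAX = 25


@dataclass(frozen=True)
class BiasResult:
    """Decision bias of one participant in one (task, block)."""

    bias: float
    ci95: Optional[Tuple[float, float]]
    task: str = ""
    block: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.ci95 is not None and not self.flagged:
            lo, hi = self.ci95
            if not lo <= self.bias <= hi:
                raise ValueError("bias must lie inside its CI")


@dataclass(frozen=True)
class SignedRankResult:
    """Wilcoxon signed-rank outcome in the reporting convention used here."""

    n: int                 # non-zero paired differences
    w_plus: float
    w_minus: float
    W: float               # the smaller of the two rank sums
    p: float               # two-tailed
    r_rb: float            # signed rank-biserial effect size
    method: str            # 'exact' or 'normal'
    median: float          # median of the non-zero differences


def decision_bias(
    fit_right_closer: PsychometricFit,
    fit_left_closer: PsychometricFit,
    task: str = "",
    block: str = "",
    with_ci: bool = True,
) -> BiasResult:
    """threshold(right closer) - threshold(left closer), with propagated CI."""
    flagged = not (fit_right_closer.converged and fit_left_closer.converged)
    bias = fit_right_closer.threshold - fit_left_closer.threshold
    ci = None
    if with_ci and not flagged and fit_right_closer.ci95 and fit_left_closer.ci95:
        ci = bias_ci(fit_right_closer, fit_left_closer)
    return BiasResult(bias=float(bias), ci95=ci, task=task, block=block, flagged=flagged)


def bias_ci(
    fit_right_closer: PsychometricFit, fit_left_closer: PsychometricFit
) -> Tuple[float, float]:
    """Root-sum-of-squares propagation of the two threshold CIs.

    The lower (upper) half-width of the bias interval is the RSS of the two
    thresholds' lower (upper) half-widths.
    """
    for f in (fit_right_closer, fit_left_closer):
        if not f.ci95 or "threshold" not in f.ci95:
            raise ValueError("both fits need a threshold CI to propagate")
    bias = fit_right_closer.threshold - fit_left_closer.threshold
    dr_lo = abs(fit_right_closer.threshold - fit_right_closer.ci95["threshold"][0])
    dr_hi = abs(fit_right_closer.ci95["threshold"][1] - fit_right_closer.threshold)
    dl_lo = abs(fit_left_closer.threshold - fit_left_closer.ci95["threshold"][0])
    dl_hi = abs(fit_left_closer.ci95["threshold"][1] - fit_left_closer.threshold)
    lo_half = float(np.hypot(dr_lo, dl_lo))
    hi_half = float(np.hypot(dr_hi, dl_hi))
    return (bias - lo_half, bias + hi_half)


def _exact_sf_counts(n: int) -> np.ndarray:
    """Counts of the W+ distribution over sign assignments of ranks 1..n."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def wilcoxon_signed_rank(
    differences: Sequence[float],
    b: Optional[Sequence[float]] = None,
) -> SignedRankResult:
    """Wilcoxon signed-rank test on differences (or on paired samples a, b).

    Exact zeros are dropped before ranking; |differences| are ranked with
    average ranks for ties.  W is reported as min(W+, W-).  For tie-free
    samples with n <= 25 the two-tailed p comes from the exact null
    distribution of W+; otherwise from the normal approximation with tie
    correction (no continuity correction).
    """
    d = np.asarray(differences, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n < 5:
        raise ValueError(
            f"need at least 5 non-zero paired differences, got {n} "
            "(signed-rank inference is degenerate below that)"
        )
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = n * (n + 1) / 2.0
    W = min(w_plus, w_minus)
    r_rb = (w_plus - w_minus) / total

    has_ties = np.unique(absd).size < n
    if n <= EXACT_N_MAX and not has_ties:
        counts = _exact_sf_counts(n)
        m = int(total)
        w_int = int(round(W))
        if m - w_int <= w_int:
            p = 1.0
        else:
            lo = counts[: w_int + 1].sum()
            hi = counts[m - w_int :].sum()
            p = float((lo + hi) / 2.0 ** n)
        method = "exact"
    else:
        mean = total / 2.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, t_counts = np.unique(absd, return_counts=True)
        var -= float((t_counts ** 3 - t_counts).sum()) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * ndtr(-abs(z)))
        method = "normal"
    return SignedRankResult(
        n=n, w_plus=w_plus, w_minus=w_minus, W=float(W),
        p=min(1.0, p), r_rb=float(r_rb), method=method,
        median=float(np.median(d)),
    )


def compare_blocks(
    bias_main: pd.Series | Sequence[float],
    bias_control: pd.Series | Sequence[float],
) -> SignedRankResult:
    """Signed-rank test on the paired (main - control) bias differences.

    Inputs must cover the same participants; pandas Series are aligned on
    their index, plain sequences positionally.
    """
    if isinstance(bias_main, pd.Series) and isinstance(bias_control, pd.Series):
        if not bias_main.index.sort_values().equals(bias_control.index.sort_values()):
            raise ValueError("main and control biases cover different participants")
        bias_control = bias_control.reindex(bias_main.index)
        a, c = bias_main.to_numpy(float), bias_control.to_numpy(float)
    else:
        a, c = np.asarray(bias_main, float), np.asarray(bias_control, float)
        if a.shape != c.shape:
            raise ValueError("main and control biases must be paired")
    return wilcoxon_signed_rank(a - c)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> Tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = float(spearmanr(x, y).statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rho_perm = (ry[perms] @ rx) / n
    p = float((1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_perm + 1))
    return rho, p


def summarize_parameters(fits: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SD of threshold, width and lapse per (task, block, condition)."""
    if fits["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants to summarize")
    g = fits.groupby(["task", "block", "condition"])[["threshold", "width", "lapse"]]
    out = g.agg(["mean", "std"])
    out.columns = [f"{p}_{stat}" for p, stat in out.columns]
    return out.reset_index()
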