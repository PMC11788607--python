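"""High-level pipeline: fit every curve, compute biases, run the group tests.

These functions operate on the flat tables defined in :mod:`reachbias.io`
and are what both the command-line interface and batch scripts call.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import bias_stats, kinematics, psychfit
from .geometry import CONDITIONS


def fit_cohort(
    trials: pd.DataFrame,
    n_boot: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Fit one psychometric curve per (participant, task, block, condition).

    Each curve pools the two staircases of its condition.  With ``n_boot > 0``
    parametric-bootstrap CIs are attached (seeded deterministically per
    curve).  Returns a flat table with point estimates, CI bounds and
    convergence flags.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    groups = trials.groupby(["participant_id", "task", "block", "condition"], sort=True)
    children = ss.spawn(groups.ngroups)
    rows = []
    for child, ((pid, task, block, condition), df) in zip(children, groups):
        data = psychfit.aggregate_trials(df)
        fit = psychfit.fit_with_ci(data, n_boot=n_boot, seed=np.random.default_rng(child))
        ci = fit.ci95 or {}
        rows.append(
            {
                "participant_id": pid, "task": task, "block": block,
                "condition": condition, "n_trials": fit.n_trials,
                "converged": fit.converged, "threshold": fit.threshold,
                "width": fit.width, "lapse": fit.lapse,
                "threshold_lo": ci.get("threshold", (np.nan, np.nan))[0],
                "threshold_hi": ci.get("threshold", (np.nan, np.nan))[1],
                "width_lo": ci.get("width", (np.nan, np.nan))[0],
                "width_hi": ci.get("width", (np.nan, np.nan))[1],
                "lapse_lo": ci.get("lapse", (np.nan, np.nan))[0],
                "lapse_hi": ci.get("lapse", (np.nan, np.nan))[1],
                "ci_unreliable": fit.ci_unreliable,
            }
        )
    return pd.DataFrame(rows)


def _fit_from_row(row: pd.Series) -> psychfit.PsychometricFit:
    ci = None
    if np.isfinite(row["threshold_lo"]):
        ci = {
            "threshold": (row["threshold_lo"], row["threshold_hi"]),
            "width": (row["width_lo"], row["width_hi"]),
            "lapse": (row["lapse_lo"], row["lapse_hi"]),
        }
    return psychfit.PsychometricFit(
        threshold=row["threshold"], width=row["width"], lapse=row["lapse"],
        n_trials=int(row["n_trials"]), converged=bool(row["converged"]),
        nll=np.nan, ci95=ci, ci_unreliable=bool(row.get("ci_unreliable", False)),
    )


def compute_biases(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-participant decision biases from a cohort fit table.

    bias = threshold(right_closer) - threshold(left_closer) per
    (participant, task, block), with the root-sum-of-squares CI when both
    thresholds carry CIs.  Rows with a non-converged side are flagged.
    """
    rows = []
    for (pid, task, block), df in fits.groupby(["participant_id", "task", "block"]):
        by_cond = {r["condition"]: _fit_from_row(r) for _, r in df.iterrows()}
        if set(by_cond) != set(CONDITIONS):
            continue
        res = bias_stats.decision_bias(
            by_cond["right_closer"], by_cond["left_closer"], task=task, block=block
        )
        lo, hi = res.ci95 if res.ci95 else (np.nan, np.nan)
        rows.append(
            {
                "participant_id": pid, "task": task, "block": block,
                "bias": res.bias, "ci_lo": lo, "ci_hi": hi, "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)


def analyze_biases(
    biases: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> Dict:
    """Group-level tests on a cohort bias table.

    Per (task, block): Wilcoxon signed-rank of the biases against zero.  Per
    task: main-vs-control paired comparison.  Across tasks: Spearman
    correlation of the main-block biases (permutation p), when both tasks are
    present.  Flagged (non-converged) rows are dropped first.
    """
    ok = biases[~biases["flagged"].astype(bool)]
    out: Dict = {"per_block": {}, "block_comparison": {}, "cross_task": None}
    for (task, block), df in ok.groupby(["task", "block"]):
        try:
            res = bias_stats.wilcoxon_signed_rank(df["bias"].to_numpy())
        except ValueError as exc:
            out["per_block"][f"{task}/{block}"] = {"error": str(exc)}
            continue
        out["per_block"][f"{task}/{block}"] = _signed_rank_dict(res)
    for task, df in ok.groupby("task"):
        wide = df.pivot(index="participant_id", columns="block", values="bias").dropna()
        if {"main", "control"} <= set(wide.columns) and len(wide) >= 5:
            try:
                res = bias_stats.compare_blocks(wide["main"], wide["control"])
            except ValueError as exc:
                out["block_comparison"][task] = {"error": str(exc)}
                continue
            out["block_comparison"][task] = _signed_rank_dict(res)
    main = ok[ok["block"] == "main"]
    wide = main.pivot(index="participant_id", columns="task", values="bias").dropna()
    if {"motion", "orientation"} <= set(wide.columns) and len(wide) >= 5:
        rho, p = bias_stats.spearman_rho(
            wide["motion"].to_numpy(), wide["orientation"].to_numpy(),
            n_perm=n_perm, seed=seed,
        )
        out["cross_task"] = {"rho": rho, "p": p, "n": int(len(wide))}
    return out


def _signed_rank_dict(res: bias_stats.SignedRankResult) -> Dict:
    return {
        "n": res.n, "median": res.median, "W": res.W,
        "w_plus": res.w_plus, "w_minus": res.w_minus,
        "r_rb": res.r_rb, "p": res.p, "method": res.method,
    }


def render_report(
    fits: pd.DataFrame,
    biases: pd.DataFrame,
    stats: Dict,
    trials: Optional[pd.DataFrame] = None,
    header: Optional[Dict] = None,
) -> str:
    """Markdown report: parameter table, bias table, test lines, kinematics."""
    lines = ["# reachbias report", ""]
    if header:
        for k, v in header.items():
            lines.append(f"- {k}: {v}")
        lines.append("")

    lines += ["## Psychometric parameters (mean (SD) across participants)", ""]
    summary = bias_stats.summarize_parameters(fits)
    lines.append("| Task | Block | Condition | Threshold | Width | Lapse rate |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in summary.iterrows():
        lines.append(
            f"| {r['task']} | {r['block']} | {r['condition']} "
            f"| {r['threshold_mean']:.1f} ({r['threshold_std']:.1f}) "
            f"| {r['width_mean']:.0f} ({r['width_std']:.0f}) "
            f"| {r['lapse_mean']:.3f} ({r['lapse_std']:.3f}) |"
        )

    lines += ["", "## Decision bias (threshold right-closer minus left-closer)", ""]
    g = biases[~biases["flagged"].astype(bool)].groupby(["task", "block"])["bias"]
    lines.append("| Task | Block | Mean bias | Median bias | n |")
    lines.append("|---|---|---|---|---|")
    for (task, block), s in g:
        lines.append(
            f"| {task} | {block} | {s.mean():.1f} | {s.median():.1f} | {len(s)} |"
        )

    lines += ["", "## Wilcoxon signed-rank tests (bias vs 0)", ""]
    for key, d in stats.get("per_block", {}).items():
        if "error" in d:
            lines.append(f"- {key}: degenerate ({d['error']})")
        else:
            lines.append(
                f"- {key}: Mdn = {d['median']:.1f}, W = {d['W']:.0f}, "
                f"r_rb = {d['r_rb']:.2f}, p = {d['p']:.4g} ({d['method']}, n = {d['n']})"
            )
    lines += ["", "## Main vs control block", ""]
    for task, d in stats.get("block_comparison", {}).items():
        if "error" in d:
            lines.append(f"- {task}: degenerate ({d['error']})")
        else:
            lines.append(
                f"- {task}: Mdn diff = {d['median']:.1f}, W = {d['W']:.0f}, "
                f"r_rb = {d['r_rb']:.2f}, p = {d['p']:.4g} (n = {d['n']})"
            )
    ct = stats.get("cross_task")
    lines += ["", "## Cross-task correlation of main-block biases", ""]
    if ct:
        lines.append(f"- Spearman rho({ct['n'] - 2}) = {ct['rho']:.2f}, p = {ct['p']:.3f}")
    else:
        lines.append("- not computed (needs both tasks)")

    if trials is not None and trials["rt_ms"].notna().any():
        lines += ["", "## Kinematics", ""]
        _, overall = kinematics.rt_summary(trials)
        for _, r in overall.iterrows():
            lines.append(
                f"- median RT, {r['task']}/{r['block']}: {r['mean_median_rt_ms']:.0f} ms"
            )
        by_reach, _ = kinematics.movement_time_summary(trials)
        for _, r in by_reach.iterrows():
            lines.append(
                f"- median movement time, {r['reach']} button: "
                f"{r['mean_median_movement_ms']:.0f} ms"
            )
        com = kinematics.change_of_mind_rate(trials)
        lines.append(f"- change-of-mind rate: {100 * com:.2f}% of completed trials")
    lines.append("")
    return "\n".join(lines)
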