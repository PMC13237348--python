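"""Behavioral costs and the connectivity-to-behavior validation layer.

Restart cost: first minus third post-cue target (RT and error rate), per
cue. Switch cost: first post-switch minus first post-repeat target. RT
analyses use correct trials only; "correct" responses faster than 200 ms
are treated as errors. Edge-behavior validation ranks Pearson correlations
between per-epoch edge values and first-target RT, and runs stepwise
(forward entry p <= 0.05, backward removal p >= 0.10) regression of
z-scored RTs on z-scored edge values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sst

from .data import TrialTable

logger = logging.getLogger(__name__)

__all__ = ["CostReport", "RegressionReport", "compute_costs",
           "rank_edge_rt_correlations", "stepwise_regression", "zscore"]

MIN_RT_MS = 200.0


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class CostReport:
    per_subject: pd.DataFrame  # one row per subject: costs in ms / ER units
    group: dict  # group means and paired t-tests
    excluded_subjects: list[str] = field(default_factory=list)


def _clean(trials: TrialTable) -> pd.DataFrame:
    df = trials.df.copy()
    too_fast = (df["correct"] == 1) & (df["rt_ms"] < MIN_RT_MS)
    if too_fast.any():
        logger.info("%d fast (<%g ms) responses recoded as errors", int(too_fast.sum()), MIN_RT_MS)
    df.loc[too_fast, "correct"] = 0
    return df


def compute_costs(trials: TrialTable) -> CostReport:
    """Per-subject restart and switch costs with paired t-tests across
    subjects. Subjects missing any cue x position cell are excluded with a
    warning."""
    df = _clean(trials)
    need = {(cue, pos) for cue in ("repeat", "switch") for pos in (1, 3)}
    rows, excluded = [], []
    for subj, g in df.groupby("subject"):
        cells_rt, cells_er = {}, {}
        ok = True
        for cue, pos in need:
            cell = g[(g["cue"] == cue) & (g["target_position"] == pos)]
            corr = cell[cell["correct"] == 1]
            if len(cell) == 0 or len(corr) == 0:
                ok = False
                break
            cells_rt[(cue, pos)] = corr["rt_ms"].mean()
            cells_er[(cue, pos)] = 1.0 - cell["correct"].mean()
        if not ok:
            logger.warning("subject %r missing a cue/position cell; excluded", subj)
            excluded.append(str(subj))
            continue
        rows.append({
            "subject": subj,
            "restart_rt_repeat": cells_rt[("repeat", 1)] - cells_rt[("repeat", 3)],
            "restart_rt_switch": cells_rt[("switch", 1)] - cells_rt[("switch", 3)],
            "switch_rt_cost": cells_rt[("switch", 1)] - cells_rt[("repeat", 1)],
            "restart_er_repeat": cells_er[("repeat", 1)] - cells_er[("repeat", 3)],
            "restart_er_switch": cells_er[("switch", 1)] - cells_er[("switch", 3)],
            "switch_er_cost": cells_er[("switch", 1)] - cells_er[("repeat", 1)],
        })
    per_subject = pd.DataFrame(rows)
    group = {}
    for col in per_subject.columns.drop("subject"):
        vals = per_subject[col].to_numpy()
        t, p = sst.ttest_1samp(vals, 0.0) if len(vals) > 1 else (np.nan, np.nan)
        group[col] = {"mean": float(vals.mean()), "t": float(t), "p": float(p)}
    return CostReport(per_subject, group, excluded)


def rank_edge_rt_correlations(
    edge_values: np.ndarray,
    rts: np.ndarray,
    condition: np.ndarray | None = None,
    condition_value: int | None = None,
    edge_index: list | None = None,
) -> pd.DataFrame:
    """Pearson r of each edge's per-epoch value against first-target RT,
    ranked by descending |r| (sign retained). Zero-variance edges are flagged
    and ranked last. Optionally restricted to one condition's epochs."""
    edge_values = np.asarray(edge_values, float)
    rts = np.asarray(rts, float)
    if edge_values.shape[0] != rts.shape[0]:
        raise ValueError("rts must align with epochs")
    if condition_value is not None:
        sel = np.asarray(condition) == condition_value
        edge_values, rts = edge_values[sel], rts[sel]
    zr = zscore(rts)
    rs, flags = [], []
    for e in range(edge_values.shape[1]):
        v = edge_values[:, e]
        if v.std() == 0:
            rs.append(np.nan)
            flags.append(True)
        else:
            rs.append(float(np.corrcoef(zscore(v), zr)[0, 1]))
            flags.append(False)
    df = pd.DataFrame({
        "edge": edge_index if edge_index is not None else list(range(edge_values.shape[1])),
        "r": rs,
        "abs_r": np.abs(rs),
        "degenerate": flags,
    })
    df = df.sort_values(["degenerate", "abs_r"], ascending=[True, False], na_position="last")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass
class RegressionReport:
    steps: list[dict]  # accepted models in order

    @property
    def final_variables(self) -> list:
        return self.steps[-1]["variables"] if self.steps else []


def stepwise_regression(
    X: np.ndarray,
    y: np.ndarray,
    names: list | None = None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_steps: int = 50,
) -> RegressionReport:
    """Forward selection with backward removal on z-scored variables.

    At each step the candidate with the smallest entry p-value joins if
    p <= entry_p; any included variable whose p rises to >= removal_p is
    dropped. Each accepted model is reported with standardized betas, p,
    standard error of estimate, model F, and adjusted R^2. Perfectly
    collinear candidates are dropped (later index loses) with a warning.
    """
    X = np.asarray(X, float)
    y = zscore(np.asarray(y, float))
    n, p_all = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p_all)]
    Xz = np.column_stack([zscore(X[:, j]) for j in range(p_all)])
    # drop exact duplicates / zero-variance candidates up front
    keep = []
    for j in range(p_all):
        if X[:, j].std() == 0:
            logger.warning("candidate %s has zero variance; dropped", names[j])
            continue
        dup = any(np.allclose(Xz[:, j], Xz[:, k]) or np.allclose(Xz[:, j], -Xz[:, k]) for k in keep)
        if dup:
            logger.warning("candidate %s is collinear with an earlier one; dropped", names[j])
            continue
        keep.append(j)

    included: list[int] = []
    steps: list[dict] = []
    prev_adj_r2 = -np.inf
    for _ in range(max_steps):
        best_j, best_p = None, np.inf
        for j in keep:
            if j in included:
                continue
            cols = included + [j]
            res = sm.OLS(y, sm.add_constant(Xz[:, cols])).fit()
            pj = res.pvalues[-1]
            if pj < best_p:
                best_p, best_j = pj, j
        if best_j is None or best_p > entry_p:
            break
        included.append(best_j)
        # backward pass
        while True:
            res = sm.OLS(y, sm.add_constant(Xz[:, included])).fit()
            pv = res.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] >= removal_p and len(included) > 1:
                included.pop(worst)
            else:
                break
        res = sm.OLS(y, sm.add_constant(Xz[:, included])).fit()
        see = float(np.sqrt(res.ssr / max(res.df_resid, 1)))
        step = {
            "variables": [names[j] for j in included],
            "beta": {names[j]: float(b) for j, b in zip(included, res.params[1:])},
            "p": {names[j]: float(q) for j, q in zip(included, res.pvalues[1:])},
            "see": see,
            "F": float(res.fvalue),
            "adj_r2": float(res.rsquared_adj),
        }
        if step["adj_r2"] <= prev_adj_r2:
            break  # the selection loop only accepts strictly improving models
        prev_adj_r2 = step["adj_r2"]
        steps.append(step)
    return RegressionReport(steps)
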