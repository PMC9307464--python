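"""Group summaries and control-referenced multiple comparisons.

Treatment groups are compared against a single control by one-way ANOVA
followed by Dunnett's many-to-one test (multivariate-t critical values),
assuming homoscedasticity. Adjusted p-values are mapped onto presentation
star tiers at the conventional GraphPad-style cutoffs
(* < 0.0332, ** < 0.0021, *** < 0.0002, **** < 0.0001), which are decoupled
from the testing alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_TIERS = ((0.0001, "****"), (0.0002, "***"), (0.0021, "**"), (0.0332, "*"))


def stars(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return "ns"
    for cutoff, mark in STAR_TIERS:
        if p < cutoff:
            return mark
    return "ns"


@dataclass
class GroupTable:
    """Long-format observations: one row per (group, replicate, value)."""

    observations: pd.DataFrame  # columns: group, replicate, value
    control_group: str
    metric: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.observations)
        missing = {"group", "replicate", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if df["group"].nunique() < 2:
            raise ValueError("at least two groups required")
        if self.control_group not in set(df["group"]):
            raise ValueError(f"control group {self.control_group!r} absent")
        self.observations = df

    def values_by_group(self) -> dict[str, np.ndarray]:
        return {
            g: sub["value"].to_numpy(dtype=float)
            for g, sub in self.observations.groupby("group", sort=False)
        }


def summarize(table: GroupTable) -> pd.DataFrame:
    """Per-group mean, SD (n-1 denominator) and n; n < 2 flags the SD absent."""
    rows = []
    for g, vals in table.values_by_group().items():
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                "sd_flag": "n<2" if len(vals) < 2 else "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaDunnettResult:
    f_statistic: float | None
    anova_p: float | None
    comparisons: pd.DataFrame  # group, mean_diff, p_unadjusted, p_adjusted, stars, significant
    alpha: float
    degenerate: bool = False
    method: str = "dunnett multivariate-t (scipy)"

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "anova_p": self.anova_p,
            "alpha": self.alpha,
            "degenerate": self.degenerate,
            "method": self.method,
            "comparisons": self.comparisons.to_dict(orient="records"),
        }


def anova_dunnett(table: GroupTable, alpha: float = 0.05, seed: int = 0) -> AnovaDunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs the control.

    Every observation is pooled (no experiment-level nesting). A table whose
    values are all identical has no variance to test against and is reported
    as non-significant by construction rather than as an error.
    """
    groups = table.values_by_group()
    control = groups.pop(table.control_group)
    if len(groups) < 1:
        raise ValueError("at least one non-control group required")
    if any(len(v) < 2 for v in list(groups.values()) + [control]):
        raise ValueError("each group needs at least two observations")

    all_vals = np.concatenate([control] + list(groups.values()))
    if np.ptp(all_vals) == 0:
        comparisons = pd.DataFrame(
            {
                "group": list(groups),
                "mean_diff": [0.0] * len(groups),
                "p_unadjusted": [np.nan] * len(groups),
                "p_adjusted": [np.nan] * len(groups),
                "stars": ["ns"] * len(groups),
                "significant": [False] * len(groups),
            }
        )
        return AnovaDunnettResult(None, None, comparisons, alpha, degenerate=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, anova_p = stats.f_oneway(control, *groups.values())
    rng = np.random.default_rng(seed)
    dunnett = stats.dunnett(
        *groups.values(), control=control, rng=rng
    )
    p_adj = np.asarray(dunnett.pvalue, dtype=float)

    # unadjusted per-comparison p: same pooled-variance t statistic, two-sided
    k = len(groups)
    n_total = len(all_vals)
    df_err = n_total - (k + 1)
    sq = 0.0
    for v in [control] + list(groups.values()):
        sq += np.sum((v - v.mean()) ** 2)
    s2 = sq / df_err
    p_unadj = []
    diffs = []
    for v in groups.values():
        se = np.sqrt(s2 * (1.0 / len(v) + 1.0 / len(control)))
        t = (v.mean() - control.mean()) / se
        p_unadj.append(2.0 * stats.t.sf(abs(t), df_err))
        diffs.append(v.mean() - control.mean())
    p_unadj = np.asarray(p_unadj)
    # multiplicity can never make a comparison more significant
    p_adj = np.maximum(p_adj, p_unadj)

    comparisons = pd.DataFrame(
        {
            "group": list(groups),
            "mean_diff": diffs,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "stars": [stars(p) for p in p_adj],
            "significant": p_adj < alpha,
        }
    )
    return AnovaDunnettResult(float(f_stat), float(anova_p), comparisons, alpha)
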