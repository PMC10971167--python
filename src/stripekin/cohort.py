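"""Cohort statistics: recruiting/plateaued fractions and ANOVA + Tukey HSD.

The per-experiment recruiting fraction treats each independent experiment as
the unit of replication (mean ± SEM across experiments per cell model);
per-cell kinetic parameters are compared across cell models with a one-way
ANOVA followed by Tukey–Kramer honestly-significant-difference post hoc
tests on all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import KineticParameters

__all__ = [
    "CellRecord",
    "PairwiseResult",
    "GroupComparison",
    "records_to_frame",
    "recruiting_fraction",
    "plateau_fraction",
    "compare_groups",
    "significance_tier",
]

PARAMETER_NAMES = (
    "lag_time_s", "association_time_s", "plateau_time_s", "dissociation_time_s",
    "duration_s", "k_on", "k_off", "fold_change",
)


@dataclass
class CellRecord:
    """One irradiated cell: identity, recruiting flag, and (if recruiting) parameters."""

    cell_model: str
    experiment_id: str
    cell_id: str
    recruiting: bool
    parameters: KineticParameters | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.recruiting and self.parameters is None and "qc_failed" not in self.flags:
            raise ValueError("recruiting cells must carry parameters unless QC-failed")
        if not self.recruiting and self.parameters is not None:
            raise ValueError("non-recruiting cells carry no parameters")


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tidy per-cell table: one row per irradiated cell, NaN parameters when absent."""
    rows = []
    for r in records:
        row = {
            "cell_model": r.cell_model,
            "experiment_id": r.experiment_id,
            "cell_id": r.cell_id,
            "recruiting": bool(r.recruiting),
            "plateau_present": r.parameters.plateau_present if r.parameters else False,
            "flags": ";".join(r.flags),
        }
        for name in PARAMETER_NAMES:
            row[name] = getattr(r.parameters, name) if r.parameters else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def recruiting_fraction(records: list[CellRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-model recruiting percentage, mean ± SEM across experiments.

    Each experiment contributes one fraction (recruiting / irradiated × 100);
    experiments with zero irradiated cells are excluded.  SEM is the sample
    standard deviation across experiments divided by √n_experiments (0 for a
    single experiment).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    per_exp = (
        df.groupby(["cell_model", "experiment_id"])["recruiting"]
        .agg(["mean", "size"])
        .reset_index()
    )
    per_exp = per_exp[per_exp["size"] > 0]
    per_exp["fraction_pct"] = per_exp["mean"] * 100.0
    out = []
    for model, grp in per_exp.groupby("cell_model"):
        fracs = grp["fraction_pct"].to_numpy()
        sem = float(np.std(fracs, ddof=1) / np.sqrt(len(fracs))) if len(fracs) > 1 else 0.0
        out.append({
            "cell_model": model,
            "recruiting_pct": float(np.mean(fracs)),
            "sem_pct": sem,
            "n_experiments": int(len(fracs)),
            "n_cells": int(grp["size"].sum()),
        })
    return pd.DataFrame(out)


def plateau_fraction(records: list[CellRecord] | pd.DataFrame) -> float:
    """Percentage of recruiting cells with a plateau phase (denominator excludes
    non-recruiting cells).  Raises when no cell recruits."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rec = df[df["recruiting"]]
    if len(rec) == 0:
        raise ValueError("plateau fraction undefined: no recruiting cells")
    return float(rec["plateau_present"].mean() * 100.0)


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    difference: float
    p_adjusted: float
    tier: str


@dataclass
class GroupComparison:
    parameter: str
    f_statistic: float
    p_value: float
    pairs: list[PairwiseResult]


def compare_groups(
    table: pd.DataFrame | dict,
    parameter: str,
    group_col: str = "cell_model",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA plus Tukey–Kramer HSD over all group pairs.

    ``table`` is either a tidy DataFrame (``group_col`` + ``parameter``
    columns; NaNs dropped pairwise) or a mapping of group name to value
    array.  Adjusted p-values use the studentized range distribution with
    the pooled within-group variance; unbalanced groups are handled by the
    Tukey–Kramer standard error.  Significance tiers *, **, *** correspond
    to 0.05, 0.01 and 0.001.
    """
    if isinstance(table, dict):
        groups = {k: np.asarray(v, dtype=float) for k, v in table.items()}
    else:
        groups = {
            name: grp[parameter].dropna().to_numpy(dtype=float)
            for name, grp in table.groupby(group_col)
        }
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    names = sorted(groups)
    data = [groups[n] for n in names]

    n_total = sum(len(g) for g in data)
    k = len(data)
    df_within = n_total - k
    grand = np.concatenate(data).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    ms_within = ss_within / df_within

    if ms_within == 0:
        # degenerate: no within-group variance
        equal_means = len({float(g.mean()) for g in data}) == 1
        f_stat, p_val = (0.0, 1.0) if equal_means else (float("inf"), 0.0)
    else:
        f_stat = (ss_between / (k - 1)) / ms_within
        p_val = float(stats.f.sf(f_stat, k - 1, df_within))

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(data[j].mean() - data[i].mean())
            if ms_within == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                # Tukey–Kramer: SE of the difference on the q scale
                se = np.sqrt(ms_within / 2.0 * (1.0 / len(data[i]) + 1.0 / len(data[j])))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
            pairs.append(PairwiseResult(
                group_a=names[i], group_b=names[j], difference=diff,
                p_adjusted=p_adj, tier=significance_tier(p_adj),
            ))
    return GroupComparison(parameter=parameter, f_statistic=float(f_stat),
                           p_value=p_val, pairs=pairs)
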