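"""Group-level summaries and statistics.

Measurements are collected into a tidy table with one row per
(embryo, group, timepoint, metric) and summarized as mean ± SEM per group.
Group comparisons use one-way ANOVA, or a two-way repeated-measures design
(group between subjects, timepoint within), followed by Bonferroni-adjusted
pairwise t-tests (adjusted p = raw p × number of comparisons, capped at 1).
Significance stars follow the usual convention: * p<0.05, ** p<0.01,
*** p<0.001.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError

GROUP_COLUMNS = ["embryo_id", "group", "timepoint", "metric", "value"]


def make_group_table(rows: list[tuple]) -> pd.DataFrame:
    """Build a tidy measurement table and enforce key uniqueness."""
    df = pd.DataFrame(rows, columns=GROUP_COLUMNS)
    key = df[["embryo_id", "timepoint", "metric"]]
    if key.duplicated().any():
        raise ParameterError("(embryo_id, timepoint, metric) must be unique")
    return df


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, timepoint, metric): mean, SEM (sd/sqrt(n), n-1 sd) and n.

    Groups with a single value get SEM = NaN; empty groups are dropped with
    a warning.
    """
    table = table.dropna(subset=["value"])
    if table.empty:
        warnings.warn("no values to summarize; empty groups excluded")
        return pd.DataFrame(columns=["group", "timepoint", "metric",
                                     "mean", "sem", "n"])
    out = (table.groupby(["group", "timepoint", "metric"], sort=True)["value"]
           .agg(mean="mean", sem=lambda v: stats.sem(v, ddof=1) if len(v) > 1 else np.nan,
                n="count")
           .reset_index())
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bonferroni(raw_p: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment: raw p × number of comparisons, capped at 1."""
    raw = np.asarray(raw_p, dtype=float)
    return np.minimum(raw * len(raw), 1.0)


@dataclass
class ComparisonResult:
    """ANOVA table plus Bonferroni-adjusted pairwise comparisons."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame


def _pairwise_ttests(values_by_group: dict, paired: bool) -> pd.DataFrame:
    names = sorted(values_by_group)
    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = values_by_group[a], values_by_group[b]
        if paired:
            res = stats.ttest_rel(va, vb)
        else:
            res = stats.ttest_ind(va, vb)
        rows.append({"group1": a, "group2": b, "raw_p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["adj_p"] = bonferroni(df["raw_p"].to_numpy())
    df["stars"] = [_stars(p) for p in df["adj_p"]]
    return df


def compare_groups(table: pd.DataFrame, design: str = "one_way",
                   metric: str | None = None) -> ComparisonResult:
    """ANOVA + Bonferroni post-hoc pairwise tests over the group factor.

    one_way
        Single-factor ANOVA across groups (timepoints pooled or absent);
        pairwise independent t-tests within the same family.
    two_way_repeated
        Group (between subjects) × timepoint (within subjects) design fitted
        as a two-way ANOVA with subject-within-group error for the repeated
        factor; requires every subject measured at every timepoint.
        Pairwise comparisons are made between groups within each timepoint.
    """
    df = table.copy()
    if metric is not None:
        df = df[df["metric"] == metric]
    df = df.dropna(subset=["value"])
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups to compare")
    if any((df["group"] == g).sum() < 2 for g in groups):
        raise ParameterError("need >= 2 values per group")

    if design == "one_way":
        samples = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in groups}
        f, p = stats.f_oneway(*samples.values())
        anova = pd.DataFrame([{"effect": "group", "F": float(f), "p": float(p),
                               "stars": _stars(float(p))}])
        pairwise = _pairwise_ttests(samples, paired=False)
        return ComparisonResult(anova=anova, pairwise=pairwise)

    if design == "two_way_repeated":
        counts = df.pivot_table(index="embryo_id", columns="timepoint",
                                values="value", aggfunc="count")
        if counts.isna().any().any() or (counts != 1).any().any():
            raise ParameterError(
                "unbalanced repeated-measures design: every subject needs "
                "exactly one value per timepoint")
        anova = _mixed_anova(df)
        frames = []
        for tp in sorted(df["timepoint"].unique()):
            sub = df[df["timepoint"] == tp]
            samples = {g: sub.loc[sub["group"] == g, "value"].to_numpy()
                       for g in groups}
            pw = _pairwise_ttests(samples, paired=False)
            pw.insert(0, "timepoint", tp)
            frames.append(pw)
        return ComparisonResult(anova=anova, pairwise=pd.concat(frames,
                                                                ignore_index=True))

    raise ParameterError(f"unknown design: {design!r}")


def _mixed_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Two-way mixed ANOVA (group between subjects, timepoint within),
    delegated to pingouin; reshaped into this package's effect/F/p schema."""
    import pingouin as pg  # deferred: pingouin pulls in heavy plotting deps

    res = pg.mixed_anova(data=df, dv="value", within="timepoint",
                         subject="embryo_id", between="group")
    name_map = {"group": "group", "timepoint": "timepoint",
                "Interaction": "group:timepoint"}
    rows = []
    for _, r in res.iterrows():
        effect = name_map.get(str(r["Source"]), str(r["Source"]))
        p = float(r["p_unc"])
        rows.append({"effect": effect, "F": float(r["F"]), "p": p,
                     "stars": _stars(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows)
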