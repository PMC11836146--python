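"""Helmet ranking and ranking-sensitivity analyses.

Helmets are ranked per strain metric by the 95th-percentile strain peak
averaged across the three impact locations (lower strain = better = rank
1); ties receive average ranks.  Agreement between the rankings induced
by different metrics is quantified with Kendall's tau-b over all
unordered metric pairs.  Cross-metric dependency is assessed with Pearson
correlations pooled over all (helmet, location) observations: 7x5
kinematic-vs-strain tests plus the 10 strain-strain pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .headmetrics import KINEMATIC_METRICS, STRAIN_METRICS

STRONG_R = 0.7


def average_across_locations(summaries: pd.DataFrame,
                             locations: tuple[str, ...] = ("XRot", "YRot", "ZRot")
                             ) -> pd.DataFrame:
    """Per-helmet arithmetic mean of per-location summary values.

    ``summaries`` is indexed by (helmet_id, location); every helmet must
    have all requested locations.
    """
    present = summaries.index.get_level_values("location")
    for loc in locations:
        if loc not in set(present):
            raise DataError(f"missing location {loc} in summaries")
    sub = summaries[np.isin(present, locations)]
    counts = sub.groupby(level="helmet_id").size()
    bad = counts[counts != len(locations)]
    if len(bad):
        raise DataError(
            f"helmets missing locations: {bad.index.tolist()}")
    return sub.groupby(level="helmet_id").mean()


def rank_helmets(values: pd.Series) -> pd.Series:
    """Ascending ranks (1 = lowest value = best); ties get average ranks."""
    v = values.to_numpy(float)
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite summary values cannot be ranked")
    return pd.Series(stats.rankdata(v, method="average"), index=values.index)


def ranking_table(summaries: pd.DataFrame,
                  metrics: tuple[str, ...] = STRAIN_METRICS) -> pd.DataFrame:
    """Ranks of each helmet under each strain metric (columns = metrics)."""
    means = average_across_locations(summaries[list(metrics)])
    return means.apply(rank_helmets)


def kendall_tau_matrix(rankings: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b between every pair of metric rankings (unit diagonal).

    ``rankings`` has one row per helmet and one column per metric; all
    columns must share the helmet index.
    """
    if rankings.isna().any().any():
        raise DataError("rankings contain missing values")
    metrics = list(rankings.columns)
    k = len(metrics)
    tau = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        t = stats.kendalltau(rankings.iloc[:, i], rankings.iloc[:, j]).statistic
        tau[i, j] = tau[j, i] = t
    return pd.DataFrame(tau, index=metrics, columns=metrics)


def metric_correlations(metric_table: pd.DataFrame,
                        kinematic: tuple[str, ...] = KINEMATIC_METRICS,
                        strain: tuple[str, ...] = STRAIN_METRICS
                        ) -> dict[str, pd.DataFrame]:
    """Pearson r and p for kinematic-vs-strain and strain-vs-strain pairs.

    All (helmet, location) rows are pooled into one sample per pair.
    Returns ``kin_strain`` (long table, len(kinematic)*len(strain) rows)
    and ``strain_strain`` (one row per unordered strain pair), each with a
    ``strong`` flag at r > 0.7.
    """
    missing = [c for c in (*kinematic, *strain) if c not in metric_table.columns]
    if missing:
        raise DataError(f"metric table missing columns {missing}")
    if metric_table[list(kinematic) + list(strain)].isna().any().any():
        raise DataError("metric table contains missing values")

    def pearson(x: str, y: str) -> tuple[float, float]:
        res = stats.pearsonr(metric_table[x], metric_table[y])
        return float(res.statistic), float(res.pvalue)

    ks = []
    for km, sm in itertools.product(kinematic, strain):
        r, p = pearson(km, sm)
        ks.append({"kinematic": km, "strain": sm, "r": r, "p": p,
                   "strong": r > STRONG_R})
    ss = []
    for a, b in itertools.combinations(strain, 2):
        r, p = pearson(a, b)
        ss.append({"a": a, "b": b, "r": r, "p": p, "strong": r > STRONG_R})
    return {"kin_strain": pd.DataFrame(ks), "strain_strain": pd.DataFrame(ss)}
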