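"""Ensemble-level distribution analyses.

Curve-level similarity: Pearson correlation between two helmets' angular-
velocity histories at the same impact location, computed on the three
directional curves concatenated into one 1800-sample vector (600 samples
per axis).  Element-level similarity: Pearson correlation between two
simulations' element-wise strain peaks on the metric's eligible element
set.  Correlation strength is banded as weak (r < 0.3), moderate
(0.3 <= r < 0.7) or strong (r >= 0.7).

Location effects on per-helmet strain summaries are tested with the
Wilcoxon matched-pairs signed-rank test (zeros discarded; exact null for
n <= 25, normal approximation above).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .kinio import KinematicsRecord
from .tractstrain import WM_REGIONS

BAND_EDGES = (0.3, 0.7)


def correlation_band(r: float) -> str:
    """Band a correlation coefficient: weak / moderate / strong."""
    a = abs(r)
    if a < BAND_EDGES[0]:
        return "weak"
    if a < BAND_EDGES[1]:
        return "moderate"
    return "strong"


@dataclass
class CorrelationMatrix:
    """Symmetric helmet-pair Pearson matrix with context metadata."""

    labels: list[str]
    r: np.ndarray
    p: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.r.shape != (k, k) or self.p.shape != (k, k):
            raise DataError("correlation matrix shape mismatch with labels")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle coefficients (one per unordered pair)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.r[iu]

    def bands(self) -> pd.DataFrame:
        rows = [
            {"a": self.labels[i], "b": self.labels[j],
             "r": self.r[i, j], "band": correlation_band(self.r[i, j])}
            for i, j in itertools.combinations(range(len(self.labels)), 2)
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def curve_similarity(rec_a: KinematicsRecord,
                     rec_b: KinematicsRecord) -> tuple[float, float, int]:
    """Pearson r between two helmets' concatenated angular-velocity curves.

    Returns (r, p, n) with n the concatenated sample count (1800 on the
    canonical grid).
    """
    if rec_a.location != rec_b.location:
        raise DataError(
            f"location mismatch: {rec_a.location} vs {rec_b.location}")
    if rec_a.n != rec_b.n or not np.array_equal(rec_a.t, rec_b.t):
        raise DataError("records are not on the same time grid")
    va = rec_a.ang_vel.T.reshape(-1)  # wx..., wy..., wz...
    vb = rec_b.ang_vel.T.reshape(-1)
    res = stats.pearsonr(va, vb)
    return float(res.statistic), float(res.pvalue), va.size


def similarity_heatmap(records: dict[tuple[str, str], KinematicsRecord],
                       location: str,
                       helmets: list[str] | None = None) -> CorrelationMatrix:
    """All-pairs curve similarity among helmets at one impact location."""
    if helmets is None:
        helmets = sorted({h for (h, loc) in records if loc == location})
    for h in helmets:
        if (h, location) not in records:
            raise DataError(f"missing record for helmet {h!r} at {location}")
    k = len(helmets)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        rij, pij, _ = curve_similarity(records[(helmets[i], location)],
                                       records[(helmets[j], location)])
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    return CorrelationMatrix(list(helmets), r, p,
                             context={"location": location, "level": "curve",
                                      "metric": "angular_velocity"})


def eligible_peaks(table: pd.DataFrame, metric: str) -> pd.Series:
    """Valid element peaks on the metric's eligible set (brain / WM)."""
    valid = table["valid"]
    if metric == "MPS":
        mask = valid
    else:
        mask = valid & table["region"].isin(WM_REGIONS)
    return table.loc[mask, metric]


def elementwise_distribution_correlation(table_a: pd.DataFrame,
                                         table_b: pd.DataFrame,
                                         metric: str) -> tuple[float, float]:
    """Pearson r between two simulations' element-wise strain peaks.

    The metric's eligible element-id sets must match exactly (whole brain
    for MPS, white matter for tract metrics).
    """
    pa = eligible_peaks(table_a, metric)
    pb = eligible_peaks(table_b, metric)
    if not pa.index.equals(pb.index):
        diff = len(set(pa.index).symmetric_difference(set(pb.index)))
        raise DataError(
            f"element id sets differ for {metric}: {diff} unmatched elements")
    res = stats.pearsonr(pa.to_numpy(), pb.to_numpy())
    return float(res.statistic), float(res.pvalue)


def elementwise_heatmap(tables: dict[str, pd.DataFrame], metric: str,
                        location: str | None = None,
                        helmets: list[str] | None = None) -> CorrelationMatrix:
    """All-pairs element-level strain-peak correlation for one metric.

    ``tables`` maps helmet id -> StrainPeakTable (all from one location).
    """
    if helmets is None:
        helmets = sorted(tables)
    missing = [h for h in helmets if h not in tables]
    if missing:
        raise DataError(f"missing strain tables for helmets {missing}")
    k = len(helmets)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        rij, pij = elementwise_distribution_correlation(
            tables[helmets[i]], tables[helmets[j]], metric)
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    return CorrelationMatrix(list(helmets), r, p,
                             context={"location": location, "level": "element",
                                      "metric": metric})


def top_fraction_elements(peaks: pd.Series, fraction: float = 0.05) -> set:
    """Ids of the ceil(fraction*n) largest-peak elements; ties broken by id."""
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    n = len(peaks)
    k = int(np.ceil(fraction * n))
    order = peaks.sort_index().sort_values(ascending=False, kind="stable")
    return set(order.index[:k])


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def normalize_field(peaks: pd.Series, summary95: float) -> pd.Series:
    """Element peaks divided by the simulation's 95th-percentile summary."""
    if not summary95 > 0:
        raise DataError("degenerate simulation: 95th-percentile summary <= 0")
    return peaks / summary95


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; all-zero differences report p = 1.
    Exact null distribution for n <= 25 (falling back to the normal
    approximation when ties make the exact method unavailable).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise DataError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def location_effect_test(summaries: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pairwise location comparisons of per-helmet summary values.

    ``summaries`` is indexed by (helmet_id, location) and carries the
    metric column.  Helmets are matched across locations; unmatched helmet
    sets are a data error.  Returns one row per location pair with the
    Wilcoxon statistic, p-value, and a significance flag at p < 0.05.
    """
    wide = summaries[metric].unstack("location")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise DataError(f"unmatched helmet sets across locations: {missing}")
    rows = []
    for la, lb in itertools.combinations(wide.columns, 2):
        stat, p = paired_wilcoxon(wide[la].to_numpy(), wide[lb].to_numpy())
        rows.append({"metric": metric, "loc_a": la, "loc_b": lb,
                     "median_a": float(wide[la].median()),
                     "median_b": float(wide[lb].median()),
                     "statistic": stat, "p": p, "significant": p < 0.05})
    return pd.DataFrame(rows)
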