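"""Group-comparison battery across priority classes.

Spearman rank correlation between variable pairs; Kruskal-Wallis omnibus
tests of a variable across the low/medium/high classes; and, when the
omnibus test is significant, Dunn's pairwise z tests with Holm step-down
adjustment. All p-values are asymptotic (t for Spearman, chi-square for
Kruskal-Wallis, two-sided normal for Dunn), appropriate for the group
sizes these comparisons run on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import StatsInputError

__all__ = ["GroupedSample", "spearman", "kruskal_wallis", "dunn_holm", "class_comparisons"]

ALPHA_DEFAULT = 0.05


@dataclass
class GroupedSample:
    """Values with group labels (at least 2 groups, each non-empty)."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise StatsInputError("values and groups must have equal length")
        labels, counts = np.unique(self.groups, return_counts=True)
        if len(labels) < 2:
            raise StatsInputError("need at least 2 groups")
        if (counts == 0).any():
            raise StatsInputError("every group needs at least one observation")
        self.labels = labels
        self.counts = counts

    def split(self) -> list[np.ndarray]:
        return [self.values[self.groups == g] for g in self.labels]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with its t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (tie-corrected); constant
    input makes the correlation undefined and is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsInputError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsInputError("spearman correlation is undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(sample: GroupedSample) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with the chi-square p-value.

    All-identical observations give H = 0 and p = 1 (no rank variation),
    rather than the undefined 0/0 of the tie-corrected formula.
    """
    if len(sample.values) < len(sample.labels) + 1:
        raise StatsInputError("Kruskal-Wallis needs n >= number of groups + 1")
    parts = sample.split()
    if np.ptp(sample.values) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*parts)
    return float(h), float(p)


def dunn_holm(
    sample: GroupedSample,
    omnibus_p: float | None = None,
    alpha: float = ALPHA_DEFAULT,
    force: bool = False,
) -> pd.DataFrame:
    """Dunn's pairwise z tests with Holm-adjusted p-values.

    z for groups (i, j) uses pooled mid-ranks with tie correction:

        z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)),
        S = (N (N + 1) / 12) - (sum_t (t^3 - t)) / (12 (N - 1)),

    two-sided normal p per pair, Holm step-down over all pairs. Mirrors the
    gating of the analysis design: when an omnibus p is supplied and is not
    below ``alpha``, an empty table is returned unless ``force`` is set.
    """
    if omnibus_p is not None and omnibus_p >= alpha and not force:
        return pd.DataFrame(columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"])
    values, groups = sample.values, sample.groups
    n = len(values)
    ranks = sps.rankdata(values)  # mid-ranks
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    s2 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    for a, b in itertools.combinations(sample.labels, 2):
        na = int((groups == a).sum())
        nb = int((groups == b).sum())
        ra = ranks[groups == a].mean()
        rb = ranks[groups == b].mean()
        se = math.sqrt(s2 * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else (ra - rb) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method="holm")[1]
    return table


def class_comparisons(
    metric_table: pd.DataFrame,
    class_column: str,
    variables: list[str],
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Kruskal-Wallis per variable across classes, Dunn-Holm where significant.

    Returns a long-format report: one omnibus row per variable plus one row
    per Dunn pair when the omnibus test clears ``alpha``.
    """
    rows = []
    for var in variables:
        sub = metric_table[[var, class_column]].dropna()
        sample = GroupedSample(sub[var].to_numpy(), sub[class_column].to_numpy())
        h, p = kruskal_wallis(sample)
        rows.append(
            {"variable": var, "test": "kruskal_wallis", "group_a": None,
             "group_b": None, "statistic": h, "p": p, "p_adjusted": None}
        )
        for _, d in dunn_holm(sample, omnibus_p=p, alpha=alpha).iterrows():
            rows.append(
                {"variable": var, "test": "dunn", "group_a": d["group_a"],
                 "group_b": d["group_b"], "statistic": d["z"], "p": d["p_raw"],
                 "p_adjusted": d["p_adjusted"]}
            )
    return pd.DataFrame.from_records(rows)
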