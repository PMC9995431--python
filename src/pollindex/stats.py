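"""Descriptive statistics, hypothesis tests, correlation and clustering.

Conventions (chosen to match mainstream statistics software output):

* quartiles by linear interpolation between order statistics;
* adjusted Fisher-Pearson skewness and bias-corrected excess kurtosis;
* Shapiro-Wilk for normality (3 <= n <= 5000), alpha = 0.05;
* two-sided Mann-Whitney U with tie correction for group comparison;
* Spearman (average ranks) or Pearson correlation with p-values, with the
  0.7 / 0.4 cuts labelling strong / moderate coefficients;
* agglomerative clustering with Ward's minimum-variance criterion on
  squared Euclidean distances.  Merge heights are reported on the Ward
  *cost* scale (the increase in within-cluster sum of squares at each
  merge), so heights are monotone and sum to the total variance about the
  grand centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .individual import individual_index_table
from .reference import ReferenceTable
from .samples import element_columns

__all__ = [
    "describe",
    "summary_table",
    "normality_test",
    "mann_whitney",
    "CorrelationResult",
    "correlation_matrix",
    "LinkageTree",
    "hca_ward",
    "element_profile_clustering",
]

#: Row order of the descriptive summary (report layout).
SUMMARY_ROWS = ("Min", "Max", "Mean", "SD", "Q1", "Med", "Q3",
                "Skewness", "Kurtosis", "CV", "n")


def describe(values) -> pd.Series:
    """Descriptive summary of one variable.

    Returns n, min, max, mean, SD, quartiles, skewness, excess kurtosis,
    CV (= SD/mean) and the Shapiro-Wilk statistic and p-value.  With n < 2
    the SD-dependent fields are NaN; for a constant sample skewness and
    kurtosis are NaN (undefined) while SD and CV are 0.
    """
    arr = pd.Series(np.asarray(values, dtype=float)).dropna()
    n = len(arr)
    if n == 0:
        raise ValueError("describe: empty sample")
    out = {
        "n": n,
        "Min": float(arr.min()),
        "Max": float(arr.max()),
        "Mean": float(arr.mean()),
        "SD": float(arr.std(ddof=1)) if n >= 2 else np.nan,
        "Q1": float(np.percentile(arr, 25)),
        "Med": float(np.percentile(arr, 50)),
        "Q3": float(np.percentile(arr, 75)),
        "Skewness": float(arr.skew()) if n >= 3 else np.nan,
        "Kurtosis": float(arr.kurt()) if n >= 4 else np.nan,
    }
    if n >= 2 and out["SD"] == 0:  # constant sample: moments undefined
        out["Skewness"] = out["Kurtosis"] = np.nan
    mean, sd = out["Mean"], out["SD"]
    if n < 2:
        out["CV"] = np.nan
    elif sd == 0:
        out["CV"] = 0.0
    else:
        out["CV"] = sd / mean if mean != 0 else np.nan
    if 3 <= n <= 5000 and np.isfinite(sd) and sd > 0:
        w, p = sps.shapiro(arr)
        out["shapiro_W"], out["shapiro_p"] = float(w), float(p)
    else:
        out["shapiro_W"], out["shapiro_p"] = np.nan, np.nan
    return pd.Series(out)


def summary_table(
    samples: pd.DataFrame,
    elements: Sequence[str] | None = None,
    by: str | None = "side",
) -> pd.DataFrame:
    """Per-group descriptive summary of each element column.

    Rows are a MultiIndex (group, statistic) in the report order
    Min..CV, n; columns are elements.  ``by=None`` summarises the whole
    table as a single group called ``"all"``.
    """
    cols = list(elements) if elements else element_columns(samples)
    if not cols:
        raise ValueError("no element columns to summarise")
    groups = [("all", samples)] if by is None or by not in samples.columns else list(samples.groupby(by, sort=True))
    blocks = []
    for gname, grp in groups:
        stats_block = pd.DataFrame({c: describe(grp[c]) for c in cols})
        rows = list(SUMMARY_ROWS) + ["shapiro_W", "shapiro_p"]
        stats_block = stats_block.loc[rows]
        stats_block.index = pd.MultiIndex.from_product([[gname], stats_block.index], names=[by or "group", "statistic"])
        blocks.append(stats_block)
    return pd.concat(blocks)


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value; valid for 3 <= n <= 5000."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if not 3 <= arr.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={arr.size}")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction.

    Returns (U of the first group, p).  Exact p for small untied samples,
    normal approximation otherwise (scipy's ``method="auto"``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise correlation matrix with p-values and strength labels."""

    method: str
    r: pd.DataFrame
    p: pd.DataFrame
    #: True where p > 0.05 (coefficient not significant at the 95% level)
    nonsignificant: pd.DataFrame
    #: "strong" (|r| > 0.7), "moderate" (0.4 < |r| <= 0.7) or "weak"
    strength: pd.DataFrame

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        out = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if self.p.at[a, b] < alpha:
                    out.append((a, b))
        return out


def _strength(r: float) -> str:
    a = abs(r)
    if a > 0.7:
        return "strong"
    if a > 0.4:
        return "moderate"
    return "weak"


def correlation_matrix(
    samples: pd.DataFrame,
    elements: Sequence[str] | None = None,
    method: str = "spearman",
) -> CorrelationResult:
    """Pairwise Spearman (tie-average ranks) or Pearson correlations.

    Requires at least 3 complete rows.  A constant column yields NaN
    coefficients, flagged as non-significant rather than raising.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    cols = list(elements) if elements else element_columns(samples)
    data = samples[cols].dropna()
    if len(data) < 3:
        raise ValueError("correlation needs at least 3 complete rows")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    func = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data[cols[i]], data[cols[j]]
            if x.nunique() < 2 or y.nunique() < 2:
                rij, pij = np.nan, np.nan
            else:
                res = func(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    nonsig = (pdf > 0.05) | rdf.isna()
    strength = rdf.map(lambda v: "undefined" if pd.isna(v) else _strength(v))
    return CorrelationResult(method=method, r=rdf, p=pdf, nonsignificant=nonsig, strength=strength)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge sequence for dendrogram rendering.

    ``linkage`` is a scipy-format matrix whose third column has been
    rescaled to the Ward cost (increase in within-cluster sum of squares,
    i.e. the squared-Euclidean Ward scale).
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    @property
    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Ordered merge steps as (member set A, member set B, height)."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        steps = []
        for step, (a, b, h, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            steps.append((sa, sb, float(h)))
            members[n + step] = sa | sb
        return steps

    def top_split(self) -> tuple[frozenset, frozenset]:
        """Member sets of the two clusters joined by the final merge."""
        a, b, _ = self.merges[-1]
        return a, b

    def to_newick(self) -> str:
        """Newick serialization; branch lengths are height differences."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: str(self.labels[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + step] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
            height[n + step] = h
        return node[n + len(self.linkage) - 1] + ";"

    def to_nested_lists(self) -> list:
        """Merge steps as plain nested lists (text-serializable)."""
        return [[sorted(a), sorted(b), h] for a, b, h in self.merges]

    def plot_dendrogram(self, ax=None):
        """Basic dendrogram via matplotlib (created on demand)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.linkage, labels=list(self.labels), ax=ax)
        ax.set_ylabel("Ward linkage cost (squared Euclidean scale)")
        return ax


def hca_ward(profiles, labels: Sequence[str] | None = None) -> LinkageTree:
    """Ward hierarchical clustering of observation rows.

    ``profiles`` is an observations x features matrix (DataFrame rows are
    labelled observations).  Heights follow the Ward cost scale: each
    merge's height is the increase in total within-cluster sum of squares,
    so the heights are non-decreasing and sum to the total sum of squares
    about the grand centroid.
    """
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in profiles.index]
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    labels = tuple(str(l) for l in labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate observation labels")
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("profiles must be finite")
    Z = hierarchy.linkage(X, method="ward")
    # scipy reports Euclidean-scale heights h with h^2/2 = Ward cost (delta ESS)
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2 / 2.0
    return LinkageTree(linkage=Z, labels=labels)


def element_profile_clustering(
    samples: pd.DataFrame,
    ref: ReferenceTable,
    index: str = "PI",
    side: str | None = None,
    location_col: str = "distance_m",
) -> LinkageTree:
    """Cluster elements by their per-location median index profiles.

    For each element the feature vector is the median of the chosen
    individual index (default PI) at each sampling location (grouped by
    ``location_col``), optionally restricted to one barrier ``side``.
    Elements whose index profiles co-vary along the transect merge early;
    an element with an order-of-magnitude larger index (Cd-like) joins
    last.
    """
    data = samples
    if side is not None:
        if "side" not in data.columns:
            raise ValueError("samples have no 'side' column")
        data = data[data["side"] == side]
        if data.empty:
            raise ValueError(f"no samples on side {side!r}")
    if location_col not in data.columns:
        raise ValueError(f"samples have no location column {location_col!r}")
    data = data.reset_index(drop=True)
    table = individual_index_table(data, ref, index=index)
    # attach location by positional sample order (one table row per sample x element)
    loc_values = data[location_col].to_numpy()
    table["location"] = np.nan
    for _, grp in table.groupby("element", sort=False):
        if len(grp) != len(data):
            raise ValueError("index table rows do not align with samples")
        table.loc[grp.index, "location"] = loc_values
    profiles = (
        table.pivot_table(index="element", columns="location", values="value", aggfunc="median")
        .dropna(axis=1, how="all")
    )
    return hca_ward(profiles, labels=list(profiles.index))
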