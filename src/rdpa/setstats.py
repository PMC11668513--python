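"""Set enrichment and group-comparison statistics.

Over-representation of a feature (RNA binding, phase-separation
capacity, PIP2-binding domains, IDR content, ...) in a protein dataset
against a background proteome is tested with the exact hypergeometric
tail; distributional comparisons of per-IDR metrics between datasets use
pairwise two-sided rank-sum tests with Benjamini-Hochberg correction.
Boxplot-convention summaries (median, quartiles, 1.5xIQR whiskers) and
kernel-density exports support the descriptive figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .proteome_io import DatasetDefinition


@dataclass
class EnrichmentResult:
    dataset: str
    feature: str
    k: int   # dataset members with the feature
    n: int   # dataset size (within background)
    K: int   # background members with the feature
    N: int   # background size
    p_value: float
    direction: str  # enriched | depleted


def hypergeometric_enrichment(
    k: int, K: int, n: int, N: int, tail: str = "upper"
) -> float:
    """Exact hypergeometric tail probability.

    X ~ Hypergeometric(N, K, n): number of feature-carrying members in a
    size-n draw from a population of N with K carriers.  ``upper`` gives
    P(X >= k) (inclusive), ``lower`` gives P(X <= k).
    """
    if not (0 <= k <= n and k <= K and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    dist = stats.hypergeom(N, K, n)
    support_max = min(n, K)
    support_min = max(0, n - (N - K))
    if tail == "upper":
        ks = np.arange(k, support_max + 1)
    else:
        ks = np.arange(support_min, k + 1)
    p = float(dist.pmf(ks).sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def annotate_membership(
    dataset: DatasetDefinition,
    feature_ids: set[str],
    background: DatasetDefinition,
    feature_name: str = "feature",
    tail: str = "upper",
) -> EnrichmentResult:
    """Hypergeometric over/under-representation of a feature list.

    The dataset is expected to lie inside the background; members
    outside it are reported with a warning and dropped from the counts.
    """
    if not dataset.members or not background.members:
        raise ValueError("empty dataset or background")
    outside = dataset.members - background.members
    if outside:
        warnings.warn(
            f"{len(outside)} members of {dataset.name!r} outside background; dropped",
            stacklevel=2,
        )
    ds = dataset.members & background.members
    feat_bg = feature_ids & background.members
    k = len(ds & feat_bg)
    n = len(ds)
    K = len(feat_bg)
    N = len(background.members)
    p = hypergeometric_enrichment(k, K, n, N, tail=tail)
    expected = n * K / N if N else 0.0
    return EnrichmentResult(
        dataset.name, feature_name, k, n, K, N, p,
        "enriched" if k >= expected else "depleted",
    )


def pairwise_wilcoxon_bh(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided rank-sum test for every unordered group pair, BH-adjusted.

    Groups with < 3 values are skipped with a warning.  The exact null
    distribution is used for small untied samples, otherwise the normal
    approximation with continuity correction (scipy ``method="auto"``).
    """
    usable = {}
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            warnings.warn(f"group {name!r} has < 3 values; skipped", stacklevel=2)
            continue
        usable[name] = v
    rows = []
    for a, b in combinations(sorted(usable), 2):
        stat, p = stats.mannwhitneyu(
            usable[a], usable[b], alternative="two-sided", method="auto"
        )
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_value": p})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


def summarize_idr_metrics(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Boxplot-convention summary per group.

    Median, 25th/75th percentiles (linear-interpolation quantiles),
    whiskers at the most extreme values within 1.5xIQR of the box, and
    the count of outliers beyond the whiskers.
    """
    rows = []
    for name in sorted(values_by_group):
        v = np.sort(np.asarray(values_by_group[name], dtype=float))
        if v.size == 0:
            raise ValueError(f"group {name!r} has no values")
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        rows.append(
            {
                "group": name,
                "n": int(v.size),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside[0],
                "whisker_high": inside[-1],
                "n_outliers": int(v.size - inside.size),
            }
        )
    return pd.DataFrame(rows)


def density_export(
    values, grid_points: int = 256, bandwidth: str | float = "scott"
) -> pd.DataFrame:
    """Gaussian-kernel density on a regular grid (for bimodality plots)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.allclose(v, v[0]):
        raise ValueError("need >= 2 distinct values for a density estimate")
    kde = stats.gaussian_kde(v, bw_method=bandwidth)
    pad = 0.1 * (v.max() - v.min())
    x = np.linspace(v.min() - pad, v.max() + pad, grid_points)
    return pd.DataFrame({"x": x, "density": kde(x)})
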