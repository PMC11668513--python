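"""Two-step identification of RNA-dependent PIP2-associated (RDPA) proteins.

The pull-down design has three conditions in triplicate: beads carrying
the wild-type PH domain (WT, high PIP2 affinity), its binding-dead R40A
mutant (background control), and WT after RNase III digestion of
double-stranded RNA.  Rows of the log2 LFQ matrix are

1. filtered to those with a complete set of observed values in at least
   one condition,
2. imputed from a per-sample downshifted normal distribution
   (mean - shift*SD, width*SD), the standard model for intensities
   missing because they fell below the detection limit,
3. tested with an S0-moderated two-sample t statistic whose null
   distribution is obtained by permuting sample labels, yielding a
   threshold-scan false-discovery-rate estimate.

Step 1 (one-sided, WT > R40A) defines the PIP2-associated proteome;
step 2 (two-sided, WT vs WT+RNaseIII, restricted to step-1 hits) splits
it into dsRNA+ (lost after RNase III) and dsRNA- (gained) proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .proteome_io import QuantMatrix


@dataclass
class ImputationParams:
    """Downshifted-normal imputation parameters (in units of the observed
    per-sample SD): draw from Normal(mean - shift*SD, (width*SD)^2)."""

    width: float = 0.3
    shift: float = 1.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


@dataclass
class RdpaCall:
    """Result of the two-step caller."""

    pip2_associated: set[str]
    dsrna_plus: set[str]
    dsrna_minus: set[str]
    step1: pd.DataFrame | None = None
    step2: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        assert self.dsrna_plus <= self.pip2_associated
        assert self.dsrna_minus <= self.pip2_associated
        assert not (self.dsrna_plus & self.dsrna_minus)


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def filter_valid_values(matrix: QuantMatrix) -> QuantMatrix:
    """Keep rows with 100% of valid values in at least one group."""
    labels = matrix.group_labels
    if len(labels) < 2:
        raise ValueError("need >= 2 groups to filter on group completeness")
    keep = np.zeros(matrix.data.shape[0], dtype=bool)
    for lab in labels:
        cols = matrix.group_columns(lab)
        keep |= matrix.data[cols].notna().all(axis=1).to_numpy()
    if not keep.any():
        warnings.warn("no rows pass the valid-value filter", stacklevel=2)
    return QuantMatrix(matrix.data.loc[keep].copy(), matrix.groups)


def impute_downshifted(
    matrix: QuantMatrix,
    params: ImputationParams | None = None,
    per_column: bool = True,
) -> QuantMatrix:
    """Replace missing cells with draws from a downshifted normal.

    Per column (the default, matching per-sample intensity distributions)
    the target is Normal(m_c - shift*s_c, (width*s_c)^2) with m_c, s_c
    the observed mean and SD of that column.  ``per_column=False`` pools
    all observed values into one global distribution.
    """
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    out = matrix.data.copy()
    values = out.to_numpy()
    if per_column:
        for j, col in enumerate(out.columns):
            v = values[:, j]
            obs = v[~np.isnan(v)]
            mask = np.isnan(v)
            if not mask.any():
                continue
            if obs.size < 3:
                raise ValueError(
                    f"column {col!r} has {obs.size} observed values; "
                    "need >= 3 to estimate the imputation distribution"
                )
            m, s = obs.mean(), obs.std(ddof=1)
            v[mask] = rng.normal(m - params.shift * s, params.width * s, mask.sum())
    else:
        obs = values[~np.isnan(values)]
        if obs.size < 3:
            raise ValueError("fewer than 3 observed values in the matrix")
        m, s = obs.mean(), obs.std(ddof=1)
        mask = np.isnan(values)
        values[mask] = rng.normal(m - params.shift * s, params.width * s, mask.sum())
    out.iloc[:, :] = values
    return QuantMatrix(out, matrix.groups)


# ---------------------------------------------------------------------------
# Moderated t statistic
# ---------------------------------------------------------------------------

def s0_statistic(x_a, x_b, s0: float = 0.2) -> float:
    """SAM-style moderated two-sample statistic.

    d = (mean(x_a) - mean(x_b)) / (SE + s0) with SE the pooled
    equal-variance standard error; s0 = 0 recovers the classical t.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    return float(_d_stats(a[None, :], b[None, :], s0)[0])


def _d_stats(A: np.ndarray, B: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise moderated statistic for 2-D (rows x replicates) arrays."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return (ma - mb) / (se + s0)


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def _null_assignments(na: int, nb: int, n_perm: int, two_sided: bool,
                      rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Distinct column relabelings used as the permutation null.

    An assignment names the pooled-column indices labeled as group A.
    The observed assignment is excluded; for a two-sided statistic the
    complement of an assignment yields the identical |d|, so unordered
    splits are enumerated once (and the observed split excluded).
    """
    n = na + nb
    observed = tuple(range(na))
    if two_sided and na == nb:
        # complementary assignments give identical |d|: enumerate one
        # representative per unordered split (the side containing column 0)
        pool = [
            c for c in combinations(range(n), na)
            if 0 in c and c != observed
        ]
    else:
        pool = [c for c in combinations(range(n), na) if c != observed]
    total = len(pool)
    if n_perm >= total:
        return pool
    idx = rng.choice(len(pool), size=n_perm, replace=False)
    return [pool[i] for i in sorted(idx)]


def permutation_fdr(
    matrix: QuantMatrix,
    group_a: str,
    group_b: str,
    s0: float = 0.2,
    alternative: str = "two_sided",
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """S0-moderated test of group_a vs group_b with permutation FDR.

    For every candidate threshold t* on the score (signed d for the
    one-sided test of group_a > group_b, |d| for two-sided), the FDR is
    estimated as the mean over label permutations of the number of
    permuted scores beyond t*, divided by the number of observed scores
    beyond t* (pi0 fixed at 1, conservative).  Each protein's q-value is
    the minimum estimated FDR over the thresholds at which it is called.

    Returns a DataFrame indexed by protein id with columns ``mean_diff``,
    ``d_stat``, ``q_value``, ``significant`` and ``direction``.
    """
    if alternative not in ("one_sided", "two_sided"):
        raise ValueError("alternative must be 'one_sided' or 'two_sided'")
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if group_a == group_b:
        raise ValueError("group labels must differ")
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    sub = matrix.data[cols_a + cols_b]
    if sub.isna().any().any():
        raise ValueError("matrix contains missing values; filter and impute first")
    X = sub.to_numpy()
    na, nb = len(cols_a), len(cols_b)
    two_sided = alternative == "two_sided"
    rng = np.random.default_rng(seed)

    d_obs = _d_stats(X[:, :na], X[:, na:], s0)
    score_obs = np.abs(d_obs) if two_sided else d_obs

    assignments = _null_assignments(na, nb, n_perm, two_sided, rng)
    all_idx = set(range(na + nb))
    perm_scores = np.empty((len(assignments), X.shape[0]))
    for i, assign in enumerate(assignments):
        ia = list(assign)
        ib = sorted(all_idx - set(assign))
        d = _d_stats(X[:, ia], X[:, ib], s0)
        perm_scores[i] = np.abs(d) if two_sided else d

    # threshold scan: candidate thresholds are the observed scores
    order = np.argsort(-score_obs, kind="stable")
    thresholds = score_obs[order]
    flat = np.sort(perm_scores.ravel())
    # number of permuted scores >= t, averaged over permutations
    n_perm_ge = flat.size - np.searchsorted(flat, thresholds, side="left")
    mean_perm = n_perm_ge / len(assignments)
    sorted_obs = np.sort(score_obs)
    n_obs_ge = score_obs.size - np.searchsorted(sorted_obs, thresholds, side="left")
    fdr = np.minimum(1.0, mean_perm / np.maximum(n_obs_ge, 1))
    # q = min FDR over thresholds at which the protein is called (t <= score)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    mean_diff = X[:, :na].mean(axis=1) - X[:, na:].mean(axis=1)
    res = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "d_stat": d_obs,
            "q_value": q,
            "significant": q < alpha,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        },
        index=sub.index,
    )
    return res


# ---------------------------------------------------------------------------
# Two-step caller
# ---------------------------------------------------------------------------

def call_rdpa(
    wt_vs_r40a: QuantMatrix,
    wt_vs_rnase: QuantMatrix,
    enriched_group: str = "WT",
    control_group: str = "R40A",
    treated_group: str = "WT_RNaseIII",
    s0: float = 0.2,
    alpha: float = 0.05,
    n_perm: int = 250,
    seed: int | None = None,
    impute_params: ImputationParams | None = None,
) -> RdpaCall:
    """Run the two-step RDPA identification.

    Step 1: one-sided test ``enriched_group`` > ``control_group`` on the
    filtered+imputed first matrix; significant proteins form the
    PIP2-associated set.  Step 2: two-sided test of ``enriched_group``
    vs ``treated_group`` on the second matrix restricted to the step-1
    set; proteins significantly lower after treatment are dsRNA+
    (positively RNA-regulated), significantly higher are dsRNA-.
    """
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    base = impute_params or ImputationParams()

    m1 = filter_valid_values(wt_vs_r40a.subset_groups([enriched_group, control_group]))
    m1 = impute_downshifted(m1, ImputationParams(base.width, base.shift, seeds[0]))
    step1 = permutation_fdr(
        m1, enriched_group, control_group, s0=s0,
        alternative="one_sided", n_perm=n_perm, alpha=alpha, seed=seeds[1],
    )
    pip2 = set(step1.index[step1["significant"]])
    if not pip2:
        warnings.warn("step 1 found no PIP2-associated proteins", stacklevel=2)
        return RdpaCall(set(), set(), set(), step1, None)

    m2 = wt_vs_rnase.subset_groups([enriched_group, treated_group]).subset_rows(pip2)
    m2 = filter_valid_values(m2)
    m2 = impute_downshifted(m2, ImputationParams(base.width, base.shift, seeds[2]))
    step2 = permutation_fdr(
        m2, enriched_group, treated_group, s0=s0,
        alternative="two_sided", n_perm=n_perm, alpha=alpha, seed=seeds[3],
    )
    sig = step2["significant"]
    dsrna_plus = set(step2.index[sig & (step2["mean_diff"] > 0)])
    dsrna_minus = set(step2.index[sig & (step2["mean_diff"] < 0)])
    return RdpaCall(pip2, dsrna_plus, dsrna_minus, step1, step2)


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

def replicate_qc_report(matrix: QuantMatrix) -> pd.DataFrame:
    """Per-sample QC used to spot outlier replicates: median observed
    intensity and mean pairwise Pearson correlation with the other
    samples (pairwise-complete).  Removal is a manual decision."""
    med = matrix.data.median()
    corr = matrix.data.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, np.nan)
    return pd.DataFrame(
        {
            "group": [matrix.groups[c] for c in matrix.data.columns],
            "n_valid": matrix.data.notna().sum(),
            "median_intensity": med,
            "mean_corr": corr.mean(axis=1, skipna=True),
        }
    )
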