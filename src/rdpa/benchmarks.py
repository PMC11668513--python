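"""Ground-truth recovery benchmarks run on the synthetic generators.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage, and measures recovery against the planted truth.  They
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discovery import ImputationParams, call_rdpa, impute_downshifted, permutation_fdr
from .imaging import VolumePair, coloc_coefficients, count_foci, rotation_null
from .physchem import classify_idr_charge, isoelectric_point
from .proteome_io import QuantMatrix
from .simulate import (
    DE_RICH,
    KR_RICH,
    ImageConfig,
    PulldownConfig,
    generate_image_stack,
    generate_pulldown_experiment,
    sample_sequence,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def two_step_recovery(
    seeds, config: PulldownConfig | None = None
) -> tuple[float, float]:
    """Mean recall and false-discovery proportion of planted dsRNA+
    proteins over the given seeds (full filter/impute/two-step run)."""
    recalls, fdps = [], []
    for seed in seeds:
        matrix, truth = generate_pulldown_experiment(config, seed=seed)
        call = call_rdpa(matrix, matrix, seed=seed)
        plus = call.dsrna_plus
        recalls.append(len(plus & truth.dsrna_plus) / len(truth.dsrna_plus))
        fdps.append(len(plus - truth.dsrna_plus) / max(len(plus), 1))
    return float(np.mean(recalls)), float(np.mean(fdps))


def null_significance_rate(
    seeds, n_rows: int = 1000, alpha: float = 0.05
) -> float:
    """Fraction of rows called significant on fully null matrices."""
    n_sig = n_tot = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        cols = [f"S{i}" for i in range(6)]
        groups = {c: ("A" if i < 3 else "B") for i, c in enumerate(cols)}
        m = QuantMatrix(
            pd.DataFrame(
                rng.normal(25, 1, (n_rows, 6)),
                index=[f"P{i}" for i in range(n_rows)],
                columns=cols,
            ),
            groups,
        )
        res = permutation_fdr(m, "A", "B", alternative="one_sided",
                              alpha=alpha, seed=seed)
        n_sig += int(res.significant.sum())
        n_tot += n_rows
    return n_sig / n_tot


def imputation_moments(
    seed: int, n_missing: int = 10_000, mean: float = 25.0, sd: float = 2.0
) -> tuple[float, float]:
    """Sample mean and SD of imputed draws for a column with the given
    observed moments (engineered exactly)."""
    z = np.arange(100, dtype=float)
    obs = mean + sd * (z - z.mean()) / z.std(ddof=1)
    col = np.concatenate([obs, np.full(n_missing, np.nan)])
    m = QuantMatrix(
        pd.DataFrame({"S1": col}, index=[f"P{i}" for i in range(col.size)]),
        {"S1": "A"},
    )
    out = impute_downshifted(m, ImputationParams(seed=seed))
    imputed = out.data.to_numpy()[100:, 0]
    return float(imputed.mean()), float(imputed.std(ddof=1))


def charge_class_recovery(seed: int, n: int = 1000, length: int = 40) -> tuple[float, float]:
    """% of D/E-rich synthetic IDRs classified acidic, and of K/R-rich
    ones classified basic."""
    rng = np.random.default_rng(seed)
    n_acid = n_base = 0
    for _ in range(n):
        acid = "".join(sample_sequence(rng, length, DE_RICH))
        base = "".join(sample_sequence(rng, length, KR_RICH))
        n_acid += classify_idr_charge(isoelectric_point(acid)) == "acidic"
        n_base += classify_idr_charge(isoelectric_point(base)) == "basic"
    return 100.0 * n_acid / n, 100.0 * n_base / n


def foci_count_recovery(seed: int, n_nuclei: int = 50, max_count: int = 20):
    """Exact-recovery rate and max absolute error of planted foci counts
    drawn uniformly from 0..max_count over ``n_nuclei`` synthetic nuclei."""
    seeds = _child_seeds(seed, n_nuclei + 1)
    rng = np.random.default_rng(seeds[0])
    exact = 0
    max_err = 0
    for i in range(n_nuclei):
        planted = int(rng.integers(0, max_count + 1))
        nucleus = generate_image_stack(ImageConfig(n_foci=planted), seed=seeds[i + 1])
        count, _ = count_foci(nucleus.target, nucleus.mask)
        exact += count == planted
        max_err = max(max_err, abs(count - planted))
    return 100.0 * exact / n_nuclei, max_err


def rotation_null_pearson(seed: int) -> float:
    """Pearson of the rotation null on two channels with independent foci."""
    nucleus = generate_image_stack(
        ImageConfig(n_foci=8, coloc_fraction=0.0, noise_sd=0.15), seed=seed
    )
    pair = VolumePair(nucleus.target, nucleus.second, nucleus.mask)
    return rotation_null(pair, 90).pearson


def coloc_identity(seed: int):
    """Coefficients for a channel paired with itself (all must be 1)."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 10, (16, 32, 32))
    return coloc_coefficients(VolumePair(v, v.copy()))
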