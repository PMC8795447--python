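"""Null simulations for the error calibration of the statistical machinery.

Each helper simulates normal null data and returns the empirical type-I /
family-wise error of the corresponding test.  The gate and Tukey helpers
use vectorized decision rules that are mathematically identical to the
per-call API (rejecting at p < alpha is equivalent to exceeding the fixed
critical value, since the p-value is a monotone function of the statistic);
that equivalence is asserted in the unit tests.  The Dunnett helper loops
the real test because its adjusted p depends on the multivariate-t family
as a whole.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .selectivity import dunnett_test

__all__ = [
    "gate_type1_error",
    "tukey_fwer",
    "dunnett_fwer",
    "fit_recovery",
]


def gate_type1_error(
    n_sim: int, n: int = 3, alpha: float = 0.05, seed: int = 0, test: str = "student"
) -> float:
    """Rejection rate of the one-sided recruitment gate under the null."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_sim, n))
    y = rng.normal(size=(n_sim, n))
    res = stats.ttest_ind(
        x, y, axis=1, equal_var=(test == "student"), alternative="greater"
    )
    return float(np.mean(res.pvalue < alpha))


def tukey_fwer(
    n_sim: int, k: int = 4, n: int = 3, alpha: float = 0.05, seed: int = 0
) -> float:
    """Family-wise error of the all-pairs studentized-range test under the null.

    Balanced design: any adjusted p < alpha ⟺ the largest pairwise q exceeds
    the studentized-range critical value, evaluated once.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n_sim, k, n))
    means = g.mean(axis=2)
    mse = g.var(axis=2, ddof=1).mean(axis=1)
    df = k * (n - 1)
    q_max = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
    crit = stats.studentized_range.ppf(1.0 - alpha, k, df)
    return float(np.mean(q_max > crit))


def dunnett_fwer(
    n_sim: int,
    k: int = 4,
    n: int = 3,
    alpha: float = 0.05,
    sidedness: str = "two-sided",
    seed: int = 0,
) -> float:
    """Family-wise error of the many-to-one test under the null (real API)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        groups = {f"g{i}": rng.normal(size=n) for i in range(k)}
        control = rng.normal(size=n)
        pvals = dunnett_test(groups, control=control, sidedness=sidedness)
        if min(pvals.values()) < alpha:
            hits += 1
    return hits / n_sim


def fit_recovery(
    n_seeds: int,
    seed: int = 0,
    log_ec50: float = -7.0,
    noise_cv: float = 0.05,
    n_experiments: int = 3,
) -> np.ndarray:
    """Absolute logEC50 errors over repeated synthetic plate round trips.

    Each seed generates one single-condition plate (7 concentrations spanning
    the EC50, matched vehicle and mock wells, multiplicative channel noise),
    reduces it and fits per-experiment curves; returns |fitted − planted|.
    """
    from .doseresponse import ConcentrationSeries, fit_concentration_response
    from .reduction import reduce_plate
    from .synth import AssayDesign, ConditionTruth, generate_bret_dataset

    conc = tuple(10.0 ** np.arange(log_ec50 - 3, log_ec50 + 4)[: 7])
    design = AssayDesign(
        conditions=("cond",),
        concentrations=(0.0,) + conc,
        n_replicates=n_experiments,
    )
    truth = ConditionTruth(log_ec50=log_ec50, noise_cv=noise_cv, top_fold=1.5)
    errors = np.empty(n_seeds)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) >> 1
    for i, s in enumerate(child_seeds):
        wells = generate_bret_dataset(design, {"cond": truth}, seed=int(s))
        reduced = reduce_plate(wells)
        sample = reduced[reduced["role"] == "sample"]
        piv = sample.pivot_table(
            index="replicate", columns="concentration_M", values="net_fold_change"
        )
        series = ConcentrationSeries(
            concentrations_M=piv.columns.to_numpy(dtype=float),
            responses=piv.to_numpy(dtype=float),
        )
        fit = fit_concentration_response(series, per_experiment=True)
        errors[i] = abs(fit.log_ec50 - log_ec50)
    return errors
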