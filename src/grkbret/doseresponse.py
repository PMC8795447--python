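"""Gated concentration–response analysis and DMR concentration–effect analysis.

A condition is fitted only if it passes the functional-recruitment gate: the
responses at the highest tested ligand concentration must be significantly
larger than the vehicle responses (one-sided two-sample t at alpha).  The
concentration–response model is the standard log-logistic

    response(c) = bottom + (top - bottom) / (1 + 10^((logEC50 - log10 c) * h))

with the Hill slope fixed at 1 by default.  EC50 uncertainty defaults to the
across-experiment SEM of per-experiment fits (one curve per independent
experiment), matching the mean-of-n-experiments reporting convention; a
pooled fit with the asymptotic SEM is available.

Label-free dynamic mass redistribution (DMR) traces are summarised by the
trapezoidal area under the empty-vector-corrected wavelength-shift curve
over [0, 1800] s, normalised to a reference response, and fitted with the
bottom constrained to zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .selectivity import anova_oneway, dunnett_test
from .types import (
    ConfigurationError,
    DataError,
    DegenerateFitError,
    DmrResponse,
    FitResult,
    GateResult,
    sem,
)

__all__ = [
    "ConcentrationSeries",
    "gate_functional_recruitment",
    "hill_logistic",
    "fit_concentration_response",
    "normalize_to_max",
    "compare_potency",
    "dmr_auc",
    "dmr_concentration_effect",
]


@dataclass
class ConcentrationSeries:
    """Replicated responses on a shared concentration grid.

    ``responses`` has shape (n_experiments, n_concentrations); NaN marks a
    missing cell.  Vehicle (c = 0) entries are allowed and are used only for
    gating/normalisation, never for fitting.
    """

    concentrations_M: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[1] != self.concentrations_M.size:
            raise DataError("responses and concentrations have mismatched shapes")
        if np.any(self.concentrations_M < 0):
            raise DataError("concentrations must be non-negative")

    @property
    def nonzero_mask(self) -> np.ndarray:
        return self.concentrations_M > 0


def gate_functional_recruitment(
    top_dose: np.ndarray,
    vehicle: np.ndarray,
    alpha: float = 0.05,
    test: str = "student",
) -> GateResult:
    """Test for a significant response increase at the top concentration.

    One-sided two-sample t of top-dose > vehicle.  ``test="student"`` (pooled
    variance, the default — exact size at small n under equal variances) or
    ``test="welch"``.  Downstream fitting refuses conditions that fail.
    """
    top_dose = np.asarray(top_dose, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if top_dose.size < 2 or vehicle.size < 2:
        raise DataError("gate requires at least 2 replicates per group")
    if test not in ("student", "welch"):
        raise ConfigurationError(f"unknown gate test {test!r}")
    diff = float(top_dose.mean() - vehicle.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            top_dose, vehicle, equal_var=(test == "student"), alternative="greater"
        )
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant
        p = 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
    return GateResult(
        is_functional=bool(p < alpha and diff > 0),
        p_value=p,
        test_label=f"one-sided {test} t",
    )


def hill_logistic(
    log_c: np.ndarray, bottom: float, top: float, log_ec50: float, hill_slope: float = 1.0
) -> np.ndarray:
    """Log-logistic concentration-response model."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log_c) * hill_slope))


def _fit_single(
    log_c: np.ndarray,
    y: np.ndarray,
    fix_slope: bool,
    fix_bottom: float | None,
    flat_tol: float,
):
    """Least-squares fit of one curve; returns (params dict, converged)."""
    span = float(y.max() - y.min())
    scale = max(abs(float(y.mean())), 1.0)
    if span <= flat_tol * scale:
        raise DegenerateFitError("responses are flat within tolerance; no EC50 is defined")
    # initial guesses: plateaus from the data, EC50 at the half-maximal response
    b0 = float(y.min()) if fix_bottom is None else fix_bottom
    t0 = float(y.max())
    half = b0 + 0.5 * (t0 - b0)
    le0 = float(log_c[int(np.argmin(np.abs(y - half)))])
    lo, hi = float(log_c.min()) - 4.0, float(log_c.max()) + 4.0

    if fix_bottom is None and fix_slope:
        f = lambda x, b, t, le: hill_logistic(x, b, t, le, 1.0)
        p0, bounds = [b0, t0, le0], ([-np.inf, -np.inf, lo], [np.inf, np.inf, hi])
        names = ("bottom", "top", "log_ec50")
    elif fix_bottom is None:
        f = hill_logistic
        p0 = [b0, t0, le0, 1.0]
        bounds = ([-np.inf, -np.inf, lo, 0.05], [np.inf, np.inf, hi, 10.0])
        names = ("bottom", "top", "log_ec50", "hill_slope")
    elif fix_slope:
        f = lambda x, t, le: hill_logistic(x, fix_bottom, t, le, 1.0)
        p0, bounds = [t0, le0], ([-np.inf, lo], [np.inf, hi])
        names = ("top", "log_ec50")
    else:
        f = lambda x, t, le, h: hill_logistic(x, fix_bottom, t, le, h)
        p0 = [t0, le0, 1.0]
        bounds = ([-np.inf, lo, 0.05], [np.inf, hi, 10.0])
        names = ("top", "log_ec50", "hill_slope")
    try:
        popt, pcov = optimize.curve_fit(
            f, log_c, y, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, optimize.OptimizeWarning):
        return dict(zip(names, p0)), None, False
    return dict(zip(names, popt)), pcov, bool(converged)


def fit_concentration_response(
    series: ConcentrationSeries,
    gate: GateResult | None = None,
    fix_slope: bool = True,
    fix_bottom: float | None = None,
    per_experiment: bool = True,
    flat_tol: float = 1e-9,
) -> FitResult:
    """Fit the log-logistic model to a concentration series.

    Requires ≥ 4 distinct non-zero concentrations.  When ``per_experiment``
    (default), each experiment (row) is fitted separately and the reported
    logEC50 is the across-experiment mean ± SEM; otherwise all points are
    pooled and the asymptotic SEM from the covariance matrix is reported.
    Supplying a failed gate raises: non-functional conditions have no curve.
    """
    if gate is not None and not gate.is_functional:
        raise ConfigurationError(
            "condition failed the functional-recruitment gate; fitting refused"
        )
    mask = series.nonzero_mask
    conc = series.concentrations_M[mask]
    if np.unique(conc).size < 4:
        raise DataError("need at least 4 distinct non-zero concentrations to fit")
    log_c = np.log10(conc)
    resp = series.responses[:, mask]

    if per_experiment and resp.shape[0] > 1:
        fits = []
        for row in resp:
            ok = np.isfinite(row)
            if ok.sum() < 4:
                continue
            params, _, conv = _fit_single(log_c[ok], row[ok], fix_slope, fix_bottom, flat_tol)
            if conv:
                fits.append(params)
        if not fits:
            return FitResult(
                bottom=float("nan"), top=float("nan"), log_ec50=float("nan"),
                log_ec50_sem=float("nan"), hill_slope=1.0, converged=False,
            )
        les = [f["log_ec50"] for f in fits]
        mean_le = float(np.mean(les))
        bottom = float(np.mean([f.get("bottom", fix_bottom) for f in fits]))
        top = float(np.mean([f["top"] for f in fits]))
        slope = float(np.mean([f.get("hill_slope", 1.0) for f in fits]))
        extrap = not (log_c.min() <= mean_le <= log_c.max())
        return FitResult(
            bottom=bottom, top=top, log_ec50=mean_le,
            log_ec50_sem=sem(les), hill_slope=slope, converged=True,
            extrapolated=extrap, n_experiments=len(fits),
            per_experiment_log_ec50=tuple(les),
        )

    flat = resp.ravel()
    x = np.tile(log_c, resp.shape[0])
    ok = np.isfinite(flat)
    params, pcov, conv = _fit_single(x[ok], flat[ok], fix_slope, fix_bottom, flat_tol)
    le = params["log_ec50"]
    le_sem = float("nan")
    if conv and pcov is not None:
        names = list(params)
        le_sem = float(np.sqrt(pcov[names.index("log_ec50"), names.index("log_ec50")]))
    return FitResult(
        bottom=float(params.get("bottom", fix_bottom if fix_bottom is not None else np.nan)),
        top=float(params["top"]),
        log_ec50=float(le),
        log_ec50_sem=le_sem,
        hill_slope=float(params.get("hill_slope", 1.0)),
        converged=conv,
        extrapolated=not (log_c.min() <= le <= log_c.max()),
        n_experiments=resp.shape[0],
    )


def normalize_to_max(series: ConcentrationSeries) -> ConcentrationSeries:
    """Scale a series so its maximal per-concentration mean response is 100 %."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(series.responses, axis=0)
    peak = float(np.nanmax(means))
    if not peak > 0:
        raise DataError("maximal mean response is not positive; cannot normalise")
    return ConcentrationSeries(
        concentrations_M=series.concentrations_M.copy(),
        responses=series.responses / peak * 100.0,
    )


def compare_potency(
    log_ec50_sets: dict,
    reference_condition: str,
    alpha: float = 0.05,
) -> dict:
    """Compare per-experiment logEC50 values against a reference condition.

    One-way ANOVA over all conditions followed by two-sided many-to-one
    (Dunnett) comparisons against the reference.  Returns
    ``{"anova_p": p, "adjusted_p": {condition: p}}``.
    """
    if reference_condition not in log_ec50_sets:
        raise ConfigurationError(f"reference condition {reference_condition!r} missing")
    _, anova_p = anova_oneway(*log_ec50_sets.values())
    others = {k: v for k, v in log_ec50_sets.items() if k != reference_condition}
    adj = dunnett_test(
        others, control=np.asarray(log_ec50_sets[reference_condition], dtype=float),
        sidedness="two-sided",
    )
    return {"anova_p": float(anova_p), "adjusted_p": adj}


def dmr_auc(time_s: np.ndarray, corrected_shift_pm: np.ndarray) -> DmrResponse:
    """Trapezoidal area under a corrected DMR trace over [0, 1800] s."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(corrected_shift_pm, dtype=float)
    if t.size != y.size:
        raise DataError("time and shift series differ in length")
    if t.min() > 0.0 or t.max() < 1800.0:
        raise DataError(
            f"trace [{t.min():g}, {t.max():g}] s does not cover the AUC window [0, 1800] s"
        )
    grid = np.unique(np.concatenate([t[(t >= 0) & (t <= 1800)], [0.0, 1800.0]]))
    vals = np.interp(grid, t, y)
    return DmrResponse(auc=float(np.trapezoid(vals, grid)))


def dmr_concentration_effect(
    aucs: dict,
    reference_auc: float,
    per_experiment: bool = True,
):
    """Normalise per-concentration AUCs to a reference and fit with bottom = 0.

    ``aucs`` maps concentration (mol/L) to replicate AUC values; effects are
    100 × AUC / reference.  Returns ``(effects, FitResult)`` where effects is
    a dict concentration → normalised replicate effects.
    """
    if not reference_auc > 0:
        raise DataError("reference AUC must be positive")
    conc = np.array(sorted(c for c in aucs if c > 0), dtype=float)
    effects = {
        float(c): (np.asarray(aucs[c], dtype=float) / reference_auc * 100.0)
        for c in sorted(aucs)
    }
    n_rep = min(len(v) for v in effects.values())
    resp = np.vstack([
        effects[float(c)][:n_rep] for c in conc
    ]).T  # (n_experiments, n_conc)
    series = ConcentrationSeries(concentrations_M=conc, responses=resp)
    fit = fit_concentration_response(
        series, fix_slope=True, fix_bottom=0.0, per_experiment=per_experiment
    )
    return effects, fit
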