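"""Reduction of dual-channel BRET well traces to Δ net BRET fold changes.

The chain, applied per well:

1. ratio[t] = acceptor[t] / donor[t]
2. mock correction: subtract the (per-timepoint) mean ratio of the matched
   mock-labelled wells — removes acceptor bleed-through / labelling background
3. window means: average the corrected ratio over the pre-stimulation
   baseline window and the post-stimulation window; their quotient is the
   per-well fold change
4. vehicle normalisation: divide by the fold change of the matched vehicle
   wells of the same condition and experimental session — the Δ net BRET
   fold change, the study's core statistic
5. percent change: (Δ net fold change − 1) × 100

``reduce_plate`` runs the whole chain over a long-format plate table;
``baseline_bars`` normalises per-condition baseline/stimulated levels to a
reference condition (the kinase-null control) for pre-coupling analysis.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import (
    ConfigurationError,
    CorrectedMeasurement,
    DataError,
    DegenerateWellError,
    NetFoldChange,
    WellTrace,
    sem,
)

__all__ = [
    "bret_ratio",
    "mock_correct",
    "window_means",
    "net_fold_change",
    "percent_change",
    "reduce_plate",
    "baseline_bars",
]


def bret_ratio(trace: WellTrace) -> np.ndarray:
    """Per-timepoint acceptor/donor ratio of one well."""
    if np.any(trace.donor <= 0):
        bad = int(np.argmax(trace.donor <= 0))
        raise DataError(
            f"well {trace.meta.well_id}: non-positive donor intensity at "
            f"timepoint index {bad}"
        )
    return trace.acceptor / trace.donor


def mock_correct(
    sample_ratio: np.ndarray,
    mock_ratios: Sequence[np.ndarray],
    mode: str = "per_timepoint",
) -> np.ndarray:
    """Subtract the mock-labelling background from a ratio series.

    ``mode="per_timepoint"`` subtracts the across-mock mean at each timepoint;
    ``mode="scalar"`` subtracts one scalar (the grand mean of all mock ratios),
    for the case where only a window-averaged mock value is trusted.
    """
    if len(mock_ratios) == 0:
        raise ConfigurationError("mock correction requires at least one mock well")
    sample_ratio = np.asarray(sample_ratio, dtype=float)
    stack = []
    for m in mock_ratios:
        m = np.asarray(m, dtype=float)
        if m.shape != sample_ratio.shape:
            raise DataError(
                "mock ratio series does not share the sample time base "
                f"({m.shape} vs {sample_ratio.shape})"
            )
        stack.append(m)
    mocks = np.vstack(stack)
    if mode == "per_timepoint":
        return sample_ratio - mocks.mean(axis=0)
    if mode == "scalar":
        return sample_ratio - float(mocks.mean())
    raise ConfigurationError(f"unknown mock correction mode {mode!r}")


def window_means(
    time: np.ndarray,
    corrected: np.ndarray,
    stimulation_time_s: float,
    baseline_duration_s: float,
    stim_duration_s: float,
) -> CorrectedMeasurement:
    """Average a corrected ratio series over the baseline and stimulated windows.

    Baseline window: [stimulation − baseline_duration, stimulation); stimulated
    window: (stimulation, stimulation + stim_duration].  The sample at the
    stimulation timepoint itself is excluded from both windows (injection
    artefact).
    """
    time = np.asarray(time, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    base_mask = (time >= stimulation_time_s - baseline_duration_s) & (
        time < stimulation_time_s
    )
    stim_mask = (time > stimulation_time_s) & (
        time <= stimulation_time_s + stim_duration_s
    )
    if base_mask.sum() < 2 or stim_mask.sum() < 2:
        raise DataError(
            f"need at least 2 samples per window, got {int(base_mask.sum())} "
            f"baseline / {int(stim_mask.sum())} stimulated"
        )
    baseline_mean = float(corrected[base_mask].mean())
    stimulated_mean = float(corrected[stim_mask].mean())
    if baseline_mean <= 0:
        raise DegenerateWellError(
            f"corrected baseline mean {baseline_mean:.4g} is not positive"
        )
    return CorrectedMeasurement(baseline_mean=baseline_mean, stimulated_mean=stimulated_mean)


def net_fold_change(
    sample: CorrectedMeasurement,
    vehicle_folds: Sequence[float],
    condition: str = "",
    concentration_M: float = float("nan"),
    replicate: int = 0,
) -> NetFoldChange:
    """Divide a sample fold change by the mean vehicle fold change."""
    if len(vehicle_folds) == 0:
        raise ConfigurationError("vehicle normalisation requires at least one vehicle well")
    vmean = float(np.mean(vehicle_folds))
    if vmean <= 0:
        raise DataError(f"mean vehicle fold change {vmean:.4g} is not positive")
    return NetFoldChange(
        value=sample.fold_change / vmean,
        condition=condition,
        concentration_M=concentration_M,
        replicate=replicate,
    )


def percent_change(net: NetFoldChange | float) -> float:
    """Δ net BRET change in per cent: (fold change − 1) × 100."""
    value = net.value if isinstance(net, NetFoldChange) else float(net)
    return (value - 1.0) * 100.0


def _group_wells(wells: Iterable[WellTrace]):
    by_key: dict = {}
    for w in wells:
        by_key.setdefault((w.meta.condition, w.meta.replicate), []).append(w)
    return by_key


def reduce_plate(
    wells: Iterable[WellTrace],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Run the full reduction over a set of well traces.

    Mock correction uses the mock wells of the same (condition, replicate)
    session when present; vehicle normalisation uses the vehicle wells of the
    same session, so each vehicle well normalised against its own session is
    exactly 1 when the session holds a single vehicle well.

    Returns a tidy per-well table with columns: condition, role,
    concentration_M, replicate, baseline_mean, stimulated_mean, fold_change,
    net_fold_change, pct_change.
    """
    config = config or RunConfig()
    rows = []
    for (condition, replicate), group in sorted(_group_wells(wells).items()):
        mocks = [w for w in group if w.meta.role == "mock"]
        mock_ratios = [bret_ratio(m) for m in mocks]
        measured: list[tuple[WellTrace, CorrectedMeasurement]] = []
        for w in group:
            if w.meta.role == "mock":
                continue
            ratio = bret_ratio(w)
            if mock_ratios:
                corrected = mock_correct(ratio, mock_ratios, mode=config.mock_mode)
            else:
                corrected = ratio
            cm = window_means(
                w.time,
                corrected,
                w.meta.stimulation_time_s,
                config.baseline_duration_s,
                config.stim_duration_s,
            )
            measured.append((w, cm))
        vehicle_folds = [
            cm.fold_change for w, cm in measured if w.meta.role == "vehicle"
        ]
        for w, cm in measured:
            if vehicle_folds:
                nfc = net_fold_change(
                    cm, vehicle_folds, condition, w.meta.concentration_M, replicate
                ).value
            else:
                nfc = float("nan")
            rows.append(
                {
                    "well_id": w.meta.well_id,
                    "condition": condition,
                    "role": w.meta.role,
                    "concentration_M": w.meta.concentration_M,
                    "replicate": replicate,
                    "baseline_mean": cm.baseline_mean,
                    "stimulated_mean": cm.stimulated_mean,
                    "fold_change": cm.fold_change,
                    "net_fold_change": nfc,
                    "pct_change": (nfc - 1.0) * 100.0 if np.isfinite(nfc) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def baseline_bars(
    reduced: pd.DataFrame,
    reference_condition: str,
) -> pd.DataFrame:
    """Normalise per-condition baseline/stimulated levels to a reference.

    The reference is the kinase-null + empty-vector condition; its mean
    baseline maps to 1 by construction.  Baselines are ligand-independent, so
    sample and vehicle wells are pooled per (condition, replicate) first;
    mean ± SEM is then taken over independent replicates.

    Returns one row per condition: n, baseline_norm_mean, baseline_norm_sem,
    stimulated_norm_mean, stimulated_norm_sem.
    """
    if reference_condition not in set(reduced["condition"]):
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not present"
        )
    per_rep = (
        reduced.groupby(["condition", "replicate"])[["baseline_mean", "stimulated_mean"]]
        .mean()
        .reset_index()
    )
    ref = float(
        per_rep.loc[per_rep["condition"] == reference_condition, "baseline_mean"].mean()
    )
    if ref <= 0:
        raise DataError("reference baseline mean is not positive")
    per_rep = per_rep.assign(
        baseline_norm=per_rep["baseline_mean"] / ref,
        stimulated_norm=per_rep["stimulated_mean"] / ref,
    )
    out = []
    for condition, grp in per_rep.groupby("condition", sort=True):
        out.append(
            {
                "condition": condition,
                "n": len(grp),
                "baseline_norm_mean": float(grp["baseline_norm"].mean()),
                "baseline_norm_sem": sem(grp["baseline_norm"].to_numpy()),
                "stimulated_norm_mean": float(grp["stimulated_norm"].mean()),
                "stimulated_norm_sem": sem(grp["stimulated_norm"].to_numpy()),
            }
        )
    return pd.DataFrame(out)


def per_replicate_baselines(reduced: pd.DataFrame, reference_condition: str) -> dict:
    """Per-condition arrays of replicate-level normalised baselines.

    Input for pre-coupling testing: each condition maps to one normalised
    baseline value per independent replicate (normalised to the reference
    condition's mean baseline).
    """
    if reference_condition not in set(reduced["condition"]):
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not present"
        )
    per_rep = (
        reduced.groupby(["condition", "replicate"])["baseline_mean"].mean().reset_index()
    )
    ref = float(
        per_rep.loc[per_rep["condition"] == reference_condition, "baseline_mean"].mean()
    )
    return {
        cond: (grp["baseline_mean"] / ref).to_numpy()
        for cond, grp in per_rep.groupby("condition", sort=True)
    }
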