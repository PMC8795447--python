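"""Seeded synthetic data with known ground truth.

Three generators emulate the study's raw inputs so that every downstream
stage is testable without external data:

* :func:`generate_bret_dataset` — dual-channel plate-reader wells with a
  3-min baseline and 5-min stimulation window, mock-labelled wells, matched
  vehicle wells, Hill-shaped concentration dependence, condition-specific
  baseline elevation (pre-coupling) and multiplicative log-normal channel
  noise.
* :func:`generate_segment_set` — receptor intracellular segments with
  phospho-motifs planted at controlled relative positions per selectivity
  group, on a background alphabet that cannot produce accidental matches.
* :func:`generate_dmr_dataset` — label-free wavelength-shift traces with a
  Hill-shaped plateau per concentration plus an empty-vector reference.

One integer seed governs a whole dataset; each well draws from its own
spawned child generator, so datasets are reproducible and individual wells
are independent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import motifs as motifs_mod
from .types import ConfigurationError, SegmentRecord, WellMeta, WellTrace

__all__ = [
    "AssayDesign",
    "ConditionTruth",
    "SegmentTruth",
    "DmrTruth",
    "generate_bret_dataset",
    "generate_segment_set",
    "generate_dmr_dataset",
    "generate_condition_matrix",
]


@dataclass(frozen=True)
class AssayDesign:
    """Plate layout: which conditions, concentrations and windows to emulate."""

    conditions: tuple
    concentrations: tuple  # mol/L; 0 entries are vehicle wells
    n_replicates: int = 3
    baseline_duration_s: float = 180.0
    stim_duration_s: float = 300.0
    sampling_interval_s: float = 10.0
    include_mock: bool = True
    n_mock_wells: int = 1

    def __post_init__(self) -> None:
        if self.baseline_duration_s <= 0 or self.stim_duration_s <= 0:
            raise ConfigurationError("window durations must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.sampling_interval_s <= 0:
            raise ConfigurationError("sampling interval must be positive")
        conc = [c for c in self.concentrations if c > 0]
        if any(c < 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be non-negative")
        if sorted(conc) != conc or len(set(conc)) != len(conc):
            raise ConfigurationError(
                "non-zero concentrations must be strictly increasing"
            )

    @property
    def stimulation_time_s(self) -> float:
        return self.baseline_duration_s

    @property
    def time_grid(self) -> np.ndarray:
        total = self.baseline_duration_s + self.stim_duration_s
        n = int(round(total / self.sampling_interval_s)) + 1
        return np.linspace(0.0, total, n)


@dataclass(frozen=True)
class ConditionTruth:
    """Ground truth for one condition's BRET behaviour.

    ``basal_ratio`` is the specific (label-dependent) acceptor/donor signal at
    rest; the measured ratio additionally contains the label-independent
    ``mock_ratio`` bleed-through, which mock subtraction removes.  With
    ``top_is_absolute`` false (default) the stimulated plateau is
    ``basal·precoupling·(1 + (top_fold−1)·h(c))``; with it true the plateau
    saturates at ``basal·top_fold`` regardless of pre-coupling, so a
    pre-coupled condition shows the elevated-baseline / dampened-dynamics
    signature.
    """

    basal_ratio: float = 0.5
    precoupling_factor: float = 1.0
    top_fold: float = 1.5
    log_ec50: float = -7.0
    hill_slope: float = 1.0
    mock_ratio: float = 0.1
    noise_cv: float = 0.05
    response_tau_s: float = 30.0
    donor_level: float = 1.0e5
    top_is_absolute: bool = False

    def __post_init__(self) -> None:
        if not (self.basal_ratio > self.mock_ratio >= 0):
            raise ConfigurationError("requires basal_ratio > mock_ratio >= 0")
        if self.top_fold < 1 or self.precoupling_factor < 1:
            raise ConfigurationError("top_fold and precoupling_factor must be >= 1")
        if self.noise_cv < 0 or self.response_tau_s < 0:
            raise ConfigurationError("noise_cv and response_tau_s must be >= 0")

    def hill(self, c: float) -> float:
        if c <= 0:
            return 0.0
        ec50 = 10.0 ** self.log_ec50
        return c**self.hill_slope / (c**self.hill_slope + ec50**self.hill_slope)

    def specific_ratio(self, t: np.ndarray, c: float, t_stim: float) -> np.ndarray:
        """Noise-free specific BRET signal over the time grid."""
        base = self.basal_ratio * self.precoupling_factor
        post = t > t_stim
        if self.response_tau_s > 0:
            rise = np.where(post, 1.0 - np.exp(-(t - t_stim) / self.response_tau_s), 0.0)
        else:
            rise = post.astype(float)
        h = self.hill(c)
        if self.top_is_absolute:
            plateau = self.basal_ratio * (
                self.precoupling_factor
                + (self.top_fold - self.precoupling_factor) * h
            )
            return base + (plateau - base) * rise
        return base * (1.0 + (self.top_fold - 1.0) * h * rise)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_bret_dataset(
    design: AssayDesign,
    truths: dict,
    seed: int,
) -> list[WellTrace]:
    """Simulate one plate: every condition × concentration × replicate.

    Per condition and replicate: one sample well per non-zero concentration,
    one vehicle well per zero concentration entry (a vehicle well is added if
    the design lists none), and ``n_mock_wells`` mock wells when
    ``include_mock``.  Deterministic for a fixed seed.
    """
    missing = [c for c in design.conditions if c not in truths]
    if missing:
        raise ConfigurationError(f"no truth entry for condition(s) {missing}")
    t = design.time_grid
    t_stim = design.stimulation_time_s
    concentrations = list(design.concentrations)
    if not any(c == 0 for c in concentrations):
        concentrations = [0.0] + concentrations

    wells: list[WellTrace] = []
    ss = np.random.SeedSequence(seed)
    # one child generator per well, in a fixed iteration order
    plan = []
    for condition in design.conditions:
        for rep in range(1, design.n_replicates + 1):
            for c in concentrations:
                role = "vehicle" if c == 0 else "sample"
                plan.append((condition, rep, c, role))
            if design.include_mock:
                for _ in range(design.n_mock_wells):
                    plan.append((condition, rep, 0.0, "mock"))
    children = ss.spawn(len(plan))
    for i, ((condition, rep, c, role), child) in enumerate(zip(plan, children)):
        rng = np.random.default_rng(child)
        truth = truths[condition]
        donor = truth.donor_level * _lognormal_factors(rng, truth.noise_cv, len(t))
        if role == "mock":
            ratio = np.full(len(t), truth.mock_ratio)
        else:
            ratio = truth.mock_ratio + truth.specific_ratio(t, c, t_stim)
        acceptor = donor * ratio * _lognormal_factors(rng, truth.noise_cv, len(t))
        meta = WellMeta(
            well_id=f"W{i:04d}",
            condition=condition,
            role=role,
            concentration_M=float(c),
            replicate=rep,
            stimulation_time_s=t_stim,
        )
        wells.append(WellTrace(time=t.copy(), donor=donor, acceptor=acceptor, meta=meta))
    return wells


def wells_to_table(wells: list[WellTrace]) -> pd.DataFrame:
    """Long-format plate table (one row per well and timepoint)."""
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": w.meta.well_id,
                    "condition": w.meta.condition,
                    "receptor": w.meta.receptor,
                    "arrestin": w.meta.arrestin,
                    "grk_label": w.meta.grk_label,
                    "role": w.meta.role,
                    "concentration_M": w.meta.concentration_M,
                    "replicate": w.meta.replicate,
                    "time_s": w.time,
                    "donor": w.donor,
                    "acceptor": w.acceptor,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# receptor-segment generator
# ---------------------------------------------------------------------------

# residues that can never match a P slot ({S, T, D, E}); proline is ordinary
_BACKGROUND_AA = "ACFGHIKLMNPQRVWY"


@dataclass(frozen=True)
class SegmentTruth:
    """A generated segment plus the exact motif hits a scanner must find."""

    record: SegmentRecord
    planted_motifs: tuple = ()  # ((motif_name, start), ...)


def _plant_positions(
    rng: np.random.Generator, length: int, motif_len: int, n_motifs: int, placement: str
) -> list[int]:
    """Draw non-overlapping starts whose relative positions obey ``placement``."""
    if motif_len > length:
        raise ConfigurationError("motif longer than segment")
    max_start = length - motif_len
    if placement == "central":
        lo, hi = 0.30, 0.70
        candidates = [
            s for s in range(max_start + 1) if lo <= s / max(length - 1, 1) <= hi
        ]
    elif placement == "peripheral":
        candidates = [
            s
            for s in range(max_start + 1)
            if s / max(length - 1, 1) <= 0.20 or s / max(length - 1, 1) >= 0.80
        ]
    elif placement == "random":
        candidates = list(range(max_start + 1))
    else:
        raise ConfigurationError(f"unknown placement {placement!r}")
    starts: list[int] = []
    for _ in range(200):
        if len(starts) == n_motifs:
            break
        if not candidates:
            break
        s = int(rng.choice(candidates))
        if all(abs(s - other) >= motif_len for other in starts):
            starts.append(s)
    if len(starts) < n_motifs:
        raise ConfigurationError(
            f"cannot plant {n_motifs} non-overlapping motifs of length "
            f"{motif_len} with placement {placement!r} in length {length}"
        )
    return sorted(starts)


def generate_segment_set(
    n_receptors_per_group: int,
    group_placement: dict,
    seed: int,
    motif: str = "PXPP",
    motifs_per_segment: int = 2,
    length_range: tuple = (45, 75),
    segment_kind: str = "Cterm",
) -> list[SegmentTruth]:
    """Generate segments with planted motifs at group-controlled positions.

    ``group_placement`` maps a selectivity-group label (e.g. ``"GRK2/3"``) to
    a placement rule: ``"central"``, ``"peripheral"`` or ``"random"``.
    Background residues are drawn from the 16 amino acids outside {S, T, D, E}
    so only planted motifs can match; each planted P slot is filled from
    {S, T, D, E} and each X slot from the background alphabet.  After
    construction the scanner is run and the segment is regenerated on any
    collision, so the truth lists exactly the hits the scanner must find.
    """
    if motif not in motifs_mod.GRAMMARS:
        raise ConfigurationError(f"unknown motif grammar {motif!r}")
    pattern = motifs_mod.GRAMMARS[motif]
    rng = np.random.default_rng(seed)
    out: list[SegmentTruth] = []
    counter = 0
    p_residues = "STDE"
    for group, placement in group_placement.items():
        for _ in range(n_receptors_per_group):
            counter += 1
            receptor_id = f"R{counter:03d}"
            for attempt in range(100):
                length = int(rng.integers(length_range[0], length_range[1] + 1))
                seq = list(rng.choice(list(_BACKGROUND_AA), size=length))
                starts = _plant_positions(
                    rng, length, len(pattern), motifs_per_segment, placement
                )
                for s in starts:
                    for k, slot in enumerate(pattern):
                        if slot == "P":
                            seq[s + k] = str(rng.choice(list(p_residues)))
                        else:
                            seq[s + k] = str(rng.choice(list(_BACKGROUND_AA)))
                sequence = "".join(seq)
                found = [
                    h
                    for h in motifs_mod.scan_pattern(sequence, pattern)
                ]
                if found == starts:
                    break
            else:  # pragma: no cover - defensive
                raise ConfigurationError("could not plant motifs without collision")
            record = SegmentRecord(
                receptor_id=receptor_id,
                segment_kind=segment_kind,
                sequence=sequence,
                group_label=group,
                receptor_class="A" if counter % 2 else "B",
            )
            out.append(
                SegmentTruth(
                    record=record,
                    planted_motifs=tuple((motif, s) for s in starts),
                )
            )
    return out


# ---------------------------------------------------------------------------
# DMR generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DmrTruth:
    """Ground truth for a label-free wavelength-shift experiment."""

    plateau_max_pm: float = 300.0
    log_ec50: float = -8.0
    hill_slope: float = 1.0
    ev_plateau_pm: float = 40.0  # empty-vector (receptor-free) background response
    response_tau_s: float = 250.0
    noise_cv: float = 0.05

    def plateau(self, c: float) -> float:
        if c <= 0:
            return 0.0
        ec50 = 10.0 ** self.log_ec50
        h = c**self.hill_slope / (c**self.hill_slope + ec50**self.hill_slope)
        return self.plateau_max_pm * h


def generate_dmr_dataset(
    concentrations: tuple,
    truth: DmrTruth,
    seed: int,
    n_replicates: int = 3,
    duration_s: float = 1800.0,
    sampling_interval_s: float = 15.0,
) -> pd.DataFrame:
    """Simulate wavelength-shift traces plus an empty-vector reference.

    Returns a long table (role, concentration_M, replicate, time_s, shift_pm);
    the AUC analysis window is [0, 1800] s, so shorter traces are refused.
    """
    if duration_s < 1800.0:
        raise ConfigurationError(
            "DMR trace must cover at least 1800 s (AUC window would be truncated)"
        )
    n = int(round(duration_s / sampling_interval_s)) + 1
    t = np.linspace(0.0, duration_s, n)
    rise = 1.0 - np.exp(-t / truth.response_tau_s)
    ss = np.random.SeedSequence(seed)
    plan = [("sample", float(c), r) for c in concentrations for r in range(1, n_replicates + 1)]
    plan += [("empty_vector", 0.0, r) for r in range(1, n_replicates + 1)]
    children = ss.spawn(len(plan))
    frames = []
    for (role, c, rep), child in zip(plan, children):
        rng = np.random.default_rng(child)
        if role == "sample":
            clean = (truth.ev_plateau_pm + truth.plateau(c)) * rise
        else:
            clean = truth.ev_plateau_pm * rise
        shift = clean * _lognormal_factors(rng, truth.noise_cv, n)
        frames.append(
            pd.DataFrame(
                {
                    "role": role,
                    "concentration_M": c,
                    "replicate": rep,
                    "time_s": t,
                    "shift_pm": shift,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# saturating-concentration condition matrix (selectivity simulations)
# ---------------------------------------------------------------------------

CONDITIONS = (
    "Control+EV",
    "dQ-GRK+EV",
    "dQ-GRK+GRK2",
    "dQ-GRK+GRK3",
    "dQ-GRK+GRK5",
    "dQ-GRK+GRK6",
)

_GROUP_ELEVATED = {
    "GRK2/3": ("dQ-GRK+GRK2", "dQ-GRK+GRK3"),
    "GRK2/3/5/6": ("dQ-GRK+GRK2", "dQ-GRK+GRK3", "dQ-GRK+GRK5", "dQ-GRK+GRK6"),
}


def generate_condition_matrix(
    n_pairs_per_group: int,
    seed: int,
    effect_sds: float = 3.0,
    noise_sd: float = 0.05,
    baseline_value: float = 1.0,
    n_replicates: int = 4,
):
    """Replicate-level saturating-concentration fold changes with planted groups.

    For a pair regulated by GRK2/3 only, rescue of GRK2 or GRK3 into the
    quadruple-knockout background restores recruitment (mean elevated by
    ``effect_sds`` replicate SDs); GRK5/6 rescue does not.  For a pair
    regulated by all four kinases, every rescue restores it.  Control+EV
    (endogenous kinases present) is elevated for every pair.

    Returns ``(matrix, truth)``: a long DataFrame (pair, condition, replicate,
    value) and a dict pair → planted group label.  The default n = 4
    independent replicates per cell reflects the study's "at least n = 3"
    design at a depth where a 3-SD effect is reliably detectable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    effect = effect_sds * noise_sd
    pairs = [("GRK2/3", i) for i in range(n_pairs_per_group)] + [
        ("GRK2/3/5/6", i) for i in range(n_pairs_per_group)
    ]
    for group, i in pairs:
        pair = f"{group.replace('/', '')}-pair{i:02d}"
        truth[pair] = group
        elevated = set(_GROUP_ELEVATED[group]) | {"Control+EV"}
        for condition in CONDITIONS:
            mu = baseline_value + (effect if condition in elevated else 0.0)
            vals = rng.normal(mu, noise_sd, size=n_replicates)
            for r, v in enumerate(vals, start=1):
                rows.append(
                    {"pair": pair, "condition": condition, "replicate": r, "value": v}
                )
    return pd.DataFrame(rows), truth
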