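"""Core domain objects shared across the pipeline.

The central observable is a dual-channel plate-reader time series per well
(luciferase donor counts and fluorophore acceptor counts).  Everything
downstream — corrected ratios, window means, fold changes, concentration–
response fits and selectivity calls — is a reduction of collections of
:class:`WellTrace` objects plus their metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrkBretError",
    "ConfigurationError",
    "DataError",
    "DegenerateWellError",
    "DegenerateFitError",
    "WellMeta",
    "WellTrace",
    "CorrectedMeasurement",
    "NetFoldChange",
    "GateResult",
    "FitResult",
    "DmrResponse",
    "ComparisonResult",
    "SelectivityCall",
    "SegmentRecord",
    "MotifHit",
    "AssociationResult",
]


class GrkBretError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(GrkBretError):
    """A request is internally inconsistent (missing condition, bad design...)."""


class DataError(GrkBretError):
    """Input data violate a contract (bad channel value, misaligned time base...)."""


class DegenerateWellError(DataError):
    """A well whose corrected baseline is non-positive; no fold change is defined."""


class DegenerateFitError(DataError):
    """Responses are flat within tolerance; a concentration-response fit is meaningless."""


@dataclass(frozen=True)
class WellMeta:
    """Identity and experimental role of one well."""

    well_id: str
    condition: str
    role: str  # "sample" | "mock" | "vehicle"
    concentration_M: float
    replicate: int
    stimulation_time_s: float
    receptor: str = ""
    arrestin: str = ""
    grk_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("sample", "mock", "vehicle"):
            raise DataError(
                f"well {self.well_id}: unknown role {self.role!r} "
                "(expected sample, mock or vehicle)"
            )
        if self.concentration_M < 0:
            raise DataError(f"well {self.well_id}: negative concentration")


@dataclass
class WellTrace:
    """One well's timestamped donor/acceptor intensity series plus metadata."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    meta: WellMeta

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise DataError(f"well {self.meta.well_id}: channel lengths differ")
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise DataError(f"well {self.meta.well_id}: time not strictly increasing")
        t0, t1 = float(self.time[0]), float(self.time[-1])
        if not (t0 <= self.meta.stimulation_time_s <= t1):
            raise DataError(
                f"well {self.meta.well_id}: stimulation time "
                f"{self.meta.stimulation_time_s} outside [{t0}, {t1}]"
            )


@dataclass(frozen=True)
class CorrectedMeasurement:
    """Window means of a mock-corrected ratio series and their quotient.

    ``fold_change = stimulated_mean / baseline_mean`` — the per-well
    stimulated/baseline BRET change before vehicle normalisation.
    """

    baseline_mean: float
    stimulated_mean: float

    @property
    def fold_change(self) -> float:
        if self.baseline_mean <= 0:
            raise DegenerateWellError("baseline mean must be positive for a fold change")
        return self.stimulated_mean / self.baseline_mean


@dataclass(frozen=True)
class NetFoldChange:
    """Vehicle-normalised fold change (the Δ net BRET fold change) for one well."""

    value: float
    condition: str
    concentration_M: float
    replicate: int


@dataclass(frozen=True)
class GateResult:
    """Outcome of the functional-recruitment gate at the top ligand concentration."""

    is_functional: bool
    p_value: float
    test_label: str


@dataclass(frozen=True)
class FitResult:
    """Four/three-parameter logistic concentration-response fit."""

    bottom: float
    top: float
    log_ec50: float
    log_ec50_sem: float
    hill_slope: float
    converged: bool
    extrapolated: bool = False
    n_experiments: int = 0
    per_experiment_log_ec50: tuple = ()

    @property
    def ec50_M(self) -> float:
        return float(10.0 ** self.log_ec50)


@dataclass(frozen=True)
class DmrResponse:
    """Area under an empty-vector-corrected wavelength-shift trace (pm·s)."""

    auc: float
    normalized_effect: float = float("nan")


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast of a multiple-comparison family."""

    label: str
    contrast: tuple  # (condition_a, condition_b)
    direction: int  # sign of mean(a) - mean(b)
    p_unadjusted: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class SelectivityCall:
    """Per GPCR–arrestin pair: kinase-selectivity group and pre-coupling flags."""

    pair: str
    group: str  # "GRK2/3", "GRK2/3/5/6" or "unclassified"
    precoupling_flags: dict = field(default_factory=dict)
    heatmap_row: tuple = ()
    leaf_position: int = -1


STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SegmentRecord:
    """One receptor intracellular segment (third intracellular loop or C-tail)."""

    receptor_id: str
    segment_kind: str  # "IL3" | "Cterm"
    sequence: str
    group_label: str = "unclassified"
    receptor_class: str = "A"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"{self.receptor_id}/{self.segment_kind}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in STANDARD_AA:
                raise DataError(
                    f"{self.receptor_id}/{self.segment_kind}: invalid residue "
                    f"{aa!r} at position {i}"
                )


@dataclass(frozen=True)
class MotifHit:
    """One motif-grammar match within a segment."""

    receptor_id: str
    segment_kind: str
    motif: str
    start: int  # 0-based index of the first matched residue
    relative_position: float  # in [0, 1]; 0 = N-terminal end of the segment
    category: str  # "central" | "peripheral"
    group_label: str = "unclassified"
    receptor_class: str = "A"


@dataclass(frozen=True)
class AssociationResult:
    """Fisher exact association between motif position category and group."""

    contingency: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p_two_sided: float


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample SD / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))
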