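"""Run configuration: every analysis choice with a documented default.

Defaults reproduce the standard pipeline: 3-min baseline / 5-min stimulation
windows, per-timepoint mock subtraction, pooled one-sided t gate at alpha
0.05, fixed Hill slope, per-experiment EC50 fitting, signed -log10 heatmap
transform capped at 16, Canberra/complete-linkage clustering, overlapping
0-based motif counting with the 0.25/0.75 breakpoints assigned central.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # reduction windows (seconds)
    baseline_duration_s: float = 180.0
    stim_duration_s: float = 300.0
    # mock subtraction: "per_timepoint" (default) or "scalar"
    mock_mode: str = "per_timepoint"
    # statistics
    alpha: float = 0.05
    gate_test: str = "student"  # "student" | "welch"
    # concentration-response fitting
    fit_per_experiment: bool = True
    fix_hill_slope: bool = True
    # selectivity heatmap / clustering
    heatmap_cap: float = 16.0
    linkage_method: str = "complete"
    pooled_error: bool = True  # Bonferroni contrasts use the ANOVA residual MSE
    # motif conventions
    motif_overlapping: bool = True
    motif_one_based: bool = False
    boundary_central: bool = True
    exclude_receptors: tuple = ()
    # randomness
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "exclude_receptors" in data:
            data["exclude_receptors"] = tuple(data["exclude_receptors"])
        return cls(**data)
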