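"""Run configuration: every tunable threshold of the screen in one place.

Defaults follow the values the screen was designed around: strict r cutoffs
0.6 / 0.5 and a median-ΔDMS cutoff of 0.15 for the structural screen, a TPM
floor of 10 and a 20-percentage-point ratio change for the antisense screen,
a 100-bp motif→TSS linking distance, and a ~15% antisense background floor
(undigested second-strand cDNA in stranded library preparation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .stages import DEFAULT_STAGE_LABELS, StageSeries


@dataclass
class RunConfig:
    stage_labels: tuple[str, ...] = DEFAULT_STAGE_LABELS

    # structural screen
    min_r_cutoffs: tuple[float, ...] = (0.6, 0.5)
    delta_median_cutoff: float = 0.15
    min_common_positions: int = 50
    stable_min_r: float = 0.8
    ac_only: bool = True

    # antisense screen
    tpm_floor: float = 10.0
    ratio_change_min: float = 0.20
    max_missing: int = 1
    antisense_background: float = 0.15
    background_margin: float = 0.05

    # motif / TSS
    motif_score_fraction: float = 0.85
    motif_score_fraction_strict: float = 0.95
    consensus_eps: float = 0.01
    region_length: int = 1000
    tss_min_count: int = 3
    tss_merge_window: int = 10
    tss_link_max_distance: int = 100

    # pulse
    pulse_delta_z: float = 1.0
    pulse_window: tuple[str, str] = ("P", "T1")

    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_labels = tuple(self.stage_labels)
        self.min_r_cutoffs = tuple(float(c) for c in self.min_r_cutoffs)
        self.pulse_window = tuple(self.pulse_window)
        if not 0.0 <= self.antisense_background < 1.0:
            raise ValueError("antisense_background must be in [0, 1)")
        if self.tpm_floor < 0:
            raise ValueError("tpm_floor must be >= 0")
        if self.min_common_positions < 3:
            raise ValueError("min_common_positions must be >= 3")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")
        if not 0 < self.consensus_eps < 0.25:
            raise ValueError("consensus_eps must be in (0, 0.25)")
        for c in self.min_r_cutoffs:
            if not -1.0 <= c <= 1.0:
                raise ValueError("r cutoffs must be in [-1, 1]")
        # validate window labels against the series
        series = self.stages
        for lab in self.pulse_window:
            series.rank(lab)

    @property
    def stages(self) -> StageSeries:
        return StageSeries(self.stage_labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat key→value YAML document; unknown keys rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stage_labels"] = list(self.stage_labels)
        data["min_r_cutoffs"] = list(self.min_r_cutoffs)
        data["pulse_window"] = list(self.pulse_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
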