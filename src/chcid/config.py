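"""Pipeline configuration: every threshold in one place.

Defaults follow unit-resolution quadrupole practice: nominal-mass binning at
0.3 Th, a 0.5% base-peak floor for the molecular ion, a 2x envelope excess
for calling an ion enhanced (real branch ions show ~3x), and a 15-RI-unit
band for the curve consistency check.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    ratio_threshold: float = 2.0  # enhanced-ion call: observed/predicted
    mask_threshold: float = 2.0  # outlier mask during the decay refit
    mz_tolerance: float = 0.3  # Th, centroid -> nominal binning
    parent_floor: float = 0.005  # fraction of base peak
    ri_tolerance: float = 15.0  # RI units, curve consistency band
    score_penalty: float = 0.5  # per unmatched predicted/observed ion
    coelution_window: float = 0.005  # minutes

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
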