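"""Meta-ROI composite SUVRs and binary tau-positivity statuses.

Three reference composites are computed from a regional panel:

* ``temporal`` — weighted average of entorhinal, amygdala, parahippocampal,
  fusiform, inferior temporal and middle temporal; abnormal above 1.23 SUVR.
* ``mtl`` — unweighted mean of entorhinal and amygdala; abnormal above 1.30.
* ``neo`` — weighted average of middle and inferior temporal; abnormal
  above 1.73.

"Weighted" uses :attr:`AtlasConfig.region_weights` (a stand-in for voxel
counts); with the default equal weights each composite is a plain mean.
All cutoffs are strict-greater comparisons and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import AtlasConfig
from .cohort import RegionSUVRPanel
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class MetaROIConfig:
    temporal_cutoff: float = 1.23
    mtl_cutoff: float = 1.30
    neo_cutoff: float = 1.73

    def __post_init__(self) -> None:
        for name in ("temporal_cutoff", "mtl_cutoff", "neo_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass(frozen=True)
class MetaROIResult:
    temporal_suvr: float
    mtl_suvr: float
    neo_suvr: float
    temporal_pos: bool
    mtl_pos: bool
    neo_pos: bool

    def statuses(self) -> tuple[bool, bool, bool]:
        return (self.temporal_pos, self.mtl_pos, self.neo_pos)


def _weighted_average(panel: RegionSUVRPanel, atlas: AtlasConfig, roi: str) -> float:
    members = atlas.meta_roi_membership.get(roi)
    if not members:
        raise ConfigError(f"atlas defines no membership for meta-ROI {roi!r}")
    missing = [r for r in members if r not in panel.region_values]
    if missing:
        raise ValidationError(
            f"participant {panel.participant_id}: meta-ROI {roi!r} member "
            f"region(s) missing from panel: {missing}"
        )
    values = np.array([panel.region_values[r] for r in members])
    weights = np.array(atlas.weights_for(members))
    return float(np.average(values, weights=weights))


def temporal_suvr(panel: RegionSUVRPanel, atlas: AtlasConfig) -> float:
    """Weighted average over the six temporal meta-ROI members."""
    return _weighted_average(panel, atlas, "temporal")


def mtl_suvr(panel: RegionSUVRPanel, atlas: AtlasConfig) -> float:
    """Unweighted mean of entorhinal and amygdala (weights ignored)."""
    members = atlas.meta_roi_membership.get("mtl")
    if not members:
        raise ConfigError("atlas defines no membership for meta-ROI 'mtl'")
    missing = [r for r in members if r not in panel.region_values]
    if missing:
        raise ValidationError(
            f"participant {panel.participant_id}: meta-ROI 'mtl' member "
            f"region(s) missing from panel: {missing}"
        )
    return float(np.mean([panel.region_values[r] for r in members]))


def neo_suvr(panel: RegionSUVRPanel, atlas: AtlasConfig) -> float:
    """Weighted average over the neocortical (middle + inferior temporal) members."""
    return _weighted_average(panel, atlas, "neo")


def classify_meta_roi(
    panel: RegionSUVRPanel, atlas: AtlasConfig, cfg: MetaROIConfig = MetaROIConfig()
) -> MetaROIResult:
    """All three composite SUVRs and strict-greater positivity statuses."""
    t = temporal_suvr(panel, atlas)
    m = mtl_suvr(panel, atlas)
    n = neo_suvr(panel, atlas)
    return MetaROIResult(
        temporal_suvr=t,
        mtl_suvr=m,
        neo_suvr=n,
        temporal_pos=t > cfg.temporal_cutoff,
        mtl_pos=m > cfg.mtl_cutoff,
        neo_pos=n > cfg.neo_cutoff,
    )
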