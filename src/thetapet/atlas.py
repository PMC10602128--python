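"""Atlas configuration: region list, weights, and meta-ROI membership.

Regional tau-PET SUVR values are indexed by a fixed, ordered list of region
names (left/right hemispheres already averaged upstream).  The shipped default
atlas has 41 regions: the 34 standard cortical parcels of a Desikan-style
parcellation plus seven medial/subcortical structures routinely reported with
them (amygdala, hippocampus, ...).  Users may supply their own region list and
weights through the configuration file; downstream code only relies on the
ordering and on the meta-ROI membership sets.

``region_weights`` stand in for per-region voxel counts in "voxel-weighted"
averages.  The shipped default is equal weights, i.e. plain means; override
with region volumes to recover a volume-weighted composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError

#: canonical lowercase region tokens of the default 41-region atlas
DEFAULT_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "frontal_pole",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "insula",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "paracentral",
    "parahippocampal",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "temporal_pole",
    "transverse_temporal",
    "amygdala",
    "hippocampus",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
)

TEMPORAL_META_ROI: tuple[str, ...] = (
    "entorhinal",
    "amygdala",
    "parahippocampal",
    "fusiform",
    "inferior_temporal",
    "middle_temporal",
)
MTL_META_ROI: tuple[str, ...] = ("entorhinal", "amygdala")
NEO_META_ROI: tuple[str, ...] = ("middle_temporal", "inferior_temporal")


@dataclass(frozen=True)
class AtlasConfig:
    """Ordered region list plus weights and meta-ROI membership.

    Parameters
    ----------
    region_names
        Ordered region tokens; this ordering defines the classifier feature
        order and the column order of every table the package writes.
    region_weights
        Positive weight per region, used by "voxel-weighted" meta-ROI
        averages.  Equal weights reduce those averages to plain means.
    meta_roi_membership
        Mapping of meta-ROI name (``temporal``, ``mtl``, ``neo``) to the
        member region subset.
    """

    region_names: tuple[str, ...] = DEFAULT_REGIONS
    region_weights: Mapping[str, float] = field(default_factory=dict)
    meta_roi_membership: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.region_names)
        if len(set(names)) != len(names):
            raise ConfigError("atlas region names must be unique")
        object.__setattr__(self, "region_names", names)
        weights = dict(self.region_weights) or {r: 1.0 for r in names}
        unknown = set(weights) - set(names)
        if unknown:
            raise ConfigError(f"weights given for unknown regions: {sorted(unknown)}")
        missing = set(names) - set(weights)
        if missing:
            raise ConfigError(f"weights missing for regions: {sorted(missing)}")
        if any(w <= 0 for w in weights.values()):
            raise ConfigError("all region weights must be > 0")
        object.__setattr__(self, "region_weights", weights)
        membership = {
            k: tuple(v) for k, v in (self.meta_roi_membership or {}).items()
        }
        if not membership:
            membership = {
                "temporal": TEMPORAL_META_ROI,
                "mtl": MTL_META_ROI,
                "neo": NEO_META_ROI,
            }
        for roi, members in membership.items():
            absent = set(members) - set(names)
            if absent:
                raise ConfigError(
                    f"meta-ROI {roi!r} references regions absent from the atlas: "
                    f"{sorted(absent)}"
                )
        object.__setattr__(self, "meta_roi_membership", membership)

    @property
    def m(self) -> int:
        return len(self.region_names)

    def index_of(self, region: str) -> int:
        return self.region_names.index(region)

    def weights_for(self, regions: Sequence[str]) -> list[float]:
        return [self.region_weights[r] for r in regions]


def default_atlas() -> AtlasConfig:
    """The shipped 41-region atlas with equal weights."""
    return AtlasConfig()
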