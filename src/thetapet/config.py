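"""Global run configuration: one YAML file with nested sections."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .atlas import AtlasConfig, default_atlas
from .errors import ConfigError
from .metaroi import MetaROIConfig
from .simulate import ArchetypeSpec, ClinicalLink, SimulationConfig, default_archetypes
from .theta import ThetaConfig


@dataclass(frozen=True)
class ClassifierConfig:
    test_fraction: float = 0.20
    k: int = 5
    repeats: int = 2
    threshold: float = 0.5


@dataclass(frozen=True)
class AttributionConfig:
    method: str = "sampled"
    n_background: int = 100
    n_permutations: int = 200


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    delimiter: str = ","
    atlas: AtlasConfig = field(default_factory=default_atlas)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    meta_roi: MetaROIConfig = field(default_factory=MetaROIConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    theta: ThetaConfig = field(default_factory=ThetaConfig)


def _build_atlas(section: dict) -> AtlasConfig:
    return AtlasConfig(
        region_names=tuple(section.get("region_names", default_atlas().region_names)),
        region_weights=section.get("region_weights", {}),
        meta_roi_membership={
            k: tuple(v) for k, v in section.get("meta_roi_membership", {}).items()
        },
    )


def _build_simulation(section: dict, seed: int) -> SimulationConfig:
    archetypes = default_archetypes()
    if "archetypes" in section:
        archetypes = tuple(
            ArchetypeSpec(
                name=a["name"],
                mean_shift=a.get("mean_shift", {}),
                within_subject_sd=a.get("within_subject_sd", 0.05),
                prevalence=a["prevalence"],
                visually_positive=a["visually_positive"],
            )
            for a in section["archetypes"]
        )
    link = ClinicalLink(**section.get("clinical_link", {}))
    return SimulationConfig(
        n=section.get("n", 2000),
        seed=section.get("seed", seed),
        baseline_mean=section.get("baseline_mean", 1.05),
        baseline_sd=section.get("baseline_sd", 0.08),
        archetypes=archetypes,
        positive_fraction=section.get("positive_fraction", 0.19),
        clinical_link=link,
    )


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load the global YAML configuration; missing sections take defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    seed = int(raw.get("seed", 0))
    return RunConfig(
        seed=seed,
        delimiter=raw.get("delimiter", ","),
        atlas=_build_atlas(raw.get("atlas", {})),
        simulation=_build_simulation(raw.get("simulation", {}), seed),
        meta_roi=MetaROIConfig(**raw.get("meta_roi", {})),
        classifier=ClassifierConfig(**raw.get("classifier", {})),
        attribution=AttributionConfig(**raw.get("attribution", {})),
        theta=ThetaConfig(**raw.get("theta", {})),
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for run manifests."""
    canonical = yaml.safe_dump(_to_plain(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj
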