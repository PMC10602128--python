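"""Synthetic tau-PET cohorts with heterogeneous deposition archetypes.

The generator emulates the statistical structure the downstream analysis
assumes: a mostly tau-negative population (default 19% visually positive,
the Mayo prevalence) in which positivity arises from distinct spatial
deposition archetypes.  Archetypes are chosen so that the meta-ROI cutoffs
(1.23 / 1.30 / 1.73 SUVR) split them into visual/meta-ROI concordant and
discordant cases by construction:

* ``negative`` — no elevation; visually negative, all meta-ROIs negative.
* ``mtl_predominant`` — entorhinal/amygdala elevation only.  Isolated
  mesial-temporal activity is rated *negative* under the visual criteria,
  but the MTL composite exceeds its cutoff: the classic visual−/MTL+
  discordant case.
* ``neocortical`` — strong middle/inferior temporal elevation; visually
  positive, NEO and temporal positive, MTL negative.
* ``diffuse`` — broad cortical elevation; visually positive and positive
  on all three meta-ROIs (the concordant-positive case).
* ``focal_atypical`` — occipital/parietal elevation only; visually
  positive while every meta-ROI stays negative (meta-ROIs miss it).

Regional SUVR = baseline draw + archetype mean shift + noise, floored at
0.5.  A participant-level random intercept (``baseline_sd``) induces
inter-region correlation on top of independent per-region noise
(``within_subject_sd``).  Clinical scores are linked to the realized tau
burden: MMSE decreases and CDR-SB increases with mean regional elevation.

All randomness flows from a single seed; per-participant sub-streams are
spawned deterministically, so cohorts are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasConfig, default_atlas
from .cohort import CohortTable, ParticipantRecord, RegionSUVRPanel
from .errors import ConfigError, ValidationError
from .metaroi import MetaROIResult

import logging

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One deposition pattern: mean SUVR elevation per region plus prevalence."""

    name: str
    mean_shift: Mapping[str, float]
    within_subject_sd: float
    prevalence: float
    visually_positive: bool

    def __post_init__(self) -> None:
        if self.within_subject_sd <= 0:
            raise ConfigError(f"archetype {self.name!r}: within_subject_sd must be > 0")
        if not 0 <= self.prevalence <= 1:
            raise ConfigError(f"archetype {self.name!r}: prevalence outside [0, 1]")


@dataclass(frozen=True)
class ClinicalLink:
    """Latent burden → clinical score link: MMSE = 29 − a·burden + ε (clipped
    to [0, 30]), CDR-SB = b·burden + ε (clipped to [0, 18])."""

    mmse_intercept: float = 29.0
    mmse_slope: float = 25.0
    mmse_sd: float = 1.5
    cdr_slope: float = 30.0
    cdr_sd: float = 1.0


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """The shipped Mayo-like archetype mix (visual-positive fraction 0.19)."""
    sd = 0.05
    return (
        ArchetypeSpec("negative", {}, sd, 0.76, visually_positive=False),
        ArchetypeSpec(
            "mtl_predominant",
            {"entorhinal": 0.45, "amygdala": 0.45},
            sd,
            0.05,
            visually_positive=False,
        ),
        ArchetypeSpec(
            "neocortical",
            {
                "middle_temporal": 0.75,
                "inferior_temporal": 0.75,
                "superior_temporal": 0.30,
                "bankssts": 0.25,
            },
            sd,
            0.05,
            visually_positive=True,
        ),
        ArchetypeSpec(
            "diffuse",
            {
                # limbic-forward typical-AD pattern: entorhinal/amygdala are
                # the strongest shifts, per the canonical staging of tau spread
                "entorhinal": 0.95,
                "amygdala": 0.95,
                "parahippocampal": 0.65,
                "fusiform": 0.70,
                "inferior_temporal": 0.85,
                "middle_temporal": 0.85,
                "superior_temporal": 0.50,
                "bankssts": 0.45,
                "inferior_parietal": 0.55,
                "superior_parietal": 0.45,
                "supramarginal": 0.45,
                "precuneus": 0.55,
                "posterior_cingulate": 0.40,
                "isthmus_cingulate": 0.40,
                "lateral_occipital": 0.50,
                "lingual": 0.35,
                "cuneus": 0.35,
                "pericalcarine": 0.30,
                "rostral_middle_frontal": 0.30,
                "superior_frontal": 0.30,
                "temporal_pole": 0.35,
                "transverse_temporal": 0.30,
            },
            sd,
            0.10,
            visually_positive=True,
        ),
        ArchetypeSpec(
            "focal_atypical",
            {
                "lateral_occipital": 0.60,
                "cuneus": 0.55,
                "pericalcarine": 0.50,
                "lingual": 0.45,
                "precuneus": 0.50,
                "superior_parietal": 0.50,
                "inferior_parietal": 0.40,
            },
            sd,
            0.04,
            visually_positive=True,
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 2000
    seed: int = 0
    baseline_mean: float = 1.05
    baseline_sd: float = 0.08
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    positive_fraction: Optional[float] = 0.19
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    suvr_floor: float = 0.5
    #: log-SD of the per-participant severity multiplier applied to the
    #: archetype shift vector; tau burden is a continuum, and mildly
    #: affected scans are exactly the ones composite cutoffs miss
    severity_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.baseline_sd <= 0:
            raise ConfigError("baseline_sd must be > 0")
        if self.positive_fraction is not None and not 0 <= self.positive_fraction <= 1:
            raise ConfigError("positive_fraction outside [0, 1]")
        total = sum(a.prevalence for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"archetype prevalences must sum to 1 (got {total:.6f})"
            )
        negatives = [a for a in self.archetypes if a.name == "negative"]
        if negatives and any(negatives[0].mean_shift.values()):
            raise ConfigError("the negative archetype must have zero mean_shift")

    def archetype_probabilities(self) -> np.ndarray:
        """Per-archetype draw probabilities.

        When ``positive_fraction`` is set, the visually-positive archetypes
        are rescaled to total exactly that fraction and the visually-negative
        ones to its complement, keeping relative prevalences within each
        group.  Otherwise the stated prevalences are used as-is.
        """
        prev = np.array([a.prevalence for a in self.archetypes], dtype=float)
        if self.positive_fraction is None:
            return prev / prev.sum()
        pos = np.array([a.visually_positive for a in self.archetypes])
        probs = prev.copy()
        pos_total, neg_total = prev[pos].sum(), prev[~pos].sum()
        if self.positive_fraction > 0 and pos_total == 0:
            raise ConfigError("positive_fraction > 0 but no visually-positive archetype")
        if self.positive_fraction > 0:
            probs[pos] = prev[pos] / pos_total * self.positive_fraction
        else:
            probs[pos] = 0.0
        if neg_total == 0:
            raise ConfigError("no visually-negative archetype defined")
        probs[~pos] = prev[~pos] / neg_total * (1 - self.positive_fraction)
        return probs


def generate_cohort(
    config: SimulationConfig, atlas: Optional[AtlasConfig] = None
) -> CohortTable:
    """Draw a synthetic cohort of ``config.n`` participants.

    Returns a :class:`CohortTable` whose ``truth`` attribute holds the
    simulation ground truth (archetype name, latent burden) per participant.
    """
    atlas = atlas or default_atlas()
    probs = config.archetype_probabilities()
    root = np.random.SeedSequence(config.seed)
    cohort_ss, participants_ss = root.spawn(2)
    rng = np.random.default_rng(cohort_ss)
    arch_idx = rng.choice(len(config.archetypes), size=config.n, p=probs)
    child_seeds = participants_ss.spawn(config.n)

    regions = atlas.region_names
    shift_vectors = {}
    for a in config.archetypes:
        unknown = set(a.mean_shift) - set(regions)
        if unknown:
            raise ConfigError(
                f"archetype {a.name!r} shifts unknown region(s): {sorted(unknown)}"
            )
        shift_vectors[a.name] = np.array(
            [a.mean_shift.get(r, 0.0) for r in regions], dtype=float
        )

    link = config.clinical_link
    records: list[tuple[ParticipantRecord, RegionSUVRPanel]] = []
    truth_rows = []
    width = len(str(config.n - 1))
    for i in range(config.n):
        arch = config.archetypes[arch_idx[i]]
        prng = np.random.default_rng(child_seeds[i])
        intercept = prng.normal(0.0, config.baseline_sd)
        noise = prng.normal(0.0, arch.within_subject_sd, size=len(regions))
        severity = float(np.exp(prng.normal(0.0, config.severity_sd)))
        x = (
            config.baseline_mean
            + intercept
            + severity * shift_vectors[arch.name]
            + noise
        )
        x = np.maximum(x, config.suvr_floor)
        burden = float(np.mean(x) - config.baseline_mean)

        mmse = link.mmse_intercept - link.mmse_slope * burden + prng.normal(0, link.mmse_sd)
        mmse = int(round(min(30.0, max(0.0, mmse))))
        cdr = link.cdr_slope * burden + prng.normal(0, link.cdr_sd)
        cdr = round(min(18.0, max(0.0, cdr)) * 2) / 2  # half-point increments

        if arch.visually_positive:
            dx_probs = (0.15, 0.35, 0.45, 0.05)
        else:
            dx_probs = (0.88, 0.08, 0.02, 0.02)
        diagnosis = prng.choice(("CU", "MCI", "AD", "DLB"), p=dx_probs)
        amyloid = bool(prng.random() < (0.95 if arch.visually_positive else 0.27))
        apoe4 = bool(prng.random() < (0.55 if amyloid else 0.20))

        pid = f"sim{i:0{width}d}"
        panel = RegionSUVRPanel(pid, dict(zip(regions, x)))
        record = ParticipantRecord(
            participant_id=pid,
            visual_rating=arch.visually_positive,
            diagnosis=str(diagnosis),
            mmse=mmse,
            cdr_sb=cdr,
            age=float(np.clip(prng.normal(67, 14), 30, 95).round(1)),
            sex="M" if prng.random() < 0.55 else "F",
            amyloid_status=amyloid,
            apoe4=apoe4,
        )
        records.append((record, panel))
        truth_rows.append(
            {
                "participant_id": pid,
                "archetype": arch.name,
                "severity": severity,
                "latent_burden": burden,
            }
        )

    return CohortTable(
        records=records,
        provenance=f"synthetic(seed={config.seed}, n={config.n})",
        truth=pd.DataFrame(truth_rows),
    )


@dataclass(frozen=True)
class ConcordanceLabel:
    participant_id: str
    concordant: bool
    #: meta-ROIs whose status disagrees with the visual rating
    disagreeing: tuple[str, ...]

    @property
    def label(self) -> str:
        return "concordant" if self.concordant else "discordant"


def label_concordance(
    cohort: CohortTable, meta: Mapping[str, MetaROIResult]
) -> dict[str, ConcordanceLabel]:
    """Visual-vs-meta-ROI concordance per participant.

    A scan is concordant when its visual status equals all three meta-ROI
    statuses; otherwise discordant, with the disagreeing meta-ROIs recorded.
    Participants with a missing visual rating are excluded (warning with a
    count in the log).
    """
    out: dict[str, ConcordanceLabel] = {}
    skipped = 0
    for rec, _ in cohort.records:
        pid = rec.participant_id
        if rec.visual_rating is None:
            skipped += 1
            continue
        if pid not in meta:
            raise ValidationError(f"no MetaROIResult for participant {pid}")
        result = meta[pid]
        statuses = dict(zip(("temporal", "mtl", "neo"), result.statuses()))
        disagreeing = tuple(
            roi for roi, status in statuses.items() if status != rec.visual_rating
        )
        out[pid] = ConcordanceLabel(pid, concordant=not disagreeing, disagreeing=disagreeing)
    if skipped:
        log.warning("label_concordance: excluded %d participant(s) without visual rating", skipped)
    return out
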