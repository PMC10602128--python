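"""Cohort data model and delimited-text I/O.

Two tables describe a cohort: a SUVR table (``participant_id`` plus one
column per atlas region, cerebellar-crus-referenced, unitless) and a metadata
table (visual tau rating, diagnosis, MMSE, CDR-SB, age, sex, amyloid status,
APOE4).  Files are comma-delimited UTF-8 with a header row; tab delimiters
are accepted via ``delimiter="\\t"``.  Missing clinical values are empty
cells and stay missing — nothing is imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .atlas import AtlasConfig
from .errors import FormatError, IntegrityError, ValidationError

log = logging.getLogger(__name__)

DIAGNOSES = ("CU", "MCI", "AD", "DLB")

METADATA_COLUMNS = (
    "participant_id",
    "visual_rating",
    "diagnosis",
    "mmse",
    "cdr_sb",
    "age",
    "sex",
    "amyloid_status",
    "apoe4",
)


@dataclass
class RegionSUVRPanel:
    """One participant's regional SUVR values in atlas order.

    SUVR values are unitless ratios referenced to the cerebellar crus and
    must be finite and strictly positive.
    """

    participant_id: str
    region_values: dict[str, float]

    def __post_init__(self) -> None:
        names = list(self.region_values)
        if len(set(names)) != len(names):
            raise ValidationError(
                f"duplicate region names for participant {self.participant_id}"
            )
        for region, value in self.region_values.items():
            v = float(value)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"participant {self.participant_id}: SUVR for region "
                    f"{region!r} must be finite and > 0, got {value!r}"
                )
            self.region_values[region] = v

    @property
    def m(self) -> int:
        return len(self.region_values)

    def values_in_order(self, regions: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.region_values[r] for r in regions], dtype=float)
        except KeyError as exc:
            raise ValidationError(
                f"participant {self.participant_id}: missing region {exc.args[0]!r}"
            ) from None


@dataclass
class ParticipantRecord:
    """Clinical metadata for one participant; optional fields may be None."""

    participant_id: str
    visual_rating: Optional[bool] = None
    diagnosis: Optional[str] = None
    mmse: Optional[int] = None
    cdr_sb: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    amyloid_status: Optional[bool] = None
    apoe4: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValidationError(
                f"participant {self.participant_id}: MMSE {self.mmse} outside [0, 30]"
            )
        if self.cdr_sb is not None and not 0 <= self.cdr_sb <= 18:
            raise ValidationError(
                f"participant {self.participant_id}: CDR-SB {self.cdr_sb} outside [0, 18]"
            )
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"participant {self.participant_id}: unknown diagnosis "
                f"{self.diagnosis!r} (expected one of {DIAGNOSES})"
            )


@dataclass
class CohortTable:
    """Joined (metadata, SUVR panel) records with a shared region ordering."""

    records: list[tuple[ParticipantRecord, RegionSUVRPanel]]
    provenance: str = ""
    #: optional simulation ground truth (archetype, latent burden) — set by
    #: the synthetic-cohort generator, absent for cohorts read from disk
    truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [rec.participant_id for rec, _ in self.records]
        if len(set(ids)) != len(ids):
            raise IntegrityError("participant_id values must be unique")
        region_lists = {tuple(panel.region_values) for _, panel in self.records}
        if len(region_lists) > 1:
            raise IntegrityError("every panel must share one region list and order")
        for rec, panel in self.records:
            if rec.participant_id != panel.participant_id:
                raise IntegrityError(
                    f"record/panel id mismatch: {rec.participant_id} vs "
                    f"{panel.participant_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def participant_ids(self) -> list[str]:
        return [rec.participant_id for rec, _ in self.records]

    @property
    def region_names(self) -> tuple[str, ...]:
        if not self.records:
            return ()
        return tuple(self.records[0][1].region_values)

    def suvr_matrix(self, regions: Optional[Iterable[str]] = None) -> np.ndarray:
        """n × m matrix of SUVRs in the given (default: stored) region order."""
        order = tuple(regions) if regions is not None else self.region_names
        return np.array(
            [panel.values_in_order(order) for _, panel in self.records], dtype=float
        )

    def visual_ratings(self) -> np.ndarray:
        """Visual ratings as a float array (1/0, NaN when missing)."""
        out = np.full(len(self.records), np.nan)
        for i, (rec, _) in enumerate(self.records):
            if rec.visual_rating is not None:
                out[i] = float(rec.visual_rating)
        return out

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for rec, _ in self.records:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "visual_rating": _encode_bool(rec.visual_rating),
                    "diagnosis": rec.diagnosis,
                    "mmse": rec.mmse,
                    "cdr_sb": rec.cdr_sb,
                    "age": rec.age,
                    "sex": rec.sex,
                    "amyloid_status": _encode_bool(rec.amyloid_status),
                    "apoe4": _encode_bool(rec.apoe4),
                }
            )
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))

    def suvr_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.suvr_matrix(), columns=list(self.region_names))
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def subset(self, ids: Iterable[str]) -> "CohortTable":
        wanted = set(ids)
        records = [
            (rec, panel) for rec, panel in self.records if rec.participant_id in wanted
        ]
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["participant_id"].isin(wanted)].reset_index(
                drop=True
            )
        return CohortTable(records=records, provenance=self.provenance, truth=truth)


def _encode_bool(v: Optional[bool]) -> Optional[int]:
    return None if v is None else int(v)


def _decode_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return bool(int(v))


def _decode_opt(v, cast):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return cast(v)


def load_cohort(
    suvr_path,
    metadata_path,
    atlas: AtlasConfig,
    delimiter: str = ",",
) -> CohortTable:
    """Read and join the SUVR and metadata tables into a :class:`CohortTable`.

    Panels are re-ordered to the atlas region order regardless of file column
    order.  Participants present in only one of the two files are reported
    (warning log) and dropped.  Non-numeric or non-positive SUVR cells raise
    :class:`ValidationError` naming the offending row.
    """
    suvr = pd.read_csv(
        suvr_path, sep=delimiter, dtype={"participant_id": str},
        float_precision="round_trip",
    )
    meta = pd.read_csv(metadata_path, sep=delimiter, dtype={"participant_id": str})

    for frame, path in ((suvr, suvr_path), (meta, metadata_path)):
        if "participant_id" not in frame.columns:
            raise FormatError(f"{path}: missing required column 'participant_id'")
        if frame["participant_id"].duplicated().any():
            dups = frame.loc[frame["participant_id"].duplicated(), "participant_id"]
            raise IntegrityError(
                f"{path}: duplicated participant_id values: {sorted(set(dups))}"
            )
    missing_regions = [r for r in atlas.region_names if r not in suvr.columns]
    if missing_regions:
        raise FormatError(
            f"{suvr_path}: missing region column(s): {missing_regions}"
        )
    missing_meta = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise FormatError(f"{metadata_path}: missing column(s): {missing_meta}")

    suvr_ids = set(suvr["participant_id"])
    meta_ids = set(meta["participant_id"])
    only_one = suvr_ids.symmetric_difference(meta_ids)
    if only_one:
        log.warning(
            "dropping %d participant(s) present in only one file: %s",
            len(only_one),
            sorted(only_one)[:10],
        )
    shared = suvr_ids & meta_ids

    for region in atlas.region_names:
        col = pd.to_numeric(suvr[region], errors="coerce")
        bad = suvr.loc[col.isna() & suvr[region].notna(), "participant_id"]
        if len(bad):
            raise ValidationError(
                f"{suvr_path}: non-numeric SUVR in column {region!r} for "
                f"participant(s) {list(bad)}"
            )
        suvr[region] = col

    meta = meta.set_index("participant_id")
    records: list[tuple[ParticipantRecord, RegionSUVRPanel]] = []
    for _, row in suvr[suvr["participant_id"].isin(shared)].iterrows():
        pid = row["participant_id"]
        panel = RegionSUVRPanel(
            participant_id=pid,
            region_values={r: row[r] for r in atlas.region_names},
        )
        mrow = meta.loc[pid]
        record = ParticipantRecord(
            participant_id=pid,
            visual_rating=_decode_bool(mrow["visual_rating"]),
            diagnosis=_decode_opt(mrow["diagnosis"], str),
            mmse=_decode_opt(mrow["mmse"], lambda v: int(round(float(v)))),
            cdr_sb=_decode_opt(mrow["cdr_sb"], float),
            age=_decode_opt(mrow["age"], float),
            sex=_decode_opt(mrow["sex"], str),
            amyloid_status=_decode_bool(mrow["amyloid_status"]),
            apoe4=_decode_bool(mrow["apoe4"]),
        )
        records.append((record, panel))
    return CohortTable(records=records, provenance=str(suvr_path))


def write_cohort(cohort: CohortTable, suvr_path, metadata_path, delimiter: str = ",") -> None:
    """Write the two cohort tables consumed by :func:`load_cohort`."""
    # %.17g guarantees exact binary round-trip of the SUVR values
    cohort.suvr_frame().to_csv(suvr_path, sep=delimiter, index=False, float_format="%.17g")
    cohort.metadata_frame().to_csv(metadata_path, sep=delimiter, index=False)


SCORE_FIXED_COLUMNS = (
    "participant_id",
    "temporal_suvr",
    "mtl_suvr",
    "neo_suvr",
    "temporal_pos",
    "mtl_pos",
    "neo_pos",
    "probability",
    "predicted_status",
    "theta",
)


def write_scores(
    cohort: CohortTable,
    results: Mapping[str, Mapping[str, float]],
    out_path,
    delimiter: str = ",",
) -> None:
    """Write the per-participant score table.

    ``results`` maps participant_id to a flat mapping holding the fixed
    score columns (meta-ROI SUVRs/statuses, predicted probability/status,
    theta) plus one ``theta_<region>`` entry per region.  An empty mapping
    yields a header-only file; ids absent from the cohort raise
    :class:`IntegrityError`.  Floats are written with 12 significant digits
    so a write/read round trip preserves at least 10.
    """
    known = set(cohort.participant_ids)
    unknown = set(results) - known
    if unknown:
        raise IntegrityError(f"results for unknown participant(s): {sorted(unknown)}")
    regions = cohort.region_names
    columns = list(SCORE_FIXED_COLUMNS) + [f"theta_{r}" for r in regions]
    rows = []
    for pid in cohort.participant_ids:  # cohort order, not dict order
        if pid not in results:
            continue
        row = {"participant_id": pid}
        row.update({k: results[pid].get(k) for k in columns[1:]})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(out_path, sep=delimiter, index=False, float_format="%.12g")


def read_scores(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    return pd.read_csv(path, sep=delimiter, dtype={"participant_id": str})
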