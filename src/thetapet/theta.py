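"""THETA: a heterogeneity-aware tau summary score.

For one scan with regional SUVRs ``x_i`` and Shapley attributions ``φ_i``
(i = 1..m), the score is the linear combination

    Θ = Σ_i φ_i  +  Σ_i φ̂_i · x_i

where ``φ̂_i = φ_i`` when φ_i lies within a percentile band of the SHAP
values (default 1st–99th, linear-interpolation percentiles) and 0
otherwise.  The first sum always runs over all m regions and equals the
model's deviation from its base probability; the second re-weights the
in-band attributions by the actual tracer uptake, so regions that both
drive the prediction and carry signal contribute most.  The per-region
decomposition θ_i = φ_i + φ̂_i·x_i sums to Θ exactly.

The percentile band may be taken over a scan's own m values
(``per_scan``, the default — keeps the score computable for a single
participant) or per region across a cohort (``cohort_per_region``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .attribution import ShapMatrix
from .cohort import CohortTable, RegionSUVRPanel
from .errors import ConfigError, IntegrityError


@dataclass(frozen=True)
class ThetaConfig:
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    percentile_scope: str = "per_scan"  # or "cohort_per_region"
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if not 0 <= self.lower_percentile < self.upper_percentile <= 100:
            raise ConfigError("need 0 <= lower < upper <= 100")
        if self.percentile_scope not in ("per_scan", "cohort_per_region"):
            raise ConfigError(f"unknown percentile_scope {self.percentile_scope!r}")


@dataclass(frozen=True)
class ThetaResult:
    theta: float
    regional_theta: dict[str, float]
    phi_sum: float
    weighted_sum: float
    included_mask: tuple[bool, ...]


def percentile_mask(phi_row: Sequence[float], cfg: ThetaConfig = ThetaConfig()) -> np.ndarray:
    """Inclusion mask for the weighted sum, per-scan scope.

    Bounds are the [lower, upper] percentiles of the row's own φ values
    (linear interpolation); region i is included iff
    ``lower_bound <= φ_i <= upper_bound``.  An all-equal row collapses the
    bounds onto the common value, so every region is included.
    """
    phi = np.asarray(phi_row, dtype=float)
    if phi.size < 2:
        raise ConfigError("percentile_mask needs at least 2 regions")
    lo, hi = np.percentile(
        phi, [cfg.lower_percentile, cfg.upper_percentile], method=cfg.interpolation
    )
    return (phi >= lo) & (phi <= hi)


def cohort_percentile_bounds(
    values: np.ndarray, cfg: ThetaConfig = ThetaConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region [lower, upper] percentile bounds across a cohort's φ matrix."""
    lo, hi = np.percentile(
        values,
        [cfg.lower_percentile, cfg.upper_percentile],
        axis=0,
        method=cfg.interpolation,
    )
    return lo, hi


def theta(
    phi_row: Sequence[float],
    panel: RegionSUVRPanel | Sequence[float],
    cfg: ThetaConfig = ThetaConfig(),
    region_names: Optional[Sequence[str]] = None,
    mask: Optional[np.ndarray] = None,
) -> ThetaResult:
    """Θ and its exact per-region decomposition for one scan.

    ``panel`` may be a :class:`RegionSUVRPanel` or a bare SUVR vector (then
    ``region_names`` labels the output).  ``mask`` overrides the per-scan
    percentile mask, which is how the cohort-per-region scope is applied.
    """
    phi = np.asarray(phi_row, dtype=float)
    if isinstance(panel, RegionSUVRPanel):
        names = list(panel.region_values)
        x = panel.values_in_order(names)
    else:
        x = np.asarray(panel, dtype=float)
        names = list(region_names) if region_names is not None else [
            f"region_{i}" for i in range(x.size)
        ]
    if phi.shape != x.shape:
        raise IntegrityError(
            f"attribution length {phi.size} does not match panel length {x.size}"
        )
    if mask is None:
        mask = percentile_mask(phi, cfg)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != phi.shape:
            raise IntegrityError("mask length does not match attribution length")
    phi_hat = np.where(mask, phi, 0.0)
    regional = phi + phi_hat * x
    phi_sum = float(np.sum(phi))
    weighted_sum = float(np.sum(phi_hat * x))
    return ThetaResult(
        theta=phi_sum + weighted_sum,
        regional_theta=dict(zip(names, regional.tolist())),
        phi_sum=phi_sum,
        weighted_sum=weighted_sum,
        included_mask=tuple(bool(b) for b in mask),
    )


def batch_theta(
    matrix: ShapMatrix,
    cohort: CohortTable,
    cfg: ThetaConfig = ThetaConfig(),
) -> pd.DataFrame:
    """Θ plus regional decomposition for every participant of a cohort.

    Returns a frame with ``participant_id``, ``theta``, ``phi_sum``,
    ``weighted_sum`` and one ``theta_<region>`` column per region.
    """
    if tuple(cohort.participant_ids) != matrix.participant_ids:
        raise IntegrityError("attribution matrix does not align with the cohort")
    X = cohort.suvr_matrix(matrix.region_names)
    if cfg.percentile_scope == "cohort_per_region":
        lo, hi = cohort_percentile_bounds(matrix.values, cfg)
        masks = (matrix.values >= lo) & (matrix.values <= hi)
    else:
        masks = np.stack([percentile_mask(row, cfg) for row in matrix.values])
    rows = []
    for i, pid in enumerate(matrix.participant_ids):
        res = theta(
            matrix.values[i], X[i], cfg,
            region_names=matrix.region_names, mask=masks[i],
        )
        row = {
            "participant_id": pid,
            "theta": res.theta,
            "phi_sum": res.phi_sum,
            "weighted_sum": res.weighted_sum,
        }
        row.update({f"theta_{r}": v for r, v in res.regional_theta.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def regional_theta_ranking(
    theta_table: pd.DataFrame, ids: Optional[Sequence[str]] = None
) -> pd.Series:
    """Median regional Θ per region for a subgroup, ranked ascending.

    Mirrors the construction of cohort-level regional profiles: select the
    subgroup, take the median of each region's θ_i, sort ascending so the
    strongest contributors appear last.
    """
    sub = theta_table
    if ids is not None:
        sub = theta_table[theta_table["participant_id"].isin(set(ids))]
    cols = [c for c in sub.columns if c.startswith("theta_")]
    medians = sub[cols].median()
    medians.index = [c[len("theta_"):] for c in cols]
    return medians.sort_values()
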