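"""Shapley-value attribution of the classifier's positive-class probability.

For a prediction function ``f`` and a panel ``x``, the attribution of region
``i`` is its Shapley value in the coalition game

    v(S) = E_b[ f(z) ],   z_j = x_j for j in S,  z_j = b_j otherwise,

where the expectation runs over rows ``b`` of a reference background sample
(the interventional, value-replacement formulation).  The base value is
``v(∅)``, the mean model output over the background, and by construction

    base_value + Σ_i φ_i = f(x)            (efficiency / additivity).

Two estimators are provided:

* :func:`exact_shapley` — full coalition enumeration, feasible for m ≤ 15
  regions.  Used as the oracle in tests and for reduced-atlas models.
* :func:`sampled_shapley` — permutation sampling with antithetic pairs
  (each drawn permutation is also traversed reversed, which cancels
  first-order noise).  After estimation the values are additively
  renormalized (a constant shared across regions) so that additivity holds
  to machine precision.

Both are deterministic given their seed and batch every model evaluation
into a single call, which keeps tree-ensemble scoring fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigError, FeasibilityError, IntegrityError

PredictFn = Callable[[np.ndarray], np.ndarray]

EXACT_MAX_REGIONS = 15


@dataclass
class ShapMatrix:
    """Per-participant, per-region attributions with their base value."""

    values: np.ndarray  # participants × regions, probability units
    base_value: float
    participant_ids: tuple[str, ...]
    region_names: tuple[str, ...]
    background_spec: dict = field(default_factory=dict)
    method: str = "exact"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participant_ids), len(self.region_names)):
            raise IntegrityError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.participant_ids)} participants × "
                f"{len(self.region_names)} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("attribution values must be finite")

    def row(self, participant_id: str) -> np.ndarray:
        return self.values[self.participant_ids.index(participant_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.region_names))
        df.insert(0, "participant_id", list(self.participant_ids))
        return df


def _coalition_means(
    predict_fn: PredictFn,
    x: np.ndarray,
    background: np.ndarray,
    inclusion: np.ndarray,
    chunk_rows: int = 400_000,
) -> np.ndarray:
    """v(S) for each coalition row of a boolean inclusion matrix.

    ``inclusion`` is (n_coalitions × m); entry True means the region takes
    the panel's value, False the background row's value.  Evaluations are
    batched: each coalition is expanded over all background rows and the
    model is called on large chunks.
    """
    n_c, m = inclusion.shape
    n_b = background.shape[0]
    out = np.empty(n_c)
    per = max(1, chunk_rows // n_b)
    for start in range(0, n_c, per):
        block = inclusion[start : start + per]
        Z = np.broadcast_to(background, (block.shape[0], n_b, m)).copy()
        mask = np.broadcast_to(block[:, None, :], Z.shape)
        Z[mask] = np.broadcast_to(x, Z.shape)[mask]
        preds = predict_fn(Z.reshape(-1, m))
        out[start : start + per] = np.asarray(preds).reshape(block.shape[0], n_b).mean(axis=1)
    return out


def exact_shapley(
    predict_fn: PredictFn,
    x: Sequence[float],
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration (m ≤ 15).

    Returns ``(phi, base_value)`` with ``base_value + phi.sum()`` equal to
    ``predict_fn(x)`` to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ConfigError("background must be a non-empty 2-D array")
    m = x.shape[0]
    if background.shape[1] != m:
        raise ConfigError("background column count must match panel length")
    if m > EXACT_MAX_REGIONS:
        raise FeasibilityError(
            f"exact enumeration over {m} regions (2^{m} coalitions) is "
            f"infeasible; use sampled_shapley for m > {EXACT_MAX_REGIONS}"
        )
    n_c = 1 << m
    codes = np.arange(n_c, dtype=np.uint32)
    inclusion = (codes[:, None] >> np.arange(m)) & 1
    inclusion = inclusion.astype(bool)
    v = _coalition_means(predict_fn, x, background, inclusion)

    sizes = inclusion.sum(axis=1)
    # w(s) = s!(m-s-1)!/m! for the coalition S (of size s) not containing i
    w = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    phi = np.empty(m)
    for i in range(m):
        without = ~inclusion[:, i]
        s_codes = codes[without]
        phi[i] = np.sum(
            w[sizes[without]] * (v[s_codes | (1 << i)] - v[s_codes])
        )
    base = float(v[0])
    return phi, base


def sampled_shapley(
    predict_fn: PredictFn,
    x: Sequence[float],
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley estimate with exact additivity.

    Antithetic pairs: each sampled permutation is also traversed in reverse.
    After averaging the marginal contributions, the residual
    ``f(x) − base − Σφ`` is spread equally over the m regions, restoring
    additivity to machine precision without biasing relative rankings.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ConfigError("background must be a non-empty 2-D array")
    m = x.shape[0]
    if background.shape[1] != m:
        raise ConfigError("background column count must match panel length")
    if n_permutations < 50:
        raise ConfigError("n_permutations must be >= 50")

    rng = np.random.default_rng(seed)
    n_pairs = (n_permutations + 1) // 2
    perms = np.empty((2 * n_pairs, m), dtype=np.intp)
    for p in range(n_pairs):
        perm = rng.permutation(m)
        perms[2 * p] = perm
        perms[2 * p + 1] = perm[::-1]
    n_perm = perms.shape[0]

    base = float(np.mean(predict_fn(background)))
    fx = float(np.asarray(predict_fn(x[None, :]))[0])

    # intermediate coalitions: inclusion[p, t] = {perm[p, 0..t]}, t < m-1
    inclusion = np.zeros((n_perm, m - 1, m), dtype=bool)
    for p in range(n_perm):
        acc = np.zeros(m, dtype=bool)
        for t in range(m - 1):
            acc[perms[p, t]] = True
            inclusion[p, t] = acc
    v_mid = _coalition_means(
        predict_fn, x, background, inclusion.reshape(-1, m)
    ).reshape(n_perm, m - 1)

    v_full = np.concatenate(
        [np.full((n_perm, 1), base), v_mid, np.full((n_perm, 1), fx)], axis=1
    )
    contrib = np.diff(v_full, axis=1)  # (n_perm, m): marginal of perm[p, t]
    phi = np.zeros(m)
    counts = np.zeros(m)
    np.add.at(phi, perms.ravel(), contrib.ravel())
    np.add.at(counts, perms.ravel(), 1.0)
    phi /= counts
    phi += (fx - base - phi.sum()) / m  # additive renormalization
    return phi, base


def attribution_matrix(
    model,
    cohort: CohortTable,
    background: CohortTable,
    method: str = "sampled",
    n_background: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
) -> ShapMatrix:
    """Stack per-participant attribution rows for a whole cohort.

    ``model`` is a :class:`~thetapet.classifier.TrainedClassifier` or any
    object exposing ``predict_proba_matrix``/callable semantics.  The
    background is a seeded subsample (default 100 rows) of the supplied
    reference cohort, typically the training set.
    """
    predict_fn = getattr(model, "predict_proba_matrix", model)
    regions = cohort.region_names
    if background.region_names != regions:
        raise IntegrityError("background and cohort must share one region ordering")
    bg_matrix = background.suvr_matrix()
    rng = np.random.default_rng(seed)
    if bg_matrix.shape[0] > n_background:
        idx = rng.choice(bg_matrix.shape[0], size=n_background, replace=False)
        bg_matrix = bg_matrix[np.sort(idx)]
    X = cohort.suvr_matrix()

    rows = np.empty_like(X)
    base = None
    for i in range(X.shape[0]):
        if method == "exact":
            phi, b = exact_shapley(predict_fn, X[i], bg_matrix)
        elif method == "sampled":
            phi, b = sampled_shapley(
                predict_fn, X[i], bg_matrix, n_permutations=n_permutations,
                seed=seed + i,
            )
        else:
            raise ConfigError(f"unknown attribution method {method!r}")
        rows[i] = phi
        base = b
    return ShapMatrix(
        values=rows,
        base_value=float(base),
        participant_ids=tuple(cohort.participant_ids),
        region_names=regions,
        background_spec={
            "n_background": int(bg_matrix.shape[0]),
            "source": background.provenance,
            "seed": seed,
            "n_permutations": n_permutations if method == "sampled" else None,
        },
        method=method,
    )


def check_additivity(
    matrix: ShapMatrix,
    model,
    cohort: CohortTable,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-participant residual |base + Σφ − p| with an over-tolerance flag."""
    predict_fn = getattr(model, "predict_proba_matrix", model)
    if tuple(cohort.participant_ids) != matrix.participant_ids:
        raise IntegrityError("matrix rows do not align with the cohort")
    p = np.asarray(predict_fn(cohort.suvr_matrix(matrix.region_names)))
    residual = np.abs(matrix.base_value + matrix.values.sum(axis=1) - p)
    return pd.DataFrame(
        {
            "participant_id": list(matrix.participant_ids),
            "residual": residual,
            "flagged": residual > tol,
        }
    )
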