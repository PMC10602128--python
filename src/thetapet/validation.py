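"""Validation experiments on synthetic cohorts and published comparison tables.

These routines back the package's claims about itself: agreement-rate
arithmetic against the published visual-vs-meta-ROI/model comparison
tables, oracle equivalence of the Shapley estimators, additivity of the
attributions, the THETA closed form, classifier recovery on the default
heterogeneous cohort, THETA repeatability across model reruns, and the
direction of the tau-positive/negative separation.  The same functions are
exercised by the test suite and by ``scripts/acceptance.py``.

Problem sizes (cohort sizes, permutation counts, background sizes) are
desk-scale: large enough for stable estimates on a single CPU, small
enough to rerun routinely; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import factorial
from typing import Optional, Sequence

import numpy as np

from .attribution import attribution_matrix, check_additivity, exact_shapley, sampled_shapley
from .atlas import AtlasConfig, default_atlas
from .classifier import repeated_runs, stratified_split, train_ensemble
from .cohort import CohortTable, RegionSUVRPanel
from .metaroi import classify_meta_roi, temporal_suvr
from .simulate import SimulationConfig, generate_cohort, label_concordance
from .stats import (
    classification_metrics,
    cohens_d_ttest,
    confusion_rates,
    icc_across_runs,
)
from .theta import ThetaConfig, batch_theta, theta

# Published visual-vs-comparator confusion counts (TP, TN) with the cohort
# totals of visually positive/negative scans.  These printed counts are the
# *inputs*; the mismatch percentages are recomputed from them.
PUBLISHED_CONFUSIONS: dict[str, dict[str, tuple[int, int]]] = {
    "mayo": {"temporal": (227, 796), "mtl": (191, 993), "neo": (185, 1028), "model": (236, 1040)},
    "adni": {"temporal": (214, 397), "mtl": (180, 526), "neo": (161, 579), "model": (179, 587)},
    "oasis3": {"temporal": (50, 260), "mtl": (40, 329), "neo": (40, 352), "model": (46, 364)},
}
#: visually positive / visually negative totals per cohort
PUBLISHED_TOTALS: dict[str, tuple[int, int]] = {
    "mayo": (245, 1045),
    "adni": (230, 601),
    "oasis3": (61, 369),
}


def table_comparison_rates() -> dict[str, dict[str, float]]:
    """Recompute every published mismatch percentage from its confusion counts.

    For each cohort/comparator cell, a reference and comparator label vector
    realizing the printed (TP, TN, totals) is constructed and run through
    :func:`confusion_rates`.  Returns
    ``{"<cohort>_<comparator>_pos_mismatch_pct": {"value": ..., "n": ...}, ...}``.
    """
    out: dict[str, dict[str, float]] = {}
    for cohort, cells in PUBLISHED_CONFUSIONS.items():
        n_pos, n_neg = PUBLISHED_TOTALS[cohort]
        for comparator, (tp, tn) in cells.items():
            reference = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
            predicted = np.concatenate(
                [
                    np.ones(tp, int), np.zeros(n_pos - tp, int),      # positives
                    np.zeros(tn, int), np.ones(n_neg - tn, int),      # negatives
                ]
            )
            rep = confusion_rates(reference, predicted)
            n = n_pos + n_neg
            out[f"{cohort}_{comparator}_pos_mismatch_pct"] = {
                "value": rep.pos_mismatch_pct(), "n": n,
            }
            out[f"{cohort}_{comparator}_neg_mismatch_pct"] = {
                "value": rep.neg_mismatch_pct(), "n": n,
            }
    return out


# --------------------------------------------------------------------------
# Shapley oracles


def brute_force_shapley(predict_fn, x, background) -> tuple[np.ndarray, float]:
    """Direct textbook summation over all coalitions (independent oracle).

    Implemented with explicit subset loops and factorial weights, sharing no
    code with :func:`exact_shapley`.  Only usable for a handful of regions.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    m = x.size

    def v(subset: tuple[int, ...]) -> float:
        Z = background.copy()
        for j in subset:
            Z[:, j] = x[j]
        return float(np.mean(predict_fn(Z)))

    phi = np.zeros(m)
    others = list(range(m))
    for i in range(m):
        rest = [j for j in others if j != i]
        for size in range(m):
            for S in combinations(rest, size):
                w = factorial(size) * factorial(m - size - 1) / factorial(m)
                phi[i] += w * (v(tuple(S) + (i,)) - v(S))
    return phi, v(())


def _oracle_model(m: int):
    """A smooth, interaction-bearing probability model on m features."""

    def f(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (
            1.6 * X[:, 0]
            + 1.1 * X[:, 1 % m]
            - 0.7 * X[:, 2 % m] * X[:, 3 % m]
            + 0.4 * X[:, (m - 1)]
            - 1.2
        )
        return 1.0 / (1.0 + np.exp(-z))

    return f


def shapley_oracle_deviations(seed: int = 0) -> dict[str, dict[str, float]]:
    """Estimator agreement: sampled vs exact (m=8) and exact vs brute force (m=3)."""
    rng = np.random.default_rng(seed)

    m8 = 8
    f8 = _oracle_model(m8)
    bg8 = rng.normal(1.1, 0.25, size=(50, m8))
    x8 = rng.normal(1.4, 0.3, size=m8)
    phi_exact, base_exact = exact_shapley(f8, x8, bg8)
    phi_sampled, base_sampled = sampled_shapley(
        f8, x8, bg8, n_permutations=2000, seed=seed + 1
    )
    sampled_dev = float(np.max(np.abs(phi_sampled - phi_exact)))

    m3 = 3
    f3 = _oracle_model(m3)
    bg3 = rng.normal(1.1, 0.25, size=(20, m3))
    x3 = rng.normal(1.4, 0.3, size=m3)
    phi_e3, base_e3 = exact_shapley(f3, x3, bg3)
    phi_b3, base_b3 = brute_force_shapley(f3, x3, bg3)
    brute_dev = float(
        max(np.max(np.abs(phi_e3 - phi_b3)), abs(base_e3 - base_b3))
    )
    return {
        "sampled_vs_exact_max_dev": {"value": sampled_dev, "n": 2000},
        "exact_vs_bruteforce_max_dev": {"value": brute_dev, "n": 2 ** m3},
    }


# --------------------------------------------------------------------------
# Synthetic-cohort experiments


def default_cohort(seed: int, n: int = 2000) -> CohortTable:
    """The default heterogeneous synthetic cohort (Mayo-like mix)."""
    return generate_cohort(SimulationConfig(n=n, seed=seed))


def _concordance_labels(cohort: CohortTable, atlas: Optional[AtlasConfig] = None):
    atlas = atlas or default_atlas()
    meta = {
        rec.participant_id: classify_meta_roi(panel, atlas)
        for rec, panel in cohort.records
    }
    return {pid: lab.label for pid, lab in label_concordance(cohort, meta).items()}, meta


def restrict_regions(cohort: CohortTable, regions: Sequence[str]) -> CohortTable:
    """A copy of the cohort whose panels keep only the given regions."""
    regions = list(regions)
    records = [
        (
            rec,
            RegionSUVRPanel(
                panel.participant_id,
                {r: panel.region_values[r] for r in regions},
            ),
        )
        for rec, panel in cohort.records
    ]
    return CohortTable(records=records, provenance=cohort.provenance, truth=cohort.truth)


REDUCED_REGIONS = (
    "entorhinal",
    "amygdala",
    "fusiform",
    "inferior_temporal",
    "middle_temporal",
    "superior_temporal",
    "lateral_occipital",
    "precuneus",
)


def additivity_residuals(
    seed: int = 0,
    n: int = 500,
    n_background: int = 8,
    n_permutations: int = 50,
) -> dict[str, dict[str, float]]:
    """Max additivity residual |base + Σφ − p| over a scored synthetic cohort.

    The sampled estimator runs on the full 41-region panel; the exact
    enumerator on a reduced 8-region panel (enumeration is infeasible at 41).
    """
    cohort = default_cohort(seed, n=n)
    conc, _ = _concordance_labels(cohort)

    split = stratified_split(cohort, conc, seed=seed)
    model = train_ensemble(cohort, split, seed=seed)
    train_cohort = cohort.subset(split.train_ids)
    matrix = attribution_matrix(
        model, cohort, train_cohort, method="sampled",
        n_background=n_background, n_permutations=n_permutations, seed=seed,
    )
    sampled_max = float(check_additivity(matrix, model, cohort)["residual"].max())

    reduced = restrict_regions(cohort, REDUCED_REGIONS)
    reduced_atlas = AtlasConfig(
        region_names=REDUCED_REGIONS,
        meta_roi_membership={
            "temporal": ("entorhinal", "amygdala", "fusiform",
                         "inferior_temporal", "middle_temporal"),
            "mtl": ("entorhinal", "amygdala"),
            "neo": ("middle_temporal", "inferior_temporal"),
        },
    )
    split_r = stratified_split(reduced, conc, seed=seed)
    model_r = train_ensemble(reduced, split_r, seed=seed, atlas=reduced_atlas)
    matrix_r = attribution_matrix(
        model_r, reduced, reduced.subset(split_r.train_ids),
        method="exact", n_background=n_background, seed=seed,
    )
    exact_max = float(check_additivity(matrix_r, model_r, reduced)["residual"].max())
    return {
        "additivity_max_residual_sampled": {"value": sampled_max, "n": n},
        "additivity_max_residual_exact": {"value": exact_max, "n": n},
    }


def theta_closed_form_error(seed: int = 0, n: int = 200, m: int = 41) -> dict:
    """Against the all-regions-included closed form Θ = Σφ(1+x), plus the
    exactness of the per-region decomposition."""
    rng = np.random.default_rng(seed)
    cfg = ThetaConfig(lower_percentile=0, upper_percentile=100)
    max_err = 0.0
    max_decomp = 0.0
    for _ in range(n):
        phi = rng.uniform(-0.2, 0.2, size=m)
        x = rng.uniform(0.6, 2.8, size=m)
        res = theta(phi, x, cfg)
        closed = float(np.sum(phi * (1.0 + x)))
        max_err = max(max_err, abs(res.theta - closed))
        max_decomp = max(
            max_decomp, abs(sum(res.regional_theta.values()) - res.theta)
        )
    return {
        "theta_closed_form_max_err": {"value": max_err, "n": n},
        "theta_decomposition_max_err": {"value": max_decomp, "n": n},
    }


def shuffle_visual_ratings(cohort: CohortTable, seed: int) -> CohortTable:
    """Copy of the cohort with visual ratings permuted across participants."""
    rng = np.random.default_rng(seed)
    ratings = [rec.visual_rating for rec, _ in cohort.records]
    perm = rng.permutation(len(ratings))
    records = [
        (dataclasses.replace(rec, visual_rating=ratings[perm[i]]), panel)
        for i, (rec, panel) in enumerate(cohort.records)
    ]
    return CohortTable(records=records, provenance=cohort.provenance + "|shuffled")


def classifier_recovery(
    seed: int = 0,
    n: int = 2000,
    n_runs: int = 10,
    n_null_seeds: int = 10,
    cohort: Optional[CohortTable] = None,
) -> dict[str, dict[str, float]]:
    """Recovery of visual labels on the default heterogeneous cohort.

    Reports the held-out balanced accuracy of a single default fit, the mean
    shuffled-label balanced accuracy over ``n_null_seeds`` refits, and the
    standard deviation (percentage points) of the balanced accuracy across
    ``n_runs`` re-splits.
    """
    cohort = cohort if cohort is not None else default_cohort(seed, n=n)
    conc, _ = _concordance_labels(cohort)

    split = stratified_split(cohort, conc, seed=seed)
    model = train_ensemble(cohort, split, seed=seed)
    test = cohort.subset(split.test_ids)
    proba = model.predict_proba_matrix(test.suvr_matrix(model.feature_order))
    y = test.visual_ratings().astype(int)
    report = classification_metrics(y, (proba > 0.5).astype(int), proba)

    null_accs = []
    for s in range(n_null_seeds):
        shuffled = shuffle_visual_ratings(cohort, seed + 100 + s)
        conc_s, _ = _concordance_labels(shuffled)
        split_s = stratified_split(shuffled, conc_s, seed=seed + 100 + s)
        model_s = train_ensemble(shuffled, split_s, seed=seed + 100 + s)
        test_s = shuffled.subset(split_s.test_ids)
        proba_s = model_s.predict_proba_matrix(
            test_s.suvr_matrix(model_s.feature_order)
        )
        y_s = test_s.visual_ratings().astype(int)
        null_accs.append(
            classification_metrics(y_s, (proba_s > 0.5).astype(int)).balanced_accuracy
        )

    runs = repeated_runs(cohort, conc, n_runs=n_runs, base_seed=seed + 1000)
    balaccs = [rep.balanced_accuracy for _, rep in runs]
    return {
        "test_balanced_accuracy": {"value": float(report.balanced_accuracy), "n": len(y)},
        "test_roc_auc": {"value": float(report.roc_auc), "n": len(y)},
        "shuffled_balanced_accuracy": {
            "value": float(np.mean(null_accs)), "n": n_null_seeds,
        },
        "repeated_runs_balacc_sd_pct": {
            "value": float(np.std(balaccs, ddof=1) * 100), "n": n_runs,
        },
    }


def theta_repeatability(
    seed: int = 0,
    n: int = 600,
    n_runs: int = 10,
    n_scored: int = 60,
    n_background: int = 8,
    n_permutations: int = 50,
) -> dict[str, dict[str, float]]:
    """ICC(2,1) of Θ across model reruns on one fixed synthetic cohort.

    The cohort and the scored-participant subset stay fixed; each run
    re-splits and refits with its own seed, re-attributes the subset and
    recomputes Θ.  Agreement across the runs-as-raters is ICC(2,1).
    """
    cohort = default_cohort(seed, n=n)
    conc, _ = _concordance_labels(cohort)
    rng = np.random.default_rng(seed)
    scored_ids = [
        cohort.participant_ids[i]
        for i in np.sort(rng.choice(len(cohort), size=n_scored, replace=False))
    ]
    scored = cohort.subset(scored_ids)

    thetas = np.empty((n_scored, n_runs))
    cfg = ThetaConfig()
    for r in range(n_runs):
        run_seed = seed + 10 + r
        split = stratified_split(cohort, conc, seed=run_seed)
        model = train_ensemble(cohort, split, seed=run_seed)
        matrix = attribution_matrix(
            model, scored, cohort.subset(split.train_ids), method="sampled",
            n_background=n_background, n_permutations=n_permutations, seed=run_seed,
        )
        table = batch_theta(matrix, scored, cfg)
        thetas[:, r] = table["theta"].to_numpy()
    icc = icc_across_runs(thetas)
    return {"theta_rerun_icc": {"value": float(icc), "n": n_scored}}


def separation_effect_sizes(
    seed: int = 0,
    n: int = 2000,
    n_scored: int = 250,
    n_background: int = 8,
    n_permutations: int = 50,
    cohort: Optional[CohortTable] = None,
) -> dict[str, dict[str, float]]:
    """Cohen's d (visual+ vs visual−) for Θ and for the temporal meta-ROI SUVR.

    Computed on one seeded subsample of the default heterogeneous cohort
    (which contains the discordant archetypes), scoring the same
    participants with both measures.
    """
    atlas = default_atlas()
    cohort = cohort if cohort is not None else default_cohort(seed, n=n)
    conc, _ = _concordance_labels(cohort, atlas)
    split = stratified_split(cohort, conc, seed=seed)
    model = train_ensemble(cohort, split, seed=seed)

    rng = np.random.default_rng(seed + 1)
    scored_ids = [
        cohort.participant_ids[i]
        for i in np.sort(rng.choice(len(cohort), size=n_scored, replace=False))
    ]
    scored = cohort.subset(scored_ids)
    matrix = attribution_matrix(
        model, scored, cohort.subset(split.train_ids), method="sampled",
        n_background=n_background, n_permutations=n_permutations, seed=seed,
    )
    table = batch_theta(matrix, scored)
    vis = scored.visual_ratings().astype(bool)
    theta_vals = table["theta"].to_numpy()
    temporal = np.array(
        [temporal_suvr(panel, atlas) for _, panel in scored.records]
    )
    d_theta = cohens_d_ttest(theta_vals[vis], theta_vals[~vis]).cohens_d
    d_temporal = cohens_d_ttest(temporal[vis], temporal[~vis]).cohens_d
    return {
        "cohens_d_theta": {"value": float(d_theta), "n": n_scored},
        "cohens_d_temporal_metaroi": {"value": float(d_temporal), "n": n_scored},
    }
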