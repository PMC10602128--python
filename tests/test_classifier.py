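"""Stratified splitting and the bagged stack ensemble."""

import dataclasses

import numpy as np
import pytest

from thetapet.atlas import AtlasConfig
from thetapet.classifier import (
    load_model,
    predict_proba,
    predict_status,
    repeated_runs,
    save_model,
    stratified_split,
    train_ensemble,
)
from thetapet.cohort import CohortTable, ParticipantRecord, RegionSUVRPanel
from thetapet.errors import ConfigError, FeatureMismatchError, TrainingError
from thetapet.simulate import SimulationConfig, default_archetypes, generate_cohort


def _two_region_cohort(n=400, seed=0, sep=1.0):
    """Linearly separable toy cohort on two regions."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        positive = i < n // 4
        a = rng.normal(1.0 + sep * positive, 0.1)
        b = rng.normal(1.0 + sep * positive, 0.1)
        records.append(
            (
                ParticipantRecord(f"t{i:03d}", visual_rating=positive),
                RegionSUVRPanel(f"t{i:03d}", {"a": max(a, 0.5), "b": max(b, 0.5)}),
            )
        )
    return CohortTable(records=records)


TWO_REGION_ATLAS = AtlasConfig(
    region_names=("a", "b"),
    meta_roi_membership={"temporal": ("a", "b"), "mtl": ("a",), "neo": ("b",)},
)


class TestStratifiedSplit:
    def test_per_stratum_share_within_one(self, synth_cohort, concordance):
        split = stratified_split(synth_cohort, concordance, 0.20, seed=3)
        by_stratum = {}
        for pid, label in split.strata.items():
            by_stratum.setdefault(label, []).append(pid)
        test_ids = set(split.test_ids)
        for label, members in by_stratum.items():
            if len(members) == 1:
                continue
            got = sum(p in test_ids for p in members)
            ideal = len(members) * 0.20
            assert abs(got - ideal) <= 1.0

    def test_cohort_of_1290_splits_near_80_20(self, concordance):
        cohort = generate_cohort(SimulationConfig(n=1290, seed=13))
        meta_free = {pid: "na" for pid in cohort.participant_ids}
        split = stratified_split(cohort, meta_free, 0.20, seed=13)
        assert len(split.train_ids) + len(split.test_ids) == 1290
        assert abs(len(split.test_ids) - 258) <= 2  # 20% of 1290, ±1 per stratum

    def test_singleton_positive_goes_to_train(self):
        cohort = _two_region_cohort(n=10, seed=1)
        # keep exactly one positive
        records = [
            (dataclasses.replace(rec, visual_rating=(i == 0)), panel)
            for i, (rec, panel) in enumerate(cohort.records)
        ]
        cohort = CohortTable(records=records)
        split = stratified_split(cohort, None, 0.2, seed=0)
        assert cohort.participant_ids[0] in split.train_ids

    def test_deterministic_given_seed(self, synth_cohort, concordance):
        a = stratified_split(synth_cohort, concordance, 0.2, seed=9)
        b = stratified_split(synth_cohort, concordance, 0.2, seed=9)
        assert a == b

    def test_covers_cohort_disjointly(self, synth_cohort, concordance, split):
        ids = set(synth_cohort.participant_ids)
        assert set(split.train_ids) | set(split.test_ids) == ids
        assert not set(split.train_ids) & set(split.test_ids)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_test_fraction_bounds(self, bad, synth_cohort, concordance):
        with pytest.raises(ConfigError):
            stratified_split(synth_cohort, concordance, bad, seed=0)


class TestTrainEnsemble:
    def test_base_learner_count_follows_k_and_repeats(self):
        cohort = _two_region_cohort()
        split = stratified_split(cohort, None, 0.2, seed=0)
        model = train_ensemble(
            cohort, split, k=5, repeats=2, seed=0, atlas=TWO_REGION_ATLAS
        )
        assert model.fit_metadata["n_base_learners"] == 10
        assert sum(len(fold) for fold in model.base_learners) == 10

    def test_separable_cohort_recovered(self):
        cohort = _two_region_cohort(n=400)
        split = stratified_split(cohort, None, 0.2, seed=0)
        model = train_ensemble(cohort, split, seed=0, atlas=TWO_REGION_ATLAS)
        test = cohort.subset(split.test_ids)
        proba = model.predict_proba_matrix(test.suvr_matrix(model.feature_order))
        y = test.visual_ratings()
        pred = proba > 0.5
        tpr = np.mean(pred[y == 1])
        tnr = np.mean(~pred[y == 0])
        assert (tpr + tnr) / 2 >= 0.95

    def test_single_class_training_rejected(self):
        cohort = _two_region_cohort(n=40)
        records = [
            (dataclasses.replace(rec, visual_rating=False), panel)
            for rec, panel in cohort.records
        ]
        cohort = CohortTable(records=records)
        split = stratified_split(cohort, None, 0.2, seed=0)
        with pytest.raises(TrainingError, match="single class"):
            train_ensemble(cohort, split, seed=0, atlas=TWO_REGION_ATLAS)

    def test_out_of_fold_discipline(self):
        """No base learner contributes stacker inputs for rows it was fit on."""
        cohort = _two_region_cohort(n=200)
        split = stratified_split(cohort, None, 0.2, seed=0)
        model = train_ensemble(cohort, split, k=4, repeats=2, seed=0,
                               atlas=TWO_REGION_ATLAS)
        for fit_folds, oof_folds in zip(
            model.fit_metadata["fit_rows"], model.fit_metadata["oof_rows"]
        ):
            n_rows = len(model.fit_metadata["train_ids"])
            covered = np.concatenate(oof_folds)
            assert sorted(covered) == list(range(n_rows))  # every row scored once
            for fit_idx, oof_idx in zip(fit_folds, oof_folds):
                assert not set(fit_idx) & set(oof_idx)

    def test_probability_range(self, model, synth_cohort):
        proba = model.predict_proba_matrix(synth_cohort.suvr_matrix(model.feature_order))
        assert np.all((proba >= 0) & (proba <= 1))

    def test_accuracy_degrades_as_shifts_shrink(self):
        """Scaling every archetype shift toward zero erodes separability."""
        accs = []
        for scale in (1.0, 0.3, 0.05):
            archs = tuple(
                dataclasses.replace(
                    a,
                    mean_shift={r: v * scale for r, v in a.mean_shift.items()},
                )
                for a in default_archetypes()
            )
            cohort = generate_cohort(
                SimulationConfig(n=600, seed=21, archetypes=archs)
            )
            split = stratified_split(cohort, None, 0.2, seed=21)
            m = train_ensemble(cohort, split, k=3, repeats=1, seed=21)
            test = cohort.subset(split.test_ids)
            proba = m.predict_proba_matrix(test.suvr_matrix(m.feature_order))
            y = test.visual_ratings()
            pred = proba > 0.5
            accs.append((np.mean(pred[y == 1]) + np.mean(~pred[y == 0])) / 2)
        assert accs[0] > accs[2] + 0.2
        assert accs[0] >= accs[1] - 0.02 and accs[1] >= accs[2] - 0.02


class TestPrediction:
    def test_region_order_of_panel_is_irrelevant(self, model, synth_cohort):
        _, panel = synth_cohort.records[0]
        reordered = RegionSUVRPanel(
            panel.participant_id,
            {r: panel.region_values[r] for r in reversed(list(panel.region_values))},
        )
        assert predict_proba(model, panel) == predict_proba(model, reordered)

    def test_identical_panels_identical_probability(self, model, synth_cohort):
        _, panel = synth_cohort.records[3]
        assert predict_proba(model, panel) == predict_proba(model, panel)

    def test_row_order_invariance(self, model, synth_cohort):
        X = synth_cohort.suvr_matrix(model.feature_order)[:50]
        perm = np.random.default_rng(0).permutation(50)
        direct = model.predict_proba_matrix(X)[perm]
        shuffled = model.predict_proba_matrix(X[perm])
        np.testing.assert_array_equal(direct, shuffled)

    def test_region_mismatch_lists_differences(self, model):
        panel = RegionSUVRPanel("p", {"a": 1.0, "b": 1.0})
        with pytest.raises(FeatureMismatchError, match="missing"):
            predict_proba(model, panel)

    def test_status_threshold_is_strict(self, model, synth_cohort):
        _, panel = synth_cohort.records[0]
        p = predict_proba(model, panel)
        assert predict_status(model, panel, threshold=p) is False
        assert predict_status(model, panel, threshold=1.0) is False
        if p > 0:
            assert predict_status(model, panel, threshold=p / 2) is True

    def test_strong_training_positive_scores_high(self, model, synth_cohort, split):
        truth = synth_cohort.truth.set_index("participant_id")
        diffuse_train = [
            pid for pid in split.train_ids
            if truth.loc[pid, "archetype"] == "diffuse"
            and truth.loc[pid, "severity"] > 1.0
        ]
        _, panel = synth_cohort.subset(diffuse_train[:1]).records[0]
        assert predict_proba(model, panel) > 0.5

    def test_model_round_trips_bit_identically(self, model, synth_cohort, tmp_path):
        X = synth_cohort.suvr_matrix(model.feature_order)[:20]
        save_model(model, tmp_path / "m.pkl", "deadbeef")
        loaded, tag = load_model(tmp_path / "m.pkl")
        assert tag == "deadbeef"
        np.testing.assert_array_equal(
            model.predict_proba_matrix(X), loaded.predict_proba_matrix(X)
        )


class TestRepeatedRuns:
    def test_requires_at_least_two_runs(self, synth_cohort, concordance):
        with pytest.raises(ConfigError):
            repeated_runs(synth_cohort, concordance, n_runs=1, base_seed=0)

    def test_same_base_seed_reproduces_metrics(self):
        cohort = _two_region_cohort(n=200)
        a = repeated_runs(cohort, None, n_runs=2, base_seed=5, k=3, repeats=1,
                          atlas=TWO_REGION_ATLAS)
        b = repeated_runs(cohort, None, n_runs=2, base_seed=5, k=3, repeats=1,
                          atlas=TWO_REGION_ATLAS)
        assert [r.balanced_accuracy for _, r in a] == [
            r.balanced_accuracy for _, r in b
        ]
        assert [r.mcc for _, r in a] == [r.mcc for _, r in b]
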