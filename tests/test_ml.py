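"""Two-step classification + random-forest profile model."""

import numpy as np
import pytest

from capstress import (
    ClassifierModel,
    DesignMatrix,
    GridSpec,
    RfParams,
    build_training_table,
    default_grid_spec,
    fit_classifier,
    fit_rf,
    make_protocol,
    predict_open,
    predict_profile,
    simulate_dataset,
    simulate_grid,
    susceptibility_map,
)
from capstress.exceptions import CVConfigError, DegenerateTrainingError, InputError
from capstress.simulator import reported_labels


@pytest.fixture(scope="module")
def reported_label_classifier(training_design):
    """Classifier trained on the 16 basic+additional runs with the observed
    open/closed outcomes."""
    return fit_classifier(training_design, reported_labels(training_design))


@pytest.fixture(scope="module")
def fitted_models(training_design, default_params):
    profiles, labels = simulate_dataset(training_design, default_params)
    classifier = fit_classifier(training_design, labels)
    table = build_training_table(profiles, labels, training_design)
    rf = fit_rf(table, RfParams(n_trees=150, seed=7), cv_folds=10)
    return classifier, rf, table


class TestClassifier:
    def test_separates_training_runs_perfectly(self, training_design, reported_label_classifier):
        labels = {l.test_id: l.state for l in reported_labels(training_design)}
        for run in training_design:
            state, _ = predict_open(
                reported_label_classifier, run.stress.pressure, run.stress.timing
            )
            assert state == labels[run.test_id], run.test_id

    def test_early_stress_always_closed(self, reported_label_classifier):
        for p in np.linspace(80, 220, 29):
            state, z = predict_open(reported_label_classifier, p, 9.0)
            assert state == "closed"

    @pytest.mark.parametrize("pressure", [125.0, 175.0])
    def test_half_past_ten_opens(self, reported_label_classifier, pressure):
        state, _ = predict_open(reported_label_classifier, pressure, 10.5)
        assert state == "open"

    def test_confidence_scale(self, reported_label_classifier):
        for p, t in [(80, 8), (220, 16), (150, 10)]:
            _, z = predict_open(reported_label_classifier, p, t)
            assert 0.0 <= z <= 100.0
        _, z_closed = predict_open(reported_label_classifier, 100, 9)
        assert z_closed < 5.0

    def test_tie_assigned_open(self):
        model = ClassifierModel(intercept=-10.0, w_pressure=0.0, w_timing=1.0)
        state, z = predict_open(model, 150.0, 10.0)  # logit exactly 0
        assert state == "open" and z == pytest.approx(50.0)

    def test_single_class_rejected(self, training_design):
        from capstress import ClassLabel

        labels = [ClassLabel(r.test_id, "open") for r in training_design]
        with pytest.raises(DegenerateTrainingError):
            fit_classifier(training_design, labels)

    def test_missing_labels_rejected(self, training_design):
        with pytest.raises(InputError):
            fit_classifier(training_design, reported_labels(training_design)[:-1])


class TestTrainingTable:
    def test_instance_count(self, fitted_models):
        _, _, table = fitted_models
        assert len(table) == 16 * 34

    def test_single_run_preserves_time_order(self, default_params):
        design = DesignMatrix((make_protocol("solo", 150, 12),))
        profiles, labels = simulate_dataset(design, default_params)
        table = build_training_table(profiles, labels, design)
        assert len(table) == 34
        assert (np.diff(table["time_min"]) > 0).all()

    def test_closed_runs_carry_state_zero(self, fitted_models):
        _, _, table = fitted_models
        closed = table[table.test_id.isin(["Test 6", "Test 11", "Test 12", "Test 14"])]
        assert (closed["state"] == 0).all()
        assert (table[~table.test_id.isin(closed.test_id)]["state"] == 1).all()

    def test_label_mismatch_rejected(self, training_design, default_params):
        profiles, labels = simulate_dataset(training_design, default_params)
        with pytest.raises(InputError):
            build_training_table(profiles, labels[:-1], training_design)


class TestRandomForest:
    def test_constant_target_predicted_exactly(self, fitted_models):
        _, _, table = fitted_models
        const = table.copy()
        const["dissolved"] = 55.0
        rf = fit_rf(const, RfParams(n_trees=30, seed=1), cv_folds=None)
        pred = rf.predict_values(1, 150, 12, np.array([3.0, 20.0, 60.0]))
        assert np.allclose(pred, 55.0)

    def test_deterministic_given_seed(self, fitted_models):
        _, _, table = fitted_models
        a = fit_rf(table, RfParams(n_trees=60, seed=3), cv_folds=None)
        b = fit_rf(table, RfParams(n_trees=60, seed=3), cv_folds=None)
        times = np.asarray([3.0, 15.0, 25.0, 45.0])
        assert np.array_equal(
            a.predict_values(1, 160, 11, times), b.predict_values(1, 160, 11, times)
        )

    def test_resubstitution_beats_grouped_cv(self, fitted_models):
        """Full-depth trees memorize the training runs, so the resubstitution
        error is far below the held-out grouped-CV error."""
        _, rf, table = fitted_models
        X = table[["state", "pressure", "timing", "time_min"]].to_numpy()
        resub_mae = float(np.mean(np.abs(rf.regressor.predict(X) - table["dissolved"])))
        assert rf.cv_report is not None
        assert resub_mae < 0.5 * rf.cv_report.mae

    def test_cv_needs_enough_runs(self, default_params):
        design = DesignMatrix(tuple(make_protocol(f"r{i}", 150 + i, 12) for i in range(5)))
        profiles, labels = simulate_dataset(design, default_params)
        table = build_training_table(profiles, labels, design)
        with pytest.raises(CVConfigError):
            fit_rf(table, RfParams(n_trees=10), cv_folds=10)
        assert fit_rf(table, RfParams(n_trees=10), cv_folds=None).cv_report is None

    def test_grouped_folds_never_split_a_run(self, fitted_models):
        _, rf, table = fitted_models
        assert rf.cv_report is not None
        # every instance of a run shares that run's single fold assignment
        assert set(rf.cv_report.fold_of_run) == set(table["test_id"].unique())
        assert len(set(rf.cv_report.fold_of_run.values())) == rf.cv_report.n_folds


class TestTwoStepPrediction:
    def test_state_consistency(self, fitted_models):
        classifier, rf, _ = fitted_models
        for p, t in [(100, 9), (200, 15), (150, 10.5), (80, 16)]:
            prof, state, z = predict_profile(classifier, rf, p, t)
            assert state == predict_open(classifier, p, t)[0]
            assert len(prof.dissolved) == 34

    def test_closed_condition_stays_flat_until_ge(self, fitted_models):
        classifier, rf, _ = fitted_models
        prof, state, _ = predict_profile(classifier, rf, 100, 9)
        assert state == "closed"
        pre_ge = prof.dissolved[prof.times <= 28]
        post_ge = prof.dissolved[prof.times >= 40]
        assert pre_ge.max() < 20
        assert post_ge.min() > 80

    def test_late_strong_stress_dose_dumps(self, fitted_models):
        classifier, rf, _ = fitted_models
        prof, state, _ = predict_profile(classifier, rf, 200, 15)
        assert state == "open"
        d = dict(zip(prof.times, prof.dissolved))
        assert d[24.0] - d[15.0] > 30  # sharp post-stress rise

    def test_predictions_within_training_range(self, fitted_models):
        classifier, rf, table = fitted_models
        lo, hi = table["dissolved"].min(), table["dissolved"].max()
        for p, t in [(80, 8.5), (220, 15.5), (130, 11)]:
            prof, _, _ = predict_profile(classifier, rf, p, t)
            assert prof.dissolved.min() >= lo - 1e-9
            assert prof.dissolved.max() <= hi + 1e-9


class TestGrid:
    def test_standard_grid_has_66_points(self):
        assert len(default_grid_spec().pairs()) == 66

    def test_grid_profile_count(self, fitted_models):
        classifier, rf, _ = fitted_models
        grid = simulate_grid(classifier, rf, default_grid_spec())
        assert len(grid) == 66
        assert len({(g.pressure, g.timing) for g in grid}) == 66

    def test_single_point_grid(self, fitted_models):
        classifier, rf, _ = fitted_models
        grid = simulate_grid(classifier, rf, GridSpec((((150.0,), (12.0,)),)))
        assert len(grid) == 1

    def test_empty_grid_rejected(self, fitted_models):
        classifier, rf, _ = fitted_models
        with pytest.raises(InputError):
            simulate_grid(classifier, rf, GridSpec(()))


class TestSusceptibilityMap:
    def test_known_corners(self, reported_label_classifier):
        smap = susceptibility_map(reported_label_classifier, [100, 150], [9, 12])
        frame = smap.to_frame()
        z = {(r.pressure_mbar, r.timing_min): r.z for r in frame.itertuples()}
        assert z[(100.0, 9.0)] < 50
        assert z[(150.0, 12.0)] > 50
        assert frame["z"].between(0, 100).all()

    def test_monotone_in_timing_for_positive_weight(self, reported_label_classifier):
        assert reported_label_classifier.w_timing > 0
        smap = susceptibility_map(reported_label_classifier, [150.0], np.linspace(8, 16, 17))
        assert (np.diff(smap.z[:, 0]) >= -1e-12).all()
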