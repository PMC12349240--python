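"""Variable screening, pseudo-absences, TSS/AUC, ensemble and the pipeline."""

import numpy as np
import pandas as pd
import pytest

from hydrotherm import sdm
from hydrotherm.grids import GridSpec, Raster
from hydrotherm.sdm import (
    EnvStack,
    FittedModel,
    ModelEvaluation,
    build_ensemble,
    evaluate_predictions,
    fit_single_model,
    sample_pseudo_absences,
    screen_variables,
)

# ---------------------------------------------------------------------------
# Independent oracles


def oracle_auc(scores, labels):
    """O(n²) pair counting with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def oracle_tss(scores, labels):
    """Exhaustive sweep of every unique threshold (rule: score >= t)."""
    best = -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        sens = tp / np.sum(labels == 1)
        spec = tn / np.sum(labels == 0)
        best = max(best, sens + spec - 1.0)
    return best


def oracle_vif(X):
    """VIF per column from the R² of that column regressed on the others."""
    import statsmodels.api as smapi

    out = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        r2 = smapi.OLS(X[:, j], smapi.add_constant(others)).fit().rsquared
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)


# ---------------------------------------------------------------------------
# Evaluation


@pytest.mark.parametrize(
    "scores, labels, auc, tss, thr",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0, 1.0, 0.8),
        ([0.9, 0.6, 0.55, 0.4], [1, 0, 1, 0], 0.75, 0.5, 0.55),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5, 0.0, 0.5),
    ],
)
def test_evaluation_worked_examples(scores, labels, auc, tss, thr):
    ev = evaluate_predictions(np.array(scores), np.array(labels))
    assert ev.auc == pytest.approx(auc)
    assert ev.tss == pytest.approx(tss)
    assert ev.optimal_threshold == pytest.approx(thr)


def test_evaluation_agrees_with_exhaustive_oracles():
    """Fast AUC/TSS match O(n²)/all-threshold oracles on random instances,
    including heavily tied score vectors."""
    rng = np.random.default_rng(0)
    for trial in range(300):
        n = int(rng.integers(4, 201))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if trial % 2 == 0:
            scores = rng.random(n)
        else:  # discrete scores force ties
            scores = rng.integers(0, 5, n) / 4.0
        ev = evaluate_predictions(scores, labels)
        assert ev.auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)
        assert ev.tss == pytest.approx(oracle_tss(scores, labels), abs=1e-12)


def test_evaluation_requires_both_classes():
    with pytest.raises(ValueError):
        evaluate_predictions(np.array([0.1, 0.9]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Screening


def _stack_from_arrays(arrays, categorical=()):
    spec = GridSpec(0, 0, 1, 1, resolution_arcmin=60.0 / arrays[next(iter(arrays))].shape[0])
    return EnvStack(
        {k: Raster(spec, v, k) for k, v in arrays.items()},
        categorical=frozenset(categorical),
    )


def _screen_setup(seed=0, n=1000):
    rng = np.random.default_rng(seed)
    shape = (40, 40)
    x1 = rng.normal(0, 1, shape)
    x2 = rng.normal(0, 1, shape)
    arrays = {"x1": x1, "x2": x2, "x3": x1 + x2, "dup": x1.copy()}
    stack = _stack_from_arrays(arrays)
    lon = rng.uniform(0, 1, n)
    lat = rng.uniform(0, 1, n)
    return stack, lon, lat


def test_identical_layers_leave_exactly_one_copy():
    stack, lon, lat = _screen_setup()
    kept, log = screen_variables(stack, lon, lat)
    assert ("x1" in kept) != ("dup" in kept)
    assert any(d["stage"] == "pearson" for d in log)


def test_screened_set_passes_brute_force_vif_and_correlation():
    stack, lon, lat = _screen_setup()
    kept, _ = screen_variables(stack, lon, lat)
    tab = stack.table_at_points(lon, lat, kept)
    r = tab.corr().to_numpy()
    np.fill_diagonal(r, 0.0)
    assert np.all(np.abs(r) < 0.7)
    vifs = oracle_vif(tab.to_numpy(float))
    assert np.all(vifs < 5.0)


def test_independent_layers_all_retained():
    rng = np.random.default_rng(4)
    arrays = {f"v{i}": rng.normal(0, 1, (40, 40)) for i in range(5)}
    stack = _stack_from_arrays(arrays)
    lon, lat = rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)
    kept, log = screen_variables(stack, lon, lat)
    assert sorted(kept) == sorted(arrays)
    assert log == []


def test_categorical_variables_bypass_screening():
    stack, lon, lat = _screen_setup()
    rng = np.random.default_rng(1)
    cat = Raster(stack.spec, rng.integers(0, 4, stack.spec.shape).astype(float),
                 "tex")
    stack2 = EnvStack({**stack.layers, "tex": cat}, categorical={"tex"})
    kept, _ = screen_variables(stack2, lon, lat)
    assert "tex" in kept


# ---------------------------------------------------------------------------
# Pseudo-absences


def test_pseudo_absences_avoid_presences_and_cap_at_eligible_cells():
    spec = GridSpec(0, 0, 1, 1, resolution_arcmin=15.0)  # 4×4 = 16 cells
    stack = EnvStack({"v": Raster(spec, np.zeros(spec.shape))})
    lon_c, lat_c = spec.center_mesh()
    pres_lon = lon_c.ravel()[:6]
    pres_lat = lat_c.ravel()[:6]
    sets, warnings = sample_pseudo_absences(stack, pres_lon, pres_lat,
                                            n_per_set=8000, n_sets=2, seed=0)
    assert warnings  # capped at the 10 free cells
    for pa in sets.values():
        assert len(pa) == 10
        rows, cols = spec.cell_of(pa["lon"].to_numpy(), pa["lat"].to_numpy())
        prow, pcol = spec.cell_of(pres_lon, pres_lat)
        assert not set(zip(rows, cols)) & set(zip(prow, pcol))


def test_pseudo_absence_sets_are_seeded_and_independent():
    spec = GridSpec(0, 0, 1, 1, resolution_arcmin=3.0)
    stack = EnvStack({"v": Raster(spec, np.zeros(spec.shape))})
    a, _ = sample_pseudo_absences(stack, [0.5], [0.5], n_per_set=50, seed=7)
    b, _ = sample_pseudo_absences(stack, [0.5], [0.5], n_per_set=50, seed=7)
    pd.testing.assert_frame_equal(a[0], b[0])
    assert not a[0].equals(a[1])  # distinct substreams per set id


# ---------------------------------------------------------------------------
# Single models and the ensemble


def _separable_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
    y = (X["a"] > 0).to_numpy().astype(int)
    return X, y


def test_separable_problem_reaches_perfect_heldout_tss():
    X, y = _separable_data()
    m = fit_single_model("glm", X, y, seed=1)
    assert m.evaluation.tss == pytest.approx(1.0)
    assert m.evaluation.auc == pytest.approx(1.0)


def test_shuffled_labels_give_null_tss():
    rng = np.random.default_rng(5)
    X, y = _separable_data(400, seed=5)
    tss = []
    for run in range(10):
        y_null = rng.permutation(y)
        m = fit_single_model("glm", X, y_null, run=run, seed=2)
        tss.append(m.evaluation.tss)
    assert abs(np.mean(tss)) <= 0.15


def test_single_model_is_deterministic():
    X, y = _separable_data()
    a = fit_single_model("rf", X, y, pa_set=1, run=3, seed=9)
    b = fit_single_model("rf", X, y, pa_set=1, run=3, seed=9)
    assert a.evaluation == b.evaluation


def test_single_class_training_data_rejected():
    X, _ = _separable_data()
    with pytest.raises(ValueError):
        fit_single_model("glm", X, np.ones(len(X)), seed=0)


def _fake_model(tss, constant):
    class _Const:
        def __init__(self, c):
            self.c = c

        def predict_proba(self, X):
            p = np.full(len(X), self.c)
            return np.column_stack([1 - p, p])

    return FittedModel(
        learner_id="const", pa_set=0, run=0,
        evaluation=ModelEvaluation(auc=0.5, tss=tss, optimal_threshold=0.5),
        estimator=_Const(constant), feature_names=["a"],
    )


class TestEnsemble:
    def test_weights_are_normalized_tss_of_retained_members(self):
        models = [_fake_model(0.6, 0.2), _fake_model(0.5, 0.4),
                  _fake_model(0.7, 0.8)]
        ens = build_ensemble(models, tss_min=0.55)
        assert len(ens.members) == 2
        assert ens.weights == pytest.approx([0.6 / 1.3, 0.7 / 1.3])

    def test_single_member_ensemble_is_that_member(self):
        ens = build_ensemble([_fake_model(0.9, 0.3)], tss_min=0.55)
        X = pd.DataFrame({"a": [0.0, 1.0]})
        assert np.allclose(ens.predict_scores(X), 0.3)

    def test_equal_tss_members_average_plainly(self):
        ens = build_ensemble([_fake_model(0.8, 0.2), _fake_model(0.8, 0.6)])
        X = pd.DataFrame({"a": [0.0]})
        assert ens.predict_scores(X)[0] == pytest.approx(0.4)

    def test_no_member_above_cutoff_is_fatal_with_best_reported(self):
        with pytest.raises(ValueError, match="0.400"):
            build_ensemble([_fake_model(0.4, 0.5)], tss_min=0.55)

    def test_ensemble_scores_are_convex_combinations(self):
        models = [_fake_model(0.6, 0.1), _fake_model(0.8, 0.9)]
        ens = build_ensemble(models)
        X = pd.DataFrame({"a": np.linspace(0, 1, 7)})
        s = ens.predict_scores(X)
        assert np.all(s >= 0.1 - 1e-12) and np.all(s <= 0.9 + 1e-12)


# ---------------------------------------------------------------------------
# Full pipeline (shared session fixture: 3 learners × 2 PA sets × 10 runs)


class TestPipeline:
    def test_model_counting_contract(self, sdm_result, sdm_config):
        expected = len(sdm_config.learners) * sdm_config.n_pa_sets * sdm_config.n_runs
        assert len(sdm_result.models) == expected == 60
        assert len(sdm_result.manifest["models"]) == expected

    def test_strong_niche_reaches_high_consensus_auc(self, sdm_result):
        assert sdm_result.pooled_evaluation.auc >= 0.95

    def test_projection_is_cellwise_convex_combination(self, sdm_result,
                                                       sdm_problem):
        stack = sdm_problem["stack"]
        valid = stack.valid_mask
        rows, cols = np.nonzero(valid)
        tab = stack.table_at_cells(rows, cols)
        member_scores = np.stack(
            [m.predict_scores(tab) for m in sdm_result.ensemble.members]
        )
        ens_scores = sdm_result.suitability.values[rows, cols]
        assert np.all(ens_scores >= member_scores.min(axis=0) - 1e-10)
        assert np.all(ens_scores <= member_scores.max(axis=0) + 1e-10)

    def test_warming_scenario_shifts_suitable_band_poleward(self, sdm_result):
        cur = sdm_result.suitability
        fut = sdm_result.scenario_suitability["warmed"]
        _, lat = cur.spec.center_mesh()
        lat_cur = lat[cur.values > 0.2].mean()
        lat_fut = lat[fut.values > 0.2].mean()
        assert lat_fut > lat_cur

    def test_manifest_records_every_fit_and_decision(self, sdm_result,
                                                     sdm_config):
        man = sdm_result.manifest
        assert man["config"]["seed"] == sdm_config.seed
        assert {m["learner"] for m in man["models"]} == set(sdm_config.learners)
        retained = [m for m in man["models"] if m["retained"]]
        assert len(retained) == len(sdm_result.ensemble.members)
        assert all(m["tss"] > sdm_config.tss_min for m in retained)
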