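"""Ensemble machinery: pseudo-absences, splits, skill scores, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from koalapop.suitability import (
    EnsembleSuitabilityModel,
    ensemble,
    generate_pseudo_absences,
    response_curve,
    score,
    split_repetitions,
    tss_curve,
    variable_importance,
    vif_screen,
)


@pytest.fixture(scope="module")
def presences(landscape):
    rng = np.random.default_rng(8)
    n = 150
    return pd.DataFrame({"longitude": rng.uniform(5, 15, n), "latitude": rng.uniform(5, 15, n)})


class TestPseudoAbsences:
    def test_reproducible_and_disjoint_from_presence_cells(self, landscape, presences):
        a = generate_pseudo_absences(landscape, presences, n=300, seed=1)
        b = generate_pseudo_absences(landscape, presences, n=300, seed=1)
        pd.testing.assert_frame_equal(a, b)
        pr, pc = landscape.cell_index(presences["longitude"], presences["latitude"])
        ar, ac = landscape.cell_index(a["longitude"], a["latitude"])
        presence_cells = set(zip(pr.tolist(), pc.tolist()))
        assert not presence_cells & set(zip(ar.tolist(), ac.tolist()))

    def test_fully_occupied_landscape_errors(self, landscape):
        xx, yy = landscape.cell_centres()
        everywhere = pd.DataFrame({"longitude": xx.ravel(), "latitude": yy.ravel()})
        with pytest.raises(ValueError):
            generate_pseudo_absences(landscape, everywhere, n=10, seed=0)

    def test_shortfall_warns_and_caps(self, landscape, presences):
        with pytest.warns(UserWarning, match="presence-free"):
            out = generate_pseudo_absences(landscape, presences, n=10**6, seed=0)
        assert len(out) < 10**6

    def test_spatially_uniform_by_chi_square(self, landscape, presences):
        # pooled over seeds, counts per quadrat should be uniform across
        # presence-free space; test on the far half that holds no presences
        counts = np.zeros((3, 3))
        for s in range(30):
            pa = generate_pseudo_absences(landscape, presences, n=400, seed=s)
            sel = pa[pa["longitude"] > 18]  # presence-free strip, 12 km wide
            qx = np.minimum(((sel["longitude"] - 18) / 4).astype(int), 2)
            qy = np.minimum((sel["latitude"] / 10).astype(int), 2)
            np.add.at(counts, (qy, qx), 1)
        stat, p = chisquare(counts.ravel())
        assert p > 0.001

    def test_empty_presences_rejected(self, landscape):
        with pytest.raises(ValueError):
            generate_pseudo_absences(landscape, pd.DataFrame({"longitude": [], "latitude": []}), n=5, seed=0)


class TestSplits:
    def test_sizes_and_determinism(self):
        y = np.r_[np.ones(100), np.zeros(400)]
        splits = split_repetitions(y, train_fraction=0.8, n_rep=20, seed=3)
        assert len(splits) == 20
        for train, test in splits:
            assert abs(len(train) - 400) <= 1 and abs(len(test) - 100) <= 1
            # stratification: class balance preserved within 2%
            assert abs(y[train].mean() - 0.2) < 0.02
        again = split_repetitions(y, train_fraction=0.8, n_rep=20, seed=3)
        for (a, _), (b, _) in zip(splits, again):
            np.testing.assert_array_equal(a, b)

    def test_validation_union_covers_most_data(self):
        y = np.r_[np.ones(100), np.zeros(100)]
        splits = split_repetitions(y, n_rep=20, seed=0)
        seen = set()
        for _, test in splits:
            seen.update(test.tolist())
        # P(a point never validates) = 0.8^20 ~ 1.2%; union covers >= 95%
        assert len(seen) >= 0.95 * len(y)

    def test_bad_repetitions_rejected(self):
        with pytest.raises(ValueError):
            split_repetitions(np.array([0, 1]), n_rep=0)


class TestScores:
    def test_perfect_separation(self):
        s = score(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert s.auc == 1.0 and s.tss == 1.0

    def test_random_predictions_near_chance(self, rng):
        aucs, tsss = [], []
        for _ in range(50):
            pred = rng.random(200)
            labels = np.r_[np.ones(100), np.zeros(100)]
            s = score(pred, labels)
            aucs.append(s.auc)
            tsss.append(s.tss)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)
        assert np.mean(tsss) < 0.2  # max-scan makes TSS positively biased but small

    def test_auc_equals_brute_force_pair_count(self):
        # hand-set scores on six points: AUC = fraction of concordant
        # presence/absence pairs (ties count half), enumerated explicitly
        pred = np.array([0.9, 0.6, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        concordant = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                concordant += 1.0 if pred[i] > pred[j] else (0.5 if pred[i] == pred[j] else 0.0)
        expected = concordant / (labels.sum() * (1 - labels).sum())
        assert score(pred, labels).auc == pytest.approx(expected, rel=1e-12)

    def test_threshold_star_maximises_tss(self):
        rng = np.random.default_rng(5)
        pred = rng.random(100)
        labels = (pred + rng.normal(0, 0.3, 100)) > 0.5
        s = score(pred, labels)
        thresholds, tss = tss_curve(pred, labels)
        assert s.tss == pytest.approx(tss.max())
        at_star = tss[np.flatnonzero(thresholds == s.threshold_star)[0]]
        assert at_star == pytest.approx(s.tss)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            score(np.array([1.2, 0.1]), np.array([1, 0]))


class TestEnsemble:
    def test_single_learner_identity(self):
        m = np.array([[0.2, 0.8]])
        out = ensemble([m[0]], [0.5])
        np.testing.assert_allclose(out, m[0])

    def test_equal_tss_gives_arithmetic_mean(self):
        a, b = np.array([0.2, 0.6]), np.array([0.4, 0.8])
        np.testing.assert_allclose(ensemble([a, b], [0.4, 0.4]), (a + b) / 2)

    def test_hand_computed_weighted_mean(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        b = np.array([0.5, 0.6, 0.7, 0.8])
        out = ensemble([a, b], [0.6, 0.3])
        np.testing.assert_allclose(out, (0.6 * a + 0.3 * b) / 0.9, rtol=1e-12)

    def test_nonpositive_tss_excluded_or_error(self):
        a, b = np.array([0.1, 0.9]), np.array([0.9, 0.1])
        np.testing.assert_allclose(ensemble([a, b], [0.5, -0.2]), a)
        with pytest.raises(ValueError):
            ensemble([a, b], [0.0, -0.1])


@pytest.fixture(scope="module")
def fitted_sdm(covariates, landscape):
    rng = np.random.default_rng(12)
    suit = covariates.true_suitability().ravel()
    labels = (rng.random(suit.size) < suit).astype(int)
    X = covariates.design_matrix()
    model = EnsembleSuitabilityModel(n_rep=5, random_state=0).fit(X, labels)
    return model, X, labels


class TestEnsembleModel:
    def test_predictions_bounded_and_weights_normalised(self, fitted_sdm):
        model, X, _ = fitted_sdm
        pred = model.predict(X)
        assert np.all((pred >= 0) & (pred <= 1))
        assert sum(model.weights_.values()) == pytest.approx(1.0)
        per = model.predict_per_learner(X)
        lo = np.min([per[n] for n in model.learner_names_], axis=0)
        hi = np.max([per[n] for n in model.learner_names_], axis=0)
        assert np.all(pred >= lo - 1e-12) and np.all(pred <= hi + 1e-12)

    def test_skill_on_structured_data(self, fitted_sdm):
        model, _, _ = fitted_sdm
        assert model.scores_["auc"].mean() > 0.75
        assert model.train_scores_.tss > 0.3

    def test_refit_deterministic(self, fitted_sdm):
        model, X, labels = fitted_sdm
        again = EnsembleSuitabilityModel(n_rep=5, random_state=0).fit(X, labels)
        np.testing.assert_allclose(model.predict(X[:50]), again.predict(X[:50]))


class TestImportanceAndCurves:
    def test_informative_variable_ranks_first_nuisance_near_zero(self, fitted_sdm, covariates):
        model, X, _ = fitted_sdm
        imp = variable_importance(model, X, names=covariates.names, n_iter=5, seed=0)
        assert imp.iloc[0]["variable"] == "rainfall"  # dominant generative driver
        nuisance = imp.set_index("variable").loc[["nuisance_1", "nuisance_2"], "importance"]
        assert (nuisance < 0.1).all()
        informative = imp.set_index("variable").loc["rainfall", "importance"]
        assert informative > nuisance.max() + 0.1

    def test_response_curve_endpoints_and_length(self, fitted_sdm, covariates):
        model, X, _ = fitted_sdm
        curve = response_curve(model, X, "rainfall", names=covariates.names, n_points=100)
        assert len(curve) == 100
        j = covariates.names.index("rainfall")
        assert curve["rainfall"].iloc[0] == X[:, j].min()
        assert curve["rainfall"].iloc[-1] == X[:, j].max()
        probe = np.tile(X.mean(axis=0), (1, 1))
        probe[0, j] = X[:, j].min()
        assert curve["suitability"].iloc[0] == pytest.approx(model.predict(probe)[0])

    def test_unknown_variable_rejected(self, fitted_sdm, covariates):
        model, X, _ = fitted_sdm
        with pytest.raises(KeyError):
            response_curve(model, X, "nope", names=covariates.names)

    def test_monotone_generative_effect_gives_monotone_curve(self, landscape):
        # a pure logistic learner on one strong monotone driver
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, 2))
        y = (rng.random(800) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(int)
        learners = {"glm": make_pipeline(StandardScaler(), LogisticRegression(max_iter=500))}
        model = EnsembleSuitabilityModel(learners=learners, n_rep=3, random_state=0).fit(X, y)
        curve = response_curve(model, X, "x0", n_points=50)
        assert np.all(np.diff(curve["suitability"]) > -1e-9)


class TestVIF:
    def test_orthogonal_covariates_unity(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        out = vif_screen(X)
        assert np.allclose(out["vif"], 1.0, atol=0.02)
        assert not out["flagged"].any()

    def test_duplicated_covariate_flagged(self, rng):
        x = rng.normal(size=500)
        X = np.column_stack([x, x, rng.normal(size=500)])
        out = vif_screen(X)
        assert out["flagged"][:2].all()

    def test_known_correlation_matches_closed_form(self, rng):
        # x2 = 0.9 x1 + noise chosen so corr ~ 0.9: VIF = 1/(1-R^2)
        n = 200000
        x1 = rng.normal(size=n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = np.column_stack([x1, x2, rng.normal(size=n)])
        out = vif_screen(X)
        assert out["vif"][0] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_single_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            vif_screen(rng.normal(size=(10, 1)))
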