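"""Probit BART: fit quality, determinism, prediction contracts, and the
AUC/TSS/threshold machinery against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import stacksdm as s
from stacksdm.raster import RasterGrid


def brute_auc(probs, labels):
    """Pairwise positive-negative comparison with half credit for ties."""
    probs = np.asarray(probs, dtype=float)
    pos = probs[np.asarray(labels) == 1]
    neg = probs[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_tss(probs, labels, threshold):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    tp = ((probs >= threshold) & (labels == 1)).sum()
    fn = ((probs < threshold) & (labels == 1)).sum()
    tn = ((probs < threshold) & (labels == 0)).sum()
    fp = ((probs >= threshold) & (labels == 0)).sum()
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


class TestAucTss:
    def test_perfect_ranking(self):
        assert s.auc_score([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pair_enumeration_example(self):
        assert s.auc_score([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == 0.75

    def test_constant_probs_tie_degeneracy(self):
        probs = np.full(20, 0.5)
        labels = np.r_[np.ones(10), np.zeros(10)]
        assert s.auc_score(probs, labels) == 0.5
        diag = s.evaluate_model(probs, labels)
        assert diag.tss == pytest.approx(0.0)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(4, 50)
            probs = rng.choice(np.round(rng.random(8), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert s.auc_score(probs, labels) == pytest.approx(brute_auc(probs, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            s.auc_score([0.1, 0.9], [1, 1])


class TestTssThreshold:
    def test_separated_probs_give_tss_one(self):
        thr = s.tss_threshold([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert thr == 0.8
        assert s.tss_at_threshold([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0], thr) == 1.0

    def test_smallest_maximizer_returned(self):
        probs = [0.9, 0.8, 0.7, 0.3]
        labels = [1, 1, 1, 0]
        assert s.tss_threshold(probs, labels) == 0.7

    def test_matches_dense_grid_scan(self):
        rng = np.random.default_rng(1)
        dense = np.linspace(0, 1, 1001)
        for _ in range(50):
            n = rng.integers(5, 40)
            probs = np.round(rng.random(n), 3)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            best = s.tss_threshold(probs, labels)
            tss_best = brute_tss(probs, labels, best)
            grid_best = max(brute_tss(probs, labels, t) for t in dense)
            assert tss_best == pytest.approx(grid_best, abs=1e-12)


class TestFitBart:
    def test_separable_fit_is_accurate(self, separable_design, separable_model):
        diag = s.evaluate_model(separable_model.train_probability(), separable_design.y)
        assert diag.auc >= 0.95

    def test_probabilities_strictly_inside_unit_interval(self, separable_model):
        probs = separable_model.train_probability()
        assert (probs > 0).all() and (probs < 1).all()

    def test_deterministic_given_seed(self, separable_design, separable_model):
        again = s.fit_bart(separable_design, s.BARTConfig.test_size(seed=7))
        np.testing.assert_array_equal(
            separable_model.train_probability(), again.train_probability()
        )

    def test_monotone_across_step(self, separable_design, separable_model):
        """Posterior mean rises across the step in covariate 1."""
        x = np.linspace(-0.9, 0.9, 7)
        X = np.column_stack([x, np.zeros_like(x)])
        probs = separable_model.predict_probability_draws(X).mean(axis=0)
        assert probs[-1] - probs[0] > 0.5
        assert np.all(np.diff(probs) > -0.1)  # monotone within MC tolerance

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError):
            s.DesignMatrix(X=X, y=np.ones(3, dtype=int))

    def test_zero_variance_design_rejected(self):
        X = pd.DataFrame({"a": np.ones(10)})
        dm = s.DesignMatrix(X=X, y=np.r_[np.ones(5), np.zeros(5)].astype(int))
        with pytest.raises(ValueError, match="zero-variance"):
            s.fit_bart(dm, s.BARTConfig.test_size())

    def test_save_load_round_trip(self, separable_model, tmp_path):
        path = tmp_path / "model.jsonl"
        separable_model.save(path)
        loaded = s.BARTModel.load(path)
        X = np.array([[0.5, 0.0], [-0.5, 0.0]])
        np.testing.assert_allclose(
            separable_model.predict_probability_draws(X),
            loaded.predict_probability_draws(X),
        )


class TestPredictOccurrence:
    @pytest.fixture(scope="class")
    def grids(self):
        rng = np.random.default_rng(5)
        geom = RasterGrid(np.zeros((10, 10)))
        return [
            geom.like(rng.uniform(-1, 1, (10, 10)), name="a"),
            geom.like(rng.uniform(-1, 1, (10, 10)), name="b"),
        ]

    def test_prediction_bounds_and_ci_positive(self, separable_model, grids):
        pred = s.predict_occurrence(separable_model, grids)
        assert ((pred.mean_probability.data > 0) & (pred.mean_probability.data < 1)).all()
        assert (pred.ci_width.data > 0).all()

    def test_missing_covariate_listed(self, separable_model, grids):
        with pytest.raises(ValueError, match="b"):
            s.predict_occurrence(separable_model, grids[:1])

    def test_extrapolation_keeps_posterior_spread(self, separable_model):
        """Cells far outside the training range inherit the boundary
        leaves' posterior spread: a sum-of-trees model extrapolates flat,
        so credible intervals stay positive and comparable to the nearest
        in-range cells (they do not inflate, nor collapse to zero)."""
        geom = RasterGrid(np.zeros((1, 20)))
        in_range = np.linspace(0.3, 0.9, 10)  # confidently-presence side
        far_out = np.linspace(5.0, 10.0, 10)
        a = geom.like(np.r_[in_range, far_out].reshape(1, 20), name="a")
        b = geom.like(np.zeros((1, 20)), name="b")
        pred = s.predict_occurrence(separable_model, [a, b])
        width = pred.ci_width.data.ravel()
        assert (width > 0).all()
        boundary = width[9]  # in-range cell nearest the extrapolated block
        assert np.median(width[10:]) >= 0.5 * boundary

    def test_thin_draws_subsamples(self, separable_model, grids):
        pred = s.predict_occurrence(separable_model, grids, thin_draws=10)
        assert ((pred.mean_probability.data >= 0) & (pred.mean_probability.data <= 1)).all()


class TestVariableImportance:
    def test_sums_to_100(self, separable_model):
        imp = s.variable_importance(separable_model)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp >= 0).all()

    def test_single_covariate_gets_all(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"only": rng.uniform(-1, 1, 100)})
        y = (X["only"] > 0).astype(int).to_numpy()
        model = s.fit_bart(s.DesignMatrix(X=X, y=y), s.BARTConfig.test_size(seed=1))
        imp = s.variable_importance(model)
        assert imp["only"] == pytest.approx(100.0)

    def test_signal_beats_noise(self):
        """Signal covariate out-ranks pure noise (median over 5 seeds)."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"signal": rng.uniform(-1, 1, 200), "noise": rng.uniform(-1, 1, 200)})
        y = (X["signal"] > 0).astype(int).to_numpy()
        margins = []
        for seed in range(5):
            model = s.fit_bart(s.DesignMatrix(X=X, y=y), s.BARTConfig.test_size(seed=seed))
            imp = s.variable_importance(model)
            margins.append(imp["signal"] - imp["noise"])
        assert np.median(margins) > 0


class TestSelectCovariates:
    @pytest.fixture(scope="class")
    def single_signal_design(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            {
                "signal": rng.uniform(-1, 1, 150),
                "noise1": rng.uniform(-1, 1, 150),
                "noise2": rng.uniform(-1, 1, 150),
            }
        )
        y = (X["signal"] > 0).astype(int).to_numpy()
        return s.DesignMatrix(X=X, y=y)

    @pytest.fixture(scope="class")
    def tiny_config(self):
        return s.BARTConfig(n_trees=10, n_iterations=100, seed=3)

    def test_signal_always_retained(self, single_signal_design, tiny_config):
        retained, trace = s.select_covariates(
            single_signal_design, tiny_config, tolerance=0.01, seed=1
        )
        assert "signal" in retained
        assert len(retained) <= 3
        assert {"n_covariates", "cv_auc", "dropped"} <= set(trace.columns)

    def test_infinite_tolerance_keeps_one(self, single_signal_design, tiny_config):
        retained, _ = s.select_covariates(
            single_signal_design, tiny_config, tolerance=np.inf, seed=1
        )
        assert len(retained) == 1


class TestBinarize:
    @pytest.fixture(scope="class")
    def prediction(self, separable_model):
        rng = np.random.default_rng(8)
        geom = RasterGrid(np.zeros((8, 8)))
        grids = [
            geom.like(rng.uniform(-1, 1, (8, 8)), name="a"),
            geom.like(rng.uniform(-1, 1, (8, 8)), name="b"),
        ]
        return s.predict_occurrence(separable_model, grids)

    def test_extreme_thresholds(self, prediction):
        assert (s.binarize(prediction, 0.0).data == 1).all()
        assert (s.binarize(prediction, 1.0).data == 0).all()

    def test_presence_count_monotone_in_threshold(self, prediction):
        counts = [s.binarize(prediction, t).data.sum() for t in np.linspace(0, 1, 21)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_prevalence_recovery_across_species(small_landscape):
    """True prevalence ranks are recovered by predicted mean prevalence
    across 10 virtual species surveyed with presence/absence labels.

    Calibration-level recovery needs true absences: with presence plus
    equal pseudoabsence training the 1:1 class balance pins every species'
    predicted base rate near 0.5 and prevalence is not identifiable, so
    this check samples Bernoulli presence/absence at random cells.
    """
    rng = np.random.default_rng(21)
    niches, _ = s.generate_species_and_tree(10, 0.5, small_landscape, seed=13)
    # spread true prevalence by shifting intercepts
    for i, n in enumerate(niches):
        n.intercept += -1.5 + 3.0 * i / 9.0
    grid = small_landscape.grid
    true_prev, pred_prev = [], []
    for i, n in enumerate(niches):
        p = s.niche_probability(n, small_landscape).data
        cells = rng.choice(p.size, size=300, replace=False)
        r, c = np.unravel_index(cells, p.shape)
        y = (rng.random(300) < p[r, c]).astype(int)
        X = pd.DataFrame({g.name: g.data[r, c] for g in small_landscape.covariates})
        model = s.fit_bart(s.DesignMatrix(X=X, y=y), s.BARTConfig.test_size(seed=16 + i))
        pred = s.predict_occurrence(model, small_landscape.covariates)
        true_prev.append(p.mean())
        pred_prev.append(pred.mean_probability.data.mean())
    from scipy.stats import spearmanr

    rho = spearmanr(true_prev, pred_prev).statistic
    assert rho > 0.8
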