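"""Stacking procedures: extraction at units, bS/pS/cS stacks, site
aggregation and stacked uncertainty, each against loop/sort oracles."""

import numpy as np
import pandas as pd
import pytest

import stacksdm as s
from stacksdm.bart import PosteriorPrediction
from stacksdm.raster import RasterGrid


def make_prediction_set(prob_stacks, thresholds, ci=None):
    geom = RasterGrid(np.zeros(prob_stacks[0].shape))
    preds = []
    for i, (p, t) in enumerate(zip(prob_stacks, thresholds)):
        name = f"sp{i + 1}"
        pp = PosteriorPrediction(
            mean_probability=geom.like(p, name="mean_probability"),
            ci_width=geom.like(ci[i] if ci is not None else np.zeros_like(p), name="ci_width"),
        )
        preds.append(
            s.SpeciesPrediction(
                species_id=name, prediction=pp, threshold=t,
                binary=geom.like((p >= t).astype(float)),
            )
        )
    return s.SpeciesPredictionSet(preds)


@pytest.fixture
def random_set():
    rng = np.random.default_rng(0)
    probs = [rng.random((5, 6)) for _ in range(4)]
    ci = [rng.random((5, 6)) for _ in range(4)]
    return make_prediction_set(probs, [0.5, 0.4, 0.6, 0.5], ci)


class TestExtractAtUnits:
    def test_cell_center_value(self, random_set):
        units = pd.DataFrame({"x": [2.5], "y": [3.5]}, index=["u1"])
        prob, binary = s.extract_at_units(random_set, units)
        # (2.5, 3.5) with 5 rows -> row 1, col 2
        sp1 = random_set.predictions[0]
        assert prob.loc["u1", "sp1"] == sp1.prediction.mean_probability.data[1, 2]
        assert binary.loc["u1", "sp1"] == sp1.binary.data[1, 2]

    def test_two_units_one_cell(self, random_set):
        units = pd.DataFrame({"x": [2.2, 2.8], "y": [3.2, 3.8]}, index=["u1", "u2"])
        prob, binary = s.extract_at_units(random_set, units)
        assert (prob.loc["u1"] == prob.loc["u2"]).all()
        assert (binary.loc["u1"] == binary.loc["u2"]).all()

    def test_boundary_point_floor_rule(self, random_set):
        units = pd.DataFrame({"x": [3.0], "y": [2.0]}, index=["edge"])
        prob, _ = s.extract_at_units(random_set, units)
        # x=3.0 -> col 3 (east); y=2.0 -> row floor((5-2)/1)=3 (south)
        expected = random_set.predictions[0].prediction.mean_probability.data[3, 3]
        assert prob.loc["edge", "sp1"] == expected

    def test_outside_unit_named(self, random_set):
        units = pd.DataFrame({"x": [99.0], "y": [1.0]}, index=["far"])
        with pytest.raises(ValueError, match="outside"):
            s.extract_at_units(random_set, units)


class TestBinaryAndProbabilityStacks:
    def test_binary_richness_example(self):
        m = pd.DataFrame([[1, 0, 1]], index=["u"], columns=["a", "b", "c"])
        assert s.stack_binary(m).richness.loc["u"] == 2

    def test_probability_richness_example(self):
        m = pd.DataFrame([[0.9, 0.7, 0.4]], index=["u"], columns=["a", "b", "c"])
        assert s.stack_probability(m).richness.loc["u"] == pytest.approx(2.0)

    def test_all_zero_layers(self, random_set):
        zero = make_prediction_set([np.zeros((3, 3))], [0.5])
        assert (s.stack_binary(zero).richness == 0).all()
        assert (s.stack_probability(zero).richness == 0).all()

    def test_cell_richness_matches_loop_oracle(self, random_set):
        bs = s.stack_binary(random_set)
        ps = s.stack_probability(random_set)
        geom = random_set.geometry
        for r in range(geom.n_rows):
            for c in range(geom.n_cols):
                unit = f"r{r}c{c}"
                expected_b = sum(sp.binary.data[r, c] for sp in random_set.predictions)
                expected_p = sum(
                    sp.prediction.mean_probability.data[r, c] for sp in random_set.predictions
                )
                assert bs.richness.loc[unit] == expected_b
                assert ps.richness.loc[unit] == pytest.approx(expected_p)

    def test_probability_outside_unit_interval_rejected(self):
        m = pd.DataFrame([[1.2]], index=["u"], columns=["a"])
        with pytest.raises(ValueError):
            s.stack_probability(m)


class TestConstrainedPrr:
    def test_top_k_example(self):
        m = pd.DataFrame([[0.9, 0.7, 0.4]], index=["u"], columns=["A", "B", "C"])
        out = s.stack_constrained_prr(m, pd.Series({"u": 2}))
        assert out.matrix.loc["u"].to_dict() == {"A": 1, "B": 1, "C": 0}

    def test_k_at_least_n_species_selects_all(self):
        m = pd.DataFrame([[0.9, 0.1]], index=["u"], columns=["A", "B"])
        out = s.stack_constrained_prr(m, pd.Series({"u": 5}))
        assert out.richness.loc["u"] == 2

    def test_alphabetical_tie_break(self):
        m = pd.DataFrame([[0.5, 0.5, 0.5]], index=["u"], columns=["C", "A", "B"])
        out = s.stack_constrained_prr(m, pd.Series({"u": 2}))
        assert out.matrix.loc["u"].to_dict() == {"C": 0, "A": 1, "B": 1}

    def test_random_instances_match_sort_oracle(self):
        rng = np.random.default_rng(3)
        species = list("ABCDEF")
        for trial in range(50):
            # quantized probabilities force frequent ties
            probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=(4, 6))
            ks = rng.integers(0, 8, size=4)
            m = pd.DataFrame(probs, index=[f"u{i}" for i in range(4)], columns=species)
            out = s.stack_constrained_prr(m, pd.Series(ks, index=m.index))
            for i, unit in enumerate(m.index):
                order = sorted(species, key=lambda sp: (-m.loc[unit, sp], sp))
                expected = set(order[: min(ks[i], 6)])
                got = set(out.matrix.columns[out.matrix.loc[unit] == 1])
                assert got == expected

    def test_richness_never_exceeds_constraint(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.random((10, 5)), index=[f"u{i}" for i in range(10)],
                         columns=list("abcde"))
        ks = pd.Series(rng.integers(0, 6, 10), index=m.index)
        out = s.stack_constrained_prr(m, ks)
        assert (out.richness <= ks).all()

    def test_negative_constraint_rejected(self):
        m = pd.DataFrame([[0.5]], index=["u"], columns=["a"])
        with pytest.raises(ValueError):
            s.stack_constrained_prr(m, pd.Series({"u": -1}))

    def test_bs_dominates_cs_when_constraint_below_bs_count(self, random_set):
        prob = s.cell_matrix(random_set, "probability")
        bs = s.stack_binary(random_set)
        ks = (bs.richness - 1).clip(lower=0)
        cs = s.stack_constrained_prr(prob, ks)
        assert (cs.richness <= bs.richness).all()


class TestAggregateToSites:
    @pytest.fixture
    def hierarchy(self):
        return pd.DataFrame(
            {"plot_id": ["p1", "p2", "p3"], "site_id": ["s1", "s1", "s2"],
             "x": [0, 0, 0], "y": [0, 0, 0]}
        )

    def test_union_example(self, hierarchy):
        m = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [1, 0, 0]], index=["p1", "p2", "p3"],
            columns=["A", "B", "C"],
        )
        out = s.aggregate_to_sites(s.stack_binary(m), hierarchy)
        assert out.matrix.loc["s1"].to_dict() == {"A": 1, "B": 1, "C": 1}
        assert out.matrix.loc["s2"].to_dict() == {"A": 1, "B": 0, "C": 0}

    def test_single_plot_site_identity(self, hierarchy):
        m = pd.DataFrame([[1, 0], [0, 0], [0, 1]], index=["p1", "p2", "p3"],
                         columns=["A", "B"])
        out = s.aggregate_to_sites(s.stack_binary(m), hierarchy)
        assert (out.matrix.loc["s2"] == m.loc["p3"]).all()

    def test_probability_max_rule(self, hierarchy):
        m = pd.DataFrame([[0.2], [0.6], [0.5]], index=["p1", "p2", "p3"], columns=["A"])
        out = s.aggregate_to_sites(s.stack_probability(m), hierarchy)
        assert out.matrix.loc["s1", "A"] == pytest.approx(0.6)

    def test_probability_noisy_or_rule(self, hierarchy):
        m = pd.DataFrame([[0.2], [0.6], [0.5]], index=["p1", "p2", "p3"], columns=["A"])
        out = s.aggregate_to_sites(s.stack_probability(m), hierarchy, probability_rule="noisy-or")
        assert out.matrix.loc["s1", "A"] == pytest.approx(1 - 0.8 * 0.4)

    def test_order_independent_and_idempotent(self, hierarchy):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(0, 2, (3, 4)), index=["p1", "p2", "p3"],
                         columns=list("abcd"))
        out1 = s.aggregate_to_sites(s.stack_binary(m), hierarchy)
        out2 = s.aggregate_to_sites(s.stack_binary(m.iloc[::-1]), hierarchy)
        pd.testing.assert_frame_equal(out1.matrix, out2.matrix)
        # aggregating a site with itself changes nothing
        self_h = pd.DataFrame({"plot_id": out1.matrix.index, "site_id": out1.matrix.index,
                               "x": 0, "y": 0})
        again = s.aggregate_to_sites(out1, self_h)
        pd.testing.assert_frame_equal(
            again.matrix.sort_index(), out1.matrix.sort_index(), check_names=False
        )

    def test_orphan_plot_rejected(self, hierarchy):
        m = pd.DataFrame([[1]], index=["p99"], columns=["A"])
        with pytest.raises(ValueError, match="p99"):
            s.aggregate_to_sites(s.stack_binary(m), hierarchy)


class TestStackUncertainty:
    def test_zero_widths(self):
        zero = make_prediction_set([np.full((3, 3), 0.5)] * 2, [0.5, 0.5])
        assert (s.stack_uncertainty(zero).data == 0).all()

    def test_single_species_identity(self):
        rng = np.random.default_rng(6)
        ci = [rng.random((4, 4))]
        one = make_prediction_set([np.full((4, 4), 0.5)], [0.5], ci)
        np.testing.assert_allclose(s.stack_uncertainty(one).data, ci[0])

    def test_matches_loop_oracle(self, random_set):
        total = s.stack_uncertainty(random_set)
        expected = np.zeros((5, 6))
        for sp in random_set.predictions:
            expected += sp.prediction.ci_width.data
        np.testing.assert_allclose(total.data, expected)


def test_richness_recovery_on_synthetic_truth(small_landscape):
    """Binary-stack richness tracks true cell richness when the model
    probabilities are the (thresholded) truth."""
    from scipy.stats import spearmanr

    niches, _ = s.generate_species_and_tree(8, 0.5, small_landscape, seed=31)
    probs = [s.niche_probability(n, small_landscape).data for n in niches]
    # binarize each species at its prevalence (calibrated threshold)
    pred_set = make_prediction_set(probs, [p.mean() for p in probs])
    bs = s.stack_binary(pred_set)
    true_richness = np.sum(probs, axis=0).ravel()
    rho = spearmanr(true_richness, bs.richness.to_numpy()).statistic
    assert rho > 0.7
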