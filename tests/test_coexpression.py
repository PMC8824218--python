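import math
from itertools import permutations

import numpy as np
import pytest

from citemo import (
    ClusterAssignment,
    NormalizedMatrix,
    ValidationError,
    coexpression_entropy,
    marginal_probs,
    quadrant_probs,
    screen_pairs,
)

EPS = 1e-6
EPS_EXCESS = 4 * EPS * math.log(1 / EPS, 4)  # bound on entropy overshoot above 1


class TestMarginals:
    @pytest.mark.parametrize(
        "values,theta,ph",
        [
            ((0.6, 0.7, 0.9), 0.5, 1.0),
            ((0.5, 0.4), 0.5, 0.5),  # boundary value counts as high
            ((0.1, 0.9, 0.3), 0.0, 1.0),
        ],
    )
    def test_examples(self, values, theta, ph):
        got_ph, got_pl = marginal_probs(np.array(values), theta)
        assert got_ph == pytest.approx(ph)
        assert got_ph + got_pl == pytest.approx(1.0)

    def test_empty_cluster_errors(self):
        with pytest.raises(ValidationError):
            marginal_probs(np.array([]), 0.5)


class TestQuadrants:
    def test_single_quadrant(self):
        v1, v2 = np.full(10, 0.8), np.full(10, 0.9)
        prof = quadrant_probs(v1, v2, 0.5)
        np.testing.assert_allclose(prof.probabilities, [1, 0, 0, 0])

    def test_exhaustive_count(self):
        # 4 cells in Q1, 3 in Q2, 2 in Q3, 1 in Q4
        v1 = np.array([0.9] * 4 + [0.1] * 3 + [0.2] * 2 + [0.8])
        v2 = np.array([0.8] * 4 + [0.7] * 3 + [0.1] * 2 + [0.3])
        prof = quadrant_probs(v1, v2, 0.5)
        assert prof.counts.tolist() == [4, 3, 2, 1]
        np.testing.assert_allclose(prof.probabilities, [0.4, 0.3, 0.2, 0.1])
        assert prof.probabilities.sum() == pytest.approx(1.0)

    def test_joint_vs_product_under_dependence(self):
        rng = np.random.default_rng(0)
        v1 = rng.random(200)
        prof = quadrant_probs(v1, v1, 0.5, product_form=True)
        ph = (v1 >= 0.5).mean()
        assert prof.probabilities[0] == pytest.approx(ph)
        assert prof.product_probabilities[0] == pytest.approx(ph**2)
        assert prof.probabilities[0] != pytest.approx(prof.product_probabilities[0])
        # both variants are distributions (algebraic identity (PH+PL)^2 = 1)
        assert prof.product_probabilities.sum() == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            quadrant_probs(np.zeros(3), np.zeros(4))


class TestEntropy:
    def test_uniform_is_exactly_one(self):
        assert coexpression_entropy(np.full(4, 0.25)) == pytest.approx(1.0, abs=1e-15)

    def test_concentrated_closed_form(self):
        # three zero quadrants replaced by eps: S = 3 * eps * log4(1/eps)
        s = coexpression_entropy(np.array([1.0, 0, 0, 0]), EPS)
        assert s == pytest.approx(3 * EPS * math.log(1 / EPS, 4), rel=1e-12)
        assert round(s, 2) == 0.0

    def test_two_quadrant_half(self):
        s = coexpression_entropy(np.array([0.5, 0.5, 0, 0]), EPS)
        assert s == pytest.approx(0.5 + 2 * EPS * math.log(1 / EPS, 4), rel=1e-9)

    def test_permutation_symmetry(self):
        p = np.array([0.55, 0.25, 0.15, 0.05])
        vals = {round(coexpression_entropy(np.array(q)), 15) for q in permutations(p)}
        assert len(vals) == 1

    def test_simplex_grid_maximal_at_uniform(self):
        # dense grid over the 4-simplex (step 0.05)
        step = 0.05
        grid_max, argmax = -1.0, None
        n = round(1 / step)
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    p = np.array([a, b, c, n - a - b - c]) * step
                    s = coexpression_entropy(p, EPS)
                    if s > grid_max:
                        grid_max, argmax = s, p
        assert grid_max <= 1.0 + EPS_EXCESS
        np.testing.assert_allclose(argmax, [0.25, 0.25, 0.25, 0.25])

    def test_negative_probability_errors(self):
        with pytest.raises(ValidationError):
            coexpression_entropy(np.array([1.2, -0.2, 0, 0]))

    def test_not_a_distribution_errors(self):
        with pytest.raises(ValidationError):
            coexpression_entropy(np.array([0.5, 0.1, 0.1, 0.1]))


class TestScreenPairs:
    def _scaled_adt(self, values):
        values = np.asarray(values, dtype=float)
        return NormalizedMatrix(values, "scaled", "adt",
                                [f"A{i}" for i in range(values.shape[0])],
                                [f"c{j}" for j in range(values.shape[1])])

    def test_combinatorial_row_count(self):
        rng = np.random.default_rng(1)
        x = self._scaled_adt(rng.random((5, 40)))
        asg = ClusterAssignment(np.repeat([0, 1], 20), "multimodal",
                                x.cell_barcodes, {})
        table = screen_pairs(x, asg)
        assert len(table) == 2 * 5 * 4 // 2
        assert (table["adt1"] != table["adt2"]).all()
        assert table["entropy"].is_monotonic_increasing

    def test_double_positive_cluster_has_minimum_entropy(self):
        from citemo import generate_cite_seq
        from citemo.normalization import clr_transform, minmax_scale
        from citemo.synthetic import preset

        spec = preset("double_positive")
        _, adt, labels = generate_cite_seq(spec)
        scaled = minmax_scale(clr_transform(adt))
        asg = ClusterAssignment(labels, "multimodal", adt.cell_barcodes, {})
        table = screen_pairs(scaled, asg)
        c, a1, a2 = spec.double_positive
        dp = table[
            (table["cluster"] == c)
            & (table["adt1"] == f"ADT{min(a1, a2):02d}")
            & (table["adt2"] == f"ADT{max(a1, a2):02d}")
        ].iloc[0]
        assert dp["entropy"] == table["entropy"].min()  # ties allowed
        assert dp["p1"] == max(dp[f"p{i}"] for i in range(1, 5))

    def test_constant_adt_missing_correlation_entropy_defined(self):
        x = self._scaled_adt(np.vstack([np.full(10, 0.7), np.linspace(0, 1, 10)]))
        asg = ClusterAssignment(np.zeros(10, dtype=int), "multimodal",
                                x.cell_barcodes, {})
        table = screen_pairs(x, asg)
        assert np.isnan(table.loc[0, "pearson"])
        assert np.isfinite(table.loc[0, "entropy"])

    def test_tiny_cluster_correlations_missing(self):
        x = self._scaled_adt(np.random.default_rng(2).random((3, 4)))
        asg = ClusterAssignment(np.array([0, 0, 1, 1]), "multimodal",
                                x.cell_barcodes, {})
        table = screen_pairs(x, asg)
        assert table["pearson"].isna().all()
        assert np.isfinite(table["entropy"]).all()

    def test_needs_two_adts(self):
        x = self._scaled_adt(np.random.default_rng(3).random((1, 5)))
        asg = ClusterAssignment(np.zeros(5, dtype=int), "multimodal",
                                x.cell_barcodes, {})
        with pytest.raises(ValidationError):
            screen_pairs(x, asg)
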