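import numpy as np
import pytest

from citemo import (
    NormalizedMatrix,
    ValidationError,
    elbow_select,
    integrate,
    pca_reduce,
)


def _scaled(values, modality="rna"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(values, "scaled", modality,
                            [f"f{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])])


def _random_scaled(n_feat, n_cells, seed=0, modality="rna"):
    rng = np.random.default_rng(seed)
    return _scaled(rng.random((n_feat, n_cells)), modality)


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 20)
        x = _scaled(np.outer([0.5, 1.0, 2.0], t))
        rep = pca_reduce(x, "all", 0)
        total = rep.explained_variance.sum()
        assert rep.explained_variance[0] / total == pytest.approx(1.0, abs=1e-10)
        assert np.all(rep.explained_variance[1:] < 1e-10)

    def test_full_reconstruction(self):
        x = _random_scaled(50, 200)
        rep = pca_reduce(x, "all", 0)
        centered = x.values - x.values.mean(axis=1, keepdims=True)
        recon = rep.loadings @ rep.components
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_toy_against_covariance_eigenvalues(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3.1]], dtype=float)  # cells x 2
        rep = pca_reduce(_scaled(pts.T), "all", 0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(pts.T, ddof=1)))[::-1]
        np.testing.assert_allclose(rep.explained_variance, eigvals, rtol=1e-10)

    def test_variance_conservation_ddof1(self):
        x = _random_scaled(30, 80, seed=3)
        rep = pca_reduce(x, "all", 0)
        total_in = x.values.var(axis=1, ddof=1).sum()
        assert rep.explained_variance.sum() == pytest.approx(total_in, rel=1e-8)

    def test_sign_convention_bit_identical(self):
        x = _random_scaled(20, 60, seed=4)
        a, b = pca_reduce(x, 5, 0), pca_reduce(x, 5, 0)
        assert np.array_equal(a.components, b.components)
        assert np.array_equal(a.loadings, b.loadings)
        for c in range(5):
            j = np.argmax(np.abs(a.loadings[:, c]))
            assert a.loadings[j, c] > 0

    def test_cell_permutation_equivariance(self):
        x = _random_scaled(15, 40, seed=5)
        perm = np.random.default_rng(1).permutation(40)
        xp = _scaled(x.values[:, perm])
        rep, repp = pca_reduce(x, 4, 0), pca_reduce(xp, 4, 0)
        np.testing.assert_allclose(repp.components, rep.components[:, perm], atol=1e-9)

    def test_k_exceeds_features(self):
        with pytest.raises(ValidationError):
            pca_reduce(_random_scaled(5, 10), 6, 0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            pca_reduce(_scaled(np.ones((4, 10))), 2, 0)

    def test_adt_passthrough_returns_matrix_unchanged(self):
        x = _random_scaled(8, 30, modality="adt")
        rep = pca_reduce(x, passthrough=True)
        np.testing.assert_array_equal(rep.components, x.values)
        assert rep.component_ids == x.feature_ids
        assert not rep.from_pca


class TestElbow:
    def test_derived_example(self):
        assert elbow_select(np.array([50, 30, 2, 1.9, 1.8, 1.7])) == 2

    def test_linear_decay_no_elbow(self):
        assert elbow_select(np.arange(10, 0, -1.0)) == 1

    def test_too_short_errors(self):
        with pytest.raises(ValidationError, match="manual"):
            elbow_select(np.array([3.0, 1.0]))

    def test_chord_distance_oracle(self):
        # brute-force perpendicular distance to the chord over all indices
        rng = np.random.default_rng(8)
        for _ in range(20):
            ev = np.sort(rng.random(rng.integers(3, 12)))[::-1]
            n = len(ev)
            p0, p1 = np.array([0, ev[0]]), np.array([n - 1, ev[-1]])
            d = p1 - p0
            dists = [
                abs(np.cross(d, np.array([i, ev[i]]) - p0)) / np.linalg.norm(d)
                for i in range(n)
            ]
            assert elbow_select(ev) == max(int(np.argmax(dists)), 1)


class TestIntegrate:
    def test_empty_adt_degenerates_to_rna_alone(self):
        x = _random_scaled(12, 50, seed=6)
        rna_rep = pca_reduce(x, 5, 0)
        adt_rep = rna_rep.truncate(0)
        merged = integrate(rna_rep, adt_rep, 3, 0)
        from citemo.normalization import minmax_rows

        direct = pca_reduce(
            _scaled(minmax_rows(rna_rep.components)), 3, 0
        )
        np.testing.assert_allclose(merged.components, direct.components, atol=1e-9)

    def test_stacked_row_count_cbmc_style(self):
        # 10 RNA components + 10 passthrough ADTs -> 20-row stacked input
        rna_rep = pca_reduce(_random_scaled(40, 100, seed=7), 10, 0)
        adt_rep = pca_reduce(_random_scaled(10, 100, seed=8, modality="adt"),
                             passthrough=True)
        merged = integrate(rna_rep, adt_rep, 15, 0)
        assert merged.k == 15 <= rna_rep.k + adt_rep.k
        assert all(i.startswith(("RNA_", "ADT_")) for i in merged.component_ids[:0])

    def test_cell_order_mismatch_errors(self):
        a = pca_reduce(_random_scaled(6, 20, seed=9), 2, 0)
        b = pca_reduce(_random_scaled(6, 20, seed=10), 2, 0)
        b.cell_barcodes = list(reversed(b.cell_barcodes))
        with pytest.raises(ValidationError, match="order"):
            integrate(a, b, 2, 0)

    def test_multimodal_variance_conserved(self):
        from citemo.normalization import minmax_rows

        rna_rep = pca_reduce(_random_scaled(12, 60, seed=11), 4, 0)
        adt_rep = pca_reduce(_random_scaled(8, 60, seed=12, modality="adt"), 4, 0)
        merged = integrate(rna_rep, adt_rep, "auto", 0)
        stacked = np.vstack([minmax_rows(rna_rep.components),
                             minmax_rows(adt_rep.components)])
        full = integrate(rna_rep, adt_rep, 8, 0)
        assert full.explained_variance.sum() == pytest.approx(
            stacked.var(axis=1, ddof=1).sum(), rel=1e-8
        )
        assert np.all(np.diff(merged.explained_variance) <= 1e-12)


class TestModalityCoverage:
    def test_multimodal_separates_both_modality_specific_pairs(self, mixed_five_bundle):
        """An RNA-only-separable pair and an ADT-only-separable pair must both be
        separated in the fused representation, while each single-modality
        representation separates only its own pair."""
        from sklearn.metrics import silhouette_score

        bundle, labels, _ = mixed_five_bundle
        rna_pair = np.isin(labels, [0, 1])  # separable only in RNA
        adt_pair = np.isin(labels, [2, 3])  # separable only in ADT

        def sil(rep, mask):
            return silhouette_score(rep.components.T[mask], labels[mask])

        multi = bundle.reps["multimodal"]
        assert sil(multi, rna_pair) > 0
        assert sil(multi, adt_pair) > 0
        assert sil(bundle.reps["rna"], rna_pair) > 0
        assert sil(bundle.reps["adt"], adt_pair) > 0
        assert sil(bundle.reps["rna"], adt_pair) < sil(multi, adt_pair)
        assert sil(bundle.reps["adt"], rna_pair) < sil(multi, rna_pair)
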