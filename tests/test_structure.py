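"""PCA, percent-variance accounting, K-means/BIC and discriminant functions."""

import numpy as np
import pytest

from girscan import io, simulate as sm, structure


class TestPercentVariance:
    def test_shares_sum_to_100(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        res = structure.run_pca(g, n_pc=5)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        assert (res.percent_variance >= 0).all() and (res.percent_variance <= 100).all()

    def test_leading_eigenvalue_share_fixes_the_rest(self):
        """With eigenvalues 134.11, 39.16 and PC1 carrying 6.79%, PC2 carries 1.98%."""
        total = 134.11 * 100.0 / 6.79
        shares = structure.percent_variance(np.array([134.11, 39.16]), total=total)
        assert round(float(shares[1]), 2) == 1.98


class TestRunPca:
    def test_pc1_carries_between_population_variance(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        res = structure.run_pca(g, n_pc=4)
        labels = sim_cohort.labels
        mask = labels.mask(g.samples, labels.populations[0])
        # between-population separation is carried by PC1 more than any other PC
        sep = [abs(res.scores[mask, k].mean() - res.scores[~mask, k].mean()) for k in range(4)]
        assert np.argmax(sep) == 0

    def test_diverged_populations_separate_in_pc1_sign(self):
        """After enough drift the two populations split cleanly on PC1.

        At desk scale (hundreds of SNPs rather than tens of thousands) the
        split time is raised so that M * Fst, which governs PC separation,
        is comparable to a chip-scale study.
        """
        from tests.conftest import small_sim_config

        cfg = small_sim_config(
            seed=400, selected_loci=[], Ne_ancestral=100, Ne_pop1=100, Ne_pop2=100,
            t_split=80, n_founder_haplotypes=200, n_sample_pop1=50, n_sample_pop2=60,
        )
        res = sm.simulate_divergence(cfg)
        g = sm.merge_genotypes(res.genotypes)
        pca = structure.run_pca(g, n_pc=2)
        mask = res.labels.mask(g.samples, "beef")
        pc1 = pca.scores[:, 0]
        assert set(np.sign(pc1[mask])).isdisjoint(set(np.sign(pc1[~mask])))

    def test_duplicating_samples_preserves_shares(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        g2 = io.GenotypeMatrix(
            g.samples + [s + "_dup" for s in g.samples],
            io.MarkerMap(g.markers.table.copy()),
            np.vstack([g.calls, g.calls]),
        )
        a = structure.run_pca(g, n_pc=3)
        b = structure.run_pca(g2, n_pc=3)
        assert np.allclose(a.percent_variance[:3], b.percent_variance[:3], atol=1e-8)

    def test_argument_validation(self, sim_cohort):
        g = sm.merge_genotypes(sim_cohort.genotypes)
        with pytest.raises(ValueError):
            structure.run_pca(g, n_pc=g.n_samples + 5)
        const = io.GenotypeMatrix(
            ["a", "b"],
            io.MarkerMap.from_arrays(["s0"], [1], [100]),
            np.array([[2], [2]], dtype=np.int8),
        )
        with pytest.raises(ValueError):
            structure.run_pca(const, n_pc=1)


def blobs(seed=0, n=150, d=80, sep=20.0, k=2):
    rng = np.random.default_rng(seed)
    centres = np.zeros((k, d))
    for i in range(k):
        centres[i, 0] = i * sep
    x = np.vstack([rng.normal(c, 1.0, size=(n, d)) for c in centres])
    return x


class TestSelectKBic:
    def test_two_blobs_select_two(self):
        model = structure.select_k_bic(blobs(k=2), k_grid=[1, 2, 3, 4], seed=0)
        assert model.best_k == 2

    def test_single_blob_selects_one(self):
        model = structure.select_k_bic(blobs(k=1), k_grid=[1, 2, 3], seed=0)
        assert model.best_k == 1

    def test_deterministic_under_seed(self):
        x = blobs(seed=3, k=2)
        a = structure.select_k_bic(x, [1, 2, 3], seed=11)
        b = structure.select_k_bic(x, [1, 2, 3], seed=11)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.allclose(a.bic, b.bic)

    def test_more_restarts_never_worse(self):
        x = blobs(seed=5, k=3, sep=6.0)
        few = structure.select_k_bic(x, [1, 2, 3, 4], seed=2, n_starts=2)
        many = structure.select_k_bic(x, [1, 2, 3, 4], seed=2, n_starts=20)
        assert many.bic.min() <= few.bic.min() + 1e-9


class TestDiscriminantFunctions:
    def test_clamped_to_k_minus_one_with_warning(self):
        x = blobs(k=2)
        labels = np.repeat([0, 1], 150)
        with pytest.warns(UserWarning, match="only 1"):
            scores = structure.discriminant_functions(x, labels, n_df=10)
        assert scores.shape[1] == 1

    def test_separated_clusters_have_disjoint_score_ranges(self):
        x = blobs(k=2)
        labels = np.repeat([0, 1], 150)
        with pytest.warns(UserWarning):
            s = structure.discriminant_functions(x, labels, n_df=10)[:, 0]
        assert max(s[labels == 0]) < min(s[labels == 1]) or max(s[labels == 1]) < min(s[labels == 0])

    def test_label_permutation_preserves_subspace(self):
        x = blobs(k=3, sep=8.0)
        labels = np.repeat([0, 1, 2], 150)
        a = structure.discriminant_functions(x, labels, n_df=2)
        perm = np.array([2, 0, 1])[labels]
        b = structure.discriminant_functions(x, perm, n_df=2)
        # identical up to sign/order of axes: compare projector matrices
        pa = a @ np.linalg.pinv(a)
        pb = b @ np.linalg.pinv(b)
        assert np.allclose(pa, pb, atol=1e-6)

    def test_single_cluster_rejected(self):
        x = blobs(k=1)
        with pytest.raises(ValueError):
            structure.discriminant_functions(x, np.zeros(len(x), dtype=int), n_df=1)
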