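"""Nyström feature map and random Fourier sketching contracts."""

import numpy as np
import pytest

from chickn import (
    KernelConfig,
    NystromModel,
    generate_matrix,
    gram_matrix,
    nystrom_fit,
    sample_frequencies,
    sketch,
    sketch_point,
    two_cluster_spec,
)
from chickn.compression import (
    estimate_sigma2,
    estimate_sigma2_from_embeddings,
    sketch_embeddings,
)


@pytest.fixture
def tiny_instance():
    mat, _ = generate_matrix(two_cluster_spec(seed=5, columns_per_cluster=10))
    cfg = KernelConfig(p=1, gamma=0.05)  # Laplacian: PD Gram guaranteed
    return mat, cfg


class TestNystrom:
    def test_full_sampling_recovers_exact_kernel(self, tiny_instance):
        mat, cfg = tiny_instance
        n = mat.n_columns
        model = nystrom_fit(mat, l=n, r=n, s=n, cfg=cfg, landmark_indices=np.arange(n))
        emb = model.embed(np.asarray(mat.values))
        G = gram_matrix(np.asarray(mat.values), cfg)
        assert np.abs(emb @ emb.T - G).max() <= 1e-6

    def test_single_landmark_is_scalar_similarity(self, tiny_instance):
        mat, cfg = tiny_instance
        model = nystrom_fit(mat, l=1, r=1, s=1, cfg=cfg, landmark_indices=np.array([0]))
        x = mat.column(3)
        lm = mat.column(0)
        from chickn import kernel

        expected = kernel(x, lm, cfg) / np.sqrt(kernel(lm, lm, cfg))
        assert model.embed_one(x)[0] == pytest.approx(expected, abs=1e-10)

    def test_embedding_matches_pseudoinverse_oracle(self, tiny_instance):
        mat, cfg = tiny_instance
        n = mat.n_columns
        l = 8
        lm = np.arange(l)
        model = nystrom_fit(mat, l=l, r=l, s=l, cfg=cfg, landmark_indices=lm)
        emb = model.embed(np.asarray(mat.values))
        G = gram_matrix(np.asarray(mat.values), cfg)
        C = G[:, lm]
        W = G[np.ix_(lm, lm)]
        oracle = C @ np.linalg.pinv(W) @ C.T
        assert np.abs(emb @ emb.T - oracle).max() <= 1e-8

    def test_identical_profiles_embed_identically(self, tiny_instance):
        mat, cfg = tiny_instance
        model = nystrom_fit(mat, l=10, r=5, s=4, cfg=cfg, seed=0)
        x = mat.column(2)
        assert np.allclose(model.embed_one(x), model.embed_one(3.7 * x))

    def test_published_sizing_accepted(self):
        from chickn import derive_parameters

        p = derive_parameters(57_140, 2, 16_384)
        assert (p["l"], p["s"]) == (240, 22)  # sizes usable without error
        assert p["s"] <= p["l"] // 2 <= p["l"]

    def test_rank_deficiency_detected(self):
        # identical landmark columns -> rank-1 landmark Gram
        values = np.tile(np.array([[1.0], [2.0], [1.0]]), (1, 6))
        from chickn import DataMatrix

        mat = DataMatrix(values, [0, 1, 2], 400 + np.arange(6.0), "synthetic")
        with pytest.raises(ValueError, match="rank"):
            nystrom_fit(mat, l=4, r=4, s=3, cfg=KernelConfig(p=1, gamma=1.0),
                        landmark_indices=np.arange(4))

    def test_invalid_sizes_rejected(self, tiny_instance):
        mat, cfg = tiny_instance
        with pytest.raises(ValueError):
            nystrom_fit(mat, l=5, r=6, s=2, cfg=cfg)

    def test_approximation_error_non_increasing_in_s(self, tiny_instance):
        mat, cfg = tiny_instance
        G = gram_matrix(np.asarray(mat.values), cfg)
        s_values = [1, 2, 4, 6, 8]
        errors = np.zeros((10, len(s_values)))
        for t in range(10):
            rng = np.random.default_rng(t)
            lm = np.sort(rng.choice(mat.n_columns, size=10, replace=False))
            for i, s in enumerate(s_values):
                model = nystrom_fit(mat, l=10, r=10, s=s, cfg=cfg, landmark_indices=lm)
                emb = model.embed(np.asarray(mat.values))
                errors[t, i] = np.linalg.norm(emb @ emb.T - G)
        mean_err = errors.mean(axis=0)
        assert np.all(np.diff(mean_err) <= 1e-9)

    def test_serialization_round_trip(self, tiny_instance, tmp_path):
        mat, cfg = tiny_instance
        model = nystrom_fit(mat, l=8, r=4, s=3, cfg=cfg, seed=1)
        path = tmp_path / "model.npz"
        model.save(path)
        back = NystromModel.load(path)
        x = mat.column(5)
        assert np.allclose(back.embed_one(x), model.embed_one(x))


class TestSigma2:
    def test_gaussian_variance_recovered(self):
        s, v = 6, 2.5
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            emb = rng.normal(0, np.sqrt(v), size=(500, s))
            estimates.append(estimate_sigma2_from_embeddings(emb))
        assert abs(np.mean(estimates) - s * v) <= 0.5 * s * v

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(100, 4))
        assert estimate_sigma2_from_embeddings(2 * emb) == pytest.approx(
            4 * estimate_sigma2_from_embeddings(emb)
        )

    def test_degenerate_embeddings_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_sigma2_from_embeddings(np.ones((50, 4)))

    def test_matrix_route_is_deterministic(self, tiny_instance):
        mat, cfg = tiny_instance
        model = nystrom_fit(mat, l=10, r=5, s=4, cfg=cfg, seed=0)
        a = estimate_sigma2(model, mat, subsample_size=15, seed=3)
        b = estimate_sigma2(model, mat, subsample_size=15, seed=3)
        assert a == b > 0


class TestFrequencies:
    def test_seed_determinism(self):
        f1 = sample_frequencies(20, 4, 1.5, seed=9)
        f2 = sample_frequencies(20, 4, 1.5, seed=9)
        assert np.array_equal(f1.frequencies, f2.frequencies)

    def test_single_frequency_shape(self):
        f = sample_frequencies(1, 7, 1.0, seed=0)
        assert f.frequencies.shape == (1, 7)

    def test_row_norm_moment(self):
        s, sigma2, m = 5, 2.0, 10_000
        f = sample_frequencies(m, s, sigma2, seed=4)
        norms2 = (f.frequencies**2).sum(axis=1)
        expected = s / sigma2
        stderr = np.sqrt(2 * s) / sigma2 / np.sqrt(m)
        assert abs(norms2.mean() - expected) <= 3 * stderr

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_frequencies(0, 3, 1.0)
        with pytest.raises(ValueError):
            sample_frequencies(5, 3, -1.0)


class TestSketch:
    def _model_and_freqs(self, tiny_instance, m=16, zero=False):
        mat, cfg = tiny_instance
        model = nystrom_fit(mat, l=10, r=5, s=4, cfg=cfg, seed=0)
        freqs = sample_frequencies(m, 4, 1.0, seed=2)
        if zero:
            object.__setattr__(freqs, "frequencies", np.zeros_like(freqs.frequencies))
        return mat, model, freqs

    def test_zero_frequencies_give_uniform_components(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance, zero=True)
        sk = sketch(mat, np.arange(mat.n_columns), model, freqs)
        assert np.allclose(sk.values, 1 / np.sqrt(freqs.m))

    def test_modulus_bound(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance)
        sk = sketch(mat, np.arange(mat.n_columns), model, freqs)
        assert np.all(np.abs(sk.values) <= 1 / np.sqrt(freqs.m) + 1e-12)

    def test_single_column_equals_point_sketch(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance)
        sk = sketch(mat, np.array([3]), model, freqs)
        point = sketch_point(model.embed_one(mat.column(3)), freqs)
        assert np.allclose(sk.values, point, atol=1e-12)

    def test_union_linearity(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance)
        A = np.arange(0, 8)
        B = np.arange(8, 20)
        skA = sketch(mat, A, model, freqs)
        skB = sketch(mat, B, model, freqs)
        skAB = sketch(mat, np.concatenate([A, B]), model, freqs)
        combined = (len(A) * skA.values + len(B) * skB.values) / (len(A) + len(B))
        assert np.abs(skAB.values - combined).max() <= 1e-12

    def test_streaming_matches_block_evaluation(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance)
        idx = np.arange(mat.n_columns)
        chunked = sketch(mat, idx, model, freqs, chunk=3)
        block = sketch_embeddings(model.embed(np.asarray(mat.values)), freqs)
        assert np.allclose(chunked.values, block.values, atol=1e-12)

    def test_point_sketch_contracts(self):
        freqs = sample_frequencies(9, 3, 1.0, seed=1)
        zero = sketch_point(np.zeros(3), freqs)
        assert np.allclose(zero, 1 / np.sqrt(9))
        any_vec = sketch_point(np.array([1.0, -2.0, 0.5]), freqs)
        assert np.allclose(np.abs(any_vec), 1 / np.sqrt(9))

    def test_empty_subset_rejected(self, tiny_instance):
        mat, model, freqs = self._model_and_freqs(tiny_instance)
        with pytest.raises(ValueError):
            sketch(mat, np.array([], dtype=int), model, freqs)
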