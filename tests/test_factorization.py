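"""Matrix factorization variants, component classification, and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiddec import (
    MultiplicativeNMF,
    ProbabilisticNMF,
    ProbabilisticSparseMF,
    SparseNMF,
    classify_components,
    factorize,
    split_components,
)
from fiddec.factorization import VARIANTS, FactorizationResult


def random_nonneg(shape, seed, scale=1.0):
    return scale * np.abs(np.random.default_rng(seed).normal(size=shape))


def make_result(W, H, variant="nmf", seed=0):
    W = np.asarray(W, float)
    H = np.asarray(H, float)
    return FactorizationResult(
        W=W,
        H=H,
        rank=W.shape[1],
        variant=variant,
        objective_trace=np.array([0.0]),
        residuals=np.zeros((W.shape[0], H.shape[1])),
        seed=seed,
    )


class TestFactorizeContract:
    @pytest.mark.parametrize(
        "variant,kwargs",
        [
            ("nmf", {}),
            # weak-penalty regime: the L1 term must not visibly bias the fit
            ("snmf", {"beta": 1e-4}),
            ("pmf", {}),
        ],
    )
    def test_rank_one_outer_product_recovered(self, variant, kwargs):
        w = np.abs(np.random.default_rng(1).normal(size=40)) + 0.1
        h = np.exp(-np.linspace(0, 3, 25)) + 0.05
        V = np.outer(w, h)
        res = factorize(V, rank=1, variant=variant, seed=0, max_iter=500,
                        tol=1e-12, **kwargs)
        rel = np.linalg.norm(V - res.reconstruction) / np.linalg.norm(V)
        assert rel <= 1e-3

    def test_rank_one_outer_product_psmf(self):
        # flat-noise off: a rank-1 PSMF must carry the full structure
        w = np.abs(np.random.default_rng(2).normal(size=40)) + 0.1
        h = np.exp(-np.linspace(0, 3, 25)) + 0.05
        V = np.outer(w, h)
        res = factorize(V, rank=1, variant="psmf", seed=0, max_iter=500,
                        tol=1e-12, flat_noise=False)
        rel = np.linalg.norm(V - res.reconstruction) / np.linalg.norm(V)
        assert rel <= 1e-3

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_nonnegativity_and_determinism(self, variant):
        V = random_nonneg((30, 20), seed=3)
        a = factorize(V, rank=3, variant=variant, seed=7, max_iter=50)
        b = factorize(V, rank=3, variant=variant, seed=7, max_iter=50)
        assert np.all(a.W >= 0) and np.all(a.H >= 0)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_random_init_also_deterministic(self, variant):
        V = random_nonneg((30, 20), seed=3)
        a = factorize(V, rank=2, variant=variant, seed=5, max_iter=30, init="random")
        b = factorize(V, rank=2, variant=variant, seed=5, max_iter=30, init="random")
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    @pytest.mark.parametrize("variant", ["nmf", "snmf", "pmf"])
    def test_objective_monotone_nonincreasing(self, variant):
        V = random_nonneg((50, 30), seed=4, scale=2.0)
        res = factorize(V, rank=3, variant=variant, seed=0, max_iter=150, tol=0.0)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-9 * np.maximum(np.abs(res.objective_trace[:-1]), 1.0))

    def test_negative_matrix_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            factorize(np.array([[1.0, -0.1], [0.2, 0.3]]), rank=1)

    def test_rank_exceeding_dimensions_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            factorize(random_nonneg((5, 4), 0), rank=5)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            factorize(random_nonneg((5, 4), 0), rank=2, variant="svd")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        rank=st.integers(1, 3),
        variant=st.sampled_from(sorted(VARIANTS)),
    )
    def test_factors_always_nonnegative(self, seed, rank, variant):
        V = random_nonneg((12, 8), seed=seed)
        res = factorize(V, rank=rank, variant=variant, seed=seed, max_iter=20)
        assert np.all(res.W >= 0)
        assert np.all(res.H >= 0)


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        est = ProbabilisticSparseMF(n_components=3, assignment_prior=0.2)
        params = est.get_params()
        assert params["n_components"] == 3
        clone = ProbabilisticSparseMF().set_params(**params)
        assert clone.get_params() == params

    def test_fit_exposes_fitted_attributes(self):
        V = random_nonneg((20, 15), seed=0)
        est = MultiplicativeNMF(n_components=2, random_state=0).fit(V)
        assert est.W_.shape == (20, 2)
        assert est.components_.shape == (2, 15)
        assert est.n_iter_ >= 1
        assert est.reconstruction_err_ >= 0

    def test_comparable_fit_to_sklearn_nmf(self):
        # independent cross-check: our multiplicative NMF should reach a
        # reconstruction error in the same range as scikit-learn's NMF
        from sklearn.decomposition import NMF as SkNMF

        V = random_nonneg((40, 30), seed=8, scale=3.0)
        ours = MultiplicativeNMF(n_components=3, random_state=0, max_iter=500,
                                 tol=1e-10).fit(V)
        theirs = SkNMF(n_components=3, init="nndsvda", max_iter=500, tol=1e-10,
                       random_state=0).fit(V)
        sk_err = np.linalg.norm(V - theirs.transform(V) @ theirs.components_)
        assert ours.reconstruction_err_ <= 1.1 * sk_err + 1e-9


class TestClassification:
    def test_denoise_labels_decaying_vs_flat(self):
        t = np.arange(20, dtype=float)
        H = np.vstack([np.exp(-t / 5.0), np.ones(20)])
        W = np.ones((10, 2))
        lab = classify_components(make_result(W, H), mode="denoise")
        assert lab.labels == ["signal", "noise"]
        assert lab.decay_ratio[0] > lab.decay_ratio[1]

    def test_t2_mode_orders_by_decay_constant(self):
        t = np.linspace(0, 1, 30)
        H = np.vstack([np.exp(-t / 0.005), np.exp(-t / 0.5), np.ones(30)])
        W = np.ones((8, 3))
        lab = classify_components(
            make_result(W, H), mode="t2_separation", segment_times=t
        )
        assert lab.labels == ["short_t2", "long_t2", "noise"]
        assert lab.fitted_tau[0] < lab.fitted_tau[1]

    def test_all_flat_components_raise(self):
        H = np.vstack([np.ones(15), 1.1 * np.ones(15)])
        W = np.ones((6, 2))
        with pytest.raises(ValueError, match="no decaying component"):
            classify_components(make_result(W, H), mode="denoise")

    def test_insufficient_rank_rejected(self):
        H = np.vstack([np.exp(-np.arange(10.0) / 3), np.ones(10)])
        W = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            classify_components(make_result(W, H), mode="t2_separation")

    def test_psmf_signal_tau_near_weighted_t2(self, sucrose_truth, sucrose_result):
        labeling = {d["label"]: d for d in sucrose_result.provenance["labeling"]}
        tau = labeling["signal"]["fitted_tau"]
        amps = np.array([ln.amplitude for ln in sucrose_truth.lines])
        t2s = np.array([ln.t2_star for ln in sucrose_truth.lines])
        weighted = float((amps * t2s).sum() / amps.sum())
        assert weighted / 2 <= tau <= weighted * 2


class TestSplitComponents:
    def _setup(self, reassign):
        t = np.arange(10.0)
        W = random_nonneg((12, 2), seed=0) + 0.1
        H = np.vstack([np.exp(-t / 3.0), np.ones(10)])
        res = make_result(W, H)
        V = res.reconstruction
        labels = classify_components(res, mode="denoise")
        return V, res, labels, split_components(V, res, labels, reassign)

    def test_split_conserves_reconstruction(self):
        V, res, labels, parts = self._setup(0)
        total = sum(parts.values())
        np.testing.assert_allclose(total, res.reconstruction, atol=1e-12)

    @pytest.mark.parametrize("reassign", [1, 3])
    def test_reassigned_noise_columns_are_zero(self, reassign):
        V, res, labels, parts = self._setup(reassign)
        assert np.all(parts["noise"][:, :reassign] == 0)
        total = sum(parts.values())
        np.testing.assert_allclose(total, res.reconstruction, atol=1e-12)

    def test_reassign_beyond_segments_rejected(self):
        V, res, labels, _ = self._setup(0)
        with pytest.raises(ValueError, match="exceeds"):
            split_components(V, res, labels, reassign_initial_segments=11)
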