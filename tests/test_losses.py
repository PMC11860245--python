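"""Loss components against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stst.autodiff import Var
from stst.losses import (
    ConfigError,
    LossSpec,
    content_loss,
    gram,
    texture_loss,
    total_loss,
    tv_loss,
)


def brute_gram(A):
    n, m = A.shape
    G = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = sum(A[i, k] * A[j, k] for k in range(m)) / (n * m)
    return G


def brute_content(A, B):
    n, m = A.shape
    return sum((A[i, j] - B[i, j]) ** 2 for i in range(n) for j in range(m)) / (2 * n * m)


def brute_texture(A, B):
    Ga, Gb = brute_gram(A), brute_gram(B)
    n = A.shape[0]
    return np.sum((Ga - Gb) ** 2) / (2 * n * n)


def brute_tv(frame):
    H, W, C = frame.shape
    total = 0.0
    for k in range(C):
        for i in range(H):
            for j in range(W):
                if i + 1 < H:
                    total += abs(frame[i + 1, j, k] - frame[i, j, k])
                if j + 1 < W:
                    total += abs(frame[i, j + 1, k] - frame[i, j, k])
    return total / (H * W * C)


class TestContentLoss:
    def test_zero_when_equal(self, rng):
        A = rng.standard_normal((3, 5))
        assert content_loss(A, A) == 0.0

    def test_hand_computed_single_entry(self):
        assert content_loss(np.array([[1.0]]), np.array([[3.0]])) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self, rng):
        A, B = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        assert content_loss(3 * A, 3 * B) == pytest.approx(9 * content_loss(A, B))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            content_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_matches_brute_force(self, rng):
        A, B = rng.standard_normal((5, 7)), rng.standard_normal((5, 7))
        assert content_loss(A, B) == pytest.approx(brute_content(A, B), rel=1e-10)


class TestGram:
    def test_zero_activations(self):
        assert np.array_equal(gram(np.zeros((3, 4))), np.zeros((3, 3)))

    def test_hand_computed_two_by_two(self):
        G = gram(np.array([[1.0, 1.0], [0.0, 0.0]]))
        assert np.allclose(G, [[0.5, 0.0], [0.0, 0.0]])

    def test_column_permutation_invariance(self, rng):
        A = rng.standard_normal((4, 9))
        perm = rng.permutation(9)
        assert np.allclose(gram(A), gram(A[:, perm]))

    def test_symmetric_psd(self, rng):
        G = gram(rng.standard_normal((6, 11)))
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-12

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        A = np.random.default_rng(seed).standard_normal((5, 7))
        assert np.allclose(gram(A), brute_gram(A), rtol=1e-6)


class TestTextureLoss:
    def test_zero_when_equal_and_under_permutation(self, rng):
        A = rng.standard_normal((4, 8))
        assert texture_loss(A, A) == 0.0
        assert texture_loss(A, A[:, rng.permutation(8)]) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_case(self):
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert texture_loss(A, np.zeros((2, 2))) == pytest.approx(0.03125)

    def test_different_spatial_sizes_allowed(self, rng):
        A, B = rng.standard_normal((4, 8)), rng.standard_normal((4, 18))
        assert texture_loss(A, B) >= 0

    def test_different_filter_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            texture_loss(rng.standard_normal((4, 8)), rng.standard_normal((5, 8)))

    def test_matches_brute_force(self, rng):
        A, B = rng.standard_normal((5, 7)), rng.standard_normal((5, 7))
        assert texture_loss(A, B) == pytest.approx(brute_texture(A, B), rel=1e-6)


class TestTVLoss:
    def test_constant_frame_is_zero(self):
        assert tv_loss(np.full((5, 5, 3), 0.3)) == 0.0

    def test_checkerboard_hand_sum(self):
        frame = np.array([[0.0, 1.0], [1.0, 0.0]])[..., None]
        assert tv_loss(frame) == pytest.approx(1.0)

    def test_complement_symmetry(self, rng):
        g = rng.uniform(0, 1, (6, 7, 3))
        assert tv_loss(1 - g) == pytest.approx(tv_loss(g), rel=1e-12)

    def test_matches_brute_force(self, rng):
        g = rng.uniform(0, 1, (6, 5, 3))
        assert tv_loss(g) == pytest.approx(brute_tv(g), rel=1e-10)

    def test_channels_first_orientation(self, rng):
        g = rng.uniform(0, 1, (8, 5, 3))
        assert tv_loss(np.moveaxis(g, -1, 0), channel_axis=0) == pytest.approx(tv_loss(g))


class TestTotalLoss:
    def _acts(self, rng, layers, n=4, m=9):
        return {l: rng.standard_normal((n, m)) for l in layers}

    def test_only_tv_on_constant_frame_is_zero(self):
        spec = LossSpec(alpha=0, beta=0, theta=0, lam=0, omega=1.0)
        assert total_loss(spec, {}, {}, g_frame=np.full((4, 4, 3), 0.5)) == 0.0

    def test_zero_when_generated_equals_target(self, rng):
        layers = ["a", "b"]
        acts = self._acts(rng, layers)
        spec = LossSpec(beta=1, lam=0, omega=0, spatial_layers=layers,
                        routing={"spatial_texture": "t"})
        L = total_loss(spec, {"t": {"spatial": acts}}, {"spatial": acts})
        assert L == pytest.approx(0.0, abs=1e-15)

    def test_additivity_of_terms(self, rng):
        sl, tl = ["s1"], ["t1"]
        t_s = self._acts(rng, sl)
        t_t = self._acts(rng, tl)
        g_s = self._acts(rng, sl)
        g_t = self._acts(rng, tl)
        spec = LossSpec(beta=1, lam=1, omega=0, spatial_layers=sl, temporal_layers=tl,
                        routing={"spatial_texture": "A", "temporal_texture": "B"})
        joint = total_loss(
            spec,
            {"A": {"spatial": t_s}, "B": {"temporal": t_t}},
            {"spatial": g_s, "temporal": g_t},
        )
        separate = texture_loss(t_s["s1"], g_s["s1"]) + texture_loss(t_t["t1"], g_t["t1"])
        assert joint == pytest.approx(separate, abs=1e-10)

    def test_missing_routed_target_raises(self, rng):
        spec = LossSpec(beta=1, lam=0, omega=0, spatial_layers=["a"], routing={})
        with pytest.raises(ConfigError):
            total_loss(spec, {}, {"spatial": self._acts(rng, ["a"])})

    def test_gradient_ready_with_var_input(self, rng):
        layers = ["a"]
        tacts = self._acts(rng, layers)
        gvar = Var(rng.standard_normal((4, 9)), requires_grad=True)
        spec = LossSpec(beta=1, lam=0, omega=0, spatial_layers=layers,
                        routing={"spatial_texture": "t"})
        L = total_loss(spec, {"t": {"spatial": tacts}}, {"spatial": {"a": gvar}})
        L.backward()
        assert np.isfinite(gvar.grad).all() and np.any(gvar.grad != 0)
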