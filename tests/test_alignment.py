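"""MMD and the alignment/contrastive losses against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spagnet import (LossWeights, align_global, align_local, contrastive,
                     mmd, total_loss)
from spagnet.alignment import mmd_t
from spagnet._tensor import Tensor


def brute_force_mmd(x, y):
    """Direct double-loop evaluation of the biased V-statistic."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    k = lambda a, b: np.exp(-0.5 * np.sum((a - b) ** 2))
    n, m = x.shape[1], y.shape[1]
    kxx = sum(k(x[:, i], x[:, j]) for i in range(n) for j in range(n)) / n ** 2
    kyy = sum(k(y[:, i], y[:, j]) for i in range(m) for j in range(m)) / m ** 2
    kxy = sum(k(x[:, i], y[:, j]) for i in range(n) for j in range(m))
    return kxx + kyy - 2 * kxy / (n * m)


class TestMMD:
    def test_identical_sets_zero(self):
        x = np.random.default_rng(0).normal(size=(3, 7))
        assert mmd(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_closed_form(self):
        # 1-D singletons {0} vs {2}: MMD = 2 - 2 exp(-2)
        got = mmd(np.array([[0.0]]), np.array([[2.0]]))
        assert got == pytest.approx(2 - 2 * np.exp(-2), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(4, 6)), rng.normal(size=(4, 9))
        assert mmd(x, y) == pytest.approx(mmd(y, x), abs=1e-12)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(3, rng.integers(2, 50)))
        y = rng.normal(size=(3, rng.integers(2, 50)))
        assert mmd(x, y) == pytest.approx(brute_force_mmd(x, y), abs=1e-10)

    def test_singleton_monotone_in_distance(self):
        dists = np.linspace(0.1, 3.0, 10)
        vals = [mmd(np.array([[0.0]]), np.array([[d]])) for d in dists]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        for d, v in zip(dists, vals):
            assert v == pytest.approx(2 - 2 * np.exp(-d ** 2 / 2), abs=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mmd_t(Tensor(np.zeros((2, 0))), Tensor(np.ones((2, 3))))

    def test_nonnegative_after_clamp(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=(2, 10))
            assert mmd(x, x + 1e-9 * rng.normal(size=(2, 10))) >= 0.0


class TestAlignGlobal:
    def test_identical_views_zero(self):
        layers = [Tensor(np.random.default_rng(0).normal(size=(3, 6)))
                  for _ in range(2)]
        assert align_global(layers, layers).item() == pytest.approx(0, abs=1e-12)

    def test_single_layer_equals_mmd(self):
        rng = np.random.default_rng(1)
        h1, h2 = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        got = align_global([Tensor(h1)], [Tensor(h2)]).item()
        assert got == pytest.approx(brute_force_mmd(h2, h1), abs=1e-10)

    def test_two_layers_mean_of_componentwise(self):
        rng = np.random.default_rng(2)
        l1 = [rng.normal(size=(3, 5)), rng.normal(size=(2, 5))]
        l2 = [rng.normal(size=(3, 5)), rng.normal(size=(2, 5))]
        got = align_global([Tensor(a) for a in l1],
                           [Tensor(a) for a in l2]).item()
        expected = np.mean([brute_force_mmd(b, a) for a, b in zip(l1, l2)])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_layer_count_mismatch_errors(self):
        with pytest.raises(ValueError, match="layer"):
            align_global([Tensor(np.ones((2, 3)))], [])


class TestAlignLocal:
    def test_identical_views_zero(self):
        rng = np.random.default_rng(0)
        layers = [Tensor(rng.normal(size=(3, 4)))]
        nb = [np.array([1, 2]), np.array([0, 3]), np.array([3, 0]),
              np.array([2, 1])]
        assert align_local(layers, layers, nb).item() == pytest.approx(
            0.0, abs=1e-12)

    def test_four_spot_chain_matches_exhaustive_loop(self):
        rng = np.random.default_rng(3)
        h1 = rng.normal(size=(3, 4))
        h2 = rng.normal(size=(3, 4))
        nb = [np.array([1]), np.array([0]), np.array([3]), np.array([2])]
        got = align_local([Tensor(h1)], [Tensor(h2)], nb).item()
        expected = np.mean([brute_force_mmd(h2[:, list(s)], h1[:, list(s)])
                            for s in nb])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_multilayer_matches_double_loop(self, small_bundle):
        rng = np.random.default_rng(4)
        n = small_bundle.expression.n_spots
        nb = small_bundle.graph.neighbor_sets
        l1 = [rng.normal(size=(3, n)), rng.normal(size=(2, n))]
        l2 = [rng.normal(size=(3, n)), rng.normal(size=(2, n))]
        got = align_local([Tensor(a) for a in l1],
                          [Tensor(a) for a in l2], nb).item()
        expected = np.mean([
            np.mean([brute_force_mmd(b[:, list(s)], a[:, list(s)])
                     for s in nb])
            for a, b in zip(l1, l2)])
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_neighbor_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            align_local([Tensor(np.ones((2, 2)))], [Tensor(np.ones((2, 2)))],
                        [np.array([], dtype=int), np.array([0])])


class TestContrastive:
    def test_identical_views_zero(self):
        layers = [Tensor(np.random.default_rng(0).normal(size=(3, 4)))]
        assert contrastive(layers, layers).item() == pytest.approx(0, abs=1e-15)

    def test_opposite_views_warn(self):
        h = Tensor(np.ones((2, 2)))
        neg = Tensor(-np.ones((2, 2)))
        with pytest.warns(UserWarning, match="zero denominator"):
            assert contrastive([h], [neg]).item() == 0.0

    def test_integer_toy_matches_hand_arithmetic(self):
        h1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        h2 = np.array([[0.0, 2.0], [1.0, 0.0]])
        got = contrastive([Tensor(h1)], [Tensor(h2)]).item()
        expected = ((h1 - h2) ** 2).sum() / np.linalg.norm(h1 + h2)
        assert got == pytest.approx(expected, abs=1e-12)


class TestTotalLoss:
    def test_all_zero_components(self):
        z = Tensor(0.0)
        assert total_loss(z, z, z, z, z, z, LossWeights()).item() == 0.0

    def test_lambda2_zero_ignores_alignment(self):
        one = Tensor(1.0)
        w = LossWeights(lambda1=0.5, lambda2=0.0)
        got = total_loss(one, one, Tensor(2.0), Tensor(99.0), Tensor(99.0),
                         Tensor(99.0), w).item()
        assert got == pytest.approx(1 + 1 + 0.5 * 2)

    def test_arithmetic_check(self):
        vals = [Tensor(v) for v in (1.0, 1.0, 2.0, 3.0, 4.0, 5.0)]
        w = LossWeights(lambda1=0.5, lambda2=0.1)
        got = total_loss(*vals, w).item()
        assert got == pytest.approx(1 + 1 + 0.5 * 2 + 0.1 * (3 + 4 + 5))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="lambda1"):
            LossWeights(lambda1=-1.0)
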