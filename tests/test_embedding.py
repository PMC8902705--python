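import math

import numpy as np
import pytest

from impaesim.constraints import ConstraintSet
from impaesim.embedding import (
    AeModel,
    AeParams,
    DiseaseEmbedding,
    ImpAeParams,
    _train,
    concatenate_hidden,
    constraint_loss,
    init_model,
    load_embedding,
    loss_and_grad,
    save_embedding,
    train_classic_ae,
    train_impae,
)
from impaesim.network_io import NodeIndex


def index_of(n: int) -> NodeIndex:
    return NodeIndex.from_ids([f"d{i:02d}" for i in range(n)], "disease")


def numeric_gradient(model: AeModel, X, eps=1e-6, **kwargs) -> AeModel:
    """Central finite differences of the joint loss over every parameter."""
    grads = {}
    for name in ("W", "b", "W_out", "d"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _ = loss_and_grad(model, X, **kwargs)
            arr[ix] = orig - eps
            lm, _ = loss_and_grad(model, X, **kwargs)
            arr[ix] = orig
            g[ix] = (lp - lm) / (2 * eps)
        grads[name] = g
    return AeModel(**grads)


def rel_error(a: np.ndarray, b: np.ndarray) -> float:
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-8)
    return float(np.abs(a - b).max() / denom)


def max_grad_rel_error(model, X, **kwargs) -> float:
    _, analytic = loss_and_grad(model, X, **kwargs)
    numeric = numeric_gradient(model, X, **kwargs)
    return max(
        rel_error(getattr(analytic, n), getattr(numeric, n))
        for n in ("W", "b", "W_out", "d")
    )


class TestGradients:
    def test_reconstruction_gradient_matches_finite_differences(self, rng):
        X = rng.random((4, 3))
        model = init_model(3, 2, seed=0)
        assert max_grad_rel_error(model, X) < 1e-5

    def test_joint_gradient_matches_finite_differences(self, rng):
        X = rng.random((5, 4))
        model = init_model(4, 2, seed=1)
        pos = (np.array([0, 1]), np.array([2, 3]))
        neg = (np.array([0]), np.array([4]))
        err = max_grad_rel_error(
            model, X, pos_idx=pos, neg_idx=neg,
            gamma=2.0, gamma1=1.5, gamma2=0.5, neg_cap=math.inf,
        )
        assert err < 1e-5

    def test_gradient_with_active_cap(self, rng):
        # hidden vectors far apart: cap binds, so capped pairs must not
        # contribute gradient
        X = rng.random((5, 4))
        model = init_model(4, 2, seed=2)
        neg = (np.array([0, 1]), np.array([2, 3]))
        err = max_grad_rel_error(
            model, X, neg_idx=neg, gamma=3.0, gamma2=2.0, neg_cap=1e-4
        )
        assert err < 1e-5


class TestClassicAe:
    def test_constant_rows_converge_to_constant_fit(self):
        X = np.full((4, 6), 0.6)
        _, _, history = _train(X, 2, 1e-2, 300, seed=0)
        assert all(a > b for a, b in zip(history[:5], history[1:6]))
        assert history[-1] < 1e-3  # best constant-output fit is exact here

    def test_separated_rows_reach_tenth_of_initial_loss(self):
        X = np.array(
            [
                [0.9, 0.05, 0.05, 0.05],
                [0.05, 0.9, 0.05, 0.05],
                [0.05, 0.05, 0.9, 0.05],
            ]
        )
        _, _, history = _train(X, 3, 1e-2, 1000, seed=42)
        assert history[-1] < history[0] / 10

    def test_final_loss_not_above_initial(self, rng):
        X = rng.random((10, 8))
        _, _, history = _train(X, 3, 1e-3, 200, seed=5)
        assert history[-1] <= history[0]

    def test_seed_determinism(self, rng):
        X = rng.random((6, 5))
        params = AeParams(hidden_dim=3, epochs=50, seed=11)
        m1, h1 = train_classic_ae(X, params)
        m2, h2 = train_classic_ae(X, params)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_hidden_dim_must_compress(self, rng):
        X = rng.random((6, 4))
        with pytest.raises(ValueError, match="hidden_dim"):
            _train(X, 4, 1e-3, 10, seed=0)

    def test_non_finite_input_reports_epoch(self):
        X = np.full((3, 4), np.nan)
        with pytest.raises(FloatingPointError, match="epoch 1"):
            _train(X, 2, 1e-3, 10, seed=0)

    @pytest.mark.parametrize(
        "kwargs", [{"hidden_dim": 0}, {"hidden_dim": 2, "epochs": 0},
                   {"hidden_dim": 2, "learning_rate": 0.0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AeParams(**kwargs)


class TestConcatenateHidden:
    def test_single_matrix_unchanged(self, rng):
        h = rng.random((3, 2))
        np.testing.assert_array_equal(concatenate_hidden([h], index_of(3)), h)

    def test_two_blocks_in_order(self):
        a = np.arange(4.0).reshape(2, 2)
        b = 10 + np.arange(4.0).reshape(2, 2)
        out = concatenate_hidden([a, b], index_of(2))
        np.testing.assert_array_equal(out[:, :2], a)
        np.testing.assert_array_equal(out[:, 2:], b)

    def test_three_blocks_slicing_oracle(self, rng):
        mats = [rng.random((5, k)) for k in (2, 3, 4)]
        out = concatenate_hidden(mats, index_of(5))
        assert out.shape == (5, 9)
        start = 0
        for m in mats:
            np.testing.assert_array_equal(out[:, start:start + m.shape[1]], m)
            start += m.shape[1]

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="rows"):
            concatenate_hidden([rng.random((3, 2)), rng.random((4, 2))],
                               index_of(3))


class TestConstraintLoss:
    def test_empty_sets_zero(self, rng):
        h = rng.random((3, 2))
        assert constraint_loss(h, index_of(3), ConstraintSet()) == 0.0

    def test_coincident_positive_pair_zero(self):
        h = np.array([[0.3, 0.7], [0.3, 0.7], [0.9, 0.1]])
        cs = ConstraintSet({("d00", "d01")}, set())
        assert constraint_loss(h, index_of(3), cs, gamma1=123.0) == 0.0

    def test_hand_arithmetic(self):
        h = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        cs = ConstraintSet({("d00", "d01")}, {("d00", "d02")})
        # gamma1 * ||h0-h1||^2 - gamma2 * ||h0-h2||^2 = 2 - 4
        assert constraint_loss(h, index_of(3), cs) == pytest.approx(-2.0)

    def test_negative_cap_applies(self):
        h = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        cs = ConstraintSet(set(), {("d00", "d02")})
        assert constraint_loss(h, index_of(3), cs, neg_cap=1.0) == (
            pytest.approx(-1.0)
        )

    def test_unknown_id_rejected(self, rng):
        cs = ConstraintSet({("d00", "zz")}, set())
        with pytest.raises(KeyError):
            constraint_loss(rng.random((3, 2)), index_of(3), cs)


class TestTrainImpae:
    def test_gamma_zero_reduces_to_classic_ae_bitwise(self, rng):
        X = rng.random((8, 6))
        cs = ConstraintSet({("d00", "d01")}, {("d02", "d03")})
        idx = index_of(8)
        emb = train_impae(
            X, cs, ImpAeParams(final_dim=3, gamma=0.0, epochs=100, seed=21), idx
        )
        _, h_classic = train_classic_ae(
            X, AeParams(hidden_dim=3, epochs=100, seed=21)
        )
        np.testing.assert_array_equal(emb.vectors, h_classic)

    def test_planted_pairs_move_as_constrained(self, rng):
        X = rng.random((10, 8))
        idx = index_of(10)
        cs = ConstraintSet({("d00", "d01")}, {("d02", "d03")})
        # balanced strengths: this instance has no collapsed hidden scale,
        # so penalty and reward are weighted equally
        common = dict(final_dim=4, epochs=300, seed=3)
        emb = train_impae(
            X, cs, ImpAeParams(gamma=100.0, gamma1=1.0, gamma2=1.0, **common), idx
        ).vectors
        ctrl = train_impae(X, cs, ImpAeParams(gamma=0.0, **common), idx).vectors

        def dist(h, a, b):
            return np.linalg.norm(h[idx.position(a)] - h[idx.position(b)])

        assert dist(emb, "d00", "d01") < dist(ctrl, "d00", "d01")
        assert dist(emb, "d02", "d03") > dist(ctrl, "d02", "d03")

    def test_seed_determinism(self, rng):
        X = rng.random((6, 5))
        cs = ConstraintSet({("d00", "d01")}, set())
        idx = index_of(6)
        params = ImpAeParams(final_dim=2, epochs=50, seed=9)
        e1 = train_impae(X, cs, params, idx)
        e2 = train_impae(X, cs, params, idx)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_constraint_ids_must_exist(self, rng):
        cs = ConstraintSet({("d00", "nope")}, set())
        with pytest.raises(KeyError):
            train_impae(rng.random((4, 3)), cs,
                        ImpAeParams(final_dim=2, epochs=5, seed=0), index_of(4))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"final_dim": 0},
            {"final_dim": 2, "gamma": -1.0},
            {"final_dim": 2, "neg_cap": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ImpAeParams(**kwargs)


class TestEmbeddingContainer:
    def test_all_zero_rows_warn(self):
        with pytest.warns(RuntimeWarning, match="all-zero"):
            DiseaseEmbedding(index_of(2), np.array([[0.0, 0.0], [1.0, 2.0]]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            DiseaseEmbedding(index_of(2), np.array([[np.inf, 0.0], [1.0, 2.0]]))

    def test_save_load_roundtrip(self, tmp_path, rng):
        emb = DiseaseEmbedding(index_of(4), rng.random((4, 3)))
        save_embedding(emb, tmp_path / "emb.tsv")
        back = load_embedding(tmp_path / "emb.tsv")
        assert back.disease_index.ids == emb.disease_index.ids
        np.testing.assert_allclose(back.vectors, emb.vectors, atol=1e-12)
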