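"""Neural Cox model: loss values, gradients, invariances, checkpointing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survmeta import (
    ModelParams,
    NetworkConfig,
    cox_loss,
    forward_features,
    init_params,
    load_checkpoint,
    loss_gradient,
    predict_risk,
    save_checkpoint,
)
from survmeta.cox_network import partial_likelihood, risk_input_gradients

from conftest import make_dataset, risk_dataset

LINEAR = ModelParams([], [], np.array([1.0]))  # risk = the single gene value


def finite_diff(params, batch, l2=0.0, eps=1e-6, activation="relu"):
    """Central-difference gradient of cox_loss over every parameter entry."""
    out = params.copy()
    for arr, garr in zip(params.arrays(), out.arrays()):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = cox_loss(params, batch, l2_scale=l2, activation=activation)
            arr[idx] = orig - eps
            lm = cox_loss(params, batch, l2_scale=l2, activation=activation)
            arr[idx] = orig
            garr[idx] = (lp - lm) / (2 * eps)
    return out


class TestInit:
    def test_shapes(self):
        cfg = NetworkConfig(n_genes=5, hidden_sizes=[4, 3], feature_size=2)
        p = init_params(cfg)
        assert [w.shape for w in p.weights] == [(5, 4), (4, 3), (3, 2)]
        assert [b.shape for b in p.biases] == [(4,), (3,), (2,)]
        assert p.beta.shape == (2,)

    def test_seed_determinism_and_variation(self):
        cfg = lambda s: NetworkConfig(n_genes=5, hidden_sizes=[4], feature_size=2,
                                      init_seed=s)
        assert init_params(cfg(1)) == init_params(cfg(1))
        assert init_params(cfg(1)) != init_params(cfg(2))


class TestForward:
    def test_zero_params_give_zero_features(self):
        p = init_params(NetworkConfig(n_genes=3, hidden_sizes=[4], feature_size=2))
        for a in p.arrays():
            a[:] = 0.0
        z = forward_features(p, np.random.default_rng(0).normal(size=(5, 3)))
        assert np.all(z == 0)

    def test_identity_single_layer(self):
        p = ModelParams([np.eye(3)], [np.zeros(3)], np.zeros(3))
        x = np.arange(6, dtype=float).reshape(2, 3)
        np.testing.assert_array_equal(
            forward_features(p, x, activation="identity"), x
        )

    def test_input_jacobian_matches_finite_differences(self, toy_net):
        _, params = toy_net
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 6))
        g = risk_input_gradients(params, x)
        eps = 1e-5
        for i in range(5):
            for j in range(6):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                beta = params.beta
                rp = forward_features(params, xp)[i] @ beta
                rm = forward_features(params, xm)[i] @ beta
                fd = (rp - rm) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_width_mismatch_errors(self, toy_net):
        _, params = toy_net
        with pytest.raises(ValueError, match="width"):
            forward_features(params, np.zeros((2, 4)))


class TestCoxLoss:
    def test_two_patient_hand_case_ln2(self):
        # equal risks, one event at y=1, one censored at y=2 -> ln 2
        ds = risk_dataset([0.0, 0.0], [1.0, 2.0], [1, 0])
        assert cox_loss(LINEAR, ds, activation="identity") == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_two_event_hand_case(self):
        # risks (1, 0), events at y = 1 and 2 -> -(1 - ln(e+1))
        ds = risk_dataset([1.0, 0.0], [1.0, 2.0], [1, 1])
        expected = -(1 - np.log(np.e + 1))
        assert cox_loss(LINEAR, ds, activation="identity") == pytest.approx(
            expected, abs=1e-12
        )

    def test_all_censored_is_zero_with_warning(self):
        ds = risk_dataset([1.0, -1.0, 0.5], [1, 2, 3], [0, 0, 0])
        with pytest.warns(UserWarning, match="no events"):
            assert cox_loss(LINEAR, ds, activation="identity") == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        risks = rng.normal(size=12)
        times = rng.exponential(5, 12) + 0.1
        events = rng.integers(0, 2, 12)
        events[0] = 1
        l0, _ = partial_likelihood(risks, times, events)
        for c in (-100.0, -3.0, 0.5, 250.0):
            lc, _ = partial_likelihood(risks + c, times, events)
            assert abs(lc - l0) < 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=-50, max_value=50))
    def test_shift_invariance_property(self, seed, shift):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        risks = rng.normal(size=n)
        times = rng.exponential(5, n) + 0.1
        events = rng.integers(0, 2, n)
        events[0] = 1
        l0, _ = partial_likelihood(risks, times, events)
        lc, _ = partial_likelihood(risks + shift, times, events)
        assert abs(lc - l0) < 1e-8

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_equal_risk_closed_form_by_enumeration(self, n):
        # all risks equal, distinct times: L = sum over events of ln |risk set|
        rng = np.random.default_rng(n)
        times = np.sort(rng.uniform(1, 10, n))
        for events in itertools.product([0, 1], repeat=n):
            expected = sum(
                np.log(n - i) for i in range(n) if events[i] == 1
            )
            got, _ = partial_likelihood(np.zeros(n), times, np.array(events))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_nonnegative_on_random_instances(self, random_batch, toy_net):
        _, params = toy_net
        assert cox_loss(params, random_batch) >= 0.0


class TestLossGradient:
    def test_matches_finite_differences(self, toy_net, random_batch):
        _, params = toy_net
        g = loss_gradient(params, random_batch, l2_scale=0.1)
        fd = finite_diff(params, random_batch, l2=0.1)
        for a, b in zip(g.arrays(), fd.arrays()):
            np.testing.assert_allclose(a, b, rtol=1e-4, atol=1e-7)

    def test_all_censored_zero_gradient(self, toy_net):
        _, params = toy_net
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.standard_normal((4, 6)), [1, 2, 3, 4], [0, 0, 0, 0])
        g = loss_gradient(params, ds)
        assert all(np.all(a == 0) for a in g.arrays())

    def test_linear_model_score_equation(self):
        # two patients, linear model: dL/dbeta = -x_1 + softmax-weighted mean
        x = np.array([[2.0], [-1.0]])
        beta = np.array([0.3])
        ds = make_dataset(x, [1.0, 2.0], [1, 1])
        p = ModelParams([], [], beta.copy())
        g = loss_gradient(p, ds, activation="identity")
        r = x[:, 0] * beta[0]
        w = np.exp(r) / np.exp(r).sum()
        expected = -(x[0, 0] - w @ x[:, 0]) - (x[1, 0] - x[1, 0])
        assert g.beta[0] == pytest.approx(expected, rel=1e-10)

    def test_descent_property(self, toy_net, random_batch):
        _, params = toy_net
        l0 = cox_loss(params, random_batch, l2_scale=0.1)
        g = loss_gradient(params, random_batch, l2_scale=0.1)
        stepped = params.copy()
        for p, gr in zip(stepped.arrays(), g.arrays()):
            p -= 1e-3 * gr
        assert cox_loss(stepped, random_batch, l2_scale=0.1) < l0


class TestPredictRisk:
    def test_zero_beta_zero_risk(self, toy_net, random_batch):
        _, params = toy_net
        params.beta[:] = 0.0
        assert np.all(predict_risk(params, random_batch).risk == 0)

    def test_identity_extractor_picks_first_gene(self):
        p = ModelParams([np.eye(3)], [np.zeros(3)],
                        np.array([1.0, 0.0, 0.0]))
        x = np.random.default_rng(2).normal(size=(4, 3))
        r = predict_risk(p, x, activation="identity").risk
        np.testing.assert_allclose(r, x[:, 0])

    def test_feature_bias_shift_adds_constant_risk(self, random_batch):
        # adding c to every feature bias shifts each risk by c * sum(beta)
        lin = ModelParams([np.eye(6)], [np.zeros(6)], np.ones(6))
        r0 = predict_risk(lin, random_batch, activation="identity").risk
        lin_shift = ModelParams([np.eye(6)], [np.full(6, 0.5)], np.ones(6))
        r1 = predict_risk(lin_shift, random_batch, activation="identity").risk
        np.testing.assert_allclose(r1 - r0, 3.0)


class TestCheckpoint:
    def test_round_trip(self, toy_net, tmp_path):
        cfg, params = toy_net
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg)
        loaded, cfg2, stats = load_checkpoint(path)
        assert loaded == params
        assert cfg2.hidden_sizes == cfg.hidden_sizes
        assert stats is None

    def test_round_trip_with_stats(self, toy_net, tmp_path):
        from survmeta import PreprocessStats

        cfg, params = toy_net
        stats = PreprocessStats(["a", "b"], np.array([1.0, 2.0]),
                                np.array([0.5, 2.0]))
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, cfg, stats=stats)
        _, _, stats2 = load_checkpoint(path)
        assert stats2.gene_ids == ["a", "b"]
        np.testing.assert_array_equal(stats2.std, stats.std)
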