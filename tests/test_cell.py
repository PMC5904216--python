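import numpy as np
import pytest

from grud.cell import (
    GRUDParameters,
    GRUParameters,
    LastObservationState,
    apply_hidden_decay,
    apply_input_decay,
    count_parameters,
    decay_rate,
    forward_sequence,
    grud_step,
    gru_step,
    init_grud_params,
    init_gru_params,
    match_hidden_size,
    params_from_jsonable,
    params_to_jsonable,
)
from grud.core import TimeSeriesSample

import oracles
from conftest import random_sample


def zero_grud_params(D, H):
    rng = np.random.default_rng(0)
    p = init_grud_params(rng, D, H)
    return {k: np.zeros_like(v) for k, v in p.items()}


class TestDecayRate:
    def test_zero_params_give_one(self):
        np.testing.assert_array_equal(
            decay_rate(np.array([0.0, 3.0, 100.0]), np.zeros(3), np.zeros(3)), 1.0
        )

    def test_closed_form_half(self):
        gamma = decay_rate(np.array([np.log(2.0)]), np.array([1.0]), np.array([0.0]))
        assert gamma[0] == pytest.approx(0.5, abs=1e-15)

    def test_rectifier_clamps_negatives(self):
        gamma = decay_rate(np.array([5.0]), np.array([-1.0]), np.array([0.0]))
        assert gamma[0] == 1.0

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            decay_rate(np.array([-0.1]), np.array([1.0]), np.array([0.0]))

    def test_range_and_boundary(self, rng):
        for _ in range(100):
            D = rng.integers(1, 6)
            delta = rng.uniform(0, 5, D)
            w = rng.normal(size=D)
            b = rng.normal(size=D)
            gamma = decay_rate(delta, w, b)
            assert np.all(gamma > 0) and np.all(gamma <= 1)
            pre = w * delta + b
            np.testing.assert_array_equal(gamma == 1.0, pre <= 0)

    def test_monotone_in_delta_for_nonneg_weights(self, rng):
        w = rng.uniform(0, 2, 4)
        b = rng.normal(size=4)
        grid = np.linspace(0, 5, 50)
        for d in range(4):
            delta = np.zeros((50, 4))
            delta[:, d] = grid
            vals = np.array([decay_rate(row, w, b)[d] for row in delta])
            assert np.all(np.diff(vals) <= 1e-15)

    def test_dense_case_matches_oracle(self, rng):
        W = rng.normal(size=(5, 3))
        b = rng.normal(size=5)
        delta = rng.uniform(0, 4, 3)
        np.testing.assert_allclose(
            decay_rate(delta, W, b), oracles.decay_oracle_dense(delta, W, b),
            atol=1e-12,
        )


class TestInputDecay:
    def test_observed_passthrough(self):
        last = LastObservationState(last_values=np.array([9.0]), seen=np.ones(1))
        out = apply_input_decay(np.array([3.0]), np.ones(1), last,
                                np.array([0.0]), np.array([0.1]))
        assert out[0] == 3.0

    def test_no_decay_keeps_last(self):
        last = LastObservationState(last_values=np.array([2.0]), seen=np.ones(1))
        out = apply_input_decay(np.zeros(1), np.zeros(1), last,
                                np.array([0.0]), np.array([1.0]))
        assert out[0] == 2.0

    def test_convex_blend(self):
        last = LastObservationState(last_values=np.array([2.0]), seen=np.ones(1))
        out = apply_input_decay(np.zeros(1), np.zeros(1), last,
                                np.array([0.0]), np.array([0.5]))
        assert out[0] == pytest.approx(1.0)

    def test_unseen_falls_back_to_mean(self):
        last = LastObservationState.initial(1)
        out = apply_input_decay(np.zeros(1), np.zeros(1), last,
                                np.array([4.0]), np.array([0.25]))
        assert out[0] == 4.0


class TestHiddenDecay:
    def test_identity_limit(self, rng):
        h = rng.normal(size=4)
        np.testing.assert_array_equal(apply_hidden_decay(h, np.ones(4)), h)

    def test_absorbing_zero(self):
        np.testing.assert_array_equal(
            apply_hidden_decay(np.zeros(3), np.full(3, 0.3)), 0.0
        )

    def test_elementwise_product(self):
        np.testing.assert_allclose(
            apply_hidden_decay(np.array([2.0, 3.0]), np.array([0.5, 1.0])),
            [1.0, 3.0],
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_hidden_decay(np.zeros(3), np.ones(2))


class TestGRUStep:
    def test_zero_params_halve_state(self, rng):
        p = {k: np.zeros_like(v) for k, v in init_gru_params(rng, 2, 3).items()}
        h_prev = rng.normal(size=3)
        np.testing.assert_allclose(gru_step(rng.normal(size=2), h_prev, p),
                                   0.5 * h_prev, atol=1e-15)

    def test_copy_gate_limit(self, rng):
        p = {k: np.zeros_like(v) for k, v in init_gru_params(rng, 2, 3).items()}
        p["b_z"] = np.full(3, -50.0)  # z ~ 0 -> h = h_prev
        h_prev = rng.normal(size=3)
        np.testing.assert_allclose(gru_step(rng.normal(size=2), h_prev, p),
                                   h_prev, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(30):
            Din = rng.integers(1, 4)
            H = rng.integers(1, 5)
            p = oracles.random_gru_params(rng, Din, H)
            x = rng.normal(size=Din)
            h_prev = rng.normal(size=H)
            np.testing.assert_allclose(
                gru_step(x, h_prev, p), oracles.gru_step_oracle(x, h_prev, p),
                atol=1e-12,
            )

    def test_nonfinite_rejected(self, rng):
        p = init_gru_params(rng, 2, 3)
        with pytest.raises(FloatingPointError):
            gru_step(np.array([np.nan, 0.0]), np.zeros(3), p)

    def test_parameter_dataclass_validates(self, rng):
        p = init_gru_params(rng, 2, 3)
        GRUParameters.from_dict(p)  # valid
        bad = dict(p, U_r=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            GRUParameters.from_dict(bad)


class TestGRUDStep:
    def test_zero_params_fully_observed(self, rng):
        D, H = 2, 3
        p = zero_grud_params(D, H)
        h_prev = rng.normal(size=H)
        h, _ = grud_step(rng.normal(size=D), np.ones(D), np.zeros(D), h_prev,
                         LastObservationState.initial(D), np.zeros(D), p)
        np.testing.assert_allclose(h, 0.5 * h_prev, atol=1e-15)

    def test_cold_start_all_missing(self, rng):
        D, H = 2, 3
        p = zero_grud_params(D, H)
        h_prev = rng.normal(size=H)
        trace = {}
        h, _ = grud_step(np.zeros(D), np.zeros(D), np.ones(D), h_prev,
                         LastObservationState.initial(D), np.zeros(D), p,
                         trace=trace)
        np.testing.assert_array_equal(trace["x_hat"], 0.0)
        np.testing.assert_allclose(h, 0.5 * h_prev, atol=1e-15)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(30):
            D = rng.integers(1, 4)
            H = rng.integers(1, 5)
            p = oracles.random_grud_params(rng, D, H)
            x = rng.normal(size=D)
            m = (rng.random(D) < 0.5).astype(float)
            delta = rng.uniform(0, 3, D)
            h_prev = rng.normal(size=H)
            last_vals = rng.normal(size=D)
            seen = (rng.random(D) < 0.7).astype(float)
            last = LastObservationState(last_values=last_vals, seen=seen)
            h, new_last = grud_step(x, m, delta, h_prev, last,
                                    np.zeros(D), p)
            h_ref, lv_ref, seen_ref = oracles.grud_step_oracle(
                x, m, delta, h_prev, last_vals, seen, np.zeros(D), p
            )
            np.testing.assert_allclose(h, h_ref, atol=1e-12)
            np.testing.assert_array_equal(new_last.last_values, lv_ref)
            np.testing.assert_array_equal(new_last.seen, seen_ref)

    def test_last_observation_update(self, rng):
        D = 3
        p = zero_grud_params(D, 2)
        last = LastObservationState.initial(D)
        x = np.array([1.0, 2.0, 3.0])
        m = np.array([1.0, 0.0, 1.0])
        _, last = grud_step(x, m, np.zeros(D), np.zeros(2), last, np.zeros(D), p)
        np.testing.assert_array_equal(last.seen, [1, 0, 1])
        np.testing.assert_array_equal(last.last_values[[0, 2]], [1.0, 3.0])

    def test_state_decay_bound(self, rng):
        # inputs missing forever, zero means, only decay weights nonzero:
        # the hidden state magnitude never grows step to step
        D, H = 2, 4
        p = zero_grud_params(D, H)
        p["W_gamma_h"] = rng.uniform(0, 1, size=(H, D))
        h = rng.normal(size=H)
        last = LastObservationState.initial(D)
        for t in range(10):
            h_new, last = grud_step(np.zeros(D), np.zeros(D), np.full(D, 1.0 + t),
                                    h, last, np.zeros(D), p)
            assert np.all(np.abs(h_new) <= np.abs(h) + 1e-15)
            h = h_new


class TestForwardSequence:
    def test_single_step(self, rng):
        s = random_sample(rng, T=1, D=2)
        p = oracles.random_gru_params(rng, 2, 3)
        hs = forward_sequence(s, p, np.zeros(2), "gru_mean")
        assert hs.shape == (1, 3)
        np.testing.assert_allclose(
            hs[0], gru_step(s.values[0] * s.mask[0], np.zeros(3), p), atol=1e-12
        )

    def test_mean_equals_forward_when_fully_observed(self, rng):
        s = random_sample(rng, missing=0.0)
        p = oracles.random_gru_params(rng, s.D, 4)
        np.testing.assert_array_equal(
            forward_sequence(s, p, np.zeros(s.D), "gru_mean"),
            forward_sequence(s, p, np.zeros(s.D), "gru_forward"),
        )

    def test_reduction_to_plain_gru(self, rng):
        # fully observed + zeroed mask/decay parameters == standard GRU
        for _ in range(20):
            s = random_sample(rng, T=5, D=3, missing=0.0)
            gru_p = oracles.random_gru_params(rng, 3, 4)
            grud_p = dict(gru_p)
            for k in ("V_r", "V_z", "V"):
                grud_p[k] = np.zeros((4, 3))
            grud_p["w_gamma_x"] = np.zeros(3)
            grud_p["b_gamma_x"] = np.zeros(3)
            grud_p["W_gamma_h"] = np.zeros((4, 3))
            grud_p["b_gamma_h"] = np.zeros(4)
            np.testing.assert_allclose(
                forward_sequence(s, grud_p, np.zeros(3), "grud"),
                forward_sequence(s, gru_p, np.zeros(3), "gru_mean"),
                atol=1e-12,
            )

    def test_unknown_mode(self, rng):
        s = random_sample(rng)
        with pytest.raises(ValueError):
            forward_sequence(s, {}, np.zeros(s.D), "gru_magic")

    def test_deterministic(self, rng):
        s = random_sample(rng)
        p = oracles.random_grud_params(rng, s.D, 4)
        a = forward_sequence(s, p, np.zeros(s.D), "grud")
        b = forward_sequence(s, p, np.zeros(s.D), "grud")
        np.testing.assert_array_equal(a, b)


class TestParameterCounting:
    def test_plain_gru_minimal(self):
        assert count_parameters("gru_mean", D=1, H=1) == 9

    def test_grud_minimal(self):
        assert count_parameters("grud", D=1, H=1) == 16

    def test_simple_triples_input(self):
        assert count_parameters("gru_simple", D=4, H=5) == \
            count_parameters("gru_mean", D=12, H=5)

    def test_enumeration_matches_shapes(self, rng):
        D, H = 3, 5
        p = init_grud_params(rng, D, H)
        total = sum(np.asarray(v).size for v in p.values())
        assert count_parameters("grud", D, H) == total
        g = init_gru_params(rng, D, H)
        assert count_parameters("gru_mean", D, H) == \
            sum(np.asarray(v).size for v in g.values())

    def test_head_count(self):
        base = count_parameters("gru_mean", 4, 8)
        with_head = count_parameters("gru_mean", 4, 8,
                                     {"n_out": 2, "batch_norm": True})
        assert with_head == base + 2 * 9 + 16


class TestMatchHiddenSize:
    def test_fixed_point(self):
        ref = count_parameters("gru_mean", 10, 32)
        assert match_hidden_size(ref, "gru_mean", 10) == 32

    def test_monotone_in_reference(self):
        sizes = [match_hidden_size(ref, "grud", 5)
                 for ref in (500, 1000, 2000, 4000)]
        assert sizes == sorted(sizes)

    def test_matches_exhaustive_scan(self):
        ref = count_parameters("gru_simple", 10, 32)
        got = match_hidden_size(ref, "grud", 10)
        brute = max(H for H in range(1, 200)
                    if count_parameters("grud", 10, H) <= ref)
        assert got == brute

    def test_infeasible(self):
        with pytest.raises(ValueError):
            match_hidden_size(5, "grud", 10)


class TestCheckpointRoundTrip:
    def test_params_json_round_trip(self, rng):
        p = init_grud_params(rng, 3, 4)
        back = params_from_jsonable(params_to_jsonable(p))
        assert set(back) == set(p)
        for k in p:
            np.testing.assert_array_equal(back[k], np.asarray(p[k]))
        GRUDParameters.from_dict(back)  # shapes still valid
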