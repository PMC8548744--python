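"""Cell semantics: trigger rule, variant equations, reductions, unrolls."""

import numpy as np
import pytest

from conftest import zero_out
from oracles import arrays_of, oracle_step, oracle_unroll

from ssrnn.cells import (
    CellParams,
    CellState,
    GRUParams,
    HistoryBuffer,
    RNNParams,
    SkipSpec,
    gru_step,
    is_trigger,
    lstm_step,
    rnn_step,
    step_model_a,
    step_model_b,
    step_model_c,
    step_model_d,
    step_model_e,
    step_model_f,
    unroll,
)

STEPS = {
    "A": step_model_a,
    "B": step_model_b,
    "C": step_model_c,
    "D": step_model_d,
    "E": step_model_e,
    "F": step_model_f,
}


# -----------------------------------------------------------------------------
# trigger rule
# -----------------------------------------------------------------------------
def test_trigger_examples():
    assert is_trigger(4, 3)  # t = 1 + 1*3
    assert not is_trigger(1, 3)  # i must be a positive integer
    assert [t for t in range(1, 11) if is_trigger(t, 2)] == [3, 5, 7, 9]


def test_trigger_matches_definition_by_enumeration():
    for skip in (2, 3, 4, 5):
        expected = {1 + i * skip for i in range(1, 120)}
        got = {t for t in range(1, 120) if is_trigger(t, skip)}
        assert got == {t for t in expected if t <= 119}


def test_trigger_validates_inputs():
    with pytest.raises(ValueError):
        is_trigger(0, 3)
    with pytest.raises(ValueError):
        is_trigger(5, 1)


# -----------------------------------------------------------------------------
# plain LSTM step
# -----------------------------------------------------------------------------
def test_zero_parameters_are_a_fixed_point(tiny_params):
    p, _ = tiny_params("none", input_dim=2, hidden_dim=3)
    zero_out(p)
    s = lstm_step(np.array([5.0, -2.0]), CellState.zeros(3), p)
    assert np.allclose(s.h.value, 0.0)
    assert np.allclose(s.c.value, 0.0)


def test_saturated_forget_gate_preserves_cell_state(tiny_params):
    p, _ = tiny_params("none", input_dim=2, hidden_dim=3)
    zero_out(p)
    p.b["f"].value[:] = 100.0  # forget gate pinned at 1
    v = np.array([0.3, -1.2, 0.7])
    s = lstm_step(np.zeros(2), CellState(np.zeros(3), v), p)
    assert np.allclose(s.c.value, v, atol=1e-6)


def test_lstm_step_matches_scalar_oracle(tiny_params):
    p, _ = tiny_params("none", input_dim=2, hidden_dim=2, seed=11)
    x = np.array([1.0, -1.0])
    h0, c0 = np.array([0.2, -0.4]), np.array([0.1, 0.3])
    s = lstm_step(x, CellState(h0, c0), p)
    h, c = oracle_step(x, h0, c0, arrays_of(p))
    assert np.allclose(s.h.value, h, atol=1e-10)
    assert np.allclose(s.c.value, c, atol=1e-10)


def test_gate_values_bounded(tiny_params):
    p, _ = tiny_params("none", input_dim=3, hidden_dim=4, seed=3)
    s = lstm_step(np.array([2.0, -3.0, 0.5]), CellState.zeros(4), p)
    assert np.all(np.abs(s.h.value) < 1.0)  # |h| = |o * tanh(c)| < 1


def test_step_rejects_bad_inputs(tiny_params):
    p, _ = tiny_params("none", input_dim=3, hidden_dim=4)
    with pytest.raises(ValueError):
        lstm_step(np.zeros(5), CellState.zeros(4), p)
    with pytest.raises(ValueError):
        lstm_step(np.array([np.nan, 0, 0]), CellState.zeros(4), p)


# -----------------------------------------------------------------------------
# variant steps against the hand oracle
# -----------------------------------------------------------------------------
@pytest.mark.parametrize("variant", ["A", "B", "C", "D", "E", "F"])
@pytest.mark.parametrize("skip", [2, 3])
def test_variant_unroll_matches_brute_force_oracle(tiny_params, variant, skip):
    p, spec = tiny_params(variant, skip=skip, input_dim=3, hidden_dim=4, seed=21)
    xs = np.random.default_rng(5).normal(size=(9, 3))
    states = unroll(xs, spec, p)
    hs, cs = oracle_unroll(xs, variant, skip, arrays_of(p))
    for s, h, c in zip(states, hs, cs):
        assert np.allclose(s.h.value, h, atol=1e-10)
        assert np.allclose(s.c.value, c, atol=1e-10)


@pytest.mark.parametrize("variant", ["A", "B", "E", "F"])
def test_discontinuous_variants_reduce_to_lstm_off_trigger(tiny_params, variant):
    """At non-trigger steps the step equals the plain LSTM on the same inputs."""
    skip = 3
    p, spec = tiny_params(variant, skip=skip, seed=9)
    rng = np.random.default_rng(1)
    t = 3  # not 1 + i*3
    hist = HistoryBuffer.from_states(
        [rng.normal(size=4) for _ in range(t - 1)], skip, 4, t
    )
    prev = CellState(hist.get(1).value, rng.normal(size=4))
    x = rng.normal(size=3)
    got = STEPS[variant](x, hist, prev, p, t)
    ref_p = p
    if variant == "E":
        # plain LSTM with the lag-1 matrices as recurrent weights
        ref_p = CellParams(3, 4, W_h={g: p.W_lag[g][0] for g in p.W_lag},
                           W_x=p.W_x, b=p.b)
    ref = lstm_step(x, prev, ref_p)
    assert np.allclose(got.h.value, ref.h.value, atol=1e-12)
    assert np.allclose(got.c.value, ref.c.value, atol=1e-12)


def test_model_a_trigger_adds_history_verbatim(tiny_params):
    p, spec = tiny_params("A", skip=3, seed=13)
    rng = np.random.default_rng(2)
    xs = rng.normal(size=(4, 3))
    states = unroll(xs, spec, p)
    # t=4 is the first trigger with skip=3: h_4 = lstm-part + h_1
    base = unroll(xs, SkipSpec("none"), p)
    assert np.allclose(
        states[3].h.value, base[3].h.value + states[0].h.value, atol=1e-10
    )


def test_model_c_additive_decomposition(tiny_params):
    p, spec = tiny_params("C", skip=3, seed=17)
    xs = np.random.default_rng(4).normal(size=(9, 3))
    states = unroll(xs, spec, p)
    pa = arrays_of(p)
    h, c = np.zeros(4), np.zeros(4)
    for t in range(1, 10):
        h_lstm, c = oracle_step(xs[t - 1], h, c, pa)
        skip_part = states[t - 4].h.value if t > 3 else np.zeros(4)
        assert np.allclose(states[t - 1].h.value - h_lstm, skip_part, atol=1e-10)
        h = states[t - 1].h.value


def test_model_f_skip2_single_summand(tiny_params):
    p, spec = tiny_params("F", skip=2, seed=23)
    xs = np.random.default_rng(6).normal(size=(3, 3))
    states = unroll(xs, spec, p)
    base = unroll(xs, SkipSpec("none"), p)
    # t=3 triggers with skip=2: h_3 = N + h_1 (sum runs over s=2 only)
    assert np.allclose(
        states[2].h.value, base[2].h.value + states[0].h.value, atol=1e-10
    )


def test_weighted_variants_require_their_weights(tiny_params):
    p, _ = tiny_params("none")
    hist = HistoryBuffer(3, 4, t=4)
    for variant in ("B", "D"):
        with pytest.raises(ValueError):
            STEPS[variant](np.zeros(3), hist, CellState.zeros(4), p, 4)
    with pytest.raises(ValueError):
        step_model_e(np.zeros(3), hist, CellState.zeros(4), p, 4)


# -----------------------------------------------------------------------------
# reduction property (zero skip weights / zero history -> plain LSTM)
# -----------------------------------------------------------------------------
@pytest.mark.parametrize("variant", ["A", "B", "C", "D", "E", "F"])
def test_reduction_to_plain_lstm_over_many_seeds(variant):
    """B/D/E with zero skip (extra-lag) weights and A/C/F with zero history
    reproduce the plain LSTM trajectory."""
    worst = 0.0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        spec = SkipSpec(variant, 3)
        p = CellParams.init(2, 3, spec=spec, rng=rng)
        if variant in ("B", "D"):
            for g in p.W_skip:
                p.W_skip[g].value[:] = 0.0
            ref = CellParams(2, 3, W_h=p.W_h, W_x=p.W_x, b=p.b)
            xs = np.random.default_rng(1000 + seed).normal(size=(7, 2))
        elif variant == "E":
            for g in p.W_lag:
                for w in p.W_lag[g][1:]:
                    w.value[:] = 0.0
            ref = CellParams(2, 3, W_h={g: p.W_lag[g][0] for g in p.W_lag},
                             W_x=p.W_x, b=p.b)
            xs = np.random.default_rng(1000 + seed).normal(size=(7, 2))
        else:
            # zero history: stop before the skip lag ever refers to a real state
            ref = p
            xs = np.random.default_rng(1000 + seed).normal(size=(3, 2))
        got = unroll(xs, spec, p)
        want = unroll(xs, SkipSpec("none"), ref)
        worst = max(worst, max(
            float(np.max(np.abs(a.h.value - b.h.value))) for a, b in zip(got, want)
        ))
    assert worst < 1e-6


def test_additive_growth_bound(tiny_params):
    """|h_t| <= 1 + max over history |h_{t-s}| for the direct-addition variants."""
    for variant in ("A", "C", "F"):
        p, spec = tiny_params(variant, skip=3, seed=31)
        xs = np.random.default_rng(8).normal(size=(12, 3))
        states = unroll(xs, spec, p)
        hs = [np.zeros(4)] * 3 + [s.h.value for s in states]
        for t in range(3, len(hs)):
            bound = 1.0 + max(np.max(np.abs(hs[t - s])) for s in range(1, 4))
            assert np.max(np.abs(hs[t])) <= bound + 1e-12


def test_unroll_is_deterministic(tiny_params):
    p, spec = tiny_params("D", skip=2, seed=5)
    xs = np.random.default_rng(9).normal(size=(8, 3))
    a = unroll(xs, spec, p)
    b = unroll(xs, spec, p)
    for s1, s2 in zip(a, b):
        assert np.array_equal(s1.h.value, s2.h.value)


def test_unroll_variant_a_differs_only_at_and_after_triggers(tiny_params):
    p, spec = tiny_params("A", skip=3, seed=41)
    xs = np.random.default_rng(10).normal(size=(9, 3))
    skip_states = unroll(xs, spec, p)
    base_states = unroll(xs, SkipSpec("none"), p)
    for t in range(1, 4):  # before the first trigger at t=4
        assert np.allclose(skip_states[t - 1].h.value, base_states[t - 1].h.value)
    assert not np.allclose(skip_states[3].h.value, base_states[3].h.value)
    assert not np.allclose(skip_states[6].h.value, base_states[6].h.value)


def test_unroll_rejects_empty_sequence(tiny_params):
    p, spec = tiny_params("none")
    with pytest.raises(ValueError):
        unroll(np.zeros((0, 3)), spec, p)


# -----------------------------------------------------------------------------
# baseline cells
# -----------------------------------------------------------------------------
def test_rnn_zero_params_zero_output():
    p = RNNParams.init(2, 3, rng=0)
    for t in p.parameters():
        t.value[:] = 0.0
    assert np.allclose(rnn_step(np.ones(2), np.ones(3), p).value, 0.0)


def test_gru_saturated_update_gate_carries_state():
    p = GRUParams.init(2, 3, rng=0)
    p.b["z"].value[:] = 100.0
    h = np.array([0.3, -0.2, 0.9])
    out = gru_step(np.array([1.0, -1.0]), h, p)
    assert np.allclose(out.value, h, atol=1e-6)


def test_rnn_and_gru_match_scalar_oracle():
    rng = np.random.default_rng(77)
    rp = RNNParams.init(2, 2, rng=rng)
    x, h = np.array([0.5, -1.5]), np.array([0.1, 0.2])
    want = np.tanh(rp.W_x.value @ x + rp.W_h.value @ h + rp.b.value)
    assert np.allclose(rnn_step(x, h, rp).value, want, atol=1e-12)
    gp = GRUParams.init(2, 2, rng=rng)
    sig = lambda z: 1 / (1 + np.exp(-z))
    z = sig(gp.W["zx"].value @ x + gp.W["zh"].value @ h + gp.b["z"].value)
    r = sig(gp.W["rx"].value @ x + gp.W["rh"].value @ h + gp.b["r"].value)
    n = np.tanh(gp.W["nx"].value @ x + r * (gp.W["nh"].value @ h) + gp.b["n"].value)
    assert np.allclose(gru_step(x, h, gp).value, z * h + (1 - z) * n, atol=1e-12)


# -----------------------------------------------------------------------------
# history buffer
# -----------------------------------------------------------------------------
def test_history_buffer_conventions():
    buf = HistoryBuffer(3, 2, t=1)
    assert np.allclose(buf.get(3).value, 0.0)  # t <= 0 entries are zeros
    buf.push(np.array([1.0, 2.0]))
    buf.push(np.array([3.0, 4.0]))
    assert buf.t == 3
    assert np.allclose(buf.get(1).value, [3.0, 4.0])
    assert np.allclose(buf.get(2).value, [1.0, 2.0])
    with pytest.raises(ValueError):
        buf.get(4)
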