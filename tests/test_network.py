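"""Unit and property tests for the agent core: sensory encoding,
feedforward dynamics, action selection, tags, traces, plasticity and the
per-step orchestration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from augment_rl import (
    ArchitectureSpec,
    LearningParams,
    Network,
    boltzmann_probabilities,
    encode_sensory,
    sigma,
    sigma_prime,
)


def make_net(n_inst=2, seed=0, **param_kw):
    params = LearningParams(**param_kw)
    return Network(n_inst, params=params, seed=seed)


def zero_weights(net):
    for w in net.weights.values():
        w[:] = 0.0
    return net


# -- sensory encoding ------------------------------------------------


@pytest.mark.parametrize(
    "x_now, x_prev, exp_on, exp_off",
    [
        ([1, 0], [0, 0], [1, 0], [0, 0]),       # stimulus onset
        ([0.3], [0.8], [0.0], [0.5]),           # partial offset
        ([0.7], [0.7], [0.0], [0.0]),           # unchanged: no transient
    ],
)
def test_encode_sensory_examples(x_now, x_prev, exp_on, exp_off):
    on, off = encode_sensory(x_now, x_prev)
    np.testing.assert_allclose(on, exp_on)
    np.testing.assert_allclose(off, exp_off)


def test_encode_sensory_rejects_length_mismatch():
    with pytest.raises(ValueError):
        encode_sensory([1.0, 2.0], [1.0])


@given(
    arrays(float, 4, elements=st.floats(0, 10)),
    arrays(float, 4, elements=st.floats(0, 10)),
)
def test_encode_sensory_properties(x_now, x_prev):
    on, off = encode_sensory(x_now, x_prev)
    assert (on >= 0).all() and (off >= 0).all()
    # a component cannot rise and fall at the same time
    assert np.all(on * off == 0)
    np.testing.assert_allclose(on - off, x_now - x_prev)


# -- activation function ---------------------------------------------


def test_sigma_midpoint_and_derivative():
    assert sigma(2.5, theta=2.5) == pytest.approx(0.5)
    assert sigma_prime(0.5) == pytest.approx(0.25)


def test_sigma_saturates_gracefully():
    assert sigma(-1e6, theta=0.0) == pytest.approx(0.0, abs=1e-200)
    assert sigma(1e6, theta=0.0) == 1.0
    assert sigma_prime(sigma(-1e6, theta=0.0)) == pytest.approx(0.0, abs=1e-200)
    assert np.isfinite(sigma([-1e300, 1e300], theta=0.0)).all()


# -- feedforward pass ------------------------------------------------


def test_forward_zero_weight_network():
    net = zero_weights(make_net(theta=2.5))
    net.step([1.0, 0.5])
    np.testing.assert_allclose(net.y_reg, sigma(0.0, 2.5))
    np.testing.assert_allclose(net.y_mem, sigma(0.0, 2.5))
    np.testing.assert_allclose(net.q, 0.0)
    assert sigma(0.0, 2.5) == pytest.approx(0.07585818, rel=1e-6)


def test_memory_integrates_transients_only():
    """A constant stimulus moves the accumulator only at onset."""
    net = make_net(n_inst=2, seed=3)
    x = [0.8, 0.3]
    net.step(x)
    after_onset = net.inp_mem.copy()
    for _ in range(3):
        net.step(x)
        np.testing.assert_array_equal(net.inp_mem, after_onset)


def test_memory_accumulator_after_on_off():
    """After a one-step stimulus, the accumulator holds v+ . x + v- . x."""
    net = make_net(n_inst=2, seed=4)
    net.beta = 0.0
    x = np.array([0.6, 0.2])
    net.step(x)
    net.step([0.0, 0.0])
    expected = net.V_mem[:2].T @ x + net.V_mem[2:].T @ x
    np.testing.assert_allclose(net.inp_mem, expected, rtol=1e-12)


def test_q_is_linear_readout_of_association_layer():
    net = make_net(n_inst=2, seed=5)
    net.step([0.4, 0.9])
    expected = (net.W_reg[0] + net.W_reg[1:].T @ net.y_reg
                + net.W_mem.T @ net.y_mem)
    np.testing.assert_allclose(net.q, expected, rtol=1e-12)


# -- action selection ------------------------------------------------


def _selection_counts(q_bias, epsilon, n=100_000, seed=0):
    net = zero_weights(make_net(n_inst=1, seed=seed, epsilon=epsilon))
    net.beta = 0.0
    net.W_reg[0, :] = q_bias  # Q-values equal the bias row
    counts = np.zeros(3, dtype=int)
    for _ in range(n):
        a, _ = net.step([0.0])
        counts[a] += 1
    return counts / n


def test_greedy_selection_is_deterministic():
    freq = _selection_counts([0.1, 0.9, 0.2], epsilon=0.0, n=2000)
    assert freq[1] == 1.0


def test_uniform_boltzmann_for_equal_values():
    freq = _selection_counts([0.0, 0.0, 0.0], epsilon=1.0)
    # ties are impossible here: identical values -> softmax branch
    np.testing.assert_allclose(freq, 1 / 3, atol=3 * 0.0015)


def test_boltzmann_closed_form():
    """With q = (ln 2, 0, 0) the softmax picks action 0 half the time."""
    freq = _selection_counts([np.log(2.0), 0.0, 0.0], epsilon=1.0)
    assert freq[0] == pytest.approx(0.5, abs=3 * 0.0016)


def test_boltzmann_probabilities_sum_to_one():
    p = boltzmann_probabilities([5.0, -3.0, 700.0, 699.0])
    assert p.sum() == pytest.approx(1.0)
    assert (p > 0).all()


# -- reward-prediction error -----------------------------------------


def _fixed_q_net(q_bias, **param_kw):
    net = zero_weights(make_net(n_inst=1, seed=0, **param_kw))
    net.W_reg[0, :] = q_bias
    return net


def test_delta_matches_sarsa_arithmetic():
    """delta = r + gamma * q_now - q_stored on a constructed transition."""
    net = _fixed_q_net([0.5, 0.0, 0.0], beta=1e-9, epsilon=0.0, gamma=0.9)
    net.beta = 0.0  # keep the bias values exact across steps
    _, d0 = net.step([0.0])
    assert np.isnan(d0)  # no previous action yet
    _, d1 = net.step([0.0], reward=0.2)
    assert d1 == pytest.approx(0.2 + 0.9 * 0.5 - 0.5)


def test_terminal_delta_treats_future_value_as_zero():
    net = _fixed_q_net([1.5, 0.0, 0.0], epsilon=0.0, gamma=0.9)
    net.beta = 0.0
    net.step([0.0])
    _, d = net.step([0.0], reward=1.5, terminal=True)
    assert d == pytest.approx(0.0)  # perfect prediction of final reward


def test_terminal_before_any_action_is_noop_reset():
    net = make_net(seed=6)
    w0 = net.copy_weights()
    a, d = net.step([0.0, 0.0], reward=1.0, terminal=True)
    assert a == -1 and np.isnan(d)
    for k, w in net.weights.items():
        np.testing.assert_array_equal(w, w0[k])


# -- traces ----------------------------------------------------------


def test_traces_accumulate_all_transients():
    net = make_net(n_inst=1, seed=7)
    net.step([1.0])            # on-transient
    np.testing.assert_allclose(net.trace, [1.0, 0.0])
    net.step([0.0])            # off-transient
    net.step([1.0])            # second on-transient
    np.testing.assert_allclose(net.trace, [2.0, 1.0])


def test_traces_stay_zero_without_transients():
    net = make_net(n_inst=2, seed=8)
    for _ in range(5):
        net.step([0.0, 0.0])
    np.testing.assert_array_equal(net.trace, 0.0)


# -- tags ------------------------------------------------------------


def test_full_decay_leaves_only_current_increment():
    """With lambda = 0 (alpha = 1) output tags equal the last activities."""
    net = make_net(seed=9, lam=0.0, epsilon=0.0)
    net.step([1.0, 0.0], force_action=2)
    net.step([1.0, 1.0], force_action=1)
    np.testing.assert_allclose(net.T_W_reg[0, 1], 1.0)
    np.testing.assert_allclose(net.T_W_reg[1:, 1], net.y_reg)
    np.testing.assert_allclose(net.T_W_mem[:, 1], net.y_mem)
    assert np.all(net.T_W_reg[:, [0, 2]] == 0)
    assert np.all(net.T_W_mem[:, [0, 2]] == 0)


def test_tag_decay_identity():
    """Tags without new contributions decay by exactly lambda * gamma."""
    net = make_net(seed=10, lam=0.2, gamma=0.9, epsilon=0.0)
    net.beta = 0.0
    # block new tag formation outside action 0's column / feedback row
    net.FB_reg[1, :] = 0.0
    net.FB_mem[1, :] = 0.0
    net.step([1.0, 0.3], force_action=0)
    tags_before = {k: v.copy() for k, v in net.tags.items()}
    net.step([1.0, 0.3], force_action=1)
    lg = 0.2 * 0.9
    for name, before in tags_before.items():
        after = net.tags[name]
        if name in ("V_reg", "V_mem"):
            np.testing.assert_allclose(after, lg * before, rtol=1e-12)
        else:
            cols = after[:, 0] if name.startswith("W") else after[0, :]
            ref = before[:, 0] if name.startswith("W") else before[0, :]
            np.testing.assert_allclose(cols, lg * ref, rtol=1e-12)


def test_feedback_gating_blocks_tag_formation():
    """Zero feedback from the winner means no new association tags."""
    net = make_net(seed=11, epsilon=0.0)
    net.FB_reg[2, 1] = 0.0
    net.step([1.0, 1.0], force_action=2)
    assert np.all(net.T_V_reg[:, 1] == 0.0)
    assert np.any(net.T_V_reg[:, 0] != 0.0)


def test_one_hot_attention_touches_single_column():
    net = make_net(seed=12, epsilon=0.0)
    net.step([0.5, 0.5], force_action=1)
    assert np.all(net.T_W_reg[:, [0, 2]] == 0.0)
    assert np.all(net.T_W_mem[:, [0, 2]] == 0.0)
    assert np.all(net.T_FB_reg[[0, 2], :] == 0.0)
    assert np.all(net.T_FB_mem[[0, 2], :] == 0.0)
    assert np.any(net.T_W_reg[:, 1] != 0.0)


def test_memory_tags_convert_traces():
    """New memory-unit tags equal trace x sigma' x feedback weight."""
    net = make_net(seed=13, lam=0.0, epsilon=0.0)
    net.step([1.0, 0.2], force_action=0)
    g = net.y_mem * (1.0 - net.y_mem) * net.FB_mem[0, :]
    np.testing.assert_allclose(net.T_V_mem, np.outer(net.trace, g),
                               rtol=1e-12)


# -- plasticity ------------------------------------------------------


def test_weight_update_is_beta_delta_tag():
    net = make_net(seed=14, epsilon=0.0)
    net.step([1.0, 0.0])
    net.step([1.0, 1.0])
    tags = {k: v.copy() for k, v in net.tags.items()}
    w_before = net.copy_weights()
    _, delta = net.step([0.0, 1.0], reward=0.3)
    for name, w in net.weights.items():
        np.testing.assert_allclose(
            w - w_before[name], net.params.beta * delta * tags[name],
            atol=1e-14)


def test_frozen_network_never_changes_weights():
    net = make_net(seed=15)
    net.freeze()
    w0 = net.copy_weights()
    for t in range(30):
        net.step([t % 2, 0.5], reward=0.1 * t, terminal=(t % 7 == 6))
    for name, w in net.weights.items():
        np.testing.assert_array_equal(w, w0[name])


# -- trial reset -----------------------------------------------------


def test_terminal_step_resets_everything_but_weights():
    net = make_net(seed=16)
    for _ in range(3):
        net.step([1.0, 0.5], reward=0.1)
    net.step([0.0, 0.0], reward=1.0, terminal=True)
    assert np.all(net.inp_mem == 0.0)
    assert np.all(net.trace == 0.0)
    for tag in net.tags.values():
        assert np.all(tag == 0.0)
    assert net.q_stored is None
    assert np.all(net.x_prev == 0.0)
    assert net.t == 0


def test_reset_reproduces_naive_activities():
    net = make_net(seed=17)
    net.freeze()
    net.step([0.0, 0.0])
    naive_y = net.y_reg.copy(), net.y_mem.copy(), net.q.copy()
    for _ in range(4):
        net.step([1.0, 0.3], reward=0.1)
    net.reset_trial()
    net.step([0.0, 0.0])
    for got, want in zip((net.y_reg, net.y_mem, net.q), naive_y):
        np.testing.assert_array_equal(got, want)


# -- learning behaviour ----------------------------------------------


def test_repeated_episode_drives_final_rpe_to_zero():
    """On a fixed deterministic episode the terminal RPE vanishes."""
    net = make_net(seed=18, epsilon=0.0)
    episode = [([1.0, 0.0], 0.0, False), ([1.0, 1.0], 0.0, False),
               ([0.0, 0.0], 1.5, True)]
    deltas = []
    for _ in range(3000):
        for x, r, terminal in episode:
            _, d = net.step(x, r, terminal, force_action=0)
        deltas.append(abs(d))
    assert deltas[-1] < 1e-3
    assert deltas[-1] < deltas[99] < deltas[9]


def test_output_layer_matches_reference_sarsa_lambda():
    """Cumulative output-weight updates equal a textbook eligibility-trace
    SARSA(lambda) learner on the (frozen) association features."""
    lam, gamma, beta = 0.4, 0.9, 0.15
    net = make_net(seed=19, lam=lam, gamma=gamma, beta=beta, epsilon=0.0)
    # zero feedback weights keep the association layer unchanged, so the
    # features evolve identically for both learners
    net.FB_reg[:] = 0.0
    net.FB_mem[:] = 0.0
    W = np.vstack([net.W_reg.copy(), net.W_mem.copy()])  # (1+J+M, K)
    e = np.zeros_like(W)
    q_prev = None
    rng = np.random.default_rng(42)
    for step in range(120):
        terminal = step % 6 == 5
        x = rng.integers(0, 2, size=2).astype(float)
        r = float(rng.random() < 0.3) * 1.5
        a = int(rng.integers(3))
        net.step(x, r, terminal, force_action=a)
        phi = np.concatenate([[1.0], net.y_reg, net.y_mem])
        if terminal:
            if q_prev is not None:
                W += beta * (r - q_prev) * e
            e[:] = 0.0
            q_prev = None
            continue
        # chosen value is read out before this step's weight update
        q_now = (phi @ W)[a]
        if q_prev is not None:
            W += beta * (r + gamma * q_now - q_prev) * e
        e *= lam * gamma
        e[:, a] += phi
        q_prev = q_now
    got = np.vstack([net.W_reg, net.W_mem])
    np.testing.assert_allclose(got, W, atol=1e-10)


def test_feedback_weights_align_with_feedforward(trained_saccade):
    """Training makes feedback and feedforward weights correlate."""
    from scipy.stats import spearmanr

    result, nets = trained_saccade
    n_pass = 0
    for net, conv in zip(nets, result.table.converged):
        if not conv:
            continue
        ff = np.concatenate([net.W_reg[1:].ravel(), net.W_mem.ravel()])
        fb = np.concatenate([net.FB_reg.T.ravel(), net.FB_mem.T.ravel()])
        if spearmanr(ff, fb).statistic > 0.8:
            n_pass += 1
    n_conv = int(result.table.converged.sum())
    assert n_pass >= 0.9 * n_conv


# -- parameter containers --------------------------------------------


def test_alpha_is_always_derived():
    p = LearningParams(lam=0.5, gamma=0.9)
    assert p.alpha == pytest.approx(0.55)


@pytest.mark.parametrize("kw", [dict(beta=-0.1), dict(lam=1.5),
                                dict(gamma=-0.2), dict(epsilon=2.0)])
def test_learning_params_validation(kw):
    with pytest.raises(ValueError):
        LearningParams(**kw)


def test_architecture_validation():
    with pytest.raises(ValueError):
        ArchitectureSpec(n_inst=0)
    with pytest.raises(ValueError):
        ArchitectureSpec(n_inst=2, init_low=0.3, init_high=0.1)
    assert ArchitectureSpec(n_inst=5).n_transient == 10
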