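"""Compiled inner loop of the agent.

One call advances the network by one discrete time step: sensory
transient encoding, trace accumulation, feedforward pass, action
selection (Max-Boltzmann), SARSA temporal-difference error, plasticity of
all tagged synapses, and tag decay/formation, in the canonical order that
makes the tags used by the update at step t exactly the ones laid down
after the action at step t-1.

All state lives in caller-owned arrays so the kernel is free of
allocation apart from small per-step scratch vectors.
"""

import numpy as np
from numba import njit

# Exponent clip keeps exp() finite; saturates the sigmoid/Boltzmann
# gracefully with no behavioural effect at the scale of these networks.
_EXP_CLIP = 500.0


@njit(cache=True)
def _sigma(inp, theta):
    z = theta - inp
    if z > _EXP_CLIP:
        z = _EXP_CLIP
    elif z < -_EXP_CLIP:
        z = -_EXP_CLIP
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def agent_step(
    x,            # (I,) instantaneous sensory vector for this step
    r,            # float reward delivered with this observation
    terminal,     # bool: this observation ends the trial
    u_explore,    # uniform draw deciding greedy vs Boltzmann branch
    u_select,     # uniform draw used by the chosen branch (and tie-breaks)
    forced,       # int: >=0 forces that action (oracle replays); -1 = policy
    beta, lam_gamma, gamma, eps, theta,
    V_reg,        # (I+1, J) input->regular, row 0 is the bias
    V_mem,        # (2I, M) transient->memory: rows 0..I-1 on, I..2I-1 off
    W_reg,        # (J+1, K) regular->Q, row 0 is the bias
    W_mem,        # (M, K) memory->Q
    FB_reg,       # (K, J) feedback Q->regular
    FB_mem,       # (K, M) feedback Q->memory
    x_prev,       # (I,) previous step's instantaneous vector (state)
    inp_mem,      # (M,) memory accumulators (state)
    q_state,      # (2,) [stored chosen q of previous step, valid flag]
    trace,        # (2I,) presynaptic sTrace onto memory units (state)
    T_V_reg, T_V_mem, T_W_reg, T_W_mem, T_FB_reg, T_FB_mem,   # tags
    y_reg_out,    # (J,) activities written for the caller
    y_mem_out,    # (M,)
    q_out,        # (K,)
):
    """Advance one step; return (action, delta).

    action is -1 on terminal steps (no action is taken); delta is NaN when
    no SARSA update was possible (first action of a trial).
    """
    I = x.shape[0]
    J = V_reg.shape[1]
    M = V_mem.shape[1]
    K = W_reg.shape[1]

    # (1) encode on/off transients against the previous step
    x_on = np.empty(I)
    x_off = np.empty(I)
    for i in range(I):
        d = x[i] - x_prev[i]
        if d > 0.0:
            x_on[i] = d
            x_off[i] = 0.0
        else:
            x_on[i] = 0.0
            x_off[i] = -d

    # (2) traces accumulate all transient presynaptic activity of the trial
    for i in range(I):
        trace[i] += x_on[i]
        trace[I + i] += x_off[i]

    # (3) feedforward pass
    for j in range(J):
        inp = V_reg[0, j]
        for i in range(I):
            inp += V_reg[1 + i, j] * x[i]
        y_reg_out[j] = _sigma(inp, theta)
    for m in range(M):
        acc = inp_mem[m]
        for i in range(I):
            acc += V_mem[i, m] * x_on[i] + V_mem[I + i, m] * x_off[i]
        inp_mem[m] = acc
        y_mem_out[m] = _sigma(acc, theta)
    for k in range(K):
        q = W_reg[0, k]
        for j in range(J):
            q += W_reg[1 + j, k] * y_reg_out[j]
        for m in range(M):
            q += W_mem[m, k] * y_mem_out[m]
        q_out[k] = q

    # (4) terminal transition: the target Q-value is zero
    if terminal:
        delta = np.nan
        if q_state[1] != 0.0:
            delta = r - q_state[0]
            if beta != 0.0:
                _apply(beta * delta, V_reg, T_V_reg)
                _apply(beta * delta, V_mem, T_V_mem)
                _apply(beta * delta, W_reg, T_W_reg)
                _apply(beta * delta, W_mem, T_W_mem)
                _apply(beta * delta, FB_reg, T_FB_reg)
                _apply(beta * delta, FB_mem, T_FB_mem)
        # trial reset: memory, traces, tags, stored Q all cleared
        for i in range(I):
            x_prev[i] = 0.0
        for m in range(M):
            inp_mem[m] = 0.0
        trace[:] = 0.0
        T_V_reg[:, :] = 0.0
        T_V_mem[:, :] = 0.0
        T_W_reg[:, :] = 0.0
        T_W_mem[:, :] = 0.0
        T_FB_reg[:, :] = 0.0
        T_FB_mem[:, :] = 0.0
        q_state[0] = 0.0
        q_state[1] = 0.0
        return -1, delta

    # (5) Max-Boltzmann action selection
    if forced >= 0:
        a = forced
    elif u_explore < eps:
        # sample from softmax of the Q-values (max-subtracted)
        qmax = q_out[0]
        for k in range(1, K):
            if q_out[k] > qmax:
                qmax = q_out[k]
        ssum = 0.0
        for k in range(K):
            z = q_out[k] - qmax
            if z < -_EXP_CLIP:
                z = -_EXP_CLIP
            ssum += np.exp(z)
        target = u_select * ssum
        acc = 0.0
        a = K - 1
        for k in range(K):
            z = q_out[k] - qmax
            if z < -_EXP_CLIP:
                z = -_EXP_CLIP
            acc += np.exp(z)
            if acc >= target:
                a = k
                break
    else:
        # greedy, ties broken uniformly at random
        qmax = q_out[0]
        for k in range(1, K):
            if q_out[k] > qmax:
                qmax = q_out[k]
        nties = 0
        for k in range(K):
            if q_out[k] == qmax:
                nties += 1
        pick = int(u_select * nties)
        if pick >= nties:
            pick = nties - 1
        a = 0
        seen = -1
        for k in range(K):
            if q_out[k] == qmax:
                seen += 1
                if seen == pick:
                    a = k
                    break

    # (6) SARSA update with the tags formed through the PREVIOUS action
    delta = np.nan
    if q_state[1] != 0.0:
        delta = r + gamma * q_out[a] - q_state[0]
        if beta != 0.0:
            _apply(beta * delta, V_reg, T_V_reg)
            _apply(beta * delta, V_mem, T_V_mem)
            _apply(beta * delta, W_reg, T_W_reg)
            _apply(beta * delta, W_mem, T_W_mem)
            _apply(beta * delta, FB_reg, T_FB_reg)
            _apply(beta * delta, FB_mem, T_FB_mem)

    # (7) tag decay (factor lam*gamma) then formation gated by the new action
    _decay(lam_gamma, T_V_reg)
    _decay(lam_gamma, T_V_mem)
    _decay(lam_gamma, T_W_reg)
    _decay(lam_gamma, T_W_mem)
    _decay(lam_gamma, T_FB_reg)
    _decay(lam_gamma, T_FB_mem)

    # output-layer tags: Hebbian with the one-hot post-selection activity
    T_W_reg[0, a] += 1.0
    for j in range(J):
        T_W_reg[1 + j, a] += y_reg_out[j]
        T_FB_reg[a, j] += y_reg_out[j]
    for m in range(M):
        T_W_mem[m, a] += y_mem_out[m]
        T_FB_mem[a, m] += y_mem_out[m]

    # association-layer tags: gated by the feedback weight of the winner
    for j in range(J):
        g = y_reg_out[j] * (1.0 - y_reg_out[j]) * FB_reg[a, j]
        T_V_reg[0, j] += g
        for i in range(I):
            T_V_reg[1 + i, j] += x[i] * g
    for m in range(M):
        g = y_mem_out[m] * (1.0 - y_mem_out[m]) * FB_mem[a, m]
        for l in range(2 * I):
            T_V_mem[l, m] += trace[l] * g

    # (8) remember the chosen value and the stimulus for the next step
    q_state[0] = q_out[a]
    q_state[1] = 1.0
    for i in range(I):
        x_prev[i] = x[i]
    return a, delta


@njit(cache=True)
def _apply(scale, w, tag):
    n0, n1 = w.shape
    for i in range(n0):
        for j in range(n1):
            w[i, j] += scale * tag[i, j]


@njit(cache=True)
def _decay(lam_gamma, tag):
    n0, n1 = tag.shape
    for i in range(n0):
        for j in range(n1):
            tag[i, j] *= lam_gamma
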