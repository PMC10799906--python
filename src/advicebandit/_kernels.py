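"""Numba-compiled inner loops for trial-sequence likelihoods and agent simulation.

The learning dynamics are inherently sequential (each trial's choice
probability depends on the state left by the previous trial), so the hot
loops are compiled with numba rather than vectorized.  The pure-Python
single-trial operations in :mod:`advicebandit.models` define the reference
semantics; these kernels must agree with them exactly, which the test suite
checks against an independently coded oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _net_values_pair(
    q_a: float,
    q_b: float,
    q_follow: float,
    q_not_follow: float,
    advised_is_a: bool,
    revealed: bool,
    omega: float,
    phi: float,
    model_id: int,
):
    """Net values of the two offered cards (a, b) under one of the five models."""
    if not revealed or model_id == 1:
        return q_a, q_b
    if model_id == 2:
        if advised_is_a:
            return q_a + phi, q_b
        return q_a, q_b + phi
    # models 3, 4, 5: blend card value with the follow / not-follow advice value
    if advised_is_a:
        net_a = omega * q_a + (1.0 - omega) * q_follow
        net_b = omega * q_b + (1.0 - omega) * q_not_follow
        if model_id == 5:
            net_a += phi
    else:
        net_a = omega * q_a + (1.0 - omega) * q_not_follow
        net_b = omega * q_b + (1.0 - omega) * q_follow
        if model_id == 5:
            net_b += phi
    return net_a, net_b


@njit(cache=False)
def _log_softmax_pair(beta: float, net_chosen: float, net_other: float) -> float:
    """log p(chosen) for a two-option softmax, stable for large beta."""
    x = beta * net_chosen
    y = beta * net_other
    m = x if x > y else y
    return (x - m) - np.log(np.exp(x - m) + np.exp(y - m))


@njit(cache=False)
def pointwise_loglik(
    offer_a: np.ndarray,
    offer_b: np.ndarray,
    advised: np.ndarray,
    revealed: np.ndarray,
    choice: np.ndarray,
    reward: np.ndarray,
    new_block: np.ndarray,
    alpha: float,
    beta: float,
    omega: float,
    phi: float,
    model_id: int,
    q_init: float,
    n_cards: int,
    out: np.ndarray,
) -> float:
    """Per-trial log-likelihoods of the observed choices; returns their sum.

    ``new_block`` marks trials at which the latent state is re-initialized
    (cards and teacher are replaced every block).  Per trial the order is:
    net values and the choice log-probability from the pre-update state, the
    card prediction error from the pre-update value, then the advice-value
    update (models 3-5, revealed trials only) followed by the card update.
    """
    q = np.empty(n_cards)
    q_follow = q_init
    q_not_follow = q_init
    total = 0.0
    for t in range(offer_a.shape[0]):
        if new_block[t]:
            for c in range(n_cards):
                q[c] = q_init
            q_follow = q_init
            q_not_follow = q_init
        a = offer_a[t]
        b = offer_b[t]
        rev = revealed[t]
        adv = advised[t]
        net_a, net_b = _net_values_pair(
            q[a], q[b], q_follow, q_not_follow, adv == a, rev, omega, phi, model_id
        )
        c = choice[t]
        r = reward[t]
        if c == a:
            lp = _log_softmax_pair(beta, net_a, net_b)
        else:
            lp = _log_softmax_pair(beta, net_b, net_a)
        out[t] = lp
        total += lp
        delta_card = r - q[c]
        if rev and model_id >= 3:
            moderator = np.abs(delta_card) if model_id == 4 else 1.0
            if c == adv:
                q_follow += alpha * (r - q_follow) * moderator
            else:
                q_not_follow += alpha * (r - q_not_follow) * moderator
        q[c] += alpha * delta_card
    return total


@njit(cache=False)
def simulate_choices(
    offer_a: np.ndarray,
    offer_b: np.ndarray,
    advised: np.ndarray,
    revealed: np.ndarray,
    p_reward: np.ndarray,
    new_block: np.ndarray,
    alpha: float,
    beta: float,
    omega: float,
    phi: float,
    model_id: int,
    q_init: float,
    n_cards: int,
    u_choice: np.ndarray,
    u_reward: np.ndarray,
    choice_out: np.ndarray,
    reward_out: np.ndarray,
) -> None:
    """Simulate one agent through a prepared environment.

    ``u_choice`` and ``u_reward`` are pre-drawn uniforms (one each per trial)
    so that simulation is a deterministic function of its inputs.
    """
    q = np.empty(n_cards)
    q_follow = q_init
    q_not_follow = q_init
    for t in range(offer_a.shape[0]):
        if new_block[t]:
            for c in range(n_cards):
                q[c] = q_init
            q_follow = q_init
            q_not_follow = q_init
        a = offer_a[t]
        b = offer_b[t]
        rev = revealed[t]
        adv = advised[t]
        net_a, net_b = _net_values_pair(
            q[a], q[b], q_follow, q_not_follow, adv == a, rev, omega, phi, model_id
        )
        p_a = np.exp(_log_softmax_pair(beta, net_a, net_b))
        c = a if u_choice[t] < p_a else b
        r = 1.0 if u_reward[t] < p_reward[t, c] else 0.0
        choice_out[t] = c
        reward_out[t] = r
        delta_card = r - q[c]
        if rev and model_id >= 3:
            moderator = np.abs(delta_card) if model_id == 4 else 1.0
            if c == adv:
                q_follow += alpha * (r - q_follow) * moderator
            else:
                q_not_follow += alpha * (r - q_not_follow) * moderator
        q[c] += alpha * delta_card
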