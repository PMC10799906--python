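"""Reinforcement-learning models of advice-taking in the student-teacher task.

Five nested models describe how a learner combines three sources of
information when choosing between two offered cards:

* **individual learning** -- Q-learning of each card's value from one's own
  outcomes (all models);
* **non-informed advice-taking** -- a fixed bias ``phi`` added to the advised
  card's value whenever advice is shown (models 2 and 5);
* **informed advice-taking** -- Q-learning of the value of following versus
  not following the teacher's advice, blended with the card values by the
  weight ``omega`` (models 3, 4 and 5; model 4 scales the advice update by
  the magnitude of the card prediction error).

Choices are generated by a softmax with inverse temperature ``beta`` over the
two offered cards' net values.  Advice influences nothing on trials where it
is concealed, and the advice values are only updated when advice was shown.

The single-trial operations here are the reference semantics; the compiled
kernels in :mod:`advicebandit._kernels` implement the same dynamics for
whole trial sequences and are used by :func:`subject_loglik`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels

MODEL_IDS = (1, 2, 3, 4, 5)

#: free parameters per model; the others are pinned (omega=1, phi=0)
FREE_PARAMS = {
    1: ("alpha", "beta"),
    2: ("alpha", "beta", "phi"),
    3: ("alpha", "beta", "omega"),
    4: ("alpha", "beta", "omega"),
    5: ("alpha", "beta", "omega", "phi"),
}

MODEL_NAMES = {
    1: "individual learning only",
    2: "fixed advice bias",
    3: "advice-value learning",
    4: "moderated advice-value learning",
    5: "combined (bias + advice-value learning)",
}


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the learner.

    alpha : learning rate in [0, 1], shared by card and advice updates.
    beta  : softmax inverse temperature, >= 0.
    omega : weight of the card value versus the advice value in the net
            valuation of a revealed-advice trial; 1 silences informed
            advice-taking.
    phi   : fixed bias added to the advised card's net value; 0 silences
            non-informed advice-taking.  Unrestricted sign.
    """

    alpha: float
    beta: float
    omega: float = 1.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")

    def pinned(self, model_id: int) -> "AgentParams":
        """Copy with the parameters a model does not use pinned to neutral."""
        _check_model(model_id)
        free = FREE_PARAMS[model_id]
        omega = self.omega if "omega" in free else 1.0
        phi = self.phi if "phi" in free else 0.0
        return replace(self, omega=omega, phi=phi)


@dataclass
class QState:
    """Latent values: one per card plus the follow / not-follow advice values."""

    q_cards: np.ndarray
    q_follow: float
    q_not_follow: float

    def copy(self) -> "QState":
        return QState(self.q_cards.copy(), self.q_follow, self.q_not_follow)


@dataclass(frozen=True)
class UpdateTrace:
    """Prediction errors of one trial, computed from pre-update values."""

    delta_card: float
    delta_advice: Optional[float] = None


@dataclass(frozen=True)
class OfferValuation:
    """Net values and softmax choice probabilities of the two offered cards."""

    offer: tuple[int, int]
    qnet: np.ndarray
    choice_probs: np.ndarray


def _check_model(model_id: int) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id}; expected one of {MODEL_IDS}")


def init_state(n_cards: int = 4, q_init: float = 0.5) -> QState:
    """Fresh latent state for the start of a block.

    All values start at ``q_init`` (default 0.5, the midpoint of the {0, 1}
    reward support).  Simulators and likelihoods call this at every block
    start because cards and teacher are replaced between blocks.
    """
    return QState(np.full(n_cards, float(q_init)), float(q_init), float(q_init))


def update_card_value(
    state: QState, choice: int, reward: float, alpha: float
) -> tuple[QState, UpdateTrace]:
    """Delta-rule update of the chosen card's value; other cards untouched."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    new = state.copy()
    delta = reward - state.q_cards[choice]
    new.q_cards[choice] = state.q_cards[choice] + alpha * delta
    return new, UpdateTrace(delta_card=float(delta))


def update_advice_value(
    state: QState,
    followed: bool,
    reward: float,
    alpha: float,
    delta_card: float,
    model_id: int,
) -> QState:
    """Update the follow or not-follow advice value after a revealed trial.

    Only models 3-5 maintain advice values; model 4 scales the update by
    ``|delta_card|`` so that outcomes already well predicted by the card
    values say little about the teacher.  Callers must not invoke this on
    concealed trials.
    """
    _check_model(model_id)
    if model_id in (1, 2):
        raise ValueError(f"model {model_id} maintains no advice values")
    moderator = abs(delta_card) if model_id == 4 else 1.0
    new = state.copy()
    if followed:
        new.q_follow = state.q_follow + alpha * (reward - state.q_follow) * moderator
    else:
        new.q_not_follow = (
            state.q_not_follow + alpha * (reward - state.q_not_follow) * moderator
        )
    return new


def net_values(
    state: QState,
    offer: Sequence[int],
    advised_card: Optional[int],
    revealed: bool,
    params: AgentParams,
    model_id: int,
) -> np.ndarray:
    """Net values of the two offered cards, in offer order.

    Concealed trials use the raw card values in every model (an unseen
    advice cannot enter the valuation).  On revealed trials model 2 adds
    ``phi`` to the advised card; models 3-4 blend each card with the
    corresponding advice value (advised card with q_follow, unadvised with
    q_not_follow) using ``omega``; model 5 does both.
    """
    _check_model(model_id)
    a, b = int(offer[0]), int(offer[1])
    if revealed:
        if advised_card is None:
            raise ValueError("revealed trial requires an advised card")
        if advised_card not in (a, b):
            raise ValueError(f"advised card {advised_card} not in offer {(a, b)}")
    if not revealed or model_id == 1:
        return np.array([state.q_cards[a], state.q_cards[b]], dtype=float)
    adv_first = advised_card == a
    net_a, net_b = _kernels._net_values_pair.py_func(
        state.q_cards[a],
        state.q_cards[b],
        state.q_follow,
        state.q_not_follow,
        adv_first,
        True,
        params.omega,
        params.phi,
        model_id,
    )
    return np.array([net_a, net_b], dtype=float)


def choice_probabilities(qnet: Sequence[float], beta: float) -> np.ndarray:
    """Softmax over the offered cards' net values, stable for large beta."""
    if beta < 0.0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    x = beta * np.asarray(qnet, dtype=float)
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def trial_step(
    state: QState,
    trial,
    params: AgentParams,
    model_id: int,
) -> tuple[float, QState, UpdateTrace]:
    """Process one observed trial: log-probability of the choice, new state.

    ``trial`` is any mapping with fields offer_a, offer_b, advised_card,
    revealed, choice, reward (a TrialTable row works).  Order of computation:
    (1) net values from the pre-update state, (2) log-probability of the
    observed choice, (3) card prediction error from the pre-update value,
    (4) advice update if revealed and the model learns advice values,
    (5) card update.
    """
    _check_model(model_id)
    params = params.pinned(model_id)
    a, b = int(trial["offer_a"]), int(trial["offer_b"])
    choice = int(trial["choice"])
    if choice not in (a, b):
        raise ValueError(f"choice {choice} not in offer {(a, b)}")
    revealed = bool(trial["revealed"])
    advised = int(trial["advised_card"]) if revealed else None
    reward = float(trial["reward"])

    qnet = net_values(state, (a, b), advised, revealed, params, model_id)
    probs = choice_probabilities(qnet, params.beta)
    logp = float(np.log(probs[0] if choice == a else probs[1]))

    delta_card = float(reward - state.q_cards[choice])
    delta_advice = None
    new_state = state
    if revealed and model_id >= 3:
        followed = choice == advised
        before = state.q_follow if followed else state.q_not_follow
        delta_advice = reward - before
        new_state = update_advice_value(
            new_state, followed, reward, params.alpha, delta_card, model_id
        )
    new_state, trace = update_card_value(new_state, choice, reward, params.alpha)
    return logp, new_state, UpdateTrace(trace.delta_card, delta_advice)


def _prepare_arrays(trials: pd.DataFrame, n_cards: int):
    """Sorted, choice-valid arrays plus block-boundary flags for the kernels."""
    required = ["subject", "session", "block", "trial"]
    for col in required:
        if col not in trials.columns:
            raise ValueError(f"trial table lacks required column '{col}'")
    order = trials[required].to_numpy()
    idx = np.lexsort((order[:, 3], order[:, 2], order[:, 1], order[:, 0]))
    if not (idx == np.arange(len(idx))).all():
        raise ValueError("trials must be sorted by subject, session, block, trial")

    observed = trials["choice"].notna().to_numpy()
    t = trials.loc[observed]
    offer_a = t["offer_a"].to_numpy(np.int64)
    offer_b = t["offer_b"].to_numpy(np.int64)
    advised = t["advised_card"].to_numpy(np.int64)
    revealed = t["revealed"].to_numpy(bool)
    choice = t["choice"].to_numpy(np.int64)
    reward = t["reward"].to_numpy(np.float64)
    if not np.all((choice == offer_a) | (choice == offer_b)):
        bad = np.nonzero(~((choice == offer_a) | (choice == offer_b)))[0]
        raise ValueError(f"choice outside offered pair at rows {bad[:10].tolist()}")
    block_key = t[["subject", "session", "block"]].to_numpy()
    new_block = np.ones(len(t), dtype=bool)
    if len(t) > 1:
        new_block[1:] = (block_key[1:] != block_key[:-1]).any(axis=1)
    if np.any((offer_a < 0) | (offer_a >= n_cards) | (offer_b < 0) | (offer_b >= n_cards)):
        raise ValueError(f"card indices outside [0, {n_cards})")
    return offer_a, offer_b, advised, revealed, choice, reward, new_block


def loglik_from_arrays(
    arrays: tuple,
    params: AgentParams,
    model_id: int,
    n_cards: int = 4,
    q_init: float = 0.5,
) -> float:
    """Total log-likelihood from pre-extracted arrays (see _prepare_arrays).

    Optimizers call the likelihood thousands of times on the same trials;
    this entry point skips the per-call DataFrame validation.
    """
    p = params.pinned(model_id)
    out = np.empty(arrays[0].shape[0])
    return float(
        _kernels.pointwise_loglik(
            *arrays, p.alpha, p.beta, p.omega, p.phi, model_id, q_init, n_cards, out
        )
    )


def subject_loglik(
    trials: pd.DataFrame,
    params: AgentParams,
    model_id: int,
    n_cards: int = 4,
    q_init: float = 0.5,
    pointwise: bool = False,
):
    """Total log-likelihood of one subject's trial sequence under a model.

    The latent state is re-initialized at every block boundary.  Trials with
    a missing choice are skipped entirely (no state update).  With
    ``pointwise=True`` also returns the per-trial log-probabilities (aligned
    with the observed-choice rows in sorted order).
    """
    _check_model(model_id)
    p = params.pinned(model_id)
    arrays = _prepare_arrays(trials, n_cards)
    out = np.empty(arrays[0].shape[0])
    total = _kernels.pointwise_loglik(
        *arrays, p.alpha, p.beta, p.omega, p.phi, model_id, q_init, n_cards, out
    )
    if pointwise:
        return float(total), out
    return float(total)
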