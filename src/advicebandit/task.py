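"""Generative model of the student-teacher restless bandit task.

The task: four cards with slowly drifting Bernoulli reward probabilities,
two of which are offered on each trial.  A virtual teacher privately picks
one of the offered cards on every trial via a softmax on the cards' *true*
reward probabilities, with an inverse temperature that itself drifts slowly,
so that the teacher's accuracy wanders within a block.  The teacher's pick
is shown to the learner as advice on a random 60% of trials and stays hidden
on the rest.  Cards and teacher are replaced at every block boundary, so all
latent trajectories restart fresh each block.

Default calibration (reflecting Gaussian walks, card probabilities on
[0.25, 0.75] with step sd 0.03; teacher beta on [1.25, 5.75] with step sd
0.1) puts the teacher's mean accuracy at ~63% with block-level accuracies
ranging over roughly 53-77%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .models import AgentParams, _check_model

#: canonical column order of a trial table
TRIAL_COLUMNS = [
    "subject",
    "session",
    "block",
    "trial",
    "offer_a",
    "offer_b",
    "advised_card",
    "revealed",
    "choice",
    "reward",
    "rt",
]

#: latent columns present only in synthetic data
LATENT_COLUMNS = ["p_reward_a", "p_reward_b", "teacher_beta", "teacher_correct"]


@dataclass(frozen=True)
class TaskConfig:
    """Task structure and latent-dynamics calibration.

    The block structure (2 sessions x 3 blocks x 130 trials, 4 cards, 2
    offered, 60% reveal) mirrors the behavioral study; the walk parameters
    are calibrated so the teacher's accuracy matches its printed band.
    All fields can be overridden, e.g. for scaled-down experiments.
    """

    n_cards: int = 4
    n_offered: int = 2
    n_sessions: int = 2
    n_blocks_per_session: int = 3
    n_trials_per_block: int = 130
    reveal_probability: float = 0.6
    reward_values: tuple[float, float] = (0.0, 1.0)
    card_walk_step_sd: float = 0.03
    card_prob_bounds: tuple[float, float] = (0.25, 0.75)
    teacher_beta_walk_step_sd: float = 0.1
    teacher_beta_bounds: tuple[float, float] = (1.25, 5.75)
    q_init: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.reveal_probability < 1.0:
            raise ValueError("reveal_probability must lie strictly in (0, 1)")
        if self.n_offered != 2:
            raise ValueError("only two-card offers are supported")
        if self.n_offered >= self.n_cards:
            raise ValueError("n_offered must be smaller than n_cards")
        for name in ("n_cards", "n_sessions", "n_blocks_per_session", "n_trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.card_prob_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("card_prob_bounds must satisfy 0 < low < high < 1")
        blo, bhi = self.teacher_beta_bounds
        if not (0.0 <= blo < bhi):
            raise ValueError("teacher_beta_bounds must satisfy 0 <= low < high")

    @property
    def n_blocks(self) -> int:
        return self.n_sessions * self.n_blocks_per_session

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.n_trials_per_block

    def replace(self, **kw) -> "TaskConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Environment:
    """Latent generative state of one task instance, flat over trials.

    Arrays are aligned in (session, block, trial) order; ``p_reward`` has one
    column per card.  ``advised_card`` is the teacher's softmax draw, present
    on every trial (it is merely hidden on concealed trials).
    """

    cfg: TaskConfig
    session: np.ndarray
    block: np.ndarray
    trial: np.ndarray
    offer_a: np.ndarray
    offer_b: np.ndarray
    p_reward: np.ndarray
    teacher_beta: np.ndarray
    advised_card: np.ndarray
    revealed: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.session.shape[0]

    @property
    def new_block(self) -> np.ndarray:
        flags = np.ones(self.n_trials, dtype=bool)
        key = np.stack([self.session, self.block], axis=1)
        flags[1:] = (key[1:] != key[:-1]).any(axis=1)
        return flags

    @property
    def teacher_correct(self) -> np.ndarray:
        """1 where the teacher's draw is the offered card with higher p_reward."""
        rows = np.arange(self.n_trials)
        p_adv = self.p_reward[rows, self.advised_card]
        other = np.where(self.advised_card == self.offer_a, self.offer_b, self.offer_a)
        p_other = self.p_reward[rows, other]
        return (p_adv >= p_other).astype(int)


def _reflecting_walk(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_steps: int,
    step_sd: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Gaussian random walk reflected at [lo, hi]; start uniform in bounds.

    Returns an array of shape ``shape + (n_steps,)``.
    """
    width = hi - lo
    x = rng.uniform(lo, hi, shape)
    out = np.empty(shape + (n_steps,))
    for t in range(n_steps):
        out[..., t] = x
        x = x + rng.normal(0.0, step_sd, shape)
        y = np.mod(x - lo, 2.0 * width)
        x = lo + np.where(y > width, 2.0 * width - y, y)
    return out


def teacher_choice_probs(p_pair: Sequence[float], beta_t: float) -> np.ndarray:
    """Probability of the teacher picking each offered card.

    Softmax with inverse temperature ``beta_t`` on the two cards' true reward
    probabilities; beta_t = 0 gives a coin flip.
    """
    if beta_t < 0.0:
        raise ValueError(f"teacher beta must be non-negative, got {beta_t}")
    p = np.asarray(p_pair, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("reward probabilities must lie in [0, 1]")
    x = beta_t * p
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def generate_environment(cfg: TaskConfig, seed: Optional[int] = None) -> Environment:
    """Draw one full task instance: walks, offers, teacher picks, reveal flags.

    Latent walks restart with a fresh uniform draw at every block boundary;
    offers are uniform over the unordered card pairs, i.i.d. per trial;
    reveal flags are i.i.d. Bernoulli(reveal_probability).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    B, T, C = cfg.n_blocks, cfg.n_trials_per_block, cfg.n_cards
    lo, hi = cfg.card_prob_bounds
    blo, bhi = cfg.teacher_beta_bounds

    p = _reflecting_walk(rng, (B, C), T, cfg.card_walk_step_sd, lo, hi)  # (B, C, T)
    beta = _reflecting_walk(rng, (B,), T, cfg.teacher_beta_walk_step_sd, blo, bhi)

    first = rng.integers(0, C, (B, T))
    second = (first + rng.integers(1, C, (B, T))) % C
    offer_a = np.minimum(first, second)
    offer_b = np.maximum(first, second)

    b_idx = np.arange(B)[:, None]
    t_idx = np.arange(T)[None, :]
    p_a = p[b_idx, offer_a, t_idx]
    p_b = p[b_idx, offer_b, t_idx]
    prob_pick_a = 1.0 / (1.0 + np.exp(-beta * (p_a - p_b)))
    pick_a = rng.random((B, T)) < prob_pick_a
    advised = np.where(pick_a, offer_a, offer_b)

    revealed = rng.random((B, T)) < cfg.reveal_probability

    block_of = np.repeat(np.arange(B), T)
    return Environment(
        cfg=cfg,
        session=block_of // cfg.n_blocks_per_session,
        block=block_of % cfg.n_blocks_per_session,
        trial=np.tile(np.arange(T), B),
        offer_a=offer_a.reshape(-1),
        offer_b=offer_b.reshape(-1),
        p_reward=np.transpose(p, (0, 2, 1)).reshape(-1, C),
        teacher_beta=beta.reshape(-1),
        advised_card=advised.reshape(-1),
        revealed=revealed.reshape(-1),
    )


def teacher_accuracy(env: Environment, per_block: bool = False):
    """Fraction of trials on which the teacher picked the better offered card."""
    correct = env.teacher_correct
    if not per_block:
        return float(correct.mean())
    df = pd.DataFrame(
        {"session": env.session, "block": env.block, "correct": correct}
    )
    return df.groupby(["session", "block"])["correct"].mean().to_numpy()


def simulate_dataset(
    model_id: int,
    params_per_subject: Sequence[AgentParams],
    cfg: TaskConfig,
    seed: Optional[int] = None,
    include_latents: bool = True,
) -> pd.DataFrame:
    """Simulate a full trial table: one independent task instance per agent.

    For each trial the agent values the offer given the (possibly revealed)
    advice, a choice is drawn from its softmax, the reward is drawn from the
    chosen card's current reward probability, and the agent's state is
    updated; state resets at every block start.  The reaction-time column is
    left empty (no generative model of RTs).
    """
    _check_model(model_id)
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    frames = []
    for subj, (params, child) in enumerate(
        zip(params_per_subject, ss.spawn(len(params_per_subject)))
    ):
        rng = np.random.default_rng(child)
        env_seed = int(rng.integers(0, 2**31 - 1))
        env = generate_environment(cfg, env_seed)
        p = params.pinned(model_id)
        n = env.n_trials
        u_choice = rng.random(n)
        u_reward = rng.random(n)
        choice = np.empty(n, dtype=np.int64)
        reward = np.empty(n)
        _kernels.simulate_choices(
            env.offer_a,
            env.offer_b,
            env.advised_card,
            env.revealed,
            env.p_reward,
            env.new_block,
            p.alpha,
            p.beta,
            p.omega,
            p.phi,
            model_id,
            cfg.q_init,
            cfg.n_cards,
            u_choice,
            u_reward,
            choice,
            reward,
        )
        df = pd.DataFrame(
            {
                "subject": subj,
                "session": env.session,
                "block": env.block,
                "trial": env.trial,
                "offer_a": env.offer_a,
                "offer_b": env.offer_b,
                "advised_card": env.advised_card,
                "revealed": env.revealed.astype(int),
                "choice": choice,
                "reward": reward,
                "rt": np.nan,
            }
        )
        if include_latents:
            rows = np.arange(n)
            df["p_reward_a"] = env.p_reward[rows, env.offer_a]
            df["p_reward_b"] = env.p_reward[rows, env.offer_b]
            df["teacher_beta"] = env.teacher_beta
            df["teacher_correct"] = env.teacher_correct
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def lesion_params(params: AgentParams, mode: str) -> AgentParams:
    """Silence one advice-taking channel of a fitted agent.

    ``"non_informed_only"`` sets omega = 1 (advice-value learning has no
    behavioral weight; only the fixed bias phi remains).  ``"informed_only"``
    sets phi = 0 (no fixed bias; only learned advice value remains).
    """
    if mode == "non_informed_only":
        return dataclasses.replace(params, omega=1.0)
    if mode == "informed_only":
        return dataclasses.replace(params, phi=0.0)
    raise ValueError(f"unknown lesion mode {mode!r}")
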