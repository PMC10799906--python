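"""Straight-line reference implementation of the five advice-taking models.

Deliberately unoptimized and independent of the package internals: plain
Python floats, explicit per-model branches, no shared helpers with the
implementation under test.  Used to cross-check trial-sequence
log-likelihoods to high precision.
"""

import math


def oracle_loglik(trials, alpha, beta, omega, phi, model_id, q_init=0.5, n_cards=4):
    """Total log-likelihood of a trial sequence.

    ``trials`` is an iterable of dicts with keys subject, session, block,
    offer_a, offer_b, advised_card, revealed, choice, reward.  State resets
    whenever (subject, session, block) changes.
    """
    total = 0.0
    prev_key = None
    q = None
    q_follow = q_not_follow = None
    for tr in trials:
        key = (tr["subject"], tr["session"], tr["block"])
        if key != prev_key:
            q = [q_init] * n_cards
            q_follow = q_init
            q_not_follow = q_init
            prev_key = key
        a, b = tr["offer_a"], tr["offer_b"]
        revealed = bool(tr["revealed"])
        adv = tr["advised_card"]
        choice = tr["choice"]
        reward = tr["reward"]

        # net values of the two offered cards
        if not revealed:
            vals = {a: q[a], b: q[b]}
        elif model_id == 1:
            vals = {a: q[a], b: q[b]}
        elif model_id == 2:
            vals = {a: q[a], b: q[b]}
            vals[adv] = vals[adv] + phi
        elif model_id in (3, 4):
            una = b if adv == a else a
            vals = {
                adv: omega * q[adv] + (1 - omega) * q_follow,
                una: omega * q[una] + (1 - omega) * q_not_follow,
            }
        elif model_id == 5:
            una = b if adv == a else a
            vals = {
                adv: omega * q[adv] + (1 - omega) * q_follow + phi,
                una: omega * q[una] + (1 - omega) * q_not_follow,
            }
        else:
            raise ValueError(model_id)

        num = math.exp(beta * vals[choice])
        den = math.exp(beta * vals[a]) + math.exp(beta * vals[b])
        total += math.log(num / den)

        delta_card = reward - q[choice]
        if revealed and model_id in (3, 4, 5):
            scale = abs(delta_card) if model_id == 4 else 1.0
            if choice == adv:
                q_follow = q_follow + alpha * (reward - q_follow) * scale
            else:
                q_not_follow = q_not_follow + alpha * (reward - q_not_follow) * scale
        q[choice] = q[choice] + alpha * delta_card
    return total
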