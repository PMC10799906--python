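"""Leave-one-block-out predictive model comparison.

For every subject and every block, each model is refit on the remaining
blocks and the per-trial log predictive density (lpd) is evaluated on the
held-out block, with the learner's state freshly initialized at the block
start (cards and teacher are new in every block, so no information carries
over).  Concatenating over blocks and subjects gives one pointwise lpd per
observed trial; a model's elpd is their sum.

Comparison follows the standard pairwise rule: for each model the pointwise
difference from the best model is summed, its standard error is
``sqrt(N * var(pointwise differences))``, and the best model is declared the
*winner* only when every rival's deficit exceeds max(4, 2 * SE).

The predictive density is a plug-in (point estimates fit on the training
blocks), not a full posterior average; this typically sharpens differences
slightly but preserves their ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import PopulationSpec, fit_subject_mle
from .models import _check_model, subject_loglik
from .task import TaskConfig, simulate_dataset


def _sorted(dataset: pd.DataFrame) -> pd.DataFrame:
    return dataset.sort_values(
        ["subject", "session", "block", "trial"], kind="mergesort"
    ).reset_index(drop=True)


def heldout_pointwise_lpd(
    dataset: pd.DataFrame,
    model_id: int,
    n_starts: int = 6,
    seed: Optional[int] = None,
    n_cards: int = 4,
    q_init: float = 0.5,
) -> pd.DataFrame:
    """Pointwise held-out log predictive densities for one model.

    Returns one row per observed-choice trial (subject, session, block,
    trial, lpd) in canonical sort order, identical across models so that
    pointwise vectors can be compared elementwise.  Subjects with fewer than
    two blocks cannot be cross-validated and are dropped with a warning.
    """
    _check_model(model_id)
    data = _sorted(dataset)
    data = data[data["choice"].notna()]
    ss = np.random.SeedSequence(seed)
    out_frames = []
    for subj, sdf in data.groupby("subject", sort=True):
        blocks = sdf[["session", "block"]].drop_duplicates().to_numpy()
        if len(blocks) < 2:
            warnings.warn(
                f"subject {subj!r} has a single block; excluded from cross-validation",
                RuntimeWarning,
            )
            continue
        fold_seeds = ss.spawn(len(blocks))
        for (sess, blk), fseed in zip(blocks, fold_seeds):
            held_mask = (sdf["session"] == sess) & (sdf["block"] == blk)
            train = sdf[~held_mask].reset_index(drop=True)
            held = sdf[held_mask].reset_index(drop=True)
            fit = fit_subject_mle(
                train,
                model_id,
                n_starts=n_starts,
                seed=int(fseed.generate_state(1)[0] % (2**31 - 1)),
                n_cards=n_cards,
                q_init=q_init,
                subject=subj,
            )
            _, lpd = subject_loglik(
                held, fit.params, model_id, n_cards=n_cards, q_init=q_init,
                pointwise=True,
            )
            out_frames.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "session": sess,
                        "block": blk,
                        "trial": held["trial"].to_numpy(),
                        "lpd": lpd,
                    }
                )
            )
    if not out_frames:
        raise ValueError("no subject had at least two blocks")
    out = pd.concat(out_frames, ignore_index=True)
    return _sorted(out)


@dataclass
class ElpdTable:
    """Model-comparison result: pointwise lpds and the pairwise summary.

    ``summary`` has one row per model: elpd, elpd difference from the best
    model, the SE of that difference, and whether the rival is beaten by the
    max(4, 2*SE) rule.  ``winner`` is the best model's id when it beats every
    rival, else None.
    """

    pointwise: pd.DataFrame  # columns: subject, session, block, trial, then lpd_<id>
    summary: pd.DataFrame
    best_model: int
    winner: Optional[int]

    def __str__(self) -> str:
        lines = [f"model comparison (winner: {self.winner})"]
        for _, row in self.summary.iterrows():
            lines.append(
                f"  model {int(row.model_id)}: elpd {row.elpd:10.1f}   "
                f"diff {row.elpd_diff:8.1f} ({row.se_diff:.1f})"
            )
        return "\n".join(lines)


def compare_models(
    dataset: pd.DataFrame,
    model_ids: Sequence[int] = (1, 2, 3, 4, 5),
    n_starts: int = 6,
    seed: Optional[int] = None,
    n_cards: int = 4,
    q_init: float = 0.5,
) -> ElpdTable:
    """Leave-one-block-out elpd comparison across models.

    All models are scored on the identical fold partition and trial set;
    misalignment is an error.
    """
    if len(model_ids) < 2:
        raise ValueError("need at least two models to compare")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(model_ids))]
    merged = None
    for mid, mseed in zip(model_ids, seeds):
        pw = heldout_pointwise_lpd(
            dataset, mid, n_starts=n_starts, seed=mseed, n_cards=n_cards, q_init=q_init
        ).rename(columns={"lpd": f"lpd_{mid}"})
        if merged is None:
            merged = pw
        else:
            keys = ["subject", "session", "block", "trial"]
            if not merged[keys].equals(pw[keys]):
                raise ValueError("pointwise lpd vectors are misaligned across models")
            merged[f"lpd_{mid}"] = pw[f"lpd_{mid}"].to_numpy()

    elpd = {mid: float(merged[f"lpd_{mid}"].sum()) for mid in model_ids}
    best = max(elpd, key=elpd.get)
    n = len(merged)
    rows = []
    all_beaten = True
    for mid in model_ids:
        diff_pw = merged[f"lpd_{mid}"].to_numpy() - merged[f"lpd_{best}"].to_numpy()
        diff = float(diff_pw.sum())
        se = float(np.sqrt(n * diff_pw.var(ddof=1))) if mid != best else 0.0
        beaten = mid != best and (-diff) > max(4.0, 2.0 * se)
        if mid != best:
            all_beaten &= beaten
        rows.append(
            {
                "model_id": mid,
                "elpd": elpd[mid],
                "elpd_diff": diff,
                "se_diff": se,
                "beaten": beaten,
                "n_points": n,
            }
        )
    summary = pd.DataFrame(rows).sort_values("elpd", ascending=False).reset_index(drop=True)
    return ElpdTable(
        pointwise=merged,
        summary=summary,
        best_model=best,
        winner=best if all_beaten else None,
    )


def model_recovery_experiment(
    generating_populations: dict[int, PopulationSpec],
    cfg: TaskConfig,
    n_subjects: int = 20,
    model_ids: Sequence[int] = (1, 2, 3, 4, 5),
    seed: Optional[int] = None,
    n_starts: int = 6,
) -> pd.DataFrame:
    """Confusion matrix of generating model (rows) versus best-scoring model.

    For each generating model, a population is simulated, the comparison is
    run, and the best model (by elpd) is tabulated; the ``winner_declared``
    column records whether the max(4, 2*SE) rule was met.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for gen_id, child in zip(sorted(generating_populations), ss.spawn(len(generating_populations))):
        s_draw, s_sim, s_cmp = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(3)]
        pop = generating_populations[gen_id]
        rng = np.random.default_rng(s_draw)
        params = [p.pinned(gen_id) for p in pop.draw(n_subjects, rng)]
        data = simulate_dataset(gen_id, params, cfg, seed=s_sim)
        table = compare_models(
            data, model_ids, n_starts=n_starts, seed=s_cmp,
            n_cards=cfg.n_cards, q_init=cfg.q_init,
        )
        rows.append(
            {
                "generating_model": gen_id,
                "best_model": table.best_model,
                "winner_declared": table.winner is not None,
            }
        )
    return pd.DataFrame(rows)
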