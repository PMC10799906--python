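"""Theory-independent statistics and the informed/non-informed signatures.

*Coherence* is choosing the same card the teacher (possibly silently)
picked.  The *reveal effect* -- higher coherence when advice is shown than
when it is concealed -- is the causal footprint of advice on choice.  Two
regression signatures then dissociate its two sources:

* **first-encounter effect** (non-informed channel): the reveal effect
  computed from only the first concealed and first revealed trial of each
  block, before any advice value could have been learned about the brand-new
  teacher.  Only a fixed bias (phi > 0) can produce it.
* **outcome x presentation interaction** (informed channel): whether the
  follow/not-follow behavior repeats from trial n to n+1 more after rewarded
  than unrewarded trials, specifically when advice was shown on both trials.
  Only outcome-driven advice-value learning (omega < 1) can produce it.

Population-level estimates come from logistic regressions with a random
intercept per subject, fit by variational Bayes (statsmodels
``BinomialBayesMixedGLM``); estimates are posterior means with Gaussian
approximate intervals (default 89%) and the probability of direction (pd),
the posterior mass on the modal sign.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .fitting import PopulationSpec
from .models import AgentParams
from .task import TaskConfig, lesion_params, simulate_dataset


@dataclass(frozen=True)
class EffectEstimate:
    """A regression coefficient (log-odds) with interval and pd."""

    estimate: float
    ci_low: float
    ci_high: float
    pd: float
    sd: float
    level: float = 0.89
    n_obs: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SignatureReport:
    """Signature analyses of one dataset (empirical or lesioned simulation)."""

    label: str
    reveal_effect: Optional[EffectEstimate] = None
    first_encounter: Optional[EffectEstimate] = None
    coherence_repeat_interaction: Optional[EffectEstimate] = None
    per_subject_reveal: Optional[pd.Series] = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"label": self.label, "notes": self.notes}
        for name in ("reveal_effect", "first_encounter", "coherence_repeat_interaction"):
            est = getattr(self, name)
            d[name] = est.to_dict() if est is not None else None
        if self.per_subject_reveal is not None:
            d["per_subject_reveal"] = {
                str(k): float(v) for k, v in self.per_subject_reveal.items()
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def coherence_column(trials: pd.DataFrame) -> pd.Series:
    """Per-trial 0/1: did the participant choose the teacher's card?

    Defined on revealed *and* concealed trials (the teacher always picks,
    the pick is just hidden on concealed trials).  Rows with a missing
    choice are excluded.
    """
    ok = trials["choice"].notna()
    t = trials[ok]
    return (t["choice"].astype(int) == t["advised_card"].astype(int)).astype(int)


def _mixed_logit(
    df: pd.DataFrame,
    formula: str,
    coef: str,
    level: float = 0.89,
) -> EffectEstimate:
    """Random-intercept logistic regression; returns one coefficient.

    Variational Bayes posterior; interval and pd from the Gaussian
    approximation.  A degenerate outcome (no variation) yields a flagged
    zero-information estimate instead of an error.
    """
    y = df[formula.split("~")[0].strip()]
    if y.nunique() < 2:
        return EffectEstimate(
            estimate=0.0, ci_low=0.0, ci_high=0.0, pd=0.5, sd=np.inf,
            level=level, n_obs=len(df), degenerate=True,
        )
    model = BinomialBayesMixedGLM.from_formula(
        formula, {"subject": "0 + C(subject)"}, df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the VB optimizer draws internal Monte Carlo samples from the legacy
        # global RNG; pin it so identical inputs give identical estimates
        state = np.random.get_state()
        np.random.seed(20240117)
        try:
            fit = model.fit_vb()
        finally:
            np.random.set_state(state)
    names = list(fit.model.exog_names)
    i = names.index(coef)
    est = float(fit.fe_mean[i])
    sd = float(fit.fe_sd[i])
    z = stats.norm.ppf(0.5 + level / 2.0)
    pdir = float(stats.norm.cdf(abs(est) / sd)) if sd > 0 else 1.0
    return EffectEstimate(
        estimate=est,
        ci_low=est - z * sd,
        ci_high=est + z * sd,
        pd=pdir,
        sd=sd,
        level=level,
        n_obs=len(df),
    )


def _with_coherence(dataset: pd.DataFrame) -> pd.DataFrame:
    df = dataset[dataset["choice"].notna()].copy()
    df["coherence"] = (
        df["choice"].astype(int) == df["advised_card"].astype(int)
    ).astype(int)
    df["revealed"] = df["revealed"].astype(int)
    return df


def reveal_effect(
    dataset: pd.DataFrame,
    level: str = "population",
    ci_level: float = 0.89,
):
    """Advice's effect on coherence, per subject or at the population level.

    ``level="subject"``: per-subject difference in coherence proportion,
    p(coherence | revealed) - p(coherence | concealed); subjects missing a
    condition are dropped with a warning.  ``level="population"``: logistic
    regression of coherence on advice presentation with subject random
    intercepts (log-odds estimate, interval, pd).
    """
    df = _with_coherence(dataset)
    if level == "subject":
        rates = (
            df.groupby(["subject", "revealed"])["coherence"].mean().unstack("revealed")
        )
        missing = rates.index[rates.isna().any(axis=1)]
        if len(missing):
            warnings.warn(
                f"{len(missing)} subject(s) lack one condition and were dropped",
                RuntimeWarning,
            )
            rates = rates.dropna()
        return (rates[1] - rates[0]).rename("reveal_effect")
    if level != "population":
        raise ValueError(f"unknown level {level!r}")
    return _mixed_logit(df, "coherence ~ revealed", "revealed", level=ci_level)


def test_retest(
    dataset: pd.DataFrame,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    ci_level: float = 0.89,
) -> EffectEstimate:
    """Correlation of standardized per-subject reveal effects across sessions.

    Pearson correlation of the session-1 versus session-2 subject reveal
    effects (each standardized within session), with a bootstrap-over-
    subjects interval.
    """
    sessions = sorted(dataset["session"].unique())
    if len(sessions) < 2:
        raise ValueError("test-retest requires two sessions")
    per_session = {}
    for s in sessions[:2]:
        eff = reveal_effect(dataset[dataset["session"] == s], level="subject")
        per_session[s] = (eff - eff.mean()) / eff.std(ddof=1)
    both = pd.concat(per_session, axis=1).dropna()
    if len(both) < 3:
        raise ValueError("fewer than 3 subjects with both sessions")
    x = both.iloc[:, 0].to_numpy()
    y = both.iloc[:, 1].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(xb, yb)[0, 1]
    boots = boots[np.isfinite(boots)]
    lo, hi = np.quantile(boots, [0.5 - ci_level / 2, 0.5 + ci_level / 2])
    pdir = float(max(np.mean(boots > 0), np.mean(boots < 0)))
    return EffectEstimate(
        estimate=r, ci_low=float(lo), ci_high=float(hi), pd=pdir,
        sd=float(np.std(boots)), level=ci_level, n_obs=n,
    )


def _first_encounter_rows(dataset: pd.DataFrame) -> pd.DataFrame:
    """First concealed and first revealed trial of every subject x block."""
    df = _with_coherence(dataset).sort_values(
        ["subject", "session", "block", "trial"], kind="mergesort"
    )
    return (
        df.groupby(["subject", "session", "block", "revealed"], as_index=False)
        .first()
    )


def first_encounter_effect(
    dataset: pd.DataFrame, ci_level: float = 0.89
) -> EffectEstimate:
    """Reveal effect restricted to each block's very first encounters.

    Each block contributes at most two trials: the first concealed and the
    first revealed one.  With a brand-new teacher every block, advice-value
    learning cannot yet have moved; a reveal effect here is the signature of
    the fixed bias (non-informed advice-taking).
    """
    rows = _first_encounter_rows(dataset)
    if rows.empty:
        raise ValueError("no eligible first-encounter trials")
    return _mixed_logit(rows, "coherence ~ revealed", "revealed", level=ci_level)


def _pair_rows(dataset: pd.DataFrame) -> pd.DataFrame:
    """Consecutive same-block trial pairs with identical advice presentation.

    Per pair (n, n+1): whether the follow/not-follow behavior repeated, the
    outcome of trial n, the (shared) presentation condition, and the
    teacher-accuracy covariate of trial n.
    """
    df = _with_coherence(dataset).sort_values(
        ["subject", "session", "block", "trial"], kind="mergesort"
    )
    df["follow"] = df["coherence"]
    g = df.groupby(["subject", "session", "block"])
    nxt = g.shift(-1)
    same_block = nxt["follow"].notna()
    same_presentation = df["revealed"] == nxt["revealed"]
    consecutive = (nxt["trial"] - df["trial"]) == 1
    keep = same_block & same_presentation & consecutive
    if "teacher_correct" in df.columns:
        teacher_acc = df["teacher_correct"].astype(float)
    else:
        # empirical fallback: per-block proxy, the mean reward obtained on
        # followed revealed trials of that block
        followed = (df["follow"] == 1) & (df["revealed"] == 1)
        proxy = (
            df[followed]
            .groupby(["subject", "session", "block"])["reward"]
            .mean()
            .rename("teacher_acc")
        )
        teacher_acc = (
            df.join(proxy, on=["subject", "session", "block"])["teacher_acc"]
            .fillna(0.5)
        )
    out = pd.DataFrame(
        {
            "subject": df["subject"],
            "repeat": (df["follow"] == nxt["follow"]).astype(int),
            "prev_reward": df["reward"].astype(float),
            "revealed": df["revealed"].astype(int),
            "teacher_acc": teacher_acc,
        }
    )[keep.to_numpy()]
    return out.reset_index(drop=True)


def coherence_repeat_interaction(
    dataset: pd.DataFrame, ci_level: float = 0.89
) -> EffectEstimate:
    """Previous-outcome x presentation interaction on coherence repetition.

    Predicts whether follow/not-follow behavior repeats from trial n to n+1
    (same block, same presentation on both trials) from the trial-n outcome,
    the presentation condition, and their interaction, controlling for the
    teacher's trial-n accuracy as a main effect; subject random intercepts.
    A positive interaction -- reward helps repetition only when advice is
    shown -- is the signature of informed advice-taking.
    """
    rows = _pair_rows(dataset)
    if rows.empty:
        raise ValueError("no eligible consecutive-trial pairs")
    return _mixed_logit(
        rows,
        "repeat ~ prev_reward * revealed + teacher_acc",
        "prev_reward:revealed",
        level=ci_level,
    )


def double_dissociation_suite(
    params_per_subject: Sequence[AgentParams],
    cfg: TaskConfig,
    seed: Optional[int] = None,
    reference_dataset: Optional[pd.DataFrame] = None,
    ci_level: float = 0.89,
) -> dict[str, SignatureReport]:
    """Run both signatures on lesioned simulations (and a reference dataset).

    Simulates an ``informed_only`` population (phi = 0: only advice-value
    learning active) and a ``non_informed_only`` population (omega = 1: only
    the fixed bias active) from the given per-subject parameters under model
    5, then computes the first-encounter effect and the outcome x
    presentation interaction on each.  If a reference dataset (empirical or
    full-model simulation) is supplied it is analyzed identically under the
    label ``"reference"``.  The expected double dissociation: the
    first-encounter effect appears only where phi is active, the interaction
    only where omega < 1 is active.
    """
    ss = np.random.SeedSequence(seed)
    sim_seeds = {m: int(c.generate_state(1)[0] % (2**31 - 1))
                 for m, c in zip(("informed_only", "non_informed_only"), ss.spawn(2))}
    reports: dict[str, SignatureReport] = {}
    datasets: dict[str, pd.DataFrame] = {}
    if reference_dataset is not None:
        datasets["reference"] = reference_dataset
    for mode in ("informed_only", "non_informed_only"):
        lesioned = [lesion_params(p, mode) for p in params_per_subject]
        datasets[mode] = simulate_dataset(5, lesioned, cfg, seed=sim_seeds[mode])
    for label, data in datasets.items():
        report = SignatureReport(label=label)
        report.per_subject_reveal = reveal_effect(data, level="subject")
        report.reveal_effect = reveal_effect(data, level="population", ci_level=ci_level)
        report.first_encounter = first_encounter_effect(data, ci_level=ci_level)
        report.coherence_repeat_interaction = coherence_repeat_interaction(
            data, ci_level=ci_level
        )
        if label == "non_informed_only" and all(
            abs(p.phi) < 1e-12 for p in params_per_subject
        ):
            report.notes.append(
                "phi is zero everywhere: the non-informed lesion retains no "
                "advice channel and shows no reveal bias by construction"
            )
        reports[label] = report
    return reports
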