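"""Trial-table interchange (CSV), validation, and preprocessing filters.

The trial table is the single interchange format for empirical and
synthetic data: one row per choice trial with columns subject, session,
block, trial, offer_a, offer_b, advised_card, revealed, choice, reward, rt
(milliseconds; may be empty for synthetic data).  Card and trial indices
are 0-based internally; 1-based sources can be remapped on import.

Preprocessing mirrors common practice for online choice data: trials with
implausibly fast or slow reaction times are dropped, subjects losing more
than a set fraction of trials that way are excluded, and subjects pressing
one key on nearly every trial are flagged as unengaged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .task import TRIAL_COLUMNS

REQUIRED_COLUMNS = TRIAL_COLUMNS

_INDEX_COLUMNS = ["offer_a", "offer_b", "advised_card", "choice"]


class SchemaError(ValueError):
    """The table does not conform to the trial-table schema."""


def validate_trials(df: pd.DataFrame) -> None:
    """Raise SchemaError on structural problems; list offending rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    ok = df["choice"].notna()
    choice = df.loc[ok, "choice"].astype(int)
    in_offer = (choice == df.loc[ok, "offer_a"].astype(int)) | (
        choice == df.loc[ok, "offer_b"].astype(int)
    )
    if not in_offer.all():
        bad = df.index[ok][~in_offer].tolist()
        raise SchemaError(f"choice outside offered pair at rows {bad[:20]}")
    adv_in = (df["advised_card"] == df["offer_a"]) | (df["advised_card"] == df["offer_b"])
    if not adv_in.all():
        bad = df.index[~adv_in].tolist()
        raise SchemaError(f"advised card outside offered pair at rows {bad[:20]}")
    same = df["offer_a"] == df["offer_b"]
    if same.any():
        raise SchemaError(f"offer repeats a card at rows {df.index[same].tolist()[:20]}")


def read_trials_csv(path, one_based: bool = False) -> pd.DataFrame:
    """Read and validate a trial table; optionally remap 1-based card indices."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if one_based:
        for col in _INDEX_COLUMNS:
            df[col] = df[col] - 1
    validate_trials(df)
    return df


def write_trials_csv(df: pd.DataFrame, path) -> None:
    """Write a trial table; canonical columns first, extras preserved."""
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df[REQUIRED_COLUMNS + extras].to_csv(path, index=False)


def import_deposit(path, column_map: dict[str, str], one_based: bool = True) -> pd.DataFrame:
    """Adapter for externally deposited datasets with different column names.

    ``column_map`` maps source column names to the schema's names; remaining
    columns are preserved as extras.  Defaults to remapping 1-based indices.
    """
    df = pd.read_csv(path).rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"column_map leaves required column(s) unmapped: {', '.join(missing)}"
        )
    if one_based:
        for col in _INDEX_COLUMNS:
            df[col] = df[col] - 1
    validate_trials(df)
    return df


@dataclass
class PreprocessReport:
    """Accounting of the preprocessing filters."""

    n_trials_in: int
    n_trials_removed_rt: int
    fraction_removed_rt: float
    subjects_excluded_rt: list = field(default_factory=list)
    subjects_flagged_key_repeat: list = field(default_factory=list)
    n_subjects_out: int = 0
    n_trials_out: int = 0
    rt_filter_applied: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess(
    dataset: pd.DataFrame,
    rt_min: float = 200.0,
    rt_max: float = 4000.0,
    max_excluded_fraction: float = 0.25,
    key_repeat_threshold: float = 0.90,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply reaction-time and engagement filters.

    Removes trials with rt outside [rt_min, rt_max] ms; excludes subjects
    whose removed-trial fraction exceeds ``max_excluded_fraction``; flags
    (does not drop) subjects repeating one response key on more than
    ``key_repeat_threshold`` of trials.  Key repetition uses a ``key``
    column when present, else the chosen screen side.  Datasets without
    recorded RTs pass through untouched, reported as such.
    """
    if not 0 < max_excluded_fraction < 1 or not 0 < key_repeat_threshold < 1:
        raise ValueError("exclusion thresholds must lie in (0, 1)")
    if rt_min < 0 or rt_max <= rt_min:
        raise ValueError("require 0 <= rt_min < rt_max")
    n_in = len(dataset)
    report = PreprocessReport(n_trials_in=n_in, n_trials_removed_rt=0, fraction_removed_rt=0.0)

    if "rt" not in dataset.columns or dataset["rt"].isna().all():
        report.rt_filter_applied = False
        out = dataset.copy()
    else:
        bad_rt = dataset["rt"].notna() & ~dataset["rt"].between(rt_min, rt_max)
        removed_frac = bad_rt.groupby(dataset["subject"]).mean()
        excluded = removed_frac.index[removed_frac > max_excluded_fraction].tolist()
        out = dataset[~bad_rt & ~dataset["subject"].isin(excluded)].copy()
        report.n_trials_removed_rt = int(bad_rt.sum())
        report.fraction_removed_rt = float(bad_rt.mean())
        report.subjects_excluded_rt = excluded

    if "key" in out.columns:
        key_stream = out["key"]
    else:
        key_stream = (out["choice"] == out["offer_b"]).astype(int).where(out["choice"].notna())
    top_key_frac = key_stream.groupby(out["subject"]).agg(
        lambda s: s.value_counts(normalize=True).iloc[0] if s.notna().any() else 0.0
    )
    report.subjects_flagged_key_repeat = top_key_frac.index[
        top_key_frac > key_repeat_threshold
    ].tolist()

    report.n_subjects_out = int(out["subject"].nunique())
    report.n_trials_out = len(out)
    return out.reset_index(drop=True), report


def run_manifest(path, config: dict, seed: Optional[int], inputs: list = ()) -> None:
    """Write a JSON manifest of a pipeline run (config, seed, input hashes)."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
    }
    for p in inputs:
        p = Path(p)
        if p.exists():
            manifest["inputs"][str(p)] = hashlib.md5(p.read_bytes()).hexdigest()
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
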