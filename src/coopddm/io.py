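"""CSV schemas and round-trip helpers for trial logs, profiles and likability
tables.  Missing values (invalid responses) are encoded as the literal token
``NA``; columns are matched by name so column order is free on input."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import Choice, Trial

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "trials_to_frame",
    "write_trials",
    "read_trials",
    "write_table",
    "read_profiles",
    "read_likability",
]

TRIAL_COLUMNS = [
    "subject_id", "session_index", "stim_condition", "trial_index",
    "opponent_id", "opponent_class", "opponent_policy", "decision_order",
    "subject_choice", "opponent_choice", "subject_rt_s", "opponent_rt_s",
    "points_subject", "cumulative_points", "valid",
]

PROFILE_REQUIRED = ["subject_id", "age", "sex", "neo_neuroticism", "neo_extraversion"]
LIKABILITY_COLUMNS = ["subject_id", "session_index", "opponent_id", "opponent_class", "sam_likability"]

NA = "NA"


class SchemaError(ValueError):
    """A table does not match its published schema."""


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "subject_id": t.subject_id,
            "session_index": t.session_index,
            "stim_condition": t.stim_condition,
            "trial_index": t.trial_index,
            "opponent_id": t.opponent_id,
            "opponent_class": t.opponent_class,
            "opponent_policy": t.opponent_policy,
            "decision_order": t.decision_order,
            "subject_choice": t.subject_choice.value if t.subject_choice is not None else np.nan,
            "opponent_choice": t.opponent_choice.value,
            "subject_rt_s": t.subject_rt if t.subject_rt is not None else np.nan,
            "opponent_rt_s": t.opponent_rt,
            "points_subject": t.points_subject,
            "cumulative_points": t.cumulative_points,
            "valid": t.valid,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, TRIAL_COLUMNS, "trial log")
    df = df[TRIAL_COLUMNS].copy()  # fixed header order on output
    bad = ~df["subject_choice"].isin(["cooperate", "deceive"]) & df["subject_choice"].notna()
    if bad.any():
        raise SchemaError(
            f"unknown subject_choice values: {sorted(df.loc[bad, 'subject_choice'].unique())}"
        )
    rts = df.loc[df["subject_rt_s"].notna(), "subject_rt_s"]
    if (rts <= 0).any():
        raise SchemaError("subject_rt_s must be positive where present")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    validate_trials(df).to_csv(path, index=False, na_rep=NA, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    df = validate_trials(df)
    df["valid"] = df["valid"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=NA, encoding="utf-8")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    _check_columns(df, PROFILE_REQUIRED, "profiles table")
    return df


def read_likability(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    _check_columns(df, LIKABILITY_COLUMNS, "likability table")
    return df
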