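"""Tidy CSV schemas and validation.

Bandit rows:  subject, session, trial, choice (1..4), reward {0,1},
              punishment {-1,0}.
Gamble rows:  subject, session, trial, phase {training, calibrated},
              trial_type {mixed, gain}, sure_amount, gamble_gain,
              gamble_loss, gambled {0,1}.
Truth rows:   subject, session, task, param, latent, value.

CSV dialect: comma-separated, UTF-8, header row, missing values as empty
cells; trial and arm indices are 1-based.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ValidationError", "read_bandit_csv", "read_gamble_csv",
           "read_truth_csv", "write_csv", "validate_bandit", "validate_gamble"]

BANDIT_COLUMNS = ["subject", "session", "trial", "choice", "reward", "punishment"]
GAMBLE_COLUMNS = ["subject", "session", "trial", "phase", "trial_type",
                  "sure_amount", "gamble_gain", "gamble_loss", "gambled"]


class ValidationError(ValueError):
    """Schema violation; the message names the offending row and column."""


def _require_columns(df, cols, what):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns: {missing}")


def _check_in(df, col, allowed, what):
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"{what} row {row}: column '{col}' has value {df[col][bad].iloc[0]!r}, "
            f"expected one of {sorted(allowed)}")


def validate_bandit(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, BANDIT_COLUMNS, "bandit")
    _check_in(df, "choice", {1, 2, 3, 4}, "bandit")
    _check_in(df, "reward", {0, 1}, "bandit")
    _check_in(df, "punishment", {-1, 0}, "bandit")
    _check_in(df, "session", {1, 2}, "bandit")
    return df


def validate_gamble(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, GAMBLE_COLUMNS, "gamble")
    _check_in(df, "session", {1, 2}, "gamble")
    _check_in(df, "phase", {"training", "calibrated"}, "gamble")
    _check_in(df, "trial_type", {"mixed", "gain"}, "gamble")
    _check_in(df, "gambled", {0, 1}, "gamble")
    mixed = df[df.trial_type == "mixed"]
    bad = mixed[(mixed.gamble_loss >= 0) | (mixed.sure_amount != 0)]
    if len(bad):
        raise ValidationError(
            f"gamble row {int(bad.index[0])}: mixed trials need gamble_loss < 0 "
            "and sure_amount == 0")
    gain = df[df.trial_type == "gain"]
    bad = gain[(gain.gamble_loss != 0) | (gain.sure_amount <= 0)]
    if len(bad):
        raise ValidationError(
            f"gamble row {int(bad.index[0])}: gain trials need gamble_loss == 0 "
            "and sure_amount > 0")
    return df


def read_bandit_csv(path) -> pd.DataFrame:
    return validate_bandit(pd.read_csv(path))


def read_gamble_csv(path) -> pd.DataFrame:
    return validate_gamble(pd.read_csv(path))


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject", "session", "task", "param", "value"], "truth")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")
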