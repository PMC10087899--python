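"""Wear-validity filtering and person-level aggregation of daily records.

A wear day is valid when it carries at least 10 h (600 min) of waking wear
time; persons contribute to analysis only with at least 4 valid days.
Person-level behavior values are arithmetic means of daily minutes over the
valid days.  Sleep (time in bed, log-based) is part of every day regardless
of waking wear validity, so the behavior means still add up to the mean day
length.  Zeros in person-level behaviors break every log-ratio operation
downstream; the default is to fail loudly, with a half-minimum replacement
strategy available opt-in.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .composition import PARTS

logger = logging.getLogger(__name__)

MIN_WEAR_MINUTES = 600.0  # 10 h of waking wear
MIN_VALID_DAYS = 4


def flag_valid_days(daily: pd.DataFrame) -> pd.Series:
    """Boolean flag per daily record: waking wear time >= 10 h."""
    wear = daily["wear_minutes"]
    if (wear < 0).any():
        bad = daily.loc[wear < 0, "person_id"].tolist()
        raise ValueError(f"negative wear minutes for persons {bad[:5]}")
    return wear >= MIN_WEAR_MINUTES


def aggregate_persons(daily: pd.DataFrame,
                      flags: pd.Series | None = None,
                      persons: pd.DataFrame | None = None,
                      min_valid_days: int = MIN_VALID_DAYS) -> pd.DataFrame:
    """Aggregate valid days to person-level means; drop under-observed persons.

    Returns a person table with mean minutes/day per behavior over valid days,
    mean day length, and n_valid_days, merged with `persons` covariates when
    given.  Persons with fewer than `min_valid_days` valid days are dropped
    and logged.
    """
    if daily.empty:
        logger.warning("aggregate_persons: empty daily input")
        return pd.DataFrame(columns=["person_id", *PARTS,
                                     "day_length_minutes", "n_valid_days"])
    if flags is None:
        flags = flag_valid_days(daily)
    valid = daily.loc[np.asarray(flags, dtype=bool)]
    counts = valid.groupby("person_id").size()
    keep = counts[counts >= min_valid_days].index
    dropped = sorted(set(daily["person_id"]) - set(keep))
    if dropped:
        logger.info("aggregate_persons: dropped %d persons with < %d valid days",
                    len(dropped), min_valid_days)
    agg = (valid[valid["person_id"].isin(keep)]
           .groupby("person_id")[[*PARTS, "day_length_minutes"]]
           .mean())
    agg["n_valid_days"] = counts.loc[agg.index]
    agg = agg.reset_index()
    if persons is not None:
        agg = agg.merge(persons, on="person_id", how="left")
    return agg


def impute_zeros(person_table: pd.DataFrame,
                 strategy: str = "fail") -> pd.DataFrame:
    """Handle zero behavior values in a person table.

    strategy="fail" raises on any zero, naming person and behavior.
    strategy="half_min_positive" replaces each zero with half the smallest
    positive observed value of that behavior across persons, then rescales
    that person's four behaviors so the day length is preserved.  Replacing
    zeros with a fixed small value distorts the composition, so this remains
    opt-in.
    """
    if strategy not in {"fail", "half_min_positive"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    table = person_table.copy()
    X = table[list(PARTS)].to_numpy(dtype=float)
    zero_mask = X == 0
    if not zero_mask.any():
        return table
    if strategy == "fail":
        i, j = np.argwhere(zero_mask)[0]
        raise ValueError(
            f"zero {PARTS[j]} time for person "
            f"{table['person_id'].iloc[i]!r}; rerun with "
            f"strategy='half_min_positive' or drop the person"
        )
    day_len = X.sum(axis=1)
    for j, part in enumerate(PARTS):
        col = X[:, j]
        if not (col > 0).any():
            raise ValueError(f"behavior {part!r} is zero for every person; "
                             "unrecoverable")
        fill = col[col > 0].min() / 2.0
        col[col == 0] = fill
    X = X / X.sum(axis=1, keepdims=True) * day_len[:, None]
    table[list(PARTS)] = X
    n = int(zero_mask.any(axis=1).sum())
    logger.info("impute_zeros: replaced zeros for %d persons (half-minimum)", n)
    return table
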