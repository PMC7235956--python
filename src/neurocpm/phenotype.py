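"""NEO-FFI scoring and cohort phenotype-table loading.

The five-factor inventory has 60 items, 12 per factor, answered on a
five-point Likert scale coded strongly disagree = 0 through strongly
agree = 4.  Designated items are reverse coded (they contribute 4 - raw),
and each factor total is the plain sum of its 12 item scores, so totals are
integers in [0, 48].  The item-to-factor key (including which items are
reversed) is a copyrighted part of the instrument and must be supplied by
the user as a CSV with columns ``item_id``, ``factor``, ``reverse``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from neurocpm.errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FACTORS",
    "LIKERT_CODES",
    "load_cohort",
    "load_item_key",
    "score_neo_ffi",
]

FACTORS = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")

LIKERT_CODES = {
    "strongly disagree": 0,
    "disagree": 1,
    "neither agree nor disagree": 2,
    "agree": 3,
    "strongly agree": 4,
}

ITEMS_PER_FACTOR = 12
N_ITEMS = 60


def load_item_key(key) -> pd.DataFrame:
    """Validate an item key (path, or DataFrame) covering all 60 items.

    Returns a DataFrame indexed by ``item_id`` (1-60) with columns
    ``factor`` and ``reverse`` (bool); requires exactly 12 items per factor.
    """
    if not isinstance(key, pd.DataFrame):
        key = pd.read_csv(key)
    required = {"item_id", "factor", "reverse"}
    missing = required - set(key.columns)
    if missing:
        raise InvalidInputError(f"item key lacks columns {sorted(missing)}")
    key = key.copy()
    key["item_id"] = key["item_id"].astype(int)
    key["factor"] = key["factor"].astype(str).str.strip().str.lower()
    key["reverse"] = key["reverse"].astype(bool)
    if sorted(key["item_id"]) != list(range(1, N_ITEMS + 1)):
        raise InvalidInputError(f"item key must cover item_ids 1..{N_ITEMS} exactly once")
    unknown = set(key["factor"]) - set(FACTORS)
    if unknown:
        raise InvalidInputError(f"unknown factors in item key: {sorted(unknown)}")
    counts = key["factor"].value_counts()
    bad = {f: int(counts.get(f, 0)) for f in FACTORS if counts.get(f, 0) != ITEMS_PER_FACTOR}
    if bad:
        raise InvalidInputError(
            f"each factor needs exactly {ITEMS_PER_FACTOR} items; got {bad}"
        )
    return key.set_index("item_id").sort_index()


def _coerce_response(value):
    """Map one Likert answer (label or 0-4 code) to its integer code; NaN if missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        label = value.strip().lower()
        if label in LIKERT_CODES:
            return LIKERT_CODES[label]
        try:
            value = float(label)
        except ValueError:
            raise InvalidInputError(f"unrecognized Likert answer {value!r}") from None
    code = float(value)
    if code != int(code) or not 0 <= code <= 4:
        raise InvalidInputError(f"Likert code must be an integer in 0..4, got {value!r}")
    return int(code)


def score_neo_ffi(responses: pd.DataFrame, key) -> tuple[pd.DataFrame, pd.Series]:
    """Score item-level NEO-FFI responses into the five factor totals.

    Parameters
    ----------
    responses
        One row per subject, one column per item named ``item_1`` ..
        ``item_60`` (or plain integers 1-60); entries are Likert labels or
        integer codes 0-4.  Missing entries are allowed but flag the subject
        for exclusion.
    key
        Item key accepted by :func:`load_item_key`.

    Returns
    -------
    (scores, excluded)
        ``scores``: one row per subject with one integer column per factor;
        rows of excluded subjects contain pandas NA.  ``excluded``: boolean
        Series marking subjects with any missing item.
    """
    key = load_item_key(key)

    def item_col(i: int):
        for cand in (f"item_{i}", i, str(i)):
            if cand in responses.columns:
                return cand
        raise InvalidInputError(f"responses lack a column for item {i}")

    coded = np.full((len(responses), N_ITEMS), np.nan)
    for i in range(1, N_ITEMS + 1):
        col = responses[item_col(i)]
        coded[:, i - 1] = [_coerce_response(v) for v in col]

    reverse = key["reverse"].to_numpy()
    scored = np.where(reverse[None, :], 4 - coded, coded)
    excluded = pd.Series(np.isnan(coded).any(axis=1), index=responses.index, name="excluded")
    if excluded.any():
        logger.info("score_neo_ffi: %d subject(s) flagged for exclusion (missing items)",
                    int(excluded.sum()))
    scores = pd.DataFrame(index=responses.index)
    for factor in FACTORS:
        cols = (key["factor"] == factor).to_numpy()
        totals = scored[:, cols].sum(axis=1)
        scores[factor] = pd.array(
            np.where(excluded, np.nan, totals), dtype="Int64"
        )
    return scores, excluded


def load_cohort(source, required: tuple[str, ...] = ("subject_id",),
                behavior_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Load and validate a cohort phenotype table.

    ``required`` columns must exist; rows with missing values in any column
    named in ``required`` or ``behavior_columns`` are dropped with a logged
    count.  Duplicate subject IDs are a hard error, as is an empty table.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if len(df) == 0:
        raise InvalidInputError("cohort table is empty")
    if "subject_id" not in df.columns:
        raise InvalidInputError("cohort table lacks a subject_id column")
    needed = list(dict.fromkeys(list(required) + list(behavior_columns)))
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(f"cohort table lacks required columns {missing_cols}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    if dupes.size:
        raise InvalidInputError(f"duplicate subject IDs: {dupes.tolist()}")
    complete = df[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("load_cohort: dropped %d incomplete row(s); %d subjects remain",
                    n_dropped, int(complete.sum()))
    out = df.loc[complete].reset_index(drop=True)
    if len(out) == 0:
        raise InvalidInputError("no complete rows remain after dropping missing values")
    return out
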