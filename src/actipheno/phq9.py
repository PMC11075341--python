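"""PHQ-9 scoring and depressive-symptom binarization.

The nine-item Patient Health Questionnaire scores each item 0-3; the total
(0-27) is dichotomized at the standard screening threshold of 10.  Records
with missing or out-of-range items are excluded listwise, never imputed, and
the association analysis additionally requires complete age, BMI, gender and
work-situation covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IncompleteRecordError

PHQ9_THRESHOLD = 10  # total >= this means depressive symptoms
PHQ9_ITEMS = [f"phq9_{k}" for k in range(1, 10)]
COVARIATE_COLUMNS = ["age", "bmi", "gender", "work"]


def score_phq9(items) -> int:
    """Sum the nine items; raises if any item is missing or outside {0,1,2,3}."""
    arr = np.asarray(items, dtype=float)
    if arr.shape != (9,):
        raise IncompleteRecordError(f"expected 9 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise IncompleteRecordError("missing item response")
    if not np.isin(arr, [0, 1, 2, 3]).all():
        raise IncompleteRecordError("item responses must be integers in 0..3")
    return int(arr.sum())


def classify_depression(total: int) -> bool:
    """True iff the total meets the screening threshold."""
    if not 0 <= total <= 27:
        raise IncompleteRecordError(f"total {total} outside 0..27")
    return total >= PHQ9_THRESHOLD


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant totals and depression flags; incomplete records get NA."""
    items = cohort[PHQ9_ITEMS].to_numpy(dtype=float)
    valid = (~np.isnan(items)).all(axis=1) & np.isin(np.nan_to_num(items, nan=-1), [0, 1, 2, 3]).all(
        axis=1
    )
    total = np.where(valid, np.nansum(items, axis=1), np.nan)
    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "phq9_total": total,
            "depressed": pd.array(
                np.where(valid, total >= PHQ9_THRESHOLD, None), dtype="boolean"
            ),
        }
    )
    return out


def filter_complete_cohort(
    cohort: pd.DataFrame, covariate_columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Complete-case subset: all nine items and all covariates present.

    Returns the retained rows (with phq9_total and depressed columns added)
    and a report of retained/excluded counts.
    """
    cov_cols = covariate_columns if covariate_columns is not None else COVARIATE_COLUMNS
    scored = score_cohort(cohort)
    merged = cohort.merge(scored, on="participant_id")
    complete_items = merged["phq9_total"].notna()
    complete_cov = merged[cov_cols].notna().all(axis=1)
    keep = complete_items & complete_cov
    retained = merged[keep].reset_index(drop=True)
    retained["phq9_total"] = retained["phq9_total"].astype(int)
    retained["depressed"] = retained["depressed"].astype(bool)
    report = {
        "input": int(len(merged)),
        "retained": int(keep.sum()),
        "excluded": int((~keep).sum()),
        "excluded_incomplete_phq9": int((~complete_items).sum()),
        "excluded_incomplete_covariates": int((complete_items & ~complete_cov).sum()),
    }
    return retained, report
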