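"""Pregnancy-incarceration exposure classification.

Every validated incarceration episode is classified against every pregnancy
window (estimated conception age to birth age, in days) into exactly one of
five temporal categories:

1. episode ended before conception;
2. episode started after the birth;
3. episode started after conception and ended before the birth;
4. episode started after conception and ended after the birth;
5. episode started, but had not ended, before conception.

A maternity with a non-zero count in category 3 or 4 is a prison pregnancy
(category 4 implies the birth happened in custody); counts only in 1 or 2
make it a prisoner-control maternity; any category-5 count means the
conception occurred in prison, which is implausible under a no-conjugal-
visit policy and censors the woman as a presumptive linkage error.  A
tolerance (days) absorbs inaccurate pregnancy dating from late or absent
antenatal presentation: an episode starting within ``tolerance`` days
before the estimated conception is treated as starting after it.
"""

from __future__ import annotations

from typing import Dict, Optional, Set

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._temporal import (
    STUDY_START,
    definitely_before,
    event_date_interval,
    feasible_birthdate_interval,
)
from .bundle import LinkedEventBundle

DEFAULT_TOLERANCE_DAYS = 14

CATEGORY_COLUMNS = ("c1", "c2", "c3", "c4", "c5")

TIMING_PATTERNS = (
    "during",
    "before_and_during",
    "after_and_during",
    "before_during_and_after",
    "before_only",
    "after_only",
    "before_and_after",
    "none",
)


def classify_episode(
    start: float,
    end: float,
    conception_age: float,
    birth_age: float,
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
) -> int:
    """Category (1-5) of one episode relative to one pregnancy.

    Boundary conventions (chosen so the five categories provably
    partition): category 1 iff end <= conception; else category 2 iff
    start > birth; else categories 3/4 iff start >= conception - tolerance
    (3 when end <= birth, 4 when end > birth); else category 5.
    """
    if np.isnan(start) or np.isnan(end) or start > end:
        raise ValueError(
            "invalid episode; inconsistent or incomplete episodes must be "
            "censored before classification"
        )
    if conception_age >= birth_age:
        raise ValueError("conception age must precede birth age")
    if end <= conception_age:
        return 1
    if start > birth_age:
        return 2
    if start >= conception_age - tolerance:
        return 3 if end <= birth_age else 4
    return 5


def classify_episodes(
    starts: np.ndarray,
    ends: np.ndarray,
    conception_age: float,
    birth_age: float,
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
) -> np.ndarray:
    """Vectorised episode categories for one pregnancy."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    cat = np.full(starts.shape, 5, dtype=int)
    in_window = starts >= conception_age - tolerance
    cat[in_window & (ends <= birth_age)] = 3
    cat[in_window & (ends > birth_age)] = 4
    cat[starts > birth_age] = 2
    cat[ends <= conception_age] = 1
    return cat


def _timing_pattern(c1: int, c2: int, during: int) -> str:
    if during:
        if c1 and c2:
            return "before_during_and_after"
        if c1:
            return "before_and_during"
        if c2:
            return "after_and_during"
        return "during"
    if c1 and c2:
        return "before_and_after"
    if c1:
        return "before_only"
    if c2:
        return "after_only"
    return "none"


def classify_maternity(
    conception_age: float,
    birth_age: float,
    starts: np.ndarray,
    ends: np.ndarray,
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
) -> Dict:
    """Category counts and derived status for one maternity."""
    cats = classify_episodes(starts, ends, conception_age, birth_age, tolerance)
    counts = {f"c{k}": int((cats == k).sum()) for k in range(1, 6)}
    if counts["c5"] >= 1:
        status = "censor_conception_in_prison"
    elif counts["c3"] + counts["c4"] >= 1:
        status = "prison_pregnancy"
    elif counts["c1"] + counts["c2"] >= 1:
        status = "prisoner_control"
    else:
        status = "community"
    return {
        **counts,
        "status": status,
        "birth_in_prison": counts["c4"] >= 1,
        "timing_pattern": _timing_pattern(
            counts["c1"], counts["c2"], counts["c3"] + counts["c4"]
        ),
    }


def classify_cohort(
    maternities: pd.DataFrame,
    episodes: pd.DataFrame,
    person_col: str = "person_id",
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
    skip_persons: Optional[Set] = None,
) -> pd.DataFrame:
    """Classify every maternity of every woman with valid episodes.

    Women in ``skip_persons`` (already censored for record-level errors,
    so their episodes cannot be trusted) are excluded.  Women with no
    episodes receive zero counts and community status.
    """
    skip = skip_persons or set()
    episode_groups = (
        dict(tuple(episodes.groupby(person_col))) if len(episodes) else {}
    )
    rows = []
    for pid, mats in maternities.groupby(person_col):
        if pid in skip:
            continue
        grp = episode_groups.get(pid)
        if grp is not None and len(grp):
            starts = grp["start_age_days"].to_numpy(dtype=float)
            ends = grp["end_age_days"].to_numpy(dtype=float)
        else:
            starts = ends = np.empty(0)
        for _, m in mats.iterrows():
            if np.isnan(m["conception_age_days"]):
                continue
            rec = classify_maternity(
                m["conception_age_days"],
                m["mother_age_days"],
                starts,
                ends,
                tolerance,
            )
            rows.append(
                {
                    person_col: pid,
                    "maternity_order": int(m["maternity_order"]),
                    **rec,
                }
            )
    cols = [person_col, "maternity_order", *CATEGORY_COLUMNS, "status",
            "birth_in_prison", "timing_pattern"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def assign_mother_status(
    classifications: pd.DataFrame, person_col: str = "person_id"
) -> pd.DataFrame:
    """Mother-level status from maternity-level classifications.

    A pregnant prisoner has at least one prison-pregnancy maternity; a
    prisoner control's maternities are all prisoner-control; a pregnant
    prisoner with both types is additionally her own control.  Women whose
    maternities carry a conception-in-prison flag are reported with status
    ``censored`` (their exclusion happens in the censoring step).
    """
    rows = []
    for pid, grp in classifications.groupby(person_col):
        statuses = set(grp["status"])
        if "censor_conception_in_prison" in statuses:
            status = "censored"
            own = False
        elif "prison_pregnancy" in statuses:
            status = "pregnant_prisoner"
            own = "prisoner_control" in statuses
        elif "prisoner_control" in statuses:
            status = "prisoner_control"
            own = False
        else:
            status = "community"
            own = False
        rows.append({person_col: pid, "status": status, "own_control": own})
    return pd.DataFrame(rows, columns=[person_col, "status", "own_control"])


def assign_index_maternity(
    mother_status: pd.DataFrame,
    classifications: pd.DataFrame,
    maternities: pd.DataFrame,
    person_col: str = "person_id",
    birth_intervals: Optional[Dict] = None,
) -> pd.DataFrame:
    """Select the single maternity representing each mother.

    Pregnant prisoners: the first maternity with a pregnancy incarceration.
    All other mothers: the first maternity in the study period (1 Jul 2000
    to 31 Dec 2006).  A year-2000 birth counts as in-period unless its
    feasible date interval proves it before 1 July.  Mothers with no
    maternity in the study period get a null index and are excluded from
    index-based analyses.
    """
    birth_intervals = birth_intervals or {}
    cls = classifications.set_index([person_col, "maternity_order"])
    out = mother_status.copy()
    index_orders = []
    for _, row in out.iterrows():
        pid = row[person_col]
        mats = maternities[maternities[person_col] == pid].sort_values(
            "maternity_order"
        )
        chosen = None
        if row["status"] == "pregnant_prisoner":
            for _, m in mats.iterrows():
                key = (pid, int(m["maternity_order"]))
                if key in cls.index and cls.loc[key, "status"] == "prison_pregnancy":
                    chosen = int(m["maternity_order"])
                    break
        else:
            for _, m in mats.iterrows():
                year = int(m["birth_year"])
                if year < 2000 or year > 2006:
                    continue
                if year == 2000:
                    iv = event_date_interval(
                        birth_intervals.get(pid), m["mother_age_days"]
                    )
                    if definitely_before(iv, STUDY_START):
                        continue
                chosen = int(m["maternity_order"])
                break
        index_orders.append(chosen)
    out["index_maternity_order"] = pd.array(index_orders, dtype="Int64")
    return out


class ExposureClassifier(BaseEstimator, TransformerMixin):
    """Transformer assigning pregnancy-incarceration exposure to a bundle.

    Parameters
    ----------
    tolerance : int, default 14
        Days of allowance for inaccurate pregnancy dating; an episode
        starting up to this many days before the estimated conception is
        not treated as a conception in prison.

    Attributes
    ----------
    classifications_ : DataFrame
        One row per classifiable maternity with c1..c5 counts, status,
        birth-in-prison flag and timing pattern.
    mother_status_ : DataFrame
        Mother-level status, own-control flag and index maternity.
    """

    def __init__(self, tolerance: int = DEFAULT_TOLERANCE_DAYS):
        self.tolerance = tolerance

    def fit(self, X: LinkedEventBundle, y=None) -> "ExposureClassifier":
        if X.maternities is None or X.decisions is None:
            raise ValueError("bundle lacks maternities/decisions; run earlier stages")
        key = X.person_key
        record_reasons = [
            c
            for c in X.decisions.columns
            if c not in (key, "conception_in_prison") and X.decisions[c].dtype == bool
        ]
        flagged = set(
            X.decisions.loc[X.decisions[record_reasons].any(axis=1), key]
        )
        self.classifications_ = classify_cohort(
            X.maternities,
            X.incarcerations,
            key,
            self.tolerance,
            skip_persons=flagged,
        )
        cip = set(
            self.classifications_.loc[
                self.classifications_["status"] == "censor_conception_in_prison", key
            ]
        )
        decisions = X.decisions.copy()
        decisions["conception_in_prison"] = decisions[key].isin(cip)
        self.decisions_ = decisions

        intervals = {
            pid: feasible_birthdate_interval(pairs)
            for pid, pairs in X.event_pairs_by_person().items()
        }
        status = assign_mother_status(self.classifications_, key)
        self.mother_status_ = assign_index_maternity(
            status, self.classifications_, X.maternities, key, intervals
        )
        return self

    def transform(self, X: LinkedEventBundle) -> LinkedEventBundle:
        if not hasattr(self, "classifications_"):
            raise RuntimeError("ExposureClassifier is not fitted")
        out = X.copy()
        out.classifications = self.classifications_.copy()
        out.mother_status = self.mother_status_.copy()
        out.decisions = self.decisions_.copy()
        out.meta["tolerance_days"] = self.tolerance
        return out
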