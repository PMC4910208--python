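"""Event-based to person-based record transformations.

Births collapse to maternities (one row per mother per birthing event; same
birth age with distinct baby references is a multiple birth, with an
identical baby reference a duplicate record).  Incarceration episodes pivot
to wide prisoner records with ordered episode slots ``start_age_1..N`` /
``end_age_1..N``, where N is the maximum episode count observed in the
population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bundle import LinkedEventBundle

#: Days from estimated conception back to the first day of the last
#: menstrual period (about 14) plus the part-week discarded by reporting
#: gestation in completed weeks (up to 6).
CONCEPTION_CORRECTION_DAYS = 17


def estimate_conception_age(mother_age_at_birth, gestational_age_weeks):
    """Estimated maternal age in days at conception.

    ``age_at_birth - gestation_weeks * 7 + 17``.  Gestation is measured
    from the last menstrual period (on average 14 days before conception)
    and reported in completed weeks (discounting up to 6 further days),
    hence the +17 day correction.  Missing gestation yields NaN, routing
    the maternity to missing-data handling rather than guessing a term.
    """
    age = np.asarray(mother_age_at_birth, dtype=float)
    gest = np.asarray(gestational_age_weeks, dtype=float)
    out = age - gest * 7 + CONCEPTION_CORRECTION_DAYS
    if out.ndim == 0:
        return float(out)
    return out


def births_to_maternities(
    births: pd.DataFrame, person_col: str = "person_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse birth events to one maternity per mother per birthing event.

    Returns ``(maternities, person_flags)``.  Births of one mother sharing
    the same ``mother_age_days`` are one maternity; plurality counts the
    distinct baby references.  A repeated baby reference at the same age is
    a duplicate birth record: one copy is kept and the woman is flagged for
    the quality audit.  Same-age births with differing recorded gestations
    are collapsed on age with a ``gestation_conflict`` warning flag.
    """
    if person_col not in births.columns:
        raise ValueError(f"births table lacks person column {person_col!r}")
    b = births.copy()

    dup_mask = b.duplicated(subset=[person_col, "mother_age_days", "baby_ref"])
    dup_persons = set(b.loc[dup_mask, person_col])
    b = b[~dup_mask]

    grouped = b.groupby([person_col, "mother_age_days"], sort=True)
    mat = grouped.agg(
        birth_year=("birth_year", "first"),
        gestation_weeks=("gestation_weeks", "first"),
        plurality=("baby_ref", "nunique"),
        n_gestations=("gestation_weeks", "nunique"),
    ).reset_index()
    conflict_persons = set(mat.loc[mat["n_gestations"] > 1, person_col])
    mat = mat.drop(columns="n_gestations")

    mat = mat.sort_values([person_col, "mother_age_days"], kind="mergesort")
    mat["maternity_order"] = mat.groupby(person_col).cumcount() + 1
    mat["conception_age_days"] = estimate_conception_age(
        mat["mother_age_days"], mat["gestation_weeks"]
    )
    mat = mat.rename(columns={"mother_age_days": "mother_age_days"})[
        [
            person_col,
            "maternity_order",
            "mother_age_days",
            "birth_year",
            "gestation_weeks",
            "conception_age_days",
            "plurality",
        ]
    ].reset_index(drop=True)

    persons = sorted(set(births[person_col]))
    flags = pd.DataFrame(
        {
            person_col: persons,
            "had_duplicate_birth": [p in dup_persons for p in persons],
            "gestation_conflict": [p in conflict_persons for p in persons],
        }
    )
    return mat, flags


def episodes_to_prisoner_records(
    episodes: pd.DataFrame, person_col: str = "person_id"
) -> pd.DataFrame:
    """Pivot incarceration episodes to wide per-prisoner records.

    Episodes are ordered by start age (ties by end age, ascending; exact
    ties are duplicates and survive into the record for the quality rules
    to flag).  Slot count N is the population maximum, computed from the
    data.  Missing bounds propagate as NaN in their slot.
    """
    if not len(episodes):
        return pd.DataFrame(columns=[person_col, "episode_count"])
    ep = episodes.copy()
    ep = ep.sort_values(
        [person_col, "start_age_days", "end_age_days"],
        kind="mergesort",
        na_position="last",
    )
    ep["slot"] = ep.groupby(person_col).cumcount() + 1
    n_max = int(ep["slot"].max())

    start = ep.pivot(index=person_col, columns="slot", values="start_age_days")
    end = ep.pivot(index=person_col, columns="slot", values="end_age_days")
    start.columns = [f"start_age_{i}" for i in start.columns]
    end.columns = [f"end_age_{i}" for i in end.columns]
    wide = pd.concat([start, end], axis=1)
    wide["episode_count"] = ep.groupby(person_col)["slot"].max()
    cols = (
        ["episode_count"]
        + [f"start_age_{i}" for i in range(1, n_max + 1)]
        + [f"end_age_{i}" for i in range(1, n_max + 1)]
    )
    return wide[cols].reset_index()


def prisoner_records_to_episodes(
    wide: pd.DataFrame, person_col: str = "person_id"
) -> pd.DataFrame:
    """Flatten wide prisoner records back to long (tidy) episodes."""
    slots = sorted(
        int(c.rsplit("_", 1)[1]) for c in wide.columns if c.startswith("start_age_")
    )
    rows = []
    for _, rec in wide.iterrows():
        for i in slots:
            if i <= rec["episode_count"]:
                rows.append(
                    (
                        rec[person_col],
                        rec[f"start_age_{i}"],
                        rec[f"end_age_{i}"],
                    )
                )
    return pd.DataFrame(rows, columns=[person_col, "start_age_days", "end_age_days"])


class PersonReshaper(BaseEstimator, TransformerMixin):
    """Transformer adding maternity and wide prisoner tables to a bundle.

    Attributes
    ----------
    n_slots_ : int
        Population-wide maximum episode count N (0 if no episodes).
    """

    def fit(self, X: LinkedEventBundle, y=None) -> "PersonReshaper":
        counts = (
            X.incarcerations.groupby(
                X.person_key if X.person_key in X.incarcerations.columns else "ppn"
            ).size()
            if len(X.incarcerations)
            else pd.Series(dtype=int)
        )
        self.n_slots_ = int(counts.max()) if len(counts) else 0
        return self

    def transform(self, X: LinkedEventBundle) -> LinkedEventBundle:
        out = X.copy()
        key = out.person_key
        births = out.births
        if key not in births.columns:
            raise ValueError(
                f"bundle not keyed by {key!r}; run IdentityResolver first"
            )
        out.maternities, out.person_flags = births_to_maternities(births, key)
        out.prisoner_records = episodes_to_prisoner_records(out.incarcerations, key)
        return out
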