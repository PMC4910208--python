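"""Quality rules and censoring for the linked cohort.

A woman's entire maternity history is censored when any of her linked
records are mutually inconsistent, since an error in one record cannot be
distinguished from a false-positive link and any such error can corrupt the
temporal relationships the exposure classification depends on.  The rules:

1. duplicated birth records;
2. implausibly many maternities (more than one in the Jun-Dec 2000 window,
   or a 3rd/5th/7th/9th/11th/13th maternity by the end of 2001..2006);
3. non-chronological maternities (completed years of age and calendar years
   advanced between successive births differ by more than one);
4. concurrent pregnancies (conception before, or less than 30 days after,
   the previous birth);
5. inconsistent incarceration data (overlapping, inverted or duplicated
   episodes);
6. missing incarceration bounds;
7. conception during incarceration (flagged by the exposure module).

Serious mental health morbidity (MHM) status, used to stratify the audit,
is defined by ICD-10 diagnosis code sets, a psychiatric-ward admission
flag, or an opiate-substitution authority.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._temporal import (
    WINDOW_2000_END,
    WINDOW_2000_START,
    completed_years,
    definitely_before,
    definitely_within,
    event_date_interval,
    feasible_birthdate_interval,
)
from .bundle import LinkedEventBundle

MATERNITY_REASONS = (
    "duplicated_births",
    "too_many_maternities",
    "non_chronological_maternities",
    "concurrent_maternities",
)
INCARCERATION_REASONS = ("inconsistent_incarceration", "missing_incarceration")
ALL_REASONS = MATERNITY_REASONS + INCARCERATION_REASONS + (
    "conception_in_prison",
    "missing_gestation",
)

#: Cumulative maternity-count thresholds: a 3rd maternity by the end of
#: 2001, a 5th by 2002, ... a 13th by 2006 is implausible.
TOO_MANY_THRESHOLDS = {2001: 3, 2002: 5, 2003: 7, 2004: 9, 2005: 11, 2006: 13}

STRATA = ("np_no_mhm", "np_mhm", "p_no_mhm", "p_mhm")
MARGINS = ("all_mhm", "all_prisoners", "all")


# ---------------------------------------------------------------------------
# Serious mental health morbidity classification
# ---------------------------------------------------------------------------

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


@dataclass(frozen=True)
class MhmCodeSets:
    """ICD-10 code sets defining serious mental health morbidity.

    Entries are either a range over three-character categories
    (``"F20-F99"``) or a code prefix (``"T40"`` covers T40.x, ``"Y87.0"``
    only Y87.0).  The psychiatric set excludes F10-F19 by construction;
    substance-related categories live in the drug and alcohol sets.
    """

    psychiatric: Tuple[str, ...] = ("F00-F09", "F20-F99")
    self_harm: Tuple[str, ...] = ("X60-X84", "Y10-Y19", "Y87.0", "Z91.5")
    drug: Tuple[str, ...] = ("F11-F19", "T40", "T42", "T43")
    alcohol: Tuple[str, ...] = (
        "E24.4", "F10", "G31.2", "G62.1", "G72.1", "I42.6", "K29.2", "K70",
        "K86.0", "O35.4", "R78.0", "T51", "X45", "X65", "Y15", "Y57.3",
        "Y90", "Y91", "Z50.2", "Z71.4", "Z72.1",
    )

    def categories(self) -> Dict[str, Tuple[str, ...]]:
        return {
            "psychiatric": self.psychiatric,
            "self_harm": self.self_harm,
            "drug": self.drug,
            "alcohol": self.alcohol,
        }


def _normalize_code(code: str) -> Optional[str]:
    c = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(c):
        return None
    return c


def _entry_matches(entry: str, code: str) -> bool:
    entry = entry.replace(".", "").upper()
    if "-" in entry:
        lo, hi = entry.split("-")
        if code[0] != lo[0]:
            return False
        num = int(code[1:3])
        return int(lo[1:3]) <= num <= int(hi[1:3])
    return code.startswith(entry)


def classify_mhm(
    codes: Iterable[str],
    psych_ward_flag: bool = False,
    ost_authority: bool = False,
    code_sets: MhmCodeSets = MhmCodeSets(),
) -> Tuple[bool, Set[str]]:
    """Classify one person's diagnosis codes and flags.

    Returns (is_mhm, matched category names).  Prefix matching means F20
    covers F20.x.  Unparseable codes are ignored with a warning.
    """
    matched: Set[str] = set()
    for raw in codes:
        code = _normalize_code(raw)
        if code is None:
            warnings.warn(f"ignoring unparseable diagnosis code {raw!r}", stacklevel=2)
            continue
        for name, entries in code_sets.categories().items():
            if any(_entry_matches(e, code) for e in entries):
                matched.add(name)
    if psych_ward_flag:
        matched.add("psych_ward")
    if ost_authority:
        matched.add("ost")
    return bool(matched), matched


def mhm_status_by_person(
    mh_admissions: pd.DataFrame,
    ost_authorities: pd.DataFrame,
    person_col: str = "person_id",
    code_sets: MhmCodeSets = MhmCodeSets(),
) -> Set:
    """Person ids meeting the MHM definition."""
    mhm: Set = set()
    ost_persons = set(ost_authorities[person_col]) if len(ost_authorities) else set()
    mhm |= ost_persons
    if len(mh_admissions):
        for pid, grp in mh_admissions.groupby(person_col):
            if pid in mhm:
                continue
            codes: List[str] = []
            for s in grp["diagnoses"].astype(str):
                codes.extend(c for c in s.split(";") if c)
            ward = bool(grp["psych_ward"].astype(bool).any())
            ok, _ = classify_mhm(codes, ward, False, code_sets)
            if ok:
                mhm.add(pid)
    return mhm


# ---------------------------------------------------------------------------
# Maternity history rules
# ---------------------------------------------------------------------------

def flag_too_many_maternities(
    maternities: pd.DataFrame, birth_interval: Optional[Tuple[int, int]] = None
) -> bool:
    """Implausibly many maternities for one woman.

    The Jun-Dec 2000 sub-window needs sub-year resolution the privacy model
    (age in days + year) lacks: a year-2000 maternity counts against the
    window only when its feasible date interval, reconstructed from all the
    woman's events, lies wholly inside it.  The cumulative thresholds count
    maternities from 2000 onward, excluding those provably before June 2000.
    """
    years = maternities["birth_year"].astype(int)
    ages = maternities["mother_age_days"].astype(int)

    in_window = 0
    counted_years: List[int] = []
    for age, year in zip(ages, years):
        if year < 2000:
            continue
        iv = event_date_interval(birth_interval, age) if year == 2000 else None
        if year == 2000:
            if definitely_within(iv, (WINDOW_2000_START, WINDOW_2000_END)):
                in_window += 1
            if definitely_before(iv, WINDOW_2000_START):
                continue
        counted_years.append(year)
    if in_window > 1:
        return True
    counted = np.array(counted_years)
    for year, threshold in TOO_MANY_THRESHOLDS.items():
        if (counted <= year).sum() >= threshold:
            return True
    return False


def flag_non_chronological(maternities: pd.DataFrame) -> bool:
    """Age in completed years and calendar years advanced disagree by > 1."""
    m = maternities.sort_values("mother_age_days")
    ages = [completed_years(a) for a in m["mother_age_days"]]
    years = list(m["birth_year"].astype(int))
    for i in range(len(ages) - 1):
        if abs((ages[i + 1] - ages[i]) - (years[i + 1] - years[i])) > 1:
            return True
    return False


def flag_concurrent(maternities: pd.DataFrame) -> bool:
    """Conception before, or less than 30 days after, the previous birth."""
    m = maternities.sort_values("mother_age_days")
    births = m["mother_age_days"].to_numpy(dtype=float)
    conceptions = m["conception_age_days"].to_numpy(dtype=float)
    for i in range(len(m) - 1):
        if np.isnan(conceptions[i + 1]):
            continue
        if conceptions[i + 1] < births[i] + 30:
            return True
    return False


# ---------------------------------------------------------------------------
# Incarceration rules
# ---------------------------------------------------------------------------

def validate_incarcerations(episodes: pd.DataFrame) -> Tuple[bool, bool]:
    """(inconsistent, missing) flags for one person's episodes.

    Episodes are half-open intervals [start, end): abutting episodes
    (release and same-day re-entry) do not overlap.  Inconsistent when any
    start exceeds its end, any episode is exactly duplicated, or any two
    episodes overlap.  Missing when any bound is absent.
    """
    starts = episodes["start_age_days"].to_numpy(dtype=float)
    ends = episodes["end_age_days"].to_numpy(dtype=float)
    missing = bool(np.isnan(starts).any() or np.isnan(ends).any())

    ok = ~(np.isnan(starts) | np.isnan(ends))
    s, e = starts[ok], ends[ok]
    if (s > e).any():
        return True, missing
    pairs = sorted(zip(s, e))
    seen = set()
    for i, (si, ei) in enumerate(pairs):
        if (si, ei) in seen:
            return True, missing
        seen.add((si, ei))
        if i and si < pairs[i - 1][1]:
            return True, missing
    return False, missing


# ---------------------------------------------------------------------------
# Decision assembly, censoring and the audit
# ---------------------------------------------------------------------------

def evaluate_quality(bundle: LinkedEventBundle) -> pd.DataFrame:
    """Evaluate the record-level rules for every woman with a maternity.

    Returns one row per person with one boolean column per reason; the
    conception-in-prison reason is left False here and set by the exposure
    stage, after which :func:`censor` applies the final exclusion.
    """
    if bundle.maternities is None or bundle.person_flags is None:
        raise ValueError("bundle lacks maternities; run PersonReshaper first")
    key = bundle.person_key
    intervals = {
        pid: feasible_birthdate_interval(pairs)
        for pid, pairs in bundle.event_pairs_by_person().items()
    }

    flags = bundle.person_flags.set_index(key)
    rows = []
    episode_groups = (
        dict(tuple(bundle.incarcerations.groupby(key)))
        if len(bundle.incarcerations)
        else {}
    )
    for pid, mat in bundle.maternities.groupby(key):
        rec = {key: pid}
        rec["duplicated_births"] = bool(flags.loc[pid, "had_duplicate_birth"])
        rec["too_many_maternities"] = flag_too_many_maternities(
            mat, intervals.get(pid)
        )
        rec["non_chronological_maternities"] = flag_non_chronological(mat)
        rec["concurrent_maternities"] = flag_concurrent(mat)
        rec["missing_gestation"] = bool(mat["conception_age_days"].isna().any())
        episodes = episode_groups.get(pid)
        if episodes is not None and len(episodes):
            inconsistent, missing = validate_incarcerations(episodes)
        else:
            inconsistent = missing = False
        rec["inconsistent_incarceration"] = inconsistent
        rec["missing_incarceration"] = missing
        rec["conception_in_prison"] = False
        rows.append(rec)
    decisions = pd.DataFrame(rows)
    if not len(decisions):
        decisions = pd.DataFrame(columns=[key, *ALL_REASONS])
    return decisions


def censor(
    decisions: pd.DataFrame, maternities: pd.DataFrame, person_col: str = "person_id"
) -> Tuple[pd.DataFrame, Set]:
    """Drop every maternity of every woman with any censoring reason."""
    d = decisions.copy()
    reason_cols = [c for c in ALL_REASONS if c in d.columns]
    d["censored"] = d[reason_cols].any(axis=1)
    censored_persons = set(d.loc[d["censored"], person_col])
    validated = maternities[~maternities[person_col].isin(censored_persons)]
    return validated.reset_index(drop=True), censored_persons


@dataclass
class CensoringAudit:
    """Stratified censoring audit (prisoner status x MHM status).

    ``counts`` has one row per reason (plus person-record, study-mother and
    censoring margin rows) and one column per stratum plus the all-MHM,
    all-prisoner and overall margins.  ``rates`` carries the matching
    per-1,000 rates and the censored percentages per 100.
    """

    counts: pd.DataFrame
    rates: pd.DataFrame
    censored_maternities: int
    censored_women: int

    def to_frame(self) -> pd.DataFrame:
        c = self.counts.add_suffix("_n")
        r = self.rates.add_suffix("_rate")
        return c.join(r)


def censoring_summary(total: int, validated: int) -> Tuple[int, float]:
    """Censored count and percentage (one decimal) from stratum margins."""
    if validated > total:
        raise ValueError("validated count exceeds total")
    censored = total - validated
    pct = round(100.0 * censored / total, 1) if total else 0.0
    return censored, pct


def _stratum(is_prisoner: bool, has_mhm: bool) -> str:
    return ("p_" if is_prisoner else "np_") + ("mhm" if has_mhm else "no_mhm")


def derive_strata(bundle: LinkedEventBundle, code_sets: MhmCodeSets = MhmCodeSets()) -> pd.DataFrame:
    """Per-person prisoner / MHM / linked status for audit stratification."""
    key = bundle.person_key
    persons = sorted(set(bundle.births[key]))
    prisoners = set(bundle.incarcerations[key]) if len(bundle.incarcerations) else set()
    mhm = mhm_status_by_person(
        bundle.mh_admissions, bundle.ost_authorities, key, code_sets
    )
    df = pd.DataFrame({key: persons})
    df["is_prisoner"] = df[key].isin(prisoners)
    df["has_mhm"] = df[key].isin(mhm)
    df["linked"] = df["is_prisoner"] | df["has_mhm"]
    df["stratum"] = [
        _stratum(p, m) for p, m in zip(df["is_prisoner"], df["has_mhm"])
    ]
    return df


def build_audit(
    decisions: pd.DataFrame,
    strata: pd.DataFrame,
    maternities: pd.DataFrame,
    person_col: str = "person_id",
) -> CensoringAudit:
    """Assemble the stratified censoring audit table.

    Reasons are not mutually exclusive, so per-reason counts can sum to
    more than the number of censored women.  Margins are checked to
    reconcile exactly (censored = total - validated in every stratum).
    """
    d = decisions.merge(strata[[person_col, "stratum"]], on=person_col, how="left")
    reason_cols = [c for c in ALL_REASONS if c in d.columns]
    d["censored"] = d[reason_cols].any(axis=1)
    d["maternity_reason"] = d[list(MATERNITY_REASONS)].any(axis=1)

    def by_stratum(mask: pd.Series) -> pd.Series:
        counts = d.loc[mask, "stratum"].value_counts()
        out = pd.Series({s: int(counts.get(s, 0)) for s in STRATA})
        out["all_mhm"] = out["np_mhm"] + out["p_mhm"]
        out["all_prisoners"] = out["p_no_mhm"] + out["p_mhm"]
        out["all"] = int(out[list(STRATA)].sum())
        return out

    rows = {"person_records": by_stratum(pd.Series(True, index=d.index))}
    for reason in reason_cols + ["maternity_reason"]:
        rows[reason] = by_stratum(d[reason])
    rows["censored_women"] = by_stratum(d["censored"])
    rows["study_mothers"] = rows["person_records"] - rows["censored_women"]
    counts = pd.DataFrame(rows).T

    totals = counts.loc["person_records"]
    if not (
        counts.loc["study_mothers"] + counts.loc["censored_women"]
    ).equals(totals):
        raise ValueError("audit margins do not reconcile")

    rates = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for row in counts.index:
        per = 100.0 if row in ("censored_women", "study_mothers") else 1000.0
        rates.loc[row] = (
            counts.loc[row] / totals.replace(0, np.nan) * per
        ).astype(float).round(1)

    censored_persons = set(d.loc[d["censored"], person_col])
    mat_per_person = maternities.groupby(person_col).size()
    censored_maternities = int(
        mat_per_person.reindex(sorted(censored_persons)).fillna(0).sum()
    )
    return CensoringAudit(
        counts=counts.astype(int),
        rates=rates,
        censored_maternities=censored_maternities,
        censored_women=int(counts.loc["censored_women", "all"]),
    )


class QualityChecker(BaseEstimator, TransformerMixin):
    """Transformer evaluating the record-level quality rules on a bundle.

    ``transform`` annotates the bundle with the per-person decision table
    (conception-in-prison still pending) and per-person strata; censoring
    itself is applied after exposure classification so the audit can
    account for all reasons at once.
    """

    def __init__(self, code_sets: MhmCodeSets = MhmCodeSets()):
        self.code_sets = code_sets

    def fit(self, X: LinkedEventBundle, y=None) -> "QualityChecker":
        self.decisions_ = evaluate_quality(X)
        self.strata_ = derive_strata(X, self.code_sets)
        return self

    def transform(self, X: LinkedEventBundle) -> LinkedEventBundle:
        if not hasattr(self, "decisions_"):
            raise RuntimeError("QualityChecker is not fitted")
        out = X.copy()
        out.decisions = self.decisions_.copy()
        out.meta["strata"] = self.strata_.copy()
        return out
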