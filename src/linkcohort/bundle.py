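"""Container for the linked event extracts and derived person-level tables.

The raw bundle holds five delimited-text tables keyed by the linkage
authority's project person number (PPN): birth records, incarceration
episodes, hospital mental-health admissions, opiate-substitution (OST)
authorities, and the PPN-UPN identity crosswalk for the corrective-services
source.  Temporal fields are always (age in days, calendar year); no table
ever carries a date.

Pipeline stages enrich a copy of the bundle with derived tables (person ids,
maternities, wide prisoner records, per-person flags) without mutating their
input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd

RAW_TABLES = (
    "births",
    "incarcerations",
    "mh_admissions",
    "ost_authorities",
    "crosswalk",
)

REQUIRED_COLUMNS: Dict[str, tuple] = {
    "births": (
        "ppn",
        "mother_age_days",
        "birth_year",
        "gestation_weeks",
        "birthweight_g",
        "baby_ref",
    ),
    "incarcerations": (
        "ppn",
        "upn",
        "start_age_days",
        "start_year",
        "end_age_days",
        "end_year",
    ),
    "mh_admissions": (
        "ppn",
        "admission_age_days",
        "admission_year",
        "diagnoses",
        "psych_ward",
    ),
    "ost_authorities": ("ppn", "authority_age_days", "authority_year"),
    "crosswalk": ("ppn", "upn"),
}

#: (table, column) pairs carrying the (age_days, year) representation of each
#: event, used by QC to reconstruct feasible birthdate windows.
TEMPORAL_PAIRS = {
    "births": (("mother_age_days", "birth_year"),),
    "incarcerations": (
        ("start_age_days", "start_year"),
        ("end_age_days", "end_year"),
    ),
    "mh_admissions": (("admission_age_days", "admission_year"),),
    "ost_authorities": (("authority_age_days", "authority_year"),),
}


@dataclass
class LinkedEventBundle:
    """The five raw linked extracts plus tables derived by pipeline stages."""

    births: pd.DataFrame
    incarcerations: pd.DataFrame
    mh_admissions: pd.DataFrame
    ost_authorities: pd.DataFrame
    crosswalk: pd.DataFrame

    # Derived along the pipeline; None until the producing stage has run.
    person_key: str = "ppn"
    maternities: Optional[pd.DataFrame] = None
    prisoner_records: Optional[pd.DataFrame] = None
    person_flags: Optional[pd.DataFrame] = None
    decisions: Optional[pd.DataFrame] = None
    classifications: Optional[pd.DataFrame] = None
    mother_status: Optional[pd.DataFrame] = None
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in RAW_TABLES:
            df = getattr(self, name)
            missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
            if missing:
                raise ValueError(f"table {name!r} is missing columns {missing}")

    def copy(self) -> "LinkedEventBundle":
        """Shallow-structure copy; each table copied so stages never mutate input."""
        kwargs = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, pd.DataFrame):
                value = value.copy()
            elif isinstance(value, dict):
                value = dict(value)
            kwargs[f.name] = value
        return LinkedEventBundle(**kwargs)

    def raw_tables(self) -> Dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in RAW_TABLES}

    def event_pairs_by_person(self) -> Dict[Any, list]:
        """All (age_days, year) observations per person across raw tables."""
        key = self.person_key
        out: Dict[Any, list] = {}
        for name, pairs in TEMPORAL_PAIRS.items():
            df = getattr(self, name)
            col = key if key in df.columns else "ppn"
            for age_col, year_col in pairs:
                sub = df[[col, age_col, year_col]].dropna()
                for pid, age, year in sub.itertuples(index=False):
                    out.setdefault(pid, []).append((int(age), int(year)))
        return out

    # -- delimited-text round trip ------------------------------------------

    def write_dir(self, path: str | Path) -> None:
        """Write all raw and derived tables as UTF-8 CSV with header rows."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, pd.DataFrame):
                value.to_csv(path / f"{f.name}.csv", index=False)

    @classmethod
    def read_dir(cls, path: str | Path) -> "LinkedEventBundle":
        path = Path(path)
        kwargs: Dict[str, Any] = {}
        for name in RAW_TABLES:
            file = path / f"{name}.csv"
            if not file.exists():
                raise FileNotFoundError(f"missing required table {file}")
            kwargs[name] = pd.read_csv(file)
        for name in (
            "maternities",
            "prisoner_records",
            "person_flags",
            "decisions",
            "classifications",
            "mother_status",
        ):
            file = path / f"{name}.csv"
            if file.exists():
                kwargs[name] = pd.read_csv(file)
        bundle = cls(**kwargs)
        if bundle.births is not None and "person_id" in bundle.births.columns:
            bundle.person_key = "person_id"
        return bundle
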