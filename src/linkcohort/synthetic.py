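"""Synthetic linked administrative event data with ground-truth labels.

The generator emulates the privacy-preserving extract a linkage authority
returns to researchers for a perinatal cohort: five event-level tables
(births, incarceration episodes, mental-health hospital admissions,
opiate-substitution authorities, and a PPN-UPN identity crosswalk) in which
every event carries only the woman's age in days and the calendar year --
never a date.  A latent birthdate per woman exists only inside the
generator, to keep (age, year) pairs mutually consistent, and is never
emitted in any event table.

Population structure under the defaults: every woman is a mother (the birth
register is the spine of the linkage); prisoner mothers are rare (0.8 %);
serious mental health morbidity affects 7 % of mothers overall and 68 % of
prisoner mothers; prisoners average 2.9 incarceration episodes (zero-
truncated geometric, capped); the unlinked majority is thinned to a 10 %
random retention sample, mirroring the control-sampling design.

Clean records are constructed to pass every downstream quality rule and to
carry an unambiguous exposure status; typed errors (duplicate births,
merged identities, overlapping / inverted / duplicated / unbounded
episodes, implausible maternity histories, conceptions inside an
incarceration episode) are injected at configurable rates and labelled in
the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._temporal import year_of_ordinal
from .bundle import LinkedEventBundle
from .config import SimulationConfig

_DATA_START = date(1998, 1, 1).toordinal()
_DATA_END = date(2006, 12, 31).toordinal()
_APDC_START = date(2000, 7, 1).toordinal()

# Diagnosis pools for mental-health admissions.  Qualifying codes are drawn
# from the psychiatric (F00-F09, F20-F99), self-harm, drug and alcohol ICD-10
# sets; fillers are common non-qualifying codes.
_QUALIFYING_CODES = (
    "F200", "F250", "F310", "F321", "F29", "F411", "F432", "F602",  # psychiatric
    "X61", "X64", "Y12", "Z915",                                     # self-harm
    "F112", "F120", "F192", "T402", "T433",                          # drug
    "F102", "F101", "K703", "T510", "Z721",                          # alcohol
)
_FILLER_CODES = ("O800", "I10", "J459", "Z370", "K590", "M545")

# Clean inter-birth spacing: at least gestation + 43 days (so the next
# conception falls >= 60 days after the previous birth, clearing the 30-day
# concurrency rule with margin) and at least 370 days (so no woman can
# accumulate three births inside any two-calendar-year counting window of
# the maternity-plausibility rule, which only sees calendar years).
_MIN_GAP_DAYS = 370
_GAP_SLACK_MEAN = 120.0


@dataclass
class GroundTruth:
    """Labels the generator guarantees about its own output.

    ``persons`` has one row per woman in the *full* population (including
    women not retained in the extract); ``maternities`` covers retained
    women only; ``errors`` lists every injected error with its type.
    """

    persons: pd.DataFrame
    maternities: pd.DataFrame
    errors: pd.DataFrame
    n_women: int
    config: SimulationConfig = None

    def error_persons(self, error_type: str) -> set:
        sel = self.errors[self.errors["error_type"] == error_type]
        return set(sel["ppn"])

    def add_errors(self, rows: List[dict]) -> None:
        if rows:
            add = pd.DataFrame(rows)
            self.errors = pd.concat([self.errors, add], ignore_index=True)


def _truncated_gestation(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    while True:
        g = rng.normal(cfg.gestation_mean_weeks, cfg.gestation_sd_weeks)
        if cfg.gestation_min_weeks <= g <= cfg.gestation_max_weeks:
            return int(round(g))


def _simulate_maternities(
    rng: np.random.Generator, cfg: SimulationConfig, first_birth: int
) -> Tuple[List[int], List[int]]:
    """Birth-day ordinals and gestations (weeks) for one woman."""
    n_mat = 1 + int(rng.poisson(cfg.maternity_rate - 1.0))
    n_mat = min(n_mat, 8)
    births = [first_birth]
    gests = [_truncated_gestation(rng, cfg)]
    for _ in range(n_mat - 1):
        g = _truncated_gestation(rng, cfg)
        gap = max(g * 7 + 43, _MIN_GAP_DAYS) + rng.exponential(_GAP_SLACK_MEAN)
        nxt = births[-1] + int(round(gap))
        if nxt > _DATA_END:
            break
        births.append(nxt)
        gests.append(g)
    return births, gests


def _place_clean_episodes(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    latent: int,
    births: List[int],
    conceptions: List[int],
) -> Tuple[List[Tuple[int, int]], Optional[int], bool]:
    """Episodes for one prisoner; returns (episodes, exposed_index, in_prison_birth).

    Clean placement keeps every non-exposure episode clear of each
    pregnancy's guarded window [conception - guard, birth], so exposure
    classification is unambiguous for any tolerance below the guard.
    """
    guard = cfg.conception_guard_days
    n_ep = int(min(rng.geometric(1.0 / cfg.episodes_per_prisoner_mean), cfg.max_episodes))
    episodes: List[Tuple[int, int]] = []
    exposed_idx: Optional[int] = None
    in_prison_birth = False

    if rng.random() < cfg.prison_pregnancy_rate:
        m = int(rng.integers(0, len(births)))
        c, b = conceptions[m], births[m]
        start = int(rng.integers(c + 1, max(c + 2, b - 20)))
        if rng.random() < cfg.birth_in_prison_given_exposed:
            cap = conceptions[m + 1] - guard - 1 if m + 1 < len(births) else b + 90
            end = min(b + int(rng.integers(5, 61)), cap)
            end = max(end, b + 1)
            in_prison_birth = True
        else:
            end = int(rng.integers(start + 1, b + 1))
        episodes.append((start, end))
        exposed_idx = m

    # Free regions between guarded pregnancy windows.
    regions: List[Tuple[int, int]] = []
    lo0 = max(_DATA_START, latent + 16 * 365)
    regions.append((lo0, conceptions[0] - guard - 1))
    for k in range(len(births) - 1):
        regions.append((births[k] + 1, conceptions[k + 1] - guard - 1))
    regions.append((births[-1] + 1, _DATA_END))
    regions = [(lo, hi) for lo, hi in regions if hi - lo > 10]

    def overlaps(s: int, e: int) -> bool:
        return any(s < e2 and s2 < e for s2, e2 in episodes)

    for _ in range(n_ep - len(episodes)):
        if not regions:
            break
        for _attempt in range(12):
            widths = np.array([hi - lo for lo, hi in regions], dtype=float)
            ridx = int(rng.choice(len(regions), p=widths / widths.sum()))
            lo, hi = regions[ridx]
            dur = int(rng.integers(3, 181))
            if hi - dur <= lo:
                continue
            s = int(rng.integers(lo, hi - dur))
            e = s + dur
            if not overlaps(s, e):
                episodes.append((s, e))
                break
    episodes.sort()
    return episodes, exposed_idx, in_prison_birth


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[LinkedEventBundle, GroundTruth]:
    """Generate a linked event bundle and its ground truth.

    With all error rates at zero the output is clean by construction: run
    through the full pipeline it censors no woman and every maternity's
    exposure classification equals the ground-truth label.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_women

    is_prisoner = rng.random(n) < cfg.prisoner_prevalence
    p_pris = cfg.prisoner_prevalence
    p_np = cfg.mhm_prevalence
    if p_pris < 1.0:
        p_np = (cfg.mhm_prevalence - p_pris * cfg.mhm_given_prisoner) / (1.0 - p_pris)
    p_np = min(max(p_np, 0.0), 1.0)
    u = rng.random(n)
    has_mhm = np.where(is_prisoner, u < cfg.mhm_given_prisoner, u < p_np)
    linked = is_prisoner | has_mhm
    retained = linked | (rng.random(n) < cfg.sampling_fraction)

    birth_rows, inc_rows, mh_rows, ost_rows, xwalk_rows = [], [], [], [], []
    truth_mat_rows = []
    latent_ord = np.zeros(n, dtype=np.int64)

    baby_seq = 0
    for i in range(n):
        pid = f"T{i:06d}"
        ppn = f"P{i:06d}"
        if not retained[i]:
            continue

        first_birth = int(rng.integers(_DATA_START, _DATA_END + 1))
        age_first = int(rng.integers(18 * 365, 40 * 365))
        latent = first_birth - age_first
        latent_ord[i] = latent
        births, gests = _simulate_maternities(rng, cfg, first_birth)
        conceptions = [b - g * 7 + 17 for b, g in zip(births, gests)]

        exposed_idx: Optional[int] = None
        in_prison_birth = False
        if is_prisoner[i]:
            episodes, exposed_idx, in_prison_birth = _place_clean_episodes(
                rng, cfg, latent, births, conceptions
            )
            upn = f"U{i:06d}"
            xwalk_rows.append((ppn, upn))
            for s, e in episodes:
                inc_rows.append(
                    (
                        ppn,
                        upn,
                        s - latent,
                        year_of_ordinal(s),
                        e - latent,
                        year_of_ordinal(e),
                    )
                )

        for k, (b, g) in enumerate(zip(births, gests)):
            n_babies = 2 if rng.random() < cfg.twin_rate else 1
            for _ in range(n_babies):
                baby_seq += 1
                weight = int(np.clip(rng.normal(3400 - 150 * (40 - g), 450), 450, 5500))
                birth_rows.append(
                    (
                        ppn,
                        b - latent,
                        year_of_ordinal(b),
                        g,
                        weight,
                        f"B{baby_seq:07d}",
                    )
                )
            if exposed_idx is not None and k == exposed_idx:
                status = "prison_pregnancy"
            elif is_prisoner[i]:
                status = "prisoner_control"
            else:
                status = "community"
            truth_mat_rows.append(
                (
                    pid,
                    ppn,
                    k + 1,
                    year_of_ordinal(b),
                    status,
                    bool(in_prison_birth) and exposed_idx == k,
                )
            )

        if has_mhm[i]:
            r = rng.random()
            has_ost = r < 0.45
            has_adm = r >= 0.25
            if has_ost:
                day = int(rng.integers(_DATA_START, _DATA_END + 1))
                ost_rows.append((ppn, day - latent, year_of_ordinal(day)))
            if has_adm:
                n_adm = 1 + int(rng.poisson(1.0))
                for _ in range(n_adm):
                    day = int(rng.integers(_APDC_START, _DATA_END + 1))
                    ward_only = rng.random() < 0.10
                    if ward_only:
                        codes = [str(rng.choice(_FILLER_CODES))]
                        ward = True
                    else:
                        codes = [str(rng.choice(_QUALIFYING_CODES))]
                        for _f in range(int(rng.integers(0, 3))):
                            codes.append(str(rng.choice(_FILLER_CODES)))
                        ward = bool(rng.random() < 0.15)
                    mh_rows.append(
                        (ppn, day - latent, year_of_ordinal(day), ";".join(codes), ward)
                    )

    bundle = LinkedEventBundle(
        births=pd.DataFrame(
            birth_rows,
            columns=[
                "ppn",
                "mother_age_days",
                "birth_year",
                "gestation_weeks",
                "birthweight_g",
                "baby_ref",
            ],
        ),
        incarcerations=pd.DataFrame(
            inc_rows,
            columns=[
                "ppn",
                "upn",
                "start_age_days",
                "start_year",
                "end_age_days",
                "end_year",
            ],
        ),
        mh_admissions=pd.DataFrame(
            mh_rows,
            columns=[
                "ppn",
                "admission_age_days",
                "admission_year",
                "diagnoses",
                "psych_ward",
            ],
        ),
        ost_authorities=pd.DataFrame(
            ost_rows, columns=["ppn", "authority_age_days", "authority_year"]
        ),
        crosswalk=pd.DataFrame(xwalk_rows, columns=["ppn", "upn"]),
    )

    persons = pd.DataFrame(
        {
            "person_id": [f"T{i:06d}" for i in range(n)],
            "ppn": [f"P{i:06d}" for i in range(n)],
            "is_prisoner": is_prisoner,
            "has_mhm": has_mhm,
            "linked": linked,
            "retained": retained,
            "latent_birth_ordinal": latent_ord,
        }
    )
    truth = GroundTruth(
        persons=persons,
        maternities=pd.DataFrame(
            truth_mat_rows,
            columns=[
                "person_id",
                "ppn",
                "maternity_order",
                "birth_year",
                "status",
                "birth_in_prison",
            ],
        ),
        errors=pd.DataFrame(
            columns=["error_type", "ppn", "person_id", "detail"]
        ),
        n_women=n,
        config=cfg,
    )

    bundle, truth = _inject_all(bundle, truth, cfg, rng)

    # Shuffle incarceration row order so downstream sorting is exercised.
    if len(bundle.incarcerations):
        perm = rng.permutation(len(bundle.incarcerations))
        bundle.incarcerations = bundle.incarcerations.iloc[perm].reset_index(drop=True)
    return bundle, truth


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

_MERGE_SIZE_VALUES = np.array([2, 3, 4, 5])
# Set-size frequencies follow the observed multiple-match multiplicity
# profile of alias-driven prisoner linkage (pairs dominate).
_MERGE_SIZE_WEIGHTS = np.array([115.0, 18.0, 2.0, 4.0])


def _pick(rng: np.random.Generator, items: list, k: int) -> list:
    k = min(k, len(items))
    if k == 0:
        return []
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[j] for j in sorted(int(x) for x in idx)]


def _latent_of(truth: GroundTruth, ppn: str) -> int:
    row = truth.persons.loc[truth.persons["ppn"] == ppn]
    return int(row["latent_birth_ordinal"].iloc[0])


def inject_identity_merge(
    bundle: LinkedEventBundle,
    rate: float,
    seed: int | np.random.Generator = 0,
    truth: Optional[GroundTruth] = None,
) -> Tuple[LinkedEventBundle, Optional[GroundTruth]]:
    """Merge sets of distinct true persons under a single shared PPN.

    ``rate`` is the proportion of crosswalk persons drawn into a merged set.
    Merged members keep their own UPNs, so the crosswalk gains
    multiple-matched rows (one PPN, several UPNs); all event tables of the
    absorbed members are re-keyed to the shared PPN, emulating a false
    positive link.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bundle = bundle.copy()
    if rate == 0.0 or not len(bundle.crosswalk):
        return bundle, truth

    ppns = sorted(bundle.crosswalk["ppn"].unique())
    target = int(round(rate * len(ppns)))
    pool = _pick(rng, ppns, len(ppns))
    rng.shuffle(pool)
    sets: List[List[str]] = []
    used = 0
    while used + 2 <= min(target + 1, len(pool)) and used + 2 <= len(pool):
        size = int(
            rng.choice(_MERGE_SIZE_VALUES, p=_MERGE_SIZE_WEIGHTS / _MERGE_SIZE_WEIGHTS.sum())
        )
        size = min(size, len(pool) - used)
        if size < 2:
            break
        sets.append(pool[used : used + size])
        used += size
        if used >= target:
            break

    mapping: Dict[str, str] = {}
    error_rows = []
    for members in sets:
        canon = members[0]
        for m in members[1:]:
            mapping[m] = canon
        error_rows.append(
            {
                "error_type": "merged_identity",
                "ppn": canon,
                "person_id": "",
                "detail": "|".join(members),
            }
        )
    for name in ("births", "incarcerations", "mh_admissions", "ost_authorities", "crosswalk"):
        df = getattr(bundle, name)
        if len(df):
            df["ppn"] = df["ppn"].map(lambda p: mapping.get(p, p))
            setattr(bundle, name, df)
    bundle.crosswalk = bundle.crosswalk.drop_duplicates().reset_index(drop=True)
    if truth is not None:
        truth.add_errors(error_rows)
        truth.maternities = truth.maternities.assign(
            ppn=truth.maternities["ppn"].map(lambda p: mapping.get(p, p))
        )
    return bundle, truth


def _inject_all(
    bundle: LinkedEventBundle,
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[LinkedEventBundle, GroundTruth]:
    """Apply every configured error type in a fixed, documented order."""
    inc = bundle.incarcerations
    births = bundle.births
    errors: List[dict] = []

    retained = truth.persons[truth.persons["retained"]]
    women_ppns = sorted(set(births["ppn"]))
    prisoner_ppns = sorted(set(inc["ppn"]))

    def n_of(rate: float, pool: list) -> int:
        return int(round(rate * len(pool)))

    # --- duplicate birth rows -------------------------------------------
    r = cfg.rate("duplicate_birth")
    if r > 0:
        for ppn in _pick(rng, women_ppns, n_of(r, women_ppns)):
            row = births[births["ppn"] == ppn].iloc[[0]]
            births = pd.concat([births, row], ignore_index=True)
            errors.append(
                {"error_type": "duplicate_birth", "ppn": ppn, "person_id": "", "detail": ""}
            )

    # --- implausibly many maternities -----------------------------------
    r = cfg.rate("excess_maternities")
    if r > 0:
        new_rows = []
        for ppn in _pick(rng, women_ppns, n_of(r, women_ppns)):
            latent = _latent_of(truth, ppn)
            for month in (2, 6, 10):
                day = date(2001, month, 1).toordinal()
                new_rows.append(
                    {
                        "ppn": ppn,
                        "mother_age_days": day - latent,
                        "birth_year": 2001,
                        "gestation_weeks": 39,
                        "birthweight_g": 3100,
                        "baby_ref": f"X{len(new_rows):06d}",
                    }
                )
            errors.append(
                {"error_type": "excess_maternities", "ppn": ppn, "person_id": "", "detail": ""}
            )
        if new_rows:
            births = pd.concat([births, pd.DataFrame(new_rows)], ignore_index=True)

    # --- non-chronological age/year drift --------------------------------
    r = cfg.rate("non_chronological_age")
    if r > 0:
        counts = births.groupby("ppn")["mother_age_days"].nunique()
        multi = sorted(counts[counts >= 2].index)
        for ppn in _pick(rng, multi, n_of(r, multi)):
            sel = births["ppn"] == ppn
            idx = births.loc[sel, "mother_age_days"].idxmax()
            births.loc[idx, "birth_year"] = int(births.loc[idx, "birth_year"]) + 3
            errors.append(
                {
                    "error_type": "non_chronological_age",
                    "ppn": ppn,
                    "person_id": "",
                    "detail": "",
                }
            )

    # --- concurrent pregnancy -------------------------------------------
    r = cfg.rate("concurrent_pregnancy")
    if r > 0:
        new_rows = []
        for ppn in _pick(rng, women_ppns, n_of(r, women_ppns)):
            latent = _latent_of(truth, ppn)
            first_age = int(births.loc[births["ppn"] == ppn, "mother_age_days"].min())
            new_age = first_age + 39 * 7  # conception 17 d after previous birth
            new_rows.append(
                {
                    "ppn": ppn,
                    "mother_age_days": new_age,
                    "birth_year": year_of_ordinal(latent + new_age),
                    "gestation_weeks": 39,
                    "birthweight_g": 2900,
                    "baby_ref": f"C{len(new_rows):06d}",
                }
            )
            errors.append(
                {
                    "error_type": "concurrent_pregnancy",
                    "ppn": ppn,
                    "person_id": "",
                    "detail": "",
                }
            )
        if new_rows:
            births = pd.concat([births, pd.DataFrame(new_rows)], ignore_index=True)

    # --- episode errors ---------------------------------------------------
    def episode_target(ppns_pool: list, rate: float) -> list:
        return _pick(rng, ppns_pool, n_of(rate, ppns_pool))

    r = cfg.rate("overlapping_episodes")
    if r > 0:
        new_rows = []
        for ppn in episode_target(prisoner_ppns, r):
            row = inc[inc["ppn"] == ppn].iloc[0]
            s, e = int(row["start_age_days"]), int(row["end_age_days"])
            mid = s + max(1, (e - s) // 2)
            mid = min(mid, e - 1) if e - 1 > s else s
            new_rows.append(
                {
                    "ppn": ppn,
                    "upn": row["upn"],
                    "start_age_days": mid,
                    "start_year": row["start_year"],
                    "end_age_days": e + 30,
                    "end_year": row["end_year"],
                }
            )
            errors.append(
                {
                    "error_type": "overlapping_episodes",
                    "ppn": ppn,
                    "person_id": "",
                    "detail": "",
                }
            )
        if new_rows:
            inc = pd.concat([inc, pd.DataFrame(new_rows)], ignore_index=True)

    r = cfg.rate("inverted_episode")
    if r > 0:
        for ppn in episode_target(prisoner_ppns, r):
            idx = inc.index[inc["ppn"] == ppn][0]
            s, e = inc.loc[idx, "start_age_days"], inc.loc[idx, "end_age_days"]
            sy, ey = inc.loc[idx, "start_year"], inc.loc[idx, "end_year"]
            inc.loc[idx, ["start_age_days", "end_age_days"]] = [e, s]
            inc.loc[idx, ["start_year", "end_year"]] = [ey, sy]
            errors.append(
                {"error_type": "inverted_episode", "ppn": ppn, "person_id": "", "detail": ""}
            )

    r = cfg.rate("duplicated_episode")
    if r > 0:
        new_rows = []
        for ppn in episode_target(prisoner_ppns, r):
            new_rows.append(inc[inc["ppn"] == ppn].iloc[0].to_dict())
            errors.append(
                {"error_type": "duplicated_episode", "ppn": ppn, "person_id": "", "detail": ""}
            )
        if new_rows:
            inc = pd.concat([inc, pd.DataFrame(new_rows)], ignore_index=True)

    r = cfg.rate("missing_episode_bound")
    if r > 0:
        for ppn in episode_target(prisoner_ppns, r):
            idx = inc.index[inc["ppn"] == ppn][0]
            inc.loc[idx, ["end_age_days", "end_year"]] = [np.nan, np.nan]
            errors.append(
                {
                    "error_type": "missing_episode_bound",
                    "ppn": ppn,
                    "person_id": "",
                    "detail": "",
                }
            )

    # --- conception inside an incarceration episode ----------------------
    r = cfg.rate("prison_conception")
    if r > 0:
        exposed = set(
            truth.maternities.loc[
                truth.maternities["status"] == "prison_pregnancy", "ppn"
            ]
        )
        new_rows = []
        for ppn in episode_target(prisoner_ppns, r):
            rows = births[births["ppn"] == ppn]
            if not len(rows):
                continue
            rows = rows.sort_values("mother_age_days")
            # Target the earliest maternity; skip the woman if her only
            # maternity already has a pregnancy incarceration episode.
            row = rows.iloc[0]
            if ppn in exposed:
                t_exposed = truth.maternities[
                    (truth.maternities["ppn"] == ppn)
                    & (truth.maternities["status"] == "prison_pregnancy")
                ]["maternity_order"].iloc[0]
                if t_exposed == 1:
                    if len(rows) < 2:
                        continue
                    row = rows.iloc[1]
            c_age = int(row["mother_age_days"]) - int(row["gestation_weeks"]) * 7 + 17
            latent = _latent_of(truth, ppn)
            upn = inc.loc[inc["ppn"] == ppn, "upn"].iloc[0]
            s, e = c_age - 25, c_age + 20
            new_rows.append(
                {
                    "ppn": ppn,
                    "upn": upn,
                    "start_age_days": s,
                    "start_year": year_of_ordinal(latent + s),
                    "end_age_days": e,
                    "end_year": year_of_ordinal(latent + e),
                }
            )
            errors.append(
                {"error_type": "prison_conception", "ppn": ppn, "person_id": "", "detail": ""}
            )
        if new_rows:
            inc = pd.concat([inc, pd.DataFrame(new_rows)], ignore_index=True)

    bundle.births = births
    bundle.incarcerations = inc
    truth.add_errors(errors)

    # --- merged identities last, so relabelling covers injected rows too --
    r = cfg.rate("merged_identity")
    if r > 0:
        bundle, truth = inject_identity_merge(bundle, r, rng, truth)
    return bundle, truth
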