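"""Exposure classification: category partition, statuses, index maternity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkcohort import (
    assign_index_maternity,
    assign_mother_status,
    classify_episode,
    classify_maternity,
)
from linkcohort.exposure import classify_episodes


def oracle_category(s, e, c, b, tol):
    """Independent restatement of the five temporal conditions.

    Returns the unique category, or raises if the conditions fail to
    partition (which the property test asserts never happens).
    """
    ended_before_conception = e <= c
    started_after_birth = s > b
    started_after_conception = s >= c - tol  # dating tolerance
    ended_before_birth = e <= b
    matches = []
    if ended_before_conception:
        matches.append(1)
    if not ended_before_conception and started_after_birth:
        matches.append(2)
    if (
        not ended_before_conception
        and not started_after_birth
        and started_after_conception
        and ended_before_birth
    ):
        matches.append(3)
    if (
        not ended_before_conception
        and not started_after_birth
        and started_after_conception
        and not ended_before_birth
    ):
        matches.append(4)
    if not ended_before_conception and not started_after_conception:
        matches.append(5)
    assert len(matches) == 1, f"partition violated: {matches}"
    return matches[0]


@pytest.mark.parametrize(
    "episode,expected",
    [
        ((9_000, 9_500), 1),
        ((9_800, 9_900), 3),
        ((9_800, 10_100), 4),
        ((10_050, 10_200), 2),
        ((9_600, 9_800), 5),  # spans conception at tolerance 0
        ((9_737, 9_900), 3),  # starts exactly at conception
        ((9_000, 9_737), 1),  # ends exactly at conception
        ((10_000, 10_100), 4),  # starts on the birth day, ends after it
    ],
)
def test_episode_categories_conception_9737_birth_10000(episode, expected):
    s, e = episode
    assert classify_episode(s, e, 9_737, 10_000, tolerance=0) == expected


def test_tolerance_reclassifies_near_conception_starts():
    # Starts 10 days before conception: category 5 strictly, 3 with tolerance 14.
    assert classify_episode(9_727, 9_900, 9_737, 10_000, tolerance=0) == 5
    assert classify_episode(9_727, 9_900, 9_737, 10_000, tolerance=14) == 3


def test_invalid_episode_is_refused():
    with pytest.raises(ValueError, match="invalid episode"):
        classify_episode(300, 250, 9_737, 10_000)
    with pytest.raises(ValueError, match="invalid episode"):
        classify_episode(np.nan, 250, 9_737, 10_000)


@settings(max_examples=500, deadline=None, derandomize=True)
@given(
    s=st.integers(0, 2_000),
    dur=st.integers(0, 800),
    c=st.integers(500, 1_200),
    gest_days=st.integers(140, 301),
    tol=st.sampled_from([0, 7, 14, 30]),
)
def test_partition_and_oracle_agreement(s, dur, c, gest_days, tol):
    e = s + dur
    b = c + gest_days
    expected = oracle_category(s, e, c, b, tol)
    assert classify_episode(s, e, c, b, tol) == expected
    assert classify_episodes([s], [e], c, b, tol)[0] == expected


def test_raising_tolerance_never_demotes_prison_pregnancy():
    """Monotonicity: tolerance only reclassifies category-5 boundary cases."""
    rng = np.random.default_rng(12)
    for _ in range(300):
        c = int(rng.integers(500, 1200))
        b = c + int(rng.integers(140, 300))
        starts = rng.integers(0, 2000, size=3)
        ends = starts + rng.integers(1, 500, size=3)
        rec0 = classify_maternity(c, b, starts, ends, tolerance=0)
        rec14 = classify_maternity(c, b, starts, ends, tolerance=14)
        if rec0["status"] == "prison_pregnancy":
            assert rec14["status"] == "prison_pregnancy"
        if rec0["status"] == "prisoner_control":
            assert rec14["status"] == "prisoner_control"


def test_maternity_status_and_timing_patterns():
    c, b = 9_737, 10_000
    rec = classify_maternity(c, b, [9_000, 9_200], [9_100, 9_300])
    assert rec["status"] == "prisoner_control"
    assert rec["timing_pattern"] == "before_only"

    rec = classify_maternity(c, b, [9_000, 9_800], [9_100, 9_900])
    assert rec["status"] == "prison_pregnancy"
    assert rec["timing_pattern"] == "before_and_during"
    assert not rec["birth_in_prison"]

    rec = classify_maternity(c, b, [9_800], [10_050])
    assert rec["status"] == "prison_pregnancy"
    assert rec["birth_in_prison"]

    # Any category-5 count censors regardless of other counts.
    rec = classify_maternity(c, b, [9_000, 9_600, 9_800], [9_100, 9_800, 9_900], tolerance=0)
    assert rec["status"] == "censor_conception_in_prison"

    rec = classify_maternity(c, b, [], [])
    assert rec["status"] == "community"
    assert rec["timing_pattern"] == "none"

    assert rec["c1"] + rec["c2"] + rec["c3"] + rec["c4"] + rec["c5"] == 0


def test_category_counts_partition_episode_count():
    rng = np.random.default_rng(3)
    c, b = 9_737, 10_000
    starts = rng.integers(8_500, 10_500, size=20)
    ends = starts + rng.integers(1, 400, size=20)
    rec = classify_maternity(c, b, starts, ends)
    assert sum(rec[f"c{k}"] for k in range(1, 6)) == 20


def _cls(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "maternity_order", "status", "birth_in_prison"],
    ).assign(c1=0, c2=0, c3=0, c4=0, c5=0)


def test_mother_status_assignment():
    cls = _cls(
        [
            ("W1", 1, "prison_pregnancy", False),
            ("W1", 2, "prisoner_control", False),
            ("W2", 1, "prisoner_control", False),
            ("W2", 2, "prisoner_control", False),
            ("W3", 1, "prison_pregnancy", True),
            ("W4", 1, "community", False),
        ]
    )
    status = assign_mother_status(cls).set_index("person_id")
    assert status.loc["W1", "status"] == "pregnant_prisoner"
    assert bool(status.loc["W1", "own_control"])
    assert status.loc["W2", "status"] == "prisoner_control"
    assert status.loc["W3", "status"] == "pregnant_prisoner"
    assert not bool(status.loc["W3", "own_control"])
    assert status.loc["W4", "status"] == "community"


def test_index_maternity_selection():
    cls = _cls(
        [
            ("W1", 1, "prisoner_control", False),
            ("W1", 2, "prison_pregnancy", False),
            ("W1", 3, "prison_pregnancy", False),
            ("W2", 1, "prisoner_control", False),
            ("W2", 2, "prisoner_control", False),
        ]
    )
    mat = pd.DataFrame(
        {
            "person_id": ["W1", "W1", "W1", "W2", "W2"],
            "maternity_order": [1, 2, 3, 1, 2],
            "mother_age_days": [8_000, 8_500, 9_000, 8_000, 8_700],
            "birth_year": [2000, 2001, 2002, 1999, 2001],
        }
    )
    status = assign_mother_status(cls)
    out = assign_index_maternity(status, cls, mat).set_index("person_id")
    # Pregnant prisoner: first maternity with a pregnancy incarceration.
    assert out.loc["W1", "index_maternity_order"] == 2
    # Control: first maternity inside the study period (1999 is outside).
    assert out.loc["W2", "index_maternity_order"] == 2


def test_mother_with_no_study_period_maternity_gets_null_index():
    cls = _cls([("W1", 1, "prisoner_control", False)])
    mat = pd.DataFrame(
        {
            "person_id": ["W1"],
            "maternity_order": [1],
            "mother_age_days": [8_000],
            "birth_year": [1998],
        }
    )
    out = assign_index_maternity(assign_mother_status(cls), cls, mat)
    assert out["index_maternity_order"].isna().all()


def test_zero_error_classification_matches_ground_truth(clean_sim):
    from linkcohort import classify_bundle

    bundle, truth = clean_sim
    result = classify_bundle(bundle)
    merged = truth.maternities.merge(
        result.classifications,
        left_on=["ppn", "maternity_order"],
        right_on=["person_id", "maternity_order"],
        how="left",
    )
    assert not merged["status_y"].isna().any()
    assert (merged["status_x"] == merged["status_y"]).all()
    assert (merged["birth_in_prison_x"] == merged["birth_in_prison_y"]).all()
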