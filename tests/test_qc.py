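"""Quality rules: MHM classification, maternity rules, episode validation, audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkcohort import censoring_summary, classify_mhm
from linkcohort.qc import (
    build_audit,
    censor,
    flag_concurrent,
    flag_non_chronological,
    flag_too_many_maternities,
    validate_incarcerations,
)

# ---------------------------------------------------------------------------
# Serious mental health morbidity classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "codes,ward,ost,expected_mhm,expected_cats",
    [
        (["F23.1"], False, False, True, {"psychiatric"}),
        (["I10"], False, False, False, set()),
        ([], False, True, True, {"ost"}),
        ([], True, False, True, {"psych_ward"}),
        (["F10.2"], False, False, True, {"alcohol"}),
        (["F11.2"], False, False, True, {"drug"}),
        (["X61"], False, False, True, {"self_harm"}),
        (["Y87.0"], False, False, True, {"self_harm"}),
        (["Y87.1"], False, False, False, set()),  # only Y87.0 qualifies
        (["T40.2"], False, False, True, {"drug"}),
        (["I42.6"], False, False, True, {"alcohol"}),
        (["F09"], False, False, True, {"psychiatric"}),
        (["F19.9", "F99"], False, False, True, {"drug", "psychiatric"}),
        (["O80.0", "Z37"], False, False, False, set()),
    ],
)
def test_mhm_code_classification(codes, ward, ost, expected_mhm, expected_cats):
    is_mhm, cats = classify_mhm(codes, ward, ost)
    assert is_mhm is expected_mhm
    assert cats == expected_cats


def test_f10_to_f19_excluded_from_psychiatric_set():
    """Substance categories are carved out of the psychiatric range."""
    for code in ("F10", "F15.2", "F19"):
        _, cats = classify_mhm([code])
        assert "psychiatric" not in cats


def test_unparseable_code_warns_and_is_ignored():
    with pytest.warns(UserWarning, match="unparseable"):
        is_mhm, cats = classify_mhm(["??", "F20"])
    assert is_mhm and cats == {"psychiatric"}


# ---------------------------------------------------------------------------
# Maternity-history rules
# ---------------------------------------------------------------------------


def _mat(rows):
    return pd.DataFrame(
        rows, columns=["mother_age_days", "birth_year", "conception_age_days"]
    )


def test_third_maternity_by_end_2001_is_flagged():
    m = _mat([(9000, 2000, 8750), (9400, 2001, 9150), (9800, 2001, 9550)])
    assert flag_too_many_maternities(m)


def test_four_maternities_spread_over_later_years_not_flagged():
    m = _mat(
        [
            (9000, 2001, 8750),
            (9400, 2002, 9150),
            (9800, 2002, 9550),
            (10200, 2003, 9950),
        ]
    )
    assert not flag_too_many_maternities(m)  # 4 by end 2002 < threshold of 5


def test_two_births_provably_in_jun_dec_2000_window_flagged():
    from datetime import date

    # Interval pinned tightly via a known latent birthdate.
    latent = date(1975, 1, 1).toordinal()
    a1 = date(2000, 8, 1).toordinal() - latent
    a2 = date(2000, 12, 1).toordinal() - latent
    m = _mat([(a1, 2000, a1 - 263), (a2, 2000, a2 - 263)])
    assert flag_too_many_maternities(m, birth_interval=(latent, latent))


def test_pre_study_maternities_do_not_count():
    m = _mat([(8000, 1998, 7750), (8400, 1999, 8150), (9200, 2001, 8950)])
    assert not flag_too_many_maternities(m)


@pytest.mark.parametrize(
    "age_years,years,expected",
    [
        ((25, 25), (2002, 2004), True),  # 0 vs 2
        ((25, 26), (2002, 2003), False),  # 1 vs 1
        ((25, 27), (2002, 2003), False),  # 2 vs 1: differ by exactly one
        ((25, 29), (2002, 2003), True),  # 4 vs 1
    ],
)
def test_non_chronological_rule(age_years, years, expected):
    m = _mat(
        [
            (int(a * 365.25) + 10, y, None)
            for a, y in zip(age_years, years)
        ]
    )
    assert flag_non_chronological(m) is expected


def test_non_chronological_matches_enumeration_oracle():
    """Exhaustive check over small (delta-age, delta-year) grids."""
    for d_age in range(0, 5):
        for d_cal in range(0, 5):
            m = _mat(
                [
                    (int(25 * 365.25) + 5, 2001, None),
                    (int((25 + d_age) * 365.25) + 5, 2001 + d_cal, None),
                ]
            )
            assert flag_non_chronological(m) is (abs(d_age - d_cal) > 1)


@pytest.mark.parametrize(
    "prev_birth,next_conception,expected",
    [
        (9000, 9020, True),  # 20 days after birth: too soon
        (9000, 9030, False),  # exactly 30 days: allowed
        (9000, 8990, True),  # conception before previous birth
    ],
)
def test_concurrent_pregnancy_rule(prev_birth, next_conception, expected):
    m = _mat(
        [
            (prev_birth, 2002, prev_birth - 263),
            (next_conception + 263, 2003, next_conception),
        ]
    )
    assert flag_concurrent(m) is expected


# ---------------------------------------------------------------------------
# Incarceration validation
# ---------------------------------------------------------------------------


def _episodes(pairs):
    return pd.DataFrame(
        {
            "start_age_days": [p[0] for p in pairs],
            "end_age_days": [p[1] for p in pairs],
        }
    )


@pytest.mark.parametrize(
    "pairs,inconsistent,missing",
    [
        ([(100, 200), (150, 250)], True, False),  # overlap
        ([(300, 250)], True, False),  # start after end
        ([(100, 200), (200, 300)], False, False),  # abutting is valid
        ([(100, 200), (100, 200)], True, False),  # duplicate
        ([(100, 200), (300, np.nan)], False, True),  # missing bound
        ([(100, 200), (250, 300)], False, False),
    ],
)
def test_episode_validation(pairs, inconsistent, missing):
    got_inc, got_miss = validate_incarcerations(_episodes(pairs))
    assert got_inc is inconsistent
    assert got_miss is missing


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 80)),
        min_size=1,
        max_size=8,
    )
)
def test_overlap_detection_matches_pairwise_oracle(pairs):
    """Half-open interval convention, brute-force all-pairs oracle."""
    eps = [(s, s + d) for s, d in pairs]
    oracle_overlap = any(
        eps[i][0] < eps[j][1] and eps[j][0] < eps[i][1]
        for i in range(len(eps))
        for j in range(i + 1, len(eps))
    )
    oracle_dup = len(set(eps)) < len(eps)
    got_inc, got_miss = validate_incarcerations(_episodes(eps))
    assert got_inc is (oracle_overlap or oracle_dup)
    assert not got_miss


# ---------------------------------------------------------------------------
# Censoring and the audit
# ---------------------------------------------------------------------------


def test_any_reason_censors_all_of_a_womans_maternities():
    decisions = pd.DataFrame(
        {
            "person_id": ["W1", "W2"],
            "concurrent_maternities": [True, False],
        }
    )
    maternities = pd.DataFrame(
        {"person_id": ["W1", "W1", "W2"], "maternity_order": [1, 2, 1]}
    )
    validated, censored = censor(decisions, maternities)
    assert censored == {"W1"}
    assert validated["person_id"].tolist() == ["W2"]


def test_censoring_summary_reproduces_printed_margins():
    assert censoring_summary(66_477, 65_853) == (624, 0.9)
    assert censoring_summary(3_087, 2_589) == (498, 16.1)
    assert censoring_summary(28_009, 27_534) == (475, 1.7)
    with pytest.raises(ValueError):
        censoring_summary(10, 11)


def test_audit_margins_reconcile(clean_bundle):
    from linkcohort.pipeline import classify_bundle
    from linkcohort.qc import derive_strata

    result = classify_bundle(clean_bundle)
    strata = derive_strata(result)
    audit = build_audit(result.decisions, strata, result.maternities)
    c = audit.counts
    # Row margins: stratum columns sum to the overall column.
    for row in c.index:
        assert c.loc[row, ["np_no_mhm", "np_mhm", "p_no_mhm", "p_mhm"]].sum() == c.loc[row, "all"]
        assert c.loc[row, "all_mhm"] == c.loc[row, "np_mhm"] + c.loc[row, "p_mhm"]
        assert c.loc[row, "all_prisoners"] == c.loc[row, "p_no_mhm"] + c.loc[row, "p_mhm"]
    # Conservation: validated + censored = total in every stratum.
    assert (
        c.loc["study_mothers"] + c.loc["censored_women"] == c.loc["person_records"]
    ).all()
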