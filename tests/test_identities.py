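"""Identity resolution: component structure, histograms, conservation."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkcohort import IdentityResolver, merge_person_events, resolve_identities


def _crosswalk(pairs):
    return pd.DataFrame(pairs, columns=["ppn", "upn"])


class UnionFind:
    """Brute-force oracle for connected components."""

    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self):
        return len({self.find(x) for x in self.parent})


def test_bijective_crosswalk_resolves_to_identity():
    cw = _crosswalk([(f"P{i}", f"U{i}") for i in range(100)])
    rep = resolve_identities(cw)
    assert rep.n_persons == 100
    assert rep.multiplicity_ppn_to_upn == {1: 100}
    assert rep.multiplicity_upn_to_ppn == {1: 100}
    assert rep.merged_person_sets == []


def test_shared_ppn_forms_single_person():
    rep = resolve_identities(_crosswalk([("P1", "UA"), ("P1", "UB")]))
    assert rep.n_persons == 1
    assert rep.multiplicity_ppn_to_upn == {2: 1}


def test_transitive_closure_over_bipartite_graph():
    # P1-UA, P2-UA, P2-UB: one person through the shared UPN.
    rep = resolve_identities(_crosswalk([("P1", "UA"), ("P2", "UA"), ("P2", "UB")]))
    assert rep.n_persons == 1
    assert rep.merged_person_sets[0] == frozenset({"P1", "P2", "UA", "UB"})


def test_normalization_trims_and_casefolds():
    rep = resolve_identities(_crosswalk([(" p1 ", "ua"), ("P1", "UA")]))
    assert rep.n_ppn == 1 and rep.n_upn == 1


def test_empty_crosswalk_is_an_input_error():
    with pytest.raises(ValueError, match="empty"):
        resolve_identities(_crosswalk([]))


def test_printed_multiplicity_histogram_arithmetic():
    """3,087 PPNs with 2/3/4/5-fold matches at 115/18/2/4 give 3,260 UPNs."""
    pairs, u = [], 0
    for mult, freq in {1: 2948, 2: 115, 3: 18, 4: 2, 5: 4}.items():
        for i in range(freq):
            ppn = f"P{mult}_{i}"
            for _ in range(mult):
                pairs.append((ppn, f"U{u:06d}"))
                u += 1
    rep = resolve_identities(_crosswalk(pairs))
    assert rep.n_ppn == 3087
    assert rep.n_upn == 3260
    assert rep.n_persons == 3087
    # With a 1:1 upn->ppn side: n_upn = n_ppn + sum (k-1) * freq.
    extra = sum((k - 1) * f for k, f in rep.multiplicity_ppn_to_upn.items())
    assert rep.n_upn == rep.n_ppn + extra


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=1, max_size=50
    )
)
def test_component_count_matches_union_find_oracle(pairs):
    cw = _crosswalk([(f"P{p}", f"U{u}") for p, u in pairs])
    rep = resolve_identities(cw)
    uf = UnionFind()
    for p, u in set(pairs):
        uf.union(("p", p), ("u", u))
    assert rep.n_persons == uf.n_components()
    assert sum(rep.multiplicity_ppn_to_upn.values()) == rep.n_ppn
    assert sum(rep.multiplicity_upn_to_ppn.values()) == rep.n_upn


def test_merge_conserves_event_rows_and_is_idempotent(clean_bundle):
    resolver = IdentityResolver().fit(clean_bundle)
    once = resolver.transform(clean_bundle)
    for name in ("births", "incarcerations", "mh_admissions", "ost_authorities"):
        assert len(getattr(once, name)) == len(getattr(clean_bundle, name))
    twice = merge_person_events(once, resolver.report_)
    for name in ("births", "incarcerations"):
        a = getattr(once, name)["person_id"]
        b = getattr(twice, name)["person_id"]
        assert a.tolist() == b.tolist()


def test_merged_person_pools_member_events():
    import pandas as pd

    from linkcohort.bundle import LinkedEventBundle

    inc = pd.DataFrame(
        {
            "ppn": ["P1", "P1", "P2"],
            "upn": ["UA", "UA", "UB"],
            "start_age_days": [100, 300, 500],
            "start_year": [2000, 2001, 2002],
            "end_age_days": [200, 400, 600],
            "end_year": [2000, 2001, 2002],
        }
    )
    empty_births = pd.DataFrame(
        columns=[
            "ppn", "mother_age_days", "birth_year",
            "gestation_weeks", "birthweight_g", "baby_ref",
        ]
    )
    bundle = LinkedEventBundle(
        births=empty_births,
        incarcerations=inc,
        mh_admissions=pd.DataFrame(
            columns=["ppn", "admission_age_days", "admission_year", "diagnoses", "psych_ward"]
        ),
        ost_authorities=pd.DataFrame(
            columns=["ppn", "authority_age_days", "authority_year"]
        ),
        crosswalk=pd.DataFrame(
            {"ppn": ["P1", "P1", "P2"], "upn": ["UA", "UB", "UB"]}
        ),
    )
    resolved = IdentityResolver().fit_transform(bundle)
    assert resolved.incarcerations["person_id"].nunique() == 1
    assert len(resolved.incarcerations) == 3
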