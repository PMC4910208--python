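"""Resolution of multiple-matched identities in the PPN-UPN crosswalk.

The linkage authority assigns one project person number (PPN) per linked
person, while the corrective-services source carries its own unique person
number (UPN).  Alias use produces multiple-matched identities: one PPN
linked to several UPNs, or one UPN appearing under several PPNs.  Each
connected component of the bipartite PPN-UPN graph is assumed to be a
single true person; the validity of that assumption is tested downstream by
the quality rules, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bundle import LinkedEventBundle

EVENT_TABLES = ("births", "incarcerations", "mh_admissions", "ost_authorities")


@dataclass
class ResolutionReport:
    """Summary of crosswalk structure after component resolution."""

    n_ppn: int
    n_upn: int
    n_persons: int
    multiplicity_ppn_to_upn: Dict[int, int]
    multiplicity_upn_to_ppn: Dict[int, int]
    merged_person_sets: List[frozenset]
    person_map: Dict[str, str] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("ppn_to_upn", k, v) for k, v in sorted(self.multiplicity_ppn_to_upn.items())
        ] + [
            ("upn_to_ppn", k, v) for k, v in sorted(self.multiplicity_upn_to_ppn.items())
        ]
        return pd.DataFrame(rows, columns=["direction", "multiplicity", "frequency"])


def normalize_crosswalk(crosswalk: pd.DataFrame) -> pd.DataFrame:
    """Trim whitespace, upper-case identifiers, drop exact duplicate rows."""
    cw = crosswalk[["ppn", "upn"]].copy()
    for col in ("ppn", "upn"):
        cw[col] = cw[col].astype(str).str.strip().str.upper()
    return cw.drop_duplicates().reset_index(drop=True)


def resolve_identities(crosswalk: pd.DataFrame) -> ResolutionReport:
    """Group PPNs and UPNs into provisional persons.

    Every connected component of the bipartite graph becomes one person,
    identified by the lexicographically smallest PPN it contains.  Both
    multiplicity histograms are reported so either reading of a
    multiple-match (shared PPN or shared UPN) is auditable.
    """
    if crosswalk is None or len(crosswalk) == 0:
        raise ValueError("crosswalk is empty; nothing to resolve")
    cw = normalize_crosswalk(crosswalk)

    g = nx.Graph()
    g.add_edges_from(
        (("ppn", p), ("upn", u)) for p, u in cw.itertuples(index=False)
    )
    person_map: Dict[str, str] = {}
    merged_sets: List[frozenset] = []
    n_persons = 0
    for comp in nx.connected_components(g):
        ppns = sorted(v for kind, v in comp if kind == "ppn")
        upns = sorted(v for kind, v in comp if kind == "upn")
        person_id = ppns[0]
        n_persons += 1
        for p in ppns:
            person_map[p] = person_id
        if len(ppns) > 1 or len(upns) > 1:
            merged_sets.append(frozenset(ppns) | frozenset(upns))

    ppn_counts = cw.groupby("ppn")["upn"].nunique()
    upn_counts = cw.groupby("upn")["ppn"].nunique()
    return ResolutionReport(
        n_ppn=int(cw["ppn"].nunique()),
        n_upn=int(cw["upn"].nunique()),
        n_persons=n_persons,
        multiplicity_ppn_to_upn=ppn_counts.value_counts().sort_index().to_dict(),
        multiplicity_upn_to_ppn=upn_counts.value_counts().sort_index().to_dict(),
        merged_person_sets=merged_sets,
        person_map=person_map,
    )


def merge_person_events(
    bundle: LinkedEventBundle, report: ResolutionReport
) -> LinkedEventBundle:
    """Re-key all event tables to resolved person ids.

    Rows whose PPN is absent from the crosswalk keep their PPN as their
    person id (non-prisoner women are legitimately outside the OIMS
    crosswalk); incarceration rows with an unknown identifier are flagged
    ``unmatched_identity`` rather than dropped.
    """
    out = bundle.copy()
    pmap = report.person_map
    for name in EVENT_TABLES + ("crosswalk",):
        df = getattr(out, name)
        if not len(df):
            df = df.copy()
            df["person_id"] = pd.Series(dtype=object)
            setattr(out, name, df)
            continue
        keys = df["ppn"].astype(str).str.strip().str.upper()
        df = df.copy()
        df["person_id"] = [pmap.get(k, k) for k in keys]
        setattr(out, name, df)
    inc = out.incarcerations
    if len(inc):
        known = inc["ppn"].astype(str).str.strip().str.upper().isin(pmap)
        inc["unmatched_identity"] = ~known
        out.incarcerations = inc
    out.person_key = "person_id"
    return out


class IdentityResolver(BaseEstimator, TransformerMixin):
    """Transformer resolving multiple-matched identities on a bundle.

    ``fit`` learns the PPN-UPN component structure from the crosswalk;
    ``transform`` re-keys every event table to the resolved person ids.

    Attributes
    ----------
    report_ : ResolutionReport
        Component counts, both multiplicity histograms, and merged sets.
    """

    def fit(self, X: LinkedEventBundle, y=None) -> "IdentityResolver":
        if not isinstance(X, LinkedEventBundle):
            raise TypeError("X must be a LinkedEventBundle")
        if len(X.crosswalk) == 0:
            # No crosswalk rows (no prisoners): trivial resolution.
            self.report_ = ResolutionReport(0, 0, 0, {}, {}, [], {})
        else:
            self.report_ = resolve_identities(X.crosswalk)
        return self

    def transform(self, X: LinkedEventBundle) -> LinkedEventBundle:
        if not hasattr(self, "report_"):
            raise RuntimeError("IdentityResolver is not fitted")
        return merge_person_events(X, self.report_)
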