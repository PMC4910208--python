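"""Control selection, whole-population estimation and the cohort report.

The linked extract contains all prisoner mothers, all mothers with serious
mental health morbidity (MHM), and a random sample (by design 10 %) of
mothers with no linked records.  The community control set is the union of
that unlinked sample and an equally-sized random fraction of non-prisoner
MHM mothers.  The whole birthing-population size is estimated by weighting
the validated unlinked count by the inverse sampling fraction and adding
the validated linked count.  Censoring risk ratios across strata use the
Katz log-normal confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bundle import LinkedEventBundle
from .qc import CensoringAudit, build_audit, censor

DEFAULT_SAMPLING_FRACTION = 0.10


def risk_ratio(
    a: int, n1: int, b: int, n2: int, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """Risk ratio (a/n1)/(b/n2) with a Katz log-normal CI.

    ``exp(ln rr +/- z * sqrt(1/a - 1/n1 + 1/b - 1/n2))``.  A zero
    numerator yields rr 0 with an undefined CI (NaN); a zero reference
    rate is an error.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if a < 0 or b < 0 or a > n1 or b > n2:
        raise ValueError("event counts must satisfy 0 <= events <= total")
    if b == 0:
        raise ValueError("reference group has zero events; risk ratio undefined")
    rr = (a / n1) / (b / n2)
    if a == 0:
        warnings.warn("zero events in exposed group; CI undefined", stacklevel=2)
        return 0.0, math.nan, math.nan
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    log_rr = math.log(rr)
    return rr, math.exp(log_rr - z * se), math.exp(log_rr + z * se)


def estimate_population(
    validated_unlinked: int, validated_linked: int, weight: float = 10.0
) -> float:
    """Whole-population estimate: weight x unlinked sample + linked count."""
    if validated_unlinked < 0 or validated_linked < 0 or weight < 0:
        raise ValueError("counts and weight must be non-negative")
    return weight * validated_unlinked + validated_linked


def population_estimate_replicates(
    n_unlinked_total: int,
    n_linked: int,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    n_replicates: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo replicates of the sampling design's population estimate.

    Each replicate draws an independent Bernoulli retention sample of the
    unlinked population at ``sampling_fraction`` and applies
    :func:`estimate_population` with the inverse-fraction weight; used to
    verify the estimator is unbiased for ``n_unlinked_total + n_linked``.
    """
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_unlinked_total, sampling_fraction, size=n_replicates)
    weight = 1.0 / sampling_fraction
    return np.array([estimate_population(d, n_linked, weight) for d in draws])


def select_community_controls(
    mothers: pd.DataFrame,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    seed: int = 0,
    person_col: str = "person_id",
) -> pd.DataFrame:
    """Select the population-based community control set.

    The union of (a) every mother with no linked records (already a random
    sample of the unlinked population by the extract design) and (b) a
    seeded simple random sample, without replacement, of non-prisoner MHM
    mothers at ``sampling_fraction``.  Prisoner mothers are never controls.
    """
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError("sampling_fraction must be in (0, 1]")
    eligible = mothers[~mothers["is_prisoner"]]
    if not len(eligible):
        raise ValueError("no eligible non-prisoner mothers to select controls from")
    unlinked = eligible[~eligible["linked"]]
    pool = eligible[eligible["has_mhm"]].sort_values(person_col)
    rng = np.random.default_rng(seed)
    k = int(round(sampling_fraction * len(pool)))
    if k and len(pool):
        take = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        sampled = pool.iloc[np.sort(take)]
    else:
        sampled = pool.iloc[:0]
    controls = pd.concat([unlinked, sampled]).drop_duplicates(subset=person_col)
    return controls.reset_index(drop=True)


@dataclass
class CohortReport:
    """Final cohort accounting: audit, exposure cross-tab and estimates."""

    audit: CensoringAudit
    validated_mothers: pd.DataFrame
    community_controls: pd.DataFrame
    exposure_crosstab: pd.DataFrame
    mother_counts: Dict[str, int]
    population_estimate: float
    coverage: Optional[float]
    prevalences: Dict[str, float]
    rr_results: List[Tuple[str, float, float, float]]
    meta: Dict = field(default_factory=dict)


def exposure_crosstab(
    classifications: pd.DataFrame,
    mother_status: pd.DataFrame,
    person_col: str = "person_id",
) -> pd.DataFrame:
    """Timing-pattern cross-tabulation of prison maternities and controls.

    Rows are timing patterns; columns split prison maternities by place of
    birth, with own-control and peer-control maternity counts alongside.
    """
    own = set(
        mother_status.loc[mother_status["own_control"], person_col]
    )
    prison = classifications[classifications["status"] == "prison_pregnancy"]
    control = classifications[classifications["status"] == "prisoner_control"]
    patterns = sorted(set(prison["timing_pattern"])) or []
    rows = []
    for pat in patterns:
        sub = prison[prison["timing_pattern"] == pat]
        rows.append(
            {
                "timing_pattern": pat,
                "birth_out_of_prison": int((~sub["birth_in_prison"]).sum()),
                "birth_in_prison": int(sub["birth_in_prison"].sum()),
                "prison_maternities": len(sub),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "timing_pattern",
            "birth_out_of_prison",
            "birth_in_prison",
            "prison_maternities",
        ],
    )
    total = {
        "timing_pattern": "total",
        "birth_out_of_prison": int(df["birth_out_of_prison"].sum()) if len(df) else 0,
        "birth_in_prison": int(df["birth_in_prison"].sum()) if len(df) else 0,
        "prison_maternities": len(prison),
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df.attrs["own_control_maternities"] = int(
        control[person_col].isin(own).sum()
    )
    df.attrs["peer_control_maternities"] = int(
        (~control[person_col].isin(own)).sum()
    )
    return df


def build_report(
    bundle: LinkedEventBundle,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    weight: Optional[float] = None,
    seed: int = 0,
    true_population: Optional[int] = None,
) -> CohortReport:
    """Assemble the cohort report from a fully classified bundle.

    ``weight`` defaults to the inverse sampling fraction.  Margins that
    fail to reconcile raise, since that indicates a pipeline bug rather
    than a data problem.
    """
    key = bundle.person_key
    if bundle.decisions is None or bundle.classifications is None:
        raise ValueError("bundle is not fully classified; run the pipeline first")
    strata = bundle.meta.get("strata")
    if strata is None:
        raise ValueError("bundle lacks strata; run QualityChecker first")
    if weight is None:
        weight = 1.0 / sampling_fraction

    audit = build_audit(bundle.decisions, strata, bundle.maternities, key)
    validated_mat, censored_persons = censor(bundle.decisions, bundle.maternities, key)
    validated = strata[~strata[key].isin(censored_persons)].reset_index(drop=True)

    status = bundle.mother_status
    status = status[~status[key].isin(censored_persons)]
    n_pregnant = int((status["status"] == "pregnant_prisoner").sum())
    n_prisoner_control = int((status["status"] == "prisoner_control").sum())
    n_own = int(status["own_control"].sum())
    n_prisoner_mothers = int(validated["is_prisoner"].sum())
    if n_pregnant + n_prisoner_control != n_prisoner_mothers:
        raise ValueError(
            "margin mismatch: pregnant prisoners + prisoner controls "
            f"({n_pregnant} + {n_prisoner_control}) != validated prisoner "
            f"mothers ({n_prisoner_mothers})"
        )

    controls = select_community_controls(validated, sampling_fraction, seed, key)

    n_unlinked = int((~validated["linked"]).sum())
    n_linked = int(validated["linked"].sum())
    pop = estimate_population(n_unlinked, n_linked, weight)
    coverage = pop / true_population if true_population else None

    prevalences = {
        "prisoner": n_prisoner_mothers / pop if pop else math.nan,
        "mhm": float(validated["has_mhm"].sum()) / pop if pop else math.nan,
    }

    counts = audit.counts
    rr_results = []
    ref_n = int(counts.loc["person_records", "np_no_mhm"])
    ref_a = int(counts.loc["maternity_reason", "np_no_mhm"])
    for label, col in (
        ("maternity_censoring_prisoners_vs_unlinked", "all_prisoners"),
        ("maternity_censoring_mhm_vs_unlinked", "all_mhm"),
    ):
        n1 = int(counts.loc["person_records", col])
        a = int(counts.loc["maternity_reason", col])
        if a and ref_a:
            rr_results.append((label, *risk_ratio(a, n1, ref_a, ref_n)))

    crosstab = exposure_crosstab(
        bundle.classifications[
            ~bundle.classifications[key].isin(censored_persons)
        ],
        status,
        key,
    )

    return CohortReport(
        audit=audit,
        validated_mothers=validated,
        community_controls=controls,
        exposure_crosstab=crosstab,
        mother_counts={
            "pregnant_prisoners": n_pregnant,
            "prisoner_controls": n_prisoner_control,
            "own_controls": n_own,
            "prisoner_mothers": n_prisoner_mothers,
            "validated_mothers": len(validated),
            "censored_women": audit.censored_women,
            "censored_maternities": audit.censored_maternities,
            "validated_maternities": len(validated_mat),
        },
        population_estimate=pop,
        coverage=coverage,
        prevalences=prevalences,
        rr_results=rr_results,
        meta={
            "weight": weight,
            "sampling_fraction": sampling_fraction,
            "seed": seed,
        },
    )


class CohortReporter(BaseEstimator, TransformerMixin):
    """Final pipeline stage producing the :class:`CohortReport`.

    ``transform`` returns the report (ending the sklearn pipeline with the
    analysis artefact rather than a bundle).
    """

    def __init__(
        self,
        sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
        weight: Optional[float] = None,
        seed: int = 0,
        true_population: Optional[int] = None,
    ):
        self.sampling_fraction = sampling_fraction
        self.weight = weight
        self.seed = seed
        self.true_population = true_population

    def fit(self, X: LinkedEventBundle, y=None) -> "CohortReporter":
        self.report_ = build_report(
            X,
            sampling_fraction=self.sampling_fraction,
            weight=self.weight,
            seed=self.seed,
            true_population=self.true_population,
        )
        return self

    def transform(self, X: LinkedEventBundle) -> CohortReport:
        if not hasattr(self, "report_"):
            raise RuntimeError("CohortReporter is not fitted")
        return self.report_
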