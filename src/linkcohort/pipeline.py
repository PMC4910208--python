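"""End-to-end orchestration of the cohort preparation pipeline."""

from __future__ import annotations

from typing import Optional

from sklearn.pipeline import Pipeline

from .bundle import LinkedEventBundle
from .cohort import DEFAULT_SAMPLING_FRACTION, CohortReport, CohortReporter
from .exposure import DEFAULT_TOLERANCE_DAYS, ExposureClassifier
from .identities import IdentityResolver
from .qc import MhmCodeSets, QualityChecker
from .reshape import PersonReshaper


def make_cohort_pipeline(
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    weight: Optional[float] = None,
    seed: int = 0,
    true_population: Optional[int] = None,
    code_sets: MhmCodeSets = MhmCodeSets(),
) -> Pipeline:
    """Full sklearn pipeline: identities -> reshape -> QC -> exposure -> report."""
    return Pipeline(
        [
            ("identities", IdentityResolver()),
            ("reshape", PersonReshaper()),
            ("qc", QualityChecker(code_sets=code_sets)),
            ("exposure", ExposureClassifier(tolerance=tolerance)),
            (
                "report",
                CohortReporter(
                    sampling_fraction=sampling_fraction,
                    weight=weight,
                    seed=seed,
                    true_population=true_population,
                ),
            ),
        ]
    )


def prepare_cohort(
    bundle: LinkedEventBundle,
    tolerance: int = DEFAULT_TOLERANCE_DAYS,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    weight: Optional[float] = None,
    seed: int = 0,
    true_population: Optional[int] = None,
) -> CohortReport:
    """Run the whole pipeline on a raw bundle and return the cohort report."""
    pipe = make_cohort_pipeline(
        tolerance=tolerance,
        sampling_fraction=sampling_fraction,
        weight=weight,
        seed=seed,
        true_population=true_population,
    )
    return pipe.fit_transform(bundle)


def classify_bundle(
    bundle: LinkedEventBundle, tolerance: int = DEFAULT_TOLERANCE_DAYS
) -> LinkedEventBundle:
    """Run the pipeline up to exposure classification, returning the bundle."""
    partial = Pipeline(
        [
            ("identities", IdentityResolver()),
            ("reshape", PersonReshaper()),
            ("qc", QualityChecker()),
            ("exposure", ExposureClassifier(tolerance=tolerance)),
        ]
    )
    return partial.fit_transform(bundle)
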