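"""End-to-end orchestration: simulate -> predict -> design -> analyze -> select.

Glue used by the command-line interface, the test suite and the
reproduction script.  Each step delegates to the corresponding module;
nothing scientific lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_analysis import (
    NaiveBaseline,
    NormalizationResult,
    ReactivityCalls,
    ThresholdRule,
    call_reactive,
    fit_naive_baseline,
    median_normalize,
)
from .array_design import PeptideArrayDesign
from .io_formats import IntensityDataset
from .synthetic_data import (
    GroundTruth,
    ReferenceSet,
    SimParams,
    gen_cohort_arrays,
    simulate_reference,
)
from .vaccine_selection import (
    VaccineDesign,
    select_fast,
    select_nonreactive,
    select_pcv,
)

log = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """Positive-rate tables for one cohort."""

    cohort_id: str
    peptide_rates: pd.DataFrame
    antigen_rates: pd.DataFrame


@dataclass
class StudyResult:
    """Everything one simulated screen produces."""

    params: SimParams
    reference: ReferenceSet
    dataset: IntensityDataset
    truth: GroundTruth
    norm: NormalizationResult
    baseline: NaiveBaseline
    calls: ReactivityCalls
    cohorts: dict[str, CohortAnalysis] = field(default_factory=dict)

    @property
    def design(self) -> PeptideArrayDesign:
        return self.reference.design

    def challenged_subjects(self, cohort_id: str) -> list[str]:
        meta = self.calls.sample_meta
        return sorted(meta.loc[meta["cohort_id"] == cohort_id, "subject_id"].unique())

    def fast(self, cohort_id: str, k: int = 10) -> VaccineDesign:
        ca = self.cohorts[cohort_id]
        return select_fast(
            self.calls, self.design, ca.peptide_rates, ca.antigen_rates,
            self.norm, k=k, cohort_id=cohort_id,
        )

    def pcv(self, subject_id: str, cohort_id: str, k: int = 10) -> VaccineDesign:
        ca = self.cohorts[cohort_id]
        return select_pcv(
            self.norm, self.calls, self.design, subject_id,
            antigen_rates=ca.antigen_rates, k=k,
        )

    def nonreactive(self, subject_id: str, cohort_id: str, k: int = 10) -> VaccineDesign:
        ca = self.cohorts[cohort_id]
        return select_nonreactive(
            self.norm, self.calls, self.design, ca.peptide_rates, subject_id, k=k
        )


def analyze_dataset(
    dataset: IntensityDataset,
    design: PeptideArrayDesign | None,
    rule: ThresholdRule | None = None,
) -> tuple[NormalizationResult, NaiveBaseline, ReactivityCalls, dict[str, CohortAnalysis]]:
    """Normalize, fit the pooled naive baseline, call reactivity, rate."""
    from .array_analysis import positive_rates

    rule = rule or ThresholdRule()
    norm = median_normalize(dataset)
    baseline = fit_naive_baseline(norm, use_log10=rule.use_log10)
    calls = call_reactive(norm, baseline, rule)
    cohorts: dict[str, CohortAnalysis] = {}
    for cohort_id in sorted(calls.sample_meta["cohort_id"].unique()):
        pep, ant = positive_rates(calls, design=design, cohort_id=cohort_id)
        cohorts[cohort_id] = CohortAnalysis(cohort_id, pep, ant)
    return norm, baseline, calls, cohorts


def run_study(params: SimParams, rule: ThresholdRule | None = None) -> StudyResult:
    """Run the whole in-silico study for one seed."""
    rng = np.random.default_rng(params.seed)
    reference = simulate_reference(params, rng)
    dataset, truth = gen_cohort_arrays(reference.design, params, rng)
    norm, baseline, calls, cohorts = analyze_dataset(dataset, reference.design, rule)
    return StudyResult(
        params=params,
        reference=reference,
        dataset=dataset,
        truth=truth,
        norm=norm,
        baseline=baseline,
        calls=calls,
        cohorts=cohorts,
    )
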