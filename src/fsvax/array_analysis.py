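"""Immunosignature analysis: normalization, baselines, reactivity calls.

Raw fluorescence intensities are median-normalized per slide (each value
divided by the median of all spot values on its slide, making slides
directly comparable).  A naive baseline — the per-peptide mean and
standard deviation of pre-challenge/unchallenged sera — defines the
reactivity threshold: a post-challenge signal is called reactive when it
exceeds the naive mean by ``k`` standard deviations (default k = 2).

Thresholding is applied on log10-transformed normalized intensities by
default.  Peptide-array fluorescence is well described as log-normal, so
the mean + 2 SD rule attains its nominal one-sided Gaussian tail
(~2.3% false positives) only on the log scale; on the raw scale the
same rule is inflated by the distribution's right skew.  Linear-scale
thresholding remains available (``ThresholdRule(use_log10=False)``), as
does the literal ``k_sd_only`` reading of the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .array_design import PeptideArrayDesign
from .io_formats import IntensityDataset

log = logging.getLogger(__name__)

#: floor used before log-transforming, to guard background-subtracted zeros
_LOG_FLOOR = 1e-12


@dataclass
class ThresholdRule:
    """Reactivity-call rule: kind, multiplier k, and working scale."""

    kind: str = "mean_plus_k_sd"
    k: float = 2.0
    use_log10: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("mean_plus_k_sd", "k_sd_only"):
            raise ValueError(f"unknown threshold rule {self.kind!r}")
        if self.k <= 0:
            raise ValueError("threshold multiplier k must be positive")


@dataclass
class NormalizationResult:
    """Slide-median normalized intensities (dimensionless) + slide medians."""

    normalized: pd.DataFrame
    slide_medians: pd.Series
    sample_meta: pd.DataFrame


@dataclass
class NaiveBaseline:
    """Per-peptide naive mean/SD (sample SD, n-1) on the working scale.

    With ``moderated=True`` the per-peptide variances are squeezed
    toward a pooled prior by the empirical-Bayes scheme standard for
    small-sample microarray baselines; ``sigma`` is additionally floored
    at ``max(abs_floor, rel_floor * |mu|)`` so that zero-variance
    peptides cannot produce infinite z-scores.
    """

    mu: pd.Series
    sigma: pd.Series
    n_naive: int
    abs_floor: float
    rel_floor: float
    use_log10: bool
    moderated: bool = True
    prior_df: float = float("inf")
    prior_var: float = float("nan")


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in variance squeezing)."""
    from scipy.special import polygamma

    if y <= 0:
        return float("inf")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def _squeeze_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Shrink per-peptide sample variances toward a fitted prior.

    Models s2 ~ prior_var * chi2_df/df scaled by an inverse-chi2 prior
    with ``prior_df`` degrees of freedom, fitted by method of moments on
    log(s2); returns posterior variances (d0*s0^2 + df*s2)/(d0 + df).
    """
    from scipy.special import digamma, polygamma

    pos = s2[s2 > 0]
    if len(pos) < 2:
        return s2, 0.0, float(np.mean(s2))
    z = np.log(pos)
    evar = float(z.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 1e-10:
        d0 = 2.0 * _inv_trigamma(evar)
        s0 = float(
            np.exp(
                z.mean()
                - digamma(df / 2.0)
                + np.log(df / 2.0)
                + digamma(d0 / 2.0)
                - np.log(d0 / 2.0)
            )
        )
        post = (d0 * s0 + df * s2) / (d0 + df)
    else:  # no detectable spread beyond chi-square noise: fully pooled
        d0 = float("inf")
        s0 = float(np.exp(z.mean() - digamma(df / 2.0) + np.log(df / 2.0)))
        post = np.full_like(s2, s0)
    return post, d0, s0


@dataclass
class ReactivityCalls:
    """Boolean calls for challenged samples, with the rule recorded."""

    calls: pd.DataFrame
    sample_meta: pd.DataFrame
    threshold_rule: dict = field(default_factory=dict)


def median_normalize(dataset: IntensityDataset) -> NormalizationResult:
    """Divide every intensity by the median of all values on its slide.

    The per-slide median of the normalized values is exactly 1; a slide
    whose median is non-positive (e.g. all zeros) is a hard error.
    """
    norm = dataset.intensities.astype(float).copy()
    medians: dict[str, float] = {}
    for slide, idx in sorted(dataset.sample_meta.groupby("slide_id").groups.items()):
        m = float(np.median(dataset.intensities.loc[idx].to_numpy()))
        if m <= 0:
            raise ValueError(f"slide {slide!r}: non-positive median intensity")
        norm.loc[idx] = dataset.intensities.loc[idx] / m
        medians[str(slide)] = m
    return NormalizationResult(norm, pd.Series(medians), dataset.sample_meta.copy())


def fit_naive_baseline(
    norm: NormalizationResult,
    use_log10: bool = True,
    abs_floor: float = 1e-6,
    rel_floor: float = 0.01,
    moderate_variance: bool = True,
) -> NaiveBaseline:
    """Per-peptide mean and SD over the naive (pre-challenge) samples.

    With tens of naive sera the raw per-peptide SD is a noisy estimate;
    peptides whose SD is undershot by chance acquire inflated
    false-positive rates that are correlated across every challenged
    sample.  ``moderate_variance`` (default) squeezes the per-peptide
    variances toward an empirical-Bayes prior fitted across peptides,
    stabilising the 2-SD threshold; set it to False for the plain
    textbook estimator.
    """
    naive_idx = norm.sample_meta.index[norm.sample_meta["group"] == "naive"]
    n = len(naive_idx)
    if n < 2:
        raise ValueError(f"need >= 2 naive samples to fit a baseline, got {n}")
    vals = norm.normalized.loc[naive_idx]
    if use_log10:
        vals = np.log10(np.maximum(vals, _LOG_FLOOR))
    mu = vals.mean(axis=0)
    s2 = vals.var(axis=0, ddof=1)
    prior_df, prior_var = 0.0, float("nan")
    if moderate_variance:
        post, prior_df, prior_var = _squeeze_variances(s2.to_numpy(), n - 1)
        sigma = pd.Series(np.sqrt(post), index=s2.index)
    else:
        sigma = np.sqrt(s2)
    floor = np.maximum(abs_floor, rel_floor * mu.abs())
    sigma = np.maximum(sigma, floor)
    return NaiveBaseline(
        mu, sigma, n, abs_floor, rel_floor, use_log10,
        moderated=moderate_variance, prior_df=prior_df, prior_var=prior_var,
    )


def call_reactive(
    norm: NormalizationResult,
    baseline: NaiveBaseline,
    rule: ThresholdRule | None = None,
) -> ReactivityCalls:
    """Call per-sample peptide reactivity for all challenged samples.

    Default rule ``mean_plus_k_sd``: reactive iff value > mu + k*sigma;
    alternative ``k_sd_only``: value > k*sigma.  Calls are monotone in
    intensity.  The rule's scale must match the baseline's.
    """
    rule = rule or ThresholdRule(use_log10=baseline.use_log10)
    if rule.use_log10 != baseline.use_log10:
        raise ValueError("threshold rule and baseline use different scales")
    if not norm.normalized.columns.equals(baseline.mu.index):
        raise ValueError("baseline was fitted on a different peptide set")
    chal_idx = norm.sample_meta.index[norm.sample_meta["group"] == "challenged"]
    if len(chal_idx) == 0:
        raise ValueError("no challenged samples: nothing to call")
    vals = norm.normalized.loc[chal_idx]
    if rule.use_log10:
        vals = np.log10(np.maximum(vals, _LOG_FLOOR))
    if rule.kind == "mean_plus_k_sd":
        threshold = baseline.mu + rule.k * baseline.sigma
    else:
        threshold = rule.k * baseline.sigma
    calls = vals.gt(threshold, axis=1)
    return ReactivityCalls(
        calls,
        norm.sample_meta.loc[chal_idx].copy(),
        threshold_rule=asdict(rule),
    )


def round_rate_pct(fraction: float) -> float:
    """Report a rate as a percentage, rounded half-up to 1 decimal."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(
        Decimal(repr(fraction * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def positive_rates(
    calls: ReactivityCalls,
    design: PeptideArrayDesign | None = None,
    cohort_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-peptide (and per-antigen) prevalence among challenged samples.

    The peptide rate is 100 * n_reactive / n_challenged; the antigen rate
    aggregates its tiles with any-reactive-tile logic, so an antigen's
    rate is always >= each of its tiles'.  ``rate_pct`` is reported to 1
    decimal (half-up); ``rate_frac`` keeps full precision.  Counts and
    denominators are reported alongside.
    """
    meta = calls.sample_meta
    if cohort_id is None:
        rows = meta.index
    else:
        rows = meta.index[meta["cohort_id"] == cohort_id]
    if len(rows) == 0:
        raise ValueError(f"no challenged samples in cohort {cohort_id!r}")
    sub = calls.calls.loc[rows]
    n = len(rows)
    pep = pd.DataFrame(
        {
            "n_reactive": sub.sum(axis=0).astype(int),
            "n_total": n,
            "rate_frac": sub.mean(axis=0),
        }
    )
    pep["rate_pct"] = pep["rate_frac"].map(round_rate_pct)
    pep.index.name = "peptide_id"

    ant = None
    if design is not None:
        rows_out = {}
        for aid in design.antigen_ids():
            tiles = [p for p in design.antigen_peptides[aid] if p in sub.columns]
            if not tiles:
                continue
            any_reactive = sub[tiles].any(axis=1)
            rows_out[aid] = {
                "n_reactive": int(any_reactive.sum()),
                "n_total": n,
                "rate_frac": float(any_reactive.mean()),
            }
        ant = pd.DataFrame.from_dict(rows_out, orient="index").sort_index()
        ant["n_reactive"] = ant["n_reactive"].astype(int)
        ant["n_total"] = ant["n_total"].astype(int)
        ant["rate_pct"] = ant["rate_frac"].map(round_rate_pct)
        ant.index.name = "antigen_id"
    return pep, ant
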