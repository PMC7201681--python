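"""Synthetic transcriptomes and array cohorts with known ground truth.

The generator emulates the study design end-to-end so every pipeline
stage is testable without external data:

* **Transcriptomes** — CDSs that start with ATG, carry no internal
  in-frame stop and end with a stop codon, each hosting one planted
  mononucleotide run (>= 7 nt).  The region downstream of the run is
  sampled with depleted T content so that frameshifted reading frames
  stay open long enough to yield array-sized frameshift peptides; a
  configurable fraction of transcripts also gets a 4-exon structure
  with a frame-disrupting internal exon.
* **Reference antigen set / array** — the real predictor and tiler are
  run on the synthetic transcriptome and the top ``n_antigens_target``
  antigens (majority microsatellite INDELs, remainder exon skips) are
  tiled into a ~200-antigen / ~800-peptide in-silico array.
* **Cohorts** — each challenged subject contributes a paired
  pre-challenge (naive, T0) and post-challenge (T7) sample.  Background
  intensity is log10-normal with per-slide multiplicative scale factors;
  a subject is seroreactive to a planted shared antigen with that
  antigen's cohort prevalence, plus a fixed number of personal antigens;
  antigen-level reactivity is thinned per tile, and reactive spots are
  multiplied by a fold effect with log-normal jitter.  Naive samples
  never receive effects.

Everything is fully determined by the seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_design import DesignParams, PeptideArrayDesign, build_design
from .fs_prediction import (
    FrameshiftAntigen,
    PredictionParams,
    predict_missplice_antigens,
    predict_ms_antigens,
    _antigen_sort_key,
    _dedup_keep_first,
)
from .io_formats import IntensityDataset, TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)


def _codon_weights(base_probs: dict[str, float]) -> np.ndarray:
    w = np.array(
        [np.prod([base_probs[b] for b in codon]) for codon in SENSE_CODONS]
    )
    return w / w.sum()


#: uniform base composition for the region upstream of the planted run
_W_UNIFORM = _codon_weights({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
#: T-depleted composition downstream of the run: stop codons all begin
#: with T, so low T keeps the shifted frames open long enough for
#: array-sized FSPs averaging ~4 tiles per antigen
_W_DEPLETED = _codon_weights({"A": 0.30, "C": 0.30, "G": 0.27, "T": 0.13})


@dataclass
class CohortSpec:
    """One tumor-challenge cohort; naive samples are the subjects' T0 sera."""

    name: str
    n_challenged: int


@dataclass
class PlantedAntigen:
    """A shared antigen planted at a given seroprevalence per cohort."""

    label: str
    prevalence: dict[str, float]

    def __post_init__(self) -> None:
        for cohort, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.label}: prevalence {p} for {cohort} not in [0,1]")


@dataclass
class SimParams:
    """All knobs of the simulation; the seed fully determines the output.

    Background fluorescence is 10**N(mu_b, sigma_b) (arbitrary units,
    mu_b=3 ~ 1000 counts); reactive spots are multiplied by
    ``effect_fold`` * 10**N(0, effect_jitter).  ``per_tile_prob`` thins
    antigen-level reactivity to individual tiles; see the methods note
    for the closed-form calibration of its default.
    """

    seed: int = 0
    n_transcripts: int = 240
    cds_len_range: tuple[int, int] = (450, 1200)
    utr3_len_range: tuple[int, int] = (150, 400)
    run_length_choices: tuple[int, ...] = (7, 8, 9, 10, 11, 12, 14)
    run_length_weights: tuple[float, ...] = (0.30, 0.22, 0.16, 0.12, 0.09, 0.06, 0.05)
    exon_fraction: float = 0.3
    n_antigens_target: int = 200
    ms_fraction: float = 0.85
    cohorts: list[CohortSpec] = field(
        default_factory=lambda: [CohortSpec("breast", 24), CohortSpec("pancreatic", 18)]
    )
    planted_shared: list[PlantedAntigen] = field(default_factory=list)
    n_personal: int = 8
    mu_b: float = 3.0
    sigma_b: float = 0.15
    effect_fold: float = 8.0
    effect_jitter: float = 0.1
    per_tile_prob: float = 0.7
    subjects_per_slide: int = 8
    slide_scale_sigma: float = 0.15
    prediction: PredictionParams = field(default_factory=PredictionParams)
    design: DesignParams = field(default_factory=DesignParams)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests, consistent with the emitted data."""

    planted_antigens: dict[str, str]  # label -> concrete antigen id
    cohort_prevalence: dict[str, dict[str, float]]  # cohort -> antigen -> p
    subjects: dict[str, dict]  # subject -> {cohort, reactive_antigens, reactive_peptides}
    slide_scales: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "planted_antigens": self.planted_antigens,
            "cohort_prevalence": self.cohort_prevalence,
            "subjects": self.subjects,
            "slide_scales": self.slide_scales,
        }


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _gen_cds(rng: np.random.Generator, n_codons: int, run_base: str, run_len: int) -> str:
    """One CDS with a planted maximal homopolymer and no in-frame stop."""
    length = 3 * n_codons
    if length < run_len + 60:
        raise ValueError("cds_len_range too small to host the planted run")
    run_start = int(rng.integers(length // 4, length // 2))
    run_start = min(run_start, length - run_len - 6)
    boundary = run_start // 3

    n_body = n_codons - 2
    n_up = max(0, min(boundary - 1, n_body))
    up = rng.choice(SENSE_CODONS, size=n_up, p=_W_UNIFORM) if n_up else []
    down = (
        rng.choice(SENSE_CODONS, size=n_body - n_up, p=_W_DEPLETED)
        if n_body - n_up
        else []
    )
    stop = STOP_CODONS[int(rng.integers(3))]
    seq = list("ATG" + "".join(up) + "".join(down) + stop)

    # plant the run and guard its flanks so it stays maximal
    for j in range(run_len):
        seq[run_start + j] = run_base
    guard = "C" if run_base != "C" else "A"
    run_span = set(range(run_start, run_start + run_len))
    gl, gr = run_start - 1, run_start + run_len
    flanks = {gl, gr}
    if gl >= 3 and seq[gl] == run_base:
        seq[gl] = guard
    if gr < length - 3 and seq[gr] == run_base:
        seq[gr] = guard

    # planting may have created in-frame stops across codon boundaries;
    # repair by mutating a non-run position (stop codons are never
    # homopolymers, so one always exists) to a base that de-stops the
    # codon without re-extending the run at a flank
    for ci in range(1, n_codons - 1):
        codon = seq[3 * ci : 3 * ci + 3]
        if "".join(codon) in STOP_CODONS:
            for k in range(3):
                pos = 3 * ci + k
                if pos in run_span:
                    continue
                for char in "CGTA":
                    if pos in flanks and char == run_base:
                        continue
                    trial = codon.copy()
                    trial[k] = char
                    if "".join(trial) not in STOP_CODONS:
                        seq[pos] = char
                        break
                else:
                    continue
                break
    return "".join(seq)


def _make_exons(rng: np.random.Generator, cds_len: int) -> list[int]:
    """A 4-exon decomposition with a frame-disrupting internal exon."""
    if cds_len < 300:
        return []
    e2 = int(rng.integers(20, 81))
    if e2 % 3 == 0:
        e2 += 1
    lo1, hi1 = 60, cds_len - e2 - 120
    e1 = int(rng.integers(lo1, min(hi1, cds_len // 3) + 1))
    rest = cds_len - e1 - e2
    e3 = int(rng.integers(60, rest - 60 + 1))
    e4 = rest - e3
    return [e1, e2, e3, e4]


def gen_transcriptome(
    params: SimParams, rng: np.random.Generator | None = None
) -> list[TranscriptModel]:
    """Generate ``n_transcripts`` CDSs with planted runs, UTRs and exons."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = params.cds_len_range
    if hi < max(params.run_length_choices) + 60:
        raise ValueError("cds_len_range too small to host a planted run")
    run_w = np.asarray(params.run_length_weights, dtype=float)
    run_w = run_w / run_w.sum()
    out = []
    for i in range(params.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        base = "ACGT"[int(rng.integers(4))]
        run_len = int(rng.choice(params.run_length_choices, p=run_w))
        cds = _gen_cds(rng, n_codons, base, run_len)
        utr3 = "".join(
            np.array(list("ACGT"))[
                rng.integers(0, 4, size=int(rng.integers(*params.utr3_len_range)))
            ]
        )
        exons = (
            _make_exons(rng, len(cds)) if rng.random() < params.exon_fraction else []
        )
        out.append(TranscriptModel(f"T{i:04d}", cds, utr3, exons))
    return out


# ---------------------------------------------------------------------------
# reference antigen set and array
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    transcripts: list[TranscriptModel]
    antigens: list[FrameshiftAntigen]
    design: PeptideArrayDesign


def select_reference_antigens(
    transcripts: list[TranscriptModel], params: SimParams
) -> list[FrameshiftAntigen]:
    """Top ``n_antigens_target`` antigens: MS INDELs first, exon skips fill.

    Microsatellite antigens are taken in their longest-repeat-first
    order up to ``ms_fraction`` of the target; frame-disrupting exon
    skips (longest peptide first) fill the remainder.
    """
    pp = params.prediction
    ms = predict_ms_antigens(transcripts, pp)
    skips: list[FrameshiftAntigen] = []
    for t in transcripts:
        if len(t.exon_lengths) >= 3:
            skips.extend(predict_missplice_antigens(t, pp))
    skips.sort(key=_antigen_sort_key)
    ms_peps = {a.fs_peptide for a in ms}
    skips = _dedup_keep_first([a for a in skips if a.fs_peptide not in ms_peps])

    target = params.n_antigens_target
    n_ms = min(len(ms), int(round(params.ms_fraction * target)))
    chosen = ms[:n_ms] + skips[: max(0, target - n_ms)]
    if len(chosen) < target:  # fall back to more MS antigens
        extra = [a for a in ms[n_ms:]][: target - len(chosen)]
        chosen += extra
    if len(chosen) < target:
        log.warning("only %d antigens available (target %d)", len(chosen), target)
    return chosen


def simulate_reference(
    params: SimParams, rng: np.random.Generator | None = None
) -> ReferenceSet:
    """Synthetic transcriptome -> predicted antigens -> tiled array."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    transcripts = gen_transcriptome(params, rng)
    antigens = select_reference_antigens(transcripts, params)
    design = build_design(antigens, transcripts, params.design)
    return ReferenceSet(transcripts, antigens, design)


# ---------------------------------------------------------------------------
# cohort arrays
# ---------------------------------------------------------------------------

def gen_cohort_arrays(
    design: PeptideArrayDesign,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityDataset, GroundTruth]:
    """Simulate the serum screen for every cohort on the given array.

    intensity(sample, peptide) =
        slide_scale * 10**N(mu_b, sigma_b)
        * (effect_fold * 10**N(0, effect_jitter)  if the sample is
           post-challenge and the spot is reactive in that subject, else 1)
    """
    if not design.peptides:
        raise ValueError("empty array design")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    antigen_ids = design.antigen_ids()
    peptide_ids = sorted(design.peptide_ids)
    n_pep = len(peptide_ids)
    col_of = {p: i for i, p in enumerate(peptide_ids)}

    # assign planted labels to concrete antigens; shared candidates are
    # drawn from the well-tiled antigens (the study's shared antigens
    # were multi-peptide by construction), falling back to all antigens
    # when the array is too small
    well_tiled = [a for a in antigen_ids if len(design.antigen_peptides[a]) >= 3]
    pool = well_tiled if len(well_tiled) >= len(params.planted_shared) else antigen_ids
    perm = [pool[i] for i in rng.permutation(len(pool))]
    if len(params.planted_shared) > len(pool):
        raise ValueError("more planted antigens than antigens on the array")
    planted_map = {
        pa.label: perm[i] for i, pa in enumerate(params.planted_shared)
    }
    planted_concrete = set(planted_map.values())
    personal_pool = sorted(set(antigen_ids) - planted_concrete)
    if params.n_personal > len(personal_pool):
        raise ValueError("personal antigen count exceeds the non-planted pool")

    cohort_prev = {
        c.name: {
            planted_map[pa.label]: pa.prevalence.get(c.name, 0.0)
            for pa in params.planted_shared
        }
        for c in params.cohorts
    }

    matrices = []
    meta_rows = []
    subjects_truth: dict[str, dict] = {}
    slide_scales: dict[str, float] = {}

    for cohort in params.cohorts:
        for s in range(cohort.n_challenged):
            subject = f"{cohort.name}_m{s:02d}"
            slide = f"{cohort.name}_sl{s // params.subjects_per_slide:02d}"
            if slide not in slide_scales:
                slide_scales[slide] = float(
                    10 ** rng.normal(0.0, params.slide_scale_sigma)
                )
            # antigen-level truth
            reactive_antigens = [
                aid
                for aid, p in sorted(cohort_prev[cohort.name].items())
                if rng.random() < p
            ]
            personal = [
                personal_pool[i]
                for i in rng.choice(
                    len(personal_pool), size=params.n_personal, replace=False
                )
            ]
            reactive_antigens = sorted(set(reactive_antigens) | set(personal))
            # per-tile thinning
            reactive_peptides: set[str] = set()
            for aid in reactive_antigens:
                for pid in design.antigen_peptides[aid]:
                    if pid in reactive_peptides:
                        continue
                    if rng.random() < params.per_tile_prob:
                        reactive_peptides.add(pid)

            background = 10 ** rng.normal(params.mu_b, params.sigma_b, size=(2, n_pep))
            post = background[1].copy()
            react_cols = [col_of[p] for p in sorted(reactive_peptides)]
            if react_cols:
                post[react_cols] *= params.effect_fold * 10 ** rng.normal(
                    0.0, params.effect_jitter, size=len(react_cols)
                )
            scale = slide_scales[slide]
            matrices.append(background[0] * scale)
            matrices.append(post * scale)
            for timepoint, group in (("T0", "naive"), ("T7", "challenged")):
                meta_rows.append(
                    {
                        "sample_id": f"{subject}_{timepoint}",
                        "group": group,
                        "slide_id": slide,
                        "cohort_id": cohort.name,
                        "subject_id": subject,
                        "timepoint": timepoint,
                    }
                )
            subjects_truth[subject] = {
                "cohort": cohort.name,
                "reactive_antigens": reactive_antigens,
                "reactive_peptides": sorted(reactive_peptides),
            }

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    mat = pd.DataFrame(np.vstack(matrices), index=meta.index, columns=peptide_ids)
    dataset = IntensityDataset(mat, meta)
    truth = GroundTruth(
        planted_antigens=planted_map,
        cohort_prevalence=cohort_prev,
        subjects=subjects_truth,
        slide_scales=slide_scales,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# study profiles
# ---------------------------------------------------------------------------

#: shared-antigen prevalences of the breast-cohort vaccine candidates
#: (denominator 24): 20, 13, 9, 8, 8 and five times 7 reactive subjects
BREAST_PREVALENCES = (
    20 / 24, 13 / 24, 9 / 24, 8 / 24, 8 / 24,
    7 / 24, 7 / 24, 7 / 24, 7 / 24, 7 / 24,
)
#: pancreatic-cohort prevalences of the same ten antigens (denominator 18)
BREAST_CROSS_PREVALENCES = (
    0.0, 1 / 18, 0.0, 5 / 18, 18 / 18,
    0.0, 0.0, 2 / 18, 8 / 18, 16 / 18,
)
#: pancreatic-cohort vaccine candidates (denominator 18)
PANCREATIC_PREVALENCES = (
    18 / 18, 17 / 18, 16 / 18, 14 / 18, 9 / 18,
    8 / 18, 6 / 18, 6 / 18, 5 / 18, 5 / 18,
)


def table1_profile(seed: int = 0) -> SimParams:
    """The study-shaped preset: two cohorts, 200 antigens, ~800 tiles.

    The breast cohort (n=24 challenged) carries ten planted shared
    antigens at the published prevalence spectrum (0.833 down to five at
    0.292); the pancreatic cohort (n=18) carries its own ten candidates
    plus cross-reactivity of the breast set.
    """
    planted = [
        PlantedAntigen(
            label=f"BC{i+1:02d}",
            prevalence={"breast": p, "pancreatic": q},
        )
        for i, (p, q) in enumerate(zip(BREAST_PREVALENCES, BREAST_CROSS_PREVALENCES))
    ] + [
        PlantedAntigen(
            label=f"PC{i+1:02d}",
            prevalence={"breast": 0.0, "pancreatic": p},
        )
        for i, p in enumerate(PANCREATIC_PREVALENCES)
    ]
    return SimParams(seed=seed, planted_shared=planted)


def minimal_profile(seed: int = 0) -> SimParams:
    """A small single-cohort preset for smoke tests and examples."""
    planted = [
        PlantedAntigen(label=f"D{i+1:02d}", prevalence={"demo": p})
        for i, p in enumerate((0.8, 0.6, 0.5, 0.4, 0.3))
    ]
    return SimParams(
        seed=seed,
        n_transcripts=60,
        n_antigens_target=40,
        cohorts=[CohortSpec("demo", 6)],
        planted_shared=planted,
        n_personal=4,
    )
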