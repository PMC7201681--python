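"""Selection of vaccine peptide sets from immunosignature reactivity.

Three designs are produced from the same screen:

* **PCV** (personal cancer vaccine): per subject, the top-k frameshift
  antigens by peak reactive-tile intensity, expanded to *all* of the
  subject's reactive tiles of those antigens — so a 10-antigen PCV can
  contain more than 10 peptides.
* **FAST** (shared vaccine): the top-k antigens by cohort positive rate
  (any-reactive-tile), each represented by its single most prevalent
  tile, giving exactly k peptides for a fixed-dose pool.
* **NR** (non-reactive control): per subject, k peptides non-reactive in
  that subject, preferring peptides that are cold across the cohort, at
  most one per antigen.

All tie-breaks are fully specified (rate, then intensity, then lexical
id) so every selection is deterministic and invariant to sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_analysis import NormalizationResult, ReactivityCalls
from .array_design import PeptideArrayDesign

log = logging.getLogger(__name__)

PCV = "PCV"
FAST = "FAST"
NR = "NR"


@dataclass
class VaccineDesign:
    """A selected peptide set with per-antigen provenance and scores."""

    design_type: str
    subject_id: str
    selected_antigens: list[tuple[str, float]]
    peptides: list[str]
    params: dict = field(default_factory=dict)

    def to_table(self, design: PeptideArrayDesign | None = None) -> pd.DataFrame:
        seqs = design.sequences if design is not None else {}
        pep_parent = {}
        if design is not None:
            chosen = {a for a, _ in self.selected_antigens}
            for pid in self.peptides:
                owners = [a for a in design.parents.get(pid, []) if a in chosen]
                pep_parent[pid] = owners[0] if owners else design.parents.get(pid, ["?"])[0]
        scores = dict(self.selected_antigens)
        rank = {a: i + 1 for i, (a, _) in enumerate(self.selected_antigens)}
        rows = []
        for pid in self.peptides:
            aid = pep_parent.get(pid, "")
            rows.append(
                {
                    "design_type": self.design_type,
                    "subject_id": self.subject_id,
                    "rank": rank.get(aid, 0),
                    "antigen_id": aid,
                    "peptide_id": pid,
                    "sequence": seqs.get(pid, ""),
                    "score": scores.get(aid, float("nan")),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "design_type", "subject_id", "rank", "antigen_id",
                "peptide_id", "sequence", "score",
            ],
        )


def _subject_rows(calls: ReactivityCalls, subject_id: str) -> pd.Index:
    meta = calls.sample_meta
    rows = meta.index[meta["subject_id"] == subject_id]
    if len(rows) == 0:
        raise ValueError(f"subject {subject_id!r} has no challenged samples")
    return rows


def select_pcv(
    norm: NormalizationResult,
    calls: ReactivityCalls,
    design: PeptideArrayDesign,
    subject_id: str,
    antigen_rates: pd.DataFrame | None = None,
    k: int = 10,
) -> VaccineDesign:
    """Personal vaccine: top-k antigens by peak reactive-tile intensity.

    Antigens are scored by the maximum normalized intensity among their
    reactive tiles in this subject; the top-k *distinct* antigens are
    chosen (ties broken by cohort antigen positive rate, then lexical
    id) and the vaccine receives every reactive tile of the chosen
    antigens, so the peptide count lies in [k, total tiles].
    """
    rows = _subject_rows(calls, subject_id)
    sub_calls = calls.calls.loc[rows].any(axis=0)
    reactive = set(sub_calls.index[sub_calls])
    if not reactive:
        raise ValueError(f"subject {subject_id!r} has no reactive peptides")
    peak = norm.normalized.loc[rows].max(axis=0)

    rate_frac = (
        antigen_rates["rate_frac"] if antigen_rates is not None else pd.Series(dtype=float)
    )
    scored = []
    for aid in design.antigen_ids():
        tiles = [p for p in design.antigen_peptides[aid] if p in reactive]
        if not tiles:
            continue
        score = float(peak[tiles].max())
        scored.append((aid, score, float(rate_frac.get(aid, 0.0)), tiles))
    scored.sort(key=lambda x: (-x[1], -x[2], x[0]))
    if len(scored) < k:
        log.warning(
            "subject %s: only %d reactive antigens (< k=%d), returning all",
            subject_id, len(scored), k,
        )
    chosen = scored[:k]
    peptides = sorted({p for _, _, _, tiles in chosen for p in tiles})
    return VaccineDesign(
        design_type=PCV,
        subject_id=subject_id,
        selected_antigens=[(aid, score) for aid, score, _, _ in chosen],
        peptides=peptides,
        params={"k_antigens": k, "tie_break": ["peak_intensity", "cohort_rate", "antigen_id"]},
    )


def select_fast(
    calls: ReactivityCalls,
    design: PeptideArrayDesign,
    peptide_rates: pd.DataFrame,
    antigen_rates: pd.DataFrame,
    norm: NormalizationResult,
    k: int = 10,
    cohort_id: str | None = None,
) -> VaccineDesign:
    """Shared vaccine: top-k antigens by cohort prevalence, one tile each.

    Antigens are ranked by their any-reactive-tile cohort positive rate
    (descending); ties are broken by the mean normalized intensity over
    the antigen's reactive (sample, tile) pairs, then lexical id.  Each
    chosen antigen contributes its most prevalent tile (ties: higher
    mean reactive intensity, then lexical id), so the vaccine holds
    exactly k peptides.  The result is invariant to sample order.
    ``cohort_id`` restricts the samples to the cohort the rates were
    computed on.
    """
    meta = calls.sample_meta
    rows = meta.index if cohort_id is None else meta.index[meta["cohort_id"] == cohort_id]
    if len(rows) < 2:
        raise ValueError("FAST selection needs a cohort of >= 2 challenged samples")
    sub = calls.calls.loc[rows]
    vals = norm.normalized.loc[rows]

    def _mean_reactive_intensity(tiles: list[str]) -> float:
        mask = sub[tiles].to_numpy()
        if not mask.any():
            return float("-inf")
        return float(vals[tiles].to_numpy()[mask].mean())

    scored = []
    for aid in design.antigen_ids():
        if aid not in antigen_rates.index:
            continue
        rate = float(antigen_rates.loc[aid, "rate_frac"])
        if rate <= 0:
            continue
        tiles = [p for p in design.antigen_peptides[aid] if p in sub.columns]
        scored.append((aid, rate, _mean_reactive_intensity(tiles), tiles))
    scored.sort(key=lambda x: (-x[1], -x[2], x[0]))
    if len(scored) < k:
        log.warning(
            "only %d antigens ever reactive (< k=%d), returning all", len(scored), k
        )
    chosen = scored[:k]

    peptides = []
    for aid, _, _, tiles in chosen:
        tile_rank = sorted(
            tiles,
            key=lambda p: (
                -float(peptide_rates.loc[p, "rate_frac"]) if p in peptide_rates.index else 0.0,
                -_mean_reactive_intensity([p]),
                p,
            ),
        )
        peptides.append(tile_rank[0])
    return VaccineDesign(
        design_type=FAST,
        subject_id="cohort",
        selected_antigens=[(aid, rate) for aid, rate, _, _ in chosen],
        peptides=peptides,
        params={"k_antigens": k, "tie_break": ["cohort_rate", "mean_intensity", "antigen_id"]},
    )


def select_nonreactive(
    norm: NormalizationResult,
    calls: ReactivityCalls,
    design: PeptideArrayDesign,
    peptide_rates: pd.DataFrame,
    subject_id: str,
    k: int = 10,
) -> VaccineDesign:
    """Negative-control vaccine: k peptides non-reactive in the subject.

    Among the subject's non-reactive peptides, the k with the lowest
    cohort positive rate are chosen (ties: lowest subject intensity,
    then lexical id), at most one per antigen so the control spans
    distinct frameshifts; if fewer antigens than k carry non-reactive
    tiles the one-per-antigen constraint is relaxed with a warning.
    """
    rows = _subject_rows(calls, subject_id)
    sub_calls = calls.calls.loc[rows].any(axis=0)
    nonreactive = [p for p in calls.calls.columns if not sub_calls[p]]
    if len(nonreactive) < k:
        raise ValueError(
            f"subject {subject_id!r} has only {len(nonreactive)} non-reactive "
            f"peptides (< k={k})"
        )
    peak = norm.normalized.loc[rows].max(axis=0)
    ordered = sorted(
        nonreactive,
        key=lambda p: (
            float(peptide_rates.loc[p, "rate_frac"]) if p in peptide_rates.index else 0.0,
            float(peak[p]),
            p,
        ),
    )
    chosen: list[str] = []
    used_antigens: set[str] = set()
    for pid in ordered:
        pars = design.parents.get(pid, [])
        if used_antigens & set(pars):
            continue
        chosen.append(pid)
        used_antigens.update(pars)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        log.warning(
            "subject %s: fewer than %d antigens with non-reactive tiles; "
            "relaxing one-per-antigen constraint", subject_id, k,
        )
        for pid in ordered:
            if pid not in chosen:
                chosen.append(pid)
                if len(chosen) == k:
                    break
    selected = [
        (design.parents.get(pid, ["?"])[0],
         float(peptide_rates.loc[pid, "rate_frac"]) if pid in peptide_rates.index else 0.0)
        for pid in chosen
    ]
    return VaccineDesign(
        design_type=NR,
        subject_id=subject_id,
        selected_antigens=selected,
        peptides=chosen,
        params={"k_peptides": k, "tie_break": ["cohort_rate", "subject_intensity", "peptide_id"]},
    )


def cross_cohort_overlap(
    fast: VaccineDesign,
    antigen_rates_other: pd.DataFrame,
    floor_pct: float = 0.0,
) -> tuple[pd.DataFrame, int]:
    """Cross-tabulate a FAST vaccine's antigens against another cohort.

    For each antigen of vaccine A, report its positive rate in cohort B;
    the second return value counts antigens whose rate exceeds
    ``floor_pct`` in *both* cohorts.  Raises when the two screens share
    no antigen at all (disjoint designs).
    """
    ids = [a for a, _ in fast.selected_antigens]
    present = [a for a in ids if a in antigen_rates_other.index]
    if not present:
        raise ValueError("no shared antigens between the vaccine and the other cohort")
    if len(present) < len(ids):
        log.warning(
            "%d vaccine antigen(s) missing from the other cohort's rates; reported as 0",
            len(ids) - len(present),
        )
    from .array_analysis import round_rate_pct

    rows = []
    n_both = 0
    for aid, rate_a in fast.selected_antigens:
        if aid in antigen_rates_other.index:
            rate_b = float(antigen_rates_other.loc[aid, "rate_frac"])
        else:
            rate_b = 0.0
        rate_a_pct = round_rate_pct(rate_a)
        rate_b_pct = round_rate_pct(rate_b)
        if rate_a_pct > floor_pct and rate_b_pct > floor_pct:
            n_both += 1
        rows.append({"antigen_id": aid, "rate_a_pct": rate_a_pct, "rate_b_pct": rate_b_pct})
    return pd.DataFrame(rows).set_index("antigen_id"), n_both
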