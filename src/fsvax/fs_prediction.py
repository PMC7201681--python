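"""Frameshift-antigen prediction from transcript models.

Two classes of RNA-processing error are modelled:

* single-base insertion/deletion (INDEL) slippage during transcription
  through a coding mononucleotide microsatellite (homopolymer) run, and
* skipping of an internal exon whose length is not a multiple of 3.

Either event shifts the downstream reading frame; translation then
proceeds in the novel frame (optionally reading through the 3'UTR) until
the first stop codon, producing a frameshift peptide (FSP).  The FSP is
the neoantigen: filters and ranking operate on the novel-frame residues
only, never on any retained wild-type prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import TranscriptModel

log = logging.getLogger(__name__)

MS_INS = "MS_INS"
MS_DEL = "MS_DEL"
EXON_SKIP = "EXON_SKIP"


@dataclass(frozen=True)
class MicrosatelliteRun:
    """A maximal mononucleotide run in a CDS (0-based start, length in nt)."""

    transcript_id: str
    base: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.base not in "ACGT":
            raise ValueError(f"invalid run base {self.base!r}")
        if self.length < 2 or self.start < 0:
            raise ValueError("invalid microsatellite run geometry")


@dataclass
class PredictionParams:
    """Tunable parameters of FS-antigen prediction.

    ``min_repeat_len`` (nt) is the shortest homopolymer considered a
    slippage-prone microsatellite; ``min_fsp_aa`` is the minimum number
    of novel-frame residues for an antigen to be kept (18, i.e. strictly
    longer than 17 aa).
    """

    min_repeat_len: int = 7
    min_fsp_aa: int = 18
    indel_deltas: tuple[int, ...] = (1, -1)
    read_through_utr3: bool = True
    genetic_code: int | str = 1

    def __post_init__(self) -> None:
        if self.min_repeat_len < 2:
            raise ValueError("min_repeat_len must be >= 2")
        if self.min_fsp_aa < 1:
            raise ValueError("min_fsp_aa must be >= 1")
        if not set(self.indel_deltas) <= {1, -1}:
            raise ValueError("indel_deltas must be a subset of {+1, -1}")


@dataclass
class FrameshiftAntigen:
    """A predicted frameshift event and the novel peptide it encodes.

    ``shift_nt_pos`` is the 0-based offset of the first frame-shifted
    codon in the mutated transcript; ``fs_peptide`` holds the novel-frame
    residues up to (exclusive) the first stop codon.  ``terminated`` is
    False for run-off peptides where the sequence ended before a stop.
    ``repeat_length`` is the homopolymer length for MS events, 0 for
    exon skips.
    """

    antigen_id: str
    source_transcript: str
    event: str
    shift_nt_pos: int
    fs_peptide: str
    terminated: bool
    repeat_length: int = 0
    event_arg: int = 0  # INDEL delta, or skipped exon index

    def __post_init__(self) -> None:
        if self.event not in (MS_INS, MS_DEL, EXON_SKIP):
            raise ValueError(f"unknown event type {self.event!r}")
        if "*" in self.fs_peptide:
            raise ValueError(f"{self.antigen_id}: stop symbol inside fs_peptide")
        if self.shift_nt_pos < 0:
            raise ValueError(f"{self.antigen_id}: negative shift position")

    @property
    def shift_aa_index(self) -> int:
        return self.shift_nt_pos // 3


# ---------------------------------------------------------------------------
# scanning and mutation
# ---------------------------------------------------------------------------

def scan_microsatellites(
    transcript: TranscriptModel, params: PredictionParams | None = None
) -> list[MicrosatelliteRun]:
    """Find all maximal mononucleotide runs >= ``min_repeat_len`` in the CDS.

    Runs are returned sorted by start and can never overlap (maximality).
    """
    params = params or PredictionParams()
    seq = transcript.cds_seq
    runs: list[MicrosatelliteRun] = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= params.min_repeat_len:
            runs.append(MicrosatelliteRun(transcript.transcript_id, seq[i], i, j - i))
        i = j
    return runs


def apply_ms_indel(
    transcript: TranscriptModel, run: MicrosatelliteRun, delta: int
) -> str:
    """Return the full mutated sequence (CDS + 3'UTR) for a +-1 INDEL.

    The indel is canonicalised at ``run.start``: every indel position
    within a homopolymer yields the identical sequence, so one copy of
    ``run.base`` is inserted at (or removed from) the run start.
    """
    if delta not in (1, -1):
        raise ValueError("delta must be +1 or -1")
    if run.transcript_id != transcript.transcript_id:
        raise ValueError("run does not belong to this transcript")
    if run.start + run.length > len(transcript.cds_seq):
        raise ValueError("run extends beyond the CDS")
    seq = transcript.full_seq
    if delta == 1:
        return seq[: run.start] + run.base + seq[run.start :]
    return seq[: run.start] + seq[run.start + 1 :]


def translate_frameshift(
    original_cds: str,
    mutated_seq: str,
    params: PredictionParams | None = None,
) -> tuple[str, int, bool]:
    """Translate a mutated transcript and extract the novel-frame peptide.

    Both sequences are read from position 0 in frame 0.  The shift index
    is the first codon (amino-acid position) whose nucleotide triplet
    differs from wild type; the FSP runs from there to the first stop
    codon.  Returns ``(fs_peptide, shift_aa_index, terminated)`` where
    ``terminated`` is False when the sequence ends before an in-frame
    stop (the peptide is kept but flagged).  A trailing partial codon is
    discarded.
    """
    params = params or PredictionParams()
    n_orig = len(original_cds) // 3
    n_mut = len(mutated_seq) // 3
    shift = None
    for i in range(min(n_orig, n_mut)):
        if mutated_seq[3 * i : 3 * i + 3] != original_cds[3 * i : 3 * i + 3]:
            shift = i
            break
    if shift is None:
        if mutated_seq == original_cds:
            # identity: no frameshift, empty peptide
            return "", n_orig, False
        shift = min(n_orig, n_mut)
    tail = mutated_seq[3 * shift :]
    tail = tail[: len(tail) // 3 * 3]
    if not tail:
        return "", shift, False
    aa = str(Seq(tail).translate(table=params.genetic_code))
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], shift, True
    return aa, shift, False


# ---------------------------------------------------------------------------
# antigen prediction
# ---------------------------------------------------------------------------

def _antigen_sort_key(a: FrameshiftAntigen) -> tuple:
    return (-a.repeat_length, -len(a.fs_peptide), a.antigen_id)


def _dedup_keep_first(antigens: list[FrameshiftAntigen]) -> list[FrameshiftAntigen]:
    """Drop antigens with an identical fs_peptide, keeping the first.

    Callers sort by repeat length (descending) beforehand, so the
    longest-repeat provenance is the one retained.
    """
    seen: set[str] = set()
    out = []
    for a in antigens:
        if a.fs_peptide in seen:
            continue
        seen.add(a.fs_peptide)
        out.append(a)
    return out


def predict_ms_antigens(
    transcripts: list[TranscriptModel],
    params: PredictionParams | None = None,
) -> list[FrameshiftAntigen]:
    """Predict FS antigens from microsatellite INDELs across transcripts.

    For every run x delta the mutated transcript is built and translated;
    antigens with fewer than ``min_fsp_aa`` novel residues are dropped;
    identical peptides are deduplicated (longest-repeat provenance kept).
    Output is sorted by repeat length descending, ties by peptide length
    descending, then antigen id — longest repeats have the highest
    slippage rates and rank first.
    """
    params = params or PredictionParams()
    out: list[FrameshiftAntigen] = []
    for t in transcripts:
        for run in scan_microsatellites(t, params):
            for delta in params.indel_deltas:
                mutated = apply_ms_indel(t, run, delta)
                if not params.read_through_utr3:
                    mutated = mutated[: len(t.cds_seq) + delta]
                fsp, shift_aa, terminated = translate_frameshift(
                    t.cds_seq, mutated, params
                )
                if len(fsp) < params.min_fsp_aa:
                    continue
                tag = "msins" if delta == 1 else "msdel"
                out.append(
                    FrameshiftAntigen(
                        antigen_id=f"{t.transcript_id}:{tag}{run.start}",
                        source_transcript=t.transcript_id,
                        event=MS_INS if delta == 1 else MS_DEL,
                        shift_nt_pos=3 * shift_aa,
                        fs_peptide=fsp,
                        terminated=terminated,
                        repeat_length=run.length,
                        event_arg=delta,
                    )
                )
    out.sort(key=_antigen_sort_key)
    return _dedup_keep_first(out)


def predict_missplice_antigens(
    transcript: TranscriptModel,
    params: PredictionParams | None = None,
) -> list[FrameshiftAntigen]:
    """Predict FS antigens from single internal exon skips.

    Only internal exons whose length is not a multiple of 3 disrupt the
    frame and can generate an antigen; in-frame skips are silent here.
    Transcripts with fewer than 3 exons produce an empty list (warning).
    """
    params = params or PredictionParams()
    exons = transcript.exon_lengths
    if len(exons) < 3:
        log.warning(
            "%s: %d exon(s), no internal exon to skip",
            transcript.transcript_id,
            len(exons),
        )
        return []
    offsets = np.concatenate([[0], np.cumsum(exons)])
    out: list[FrameshiftAntigen] = []
    for idx in range(1, len(exons) - 1):
        if exons[idx] % 3 == 0:
            continue
        start = int(offsets[idx])
        skipped_cds = transcript.cds_seq[:start] + transcript.cds_seq[start + exons[idx] :]
        mutated = skipped_cds + (transcript.utr3_seq if params.read_through_utr3 else "")
        fsp, shift_aa, terminated = translate_frameshift(transcript.cds_seq, mutated, params)
        if len(fsp) < params.min_fsp_aa:
            continue
        out.append(
            FrameshiftAntigen(
                antigen_id=f"{transcript.transcript_id}:skip{idx}",
                source_transcript=transcript.transcript_id,
                event=EXON_SKIP,
                shift_nt_pos=3 * shift_aa,
                fs_peptide=fsp,
                terminated=terminated,
                repeat_length=0,
                event_arg=idx,
            )
        )
    return out


def predict_antigens(
    transcripts: list[TranscriptModel],
    params: PredictionParams | None = None,
) -> list[FrameshiftAntigen]:
    """All FS antigens (MS INDEL + exon skip), deduplicated on peptide identity.

    MS antigens keep their repeat-length ranking and precede exon-skip
    antigens (repeat_length 0), which are ordered by peptide length.
    """
    params = params or PredictionParams()
    ms = predict_ms_antigens(transcripts, params)
    skips: list[FrameshiftAntigen] = []
    for t in transcripts:
        if len(t.exon_lengths) >= 3:
            skips.extend(predict_missplice_antigens(t, params))
    skips.sort(key=_antigen_sort_key)
    return _dedup_keep_first(ms + skips)


def wildtype_prefix(antigen: FrameshiftAntigen, transcript: TranscriptModel) -> str:
    """Wild-type residues retained upstream of the frameshift point."""
    if transcript.transcript_id != antigen.source_transcript:
        raise ValueError("transcript does not match antigen provenance")
    return transcript.protein()[: antigen.shift_aa_index]


# ---------------------------------------------------------------------------
# EST-frequency scoring
# ---------------------------------------------------------------------------

def score_est_frequency(counts: pd.DataFrame) -> pd.DataFrame:
    """Rank antigens by tumor-vs-normal EST library enrichment.

    ``counts`` is indexed by antigen id with columns ``tumor_hits``,
    ``tumor_total``, ``normal_hits``, ``normal_total``.  The score is

        log2((tumor_hits/tumor_total + eps) / (normal_hits/normal_total + eps))

    with ``eps = 1 / max(tumor_total, normal_total)`` per antigen; high
    tumor frequency and low normal frequency give large positive scores.
    Returns the input with a ``score`` column, sorted score-descending.
    """
    needed = ["tumor_hits", "tumor_total", "normal_hits", "normal_total"]
    missing = [c for c in needed if c not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns {missing}")
    vals = counts[needed].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative counts are not allowed")
    if (vals[:, [1, 3]] <= 0).any():
        raise ValueError("library totals must be positive")
    eps = 1.0 / np.maximum(vals[:, 1], vals[:, 3])
    tumor_freq = vals[:, 0] / vals[:, 1]
    normal_freq = vals[:, 2] / vals[:, 3]
    score = np.log2((tumor_freq + eps) / (normal_freq + eps))
    out = counts.copy()
    out["score"] = score
    return out.sort_values("score", ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# antigen table / FASTA round trips
# ---------------------------------------------------------------------------

ANTIGEN_COLUMNS = [
    "antigen_id", "source_transcript", "event", "event_arg",
    "shift_nt_pos", "repeat_length", "terminated", "fs_peptide",
]


def antigens_to_table(antigens: list[FrameshiftAntigen]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antigen_id": a.antigen_id,
                "source_transcript": a.source_transcript,
                "event": a.event,
                "event_arg": a.event_arg,
                "shift_nt_pos": a.shift_nt_pos,
                "repeat_length": a.repeat_length,
                "terminated": a.terminated,
                "fs_peptide": a.fs_peptide,
            }
            for a in antigens
        ],
        columns=ANTIGEN_COLUMNS,
    )


def antigens_from_table(df: pd.DataFrame) -> list[FrameshiftAntigen]:
    return [
        FrameshiftAntigen(
            antigen_id=str(r.antigen_id),
            source_transcript=str(r.source_transcript),
            event=str(r.event),
            event_arg=int(r.event_arg),
            shift_nt_pos=int(r.shift_nt_pos),
            repeat_length=int(r.repeat_length),
            terminated=bool(r.terminated),
            fs_peptide=str(r.fs_peptide),
        )
        for r in df.itertuples()
    ]


def antigens_to_fasta(path, antigens: list[FrameshiftAntigen]) -> None:
    """Peptide FASTA with key=value annotations in the description line."""
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(a.fs_peptide),
            id=a.antigen_id,
            description=(
                f"event={a.event} shift_nt_pos={a.shift_nt_pos} "
                f"repeat_length={a.repeat_length} terminated={a.terminated}"
            ),
        )
        for a in antigens
    ]
    SeqIO.write(records, str(path), "fasta")
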