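"""File-format layer for the frameshift-vaccine pipeline.

Handles every external representation the pipeline touches: FASTA
(nucleotide and peptide), exon models (3-column TSV or GFF3), GenePix
results-style tab-delimited scanner exports, sample-by-peptide intensity
matrices with sample metadata, and JSON configuration.

All sequence coordinates are 0-based, half-open.  Readers validate
eagerly and raise ``ValueError`` with a message naming the offending
record; nothing is silently repaired except the documented cases
(case normalisation, ``U``->``T`` for nucleotide input, and flooring of
background-subtracted intensities at zero).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_GROUPS = ("naive", "challenged")

#: metadata columns required for every array sample
REQUIRED_META = ("group", "slide_id")
#: optional metadata columns, filled with "" when absent
OPTIONAL_META = ("cohort_id", "subject_id", "timepoint")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A coding sequence with optional exon decomposition and 3'UTR.

    ``cds_seq`` starts at the annotated start codon in frame 0.
    ``exon_lengths`` is an optional decomposition of the CDS into exon
    segments (lengths in nt, summing to ``len(cds_seq)``); an empty list
    means single-exon or unknown structure.
    """

    transcript_id: str
    cds_seq: str
    utr3_seq: str = ""
    exon_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper().replace("U", "T")
        self.utr3_seq = self.utr3_seq.upper().replace("U", "T")
        if len(self.cds_seq) < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")
        for name, seq in (("cds_seq", self.cds_seq), ("utr3_seq", self.utr3_seq)):
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(
                    f"{self.transcript_id}: non-ACGT characters {sorted(bad)} in {name}"
                )
        if self.exon_lengths:
            if any(int(x) <= 0 for x in self.exon_lengths):
                raise ValueError(f"{self.transcript_id}: non-positive exon length")
            if sum(self.exon_lengths) != len(self.cds_seq):
                raise ValueError(
                    f"{self.transcript_id}: exon lengths sum to "
                    f"{sum(self.exon_lengths)}, CDS is {len(self.cds_seq)} nt"
                )

    @property
    def full_seq(self) -> str:
        """CDS followed by the 3'UTR."""
        return self.cds_seq + self.utr3_seq

    def protein(self) -> str:
        """Frame-0 translation of the CDS, trailing stop symbol stripped."""
        n = len(self.cds_seq) // 3 * 3
        aa = str(Seq(self.cds_seq[:n]).translate())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass
class IntensityDataset:
    """Sample-by-peptide fluorescence intensities plus sample metadata.

    ``intensities`` is a samples x peptides DataFrame of non-negative
    values; ``sample_meta`` is indexed by sample id and carries at least
    ``group`` (naive/challenged) and ``slide_id``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ints, meta = self.intensities, self.sample_meta
        if ints.index.has_duplicates:
            raise ValueError("duplicate sample ids in intensity matrix")
        if ints.columns.has_duplicates:
            raise ValueError("duplicate peptide ids in intensity matrix")
        if not ints.index.equals(meta.index):
            raise ValueError("sample ids of matrix and metadata disagree")
        missing = [c for c in REQUIRED_META if c not in meta.columns]
        if missing:
            raise ValueError(f"sample metadata lacks required columns {missing}")
        bad_groups = set(meta["group"]) - set(VALID_GROUPS)
        if bad_groups:
            raise ValueError(f"invalid sample groups {sorted(bad_groups)}")
        if meta["slide_id"].isna().any() or (meta["slide_id"] == "").any():
            raise ValueError("every sample needs a slide_id")
        vals = ints.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("intensities must be finite and non-negative")

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    # -- round trips --------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        write_matrix_tsv(matrix_path, self.intensities)
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "IntensityDataset":
        ints = read_matrix_tsv(matrix_path)
        meta = read_sample_meta(meta_path)
        return cls(ints, meta.loc[ints.index])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased; for ``moltype="dna"`` any ``U`` is converted
    to ``T``.  Duplicate record ids and empty files are hard errors.
    """
    if moltype not in ("dna", "protein"):
        raise ValueError(f"unknown moltype {moltype!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if moltype == "dna":
            seq = seq.replace("U", "T")
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# exon models
# ---------------------------------------------------------------------------

def read_exon_table(path: str | Path) -> dict[str, list[int]]:
    """Read a 3-column exon TSV (transcript_id, exon_index, exon_length)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"transcript_id", "exon_index", "exon_length"}
    if not needed.issubset(df.columns):
        raise ValueError(f"exon table needs columns {sorted(needed)}, got {list(df.columns)}")
    out: dict[str, list[int]] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("exon_index")
        if list(grp["exon_index"]) != list(range(len(grp))):
            raise ValueError(f"{tid}: exon_index must be 0..n-1 without gaps")
        out[str(tid)] = [int(x) for x in grp["exon_length"]]
    return out


def write_exon_table(path: str | Path, exons: dict[str, list[int]]) -> None:
    rows = [
        {"transcript_id": tid, "exon_index": i, "exon_length": ln}
        for tid, lens in exons.items()
        for i, ln in enumerate(lens)
    ]
    pd.DataFrame(rows, columns=["transcript_id", "exon_index", "exon_length"]).to_csv(
        path, sep="\t", index=False
    )


def read_gff3_exons(path: str | Path) -> dict[str, list[int]]:
    """Extract per-transcript exon lengths from a GFF3 file.

    Exon features are grouped by their ``Parent`` attribute and ordered by
    start coordinate; the returned lengths are in transcript order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id])
        for parent in parents:
            by_parent.setdefault(parent, []).append((exon.start, exon.end))
    out = {}
    for parent, spans in by_parent.items():
        spans.sort()
        out[parent] = [end - start + 1 for start, end in spans]
    return out


def load_transcripts(
    cds_fasta: str | Path,
    utr3_fasta: str | Path | None = None,
    exon_table: str | Path | None = None,
) -> list[TranscriptModel]:
    """Assemble TranscriptModels from a CDS FASTA plus optional companions.

    ``utr3_fasta`` records are matched to CDS records by id (missing ids
    get an empty 3'UTR); ``exon_table`` may be a TSV (see
    :func:`read_exon_table`) or a GFF3 file.
    """
    utr3 = dict(read_fasta(utr3_fasta)) if utr3_fasta else {}
    exons: dict[str, list[int]] = {}
    if exon_table is not None:
        looks_gff = Path(exon_table).suffix.lower() in (".gff", ".gff3")
        if looks_gff or Path(exon_table).read_text(errors="ignore").startswith("##gff-version"):
            exons = read_gff3_exons(exon_table)
        else:
            exons = read_exon_table(exon_table)
    return [
        TranscriptModel(tid, seq, utr3.get(tid, ""), exons.get(tid, []))
        for tid, seq in read_fasta(cds_fasta)
    ]


# ---------------------------------------------------------------------------
# GenePix-results-style files
# ---------------------------------------------------------------------------

def read_gpr_like(
    path: str | Path,
    value_column: str = "F647 Median",
    background_column: str | None = "B647 Median",
    subtract_background: bool = True,
) -> dict[str, float]:
    """Read one sample's spot intensities from a GenePix-style export.

    The file is tab-delimited with an optional ATF-style preamble; the
    column header is the first line containing a ``Name`` (or ``ID``)
    field.  When a background column is present and subtraction enabled,
    intensity = max(foreground - background, 0); replicate spots of the
    same peptide are collapsed by median.
    """
    lines = Path(path).read_text().splitlines()
    header_idx = None
    header_fields: list[str] = []
    for i, line in enumerate(lines):
        fields = [f.strip().strip('"') for f in line.split("\t")]
        if len(fields) >= 2 and ("Name" in fields or "ID" in fields):
            header_idx = i
            header_fields = fields
            break
    if header_idx is None:
        raise ValueError(f"{path}: no header line with a Name/ID column found")
    if value_column not in header_fields:
        raise ValueError(
            f"{path}: value column {value_column!r} not found; "
            f"available columns: {header_fields}"
        )
    name_col = "Name" if "Name" in header_fields else "ID"

    import io as _io

    df = pd.read_csv(
        _io.StringIO("\n".join(lines[header_idx:])), sep="\t", quotechar='"'
    )
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    names = df[name_col].astype(str).str.strip().str.strip('"')
    keep = names != ""
    df, names = df[keep], names[keep]

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            pos = int(np.flatnonzero(vals.isna().to_numpy())[0])
            lineno = header_idx + 2 + pos  # 1-based line of the offending row
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {lineno}")
        return vals.to_numpy(dtype=float)

    fg = _numeric(value_column)
    if background_column and background_column in df.columns and subtract_background:
        values = np.maximum(fg - _numeric(background_column), 0.0)
    else:
        values = fg
    series = pd.Series(values, index=names.to_numpy())
    return series.groupby(level=0).median().to_dict()


# ---------------------------------------------------------------------------
# matrices and metadata
# ---------------------------------------------------------------------------

def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    meta.index = meta.index.astype(str)
    missing = [c for c in REQUIRED_META if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata lacks required columns {missing}")
    for col in OPTIONAL_META:
        if col not in meta.columns:
            meta[col] = ""
    return meta


def assemble_dataset(
    per_sample_maps: list[dict[str, float]],
    sample_meta: pd.DataFrame | list[dict],
) -> IntensityDataset:
    """Combine per-sample (peptide -> intensity) maps into one dataset.

    Peptides are restricted to the intersection across samples (a warning
    is logged when any are dropped); columns are ordered by sorted peptide
    id, rows follow the input sample order.
    """
    if isinstance(sample_meta, list):
        meta = pd.DataFrame(sample_meta)
        if "sample_id" not in meta.columns:
            raise ValueError("sample metadata records need a sample_id field")
        meta = meta.set_index("sample_id")
    else:
        meta = sample_meta.copy()
    missing = [c for c in REQUIRED_META if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks required columns {missing}")
    for col in OPTIONAL_META:
        if col not in meta.columns:
            meta[col] = ""
    if len(per_sample_maps) != len(meta):
        raise ValueError("number of sample maps and metadata rows differ")

    shared = set(per_sample_maps[0])
    union = set(per_sample_maps[0])
    for m in per_sample_maps[1:]:
        shared &= set(m)
        union |= set(m)
    if not shared:
        raise ValueError("no peptide id shared across all samples")
    if shared != union:
        log.warning(
            "dropping %d peptide(s) absent from at least one sample",
            len(union - shared),
        )
    peptides = sorted(shared)
    mat = pd.DataFrame(
        [[m[p] for p in peptides] for m in per_sample_maps],
        index=meta.index,
        columns=peptides,
        dtype=float,
    )
    return IntensityDataset(mat, meta)


# ---------------------------------------------------------------------------
# JSON config helpers
# ---------------------------------------------------------------------------

def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
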