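"""Tiled 20mer peptide design: the in-silico frameshift peptide array.

Each frameshift antigen is represented by overlapping fixed-length tiles
(default 20mers with a 10-residue step) covering the novel-frame peptide.
When the FSP alone is shorter than one tile, wild-type residues upstream
of the shift point pad the window so every spot is full length; the
number of native residues per tile is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .fs_prediction import FrameshiftAntigen, wildtype_prefix
from .io_formats import TranscriptModel, write_fasta

log = logging.getLogger(__name__)


@dataclass
class DesignParams:
    tile_len: int = 20
    tile_step: int = 10
    max_tiles_per_antigen: int = 6
    pad_with_native: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.tile_step <= self.tile_len:
            raise ValueError("need 1 <= tile_step <= tile_len")
        if self.max_tiles_per_antigen < 1:
            raise ValueError("max_tiles_per_antigen must be >= 1")


@dataclass(frozen=True)
class ArrayPeptide:
    """One spot: a fixed-length tile with parent-antigen provenance.

    ``tile_start`` is the 0-based offset into (native_prefix + fs_peptide);
    ``n_native_prefix_aa`` counts wild-type context residues included.
    """

    peptide_id: str
    sequence: str
    parent_antigen: str
    tile_start: int
    n_native_prefix_aa: int


@dataclass
class PeptideArrayDesign:
    """The full in-silico array: spots plus the antigen<->peptide index.

    ``parents`` maps each spot to every antigen sharing its sequence
    (duplicate 20mers across antigens are collapsed to one spot).
    """

    peptides: list[ArrayPeptide]
    parents: dict[str, list[str]] = field(default_factory=dict)
    antigen_peptides: dict[str, list[str]] = field(default_factory=dict)

    @property
    def peptide_ids(self) -> list[str]:
        return [p.peptide_id for p in self.peptides]

    @property
    def sequences(self) -> dict[str, str]:
        return {p.peptide_id: p.sequence for p in self.peptides}

    def antigen_ids(self) -> list[str]:
        return sorted(self.antigen_peptides)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptide_id": p.peptide_id,
                    "sequence": p.sequence,
                    "parent_antigen": p.parent_antigen,
                    "tile_start": p.tile_start,
                    "n_native_prefix_aa": p.n_native_prefix_aa,
                    "all_parents": ";".join(self.parents[p.peptide_id]),
                }
                for p in self.peptides
            ],
            columns=[
                "peptide_id", "sequence", "parent_antigen",
                "tile_start", "n_native_prefix_aa", "all_parents",
            ],
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PeptideArrayDesign":
        peptides = []
        parents: dict[str, list[str]] = {}
        antigen_peptides: dict[str, list[str]] = {}
        for r in df.itertuples():
            pep = ArrayPeptide(
                peptide_id=str(r.peptide_id),
                sequence=str(r.sequence),
                parent_antigen=str(r.parent_antigen),
                tile_start=int(r.tile_start),
                n_native_prefix_aa=int(r.n_native_prefix_aa),
            )
            peptides.append(pep)
            pars = str(r.all_parents).split(";") if r.all_parents else [pep.parent_antigen]
            parents[pep.peptide_id] = pars
            for a in pars:
                antigen_peptides.setdefault(a, []).append(pep.peptide_id)
        antigen_peptides = {a: sorted(p) for a, p in antigen_peptides.items()}
        return cls(peptides, parents, antigen_peptides)

    def to_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeptideArrayDesign":
        return cls.from_table(pd.read_csv(path, sep="\t", keep_default_na=False))

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, [(p.peptide_id, p.sequence) for p in self.peptides])


def tile_antigen(
    antigen: FrameshiftAntigen,
    native_prefix: str,
    params: DesignParams | None = None,
) -> list[ArrayPeptide]:
    """Tile one antigen into fixed-length windows.

    Windows start at the FSP and advance by ``tile_step``; a final window
    right-anchored at the C-terminus is always included so the peptide
    end is covered.  When the FSP alone is shorter than one tile and
    ``pad_with_native`` is set, the single window is right-anchored and
    padded with wild-type prefix residues across the junction.  No tile
    ever consists solely of native residues.  When the window count
    exceeds ``max_tiles_per_antigen``, the right-anchored (C-terminal)
    tiles are kept preferentially, which can leave the FSP N-terminus
    uncovered for very long peptides.
    """
    params = params or DesignParams()
    tile_len = params.tile_len
    full = native_prefix + antigen.fs_peptide
    n_prefix = len(native_prefix)
    total = len(full)
    if total < tile_len:
        log.warning(
            "%s: %d aa available < tile length %d, antigen skipped",
            antigen.antigen_id, total, tile_len,
        )
        return []
    if len(antigen.fs_peptide) >= tile_len:
        starts = list(range(n_prefix, total - tile_len + 1, params.tile_step))
    else:
        if not params.pad_with_native:
            log.warning(
                "%s: FSP shorter than tile length and padding disabled, skipped",
                antigen.antigen_id,
            )
            return []
        starts = [total - tile_len]
    anchor = total - tile_len
    if anchor not in starts:
        starts.append(anchor)
    # a tile must contain at least one novel-frame residue
    starts = sorted({s for s in starts if s + tile_len > n_prefix})
    if len(starts) > params.max_tiles_per_antigen:
        starts = starts[-params.max_tiles_per_antigen :]
    return [
        ArrayPeptide(
            peptide_id=f"{antigen.antigen_id}|{s:03d}",
            sequence=full[s : s + tile_len],
            parent_antigen=antigen.antigen_id,
            tile_start=s,
            n_native_prefix_aa=max(0, n_prefix - s),
        )
        for s in starts
    ]


def build_design(
    antigens: list[FrameshiftAntigen],
    transcripts: list[TranscriptModel],
    params: DesignParams | None = None,
) -> PeptideArrayDesign:
    """Tile every antigen and assemble the array design.

    Duplicate tile sequences across antigens are collapsed to a single
    spot carrying all parent antigens.  Raises on an empty antigen list
    or on antigens referencing unknown transcripts.
    """
    if not antigens:
        raise ValueError("cannot build a design from zero antigens")
    params = params or DesignParams()
    tmap = {t.transcript_id: t for t in transcripts}
    peptides: list[ArrayPeptide] = []
    parents: dict[str, list[str]] = {}
    antigen_peptides: dict[str, list[str]] = {}
    by_seq: dict[str, str] = {}
    for antigen in antigens:
        if antigen.source_transcript not in tmap:
            raise ValueError(
                f"{antigen.antigen_id}: unknown transcript {antigen.source_transcript}"
            )
        prefix = wildtype_prefix(antigen, tmap[antigen.source_transcript])
        tiles = tile_antigen(antigen, prefix, params)
        plist = antigen_peptides.setdefault(antigen.antigen_id, [])
        for tile in tiles:
            if tile.sequence in by_seq:
                spot = by_seq[tile.sequence]
                if antigen.antigen_id not in parents[spot]:
                    parents[spot].append(antigen.antigen_id)
                if spot not in plist:
                    plist.append(spot)
            else:
                by_seq[tile.sequence] = tile.peptide_id
                peptides.append(tile)
                parents[tile.peptide_id] = [antigen.antigen_id]
                plist.append(tile.peptide_id)
    antigen_peptides = {a: sorted(p) for a, p in antigen_peptides.items() if p}
    n_ant = len(antigen_peptides)
    if n_ant == 0:
        raise ValueError("no antigen produced any tile")
    log.info(
        "array design: %d antigens, %d peptides, %.2f tiles/antigen",
        n_ant, len(peptides), len(peptides) / n_ant,
    )
    return PeptideArrayDesign(peptides, parents, antigen_peptides)
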