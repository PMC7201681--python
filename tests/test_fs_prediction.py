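import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fsvax import (
    PredictionParams,
    TranscriptModel,
    apply_ms_indel,
    predict_missplice_antigens,
    predict_ms_antigens,
    scan_microsatellites,
    score_est_frequency,
    translate_frameshift,
)
from fsvax.fs_prediction import MicrosatelliteRun, wildtype_prefix

# independent codon table for the manual codon-walk oracle (kept separate
# from the implementation's translation machinery on purpose)
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def codon_walk_oracle(original, mutated):
    """Brute-force reference for translate_frameshift."""
    n = min(len(original), len(mutated)) // 3
    shift = None
    for i in range(n):
        if original[3 * i : 3 * i + 3] != mutated[3 * i : 3 * i + 3]:
            shift = i
            break
    if shift is None:
        if mutated == original:
            return "", len(original) // 3, False
        shift = n
    pep = []
    for j in range(3 * shift, len(mutated) - 2, 3):
        aa = CODON_TABLE[mutated[j : j + 3]]
        if aa == "*":
            return "".join(pep), shift, True
        pep.append(aa)
    return "".join(pep), shift, False


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestScanMicrosatellites:
    def test_planted_seven_base_run(self):
        t = TranscriptModel("t", "ATG" + "AAAAAAA" + "GGCTGCTAA")
        runs = scan_microsatellites(t)
        assert [(r.base, r.start, r.length) for r in runs] == [("A", 3, 7)]

    def test_six_base_run_is_below_threshold(self):
        t = TranscriptModel("t", "ATG" + "AAAAAA" + "GGCTGCTAA")
        assert scan_microsatellites(t) == []

    def test_adjacent_runs_of_different_bases(self):
        t = TranscriptModel("t", "CCCCCCCTTTTTTTT" + "GAGCTAGCA")
        runs = scan_microsatellites(t)
        assert [(r.base, r.length) for r in runs] == [("C", 7), ("T", 8)]

    def test_agrees_with_regex_bruteforce_on_random_kilobases(self, rng):
        pattern = re.compile(r"([ACGT])\1{6,}")
        for _ in range(200):
            seq = random_seq(rng, 1000)
            t = TranscriptModel("t", seq)
            ours = [(r.base, r.start, r.length) for r in scan_microsatellites(t)]
            regex = [(m.group(1), m.start(), m.end() - m.start()) for m in pattern.finditer(seq)]
            assert ours == regex

    def test_runs_never_overlap_and_are_sorted(self, rng):
        for _ in range(50):
            t = TranscriptModel("t", random_seq(rng, 500))
            runs = scan_microsatellites(t, PredictionParams(min_repeat_len=3))
            for a, b in zip(runs, runs[1:]):
                assert a.start + a.length <= b.start


class TestApplyMsIndel:
    def test_deletion_shrinks_run_only(self, simple_transcript):
        run = scan_microsatellites(simple_transcript)[0]
        mutated = apply_ms_indel(simple_transcript, run, -1)
        assert mutated == "ATG" + "AAAAAA" + "GCGATTAA" + simple_transcript.utr3_seq
        assert len(mutated) == len(simple_transcript.full_seq) - 1

    def test_insertion_then_deletion_is_identity(self, simple_transcript):
        run = scan_microsatellites(simple_transcript)[0]
        plus = apply_ms_indel(simple_transcript, run, +1)
        t2 = TranscriptModel("t1", plus[: len(simple_transcript.cds_seq) + 1],
                             simple_transcript.utr3_seq)
        run2 = scan_microsatellites(t2)[0]
        assert apply_ms_indel(t2, run2, -1) == simple_transcript.full_seq

    def test_indel_position_within_run_is_canonical(self, simple_transcript):
        # removing any of the 7 A's yields the same sequence as removing the first
        run = scan_microsatellites(simple_transcript)[0]
        canon = apply_ms_indel(simple_transcript, run, -1)
        full = simple_transcript.full_seq
        for offset in range(run.length):
            manual = full[: run.start + offset] + full[run.start + offset + 1 :]
            assert manual == canon

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, -1]))
    def test_mutated_length_differs_by_one(self, seed, delta):
        rng = np.random.default_rng(seed)
        seq = "ATG" + "G" * int(rng.integers(7, 15)) + random_seq(rng, 60)
        t = TranscriptModel("t", seq)
        run = scan_microsatellites(t)[0]
        assert len(apply_ms_indel(t, run, delta)) == len(t.full_seq) + delta


class TestTranslateFrameshift:
    CDS = "ATGAAAAAAAGCGATTAA"  # M K K S D *

    def test_single_deletion_manual_oracle(self):
        mutated = "ATGAAAAAAGCGATTAA"
        fsp, shift, terminated = translate_frameshift(self.CDS, mutated)
        assert (fsp, shift, terminated) == ("AI", 3, False)

    def test_single_insertion_manual_oracle(self):
        mutated = "ATGAAAAAAAAGCGATTAA"
        fsp, shift, terminated = translate_frameshift(self.CDS, mutated)
        assert fsp.startswith("KRL")
        assert shift == 3
        assert not terminated

    def test_identity_gives_empty_peptide(self):
        fsp, _, _ = translate_frameshift(self.CDS, self.CDS)
        assert fsp == ""

    def test_stop_in_novel_frame_terminates(self):
        # deletion shifts into a frame containing TAA soon after
        cds = "ATGAAAAAAATAACGCGCGCGC"
        mutated = cds[:3] + cds[4:]  # remove one A
        fsp, shift, terminated = translate_frameshift(cds, mutated)
        assert terminated
        assert "*" not in fsp

    def test_codon_walk_agreement(self, rng):
        """200 random INDEL and exon-skip events agree with the oracle."""
        checked = 0
        while checked < 200:
            seq = "ATG" + random_seq(rng, 120)
            kind = rng.random()
            if kind < 0.5:  # single-base indel at a random position
                pos = int(rng.integers(3, len(seq) - 3))
                if rng.random() < 0.5:
                    mutated = seq[:pos] + "ACGT"[int(rng.integers(4))] + seq[pos:]
                else:
                    mutated = seq[:pos] + seq[pos + 1 :]
            else:  # internal segment removal (exon-skip shaped)
                start = int(rng.integers(3, len(seq) // 2))
                skip = int(rng.integers(1, 40))
                mutated = seq[:start] + seq[start + skip :]
            assert translate_frameshift(seq, mutated) == codon_walk_oracle(seq, mutated)
            checked += 1


class TestPredictMsAntigens:
    def test_filter_and_ranking(self, rng):
        """A long-repeat/long-FSP antigen survives; a short FSP is dropped."""
        # transcript A: 8-nt run, open downstream frame -> long FSP
        open_tail = "GCT" * 40  # alanine-only, no stop in any frame
        ta = TranscriptModel("ta", "ATG" + "A" * 8 + "C" + open_tail + "TAA")
        # transcript B: 7-nt run, shifted frame hits a stop almost at once
        tb = TranscriptModel(
            "tb", "ATG" + "G" * 7 + "ATTACCGCGGCGGCGGCGGCGGCGGCGTGA", ""
        )
        ants = predict_ms_antigens([ta, tb], PredictionParams(min_fsp_aa=18))
        assert all(len(a.fs_peptide) >= 18 for a in ants)
        assert all(a.source_transcript == "ta" for a in ants)
        assert [a.repeat_length for a in ants] == sorted(
            (a.repeat_length for a in ants), reverse=True
        )

    def test_no_runs_no_antigens(self):
        t = TranscriptModel("t", "ATGGCAGCAGCATAA")
        assert predict_ms_antigens([t]) == []

    def test_identical_peptides_deduplicated(self):
        tail = "GCT" * 30 + "TAA"
        t1 = TranscriptModel("t1", "ATG" + "A" * 8 + "C" + tail)
        t2 = TranscriptModel("t2", "ATG" + "A" * 8 + "C" + tail)
        ants = predict_ms_antigens([t1, t2])
        peps = [a.fs_peptide for a in ants]
        assert len(peps) == len(set(peps))

    def test_wildtype_prefix_matches_translation(self, small_study):
        """Residues before the shift equal the wild-type prefix for all antigens."""
        tmap = {t.transcript_id: t for t in small_study.reference.transcripts}
        for a in small_study.reference.antigens:
            t = tmap[a.source_transcript]
            prefix = wildtype_prefix(a, t)
            assert prefix == t.protein()[: a.shift_aa_index]

    def test_deletion_then_reinsertion_restores_wildtype_protein(self, rng):
        from Bio.Seq import Seq

        for _ in range(20):
            seq = "ATG" + "T" * int(rng.integers(7, 12)) + random_seq(rng, 90)
            t = TranscriptModel("t", seq)
            run = scan_microsatellites(t)[0]
            deleted = apply_ms_indel(t, run, -1)
            t_del = TranscriptModel("t", deleted)
            run_del = scan_microsatellites(t_del, PredictionParams(min_repeat_len=run.length - 1))[0]
            restored = apply_ms_indel(t_del, run_del, +1)
            assert restored == seq
            n = len(seq) // 3 * 3
            assert str(Seq(restored[:n]).translate()) == str(Seq(seq[:n]).translate())


class TestPredictMissplice:
    def _gene(self, exons, tail="GCA"):
        # frame-0 open CDS whose internal exon boundaries are arbitrary
        total = sum(exons)
        body = ("GCT GCA GCC GCG".replace(" ", "") * total)[: total - 6]
        cds = "ATG" + body + "TAA"
        return TranscriptModel("g", cds, "GTTGTTGTTGTTGTTGTTGTTGTTGTTGTTGTTGTT", list(exons))

    def test_frame_disrupting_internal_exon(self):
        t = self._gene([30, 10, 62])
        ants = predict_missplice_antigens(t, PredictionParams(min_fsp_aa=1))
        assert len(ants) == 1
        a = ants[0]
        # oracle: remove the exon and walk codons
        skipped = t.cds_seq[:30] + t.cds_seq[40:] + t.utr3_seq
        fsp, shift, term = codon_walk_oracle(t.cds_seq, skipped)
        assert (a.fs_peptide, a.shift_aa_index, a.terminated) == (fsp, shift, term)

    def test_in_frame_skip_is_silent(self):
        t = self._gene([30, 9, 63])
        assert predict_missplice_antigens(t, PredictionParams(min_fsp_aa=1)) == []

    def test_two_internal_exons_give_up_to_two_events(self):
        t = self._gene([30, 10, 11, 63])
        ants = predict_missplice_antigens(t, PredictionParams(min_fsp_aa=1))
        assert 1 <= len(ants) <= 2
        assert {a.event_arg for a in ants} <= {1, 2}

    def test_too_few_exons_warns_and_returns_empty(self, caplog):
        import logging

        t = TranscriptModel("t", "ATGGCAGCATAA", exon_lengths=[6, 6])
        with caplog.at_level(logging.WARNING):
            assert predict_missplice_antigens(t) == []
        assert "exon" in caplog.text


class TestEstFrequencyScore:
    def test_sign_conventions(self):
        df = pd.DataFrame(
            {
                "tumor_hits": [10, 5], "tumor_total": [100, 100],
                "normal_hits": [0, 5], "normal_total": [100, 100],
            },
            index=["enriched", "flat"],
        )
        out = score_est_frequency(df)
        assert out.loc["enriched", "score"] > 0
        assert out.loc["flat", "score"] == pytest.approx(0.0)

    def test_ranking_agrees_with_bruteforce(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "tumor_hits": rng.integers(0, 50, n),
                "tumor_total": 100,
                "normal_hits": rng.integers(0, 50, n),
                "normal_total": 80,
            },
            index=[f"a{i}" for i in range(n)],
        )
        out = score_est_frequency(df)
        eps = 1 / 100

        def key(r):
            return (r.tumor_hits / 100 + eps) / (r.normal_hits / 80 + eps)

        brute = sorted(df.itertuples(), key=key, reverse=True)
        assert list(out.index) == [r.Index for r in brute]

    def test_monotone_in_tumor_frequency(self):
        df = pd.DataFrame(
            {
                "tumor_hits": [1, 2, 3], "tumor_total": [100] * 3,
                "normal_hits": [4] * 3, "normal_total": [100] * 3,
            },
            index=list("abc"),
        )
        scores = score_est_frequency(df).sort_index()["score"]
        assert scores.is_monotonic_increasing

    def test_negative_counts_rejected(self):
        df = pd.DataFrame(
            {"tumor_hits": [-1], "tumor_total": [10], "normal_hits": [0], "normal_total": [10]}
        )
        with pytest.raises(ValueError, match="negative"):
            score_est_frequency(df)
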