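# Methods

## Frameshift-antigen prediction

A transcript model is a CDS (frame 0, starting at the annotated start
codon), an optional 3′UTR, and an optional exon decomposition; all
coordinates are 0-based, half-open. Two RNA-processing errors are
modelled.

**Microsatellite INDELs.** Maximal mononucleotide runs of length
≥ `min_repeat_len` (default 7 nt, the shortest run with an appreciable
transcription-slippage rate) are enumerated in the CDS. For each run,
both a +1 insertion and a −1 deletion are generated. Within a
homopolymer every indel position yields the same sequence, so indels are
canonicalized at the run start. Longer runs slip more often, so antigens
are ranked by repeat length (ties: FSP length, then id).

**Exon skipping.** For transcripts with ≥ 3 exons, each internal exon
whose length is not a multiple of 3 generates a skip event; in-frame
skips change the protein but not the frame and are not frameshift
antigens. Multi-exon skips and cryptic splice sites are out of scope.

**Frameshift translation.** The mutated sequence is translated from
position 0 in frame 0. The shift index is the first codon that differs
from wild type; the frameshift peptide (FSP) is the run of novel-frame
residues from there to the first stop codon, reading through the 3′UTR
when available (`read_through_utr3=True`). Peptides that run off the end
of the sequence before a stop are kept and flagged `terminated=False`.
Antigens are kept when the FSP has at least `min_fsp_aa = 18` novel
residues — "longer than 17" read strictly, counting only residues after
the shift point, since those are the neoantigen. Identical FSPs are
deduplicated, keeping the longest-repeat provenance; near-duplicates
are deliberately not collapsed.

**EST-frequency scoring.** For user-supplied (tumor, normal) EST hit
counts, antigens are scored `log2((h_t/N_t + ε)/(h_n/N_n + ε))` with
`ε = 1/max(N_t, N_n)` per antigen — monotone increasing in tumor
frequency, decreasing in normal frequency, and finite at zero counts.

## Array design

Each antigen is tiled into 20mers at a 10-residue step starting at the
FSP, with a final right-anchored tile so the C-terminus is always
covered. An FSP shorter than one tile is represented by a single
right-anchored tile padded across the junction with wild-type residues
(`n_native_prefix_aa` recorded); no tile is ever purely wild-type. At
most `max_tiles_per_antigen = 6` tiles are kept, preferring the
C-terminal ones, which can leave the N-terminus of very long FSPs
uncovered. Identical tile sequences across antigens collapse to one
spot with all parents recorded. The 50%-overlap step was chosen so that
a 200-antigen design lands near 4 tiles per antigen (the published
788/200 spot-to-antigen ratio); the original array's tiling scheme is
unpublished, so this is a reconstruction, not a claim.

## Immunosignature analysis

**Normalization.** Raw intensities are divided by the median of all
spot values on their slide; the per-slide normalized median is exactly
1 and the transform is idempotent and invariant to per-slide rescaling.
Slides with non-positive medians are rejected.

**Naive baseline.** The baseline pools all pre-challenge (T0) sera in
the run (per-subject paired analysis is possible by restricting the
sample metadata). Per peptide, μ is the mean and σ the sample SD
(n−1) of the naive values. Two stabilizations are applied:

* *Variance moderation* (default on). With a few dozen naive sera the
  per-peptide SD is noisy; peptides whose SD is undershot by chance get
  false-positive rates of 5–15% that are correlated across every
  challenged sample. Per-peptide variances are therefore squeezed
  toward an inverse-chi-square prior whose scale and degrees of freedom
  are fitted across peptides by method of moments on log s² — the
  standard small-sample microarray treatment. The plain estimator is
  available (`moderate_variance=False`).
* *SD floor* `max(1e-6, 0.01·|μ|)`, so constant peptides cannot produce
  infinite z-scores.

**Reactivity calls.** A challenged sample is reactive for a peptide
when its value exceeds μ + kσ with k = 2 (the literal `k_sd_only`
variant, value > kσ, is selectable). Thresholding operates on
log10-transformed normalized intensities by default: array fluorescence
is well described as log-normal, and only on the log scale does the
mean + 2 SD rule attain its nominal one-sided Gaussian tail. On the raw
scale the same rule has a ~4.3% tail (right skew); linear-scale calling
is available via `ThresholdRule(use_log10=False)` / `--linear-scale`.

With μ, σ estimated from n naive samples, the exact null tail of the
plain rule is `P(t_{n−1} > k/√(1+1/n))` — about 3.1% at n = 24 —
converging to `1 − Φ(2) ≈ 2.3%` as n grows; with moderated (effectively
pooled) variances it is `Φ̄(k/√(1+1/n))`, about 2.5% at n = 24. The
null-calibration tests assert these closed forms.

**Positive rates.** Peptide rate = 100 · reactive/challenged, reported
half-up to one decimal (full precision kept internally); antigen rates
aggregate tiles with any-reactive-tile logic, so an antigen's rate
dominates each of its tiles'. Counts and denominators are always
reported alongside. No multiple-testing correction is applied, matching
the screening protocol the pipeline reproduces.

## Vaccine selection

All tie-breaks are fully specified so selections are deterministic and
invariant to sample order.

* **PCV** — antigens scored by the maximum normalized intensity among
  the subject's reactive tiles; top-10 distinct antigens (ties: cohort
  antigen rate, then id); the vaccine contains *all* reactive tiles of
  the chosen antigens, so its size lies in [10, total tiles].
* **FAST** — antigens ranked by cohort positive rate (ties: mean
  normalized intensity over reactive sample×tile pairs, then id);
  top-10 antigens, each represented by its most prevalent tile (ties:
  intensity, then id), giving exactly 10 peptides for a fixed-dose
  pool. "Top 10 candidates" is read at the antigen level with one
  representative tile; a peptide-level reading is possible by ranking
  `peptide_rates` directly.
* **NR** — among peptides non-reactive in the subject, the 10 with the
  lowest cohort rate (ties: subject intensity, then id), at most one
  per antigen so the control spans distinct frameshifts; the constraint
  is relaxed with a warning if fewer antigens qualify.

## Synthetic cohorts

The generator emulates the study design with known ground truth.

* **Transcriptome** (default 240 transcripts, CDS 450–1200 nt, 3′UTR
  150–400 nt): CDSs start ATG, end in a stop, and contain no internal
  in-frame stop. Each transcript hosts one planted homopolymer
  (lengths 7–14, geometric-ish weights). The region downstream of the
  run is sampled T-depleted (T weight 0.13) — stop codons all begin
  with T — so shifted frames stay open long enough for array-sized
  FSPs; this yields ~3.9 tiles/antigen, the published spot-to-antigen
  ratio. 30% of transcripts get a 4-exon structure with a
  frame-disrupting internal exon.
* **Reference array**: the real predictor and tiler run on the
  synthetic transcriptome; the top 200 antigens are kept, ≥ 85%
  microsatellite INDELs ranked longest-repeat-first, the remainder the
  longest exon-skip FSPs.
* **Cohorts**: each challenged subject contributes a paired T0 (naive)
  and T7 (challenged) sample on the same slide (8 subjects per slide).
  `intensity = slide_scale · 10^N(3, 0.15)`, times
  `8 · 10^N(0, 0.1)` for reactive spots of challenged samples; naive
  samples never carry effects. A subject is seroreactive to each
  planted shared antigen with that antigen's cohort prevalence, plus 8
  personal antigens drawn from the non-planted pool (chosen so subjects
  carry the ~10+ reactive antigens personal-vaccine selection needs);
  antigen events are thinned per tile with probability 0.7. Planted
  shared labels are assigned to antigens with ≥ 3 tiles, as the study's
  shared candidates were multi-peptide.
* **`table1_profile()`**: two cohorts — breast (n=24) with ten planted
  antigens at prevalences {20, 13, 9, 8, 8, 7, 7, 7, 7, 7}/24 and
  pancreatic (n=18) with ten candidates at
  {18, 17, 16, 14, 9, 8, 6, 6, 5, 5}/18 plus the breast set's
  pancreatic cross-reactivities, so cross-cohort overlap is non-trivial
  by construction.

**What the generator does not emulate:** peptide-specific baseline
binding differences, spatial slide artifacts, within-antigen correlated
antibody binding across overlapping tiles, titer kinetics between
timepoints, and inter-subject variability in effect size. Passing
recovery tests therefore demonstrate correctness of the selection logic
under the stated noise model, not performance on real sera.

## Known limitations and open behaviour

* With the 2-SD rule, any-reactive-tile aggregation over ~4 tiles gives
  every antigen a ~9% false antigen-level rate per subject. Across ~190
  non-planted antigens the maximum of Bin(24, ~0.13) reaches 8–9
  apparent reactives — the same order as the realized counts of planted
  antigens at 29% prevalence. Shared-vaccine recovery of those weakest
  planted antigens is therefore intrinsically noisy (mean ~7.5/10
  recovered); the recovery test records this behaviour. Requiring ≥ 2
  reactive tiles per antigen would cut the false antigen rate ~20-fold
  but is not the default, as the any-tile rule is the screening
  protocol being reproduced.
* Synthetic PCVs average ~30 peptides (range ~16–46) because ~4 tiles ×
  0.7 tile-reactivity × 10 antigens exceeds the 13–23 peptides per
  mouse reported for the physical array, whose per-antigen tile counts
  are unpublished; the size distribution is reported by the tests
  rather than asserted.
* The survivor rule's "volume < 1000 mm³ and/or no clinical signs" is
  resolved conservatively as *and* (a symptom-free mouse with a 1500 mm³
  tumor should not count as a survivor); the *or* reading is available
  via `require_no_signs=False`.
* GPR-style input supports the single-channel (647 nm) results dialect
  with an optional ATF preamble; background handling is
  subtract-then-floor-at-zero with replicate collapse by median, and
  peptides missing from any sample are dropped to the intersection
  rather than imputed.
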