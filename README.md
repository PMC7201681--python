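# fsvax

Frameshift-neoantigen vaccine design from peptide-array immunosignatures.

Tumors make frameshift peptides (FSPs) not from DNA mutations but from
errors in RNA production: transcription slippage through coding
mononucleotide microsatellites (single-base INDELs) and mis-splicing
that skips an internal exon whose length is not a multiple of 3. Either
error shifts the reading frame, and translation continues in the novel
frame until the first stop codon. Because these error sites are
predictable from transcript sequence alone, all candidate FSPs can be
pre-synthesized as a peptide array and screened against serum — the
antibody-binding pattern (the immunosignature) then identifies the
immunogenic neoantigens for a personal vaccine (PCV), a pre-made shared
vaccine (FAST), or a non-reactive control set (NR).

`fsvax` implements that pipeline end to end, plus a synthetic-data
generator with planted ground truth so every stage is testable without
access to array scans:

* **`fs_prediction`** — maximal homopolymer runs ≥ 7 nt in a CDS; ±1
  INDELs per run (canonicalized at the run start) and single internal
  exon skips; novel-frame translation through the 3′UTR; antigens kept
  when the FSP has ≥ 18 novel residues, ranked by repeat length (longer
  homopolymers have higher slippage rates). EST-frequency enrichment
  scoring, `log2((f_tumor + ε)/(f_normal + ε))`, for user-supplied count
  tables.
* **`array_design`** — overlapping 20mer tiles (10-residue step, final
  tile right-anchored) covering each FSP, padded across the junction
  with wild-type residues when the FSP is short; duplicate tiles are
  collapsed to multi-parent spots.
* **`array_analysis`** — per-slide median normalization (each value
  divided by its slide's median); a naive baseline (per-peptide mean μ
  and SD σ of pre-challenge sera, empirical-Bayes variance moderation by
  default); reactivity calls `x > μ + kσ` with k = 2 on log10 intensity;
  peptide and antigen (any-reactive-tile) positive rates.
* **`vaccine_selection`** — PCV: a subject's top-10 antigens by peak
  reactive-tile intensity, expanded to all reactive tiles; FAST: the
  cohort's top-10 antigens by positive rate, one representative tile
  each; NR: 10 peptides non-reactive in the subject and cold across the
  cohort; cross-cohort rate tabulation.
* **`synthetic_data`** — transcriptomes with planted runs and exon
  structures; a ~200-antigen / ~780-peptide in-silico array built by the
  real predictor; cohorts (breast n=24, pancreatic n=18 challenged, each
  subject with paired pre/post-challenge sera) with log-normal
  background, per-slide scale factors, planted shared antigens at a
  prescribed prevalence spectrum, personal antigens, and 8-fold
  multiplicative effects.
* **`study_stats`** — tumor-volume bookkeeping
  (`volume = length × width² / 2`, survivor rule, tumor-free counts).

## Worked example

```python
from fsvax import run_study, table1_profile, cross_cohort_overlap

res = run_study(table1_profile(seed=1))
print(len(res.design.antigen_peptides), len(res.design.peptides))
# 200 777            <- antigens and 20mer spots on the in-silico array

fast = res.fast("breast")           # shared vaccine for the breast cohort
for aid, rate in fast.selected_antigens[:3]:
    print(aid, res.cohorts["breast"].antigen_rates.loc[aid, "rate_pct"])
# T0187:msins388 87.5        <- antigen reactive in 21/24 challenged mice
# T0115:msins438 54.2        <- 13/24
# T0136:msins23  41.7        <- 10/24

pcv = res.pcv("breast_m00", "breast")   # personal vaccine for one mouse
print(len(pcv.selected_antigens), len(pcv.peptides))
# 10 27              <- 10 antigens expand to 27 reactive tiles

table, n_both = cross_cohort_overlap(fast, res.cohorts["pancreatic"].antigen_rates)
print(n_both)
# 9                  <- breast-vaccine antigens also reactive in the pancreatic cohort
```

Positive rates are percentages of challenged subjects whose sample
exceeds the naive mean by 2 SD for at least one tile of the antigen;
with a denominator of 24, printed rates fall on the 100/24 lattice
(83.3, 54.2, 37.5, 33.3, 29.2, …).

The same run is available from the shell:

```
fsvax run-all --profile table1 --seed 1 --out out/
```

which writes the transcriptome, antigen table, array design, intensity
matrix, normalized matrix, reactivity calls, positive-rate tables and
all vaccine designs, byte-reproducibly for a given seed.

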