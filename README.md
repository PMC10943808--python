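# bcelldyn

Longitudinal B-cell receptor (BCR) repertoire dynamics under B-cell
depleting therapy.

Conventional cytometry loses sight of B cells after anti-CD20 treatment
(rituximab) long before the repertoire actually recovers, so clinically
relevant repopulation is detected late or not at all. `bcelldyn` implements
a sensitive, sequencing-based alternative for rheumatoid-arthritis cohorts
sampled at months 0, 1, 3, 6 and 12 after treatment: it quantifies each
visit's repertoire from UMI-annotated AIRR rearrangement tables, tracks the
percentage of unmutated BCR clonotypes — a proxy for antigen-naive B-cell
influx — and calls per-patient *post-depletion* and *post-repopulation*
timepoints from its collapse and recovery. It then tests whether the timing
of those endpoints is associated with disease activity (DAS28, EULAR
response) and with anti-drug antibody (ADA) development.

## The statistics at its core

For each sample, clonotypes are unique IGHV–IGHD–IGHJ rearrangements at the
nucleotide level, with abundance measured in distinct UMIs (sequences under
3 UMIs are discarded). Four indices summarise a repertoire:

* clonal expansion — Gini inequality coefficient *G* of UMIs per clonotype,
  `G = (2·Σᵢ i·x₍ᵢ₎)/(n·Σ x) − (n+1)/n` on ascending counts;
* clonal diversity — Shannon entropy `H = −Σ pᵢ ln pᵢ` of clonotypes per
  clonal lineage (single-linkage junction clustering at 0.15 normalized
  Hamming distance within V gene / J gene / junction-length groups);
* SHM load — mean IGHV mutation frequency (mismatches per compared base,
  IMGT columns ≤ 312, gaps excluded);
* percent unmutated — share of clonotypes with zero IGHV mismatches.

The endpoint threshold is the cohort baseline mean minus two SDs of the
percent-unmutated distribution (4.4 % for a 40.0 ± 17.8 baseline). A
patient's post-depletion timepoint is the first visit strictly below the
threshold, repopulation the first later visit at or above it; failed
samples are imputed as complete depletion (they can never satisfy the
repopulation side). Group contrasts are normality-gated (D'Agostino–Pearson
K²): unpaired t-test / one-way ANOVA + Bonferroni, or Mann–Whitney /
Kruskal–Wallis + Dunn; contingency tables use Fisher's exact test; DAS28
changes are classified by EULAR response criteria.

A synthetic-cohort generator (`bcelldyn simulate`) emulates a 23-patient
longitudinal study — calibrated percent-unmutated trajectories with planted
depletion/repopulation months, visit-dependent Gini/Shannon/mutation-load
targets, DAS28 trajectories that differ by repopulation group, ADA status
coupled to repopulation, and realistic missing/failed samples — with the
planted truth written alongside, so every downstream stage can be validated
by parameter recovery. See `docs/methods.md` for the model details.

## Worked example

Simulate a cohort, compute metrics, call endpoints, and test the clinical
association:

```bash
bcelldyn simulate --out demo --seed 3
bcelldyn metrics   --airr-dir demo/airr --clinical demo/clinical.csv --out demo/metrics.tsv
bcelldyn endpoints --metrics demo/metrics.tsv --clinical demo/clinical.csv --out demo/endpoints.csv
bcelldyn associate --metrics demo/metrics.tsv --clinical demo/clinical.csv --out demo/report
```

which prints

```
wrote 108 repertoire tables for 23 patients to demo
wrote metrics for 108 samples to demo/metrics.tsv
threshold 7.18% (baseline 42.0 ± 17.4); wrote 23 endpoint calls to demo/endpoints.csv
threshold 7.18%; wrote 15 contrasts to demo/report
```

The threshold line is this cohort's recomputed mean − 2·SD cut-off (each
simulated cohort realizes its own baseline distribution). `metrics.tsv`
holds one row per sample, e.g. patient P01 at baseline vs month 1:

```
patient_id  visit_month  gini   shannon  mean_mutation_freq  pct_unmutated
P01         0            0.293  7.530    0.044               13.66
P01         1            0.503  4.689    0.074               1.70
```

— after treatment the repertoire collapses to fewer, more expanded
(Gini 0.29 → 0.50), less diverse (Shannon 7.53 → 4.69) and more mutated
clonotypes, and P01's unmutated fraction drops below the threshold
(depletion called at month 1). Across this cohort the month-1 means are
Gini 0.54, Shannon 4.74, mutation load 0.071 vs baseline 0.25 / 7.54 /
0.039. `demo/report/contrasts.csv` contains the headline association: early
repopulators improve more between months 6 and 12,

```
delta_das28_6_12_by_repopulator,all,t_unpaired,-3.36,0.0033
```

i.e. an unpaired t statistic of −3.36, p ≈ 0.003, reflecting the planted
−1.17 vs 0.18 DAS28-change contrast.

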