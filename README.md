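# rdpa — RNA-dependent PIP2-associated proteome analysis

Nuclear phosphatidylinositol 4,5-bisphosphate (PIP2) resides in
membraneless compartments — nuclear speckles, nucleoli, nuclear lipid
islets — whose integrity depends on RNA. `rdpa` implements the
computational pipeline for identifying **RNA-dependent PIP2-associated
(RDPA) proteins** from label-free pull-down proteomics and for
characterizing the intrinsically disordered regions (IDRs) through which
they are thought to engage PIP2. It is aimed at proteomics
bioinformaticians who have a log2 LFQ intensity matrix from a
three-condition PH-domain pull-down (wild-type probe, binding-dead R40A
mutant, wild-type after RNase III digestion of dsRNA) plus standard
sequence-level annotations, and want a tested, reproducible version of
every downstream step.

## What it computes

**Discovery.** Rows of the LFQ matrix are filtered to those with 100%
valid values in at least one condition; remaining missing values are
imputed from a per-sample downshifted normal,
`N(m − 1.8·s, (0.3·s)²)` with `m`, `s` the observed column mean and SD.
Differential enrichment uses the moderated statistic

    d = (x̄_A − x̄_B) / (SE + S0),      S0 = 0.2

with SE the pooled two-sample standard error, and a permutation-based
FDR: for each threshold `t` on the (signed or absolute) statistic,
`FDR(t) = E_perm[#{d_perm ≥ t}] / #{d_obs ≥ t}`, and each protein's
q-value is the smallest FDR over thresholds at which it is called.
Step 1 (one-sided, WT > R40A, FDR < 0.05) defines the PIP2-associated
proteome; step 2 (two-sided, WT vs WT+RNaseIII, restricted to step-1
hits) splits it into dsRNA+ (lost after RNase III) and dsRNA− (gained).

**Sequence characterization.** Polybasic PIP2-binding motifs
`[KR]-x(3,7)-K-x-[KR]-[KR]`, `[KR]-x(3,7)-K-x-[KR]` and
`[KR]-x(3,7)-K-x-K` are scanned with ScanProsite's greedy, no-overlap
semantics. A motif counts as inside an IDR when ≥3 disorder predictors
each report a ≥20-residue interval containing its span. Per-IDR
physicochemistry covers the isoelectric point (Henderson–Hasselbalch
net charge, bisection root-finding, EMBOSS pKa set), Kyte–Doolittle
GRAVY, D/E and K/R counts, and an acidic (pI < 7) / basic split.
PTM sites (phosphorylation, acetylation, methylation, sumoylation,
ubiquitination) are intersected with motif-containing IDRs; enrichment
of annotations across protein datasets uses the exact hypergeometric
tail, and between-dataset metric comparisons use BH-corrected two-sided
rank-sum tests.

**Imaging.** 3D nucleus segmentation (Gaussian blur + Otsu + connected
components), foci counting with a 10-voxel minimum size filter
(26-connectivity), Pearson/Spearman/Manders colocalization, and a
deterministic randomization null that rotates one channel by a right
angle in-plane about the nuclear centroid.

Because raw MS data and versioned external databases are not
redistributable, the package ships generators (`rdpa.simulate`) that
produce every input with planted ground truth — enrichment effects,
IDR charge composition, motif and PTM positions, foci counts — so each
stage is benchmarked by recovery, not by fixtures.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
simulated inputs and write their tables to `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_call_rdpa.py
```

prints, for the default design (2,000 protein groups, 195 planted
PIP2-associated proteins of which 150 dsRNA+ and 15 dsRNA−, ±2.0 log2
effects, replicate SD 0.3, 3+3+3 samples):

```
step 1: 182 PIP2-associated protein groups
step 2: 138 dsRNA+ (lost after RNase III), 15 dsRNA- (gained)
vs planted truth: recall 0.920, false-discovery proportion 0.000
```

i.e. step 1 recovers the planted PIP2-associated set almost completely,
and step 2 recovers 92% of the planted dsRNA+ proteins with no false
dsRNA+ calls at FDR < 0.05. Continuing with
`03_idr_physchem.py` … `06_image_quantification.py` annotates consensus
IDRs (168 regions; acidic median pI 3.7 vs basic 12.1, median GRAVY
−0.94), localizes K/R motifs (75.5% of long-motif sites inside IDRs on
this simulation), tabulates PTMs in motif-containing IDRs, and counts
planted nuclear foci with 100% exact recovery while the rotation null
drops the colocalization Pearson from 0.39 to 0.02.

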