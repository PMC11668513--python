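# Methods

This note records the models, parameter choices and numerical decisions
behind `rdpa`, and what the synthetic benchmarks do and do not
demonstrate.

## Differential enrichment (two-step discovery)

**Filtering.** A protein group is testable only if some condition has a
complete set of observed replicates ("100% valid values in at least one
group"). This keeps the classic pull-down signature — present in WT,
absent in control — while discarding rows that are sporadic everywhere.

**Imputation.** Missing LFQ values are treated as censored low
intensities. Each missing cell in sample *c* is drawn from
`N(m_c − shift·s_c, (width·s_c)²)` with `m_c`, `s_c` the observed mean
and SD of that sample and defaults `shift = 1.8`, `width = 0.3`. The
per-sample variant is the default because detection limits are
instrument-run properties; a pooled global mode is available
(`per_column=False`). Columns need ≥3 observed values; fewer is an
error rather than a silent wide-variance draw. Imputation is seeded and
bit-reproducible.

**Moderated statistic.** `d = (mean difference) / (SE + S0)` with SE the
pooled equal-variance standard error and `S0 = 0.2`. S0 enters
additively on the standard-error scale (the SAM convention): it damps
the t-statistic's heavy small-sample tails by flooring the denominator,
so that a large `d` requires both a real fold-change and a stable one.
With `S0 = 0` the statistic reduces exactly to the classical pooled t
(verified against an independent textbook implementation).

**Permutation FDR.** The null is built from complete relabelings of the
pooled columns. The observed assignment is excluded, and for the
two-sided statistic complementary assignments (which give identical
|d|) are enumerated once — with 3v3 replicates this leaves 19 distinct
one-sided and 9 two-sided null relabelings, and `n_perm` larger than
that triggers exact enumeration. Retaining the identity assignment
would floor every estimated FDR at `1/n_perm` and make FDR < 0.05
structurally unreachable at this design size. For each candidate
threshold `t` (the observed scores themselves), `FDR(t)` is the mean
number of permuted scores beyond `t` divided by the observed count
beyond `t`, with the null proportion π0 fixed at 1 (conservative); a
protein's q-value is the minimum `FDR(t)` over thresholds at which it
is called, which makes q monotone in the score and resolves ties
deterministically. Under a fully null simulation the realized
significant fraction at α = 0.05 is ~0 (benchmarked at ≤2% over 20
seeds).

**Two-step logic.** Step 1 is one-sided (enrichment of the wild-type
probe over the binding-dead R40A control); step 2 is two-sided on the
step-1 hits only, so the dsRNA+ / dsRNA− split never resurrects a
protein that failed step 1. Replicate QC (per-sample median intensity
and mean inter-sample correlation) is reported for outlier inspection;
removal is a manual choice, never automatic.

## IDR annotation

Disorder intervals are 1-based inclusive (PROSITE/UniProt convention);
converters to 0-based half-open exist only at the I/O boundary.
Intervals are normalized per predictor (sorted, touching/overlapping
runs merged). Two notions are used deliberately:

* *protein has an IDR*: any single-predictor interval of ≥20 residues
  (a ≥30 threshold is the same function with another `min_len`);
* *consensus IDR*: maximal runs of residues covered by ≥k predictors
  (default k = 3), filtered to ≥20 residues, with `support` the minimum
  coverage over the run. This is the unit for per-IDR metrics and for
  the PTM table.

For motif localization, "inside an IDR" means ≥k predictors each have a
≥20-residue interval **fully containing** the motif span — full
containment rather than overlap, because a motif partially sticking out
of a disordered region is not "at" a disordered site; an overlap mode
is exposed for sensitivity analysis. Per-IDR pI/GRAVY are computed on
the coverage consensus by default (single-predictor mode available).

## Motif scanning

The three polybasic patterns are compiled from their PROSITE strings;
the wildcard x matches the 20 canonical residues plus X. Scanning is
greedy and non-overlapping: leftmost start wins, at one start the
longest feasible x(3,7) run wins, and the scan resumes immediately
after an accepted hit. Python's regex engine implements exactly these
semantics, and an independent brute-force oracle (enumerate all
(start, run-length) candidates, sort by (start, −length), accept
non-overlapping) is held equal to it on 10,000 random K/R-enriched
sequences per pattern. The three patterns are scanned independently
since they are reported separately; the long pattern's hits always
nest a mid-pattern match at the same start.

## Physicochemistry

Net charge is the Henderson–Hasselbalch sum over the free termini and
D/E/C/Y/H/K/R side chains; the pKa set defaults to EMBOSS values
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1) and is a plain dataclass, since published pI values depend on
the chosen scale. Charge is monotone decreasing in pH and bracketed by
the termini, so bisection on [0, 14] (tolerance 1e-4 pH) always
converges; the returned pI satisfies |Q(pI)| < 1e-3 and agrees with a
1e-4-step grid search to 0.001. GRAVY is the mean Kyte–Doolittle
hydropathy with X excluded from numerator and denominator. The
acidic/basic IDR split is at pI < 7, with pI = 7 classified basic;
bimodality is reported descriptively (kernel-density export), not via
a mixture fit.

## Set statistics

Over-representation uses the inclusive upper hypergeometric tail
P(X ≥ k) computed by exact pmf summation (lower tail for depletion);
dataset members outside the declared background are dropped with a
warning. Rank-sum comparisons are two-sided Mann–Whitney tests — exact
null for small untied samples, normal approximation with continuity
correction otherwise — BH-adjusted over the family of unordered pairs.
Summaries follow boxplot conventions: median, linear-interpolation
(type-7) quartiles, whiskers at the most extreme values within 1.5×IQR.

## Image quantification

Nuclei are segmented from the DAPI channel by 3D Gaussian blur
(default σ = 2 voxels), global Otsu threshold and 26-connected
components. Foci counting blurs the target channel (default σ = 1.5
voxels) using **normalized masked convolution** — the kernel is
renormalized over in-mask voxels — so that the empty exterior never
drags down boundary intensities or distorts the within-mask Otsu
threshold. Components smaller than 10 voxels are discarded (keep-if
≥10). Foci are small puncta by definition, so if the automatic
threshold marks more than 25% of the nucleus as bright there is no
separable foci class (the focus-free case, where Otsu can only split
noise) and zero foci are reported with a warning; a fixed threshold
bypasses both Otsu and this guard.

Colocalization coefficients are computed over in-mask voxels. Manders
M1/M2 default to the classic zero-threshold definition (fraction of one
channel's intensity in voxels where the other is positive), for which
identical channels give exactly M1 = M2 = 1; the thresholded variant
(per-channel in-mask Otsu) is available and is what the analysis driver
reports, as it is far more discriminative on images with diffuse
background. The randomization null rotates each z-slice of channel 2 by
90/180/270° about the mask centroid rounded to the nearest voxel — an
exact lattice permutation that preserves the intensity histogram, needs
no interpolation, and is fully deterministic; coefficients are then
computed over the intersection of the mask with its rotated image.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (config, seed).

**Pull-down.** Latent log2 abundances are `N(25, 2²)`; replicate noise
SD 0.3; 195 planted PIP2-associated proteins are shifted +2.0 in WT vs
R40A, of which 150 (dsRNA+) are shifted −2.0 and 15 (dsRNA−) +2.0 in
the RNase III condition; 3 replicates per condition, 2,000 protein
groups. Missingness is missing-not-at-random — logistic in the noisy
intensity with midpoint 19.0 and scale 0.8 log2 units, plus 1% uniform
MCAR — which concentrates dropout in depleted control/treated cells
(the structure the downshifted imputation presumes) and yields ~2%
missing cells overall, consistent with a matrix of reliably quantified
protein groups. Under these conditions the two-step caller recovers
≥90% of planted dsRNA+ proteins with observed false-discovery
proportion ≤0.1 (averaged over 5 seeds). Not emulated: correlated
noise between protein groups, ratio compression, protein-group
inference errors, or shared peptide effects — so the benchmark
demonstrates the statistics, not MS preprocessing.

**Proteome.** 150 proteins of 200–600 residues from vertebrate-like
background frequencies; Poisson(1.2) IDRs per protein of 40–90
residues, each acidic (D+E 30%, K+R 5%) or basic (K+R 30%, D+E 5%);
a 9-predictor panel re-reports each truth IDR with ±3-residue boundary
jitter and 10% dropout, so the ≥3-predictor consensus rule is
meaningfully exercised. Motifs are planted inside IDRs with an inner
margin of 13 + jitter residues — enough that any greedy hit touching
the planted span (which can extend at most 11 residues left and 5
right of it) stays inside every jittered predictor interval — and
planted spans are kept >12 residues apart so no single hit can bridge
two of them; every planted motif is verified by the scanner before
emission. Accidental motifs in K/R-rich background are allowed by
default (the scanner defines sequence-level truth); a strict mode
re-draws residues until only planted hits remain. PTM sites are planted
per IDR (phospho 0.4, acetyl 0.2, ubiquitin 0.15, methyl 0.1, sumo
0.05) plus Poisson(0.5) background sites per protein. Real disorder
predictors disagree more structurally than jittered truth; the
benchmark validates the consensus arithmetic, not predictor biology.

**Images.** One ellipsoidal nucleus (semi-axes 18×34×34 voxels in a
50×100×100 grid) per stack; foci are Gaussian profiles (σ = 1.5 voxels,
≈3-voxel radius) with peak 10× background, placed ≥10.5 voxels apart
and well inside the nucleus; Gaussian read noise SD 0.2. At this SNR
and separation, planted counts 0–20 are recovered exactly in ≥90% of
nuclei (in practice 100%). A second channel can share a configured
fraction of foci for colocalization benchmarks. Not emulated:
anisotropic voxels, depth-dependent attenuation, chromatic shifts, or
touching nuclei.

## Problem sizes

Defaults are chosen so that the full test suite runs in about half a
minute and the reproduction script in ~20 s on one CPU: 5 discovery
seeds × 2,000 proteins, 20 null seeds × 1,000 rows, 50 nuclei,
10,000 scanner sequences per pattern in the suite (6,000 total in the
script), 500–1,000 cases for the remaining oracles.

## Known limitations

* The permutation null at 3v3 has only 19 (9 two-sided) distinct
  relabelings, so q-values are coarse; the threshold-scan estimator
  compensates by borrowing across proteins, but single-protein
  inference at this design size is inherently crude.
* Downshifted imputation biases low-abundance contrasts toward the
  column's imputation centre; planted effects on proteins near the
  detection limit are partially erased, which is faithful to the
  method, not an artifact of this implementation.
* The pI model ignores charge interactions between neighbouring
  residues and phospho-residue charge.
* Otsu-based foci thresholds assume a bright, sparse foci class; dim
  or dense foci regimes need the fixed/percentile threshold options.
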