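# Methods

`cytoprof` implements the analysis stack for a two-arm, two-timepoint
mass-cytometry (CyTOF) immune-profiling study — antibody-panel event
matrices per sample, paired TCRβ repertoires and an immune gene panel —
together with a synthetic cohort generator that makes the whole stack
testable end to end without patient data. This note records the models,
the parameters that matter, and the design decisions taken where the
methodology was genuinely open.

## Preprocessing and QC

Raw ion counts are transformed with `asinh(x / c)`, cofactor `c = 5`
(mass-cytometry convention); the transform is exactly invertible via
`sinh(y) * c`. Sample retention applies a strict live-singlet threshold:
a sample is kept only if its event count is **greater than** 10,000. An
on-treatment sample whose baseline partner failed QC is excluded as well
(`excluded_paired`): its within-patient comparison no longer exists.

Batch-effect QC clusters samples by the Earth Mover's Distance between
their immune-composition vectors. The EMD is solved exactly as an
optimal-transport linear program (HiGHS); the default ground distance is
the unit cost between distinct populations, under which the EMD equals
half the L1 distance between compositions. The clustering is average
linkage; linkage and cut height are declared defaults, not estimates —
they can be changed in the call. QC passes when all replicate control
samples fall into a single flat cluster. Marker enrichment (MEM) scores,
`sign(ΔMed)·(|ΔMed| + IQR_ref/IQR_pop − 1)` with IQRs floored at 1e-6,
quantify which markers distinguish a population from a reference.

## SPADE

The classical pipeline: density-dependent downsampling per sample, pooled
clustering to a fixed node count (default 150), a minimum spanning tree
over node medians, and upsampling of every cell to its nearest node. L1
distance is used throughout (configurable to L2). Local density is the
neighbor count within radius `r = α · median nearest-neighbor distance`
(α = 5); the keep probability is `min(1, TD/density)` with the target
density TD tuned by bisection so the expected kept fraction matches the
requested rate (default 10%). No hard outlier removal is applied — the
low-density tail is always keep-eligible. Clustering is average-linkage
agglomerative for ≤3,000 cells and (mini-batch) k-means above that, with
empty clusters repaired by splitting the largest; node medians are always
recomputed as per-channel medians of members. Nearest-node ties break to
the lowest node id for determinism.

Gating is rule-based: each population is a conjunction of
`channel above/below threshold` rules plus its ancestors' rules, on the
arcsinh scale; a node (gating operates on node medians, mirroring bubble
practice; per-cell gating is available) belongs to the deepest satisfied
population, otherwise "ungated". Population counts roll up the hierarchy,
so child ≤ parent holds by construction, and `%total(child) =
%parent(child) · %total(parent)` exactly. A population with a zero-count
parent has undefined `%parent` and is excluded downstream (the tabular
analogue of graying out an empty node).

## Differential statistics

The unit statistic is the mean marker intensity (MMI): the arithmetic
mean of arcsinh intensities over a unit's cells in one sample; empty
units yield no value rather than zero. Group comparisons use the Welch
two-sample t-test (Satterthwaite df). Degenerate-variance conventions:
both groups constant and equal → t = 0, p = 1; constant and unequal →
p = 0. Units lacking an MMI in any sample of a comparison are dropped
from that comparison.

Multiplicity over the dependent (unit, marker) family is corrected with a
single-step maxT bootstrap: each group is mean-centered per hypothesis
(null enforcement), samples are resampled with replacement within groups
(columns shared across hypotheses, preserving dependence), all Welch
statistics are recomputed, and
`adj_p_i = (1 + #{b: max_j |t*_bj| ≥ |t_i|}) / (B + 1)` with B = 1000 by
default, followed by monotonicity enforcement. The scheme is our choice:
the goal (family-wise control under dependence) is fixed, the algorithm
was open. Paired fold change is the within-patient on-treatment minus
baseline MMI difference (a difference on the arcsinh scale, not a ratio),
averaged per group; unpaired patients are excluded. Positivity fractions
use strict thresholds (e.g. MSI > 0.25 for CD137+, MSI > 1 for CD69+/
CD27+). The dim/bright subset ratio is tested on treatment with the
paired machinery (Wilcoxon on within-patient ratio changes), since the
design is paired and the bright-cell denominator is small. Analyses can
be re-run excluding a named patient set (outlier-exclusion hook).

## Centile-bin analysis and the weighted-ECDF permutation test

Bins are defined by order-statistic centiles (default 100) of the pooled
cells of all conditions; tied consecutive edges — a value spike holding
more than 1% of cells — merge into a single bin, keeping edges strictly
ascending. Per-condition bin fractions and per-bin condition shares feed
the bin plots.

The distributional test compares sample-weighted empirical CDFs: each
cell weighs `1/(n_cells(sample) · n_samples)`, so every sample
contributes equal mass and a million-cell sample cannot drown a small
one. The statistic is the supremum difference between the two condition
ECDFs on the pooled-order-statistics grid (an integrated-L1 variant is
available behind a flag); it is invariant to monotone transforms of the
intensity scale. The null permutes condition labels at the **sample**
level (whole samples swap labels), respecting within-sample correlation;
paired designs swap each pair with probability 1/2. p = (1 + exceedances)
/ (B + 1). No closed-form reference distribution exists once weights are
unequal, hence permutation only.

## TCR repertoire

Clonality is `1 − H/ln R` (Shannon entropy in nats, richness R), i.e.
1 − Pielou evenness — the de-facto definition for the immunosequencing
assay; the log base cancels. A monoclonal repertoire (R = 1) is defined
as clonality 1. Richness is the count of distinct observed clones.
Paired baseline/on-treatment comparisons report group medians with a
Wilcoxon signed-rank p (all-zero differences → p = 1). The clonality-
change vs CD8 expansion link is Spearman rank correlation. Baseline-
richness survival stratification (median or quartile split) uses a
Kaplan-Meier estimator and two-group log-rank test implemented from
first principles (the 2×2-per-failure-time form); `lifelines` serves as
an independent oracle in the tests only.

## Expression with abundance correction

Counts are normalized per sample so the geometric mean of housekeeping
genes equals a fixed target level (500), then log2(x+1); the factor
depends only on the sample's own counts, so rescaling a sample is an
exact no-op. The paired model works on explicit within-patient
differences (on-treatment − baseline) per gene and tests their mean —
deliberately replacing a random-effect/duplicate-correlation formulation
with the equivalent-estimand paired contrast for a two-timepoint design.
The abundance-corrected model adds within-patient changes of
cytometry-derived %total fractions, logit-transformed with ε = 1e-4, as
covariates; the reported test is the treatment term conditional on
composition change. Collinear or constant covariates are dropped with a
warning, which also makes the corrected model reduce exactly to the
uncorrected one when abundances do not change. BH (FDR) adjustment is
applied across genes — the conventional choice for the expression arm —
not maxT.

## Visualization transforms

Blend coloring maps each analyzed node to (decrease/increase,
significant/nonsignificant) using the fold-change sign and the **raw**
p-value at α = 0.05 (the tree is an exploratory display); unanalyzed
nodes are "excluded". Radviz places the selected channels equally spaced
on the unit circle (anchor order = declared channel order; no ordering
optimizer) and each cell at the convex combination of anchors weighted by
its min-max-normalized intensities; all-zero cells sit at the origin.
Fan-chart tables are per-condition centile grids (5–95 by 5), monotone by
construction, centered on the median.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Structure: 40 treated-arm and 45 control-arm patients at
baseline, of whom 31 and 33 contribute paired on-treatment samples, plus
38 replicate technical control samples; responder fractions 92.5% and
77.8% assigned as deterministic counts. Cell events are drawn directly on
the arcsinh scale — each population is multivariate normal per channel
around a phenotype resolved by inheritance down a 16-population
whole-blood hierarchy (literature-style fractions; every setting
config-overridable). Raw-scale export uses the inverse transform. Metadata
event counts (~60k) emulate instrument acquisition; generated matrices
default to 1,500 cells/sample — a desk-scale subsample that keeps the full
pipeline in seconds.

Within-patient correlation comes from patient-level lognormal abundance
effects (sd 0.25) and per-channel offsets (sd 0.05) shared across
timepoints, with extra per-sample noise (sd 0.12). Spiked treated-arm
effects: CD38 −1.0 shift on NK/B/monocyte/CD4 populations, NK depletion
biased to CD56dim (×0.40 vs ×0.75), CD8 memory/TEM/TEMRA expansion
(×1.6/1.5/1.4), Treg ×0.55 and MDSC ×0.50 depletion, activation shifts
(CD69, CD27, CD137, HLA-DR) on persisting NK cells. A per-patient latent
"depth of response" (sd 0.25 on the log scale) scales every effect and the
repertoire expansion jointly, which is what makes the clonality–CD8
correlation recoverable. Abundance multipliers act on the affected
subtree's leaf weights before renormalization; with realistic population
sizes the renormalization bias is well inside the ±20% recovery
tolerance.

Repertoires follow a rank power law `p_i ∝ i^(−s)` over a patient-level
clone pool (400 clones, lognormal sd 0.30), multinomially sampled to
20,000 templates; s = 0.90 at baseline rising by 0.15 on treatment in the
treated arm, which puts baseline clonality near 0.17 and on-treatment
near 0.26 — realistic magnitudes for the assay, asserted nowhere.
Progression times are exponential with the treated-arm hazard decreasing
in the latent richness factor (log-HR 0.6 per SD) and administrative
censoring uniform over 24–48 months (≈70% events). Gene counts are
`max(scale · fraction, floor)` for abundance-linked genes (8 NK-linked, 8
CD8-linked), constant for others, times lognormal noise (sd 0.15), Poisson
sampled; three genes carry true ±1 log2 treatment shifts so the
abundance-correction contrast has both signal types.

What the generator does **not** emulate: doublets/debris, bead events,
spillover, channel crosstalk, non-Gaussian (bimodal within-population)
marker distributions, batch drift, or clone overlap structure between
patients. Passing tests therefore demonstrate correctness of the
algorithms under a clean generative model, not robustness to instrument
artifacts.

## Problem sizes and numerics

Validation suites run at desk scale as the package's own choice: recovery
replicates use 30 treated patients (fully paired) at 700 cells/sample with
B = 200 resamples; calibration suites use 200 replicates (type-I error,
family-wise error with H = 50 correlated hypotheses) and 1,000 null Welch
tests. Tolerances: EMD LP vs flow oracle 1e-4 relative; arcsinh
round-trip 1e-9; %total chain identity 1e-9. Degenerate inputs are
handled explicitly throughout: empty units excluded rather than imputed,
zero-variance Welch conventions above, IQR floors in MEM, NaN subset
ratios on zero denominators, fewer cells than nodes reduces the node
count with a warning.

## Known limitations

- The agglomerative/k-means switch means very large cohorts cluster with
  k-means in L2, an approximation to the L1 tree the small-input path
  builds.
- The weighted-ECDF permutation p is granular at 1/(B+1); with few
  samples per condition the permutation space is small and p-values are
  conservative.
- The abundance-corrected model is linear in logit-fraction changes; a
  gene driven nonlinearly by composition may retain residual
  significance.
- Survival stratification uses the observed (sampled) richness, so the
  split misclassifies patients near the median, attenuating the measured
  hazard ratio relative to the generator's latent coupling.
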