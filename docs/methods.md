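# Methods

This note documents the models, default parameters and numerical choices
behind each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Image quantification

Segmentation is deliberately simple: threshold (Otsu by default, fixed
override) the reporter channel — its maximum projection in 2D mode — and
take connected components (8-connectivity in 2D, 26 in 3D) whose physical
size lies in `[min_size, max_size]` (default 10–10⁵ µm²/µm³, converted from
voxels via `voxel_size`).  No watershed splitting or instance segmentation
is attempted; the synthetic fixtures guarantee separated cells, and on real
material the size filter is the only defence against merges.  Per-cell mean
and maximum intensities are computed per channel over ROI voxels (labelled
reductions, verified against a per-voxel loop).

Classification uses the *mean* identity-marker intensity; marker
co-positivity calls use the configured statistic (*max* by default).  The
boundary convention is `statistic ≥ threshold ⇒ positive` everywhere, which
makes classification monotone in the threshold.  Threshold rules: `fixed`,
`otsu_on_cells` (Otsu over the per-cell statistic; the resolved value is
logged to the run manifest) and `quantile_of_negative_control` (default
q = 0.95 of supplied negative-control intensities).  A degenerate Otsu
input (constant intensities) classifies all cells typical with a warning
rather than raising, so pathological sections do not abort a cohort run.

Cohort statistics aggregate at the animal level — sections are pooled
within animal before any percentage is formed — to avoid pseudo-replication.
Percentages use the lineage-positive count as denominator for class shares
and the class size for marker shares.  Two groups are compared with an
unpaired two-tailed t-test; three or more with one-way ANOVA gated by a
per-group Shapiro–Wilk check (α = 0.05; the gate outcome is reported, not
enforced) and followed by Tukey's HSD.  Report percentages are rounded
half-up to integers (8/9/7 of 24 → 33/38/29).

## 3D spatial statistics

Densities are estimated with a Gaussian product kernel; the default
bandwidth is Scott's rule per axis, hₐ = σ̂ₐ n^(−1/7) (d = 3), with
Silverman and fixed alternatives.  Grid evaluation exploits the kernel's
separability (per-axis Gaussian factor matrices contracted over points) and
is tested to 1e−10 against a direct per-node kernel sum.  The default grid
spacing is 25 µm with the grid padded by three bandwidths so each field
integrates to 1 within 5 %.

The "occupied region" restricting the node-wise test is the super-level set
of the all-cells density at a threshold chosen as the `occupancy_quantile`
(default 0.25) of the density evaluated **at the cell positions**.  Taking
the quantile over cell-local densities rather than over grid-node values
makes the region cover where the densest 75 % of cells actually sit and
keeps it independent of how far the evaluation grid is padded; a node-value
quantile would sweep in arbitrarily large near-empty margins.

The local test computes, per animal, normalised density fields for each
subpopulation on the shared grid and applies a two-tailed paired t-test
across animals to the per-animal (typical − ghost) differences at every
occupied node.  Animals are the sampling unit (pairing avoids
pseudo-replication); all-zero paired differences give p = 1 by convention,
and a zero-variance nonzero difference is reported at the p floor (1e−300)
rather than 0 so p ∈ (0, 1].  A permutation variant (labels shuffled within
animal, two-tailed on the mean difference, add-one corrected) is available
for calibration checks.  No multiple-testing correction is applied by
default — the node field is a descriptive map — but Benjamini–Hochberg is
available.

Rostro-caudal structure is summarised by the empirical CDF of positions
along the third axis (pooled across animals) and a least-squares fit of
Φ((x−μ)/σ).  Initial values come from interpolating the 16/50/84 %
crossings, with two fallback starts; σ is bounded positive.  The
extra-sum-of-squares F-test compares one shared (μ, σ) on the concatenated
data against separate fits, F = [(RSS_pooled − RSS_sep)/2]/[RSS_sep/(n−4)],
p from the F(2, n−4) tail.  **Known approximation:** cumulative fractions
are treated as independent observations, as in the graphing convention this
test mirrors.  Empirical-CDF residuals are in fact strongly correlated, so
the test is anticonservative as a formal hypothesis test on raw CDFs; the
package's calibration check therefore exercises the F-test engine under its
own regression model (independent noise around a true Gaussian CDF at fixed
abscissae), where its type-I error is nominal.  With thousands of points
per subpopulation the fitted means recover a simulated 200 µm shift to a
few micrometres, which is the quantity of scientific interest.

## Electrophysiology

Input resistance is the least-squares slope of steady-state deflection
against injected current over hyperpolarizing steps (0 to −80 pA in −10 pA
increments in the standard protocol); mV/pA = GΩ, reported in MΩ.  Spike
onsets are dV/dt > 20 mV/ms crossings; window means mask ±5 ms around each
onset and, when a current trace is present, any sample during or within
50 ms after nonzero current injection.  AP features at rheobase (lowest
spiking step): threshold at the first crossing, amplitude = peak −
threshold, halfwidth at half-amplitude by linear interpolation, fAHP as the
drop below threshold within 5 ms of the peak, mAHP within 50–200 ms.
These windows are field-standard conventions; recordings with no spiking
step return a flagged no-rheobase result.

Hormone responses use a 30 s pre window ending at application onset and a
30 s post window starting 300 s after onset.  ΔRMP is the difference of
spike-masked window means; Ri pre/post comes from −5 pA monitor-pulse
deflections (last half of each pulse against its immediate pre-pulse
baseline, averaged over pulses fully inside the window).  The rule —
activated iff ΔRMP ≥ +2 mV **and** |ΔRi| ≥ 10 %, inhibited iff
ΔRMP ≤ −2 mV and |ΔRi| ≥ 10 % — reads the "10 % change" criterion as a
magnitude (direction is carried separately) and requires both criteria
jointly; an `or` combination is available for sensitivity analysis.
Boundaries are inclusive.  Category × population tables are tested with
Pearson chi-squared without continuity correction; a fixed-margin
permutation null (multivariate hypergeometric rows) is provided and agrees
with the asymptotic p to well within 0.01 on the study's 24-cell tables.

## Patch-seq clustering

Normalisation is log1p of counts-per-10⁴ — the least surprising convention
for small full-length single-cell libraries; no highly-variable-gene
selection is applied by default in the tens-of-cells regime.  Cells are
embedded by PCA (20 components, capped at cells − 1; deterministic full
SVD), connected in an unweighted kNN-union graph (k = 10, Euclidean in PC
space) and partitioned by Leiden (modularity with a resolution parameter)
over the grid 0.1–2.0 in steps of 0.1.  The mean silhouette in PC space is
computed for every partition with ≥ 2 clusters; the resolution maximising
it is selected, ties going to the smallest resolution, and clusters are
relabelled by decreasing size.  If no resolution produces ≥ 2 clusters, or
the best silhouette falls below `min_silhouette`, the degenerate
single-cluster result is returned.  Relative expression is cluster mean
minus rest mean on the log scale; a marker-panel score averages this over
panel genes (absent genes are reported, not fatal).  QC reports per-cluster
totals and mitochondrial/ribosomal count fractions (gene flags from name
prefixes `mt-`, `Rps/Rpl/Mrps/Mrpl`) with one-way ANOVAs across clusters.
Composition shift between diets is Pearson chi-squared on the cluster ×
condition count table, with per-condition cluster percentages.

## Synthetic data: what it emulates, and what it does not

*Image stacks* (default 32 × 288 × 288 voxels at 1 µm, 200 cells, 10 %
ghost): spheres (radius ~N(3, 0.4) µm, floored at 2.2 µm) whose XY-
projection disks are separated by ≥ 3 µm (rejection sampling, ≤ 10⁴
retries), a reporter channel equally bright for both classes, an identity
channel bright only in typical cells, additive Gaussian voxel noise clipped
at 0.  Ghost count is round(n · fraction) exactly, not binomial, so fixture
sizes are stable.  Not modelled: PSFs, clearing artefacts, touching cells,
intensity gradients — so passing recovery tests demonstrates the pipeline's
arithmetic, not robustness to real optics.

*Point clouds*: trivariate normals per subpopulation (default σ = 100, 100,
120 µm — compact subdomains a few hundred µm across, commensurate with an
ARC-scale volume), ghost centre displaced 200 µm along the rostro-caudal
axis, animals assigned round-robin (per-animal counts differ by ≤ 1).  At
the default 2000 cells per subpopulation the CDF-fitted means resolve the
shift to well under 10 µm.

*Ephys cohorts*: constant RMP (−55 mV) plus white noise (0.3 mV default),
the hormone effect ramping linearly over 120 s after onset to the class
effect size (±4 mV, ±15 % by default — comfortably beyond the 2 mV/10 %
thresholds relative to noise), instantaneous ohmic deflections to −5 pA
pulses (0.5 s every 2 s) scaled by the evolving Ri, sampled at 500 Hz.
Membrane time constants, spikes and synaptic noise are not simulated, so Ri
deflections are square; the analysis still uses only the pulse steady
state, as it would on filtered real traces.

*Count matrices*: negative binomial with variance = μ + μ²/θ (θ = 2), the
76-cell cohort split 45/13/12/6 across clusters and 38/38 between diets;
each cluster carries 40 exclusive marker genes at 8-fold elevated mean over
a baseline of 2 (neuronal subtypes differ in tens-to-hundreds of genes);
an 8-gene identity program (high baseline, mean 20) is depleted 4-fold in
the two designated ghost-like clusters.  Ambient RNA, doublets, dropout
beyond NB sampling and batch effects are not modelled.

## Problem sizes in the tests and acceptance script

The test suite and `scripts/acceptance.py` use the generator defaults
(5 × 200-cell stacks, 2000 + 2000-point clouds, 24-cell ephys cohorts over
5–10 seeds, 10 replicate null clouds of 400 + 400 points, 76- and 180-cell
count matrices over 10 seeds, 10⁵ permutation draws, 1000–2000 simulated
nulls for the F/ANOVA calibrations); these sizes make every Monte-Carlo
bound in the tests sharp while a full run completes in about a minute.

## Known limitations

- Segmentation cannot split touching cells; on dense real tissue a
  dedicated instance segmenter should replace `segment_cells_*` (the rest
  of the pipeline only needs a label map).
- The extra-sum-of-squares comparison of empirical CDFs is descriptive
  (see above); for a calibrated two-sample location test use the node-wise
  field or a rank test on the raw positions.
- Leiden on a kNN graph with k = 10 can absorb clusters smaller than ~k
  into a neighbour; the 6-cell cluster in the default cohort is recovered
  in most but not all seeds (merges keep ARI ≥ 0.9).
- The chi-squared permutation helper assumes a 2-row table (the study's
  design); larger designs fall back to the asymptotic test.
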