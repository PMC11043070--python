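# ghostmap

Analysis pipeline for lineage-traced **"Ghost" neurons** — cells that carry a
permanent lineage reporter (e.g. tdTomato or ZsGreen switched on by a
*Pomc*-promoter CreERT2) but express negligible levels of the identity marker
itself, making them invisible to promoter-based detection.  The package
covers the four computational stages of a Ghost-cell study of the arcuate
nucleus (ARC), for imaging scientists and electrophysiologists who want a
scriptable, testable replacement for the usual FIJI/Prism/notebook mix:

1. **Image quantification** (`ghostmap.imagequant`): reporter-positive cells
   are segmented as thresholded connected components (8-connected on 2D
   maximum projections or 26-connected in 3D), mean/max intensities are
   measured per cell and channel, and cells are classified *typical* vs
   *ghost* by mean identity-marker intensity (Otsu or fixed threshold; the
   rule "statistic ≥ threshold ⇒ positive" is used everywhere).  Cohort
   statistics aggregate per animal (sections pooled first): Student t,
   Shapiro-gated one-way ANOVA with Tukey post-hoc, Pearson correlation.
2. **3D spatial statistics** (`ghostmap.spatial`): Gaussian-product-kernel
   density fields f̂(x) = (1/n) Σᵢ Πₐ φ((xₐ−Xᵢₐ)/hₐ)/hₐ on a regular grid
   (Scott's rule per axis), super-level-set ("isosurface") summaries, a
   node-wise paired t-test across animals on typical−ghost local density
   restricted to the space occupied by the neurons ("p-value spheres"), and
   a rostro-caudal comparison fitting Gaussian CDFs Φ((x−μ)/σ) to the two
   empirical cumulative distributions with an extra-sum-of-squares F-test
   F = [(RSS_pooled−RSS_sep)/2] / [RSS_sep/(n−4)].
3. **Electrophysiology** (`ghostmap.ephys`): input resistance from
   hyperpolarizing step trains (slope of ΔV vs I), spike-masked resting
   membrane potential, rheobase and AP shape features (threshold at
   dV/dt > 20 mV/ms, amplitude, halfwidth, fAHP/mAHP), pre/post hormone
   deltas from −5 pA monitor pulses, and the response rule: *activated* iff
   ΔRMP ≥ +2 mV and |ΔRi| ≥ 10 %; *inhibited* iff ΔRMP ≤ −2 mV and
   |ΔRi| ≥ 10 %; otherwise *non-responsive*.  Category distributions are
   compared by Pearson chi-squared (a permutation null is built in).
4. **Patch-seq clustering** (`ghostmap.patchseq`): log1p counts-per-10⁴
   normalisation, PCA → kNN-union graph → Leiden over a resolution grid
   with mean-silhouette model selection, relative expression
   (cluster mean − rest mean), marker-panel scores, QC (totals, mito/ribo
   fractions) and diet-composition shift testing (chi-squared on the
   cluster × condition table).

A synthetic-data module (`ghostmap.simulate`) generates every input with
known ground truth — image stacks with a prescribed ghost fraction,
caudally shifted 3D point clouds, hormone-response cohorts with prescribed
ΔRMP/ΔRi classes, and negative-binomial count matrices with cluster marker
programs — so the whole pipeline runs and is tested without any external
download.

## Worked example

```python
import numpy as np
import ghostmap as gm

# hormone-response cohort: 8 activated / 9 inhibited / 7 non-responsive
# typical cells vs 5 / 2 / 17 ghost cells
calls_t = [gm.classify_response(*d) for d in
           [(4.0, 15.0)] * 8 + [(-4.0, -15.0)] * 9 + [(0.0, 0.0)] * 7]
calls_g = [gm.classify_response(*d) for d in
           [(4.0, 15.0)] * 5 + [(-4.0, -15.0)] * 2 + [(0.0, 0.0)] * 17]
import pandas as pd
table = pd.DataFrame([gm.summarize_calls(calls_t), gm.summarize_calls(calls_g)],
                     index=["typical", "ghost"])
rep = gm.response_contingency_test(table)
print(rep["percentages"])          #            activated  inhibited  nonresponsive
                                   # typical           33         38             29
                                   # ghost             21          8             71
print(round(rep["chi2"], 3), round(rep["p"], 4))   # 9.314 0.0095

# spatial shift: ghost subpopulation displaced 200 um caudally
cloud = gm.gen_point_cloud(gm.SpatialSpec(seed=1))
ft = gm.compare_fits_extra_ss(
    gm.cumulative_axis_distribution(cloud, "typical"),
    gm.cumulative_axis_distribution(cloud, "ghost"))
print(round(ft["fit_b"].mu - ft["fit_a"].mu, 1))   # 204.2  (um, recovered shift)
print(ft["p"] < 0.001)                             # True
```

The percentage table reads: 33 % of typical cells were activated by the
hormone and 71 % of ghost cells did not respond at all; the chi-squared
p-value (0.0095) says the two response profiles differ.  The spatial block
recovers the simulated 200 µm caudal displacement of the ghost
subpopulation from the fitted Gaussian-CDF means and rejects a shared
distribution at p < 0.001.

The same stages are scriptable from the shell:

```bash
ghostmap --outdir out simulate stack
ghostmap --outdir out quantify --stack out/stack.tif
ghostmap --outdir out classify --cells out/cells.csv
```

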