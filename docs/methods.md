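# Methods

This note documents the models behind each `granulekit` stage, the defaults
and why they hold, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the underlying protocol left the design
open.

## Granule segmentation and measurement (`granulekit.imaging`)

**Model.** Granules are bright, roughly diffraction-limited objects on a
noisy background. Segmentation thresholds are anchored on a background model
(mean μ, sd σ): the minimum threshold is `μ + k₁·σ` (in-vivo granules,
k₁ = 1), `2·μ` (heat-shock series, where granule growth makes the sd-based
rule unstable), or `μ + k₂·σ` with k₁ = 2 for in-vitro condensation
reactions; the maximum threshold `μ + k₂·σ` (k₂ = 6 in vivo, 4 in vitro)
*clips* bright pixels but never removes them — excluding saturated granule
cores would fragment objects. Objects smaller than 2 px (in vivo) or 4 px
(in vitro) are noise and removed with a strict `< min_size` rule, so a
2-px object survives a 2-px filter.

**Background without an ROI.** The background estimate uses iterative
one-sided 4σ clipping: pixels more than 4 sd above the running mean are
excluded until the estimate stabilises. On an object-free Gaussian image the
clip removes ~3·10⁻⁵ of pixels and biases the mean by <0.1% of σ and the sd
by <0.3%, so spot-free images are estimated essentially unbiased; a
first-pass Otsu mask (the obvious alternative) splits a pure-noise histogram
in half and underestimates the mean by roughly one σ. Dense-foreground
images should supply an explicit ROI.

**Watershed.** Connected components use 8-connectivity. Touching granules
are split by a watershed on the euclidean distance transform, seeded from
its local maxima with a minimum seed separation of 3 px; connected peak
plateaus collapse to a single seed, labelled in raster order so marker ids
and tie-breaks are deterministic. A bare 3×3-neighbourhood peak rule
over-splits single spots on noisy distance transforms — the 3-px separation
is safe for objects kept apart by ≥ 4 spot-sigmas.

**Measurement.** Raw integrated intensity is the pixel sum over the object
mask per channel; the corrected intensity subtracts `correction × area`,
where the correction is the nuclear background mean when supplied (in-embryo
series) and the channel background mean otherwise. Negative corrected
intensities are unphysical and clip to 0 with a warning. `Log(I)` is log₁₀
of the corrected intensity; the radius is `sqrt(area·px²/π)` µm, an upper
bound for sub-resolution objects. Z-planes are processed independently and
aggregated afterwards.

## Phase classification (`granulekit.phase`)

Log(I) histograms use bins of exactly 0.2 units anchored at 0 (every edge an
integer multiple of 0.2), so histograms from different runs share a grid.
Radius histograms use 0.06 µm bins and also report the fraction of objects
below 0.4 µm, the nominal condensate size bound.

**Intersection threshold.** Given reference histograms from an all-aggregate
reaction and an all-condensate reaction, the "minimum at the intersection"
is operationalized deterministically: among the bins strictly between the
two modes where the sign of `h_cond − h_agg` changes, pick the one with the
smallest pointwise minimum of the two histograms; ties break to the lower
bin; non-overlapping supports return the support midpoint with a warning.
This reading is exhaustive-scan testable and reproduces the analytic density
crossing of two equal-sd log-normal families to within one bin.

**Boundary convention.** An object with Log(I) exactly equal to the
threshold (default 4.6) is a *condensate*. The alternative convention
(boundary → aggregate) is detected: when boundary-sitting objects move the
condensate percentage by more than 0.5 points a warning is raised. A
reaction's overall state is `soluble` with no objects, otherwise the class
holding the larger total integrated intensity (ties → aggregate, the
larger-object class).

**Partition arithmetic.** With molecule fraction `f` in granules of volume
fraction `v`, granule concentration ∝ `f/v` and cytoplasm concentration ∝
`(1−f)/(1−v)`; the default enrichment is their ratio
`(f/v)·((1−v)/(1−f))`. The plain `f/v` form is exposed as an option; with
the measured inputs (f = 21%, 34%; v = 5.9%) the ratio form averages to 6.2
(~6-fold), the plain form to 4.7.

## FRAP kinetics (`granulekit.frap`)

Normalization is `nI = (I − I_bkg)/(I_i − I_bkgi)` with the pre-bleach
values `I_i`, `I_bkgi` averaged over **all** pre-bleach frames (the protocol
does not say one frame or an average; averaging is lower-variance and is the
documented choice). Fitting uses the differenced series
`nI(t) − nI(0⁺) = A_rec·(1 − e^(−kt))`, t from the bleach, so the bleach
floor is removed and the model needs no intercept; `A_rec` is the mobile
fraction above the floor. Bounds: `A_rec ∈ [0, 1.5]` (recovery cannot much
exceed pre-bleach), `k ≥ 0`. Initial guesses are `A_rec = last value`,
`k = ln2 / time-to-half-recovery`, with 5 multi-start rate scalings
(×0.04…×25); non-convergence is reported with `converged = False`, never
silently replaced. `model="auto"` switches to the through-origin linear fit
`nI = kt` when the fitted exponential gives `k·t_max < 0.2` — over such a
window the exponential is indistinguishable from its tangent and `k` and
`A_rec` are not separately identifiable (only their product, the initial
rate). A flat post-bleach series returns `A_rec = 0` with `k` missing.

Photobleach correction fits a mono-exponential rate λ to a cytoplasm
reference normalized to its first frame and multiplies the series by
`e^{+λt}`; a brightening reference clamps λ to 0 with a warning. Because
pre-bleach frames also bleach, correction should precede normalization when
λ is appreciable. The ex-vivo persistence ratio is
`I_A·e^{+λ·Δt} / I_B`; it is a *minimal* estimate of granule retention since
granules drifting out of the field deplete `I_A` only.

## iCLIP transcript sets and metagene (`granulekit.iclip`)

A gene is **bound** when its read count reaches the background threshold
(default 60, set by the control library) in *both* pull-down replicates;
"lower than 60 removed" is strict, so counts of exactly 60 are included. A
quantile mode over non-zero control counts (numpy linear interpolation) is
provided for sensitivity analysis. Ranks are per-replicate descending
competition ranks (ties share the smaller rank; the next rank skips). The
anchored subset keeps bound genes ranking at or above a named anchor in
*either* replicate — at-or-above, since under any other reading the anchor
would not belong to the set built around its own cluster.

Metagene profiles follow the scale-regions convention: 800 unscaled 1-nt
upstream bins, the gene body linearly rescaled to 2000 bins
(`bin = ⌊d·2000/L⌋`), 1500 unscaled downstream bins; minus-strand genes are
fully mirrored into transcript orientation before binning. Each toeprint
counts once at its strand-aware 5′ end (the conventional cross-link
position), only toward genes on its own strand, weighted to counts per
million library toeprints. Genes with body < 200 nt or all-zero coverage are
skipped and logged; the profile is the mean over surviving genes, so total
profile mass × gene count equals the CPM mass landing in the modelled
windows (conservation, no double counting). All coordinates are 0-based,
half-open.

RPKM is `10⁹·count/(length·library)`; Spearman correlation uses
average-rank tie handling (cross-checked in the tests against a brute-force
rank-then-Pearson computation); ribosome occupancy is the footprint/mRNA
RPKM ratio with a default low-occupancy flag at 0.1.

## Synthetic data (`granulekit.synthetic`)

**Scenes.** Spots are isotropic 2-D Gaussians truncated at 4σ — the
diffraction-limited appearance of sub-resolution granules with a finite
footprint. A channel is camera noise `N(μ_bg, σ_bg)` + a uniform diffuse
cytoplasm level + spots. The realized partition fraction *f* is defined
mask-based: all non-camera signal inside the union 4σ footprint over the
total — this is the quantity a mask measurement can recover, and it counts
the cytoplasmic molecules sitting under the footprint (a ~4-point effect at
v ≈ 6%). `scene_for_partition` inverts this definition to hit a target
(f, v): the granule count follows from v and the footprint area, the
cytoplasm level from `c = S(1−f)/(N(f−v))`. Default scene: 256² px at
0.1 µm/px, background (100, 5) AU, spot σ = 1.5 px, amplitude 400 AU
(SNR 80), targets f = 0.30 (the measured per-transcript fractions are
21–34%) and v = 0.059.

**FRAP traces.** Pre-bleach frames at normalized level 1, post-bleach
`depth + A_rec(1 − e^{−k(t−t_b)})`, the whole raw trace scaled by
`e^{−λt}`, Gaussian noise added on the normalized scale, then mapped to AU
(granule 1000, background 100). Defaults `A_rec = 0.8`, `k = 0.02 s⁻¹`,
frames every 3 s for 300 s — the acquisition cadence of the in-vitro FRAP
protocol, with `k·t_max ≈ 5.7` well inside the identifiable regime.

**Count tables.** Control and unbound-gene counts follow a negative
binomial (r = 2, p = 0.2; mean 8), bound genes a shifted log-normal
(`40 + lognormal(5, 0.8)`, median ≈ 190) in both replicates — the
distributional forms are stand-ins (the real background law is not
published), chosen only to reproduce the background-vs-signal separation
the thresholding rule assumes. Defaults: 1000 genes, 60 bound.

**Toeprints.** 20-nt intervals whose 5′ end is uniform within a region
drawn by the (5′UTR, CDS, 3′UTR) weights; weights on regions a gene lacks
redistribute proportionally with a log message. Gene models are
single-isoform, non-overlapping, strand-alternating.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no PSF convolution of extended objects (spots are
ideal Gaussians), no 3-D stacks, no autofluorescence gradients or uneven
illumination, iid pixel noise rather than correlated camera noise, no
reaction–diffusion structure in FRAP recovery (strictly first-order), no
sequencing-read level effects (PCR duplicates, mappability, length bias) in
count tables, and single-isoform gene models. Recovery guarantees
(segmentation recall/precision ≥ 0.95, partition within 2 points, FRAP bias
bounds) are statements about these idealized conditions.

## Problem sizes and determinism

Tests and the demo pipeline use 256² scenes with ~34 granules, 100-frame
traces, 200-trace recovery ensembles, 1000-gene count tables and 10–30 gene
metagene sets — small enough to run the whole suite in seconds while leaving
every estimator comfortably inside its asymptotic regime. Every generator
takes an explicit seed (numpy `default_rng`); identical config + seed gives
byte-identical outputs, which the pipeline tests assert.

## Known limitations

* The heat-shock threshold rule (`2μ` min, `μ + 6σ` max) is inconsistent
  when `μ > 6σ`; `ThresholdRule.bounds` raises rather than guessing.
* The intersection threshold assumes unimodal-ish references with ordered
  modes; strongly multimodal references should be inspected before trusting
  the crossing.
* `condition_state` summarizes by total intensity, not object morphology;
  irregularity itself is not measured.
* Accession-scale reconstructions (real iCLIP replicates, the published
  source-data correlations) require the deposited sequencing data and are
  out of scope for the bundled tests, which validate the identical machinery
  on synthetic tables instead.
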