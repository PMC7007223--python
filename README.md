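# granulekit

Quantification toolkit for RNA-granule condensates.

Membraneless RNA/protein condensates — such as the P granules of the
*C. elegans* germline — recruit specific mRNAs by co-condensation with
intrinsically disordered proteins. Quantifying that recruitment spans four
very different kinds of measurement, and `granulekit` implements all of them
as one tested, reusable pipeline:

1. **Granule imaging** — background-anchored intensity thresholding
   (`min = μ_bg + k₁·σ_bg` or `k₀·μ_bg`, `max = μ_bg + k₂·σ_bg`), watershed
   separation of touching granules, a minimum-pixel noise filter, and
   per-object, per-channel background-corrected integrated intensities,
   channel ratios and mask-based percent enrichment.
2. **Phase classification** — in-vitro reactions produce either small uniform
   RNA-dependent *condensates* or large irregular RNA-independent
   *aggregates*. Objects are histogrammed on Log(I) = log₁₀(total intensity)
   in 0.2-unit bins; the intersection of two reference histograms sets the
   class boundary (default Log(I) ≤ 4.6 → condensate), and the partition
   arithmetic converts a molecule fraction *f* and granule volume fraction
   *v* into a granule/cytoplasm concentration enrichment
   `(f/v)·((1−v)/(1−f))`.
3. **FRAP kinetics** — traces are normalized as
   `nI = (I − I_bkg)/(I_i − I_bkgi)`, corrected for acquisition
   photobleaching with a cytoplasm reference, and fitted to the first-order
   recovery `nI = A_rec·(1 − e^(−kt))` (or `nI = kt` in the linear regime),
   plus bleach-corrected persistence ratios `I_A/I_B` for ex-vivo extrusion.
4. **iCLIP transcript sets** — per-gene read counts from two pull-down
   replicates against a control library yield bound-transcript sets
   (count ≥ 60 in both replicates), rank-anchored subsets (competition
   ranks, at-or-above the anchor in either replicate), RPKM, Spearman
   correlation, ribosome occupancy, and strand-aware scale-regions metagene
   profiles (800 nt upstream / 2000 body bins / 1500 nt downstream, 1-nt
   bins, CPM-normalized).

A first-class `synthetic` module generates every input class with exact
ground truth — Gaussian-spot scenes with known partition and volume
fractions, first-order FRAP traces, background-plus-signal count tables, and
weighted toeprint intervals — so every downstream stage is testable without
any data download.

## Worked example

The two best-quantified granule transcripts have molecule fractions of 21%
and 34% inside granules that occupy 5.9% of the cell volume:

```bash
$ granule-quant enrich --f 0.21 --f 0.34 --v 0.059
{"fold": [4.23964814417507, 8.216230097586033], "mean_fold": 6.227939120880551}
```

Each fold is the granule-to-cytoplasm concentration ratio
`(f/v)·((1−v)/(1−f))`: a transcript with only a fifth of its molecules in
granules is still ~4–8× more concentrated there than in the cytoplasm,
because the granules are so small — on average a ~6-fold enrichment.

The full demo pipeline runs every stage on synthetic inputs:

```bash
$ granule-quant run --out demo_out --seed 1
```

prints (abbreviated):

```json
{
  "true_partition_fraction": 0.2997294210494936,
  "true_volume_fraction": 0.0583953857421875,
  "mean_concentration_enrichment": 6.227939120880551,
  "frap_fit": {"model": "exponential", "a_rec": 0.7824, "k": 0.01943, "converged": true},
  "n_bound_transcripts": 60,
  "metagene_genes": 20
}
```

The scene was generated with a true partition fraction of 0.30 and volume
fraction 0.059; the FRAP trace with `A_rec = 0.8`, `k = 0.02 s⁻¹` and noise
sd 0.02; the count table with 60 signal genes — so each printed number can be
read directly against its ground truth. Per-stage subcommands
(`simulate`, `segment`, `classify`, `enrich`, `frap-fit`, `persistence`,
`iclip-rank`, `metagene`, `print-config`) expose the same operations on your
own TIFF/CSV/TSV/BED files.

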