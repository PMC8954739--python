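# msidissect

Digital dissection of mass-spectrometry-imaging (MSI) data: segment tissue
sections into histological compartments, quantify drug distribution per
compartment, and validate imaging abundances against extraction-based
LC-MS/MS concentrations.

## The problem

In oral-absorption pharmacokinetic studies, LC-MS/MS quantification of
tissue extracts gives accurate total drug concentrations but destroys all
spatial information: drug still sitting in the intestinal lumen (bowel
content) is indistinguishable from drug absorbed into the mucosa and deeper
tissue layers. MSI (DESI at ~75 µm, MALDI at ~10 µm pixel size) preserves
that spatial dimension. `msidissect` turns MSI pixel spectra into
compartment-level pharmacokinetic read-outs:

1. **Tissue masking** — separate section from slide background by TIC
   (total ion current) thresholding.
2. **Normalization** — per-spectrum TIC normalization (applied to MALDI
   data; DESI is analyzed raw), compensating spectrum-to-spectrum
   variation.
3. **Digital dissection** — bisecting k-means clustering of pixel spectra
   binned over the structural-lipid range *m/z* 750–850, with correlation
   distance *d*(u, v) = 1 − Pearson r(u, v) as metric. The divisive scheme
   repeatedly 2-means-splits the cluster with the largest within-cluster
   sum of distances until *k* clusters exist (*k* = 3: lumen, mucosa, and
   an unresolved outer mixture of crypts/submucosa/muscularis). Clusters
   are mapped to compartments by lipid marker ions or a manual mapping.
4. **Quantification** — per-compartment sums/means/SDs of each drug's ion
   image; the **absorbed fraction** = (mucosa + outer tissue) / (all
   compartments incl. lumen); **LOD/LLOQ** = 3× and 10× the SD of the
   drug-window abundance across vehicle (undosed) tissue pixels; Bateman
   abundance–time profiles per compartment.
5. **Cross-platform correlation** — ordinary least squares of MSI section
   means against LC-MS/MS concentrations (R², 95 % mean-response
   confidence bands, intercept/sensitivity diagnostics), and MALDI-vs-DESI
   comparison.

Because real MSI cohorts are large and annotation-bound, the package ships
a ground-truthed **synthetic phantom generator**: concentric
intestine-like sections (lumen disc, mucosa ring, outer ring) with
compartment-specific lipid peaks, drug ions following one-compartment
Bateman kinetics (lumen A₀·e^(−kₐt); tissue A₀·kₐ/(kₐ−kₑ)·(e^(−kₑt) −
e^(−kₐt))), seeded pixel noise, and matched concentration tables — so every
stage is testable against known truth.

Theoretical adduct masses are computed from molecular formulas with
monoisotopic atomic masses; the four benchmark compounds give
[M+H]⁺ *m/z* 472.32 (terfenadine), 256.17 (diphenhydramine), 272.20
(dextromethorphan) and 423.17 (losartan).

## Worked example

The `demo` subcommand generates a full synthetic study (4 timepoints ×
3 animals × 3 specimens plus vehicle controls, 48×48-pixel MALDI sections
at default noise) and runs the whole pipeline:

```
$ msidissect demo --seed 1

Absorbed-fraction summary (per drug):
modality        drug_name     mean       sd      min      max  n  n_undefined
   MALDI dextromethorphan 0.859341 0.143008 0.557486 0.986212 36            0
   MALDI  diphenhydramine 0.905155 0.110160 0.653299 0.992783 36            0
   MALDI         losartan 0.722482 0.205188 0.359044 0.958917 36            0
   MALDI      terfenadine 0.825069 0.174045 0.481633 0.991384 36            0

MSI vs LC-MS/MS regression (per drug):
modality        drug_name    slope  intercept  r_squared  n
   MALDI      terfenadine 0.000148   0.000587   0.935415 36
   MALDI         losartan 0.000149   0.000475   0.970428 36
   MALDI dextromethorphan 0.000147   0.000470   0.980280 36
   MALDI  diphenhydramine 0.000148   0.000423   0.973336 36

Detection limits from vehicle sections:
modality        drug_name  background_sd      lod     lloq  n_background_pixels
   MALDI      terfenadine       0.000122 0.000366 0.001222                 3616
   ...
```

Reading the output: each drug's absorbed fraction is the share of its
sectional signal in tissue rather than lumen, summarized as mean ± SD and
range over the 36 dosed specimens (fractions rise with time as the lumen
empties, and vary with the simulated bowel-content differences). The
regressions show that TIC-normalized MSI section means track the "true"
extraction-based concentrations linearly (R² ≈ 0.94–0.98 at the default
noise level); slopes are on the normalized-abundance-per-concentration
scale. Detection limits derive from the three vehicle sections' background
in each drug's mass window.

The same stages are available as a library (`generate_cohort`,
`run_pipeline`, `segment_dataset`, `BisectingKMeans`, `absorbed_fraction`,
`detection_limits`, `ols_regression`, ...) and as file-based subcommands
`simulate`, `segment`, `quantify`, `correlate` and `run` operating on
imzML/CSV inputs.

`BisectingKMeans` follows the scikit-learn estimator API (`fit`,
`predict`, `labels_`, `cluster_centers_`, `get_params`) and composes with
sklearn model-selection tooling.

## Layout

```
src/msidissect/
  io.py            imzML read/write (pyimzml), concentration tables
  preprocess.py    TIC normalization, masks, ion images, feature matrices
  segmentation.py  correlation-distance bisecting k-means, compartments, ARI
  quantify.py      adduct masses, abundances, absorbed fraction, LOD/LLOQ
  correlate.py     OLS, confidence bands, cross-technique diagnostics
  phantom.py       ground-truthed synthetic phantom and cohort generator
  pipeline.py      end-to-end orchestration and result tables
  cli.py           command-line interface
docs/methods.md    model, parameters, numerical choices, limitations
```
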