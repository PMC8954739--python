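# Methods

This note documents the models, default parameters, numerical conventions
and known limitations of `msidissect`, in the spirit of a package methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and I/O

An `MSIDataset` is a sparse pixel grid of spectra. Pixels never acquired
are absent, not zero-filled: zero-filling would bias TIC statistics and the
background SD used for detection limits. imzML files are read and written
through pyimzml; both continuous (shared m/z axis) and processed (per-pixel
axes) binary modes are supported for reading, and writing picks continuous
mode automatically when all spectra share an axis. imzML uses 1-based
(x, y) pixel indices while the in-memory grid is 0-based row-major
(row, col); the conversion happens only at the I/O boundary, so off-by-one
risk is confined to one module. Both m/z and intensity arrays are stored as
64-bit floats, making the write→read round trip lossless (the suite asserts
bitwise identity). Since imzML carries no study metadata, a JSON sidecar
(`<name>.meta.json`) holds modality, pixel size and specimen fields.

## Preprocessing

**TIC normalization** divides a spectrum by its summed intensity,
compensating spectrum-to-spectrum variation in desorption/ionization
efficiency. It is applied to MALDI data and not to DESI data by default
(both switchable per run config). Zero-TIC spectra are left all-zero and
flagged rather than raising, since blank pixels are routine. Normalizing
twice is an error: the operation is not idempotent on the flag and silently
double-normalized data is a classic source of wrong abundances.

**Ion images** integrate a symmetric mass window around a target ion.
Default half-widths are resolution-matched: ±0.01 Da for DESI
(Orbitrap-class resolving power) and ±0.1 Da for MALDI (TOF-class). The
window is a closed interval; ppm widths are converted at the window center.

**Tissue masks** threshold the TIC image. Two rules are provided:

* `quantile` — keep pixels with TIC ≥ the q-quantile of recorded-pixel
  TICs (ties kept, zero-TIC pixels always excluded). Correct when the
  operator matches q to the slide's background fraction, but an order
  statistic can land inside a tissue TIC band and then drops whole
  low-TIC regions.
* `relative` (pipeline default) — keep pixels with TIC above 5 % of the
  robust tissue level (95th-percentile TIC). Blank-slide background TIC
  sits orders of magnitude below tissue TIC, so this cut needs no
  knowledge of the background fraction. The 5 % fraction is configurable;
  on real data with chemically noisy backgrounds a larger fraction or the
  quantile rule may be preferable.

**Feature matrices** bin each masked pixel's spectrum over m/z 750–850
(the structural-lipid range that outlines morphology) into equal-width,
left-closed right-open 0.1 Da bins. Binning is used instead of peak
picking deliberately: it is deterministic, resolution-agnostic, and exactly
conserves the in-range intensity per pixel (asserted in the suite).

## Segmentation

Pixel spectra are clustered by **bisecting k-means under correlation
distance** d(u, v) = 1 − Pearson r(u, v) ∈ [0, 2]. Correlation distance
compares spectral *shape* irrespective of scale, making the clustering
insensitive to per-pixel intensity variation. Conventions:

* Zero-variance vectors have undefined correlation; d = 1 by convention,
  with a warning.
* No exact centroid exists under correlation distance. The arithmetic mean
  of member rows is used as centroid with assignment by minimal
  correlation distance — the common practical compromise, documented as an
  approximation. Convergence when assignments stabilize, capped at 100
  Lloyd iterations.
* Each 2-split is the best of `n_restarts` (default 10) seeded
  initializations, each seeding the two centroids with two distinct member
  rows drawn at random. An emptied cluster is repaired by moving in the
  row farthest from the surviving centroid.
* The cluster chosen for splitting is the one with the largest
  within-cluster sum of distances (the most heterogeneous) — standard in
  the bisecting k-means literature; largest-cardinality is the usual
  alternative. Singleton clusters and clusters of constant rows are never
  split.
* Defaults: k = 3 (lumen / mucosa / outer tissue), seed mandatory in the
  run config for reproducibility. Off-tissue pixels are excluded before
  clustering.

On small inputs the suite checks the first 2-split against the exhaustive
enumeration of all 2^(n−1)−1 bipartitions of the same objective. Note that
on *unstructured* matrices (i.i.d. noise rows) alternating minimization
cannot always reach the enumerated optimum from any seeding; the oracle
check is therefore posed on matrices with group structure, which is what
tissue feature matrices look like and where restarts reliably attain the
optimum.

Clusters are mapped to histological compartments either manually or by
marker ions: each cluster takes the compartment whose marker window has the
highest cluster-mean z-score (standardized across clusters), larger
clusters choosing first on ties. The mapping must contain at least one
tissue compartment; k = 1 is rejected outright since lumen cannot be
separated from tissue.

Agreement between segmentations is measured by the adjusted Rand index
over the shared masked support (scikit-learn implementation), which is
invariant to label renaming.

## Quantification

**Adduct masses.** Monoisotopic atomic masses (IUPAC 2021 table, 6
decimals: C 12.000000, H 1.007825, N 14.003074, O 15.994915, S 31.972071,
Cl 34.968853, Br 78.918338, P 30.973762, F 18.998403) are summed per
formula; the adduct adds the cation mass less one electron ([M+H]⁺
+1.007276, [M+Na]⁺ +22.989218, [M+K]⁺ +38.963158). A drug definition may
override the theoretical m/z with an observed value within 0.02 Th
(losartan's DESI [M+K]⁺ is stored as the observed 461.129, ~0.004 Th above
theory).

**Absorbed fraction** = Σ(tissue compartment sums) / Σ(all compartment
sums including lumen), per specimen; 0/0 is flagged undefined rather than
coerced. Compartment *sums* (mean × area) are used rather than means so
that unequal compartment areas are respected; the mean-based variant is
available by aggregating the per-compartment means directly. Fractions are
computed on the per-modality normalization convention (TIC-normalized for
MALDI). Cohort summaries report mean, sample SD, min and max over
specimens.

**Detection limits.** LOD = 3×SD and LLOQ = 10×SD of the drug-window
abundance across vehicle tissue, so LLOQ/LOD = 10/3 exactly. The default
pools per-pixel abundances across all vehicle sections (maximizing n); a
per-section-means pooling is provided as the config-switchable alternative
since "across the vehicle tissues" admits both readings.

**Sample SDs use the n−1 denominator throughout** — cohorts here are
small (three animals per timepoint).

**Time profiles** aggregate per-specimen compartment means per timepoint
(mean, sample SD, n), with vehicle specimens reported at t = 0 as the
background level.

## Correlation

Simple OLS with free intercept (statsmodels), one point per specimen
(technical LC-MS/MS replicates averaged first). The MSI side of each point
is the mean abundance over *all* masked pixels, lumen included — the
whole-section mean — with the tissue-only mean available via the
compartment tables. R² is flagged undefined when y is constant; constant x
is an error. Confidence bands are **mean-response** bands,
ŷ ± t₍0.975,n−2₎·s·√(1/n + (x−x̄)²/Sxx), not prediction bands. Diagnostics
follow the standard cross-technique reading: positive x-intercept shift →
poorer detection limits of the x-axis technique; positive y-intercept with
nonzero LOD → chemical background on the y-axis technique; slope →
relative sensitivity. Regressions are never forced through the origin —
the intercept is itself diagnostic. Points below LOD or between LOD and
LLOQ are counted, not removed; no outlier rejection is performed.

## Phantom generator

The phantom captures only the structure the statistics need, not
histological realism:

* **Geometry**: concentric annuli on a 64×64 grid (default) — lumen disc
  (radius 9 px), mucosa ring (to 18 px), outer ring (to 26 px), empty
  background outside — with an optional sinusoidal villi perturbation of
  the lumen boundary (off by default). Real villous morphology is far more
  complex; the phantom preserves the compartment topology only.
* **Lipid chemistry**: each compartment has a fixed peak profile in
  m/z 750–850 totalling 100 intensity units, so all compartments carry the
  same lipid load and TIC normalization rescales them alike. The two
  tissue compartments share the PC(34:2)/PC(34:1) [M+K]⁺ channels
  (796.53/798.54) in different ratios while the luminal bowel-content
  profile is disjoint — tissues resemble each other more than either
  resembles lumen, as in real sections, which also fixes the k = 2
  merge order (lumen splits off first).
* **Drug kinetics**: lumen abundance A₀·e^(−kₐt); tissue follows the
  Bateman function A₀·kₐ/(kₐ−kₑ)·(e^(−kₑt) − e^(−kₐt)) (limit
  A₀·kₐ·t·e^(−kₐt) at kₐ = kₑ), scaled by per-compartment partition
  weights, default lumen 6.0 ≫ mucosa 0.6 > outer 0.25 (drug-rich bowel
  content, passively absorbed drug declining with depth). Default
  A₀ = 2 intensity units per drug keeps the summed drug signal a small
  share (~5 %) of the lipid TIC, as for trace-level drug ions in real
  spectra; at much larger amplitudes the drugs' own TIC contribution
  visibly distorts TIC-normalized fractions. Per-drug rates (kₐ, kₑ in
  1/h): terfenadine (1.2, 0.25), losartan (0.9, 0.35), dextromethorphan
  (1.5, 0.40), diphenhydramine (1.8, 0.30) — plausible oral-absorption
  values spanning early t_max ≈ 1–2 h. An optional enterohepatic term adds
  a secondary luminal bump after a configurable lag (off by default).
* **Noise** (all seeded; all vanish at σ = 0): per-channel multiplicative
  log-normal (σ 0.15), per-pixel log-normal TIC factor (σ 0.10), and
  additive half-normal baseline on every channel (σ 0.02) — the only
  signal on background pixels and in vehicle drug windows, hence what
  detection limits are estimated from.
* **m/z axis**: one shared sparse axis — the union of lipid, drug and a
  few signal-free channels (~17 values) — written as continuous-mode
  imzML. A dense regularly-spaced axis would multiply memory by four
  orders of magnitude without adding information to any statistic
  computed here.
* **Ground truth** per section: the label grid, noiseless per-compartment
  drug totals, the exact absorbed fraction implied by the partition
  weights and Bateman values, and noiseless section totals/means.
  `calibrate_lumen_partition` solves the lumen weight so the true fraction
  at a chosen timepoint equals a target exactly.
* **Cohorts**: timepoints 1/2/4/6 h × 3 animals × 3 specimens by default,
  plus one vehicle animal (3 specimens, drug amplitude 0). Per-specimen
  biology: log-normal A₀ jitter (σ 0.5, reproducing the ~5-fold
  inter-animal spread seen in such studies) and ±1 px geometry jitter.
  Concentration table rows are noiseless section totals × a calibration
  factor (0.05) × log-normal measurement noise (σ 0.10, typical LC-MS/MS
  precision). When both modalities are requested, the same specimen truth
  underlies both renderings with independent noise.

What passing on phantoms does **not** show: robustness to real villous
morphology, isotope envelopes, matrix/solvent clusters, compartment-
dependent ion suppression, instrument drift, or mis-registration between
the MSI section and the extracted specimen half. The phantom's compartment
spectra are far cleaner than real tissue spectra, so segmentation accuracy
on phantoms is an upper bound.

## Determinism

Every stochastic component (phantom noise, cohort jitter, k-means
restarts) draws from a `numpy.random.Generator` seeded from an explicit
integer; pipeline re-runs with the same config produce byte-identical
result tables, and a provenance record (config hash, seed, version) is
written with every run. One caveat: the imzML standard embeds a fresh UUID
in each file, so two writes of identical data differ in that field (and in
the ibd's leading UUID bytes) while all coordinates and arrays are
identical — dataset-level determinism is what the suite asserts.

## Problem sizes in the suite

Tests run phantoms at 32–64 px grids and cohorts of up to 39 sections;
these sizes exercise every code path with comfortable statistical margins
(masked sections of ~600–2100 pixels, feature matrices of ~1000 bins)
while keeping the whole suite around a minute.
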