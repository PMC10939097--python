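# Methods

This note documents the models, numerical choices and open design decisions
behind `fibermsi`, and what the synthetic benchmarks do and do not
demonstrate about real MSI data.

## Data model and coordinates

An MSI acquisition is a set of mass spectra indexed by pixel. Internally,
coordinates are 0-based `(col, row)` with origin top-left and row-major
rasterization — the convention of the mask/image formats the package
exchanges labels with; imzML's 1-based coordinates are shifted on read and
restored on write. Sparse acquisitions are carried as absent pixels: they
render as NaN in ion images, are skipped by the NaN-aware median filter,
and never enter statistics. Both continuous and processed imzML dialects
are accepted; after peak picking everything is per-pixel centroid lists.
m/z is stored as float64 and intensity as float32 in written imzML, which
bounds round-trip error at float32 resolution (~1e-7 relative).

## Preprocessing

**Baseline removal** uses grey morphological opening (rolling minimum then
rolling maximum, width `baseline_window` bins, default 51). The window must
exceed the widest genuine peak; an opening then passes under peaks but
follows smooth baseline drift. Vendor packages do not disclose their
baseline algorithms, so this is the package's own choice of a standard,
parameter-light method. Centroid input is rejected with a pointer to skip
the step.

**RMS normalization** divides each pixel's intensities by
`sqrt(mean(intensity^2))`, making pixels comparable when ionization
efficiency drifts across a section. In the full chain the picked peak
intensities are divided by the RMS factor of the pixel's baseline-corrected
profile spectrum. Order (pick → normalize) is a design choice; the
normalization tag is recorded on the peak table. Note the compositional
("closure") consequence: scaling by a per-spectrum factor makes intensities
relative, so strong markers in one class depress that class's other
features. With realistic peak counts (~10^3) the effect is small; at
desk-scale feature counts (tens) it is visible as systematic offsets in
non-marker features between classes — see *Limitations*.

**Peak picking** estimates noise as `1.4826 * MAD` of the spectrum and
detects local maxima whose height above the residual background level (the
spectrum median) is at least `snr_min` (default 3) noise units. Measuring
signal above the median rather than above zero keeps positive noise floors
from producing spurious detections: on pure-noise spectra around a positive
floor the false-detection rate at S/N 5 is ~0. If the MAD collapses to zero
(sparse spectra), the smallest positive intensity substitutes with a
warning.

**Alignment** pools all pixels' peaks, sorts by m/z, and groups greedily so
each cluster's relative diameter stays within `align_tol_ppm` (default
10 ppm, mirroring the annotation tolerance). This diameter-bounded grouping
coincides with single-linkage gap clustering for well-separated features
and guarantees the diameter invariant that plain single linkage does not.
The consensus m/z is the intensity-weighted mean of members; per-pixel apex
intensities fill the matrix (0 = not detected); features present in fewer
than `min_pixel_fraction` (default 1%) of pixels are dropped.

**Denoising** of ion images is a NaN-aware k×k median filter (default 3×3):
medians preserve step edges between fiber regions while removing
single-pixel impulses, and excluding NaNs keeps missing pixels from
bleeding into neighbours.

## Segmentation

Pixel feature vectors (optionally per-feature median-denoised) are z-scored
per feature — otherwise high-abundance lipids dominate the Euclidean
metric — and clustered with K-means (k-means++ initialization, 10 restarts,
best inertia, fixed seed). "Semi-supervised" segmentation is interpreted
as unsupervised clustering followed by operator curation: a Ward dendrogram
over class centroids guides `merge_classes`, which relabels pixels and
recombines centroids as pixel-count-weighted means (conserving the total
intensity mass), e.g. to fold artifact classes into neighbours after
comparison with histology. `k` defaults to 9 — a typical class count for a
mixed fast/slow muscle section — and is a config parameter; the class
count in real sections is an operator decision made against the dendrogram
and the immunofluorescence overlay.

## Co-registration and composition scoring

Adjacent sections (one stained, one measured) differ by rotation,
translation and a small scale change, so the default registration model is
a least-squares similarity transform fitted to operator-picked landmark
pairs (affine behind a flag for sheared sections). Label masks are
resampled by nearest-neighbor lookup of each MSI pixel center through the
inverse transform — labels are categorical; interpolation would invent
classes — with out-of-bounds pixels set to background. The MSI-class ×
fiber-type composition table counts co-occupied pixels, normalizes rows,
and converts fractions to an ordinal 0-3 "+" score by counting crossed
band thresholds (default 0.05/0.25/0.50, chosen to reproduce a four-level
"+" scale; the bands are configurable because published "+" tables rarely
state numeric cutoffs).

## Statistics

- **t test**: pooled-variance Student's t (the form quoted in figure
  legends), Welch behind a flag; two-sided p; BH-adjusted p reported next
  to raw p, since the conventional filter is raw p < 0.05. Degenerate
  zero-variance/equal-mean features get t = 0, p = 1. log2 fold change is
  reported from group means when both are positive. The LC-MS screen
  log2-transforms intensities first (the standard metabolomics convention;
  multiplicative noise becomes additive), with `log_transform=False` for
  raw testing.
- **AUC**: midrank Mann-Whitney, exact for ties; "discriminative" is
  symmetric (≥ 0.7 or ≤ 0.3) because direction depends only on which group
  is called positive.
- **ICC(C,k)**: from the two-way ANOVA without interaction on a complete
  target × rater matrix, `(MS_T − MS_E)/MS_T`. The layout is the caller's
  choice (the operation takes an explicit matrix per feature), because
  which experimental axis plays "rater" varies between designs. Bands:
  ≥ 0.75 excellent, 0.60-0.75 good, 0.40-0.60 fair, < 0.40 poor. MS_T = 0
  returns NaN with a warning. Replicate analyses run on log2 intensities
  without RMS normalization: variance components are multiplicative in MSI
  data (hence additive on the log scale), and per-spectrum normalization
  would inject shared noise into every feature of a pixel-replicate.
- **PCA**: column-centered SVD; component signs fixed so the
  largest-|loading| entry is positive, making outputs
  implementation-independent.
- **PLS-DA / VIP**: PLS2 (NIPALS) on autoscaled X against a 0/1 group
  indicator; VIP from unit-norm X-weights and per-component explained
  response variance, so Σ VIP² = p exactly — asserted to 1e-6 in tests.
  Constant features are dropped with a warning. The biomarker gate is
  VIP ≥ 1 and |first-component loading| ≥ 0.05, both inclusive.
- **QEA**: globaltest Q for a binomial outcome — the quadratic form of the
  group-indicator residuals in the kernel of the autoscaled set submatrix,
  scaled by `m μ(1−μ)`. Significance is by label permutation (≥ 100
  permutations, +1-corrected so p > 0, one shared permutation stream per
  call so sets are comparable), Bonferroni-corrected across tested sets.
  Permutation rather than asymptotic p-values are the reference because
  they are exact at any n. Set members absent from the matrix are dropped
  (the survivor count is reported); a fully absent set is an error naming
  the missing ids.

## Annotation

Features match (metabolite, adduct) candidates whose theoretical m/z lies
within `tol_ppm` (default 10). Default adducts: [M+H]+, [M+Na]+, [M+K]+ in
positive mode, [M−H]− in negative; reference rows may instead carry
precomputed adduct m/z. All candidates within tolerance are retained and
ranked by |ppm error| — resolving identities needs orthogonal evidence
(MS/MS), which is out of scope. The search window is computed relative to
the feature and widened by 1%, while the binding check is relative to the
theoretical mass, so acceptance is symmetric at the window edge.

## Synthetic data: what it emulates, and what it does not

The "muscle" phantom lays down elongated vertical bands (slow type 1,
fast 2a, fast glycolytic 2b) emulating longitudinal fiber sections, and
embeds a rare oxidative 2b subclass as scattered 2-pixel-wide patches
covering a configurable 2-10% (default 5%) of the parent region — the
discovery scenario for a minority metabolic class. Patches are 2 pixels
wide so the 3×3 median denoising cannot erase them, which a 1-pixel line
would not survive.

Each class carries `n_marker_per_class` (default 5) fingerprint features at
`2^effect` (default 4×) abundance: phospholipid-like for slow fibers,
anserine-like dipeptides for fast 2a, glycolytic intermediates for fast 2b,
acylcarnitine-like markers for the oxidative subclass. Intensities follow a
log-normal model: log2 intensity = log2(base) + effect·[in class] +
σ_T·T(pixel) + σ_E·E(pixel, replicate), with base abundances spanning
2^6-2^9. Pixel noise is σ = effect/snr (snr default 4); passing explicit
`variance_components` replaces it with the exact two-way structure so
ICC(C,k) has the closed form k·σ²_T/(k·σ²_T+σ²_E). Spectra are rendered as
profile-mode Gaussian peaks (σ = 0.01 Da, 9 samples per peak with the
center sample on the apex) on a sparse shared axis, over a smooth
exponentially decaying additive baseline, and round-trip through imzML.

Problem sizes in tests and the acceptance script — 48×48 phantoms,
60 features, 200-feature/4-replicate ICC runs, 1000-feature null tables,
499-999 permutations — are chosen as the smallest sizes at which the
statistical expectations concentrate well inside their tolerance bands.

What passing these benchmarks does **not** show: real spectra have
isotope envelopes, matrix clusters, mass-calibration drift and
peak-shape/resolution structure the generator omits; real fiber geometry
is not rectilinear; real replicate variance is not exactly two-way
Gaussian; and real annotation is many-to-many at 10 ppm. The benchmarks
verify the algorithms, not instrument physics.

## Limitations

- RMS normalization is compositional: with few features and strong
  markers, non-marker features acquire systematic between-class offsets
  (visible in the pipeline's enrichment table as inflated decoy-set
  significance at desk scale). With realistic feature counts the offset
  shrinks roughly with the markers' share of total spectral energy.
- Pixels are spatially correlated; pixel-level p-values overstate
  evidence. The pipeline's enrichment stage therefore tests a fixed-size
  seeded subsample of pixels per class rather than all pixels; proper
  replicate-level inference needs multiple sections.
- The Q statistic's permutation null conditions on the observed labels;
  per-dataset type-I rates fluctuate (the calibration tests average over
  independent datasets).
- K-means assumes roughly isotropic classes in z-scored space; strongly
  unbalanced or non-convex metabolic regions may need larger k plus
  dendrogram-guided merging.
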