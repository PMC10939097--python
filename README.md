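# fibermsi

Spatial metabolomics of skeletal-muscle fiber types from MALDI mass
spectrometry imaging (MSI).

Skeletal muscle is a mosaic of metabolically distinct myofibers — slow
oxidative type 1 fibers rich in mitochondria, and fast type 2a/2x/2b fibers
spanning a glycolytic-to-oxidative range. MSI acquires a full mass spectrum
at every pixel of a tissue section, so fiber-type metabolism can be mapped
without dissection: fast fibers carry fingerprints like anserine, slow and
oxidative fibers carry acylcarnitines and other fatty-acid-oxidation
intermediates. `fibermsi` packages the full analysis chain needed to turn
imzML datacubes into such maps, for analysts who want a scripted,
reproducible alternative to point-and-click MSI software:

- **I/O and containers** — imzML/ibd read & write (via pyimzML), peak
  tables, ion images, ROI label maps, metabolite reference tables, GMT set
  libraries (`fibermsi.core`).
- **Preprocessing** — morphological-opening baseline removal, per-pixel
  root-mean-square (RMS) normalization, MAD-based S/N peak picking,
  ppm-window peak alignment across pixels, NaN-aware edge-preserving median
  filtering of ion images (`fibermsi.preprocess`).
- **Segmentation** — K-means over standardized pixel spectra with a Ward
  dendrogram on class centroids and operator-guided class merging
  (`fibermsi.segmentation`).
- **Co-registration** — landmark similarity/affine transforms mapping
  immunofluorescence fiber-type masks onto the MSI grid, plus the
  class-vs-fiber-type composition table with ordinal "+" scores
  (`fibermsi.coregistration`).
- **Statistics** — Student's t with BH correction, midrank ROC AUC
  screening (discriminative at AUC ≥ 0.7 or ≤ 0.3), ICC(C,k)
  reproducibility with the 0.75/0.60/0.40 bands, PCA, and PLS-DA with VIP
  scores and the VIP ≥ 1 & |loading| ≥ 0.05 biomarker gate
  (`fibermsi.stats`).
- **Annotation & enrichment** — precise-mass adduct matching at 10 ppm
  against HMDB-style tables (`fibermsi.annotation`), and quantitative
  metabolite-set enrichment via the globaltest Q statistic with permutation
  p-values and Bonferroni correction (`fibermsi.enrichment`).
- **Cross-platform validation** — LC-MS feature-table ingestion, the same
  differential screen, identity-level Venn overlap
  (`fibermsi.crossplatform`).
- **Ground truth** — a synthetic-data generator that plants fiber-type
  geometry (including a rare oxidative 2b subclass), fingerprint markers,
  noise and replicate variance components, so every stage is verifiable
  (`fibermsi.synthetic`).

## The statistics at the core

For a feature with intensities \(x\) in groups of sizes \(n_1, n_2\):

- **AUC** = \(U/(n_1 n_2)\), the Mann-Whitney statistic with midranks
  (ties count ½) — the probability that a random pixel of one class
  exceeds one of the other.
- **ICC(C,k)** = \((MS_T - MS_E)/MS_T\) from the two-way ANOVA of a
  target × rater (region × replicate-acquisition) matrix: the two-way
  mixed-model intraclass correlation, consistency, average measures. For
  planted variance components it approaches
  \(k\sigma^2_T/(k\sigma^2_T+\sigma^2_E)\).
- **VIP** for PLS-DA component weights \(w_{ja}\) and per-component
  explained response variance \(SSY_a\):
  \(\mathrm{VIP}_j = \sqrt{p\,\sum_a w_{ja}^2 SSY_a / \sum_a SSY_a}\),
  so \(\sum_j \mathrm{VIP}_j^2 = p\).
- **QEA** for a set of \(m\) metabolites with autoscaled submatrix \(X\)
  and binary outcome \(y\), \(\hat\mu = \bar y\):
  \(Q = (y-\hat\mu)^\top X X^\top (y-\hat\mu) / (m\,\hat\mu(1-\hat\mu))\),
  with significance from label permutation and Bonferroni correction
  across sets.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from fibermsi import make_phantom, simulate_msi, dataset_to_peaktable, segment

truth = make_phantom(48, 48, layout="muscle", seed=7, rare_frac=0.05)
(ds,), truth = simulate_msi(truth, n_features=60, n_marker_per_class=5,
                            snr=4.0, seed=7)
pt = dataset_to_peaktable(ds)        # 61 consensus features x 2304 pixels
seg = segment(pt, k=4, seed=0, denoise=True)
true_labels = truth.class_map.labels[pt.coords[:, 1], pt.coords[:, 0]]
print(adjusted_rand_score(true_labels, seg.pixel_labels))   # 0.979
print(seg.class_counts())            # {1: 877, 2: 719, 3: 682, 4: 26}
```

The adjusted Rand index of 0.979 means the unsupervised segmentation
recovers the planted fiber-type geometry almost pixel-perfectly, and the
26-pixel class 4 is the rare oxidative 2b subclass (~5% of the 2b region)
isolated as its own metabolic class. `examples/` contains one short script
per capability (segmentation, biomarker screening, ICC reproducibility,
annotation + enrichment, LC-MS cross-validation, the full pipeline); each
prints its results with a note on what they mean.

A thin CLI wraps the same calls:

```sh
fibermsi simulate --preset muscle --seed 7 --out data/
fibermsi preprocess data/replicate_1.imzML --out peaks.csv
fibermsi segment peaks.csv --k 4 --seed 0 --out seg/
fibermsi run-all config.yaml --out out/
```

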