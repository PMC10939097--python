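"""Spectrum-level preprocessing and ion-image denoising.

The standard MSI preprocessing chain applied here mirrors common vendor
pipelines: baseline removal (morphological opening), root-mean-square (RMS)
normalization per pixel, signal-to-noise peak picking, cross-pixel peak
alignment into a consensus :class:`~fibermsi.core.PeakTable`, and
edge-preserving median filtering of ion images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core import IonImage, PeakTable, Spectrum, ValidationError


@dataclass
class PreprocessConfig:
    """Thresholds for the preprocessing chain.

    baseline_window : width (in m/z bins) of the morphological opening used
        for baseline estimation; must cover the widest real peak.
    snr_min : minimal peak signal-to-noise ratio (noise from MAD).
    align_tol_ppm : relative clustering window for cross-pixel alignment;
        default matches the 10 ppm mass tolerance used for annotation.
    min_pixel_fraction : features detected in fewer pixels are dropped.
    median_kernel : odd width of the median filter for ion-image denoising.
    """

    baseline_window: int = 51
    snr_min: float = 3.0
    align_tol_ppm: float = 10.0
    min_pixel_fraction: float = 0.01
    median_kernel: int = 3

    def __post_init__(self):
        if self.baseline_window < 3:
            raise ValidationError("baseline_window must be >= 3")
        if self.snr_min <= 0 or self.align_tol_ppm <= 0:
            raise ValidationError("snr_min and align_tol_ppm must be positive")
        if not 0 <= self.min_pixel_fraction <= 1:
            raise ValidationError("min_pixel_fraction must be in [0, 1]")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValidationError("median_kernel must be odd and >= 3")


@dataclass
class PeakList:
    """Centroided peaks of one pixel: (mz, intensity, snr) triples."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.snr)):
            raise ValidationError("peak arrays must share a length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("peak m/z must be strictly increasing")

    def __len__(self):
        return len(self.mz)


# ---------------------------------------------------------------------------
# Per-spectrum steps
# ---------------------------------------------------------------------------

def remove_baseline(s: Spectrum, window: int = 51) -> Spectrum:
    """Subtract a morphological-opening baseline estimate from a profile spectrum.

    The baseline is a rolling minimum followed by a rolling maximum of the
    same width (grey opening). The result is clipped at zero; the m/z axis
    is unchanged. ``window`` must exceed the widest genuine peak or peaks
    will be eroded into the baseline.
    """
    if s.mode != "profile":
        raise ValidationError(
            "baseline removal needs a profile spectrum; centroid data is "
            "already baseline-free — skip this step")
    if window < 3:
        raise ValidationError("window must be >= 3")
    baseline = ndi.grey_opening(s.intensity, size=window, mode="nearest")
    return Spectrum(s.mz, np.clip(s.intensity - baseline, 0.0, None), mode=s.mode)


def rms_normalize(s: Spectrum):
    """Scale a spectrum so the RMS of its intensities is 1.

    Returns the normalized spectrum and the scaling factor
    ``sqrt(mean(intensity^2))``.
    """
    peak = float(s.intensity.max())
    if peak == 0.0:
        raise ValidationError("all-zero spectrum: RMS normalization undefined")
    # scale by the maximum first so squaring cannot under/overflow
    factor = peak * float(np.sqrt(np.mean((s.intensity / peak) ** 2)))
    return Spectrum(s.mz, s.intensity / factor, mode=s.mode), factor


def _mad_noise(x: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def pick_peaks(s: Spectrum, snr_min: float = 3.0) -> PeakList:
    """Detect local maxima exceeding ``snr_min`` times the MAD noise level.

    The spectrum is assumed baseline-corrected. If the MAD estimate collapses
    to zero on a sparse spectrum, the smallest positive intensity is used as
    the noise scale instead (with a warning).
    """
    y = s.intensity
    if len(y) < 3 or not np.any(y > 0):
        return PeakList(np.empty(0), np.empty(0), np.empty(0))
    noise = _mad_noise(y)
    if noise == 0.0:
        noise = float(y[y > 0].min())
        warnings.warn("MAD noise estimate is zero; falling back to smallest "
                      "positive intensity", stacklevel=2)
    # signal = height above the residual background level (median)
    snr = (y - np.median(y)) / noise
    # strict rise on the left, fall-or-equal on the right keeps plateaus once
    left = np.r_[True, y[1:] > y[:-1]]
    right = np.r_[y[:-1] > y[1:], True]
    apex = left & right & (snr >= snr_min) & (y > 0)
    idx = np.flatnonzero(apex)
    return PeakList(s.mz[idx], y[idx], snr[idx])


# ---------------------------------------------------------------------------
# Cross-pixel alignment
# ---------------------------------------------------------------------------

def align_peaks(peaklists, coords, tol_ppm: float = 10.0,
                min_pixel_fraction: float = 0.01,
                normalization: str = "none") -> PeakTable:
    """Cluster per-pixel peaks along m/z into consensus features.

    All peaks are pooled, sorted by m/z, and greedily grouped so that each
    cluster's relative diameter stays within ``tol_ppm`` (a diameter-bounded
    variant of single-linkage along the m/z axis). The consensus feature m/z
    is the intensity-weighted mean of its members; the table holds each
    pixel's apex intensity (0 where absent). Features detected in fewer than
    ``min_pixel_fraction`` of pixels are dropped.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    coords = np.asarray(coords, dtype=int)
    n_pixels = len(peaklists)
    if n_pixels == 0 or all(len(pl) == 0 for pl in peaklists):
        raise ValidationError("need at least one nonempty peak list")
    if coords.shape != (n_pixels, 2):
        raise ValidationError("coords must match peaklists")

    mz_all = np.concatenate([pl.mz for pl in peaklists])
    int_all = np.concatenate([pl.intensity for pl in peaklists])
    pix_all = np.concatenate([np.full(len(pl), j) for j, pl in enumerate(peaklists)])
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all, pix_all = mz_all[order], int_all[order], pix_all[order]

    # greedy diameter-bounded grouping over the sorted pooled peaks
    cluster_id = np.empty(len(mz_all), dtype=int)
    start_mz, cid = mz_all[0], 0
    for i, m in enumerate(mz_all):
        if (m - start_mz) / start_mz * 1e6 > tol_ppm:
            cid += 1
            start_mz = m
        cluster_id[i] = cid
    n_clusters = cid + 1

    w = np.where(int_all > 0, int_all, 1e-30)
    sum_w = np.bincount(cluster_id, weights=w, minlength=n_clusters)
    sum_wm = np.bincount(cluster_id, weights=w * mz_all, minlength=n_clusters)
    feature_mz = sum_wm / sum_w

    matrix = np.zeros((n_clusters, n_pixels))
    # apex intensity: keep the strongest member if one pixel contributes twice
    np.maximum.at(matrix, (cluster_id, pix_all), int_all)

    support = (matrix > 0).mean(axis=1)
    keep = support >= min_pixel_fraction
    feature_mz, matrix = feature_mz[keep], matrix[keep]
    if len(feature_mz) == 0:
        raise ValidationError("no feature passed the min_pixel_fraction filter")
    order = np.argsort(feature_mz)
    return PeakTable(feature_mz[order], matrix[order], coords,
                     normalization=normalization)


def dataset_to_peaktable(ds, config: PreprocessConfig | None = None) -> PeakTable:
    """Full per-pixel chain: baseline removal, peak picking, RMS scaling, alignment.

    Profile spectra are baseline-corrected and centroided; each pixel's picked
    intensities are divided by the RMS factor of its full (baseline-corrected)
    spectrum, so pixel-to-pixel ionization efficiency differences cancel.
    Centroid input skips baseline removal and normalizes by the RMS of the
    centroid intensities.
    """
    config = config or PreprocessConfig()
    peaklists = []
    for spec in ds.spectra:
        if spec.mode == "profile":
            corrected = remove_baseline(spec, config.baseline_window)
            factor = float(np.sqrt(np.mean(corrected.intensity ** 2)))
            peaks = pick_peaks(corrected, config.snr_min)
        else:
            factor = float(np.sqrt(np.mean(spec.intensity ** 2)))
            peaks = PeakList(spec.mz, spec.intensity,
                             np.full(len(spec.mz), np.inf))
        if factor > 0:
            peaks = PeakList(peaks.mz, peaks.intensity / factor, peaks.snr)
        peaklists.append(peaks)
    return align_peaks(peaklists, ds.coords, tol_ppm=config.align_tol_ppm,
                       min_pixel_fraction=config.min_pixel_fraction,
                       normalization="rms")


def align_replicates(datasets, config: PreprocessConfig | None = None,
                     min_fraction: float = 0.5):
    """Jointly align peaks across replicate acquisitions of the same section.

    Each dataset must cover the same pixel grid. Spectra are baseline
    corrected and picked per pixel, then pooled across replicates for one
    consensus alignment, so a feature's intensity is directly comparable
    between acquisitions (intensities are left unnormalized: replicate
    studies quantify raw measurement variance). Features detected in fewer
    than ``min_fraction`` of pixel-replicate pairs are dropped.

    Returns ``(feature_mz, X, coords)`` where ``X`` has shape
    (n_features, n_pixels, n_replicates) — per feature, the target x rater
    matrix used for ICC reproducibility analysis.
    """
    config = config or PreprocessConfig()
    k = len(datasets)
    if k < 2:
        raise ValidationError("need >= 2 replicate datasets")
    base_coords = datasets[0].coords
    for d in datasets[1:]:
        if not np.array_equal(d.coords, base_coords):
            raise ValidationError("replicates must share the pixel grid")
    peaklists, pseudo = [], []
    offset = int(base_coords[:, 1].max()) + 1
    for r, d in enumerate(datasets):
        for spec, (c, row) in zip(d.spectra, d.coords):
            if spec.mode == "profile":
                spec = remove_baseline(spec, config.baseline_window)
                peaklists.append(pick_peaks(spec, config.snr_min))
            else:
                peaklists.append(PeakList(spec.mz, spec.intensity,
                                          np.full(len(spec.mz), np.inf)))
            pseudo.append((c, row + r * offset))
    pt = align_peaks(peaklists, np.array(pseudo), tol_ppm=config.align_tol_ppm,
                     min_pixel_fraction=min_fraction)
    n_pix = len(base_coords)
    X = pt.matrix.reshape(pt.n_features, k, n_pix).transpose(0, 2, 1)
    return pt.feature_mz, X, base_coords


# ---------------------------------------------------------------------------
# Ion-image denoising
# ---------------------------------------------------------------------------

def median_filter_image(values: np.ndarray, kernel: int = 3) -> np.ndarray:
    """NaN-aware kernel x kernel median filter on a 2D array.

    NaNs are excluded from each window and NaN pixels remain NaN, so missing
    pixels never contaminate their neighbours. Step edges between constant
    regions are preserved (the window median on either side equals that
    side's value).
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValidationError("kernel must be odd and >= 3")
    values = np.asarray(values, dtype=float)
    nan_mask = np.isnan(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = ndi.generic_filter(values, np.nanmedian, size=kernel,
                                 mode="constant", cval=np.nan)
    out[nan_mask] = np.nan
    return out


def denoise_ion_image(img: IonImage, kernel: int = 3) -> IonImage:
    """Edge-preserving median filter applied to one ion image."""
    return IonImage(median_filter_image(img.values, kernel),
                    img.feature_mz, img.tol_ppm)
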