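"""Co-registration of immunofluorescence fiber-type masks with the MSI grid.

Adjacent tissue sections (one stained for fiber-type markers, one measured
by MSI) differ by a rigid motion plus a scale change, so a similarity
transform fitted to operator-picked landmark pairs suffices; an affine model
is available for sections with shear. Label masks are resampled by
nearest-neighbor lookup (labels are categorical) and the overlap of MSI
metabolic classes with fiber types is scored as an ordinal "+" table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, SimilarityTransform

from .core import ROILabelMap, ValidationError


@dataclass
class LandmarkTransform:
    """Least-squares similarity (or affine) map from source mask pixels to
    destination (MSI) pixels, with the residual RMSE over the landmarks."""

    scale: float
    rotation: float
    translation: tuple
    rmse: float
    _tform: object = None

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self._tform(np.asarray(pts, dtype=float))

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        return self._tform.inverse(np.asarray(pts, dtype=float))


@dataclass
class CompositionMatrix:
    """MSI-class x fiber-type cross-tabulation with ordinal '+' scores.

    ``counts`` are co-occupied pixel counts; ``row_fractions`` normalize each
    MSI class to 1; ``ordinal_scores`` count how many band thresholds each
    fraction reaches (0 = "-", 3 = "+++", at the default bands).
    """

    counts: pd.DataFrame
    row_fractions: pd.DataFrame
    ordinal_scores: pd.DataFrame
    bands: tuple

    def glyph_table(self) -> pd.DataFrame:
        """Render the ordinal scores as '-'/'+'/'++'/'+++' glyphs."""
        return self.ordinal_scores.map(lambda s: "+" * int(s) if s else "-")


def fit_landmarks(src, dst, model: str = "similarity") -> LandmarkTransform:
    """Fit a similarity (default) or affine transform to landmark pairs.

    Minimizes the sum of squared distances between transformed source points
    and destination points; at least 2 non-coincident pairs are required
    (3 for affine).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    min_pairs = 3 if model == "affine" else 2
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValidationError("src and dst must both be (n, 2) point arrays")
    if len(src) < min_pairs:
        raise ValidationError(f"need at least {min_pairs} landmark pairs")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValidationError("landmark points are coincident")

    cls = AffineTransform if model == "affine" else SimilarityTransform
    tform = cls.from_estimate(src, dst)
    if not tform:
        raise ValidationError("degenerate landmark configuration")
    resid = tform(src) - dst
    rmse = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    scale = tform.scale if np.isscalar(tform.scale) else float(np.mean(tform.scale))
    return LandmarkTransform(float(scale), float(tform.rotation),
                             (float(tform.translation[0]),
                              float(tform.translation[1])),
                             rmse, _tform=tform)


def read_landmarks(path):
    """Read landmark pairs from CSV with columns src_x,src_y,dst_x,dst_y."""
    df = pd.read_csv(path)
    need = {"src_x", "src_y", "dst_x", "dst_y"}
    if not need <= set(df.columns):
        raise ValidationError(f"landmark CSV needs columns {sorted(need)}")
    return df[["src_x", "src_y"]].to_numpy(float), df[["dst_x", "dst_y"]].to_numpy(float)


def resample_mask(mask: ROILabelMap, T: LandmarkTransform,
                  grid_shape: tuple) -> ROILabelMap:
    """Resample a label mask onto the MSI grid through a fitted transform.

    Each MSI pixel center (col, row) is mapped back through the inverse
    transform and assigned the nearest source label; pixels falling outside
    the mask become background (0). Nearest-neighbor lookup keeps labels
    categorical — interpolation would invent classes at boundaries.
    """
    n_rows, n_cols = grid_shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
    src_pts = T.inverse(pts)
    src_col = np.rint(src_pts[:, 0]).astype(int)
    src_row = np.rint(src_pts[:, 1]).astype(int)
    h, w = mask.labels.shape
    inb = (src_col >= 0) & (src_col < w) & (src_row >= 0) & (src_row < h)
    out = np.zeros(n_rows * n_cols, dtype=int)
    out[inb] = mask.labels[src_row[inb], src_col[inb]]
    return ROILabelMap(out.reshape(n_rows, n_cols),
                       label_names=dict(mask.label_names))


def composition(seg_labels: ROILabelMap, fiber_labels: ROILabelMap,
                bands: tuple = (0.05, 0.25, 0.50)) -> CompositionMatrix:
    """Cross-tabulate MSI metabolic classes against fiber types.

    Only pixels assigned in both maps contribute. Row fractions are the
    share of each fiber type within an MSI class, and the ordinal score is
    the number of band thresholds the fraction reaches — the "+" scale used
    to summarize which fiber subtypes make up each metabolic class.
    """
    if seg_labels.labels.shape != fiber_labels.labels.shape:
        raise ValidationError("label maps must share a grid")
    bands = tuple(bands)
    if not all(0 < b < 1 for b in bands) or list(bands) != sorted(set(bands)):
        raise ValidationError("bands must be strictly increasing in (0, 1)")
    a, b = seg_labels.labels.ravel(), fiber_labels.labels.ravel()
    both = (a > 0) & (b > 0)
    if not both.any():
        raise ValidationError("label maps have no co-occupied pixels")
    counts = pd.crosstab(pd.Series(a[both], name="msi_class"),
                         pd.Series(b[both], name="fiber_type"))
    counts.index = [seg_labels.label_names.get(i, str(i)) for i in counts.index]
    counts.columns = [fiber_labels.label_names.get(i, str(i)) for i in counts.columns]
    frac = counts.div(counts.sum(axis=1), axis=0)
    scores = frac.map(lambda f: int(sum(f >= t for t in bands)))
    return CompositionMatrix(counts, frac, scores, bands)
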