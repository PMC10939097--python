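"""Domain types and I/O for mass spectrometry imaging (MSI) data.

The central objects are:

* :class:`Spectrum` — one mass spectrum (profile or centroid).
* :class:`MSIDataset` — a pixel-indexed collection of spectra on a 2D grid;
  the raw datacube as read from imzML.
* :class:`PeakTable` — the consensus feature (m/z) x pixel intensity matrix
  produced by peak picking and alignment; all downstream statistics operate
  on this object.
* :class:`IonImage` — the 2D spatial distribution of one feature.
* :class:`ROILabelMap` — an integer class label per pixel (segmentation
  output or immunofluorescence-derived fiber types).
* :class:`MetaboliteDB` / :class:`MetaboliteSetLibrary` — tabular side
  inputs for annotation and set enrichment.

Coordinates are 0-based ``(col, row)`` with origin at the top-left, matching
raster-image conventions; imzML's 1-based coordinates are shifted on read.
Missing pixels (sparse acquisitions) are simply absent from the dataset and
render as NaN in ion images.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ImzMLParseError(RuntimeError):
    """Raised when an imzML/ibd pair cannot be read consistently."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class FeatureNotFoundError(KeyError):
    """Raised when no consensus feature lies within the requested ppm window."""


def ppm_diff(observed: float, reference: float) -> float:
    """Signed relative mass difference in parts per million."""
    return (observed - reference) / reference * 1e6


# ---------------------------------------------------------------------------
# Spectrum / dataset
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """A single mass spectrum.

    Parameters
    ----------
    mz : array of m/z values in Da, strictly increasing.
    intensity : non-negative abundances (arbitrary units), same length as mz.
    mode : ``"profile"`` or ``"centroid"``.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValidationError(
                f"mz ({len(self.mz)}) and intensity ({len(self.intensity)}) "
                "lengths differ"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")
        if self.mode not in ("profile", "centroid"):
            raise ValidationError(f"unknown spectrum mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MSIDataset:
    """Pixel-indexed collection of spectra on a 2D grid.

    ``coords`` holds one 0-based ``(col, row)`` pair per spectrum; pairs are
    unique. ``pixel_size_um`` is the center-to-center pixel spacing (typical
    MALDI acquisitions use 25-50 um).
    """

    spectra: list
    coords: np.ndarray
    pixel_size_um: float = 50.0
    polarity: str = "positive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.spectra) == 0:
            raise ValidationError("dataset must contain at least one spectrum")
        if self.coords.shape != (len(self.spectra), 2):
            raise ValidationError("coords must be (n_spectra, 2)")
        if np.any(self.coords < 0):
            raise ValidationError("coords must be non-negative")
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != len(self.coords):
            raise ValidationError("duplicate pixel coordinates")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid_shape(self) -> tuple:
        """(n_rows, n_cols) of the bounding grid."""
        return (int(self.coords[:, 1].max()) + 1,
                int(self.coords[:, 0].max()) + 1)


@dataclass
class PeakTable:
    """Consensus feature x pixel intensity matrix.

    ``matrix[i, j]`` is the intensity of feature ``feature_mz[i]`` in the
    pixel at ``coords[j]``; a value of 0 means the peak was not detected in
    that pixel. ``normalization`` records whether per-pixel RMS scaling was
    applied at build time.
    """

    feature_mz: np.ndarray
    matrix: np.ndarray
    coords: np.ndarray
    normalization: str = "none"

    def __post_init__(self):
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.matrix.shape != (len(self.feature_mz), len(self.coords)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.feature_mz)} features x {len(self.coords)} pixels"
            )
        if len(self.feature_mz) > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValidationError("feature_mz must be strictly increasing")
        if np.any(self.matrix < 0):
            raise ValidationError("intensities must be non-negative")
        if self.normalization not in ("none", "rms"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def grid_shape(self) -> tuple:
        return (int(self.coords[:, 1].max()) + 1,
                int(self.coords[:, 0].max()) + 1)

    def feature_image(self, index: int) -> np.ndarray:
        """Render one feature row onto the bounding grid (NaN = no pixel)."""
        img = np.full(self.grid_shape, np.nan)
        img[self.coords[:, 1], self.coords[:, 0]] = self.matrix[index]
        return img


@dataclass
class IonImage:
    """2D map of a single feature's intensity (NaN at unoccupied pixels)."""

    values: np.ndarray
    feature_mz: float
    tol_ppm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("ion image must be 2-D")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValidationError("ion image values must be >= 0 or NaN")


@dataclass
class ROILabelMap:
    """Integer class label per pixel; 0 means background/unassigned."""

    labels: np.ndarray
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            # auto-name rather than fail: names are presentation only
            for lab in sorted(missing):
                self.label_names[int(lab)] = f"class_{int(lab)}"

    @property
    def classes(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        u = np.unique(self.labels)
        return u[u > 0]


# ---------------------------------------------------------------------------
# Tabular side inputs
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteDB:
    """Reference table of metabolites for precise-mass annotation.

    Backed by a DataFrame with columns ``id``, ``name``, and either
    ``neutral_mass`` (monoisotopic, Da) or a precomputed ``adduct_mz`` with
    its ``adduct`` label; an optional ``class`` column carries chemical-class
    tags used to build set libraries.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"id", "name"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"MetaboliteDB requires columns {sorted(required)}")
        if not ("neutral_mass" in self.table.columns
                or "adduct_mz" in self.table.columns):
            raise ValidationError("MetaboliteDB needs neutral_mass or adduct_mz")
        if self.table["id"].duplicated().any():
            dups = self.table.loc[self.table["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        for col in ("neutral_mass", "adduct_mz"):
            if col in self.table.columns:
                vals = self.table[col].dropna()
                if (vals <= 0).any():
                    raise ValidationError(f"{col} values must be positive")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MetaboliteSetLibrary:
    """Named metabolite sets (GMT-style), e.g. pathway or lipid-class sets."""

    sets: dict

    def __post_init__(self):
        if len(set(self.sets)) != len(self.sets):
            raise ValidationError("set names must be unique")
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def read_imzml(path, pixel_size_um: float | None = None,
               polarity: str | None = None, mode: str = "profile") -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Pixel size and polarity are taken from the file metadata when present,
    falling back to the arguments (defaults: 50 um, positive). imzML 1-based
    pixel coordinates are shifted to this package's 0-based convention.

    Raises
    ------
    ImzMLParseError
        If the ibd companion is missing or truncated, the XML is malformed,
        or a pixel's m/z and intensity arrays disagree in length.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(str(path))[0] + ".ibd"
    if not os.path.exists(ibd):
        raise ImzMLParseError(f"companion ibd file not found: {ibd}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML or header
        raise ImzMLParseError(f"cannot parse {path}: {exc}") from exc

    file_polarity = getattr(parser, "polarity", None)
    if file_polarity in ("positive", "negative"):
        polarity = file_polarity
    if polarity is None:
        polarity = "positive"
    meta = dict(parser.imzmldict or {})
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel size x", 50.0) or 50.0)

    spectra, coords = [], []
    for i, (x, y, *_) in enumerate(parser.coordinates):
        try:
            mzs, ints = parser.getspectrum(i)
        except Exception as exc:
            raise ImzMLParseError(
                f"cannot read spectrum for pixel index {i} "
                f"(imzML coords x={x}, y={y}): {exc}") from exc
        if len(mzs) != len(ints):
            raise ImzMLParseError(
                f"pixel index {i} (x={x}, y={y}): m/z and intensity arrays "
                f"have different lengths ({len(mzs)} vs {len(ints)})")
        intensities = np.clip(np.asarray(ints, dtype=float), 0.0, None)
        spectra.append(Spectrum(np.asarray(mzs, dtype=float), intensities, mode=mode))
        coords.append((int(x) - 1, int(y) - 1))
    return MSIDataset(spectra, np.array(coords), pixel_size_um=pixel_size_um,
                      polarity=polarity, metadata=meta)


def write_imzml(ds: MSIDataset, path) -> str:
    """Write an :class:`MSIDataset` as processed imzML (+ibd).

    m/z values are stored as float64 and intensities as float32, so a
    round-trip through :func:`read_imzml` reproduces intensities to float32
    precision. Returns the imzML path written.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(ds) == 0:
        raise ValidationError("refusing to write empty dataset")
    spec_type = "profile" if ds.spectra[0].mode == "profile" else "centroid"
    with ImzMLWriter(str(path), mode="processed", spec_type=spec_type,
                     polarity=ds.polarity) as writer:
        for spec, (col, row) in zip(ds.spectra, ds.coords):
            writer.addSpectrum(spec.mz, spec.intensity,
                               (int(col) + 1, int(row) + 1))
    return str(path)


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------

def get_ion_image(pt: PeakTable, mz: float, tol_ppm: float = 10.0) -> IonImage:
    """Extract the ion image of the consensus feature nearest to ``mz``.

    Selects the single feature with minimal \\|delta\\| ppm to the query, provided
    it falls within ``tol_ppm``; unoccupied grid pixels are NaN.
    """
    if pt.n_features == 0:
        raise ValidationError("empty peak table")
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    dppm = np.abs((pt.feature_mz - mz) / mz * 1e6)
    best = int(np.argmin(dppm))
    if dppm[best] > tol_ppm:
        raise FeatureNotFoundError(
            f"no feature within {tol_ppm} ppm of m/z {mz}; nearest candidate "
            f"is {pt.feature_mz[best]:.4f} at {dppm[best]:.1f} ppm")
    return IonImage(pt.feature_image(best), float(pt.feature_mz[best]), tol_ppm)


# ---------------------------------------------------------------------------
# Label maps, metabolite tables and GMT set libraries
# ---------------------------------------------------------------------------

def read_label_map(path) -> ROILabelMap:
    """Read a label map from an indexed PNG or a CSV integer grid."""
    path = str(path)
    if path.lower().endswith(".png"):
        from PIL import Image

        img = Image.open(path)
        if img.mode not in ("P", "L", "I", "I;16"):
            raise ValidationError(
                f"label PNG must be indexed or grayscale, got mode {img.mode}")
        labels = np.asarray(img, dtype=int)
    else:
        labels = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return ROILabelMap(labels)


def write_label_map(roi: ROILabelMap, path) -> str:
    """Write a label map as indexed PNG (``.png``) or CSV grid (otherwise)."""
    path = str(path)
    if path.lower().endswith(".png"):
        from PIL import Image

        if roi.labels.max() > 255:
            raise ValidationError("PNG label maps support at most 255 classes")
        Image.fromarray(roi.labels.astype(np.uint8), mode="L").save(path)
    else:
        np.savetxt(path, roi.labels, fmt="%d", delimiter=",")
    return path


def write_peaktable(pt: PeakTable, path) -> str:
    """Persist a peak table as CSV: one row per feature, pixel columns ``c<col>_r<row>``."""
    cols = [f"c{c}_r{r}" for c, r in pt.coords]
    df = pd.DataFrame(pt.matrix, columns=cols)
    df.insert(0, "feature_mz", pt.feature_mz)
    df.insert(1, "normalization", pt.normalization)
    df.to_csv(path, index=False)
    return str(path)


def read_peaktable(path) -> PeakTable:
    """Read a peak table written by :func:`write_peaktable`."""
    df = pd.read_csv(path)
    pix_cols = [c for c in df.columns if c.startswith("c") and "_r" in c]
    coords = np.array([[int(c[1:].split("_r")[0]), int(c.split("_r")[1])]
                       for c in pix_cols])
    norm = str(df["normalization"].iloc[0]) if len(df) else "none"
    return PeakTable(df["feature_mz"].to_numpy(), df[pix_cols].to_numpy(),
                     coords, normalization=norm)


def read_metabolite_db(path) -> MetaboliteDB:
    """Read a metabolite reference table from CSV (id,name,neutral_mass[,...])."""
    return MetaboliteDB(pd.read_csv(path))


def read_gmt(path) -> MetaboliteSetLibrary:
    """Read a GMT set library: tab-separated ``name, description, id, id...``."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member id")
            name, members = parts[0], [p for p in parts[2:] if p]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = members
    return MetaboliteSetLibrary(sets)


def write_gmt(lib: MetaboliteSetLibrary, path, descriptions: dict | None = None) -> str:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in lib.items():
            fh.write("\t".join([name, descriptions.get(name, "")] + list(members)))
            fh.write("\n")
    return str(path)
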