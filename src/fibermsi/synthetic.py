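"""Ground-truthed synthetic data: muscle-section phantoms, MSI datacubes,
replicate acquisitions and LC-MS tables.

The phantom emulates a longitudinal hindlimb muscle section: elongated
vertical bands of slow (type 1), fast 2a and fast glycolytic 2b fiber
regions, with a rare oxidative 2b subclass embedded as small patches inside
the 2b region (a few percent of its pixels). Each class carries a set of
fingerprint marker features — phospholipid-like for slow fibers,
anserine-like dipeptides for fast 2a, glycolytic intermediates for fast 2b,
and acylcarnitine-like markers for the rare oxidative subclass — multiplied
by a planted fold change in their class.

Intensities follow a multiplicative (log-normal) noise model: on the log2
scale, intensity = log2(base) + effect*[pixel in class] + sigma_T*T +
sigma_E*E, where T is a per-pixel random effect shared by replicate
acquisitions and E is independent per acquisition, giving the intraclass
correlation a closed-form expectation. Spectra are rendered as profile-mode
Gaussian peaks on a sparse m/z axis with a smooth additive baseline, and
round-trip through imzML.

All generators are deterministic given their seed, and every planted
parameter is recorded in :class:`SimTruth` for downstream recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (MetaboliteDB, MetaboliteSetLibrary, MSIDataset,
                   ROILabelMap, Spectrum, ValidationError)

CLASS_NAMES = {1: "slow_type1", 2: "fast_2a", 3: "fast_2b_glycolytic",
               4: "fast_2b_oxidative"}
#: marker family planted per phantom class
MARKER_KINDS = {1: "phospholipid", 2: "anserine_like", 3: "glycolytic",
                4: "acylcarnitine"}

_PROTON = 1.00727646688

# profile peak rendering: sample offsets (Da) around each feature center and
# the Gaussian shape factors at those offsets (sigma = 0.01 Da); the center
# sample sits exactly on the apex
_PEAK_OFFSETS = np.array([-0.08, -0.06, -0.04, -0.02, 0.0, 0.02, 0.04, 0.06, 0.08])
_PEAK_SIGMA = 0.01
_PEAK_SHAPE = np.exp(-0.5 * (_PEAK_OFFSETS / _PEAK_SIGMA) ** 2)


@dataclass
class SimTruth:
    """Planted ground truth: class map, marker effects, noise components."""

    class_map: ROILabelMap
    effect_table: pd.DataFrame = None   # feature_id, mz, target_class, log2_effect, kind
    variance_components: tuple = (0.0, 0.0)   # (sigma2_target, sigma2_error)
    seed: int = 0
    rare_parent: int | None = None
    rare_label: int | None = None
    feature_mz: np.ndarray = None
    feature_ids: np.ndarray = None
    base_intensity: np.ndarray = None

    def marker_ids(self, kind: str) -> list:
        t = self.effect_table
        return t.loc[t["kind"] == kind, "feature_id"].tolist()


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

def make_phantom(width: int = 48, height: int = 48, layout: str = "muscle",
                 seed: int = 0, rare_frac: float = 0.05,
                 band_width: int | None = None) -> SimTruth:
    """Generate a planted fiber-type label map.

    ``"two_region"`` splits the grid into two vertical halves. ``"muscle"``
    lays down elongated vertical bands cycling through slow / fast-2a /
    fast-2b classes and embeds small 2-pixel-wide patches of the rare
    oxidative 2b subclass (class 4) covering ``rare_frac`` of the parent 2b
    pixels. Deterministic for a fixed seed.
    """
    if width < 16 or height < 16:
        raise ValidationError("phantom must be at least 16 x 16")
    rng = np.random.default_rng(seed)

    if layout == "two_region":
        labels = np.ones((height, width), dtype=int)
        labels[:, width // 2:] = 2
        names = {1: CLASS_NAMES[1], 2: CLASS_NAMES[2]}
        return SimTruth(ROILabelMap(labels, names), seed=seed)

    if layout != "muscle":
        raise ValidationError(f"unknown phantom layout {layout!r}")
    if not 0.02 <= rare_frac <= 0.10:
        raise ValidationError("rare_frac must lie in [0.02, 0.10]")

    bw = band_width or max(3, width // 9)
    labels = np.ones((height, width), dtype=int)
    for b, col0 in enumerate(range(0, width, bw)):
        labels[:, col0:col0 + bw] = 1 + (b % 3)

    # rare oxidative-2b patches: 2-wide vertical runs inside the 2b region
    parent = 3
    parent_cols = np.unique(np.nonzero(labels == parent)[1])
    # patches are 2 pixels wide so a 3x3 median filter cannot erase them
    pair_cols = parent_cols[np.isin(parent_cols + 1, parent_cols)]
    n_parent = int((labels == parent).sum())
    target = int(round(rare_frac * n_parent))
    placed = 0
    guard = 0
    while placed < target and guard < 10_000:
        guard += 1
        col = int(rng.choice(pair_cols))
        run = int(rng.integers(max(3, height // 12), max(4, height // 6) + 1))
        row0 = int(rng.integers(0, height - run))
        block = labels[row0:row0 + run, col:col + 2]
        new = int(np.sum(block == parent))
        if new == 0:
            continue
        take = block == parent
        if placed + new > target:
            # trim rows from the end to land near the target count
            excess = placed + new - target
            flat = np.flatnonzero(take.ravel())
            take.ravel()[flat[len(flat) - excess:]] = False
            new -= excess
        block[take] = 4
        placed += new
    names = dict(CLASS_NAMES)
    return SimTruth(ROILabelMap(labels, names), seed=seed,
                    rare_parent=parent, rare_label=4)


# ---------------------------------------------------------------------------
# MSI simulation
# ---------------------------------------------------------------------------

def _assign_features(truth: SimTruth, n_features: int, n_marker_per_class: int,
                     marker_log2_effect: float, rng) -> pd.DataFrame:
    classes = [int(c) for c in truth.class_map.classes]
    if n_features < len(classes) * n_marker_per_class:
        raise ValidationError("n_features must cover all class markers")
    # well-separated m/z centers on a 0.5 Da grid within 100-1000
    grid = np.arange(100.0, 1000.0, 0.5)
    mz = np.sort(rng.choice(grid, size=n_features, replace=False))
    mz += rng.uniform(-0.05, 0.05, size=n_features)  # off-grid jitter

    target = np.zeros(n_features, dtype=int)
    effect = np.zeros(n_features)
    kind = np.array(["background"] * n_features, dtype=object)
    marker_idx = rng.choice(n_features, size=len(classes) * n_marker_per_class,
                            replace=False)
    for ci, cls in enumerate(classes):
        idx = marker_idx[ci * n_marker_per_class:(ci + 1) * n_marker_per_class]
        target[idx] = cls
        effect[idx] = marker_log2_effect
        kind[idx] = MARKER_KINDS.get(cls, f"class{cls}_marker")
    fid = np.array([f"{kind[i]}_{i:03d}" if target[i] else f"bg_{i:03d}"
                    for i in range(n_features)], dtype=object)
    return pd.DataFrame({"feature_id": fid, "mz": mz, "target_class": target,
                         "log2_effect": effect, "kind": kind})


def simulate_msi(truth: SimTruth, n_features: int = 60,
                 n_marker_per_class: int = 5, snr: float = 4.0,
                 replicates: int = 1, seed: int = 0,
                 marker_log2_effect: float = 2.0,
                 variance_components: tuple | None = None,
                 base_log2_range: tuple = (6.0, 9.0),
                 baseline_amp: float = 5.0):
    """Render replicate profile-mode MSI datacubes from a phantom.

    Marker features are multiplied by ``2**marker_log2_effect`` inside their
    class. Pixel noise is log-normal with log2 standard deviation
    ``marker_log2_effect / snr``; passing ``variance_components =
    (sigma2_target, sigma2_error)`` instead plants an exact two-way
    random-effects structure (per-pixel effect shared across replicates plus
    independent acquisition error, both on the log2 scale), replacing the
    snr-derived noise so the intraclass correlation has the closed-form
    expectation k*s2t / (k*s2t + s2e).

    Returns ``(datasets, truth)`` where ``datasets`` is one
    :class:`MSIDataset` per replicate and ``truth`` is updated with the
    planted feature table and variance components.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    feats = _assign_features(truth, n_features, n_marker_per_class,
                             marker_log2_effect, rng)
    labels = truth.class_map.labels
    rows, cols = np.nonzero(labels > 0)
    coords = np.column_stack([cols, rows])
    pix_class = labels[rows, cols]
    n_pix = len(rows)

    if variance_components is not None:
        sigma_t = float(np.sqrt(variance_components[0]))
        sigma_e = float(np.sqrt(variance_components[1]))
    else:
        sigma_t = 0.0
        sigma_e = marker_log2_effect / snr if np.isfinite(snr) else 0.0
        variance_components = (0.0, sigma_e ** 2)

    base = 2.0 ** rng.uniform(*base_log2_range, size=n_features)
    log2_clean = np.log2(base)[None, :] + np.where(
        pix_class[:, None] == feats["target_class"].to_numpy()[None, :],
        feats["log2_effect"].to_numpy()[None, :], 0.0)
    T = rng.standard_normal((n_pix, n_features)) * sigma_t

    # sparse shared m/z axis: a window of profile samples per feature
    mz_axis = (feats["mz"].to_numpy()[:, None] + _PEAK_OFFSETS[None, :]).ravel()
    order = np.argsort(mz_axis)
    mz_axis = mz_axis[order]
    scatter = order.argsort().reshape(n_features, len(_PEAK_OFFSETS))
    baseline = baseline_amp * np.exp(-(mz_axis - 100.0) / 300.0)

    datasets = []
    for _ in range(replicates):
        E = rng.standard_normal((n_pix, n_features)) * sigma_e
        inten = 2.0 ** (log2_clean + T + E)  # n_pix x n_features
        Y = np.tile(baseline, (n_pix, 1))
        Y[:, scatter.ravel()] += np.repeat(inten, len(_PEAK_OFFSETS), axis=1) \
            * np.tile(_PEAK_SHAPE, n_features)[None, :]
        spectra = [Spectrum(mz_axis, Y[i], mode="profile") for i in range(n_pix)]
        datasets.append(MSIDataset(spectra, coords.copy(), pixel_size_um=50.0,
                                   polarity="positive",
                                   metadata={"synthetic": "true"}))

    truth.effect_table = feats
    truth.variance_components = tuple(variance_components)
    truth.feature_mz = feats["mz"].to_numpy()
    truth.feature_ids = feats["feature_id"].to_numpy()
    truth.base_intensity = base
    return datasets, truth


# ---------------------------------------------------------------------------
# LC-MS simulation and side tables
# ---------------------------------------------------------------------------

def simulate_lcms(n_features: int = 200, n_per_group: int = 3,
                  planted: list | None = None, seed: int = 0,
                  noise_log2_sd: float = 0.5,
                  groups: tuple = ("fast", "slow")):
    """Simulate an LC-MS feature table with planted group effects.

    ``planted`` is a list of ``(feature_index, log2fc)`` pairs (positive fc
    means higher in the first group); unlisted features are null. Returns
    ``(LCMSTable, truth_frame)`` with metabolite ids shared with
    :func:`make_metabolite_db` so annotation and Venn comparisons can be
    exercised end to end.
    """
    from .crossplatform import LCMSTable

    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    planted = planted or []
    mz = np.sort(rng.uniform(100, 1000, size=n_features))
    ids = np.array([f"met_{i:04d}" for i in range(n_features)])
    base_log2 = rng.uniform(8, 14, size=n_features)
    effect = np.zeros(n_features)
    for idx, fc in planted:
        effect[idx] = fc

    samples, labels = [], []
    for g, gname in enumerate(groups):
        for r in range(n_per_group):
            shift = effect / 2 if g == 0 else -effect / 2
            vals = 2.0 ** (base_log2 + shift
                           + rng.standard_normal(n_features) * noise_log2_sd)
            samples.append(vals)
            labels.append(f"{gname}_{r + 1}")
    matrix = pd.DataFrame(np.column_stack(samples), index=ids, columns=labels)
    features = pd.DataFrame({"id": ids, "mz": mz,
                             "rt": rng.uniform(0.5, 20.0, size=n_features)})
    group_map = {s: s.rsplit("_", 1)[0] for s in labels}
    truth = pd.DataFrame({"id": ids, "mz": mz, "log2_effect": effect})
    return LCMSTable(features, matrix, group_map), truth


def make_metabolite_db(feature_mz, feature_ids, adduct: str = "[M+H]+",
                       classes=None) -> MetaboliteDB:
    """Reference table whose [M+H]+ ions coincide with the given feature m/z."""
    feature_mz = np.asarray(feature_mz, dtype=float)
    table = pd.DataFrame({
        "id": np.asarray(feature_ids),
        "name": [str(f) for f in feature_ids],
        "neutral_mass": feature_mz - _PROTON,
    })
    if classes is not None:
        table["class"] = np.asarray(classes)
    return MetaboliteDB(table)


def make_set_library(truth: SimTruth, n_decoy_sets: int = 3,
                     decoy_size: int = 5, seed: int = 0) -> MetaboliteSetLibrary:
    """Set library with one set per planted marker family plus decoy sets of
    background features (mirrors pathway/lipid-class libraries like an
    "acyl carnitines" set)."""
    rng = np.random.default_rng(seed)
    sets = {}
    t = truth.effect_table
    for kind in sorted(set(t.loc[t["target_class"] > 0, "kind"])):
        sets[kind] = t.loc[t["kind"] == kind, "feature_id"].tolist()
    background = t.loc[t["target_class"] == 0, "feature_id"].to_numpy()
    for d in range(n_decoy_sets):
        size = min(decoy_size, len(background))
        sets[f"decoy_{d}"] = list(rng.choice(background, size=size, replace=False))
    return MetaboliteSetLibrary(sets)
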