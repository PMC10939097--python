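"""LC-MS feature-table ingestion and cross-platform validation of MSI findings.

LC-MS data enters as a finished feature table (Progenesis-style export:
feature id, m/z, optional retention time, one intensity column per sample).
The same differential machinery used on MSI region spectra is applied, and
agreement between platforms is quantified as an identity-level Venn overlap
of the significant metabolite lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .stats import ttest_features


@dataclass
class LCMSTable:
    """Feature x sample intensity table with per-sample group labels."""

    features: pd.DataFrame       # columns: id, mz[, rt]
    matrix: pd.DataFrame         # index: feature id, columns: sample names
    groups: dict                 # sample name -> group label

    def __post_init__(self):
        if self.features["id"].duplicated().any():
            dups = self.features.loc[self.features["id"].duplicated(), "id"]
            raise ValidationError(f"duplicate feature ids: {dups.tolist()}")
        if (self.matrix.to_numpy(float) < 0).any():
            raise ValidationError("negative intensities in LC-MS matrix")
        missing = [s for s in self.matrix.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_vector(self) -> np.ndarray:
        return np.asarray([self.groups[s] for s in self.matrix.columns])


@dataclass
class OverlapResult:
    """Exact partition of two id sets: A-only, B-only and the intersection."""

    only_a: set
    only_b: set
    both: set

    @property
    def counts(self) -> dict:
        return {"only_a": len(self.only_a), "only_b": len(self.only_b),
                "both": len(self.both)}


def load_lcms(path, groups: dict) -> LCMSTable:
    """Load a feature x sample CSV (columns: id, mz[, rt], then samples).

    ``groups`` maps each sample column name to its group label; every
    non-annotation column must be covered.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or "mz" not in df.columns:
        raise ValidationError("LC-MS CSV needs 'id' and 'mz' columns")
    meta_cols = [c for c in ("id", "mz", "rt") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValidationError("LC-MS CSV has no sample columns")
    matrix = df[sample_cols].astype(float)
    matrix.index = df["id"]
    return LCMSTable(df[meta_cols].copy(), matrix, dict(groups))


def save_lcms(table: LCMSTable, path) -> str:
    out = pd.concat([table.features.reset_index(drop=True),
                     table.matrix.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
    return str(path)


def differential_lcms(table: LCMSTable, p_max: float = 0.05,
                      group_a=None, group_b=None,
                      log_transform: bool = True) -> pd.DataFrame:
    """Per-metabolite Student's t test; returns features with raw p < ``p_max``.

    Intensities are log2-transformed before testing (the standard
    metabolomics convention: multiplicative noise becomes additive and fold
    changes become differences of log means); pass ``log_transform=False``
    to test raw intensities. The full statistics table (including
    BH-adjusted p) is attached as the ``stats`` attribute of the returned
    frame for threshold-free inspection.
    """
    M = table.matrix.to_numpy(float).T  # samples x features
    if log_transform:
        M = np.log2(M + 1e-9)
    stats = ttest_features(M, table.group_vector(),
                           feature_names=table.matrix.index.to_numpy(),
                           group_a=group_a, group_b=group_b)
    if log_transform:
        # difference of log2 means = log2 of the geometric-mean fold change
        stats["log2fc"] = stats["mean_a"] - stats["mean_b"]
    sig = stats[stats["p"] < p_max].reset_index(drop=True)
    sig.attrs["stats"] = stats
    return sig


def venn(a, b) -> OverlapResult:
    """Exact two-set partition of metabolite id collections."""
    a, b = set(a), set(b)
    return OverlapResult(only_a=a - b, only_b=b - a, both=a & b)
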