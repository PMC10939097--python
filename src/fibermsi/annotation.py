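"""Precise-mass metabolite annotation of consensus MSI features.

Each consensus feature m/z is matched against theoretical adduct ion masses
derived from a metabolite reference table (HMDB/METLIN-style) within a ppm
tolerance (default 10 ppm). All candidates within the window are retained
and ranked by absolute mass error; identity disambiguation (e.g. via
on-tissue MS/MS) is outside the scope of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetaboliteDB, ValidationError

PROTON = 1.00727646688
#: Mass shifts (Da) for singly charged adduct ions, keyed by adduct label.
ADDUCT_SHIFTS = {
    "[M+H]+": PROTON,
    "[M+Na]+": 22.98922 - 5.48579909e-4,   # Na mass minus electron
    "[M+K]+": 38.9637064 - 5.48579909e-4,  # K mass minus electron
    "[M-H]-": -PROTON,
}
DEFAULT_ADDUCTS = {
    "positive": ("[M+H]+", "[M+Na]+", "[M+K]+"),
    "negative": ("[M-H]-",),
}


@dataclass
class AnnotationRecord:
    feature_mz: float
    metabolite_id: str
    name: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


def _candidate_ions(db: MetaboliteDB, adducts) -> pd.DataFrame:
    """Expand the reference table into (id, name, adduct, theoretical m/z) ions."""
    rows = []
    t = db.table
    has_neutral = "neutral_mass" in t.columns
    has_precomp = "adduct_mz" in t.columns
    for _, rec in t.iterrows():
        if has_precomp and pd.notna(rec.get("adduct_mz")):
            rows.append((rec["id"], rec["name"],
                         rec.get("adduct", "precomputed"), float(rec["adduct_mz"])))
            continue
        if has_neutral and pd.notna(rec.get("neutral_mass")):
            for ad in adducts:
                rows.append((rec["id"], rec["name"], ad,
                             float(rec["neutral_mass"]) + ADDUCT_SHIFTS[ad]))
    if not rows:
        raise ValidationError("reference table produced no candidate ions")
    return pd.DataFrame(rows, columns=["id", "name", "adduct", "mz"])


def annotate_features(feature_mz, db: MetaboliteDB, polarity: str = "positive",
                      adducts=None, tol_ppm: float = 10.0) -> pd.DataFrame:
    """Match feature m/z values against metabolite adduct ions within ``tol_ppm``.

    Returns a DataFrame of all (feature, metabolite, adduct) matches with
    signed ppm errors, sorted per feature by |ppm_error|. A feature may
    carry several candidates or none. The result is independent of the
    reference-table row order.
    """
    if len(db) == 0:
        raise ValidationError("empty metabolite reference table")
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS[polarity]
    unknown = set(adducts) - set(ADDUCT_SHIFTS)
    if unknown:
        raise ValidationError(
            f"unknown adduct(s) {sorted(unknown)}; known: "
            f"{sorted(ADDUCT_SHIFTS)}")

    ions = _candidate_ions(db, adducts).sort_values(
        ["mz", "id", "adduct"], kind="stable").reset_index(drop=True)
    ion_mz = ions["mz"].to_numpy()

    records = []
    for fmz in np.asarray(feature_mz, dtype=float):
        # window slightly widened: the binding check below is relative to the
        # theoretical mass, which can sit just outside a feature-relative window
        tol_da = fmz * tol_ppm / 1e6 * 1.01
        lo = np.searchsorted(ion_mz, fmz - tol_da, side="left")
        hi = np.searchsorted(ion_mz, fmz + tol_da, side="right")
        for _, ion in ions.iloc[lo:hi].iterrows():
            ppm = (fmz - ion["mz"]) / ion["mz"] * 1e6
            if abs(ppm) <= tol_ppm:
                records.append((fmz, ion["id"], ion["name"], ion["adduct"],
                                ion["mz"], ppm))
    out = pd.DataFrame(records, columns=["feature_mz", "metabolite_id", "name",
                                         "adduct", "theoretical_mz", "ppm_error"])
    return out.sort_values(["feature_mz", "ppm_error"],
                           key=lambda c: np.abs(c) if c.name == "ppm_error" else c,
                           kind="stable").reset_index(drop=True)
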