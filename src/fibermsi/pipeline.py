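"""Config-driven end-to-end analysis runner.

Executes the full analysis graph on real or synthetic inputs:

    read/simulate -> preprocess -> segment -> (co-register) -> region stats
    -> annotate -> set enrichment -> (LC-MS cross-validation)

Every stage writes its artifact (CSV/JSON) into the output directory, and a
run manifest records seeds, thresholds and package versions, so identical
configs yield byte-identical tabular outputs. Stage failures abort with the
stage name; partial outputs are kept next to a ``FAILED_<stage>`` marker.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_features
from .core import (ROILabelMap, ValidationError, read_gmt, read_imzml,
                   read_label_map, read_metabolite_db, write_label_map,
                   write_peaktable)
from .coregistration import composition, fit_landmarks, read_landmarks, resample_mask
from .crossplatform import differential_lcms, load_lcms, venn
from .enrichment import qea
from .preprocess import PreprocessConfig, dataset_to_peaktable
from .segmentation import class_mean_spectra, merge_classes, segment
from .stats import auc_features, plsda, select_biomarkers, ttest_features
from .synthetic import (make_metabolite_db, make_phantom, make_set_library,
                        simulate_msi)

log = logging.getLogger("fibermsi")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run`. See the YAML example in the
    package README; every threshold printed in reports lives here."""

    input: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=lambda: {"k": 9, "seed": 42,
                                                        "denoise": True})
    registration: dict = field(default_factory=dict)
    stats: dict = field(default_factory=lambda: {
        "p_max": 0.05, "auc_min": 0.7, "vip_min": 1.0, "loading_min": 0.05})
    annotation: dict = field(default_factory=lambda: {"tol_ppm": 10.0})
    enrichment: dict = field(default_factory=lambda: {"n_perm": 499, "seed": 1})
    crossval: dict = field(default_factory=dict)

    def __post_init__(self):
        k = int(self.segmentation.get("k", 9))
        if k < 2:
            raise ValidationError("segmentation.k must be >= 2")
        for key, lo, hi in (("p_max", 0, 1), ("auc_min", 0.5, 1),
                            ("vip_min", 0, None), ("loading_min", 0, None)):
            v = self.stats.get(key)
            if v is not None and (v < lo or (hi is not None and v > hi)):
                raise ValidationError(f"stats.{key}={v} out of range")
        if float(self.annotation.get("tol_ppm", 10.0)) <= 0:
            raise ValidationError("annotation.tol_ppm must be positive")
        for section in ("input", "registration", "annotation",
                        "enrichment", "crossval"):
            cfg = getattr(self, section)
            for key, val in cfg.items():
                if key.endswith(("path", "csv", "gmt")) and val is not None:
                    if not Path(val).exists():
                        raise ValidationError(
                            f"{section}.{key}: path {val!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)


def _stage(name, func, outdir):
    log.info("stage %s", name)
    try:
        return func()
    except Exception as exc:
        (Path(outdir) / f"FAILED_{name}").write_text(str(exc))
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the configured pipeline; returns the report dictionary.

    The report only aggregates numbers already written by stage artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    report: dict = {"version": __version__}
    truth = None

    # ---- input ------------------------------------------------------------
    def load_input():
        nonlocal truth
        cfg = config.input
        if "synthetic" in cfg:
            s = dict(cfg["synthetic"])
            truth = make_phantom(width=int(s.get("width", 48)),
                                 height=int(s.get("height", 48)),
                                 layout=s.get("preset", "muscle"),
                                 seed=int(s.get("seed", 7)),
                                 rare_frac=float(s.get("rare_frac", 0.05)))
            datasets, truth = simulate_msi(
                truth, n_features=int(s.get("n_features", 60)),
                n_marker_per_class=int(s.get("n_marker_per_class", 5)),
                snr=float(s.get("snr", 4.0)),
                replicates=int(s.get("replicates", 1)),
                seed=int(s.get("seed", 7)))
            return datasets[0]
        paths = cfg.get("imzml_path") or cfg.get("imzml")
        if not paths:
            raise ValidationError("input needs 'synthetic' or 'imzml_path'")
        return read_imzml(paths if isinstance(paths, str) else paths[0])

    ds = _stage("input", load_input, outdir)
    report["n_pixels"] = len(ds)

    # ---- preprocess -------------------------------------------------------
    def preprocess():
        pcfg = PreprocessConfig(**config.preprocess)
        pt = dataset_to_peaktable(ds, pcfg)
        write_peaktable(pt, outdir / "peak_table.csv")
        return pt

    pt = _stage("preprocess", preprocess, outdir)
    report["n_features"] = pt.n_features

    # ---- segmentation -----------------------------------------------------
    def do_segment():
        scfg = config.segmentation
        seg = segment(pt, k=int(scfg.get("k", 9)), seed=int(scfg.get("seed", 42)),
                      denoise=bool(scfg.get("denoise", True)))
        merges = scfg.get("merges") or {}
        if merges:
            seg = merge_classes(seg, {int(a): int(b) for a, b in merges.items()})
        write_label_map(seg.labels, outdir / "segmentation_labels.csv")
        pd.DataFrame(seg.centroids,
                     index=[f"class_{i + 1}" for i in range(seg.k)],
                     columns=[f"{m:.4f}" for m in pt.feature_mz]
                     ).to_csv(outdir / "segmentation_centroids.csv")
        dendro = {"children": seg.dendrogram[:, :2].astype(int).tolist(),
                  "heights": seg.dendrogram[:, 2].tolist()}
        (outdir / "segmentation_dendrogram.json").write_text(
            json.dumps(dendro, indent=1))
        return seg

    seg = _stage("segmentation", do_segment, outdir)
    report["segmentation_k"] = seg.k
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        true_pix = truth.class_map.labels[pt.coords[:, 1], pt.coords[:, 0]]
        report["segmentation_ari"] = float(
            adjusted_rand_score(true_pix, seg.pixel_labels))

    # ---- co-registration (optional) ---------------------------------------
    fiber_map = None
    if config.registration:
        def register():
            rcfg = config.registration
            mask = read_label_map(rcfg["mask_path"])
            if "landmarks_csv" in rcfg:
                src, dst = read_landmarks(rcfg["landmarks_csv"])
                T = fit_landmarks(src, dst, model=rcfg.get("model", "similarity"))
            else:  # same-grid overlay
                T = fit_landmarks([[0, 0], [1, 0], [0, 1]],
                                  [[0, 0], [1, 0], [0, 1]])
            resampled = resample_mask(mask, T, seg.labels.labels.shape)
            write_label_map(resampled, outdir / "fiber_types_on_grid.csv")
            comp = composition(seg.labels, resampled)
            comp.counts.to_csv(outdir / "composition_counts.csv")
            comp.glyph_table().to_csv(outdir / "composition_scores.csv")
            return resampled
        fiber_map = _stage("registration", register, outdir)
    elif truth is not None:
        fiber_map = truth.class_map

    # ---- region statistics ------------------------------------------------
    def region_stats():
        scfg = config.stats
        labmap = fiber_map if fiber_map is not None else seg.labels
        lab_at_pix = labmap.labels[pt.coords[:, 1], pt.coords[:, 0]]
        classes = [c for c in np.unique(lab_at_pix) if c > 0]
        if len(classes) < 2:
            raise ValidationError("need two classes for differential stats")
        ca = int(scfg.get("class_a", classes[0]))
        cb = int(scfg.get("class_b", classes[1]))
        mask = np.isin(lab_at_pix, [ca, cb])
        M = pt.matrix[:, mask].T
        grp = lab_at_pix[mask]
        names = np.array([f"{m:.4f}" for m in pt.feature_mz])
        tt = ttest_features(M, grp, feature_names=names, group_a=ca, group_b=cb)
        au = auc_features(M, grp, positive_group=ca, feature_names=names,
                         threshold=float(scfg.get("auc_min", 0.7)))
        stats = tt.merge(au, on="feature")
        model = plsda(M, grp, n_components=2, feature_names=names)
        vip = pd.DataFrame({"feature": model.feature_names, "vip": model.vip,
                            "loading1": model.x_loadings[:, 0]})
        stats = stats.merge(vip, on="feature", how="left")
        stats.to_csv(outdir / "feature_stats.csv", index=False)
        biomarkers = select_biomarkers(model,
                                       vip_min=float(scfg.get("vip_min", 1.0)),
                                       loading_min=float(scfg.get("loading_min", 0.05)))
        pd.Series(biomarkers, name="feature").to_csv(
            outdir / "plsda_biomarkers.csv", index=False)
        means = class_mean_spectra(pt, labmap)
        pd.DataFrame(means, index=names).to_csv(outdir / "class_mean_spectra.csv")
        return stats, (ca, cb), mask, grp

    stats, contrast, pix_mask, pix_groups = _stage("stats", region_stats, outdir)
    report["contrast"] = list(contrast)
    report["n_significant"] = int((stats["p"] < config.stats.get("p_max", 0.05)).sum())
    report["n_discriminative"] = int(stats["discriminative"].sum())

    # ---- annotation -------------------------------------------------------
    def annotate():
        acfg = config.annotation
        if "db_csv" in acfg:
            db = read_metabolite_db(acfg["db_csv"])
        elif truth is not None:
            db = make_metabolite_db(truth.feature_mz, truth.feature_ids)
        else:
            return None
        ann = annotate_features(pt.feature_mz, db,
                                polarity=acfg.get("polarity", "positive"),
                                tol_ppm=float(acfg.get("tol_ppm", 10.0)))
        ann.to_csv(outdir / "annotations.csv", index=False)
        return ann

    annotations = _stage("annotation", annotate, outdir)
    if annotations is not None:
        report["n_annotated"] = int(annotations["feature_mz"].nunique())

    # ---- enrichment -------------------------------------------------------
    def enrich():
        ecfg = config.enrichment
        if "gmt" in ecfg:
            lib = read_gmt(ecfg["gmt"])
        elif truth is not None:
            lib = make_set_library(truth, seed=int(ecfg.get("seed", 1)))
        else:
            return None
        if annotations is None or annotations.empty:
            return None
        # map each feature to its best annotation id
        best = annotations.loc[
            annotations.groupby("feature_mz")["ppm_error"]
            .transform(lambda s: s.abs() == s.abs().min())]
        best = best.drop_duplicates("feature_mz")
        fnames = np.array([f"{m:.4f}" for m in pt.feature_mz])
        mz_to_id = {f"{m:.4f}": i for m, i in
                    zip(best["feature_mz"], best["metabolite_id"])}
        keep = [i for i, f in enumerate(fnames) if f in mz_to_id]
        # testing every pixel would treat thousands of correlated spectra as
        # independent replicates; draw a fixed-size seeded sample per class
        # instead, keeping pixel-level variability in the test
        n_sample = int(ecfg.get("pixels_per_group", 20))
        rng = np.random.default_rng(int(ecfg.get("seed", 1)))
        X = pt.matrix[keep][:, pix_mask].T
        sel, sel_groups = [], []
        for g in np.unique(pix_groups):
            idx = np.flatnonzero(pix_groups == g)
            take = rng.choice(idx, size=min(n_sample, len(idx)), replace=False)
            sel.extend(take)
            sel_groups.extend([g] * len(take))
        M = pd.DataFrame(X[sel], columns=[mz_to_id[fnames[i]] for i in keep])
        res = qea(M, np.asarray(sel_groups), lib,
                  n_perm=int(ecfg.get("n_perm", 499)),
                  seed=int(ecfg.get("seed", 1)))
        res.to_csv(outdir / "enrichment.csv", index=False)
        return res

    enr = _stage("enrichment", enrich, outdir)
    if enr is not None:
        report["enriched_sets"] = enr.loc[enr["p_bonf"] < 0.05, "set"].tolist()

    # ---- LC-MS cross-validation (optional) --------------------------------
    if config.crossval:
        def crossval():
            ccfg = config.crossval
            table = load_lcms(ccfg["lcms_csv"], ccfg["groups"])
            sig = differential_lcms(table, p_max=float(
                config.stats.get("p_max", 0.05)))
            sig.to_csv(outdir / "lcms_differential.csv", index=False)
            msi_ids = (set(annotations["metabolite_id"])
                       if annotations is not None else set())
            ov = venn(msi_ids, set(sig["feature"]))
            (outdir / "venn.json").write_text(json.dumps(
                {"only_msi": sorted(ov.only_a), "only_lcms": sorted(ov.only_b),
                 "both": sorted(ov.both), "counts": ov.counts}, indent=1))
            return ov
        ov = _stage("crossval", crossval, outdir)
        report["venn_counts"] = ov.counts

    # ---- manifest ---------------------------------------------------------
    manifest = {"config": asdict(config), "report": report}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         default=str))
    return report
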