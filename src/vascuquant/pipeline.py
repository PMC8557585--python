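"""Study-level workflow: synthesize -> quantify SMI -> quantify IHC -> stats.

A *study* is a directory with one sub-directory per patient (sonogram frames,
ROI annotations, micrographs, sampling-field annotations), a cohort CSV, and
a ``study.yaml`` configuration that ties them together.  The functions here
are the programmatic pipeline; the ``vascuquant`` command wraps them.

All outputs are deterministic for a fixed configuration and seed; every table
carries a header comment with the seed and a configuration hash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .ihc import (Cd34Profile, SamplingRect, StainMatrix, cd34_fraction,
                  cd34_summary, rgb_to_od, unmix)
from .records import cohort_to_frame
from .roi import RoiPolygon
from .smi import PROFILE_FIELDS, ThresholdRule, compute_profile
from .stats import (correlation_frame, correlation_table, group_summary,
                    partial_spearman, wilcoxon_rank_sum)
from .synth import CohortSpec, IhcSceneSpec, SmiSceneSpec, generate_cohort, \
    generate_ihc_scene, generate_smi_scene

log = logging.getLogger("vascuquant")

CD34_FIELDS = ("cd34_100_fold", "cd34_25_fold", "cd34_all")

# default geometry of synthesized studies
_SMI_SHAPE = (160, 220)
_NODE_RECT = ((30.0, 30.0), (90.0, 100.0))
_PAR_RECT = ((30.0, 130.0), (90.0, 200.0))
_IHC_SHAPE = (240, 240)
_FIELDS_100X = [(10, 10), (10, 130), (130, 10), (130, 130)]
_FIELD_SIZE_100X = 100
_FIELD_25X = ((20, 20), 200)


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg["_base_dir"] = str(Path(path).parent)
    return cfg


def _resolve(cfg: Mapping[str, Any], relpath: str) -> Path:
    return Path(cfg.get("_base_dir", ".")) / relpath


def _threshold_rule(cfg: Mapping[str, Any]) -> ThresholdRule:
    tc = cfg.get("threshold", {"method": "isodata"})
    if tc.get("method") == "fixed":
        return ThresholdRule.fixed(int(tc["value"]))
    return ThresholdRule.isodata()


def _stain_matrix(cfg: Mapping[str, Any]) -> StainMatrix:
    sc = cfg.get("stain_matrix")
    if not sc:
        return StainMatrix()
    return StainMatrix(hematoxylin=tuple(sc["hematoxylin"]),
                       fast_red=tuple(sc["fast_red"]))


# ---------------------------------------------------------------------------
# synthesis

def synthesize_study(out_dir: str | Path, seed: int,
                     cohort_spec: CohortSpec | None = None,
                     speckle_sd: float = 8.0,
                     noise_od_sd: float = 0.0,
                     parenchyma_fraction: float = 0.15) -> Path:
    """Write a complete synthetic study directory; returns the config path.

    Per patient the generated SMI node/parenchyma vessel fractions are chosen
    so their ratio equals the cohort record's quotient (clipped to [0, 0.9]),
    and the IHC vessel fraction equals the record's CD34 fraction, so the
    downstream pipeline can be validated against the cohort table.  Exact
    per-field ground-truth fractions are written to ``ground_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(seed)
    if cohort_spec is None:
        cohort_spec = CohortSpec(seed=base_seed)
    records = generate_cohort(cohort_spec)
    seeder = np.random.default_rng(base_seed + 1)

    node_roi_l = RoiPolygon(_NODE_RECT, role="node_A", plane="longitudinal")
    node_roi_c = RoiPolygon(_NODE_RECT, role="node_A", plane="cross")
    par_roi_l = RoiPolygon(_PAR_RECT, role="parenchyma_B", plane="longitudinal")
    par_roi_c = RoiPolygon(_PAR_RECT, role="parenchyma_B", plane="cross")
    tot_node = RoiPolygon(_NODE_RECT, role="total_node", plane="longitudinal")
    tot_par = RoiPolygon(_PAR_RECT, role="total_parenchyma",
                         plane="longitudinal")

    patients_cfg = []
    gt_rows = []
    for rec in records:
        pdir = out / rec.patient_id
        pdir.mkdir(exist_ok=True)
        node_frac = float(np.clip(rec.quotient * parenchyma_fraction, 0.0, 0.9))

        frame_names = {"longitudinal": ["smi_long_1.png", "smi_long_2.png"],
                       "cross": ["smi_cross_1.png", "smi_cross_2.png"],
                       "total": ["smi_total.png"]}
        for names in frame_names.values():
            for name in names:
                scene = SmiSceneSpec(
                    image_height_px=_SMI_SHAPE[0],
                    image_width_px=_SMI_SHAPE[1],
                    node_polygon=node_roi_l,
                    parenchyma_polygon=par_roi_l,
                    node_vessel_fraction=node_frac,
                    parenchyma_vessel_fraction=parenchyma_fraction,
                    speckle_sd=speckle_sd,
                    seed=int(seeder.integers(2 ** 31)))
                image, _ = generate_smi_scene(scene)
                vio.write_image(pdir / name, image)
        vio.write_rois(pdir / "rois.json",
                       [node_roi_l, node_roi_c, par_roi_l, par_roi_c,
                        tot_node, tot_par])

        # IHC: one 100x and one 25x micrograph, vessel fraction = CD34 outcome
        fields_100x = [SamplingRect(top_left=tl, height_px=_FIELD_SIZE_100X,
                                    width_px=_FIELD_SIZE_100X,
                                    magnification="x100")
                       for tl in _FIELDS_100X]
        field_25x = SamplingRect(top_left=_FIELD_25X[0],
                                 height_px=_FIELD_25X[1],
                                 width_px=_FIELD_25X[1], magnification="x25")
        gt_frac: dict[str, float] = {}
        for mag, name in (("x100", "ihc_100x.png"), ("x25", "ihc_25x.png")):
            scene = IhcSceneSpec(
                image_height_px=_IHC_SHAPE[0], image_width_px=_IHC_SHAPE[1],
                vessel_mask_fraction=rec.cd34_fraction,
                noise_od_sd=noise_od_sd, magnification=mag,
                seed=int(seeder.integers(2 ** 31)))
            rgb, truth = generate_ihc_scene(scene)
            vio.write_image(pdir / name, rgb)
            mask = truth["vessel_mask"]
            if mag == "x100":
                for i, rect in enumerate(fields_100x):
                    sub = mask[rect.slices()]
                    gt_frac[f"gt_100x_{i}"] = float(sub.sum()) / rect.pixel_count
            else:
                sub = mask[field_25x.slices()]
                gt_frac["gt_25x"] = float(sub.sum()) / field_25x.pixel_count
        vio.write_fields(pdir / "fields.json", fields_100x, field_25x)

        gt100 = [gt_frac[f"gt_100x_{i}"] for i in range(4)]
        gt_profile = cd34_summary(gt100, gt_frac["gt_25x"])
        gt_rows.append({"patient_id": rec.patient_id, **gt_frac,
                        **{f"gt_{k}": v for k, v in
                           gt_profile.as_dict().items()}})

        patients_cfg.append({
            "patient_id": rec.patient_id,
            "smi": {"longitudinal": [f"{rec.patient_id}/{n}" for n in
                                     frame_names["longitudinal"]],
                    "cross": [f"{rec.patient_id}/{n}" for n in
                              frame_names["cross"]],
                    "total": f"{rec.patient_id}/smi_total.png",
                    "rois": f"{rec.patient_id}/rois.json"},
            "ihc": {"image_100x": f"{rec.patient_id}/ihc_100x.png",
                    "image_25x": f"{rec.patient_id}/ihc_25x.png",
                    "fields": f"{rec.patient_id}/fields.json"},
        })

    cohort = cohort_to_frame(records)
    vio.write_table(out / "cohort.csv", cohort, seed=base_seed, cfg_hash="synth")
    vio.write_table(out / "ground_truth.csv", pd.DataFrame(gt_rows),
                    seed=base_seed, cfg_hash="synth")

    config = {
        "seed": base_seed,
        "threshold": {"method": "fixed", "value": 100},
        "positive_threshold": 0.15,
        "stats_mode": "auto",
        "cohort_csv": "cohort.csv",
        "patients": patients_cfg,
    }
    cfg_path = out / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path


# ---------------------------------------------------------------------------
# quantification stages

_ROLE_KEYS = {("node_A", "longitudinal"): "A_long",
              ("node_A", "cross"): "A_cross",
              ("parenchyma_B", "longitudinal"): "B_long",
              ("parenchyma_B", "cross"): "B_cross"}


def _roi_map(rois: list[RoiPolygon]) -> dict[str, RoiPolygon]:
    mapping: dict[str, RoiPolygon] = {}
    for roi in rois:
        if roi.role in ("total_node", "total_parenchyma"):
            mapping[roi.role] = roi
        else:
            key = _ROLE_KEYS.get((roi.role, roi.plane))
            if key:
                mapping[key] = roi
    return mapping


def run_smi(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Quantify every patient's sonograms; writes ``profiles.csv``.

    Per-patient failures (missing files, degenerate ROIs) are logged and
    recorded in ``smi_errors.json``; the run continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rule = _threshold_rule(config)
    rows, errors = [], {}
    for pat in config.get("patients", []):
        pid = pat["patient_id"]
        try:
            sm = pat["smi"]
            images = {
                "longitudinal": [vio.read_gray_image(_resolve(config, p))
                                 for p in sm["longitudinal"]],
                "cross": [vio.read_gray_image(_resolve(config, p))
                          for p in sm["cross"]],
                "total": vio.read_gray_image(_resolve(config, sm["total"])),
            }
            rois = _roi_map(vio.read_rois(_resolve(config, sm["rois"])))
            profile = compute_profile(images, rois, rule)
            rows.append({"patient_id": pid, **profile.as_dict()})
            log.info("smi %s: rois=%d threshold=%s", pid, len(rois), rule)
        except (OSError, ValueError, KeyError) as exc:
            log.error("smi %s failed: %s", pid, exc)
            errors[pid] = str(exc)
    frame = pd.DataFrame(rows, columns=["patient_id", *PROFILE_FIELDS])
    path = out / "profiles.csv"
    vio.write_table(path, frame, seed=config.get("seed"),
                    cfg_hash=vio.config_hash({k: v for k, v in config.items()
                                              if not k.startswith("_")}))
    if errors:
        (out / "smi_errors.json").write_text(json.dumps(errors, indent=1))
    return path


def run_ihc(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Quantify every patient's CD34 micrographs; writes ``cd34.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stains = _stain_matrix(config)
    thr = float(config.get("positive_threshold", 0.15))
    rows, errors = [], {}
    for pat in config.get("patients", []):
        pid = pat["patient_id"]
        try:
            ih = pat["ihc"]
            fields_100x, field_25x = vio.read_fields(
                _resolve(config, ih["fields"]))
            img100 = vio.read_rgb_image(_resolve(config, ih["image_100x"]))
            img25 = vio.read_rgb_image(_resolve(config, ih["image_25x"]))
            fr100 = unmix(rgb_to_od(img100), stains)[..., 1]
            fr25 = unmix(rgb_to_od(img25), stains)[..., 1]
            f100 = [cd34_fraction(fr100, rect, thr) for rect in fields_100x]
            f25 = cd34_fraction(fr25, field_25x, thr)
            profile = cd34_summary(f100, f25)
            rows.append({"patient_id": pid, **profile.as_dict()})
        except (OSError, ValueError, KeyError) as exc:
            log.error("ihc %s failed: %s", pid, exc)
            errors[pid] = str(exc)
    frame = pd.DataFrame(rows, columns=["patient_id", *CD34_FIELDS])
    path = out / "cd34.csv"
    vio.write_table(path, frame, seed=config.get("seed"),
                    cfg_hash=vio.config_hash({k: v for k, v in config.items()
                                              if not k.startswith("_")}))
    if errors:
        (out / "ihc_errors.json").write_text(json.dumps(errors, indent=1))
    return path


# ---------------------------------------------------------------------------
# statistics stage

def _summary_rows(frame: pd.DataFrame, params: tuple[str, ...],
                  mode: str) -> pd.DataFrame:
    rows = []
    for param in params:
        if param not in frame.columns:
            continue
        values = frame[param].to_numpy(dtype=float)
        labels = frame["label"].tolist()
        summ = group_summary(values, labels)
        row: dict[str, Any] = {"parameter": param}
        for grp in ("benign", "malignant"):
            s = summ.get(grp, {"n": 0, "mean": np.nan, "sd": np.nan,
                               "median": np.nan, "min": np.nan, "max": np.nan})
            row.update({f"{grp}_{k}": s[k] for k in
                        ("n", "mean", "sd", "median", "min", "max")})
        x = values[np.asarray(labels) == "benign"]
        y = values[np.asarray(labels) == "malignant"]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size and y.size:
            res = wilcoxon_rank_sum(x, y, mode=mode)
            row.update({"p_value": res.p_value, "test": res.method,
                        "n_used": res.n_used})
        else:
            row.update({"p_value": np.nan, "test": "undefined", "n_used": 0})
        rows.append(row)
    return pd.DataFrame(rows)


def run_stats(profiles_csv: str | Path, cd34_csv: str | Path,
              cohort_csv: str | Path, out_dir: str | Path,
              mode: str = "auto", seed: int | None = None) -> dict[str, Any]:
    """Merge the stage outputs and emit the three study tables plus a report.

    ``table2.csv``: SMI parameter group summaries + rank-sum p-values;
    ``table3.csv``: the same for the CD34 fractions; ``table4.csv``: the
    Spearman correlation of every (SMI, CD34) parameter pair.  The JSON run
    report records per-cell n, exclusions, unmatched patients, and the
    partial Spearman of the headline pair controlling age and BMI.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = vio.read_table(profiles_csv)
    cd34 = vio.read_table(cd34_csv)
    cohort = vio.read_table(cohort_csv)

    merged = cohort.merge(profiles, on="patient_id", how="inner",
                          suffixes=("", "_smi"))
    merged = merged.merge(cd34, on="patient_id", how="inner",
                          suffixes=("", "_ihc"))
    unmatched = sorted(set(cohort["patient_id"])
                       .symmetric_difference(merged["patient_id"]))

    wilcoxon_mode = "auto" if mode in ("auto", "exact") else mode
    table2 = _summary_rows(merged, PROFILE_FIELDS, wilcoxon_mode)
    table3 = _summary_rows(merged, CD34_FIELDS, wilcoxon_mode)
    smi_present = tuple(p for p in PROFILE_FIELDS if p in merged.columns)
    table = correlation_table(merged, smi_present, CD34_FIELDS, mode=mode)
    table4 = correlation_frame(table)

    cfg_hash = vio.config_hash({"profiles": Path(profiles_csv).name,
                                "cd34": Path(cd34_csv).name,
                                "cohort": Path(cohort_csv).name, "mode": mode})
    vio.write_table(out / "table2.csv", table2, seed=seed, cfg_hash=cfg_hash)
    vio.write_table(out / "table3.csv", table3, seed=seed, cfg_hash=cfg_hash)
    vio.write_table(out / "table4.csv", table4, seed=seed, cfg_hash=cfg_hash)

    report: dict[str, Any] = {
        "seed": seed,
        "config_hash": cfg_hash,
        "n_patients": int(len(merged)),
        "unmatched_patient_ids": unmatched,
        "cells": {f"{sp}|{cp}": {"n_used": res.n_used,
                                 "missing_excluded": res.missing_excluded}
                  for (sp, cp), res in table.items()},
    }
    # headline pair controlling age and BMI, as in the study's partial analysis
    key_smi = "quotient_longitudinal_area_fraction"
    if key_smi in merged.columns and len(merged) >= 6:
        res = partial_spearman(merged[key_smi], merged["cd34_100_fold"],
                               merged[["age", "bmi"]].to_numpy())
        report["partial_spearman_age_bmi"] = {
            "pair": [key_smi, "cd34_100_fold"],
            "r": None if np.isnan(res.statistic) else res.statistic,
            "p_value": None if np.isnan(res.p_value) else res.p_value,
            "n_used": res.n_used}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def run_all(config_path: str | Path, out_dir: str | Path) -> dict[str, Any]:
    """smi + ihc + stats for an existing study configuration."""
    config = load_config(config_path)
    out = Path(out_dir)
    profiles = run_smi(config, out)
    cd34 = run_ihc(config, out)
    cohort = _resolve(config, config["cohort_csv"])
    return run_stats(profiles, cd34, cohort, out,
                     mode=config.get("stats_mode", "auto"),
                     seed=config.get("seed"))
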