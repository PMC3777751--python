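"""End-to-end orchestration: simulate -> preprocess -> quantify -> clean ->
PVC/ROI -> statistics, with config, logging, caching, and provenance.

The pipeline always simulates the cohort covariate/biomarker table.  For a
configurable number of subjects it additionally simulates the full image
chain: a subject-specific phantom whose meta-ROI territory perfusion is set
from the subject's true biomarker value, pushed through preprocessing,
quantification, adaptive cleaning, partial-volume correction, and ROI
extraction; the measured ROI means then replace the table's values and
subjects failing image-level QC are excluded from the statistics.

Every run writes a manifest (seed, config hash, package versions) and an
audit log with one line per removed CBF time point and its correlation.
Stage outputs are cached by config hash; ``force`` recomputes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import (
    CohortSpec,
    PhantomSpec,
    make_ground_truth,
    phantom_roi_specs,
    simulate_cohort,
    simulate_subject_series,
)
from .preprocess import make_brain_mask, preprocess_series
from .pvc import load_roi_specs, pve_correct, roi_mean_cbf, sphere_mask
from .qc import run_qc
from .quantify import QuantParams, quantify_series
from .stats import group_model, partial_correlation, stepwise_hierarchical
from .types import save_volume

log = logging.getLogger("aslprodrome.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "aslprodrome_out"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    quant: QuantParams = field(default_factory=QuantParams)
    image_subjects: int = 0  # subjects simulated at image level (0 = table only)
    corrupt_subjects: int = 0  # image subjects given a QC-failing corruption
    fwhm_mm: float = 4.0
    cutoff_hz: float = 0.01
    do_motion_correct: bool = True
    gm_threshold: float = 0.5
    pvc_wm_ratio: float = 0.4
    pvc_gm_floor: float = 0.3
    cc_floor: float = 0.15
    cc_k_sd: float = 2.0
    fd_threshold_mm: float = 1.5
    initial_k_sd: float = 2.5
    roi_config: str | None = None  # YAML path; default: phantom-space ROIs
    force: bool = False

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("force", None)
        payload.pop("out_dir", None)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        text = json.dumps(clean(payload), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for key in ("grid_shape", "voxel_size"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            if "outlier_schedule" in ph:
                ph["outlier_schedule"] = tuple(
                    (int(i), str(k)) for i, k in ph["outlier_schedule"]
                )
            kwargs["phantom"] = PhantomSpec(**ph)
        if "quant" in kwargs:
            kwargs["quant"] = QuantParams(**kwargs["quant"])
        return cls(**kwargs)


def _subject_cbf_map(base_cbf, meta_mask, ctrl_factor, meta_factor):
    """Scale the baseline CBF map: the meta-ROI territory follows the
    subject's (possibly reduced) perfusion, everywhere else the subject's
    group-independent global level."""
    out = base_cbf * ctrl_factor
    out[meta_mask] = base_cbf[meta_mask] * meta_factor
    return out


def _corrupt_series(series, kind: str):
    """Inject a subject-level QC failure: 'coverage' zeroes the bottom 40 %
    of slices in every volume; 'negativity' swaps label and control frames
    so quantified CBF turns negative."""
    data = series.data.copy()
    if kind == "coverage":
        nz = data.shape[2]
        data[:, :, : int(0.4 * nz), :] = 0.0
        return series.copy_with(data)
    if kind == "negativity":
        out = data.copy()
        for lab, ctl in series.pair_indices:
            out[..., lab], out[..., ctl] = data[..., ctl], data[..., lab]
        return series.copy_with(out)
    raise ValueError(f"unknown corruption kind {kind!r}")


def _process_image_subject(
    cfg: PipelineConfig,
    phantom_spec: PhantomSpec,
    truth,
    roi_masks: dict[str, np.ndarray],
    gm_mask: np.ndarray,
    subject_dir: Path,
    corruption: str | None,
) -> dict:
    series = simulate_subject_series(phantom_spec, truth, params=cfg.quant)
    if corruption:
        series = _corrupt_series(series, corruption)
    series, motion, brain_mask = preprocess_series(
        series,
        truth.tissue,
        fwhm_mm=cfg.fwhm_mm,
        cutoff_hz=cfg.cutoff_hz,
        do_motion_correct=cfg.do_motion_correct,
    )
    cbf = quantify_series(series, params=cfg.quant)
    report, final_map = run_qc(
        cbf,
        gm_mask,
        brain_mask,
        motion=motion,
        series=series,
        fd_threshold_mm=cfg.fd_threshold_mm,
        initial_k_sd=cfg.initial_k_sd,
        cc_floor=cfg.cc_floor,
        k_sd=cfg.cc_k_sd,
        coverage_mask=truth.tissue.total > 0.5,
    )
    for idx in report.removed_indices():
        log.info(
            "removed CBF time point %d (CC=%.3f)", idx, report.cc_per_map[idx]
        )
    corrected, included = pve_correct(
        final_map, truth.tissue, wm_ratio=cfg.pvc_wm_ratio, gm_floor=cfg.pvc_gm_floor
    )
    subject_dir.mkdir(parents=True, exist_ok=True)
    save_volume(subject_dir / "cbf_final.nii.gz", final_map, series.affine)
    report.to_json(subject_dir / "qc_report.json")
    np.savetxt(subject_dir / "motion_params.tsv", motion, delimiter="\t")
    qc_pass = bool(report.coverage_ok) and bool(report.negativity_ok)
    out = {"qc_pass": qc_pass, "n_removed": report.n_removed_total}
    if qc_pass:
        for name, mask in roi_masks.items():
            out[f"{name}_roi_cbf"] = roi_mean_cbf(corrected, mask, gm_mask, included)
    return out


def run_stats(table: pd.DataFrame) -> dict:
    """The statistical battery on the surviving cohort rows."""
    used = table[table["qc_pass"]].copy()
    if used["group"].astype(str).nunique() < 2:
        raise ValueError("fewer than 2 groups survive QC; statistics aborted")
    results: dict = {"n_used": int(len(used))}
    for outcome in ("meta_roi_cbf", "control_roi_cbf", "hippo_norm"):
        gm = group_model(used, outcome)
        results[outcome] = dataclasses.asdict(gm)
    cov = used[["age", "education"]].to_numpy(dtype=float)
    for predictor in ("meta_roi_cbf", "hippo_norm"):
        r, p = partial_correlation(
            used[predictor].to_numpy(dtype=float),
            used["cdr_sb"].to_numpy(dtype=float),
            cov,
        )
        results[f"partial_r_cdr_{predictor}"] = {"r": r, "p": p}
    sw = stepwise_hierarchical(used, outcome="cdr_sb")
    results["stepwise_cdr"] = dataclasses.asdict(sw)
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns a summary dict with the cohort table path, stats, and QC
    exclusion bookkeeping.  A cached result (same config hash) is reused
    unless ``force``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists() and not config.force:
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash:
            log.info("cached run found (hash %s); skipping recompute", chash)
            stats = json.loads((out / "stats.json").read_text())
            return {
                "cohort_csv": str(out / "cohort.csv"),
                "stats": stats,
                "manifest": manifest,
                "cached": True,
            }

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        rng = np.random.default_rng(config.seed)
        cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
        table = simulate_cohort(cohort_spec)
        log.info("simulated cohort: %d subjects", len(table))

        failures: list[dict] = []
        n_excluded = 0
        if config.image_subjects > 0:
            base_spec = dataclasses.replace(config.phantom, seed=config.seed)
            truth0 = make_ground_truth(base_spec)
            if config.roi_config:
                rois = load_roi_specs(config.roi_config)
            else:
                rois = phantom_roi_specs(base_spec)
            roi_masks = {
                r.name: sphere_mask(r, tuple(base_spec.grid_shape), base_spec.affine)
                for r in rois
            }
            meta_mask = roi_masks["meta"]
            gm_mask = truth0.tissue.gm > config.gm_threshold
            n_img = min(config.image_subjects, len(table))
            img_rows = rng.choice(len(table), size=n_img, replace=False)
            corrupt_rows = set(
                int(i)
                for i in rng.choice(
                    img_rows, size=min(config.corrupt_subjects, n_img), replace=False
                )
            )
            child_seeds = rng.integers(0, 2**31 - 1, size=n_img)
            for j, row_i in enumerate(img_rows):
                row = table.iloc[int(row_i)]
                sid = row["subject_id"]
                meta_factor = row["meta_roi_cbf_true"] / base_spec.gm_cbf_true
                ctrl_factor = row["control_roi_cbf"] / base_spec.gm_cbf_true
                cbf_map = _subject_cbf_map(
                    truth0.cbf_map, meta_mask, ctrl_factor, meta_factor
                )
                truth = dataclasses.replace(truth0, cbf_map=cbf_map)
                subj_spec = dataclasses.replace(
                    base_spec, seed=int(child_seeds[j])
                )
                corruption = None
                if int(row_i) in corrupt_rows:
                    kind_i = sorted(corrupt_rows).index(int(row_i))
                    corruption = "coverage" if kind_i % 2 == 0 else "negativity"
                try:
                    res = _process_image_subject(
                        config,
                        subj_spec,
                        truth,
                        roi_masks,
                        gm_mask,
                        out / "subjects" / str(sid),
                        corruption,
                    )
                except Exception as exc:  # per-subject failure; continue
                    log.error("subject %s failed: %s", sid, exc)
                    failures.append({"subject_id": str(sid), "error": str(exc)})
                    table.loc[table.index[int(row_i)], "qc_pass"] = False
                    n_excluded += 1
                    continue
                idx = table.index[int(row_i)]
                table.loc[idx, "qc_pass"] = res["qc_pass"]
                if res["qc_pass"]:
                    table.loc[idx, "meta_roi_cbf"] = res["meta_roi_cbf"]
                    table.loc[idx, "control_roi_cbf"] = res["control_roi_cbf"]
                else:
                    n_excluded += 1
                    log.info("subject %s excluded by image QC", sid)

        cohort_csv = out / "cohort.csv"
        table.to_csv(cohort_csv, index=False)
        stats = run_stats(table)
        (out / "stats.json").write_text(json.dumps(stats, indent=2, default=str))

        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config_hash": chash,
            "n_subjects": int(len(table)),
            "n_image_subjects": int(min(config.image_subjects, len(table))),
            "n_excluded": int(n_excluded),
            "failures": failures,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return {
            "cohort_csv": str(cohort_csv),
            "stats": stats,
            "manifest": manifest,
            "cached": False,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
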