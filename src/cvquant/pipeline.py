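"""End-to-end orchestration: manifest in, metrics table and stats report out.

A run processes every manifest row through the fixed chain
denoise -> top-hat -> local-phase -> active-contour segmentation -> ROI crop
-> skeleton metrics, assembles the study table, runs the statistical stage,
and persists all intermediates plus a machine-readable run log.  Re-running
with an identical config and seed reproduces byte-identical CSV outputs.

Exit status convention (used by the CLI): 0 full success, 2 partial
(some images failed and were skipped), 1 fatal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cvio
from .metrics import compute_metrics, skeletonize
from .preprocess import enhance_chain
from .segment import IPACParams, crop_roi, ipac_segment
from .stats import (cytokine_matrix, group_change_tests, leakage_regression,
                    stage_contrasts)
from .synthetic import RenderParams, StudyConfig, generate_study
from .types import ROIPolygon

__all__ = ["RunConfig", "run_pipeline", "write_synthetic_inputs", "default_config"]

log = logging.getLogger(__name__)

MANIFEST_BASE_COLUMNS = ["image_path", "roi_path", "eye", "week", "arm",
                         "stage", "leakage_s"]


def default_config() -> dict:
    """Default parameter blocks for every stage, YAML-serializable."""
    return {
        "seed": 0,
        "preprocess": {"median_window": 3, "gaussian_sigma": 1.0,
                       "struct_radius": 8, "scales": [4, 8, 16], "orientations": 6},
        "segment": dataclasses.asdict(IPACParams()),
        "metrics": {"method": "zhang"},
        "stats": {"pre_week": 2, "post_week": 4,
                  "arms": ["aflibercept", "saline"]},
        "synth": {"frame": [128, 128], "speckle_shape": 20.0},
    }


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration: manifest, output dir, parameter blocks."""

    manifest: Path
    outdir: Path
    params: dict = dataclasses.field(default_factory=default_config)

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.outdir = Path(self.outdir)
        base = default_config()
        merged = {**base, **(self.params or {})}
        for key, block in base.items():
            if isinstance(block, dict):
                merged[key] = {**block, **(merged.get(key) or {})}
        self.params = merged

    @property
    def seed(self) -> int:
        return int(self.params.get("seed", 0))


def write_synthetic_inputs(outdir: str | Path, seed: int = 0,
                           frame: tuple[int, int] = (128, 128),
                           speckle_shape: float = 20.0,
                           arm_sizes: dict[str, int] | None = None,
                           visit_weeks: list[float] | None = None) -> Path:
    """Generate a rendered synthetic study and write it as pipeline inputs.

    Produces per-record TIFF angiograms, ground-truth mask PNGs, a shared
    full-frame ROI JSON and a manifest CSV; returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    cfg_kwargs = {}
    if arm_sizes:
        cfg_kwargs["arm_sizes"] = arm_sizes
    if visit_weeks is not None:
        cfg_kwargs["visit_weeks"] = visit_weeks
        ntraj = len(visit_weeks)
        base = StudyConfig()
        cfg_kwargs["trajectory_means"] = {
            arm: means[:ntraj] for arm, means in base.trajectory_means.items()}
    config = StudyConfig(seed=seed, render=True, frame=frame,
                         render_params=RenderParams(speckle_shape=speckle_shape),
                         **cfg_kwargs)
    records, fixtures = generate_study(config)

    roi = ROIPolygon.full_frame(frame)
    roi_path = outdir / "roi.json"
    cvio.write_roi(roi, roi_path)

    cyto_names = list(records[0].cytokines) if records else []
    rows = []
    for rec in records:
        tree, img = fixtures[(rec.eye, rec.week)]
        stem = f"{rec.eye}_w{rec.week:g}"
        img_path = outdir / "images" / f"{stem}.tif"
        cvio.write_angiogram(img, img_path)
        cvio.write_mask(tree.mask, outdir / "images" / f"{stem}_truth.png")
        row = {"image_path": str(img_path), "roi_path": str(roi_path),
               "eye": rec.eye, "week": rec.week, "arm": rec.arm,
               "stage": rec.stage, "leakage_s": rec.leakage_s}
        for name in cyto_names:
            row[name] = rec.cytokines.get(name, float("nan"))
        rows.append(row)
    manifest = outdir / "manifest.csv"
    cvio.write_table(pd.DataFrame(rows), manifest, config_hash="synthetic", seed=seed)
    return manifest


def process_image(image_path: str | Path, roi_path: str | Path | None,
                  params: dict):
    """Run one image through the full per-image chain; returns
    ``(cropped_map, skeleton, metrics_free_map_state)`` pieces used by the
    pipeline and the CLI subcommands."""
    img = cvio.read_image(image_path)
    pp = params.get("preprocess", {})
    den, _th, phase = enhance_chain(
        img,
        median_window=int(pp.get("median_window", 3)),
        gaussian_sigma=float(pp.get("gaussian_sigma", 1.0)),
        struct_radius=int(pp.get("struct_radius", 8)),
        scales=tuple(pp.get("scales", (4, 8, 16))),
        orientations=int(pp.get("orientations", 6)),
    )
    seg_kwargs = {k: v for k, v in (params.get("segment") or {}).items()
                  if k in IPACParams.__dataclass_fields__}
    vmap, state = ipac_segment(phase, den, IPACParams(**seg_kwargs))
    if roi_path:
        roi = cvio.read_roi(roi_path)
    else:
        roi = ROIPolygon.full_frame(vmap.shape)
    cropped = crop_roi(vmap, roi)
    skel = skeletonize(cropped, method=params.get("metrics", {}).get("method", "zhang"))
    return img, cropped, skel, state


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline for one run configuration.

    Returns a summary dict with ``exit_code`` (0/2/1), the metrics table
    path, per-image failures, and the stats report path.
    """
    outdir = config.outdir
    (outdir / "intermediate").mkdir(parents=True, exist_ok=True)
    chash = cvio.config_hash(config.params)

    try:
        manifest = cvio.read_table(config.manifest)
    except Exception as exc:  # noqa: BLE001
        log.error("cannot read manifest %s: %s", config.manifest, exc)
        return {"exit_code": 1, "error": str(exc)}
    missing = [c for c in ("image_path",) if c not in manifest.columns]
    if missing:
        return {"exit_code": 1, "error": f"manifest lacks columns {missing}"}

    cyto_cols = [c for c in manifest.columns if c not in MANIFEST_BASE_COLUMNS]
    rows = []
    failures = []
    for _, mrow in manifest.iterrows():
        stem = Path(str(mrow["image_path"])).stem
        try:
            _img, cropped, skel, state = process_image(
                mrow["image_path"], mrow.get("roi_path"), config.params)
            m = compute_metrics(cropped,
                                method=config.params["metrics"]["method"],
                                eye=str(mrow.get("eye")), week=mrow.get("week"),
                                arm=str(mrow.get("arm")))
            cvio.write_mask(cropped, outdir / "intermediate" / f"{stem}_mask.png")
            cvio.write_mask(skel, outdir / "intermediate" / f"{stem}_skel.png")
            row = {"eye": mrow.get("eye"), "week": mrow.get("week"),
                   "arm": mrow.get("arm"), "VD": m.vd, "VBA": m.vba,
                   "VW": m.vw, "roi_px": m.roi_px,
                   "stage": mrow.get("stage"), "leakage_s": mrow.get("leakage_s"),
                   "converged": state.converged}
            for c in cyto_cols:
                row[c] = mrow.get(c)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001
            log.error("image %s failed: %s", mrow["image_path"], exc)
            failures.append({"image": str(mrow["image_path"]), "error": str(exc)})

    metrics_path = outdir / "metrics.csv"
    df = pd.DataFrame(rows)
    cvio.write_table(df, metrics_path, config_hash=chash, seed=config.seed)

    stats_out = analyze_table(df, config.params, outdir, chash, config.seed) if len(df) else {}

    run_log = {
        "config_hash": chash, "seed": config.seed,
        "n_images": int(len(manifest)), "n_processed": len(rows),
        "failures": failures, "artifacts": {
            "metrics_csv": str(metrics_path), **stats_out,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)

    exit_code = 0 if not failures else (2 if rows else 1)
    return {"exit_code": exit_code, "metrics_csv": str(metrics_path),
            "failures": failures, **stats_out}


def analyze_table(df: pd.DataFrame, params: dict, outdir: Path,
                  chash: str, seed: int) -> dict:
    """Statistical stage on an assembled study table; writes report files."""
    sp = params.get("stats", {})
    report: dict = {}
    lines: list[str] = [f"cvquant analysis report (config {chash}, seed {seed})", ""]

    for metric in ("VD", "VBA", "VW"):
        if metric not in df.columns:
            continue
        try:
            res = stage_contrasts(df, metric)
            report[f"stage_contrasts_{metric}"] = dataclasses.asdict(res)
            lines.append(f"Stage contrasts for {metric} ({res.model}):")
            for g in res.group_means:
                lines.append(f"  stage {g}: {res.group_means[g]:.2f} "
                             f"+/- {res.group_sds[g]:.2f} (n={res.group_ns[g]})")
            for g, d in res.mean_differences.items():
                if d is not None:
                    lines.append(f"  diff {res.metric} (1-2 minus {g}): "
                                 f"{d:.2f} (p={res.p_values[g]:.3g})")
        except ValueError as exc:
            lines.append(f"Stage contrasts for {metric}: skipped ({exc})")
        lines.append("")

    if "leakage_s" in df.columns and df["leakage_s"].notna().sum() >= 3:
        try:
            reg = leakage_regression(df)
            report["leakage_regression"] = dataclasses.asdict(reg)
            lines.append(
                f"Leakage ~ VD: slope {reg.slope:.3f} s/%, intercept "
                f"{reg.intercept:.1f} s, r {reg.r:.3f}, r^2 {reg.r_squared:.3f}, "
                f"p {reg.p_value:.3g}, n {reg.n}")
        except ValueError as exc:
            lines.append(f"Leakage regression skipped ({exc})")
        lines.append("")

    try:
        cm = cytokine_matrix(df, max_week=sp.get("pre_week"))
        report["cytokine_matrix"] = dataclasses.asdict(cm)
        if cm.rho:
            lines.append("Spearman rho (analyte x metric):")
            for a, row in cm.rho.items():
                cells = ", ".join(f"{m}={v:.3f}" if v is not None else f"{m}=NA"
                                  for m, v in row.items())
                lines.append(f"  {a}: {cells}")
        if cm.excluded_below_lod:
            lines.append("Below limits of detection: " + ", ".join(cm.excluded_below_lod))
    except Exception as exc:  # noqa: BLE001
        lines.append(f"Cytokine matrix skipped ({exc})")
    lines.append("")

    try:
        gt = group_change_tests(df, pre_week=sp.get("pre_week", 2),
                                post_week=sp.get("post_week", 4),
                                arms=tuple(sp.get("arms", ("aflibercept", "saline"))))
        report["group_change_tests"] = gt
        for arm, res in gt["paired"].items():
            lines.append(f"Paired t ({arm}): t={res['t']:.3f} p={res['p']:.3g} "
                         f"n={res['n']} mean change {res['mean_change']:.2f}")
        ind = gt["independent"]
        lines.append(f"Independent t ({ind['arms'][0]} vs {ind['arms'][1]}): "
                     f"t={ind['t']:.3f} p={ind['p']:.3g}")
    except Exception as exc:  # noqa: BLE001
        lines.append(f"Group change tests skipped ({exc})")

    report_txt = outdir / "stats_report.txt"
    report_txt.write_text("\n".join(lines) + "\n")
    report_json = outdir / "stats_report.json"
    with open(report_json, "w") as fh:
        json.dump({"config_hash": chash, "seed": seed, "results": report},
                  fh, indent=1, default=_json_default)
    return {"stats_report_txt": str(report_txt), "stats_report_json": str(report_json)}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
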