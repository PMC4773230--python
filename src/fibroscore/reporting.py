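"""End-to-end pipeline orchestration and publication-style outputs.

The run configuration is a versioned YAML mapping; unknown keys are a hard
error so silent typos cannot change an analysis.  Every number in a rendered
text table is the machine-readable value rounded to the printed precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cam import HuThresholds, cam_score, result_to_dict
from .ct_io import read_dicom_series, read_mask, read_nifti, write_mask
from .segmentation import SegmentationParams, segment_lungs
from .stats import RegressionResult, compare_groups, describe, fit_multivariate
from .warrick import read_findings_csv, score_studies

logger = logging.getLogger("fibroscore")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        self.stage = stage
        self.input_id = input_id
        super().__init__(f"[{stage}] {input_id}: {cause}")


CONFIG_SCHEMA_VERSION = 1
_ALLOWED_KEYS = {
    "schema_version", "seed", "output_dir", "volumes", "segmentation",
    "thresholds", "findings_csv", "warrick_aggregate", "cohort_csv",
    "regression_outcome", "regression_covariates", "verbosity",
}
_ALLOWED_SEG_KEYS = {"hu_low", "hu_high", "opening_mm", "min_component_voxels", "exclude_airways"}
_ALLOWED_THRESH_KEYS = {"lung_low", "normal_cut", "ild_cut", "lung_high"}


@dataclasses.dataclass
class RunConfig:
    output_dir: Path
    volumes: list[dict]
    segmentation: SegmentationParams
    thresholds: HuThresholds
    findings_csv: Path | None = None
    warrick_aggregate: str = "mean"
    cohort_csv: Path | None = None
    regression_outcome: str | None = None
    regression_covariates: list[str] | None = None
    seed: int = 0
    verbosity: str = "info"


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if raw.get("schema_version") != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {raw.get('schema_version')!r}; expected {CONFIG_SCHEMA_VERSION}"
        )
    seg_raw = raw.get("segmentation", {}) or {}
    unknown = set(seg_raw) - _ALLOWED_SEG_KEYS
    if unknown:
        raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
    thr_raw = raw.get("thresholds", {}) or {}
    unknown = set(thr_raw) - _ALLOWED_THRESH_KEYS
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    thresholds = HuThresholds(
        lung_low=thr_raw.get("lung_low", -1024.0),
        normal_cut=thr_raw.get("normal_cut", -700.0),
        ild_cut=thr_raw.get("ild_cut", -500.0),
        lung_high=thr_raw.get("lung_high", -200.0),
    )
    if not (-1024.0 <= thresholds.lung_low and thresholds.lung_high <= -200.0):
        raise ValueError("thresholds must lie within [-1024, -200]")
    segmentation = SegmentationParams(
        lung_hu_low=seg_raw.get("hu_low", thresholds.lung_low),
        lung_hu_high=seg_raw.get("hu_high", thresholds.lung_high),
        min_component_voxels=seg_raw.get("min_component_voxels"),
        opening_radius_mm=seg_raw.get("opening_mm", 1.0),
        exclude_airways=seg_raw.get("exclude_airways", True),
    )
    return RunConfig(
        output_dir=Path(raw.get("output_dir", "fibroscore_out")),
        volumes=list(raw.get("volumes", [])),
        segmentation=segmentation,
        thresholds=thresholds,
        findings_csv=Path(raw["findings_csv"]) if raw.get("findings_csv") else None,
        warrick_aggregate=raw.get("warrick_aggregate", "mean"),
        cohort_csv=Path(raw["cohort_csv"]) if raw.get("cohort_csv") else None,
        regression_outcome=raw.get("regression_outcome"),
        regression_covariates=raw.get("regression_covariates"),
        seed=int(raw.get("seed", 0)),
        verbosity=raw.get("verbosity", "info"),
    )


def load_volume(path: str | Path):
    p = Path(path)
    if p.is_dir():
        return read_dicom_series(p)
    return read_nifti(p)


def run_pipeline(config: RunConfig) -> dict:
    """Execute segment -> cam -> (warrick ingest) -> cohort stats.

    Returns the run manifest (also written to ``manifest.json``); the first
    hard error raises a :class:`PipelineError` naming the stage and input.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "parameters": {
            "segmentation": dataclasses.asdict(config.segmentation),
            "thresholds": dataclasses.asdict(config.thresholds),
        },
        "inputs": [dict(v) for v in config.volumes],
        "stages": [],
    }

    cam_rows = []
    for vol_entry in config.volumes:
        vol_id = str(vol_entry.get("id", Path(str(vol_entry["path"])).stem))
        try:
            volume = load_volume(vol_entry["path"])
        except Exception as exc:
            raise PipelineError("segment", vol_id, exc) from exc
        try:
            if vol_entry.get("mask"):
                mask = read_mask(vol_entry["mask"], label="lung")
            else:
                mask = segment_lungs(volume, config.segmentation)
                write_mask(mask, volume, out / f"{vol_id}_lungmask.nii.gz")
        except Exception as exc:
            raise PipelineError("segment", vol_id, exc) from exc
        logger.info("segment: %s (%d lung voxels)", vol_id, mask.count())
        try:
            result = cam_score(volume, mask, config.thresholds)
        except Exception as exc:
            raise PipelineError("cam", vol_id, exc) from exc
        report = {"id": vol_id, **result_to_dict(result)}
        (out / f"{vol_id}_cam.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        cam_rows.append({"id": vol_id, "fibrosis_pct": result.fibrosis_pct,
                         "total_lung_volume_ml": result.total_lung_volume_ml})
        logger.info("cam: %s fibrosis %.1f%%", vol_id, result.fibrosis_pct)
    if config.volumes:
        pd.DataFrame(cam_rows).to_csv(out / "cam_scores.csv", index=False)
        manifest["stages"].append({"name": "segment", "status": "completed", "n_inputs": len(config.volumes)})
        manifest["stages"].append({"name": "cam", "status": "completed", "n_inputs": len(config.volumes)})

    if config.findings_csv is not None:
        try:
            assessments = read_findings_csv(config.findings_csv)
            scores = score_studies(assessments, aggregate=config.warrick_aggregate)
        except Exception as exc:
            raise PipelineError("warrick", str(config.findings_csv), exc) from exc
        scores.to_csv(out / "warrick_scores.csv", index=False)
        manifest["stages"].append({"name": "warrick", "status": "completed", "n_inputs": len(scores)})
        logger.info("warrick: %d studies scored", len(scores))

    if config.cohort_csv is not None:
        try:
            cohort = pd.read_csv(config.cohort_csv)
            outputs = cohort_reports(
                cohort,
                out,
                outcome=config.regression_outcome,
                covariates=config.regression_covariates,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("cohort_stats", str(config.cohort_csv), exc) from exc
        manifest["stages"].append({"name": "cohort_stats", "status": "completed", "outputs": outputs})
        logger.info("cohort_stats: %d reports", len(outputs))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Tables and figures
# ---------------------------------------------------------------------------

DEFAULT_TABLE_VARIABLES = [
    "age", "disease_duration", "mrss", "borg", "vas_breathing", "haq_di",
    "dlco_pct", "fvc_pct", "covr_extent", "covr_severity", "covr_total",
    "cam_fibrosis_pct",
]

DEFAULT_REGRESSION_COVARIATES = [
    "age", "sex", "disease_duration", "anti_topo_I", "mrss",
    "haq_di", "borg", "fvc_pct", "dlco_pct",
]


def render_table1(cohort: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Baseline descriptives: one row per variable (mean, SD, median, IQR)."""
    variables = [v for v in (variables or DEFAULT_TABLE_VARIABLES) if v in cohort.columns]
    rows = [{"variable": v, **describe(cohort, v)} for v in variables]
    return pd.DataFrame(rows).set_index("variable")


def render_table2(
    cohort: pd.DataFrame,
    group: str = "subtype",
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subtype descriptives with the two-group comparison statistic."""
    variables = [v for v in (variables or DEFAULT_TABLE_VARIABLES) if v in cohort.columns]
    levels = sorted(cohort[group].astype(str).unique())
    rows = []
    for v in variables:
        row: dict = {"variable": v}
        for level in levels:
            d = describe(cohort[cohort[group].astype(str) == level], v)
            for key in ("mean", "sd", "median", "iqr_low", "iqr_high"):
                row[f"{level}_{key}"] = d[key]
        cmp = compare_groups(cohort, v, group=group)
        row["statistic"] = cmp["statistic"]
        row["p"] = cmp["p"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def render_table3(result: RegressionResult) -> pd.DataFrame:
    """Regression summary: coefficient / SE / r_partial / t / p per covariate."""
    table = result.table[["coefficient", "std_error", "r_partial", "t", "p"]].copy()
    return table


def format_table_text(table: pd.DataFrame, decimals: int = 2) -> str:
    return table.round(decimals).to_string()


def cohort_reports(
    cohort: pd.DataFrame,
    out_dir: str | Path,
    outcome: str | None = None,
    covariates: Sequence[str] | None = None,
) -> list[str]:
    """Write Table-1/2/3-style CSV + text reports and Fig-2-style scatter SVGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    t1 = render_table1(cohort)
    t1.to_csv(out / "table1_baseline.csv")
    (out / "table1_baseline.txt").write_text(format_table_text(t1) + "\n")
    written += ["table1_baseline.csv", "table1_baseline.txt"]

    if "subtype" in cohort.columns and cohort["subtype"].nunique() == 2:
        t2 = render_table2(cohort)
        t2.to_csv(out / "table2_by_subtype.csv")
        (out / "table2_by_subtype.txt").write_text(format_table_text(t2) + "\n")
        written += ["table2_by_subtype.csv", "table2_by_subtype.txt"]

    outcome = outcome or ("cam_fibrosis_pct" if "cam_fibrosis_pct" in cohort.columns else None)
    if outcome is not None:
        covs = [c for c in (covariates or DEFAULT_REGRESSION_COVARIATES) if c in cohort.columns]
        frame = cohort.copy()
        for c in covs:  # encode binaries for the design matrix
            if not pd.api.types.is_numeric_dtype(frame[c]):
                frame[c] = frame[c].astype("category").cat.codes
            elif pd.api.types.is_bool_dtype(frame[c]):
                frame[c] = frame[c].astype(int)
        result = fit_multivariate(frame, outcome, covs)
        t3 = render_table3(result)
        t3.to_csv(out / f"table3_regression_{outcome}.csv")
        footer = (
            f"\nn = {result.n}, k = {result.k}, multiple R = {result.r_multiple:.3f}, "
            f"adjusted R^2 = {result.r2_adjusted:.3f}\n"
        )
        (out / f"table3_regression_{outcome}.txt").write_text(
            format_table_text(t3, decimals=4) + footer
        )
        written += [f"table3_regression_{outcome}.csv", f"table3_regression_{outcome}.txt"]

    written += scatter_plots(cohort, out)
    return written


_SCATTER_PAIRS = [
    ("cam_fibrosis_pct", "covr_total"),
    ("cam_fibrosis_pct", "fvc_pct"),
    ("cam_fibrosis_pct", "dlco_pct"),
    ("cam_fibrosis_pct", "haq_di"),
]


def scatter_plots(cohort: pd.DataFrame, out_dir: str | Path) -> list[str]:
    """CaM-vs-measure scatter plots with least-squares regression lines."""
    out = Path(out_dir)
    written = []
    for x, y in _SCATTER_PAIRS:
        if x not in cohort.columns or y not in cohort.columns:
            continue
        sub = cohort[[x, y]].dropna()
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.scatter(sub[x], sub[y], s=12, alpha=0.6, edgecolors="none")
        slope, intercept = np.polyfit(sub[x], sub[y], 1)
        xs = np.array([sub[x].min(), sub[x].max()])
        ax.plot(xs, slope * xs + intercept, color="crimson", lw=1.5)
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        fig.tight_layout()
        name = f"scatter_{x}_vs_{y}.svg"
        fig.savefig(out / name)
        plt.close(fig)
        written.append(name)
    return written
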