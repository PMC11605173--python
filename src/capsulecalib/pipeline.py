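"""End-to-end analysis: images + measurements -> growth constant, calibration,
thickness predictions and formation threshold.

Stages (per image): segmentation, centre-region selection, colour statistics,
outer-radius measurement.  Then, on the merged per-sample table:

1. the growth constant ``alpha`` is fitted (through-origin, linearised) on
   samples whose shell thickness was directly measured;
2. an affine colour calibration (thickness on R-B) is fitted on the
   calibration-eligible samples (measured thickness, concentration at or
   above ``calibration_min_conc`` - thinner shells cannot be measured
   directly, which is the whole reason for the colour route);
3. every sample, measurable or not, receives a colour-predicted thickness
   and an absent/continuous classification;
4. per-concentration aggregates and the formation threshold are derived.

Per-image failures are logged and the sample is reported as skipped; only a
run with zero usable images is fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import calibration as cal
from . import colorimetry as col
from . import geometry as geo
from .errors import PipelineError, SchemaError

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "DEFAULT_COLUMN_MAP",
    "load_external_measurements",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger(__name__)

#: canonical name -> header expected in external measurement tables
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "sample_id": "sample_id",
    "conc_mM": "conc_mM",
    "R_c_um": "R_c_um",
    "h_um": "h_um",
}

MANIFEST_COLUMNS = ("image_path", "sample_id", "conc_mM", "scale_um_per_px")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the end-to-end analysis.

    ``centre_fraction`` sizes the centre sampling disc as a fraction of the
    capsule's equivalent radius; ``background_erosion`` (px) excludes halo
    pixels near the capsule from background statistics;
    ``absence_tolerance`` (um) is the cut below which a colour-predicted
    thickness is classified shell-absent; ``calibration_min_conc`` (mM)
    marks the concentration from which direct thickness measurement is
    considered possible.
    """

    centre_fraction: float = 0.1
    background_erosion: int = 5
    absence_tolerance: float = 0.0
    calibration_min_conc: float = 5.0
    column_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_MAP)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.centre_fraction <= 0.5:
            raise ValueError("centre_fraction must lie in (0, 0.5]")
        if self.background_erosion < 0:
            raise ValueError("background_erosion must be non-negative")
        if self.calibration_min_conc < 0:
            raise ValueError("calibration_min_conc must be non-negative")


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, ready for serialisation."""

    alpha_hat: float
    alpha_rss: float
    n_alpha: int
    calibration: cal.ColourCalibration
    per_sample: pd.DataFrame
    aggregates: pd.DataFrame
    formation_threshold: Optional[float]
    config: PipelineConfig


def load_external_measurements(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a measurements CSV into the canonical schema.

    ``column_map`` maps canonical names (``sample_id``, ``conc_mM``,
    ``R_c_um``, ``h_um``) to the file's actual headers.  Rows with a blank
    thickness are retained and flagged ``measurable = False`` rather than
    dropped - those are exactly the samples the colour route exists for.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    missing = [ext for ext in cmap.values() if ext not in df.columns]
    if missing:
        raise SchemaError(
            f"measurements file {path} lacks columns {missing}; found {list(df.columns)}"
        )
    out = pd.DataFrame(
        {canon: df[ext] for canon, ext in cmap.items()}
    )
    out["conc_mM"] = pd.to_numeric(out["conc_mM"], errors="raise")
    out["R_c_um"] = pd.to_numeric(out["R_c_um"], errors="coerce")
    out["h_um"] = pd.to_numeric(out["h_um"], errors="coerce")
    out["measurable"] = out["h_um"].notna() & (out["h_um"] > 0)
    return out


def _analyse_image(
    image_path: Path, sample_id: str, conc: float, scale: float, config: PipelineConfig
) -> dict:
    """Colour metrics and outer radius for one image (raises on failure)."""
    pixels = iio.imread(image_path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # tolerate RGBA PNGs
        pixels = pixels[..., :3]
    image = col.CapsuleImage(
        pixels=pixels, sample_id=sample_id, conc=conc, scale=scale
    )
    seg = col.segment_capsule(image)
    centre = col.centre_region(seg, fraction=config.centre_fraction)
    stats = col.extract_colour_stats(
        image, centre, seg, background_erosion=config.background_erosion
    )
    return {
        "R_mean": stats.R_mean,
        "G_mean": stats.G_mean,
        "B_mean": stats.B_mean,
        "R_bg": stats.R_bg,
        "metric_R": stats.metric_R,
        "R_minus_bg": stats.metric_R_minus_bg,
        "R_minus_B": stats.metric_R_minus_B,
        "outer_radius_um": col.measure_radius(seg, scale),
    }


def run_pipeline(
    manifest: str | Path,
    measurements: str | Path | None,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the full analysis for a dataset manifest.

    ``manifest`` is a CSV with columns ``image_path`` (relative to the
    manifest's directory or absolute), ``sample_id``, ``conc_mM`` and
    ``scale_um_per_px``.  ``measurements`` is the direct-measurement table
    (canonical schema via ``config.column_map``); it is required, because
    the colour calibration cannot exist without measured thicknesses.
    """
    manifest_path = Path(manifest)
    mdf = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in mdf.columns]
    if missing:
        raise SchemaError(f"manifest lacks columns {missing}")
    if measurements is None:
        raise PipelineError(
            "a measurements table is required: the colour calibration needs "
            "directly measured shell thicknesses"
        )
    meas = load_external_measurements(measurements, column_map=config.column_map)

    rows = []
    for rec in mdf.itertuples(index=False):
        ipath = Path(rec.image_path)
        if not ipath.is_absolute():
            ipath = manifest_path.parent / ipath
        row = {
            "sample_id": rec.sample_id,
            "conc_mM": float(rec.conc_mM),
            "skipped": False,
        }
        try:
            row.update(
                _analyse_image(
                    ipath,
                    str(rec.sample_id),
                    float(rec.conc_mM),
                    float(rec.scale_um_per_px),
                    config,
                )
            )
        except Exception as exc:
            logger.warning("skipping sample %s: %s", rec.sample_id, exc)
            row["skipped"] = True
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    usable = per_sample[~per_sample["skipped"]]
    if usable.empty:
        raise PipelineError("no image in the manifest could be analysed")

    per_sample = per_sample.merge(
        meas[["sample_id", "R_c_um", "h_um", "measurable"]], on="sample_id", how="left"
    )
    per_sample["measurable"] = per_sample["measurable"].fillna(False).astype(bool)

    # growth constant from directly measured thicknesses
    obs = per_sample[per_sample["measurable"]]
    if len(obs) < 2:
        raise PipelineError(
            "fewer than two directly measured thicknesses; cannot fit the growth law"
        )
    fit = geo.fit_alpha(
        obs[["conc_mM", "R_c_um", "h_um"]].rename(columns=str)
    )

    # colour calibration on measurable, calibration-eligible, analysed samples
    eligible = per_sample[
        per_sample["measurable"]
        & ~per_sample["skipped"]
        & (per_sample["conc_mM"] >= config.calibration_min_conc)
    ]
    if len(eligible) < 2:
        raise PipelineError(
            "fewer than two calibration-eligible samples with colour metrics"
        )
    calibration = cal.fit_colour_calibration(
        eligible[["R_minus_B", "h_um"]].rename(columns=str)
    )

    # colour-predicted thickness and status for every analysed sample
    h_pred, status = [], []
    for rec in per_sample.itertuples(index=False):
        if rec.skipped:
            h_pred.append(np.nan)
            status.append("skipped")
        else:
            est = cal.predict_thickness_from_colour(
                calibration, rec.R_minus_B, tolerance=config.absence_tolerance
            )
            h_pred.append(est.h_pred)
            status.append(est.status)
    per_sample["h_pred_um"] = h_pred
    per_sample["status"] = status

    analysed = per_sample[~per_sample["skipped"]]
    agg_rb = cal.aggregate_by_concentration(
        analysed.rename(columns={"R_minus_B": "R_minus_B"}), value_name="R_minus_B"
    )
    agg_h = cal.aggregate_by_concentration(analysed, value_name="h_pred_um")
    aggregates = agg_rb.merge(agg_h.drop(columns="n"), on="conc_mM")

    threshold = cal.detect_formation_threshold(
        analysed[["conc_mM", "status"]]
    )

    return AnalysisReport(
        alpha_hat=fit.model.alpha,
        alpha_rss=fit.rss,
        n_alpha=fit.n,
        calibration=calibration,
        per_sample=per_sample,
        aggregates=aggregates,
        formation_threshold=threshold,
        config=config,
    )


def _fig_linearized(report: AnalysisReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_sample
    obs = df[df["measurable"] & ~df["skipped"]]
    x = obs["conc_mM"].to_numpy(float)
    y = geo.linearized_response(
        obs["h_um"].to_numpy(float), obs["R_c_um"].to_numpy(float)
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, "o", label="linearised measurements")
    xs = np.linspace(0, max(x.max(), 1) * 1.05, 50)
    ax.plot(xs, report.alpha_hat * xs, "-", label=f"fit: y = {report.alpha_hat:.3f} x")
    ax.set_xlabel("CaCl$_2$ concentration (mM)")
    ax.set_ylabel("$(h/R_c + 1)^3 - 1$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_calibration(report: AnalysisReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_sample[~report.per_sample["skipped"]]
    meas = df[df["measurable"]]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(meas["R_minus_B"], meas["h_um"], "o", label="measured")
    ax.plot(df["R_minus_B"], df["h_pred_um"], "x", label="predicted")
    xs = np.linspace(df["R_minus_B"].min(), df["R_minus_B"].max(), 50)
    c = report.calibration
    ax.plot(xs, c.predict(xs), "-", label=f"h = {c.slope:.3f}(R-B) + {c.intercept:.2f}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("R - B colour intensity")
    ax.set_ylabel("shell thickness (um)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report artefacts; returns a name -> path mapping.

    Artefacts: ``per_sample.csv``, ``aggregates.csv``, ``calibration.json``
    (schema-versioned), ``summary.txt`` and two figures (linearised growth
    fit; thickness vs R-B calibration).  Figures are for inspection only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_sample": out / "per_sample.csv",
        "aggregates": out / "aggregates.csv",
        "calibration": out / "calibration.json",
        "summary": out / "summary.txt",
        "fig_linearized": out / "fig_linearized_fit.png",
        "fig_calibration": out / "fig_colour_calibration.png",
    }
    cols = [
        "sample_id",
        "conc_mM",
        "R_minus_B",
        "h_pred_um",
        "status",
        "R_c_um",
        "h_um",
        "measurable",
        "outer_radius_um",
        "skipped",
    ]
    present = [c for c in cols if c in report.per_sample.columns]
    report.per_sample.to_csv(paths["per_sample"], index=False, columns=present)
    report.aggregates.to_csv(paths["aggregates"], index=False)
    c = report.calibration
    paths["calibration"].write_text(
        json.dumps(
            {
                "schema_version": 1,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "n": c.n,
            },
            indent=2,
        )
        + "\n"
    )
    thr = report.formation_threshold
    threshold_line = (
        f"formation threshold: {thr:g} mM (all replicates shell-absent at and below)"
        if thr is not None
        else "no formation threshold detected"
    )
    n_skip = int(report.per_sample["skipped"].sum())
    summary = "\n".join(
        [
            "capsule shell-thickness analysis",
            f"alpha = {report.alpha_hat:.3f} mM^-1 "
            f"(through-origin fit, n = {report.n_alpha}, RSS = {report.alpha_rss:.4g})",
            f"colour calibration: h = {c.slope:.4f} (R-B) {c.intercept:+.4f} um, "
            f"r^2 = {c.r_squared:.4f}, n = {c.n}",
            threshold_line,
            f"samples: {len(report.per_sample)} ({n_skip} skipped)",
            "",
        ]
    )
    paths["summary"].write_text(summary)
    _fig_linearized(report, paths["fig_linearized"])
    _fig_calibration(report, paths["fig_calibration"])
    return paths
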