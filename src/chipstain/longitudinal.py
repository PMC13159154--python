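"""Longitudinal label-free drug-response analysis.

Predicted (or true) fluorescence images are post-processed into chip-level
features — sum area and sum intensity per channel plus the derived live
features (DAPI minus TRITC-positive within the DAPI mask) — across culture
days. The day-8 endpoint minus the day-6 pre-treatment baseline isolates
the drug-induced change from chip-to-chip seeding variability; three
dose-response readout strategies built on these features are fitted and
compared.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assaystats, segment, simulate, staining
from .config import ConfigurationError, SimConfig
from .imagecore import Channel, ChipImage, gaussian_smooth

logger = logging.getLogger("chipstain.pipeline")

LONGITUDINAL_DAYS = (0, 2, 4, 6, 8)
APPROACHES = ("endpoint_day8", "delta_dapi", "delta_live")


@dataclass
class PostprocessParams:
    smooth_sigma_px: float = 1.0
    min_area_px: int = segment.DEFAULT_MIN_AREA_PX


@dataclass
class PostprocessResult:
    mask: np.ndarray
    sum_area: int
    sum_intensity: float
    qc_ok: bool = True


def postprocess(
    pred: ChipImage,
    channel: Channel | None = None,
    params: PostprocessParams | None = None,
) -> PostprocessResult:
    """Turn one fluorescence image into a stain mask and its summary features.

    Gaussian smoothing → Otsu thresholding (2-class for the all-nuclei DAPI
    channel, 3-class top class for the dead-cell TRITC channel) → removal of
    sub-minimum-area components. ``sum_area`` is the mask pixel count and
    ``sum_intensity`` the raw-image intensity sum within the mask. A
    degenerate image (too few gray levels for Otsu) yields a zero-feature
    record flagged ``qc_ok=False`` instead of an exception.
    """
    params = params or PostprocessParams()
    channel = Channel(channel or pred.channel)
    n_classes = 3 if channel is Channel.TRITC else 2
    smoothed = gaussian_smooth(pred, params.smooth_sigma_px)
    try:
        mask = segment.foreground_mask(smoothed, n_classes=n_classes)
    except segment.DegenerateHistogramError:
        return PostprocessResult(
            mask=np.zeros(pred.shape, dtype=bool), sum_area=0, sum_intensity=0.0,
            qc_ok=False,
        )
    labels, _ = segment.segment_mask(mask, params.min_area_px)
    mask = labels > 0
    pixels = pred.astype_float()
    return PostprocessResult(
        mask=mask,
        sum_area=int(mask.sum()),
        sum_intensity=float(pixels[mask].sum()),
        qc_ok=True,
    )


@dataclass
class LiveFeatures:
    live_area: int
    live_intensity: float
    dapi_mask: np.ndarray
    tritc_mask: np.ndarray


def live_features(
    dapi_img: ChipImage,
    tritc_img: ChipImage,
    params: PostprocessParams | None = None,
) -> LiveFeatures:
    """Live-cell features: DAPI minus TRITC-positive within the DAPI mask.

    ``live_area = |dapi_mask| − |tritc_mask ∩ dapi_mask|`` (exact set
    arithmetic); ``live_intensity`` is the DAPI-image intensity summed over
    the live mask.
    """
    if dapi_img.shape != tritc_img.shape:
        raise ValueError("channel images must share one shape")
    dapi_res = postprocess(dapi_img, Channel.DAPI, params)
    tritc_res = postprocess(tritc_img, Channel.TRITC, params)
    live_mask = dapi_res.mask & ~tritc_res.mask
    dapi_pixels = dapi_img.astype_float()
    return LiveFeatures(
        live_area=int(live_mask.sum()),
        live_intensity=float(dapi_pixels[live_mask].sum()),
        dapi_mask=dapi_res.mask,
        tritc_mask=tritc_res.mask,
    )


def chip_day_record(
    chip_id: str,
    day: int,
    dose: float,
    dapi_img: ChipImage,
    tritc_img: ChipImage,
    params: PostprocessParams | None = None,
) -> dict:
    """One longitudinal table row from a chip's two stain images."""
    dapi_res = postprocess(dapi_img, Channel.DAPI, params)
    tritc_res = postprocess(tritc_img, Channel.TRITC, params)
    live_mask = dapi_res.mask & ~tritc_res.mask
    dapi_pixels = dapi_img.astype_float()
    tritc_within = tritc_res.mask & dapi_res.mask
    return {
        "chip_id": chip_id,
        "day": day,
        "dose": dose,
        "dapi_sum_area": dapi_res.sum_area,
        "dapi_sum_intensity": dapi_res.sum_intensity,
        "tritc_sum_area": tritc_res.sum_area,
        "tritc_sum_intensity": tritc_res.sum_intensity,
        "tritc_area_within_dapi": int(tritc_within.sum()),
        "live_area": int(live_mask.sum()),
        "live_intensity": float(dapi_pixels[live_mask].sum()),
        "qc_ok": dapi_res.qc_ok and tritc_res.qc_ok,
    }


def baseline_change(
    records: pd.DataFrame,
    feature: str,
    baseline_day: int = 6,
    endpoint_day: int = 8,
) -> pd.Series:
    """Per-chip endpoint-minus-baseline change of one feature.

    ``delta = value(day 8) − value(day 6)``; negative values mean net death
    or shrinkage. Raises if any chip lacks the baseline (or endpoint) day.
    """
    wide = records.pivot_table(index="chip_id", columns="day", values=feature, aggfunc="first")
    for day, label in ((baseline_day, "baseline"), (endpoint_day, "endpoint")):
        if day not in wide.columns or wide[day].isna().any():
            missing = (
                list(wide.index[wide[day].isna()]) if day in wide.columns else list(wide.index)
            )
            raise ValueError(f"{label} day {day} unavailable for chips: {missing}")
    return wide[endpoint_day] - wide[baseline_day]


@dataclass
class ApproachResult:
    approach: str
    responses: pd.DataFrame  # chip_id, dose, value, normalized
    fit: assaystats.DoseResponseResults | None
    dynamic_range: float  # (vehicle mean − top-dose mean) in vehicle-SD units

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "dynamic_range": self.dynamic_range,
            "fit": self.fit.to_dict() if self.fit is not None else None,
        }


@dataclass
class ApproachComparison:
    results: dict[str, ApproachResult]

    def ranked(self) -> list[str]:
        """Approaches by descending sensitivity (dynamic range)."""
        return sorted(
            self.results, key=lambda a: (-self.results[a].dynamic_range, a)
        )

    def to_dict(self) -> dict:
        return {
            "ranked_by_sensitivity": self.ranked(),
            "approaches": {k: v.to_dict() for k, v in self.results.items()},
        }


def _approach_values(records: pd.DataFrame, approach: str) -> pd.DataFrame:
    endpoint = records[records["day"] == 8]
    if approach == "endpoint_day8":
        vals = endpoint.set_index("chip_id")["live_area"]
    elif approach == "delta_dapi":
        vals = baseline_change(records, "dapi_sum_area")
    elif approach == "delta_live":
        vals = baseline_change(records, "live_area")
    else:
        raise ValueError(f"unknown approach {approach!r}")
    doses = endpoint.set_index("chip_id")["dose"]
    return pd.DataFrame({"dose": doses, "value": vals}).reset_index()


def compare_approaches(records: pd.DataFrame, doses: list[float] | None = None) -> ApproachComparison:
    """Fit and compare the three dose-response readout strategies.

    All three use the same chips: the day-8 endpoint live area alone, the
    day-8−day-6 change in total (DAPI) area, and the day-8−day-6 change in
    live area. Each readout is normalized to the vehicle mean and fitted
    with the 4PL model over positive doses; the sensitivity summary is the
    dynamic range — vehicle mean minus top-dose mean, in units of the
    vehicle SD.
    """
    results = {}
    for approach in APPROACHES:
        table = _approach_values(records, approach)
        if doses is not None:
            table = table[table["dose"].isin(doses)]
        vehicle = table.loc[table["dose"] == 0, "value"].to_numpy(dtype=float)
        if len(vehicle) < 2:
            raise ValueError("need >= 2 vehicle chips per approach")
        table = table.copy()
        table["normalized"] = assaystats.normalize_to_vehicle(
            table["value"].to_numpy(dtype=float), vehicle
        )
        treated = table[table["dose"] > 0]
        top_dose = treated["dose"].max()
        top_vals = treated.loc[treated["dose"] == top_dose, "value"].to_numpy(dtype=float)
        vehicle_sd = vehicle.std(ddof=1)
        dynamic_range = (
            float((vehicle.mean() - top_vals.mean()) / vehicle_sd)
            if vehicle_sd > 0
            else float("inf")
        )
        fit = None
        if treated["dose"].nunique() >= 4:
            fit = assaystats.fit_dose_response(
                treated["dose"].to_numpy(dtype=float),
                treated["normalized"].to_numpy(dtype=float),
            )
        results[approach] = ApproachResult(
            approach=approach, responses=table, fit=fit, dynamic_range=dynamic_range
        )
    return ApproachComparison(results=results)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def demo_config() -> dict:
    """A small, fast configuration exercising every pipeline stage."""
    return {
        "simulation": {
            "channel_width_px": 128,
            "channel_height_px": 96,
            "seeding_density": 40,
            "noise_sd": 300.0,
            "stain_unevenness_amplitude": 0.1,
        },
        "dataset": {
            "n_chips": 12,
            "days": list(LONGITUDINAL_DAYS),
            "doses": [0.0, 0.1, 1.0, 10.0, 100.0],
            "treatment_start_day": 6,
        },
        "training": {
            "epochs": 3,
            "batch_size": 8,
            "learning_rate": 1e-4,
            "base_filters": 8,
            "depth": 2,
            "patch_size_px": 64,
            "stride_px": 48,
        },
        "analysis": {"baseline_day": 6, "endpoint_day": 8},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> dict:
    """Run simulate → train → predict → post-process → dose-response end to end.

    Writes ``report.json``, ``records.csv``, the dataset manifest and a
    ``checksums.json`` over the report files; a fixed seed reproduces the
    checksums exactly. Timings go to the log only, so reruns are
    byte-identical.
    """
    t_start = time.perf_counter()
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping or a YAML path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimConfig.from_dict({**config.get("simulation", {}), "seed": seed})
    ds_cfg = config.get("dataset", {})
    tr_cfg = config.get("training", {})
    an_cfg = config.get("analysis", {})
    days = list(ds_cfg.get("days", LONGITUDINAL_DAYS))
    doses = list(ds_cfg.get("doses", [0.0, 0.1, 1.0, 10.0, 100.0]))

    logger.info("stage=simulate start")
    t0 = time.perf_counter()
    manifest = simulate.generate_dataset(
        sim_cfg,
        n_chips=int(ds_cfg.get("n_chips", 12)),
        days=days,
        doses=doses,
        out_dir=out_dir / "dataset",
        treatment_start_day=int(ds_cfg.get("treatment_start_day", 6)),
    )
    logger.info("stage=simulate done elapsed=%.1fs", time.perf_counter() - t0)

    def _load(row, col, channel):
        return simulate.load_image(
            out_dir / "dataset", row[col], channel,
            chip_id=row["chip_id"], day=int(row["day"]),
        )

    endpoint_day = int(an_cfg.get("endpoint_day", 8))
    patch = staining.PatchSpec(
        patch_size_px=int(tr_cfg.get("patch_size_px", 224)),
        stride_px=int(tr_cfg.get("stride_px", 112)),
    )
    hyper = staining.TrainConfig(
        epochs=int(tr_cfg.get("epochs", 25)),
        batch_size=int(tr_cfg.get("batch_size", 8)),
        learning_rate=float(tr_cfg.get("learning_rate", 1e-4)),
        base_filters=int(tr_cfg.get("base_filters", 16)),
        depth=int(tr_cfg.get("depth", 2)),
        patch=patch,
        seed=seed,
    )

    models = {}
    for channel, col in ((Channel.DAPI, "dapi_path"), (Channel.TRITC, "tritc_path")):
        t0 = time.perf_counter()
        logger.info("stage=train channel=%s start", channel.value)
        pairs = {"train": [], "val": []}
        for _, row in manifest[manifest["day"] == endpoint_day].iterrows():
            if row["split"] in pairs:
                pairs[row["split"]].append(
                    (_load(row, "bf_path", Channel.BF), _load(row, col, channel))
                )
        models[channel] = staining.train_translation(
            pairs["train"], pairs["val"], channel, hyper
        )
        logger.info(
            "stage=train channel=%s done elapsed=%.1fs", channel.value,
            time.perf_counter() - t0,
        )

    logger.info("stage=predict+postprocess start")
    t0 = time.perf_counter()
    params = PostprocessParams()
    records = []
    for _, row in manifest.sort_values(["chip_id", "day"]).iterrows():
        bf = _load(row, "bf_path", Channel.BF)
        pred_dapi = models[Channel.DAPI].predict(bf)
        pred_tritc = models[Channel.TRITC].predict(bf)
        records.append(
            chip_day_record(
                row["chip_id"], int(row["day"]), float(row["dose"]),
                pred_dapi, pred_tritc, params,
            )
        )
    records = pd.DataFrame(records)
    logger.info("stage=predict+postprocess done elapsed=%.1fs", time.perf_counter() - t0)

    comparison = compare_approaches(records)

    records_path = out_dir / "records.csv"
    records.to_csv(records_path, index=False, float_format="%.6g")
    report = {
        "seed": seed,
        "n_chips": int(manifest["chip_id"].nunique()),
        "days": days,
        "doses": doses,
        "training": {
            ch.value: {
                "epochs_run": len(models[ch].training_log),
                "best_val_loss": models[ch].training_log[-1]["best_val_loss"],
            }
            for ch in models
        },
        "comparison": comparison.to_dict(),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    checksums = {
        "report.json": _sha256(report_path),
        "records.csv": _sha256(records_path),
        "dataset/manifest.csv": _sha256(out_dir / "dataset" / "manifest.csv"),
    }
    (out_dir / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
    logger.info("pipeline done total=%.1fs", time.perf_counter() - t_start)
    report["checksums"] = checksums
    return report
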