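"""File I/O and the end-to-end sweep driver.

Formats: PNG/TIFF for images (8/16-bit integer grayscale rescaled to [0, 1],
or 32-bit float taken as-is), CSV (one value per row) for signals, JSON for
run configuration, HDF5 for volumetric response tensors (axis labels and the
noise schedule stored as attributes), CSV for human-readable summaries.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .noise import NoiseSchedule
from .records import CleanRecord
from .response import (
    VolumetricResponse,
    best_settings,
    family_summary,
    recommend_across_families,
    volumetric_response,
)
from .synthetic import make_bank

logger = logging.getLogger("wavemap")

_CSV_FLOAT_FORMAT = "%.12g"


def load_record(path: str | Path, kind: str) -> CleanRecord:
    """Load a gold-standard record from disk.

    Images: PNG/TIFF, single-channel; integer data is rescaled by its dtype
    range to [0, 1], float data must already lie in [0, 1]. Signals: CSV with
    exactly one numeric value per row (blank or non-numeric rows rejected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if kind == "image":
        arr = iio.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected single-channel grayscale, got shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.integer):
            data = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            data = arr.astype(np.float64)
            if data.min() < 0.0 or data.max() > 1.0:
                raise ValueError(f"{path}: float image values outside [0, 1]")
        return CleanRecord(data=data, kind="image", label=path.stem, provenance="file")
    if kind == "signal":
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                stripped = line.strip()
                if not stripped:
                    raise ValueError(f"{path}: blank line {lineno}")
                try:
                    values.append(float(stripped))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {stripped!r} at line {lineno}"
                    ) from None
        return CleanRecord(
            data=np.asarray(values), kind="signal", label=path.stem, provenance="file"
        )
    raise ValueError(f"kind must be 'image' or 'signal', got {kind!r}")


def save_record(record: CleanRecord, path: str | Path) -> None:
    """Write a record: .png → 16-bit grayscale, .tif/.tiff → 32-bit float,
    .csv → one value per row."""
    path = Path(path)
    suffix = path.suffix.lower()
    if record.kind == "image":
        if suffix == ".png":
            iio.imwrite(path, np.round(record.data * 65535).astype(np.uint16))
        elif suffix in (".tif", ".tiff"):
            tifffile.imwrite(path, record.data.astype(np.float32))
        else:
            raise ValueError(f"unsupported image format {suffix!r}")
    else:
        if suffix != ".csv":
            raise ValueError(f"signals are written as CSV, got {suffix!r}")
        np.savetxt(path, record.data, fmt="%.17g")


def save_response(vr: VolumetricResponse, path: str | Path) -> None:
    """Persist a volumetric response as HDF5 with labeled axes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("tensor", data=vr.tensor)
        ds.attrs["axes"] = ["level", "order", "eta", "item"]
        ds.attrs["metric"] = vr.metric
        ds.attrs["family"] = vr.family
        ds.attrs["schedule_levels"] = vr.schedule.levels
        ds.attrs["schedule_kind"] = vr.schedule.kind
        ds.attrs["item_ids"] = vr.item_ids


def load_response(path: str | Path) -> VolumetricResponse:
    with h5py.File(path, "r") as f:
        ds = f["tensor"]
        return VolumetricResponse(
            tensor=ds[()],
            metric=ds.attrs["metric"],
            family=ds.attrs["family"],
            schedule=NoiseSchedule(
                levels=np.asarray(ds.attrs["schedule_levels"]),
                kind=ds.attrs["schedule_kind"],
            ),
            item_ids=list(ds.attrs["item_ids"]),
        )


def build_bank(config: RunConfig) -> list[CleanRecord]:
    """Materialize the record bank named by a config's ``inputs`` block."""
    if "synthetic" in config.inputs:
        spec = config.inputs["synthetic"]
        return make_bank(
            n_images=spec.get("n_images", 0),
            n_signals=spec.get("n_signals", 0),
            seed=spec.get("seed", config.master_seed),
            image_size=spec.get("image_size", 128),
            signal_length=spec.get("signal_length", 4096),
        )
    if "paths" in config.inputs:
        return [load_record(e["path"], e["kind"]) for e in config.inputs["paths"]]
    raise ValueError("config.inputs must contain 'synthetic' or 'paths'")


def run_sweep(
    config: RunConfig, bank: list[CleanRecord] | None = None
) -> dict[str, dict[str, VolumetricResponse]]:
    """Execute the full sweep a config describes and persist every product.

    Writes, under ``config.output_dir``: one HDF5 tensor per (family, metric),
    ``recommendations.csv`` (per-η winner across families, per metric),
    ``family_summary.csv``, ``best_settings.csv`` (per family), the resolved
    config, and a log with per-stage timings. Reruns of the same config are
    byte-identical in their CSV outputs. Returns ``{family: {metric: vr}}``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_json(out_dir / "config.json")
    if bank is None:
        bank = build_bank(config)
    if not bank:
        raise ValueError("record bank is empty")
    schedule = config.schedule()
    logger.info("sweep start: %d records, %d noise levels, families=%s",
                len(bank), len(schedule), ",".join(config.families))

    responses: dict[str, dict[str, VolumetricResponse]] = {}
    for family in config.families:
        t0 = time.perf_counter()
        responses[family] = volumetric_response(
            bank,
            family,
            schedule,
            metric=tuple(config.metrics),
            master_seed=config.master_seed,
            n_levels=max(config.levels),
            n_orders=max(config.orders),
            adjust_low_in=config.adjust_low_in if config.apply_adjust else None,
            threshold_rule=config.threshold_rule,
            speckle_variance=config.speckle_variance,
            impulse_p=config.impulse_p,
            gaussian_interpretation=config.gaussian_interpretation,
        )
        logger.info("family %s swept in %.2fs (seed=%d)",
                    family, time.perf_counter() - t0, config.master_seed)
        for metric, vr in responses[family].items():
            save_response(vr, out_dir / f"response_{family}_{metric}.h5")

    best_rows = []
    rec_rows = []
    summaries = []
    for metric in config.metrics:
        per_family = {fam: responses[fam][metric] for fam in config.families}
        for fam, vr in per_family.items():
            tbl = best_settings(vr).table
            tbl.insert(0, "metric", metric)
            best_rows.append(tbl)
        rec_rows.append(recommend_across_families(per_family))
        summaries.append(family_summary(per_family))
    pd.concat(best_rows, ignore_index=True).to_csv(
        out_dir / "best_settings.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    pd.concat(rec_rows, ignore_index=True).to_csv(
        out_dir / "recommendations.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    pd.concat(summaries, ignore_index=True).to_csv(
        out_dir / "family_summary.csv", index=False, float_format=_CSV_FLOAT_FORMAT
    )
    logger.info("sweep products written to %s", out_dir)
    return responses
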