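"""Spatial and volumetric denoising-response maps and setting recommendations.

The central objects of the package. A *spatial response map* is the K×N
matrix of one quality metric evaluated over decomposition level k (rows)
× wavelet order n (columns) for one degraded record — the grid an analyst
reads to pick settings. Stacking spatial maps along a noise-intensity axis η
and an input-item axis gives the *volumetric response*, a 4D tensor
(level, order, η index, item index) per metric and family, from which the
best achievable quality, the best settings per noise level, and per-family
robustness summaries are extracted.

Grid cells that a record cannot support (decomposition level deeper than the
record size admits for that filter length) are NaN and excluded from every
extremum and mean, so infeasible deep levels never masquerade as poor
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd

from .metrics import HIGHER_IS_BETTER, METRICS, compute_report
from .noise import NoiseSchedule, composite_noise
from .records import CleanRecord
from .wavelets import (
    MAX_LEVEL,
    MAX_ORDER,
    InfeasibleLevelError,
    WaveletConfig,
    adjust_intensity,
    denoise,
)


@dataclass
class SpatialResponseMap:
    """K×N matrix of one metric over (level, order) for one degraded record."""

    values: np.ndarray  # rows = level 1..K, cols = order 1..N; NaN = missing
    metric: str
    family: str
    eta: float
    item_id: str

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.values.shape[0] + 1)

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, self.values.shape[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.levels, name="level"),
            columns=pd.Index(self.orders, name="order"),
        )


@dataclass
class VolumetricResponse:
    """4D response tensor with axes (level, order, noise index η, item index)."""

    tensor: np.ndarray
    metric: str
    family: str
    schedule: NoiseSchedule
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tensor.ndim != 4:
            raise ValueError("volumetric response must be 4D (level, order, eta, item)")
        if self.tensor.shape[2] != len(self.schedule):
            raise ValueError("η axis length must equal schedule length")

    @property
    def n_eta(self) -> int:
        return self.tensor.shape[2]

    @property
    def n_items(self) -> int:
        return self.tensor.shape[3]

    def spatial_slice(self, eta_index: int, item_index: int) -> SpatialResponseMap:
        return SpatialResponseMap(
            values=self.tensor[:, :, eta_index, item_index],
            metric=self.metric,
            family=self.family,
            eta=float(self.schedule.levels[eta_index]),
            item_id=self.item_ids[item_index] if self.item_ids else str(item_index),
        )


@dataclass
class Recommendation:
    """Per-η best settings extracted from a volumetric response.

    ``table`` has one row per η with the winning (level, order), the best
    value, and the number of feasible cells; ``ranking`` holds, per η, all
    feasible (level, order, value) triples from best to worst.
    """

    metric: str
    family: str
    table: pd.DataFrame
    ranking: list[pd.DataFrame]


def _evaluate_grid(
    clean: np.ndarray,
    degraded: np.ndarray,
    family: str,
    metrics: tuple[str, ...],
    n_levels: int,
    n_orders: int,
    adjust_low_in: float | None,
    threshold_rule: str,
) -> dict[str, np.ndarray]:
    """Denoise once per grid cell and score all requested metrics."""
    grids = {m: np.full((n_levels, n_orders), np.nan) for m in metrics}
    is_image = clean.ndim == 2
    for level in range(1, n_levels + 1):
        for order in range(1, n_orders + 1):
            config = WaveletConfig(family, order, level, threshold_rule)
            try:
                restored = denoise(degraded, config)
            except InfeasibleLevelError:
                continue
            if is_image and adjust_low_in is not None:
                restored = adjust_intensity(restored, adjust_low_in)
            report = compute_report(restored, clean).as_dict()
            for m in metrics:
                grids[m][level - 1, order - 1] = report[m]
    return grids


def spatial_map(
    clean: CleanRecord,
    degraded: CleanRecord | np.ndarray,
    family: str,
    metric: str,
    n_levels: int = MAX_LEVEL,
    n_orders: int = MAX_ORDER,
    eta: float = float("nan"),
    adjust_low_in: float | None = None,
    threshold_rule: str = "universal_soft",
) -> SpatialResponseMap:
    """Denoise one degraded record over the (level, order) grid and score it.

    Cell (k, n) holds ``metric(denoise(degraded, family, order=n, level=k),
    clean)``; for images the intensity adjustment (if ``adjust_low_in`` is
    set) is applied before scoring. Infeasible or metric-degenerate cells are
    NaN.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    deg = degraded.data if isinstance(degraded, CleanRecord) else np.asarray(degraded, float)
    if deg.shape != clean.data.shape:
        raise ValueError("clean and degraded shapes must match")
    grids = _evaluate_grid(
        clean.data, deg, family, (metric,), n_levels, n_orders, adjust_low_in, threshold_rule
    )
    return SpatialResponseMap(
        values=grids[metric], metric=metric, family=family, eta=eta, item_id=clean.label
    )


def volumetric_response(
    bank: list[CleanRecord],
    family: str,
    schedule: NoiseSchedule,
    metric: str | tuple[str, ...] = METRICS,
    master_seed: int = 0,
    n_levels: int = MAX_LEVEL,
    n_orders: int = MAX_ORDER,
    adjust_low_in: float | dict[str, float] | None = None,
    threshold_rule: str = "universal_soft",
    speckle_variance: float = 0.05,
    impulse_p: float = 0.05,
    gaussian_interpretation: str = "mean",
) -> VolumetricResponse | dict[str, VolumetricResponse]:
    """Sweep a record bank over the noise schedule for one wavelet family.

    tensor[k, n, i, j] is the spatial-map cell for item ``j`` degraded by the
    composite noise at η = schedule[i]. The noise seed for each (i, j) is
    derived from ``(master_seed, i, j)``, so tensors are exactly reproducible
    and independent of sweep order. Passing a tuple of metrics evaluates all
    of them in a single denoising pass and returns a dict.

    ``adjust_low_in`` may be a single float, a mapping from a record's
    ``meta['phantom_kind']``/label to a float, or None (no adjustment).
    """
    single = isinstance(metric, str)
    metrics = (metric,) if single else tuple(metric)
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    if not bank:
        raise ValueError("bank must be nonempty")
    tensors = {
        m: np.full((n_levels, n_orders, len(schedule), len(bank)), np.nan) for m in metrics
    }
    for j, record in enumerate(bank):
        low_in = _resolve_low_in(adjust_low_in, record)
        for i, eta in enumerate(schedule.levels):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(master_seed), int(i), int(j)])
            )
            degraded = composite_noise(
                record,
                float(eta),
                rng,
                speckle_variance=speckle_variance,
                impulse_p=impulse_p,
                gaussian_interpretation=gaussian_interpretation,
            )
            grids = _evaluate_grid(
                record.data,
                degraded.data,
                family,
                metrics,
                n_levels,
                n_orders,
                low_in,
                threshold_rule,
            )
            for m in metrics:
                tensors[m][:, :, i, j] = grids[m]
    item_ids = [r.label for r in bank]
    out = {
        m: VolumetricResponse(
            tensor=tensors[m], metric=m, family=family, schedule=schedule, item_ids=item_ids
        )
        for m in metrics
    }
    return out[metric] if single else out


def _resolve_low_in(
    adjust_low_in: float | dict[str, float] | None, record: CleanRecord
) -> float | None:
    if adjust_low_in is None or record.kind == "signal":
        return None
    if isinstance(adjust_low_in, dict):
        key = record.meta.get("phantom_kind", record.label)
        return adjust_low_in.get(key, adjust_low_in.get("default"))
    return float(adjust_low_in)


def _best_of_matrix(matrix: np.ndarray, metric: str) -> tuple[float, int, int]:
    """Extremum of a (level, order) matrix with NaNs; ties → lowest level,
    then lowest order (row-major scan order guarantees this)."""
    if np.all(np.isnan(matrix)):
        raise ValueError("all cells missing in this slice")
    best = np.nanmax(matrix) if metric in HIGHER_IS_BETTER else np.nanmin(matrix)
    rows, cols = np.where(matrix == best)
    return float(best), int(rows[0]) + 1, int(cols[0]) + 1


def best_settings(vr: VolumetricResponse, item_aggregate: str = "mean") -> Recommendation:
    """Per-η best (level, order) after aggregating the item axis.

    Items are combined by NaN-aware mean (median available); the extremum —
    max for corr/psnr, min for mse/ed — is then located on the (level, order)
    grid. The reported value always equals the aggregated tensor value at the
    reported index.
    """
    agg = {"mean": np.nanmean, "median": np.nanmedian}[item_aggregate]
    rows = []
    rankings = []
    for i in range(vr.n_eta):
        slab = vr.tensor[:, :, i, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            matrix = agg(slab, axis=2)
        value, level, order = _best_of_matrix(matrix, vr.metric)
        feasible = int(np.sum(~np.isnan(matrix)))
        rows.append(
            {
                "eta": float(vr.schedule.levels[i]),
                "family": vr.family,
                "level": level,
                "order": order,
                "best_value": value,
                "n_feasible_cells": feasible,
            }
        )
        lv, od = np.nonzero(~np.isnan(matrix))
        rank = pd.DataFrame(
            {"level": lv + 1, "order": od + 1, "value": matrix[lv, od]}
        ).sort_values(
            "value", ascending=vr.metric not in HIGHER_IS_BETTER, kind="mergesort"
        ).reset_index(drop=True)
        rankings.append(rank)
    return Recommendation(
        metric=vr.metric, family=vr.family, table=pd.DataFrame(rows), ranking=rankings
    )


def max_achievable_curve(vr: VolumetricResponse, item_aggregate: str = "mean") -> np.ndarray:
    """Best-achievable metric value per η, regardless of (level, order).

    The optimum over the grid is taken per item first, then items are
    averaged — the 'highest achievable' reading; set
    ``item_aggregate='median'`` for the robust alternative.
    """
    extremum = np.nanmax if vr.metric in HIGHER_IS_BETTER else np.nanmin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_item = extremum(vr.tensor, axis=(0, 1))  # (n_eta, n_items)
        agg = {"mean": np.nanmean, "median": np.nanmedian}[item_aggregate]
        return agg(per_item, axis=1)


def best_values_flat(vr: VolumetricResponse) -> np.ndarray:
    """All per-η-per-item best values, flattened (the population the
    robustness tests compare between datasets)."""
    extremum = np.nanmax if vr.metric in HIGHER_IS_BETTER else np.nanmin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_item = extremum(vr.tensor, axis=(0, 1))
    return per_item.ravel()


def family_summary(vrs: dict[str, VolumetricResponse]) -> pd.DataFrame:
    """Per-family mean achievable value and difference from the best family.

    ``difference`` is family mean − best family mean, so the winning family
    scores 0 and, for metrics where higher is better, the rest are negative.
    """
    if not vrs:
        raise ValueError("need at least one family")
    metrics_set = {vr.metric for vr in vrs.values()}
    if len(metrics_set) > 1:
        raise ValueError(f"mixed metrics in family summary: {metrics_set}")
    metric = metrics_set.pop()
    shapes = {vr.tensor.shape[2:] for vr in vrs.values()}
    if len(shapes) > 1:
        raise ValueError("families must share schedule and bank")
    means = {fam: float(np.nanmean(best_values_flat(vr))) for fam, vr in vrs.items()}
    best = max(means.values()) if metric in HIGHER_IS_BETTER else min(means.values())
    return pd.DataFrame(
        [
            {
                "family": fam,
                "metric": metric,
                "mean_best_value": mean,
                "difference_from_best": mean - best,
            }
            for fam, mean in means.items()
        ]
    )


def recommend_across_families(
    vrs: dict[str, VolumetricResponse], item_aggregate: str = "mean"
) -> pd.DataFrame:
    """Per-η overall winner across families (family order breaks exact ties)."""
    per_family = {f: best_settings(vr, item_aggregate).table for f, vr in vrs.items()}
    metric = next(iter(vrs.values())).metric
    hib = metric in HIGHER_IS_BETTER
    rows = []
    n_eta = len(next(iter(per_family.values())))
    for i in range(n_eta):
        candidates = [tbl.iloc[i] for tbl in per_family.values()]
        best_row = max(candidates, key=lambda r: r["best_value"]) if hib else min(
            candidates, key=lambda r: r["best_value"]
        )
        rows.append(dict(best_row))
    out = pd.DataFrame(rows)
    out.insert(0, "metric", metric)
    return out
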