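"""Similarity/difference metrics between a denoised record and its gold standard.

Four quantities: mean squared error, Pearson correlation over all elements,
Euclidean distance, and PSNR. ED and MSE are algebraically tied
(ED² = m·n·MSE); PSNR is 10·log10(peak²/MSE) with peak fixed at 1.0 for
normalized images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METRICS = ("corr", "mse", "ed", "psnr")
#: Metrics where larger is better (the rest are minimized).
HIGHER_IS_BETTER = frozenset({"corr", "psnr"})


class DegenerateMetricError(ValueError):
    """Metric undefined on this input (e.g. correlation of a constant array)."""


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty arrays")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean of squared elementwise differences."""
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def corr2d(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over all elements (means removed). Works for 1D too.

    Raises :class:`DegenerateMetricError` on constant input — the quantity is
    undefined there and silently reporting 0 would bias family summaries.
    """
    x, y = _check_shapes(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise DegenerateMetricError("correlation undefined for constant input")
    return float(np.clip(np.sum(xc * yc) / denom, -1.0, 1.0))


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Square root of the sum of squared differences (Frobenius distance)."""
    x, y = _check_shapes(x, y)
    return float(np.sqrt(np.sum((x - y) ** 2)))


def psnr(mse_value: float, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10·log10(peak²/MSE), in dB; +inf at MSE = 0."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    if mse_value < 0:
        raise ValueError("mse must be >= 0")
    if mse_value == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse_value))


@dataclass
class MetricReport:
    """All four metrics for one (denoised, gold-standard) pair.

    ``corr`` is NaN when undefined (constant input); aggregation layers
    exclude NaNs rather than treating them as zeros.
    """

    mse: float
    corr: float
    euclidean_distance: float
    psnr_db: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "corr": self.corr,
            "ed": self.euclidean_distance,
            "psnr": self.psnr_db,
        }


def compute_report(x: np.ndarray, y: np.ndarray, peak: float = 1.0) -> MetricReport:
    """Evaluate all metrics at once (one pass over the pair)."""
    m = mse(x, y)
    try:
        c = corr2d(x, y)
    except DegenerateMetricError:
        c = float("nan")
    return MetricReport(
        mse=m,
        corr=c,
        euclidean_distance=float(np.sqrt(m * np.asarray(x).size)),
        psnr_db=psnr(m, peak),
    )
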