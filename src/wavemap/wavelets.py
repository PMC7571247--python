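"""Discrete wavelet decomposition, universal-threshold shrinkage, intensity adjust.

Three orthogonal families are supported — Daubechies, Symlet, Coiflet — at
orders 1..5 and decomposition levels 1..5 (order is capped at 5 because the
highest available Coiflet order is 5, which keeps the sweep grid square).
Denoising follows the classical global-threshold recipe: estimate the noise
scale σ from the finest detail band with the MAD estimator, form the
universal threshold T = σ·sqrt(2·ln N), shrink all detail coefficients, and
reconstruct. The DWT itself is delegated to PyWavelets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage import exposure

FAMILIES = ("daubechies", "symlet", "coiflet")
MAX_ORDER = 5
MAX_LEVEL = 5
THRESHOLD_RULES = ("universal_soft", "universal_hard")

#: Scale factor relating the median absolute deviation to σ for Gaussian data.
MAD_TO_SIGMA = 0.6745


class InfeasibleLevelError(ValueError):
    """Requested decomposition level exceeds what the record size admits."""


def pywt_name(family: str, order: int) -> str:
    """Map (family, order) to the PyWavelets wavelet name.

    Symlet order 1 coincides with Daubechies order 1 (both are Haar), and
    PyWavelets only ships symlets from order 2, so sym1 maps to db1.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(
            f"order must be in 1..{MAX_ORDER} (the highest available Coiflet order is 5), "
            f"got {order}"
        )
    if family == "daubechies":
        return f"db{order}"
    if family == "symlet":
        return "db1" if order == 1 else f"sym{order}"
    return f"coif{order}"


@dataclass(frozen=True)
class WaveletConfig:
    """One point of the sweep grid: family, order, level, threshold rule."""

    family: str
    order: int
    level: int
    threshold_rule: str = "universal_soft"

    def __post_init__(self) -> None:
        pywt_name(self.family, self.order)  # validates family and order
        if not 1 <= self.level <= MAX_LEVEL:
            raise ValueError(f"level must be in 1..{MAX_LEVEL}, got {self.level}")
        if self.threshold_rule not in THRESHOLD_RULES:
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(pywt_name(self.family, self.order))


def filter_bank(family: str, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return the orthonormal (dec_lo, dec_hi, rec_lo, rec_hi) filter quadruple."""
    w = pywt.Wavelet(pywt_name(family, order))
    return tuple(np.asarray(f, dtype=np.float64) for f in (w.dec_lo, w.dec_hi, w.rec_lo, w.rec_hi))


def save_filter_table(path) -> None:
    """Write all supported filters as plain text: one line per filter,
    ``family order which coeff coeff ...`` with space-separated decimals."""
    with open(path, "w") as fh:
        for family in FAMILIES:
            for order in range(1, MAX_ORDER + 1):
                quad = filter_bank(family, order)
                for which, filt in zip(("dec_lo", "dec_hi", "rec_lo", "rec_hi"), quad):
                    coeffs = " ".join(repr(float(c)) for c in filt)
                    fh.write(f"{family} {order} {which} {coeffs}\n")


def load_filter_table(path) -> dict[tuple[str, int, str], np.ndarray]:
    """Read a filter table written by :func:`save_filter_table` (bit-exact)."""
    table: dict[tuple[str, int, str], np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            family, order, which = parts[0], int(parts[1]), parts[2]
            table[(family, order, which)] = np.array([float(c) for c in parts[3:]])
    return table


def max_feasible_level(data_shape: tuple[int, ...], family: str, order: int) -> int:
    """Largest decomposition level the record size admits for this filter."""
    filt_len = pywt.Wavelet(pywt_name(family, order)).dec_len
    return pywt.dwt_max_level(min(data_shape), filt_len)


def is_feasible(data_shape: tuple[int, ...], config: WaveletConfig) -> bool:
    return config.level <= max_feasible_level(data_shape, config.family, config.order)


@dataclass
class CoefficientPyramid:
    """Multi-level DWT coefficients plus the metadata needed to invert them."""

    coeffs: list  # pywt wavedec/wavedec2 coefficient list
    config: WaveletConfig
    mode: str
    shape: tuple[int, ...]

    @property
    def approximation(self) -> np.ndarray:
        return self.coeffs[0]

    @property
    def details(self) -> list:
        """Detail bands, coarsest first; per level a 1D array or an (H, V, D) triple."""
        return self.coeffs[1:]

    @property
    def finest_details(self) -> np.ndarray:
        """Finest-scale detail coefficients used for noise estimation.

        1D: the level-1 detail band. 2D: the level-1 diagonal (HH) subband,
        the standard choice for noise estimation in images because it carries
        the least image structure.
        """
        finest = self.coeffs[-1]
        if isinstance(finest, (tuple, list)):
            return np.asarray(finest[2])
        return np.asarray(finest)

    def n_samples(self) -> int:
        """Total element count of the original record (drives the threshold)."""
        return int(np.prod(self.shape))


def decompose(data: np.ndarray, config: WaveletConfig, mode: str = "symmetric") -> CoefficientPyramid:
    """Multi-level DWT of a 1D or 2D array at the configured level.

    Raises :class:`InfeasibleLevelError` when the record is too small for the
    requested level with this filter length; callers record a missing cell.
    """
    data = np.asarray(data, dtype=np.float64)
    if not is_feasible(data.shape, config):
        raise InfeasibleLevelError(
            f"level {config.level} infeasible for shape {data.shape} with "
            f"{pywt_name(config.family, config.order)} "
            f"(max {max_feasible_level(data.shape, config.family, config.order)})"
        )
    wavedec = pywt.wavedec if data.ndim == 1 else pywt.wavedec2
    coeffs = wavedec(data, config.wavelet, mode=mode, level=config.level)
    return CoefficientPyramid(coeffs=coeffs, config=config, mode=mode, shape=data.shape)


def reconstruct(pyramid: CoefficientPyramid) -> np.ndarray:
    """Inverse DWT; output cropped to the original shape."""
    waverec = pywt.waverec if len(pyramid.shape) == 1 else pywt.waverec2
    out = waverec(pyramid.coeffs, pyramid.config.wavelet, mode=pyramid.mode)
    slices = tuple(slice(0, s) for s in pyramid.shape)
    return np.asarray(out)[slices]


def estimate_sigma(pyramid: CoefficientPyramid) -> float:
    """Robust noise-scale estimate: median(|finest details|) / 0.6745."""
    finest = pyramid.finest_details
    if finest.size == 0:
        raise ValueError("empty finest detail band")
    return float(np.median(np.abs(finest)) / MAD_TO_SIGMA)


def universal_threshold(sigma: float, n_samples: int) -> float:
    """Donoho–Johnstone universal threshold T = σ·sqrt(2·ln n)."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(sigma * np.sqrt(2.0 * np.log(n_samples)))


def _shrink_band(band: np.ndarray, threshold: float, rule: str) -> np.ndarray:
    band = np.asarray(band)
    if rule == "universal_soft":
        return np.sign(band) * np.maximum(np.abs(band) - threshold, 0.0)
    return band * (np.abs(band) > threshold)


def shrink(pyramid: CoefficientPyramid, threshold: float, rule: str | None = None) -> CoefficientPyramid:
    """Threshold all detail bands (approximation untouched).

    Soft: c → sign(c)·max(|c|−T, 0). Hard: c → c·1[|c|>T].
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rule = rule or pyramid.config.threshold_rule
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {rule!r}")
    new_coeffs = [np.asarray(pyramid.coeffs[0]).copy()]
    for band in pyramid.coeffs[1:]:
        if isinstance(band, (tuple, list)):
            new_coeffs.append(tuple(_shrink_band(b, threshold, rule) for b in band))
        else:
            new_coeffs.append(_shrink_band(band, threshold, rule))
    return CoefficientPyramid(
        coeffs=new_coeffs, config=pyramid.config, mode=pyramid.mode, shape=pyramid.shape
    )


def denoise(data: np.ndarray, config: WaveletConfig, mode: str = "symmetric") -> np.ndarray:
    """Global-threshold wavelet shrinkage of a 1D or 2D array.

    One threshold T = σ̂·sqrt(2·ln N) (N = total element count) is applied to
    every detail level. Output has the input's shape.
    """
    pyramid = decompose(data, config, mode=mode)
    sigma = estimate_sigma(pyramid)
    threshold = universal_threshold(sigma, pyramid.n_samples())
    return reconstruct(shrink(pyramid, threshold))


def adjust_intensity(image: np.ndarray, low_in: float, high_in: float = 1.0) -> np.ndarray:
    """Linear contrast stretch mapping [low_in, high_in] onto [0, 1], clipping outside.

    Applied after 2D denoising to restore the contrast that additive-noise
    brightening and shrinkage compress; typical low_in ≈ 0.4–0.6.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("adjust_intensity expects a 2D image")
    if not 0.0 <= low_in < 1.0:
        raise ValueError("low_in must lie in [0, 1)")
    if not low_in < high_in <= 1.0:
        raise ValueError("high_in must lie in (low_in, 1]")
    return exposure.rescale_intensity(image, in_range=(low_in, high_in), out_range=(0.0, 1.0))
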