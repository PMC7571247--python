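"""Noise models applied to gold-standard records.

1D records are degraded by additive white Gaussian noise specified through a
signal-to-noise ratio measured on the input (``awgn(x, snr, 'measured')``
semantics) plus symmetric impulse noise of prescribed variance. 2D records
are degraded by additive Gaussian noise, salt-and-pepper impulses, and
multiplicative speckle ``J = I + n*I`` with a zero-mean uniform multiplier
field ``n``. Composite schedules raise the intensity parameter η step by
step to emulate dynamically increasing noise.

All stochastic operations accept either an integer seed or a
``numpy.random.Generator`` and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CleanRecord

#: Default speckle multiplier variance (held constant along 2D schedules).
DEFAULT_SPECKLE_VARIANCE = 0.05
#: Default variance of the 2D additive Gaussian noise when its parameter is a mean.
DEFAULT_GAUSSIAN_VARIANCE = 0.01
#: Default per-sample impulse occurrence probability for the 1D impulse model.
DEFAULT_IMPULSE_P = 0.05

NOISE_KINDS = (
    "awgn_1d",
    "impulse_1d",
    "gaussian_2d",
    "salt_pepper_2d",
    "speckle_2d",
    "composite_1d",
    "composite_2d",
)

_REQUIRED_FIELDS = {
    "awgn_1d": ("snr_db",),
    "impulse_1d": ("impulse_variance",),
    "gaussian_2d": ("gauss_param",),
    "salt_pepper_2d": ("sp_density",),
    "speckle_2d": ("speckle_variance",),
    "composite_1d": ("eta",),
    "composite_2d": ("eta",),
}


def _as_rng(rng: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class NoiseSpec:
    """A parameterized noise description, serializable to/from JSON dicts."""

    kind: str
    snr_db: float | None = None
    impulse_variance: float | None = None
    gauss_param: float | None = None
    sp_density: float | None = None
    speckle_variance: float | None = None
    eta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        for name in _REQUIRED_FIELDS[self.kind]:
            if getattr(self, name) is None:
                raise ValueError(f"noise kind {self.kind!r} requires field {name!r}")
        if self.sp_density is not None and not 0.0 <= self.sp_density <= 1.0:
            raise ValueError("sp_density must lie in [0, 1]")
        for name in ("impulse_variance", "speckle_variance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)

    def apply(self, record: CleanRecord, rng: np.random.Generator | int | None = None) -> CleanRecord:
        """Apply this noise to a record; seed defaults to the spec's own."""
        r = _as_rng(self.seed if rng is None else rng)
        if self.kind == "awgn_1d":
            return add_awgn_1d(record, self.snr_db, r)
        if self.kind == "impulse_1d":
            return add_impulse_1d(record, self.impulse_variance, r)
        if self.kind == "gaussian_2d":
            return add_gaussian_2d(record, self.gauss_param, r)
        if self.kind == "salt_pepper_2d":
            return add_salt_pepper(record, self.sp_density, r)
        if self.kind == "speckle_2d":
            return add_speckle(record, self.speckle_variance, r)
        speckle = (
            self.speckle_variance
            if self.speckle_variance is not None
            else DEFAULT_SPECKLE_VARIANCE
        )
        return composite_noise(record, self.eta, r, speckle_variance=speckle)


@dataclass
class NoiseSchedule:
    """An ordered axis of noise intensities η (strictly increasing)."""

    levels: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.kind not in ("schedule_1d", "schedule_2d"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.levels.size == 0:
            raise ValueError("schedule must be nonempty")
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("schedule levels must be strictly increasing")

    def __len__(self) -> int:
        return int(self.levels.size)

    def to_dict(self) -> dict:
        return {"levels": self.levels.tolist(), "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return cls(levels=np.asarray(d["levels"]), kind=d["kind"])


def default_schedule(kind: str) -> NoiseSchedule:
    """The default intensity axes: 1D SNR 0.05..10 dB step 0.05 (200 levels);
    2D parameter 0, 0.1, ..., 1.0 (11 levels)."""
    if kind == "schedule_1d":
        return NoiseSchedule(levels=np.arange(1, 201) * 0.05, kind=kind)
    if kind == "schedule_2d":
        return NoiseSchedule(levels=np.arange(11) * 0.1, kind=kind)
    raise ValueError(f"unknown schedule kind {kind!r}")


def _data_1d(record: CleanRecord | np.ndarray) -> np.ndarray:
    x = record.data if isinstance(record, CleanRecord) else np.asarray(record, float)
    if x.ndim != 1:
        raise ValueError("expected a 1D signal")
    return x


def _data_2d(record: CleanRecord | np.ndarray) -> np.ndarray:
    x = record.data if isinstance(record, CleanRecord) else np.asarray(record, float)
    if x.ndim != 2:
        raise ValueError("expected a 2D image")
    return x


def _wrap(record: CleanRecord | np.ndarray, data: np.ndarray):
    if isinstance(record, CleanRecord):
        return record.copy_with(data)
    return data


def add_awgn_1d(
    signal: CleanRecord | np.ndarray, snr_db: float, rng: np.random.Generator | int
) -> CleanRecord | np.ndarray:
    """Add white Gaussian noise at a given SNR measured on the input.

    Noise power is ``P_signal / 10**(snr_db/10)`` with ``P_signal`` the mean
    square of the input ('measured' semantics).
    """
    x = _data_1d(signal)
    p_signal = float(np.mean(x**2))
    if p_signal == 0.0:
        raise ValueError("SNR undefined for an all-zero signal")
    rng = _as_rng(rng)
    noise_power = p_signal / 10.0 ** (snr_db / 10.0)
    noisy = x + rng.normal(0.0, np.sqrt(noise_power), size=x.shape)
    return _wrap(signal, noisy)


def add_impulse_1d(
    signal: CleanRecord | np.ndarray,
    variance: float,
    rng: np.random.Generator | int,
    p: float = DEFAULT_IMPULSE_P,
) -> CleanRecord | np.ndarray:
    """Add symmetric impulse noise of prescribed variance.

    Impulses of amplitude ±A hit each sample independently with probability
    ``p``; A = sqrt(variance / p) so the added noise has exactly the requested
    variance (and zero mean by the ± symmetry).
    """
    x = _data_1d(signal)
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = _as_rng(rng)
    if variance == 0.0:
        return _wrap(signal, x.copy())
    amplitude = np.sqrt(variance / p)
    hits = rng.random(x.shape) < p
    signs = rng.choice([-1.0, 1.0], size=x.shape)
    return _wrap(signal, x + hits * signs * amplitude)


def add_gaussian_2d(
    image: CleanRecord | np.ndarray,
    gauss_param: float,
    rng: np.random.Generator | int,
    variance: float = DEFAULT_GAUSSIAN_VARIANCE,
    interpretation: str = "mean",
    clip: bool = True,
) -> CleanRecord | np.ndarray:
    """Add Gaussian noise to an image and clip to [0, 1].

    With ``interpretation='mean'`` (default) the swept parameter is the noise
    mean and the variance stays fixed at 0.01, matching
    ``imnoise(I,'gaussian',m)``. With ``interpretation='variance'`` the
    parameter is the variance and the mean is 0 — the alternative reading of
    the same sweep. ``clip=False`` exposes the pre-clip field for moment
    checks.
    """
    x = _data_2d(image)
    rng = _as_rng(rng)
    if interpretation == "mean":
        mean, var = gauss_param, variance
    elif interpretation == "variance":
        mean, var = 0.0, gauss_param
    else:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    if var < 0:
        raise ValueError("variance must be >= 0")
    noisy = x + mean + (rng.normal(0.0, np.sqrt(var), size=x.shape) if var > 0 else 0.0)
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    return _wrap(image, noisy)


def add_salt_pepper(
    image: CleanRecord | np.ndarray, d: float, rng: np.random.Generator | int
) -> CleanRecord | np.ndarray:
    """Set a fraction ``d`` of pixels (in expectation) to 0 or 1, equiprobably."""
    x = _data_2d(image)
    if not 0.0 <= d <= 1.0:
        raise ValueError("density d must lie in [0, 1]")
    rng = _as_rng(rng)
    out = x.copy()
    hits = rng.random(x.shape) < d
    salt = rng.random(x.shape) < 0.5
    out[hits & salt] = 1.0
    out[hits & ~salt] = 0.0
    return _wrap(image, out)


def speckle_field(
    shape: tuple[int, int],
    variance: float = DEFAULT_SPECKLE_VARIANCE,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """The zero-mean uniform multiplier field n of the speckle model J = I + n*I.

    n is i.i.d. uniform on [−sqrt(3v), +sqrt(3v)], giving mean 0 and variance
    ``variance`` exactly.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = _as_rng(rng)
    half_width = np.sqrt(3.0 * variance)
    return rng.uniform(-half_width, half_width, size=shape)


def add_speckle(
    image: CleanRecord | np.ndarray,
    speckle_variance: float = DEFAULT_SPECKLE_VARIANCE,
    rng: np.random.Generator | int = 0,
) -> CleanRecord | np.ndarray:
    """Multiplicative speckle J = I + n*I, clipped to [0, 1]."""
    x = _data_2d(image)
    n = speckle_field(x.shape, speckle_variance, rng)
    return _wrap(image, np.clip(x + n * x, 0.0, 1.0))


def composite_noise(
    record: CleanRecord,
    eta: float,
    rng: np.random.Generator | int,
    speckle_variance: float = DEFAULT_SPECKLE_VARIANCE,
    impulse_p: float = DEFAULT_IMPULSE_P,
    gaussian_interpretation: str = "mean",
) -> CleanRecord:
    """The composite degradation applied at one schedule step η.

    1D: AWGN at snr_db = η then impulse noise with variance 1/η (η must be
    positive). 2D: Gaussian (parameter η) → speckle (constant variance)
    → salt-and-pepper (density η); applying salt-and-pepper last keeps its
    extreme pixels intact for the denoiser.
    """
    rng = _as_rng(rng)
    if record.kind == "signal":
        if eta <= 0:
            raise ValueError("1D composite noise requires eta > 0 (impulse variance 1/eta)")
        out = add_awgn_1d(record, eta, rng)
        return add_impulse_1d(out, 1.0 / eta, rng, p=impulse_p)
    out = add_gaussian_2d(record, eta, rng, interpretation=gaussian_interpretation)
    out = add_speckle(out, speckle_variance, rng)
    return add_salt_pepper(out, eta, rng)
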