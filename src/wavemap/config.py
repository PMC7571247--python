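"""Run configuration: one JSON-serializable object that pins down a sweep."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .metrics import METRICS
from .noise import DEFAULT_IMPULSE_P, DEFAULT_SPECKLE_VARIANCE, NoiseSchedule, default_schedule
from .wavelets import FAMILIES, MAX_LEVEL, MAX_ORDER, WaveletConfig

#: Default intensity-adjust low_in per phantom kind (CT-like / MR-like / other).
DEFAULT_ADJUST_LOW_IN = {"piecewise": 0.45, "smooth_textured": 0.40, "default": 0.50}


@dataclass
class RunConfig:
    """Everything a sweep needs, validated up front and round-trippable to JSON.

    ``inputs`` selects the record bank: either
    ``{"synthetic": {"n_images": ..., "n_signals": ..., "image_size": ...,
    "signal_length": ...}}`` or ``{"paths": [{"path": ..., "kind": ...}, ...]}``.
    """

    families: tuple[str, ...] = FAMILIES
    orders: tuple[int, ...] = tuple(range(1, MAX_ORDER + 1))
    levels: tuple[int, ...] = tuple(range(1, MAX_LEVEL + 1))
    schedule_kind: str = "schedule_2d"
    schedule_levels: list[float] | None = None
    metrics: tuple[str, ...] = METRICS
    threshold_rule: str = "universal_soft"
    impulse_p: float = DEFAULT_IMPULSE_P
    gaussian_interpretation: str = "mean"
    speckle_variance: float = DEFAULT_SPECKLE_VARIANCE
    adjust_low_in: dict = field(default_factory=lambda: dict(DEFAULT_ADJUST_LOW_IN))
    apply_adjust: bool = True
    master_seed: int = 0
    inputs: dict = field(
        default_factory=lambda: {"synthetic": {"n_images": 2, "n_signals": 0}}
    )
    output_dir: str = "wavemap_run"

    def __post_init__(self) -> None:
        for fam in self.families:
            for order in self.orders:
                for level in self.levels:
                    WaveletConfig(fam, order, level, self.threshold_rule)
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if not 0.0 < self.impulse_p <= 1.0:
            raise ValueError("impulse_p must lie in (0, 1]")
        if self.gaussian_interpretation not in ("mean", "variance"):
            raise ValueError("gaussian_interpretation must be 'mean' or 'variance'")
        if self.speckle_variance < 0:
            raise ValueError("speckle_variance must be >= 0")
        self.schedule()  # validates schedule fields

    def schedule(self) -> NoiseSchedule:
        if self.schedule_levels is not None:
            return NoiseSchedule(levels=self.schedule_levels, kind=self.schedule_kind)
        return default_schedule(self.schedule_kind)

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        for key in ("families", "orders", "levels", "metrics"):
            d[key] = list(d[key])
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        for key in ("families", "orders", "levels", "metrics"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
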