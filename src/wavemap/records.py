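"""Gold-standard records: the clean signals/images everything is scored against."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum length for a 1D record.
MIN_SIGNAL_LENGTH = 64
#: Minimum edge length for a 2D record.
MIN_IMAGE_EDGE = 32


@dataclass
class CleanRecord:
    """A gold-standard 1D signal or 2D image.

    Parameters
    ----------
    data
        1D float array (signals, any finite range) or 2D float array
        (images, values in [0, 1]).
    kind
        ``"signal"`` or ``"image"``; must agree with ``data.ndim``.
    label
        Free-text identifier used in reports and file names.
    provenance
        ``"synthetic"`` for generated fixtures, ``"file"`` for loaded data.
    """

    data: np.ndarray
    kind: str
    label: str = ""
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.kind not in ("signal", "image"):
            raise ValueError(f"kind must be 'signal' or 'image', got {self.kind!r}")
        if self.provenance not in ("synthetic", "file"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("record contains non-finite values")
        if self.kind == "signal":
            if self.data.ndim != 1:
                raise ValueError("signal records must be 1D")
            if self.data.size < MIN_SIGNAL_LENGTH:
                raise ValueError(
                    f"signal length {self.data.size} below minimum {MIN_SIGNAL_LENGTH}"
                )
        else:
            if self.data.ndim != 2:
                raise ValueError("image records must be 2D")
            if min(self.data.shape) < MIN_IMAGE_EDGE:
                raise ValueError(
                    f"image edge {min(self.data.shape)} below minimum {MIN_IMAGE_EDGE}"
                )
            if self.data.min() < 0.0 or self.data.max() > 1.0:
                raise ValueError("image intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "CleanRecord":
        """Return a record with the same metadata but new data (e.g. degraded)."""
        out = object.__new__(CleanRecord)
        out.data = np.asarray(data, dtype=np.float64)
        out.kind = self.kind
        out.label = self.label
        out.provenance = self.provenance
        out.meta = dict(self.meta)
        return out
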