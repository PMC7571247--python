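"""Synthetic gold-standard fixtures.

The sweep pipeline is exercised on three structural archetypes of biomedical
data: piecewise-constant high-contrast images (CT-like, sharp tissue/bone
boundaries), smooth low-frequency images with mild texture (MR-like soft
tissue), and burst-modulated broadband 1D signals (EMG-like muscle activity).
These phantoms reproduce the *structure* that matters to wavelet denoising —
edges, smooth gradients, bursts — not the imaging physics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .records import MIN_IMAGE_EDGE, MIN_SIGNAL_LENGTH, CleanRecord

#: Minimum number of samples a single burst window needs.
_MIN_BURST_SPAN = 32

PHANTOM_KINDS = ("piecewise", "smooth_textured")


def _child_seed(seed: int, index: int) -> int:
    """Derive a per-record seed by hashing (seed, index); avoids collisions."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def make_phantom_image(size: int, kind: str, seed: int) -> CleanRecord:
    """Generate a square synthetic phantom image with values in [0, 1].

    ``piecewise`` yields a dark background with 3–8 constant-intensity
    ellipses, every ellipse at least 0.2 above the background (high-contrast,
    CT-like). ``smooth_textured`` yields a low-frequency intensity gradient
    plus band-limited texture of amplitude ≤ 0.2 (MR-like). Deterministic
    given ``seed``.
    """
    if size < MIN_IMAGE_EDGE:
        raise ValueError(f"size {size} below minimum {MIN_IMAGE_EDGE}")
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / (size - 1)

    if kind == "piecewise":
        background = 0.05
        img = np.full((size, size), background)
        n_ellipses = int(rng.integers(3, 9))
        for _ in range(n_ellipses):
            cy, cx = rng.uniform(0.15, 0.85, size=2)
            ry, rx = rng.uniform(0.06, 0.28, size=2)
            theta = rng.uniform(0.0, np.pi)
            # constant intensity, gap >= 0.2 above background
            intensity = rng.uniform(background + 0.2, 1.0)
            dy, dx = yy - cy, xx - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            img[(u / ry) ** 2 + (v / rx) ** 2 <= 1.0] = intensity
    else:
        # low-frequency gradient: oriented cosine ramp across the frame
        phi = rng.uniform(0.0, np.pi)
        ramp = yy * np.cos(phi) + xx * np.sin(phi)
        img = 0.45 + 0.25 * np.cos(np.pi * ramp + rng.uniform(0, 2 * np.pi))
        # band-limited texture: heavily smoothed white noise, amplitude <= 0.2
        texture = rng.standard_normal((size, size))
        texture = ndimage.gaussian_filter(texture, sigma=size / 32.0, mode="wrap")
        peak = np.max(np.abs(texture))
        if peak > 0:
            texture *= 0.15 / peak
        img = img + texture

    img = np.clip(img, 0.0, 1.0)
    return CleanRecord(
        data=img,
        kind="image",
        label=f"phantom-{kind}-{seed}",
        provenance="synthetic",
        meta={"phantom_kind": kind, "seed": int(seed)},
    )


def make_emg_like_signal(n: int, n_bursts: int, seed: int) -> CleanRecord:
    """Generate a burst-modulated broadband signal.

    A zero-mean broadband carrier (white Gaussian, mildly band-limited) is
    multiplied by an envelope that is near-zero at baseline and rises to 1
    inside ``n_bursts`` raised-cosine burst windows, emulating interference-
    pattern muscle activity between quiet intervals. Deterministic given
    ``seed``.
    """
    if n < MIN_SIGNAL_LENGTH:
        raise ValueError(f"n {n} below minimum {MIN_SIGNAL_LENGTH}")
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    if n_bursts * _MIN_BURST_SPAN > n:
        raise ValueError(
            f"{n_bursts} bursts of span >= {_MIN_BURST_SPAN} do not fit in {n} samples"
        )
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n)
    # light smoothing keeps the carrier broadband but not pure white
    carrier = np.convolve(carrier, np.ones(3) / np.sqrt(3.0), mode="same")

    envelope = np.full(n, 0.02)  # quiet baseline, tiny residual tone
    span = n // n_bursts
    width = max(_MIN_BURST_SPAN // 2, span // 2)
    for b in range(n_bursts):
        start = b * span + (span - width) // 2
        t = np.arange(width)
        envelope[start : start + width] = np.maximum(
            envelope[start : start + width],
            0.5 * (1.0 - np.cos(2.0 * np.pi * t / (width - 1))),
        )
    signal = carrier * envelope
    return CleanRecord(
        data=signal,
        kind="signal",
        label=f"emg-like-{n_bursts}burst-{seed}",
        provenance="synthetic",
        meta={"n_bursts": int(n_bursts), "seed": int(seed), "burst_width": int(width)},
    )


def burst_windows(record: CleanRecord) -> list[tuple[int, int]]:
    """Return the (start, stop) sample windows of each burst of an EMG phantom."""
    n = record.data.size
    n_bursts = record.meta["n_bursts"]
    width = record.meta["burst_width"]
    span = n // n_bursts
    return [
        (b * span + (span - width) // 2, b * span + (span - width) // 2 + width)
        for b in range(n_bursts)
    ]


def make_bank(
    n_images: int,
    n_signals: int,
    seed: int,
    image_size: int = 128,
    signal_length: int = 4096,
) -> list[CleanRecord]:
    """Generate a bank of ``n_images`` phantoms followed by ``n_signals`` signals.

    Image kinds alternate piecewise / smooth_textured; per-record seeds are
    hashed from ``(seed, index)`` so banks are reproducible and collision-free.
    """
    if n_images < 0 or n_signals < 0:
        raise ValueError("counts must be >= 0")
    bank: list[CleanRecord] = []
    for i in range(n_images):
        kind = PHANTOM_KINDS[i % 2]
        bank.append(make_phantom_image(image_size, kind, _child_seed(seed, i)))
    for j in range(n_signals):
        bank.append(
            make_emg_like_signal(
                signal_length, 1 + j % 3, _child_seed(seed, n_images + j)
            )
        )
    return bank
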