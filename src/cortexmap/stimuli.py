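"""Input generation: background injection, retinal waves, Poisson spike
encoding of images, stereo/ON-OFF preprocessing, flag patterns and a
synthetic natural-image surrogate.

All frames are 2-D intensity grids scaled to [0, 1].  Poisson interspike-
interval encoding converts intensities into spike trains: the ISI of a pixel
is Poisson-distributed with mean ``isi_base * image_mean / pixel`` (ms), so a
constant frame reproduces the published Poisson ISI at the image mean while
brighter pixels fire proportionally faster; zero-intensity pixels never
spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import NoiseParams, RetinalWaveParams, StereoParams

__all__ = [
    "StimulusFrame",
    "background_injection",
    "generate_retinal_wave",
    "encode_poisson",
    "make_stereo_pair",
    "make_on_off",
    "route_on_off",
    "generate_flag_pattern",
    "synthetic_natural_surrogate",
    "downsample",
]

_DIRECTIONS = np.array([
    (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)
], dtype=float)  # 8-way compass, 45 degree increments


@dataclass
class StimulusFrame:
    """A 2-D intensity image destined for Poisson spike encoding."""

    pixels: np.ndarray
    eye: str = "both"          # 'left' | 'right' | 'both'
    channel: str = "raw"       # 'raw' | 'ON' | 'OFF'

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")


def background_injection(n_neurons: int, params: NoiseParams, rng) -> np.ndarray:
    """Per-neuron injected current for one injection window.

    Draws r ~ U(0,1) per neuron; u(r) = 1 iff r >= mu (or, with the
    ``inject_fraction`` override, iff r < fraction); the injected magnitude is
    ``A * u(r) * conversion_g`` held for the window duration.  A fresh random
    subset is drawn every window by calling this again.
    """
    r = rng.random(n_neurons)
    if params.inject_fraction is None:
        u = r >= params.mu
    else:
        u = r < params.inject_fraction
    return params.A * u.astype(float) * params.conversion_g


def downsample(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Down-sample a frame to ``shape``, preserving the mean intensity.

    Uses exact block averaging when the sizes divide, bilinear resampling
    otherwise.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    H, W = shape
    if h % H == 0 and w % W == 0:
        return frame.reshape(H, h // H, W, w // W).mean(axis=(1, 3))
    zoomed = ndimage.zoom(frame, (H / h, W / w), order=1, mode="grid-wrap")
    return np.clip(zoomed, 0.0, 1.0)


def generate_retinal_wave(params: RetinalWaveParams, rng,
                          out_shape: tuple[int, int] | None = None):
    """One retinal wave for one eye: a list of per-ms frames.

    For each of N randomly chosen initiation sites a direction is drawn from
    the 8-way set; a ``burst_size`` x ``burst_size`` neighborhood around the
    moving center is activated each ms with Gaussian strength falloff, the
    center advancing ``velocity`` lattice steps per ms along the direction
    (periodic wrap).  The wave terminates after ``duration`` ms.  Frames are
    down-sampled to ``out_shape`` (the LGN lattice) when given.
    """
    g = params.grid
    frames = []
    n = params.n_sites
    sites = rng.integers(0, g, size=(n, 2)).astype(float)
    dirs = _DIRECTIONS[rng.integers(0, 8, size=n)]
    half = params.burst_size / 2.0
    yy, xx = np.mgrid[0:g, 0:g].astype(float)
    for t in range(params.duration):
        frame = np.zeros((g, g))
        centers = sites + params.velocity * t * dirs
        for c in centers:
            dy = (yy - c[0] + g / 2) % g - g / 2
            dx = (xx - c[1] + g / 2) % g - g / 2
            inside = (np.abs(dy) <= half) & (np.abs(dx) <= half)
            strength = np.exp(-(dy ** 2 + dx ** 2) / (2 * params.falloff_sigma ** 2))
            frame = np.maximum(frame, inside * strength)
        if out_shape is not None:
            frame = downsample(frame, out_shape)
        frames.append(frame)
    if params.gap_ms:
        blank = np.zeros(out_shape if out_shape is not None else (g, g))
        frames.extend([blank] * params.gap_ms)
    return frames


def encode_poisson(frame, duration_ms: int, rng, isi_base_ms: float = 20.0) -> np.ndarray:
    """Poisson ISI spike encoding of a frame.

    Returns a boolean array of shape ``(n_pixels, duration_ms)``.  Each
    pixel's interspike intervals are drawn from a Poisson distribution whose
    mean is ``isi_base_ms * image_mean / intensity`` (floored at 1 ms), so the
    image mean sets the base rate and pixel intensity modulates it; for a
    constant-intensity frame the ISI is Poisson(isi_base_ms) exactly.
    Zero-intensity pixels emit no spikes.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    pixels = np.asarray(frame.pixels if isinstance(frame, StimulusFrame) else frame,
                        dtype=float).ravel()
    n = pixels.size
    spikes = np.zeros((n, duration_ms), dtype=bool)
    active = pixels > 0
    if not active.any():
        return spikes
    mean = pixels.mean()
    lam = isi_base_ms * mean / pixels[active]
    idx = np.flatnonzero(active)
    t = np.maximum(1, rng.poisson(lam))  # first spike time per active pixel
    while True:
        live = t <= duration_ms
        if not live.any():
            break
        spikes[idx[live], t[live] - 1] = True
        t = t + np.maximum(1, rng.poisson(lam))
        t[~live] = duration_ms + 1
    return spikes


def encode_frames_rate(frames, peak_rate_hz: float, rng, dt_ms: float = 1.0) -> np.ndarray:
    """Poisson (Bernoulli-thinned) encoding of a per-ms frame sequence.

    For time-varying stimuli such as retinal waves, each pixel spikes in each
    1 ms frame with probability ``intensity * peak_rate_hz * dt / 1000`` — an
    inhomogeneous Poisson process at the simulation resolution whose rate is
    proportional to intensity, with a fully driven pixel firing at
    ``peak_rate_hz``.  Returns a boolean array (n_pixels, n_frames).
    """
    stack = np.stack([np.asarray(f, dtype=float).reshape(-1) for f in frames], axis=1)
    p = np.clip(stack * peak_rate_hz * dt_ms / 1000.0, 0.0, 1.0)
    return rng.random(p.shape) < p


def make_stereo_pair(frame: StimulusFrame, params: StereoParams, rng):
    """Create a (left, right) stereo pair from one frame.

    The right-eye image is the left translated by a uniformly drawn integer
    shift bounded by ``max_shift`` in each axis and rescaled about its center
    by a factor drawn from ``scale_range``; out-of-frame pixels replicate the
    edge.
    """
    left = StimulusFrame(frame.pixels.copy(), eye="left", channel=frame.channel)
    dx = int(rng.integers(-params.max_shift, params.max_shift + 1))
    dy = int(rng.integers(-params.max_shift, params.max_shift + 1))
    s = float(rng.uniform(*params.scale_range))
    right_px = affine_resample(frame.pixels, shift=(dy, dx), scale=s)
    right = StimulusFrame(right_px, eye="right", channel=frame.channel)
    return left, right


def affine_resample(pixels: np.ndarray, shift=(0, 0), scale: float = 1.0) -> np.ndarray:
    """Translate then rescale (about the center) with edge replication."""
    out = ndimage.shift(pixels, shift, order=1, mode="nearest")
    if scale != 1.0:
        h, w = pixels.shape
        center = (np.array([h, w]) - 1) / 2.0
        matrix = np.eye(2) / scale
        offset = center - matrix @ center
        out = ndimage.affine_transform(out, matrix, offset=offset, order=1,
                                       mode="nearest")
    return np.clip(out, 0.0, 1.0)


def make_on_off(frame: StimulusFrame, mode: str = "mean_centered"):
    """Split a frame into (ON, OFF) channels.

    ON passes the frame through; OFF is the rectified inverse — either
    ``max(0, mean - pixel)`` (mean-centered, default: avoids a constant
    pedestal) or ``max(0, 1 - pixel)``.
    """
    px = frame.pixels
    on = StimulusFrame(px.copy(), eye=frame.eye, channel="ON")
    if mode == "mean_centered":
        off_px = np.clip(px.mean() - px, 0.0, 1.0)
    elif mode == "one_minus":
        off_px = np.clip(1.0 - px, 0.0, 1.0)
    else:
        raise ValueError("mode must be 'mean_centered' or 'one_minus'")
    off = StimulusFrame(off_px, eye=frame.eye, channel="OFF")
    return on, off


def route_on_off(on: StimulusFrame, off: StimulusFrame,
                 rgc_shape: tuple[int, int]) -> np.ndarray:
    """Pack ON and OFF channels onto one RGC sheet (top/bottom halves).

    Each channel is down-sampled to half-height regions of the RGC lattice
    (e.g. 48x24 each on a 48x48 sheet).
    """
    H, W = rgc_shape
    half = H // 2
    top = downsample(on.pixels, (half, W))
    bottom = downsample(off.pixels, (H - half, W))
    return np.concatenate([top, bottom], axis=0)


def generate_flag_pattern(rng, shape: tuple[int, int] = (48, 48)) -> StimulusFrame:
    """A flag-like block pattern composed only of 0 and 90 degree bars.

    The frame is split into vertical blocks, each filled with either
    horizontal or vertical stripes of random period and phase, so oriented
    energy is concentrated at 0/90 degrees (corner artifacts aside).
    """
    H, W = shape
    img = np.zeros((H, W))
    n_blocks = int(rng.integers(1, 4))
    edges = np.sort(rng.choice(np.arange(4, W - 3), size=n_blocks - 1, replace=False)) \
        if n_blocks > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], edges, [W]])
    yy, xx = np.mgrid[0:H, 0:W]
    for b in range(n_blocks):
        x0, x1 = bounds[b], bounds[b + 1]
        period = int(rng.integers(4, 13))
        phase = int(rng.integers(0, period))
        horizontal = bool(rng.integers(0, 2))
        coord = yy if horizontal else xx
        stripes = (((coord + phase) // (period // 2 + 1)) % 2).astype(float)
        img[:, x0:x1] = stripes[:, x0:x1]
    return StimulusFrame(img)


def synthetic_natural_surrogate(rng, shape: tuple[int, int] = (48, 48)) -> StimulusFrame:
    """A textured image with a natural-image-like 1/f amplitude spectrum.

    Shapes white Gaussian noise in the Fourier domain by 1/|f|, which yields
    broadband, approximately isotropic orientation content; intensities are
    rescaled to [0, 1].  Stands in for natural-photograph crops.
    """
    H, W = shape
    noise = rng.standard_normal((H, W))
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC; re-added by normalization
    spectrum = np.fft.fft2(noise) / f
    img = np.real(np.fft.ifft2(spectrum))
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return StimulusFrame(img)
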