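"""Map and stability analyses derived from network state.

* RCM (recurrent cortical map): anisotropy of local E->E connectivity found
  by matching zero-mean Gaussian-bar templates at four orientations against
  each neuron's neighborhood weight image, then combining the per-orientation
  match scores with the angle-doubling vector sum.
* ODM (ocular dominance map): per-neuron eye labeling by the larger summed
  geniculocortical weight, smoothed with a 3x3 median filter, plus the
  separation statistics and dominance fractions tracked over development.
* OSM (orientation selectivity map): oriented-bar probing of a cloned,
  plasticity-frozen network; differential rate images at complementary
  orientations are converted to doubled-angle Cartesian components, median
  filtered (9x9 at full scale), and read out in polar form as preference
  (halved angle) and selectivity (magnitude).
* Orientation gradients, fractures (>= 90 degree line discontinuities) and
  pinwheel-like patterns (winding-number test on 3x3 rings).
* Stability traces: symmetric KL similarity between max-normalized weight
  histograms, and excitatory/inhibitory current balance over 200 ms windows.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import OsmProtocolParams, RcmParams
from .stimuli import encode_poisson

__all__ = [
    "OrientationMap",
    "OdmMap",
    "StabilityTrace",
    "gaussian_bar_template",
    "compute_rcm",
    "compute_odm",
    "odm_separation_stats",
    "dominance_fraction",
    "measure_osm",
    "osm_vector_sum",
    "orientation_gradient",
    "find_fractures",
    "find_pinwheel_like",
    "kl_similarity",
    "current_balance",
]


@dataclass
class OrientationMap:
    """Per-neuron preference angle [0, 180), selectivity and gradient."""

    preference: np.ndarray          # degrees, shape (H, W)
    selectivity: np.ndarray         # non-negative magnitude
    source: str                     # 'rcm' | 'osm'
    gradient: np.ndarray | None = None
    undefined: np.ndarray | None = None  # bool mask where selectivity ~ 0


@dataclass
class OdmMap:
    """Eye labeling per E neuron with the underlying weight sums."""

    label: np.ndarray               # +1 left, -1 right, 0 binocular (H, W)
    sum_left: np.ndarray
    sum_right: np.ndarray


@dataclass
class StabilityTrace:
    """Per-synapse-class KL series and E-I current-difference series."""

    kl_steps: list = field(default_factory=list)
    kl: dict = field(default_factory=dict)            # class -> list of S values
    balance_steps: np.ndarray | None = None
    balance_instant: np.ndarray | None = None
    balance_running: np.ndarray | None = None


# ---------------------------------------------------------------------------
# RCM
# ---------------------------------------------------------------------------

def gaussian_bar_template(phi: float, gamma: float, params: RcmParams,
                          window: int) -> np.ndarray:
    """Zero-mean oriented Gaussian ridge over a ``window``-sided neighborhood.

    The ridge runs at angle ``phi`` (degrees), offset ``gamma`` along its
    normal, with width sigma_a across the bar and sigma_b along it; a
    constant is subtracted so the template sums to exactly zero.
    """
    r = window // 2
    x, y = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
    across = x * c + y * s - gamma
    along = y * c - x * s
    g = np.exp(-across ** 2 / (2 * params.sigma_a ** 2)) * \
        np.exp(-along ** 2 / (2 * params.sigma_b ** 2))
    return g - g.mean()


def _template_bank(params: RcmParams, window: int):
    gammas = np.arange(params.gamma_range[0], params.gamma_range[1] + 1e-9,
                       params.gamma_step)
    bank = np.stack([
        np.stack([gaussian_bar_template(phi, g, params, window) for g in gammas])
        for phi in params.phi_set
    ])  # (n_phi, n_gamma, win, win)
    return bank


def compute_rcm(neighborhood_weights: np.ndarray, params: RcmParams,
                lattice_shape: tuple[int, int] | None = None) -> OrientationMap:
    """Recurrent cortical map from per-neuron E->E neighborhood weights.

    ``neighborhood_weights`` has shape (n_neurons, win, win).  For each
    neuron and each template orientation phi, R(phi) is the maximum over the
    offset sweep gamma of the template/weight inner product; the four scores
    are combined as doubled-angle vectors and the preferred orientation is
    half the resultant angle.  Neurons whose resultant magnitude falls below
    ``rs_threshold`` times their neighborhood weight norm (e.g. isotropic
    neighborhoods, where orthogonal contributions cancel) are flagged
    undefined.  Neurons with an empty neighborhood are flagged as well.
    """
    w = np.asarray(neighborhood_weights, dtype=float)
    n, win, _ = w.shape
    bank = _template_bank(params, win)
    flat_w = w.reshape(n, -1)
    flat_bank = bank.reshape(bank.shape[0], bank.shape[1], -1)
    scores = np.einsum("nk,pgk->npg", flat_w, flat_bank)
    R = scores.max(axis=2)  # (n, n_phi)
    ang = np.deg2rad(2.0 * np.asarray(params.phi_set))
    sx = R @ np.cos(ang)
    sy = R @ np.sin(ang)
    rs = np.hypot(sx, sy)
    pref = (np.rad2deg(np.arctan2(sy, sx)) / 2.0) % 180.0
    norm = np.linalg.norm(flat_w, axis=1)
    empty = norm == 0
    undefined = empty | (rs < params.rs_threshold * np.maximum(norm, 1e-300))
    if lattice_shape is None:
        side = int(round(np.sqrt(n)))
        lattice_shape = (side, side)
    return OrientationMap(
        preference=pref.reshape(lattice_shape),
        selectivity=rs.reshape(lattice_shape),
        source="rcm",
        undefined=undefined.reshape(lattice_shape),
    )


# ---------------------------------------------------------------------------
# ODM
# ---------------------------------------------------------------------------

def compute_odm(sum_left: np.ndarray, sum_right: np.ndarray,
                lattice_shape: tuple[int, int], smoothing: int = 3) -> OdmMap:
    """Eye labels from summed geniculocortical weights.

    Labels by the larger eye-wise sum (exact tie -> binocular), then median
    filters the +1/0/-1 label image (periodic wrap) to remove speckle.
    Labels are invariant to any common positive rescaling of the weights.
    """
    sl = np.asarray(sum_left, dtype=float).reshape(lattice_shape)
    sr = np.asarray(sum_right, dtype=float).reshape(lattice_shape)
    label = np.sign(sl - sr).astype(int)
    if smoothing and smoothing > 1:
        label = ndimage.median_filter(label, size=smoothing, mode="wrap")
    return OdmMap(label=label, sum_left=sl, sum_right=sr)


def odm_separation_stats(odm: OdmMap) -> dict:
    """Mean/std of the left-right weight-sum difference per labeled group.

    The difference is oriented toward the group's dominant eye, matching the
    semilog separation plots tracked over development; population (ddof=0)
    standard deviation.
    """
    diff = odm.sum_left - odm.sum_right
    out = {}
    for name, mask, sign in (("left", odm.label > 0, 1.0),
                             ("right", odm.label < 0, -1.0)):
        vals = sign * diff[mask]
        if vals.size:
            out[f"mean_{name}"] = float(vals.mean())
            out[f"std_{name}"] = float(vals.std())
        else:
            out[f"mean_{name}"] = 0.0
            out[f"std_{name}"] = 0.0
    return out


def dominance_fraction(odm: OdmMap, eye: str = "left") -> float:
    """Average eye-dominance fraction (percent) over one labeled group.

    Per neuron: (sum_dominant - sum_nondominant) / (sum_dominant +
    sum_nondominant), averaged over neurons labeled ``eye`` and expressed in
    percent.
    """
    if eye == "left":
        mask, dom, non = odm.label > 0, odm.sum_left, odm.sum_right
    elif eye == "right":
        mask, dom, non = odm.label < 0, odm.sum_right, odm.sum_left
    else:
        raise ValueError("eye must be 'left' or 'right'")
    if not mask.any():
        return 0.0
    tot = dom[mask] + non[mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, (dom[mask] - non[mask]) / tot, 0.0)
    return float(frac.mean() * 100.0)


# ---------------------------------------------------------------------------
# OSM
# ---------------------------------------------------------------------------

def _bar_frame(shape, alpha_deg, center, length, width, intensity=1.0):
    """Oriented rectangular bar on an LGN-sized frame (clipped at edges)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = center
    c, s = np.cos(np.deg2rad(alpha_deg)), np.sin(np.deg2rad(alpha_deg))
    along = (xx - cx) * c + (yy - cy) * s
    across = -(xx - cx) * s + (yy - cy) * c
    bar = (np.abs(along) <= length / 2.0) & (np.abs(across) <= width / 2.0)
    return np.clip(bar.astype(float) * intensity, 0.0, 1.0)


def measure_osm(network, params: OsmProtocolParams | None = None,
                rng=None) -> dict[float, np.ndarray]:
    """Oriented-bar probing protocol: one E rate image per orientation.

    The network state is cloned and plasticity frozen (the probe is
    non-invasive and repeatable).  For each orientation in {0, 45, 90, 135}
    degrees, both eyes' LGN sheets are stimulated with an oriented bar; the
    probe position tiles the sheet across trials (so every retinotopic
    region is sampled) with bilateral jitter of alternating sign; E spikes
    are counted over the protocol window and returned in Hz.
    """
    cfg = network.config
    params = params or cfg.osm
    rng = rng or np.random.default_rng(network.master_seed + 9173)
    shape = cfg.lgn_shape
    if params.bar_length > max(shape):
        import warnings

        warnings.warn("probe bar exceeds LGN frame; clipping", stacklevel=2)
    # probe centers tile the LGN so the whole cortical sheet is mapped
    side = max(1, int(np.ceil(np.sqrt(params.n_trials))))
    centers = [((i + 0.5) * shape[0] / side, (j + 0.5) * shape[1] / side)
               for i in range(side) for j in range(side)]
    per_trial = max(1, params.window_steps // len(centers))
    rates = {}
    for alpha in (0.0, 45.0, 90.0, 135.0):
        probe = copy.deepcopy(network)
        probe.plasticity_enabled = False
        counts = np.zeros(probe.populations["E"].n)
        jit = rng.integers(0, params.max_jitter + 1, size=(len(centers), 2))
        for trial, center in enumerate(centers):
            sign = 1 if trial % 2 == 0 else -1
            c = ((center[0] + sign * jit[trial, 0]) % shape[0],
                 (center[1] + sign * jit[trial, 1]) % shape[1])
            frame = _bar_frame(shape, alpha, c, params.bar_length,
                               params.bar_width, params.bar_intensity)
            spikes = encode_poisson(frame, per_trial, rng, cfg.isi_base_ms)
            for step in range(per_trial):
                s = probe.step(spikes[:, step], spikes[:, step])
                np.add.at(counts, s["E"], 1)
        window_s = len(centers) * per_trial * cfg.dt / 1000.0
        rates[alpha] = (counts / window_s).reshape(cfg.layer4_shape)
    return rates


def osm_vector_sum(rate_images: dict[float, np.ndarray],
                   smoothing: int = 9) -> OrientationMap:
    """Blasdel angle-doubling vector sum of four orientation rate images.

    Differential images from complementary pairs (0-90, 45-135) become the
    doubled-angle Cartesian components; the summed x and y images are median
    filtered (periodic wrap) and converted to polar: preference is half the
    angle, selectivity the magnitude.  Equal responses at orthogonal
    orientations cancel exactly.
    """
    d0 = np.asarray(rate_images[0.0], dtype=float) - np.asarray(rate_images[90.0])
    d45 = np.asarray(rate_images[45.0], dtype=float) - np.asarray(rate_images[135.0])
    x, y = d0, d45  # cos/sin components at doubled angles 0 and 90 degrees
    if smoothing and smoothing > 1:
        x = ndimage.median_filter(x, size=smoothing, mode="wrap")
        y = ndimage.median_filter(y, size=smoothing, mode="wrap")
    pref = (np.rad2deg(np.arctan2(y, x)) / 2.0) % 180.0
    sel = np.hypot(x, y)
    return OrientationMap(preference=pref, selectivity=sel, source="osm")


# ---------------------------------------------------------------------------
# gradients, fractures, pinwheel-like patterns
# ---------------------------------------------------------------------------

def _circ_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular difference of orientation angles, result in [-90, 90)."""
    return (a - b + 90.0) % 180.0 - 90.0


def orientation_gradient(omap: OrientationMap) -> np.ndarray:
    """Circular-aware gradient magnitude of the preference image.

    One-step circular differences (mod 180) along each lattice axis with
    periodic wrap; the magnitude is the Euclidean norm of the two components,
    so a 0/90 degree half-plane boundary reads 90 and 178-vs-2 neighbors read
    4.  The result is stored on the map and returned.
    """
    p = omap.preference
    gx = _circ_diff_deg(np.roll(p, -1, axis=1), p)
    gy = _circ_diff_deg(np.roll(p, -1, axis=0), p)
    grad = np.abs(gx + 1j * gy)
    # the two components are each bounded by 90; cap at the circular maximum
    grad = np.minimum(grad, 90.0)
    omap.gradient = grad
    return grad


def find_fractures(gradient: np.ndarray, threshold: float = 90.0,
                   min_line: int = 3) -> dict:
    """Detect discontinuities: fracture lines vs isolated dots.

    Fractures are connected runs of gradient >= threshold of at least
    ``min_line`` pixels ("a short line between two contiguous regions with a
    gradient of 90 degrees or more"); smaller components are reported as dots.
    """
    high = gradient >= threshold - 1e-9
    labels, n = ndimage.label(high, structure=np.ones((3, 3), dtype=int))
    lines, dots = [], []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        (lines if coords.shape[0] >= min_line else dots).append(coords)
    return {"mask": high, "lines": lines, "dots": dots}


def find_pinwheel_like(omap: OrientationMap) -> np.ndarray:
    """Loci where preference winds through +-180 degrees around a 3x3 ring.

    Walks the 8-neighbor ring around each lattice point (periodic wrap),
    accumulating circular orientation differences; a net winding of +-180
    degrees marks a pinwheel-like pattern.  Returns a boolean mask.
    """
    p = omap.preference
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    vals = [np.roll(p, (-dy, -dx), axis=(0, 1)) for dy, dx in ring]
    total = np.zeros_like(p)
    for k in range(8):
        total += _circ_diff_deg(vals[(k + 1) % 8], vals[k])
    return np.abs(np.abs(total) - 180.0) < 1e-6


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def kl_similarity(W1, W2, n_bins: int = 50, eps: float = 1e-12,
                  proper_normalization: bool = False) -> float:
    """Symmetric KL similarity between two weight sets on [0, 1].

    Histograms are normalized by their maximum bin (as published; with
    ``proper_normalization`` they are normalized to probability vectors
    instead), and the symmetric KL sum is computed with an additive eps in
    numerator and denominator of the log.  S >= 0, S = 0 iff the normalized
    histograms coincide, and S(W1, W2) = S(W2, W1).
    """
    w1 = np.asarray(W1, dtype=float).ravel()
    w2 = np.asarray(W2, dtype=float).ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h1, _ = np.histogram(np.clip(w1, 0, 1), bins=edges)
    h2, _ = np.histogram(np.clip(w2, 0, 1), bins=edges)
    if proper_normalization:
        p1 = h1 / max(1, h1.sum())
        p2 = h2 / max(1, h2.sum())
    else:
        p1 = h1 / max(1, h1.max())
        p2 = h2 / max(1, h2.max())
    ratio = np.log((p1 + eps) / (p2 + eps))
    s = 0.5 * (np.sum(p1 * ratio) + np.sum(p2 * -ratio))
    return float(max(0.0, s))


def current_balance(exc_currents, inh_currents, window: int = 200,
                    dt: float = 1.0) -> StabilityTrace:
    """E-I current-difference trace from per-step population means.

    The difference (excitatory minus inhibitory magnitude) is averaged over
    ``window``-ms blocks (instantaneous series) and accompanied by the
    running mean over the whole recording.
    """
    exc = np.asarray(exc_currents, dtype=float)
    inh = np.asarray(inh_currents, dtype=float)
    diff = exc - inh
    k = max(1, int(round(window / dt)))
    n_blocks = diff.size // k
    trace = StabilityTrace()
    if n_blocks == 0:
        trace.balance_steps = np.array([])
        trace.balance_instant = np.array([])
        trace.balance_running = np.array([])
        return trace
    blocks = diff[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)
    trace.balance_steps = (np.arange(1, n_blocks + 1) * k).astype(float)
    trace.balance_instant = blocks
    trace.balance_running = np.cumsum(blocks) / np.arange(1, n_blocks + 1)
    return trace
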