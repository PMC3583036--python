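"""Developmental-phase orchestration and perturbation experiments.

Phase 1 drives the network with background injection only; Phase 2 adds
independent per-eye retinal waves; Phase 3 switches to Poisson-encoded
natural-surrogate stereo pairs split into ON/OFF channels.  Perturbations
cover inhibition ablation (removed or frozen), retinal lesions of one eye,
and prolonged exposure to flag patterns on a developed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .map_analysis import (
    OdmMap,
    compute_odm,
    compute_rcm,
    current_balance,
    dominance_fraction,
    kl_similarity,
    measure_osm,
    odm_separation_stats,
    osm_vector_sum,
    StabilityTrace,
)
from .network_core import Network
from .stimuli import (
    StimulusFrame,
    downsample,
    encode_frames_rate,
    encode_poisson,
    generate_flag_pattern,
    generate_retinal_wave,
    make_on_off,
    make_stereo_pair,
    route_on_off,
    synthetic_natural_surrogate,
)

__all__ = [
    "PhaseSchedule",
    "PerturbationSpec",
    "StimulusStream",
    "run_phase",
    "ablate_inhibition",
    "lesion_rgc",
    "prolonged_exposure",
]

_MODES = ("noise_only", "retinal_waves", "natural_stereo", "flags")


@dataclass
class PhaseSchedule:
    """One developmental phase: input mode, duration and analysis cadence."""

    phase: int
    mode: str
    duration: int
    kl_every: int = 5000
    maps_every: int | None = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class PerturbationSpec:
    """A perturbation experiment descriptor."""

    kind: str  # 'no_inhibition' | 'fixed_inhibition' | 'rgc_lesion' | 'prolonged_flags'
    lesion_fraction: float = 0.0
    lesion_eye: str = "right"
    fixed_z: float = 0.0
    flag_exposure_s: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must lie in [0, 1]")


class StimulusStream:
    """Queue of per-ms retinogeniculate spike arrays for both eyes."""

    def __init__(self, net: Network, mode: str):
        self.net = net
        self.cfg = net.config
        self.mode = mode
        self.queue_l: list[np.ndarray] = []
        self.queue_r: list[np.ndarray] = []

    def next(self):
        if self.mode == "noise_only":
            return None, None
        if not self.queue_l or not self.queue_r:
            self._refill()
        l = self.queue_l.pop(0) if self.queue_l else None
        r = self.queue_r.pop(0) if self.queue_r else None
        return l, r

    # ------------------------------------------------------------------
    def _refill(self):
        cfg = self.cfg
        if self.mode == "retinal_waves":
            # independent waves per eye, generated on the retinal lattice and
            # down-sampled to the LGN sheet
            for queue, rng in ((self.queue_l, self.net.rng_stim_left),
                               (self.queue_r, self.net.rng_stim_right)):
                frames = generate_retinal_wave(cfg.waves, rng, cfg.lgn_shape)
                spikes = encode_frames_rate(frames, cfg.wave_peak_rate_hz, rng,
                                            cfg.dt)
                queue.extend(spikes[:, k] for k in range(spikes.shape[1]))
            return
        # image-based modes share one source image per presentation
        rng = self.net.rng_stim_left
        if self.mode == "natural_stereo":
            base = synthetic_natural_surrogate(rng, cfg.lgn_shape)
            present = cfg.image_present_ms
        elif self.mode == "flags":
            base = generate_flag_pattern(rng, cfg.lgn_shape)
            lo, hi = cfg.flag_present_range
            present = int(rng.integers(lo, hi + 1))
        else:  # pragma: no cover
            raise ValueError(self.mode)
        left, right = make_stereo_pair(base, cfg.stereo, rng)
        for frame, queue, enc_rng in ((left, self.queue_l, self.net.rng_stim_left),
                                      (right, self.queue_r, self.net.rng_stim_right)):
            on, off = make_on_off(frame, cfg.off_mode)
            rgc = route_on_off(on, off, cfg.lgn_shape)
            spikes = encode_poisson(rgc, present, enc_rng, cfg.isi_base_ms)
            queue.extend(spikes[:, k] for k in range(present))


def run_phase(net: Network, schedule: PhaseSchedule, collect_maps: bool = False,
              measure_osm_maps: bool = False) -> dict:
    """Run one developmental phase; returns analysis artifacts.

    Artifacts: per-step E spike counts, KL stability traces per intracortical
    synapse class (consecutive-snapshot similarity at the configured
    cadence), the E-I balance trace, the end-of-phase ODM (and RCM/OSM when
    ``collect_maps``).  Fully reproducible from the network's master seed.
    """
    if schedule.duration == 0:
        return {"counts": np.zeros(0, dtype=np.int32), "kl": StabilityTrace(),
                "odm": None, "balance": StabilityTrace()}
    cfg = net.config
    stream = StimulusStream(net, schedule.mode)
    counts = np.empty(schedule.duration, dtype=np.int32)
    kl_trace = StabilityTrace()
    prev_hist = net.class_weights()
    balance_start = len(net.exc_current_trace)
    for i in range(schedule.duration):
        l, r = stream.next()
        spikes = net.step(l, r)
        counts[i] = spikes["E"].size
        if schedule.kl_every and (i + 1) % schedule.kl_every == 0:
            cur = net.class_weights()
            kl_trace.kl_steps.append(net.step_count)
            for cls, w in cur.items():
                kl_trace.kl.setdefault(cls, []).append(
                    kl_similarity(prev_hist[cls], w, cfg.kl_bins))
            prev_hist = cur
    sl, sr = net.lgn_weight_sums()
    odm = compute_odm(sl, sr, cfg.layer4_shape)
    artifacts = {
        "counts": counts,
        "kl": kl_trace,
        "odm": odm,
        "odm_stats": odm_separation_stats(odm),
        "dominance_left": dominance_fraction(odm, "left"),
        "dominance_right": dominance_fraction(odm, "right"),
        "mean_rate_hz": net.mean_rate(counts),
        "balance": current_balance(
            net.exc_current_trace[balance_start:],
            net.inh_current_trace[balance_start:],
            cfg.balance_window, cfg.dt),
    }
    if collect_maps:
        artifacts["rcm"] = compute_rcm(net.ee_weight_neighborhoods(), cfg.rcm,
                                       cfg.layer4_shape)
    if measure_osm_maps:
        artifacts["osm"] = osm_vector_sum(measure_osm(net),
                                          smoothing=cfg.osm.median_filter)
    return artifacts


def ablate_inhibition(net: Network, mode: str, fixed_value: float | None = None) -> Network:
    """Apply an inhibition ablation in place and return the network.

    ``no_inhibition`` zeroes every inhibitory weight and disables I-STDP;
    ``fixed_inhibition`` freezes all inhibitory weights at ``fixed_value``
    (normalized scale) with I-STDP off; ``plastic`` restores I-STDP (weights
    are left as they are).
    """
    if mode == "plastic":
        net.config.istdp_on = True
        net.config.fixed_inhibition_value = None
        return net
    if mode == "no_inhibition":
        value = 0.0
    elif mode == "fixed_inhibition":
        if fixed_value is None:
            raise ValueError("fixed_inhibition requires fixed_value")
        value = float(fixed_value)
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")
    net.config.istdp_on = False
    net.config.fixed_inhibition_value = value
    for proj in net.projections:
        if proj.kind == "inh":
            proj.w[:] = value
            # an all-zero fixed projection can never contribute anything;
            # the simulator skips it entirely
            proj.silenced = value == 0.0
    return net


def lesion_rgc(net: Network, fraction: float, eye: str, rng=None) -> np.ndarray:
    """Silence a random fraction of one eye's RGCs for all subsequent input.

    The lesion set is drawn once and fixed for the run; returns the 0/1 mask
    applied to that eye's retinogeniculate spike stream.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    eye_key = {"left": "L", "right": "R"}[eye]
    n = net.populations[f"LGN_E_{eye_key}"].n
    rng = rng or net.rng_misc
    mask = np.ones(n)
    n_out = int(round(fraction * n))
    if n_out:
        out = rng.choice(n, size=n_out, replace=False)
        mask[out] = 0.0
    net.lesion_mask[eye_key] = mask
    return mask


def _pref_near(pref: np.ndarray, targets=(0.0, 90.0), tol: float = 22.5,
               mask: np.ndarray | None = None) -> int:
    """Count of neurons whose preference lies within ``tol`` of any target.

    ``mask`` restricts the count to responsive neurons (unresponsive cells
    carry no preference: their vector sum is zero and would read as 0
    degrees).
    """
    count = np.zeros(pref.shape, dtype=bool)
    for t in targets:
        d = np.abs((pref - t + 90.0) % 180.0 - 90.0)
        count |= d <= tol
    if mask is not None:
        count &= mask
    return int(count.sum())


def prolonged_exposure(net: Network, exposure_s: float,
                       osm_params=None) -> dict:
    """Expose a developed network to flag patterns and report map changes.

    Measures the OSM and ODM before exposure, runs the flag stream for
    ``exposure_s`` seconds of simulated time, re-measures, and reports:
    the fraction of neurons whose preference moved by more than 22.5 degrees,
    the change in the count of neurons preferring 0 or 90 degrees, the ODM
    label-flip fraction, and the E->E KL change.
    """
    cfg = net.config
    osm_before = osm_vector_sum(measure_osm(net, osm_params),
                                smoothing=cfg.osm.median_filter)
    sl, sr = net.lgn_weight_sums()
    odm_before = compute_odm(sl, sr, cfg.layer4_shape)
    w_before = net.proj_by_name["E->E"].w.copy()

    steps = int(round(exposure_s * 1000.0 / cfg.dt))
    if steps:
        schedule = PhaseSchedule(phase=3, mode="flags", duration=steps,
                                 kl_every=0)
        run_phase(net, schedule)

    osm_after = osm_vector_sum(measure_osm(net, osm_params),
                               smoothing=cfg.osm.median_filter)
    sl, sr = net.lgn_weight_sums()
    odm_after = compute_odm(sl, sr, cfg.layer4_shape)

    moved = np.abs((osm_after.preference - osm_before.preference + 90.0)
                   % 180.0 - 90.0) > 22.5
    responsive_b = osm_before.selectivity > 0
    responsive_a = osm_after.selectivity > 0
    n_before = _pref_near(osm_before.preference, mask=responsive_b)
    n_after = _pref_near(osm_after.preference, mask=responsive_a)
    return {
        "osm_before": osm_before,
        "osm_after": osm_after,
        "pref_shift_fraction": float(moved.mean()) if steps else 0.0,
        "cardinal_count_before": n_before,
        "cardinal_count_after": n_after,
        "cardinal_increase": (n_after - n_before) / max(1, n_before),
        "odm_flip_fraction": float(np.mean(odm_after.label != odm_before.label))
        if steps else 0.0,
        "rcm_kl_change": kl_similarity(w_before, net.proj_by_name["E->E"].w,
                                       cfg.kl_bins) if steps else 0.0,
    }
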