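"""Continuous excitatory and inhibitory spike-timing-dependent plasticity.

Both rules act on the timing difference ``dt = t_pre - t_post`` of the most
recent pre/post spike pair (nearest-neighbor pairing) and keep every weight
hard-bounded in ``[0, g_max]``.

E-STDP (excitatory synapses, asymmetric window)::

    F(dt) =  A+ * exp( dt / tau+)   if dt < 0   (pre before post: potentiate)
            -A- * exp(-dt / tau-)   if dt >= 0  (post before pre: depress)
    w <- clip(w + g_E_max * F(dt), 0, g_E_max)

with A- derived from the depression/potentiation ratio
beta = |A- tau-| / |A+ tau+|.

I-STDP (inhibitory synapses, symmetric in |dt|)::

    |dt| <= lambda                -> z <- z + B+   (more inhibitory)
    lambda < |dt| <= lambda+delta -> z <- z - B-   (less inhibitory)
    otherwise                     -> unchanged
    z clipped to [0, g_I_max]

The published g_I_max (0.0035) is smaller than B+ (0.045), so a single
inner-window pairing saturates an inhibitory synapse; this is implemented
as printed and a warning is logged once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import EstdpParams, IstdpParams

__all__ = [
    "estdp_F",
    "estdp_update",
    "istdp_update",
    "PairingState",
    "process_spikes",
    "apply_step_plasticity",
]

log = logging.getLogger(__name__)
_saturation_warned = False


def estdp_F(delta_t, params: EstdpParams):
    """Dimensionless E-STDP change factor for ``delta_t = t_pre - t_post``.

    Accepts scalars or arrays.  Negative ``delta_t`` (pre before post)
    potentiates, non-negative depresses; both branches decay exponentially.
    """
    dt = np.asarray(delta_t, dtype=float)
    with np.errstate(over="ignore"):
        pot = params.A_plus * np.exp(np.minimum(dt, 0.0) / params.tau_plus)
        dep = -params.A_minus * np.exp(-np.maximum(dt, 0.0) / params.tau_minus)
    out = np.where(dt < 0, pot, dep)
    # an infinitely remote partner produces no change
    out = np.where(np.isfinite(dt), out, 0.0)
    return out if out.ndim else float(out)


def estdp_update(w_old, delta_t, params: EstdpParams):
    """Apply one E-STDP event on the scaled weight axis [0, g_E_max]."""
    dw = params.g_E_max * np.asarray(estdp_F(delta_t, params))
    return np.clip(w_old + dw, 0.0, params.g_E_max)


def istdp_delta(delta_t, params: IstdpParams):
    """Signed inhibitory weight change (scaled axis) for one pairing."""
    adt = np.abs(np.asarray(delta_t, dtype=float))
    dz = np.where(
        adt <= params.lam,
        params.B_plus,
        np.where(adt <= params.lam + params.delta, -params.B_minus, 0.0),
    )
    dz = np.where(np.isfinite(adt), dz, 0.0)
    return dz if dz.ndim else float(dz)


def istdp_update(z_old, delta_t, params: IstdpParams):
    """Apply one I-STDP event on the scaled weight axis [0, g_I_max]."""
    global _saturation_warned
    if params.B_plus > params.g_I_max and not _saturation_warned:
        log.warning(
            "I-STDP inner-window step B+=%g exceeds g_I_max=%g: a single "
            "coincident pairing saturates the synapse (implemented as printed)",
            params.B_plus, params.g_I_max,
        )
        _saturation_warned = True
    return np.clip(z_old + istdp_delta(delta_t, params), 0.0, params.g_I_max)


@dataclass
class PairingState:
    """Most recent pre/post spike time per neuron (nearest-neighbor pairing)."""

    last_pre: np.ndarray
    last_post: np.ndarray
    scheme: str = "nearest"

    @classmethod
    def empty(cls, n_pre: int, n_post: int) -> "PairingState":
        return cls(np.full(n_pre, -np.inf), np.full(n_post, -np.inf))


def process_spikes(events, pairing: PairingState, projections):
    """Event-driven reference application of both STDP rules.

    Parameters
    ----------
    events
        Time-ordered iterable of ``(t, side, neuron_index)`` with side in
        {'pre', 'post'}.  Events sharing a time stamp are simultaneous.
    pairing
        Nearest-neighbor pairing state shared by all projections (all
        projections are assumed to connect the same pre/post populations).
    projections
        Iterable of objects with ``pre_idx``, ``post_idx``, ``w`` (scaled
        axis), ``rule`` in {'estdp', 'istdp', None} and ``params``.

    On every post spike the update pairs with the afferent's most recent pre
    spike (including a simultaneous one, dt = 0); on every pre spike it pairs
    with the target's most recent strictly earlier post spike, so that
    simultaneous pairs are counted exactly once.

    This path is the small-scale oracle; the simulator uses the vectorized
    :func:`apply_step_plasticity`, which is tested for equivalence against it.
    """
    events = sorted(events, key=lambda e: e[0])
    i = 0
    n = len(events)
    while i < n:
        t = events[i][0]
        batch = []
        while i < n and events[i][0] == t:
            batch.append(events[i])
            i += 1
        pre_now = {e[2] for e in batch if e[1] == "pre"}
        post_now = {e[2] for e in batch if e[1] == "post"}
        for proj in projections:
            if proj.rule is None:
                continue
            for k in range(len(proj.pre_idx)):
                a, b = int(proj.pre_idx[k]), int(proj.post_idx[k])
                # pre spike pairs with the most recent strictly earlier post
                if a in pre_now and np.isfinite(pairing.last_post[b]):
                    dt = t - pairing.last_post[b]
                    proj.w[k] = _apply_rule(proj, k, dt)
                # post spike pairs with the most recent pre (dt = 0 allowed)
                if b in post_now:
                    t_pre = t if a in pre_now else pairing.last_pre[a]
                    if np.isfinite(t_pre):
                        proj.w[k] = _apply_rule(proj, k, t_pre - t)
        for j in pre_now:
            pairing.last_pre[j] = t
        for j in post_now:
            pairing.last_post[j] = t
    return projections


def _apply_rule(proj, k, dt):
    if proj.rule == "estdp":
        return float(estdp_update(proj.w[k], dt, proj.params))
    if proj.rule == "istdp":
        return float(istdp_update(proj.w[k], dt, proj.params))
    raise ValueError(f"unknown plasticity rule {proj.rule!r}")


def apply_step_plasticity(
    proj,
    pre_spiked: np.ndarray,
    post_spikes: np.ndarray,
    pre_spikes: np.ndarray,
    last_pre: np.ndarray,
    last_post: np.ndarray,
    t: float,
    pre_sel: np.ndarray | None = None,
) -> None:
    """Vectorized one-step STDP application for one projection.

    ``proj.w`` is on the normalized [0, 1] axis; because the published update
    is ``dw = g_max * F`` with clipping at [0, g_max], the normalized update
    is exactly ``w <- clip(w + F, 0, 1)`` (and ``dz/g_I_max`` for I-STDP).

    ``last_pre``/``last_post`` must still hold the spike times of strictly
    earlier steps; ``pre_spiked`` marks this step's pre spikes so that
    simultaneous pairs are handled once, on the post-spike side (dt = 0).
    """
    rule = proj.rule
    if rule is None:
        return
    if rule not in ("estdp", "istdp"):
        raise ValueError(f"unknown plasticity rule {rule!r}")
    p = proj.params
    if rule == "istdp":
        b_plus = p.B_plus / p.g_I_max
        b_minus = p.B_minus / p.g_I_max
        outer = p.lam + p.delta

    # pre spikes this step vs most recent strictly earlier post spike (dt > 0)
    if pre_spikes.size:
        sel = proj.conns_of_pre(pre_spikes) if pre_sel is None else pre_sel
        if sel.size:
            dt = t - last_post[proj.post_idx[sel]]
            if rule == "estdp":
                dw = -p.A_minus * np.exp(-dt / p.tau_minus)  # exp(-inf) = 0
            else:
                dw = np.where(dt <= p.lam, b_plus,
                              np.where(dt <= outer, -b_minus, 0.0))
            proj.w[sel] = np.clip(proj.w[sel] + dw, 0.0, 1.0)
    # post spikes this step vs most recent pre spike (same-step pre -> dt = 0)
    if post_spikes.size:
        sel = proj.conns_of_post(post_spikes)
        if sel.size:
            pre_of = proj.pre_idx[sel]
            t_pre = np.where(pre_spiked[pre_of], t, last_pre[pre_of])
            dt = t_pre - t  # <= 0
            if rule == "estdp":
                dw = p.A_plus * np.exp(dt / p.tau_plus)
                dw[dt >= 0] = -p.A_minus  # simultaneous pair: printed dt>=0 branch
            else:
                adt = -dt
                dw = np.where(adt <= p.lam, b_plus,
                              np.where(adt <= outer, -b_minus, 0.0))
            proj.w[sel] = np.clip(proj.w[sel] + dw, 0.0, 1.0)
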