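"""Conductance-based LIF network on periodic 2-D lattices.

Builds the two-stage topology (per-eye LGN E-I networks feeding layer-4 E,
I1 and I2 sheets) and advances all membrane potentials and synaptic
conductance traces by forward Euler at 1 ms resolution.

Membrane equation (voltages mV, conductances dimensionless)::

    tau_m dV/dt = (V_rest - V) + w(t)(E_ex - V) - z(t)(E_inh - V) + I_inj

where ``w``/``z`` are the summed excitatory/inhibitory conductance traces,
each decaying exponentially with tau_AMPA / tau_GABA and incremented by
``weight * g_max`` per presynaptic spike (delivered with a one-step delay).
A neuron spikes when V >= V_T (ties fire) and is reset to V_reset.

All lattices wrap periodically: topmost/bottommost rows and leftmost/
rightmost columns are neighbors.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, ConnectivityParams, SimConfig
from .plasticity import apply_step_plasticity

__all__ = [
    "NeuronPopulation",
    "SynapseProjection",
    "connection_probability",
    "build_topology",
    "step_membrane",
    "decay_and_deliver",
    "Network",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    pass


_EMPTY_IDX = np.empty(0, dtype=np.int64)


def connection_probability(dx, dy, params: ConnectivityParams):
    """Connection probability at periodic lattice offset (dx, dy).

    Evaluates the published Gaussian density ``alpha * exp(-(dx^2+dy^2) / D)``
    with D = 2*sigma (as printed) or D = 2*sigma^2 (standard variant), and
    clips to 1 since the published alpha values exceed 1 near the center
    (guaranteed connection inside the core).
    """
    if params.sigma <= 0:
        raise ConfigError("sigma must be > 0")
    d2 = np.asarray(dx, dtype=float) ** 2 + np.asarray(dy, dtype=float) ** 2
    denom = 2.0 * params.sigma if params.gaussian_variant == "as_printed" \
        else 2.0 * params.sigma ** 2
    p = np.minimum(1.0, params.alpha * np.exp(-d2 / denom))
    return p if p.ndim else float(p)


class NeuronPopulation:
    """Membrane state and spike bookkeeping for one 2-D sheet of LIF neurons."""

    def __init__(self, name: str, shape: tuple[int, int], role: str, params):
        if role not in ("E", "I"):
            raise ConfigError("role must be 'E' or 'I'")
        self.name = name
        self.shape = tuple(shape)
        self.role = role
        self.params = params
        n = shape[0] * shape[1]
        self.n = n
        self.V = np.full(n, params.V_rest, dtype=float)
        self.g_exc = np.zeros(n)
        self.g_inh = np.zeros(n)
        self.last_spike = np.full(n, -np.inf)
        self.I_inj = np.zeros(n)
        self.spiked = np.zeros(n, dtype=bool)  # this step
        self._decay_exc = None  # cached per-dt decay factors
        self._decay_inh = None
        self._decay_dt = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"V": self.V, "g_exc": self.g_exc, "g_inh": self.g_inh,
                "last_spike": self.last_spike, "I_inj": self.I_inj}


def step_membrane(pop: NeuronPopulation, dt: float, t: float) -> np.ndarray:
    """Euler-update one population's membrane potentials; return spike indices.

    Spiking neurons (V >= V_T, ties fire) are reset to V_reset and their
    last-spike time set to ``t``.  Raises on a non-finite membrane value,
    naming the first offending neuron.
    """
    p = pop.params
    V = pop.V
    # a neuron already at/above threshold on entry fires regardless of the
    # leak this step (ties fire); in normal operation this set is empty since
    # spiking neurons were reset the step they crossed
    pre_over = V >= p.V_T
    dV = (dt / p.tau_m) * (
        (p.V_rest - V)
        + pop.g_exc * (p.E_ex - V)
        - pop.g_inh * (p.E_inh - V)
        + pop.I_inj
    )
    V += dV
    if p.V_floor is not None:
        np.maximum(V, p.V_floor, out=V)
    if not np.all(np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise NumericalInstabilityError(
            f"non-finite membrane potential in population {pop.name!r}, neuron {bad}"
        )
    spikes = np.flatnonzero((V >= p.V_T) | pre_over)
    if spikes.size:
        V[spikes] = p.V_reset
        pop.last_spike[spikes] = t
    pop.spiked[:] = False
    pop.spiked[spikes] = True
    return spikes


class SynapseProjection:
    """A fixed or plastic weight set between two populations.

    Weights are normalized to [0, 1]; ``g_max`` is the conductance scale, so
    a presynaptic spike increments the target's trace by ``weight * g_max``.
    Adjacency is stored as flat (pre_idx, post_idx) connection lists with CSR
    indices by pre and by post for vectorized delivery and STDP.
    """

    def __init__(self, name, pre, post, synapse_class, kind, rule,
                 pre_idx, post_idx, w, g_max, params=None, offsets=None):
        if kind not in ("exc", "inh"):
            raise ConfigError("kind must be 'exc' or 'inh'")
        self.name = name
        self.pre = pre
        self.post = post
        self.synapse_class = synapse_class
        self.kind = kind
        self.rule = rule            # 'estdp' | 'istdp' | None
        self.pre_idx = np.asarray(pre_idx, dtype=np.int64)
        self.post_idx = np.asarray(post_idx, dtype=np.int64)
        self.w = np.asarray(w, dtype=float)
        self.g_max = float(g_max)
        self.params = params
        self.offsets = offsets      # (M, 2) lattice offsets for same-window maps
        self.silenced = False       # all-zero fixed projection: skip entirely
        if self.pre is self.post and np.any(self.pre_idx == self.post_idx):
            raise ConfigError(f"self-connections in projection {name}")
        self._csr_pre = None
        self._csr_post = None

    @property
    def n_conn(self) -> int:
        return self.pre_idx.size

    # ------------------------------------------------------------- indexing
    def _build_csr(self, idx: np.ndarray, n: int):
        order = np.argsort(idx, kind="stable")
        counts = np.bincount(idx, minlength=n)
        indptr = np.concatenate(([0], np.cumsum(counts)))
        return order.astype(np.int64), indptr.astype(np.int64)

    def _ensure_csr(self):
        if self._csr_pre is None:
            self._csr_pre = self._build_csr(self.pre_idx, self.pre.n)
            self._csr_post = self._build_csr(self.post_idx, self.post.n)

    @staticmethod
    def _gather(order, indptr, neurons):
        # spike sets are small (tens of neurons), so slicing beats fancy
        # repeat-based indexing here
        parts = [order[indptr[i]:indptr[i + 1]] for i in neurons]
        if not parts:
            return np.empty(0, dtype=np.int64)
        if len(parts) == 1:
            return parts[0]
        return np.concatenate(parts)

    def conns_of_pre(self, neurons: np.ndarray) -> np.ndarray:
        """Connection indices whose presynaptic neuron is in ``neurons``."""
        self._ensure_csr()
        return self._gather(*self._csr_pre, neurons)

    def conns_of_post(self, neurons: np.ndarray) -> np.ndarray:
        self._ensure_csr()
        return self._gather(*self._csr_post, neurons)

    # ------------------------------------------------------------- delivery
    def deliver(self, spikes: np.ndarray, sel: np.ndarray | None = None) -> None:
        """Add ``weight * g_max`` to the target trace for each spike's fanout.

        ``sel`` may carry a precomputed ``conns_of_pre(spikes)`` result (the
        simulator reuses the plasticity gather of the previous step).
        """
        if spikes.size == 0:
            return
        if sel is None:
            sel = self.conns_of_pre(spikes)
        if sel.size == 0:
            return
        target = self.post.g_exc if self.kind == "exc" else self.post.g_inh
        target += np.bincount(self.post_idx[sel], weights=self.w[sel],
                              minlength=self.post.n) * self.g_max


def decay_and_deliver(projections, spikes_by_pop: dict, populations, dt: float,
                      sel_cache: dict | None = None) -> None:
    """Exponentially decay all conductance traces, then deliver spikes.

    Excitatory traces decay with tau_AMPA, inhibitory with tau_GABA; each
    presynaptic spike increments the postsynaptic trace by weight * g_max.
    ``sel_cache`` optionally maps projection names to precomputed fanout
    index arrays for the given spike sets.
    """
    for pop in populations:
        if pop._decay_dt != dt:
            pop._decay_exc = np.exp(-dt / pop.params.tau_ampa)
            pop._decay_inh = np.exp(-dt / pop.params.tau_gaba)
            pop._decay_dt = dt
        pop.g_exc *= pop._decay_exc
        pop.g_inh *= pop._decay_inh
    for proj in projections:
        if proj.silenced:
            continue
        spikes = spikes_by_pop.get(proj.pre.name)
        if spikes is not None and len(spikes):
            sel = sel_cache.get(proj.name) if sel_cache else None
            proj.deliver(np.asarray(spikes), sel)


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def _lattice_offsets(window: int, exclude_center: bool):
    r = window // 2
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    dx, dy = dx.ravel(), dy.ravel()
    if exclude_center:
        keep = ~((dx == 0) & (dy == 0))
        dx, dy = dx[keep], dy[keep]
    return dx, dy


def _wrap_index(rows, cols, shape):
    return (rows % shape[0]) * shape[1] + (cols % shape[1])


def _sample_initial_weights(n, cfg: SimConfig, rng):
    lo, hi = cfg.init_high_range
    w = np.full(n, cfg.init_low_value)
    high = rng.random(n) >= cfg.init_low_prob
    w[high] = rng.uniform(lo, hi, high.sum())
    return w


def _gaussian_projection(name, pre, post, synapse_class, kind, rule,
                         conn: ConnectivityParams, window, cfg, rng, params):
    """Same-lattice projection sampled from the Gaussian density profile."""
    shape = pre.shape
    dx, dy = _lattice_offsets(window, exclude_center=(pre is post))
    probs = connection_probability(dx, dy, conn)
    rows, cols = np.divmod(np.arange(pre.n), shape[1])
    pre_list, post_list, off_list = [], [], []
    for k in range(dx.size):
        mask = rng.random(pre.n) < probs[k]
        if not mask.any():
            continue
        src = np.flatnonzero(mask)
        tgt = _wrap_index(rows[src] + dx[k], cols[src] + dy[k], shape)
        pre_list.append(src)
        post_list.append(tgt)
        off_list.append(np.broadcast_to([dx[k], dy[k]], (src.size, 2)))
    pre_idx = np.concatenate(pre_list) if pre_list else np.empty(0, dtype=np.int64)
    post_idx = np.concatenate(post_list) if post_list else np.empty(0, dtype=np.int64)
    offsets = np.concatenate(off_list) if off_list else np.empty((0, 2), dtype=np.int64)
    w = _sample_initial_weights(pre_idx.size, cfg, rng)
    g_max = cfg.estdp.g_E_max if kind == "exc" else cfg.istdp.g_I_max
    return SynapseProjection(name, pre, post, synapse_class, kind, rule,
                             pre_idx, post_idx, w, g_max, params, offsets)


def _cross_scale_projection(name, pre, post, synapse_class, kind, rule,
                            window, prob, init_w, cfg, rng, params,
                            ensure_full_cover=False):
    """Feedforward projection between lattices of different sizes.

    Each presynaptic neuron maps to its scaled position on the target
    lattice and connects at random within a ``window``-sided neighborhood.
    With ``ensure_full_cover`` every target neuron is guaranteed at least one
    afferent (nearest source added where sampling left a gap).
    """
    sh_pre, sh_post = pre.shape, post.shape
    ry = sh_post[0] / sh_pre[0]
    rx = sh_post[1] / sh_pre[1]
    rows, cols = np.divmod(np.arange(pre.n), sh_pre[1])
    c_rows = np.floor(rows * ry).astype(int)
    c_cols = np.floor(cols * rx).astype(int)
    dx, dy = _lattice_offsets(window, exclude_center=False)
    pre_list, post_list = [], []
    for k in range(dx.size):
        mask = rng.random(pre.n) < prob
        src = np.flatnonzero(mask)
        if src.size == 0:
            continue
        tgt = _wrap_index(c_rows[src] + dx[k], c_cols[src] + dy[k], sh_post)
        pre_list.append(src)
        post_list.append(tgt)
    pre_idx = np.concatenate(pre_list) if pre_list else np.empty(0, dtype=np.int64)
    post_idx = np.concatenate(post_list) if post_list else np.empty(0, dtype=np.int64)
    if ensure_full_cover:
        covered = np.zeros(post.n, dtype=bool)
        covered[post_idx] = True
        missing = np.flatnonzero(~covered)
        if missing.size:
            m_rows, m_cols = np.divmod(missing, sh_post[1])
            src = _wrap_index(np.round(m_rows / ry).astype(int),
                              np.round(m_cols / rx).astype(int), sh_pre)
            pre_idx = np.concatenate([pre_idx, src])
            post_idx = np.concatenate([post_idx, missing])
    # drop duplicate (pre, post) pairs
    key = pre_idx * post.n + post_idx
    _, uniq = np.unique(key, return_index=True)
    pre_idx, post_idx = pre_idx[uniq], post_idx[uniq]
    w = np.full(pre_idx.size, init_w, dtype=float)
    g_max = cfg.estdp.g_E_max if kind == "exc" else cfg.istdp.g_I_max
    return SynapseProjection(name, pre, post, synapse_class, kind, rule,
                             pre_idx, post_idx, w, g_max, params)


def build_topology(config: SimConfig, rng_seed: int):
    """Construct all populations and synapse projections of the model.

    Returns ``(populations, projections)`` where populations is an ordered
    dict by name.  Reproducible: the same seed yields identical adjacency and
    initial weights.
    """
    config.validate()
    if config.neighborhood >= min(config.layer4_shape):
        raise ConfigError("neighborhood larger than lattice")
    rng = np.random.default_rng(rng_seed)
    np_ = config.neuron

    pops = {}
    pops["E"] = NeuronPopulation("E", config.layer4_shape, "E", np_)
    pops["I1"] = NeuronPopulation("I1", config.layer4_shape, "I", np_)
    pops["I2"] = NeuronPopulation("I2", config.i2_shape, "I", np_)
    for eye in ("L", "R"):
        pops[f"LGN_E_{eye}"] = NeuronPopulation(f"LGN_E_{eye}", config.lgn_shape, "E", np_)
        pops[f"LGN_I_{eye}"] = NeuronPopulation(f"LGN_I_{eye}", config.lgn_shape, "I", np_)

    ce, ci = config.conn_exc, config.conn_inh
    es, is_ = config.estdp, config.istdp
    win = config.neighborhood
    projs = []

    # four intracortical synapse classes
    projs.append(_gaussian_projection("E->E", pops["E"], pops["E"], "E->E",
                                      "exc", "estdp", ce, win, config, rng, es))
    projs.append(_gaussian_projection("E->I1", pops["E"], pops["I1"], "E->I",
                                      "exc", "estdp", ce, win, config, rng, es))
    projs.append(_gaussian_projection("I1->E", pops["I1"], pops["E"], "I->E",
                                      "inh", "istdp", ci, win, config, rng, is_))
    projs.append(_gaussian_projection("I1->I1", pops["I1"], pops["I1"], "I->I",
                                      "inh", "istdp", ci, win, config, rng, is_))

    # geniculocortical afferents (sparse random, every E covered by each eye)
    p_lgn = config.lgn_connect_prob
    for eye in ("L", "R"):
        proj = _cross_scale_projection(
            f"LGN_E_{eye}->E", pops[f"LGN_E_{eye}"], pops["E"], "LGN->E",
            "exc", "estdp", config.lgn_fanout, p_lgn,
            config.lgn_initial_weight, config, rng, es, ensure_full_cover=True)
        proj.g_max = config.g_lgn
        projs.append(proj)
        # feedforward inhibition pathway
        projs.append(_gaussian_projection(
            f"LGN_E_{eye}->I2", pops[f"LGN_E_{eye}"], pops["I2"], "LGN->I2",
            "exc", "estdp", ce, config.i2_fanout, config, rng, es))
    projs.append(_cross_scale_projection(
        "I2->E", pops["I2"], pops["E"], "I->E", "inh", "istdp",
        config.i2_fanout, p_lgn, config.init_low_value, config, rng, is_))

    # per-eye LGN E-I recurrence
    for eye in ("L", "R"):
        projs.append(_gaussian_projection(
            f"LGN_E_{eye}->LGN_I_{eye}", pops[f"LGN_E_{eye}"], pops[f"LGN_I_{eye}"],
            "E->I", "exc", "estdp", ce, config.lgn_fanout, config, rng, es))
        projs.append(_gaussian_projection(
            f"LGN_I_{eye}->LGN_E_{eye}", pops[f"LGN_I_{eye}"], pops[f"LGN_E_{eye}"],
            "I->E", "inh", "istdp", config.conn_inh_lgn, config.lgn_fanout,
            config, rng, is_))

    # mutual inhibition between the two eyes' relay populations: each relay
    # inhibits the other eye's relays at and around the matching retinotopic
    # position, so a wave in one eye suppresses the other eye's relays there
    for a, b in (("L", "R"), ("R", "L")):
        projs.append(_cross_scale_projection(
            f"LGN_E_{a}-|LGN_E_{b}", pops[f"LGN_E_{a}"], pops[f"LGN_E_{b}"],
            "LGNL<->LGNR", "inh", "istdp", config.cross_eye_window, 1.0,
            config.lgn_initial_weight, config, rng, is_))

    return pops, projs


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class Network:
    """The full model: populations, projections, drive, plasticity, traces."""

    def __init__(self, config: SimConfig, master_seed: int | None = None):
        self.config = config
        seed = config.master_seed if master_seed is None else master_seed
        self.master_seed = seed
        ss = np.random.SeedSequence(seed)
        topo_seed, inj_seed, stim_l, stim_r, misc = ss.spawn(5)
        self.populations, self.projections = build_topology(
            config, topo_seed.generate_state(1)[0])
        self.proj_by_name = {p.name: p for p in self.projections}
        self.rng_inject = np.random.default_rng(inj_seed)
        self.rng_stim_left = np.random.default_rng(stim_l)
        self.rng_stim_right = np.random.default_rng(stim_r)
        self.rng_misc = np.random.default_rng(misc)
        self.step_count = 0
        self.plasticity_enabled = True
        self.record_events = False
        self.events: list[tuple[int, str, int]] = []
        self._prev_spikes: dict[str, np.ndarray] = {}
        self._prev_sel: dict[str, np.ndarray] = {}
        # per-step mean E currents (for the balance trace)
        self.exc_current_trace: list[float] = []
        self.inh_current_trace: list[float] = []
        self.spike_counts = {name: 0 for name in self.populations}
        self.lesion_mask = {"L": None, "R": None}

    # ------------------------------------------------------------ injection
    def _refresh_injection(self):
        nz = self.config.noise
        gain = self.config.injection_gain
        frac = nz.inject_fraction
        for pop in self.populations.values():
            r = self.rng_inject.random(pop.n)
            u = (r >= nz.mu) if frac is None else (r < frac)
            pop.I_inj[:] = nz.A * u * nz.conversion_g * gain

    # ----------------------------------------------------------------- step
    def step(self, rgc_left: np.ndarray | None = None,
             rgc_right: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Advance the whole model by one time step.

        ``rgc_left``/``rgc_right`` are optional boolean (or 0/1) arrays of
        retinogeniculate spikes, one entry per LGN relay neuron of that eye,
        delivered as fixed-conductance excitatory input this step.
        """
        cfg = self.config
        dt = cfg.dt
        t = (self.step_count + 1) * dt
        pops = list(self.populations.values())

        # conductance kinetics + recurrent delivery of last step's spikes
        # (reusing the fanout gathers computed during last step's plasticity)
        decay_and_deliver(self.projections, self._prev_spikes, pops, dt,
                          self._prev_sel)

        # external retinogeniculate drive
        for eye, spikes in (("L", rgc_left), ("R", rgc_right)):
            if spikes is None:
                continue
            s = np.asarray(spikes, dtype=float).ravel()
            mask = self.lesion_mask[eye]
            if mask is not None:
                s = s * mask
            self.populations[f"LGN_E_{eye}"].g_exc += cfg.g_rgc * s

        # background injection schedule
        if self.step_count % max(1, int(round(cfg.noise.window / dt))) == 0:
            self._refresh_injection()

        # balance bookkeeping uses pre-update V of the cortical E sheet
        e = self.populations["E"]
        # magnitudes of the two synaptic current terms of the membrane equation
        self.exc_current_trace.append(float(np.mean(e.g_exc * (e.params.E_ex - e.V))))
        self.inh_current_trace.append(float(np.mean(e.g_inh * (e.params.E_inh - e.V))))

        # membrane update + threshold crossing; the pre-update last-spike
        # times are kept so plasticity can pair against strictly earlier spikes
        spikes = {}
        for pop in pops:
            saved = pop.last_spike.copy()
            s = step_membrane(pop, dt, t)
            # keep strictly-earlier times around for pairing
            pop._last_before = saved  # type: ignore[attr-defined]
            spikes[pop.name] = s
            self.spike_counts[pop.name] += s.size
            if self.record_events and s.size:
                self.events.extend((self.step_count, pop.name, int(i)) for i in s)

        new_sel: dict[str, np.ndarray] = {}
        for proj in self.projections:
            if proj.silenced:
                continue
            pre_spikes = spikes[proj.pre.name]
            pre_sel = proj.conns_of_pre(pre_spikes) if pre_spikes.size \
                else _EMPTY_IDX
            new_sel[proj.name] = pre_sel
            if not self.plasticity_enabled or proj.rule is None:
                continue
            if proj.rule == "estdp" and not cfg.estdp_on:
                continue
            if proj.rule == "istdp" and not cfg.istdp_on:
                continue
            apply_step_plasticity(
                proj,
                pre_spiked=proj.pre.spiked,
                post_spikes=spikes[proj.post.name],
                pre_spikes=pre_spikes,
                last_pre=proj.pre._last_before,  # type: ignore[attr-defined]
                last_post=proj.post._last_before,  # type: ignore[attr-defined]
                t=t,
                pre_sel=pre_sel,
            )

        self._prev_spikes = spikes
        self._prev_sel = new_sel
        self.step_count += 1
        return spikes

    def run(self, n_steps: int, stimulus=None) -> np.ndarray:
        """Run ``n_steps``; returns per-step E spike counts.

        ``stimulus`` is an optional callable ``step -> (rgc_left, rgc_right)``.
        """
        counts = np.empty(n_steps, dtype=np.int32)
        for i in range(n_steps):
            l = r = None
            if stimulus is not None:
                l, r = stimulus(self.step_count)
            s = self.step(l, r)
            counts[i] = s["E"].size
        return counts

    # ------------------------------------------------------------- analysis
    def mean_rate(self, counts: np.ndarray, pop: str = "E") -> float:
        """Population-mean firing rate in Hz over the counted steps."""
        n = self.populations[pop].n
        t_s = counts.size * self.config.dt / 1000.0
        return float(counts.sum() / (n * t_s))

    def ee_weight_neighborhoods(self) -> np.ndarray:
        """Dense (n_E, win, win) outgoing E->E weight images per neuron."""
        proj = self.proj_by_name["E->E"]
        win = self.config.neighborhood
        r = win // 2
        out = np.zeros((proj.pre.n, win, win))
        ox = proj.offsets[:, 0] + r
        oy = proj.offsets[:, 1] + r
        out[proj.pre_idx, ox, oy] = proj.w
        return out

    def lgn_weight_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-E-neuron summed geniculocortical weights (left, right)."""
        sums = []
        for eye in ("L", "R"):
            proj = self.proj_by_name[f"LGN_E_{eye}->E"]
            s = np.zeros(proj.post.n)
            np.add.at(s, proj.post_idx, proj.w)
            sums.append(s)
        return sums[0], sums[1]

    def class_weights(self) -> dict[str, np.ndarray]:
        """Normalized layer-4 weights by intracortical synapse class."""
        names = {"E->E": "E->E", "E->I": "E->I1", "I->E": "I1->E", "I->I": "I1->I1"}
        return {cls: self.proj_by_name[name].w.copy() for cls, name in names.items()}
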