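# Methods

`cortexmap` simulates the activity-dependent development of functional maps
(ocular dominance, orientation selectivity, recurrent-connectivity
anisotropy) in a thalamocortical spiking circuit, and provides the analysis
suite that reads those maps out of the evolving synaptic conductances.

## Model

### Neurons

All neurons are conductance-based leaky integrate-and-fire units on periodic
2-D lattices, integrated by forward Euler at `dt = 1 ms`:

    tau_m dV/dt = (V_rest - V) + w(t) (E_ex - V) - z(t) (E_inh - V) + I_inj

with `tau_m = 20 ms`, `E_ex = 0 mV`, `E_inh = 0 mV`, `V_rest = -74 mV`,
`V_reset = -60 mV`, `V_T = -54 mV`. `w` and `z` are the summed excitatory
and inhibitory conductance traces; each presynaptic spike adds
`weight x g_max` to the target trace (one-step synaptic delay), and traces
decay with `tau_AMPA = 10 ms` / `tau_GABA = 50 ms`. A neuron at or above
`V_T` fires (ties fire) and is reset.

Because `E_inh = 0` enters through an explicit minus sign, the inhibitory
term is a current proportional to `-z V` rather than a conductance pulling
toward a reversal potential below rest: it is hyperpolarizing at
physiological voltages but grows without bound as V falls, so the membrane
equation has no stable lower fixed point once `z` is large. We bound V with
a hard floor `V_floor = -90 mV` (configurable, set to `None` to disable),
which plays the role an inhibitory reversal potential would otherwise play.
Without the floor, strongly inhibited neurons diverge numerically.

### Topology

Two stages: a per-eye LGN (excitatory relay sheet + inhibitory sheet, with
mutual inhibition between the two eyes' relay sheets) and layer 4
(E sheet, feedback inhibitory sheet I1 matching E in size, feedforward
inhibitory sheet I2 matching the LGN in size). Within a stage, connection
probability at lattice offset `(dx, dy)` follows the published Gaussian
density `min(1, alpha exp(-(dx^2+dy^2) / (2 sigma)))` — the denominator is
`2 sigma`, exactly as printed, with a `gaussian_variant="standard"` switch
for the conventional `2 sigma^2` — using `alpha_E = 2.5, sigma_E = 1.0` for
excitatory and `alpha_I = 3.5` for inhibitory projections, restricted to an
odd-sided neighborhood window (19x19 at full scale).
Because `alpha > 1`, the density is clipped at 1: connections inside the
kernel core are guaranteed.

Geniculocortical projections are sparse and random: each relay neuron
projects into a window of layer-4 E cells around its retinotopic position
(`lgn_fanout`, 19 at full scale — the relay's "neuron and its neighborhood")
with probability `lgn_connect_prob = 0.18` per target, giving each E cell a
handful of strong afferents per eye; every E cell is guaranteed at least
one afferent from each eye. The geniculocortical conductance scale `g_lgn`
defaults to the intracortical g_E_max and is exposed separately. Relays
also drive I2, which projects back onto the same E neighborhoods
(feedforward inhibition, narrower `i2_fanout` window). Between the two
eyes' relay sheets, mutual inhibitory connections cover a small retinotopic
footprint (`cross_eye_window`, 3x3).

Within the cortex the inhibitory kernel is broad (`sigma = 2.0` under the
as-printed form): the published connectivity figure draws inhibition as the
broad kernel, and the narrow printed sigma_I would leave inhibitory
plasticity with too little capacity to balance the sheet. Inside the LGN
the printed narrow kernel (`conn_inh_lgn`, sigma 0.5) is kept.

Initial weights: intracortical synapses draw from the bimodal mixture
{0.12 with probability 0.9, U(0.5, 1.0) with probability 0.1} (normalized
scale); all geniculocortical synapses start equal (`lgn_initial_weight = 1`)
so every E cell begins exactly binocular.

### Plasticity

Excitatory synapses follow asymmetric E-STDP: `F(dt) = A+ exp(dt/tau+)` for
`dt = t_pre - t_post < 0`, `-A- exp(-dt/tau-)` for `dt >= 0`, with
`dw = g_max F(dt)` and hard clipping to `[0, g_max]`; `tau+ = tau- = 20 ms`
and the depression/potentiation ratio `beta = |A- tau-|/|A+ tau+| = 1.02`.
The published potentiation amplitude is printed as 0.0, which would nullify
learning and contradicts the printed beta; `A_plus` is therefore a free
parameter (default 0.03) and `A_minus` is derived from beta.

Inhibitory synapses follow a symmetric-in-|dt| I-STDP: more inhibitory
(`+B+`) for `|dt| <= lambda = 12 ms`, less inhibitory (`-B-`) for
`lambda < |dt| <= lambda + delta = 52 ms`, unchanged beyond, clipped to
`[0, g_I_max]`. The published inhibitory conductance ceiling (0.0035) is
one tenth of the excitatory one; at that value inhibitory currents are an
order of magnitude below excitatory currents at every drive level and no
excitation-inhibition-balanced regime exists, contradicting the model's
reported operating point (~10 Hz balanced vs ~100 Hz disinhibited). We read
it as a decimal misprint and default `g_I_max = 0.035 = g_E_max`; the
printed value remains available in the config. Since `B+ > g_I_max`, a
single inner-window pairing saturates an inhibitory synapse; this is kept
as printed (a warning is logged).

Pairing is nearest-neighbor (each spike pairs with the partner's most
recent spike); simultaneous pre/post spikes pair exactly once, on the
post-spike side, taking the printed `dt >= 0` branch. An event-driven
reference implementation (`plasticity.process_spikes`) defines these
semantics; the simulator's vectorized per-step path is tested for exact
equivalence against it on random rasters.

### Background drive

Every population receives the published random voltage injection: each
30 ms window a fresh random subset of neurons (`u(r) = 1` iff `r >= mu`,
`mu = 0.65`, i.e. 35% of neurons — the printed formula; the surrounding
text says 60%, and an `inject_fraction` override is provided) receives a
constant current `A x u(r) x 0.00125` with `A = 1.07`. Taken literally in
the mV-scale units of the membrane equation this product (~0.0013) could
never fire a neuron, so the network multiplies it by a dimensionless
`injection_gain`. This gain and the retinogeniculate conductance scale
(`g_rgc`, the increment per RGC spike onto a relay cell) are the only two
drive scales the source material leaves undetermined; both were calibrated
once, at the desk-scale preset, so that the network sits in its reported
operating regimes — a balanced Phase-1 rate near 10 Hz, a disinhibited rate
near 100 Hz, and retinal waves that robustly drive both the LGN and
layer 4 — and then frozen. They are configuration constants, not per-run
tuning knobs.

### Stimuli

*Phase 1 (early experience-independent)*: background injection only.

*Phase 2 (late experience-independent)*: retinal waves, generated
independently per eye on a retinal lattice and down-sampled to the LGN
sheet. Each wave picks N random initiation sites and one of 8 directions
per site; a 10x10 neighborhood around each moving center (velocity 2
lattice steps/ms) is activated each millisecond with Gaussian strength
falloff (sigma 2.5, unstated in the source; configurable), for 10 ms.
Waves are delivered back-to-back (configurable gap). Wave frames are
encoded as spikes by per-millisecond Bernoulli thinning with
`P(spike) = intensity x wave_peak_rate_hz x dt/1000` — an inhomogeneous
Poisson process at the simulation resolution. (Feeding each 1 ms frame of a
moving wave through a restarted interspike-interval draw would collapse the
realized rate to a few percent of the intended one, so the thinned form is
used for time-varying frame sequences; static images go through the ISI
encoder below.)

*Phase 3 (experience-dependent)*: textured synthetic images with a 1/f
amplitude spectrum stand in for natural-photograph crops. Each image
becomes a stereo pair (right image shifted by up to 10 px per axis and
rescaled by s in [1, 1.05], edge-replicated), split into ON and OFF
channels (OFF = rectified mean-centered inverse by default;
`off_mode="one_minus"` for the rectified plain inverse), packed onto the
top/bottom halves of each eye's RGC sheet, and encoded by the Poisson ISI
procedure: per pixel, interspike intervals are Poisson with mean
`isi_base x image_mean / intensity` ms (floored at 1 ms), so a
constant-intensity frame reproduces a Poisson ISI at the image mean exactly
while brighter pixels fire proportionally faster and zero pixels stay
silent. The source text states both that the Poisson mean is the image mean
and that spikes are generated per pixel; the rate-proportional reading is
the only one consistent with any orientation information reaching the
cortex.

Flag patterns (stability probes) are block compositions of horizontal and
vertical stripes only, presented for 10-100 ms each.

## Map analysis

*RCM*: per E neuron, the outgoing E->E neighborhood weight image is matched
against zero-mean oriented Gaussian-bar templates (widths sigma_a = 2.5
across, sigma_b = 5.7 along; note these enter as `2 sigma^2`, unlike the
connectivity formula) at orientations {0, 45, 90, 135} degrees, maximizing
over a transverse offset sweep gamma in [-8, 8]. The four match scores
combine as vectors at doubled angles; the preferred orientation is half the
resultant angle and the resultant length is the confidence. Resultants
below 5% of the neighborhood weight norm are flagged "undefined" (the
doubled-angle sum of an isotropic neighborhood cancels to numerical noise).

*ODM*: each E neuron is labeled by the eye with the larger summed
geniculocortical weight (exact tie = binocular), and the +1/0/-1 label
image is median filtered 3x3 (periodic wrap). Separation statistics
(mean/std of the eye-wise weight-sum difference per labeled group) and the
per-neuron dominance fraction `(sum_dom - sum_nondom)/(sum_dom + sum_nondom)`
are tracked over development.

*OSM*: the network state is cloned and plasticity frozen (probing is
non-invasive; the source does not state whether probing altered weights).
Both eyes are stimulated with an oriented bar (15 x 5 px at full scale,
scaled with the LGN sheet), jittered bilaterally by < 7 px with alternating
sign across trials (8 trials per orientation by default; the exact trial
schedule is unstated). E spikes are counted over the protocol window
(10,000 steps at full scale; reduced in the desk-scale presets). The four
rate images combine via the angle-doubling vector sum: differential images
(0-90, 45-135) form the doubled-angle Cartesian components, which are
median filtered (9x9 at full scale, wrap) and converted to polar preference
and selectivity.

*Gradients and discontinuities*: one-step circular differences (mod 180,
periodic wrap) per axis, combined as a Euclidean norm capped at 90 degrees.
(The one-step form is used rather than a centered two-step difference so
that a 0/90-degree half-plane boundary reads the full 90-degree
discontinuity.) Fractures are connected components of gradient >= 90
degrees spanning at least 3 pixels; smaller components are reported as
dots. Pinwheel-like patterns are detected by a winding-number test —
accumulating circular differences around each 3x3 ring and flagging a net
winding of +-180 degrees — never from gradient point singularities, which
the median smoothing removes.

*Stability*: weight histograms (50 uniform bins on [0, 1]) are normalized
by their maximum bin, exactly as published (the "distributions" are not
probability vectors; a `proper_normalization` switch provides sum
normalization), and compared with the symmetric KL sum, computed with an
additive epsilon = 1e-12 inside the log. The per-class KL between
consecutive snapshots every 5000 steps is the stability trace. The E-I
balance trace records, per step, the population means of the two synaptic
current terms of the membrane equation over the E sheet, block-averaged
over 200 ms windows, with a running mean alongside.

## Scales and problem sizes

The full-scale configuration (128x128 E/I1 sheets, 48x48 LGN per eye,
millions of steps) is the published one and is cluster-scale. The package's
quantitative experiments run at the `test_preset`: 32x32 E/I1, 24x24
LGN/I2, 9x9 neighborhoods, phase durations 50k/100k/100k steps, retinal
waves generated at 48x48 and down-sampled 2x, with wave-site count scaled
with retinal area (N = 2) and the OSM protocol shortened (1000-step
windows, 4 trials). All ratios of the full-scale network are preserved.
The unit/property tests use a further-reduced `mini_preset` (16x16 sheets).

## Known limitations

* The two drive scales are calibrated, not derived; absolute firing rates
  at other lattice sizes will differ until the gains are recalibrated.
* **Direction and depth of ocular competition.** Under nearest-neighbor
  pairing with a depression-biased window (beta > 1), every presynaptic
  spike that is not shortly followed by a postsynaptic spike is net
  depressing. At desk scale the relay background rate exceeds the
  inhibition-clamped cortical rate, so geniculocortical plasticity is
  depression-led: structured input still separates the two eyes (the
  dominance fraction rises once retinal waves start), but the separation
  saturates far below the mature regime, and silencing one eye shifts
  labels toward the *silenced* eye rather than the intact one. A
  single-cell model with an idealized firing-rate clamp does reach the
  mature winner-take-all regime (near-total separation) when the
  postsynaptic neuron can match each afferent's per-visit spike count;
  the full desk-scale network cannot sustain that regime because the
  saturating inhibitory rule's clamping range is limited. Results that
  depend on potentiation-led competition (mature dominance fractions,
  lesion dose-response direction, experience-driven recruitment of
  cardinal orientation preferences) should therefore not be read off
  desk-scale runs.
* Orientation-map probing competes with the ongoing background drive: at
  desk scale most E cells' bar-evoked rate differentials are at noise
  level, and the smoothed preference maps are sparse and strongly
  quantized.
* With `E_inh = 0` as printed, inhibition is a subtractive current rather
  than shunting toward a reversal; the V floor bounds but does not remove
  this distortion.
* Pinwheel detection reports winding loci only; no pinwheel-density
  statistics are attempted, and linear-zone detection is not implemented.
* The synthetic natural-image surrogate reproduces the 1/f spectrum and
  broadband orientation content of photographs but none of their higher-
  order structure (objects, occlusions, shadows); conclusions about real
  visual experience rest on the orientation statistics only.
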