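# Methods

## The transport model

A transport event moves `n_s` molecules of each species `s` in a set
`S` across the membrane, from compartment `c_s` to `d_s`
(0 = extracellular, 1 = intracellular).  The work for one event, in
units of kT, is

    dG = delta_Ext * q v_Ext / kT
       + sum_s n_s (c_s - d_s) [ ln([s]_0/[s]_1) - z_s v / v_T ],

with `v` the membrane potential, `v_T = kT/q` the thermal voltage and
`v_Ext` the potential equivalent of an external energy source (ATP
hydrolysis for pumps; `delta_Ext = 1` exactly when the chemical part of
the energy is uphill).  Forward and backward event rates follow a
Butler–Volmer-type split of the Boltzmann factor,

    alpha = r exp(-b dG),    beta = r exp((1-b) dG),

so that `alpha/beta = exp(-dG)` identically (detailed balance holds for
every rate `r` and bias `b`), and the net flux is `Phi = alpha - beta`.
The bias `b` in [0, 1] is the package's one rectification parameter:
`b = 1/2` gives a hyperbolic-sine current, `b -> 0` saturates the
forward direction (inward rectification for a K+ channel), `b -> 1`
the backward direction.  For ionic mechanisms the energy collapses to
`dG = (v_o - eta v)/v_T` with `eta = sum n_s (c_s - d_s) z_s` the net
charge count and `v_o = delta_Ext v_Ext + sum n_s z_s (c_s - d_s) v_s`
a composite of Nernst potentials; the current density is
`i = q eta Phi`, zero exactly at `v = v_o/eta`.

Both the concentration-explicit and the `(eta, v_o)` evaluation paths
are implemented (`flux` and `flux_ionic`) and tested to agree to 1e-10
relative; energies are carried internally in kT so no unit constants
ever appear inside an exponent.

Approximations derived from this law, each tested against the exact
current: the Taylor expansion about the reversal potential with
coefficients `1, (b - 1/2), (3b^2 - 3b + 1)/6` (the linear term is the
conductance model with `g = eta^2 q r / v_T`, the exact tangent at
reversal — which is why conductance models cannot rectify); the
Goldman–Hodgkin–Katz constant-field current, which equals the
two-exponential form with a voltage-dependent amplitude for *any*
bias; and the `b in {0, 1/2, 1}` closed forms.

### Units

Voltages in mV, time in ms, concentrations in mM (intracellular Ca2+
in uM), rates `r` in molecules/ms/um^2, currents in pA/um^2 (membrane
models: pA/pF after capacitance normalisation), conductances in
nS/um^2.  The default temperature is 310 K (`v_T = 26.71 mV`),
configurable everywhere through a `Constants` object.  The ATP
potential defaults (`dG0 = -30.5 kJ/mol`, ATP 2 mM, ADP 1.33 mM,
Pi 10 mM) are a calibration to the commonly quoted
`v_ATP ~ -450 mV`; the membrane models override `v_ATP` with their own
tabulated values (-420 / -430 mV).

## Membrane models

Each mechanism contributes a capacitance-normalised current
`J_l = a_l p_l phi_l(v)` with `phi_l` the two-exponential kernel at the
mechanism's `(eta_l, v_o_l)` and `dv/dt = -sum J_l (+ i_stim/C_m)`.
Gates follow a logistic steady state
`F_u(v) = 1/(1 + exp(-g_u (v - v_u)/v_T))` and the activation flow
`dw/dt = w^k_w (F_w - w) R_w(v)` with a biased two-exponential rate
`R_w`; gating rates printed as "per second" in the source tables are
read on the ms scale (0.005/ms, 2/ms), without which the models are
three orders of magnitude slow; a `literal_rate_units` flag restores
the literal reading.

### Sign conventions (the one genuinely open design point)

Amplitudes are tabulated as positive magnitudes, but the physical
amplitude `eta N r q` carries the sign of `eta`.  Writing every term
with its thermodynamic sign (channels signed by `eta`, exchanger
negative with `eta = -1`) produces a system whose rest state near
-76 mV is globally stable: it never pacemakes, from any initial
condition, under any sign combination of the remaining terms (checked
by brute force).  The unique sign assignment that oscillates — and
simultaneously reproduces the double-peaked Ca2+ current, the
order-of-magnitude gap between carrier and channel currents, and the
exchanger-current reversal within each cycle — is:

* L-type Ca2+ (and, in the interneuron, transient Na+) currents signed
  by `sign(eta) = -1` (inward, depolarising);
* K+ channel and Na-K pump currents positive (outward above reversal);
* the Na-Ca exchanger current with its *positive* printed amplitude on
  the `eta = -1` kernel, i.e. the negative of its thermodynamic sign;
* the Ca2+ balance `dc/dt = r_c (c_inf - c) - k_c (J_CaL + J_NaCa)`,
  the only bookkeeping under which Ca2+ influx through either pathway
  raises `c`.

This is implemented as the package's convention and documented here
rather than hidden, because it is the single deviation from a
mechanical transcription of the model equations that the dynamics
force.

### Pacemaker (SAN) specifics

States `(v, w, c)`: potential, K+ activation (doubling as L-type
inactivation through the `(1 - w)` factor), intracellular Ca2+ (uM).
The Ca2+ Nernst potential is dynamic,
`v_Ca = (v_T/2) ln(ca_out / c)`, with extracellular Ca2+ fixed at
2 mM (not part of the published table; periods shift by roughly
-70 ms/+120 ms at 3 mM/1.5 mM, amplitudes by only a few mV).  The
exchanger reversal `3 v_Na - 2 v_Ca(c)` sweeps from about -84 mV at
resting Ca2+ to about -47 mV at the cycle's Ca2+ peak, carrying the
reversal crossing through the voltage trace once per cycle.

With the tabulated parameters at 310 K the model settles on a limit
cycle with period 375 ms, amplitude (max - min over steady cycles)
82 mV, and maximal upstroke 4.1 V/s.  The reference description of the
underlying recordings quotes a period near 400 ms (the model is within
7%) and an amplitude near 70 mV; the model's amplitude is ~82 mV and
is insensitive to the two free choices (temperature, extracellular
Ca2+) over physiological ranges, so that gap is reported as-is rather
than tuned away.  The inward Ca2+ current shows exactly two local
minima per cycle; removing the `(1 - w)` inactivation leaves both
minima in place, confirming the double peak is a consequence of the
voltage trajectory passing twice through the maximal-driving-force
region, not of gating.

### Interneuron (FS) specifics

States `(v, w)`; `w` is K+ activation and Na+ inactivation at once,
with quasi-steady Na+ activation `F_m`.  At rest the pump pins the
potential near its own reversal (-72 mV).  A current step enters as
`+i_stim/C_m` after a 500 ms settling window.  With the tabulated
parameters the rheobase (minimal step giving >= 3 spikes in the last
500 ms of a 2 s step, bisected to 1 pA between 0 and 100 pA) is
43.75 pA, inside the published 40-50 pA window, and the maximal
upstroke during 80 pA-evoked spiking is 117 V/s, inside the published
100-200 V/s range.

## IV fitting

The fitted curve is `i(v) = rq [exp(bX) - exp((b-1)X)]` with
`X = |z|(v - v_o)/v_T`.  The charge factor matters: the embedded
AMPA-Kainate recordings were made in a Ca2+ ringer, so the current is
carried by a divalent ion and the exponential scale is `v_T/2`
(13.4 mV at 310 K).  A fit with `|z| = 1` cannot pass through the
hyperpolarised limb of these data at all; freeing the voltage scale
recovers 13.3-15 mV, confirming the divalent reading.  The loss is
unweighted least squares (box-constrained trust-region, `b` in [0, 1],
`rq >= 0`) with a deterministic data-driven start: `v_o` from the
interpolated zero crossing, `b = 1/2`, `rq` from the slope at the
crossing.  A `1/|i|` weighting is available behind a flag.  Standard
errors are Gauss-Newton estimates from the Jacobian at the optimum.

On the embedded data OLS yields `b = 0.458` (GluR3) and `0.399`
(GluR1+GluR3), within 0.05 of the published curve parameters 0.45 and
0.35.  The published reversal values (-30/-35 mV) are not recovered to
3 mV by least squares under any standard weighting — the published
GluR3 reversal lies above the data's own interpolated zero crossing
(-34.6 mV) — so the published `(v_o, rq)` pairs are evidently not a
least-squares optimum of the printed table; the corresponding checks
are left failing with this explanation rather than loosened.

## Synthetic IV data

`generate_synthetic_iv` draws i.i.d. Gaussian current noise of fixed
standard deviation around the exact model curve on a user grid
(default study: 25 points, -100..30 mV, 5 pA noise, seeded
`default_rng`).  It emulates voltage-clamp steady-state measurements
with homoscedastic noise; it does not emulate series-resistance error,
voltage-dependent noise, or digitisation bias, so recovery results
bound estimator behaviour under the model, not instrument physics.
The recovery study (100 seeded draws over `v_o in [-60, 0]`,
`b in [0.2, 0.8]`, `rq in [5, 50]`) gives median `|b_hat - b| < 0.05`.

## Numerical choices

* Integrator: `solve_ivp` LSODA, `rtol 1e-8`, `atol 1e-10`,
  `max_step 0.1 ms` (the exponential currents are stiff near spikes);
  trajectories are sampled at 0.5 ms (pacemaker) / 0.05 ms
  (interneuron) with the dense interpolant retained.  Loosening to
  `rtol 1e-6, max_step 0.5` moves the pacemaker period by < 0.1%.
* Upstroke velocity is measured on the dense output resampled at
  0.01 ms; on the sampling grid alone the brief interneuron upstroke
  is underestimated.
* Spike detection: linear interpolation of upward threshold crossings;
  thresholds -30 mV (pacemaker) / 0 mV (interneuron), both
  mid-upstroke; metrics over the last 5 cycles after a 2000 ms
  transient.  Standard problem sizes: 7 s pacemaker runs, 2.5 s
  interneuron runs (2 s step after 0.5 s settling).
* GHK at `v = 0`: the removable singularity is evaluated through
  `expm1` (exact for small arguments) with the analytic limit
  substituted at exactly zero.
* `w` stays in [0, 1] because the flow vanishes at both ends
  (`w^k_w` factor and `F_w - w`); `c > 0` because the inward Ca2+
  current diverges as `c -> 0`.  Both are asserted numerically along
  trajectories; the solver-facing right-hand side floors `c` at 1e-9
  to keep the logarithm finite during trial steps.

## Known limitations

* Na+/K+ concentrations are static; only Ca2+ is dynamic, and its
  balance is a single-pool linear relaxation (no SR/buffering
  machinery).
* The rate `r` is a phenomenological constant: no temperature or pore
  geometry model, no organelle compartments, no time-varying
  ATP/ADP/Pi pools.
* Gating is deterministic and one-variable per model; no stochastic
  channel noise, no spatial structure.
* The exchanger sign convention is adopted from the dynamics (above);
  a strictly thermodynamic signing is available to users building
  mechanisms directly from `TransportMechanism`, where currents always
  carry `q eta` signs.
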