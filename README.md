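# thermoflux

Thermodynamic models of passive and active transmembrane transport,
for electrophysiologists and modellers who want channels, pumps,
exchangers and symporters described by **one** current law instead of
a zoo of ad-hoc formulas.

A transport event that moves `n_s` molecules of each species `s` from
compartment `c_s` to `d_s` costs (in kT)

```
ΔG = δ_Ext·q·v_Ext/kT + Σ_s n_s (c_s − d_s) [ ln([s]₀/[s]₁) − z_s v/v_T ]
```

and proceeds with Boltzmann-weighted forward/backward rates
`α = r·e^{−bΔG}`, `β = r·e^{(1−b)ΔG}`, so the net flux is
`Φ = α − β` and, for electrogenic transport (net charge count
`η = Σ n_s(c_s−d_s)z_s ≠ 0`), the current is

```
i(v) = q η r [ e^{b(ηv−v_o)/v_T} − e^{(b−1)(ηv−v_o)/v_T} ]
```

with reversal potential `v_o/η` and a single rectification bias
`b ∈ [0,1]` (½ = symmetric sinh, 0/1 = saturating inward/outward
rectifier).  Conductance-based (ohmic) currents are the tangent of
this curve at reversal (`g = η²qr/v_T`), and the
Goldman–Hodgkin–Katz constant-field equation is the same curve with a
voltage-dependent amplitude — both identities are part of the test
suite.

The package provides:

* **`thermoflux.transport`** — energy bookkeeping, flux and current
  for arbitrary mechanisms; **`thermoflux.catalog`** — 12 classic
  mechanisms (Cl⁻/K⁺/Na⁺/Ca²⁺ channels, Na-K/Ca/H ATPases, Na-Ca and
  Na-H exchangers, Na-I/K-Cl/Na-K-Cl symporters) with their η and
  reversal compositions.
* **`thermoflux.approx`** — the approximation ladder (Taylor,
  conductance, GHK, sinh, rectifier limits).
* **`thermoflux.iv`** — `RectifiedIVModel.fit()` for current–voltage
  data, with the digitised AMPA-Kainate receptor recordings (GluR3 and
  GluR1+GluR3 in Ca²⁺ ringer) embedded.
* **`thermoflux.membrane` / `thermoflux.analysis`** — a cardiac
  sinoatrial-node pacemaker (states v, w, c) and a striatal
  fast-spiking interneuron (v, w) built from these currents, plus
  spike metrics, rheobase bisection and Ca²⁺-current peak analysis.
* A CLI: `thermoflux {catalog,fit,approx,simulate,analyze,rheobase}`.

## Worked example

Fit the rectified current to the GluR3 oocyte recordings (Ca²⁺-carried,
so the exponential voltage scale is v_T/2):

```python
import thermoflux as tf
from thermoflux.analysis import spike_metrics

res = tf.fit_iv(tf.ampa_kainate_dataset("GluR3"), charge=2)
print(res.summary())
```

```
Rectified IV curve fit
==============================================
dataset:        GluR3
n observations: 14
converged:      True (`ftol` termination condition is satisfied.)
residual SS:    568.998 pA^2
----------------------------------------------
param         estimate       std err
v_o            -33.451          1.27
b              0.45799        0.0116
rq              23.602         0.374
```

`b ≈ 0.46 < ½` says the receptor current is inwardly rectified — the
inward limb grows faster than the outward one — and `v_o ≈ −33 mV` is
the fitted reversal.  Then run the pacemaker with its published
parameter set and measure the oscillation:

```python
traj = tf.SANModel().simulate(t_max=7000.0)   # 7 s, 2 s transient
m = spike_metrics(traj, threshold_mV=-30.0)
print(f"period    {m.period_ms:7.1f} ms")
print(f"amplitude {m.amplitude_mV:7.1f} mV")
print(f"max dv/dt {m.max_dvdt_V_per_s:7.2f} V/s")
```

```
period      375.0 ms
amplitude    81.9 mV
max dv/dt    4.11 V/s
```

A period of ~0.4 s and an upstroke well under 10 V/s are the signature
of a Ca²⁺-driven (not Na⁺-driven) cardiac pacemaker; the inward
Ca²⁺ current `traj.currents["J_CaL"]` shows its characteristic double
peak per cycle.  The same machinery gives the interneuron's rheobase:

```python
from thermoflux.analysis import find_rheobase
find_rheobase(tf.FSModel(), 0.0, 100.0, resolution_pA=1.0)  # -> 43.75 pA
```

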