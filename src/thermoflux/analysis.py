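"""Spike metrics, rheobase search and Ca2+-current peak structure.

Operates on :class:`~thermoflux.membrane.Trajectory` objects.  Times in
ms, potentials in mV; upstroke velocities in V/s (numerically equal to
mV/ms).  Unless noted otherwise, the first 2000 ms of a trajectory are
treated as transient and excluded from every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .membrane import FSModel, Trajectory

__all__ = [
    "SpikeMetrics",
    "CaExtrema",
    "detect_spikes",
    "spike_metrics",
    "find_rheobase",
    "ca_current_extrema",
    "TRANSIENT_MS",
]

#: Default transient discarded before computing any metric, ms.
TRANSIENT_MS = 2000.0

#: Default spike-detection thresholds, mV (mid-upstroke for each model).
SAN_THRESHOLD_MV = -30.0
FS_THRESHOLD_MV = 0.0


@dataclass(frozen=True)
class SpikeMetrics:
    """Periodicity summary of a spiking/pacemaking voltage trace."""

    period_ms: float
    amplitude_mV: float
    max_dvdt_V_per_s: float
    firing_rate_Hz: float
    n_spikes: int


def detect_spikes(trajectory: Trajectory, threshold_mV: float,
                  t_min: float = 0.0) -> np.ndarray:
    """Upward threshold-crossing times, linearly interpolated (ms).

    Returns a strictly increasing (possibly empty) array of the times at
    which v crosses the threshold from below, restricted to
    ``t >= t_min``.
    """
    t = trajectory.times
    v = trajectory.v
    keep = t >= t_min
    t, v = t[keep], v[keep]
    if t.size < 2:
        return np.empty(0)
    below = v[:-1] < threshold_mV
    above = v[1:] >= threshold_mV
    idx = np.nonzero(below & above)[0]
    frac = (threshold_mV - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def spike_metrics(trajectory: Trajectory, threshold_mV: float,
                  n_cycles: int = 5, transient_ms: float = TRANSIENT_MS,
                  dvdt_dt: float = 0.01) -> SpikeMetrics:
    """Period, amplitude and upstroke velocity over the last ``n_cycles``.

    Period is the mean inter-crossing interval; amplitude is
    ``max(v) - min(v)`` over the analysed cycles; the maximum dv/dt is
    taken from the dense solver output resampled at ``dvdt_dt`` ms so
    the brief upstroke is not undersampled.

    Raises
    ------
    ValueError
        If fewer than ``n_cycles + 1`` crossings remain after the
        transient (the trace is not usefully periodic).
    """
    crossings = detect_spikes(trajectory, threshold_mV, t_min=transient_ms)
    if crossings.size < n_cycles + 1:
        raise ValueError(
            f"not periodic: {crossings.size} crossings after {transient_ms:g} ms, "
            f"need {n_cycles + 1}"
        )
    window = crossings[-(n_cycles + 1):]
    period = float(np.mean(np.diff(window)))
    t, v = trajectory.times, trajectory.v
    in_window = (t >= window[0]) & (t <= window[-1])
    amplitude = float(v[in_window].max() - v[in_window].min())
    _, v_fine = trajectory.resample_v(dvdt_dt, window[0], window[-1])
    max_dvdt = float(np.max(np.diff(v_fine)) / dvdt_dt)  # mV/ms == V/s
    return SpikeMetrics(
        period_ms=period,
        amplitude_mV=amplitude,
        max_dvdt_V_per_s=max_dvdt,
        firing_rate_Hz=1000.0 / period,
        n_spikes=int(crossings.size),
    )


def _sustained_spiking(model: FSModel, stim: float, threshold_mV: float,
                       step_ms: float, settle_ms: float,
                       min_spikes: int, tail_ms: float) -> bool:
    traj = model.simulate(stim_amplitude=stim, stim_onset=settle_ms,
                          t_max=settle_ms + step_ms)
    crossings = detect_spikes(traj, threshold_mV,
                              t_min=settle_ms + step_ms - tail_ms)
    return crossings.size >= min_spikes


def find_rheobase(model: FSModel, stim_lo: float = 0.0, stim_hi: float = 100.0,
                  resolution_pA: float = 1.0, threshold_mV: float = FS_THRESHOLD_MV,
                  step_ms: float = 2000.0, settle_ms: float = 500.0,
                  min_spikes: int = 3, tail_ms: float = 500.0) -> float:
    """Minimal current step (pA) that elicits sustained spiking, by bisection.

    A step amplitude counts as "spiking" when the response contains at
    least ``min_spikes`` threshold crossings in the final ``tail_ms`` of
    a ``step_ms`` step — transient onset spiking without maintained
    firing does not qualify.  The bracket [stim_lo, stim_hi] must be
    silent at the bottom and spiking at the top; the returned value is
    the upper edge of the final bracket, within ``resolution_pA`` of the
    true transition.
    """
    if stim_lo >= stim_hi:
        raise ValueError("stim_lo must be below stim_hi")

    def spiking(s: float) -> bool:
        return _sustained_spiking(model, s, threshold_mV, step_ms,
                                  settle_ms, min_spikes, tail_ms)

    if spiking(stim_lo):
        raise ValueError(f"lower endpoint {stim_lo} pA already spikes: no bracket")
    if not spiking(stim_hi):
        raise ValueError(f"upper endpoint {stim_hi} pA does not spike: no bracket")
    lo, hi = stim_lo, stim_hi
    while hi - lo > resolution_pA:
        mid = 0.5 * (lo + hi)
        if spiking(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class CaExtrema:
    """Interior extrema of the L-type Ca2+ current within one cycle."""

    minima_times: np.ndarray
    minima_values: np.ndarray
    maxima_times: np.ndarray
    maxima_values: np.ndarray

    @property
    def n_minima(self) -> int:
        return int(self.minima_times.size)


def _interior_extrema(t: np.ndarray, y: np.ndarray):
    dy = np.diff(y)
    mins = np.nonzero((dy[:-1] < 0) & (dy[1:] > 0))[0] + 1
    maxs = np.nonzero((dy[:-1] > 0) & (dy[1:] < 0))[0] + 1
    return mins, maxs


def ca_current_extrema(trajectory: Trajectory, threshold_mV: float = SAN_THRESHOLD_MV,
                       transient_ms: float = TRANSIENT_MS,
                       cycle_index: int = -2) -> CaExtrema:
    """Local extrema of J_CaL within one steady pacemaking cycle.

    The cycle is delimited by consecutive upward threshold crossings
    (``cycle_index`` counts from the end; the default -2 is the last
    complete cycle).  The pacemaker's inward Ca2+ current shows two
    local minima (two maxima of current amplitude) per cycle: once on
    the upstroke and once on the downstroke, both passages through the
    voltage of maximal inward driving force.
    """
    if "J_CaL" not in trajectory.currents:
        raise ValueError("trajectory has no J_CaL trace")
    crossings = detect_spikes(trajectory, threshold_mV, t_min=transient_ms)
    if crossings.size < 2:
        raise ValueError("need at least one full cycle after the transient")
    t0, t1 = crossings[cycle_index - 1], crossings[cycle_index]
    t = trajectory.times
    sel = (t >= t0) & (t < t1)
    tt = t[sel]
    j = trajectory.currents["J_CaL"][sel]
    mins, maxs = _interior_extrema(tt, j)
    return CaExtrema(
        minima_times=tt[mins], minima_values=j[mins],
        maxima_times=tt[maxs], maxima_values=j[maxs],
    )
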