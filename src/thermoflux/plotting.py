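"""Optional matplotlib helpers (not required by any analysis)."""

from __future__ import annotations

from .membrane import Trajectory


def plot_trajectory(trajectory: Trajectory, ax=None, show_currents: bool = False):
    """Plot v(t); optionally the per-mechanism currents on a twin axis.

    Returns the matplotlib axes.  Imports matplotlib lazily so the rest
    of the package has no hard plotting dependency.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trajectory.times, trajectory.v, color="0.2", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("v (mV)")
    if show_currents and trajectory.currents:
        ax2 = ax.twinx()
        for name, j in trajectory.currents.items():
            ax2.plot(trajectory.times, j, lw=0.6, alpha=0.7, label=name)
        ax2.set_ylabel("J (pA/pF)")
        ax2.legend(fontsize=7, loc="upper right")
    return ax
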