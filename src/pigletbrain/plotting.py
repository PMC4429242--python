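"""Quick-look figures for simulations and cohort averages (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_simulation(res, axes=None):
    """2x3 panel: NIRS changes, pH, CMRO2/CBF percent, NTP fraction."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    ax = axes.ravel()
    tmin = res.t / 60.0
    o = res.observables
    ax[0].plot(tmin, 1e3 * o["dHbO2_mM"], label="dHbO2")
    ax[0].plot(tmin, 1e3 * o["dHHb_mM"], label="dHHb")
    ax[0].set_ylabel("uM change")
    ax[0].legend(fontsize=8)
    ax[1].plot(tmin, 1e3 * o["doxCCO_mM"], color="tab:green")
    ax[1].set_ylabel("doxCCO (uM)")
    ax[2].plot(tmin, o["pH"], color="tab:red")
    ax[2].set_ylabel("pH_i")
    ax[3].plot(tmin, o["cmro2_pct"], color="tab:purple")
    ax[3].set_ylabel("CMRO2 (% baseline)")
    ax[4].plot(tmin, o["cbf_pct"], color="tab:orange")
    ax[4].set_ylabel("CBF (% baseline)")
    ax[5].plot(tmin, 100 * o["ntp_frac"], color="tab:brown")
    ax[5].set_ylabel("NTP (% baseline)")
    for a in ax:
        a.set_xlabel("time (min)")
    return axes


def plot_group_average(ga, signal: str, ax=None):
    """Section means +/- SD on the common timeline for one signal."""
    import matplotlib.pyplot as plt

    from .group import to_common_timeline

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t, traces, pb = to_common_timeline(ga)
    m = traces[signal]
    sd = ga.sd[signal].reshape(-1)
    ax.plot(t / 60.0, m, "-o", ms=3, label=signal)
    ax.fill_between(
        t / 60.0,
        m - np.nan_to_num(sd),
        m + np.nan_to_num(sd),
        alpha=0.25,
    )
    for e in pb.edges[1:-1]:
        ax.axvline(e / 60.0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(signal)
    return ax
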