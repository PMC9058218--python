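"""Minimal figures: k(T) for an activated pathway and scan-profile overlays."""

from __future__ import annotations

from .scans import ScanProfile


def plot_temperature_profile(points: list[tuple[float, float]], ax=None):
    """Semilog plot of k(T) pairs from :func:`radscav.tst.temperature_profile`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t, k = zip(*points)
    ax.semilogy(t, k, "o-")
    ax.set_xlabel("T (K)")
    ax.set_ylabel(r"k (M$^{-1}$ s$^{-1}$)")
    return ax


def plot_scans(profiles: list[ScanProfile], crossing=None, ax=None):
    """Overlay scan profiles; mark a spin crossing point if given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for prof in profiles:
        r, e = prof.along_approach()
        ax.plot(r, e, label=prof.spin_label or "scan")
    if crossing is not None:
        ax.plot([crossing[0]], [crossing[1]], "k*", markersize=12, label="SCP")
    ax.invert_xaxis()  # approach runs right to left
    ax.set_xlabel("distance (pm)")
    ax.set_ylabel(r"$\Delta$E (kJ mol$^{-1}$)")
    ax.legend()
    return ax
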