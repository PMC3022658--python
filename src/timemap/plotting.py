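"""Optional matplotlib visualizations (requires the ``plots`` extra)."""

from __future__ import annotations

import numpy as np


def _require_pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (install the 'plots' extra)"
        ) from err
    return plt


def plot_topography(topography, montage, ax=None, n_grid=100):
    """Interpolated top-down view of one scalp map.

    Projects the upper-hemisphere electrodes to the plane (azimuthal
    equidistant) and shows a nearest/linear-interpolated voltage map.
    """
    plt = _require_pyplot()
    from scipy.interpolate import griddata

    pos = montage.positions
    theta = np.arccos(np.clip(pos[:, 2], -1, 1))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    r = theta / np.pi * 2.0
    x, y = r * np.cos(phi), r * np.sin(phi)
    gx, gy = np.meshgrid(
        np.linspace(-1.05, 1.05, n_grid), np.linspace(-1.05, 1.05, n_grid)
    )
    gz = griddata((x, y), np.asarray(topography), (gx, gy), method="linear")
    gz[np.hypot(gx, gy) > 1.02] = np.nan
    if ax is None:
        _, ax = plt.subplots()
    lim = np.nanmax(np.abs(gz))
    im = ax.pcolormesh(gx, gy, gz, shading="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.scatter(x, y, s=4, c="k")
    ax.set_aspect("equal")
    ax.set_axis_off()
    return im


def plot_cv_curve(results, ax=None):
    """Cross-validation criterion against the number of template maps."""
    plt = _require_pyplot()
    if ax is None:
        _, ax = plt.subplots()
    curve = results.cv_curve
    ax.plot(curve["q"], curve["cv"], "o-")
    ax.axvline(results.n_maps, color="r", ls="--", lw=1)
    ax.set_xlabel("number of template maps q")
    ax.set_ylabel("cross-validation criterion")
    return ax


def plot_segmentation(results, condition=None, ax=None):
    """GFP trace of the group data colored by assigned microstate."""
    plt = _require_pyplot()
    from .microstates import gfp

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    seg = results.segmentation()
    if condition is None:
        condition = next(iter(seg))
    sl = results.model.condition_slices.get(condition, slice(None))
    data = results.model.data[:, sl]
    labels = seg[condition]
    g = gfp(data)
    t = np.arange(g.size) * 1000.0 / results.sfreq
    cmap = plt.get_cmap("tab10")
    for k in range(results.n_maps):
        ax.fill_between(t, 0, g, where=labels == k, color=cmap(k % 10), alpha=0.6)
    ax.plot(t, g, "k", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("GFP (uV)")
    ax.set_title(condition)
    return ax
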