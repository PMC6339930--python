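"""Figure export: the three-map layout (firing field, rate map, autocorrelogram)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import spatial_maps
from .trajectory import Trajectory


def three_map_figure(traj: Trajectory, response: np.ndarray, bin_size: float = 0.02,
                     smoothing_sigma: float = 1.0, threshold_quantile: float = 0.8,
                     title: str = ""):
    """Firing-field scatter, rate map and autocorrelogram side by side."""
    rm = spatial_maps.rate_map(traj, response, bin_size, smoothing_sigma)
    ac = spatial_maps.autocorrelogram(rm)
    points = spatial_maps.firing_field_map(traj, response, threshold_quantile)

    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.5))
    axes[0].plot(traj.x, traj.y, color="0.7", lw=0.3)
    if len(points):
        axes[0].plot(points[:, 0], points[:, 1], ".", color="red", ms=1.5)
    axes[0].set_title("firing field")
    axes[0].set_aspect("equal")

    xmin, ymin, xmax, ymax = rm.extent
    axes[1].imshow(rm.grid, origin="lower", extent=(xmin, xmax, ymin, ymax),
                   cmap="jet")
    axes[1].set_title("rate map")

    L = ac.max_lag_bins * ac.bin_size
    axes[2].imshow(ac.r, origin="lower", extent=(-L, L, -L, L), cmap="jet",
                   vmin=-1, vmax=1)
    try:
        axes[2].set_title(f"autocorrelogram (HGS {spatial_maps.hgs(ac):.2f})")
    except Exception:
        axes[2].set_title("autocorrelogram")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_three_map_figure(traj: Trajectory, response: np.ndarray, path,
                          **kwargs) -> None:
    fig = three_map_figure(traj, response, **kwargs)
    fig.savefig(path, dpi=150)
    plt.close(fig)
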