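"""Optional plot helpers (cosmetic reporting, not part of the metrics).

Gaze-density maps in facial-plane coordinates, in the style of per-
condition kernel-density heatmaps with the eye area outlined.
"""
from __future__ import annotations

import numpy as np


def gaze_density_plot(uv, landmark_uv, eye_radius_cm: float = 6.3, ax=None,
                      gridsize: int = 120, cmap: str = "magma"):
    """Kernel-density map of gaze points in the partner's facial plane.

    Parameters
    ----------
    uv : (n, 2) array
        In-plane gaze coordinates in cm (NaN rows are dropped).
    landmark_uv : mapping
        Landmark name -> (u, v); eye landmarks get the AOI circle drawn.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle
    from scipy.stats import gaussian_kde

    uv = np.asarray(uv, dtype=float)
    uv = uv[np.isfinite(uv).all(axis=1)]
    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 4))
    if len(uv) >= 10:
        kde = gaussian_kde(uv.T)
        lo = uv.min(axis=0) - 5
        hi = uv.max(axis=0) + 5
        gu, gv = np.meshgrid(np.linspace(lo[0], hi[0], gridsize),
                             np.linspace(lo[1], hi[1], gridsize))
        dens = kde(np.vstack([gu.ravel(), gv.ravel()])).reshape(gu.shape)
        ax.pcolormesh(gu, gv, dens, cmap=cmap, shading="auto")
    for name, (u, v) in landmark_uv.items():
        ax.plot(u, v, "ko", ms=3)
        if "eye" in name:
            ax.add_patch(Circle((u, v), eye_radius_cm, fill=False,
                                ls=":", ec="white", lw=1.2))
    ax.set_xlabel("u (cm)")
    ax.set_ylabel("v (cm)")
    ax.set_aspect("equal")
    return ax
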