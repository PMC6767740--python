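"""Radial intensity distribution: FracAtD, MeanFrac and RadialCV per ring.

The mask is partitioned into ``n_rings`` concentric rings of equal
normalized-distance width, where a pixel's normalized distance is
d_centroid / (d_centroid + d_edge) — 0 at the centroid, approaching 1 at
the mask boundary. Per ring:

* FracAtD  — fraction of total within-mask intensity falling in the ring;
* MeanFrac — FracAtD divided by the ring's fraction of the mask area
             (1 everywhere for a uniformly lit object);
* RadialCV — coefficient of variation of the ring's intensity across
             ``n_wedges`` angular wedges around the centroid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def radial_names(n_rings: int = 4) -> list[str]:
    stats = ("FracAtD", "MeanFrac", "RadialCV")
    return [f"{stat}_{r + 1}of{n_rings}" for stat in stats for r in range(n_rings)]


def radial_distribution(
    image: np.ndarray,
    mask: np.ndarray,
    n_rings: int = 4,
    n_wedges: int = 8,
) -> np.ndarray:
    """3 x ``n_rings`` values ordered as ``radial_names`` (FracAtD block first)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("radial_distribution requires a non-empty mask")
    total = image[mask].sum()
    if total <= 0:
        raise ValueError("radial_distribution requires positive total intensity")

    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    d_cent = np.hypot(yy - centroid[0], xx - centroid[1])
    d_edge = ndimage.distance_transform_edt(mask)
    denom = d_cent + d_edge
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_dist = np.where(denom > 0, d_cent / denom, 0.0)
    ring = np.minimum((norm_dist * n_rings).astype(int), n_rings - 1)

    theta = np.arctan2(yy - centroid[0], xx - centroid[1])  # [-pi, pi]
    wedge = np.minimum(
        ((theta + np.pi) / (2.0 * np.pi) * n_wedges).astype(int), n_wedges - 1
    )

    area_total = mask.sum()
    frac_at_d = np.zeros(n_rings)
    mean_frac = np.zeros(n_rings)
    radial_cv = np.zeros(n_rings)
    for r in range(n_rings):
        sel = mask & (ring == r)
        ring_area = sel.sum()
        ring_intensity = image[sel].sum()
        frac_at_d[r] = ring_intensity / total
        if ring_area > 0:
            mean_frac[r] = frac_at_d[r] / (ring_area / area_total)
            wedge_sums = np.bincount(wedge[sel], weights=image[sel], minlength=n_wedges)
            mean_w = wedge_sums.mean()
            radial_cv[r] = wedge_sums.std() / mean_w if mean_w > 0 else 0.0
    return np.concatenate([frac_at_d, mean_frac, radial_cv])
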