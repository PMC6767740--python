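"""Within-mask and mask-edge intensity statistics."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

INTENSITY_NAMES = [
    "IntegratedIntensity",
    "MeanIntensity",
    "StdIntensity",
    "MinIntensity",
    "MaxIntensity",
    "MedianIntensity",
    "MADIntensity",
    "LowerQuartileIntensity",
    "UpperQuartileIntensity",
    "IntegratedIntensityEdge",
    "MeanIntensityEdge",
    "StdIntensityEdge",
    "MinIntensityEdge",
    "MaxIntensityEdge",
    "MassDisplacement",
]


def mask_edge(mask: np.ndarray) -> np.ndarray:
    """The 1-pixel-thick inner boundary of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, border_value=0)
    edge = mask & ~interior
    return edge if edge.any() else mask  # tiny masks are all edge


def intensity_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The 15 intensity descriptors, ordered as ``INTENSITY_NAMES``.

    MAD is the median absolute deviation from the within-mask median; mass
    displacement is the Euclidean distance (px) between the mask centroid
    and the intensity-weighted centroid, zero when total intensity is zero.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("intensity_features requires a non-empty mask")
    vals = image[mask]
    median = float(np.median(vals))
    edge_vals = image[mask_edge(mask)]

    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    total = vals.sum()
    if total > 0:
        weighted = (coords * vals[:, None]).sum(axis=0) / total
        displacement = float(np.hypot(*(weighted - centroid)))
    else:
        displacement = 0.0

    return np.array(
        [
            float(vals.sum()),
            float(vals.mean()),
            float(vals.std()),
            float(vals.min()),
            float(vals.max()),
            median,
            float(np.median(np.abs(vals - median))),
            float(np.percentile(vals, 25)),
            float(np.percentile(vals, 75)),
            float(edge_vals.sum()),
            float(edge_vals.mean()),
            float(edge_vals.std()),
            float(edge_vals.min()),
            float(edge_vals.max()),
            displacement,
        ]
    )
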