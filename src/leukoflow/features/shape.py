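"""Mask-derived shape descriptors: 20 scalar measures plus 30 Zernike magnitudes."""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

SCALAR_SHAPE_NAMES = [
    "Area",
    "Perimeter",
    "FormFactor",
    "Eccentricity",
    "Solidity",
    "Extent",
    "Compactness",
    "MajorAxisLength",
    "MinorAxisLength",
    "AspectRatio",
    "Orientation",
    "EquivalentDiameter",
    "EulerNumber",
    "MaxRadius",
    "MeanRadius",
    "MedianRadius",
    "MinFeretDiameter",
    "MaxFeretDiameter",
    "ConvexArea",
    "BoundingBoxArea",
]

#: (n, m) index pairs for Zernike magnitudes: degrees 0-9, m >= 0, n - m even.
ZERNIKE_INDICES: list[tuple[int, int]] = [
    (n, m) for n in range(10) for m in range(n % 2, n + 1, 2)
]

SHAPE_NAMES = SCALAR_SHAPE_NAMES + [f"Zernike_{n}_{m}" for n, m in ZERNIKE_INDICES]


def _min_feret(mask: np.ndarray) -> float:
    """Minimum caliper width via rotating calipers on the pixel-center hull.

    One pixel is added to the center-to-center width to account for pixel
    extent. Degenerate (collinear / tiny) masks fall back to the smaller
    bounding-box side.
    """
    pts = np.argwhere(mask).astype(float)
    fallback = float(min(np.ptp(pts[:, 0]) + 1, np.ptp(pts[:, 1]) + 1))
    if len(pts) < 3:
        return fallback
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return fallback
    vertices = pts[hull.vertices]
    widths = []
    n_v = len(vertices)
    for i in range(n_v):
        p, q = vertices[i], vertices[(i + 1) % n_v]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(np.abs((vertices - p) @ normal).max())
    if not widths:
        return fallback
    return float(min(widths) + 1.0)


def zernike_magnitudes(mask: np.ndarray, indices=None) -> np.ndarray:
    """Zernike moment magnitudes of the binary mask on its enclosing unit disk.

    The mask is centered at its centroid and scaled so that the farthest
    mask pixel sits on the unit circle; moments are normalized by the pixel
    count, which makes magnitudes comparable across object sizes and
    invariant under rotation.
    """
    if indices is None:
        indices = ZERNIKE_INDICES
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("zernike_magnitudes requires a non-empty mask")
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    rmax = np.hypot(rel[:, 0], rel[:, 1]).max()
    if rmax == 0.0:
        rmax = 0.5  # single pixel: any positive scale gives rho = 0
    rho = np.hypot(rel[:, 0], rel[:, 1]) / rmax
    theta = np.arctan2(rel[:, 0], rel[:, 1])
    n_px = len(pts)

    out = np.empty(len(indices))
    rho_pow = {p: rho**p for p in range(10)}
    for idx, (n, m) in enumerate(indices):
        radial = np.zeros(n_px)
        for s in range((n - m) // 2 + 1):
            c = (
                (-1) ** s
                * math.factorial(n - s)
                / (
                    math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)
                )
            )
            radial += c * rho_pow[n - 2 * s]
        moment = (n + 1) / np.pi * np.sum(radial * np.exp(-1j * m * theta)) / n_px
        out[idx] = np.abs(moment)
    return out


def shape_features(mask: np.ndarray) -> np.ndarray:
    """The 50 shape descriptors of a binary mask, ordered as ``SHAPE_NAMES``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape_features requires a non-empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    form_factor = 1.0 if perimeter == 0 else 4.0 * np.pi * area / perimeter**2
    compactness = 0.0 if area == 0 else perimeter**2 / (4.0 * np.pi * area)
    major, minor = float(props.axis_major_length), float(props.axis_minor_length)
    aspect = 1.0 if major == 0 else minor / major
    edt = ndimage.distance_transform_edt(mask)
    radii = edt[mask]
    try:
        max_feret = float(props.feret_diameter_max)
    except (ValueError, QhullError):
        pts = np.argwhere(mask)
        max_feret = float(np.hypot(np.ptp(pts[:, 0]) + 1, np.ptp(pts[:, 1]) + 1))
    scalars = np.array(
        [
            area,
            perimeter,
            form_factor,
            float(props.eccentricity),
            float(props.solidity),
            float(props.extent),
            compactness,
            major,
            minor,
            aspect,
            float(props.orientation),
            float(props.equivalent_diameter_area),
            float(props.euler_number),
            float(radii.max()),
            float(radii.mean()),
            float(np.median(radii)),
            _min_feret(mask),
            max_feret,
            float(props.area_convex),
            float(props.area_bbox),
        ]
    )
    return np.concatenate([scalars, zernike_magnitudes(mask)])
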