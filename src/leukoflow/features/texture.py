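"""The 13 classical gray-level co-occurrence (Haralick) texture statistics.

Pixels inside the mask are quantized to ``levels`` gray values by
equal-width binning of the within-mask intensity range; the co-occurrence
matrix at a given (scale, angle) counts quantized pairs whose *both*
endpoints lie in the mask, is symmetrized and normalized. Entropies use
log base 2.

Degenerate conventions (single-cell matrices or masks with no valid pixel
pair at the offset): energy 1, contrast 0, entropies 0, correlation-type
measures 0.
"""

from __future__ import annotations

import numpy as np

HARALICK_NAMES = [
    "AngularSecondMoment",
    "Contrast",
    "Correlation",
    "Variance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InfoMeas1",
    "InfoMeas2",
]

ANGLES = (0, 45, 90, 135)

#: Row/column pixel offset per angle (image row axis points down).
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Feature values assigned when no pixel pair exists at the offset.
DEGENERATE = np.array([1.0, 0, 0, 0, 1.0, 0, 0, 0, 0, 0, 0, 0, 0])


def quantize(image: np.ndarray, mask: np.ndarray, levels: int = 8) -> np.ndarray:
    """Equal-width quantization of within-mask intensities to 0..levels-1."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    q = np.zeros(image.shape, dtype=np.intp)
    vals = image[mask]
    if vals.size == 0:
        return q
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q[mask] = np.minimum(
            ((image[mask] - lo) / (hi - lo) * levels).astype(np.intp), levels - 1
        )
    return q


def cooccurrence_matrix(
    quantized: np.ndarray,
    mask: np.ndarray,
    scale: int,
    angle: int,
    levels: int = 8,
) -> np.ndarray:
    """Symmetric, normalized GLCM over within-mask pixel pairs at (scale, angle)."""
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}, got {angle}")
    if scale < 1:
        raise ValueError("scale (offset distance) must be >= 1")
    dr, dc = (scale * d for d in _OFFSETS[angle])
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((levels, levels))
    a = quantized[r0:r1, c0:c1]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount(
        (a[valid] * levels + b[valid]).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    p = counts + counts.T  # symmetric
    total = p.sum()
    return p / total if total > 0 else p.astype(float)


def haralick_from_matrix(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalized co-occurrence matrix."""
    if p.sum() == 0:
        return DEGENERATE.copy()
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sigma_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sigma_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    asm = (p**2).sum()
    contrast = ((ii - jj) ** 2 * p).sum()
    if sigma_x > 0 and sigma_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()

    # distributions of i+j and |i-j|
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * levels - 1)
    p_diff = np.bincount(
        np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=levels
    )
    k_sum = np.arange(p_sum.size)
    k_diff = np.arange(p_diff.size)
    sum_average = (k_sum * p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    sum_entropy = -np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))
    entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
    diff_average = (k_diff * p_diff).sum()
    diff_variance = ((k_diff - diff_average) ** 2 * p_diff).sum()
    diff_entropy = -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))

    # information measures of correlation
    hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    pxpy = np.outer(px, py)
    valid = (p > 0) & (pxpy > 0)
    hxy1 = -np.sum(p[valid] * np.log2(pxpy[valid]))
    hxy2 = -np.sum(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0]))
    denom = max(hx, hy)
    infomeas1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    infomeas2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            diff_variance,
            diff_entropy,
            infomeas1,
            infomeas2,
        ]
    )


def haralick_features(
    image: np.ndarray,
    mask: np.ndarray,
    scale: int,
    angle: int,
    levels: int = 8,
) -> np.ndarray:
    """13 Haralick statistics at one (scale, angle), ordered as ``HARALICK_NAMES``."""
    q = quantize(image, mask, levels)
    return haralick_from_matrix(cooccurrence_matrix(q, mask, scale, angle, levels))


def haralick_battery(
    image: np.ndarray,
    mask: np.ndarray,
    scales=(3, 8),
    angles=ANGLES,
    levels: int = 8,
) -> np.ndarray:
    """All (scale, angle) combinations concatenated; quantization done once."""
    q = quantize(image, mask, levels)
    blocks = [
        haralick_from_matrix(cooccurrence_matrix(q, mask, s, a, levels))
        for s in scales
        for a in angles
    ]
    return np.concatenate(blocks)
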