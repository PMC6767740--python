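"""Synthetic imaging-flow-cytometry cohorts for the WBC pipeline.

Generates per-cell paired brightfield (BF) and darkfield (DF) tiles with the
statistical structure the downstream pipeline assumes: five leukocyte
phenotypes with class-specific size, granularity, intensity and texture;
donor-level batch effects (illumination gain, focus jitter, size scaling);
class proportions drawn from clinical reference ranges; and artifact events
(blur, debris, doublets) for gating tests.

The image-formation model is deliberately simple — a smooth disk with a
nucleus region and multiplicative texture for BF, Poisson-placed bright
granules on a flat background for DF — because the pipeline consumes
morphological *features*, not photorealism. Every parameter is exposed.

Reproducibility contract: one master seed; each donor receives a child
stream derived by stable hashing of the donor ID, so a donor's cells are
bit-identical regardless of cohort composition or generation order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CellPhenotypeSpec",
    "DonorSpec",
    "CellEvent",
    "BatchEffectConfig",
    "GenerationError",
    "sample_donor",
    "render_cell",
    "inject_artifact",
    "sample_cohort",
]

ARTIFACT_KINDS = ("blur", "debris", "doublet")


class GenerationError(ValueError):
    """Raised when a cell cannot be rendered under the requested geometry."""


@dataclass(frozen=True)
class CellPhenotypeSpec:
    """Image-formation parameters for one leukocyte class.

    Intensities are grayscale units in [0, 1]; lengths are pixels;
    ``granule_density`` is expected granules per 100 px² of cell area in the
    darkfield channel; ``nucleus_fraction`` is the fraction of the cell area
    occupied by the (darker) nucleus disk.
    """

    class_name: str
    radius_mean: float
    radius_sd: float
    granule_density: float
    granule_radius: float
    bf_base_intensity: float
    df_base_intensity: float
    texture_roughness: float
    edge_sharpness: float
    nucleus_fraction: float

    def __post_init__(self) -> None:
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        for name in ("bf_base_intensity", "df_base_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.granule_density < 0:
            raise ValueError("granule_density must be non-negative")
        if not 0.0 < self.nucleus_fraction < 1.0:
            raise ValueError("nucleus_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class BatchEffectConfig:
    """Distributions of donor-level nuisance variation.

    ``gain_log_sd`` — SD of the log of the per-channel illumination gain
    (log-normal, median 1). ``focus_sigma_max`` — per-donor residual defocus
    is drawn uniformly from [0, focus_sigma_max] pixels. ``size_log_sd`` —
    SD of the log of the donor size-scaling factor.
    """

    gain_log_sd: float = 0.10
    focus_sigma_max: float = 0.35
    size_log_sd: float = 0.04

    def __post_init__(self) -> None:
        if min(self.gain_log_sd, self.focus_sigma_max, self.size_log_sd) < 0:
            raise ValueError("batch-effect parameters must be non-negative")


#: Stronger donor-level variation, used to demonstrate the optimistic bias of
#: row-level (shuffle-and-split) cross-validation relative to subject-wise CV.
STRONG_BATCH_EFFECTS = BatchEffectConfig(
    gain_log_sd=0.5, focus_sigma_max=0.6, size_log_sd=0.18
)


@dataclass(frozen=True)
class DonorSpec:
    """One blood donor: class proportions plus batch-effect parameters."""

    donor_id: str
    illumination_gain: dict[str, float]  # per channel, multiplicative
    focus_sigma: float  # residual defocus blur SD, px
    size_scale: float  # multiplicative cell-size factor
    class_proportions: dict[str, float]  # five generator classes -> fraction

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(g <= 0 for g in self.illumination_gain.values()):
            raise ValueError("illumination gains must be positive")
        if self.size_scale <= 0:
            raise ValueError("size_scale must be positive")


@dataclass
class CellEvent:
    """One captured event: paired BF/DF tiles plus ground truth."""

    event_id: str
    donor_id: str
    bf_image: np.ndarray
    df_image: np.ndarray
    truth_stage1: str = "unknown"  # 4 classes, "artifact" or "unknown"
    truth_stage2: str = "n/a"  # "B", "T" or "n/a"
    artifact_kind: str = "none"

    def __post_init__(self) -> None:
        if self.bf_image.shape != self.df_image.shape:
            raise ValueError("BF and DF images must share a shape")


def _child_seed(master_seed: int, donor_id: str) -> int:
    """Stable per-donor seed: CRC32 of '<seed>|<donor_id>', kept below 2^31."""
    return zlib.crc32(f"{master_seed}|{donor_id}".encode()) & 0x7FFFFFFF


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_donor(
    seed_or_rng,
    reference_ranges: dict[str, tuple[float, float]] | None = None,
    *,
    donor_id: str = "D000",
    b_fraction: float | None = None,
    batch: BatchEffectConfig | None = None,
) -> DonorSpec:
    """Draw one donor's class proportions and batch-effect parameters.

    Class fractions are drawn uniformly within the clinical reference
    interval of each stage-1 class, renormalized to sum to one, and the
    lymphocyte mass is split between B and T by ``b_fraction``
    (default 0.25 B / 0.75 T).
    """
    from .presets import DEFAULT_B_FRACTION, REFERENCE_RANGES

    rng = _as_rng(seed_or_rng)
    ranges = REFERENCE_RANGES if reference_ranges is None else reference_ranges
    if b_fraction is None:
        b_fraction = DEFAULT_B_FRACTION
    if not 0.0 <= b_fraction <= 1.0:
        raise ValueError("b_fraction must lie in [0, 1]")
    if not ranges:
        raise ValueError("reference_ranges must be non-empty")
    for cls, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"inverted reference range for {cls!r}: ({lo}, {hi})")
        if lo < 0:
            raise ValueError(f"negative reference bound for {cls!r}")

    raw = {cls: rng.uniform(lo, hi) for cls, (lo, hi) in ranges.items()}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("degenerate reference ranges: all fractions zero")
    fractions = {cls: v / total for cls, v in raw.items()}

    proportions: dict[str, float] = {}
    for cls, frac in fractions.items():
        if cls == "lymphocyte":
            proportions["lymphocyte_B"] = frac * b_fraction
            proportions["lymphocyte_T"] = frac * (1.0 - b_fraction)
        else:
            proportions[cls] = frac

    batch = BatchEffectConfig() if batch is None else batch
    gain = {
        "BF": float(np.exp(rng.normal(0.0, batch.gain_log_sd))),
        "DF": float(np.exp(rng.normal(0.0, batch.gain_log_sd))),
    }
    focus_sigma = float(rng.uniform(0.0, batch.focus_sigma_max))
    # clipped so the largest phenotype still fits the default 64 px tile
    size_scale = float(
        np.clip(np.exp(rng.normal(0.0, batch.size_log_sd)), 2.0 / 3.0, 4.0 / 3.0)
    )
    return DonorSpec(
        donor_id=donor_id,
        illumination_gain=gain,
        focus_sigma=focus_sigma,
        size_scale=size_scale,
        class_proportions=proportions,
    )


# --- image formation ------------------------------------------------------

_BF_BACKGROUND = 0.02
_DF_NOISE_SCALE = 0.5  # DF texture noise amplitude relative to BF roughness
_NUCLEUS_CONTRAST = 0.45  # nucleus darkening relative to cytoplasm in BF

#: Per-cell biological variability around the phenotype spec (SDs). Without
#: it every cell of a class would be parameter-identical and even tiny
#: class differences would be perfectly learnable.
_CELL_JITTER = {
    "nucleus_fraction": 0.05,
    "edge_sharpness": 0.35,
    "bf_base_intensity": 0.02,
    "texture_roughness": 0.012,
}


def _distance_map(shape: tuple[int, int], center: np.ndarray) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1])


def _soft_disk(d: np.ndarray, radius: float, sharpness: float) -> np.ndarray:
    # logistic edge rolloff; sharpness ~2 gives a 1-2 px transition band
    return 1.0 / (1.0 + np.exp(np.clip(sharpness * (d - radius), -60, 60)))


def render_cell(
    phenotype: CellPhenotypeSpec,
    donor: DonorSpec,
    rng: np.random.Generator,
    *,
    tile_shape: tuple[int, int] = (64, 64),
    event_id: str = "E0",
) -> CellEvent:
    """Render one cell as paired BF/DF tiles under a donor's batch effects.

    BF: smooth disk of donor-scaled radius with a darker concentric nucleus,
    multiplicative texture noise and a logistic edge rolloff. DF: flat
    background at ``df_base_intensity`` plus bright granules Poisson-placed
    inside the cell at ``granule_density`` per 100 px². Donor illumination
    gain and residual defocus apply to both channels.
    """
    from .presets import stage1_label, stage2_label

    rng = _as_rng(rng)
    h, w = tile_shape
    if 4.0 * phenotype.radius_mean * donor.size_scale > min(h, w):
        raise GenerationError(
            f"cell of mean radius {phenotype.radius_mean * donor.size_scale:.1f} px "
            f"does not fit a {h}x{w} tile (need tile >= 4x radius)"
        )

    radius = max(2.0, rng.normal(phenotype.radius_mean, phenotype.radius_sd))
    radius *= donor.size_scale
    # per-cell biological variability around the class phenotype
    nucleus_fraction = float(
        np.clip(
            rng.normal(phenotype.nucleus_fraction, _CELL_JITTER["nucleus_fraction"]),
            0.05,
            0.95,
        )
    )
    edge_sharpness = max(
        1.0, rng.normal(phenotype.edge_sharpness, _CELL_JITTER["edge_sharpness"])
    )
    bf_base = float(
        np.clip(
            rng.normal(phenotype.bf_base_intensity, _CELL_JITTER["bf_base_intensity"]),
            0.0,
            1.0,
        )
    )
    roughness = max(
        0.0, rng.normal(phenotype.texture_roughness, _CELL_JITTER["texture_roughness"])
    ) if phenotype.texture_roughness > 0 else 0.0

    center = np.array([h / 2.0, w / 2.0]) + rng.uniform(-2.0, 2.0, size=2)
    d = _distance_map((h, w), center)
    cell = _soft_disk(d, radius, edge_sharpness)

    # brightfield: cytoplasm disk with darker nucleus, multiplicative texture
    nucleus_radius = radius * np.sqrt(nucleus_fraction)
    nucleus = _soft_disk(d, nucleus_radius, edge_sharpness * 1.3)
    bf = _BF_BACKGROUND + bf_base * cell * (1.0 - _NUCLEUS_CONTRAST * nucleus)
    if roughness > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 0.8)
        bf *= 1.0 + roughness * noise * cell

    # darkfield: flat background plus bright granules inside the cell
    df = np.full((h, w), phenotype.df_base_intensity, dtype=float)
    cell_area = np.pi * radius**2
    n_granules = int(rng.poisson(phenotype.granule_density * cell_area / 100.0))
    if n_granules > 0:
        u = rng.uniform(0.0, 1.0, n_granules)
        theta = rng.uniform(0.0, 2.0 * np.pi, n_granules)
        gy = center[0] + np.sqrt(u) * 0.85 * radius * np.sin(theta)
        gx = center[1] + np.sqrt(u) * 0.85 * radius * np.cos(theta)
        amp = rng.uniform(0.45, 0.85, n_granules)
        sigma = max(0.4, phenotype.granule_radius / 1.5)
        yy, xx = np.mgrid[0:h, 0:w]
        for k in range(n_granules):
            df += amp[k] * np.exp(
                -((yy - gy[k]) ** 2 + (xx - gx[k]) ** 2) / (2.0 * sigma**2)
            )
    if roughness > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), 0.8)
        df *= 1.0 + _DF_NOISE_SCALE * roughness * noise

    bf = bf * donor.illumination_gain["BF"]
    df = df * donor.illumination_gain["DF"]
    if donor.focus_sigma > 0:
        bf = ndimage.gaussian_filter(bf, donor.focus_sigma)
        df = ndimage.gaussian_filter(df, donor.focus_sigma)

    return CellEvent(
        event_id=event_id,
        donor_id=donor.donor_id,
        bf_image=np.clip(bf, 0.0, 1.0),
        df_image=np.clip(df, 0.0, 1.0),
        truth_stage1=stage1_label(phenotype.class_name),
        truth_stage2=stage2_label(phenotype.class_name) or "n/a",
    )


def _shift_image(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def inject_artifact(
    event: CellEvent,
    kind: str,
    rng,
    *,
    blur_sigma_min: float = 3.0,
) -> CellEvent:
    """Return a copy of ``event`` degraded into a gating artifact.

    ``blur`` applies a Gaussian defocus of sigma >= ``blur_sigma_min``;
    ``debris`` replaces the cell with a sub-threshold speck; ``doublet``
    overlays a translated copy of the cell at roughly twice its radius,
    producing an elongated mask. Ground truth becomes ``artifact``.
    """
    rng = _as_rng(rng)
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")

    bf, df = event.bf_image.copy(), event.df_image.copy()
    if kind == "blur":
        sigma = blur_sigma_min + rng.uniform(0.0, 2.0)
        bf = ndimage.gaussian_filter(bf, sigma)
        df = ndimage.gaussian_filter(df, sigma)
    elif kind == "debris":
        h, w = bf.shape
        center = np.array([h, w]) / 2.0 + rng.uniform(-6.0, 6.0, size=2)
        radius = rng.uniform(1.2, 2.2)
        d = _distance_map((h, w), center)
        speck = _soft_disk(d, radius, 4.0)
        bf = _BF_BACKGROUND + 0.5 * speck
        df = np.full_like(df, 0.02)
    else:  # doublet
        # translate a copy of the cell by ~2 radii (estimated from the BF
        # footprint) and merge; the union mask is elongated
        fg = bf > (bf.min() + 0.5 * (bf.max() - bf.min()))
        radius = max(3.0, np.sqrt(fg.sum() / np.pi))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        dy = int(round(2.0 * radius * np.sin(theta)))
        dx = int(round(2.0 * radius * np.cos(theta)))
        bf = np.maximum(bf, _shift_image(bf, dy, dx, bf.min()))
        df = np.maximum(df, _shift_image(df, dy, dx, df.min()))

    return replace(
        event,
        bf_image=np.clip(bf, 0.0, 1.0),
        df_image=np.clip(df, 0.0, 1.0),
        truth_stage1="artifact",
        truth_stage2="n/a",
        artifact_kind=kind,
    )


@dataclass
class Cohort:
    """A generated cohort: events, per-event manifest and donor specs."""

    events: list[CellEvent]
    manifest: pd.DataFrame
    donors: list[DonorSpec] = field(default_factory=list)


def sample_cohort(
    n_donors: int = 13,
    cells_per_donor: int = 500,
    artifact_fraction: float = 0.0,
    seed: int = 0,
    *,
    phenotypes: dict[str, CellPhenotypeSpec] | None = None,
    reference_ranges: dict[str, tuple[float, float]] | None = None,
    batch: BatchEffectConfig | None = None,
    b_fraction: float | None = None,
    tile_shape: tuple[int, int] = (64, 64),
    blur_sigma_min: float = 3.0,
) -> Cohort:
    """Generate a multi-donor cohort of rendered cell events.

    Per-donor class counts are multinomial on the donor's sampled
    proportions; ``artifact_fraction`` of events are passed through
    :func:`inject_artifact` with a uniformly chosen kind.
    """
    from .presets import default_phenotypes

    if n_donors < 2:
        raise ValueError("need at least 2 donors for any cross-validation use")
    if not 0.0 <= artifact_fraction <= 1.0:
        raise ValueError("artifact_fraction must lie in [0, 1]")
    phenotypes = default_phenotypes() if phenotypes is None else phenotypes
    if cells_per_donor < len(phenotypes):
        warnings.warn(
            f"cells_per_donor={cells_per_donor} is below the number of classes "
            f"({len(phenotypes)}); some classes may be absent per donor",
            stacklevel=2,
        )

    events: list[CellEvent] = []
    donors: list[DonorSpec] = []
    for i in range(n_donors):
        donor_id = f"D{i:03d}"
        child = _child_seed(seed, donor_id)
        donor_rng = np.random.default_rng(child)
        donor = sample_donor(
            donor_rng,
            reference_ranges,
            donor_id=donor_id,
            b_fraction=b_fraction,
            batch=batch,
        )
        donors.append(donor)

        classes = sorted(donor.class_proportions)
        probs = np.array([donor.class_proportions[c] for c in classes])
        counts = donor_rng.multinomial(cells_per_donor, probs)
        labels = np.repeat(classes, counts)
        donor_rng.shuffle(labels)
        is_artifact = donor_rng.random(cells_per_donor) < artifact_fraction
        kinds = donor_rng.choice(ARTIFACT_KINDS, size=cells_per_donor)
        for j, cls in enumerate(labels):
            event = render_cell(
                phenotypes[cls],
                donor,
                donor_rng,
                tile_shape=tile_shape,
                event_id=f"{donor_id}_E{j:05d}",
            )
            if is_artifact[j]:
                event = inject_artifact(
                    event, str(kinds[j]), donor_rng, blur_sigma_min=blur_sigma_min
                )
            events.append(event)

    manifest = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "donor_id": [e.donor_id for e in events],
            "truth_stage1": [e.truth_stage1 for e in events],
            "truth_stage2": [e.truth_stage2 for e in events],
            "artifact_kind": [e.artifact_kind for e in events],
        }
    )
    return Cohort(events=events, manifest=manifest, donors=donors)
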