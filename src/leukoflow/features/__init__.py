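"""The morphological feature battery: 213 named features per channel.

Per channel (BF, then DF) the default configuration measures

* 50 shape descriptors (20 scalars + 30 Zernike magnitudes) — mask-derived,
  hence identical across channels but emitted per channel so each channel
  block is self-contained;
* 15 intensity statistics (within-mask, mask-edge, mass displacement);
* 104 texture statistics (13 Haralick measures x 2 scales {3, 8} x
  4 angles {0, 45, 90, 135});
* 32 granularity elements (16-element spectra at structuring-element
  radii {1, 2});
* 12 radial-distribution values (FracAtD / MeanFrac / RadialCV x 4 rings),

totalling 213 features per channel and 426 per cell. Column names follow
``<Channel>_<Category>_<Name>[_<scale>_<angle>]`` and are resolvable from
the human-readable names used in feature-importance tables (e.g.
``"MAD intensity"`` / Darkfield -> ``DF_Intensity_MADIntensity``).

A single mask — segmented from the brightfield image — is used for both
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..synth import CellEvent
from .granularity import granularity_spectrum
from .intensity import INTENSITY_NAMES, intensity_features
from .radial import radial_distribution, radial_names
from .shape import SHAPE_NAMES, shape_features, zernike_magnitudes
from .texture import ANGLES, HARALICK_NAMES, haralick_battery, haralick_features

__all__ = [
    "FeatureConfig",
    "FeatureManifest",
    "FeatureVector",
    "build_manifest",
    "extract_features",
    "extract_table",
    "shape_features",
    "intensity_features",
    "haralick_features",
    "granularity_spectrum",
    "radial_distribution",
    "zernike_magnitudes",
]

CHANNELS = ("BF", "DF")
EXPECTED_PER_CHANNEL = 213


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the default battery; changing them changes the manifest."""

    texture_scales: tuple[int, ...] = (3, 8)
    texture_angles: tuple[int, ...] = ANGLES
    gray_levels: int = 8
    granularity_radii: tuple[int, ...] = (1, 2)
    granularity_length: int = 16
    n_rings: int = 4
    n_wedges: int = 8


@dataclass(frozen=True)
class ManifestEntry:
    name: str  # full column name, e.g. "BF_Texture_Contrast_3_0"
    category: str  # shape | intensity | texture | granularity | radial
    channel: str  # BF | DF
    parameters: dict = field(default_factory=dict, hash=False)


class FeatureManifest:
    """Ordered feature-column catalogue (BF block first, then DF)."""

    def __init__(self, entries: list[ManifestEntry], config: FeatureConfig):
        self.entries = entries
        self.config = config
        self.names = [e.name for e in entries]
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.entries)

    def per_channel(self, channel: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.channel == channel]

    def index_of(self, name: str) -> int:
        return self._index[name]

    def resolve(self, feature: str, channel: str) -> str:
        """Map a human-readable feature/channel pair to a manifest column.

        Accepts the naming style of importance tables: ``"MAD intensity"``,
        ``"Std intensity edge"``, ``"Granularity 1"``,
        ``"MeanFrac Radial Distribution 4of4"``,
        ``"DifferenceVariance Texture 3_0"`` with channel ``"Brightfield"``
        or ``"Darkfield"`` (or ``"BF"``/``"DF"``).
        """
        ch = {"brightfield": "BF", "darkfield": "DF", "bf": "BF", "df": "DF"}[
            channel.strip().lower()
        ]
        key = " ".join(feature.strip().lower().split())
        alias = _TABLE_ALIASES.get(key)
        if alias is None:
            raise KeyError(f"unrecognized feature name {feature!r}")
        column = f"{ch}_{alias}"
        if column not in self._index:
            raise KeyError(f"{column} not present in this manifest")
        return column

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "category": [e.category for e in self.entries],
                "channel": [e.channel for e in self.entries],
                "parameters": [e.parameters for e in self.entries],
            }
        )


#: Human-readable aliases (importance-table style) -> channel-less column tail.
_TABLE_ALIASES: dict[str, str] = {
    "mad intensity": "Intensity_MADIntensity",
    "std intensity": "Intensity_StdIntensity",
    "integrated intensity": "Intensity_IntegratedIntensity",
    "lower quartile intensity": "Intensity_LowerQuartileIntensity",
    "upper quartile intensity": "Intensity_UpperQuartileIntensity",
    "mean intensity": "Intensity_MeanIntensity",
    "median intensity": "Intensity_MedianIntensity",
    "min intensity": "Intensity_MinIntensity",
    "max intensity": "Intensity_MaxIntensity",
    "std intensity edge": "Intensity_StdIntensityEdge",
    "integrated intensity edge": "Intensity_IntegratedIntensityEdge",
    "mean intensity edge": "Intensity_MeanIntensityEdge",
    "mass displacement": "Intensity_MassDisplacement",
}
for _k in range(1, 17):
    _TABLE_ALIASES[f"granularity {_k}"] = f"Granularity_{_k}_r1"
for _r in range(1, 5):
    for _stat in ("FracAtD", "MeanFrac", "RadialCV"):
        _TABLE_ALIASES[f"{_stat.lower()} radial distribution {_r}of4"] = (
            f"Radial_{_stat}_{_r}of4"
        )
for _h in HARALICK_NAMES:
    for _s in (3, 8):
        for _a in ANGLES:
            _TABLE_ALIASES[f"{_h.lower()} texture {_s}_{_a}"] = f"Texture_{_h}_{_s}_{_a}"


def build_manifest(config: FeatureConfig | None = None) -> FeatureManifest:
    """Build the ordered manifest; asserts the 213-per-channel contract."""
    config = FeatureConfig() if config is None else config
    entries: list[ManifestEntry] = []
    for ch in CHANNELS:
        for name in SHAPE_NAMES:
            entries.append(ManifestEntry(f"{ch}_Shape_{name}", "shape", ch))
        for name in INTENSITY_NAMES:
            entries.append(ManifestEntry(f"{ch}_Intensity_{name}", "intensity", ch))
        for scale in config.texture_scales:
            for angle in config.texture_angles:
                for name in HARALICK_NAMES:
                    entries.append(
                        ManifestEntry(
                            f"{ch}_Texture_{name}_{scale}_{angle}",
                            "texture",
                            ch,
                            {"scale": scale, "angle": angle},
                        )
                    )
        for radius in config.granularity_radii:
            for k in range(1, config.granularity_length + 1):
                entries.append(
                    ManifestEntry(
                        f"{ch}_Granularity_{k}_r{radius}",
                        "granularity",
                        ch,
                        {"element": k, "radius": radius},
                    )
                )
        for name in radial_names(config.n_rings):
            entries.append(ManifestEntry(f"{ch}_Radial_{name}", "radial", ch))

    manifest = FeatureManifest(entries, config)
    per_channel = len(manifest) // len(CHANNELS)
    if (
        config == FeatureConfig()
        and per_channel != EXPECTED_PER_CHANNEL
    ):
        raise AssertionError(
            f"default manifest must have {EXPECTED_PER_CHANNEL} features per "
            f"channel, got {per_channel}"
        )
    return manifest


@dataclass
class FeatureVector:
    """One gated cell's feature row, ordered by the manifest."""

    event_id: str
    donor_id: str
    values: np.ndarray


def _channel_features(
    image: np.ndarray, mask: np.ndarray, shape_block: np.ndarray, config: FeatureConfig
) -> np.ndarray:
    blocks = [
        shape_block,
        intensity_features(image, mask),
        haralick_battery(
            image,
            mask,
            scales=config.texture_scales,
            angles=config.texture_angles,
            levels=config.gray_levels,
        ),
    ]
    for radius in config.granularity_radii:
        blocks.append(
            granularity_spectrum(image, mask, radius, config.granularity_length)
        )
    blocks.append(radial_distribution(image, mask, config.n_rings, config.n_wedges))
    return np.concatenate(blocks)


def extract_features(
    event: CellEvent, mask: np.ndarray, manifest: FeatureManifest
) -> FeatureVector:
    """Measure the full battery on one event (BF block, then DF block).

    The mask comes from brightfield segmentation and is shared by both
    channels; shape features are computed once and replicated per channel.
    Any non-finite value raises — it indicates a measurement bug, not a
    property of the cell.
    """
    shape_block = shape_features(mask)
    values = np.concatenate(
        [
            _channel_features(event.bf_image, mask, shape_block, manifest.config),
            _channel_features(event.df_image, mask, shape_block, manifest.config),
        ]
    )
    if len(values) != len(manifest):
        raise RuntimeError(
            f"extracted {len(values)} values but manifest has {len(manifest)}"
        )
    if not np.all(np.isfinite(values)):
        bad = [manifest.names[i] for i in np.flatnonzero(~np.isfinite(values))]
        raise FloatingPointError(f"non-finite feature values: {bad[:5]}")
    return FeatureVector(event.event_id, event.donor_id, values)


def extract_table(
    events: list[CellEvent],
    masks: dict[str, np.ndarray],
    manifest: FeatureManifest | None = None,
) -> pd.DataFrame:
    """Feature table for all events with a mask (i.e. gated-in singlets).

    Columns: ``event_id, donor_id, truth_stage1, truth_stage2`` followed by
    the 426 manifest columns.
    """
    manifest = build_manifest() if manifest is None else manifest
    rows = []
    meta = []
    for event in events:
        mask = masks.get(event.event_id)
        if mask is None:
            continue
        fv = extract_features(event, mask, manifest)
        rows.append(fv.values)
        meta.append(
            (event.event_id, event.donor_id, event.truth_stage1, event.truth_stage2)
        )
    if not rows:
        raise ValueError("no events with masks to extract")
    table = pd.DataFrame(np.vstack(rows), columns=manifest.names)
    head = pd.DataFrame(
        meta, columns=["event_id", "donor_id", "truth_stage1", "truth_stage2"]
    )
    return pd.concat([head, table], axis=1)
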