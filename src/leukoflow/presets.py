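"""Phenotype presets, clinical reference ranges and cohort presets.

The image-formation parameters below are package inventions: they are chosen
so that the five modelled leukocyte classes reproduce the *qualitative*
morphological contrasts the workflow exploits — granulocytes carry dense
darkfield granularity, monocytes are the largest cells, lymphocytes are
small with a high nucleus fraction, and the B/T contrast is deliberately
subtle (small shifts in nucleus fraction, edge sharpness and granule
density) so that the second classification stage is harder than the first.
All values are configuration, not physiology.
"""

from __future__ import annotations

from .synth import CellPhenotypeSpec

#: Clinical reference intervals for the WBC differential count, as fractions.
#: Lymphocytes 20-40%, eosinophils 1-6%, monocytes 2-10%, neutrophils 40-80%.
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "lymphocyte": (0.20, 0.40),
    "eosinophil": (0.01, 0.06),
    "monocyte": (0.02, 0.10),
    "neutrophil": (0.40, 0.80),
}

#: Same intervals on the percentage scale used for differential-count reports.
REFERENCE_RANGES_PCT: dict[str, tuple[float, float]] = {
    k: (lo * 100.0, hi * 100.0) for k, (lo, hi) in REFERENCE_RANGES.items()
}

#: Fraction of lymphocytes that are B cells (the remainder are T cells).
DEFAULT_B_FRACTION = 0.25

STAGE1_CLASSES = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")
CELL_CLASSES = (
    "eosinophil",
    "lymphocyte_B",
    "lymphocyte_T",
    "monocyte",
    "neutrophil",
)


def default_phenotypes() -> dict[str, CellPhenotypeSpec]:
    """The five default cell phenotypes ("well-separated" stage 1, subtle B/T)."""
    return {
        "neutrophil": CellPhenotypeSpec(
            class_name="neutrophil",
            radius_mean=9.0,
            radius_sd=0.7,
            granule_density=2.4,
            granule_radius=1.0,
            bf_base_intensity=0.55,
            df_base_intensity=0.055,
            texture_roughness=0.09,
            edge_sharpness=4.0,
            nucleus_fraction=0.35,
        ),
        "eosinophil": CellPhenotypeSpec(
            class_name="eosinophil",
            radius_mean=10.2,
            radius_sd=0.7,
            granule_density=4.5,
            granule_radius=1.8,
            bf_base_intensity=0.60,
            df_base_intensity=0.09,
            texture_roughness=0.12,
            edge_sharpness=4.0,
            nucleus_fraction=0.30,
        ),
        "monocyte": CellPhenotypeSpec(
            class_name="monocyte",
            radius_mean=12.0,
            radius_sd=0.9,
            granule_density=0.7,
            granule_radius=0.9,
            bf_base_intensity=0.40,
            df_base_intensity=0.035,
            texture_roughness=0.10,
            edge_sharpness=4.5,
            nucleus_fraction=0.48,
        ),
        "lymphocyte_T": CellPhenotypeSpec(
            class_name="lymphocyte_T",
            radius_mean=7.0,
            radius_sd=0.5,
            granule_density=0.22,
            granule_radius=0.8,
            bf_base_intensity=0.46,
            df_base_intensity=0.020,
            texture_roughness=0.050,
            edge_sharpness=4.5,
            nucleus_fraction=0.83,
        ),
        "lymphocyte_B": CellPhenotypeSpec(
            class_name="lymphocyte_B",
            radius_mean=7.15,
            radius_sd=0.5,
            granule_density=0.30,
            granule_radius=0.8,
            bf_base_intensity=0.465,
            df_base_intensity=0.022,
            texture_roughness=0.055,
            edge_sharpness=4.25,
            nucleus_fraction=0.78,
        ),
    }


def stage1_label(class_name: str) -> str:
    """Collapse the five generator classes onto the four stage-1 labels."""
    if class_name.startswith("lymphocyte"):
        return "lymphocyte"
    return class_name


def stage2_label(class_name: str) -> str | None:
    """B/T label for lymphocyte classes, ``None`` for everything else."""
    if class_name == "lymphocyte_B":
        return "B"
    if class_name == "lymphocyte_T":
        return "T"
    return None
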