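"""Shared fixtures: clean donors, rendered events and tabular cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leukoflow import presets, synth


@pytest.fixture(scope="session")
def phenotypes():
    return presets.default_phenotypes()


@pytest.fixture()
def clean_donor():
    """A donor with no batch effects (unit gain, no defocus, unit size)."""
    proportions = {cls: 1.0 / len(presets.CELL_CLASSES) for cls in presets.CELL_CLASSES}
    return synth.DonorSpec(
        donor_id="D_clean",
        illumination_gain={"BF": 1.0, "DF": 1.0},
        focus_sigma=0.0,
        size_scale=1.0,
        class_proportions=proportions,
    )


@pytest.fixture()
def neutrophil_event(phenotypes, clean_donor):
    rng = np.random.default_rng(42)
    return synth.render_cell(
        phenotypes["neutrophil"], clean_donor, rng, event_id="E_neutro"
    )


def disk_mask(shape=(64, 64), center=None, radius=10.0) -> np.ndarray:
    """Rasterized disk: pixel centers within ``radius`` of ``center``."""
    h, w = shape
    if center is None:
        center = (h / 2.0 - 0.5, w / 2.0 - 0.5)
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


@pytest.fixture()
def disk():
    return disk_mask()


def make_tabular_cohort(
    n_donors: int = 4,
    rows_per_donor: int = 40,
    separation: float = 3.0,
    donor_shift: float = 0.0,
    n_features: int = 6,
    classes=("eosinophil", "lymphocyte", "monocyte", "neutrophil"),
    class_weights=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian feature table shaped like the image-derived one.

    ``separation`` is the between-class mean distance in SD units;
    ``donor_shift`` adds a donor-specific offset to every feature,
    mimicking batch effects without rendering any image.
    """
    rng = np.random.default_rng(seed)
    if class_weights is None:
        class_weights = np.ones(len(classes)) / len(classes)
    centers = rng.normal(0.0, 1.0, size=(len(classes), n_features)) * separation
    rows = []
    for d in range(n_donors):
        offset = rng.normal(0.0, donor_shift, size=n_features)
        labels = rng.choice(len(classes), size=rows_per_donor, p=class_weights)
        for j, k in enumerate(labels):
            stage1 = classes[k]
            stage2 = (
                rng.choice(["B", "T"], p=[0.25, 0.75])
                if stage1 == "lymphocyte"
                else "n/a"
            )
            rows.append(
                {
                    "event_id": f"D{d:02d}_E{j:04d}",
                    "donor_id": f"D{d:02d}",
                    "truth_stage1": stage1,
                    "truth_stage2": stage2,
                    **{
                        f"f{i}": centers[k, i] + offset[i] + rng.normal()
                        for i in range(n_features)
                    },
                }
            )
    return pd.DataFrame(rows)
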