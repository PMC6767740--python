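"""Feature-battery oracles: hand-computed cases, enumeration and invariances."""

import numpy as np
import pytest

from leukoflow import features, synth
from leukoflow.features import granularity, intensity, radial, shape, texture
from tests.conftest import disk_mask


@pytest.fixture(scope="module")
def manifest():
    return features.build_manifest()


@pytest.fixture()
def blob():
    """An asymmetric test mask (no rotational symmetry)."""
    mask = disk_mask((32, 32), (15, 14), 8.0)
    mask[8:18, 20:26] = True
    mask[20:26, 6:10] = False
    return mask


class TestManifest:
    def test_213_features_per_channel_426_total(self, manifest):
        assert len(manifest) == 426
        assert len(manifest.per_channel("BF")) == 213
        assert len(manifest.per_channel("DF")) == 213
        assert len(set(manifest.names)) == 426

    def test_category_decomposition(self, manifest):
        by_cat = {}
        for e in manifest.per_channel("BF"):
            by_cat[e.category] = by_cat.get(e.category, 0) + 1
        assert by_cat == {
            "shape": 50,
            "intensity": 15,
            "texture": 104,
            "granularity": 32,
            "radial": 12,
        }

    @pytest.mark.parametrize(
        ("alias", "channel", "expected"),
        [
            ("MAD intensity", "Darkfield", "DF_Intensity_MADIntensity"),
            ("Std intensity", "Darkfield", "DF_Intensity_StdIntensity"),
            ("Integrated intensity", "Darkfield", "DF_Intensity_IntegratedIntensity"),
            (
                "Lower quartile intensity",
                "Brightfield",
                "BF_Intensity_LowerQuartileIntensity",
            ),
            ("Granularity 1", "Darkfield", "DF_Granularity_1_r1"),
            ("Mean Intensity", "Brightfield", "BF_Intensity_MeanIntensity"),
            (
                "Upper quartile intensity",
                "Darkfield",
                "DF_Intensity_UpperQuartileIntensity",
            ),
            ("Granularity 1", "Brightfield", "BF_Granularity_1_r1"),
            ("Std intensity edge", "Brightfield", "BF_Intensity_StdIntensityEdge"),
            (
                "Integrated intensity edge",
                "Darkfield",
                "DF_Intensity_IntegratedIntensityEdge",
            ),
            (
                "MeanFrac Radial Distribution 4of4",
                "Brightfield",
                "BF_Radial_MeanFrac_4of4",
            ),
            (
                "FracAtD Radial Distribution 4of4",
                "Brightfield",
                "BF_Radial_FracAtD_4of4",
            ),
            (
                "DifferenceVariance Texture 3_0",
                "Brightfield",
                "BF_Texture_DifferenceVariance_3_0",
            ),
            ("Granularity 3", "Brightfield", "BF_Granularity_3_r1"),
        ],
    )
    def test_importance_table_names_resolve(self, manifest, alias, channel, expected):
        assert manifest.resolve(alias, channel) == expected


class TestShape:
    def test_disk_form_factor_near_one_and_zernike_axisymmetric(self, disk):
        values = shape.shape_features(disk)
        named = dict(zip(shape.SHAPE_NAMES, values))
        assert abs(named["FormFactor"] - 1.0) < 0.1
        assert 0.95 <= named["AspectRatio"] <= 1.0
        # rotational symmetry: only m=0 Zernike terms survive
        # rasterization leaves small residuals, larger at high degree
        for (n, m), z in zip(shape.ZERNIKE_INDICES, values[20:]):
            if m != 0:
                assert z < 0.05, (n, m, z)

    def test_zernike_magnitudes_invariant_under_90_degree_rotation(self, blob):
        a = shape.zernike_magnitudes(blob)
        b = shape.zernike_magnitudes(np.rot90(blob))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_pixel_mask(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        named = dict(zip(shape.SHAPE_NAMES, shape.shape_features(mask)))
        assert named["Area"] == 1
        assert named["EulerNumber"] == 1

    def test_rectangle_scalars_match_geometry(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[10:20, 5:45]= True
        named = dict(zip(shape.SHAPE_NAMES, shape.shape_features(mask)))
        assert named["Area"] == 400
        assert named["BoundingBoxArea"] == 400
        assert named["ConvexArea"] == pytest.approx(400, rel=0.02)
        assert named["Extent"] == pytest.approx(1.0)
        assert named["Solidity"] == pytest.approx(1.0, rel=0.02)
        assert named["MinFeretDiameter"] == pytest.approx(10, abs=0.5)
        assert named["MaxFeretDiameter"] == pytest.approx(
            np.hypot(10, 40), rel=0.05
        )
        assert named["MaxRadius"] == pytest.approx(5.0, abs=0.5)

    def test_scalars_invariant_under_rotation_except_orientation(self, blob):
        a = dict(zip(shape.SHAPE_NAMES, shape.shape_features(blob)))
        b = dict(zip(shape.SHAPE_NAMES, shape.shape_features(np.rot90(blob))))
        for name in shape.SCALAR_SHAPE_NAMES:
            if name == "Orientation":
                continue
            assert a[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name


class TestIntensity:
    def test_hand_computed_four_pixel_case(self):
        img = np.zeros((2, 3))
        mask = np.zeros((2, 3), dtype=bool)
        img[0, 0], img[0, 1], img[1, 0], img[1, 1] = 1, 2, 3, 4
        mask[0, 0] = mask[0, 1] = mask[1, 0] = mask[1, 1] = True
        named = dict(zip(intensity.INTENSITY_NAMES, intensity.intensity_features(img, mask)))
        assert named["IntegratedIntensity"] == 10
        assert named["MedianIntensity"] == 2.5
        # MAD = median(|x - 2.5|) = median(1.5, 0.5, 0.5, 1.5) = 1.0
        assert named["MADIntensity"] == 1.0
        assert named["MinIntensity"] == 1 and named["MaxIntensity"] == 4

    def test_uniform_intensity_degenerates(self, disk):
        img = np.full(disk.shape, 0.37)
        named = dict(zip(intensity.INTENSITY_NAMES, intensity.intensity_features(img, disk)))
        assert named["MeanIntensity"] == pytest.approx(0.37)
        assert named["StdIntensity"] == pytest.approx(0.0, abs=1e-12)
        assert named["MADIntensity"] == 0.0
        assert named["MassDisplacement"] == pytest.approx(0.0, abs=1e-9)

    def test_ramp_shifts_mass_centroid_along_ramp_axis(self, disk):
        img = np.tile(np.linspace(0.1, 1.0, disk.shape[1]), (disk.shape[0], 1))
        named = dict(zip(intensity.INTENSITY_NAMES, intensity.intensity_features(img, disk)))
        assert named["MassDisplacement"] > 0.3
        # oracle: explicit centroid comparison
        coords = np.argwhere(disk).astype(float)
        weights = img[disk]
        weighted = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        oracle = float(np.hypot(*(weighted - coords.mean(axis=0))))
        assert named["MassDisplacement"] == pytest.approx(oracle, rel=1e-9)

    def test_edge_statistics_use_boundary_ring_only(self):
        mask = disk_mask((32, 32), radius=8.0)
        img = np.where(mask, 0.2, 0.0)
        ring = intensity.mask_edge(mask)
        img[ring] = 0.9
        named = dict(zip(intensity.INTENSITY_NAMES, intensity.intensity_features(img, mask)))
        assert named["MeanIntensityEdge"] == pytest.approx(0.9)
        assert named["MaxIntensity"] == pytest.approx(0.9)
        assert named["MinIntensityEdge"] == pytest.approx(0.9)


def haralick_oracle(image, mask, scale, angle, levels=8):
    """Independent enumeration: loop over all pixel pairs, then direct sums."""
    q = texture.quantize(image, mask, levels)
    offs = {0: (0, scale), 45: (-scale, scale), 90: (-scale, 0), 135: (-scale, -scale)}
    dr, dc = offs[angle]
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dr, x + dc
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                counts[q[y, x], q[y2, x2]] += 1
                counts[q[y2, x2], q[y, x]] += 1
    if counts.sum() == 0:
        return texture.DEGENERATE.copy()
    p = counts / counts.sum()
    i = np.arange(levels)
    px, py = p.sum(1), p.sum(0)
    mx, my = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mx) ** 2 * px).sum())
    sy = np.sqrt(((i - my) ** 2 * py).sum())
    asm = contrast = idm = corr_num = var = ent = 0.0
    p_sum = np.zeros(2 * levels - 1)
    p_diff = np.zeros(levels)
    for a in range(levels):
        for b in range(levels):
            v = p[a, b]
            asm += v * v
            contrast += (a - b) ** 2 * v
            idm += v / (1 + (a - b) ** 2)
            corr_num += a * b * v
            var += (a - mx) ** 2 * v
            if v > 0:
                ent -= v * np.log2(v)
            p_sum[a + b] += v
            p_diff[abs(a - b)] += v
    corr = (corr_num - mx * my) / (sx * sy) if sx > 0 and sy > 0 else 0.0
    ks = np.arange(len(p_sum))
    kd = np.arange(levels)
    sum_avg = (ks * p_sum).sum()
    sum_var = ((ks - sum_avg) ** 2 * p_sum).sum()
    sum_ent = -sum(v * np.log2(v) for v in p_sum if v > 0)
    diff_avg = (kd * p_diff).sum()
    diff_var = ((kd - diff_avg) ** 2 * p_diff).sum()
    diff_ent = -sum(v * np.log2(v) for v in p_diff if v > 0)
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hy = -sum(v * np.log2(v) for v in py if v > 0)
    hxy1 = hxy2 = 0.0
    for a in range(levels):
        for b in range(levels):
            pp = px[a] * py[b]
            if pp > 0:
                hxy2 -= pp * np.log2(pp)
                if p[a, b] > 0:
                    hxy1 -= p[a, b] * np.log2(pp)
    im1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    im2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - ent))))
    return np.array(
        [asm, contrast, corr, var, idm, sum_avg, sum_var, sum_ent, ent,
         diff_var, diff_ent, im1, im2]
    )


class TestHaralick:
    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("scale", [1, 3])
    def test_matches_bruteforce_enumeration_on_16x16(self, scale, angle):
        rng = np.random.default_rng(11)
        img = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.25
        got = texture.haralick_features(img, mask, scale, angle)
        want = haralick_oracle(img, mask, scale, angle)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_constant_image_degenerate_convention(self, disk):
        img = np.full(disk.shape, 0.5)
        named = dict(
            zip(texture.HARALICK_NAMES, texture.haralick_features(img, disk, 1, 0))
        )
        assert named["Contrast"] == 0.0
        assert named["AngularSecondMoment"] == 1.0
        assert named["Entropy"] == 0.0
        assert named["Correlation"] == 0.0

    def test_checkerboard_contrast_from_hand_count(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        mask = np.ones((4, 4), dtype=bool)
        named = dict(
            zip(texture.HARALICK_NAMES, texture.haralick_features(board, mask, 1, 0))
        )
        # every horizontal neighbor pair flips level 0 <-> 7: contrast = 49
        assert named["Contrast"] == pytest.approx(49.0)
        oracle = haralick_oracle(board, mask, 1, 0)
        np.testing.assert_allclose(
            [named[n] for n in texture.HARALICK_NAMES], oracle, atol=1e-12
        )

    def test_transpose_swaps_0_and_90_degrees(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12))
        mask = rng.random((12, 12)) > 0.2
        a = texture.haralick_features(img, mask, 2, 0)
        b = texture.haralick_features(img.T, mask.T, 2, 90)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_offset_outside_mask_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        got = texture.haralick_features(np.random.default_rng(0).random((10, 10)), mask, 3, 0)
        np.testing.assert_array_equal(got, texture.DEGENERATE)


class TestGranularity:
    def test_small_granules_removed_by_first_opening(self):
        img = np.zeros((48, 48))
        mask = np.ones((48, 48), dtype=bool)
        rng = np.random.default_rng(4)
        for _ in range(8):  # radius-1 granules (5-px plus shapes)
            y, x = rng.integers(6, 42, 2)
            img[y, x] = img[y - 1, x] = img[y + 1, x] = img[y, x - 1] = img[y, x + 1] = 0.8
        spectrum = granularity.granularity_spectrum(img, mask, element_radius=2)
        assert spectrum[0] == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(spectrum[1:], 0.0, atol=1e-9)

    def test_constant_image_all_zero(self, disk):
        spectrum = granularity.granularity_spectrum(np.full(disk.shape, 0.6), disk, 1)
        np.testing.assert_array_equal(spectrum, np.zeros(16))

    def test_nonnegative_with_cumsum_at_most_100(self, disk):
        rng = np.random.default_rng(5)
        for seed in range(3):
            img = np.random.default_rng(seed).random(disk.shape)
            spectrum = granularity.granularity_spectrum(img, disk, 1)
            assert (spectrum >= -1e-9).all()
            assert spectrum.sum() <= 100.0 + 1e-9

    def test_invariant_under_intensity_scaling(self, disk):
        img = np.random.default_rng(6).random(disk.shape)
        a = granularity.granularity_spectrum(img, disk, 1)
        b = granularity.granularity_spectrum(5.0 * img, disk, 1)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestRadial:
    def test_uniform_disk_fracs_match_area_and_meanfrac_one(self):
        # large disk so innermost-ring discretization stays small
        mask = disk_mask((64, 64), radius=28.0)
        img = np.where(mask, 0.5, 0.0)
        out = radial.radial_distribution(img, mask)
        frac, mean_frac, cv = out[:4], out[4:8], out[8:]
        # uniform intensity: FracAtD must equal the ring's area fraction
        np.testing.assert_allclose(mean_frac, 1.0, atol=1e-9)
        assert frac.sum() == pytest.approx(1.0)
        assert (cv < 0.15).all()

    def test_point_mass_at_centroid_in_first_ring(self, disk):
        img = np.zeros(disk.shape)
        coords = np.argwhere(disk)
        cy, cx = np.round(coords.mean(axis=0)).astype(int)
        img[cy, cx] = 1.0
        out = radial.radial_distribution(img, disk)
        np.testing.assert_allclose(out[:4], [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_frac_at_d_sums_to_one_for_any_image(self, blob):
        img = np.random.default_rng(7).random(blob.shape) + 0.01
        out = radial.radial_distribution(img, blob)
        assert out[:4].sum() == pytest.approx(1.0)

    def test_zero_intensity_rejected(self, disk):
        with pytest.raises(ValueError):
            radial.radial_distribution(np.zeros(disk.shape), disk)


class TestExtract:
    @pytest.fixture()
    def event_and_mask(self):
        from leukoflow import gating, presets

        donor = synth.DonorSpec(
            "D0", {"BF": 1.0, "DF": 1.0}, 0.0, 1.0,
            {c: 0.2 for c in presets.CELL_CLASSES},
        )
        event = synth.render_cell(
            presets.default_phenotypes()["eosinophil"],
            donor,
            np.random.default_rng(13),
        )
        return event, gating.segment_primary_object(event.bf_image)

    def test_identical_events_give_identical_vectors(self, event_and_mask, manifest):
        event, mask = event_and_mask
        a = features.extract_features(event, mask, manifest)
        b = features.extract_features(event, mask, manifest)
        np.testing.assert_array_equal(a.values, b.values)
        assert len(a.values) == 426

    def test_intensity_scale_equivariance(self, event_and_mask, manifest):
        from dataclasses import replace

        event, mask = event_and_mask
        c = 0.5
        scaled = replace(
            event, bf_image=c * event.bf_image, df_image=c * event.df_image
        )
        a = features.extract_features(event, mask, manifest).values
        b = features.extract_features(scaled, mask, manifest).values
        for i, entry in enumerate(manifest.entries):
            name = entry.name
            if entry.category in ("shape",):
                assert b[i] == pytest.approx(a[i], rel=1e-9), name
            elif entry.category in ("texture", "granularity"):
                assert b[i] == pytest.approx(a[i], rel=1e-6, abs=1e-6), name
            elif entry.category == "radial":
                assert b[i] == pytest.approx(a[i], rel=1e-6, abs=1e-9), name
            elif entry.category == "intensity" and "MassDisplacement" not in name:
                assert b[i] == pytest.approx(c * a[i], rel=1e-9, abs=1e-12), name

    def test_rotation_90_invariance_of_rotation_safe_features(
        self, event_and_mask, manifest
    ):
        event, mask = event_and_mask
        rot = synth.CellEvent(
            event_id=event.event_id,
            donor_id=event.donor_id,
            bf_image=np.rot90(event.bf_image).copy(),
            df_image=np.rot90(event.df_image).copy(),
        )
        a = features.extract_features(event, mask, manifest).values
        b = features.extract_features(rot, np.rot90(mask).copy(), manifest).values
        for i, entry in enumerate(manifest.entries):
            if entry.category in ("intensity", "granularity", "radial"):
                assert b[i] == pytest.approx(a[i], rel=1e-6, abs=1e-9), entry.name
            elif entry.category == "shape" and "Orientation" not in entry.name:
                assert b[i] == pytest.approx(a[i], rel=1e-5, abs=1e-8), entry.name

    def test_extract_table_schema(self, event_and_mask, manifest):
        event, mask = event_and_mask
        table = features.extract_table([event], {event.event_id: mask}, manifest)
        assert list(table.columns[:4]) == [
            "event_id",
            "donor_id",
            "truth_stage1",
            "truth_stage2",
        ]
        assert table.shape == (1, 430)
        assert np.isfinite(table[manifest.names].to_numpy()).all()
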