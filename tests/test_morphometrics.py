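import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spheromap import morphometrics as mm
from spheromap import simdata


def toy_stack(volume, labels, voxel=(1.0, 1.0, 1.0), tissue=None, channels=None):
    volume = np.asarray(volume, np.float32)
    labels = np.asarray(labels, np.int32)
    channels = channels or [f"ch{i}" for i in range(volume.shape[-1])]
    centroid = tuple((np.array(labels.shape) - 1) / 2 * np.array(voxel))
    return mm.SpheroidStack(
        volume=volume, channel_names=channels, labels=labels,
        voxel_size_um=voxel, centroid_um=centroid, tissue_mask=tissue,
    )


class TestFrameIntensity:
    def test_constant_channel_mean_every_frame(self):
        vol = np.full((3, 4, 4, 1), 7.0)
        labels = np.ones((3, 4, 4))
        table = mm.frame_intensity(toy_stack(vol, labels), ["ch0"])
        assert (table["mean_ch0"] == 7.0).all()
        assert len(table) == 3

    def test_proportional_channels_give_constant_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 5, size=(3, 4, 4))
        vol = np.stack([2 * a, a], axis=-1)
        labels = np.ones((3, 4, 4))
        table = mm.frame_intensity(
            toy_stack(vol, labels), ["ch0", "ch1"], ratio=("ch0", "ch1")
        )
        np.testing.assert_allclose(table["ratio_ch0_ch1"], 2.0, rtol=1e-5)

    def test_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(size=(3, 5, 5, 2)).astype(np.float32)
        labels = (rng.uniform(size=(3, 5, 5)) > 0.5).astype(np.int32)
        labels[1] = 0  # an empty frame must be omitted and listed
        stack = toy_stack(vol, labels)
        table = mm.frame_intensity(stack, ["ch0"])
        assert table.attrs["omitted_frames"] == [1]
        for _, row in table.iterrows():
            z = int(row["frame"])
            total, count = 0.0, 0
            for yy in range(5):
                for xx in range(5):
                    if labels[z, yy, xx]:
                        total += float(vol[z, yy, xx, 0])
                        count += 1
            assert row["mean_ch0"] == pytest.approx(total / count, rel=1e-6)

    def test_fully_empty_mask_rejected(self):
        stack = toy_stack(np.zeros((2, 3, 3, 1)), np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            mm.frame_intensity(stack, ["ch0"])


class TestLineProfile:
    def test_constant_image(self):
        img = np.full((10, 10), 7.0)
        prof = mm.line_profile(img, (1, 1), (8, 8), 25)
        np.testing.assert_allclose(prof, 7.0)

    def test_linear_ramp_profile(self):
        img = np.tile(np.arange(10.0), (10, 1))
        prof = mm.line_profile(img, (5, 0), (5, 9), 10)
        np.testing.assert_allclose(prof, np.linspace(0, 9, 10), atol=1e-9)

    def test_matches_bilinear_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(8, 8))
        start, end = np.array([1.3, 2.1]), np.array([6.2, 5.7])
        prof = mm.line_profile(img, start, end, 7)
        for i, t in enumerate(np.linspace(0, 1, 7)):
            r, c = start * (1 - t) + end * t
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            expected = (
                img[r0, c0] * (1 - fr) * (1 - fc)
                + img[r0 + 1, c0] * fr * (1 - fc)
                + img[r0, c0 + 1] * (1 - fr) * fc
                + img[r0 + 1, c0 + 1] * fr * fc
            )
            assert prof[i] == pytest.approx(expected, abs=1e-12)

    def test_zero_length_line_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            mm.line_profile(np.zeros((5, 5)), (2, 2), (2, 2))

    def test_endpoint_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mm.line_profile(np.zeros((5, 5)), (0, 0), (7, 7))


def ellipsoid_stack(major_dir, center_offset, semi=(4.0, 1.5, 1.5), voxel=(0.5, 0.5, 0.5)):
    """Single-nucleus stack with a known major axis, offset from the centroid."""
    shape = (61, 61, 61)
    vz, vy, vx = voxel
    centroid = (np.array(shape) - 1) / 2 * np.array(voxel)
    center = centroid + np.asarray(center_offset, float)
    e1 = np.asarray(major_dir, float)
    e1 /= np.linalg.norm(e1)
    tmp = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, tmp); e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz * vz, yy * vy, xx * vx], axis=-1) - center
    q = ((coords @ e1) / semi[0]) ** 2 + ((coords @ e2) / semi[1]) ** 2 + (
        (coords @ e3) / semi[2]
    ) ** 2
    labels = (q <= 1).astype(np.int32)
    vol = np.stack([labels * 50.0], axis=-1)
    return toy_stack(vol, labels, voxel)


class TestNuclearOrientation:
    def test_radial_nucleus_is_near_zero_degrees(self):
        stack = ellipsoid_stack(major_dir=(0, 0, 1), center_offset=(0, 0, 10))
        (m,) = mm.nuclear_orientation(stack)
        assert m.angle_deg < 5.0
        assert not m.degenerate

    def test_tangential_nucleus_is_near_ninety_degrees(self):
        stack = ellipsoid_stack(major_dir=(0, 1, 0), center_offset=(0, 0, 10))
        (m,) = mm.nuclear_orientation(stack)
        assert m.angle_deg > 85.0

    def test_spherical_nucleus_flagged_degenerate(self):
        stack = ellipsoid_stack(
            major_dir=(0, 0, 1), center_offset=(0, 0, 10), semi=(2.0, 2.0, 2.0)
        )
        (m,) = mm.nuclear_orientation(stack)
        assert m.degenerate

    def test_orientation_invariant_to_rigid_rotation(self):
        # rotate the whole stack 90 degrees about z (swap y/x axes)
        stack = ellipsoid_stack(major_dir=(0, 1, 0), center_offset=(0, 6, 8))
        (m1,) = mm.nuclear_orientation(stack)
        rot_labels = np.rot90(stack.labels, axes=(1, 2)).copy()
        rot_vol = np.rot90(stack.volume, axes=(1, 2)).copy()
        rot = toy_stack(rot_vol, rot_labels, stack.voxel_size_um)
        (m2,) = mm.nuclear_orientation(rot)
        assert m1.angle_deg == pytest.approx(m2.angle_deg, abs=2.0)

    def test_tiny_nuclei_skipped_and_all_skipped_is_error(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels[2, 2, 2] = 1  # single voxel: below the minimum
        stack = toy_stack(np.zeros((5, 5, 5, 1)), labels)
        with pytest.raises(ValueError, match="skipped"):
            with pytest.warns(UserWarning):
                mm.nuclear_orientation(stack)

    def test_no_labels_rejected(self):
        stack = toy_stack(np.zeros((5, 5, 5, 1)), np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="no nucleus labels"):
            mm.nuclear_orientation(stack)

    def test_physical_units_respected_under_anisotropy(self):
        # same physical ellipsoid rasterised with anisotropic voxels
        iso = ellipsoid_stack((0, 0, 1), (0, 0, 10), voxel=(0.5, 0.5, 0.5))
        aniso = ellipsoid_stack((0, 0, 1), (0, 0, 10), voxel=(1.0, 0.5, 0.5))
        (m1,) = mm.nuclear_orientation(iso)
        (m2,) = mm.nuclear_orientation(aniso)
        assert m1.angle_deg == pytest.approx(m2.angle_deg, abs=2.0)


class TestOrientationRatio:
    def _morph(self, angle, degenerate=False):
        return mm.NucleusMorphometry(
            1, np.zeros(3), np.zeros(3), angle, 100, degenerate, {}
        )

    def test_all_radial_gives_zero(self):
        assert mm.orientation_ratio([self._morph(a) for a in (5, 10, 20)]) == 0.0

    def test_all_tangential_gives_infinite_sentinel(self):
        assert mm.orientation_ratio([self._morph(a) for a in (80, 85)]) == math.inf

    def test_mixed_counts(self):
        morphs = [self._morph(a) for a in (80, 80, 80, 10, 10)]
        assert mm.orientation_ratio(morphs) == pytest.approx(1.5)

    def test_degenerate_excluded_and_empty_rejected(self):
        morphs = [self._morph(80, degenerate=True)]
        with pytest.raises(ValueError):
            mm.orientation_ratio(morphs)


class TestEpithelialThickness:
    def _shell(self, inner, outer, voxel):
        shape = tuple(int(np.ceil(2 * (outer + 4) / v)) | 1 for v in voxel)
        centroid = (np.array(shape) - 1) / 2 * np.array(voxel)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        radius = np.linalg.norm(
            np.stack([zz * voxel[0], yy * voxel[1], xx * voxel[2]], -1) - centroid,
            axis=-1,
        )
        tissue = (radius >= inner) & (radius <= outer)
        return toy_stack(
            np.zeros(shape + (1,)), np.zeros(shape), voxel, tissue=tissue
        )

    def test_shell_thickness_recovered(self):
        stack = self._shell(20.0, 30.0, (0.5, 0.5, 0.5))
        values = mm.epithelial_thickness(stack, n_sectors=32)
        assert np.mean(values) == pytest.approx(10.0, abs=0.25)

    def test_anisotropic_voxels_same_physical_answer(self):
        stack = self._shell(20.0, 30.0, (1.0, 0.5, 0.5))
        values = mm.epithelial_thickness(stack, n_sectors=32)
        assert np.mean(values) == pytest.approx(10.0, abs=0.5)

    def test_matches_ray_marching_oracle_on_wobbled_shell(self):
        voxel = (0.5, 0.5, 0.5)
        shape = (101, 101, 101)
        centroid = (np.array(shape) - 1) / 2 * np.array(voxel)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        phys = np.stack([zz * voxel[0], yy * voxel[1], xx * voxel[2]], -1) - centroid
        radius = np.linalg.norm(phys, axis=-1)
        with np.errstate(invalid="ignore"):
            wobble = 2.0 * (phys[..., 0] / np.maximum(radius, 1e-9))
        tissue = (radius >= 15.0 + wobble) & (radius <= 21.0 + wobble)
        stack = toy_stack(np.zeros(shape + (1,)), np.zeros(shape), voxel, tissue=tissue)
        values = mm.epithelial_thickness(stack, n_sectors=16)
        # oracle: fine independent ray march along the same direction lattice
        i = np.arange(16) + 0.5
        z = 1.0 - 2.0 * i / 16
        phi_d = np.pi * (1 + np.sqrt(5.0)) * i
        s = np.sqrt(1 - z * z)
        dirs = np.column_stack([z, s * np.cos(phi_d), s * np.sin(phi_d)])
        oracle = []
        for d in dirs:
            ts = np.arange(0.0, 40.0, 0.05)
            pts = centroid + ts[:, None] * d
            idx = np.round(pts / voxel).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            hit = np.zeros(len(ts), bool)
            hit[ok] = tissue[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            if hit.any():
                oracle.append(ts[hit][-1] - ts[hit][0])
        assert np.mean(values) == pytest.approx(np.mean(oracle), abs=0.5)

    def test_missing_mask_rejected(self):
        stack = toy_stack(np.zeros((3, 3, 3, 1)), np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="no tissue mask"):
            mm.epithelial_thickness(stack)


class TestIntensities:
    def test_spheroid_intensity_additive_over_slices(self):
        vol = np.zeros((2, 2, 2, 1))
        vol[0, ..., 0] = 2.5  # slice sums 10 and 20
        vol[1, ..., 0] = 5.0
        labels = np.ones((2, 2, 2))
        assert mm.spheroid_intensity(toy_stack(vol, labels), "ch0") == pytest.approx(30.0)

    def test_zero_channel_sums_to_zero(self):
        stack = toy_stack(np.zeros((2, 3, 3, 1)), np.ones((2, 3, 3)))
        assert mm.spheroid_intensity(stack, "ch0") == 0.0

    def test_matches_voxel_loop(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(size=(3, 4, 4, 1)).astype(np.float32)
        labels = (rng.uniform(size=(3, 4, 4)) > 0.4).astype(np.int32)
        stack = toy_stack(vol, labels)
        total = mm.spheroid_intensity(stack, "ch0")
        oracle = sum(
            float(vol[z, y, x, 0])
            for z in range(3) for y in range(4) for x in range(4)
            if labels[z, y, x]
        )
        assert total == pytest.approx(oracle, rel=1e-6)

    def test_empty_mask_rejected(self):
        stack = toy_stack(np.ones((2, 2, 2, 1)), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            mm.spheroid_intensity(stack, "ch0")

    def test_dapi_normalization(self):
        m = mm.NucleusMorphometry(
            1, np.zeros(3), np.zeros(3), 10.0, 100, False,
            {"DAPI": 50.0, "VTCN1": 100.0},
        )
        (out,) = mm.dapi_normalize([m], "VTCN1")
        assert out.dapi_normalized["VTCN1"] == pytest.approx(2.0)

    def test_channel_equal_to_dapi_normalises_to_one(self):
        m = mm.NucleusMorphometry(
            1, np.zeros(3), np.zeros(3), 10.0, 100, False,
            {"DAPI": 80.0, "SOX2": 80.0},
        )
        (out,) = mm.dapi_normalize([m], "SOX2")
        assert out.dapi_normalized["SOX2"] == 1.0

    def test_zero_dapi_skipped_with_warning(self):
        m = mm.NucleusMorphometry(
            1, np.zeros(3), np.zeros(3), 10.0, 100, False,
            {"DAPI": 0.0, "SOX2": 80.0},
        )
        with pytest.warns(UserWarning, match="zero DAPI"):
            out = mm.dapi_normalize([m], "SOX2")
        assert out == []


class TestCompareGroups:
    def test_mannwhitney_exact_small_groups(self):
        res = mm.compare_groups({"a": [1, 2], "b": [3, 4]}, "mann_whitney")
        assert res.p_value == pytest.approx(1 / 3)

    def test_welch_identical_groups(self):
        res = mm.compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "welch_t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        res = mm.compare_groups({"a": a, "b": b}, "welch_t")
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_shapiro_on_uniform_data_rejects(self):
        rng = np.random.default_rng(5)
        res = mm.compare_groups({"g": rng.uniform(size=200)}, "shapiro_wilk")
        assert res.p_value < 0.01

    def test_kruskal_dunn_structure_and_identical_groups(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=8)
        res = mm.compare_groups(
            {"a": base, "b": base + 5.0, "c": base - 5.0}, "kruskal_dunn"
        )
        assert res.posthoc is not None and len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] <= 1.0).all()
        assert res.p_value < 0.01
        sym = mm.compare_groups(
            {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]},
            "kruskal_dunn",
        )
        np.testing.assert_allclose(sym.posthoc["z"].abs(), 0.0, atol=1e-12)

    def test_dunn_z_matches_manual_formula(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [10.0, 11.0, 12.0]}
        res = mm.compare_groups(groups, "kruskal_dunn")
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        mr = {"a": ranks[:3].mean(), "b": ranks[3:6].mean(), "c": ranks[6:].mean()}
        se = math.sqrt(n * (n + 1) / 12.0 * (1 / 3 + 1 / 3))
        z_ab = (mr["a"] - mr["b"]) / se
        row = res.posthoc[(res.posthoc["group_a"] == "a") & (res.posthoc["group_b"] == "b")]
        assert row["z"].iloc[0] == pytest.approx(z_ab, abs=1e-12)

    def test_rank_tests_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        p1 = mm.compare_groups({"a": a, "b": b}, "mann_whitney").p_value
        p2 = mm.compare_groups(
            {"a": np.exp(a), "b": np.exp(b)}, "mann_whitney"
        ).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_undersized_groups_rejected_naming_method(self):
        with pytest.raises(ValueError, match="kruskal_dunn"):
            mm.compare_groups({"a": [1, 2], "b": [1, 2], "c": [1, 2]}, "kruskal_dunn")
        with pytest.raises(ValueError, match="welch_t"):
            mm.compare_groups({"a": [1], "b": [1, 2, 3]}, "welch_t")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            mm.compare_groups({"a": [1, 2, 3]}, "anova")


class TestEndToEndDiscrimination:
    def test_epi_vs_am_architecture_contrast(self, epi_stack, am_stack):
        epi = mm.nuclear_orientation(epi_stack)
        am = mm.nuclear_orientation(am_stack)
        assert np.median([m.angle_deg for m in epi]) < 15.0
        assert np.median([m.angle_deg for m in am]) > 75.0
        t_epi = np.mean(mm.epithelial_thickness(epi_stack))
        t_am = np.mean(mm.epithelial_thickness(am_stack))
        assert t_epi / t_am > 5.0

    def test_orientation_ratio_separates_kinds(self, epi_stack, am_stack):
        epi = mm.nuclear_orientation(epi_stack)
        am = mm.nuclear_orientation(am_stack)
        r_epi = mm.orientation_ratio(epi)
        r_am = mm.orientation_ratio(am)
        assert r_epi < 0.1
        assert r_am == math.inf or r_am > 10.0
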