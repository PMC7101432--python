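import numpy as np
import pandas as pd
import pytest

from petmodnet.imaging import PETVolume, TumorMask
from petmodnet.radiomics import (
    COOC_FEATURES,
    DIRECTIONS_13,
    DiscretizationConfig,
    FEATURE_NAMES,
    CoocMatrix,
    SizeZoneMatrix,
    build_cooc_merged,
    build_szm,
    cooc_features,
    discretize_fbn,
    extract_features,
    intensity_features,
    normalize_cohort_features,
    shape_features,
    szm_features,
)
from ._oracles import brute_force_cooc, brute_force_szm

ALL_26_OFFSETS = [d for d in DIRECTIONS_13] + [tuple(-x for x in d) for d in DIRECTIONS_13]


def grid_to_vol_mask(values, spacing=(1.0, 1.0, 1.0), mask=None):
    vol = PETVolume(np.asarray(values, dtype=float), spacing, calibrated=True)
    m = np.ones(vol.values.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    return vol, TumorMask(m, spacing)


class TestDiscretization:
    def test_fbn_formula(self):
        values = np.zeros((1, 1, 3))
        values[0, 0] = [0.0, 32.0, 64.0]
        vol, mask = grid_to_vol_mask(values)
        disc, degenerate = discretize_fbn(vol, mask, DiscretizationConfig(64))
        assert not degenerate
        assert disc[0, 0, 0] == 1
        assert disc[0, 0, 1] == 33  # floor(64*32/64) + 1
        assert disc[0, 0, 2] == 64  # the maximum maps into the top bin, not 65

    def test_constant_roi_flagged(self):
        vol, mask = grid_to_vol_mask(np.full((2, 2, 2), 3.0))
        disc, degenerate = discretize_fbn(vol, mask)
        assert degenerate and np.all(disc[mask.data] == 1)

    def test_all_64_bins_attainable(self):
        rng = np.random.default_rng(0)
        vol, mask = grid_to_vol_mask(rng.uniform(0, 20, (12, 12, 12)))
        disc, _ = discretize_fbn(vol, mask, DiscretizationConfig(64))
        assert disc[mask.data].min() == 1 and disc[mask.data].max() == 64
        assert len(np.unique(disc[mask.data])) == 64


class TestCoocMatrix:
    def test_single_pair(self):
        disc = np.array([[[1, 2]]], dtype=np.int32)
        _, mask = grid_to_vol_mask(disc)
        M = build_cooc_merged(disc, mask)
        assert M.p[0, 1] == 0.5 and M.p[1, 0] == 0.5
        assert M.p.sum() == pytest.approx(1.0)

    def test_constant_roi(self):
        disc = np.ones((2, 2, 2), dtype=np.int32)
        _, mask = grid_to_vol_mask(disc)
        M = build_cooc_merged(disc, mask)
        assert M.p[0, 0] == pytest.approx(1.0)

    def test_thirteen_directions_enumerated(self):
        assert len(set(DIRECTIONS_13)) == 13
        # no direction appears together with its opposite ...
        assert not set(DIRECTIONS_13) & {tuple(-x for x in d) for d in DIRECTIONS_13}
        # ... and together with the opposites they tile the 26-neighbourhood
        closure = set(DIRECTIONS_13) | {tuple(-x for x in d) for d in DIRECTIONS_13}
        neigh26 = {
            (i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        }
        assert closure == neigh26

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        disc = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)
        mask = rng.uniform(size=(4, 4, 4)) < 0.8
        mask.flat[0] = True  # keep nonempty
        _, tm = grid_to_vol_mask(disc, mask=mask)
        M = build_cooc_merged(disc, tm)
        oracle = brute_force_cooc(disc, mask, DIRECTIONS_13)
        assert M.p.shape == oracle.shape
        assert np.max(np.abs(M.p - oracle)) < 1e-12

    def test_symmetry_and_normalization(self):
        rng = np.random.default_rng(7)
        disc = rng.integers(1, 7, size=(5, 5, 5)).astype(np.int32)
        _, tm = grid_to_vol_mask(disc)
        M = build_cooc_merged(disc, tm)
        assert np.allclose(M.p, M.p.T)
        assert M.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestCoocFeatures:
    def test_two_bin_hand_case(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = cooc_features(CoocMatrix(p, 2))
        assert f["angular_second_moment"] == pytest.approx(0.5)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["inertia"] == pytest.approx(1.0)
        assert f["inverse_difference_moment"] == pytest.approx(0.5)
        assert f["homogeneity"] == pytest.approx(0.5)

    def test_degenerate_single_cell(self):
        p = np.zeros((2, 2))
        p[0, 0] = 1.0
        f = cooc_features(CoocMatrix(p, 2))
        assert f["angular_second_moment"] == 1.0
        assert f["inertia"] == 0.0
        assert f["entropy"] == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(size=(4, 4))
        p = (raw + raw.T) / (raw + raw.T).sum()
        f = cooc_features(CoocMatrix(p, 4))
        asm = idm = hom = dis = inertia = ent = 0.0
        mi = mj = 0.0
        for i in range(4):
            for j in range(4):
                mi += (i + 1) * p[i, j]
                mj += (j + 1) * p[i, j]
        si = sj = corr = 0.0
        for i in range(4):
            for j in range(4):
                v = p[i, j]
                d = (i + 1) - (j + 1)
                asm += v * v
                idm += v / (1 + d * d)
                hom += v / (1 + abs(d))
                dis += v * abs(d)
                inertia += v * d * d
                if v > 0:
                    ent -= v * np.log2(v)
                si += v * ((i + 1) - mi) ** 2
                sj += v * ((j + 1) - mj) ** 2
                corr += v * ((i + 1) - mi) * ((j + 1) - mj)
        corr /= np.sqrt(si * sj)
        for name, expected in [
            ("angular_second_moment", asm),
            ("inverse_difference_moment", idm),
            ("homogeneity", hom),
            ("dissimilarity", dis),
            ("inertia", inertia),
            ("entropy", ent),
            ("correlation", corr),
        ]:
            assert f[name] == pytest.approx(expected, abs=1e-12), name


class TestSizeZone:
    def test_constant_roi_single_zone(self):
        disc = np.ones((2, 2, 2), dtype=np.int32)
        _, tm = grid_to_vol_mask(disc)
        Z = build_szm(disc, tm)
        assert Z.n_zones == 1
        assert Z.n[0, 7] == 1  # one zone of size 8

    def test_checkerboard_single_slice_connects_diagonally(self):
        # 2D checkerboard of 2 bins inside a 1-thick slab: 26-connectivity
        # joins equal bins diagonally, so each bin forms one zone
        ij = np.add.outer(np.arange(4), np.arange(4)) % 2
        disc = (ij + 1).astype(np.int32)[None, :, :]
        _, tm = grid_to_vol_mask(disc)
        Z = build_szm(disc, tm)
        assert Z.n_zones == 2
        assert Z.n[0, 7] == 1 and Z.n[1, 7] == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        disc = rng.integers(1, 5, size=(4, 4, 4)).astype(np.int32)
        mask = rng.uniform(size=(4, 4, 4)) < 0.85
        mask.flat[0] = True
        _, tm = grid_to_vol_mask(disc, mask=mask)
        Z = build_szm(disc, tm)
        oracle = brute_force_szm(np.where(mask, disc, 0), mask)
        got = {
            (i + 1, s + 1): int(Z.n[i, s])
            for i in range(Z.n.shape[0])
            for s in range(Z.n.shape[1])
            if Z.n[i, s]
        }
        assert got == oracle
        # structural invariants of the matrix
        assert Z.n.sum() == Z.n_zones
        sizes = np.arange(1, Z.n.shape[1] + 1)
        assert (Z.n * sizes).sum() == Z.n_voxels

    def test_feature_hand_cases(self):
        n = np.zeros((1, 8))
        n[0, 7] = 1  # single zone of 8 voxels, bin 1
        f = szm_features(SizeZoneMatrix(n, 1, n_zones=1, n_voxels=8))
        assert f["zone_percentage"] == pytest.approx(1 / 8)
        assert f["large_area_emphasis"] == pytest.approx(64)
        assert f["high_intensity_large_area_emphasis"] == pytest.approx(64)
        assert f["intensity_variability"] == pytest.approx(1)
        assert f["size_zone_variability"] == pytest.approx(1)

        n = np.zeros((8, 1))
        n[:, 0] = 1  # 8 isolated voxels, all distinct bins
        f = szm_features(SizeZoneMatrix(n, 8, n_zones=8, n_voxels=8))
        assert f["zone_percentage"] == pytest.approx(1.0)
        assert f["large_area_emphasis"] == pytest.approx(1.0)

    def test_features_match_naive_summation(self):
        rng = np.random.default_rng(5)
        n = rng.integers(0, 4, size=(5, 6)).astype(float)
        n[0, 0] += 1
        Nz = n.sum()
        Z = SizeZoneMatrix(n, 5, n_zones=int(Nz), n_voxels=int(sum(
            n[i, s] * (s + 1) for i in range(5) for s in range(6)
        )))
        f = szm_features(Z)
        acc = {k: 0.0 for k in f}
        for i in range(5):
            for s in range(6):
                v = n[i, s]
                b, z = i + 1.0, s + 1.0
                acc["small_area_emphasis"] += v / z**2
                acc["large_area_emphasis"] += v * z**2
                acc["high_intensity_emphasis"] += v * b**2
                acc["low_intensity_emphasis"] += v / b**2
                acc["high_intensity_large_area_emphasis"] += v * b**2 * z**2
                acc["low_intensity_large_area_emphasis"] += v / (b**2 * z**2)
        for i in range(5):
            acc["intensity_variability"] += n[i, :].sum() ** 2
        for s in range(6):
            acc["size_zone_variability"] += n[:, s].sum() ** 2
        for k in acc:
            acc[k] /= Nz
        acc["zone_percentage"] = Nz / Z.n_voxels
        for k, v in acc.items():
            assert f[k] == pytest.approx(v, abs=1e-12), k


class TestShapeFeatures:
    def test_cube_closed_form(self):
        # formulas checked with the analytic surface of a cube substituted
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:11, 1:11, 1:11] = True
        tm = TumorMask(mask, (1.0, 1.0, 1.0))
        f = shape_features(tm, surface_area_mm2=6 * 10.0**2)
        expected = np.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        assert f["sphericity"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.80600, abs=1e-5)
        assert f["irregularity"] == pytest.approx(1 - expected, abs=1e-12)

    def test_digitized_sphere_near_unity(self):
        r = 10
        coords = np.stack(np.meshgrid(*[np.arange(24)] * 3, indexing="ij"), axis=-1)
        mask = np.linalg.norm(coords - 11.5, axis=-1) <= r
        tm = TumorMask(mask, (1.0, 1.0, 1.0))
        f = shape_features(tm)
        assert 0.95 <= f["sphericity"] <= 1.02
        assert 0.86 <= f["compactness_v2"] <= 1.02
        assert f["spherical_disproportion"] >= 1 / 1.02
        # distance-transform oracle: deepest voxel is about one radius deep
        assert f["max_distance_to_background"] == pytest.approx(r, abs=1.5)

    def test_compactness_identity(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[4:10, 3:11, 5:9] = True
        mask[6:8, 2:4, 6:8] = True
        tm = TumorMask(mask, (1.0, 1.3, 0.8))
        f = shape_features(tm)
        assert f["compactness_v2"] == pytest.approx(f["sphericity"] ** 3, abs=1e-9)
        assert f["spherical_disproportion"] == pytest.approx(1 / f["sphericity"], abs=1e-9)

    def test_edge_touching_mask_rejected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0:3, 2:4, 2:4] = True
        with pytest.raises(ValueError):
            shape_features(TumorMask(mask, (1, 1, 1)))


class TestIntensityFeatures:
    def test_constant_roi(self):
        values = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.ravel()[:10] = True
        values[mask] = 5.0
        vol = PETVolume(values, (2.0, 2.0, 2.0), calibrated=True)
        f = intensity_features(vol, TumorMask(mask, (2.0, 2.0, 2.0)))
        assert f["SUVmax"] == 5.0
        assert f["SUV_COV"] == 0.0
        assert f["MATV"] == pytest.approx(0.08)  # 10 voxels x 8 mm^3 = 0.08 ml
        assert f["TLG"] == pytest.approx(0.4)

    def test_two_value_cov(self):
        values = np.zeros((1, 1, 4))
        values[0, 0] = [2, 4, 2, 4]
        vol = PETVolume(values, (1, 1, 1), calibrated=True)
        f = intensity_features(vol, TumorMask(np.ones_like(values, bool), (1, 1, 1)))
        assert f["SUV_COV"] == pytest.approx(1 / 3)  # population SD 1, mean 3

    def test_matches_direct_formulas(self, rng):
        values = rng.uniform(1, 9, (5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) < 0.5
        mask.flat[0] = True
        vol = PETVolume(values, (3.0, 3.0, 3.0), calibrated=True)
        f = intensity_features(vol, TumorMask(mask, (3.0, 3.0, 3.0)))
        x = values[mask]
        assert f["SUVmean"] == pytest.approx(x.mean())
        assert f["SUV_COV"] == pytest.approx(x.std() / x.mean())
        assert f["TLG"] == pytest.approx(x.mean() * mask.sum() * 27 / 1000)


class TestBattery:
    def test_exactly_28_finite_features(self, uniform_phantom):
        vol, mask = uniform_phantom
        row = extract_features(vol, mask)
        assert list(row.index) == list(FEATURE_NAMES)
        assert len(row) == 28
        assert np.all(np.isfinite(row.to_numpy()))

    def test_repeated_extraction_bit_identical(self, uniform_phantom):
        vol, mask = uniform_phantom
        a = extract_features(vol, mask)
        b = extract_features(vol, mask)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_degenerate_constant_roi_has_no_nan(self):
        values = np.zeros((10, 10, 10))
        mask = np.zeros_like(values, dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        values[mask] = 4.0
        vol = PETVolume(values, (1, 1, 1), calibrated=True)
        row = extract_features(vol, TumorMask(mask, (1, 1, 1)))
        assert not row.isna().any()

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(1, 10, (16, 16, 16))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:12, 3:13, 5:11] = True
        vol = PETVolume(values, (1, 1, 1), calibrated=True)
        base = extract_features(vol, TumorMask(mask, (1, 1, 1)))
        for axes in [(0, 1), (0, 2), (1, 2)]:
            rv = PETVolume(np.rot90(values, axes=axes).copy(), (1, 1, 1), calibrated=True)
            rm = TumorMask(np.rot90(mask, axes=axes).copy(), (1, 1, 1))
            rot = extract_features(rv, rm)
            # texture/intensity are exactly invariant; the surface mesh is
            # invariant only to the triangulation tolerance (~1e-7 relative)
            assert np.allclose(base.to_numpy(), rot.to_numpy(), rtol=1e-5), axes

    def test_texture_invariant_to_affine_intensity_rescale(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(2, 9, (10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        vol_a = PETVolume(values, (1, 1, 1), calibrated=True)
        vol_b = PETVolume(3.5 * values + 11.0, (1, 1, 1), calibrated=True)
        tm = TumorMask(mask, (1, 1, 1))
        a = extract_features(vol_a, tm)
        b = extract_features(vol_b, tm)
        texture = list(COOC_FEATURES) + [
            n for n in FEATURE_NAMES if n.endswith("emphasis") or "variability" in n or n == "zone_percentage"
        ]
        for name in texture:
            assert a[name] == pytest.approx(b[name], rel=1e-12), name


class TestNormalization:
    def test_min_max_mapping(self):
        t = pd.DataFrame({"f": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        out = normalize_cohort_features(t)
        assert list(out["f"]) == [0.0, 0.5, 1.0]

    def test_extremes_map_to_zero_and_one(self, rng):
        t = pd.DataFrame(rng.uniform(0, 50, (10, 4)), columns=list("abcd"))
        out = normalize_cohort_features(t)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_threshold_percent_round_trip(self):
        from petmodnet.modnet import threshold_to_percent

        t = pd.DataFrame({"SUV_COV": np.linspace(0.1, 0.9, 9)})
        out = normalize_cohort_features(t)
        # a normalized cut at 0.792 displays as 79.2% of the cohort range
        assert threshold_to_percent(0.792) == "79.2%"
        raw = 0.1 + 0.792 * (0.9 - 0.1)
        renorm = (raw - 0.1) / (0.9 - 0.1)
        assert threshold_to_percent(renorm) == "79.2%"

    def test_constant_feature_dropped_with_warning(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0], "g": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            out = normalize_cohort_features(t)
        assert list(out.columns) == ["f"]
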