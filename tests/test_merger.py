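import itertools
import math

import numpy as np
import pytest

from incellproc.merger import (
    MergedReflection,
    cc_half,
    completeness,
    diffraction_power_slices,
    enumerate_unique_hkl,
    get_point_group,
    map_to_asu,
    map_to_asu_array,
    merge,
    point_group_from_operators,
    rsplit,
    scale_crystals,
    shell_stats,
    split_half_datasets,
)
from incellproc.reflection_filter import d_spacing
from incellproc.stream_io import (
    Chunk,
    CrystalRecord,
    Orientation,
    ReflectionRecord,
    StreamDataset,
    UnitCell,
)
from incellproc.synthetic_data import simulate_scan
from incellproc.wedge_finder import ScanGeometry


def crystal(cell, obs, scale=1.0, sigma=1.0):
    """obs: dict hkl -> intensity (already scaled by caller if needed)."""
    refls = [
        ReflectionRecord(h, k, l, v * scale, sigma, abs(v) * scale, 1.0, 5.0, 5.0)
        for (h, k, l), v in obs.items()
    ]
    return CrystalRecord(cell, Orientation(np.eye(3)), 2.0, refls)


def dataset_of(cell, crystal_obs, scales=None):
    scales = scales or [1.0] * len(crystal_obs)
    chunks = [
        Chunk(i, f"i{i}", f"//{i}", 10, [crystal(cell, obs, s)])
        for i, (obs, s) in enumerate(zip(crystal_obs, scales))
    ]
    return StreamDataset(chunks=chunks)


CELL = UnitCell(15.0, 15.0, 15.0, 90, 90, 90, lattice_type="cubic")


class TestPointGroups:
    def test_friedel_mapping(self):
        pg = get_point_group("-1")
        assert map_to_asu(-1, -2, -3, pg) == (1, 2, 3)

    def test_identity_group_leaves_input(self):
        pg = get_point_group("1")
        assert map_to_asu(3, -1, 2, pg) == (3, -1, 2)

    def test_expected_orders(self):
        for name, order in [("1", 1), ("-1", 2), ("2/m", 4), ("mmm", 8),
                            ("4/mmm", 16), ("6/m", 12), ("6/mmm", 24), ("m-3", 24)]:
            assert len(get_point_group(name).operators) == order

    def test_unknown_group_errors(self):
        with pytest.raises(ValueError):
            get_point_group("17")

    def test_unclosed_operator_set_rejected(self):
        rot4 = [[0, -1, 0], [1, 0, 0], [0, 0, 1]]
        with pytest.raises(ValueError, match="closed"):
            point_group_from_operators("bad", [np.eye(3, dtype=int), rot4])

    def test_orbit_representative_consistent_6m(self):
        pg = get_point_group("6/m")
        rng = np.random.default_rng(0)
        for _ in range(50):
            hkl = tuple(int(x) for x in rng.integers(-6, 7, 3))
            if hkl == (0, 0, 0):
                continue
            rep = map_to_asu(*hkl, pg)
            # brute-force orbit: representative must be reachable and maximal
            orbit = {tuple(int(v) for v in np.array(hkl) @ m) for m in pg.matrices}
            assert rep == max(orbit)

    def test_whole_orbit_maps_to_same_representative(self):
        pg = get_point_group("mmm")
        for hkl in itertools.product(range(-4, 5), repeat=3):
            if hkl == (0, 0, 0):
                continue
            rep = map_to_asu(*hkl, pg)
            for m in pg.matrices:
                img = tuple(int(v) for v in np.array(hkl) @ m)
                assert map_to_asu(*img, pg) == rep

    def test_vectorized_matches_scalar(self):
        pg = get_point_group("4/mmm", friedel=True)
        rng = np.random.default_rng(1)
        arr = rng.integers(-5, 6, size=(200, 3))
        arr = arr[(arr != 0).any(axis=1)]
        vec = map_to_asu_array(arr, pg)
        for row, out in zip(arr, vec):
            assert tuple(int(x) for x in out) == map_to_asu(*(int(v) for v in row), pg)


class TestScaling:
    def test_single_crystal_scale_is_one(self):
        ds = dataset_of(CELL, [{(1, 0, 0): 10.0, (2, 0, 0): 5.0}])
        res = scale_crystals(ds, get_point_group("1"))
        assert list(res.scales.values()) == [1.0]

    def test_two_crystal_factor_of_two_recovered(self):
        obs = {(1, 0, 0): 10.0, (2, 0, 0): 6.0, (2, 1, 0): 3.0}
        ds = dataset_of(CELL, [obs, obs], scales=[1.0, 2.0])
        res = scale_crystals(ds, get_point_group("1"), n_rounds=50, tol=1e-14)
        s = list(res.scales.values())
        assert s[1] / s[0] == pytest.approx(2.0, abs=1e-9)

    def test_scales_invariant_under_crystal_relabeling(self):
        obs1 = {(1, 0, 0): 10.0, (2, 0, 0): 6.0}
        obs2 = {(1, 0, 0): 14.0, (2, 0, 0): 9.0}
        ds_a = dataset_of(CELL, [obs1, obs2])
        ds_b = dataset_of(CELL, [obs2, obs1])
        sa = scale_crystals(ds_a, get_point_group("1"), 50, 1e-14).scales
        sb = scale_crystals(ds_b, get_point_group("1"), 50, 1e-14).scales
        assert sorted(sa.values()) == pytest.approx(sorted(sb.values()))

    def test_disconnected_crystal_flagged_scale_one(self):
        ds = dataset_of(CELL, [{(1, 0, 0): 10.0}, {(1, 0, 0): 12.0}, {(5, 0, 0): 7.0}])
        res = scale_crystals(ds, get_point_group("1"))
        assert res.flagged == [(2, 0)]
        assert res.scales[(2, 0)] == 1.0

    def test_noisy_recovery_within_one_percent(self):
        rng = np.random.default_rng(42)
        geom = ScanGeometry(40, 4, 0.1)
        errors = []
        for seed in range(5):
            ds, truth = simulate_scan(
                geom, n_crystals=6, cell=CELL, noise_fraction=0.01, seed=seed,
                d_min=3.0, reflections_per_frame=40,
            )
            res = scale_crystals(ds, get_point_group("1"), n_rounds=50, tol=1e-12)
            by_frame = {}
            for x in truth.crystals:
                for f in range(x.start_frame, x.end_frame + 1):
                    by_frame[f] = x.scale
            true = np.array([by_frame[f] for f, _ in res.scales])
            est = np.array(list(res.scales.values()))
            ratio = est / true
            ratio /= ratio.mean()
            errors.extend(np.abs(ratio - 1.0))
        assert np.median(errors) < 0.01


class TestMerge:
    def test_single_observation(self):
        ds = dataset_of(CELL, [{(1, 0, 0): 10.0}])
        merged = merge(ds, get_point_group("1"))
        m = merged[0]
        assert (m.intensity_merged, m.sigma_merged, m.n_obs) == (10.0, 1.0, 1)

    def test_two_observations_hand_arithmetic(self):
        ds = dataset_of(CELL, [{(1, 0, 0): 10.0}, {(1, 0, 0): 12.0}])
        m = merge(ds, get_point_group("1"))[0]
        assert m.intensity_merged == pytest.approx(11.0)
        assert m.sigma_merged == pytest.approx(1.0)  # sd sqrt(2) / sqrt(2)
        assert m.n_obs == 2

    def test_invariant_under_chunk_permutation(self):
        obs = [{(1, 0, 0): 10.0, (2, 0, 0): 4.0}, {(1, 0, 0): 13.0}, {(2, 0, 0): 6.0}]
        ds = dataset_of(CELL, obs)
        ds_rev = dataset_of(CELL, obs[::-1])
        assert merge(ds, get_point_group("1")) == merge(ds_rev, get_point_group("1"))

    def test_symmetry_mates_merge_under_friedel(self):
        ds = dataset_of(CELL, [{(1, 2, 3): 10.0, (-1, -2, -3): 14.0}])
        merged = merge(ds, get_point_group("-1"))
        assert len(merged) == 1
        assert merged[0].intensity_merged == pytest.approx(12.0)

    def test_empty_dataset(self):
        assert merge(StreamDataset(chunks=[]), get_point_group("1")) == []


class TestFiguresOfMerit:
    def mr(self, hkl, i):
        return MergedReflection(hkl, i, 0.1, 2)

    def test_rsplit_identical_halves_is_zero(self):
        half = [self.mr((1, 0, 0), 10.0), self.mr((2, 0, 0), 4.0)]
        assert rsplit(half, half) == 0.0

    def test_rsplit_single_pair_hand_value(self):
        assert rsplit([self.mr((1, 0, 0), 12.0)], [self.mr((1, 0, 0), 8.0)]) == pytest.approx(
            0.28284, abs=1e-5
        )

    def test_rsplit_scale_invariant(self):
        h1 = [self.mr((1, 0, 0), 12.0), self.mr((2, 0, 0), 5.0)]
        h2 = [self.mr((1, 0, 0), 8.0), self.mr((2, 0, 0), 6.0)]
        base = rsplit(h1, h2)
        g = 3.7
        h1s = [self.mr(m.hkl_asu, g * m.intensity_merged) for m in h1]
        h2s = [self.mr(m.hkl_asu, g * m.intensity_merged) for m in h2]
        assert rsplit(h1s, h2s) == pytest.approx(base, rel=1e-12)

    def test_cc_half_identical(self):
        half = [self.mr((1, 0, 0), 10.0), self.mr((2, 0, 0), 4.0), self.mr((3, 0, 0), 7.0)]
        assert cc_half(half, half) == pytest.approx(1.0)

    def test_cc_half_anti_ordered(self):
        h1 = [self.mr((1, 0, 0), 1.0), self.mr((2, 0, 0), 2.0), self.mr((3, 0, 0), 3.0)]
        h2 = [self.mr((1, 0, 0), 3.0), self.mr((2, 0, 0), 2.0), self.mr((3, 0, 0), 1.0)]
        assert cc_half(h1, h2) == pytest.approx(-1.0)

    def test_cc_half_zero_variance_undefined(self):
        h1 = [self.mr((i, 0, 0), 5.0) for i in range(1, 5)]
        assert math.isnan(cc_half(h1, h1))

    def test_rsplit_zero_denominator_undefined(self):
        h1 = [self.mr((1, 0, 0), 5.0)]
        h2 = [self.mr((1, 0, 0), -5.0)]
        assert math.isnan(rsplit(h1, h2))

    def test_noise_free_simulation_perfect_foms(self, small_scan):
        _, ds, truth = small_scan
        pg = get_point_group("1")
        res = scale_crystals(ds, pg, n_rounds=100, tol=1e-13)
        h1, h2 = split_half_datasets(ds)
        m1 = merge(h1, pg, res.scales)
        m2 = merge(h2, pg, res.scales)
        assert rsplit(m1, m2) <= 1e-6
        assert cc_half(m1, m2) == pytest.approx(1.0, abs=1e-12)

    def test_foms_improve_as_noise_decreases(self):
        geom = ScanGeometry(40, 4, 0.1)
        rsplits = []
        for noise in (0.10, 0.05, 0.01):
            ds, _ = simulate_scan(
                geom, n_crystals=6, cell=CELL, noise_fraction=noise, seed=9,
                d_min=3.0, reflections_per_frame=40,
            )
            pg = get_point_group("1")
            res = scale_crystals(ds, pg, n_rounds=50, tol=1e-12)
            h1, h2 = split_half_datasets(ds)
            rsplits.append(rsplit(merge(h1, pg, res.scales), merge(h2, pg, res.scales)))
        assert rsplits[0] > rsplits[1] > rsplits[2]


class TestCompleteness:
    def full_sphere_dataset(self, d_min):
        pg = get_point_group("1")
        obs = {hkl: 100.0 for hkl in enumerate_unique_hkl(pg, CELL, d_min)}
        return dataset_of(CELL, [obs])

    def test_full_sphere_is_complete(self):
        ds = self.full_sphere_dataset(4.0)
        merged = merge(ds, get_point_group("1"))
        pct, red = completeness(merged, get_point_group("1"), CELL, 4.0)
        assert pct == 100.0
        assert red == 1.0

    def test_half_deleted_matches_enumeration(self):
        pg = get_point_group("1")
        ds = self.full_sphere_dataset(4.0)
        merged = merge(ds, pg)
        kept = merged[::2]
        possible = enumerate_unique_hkl(pg, CELL, 4.0)
        pct, _ = completeness(kept, pg, CELL, 4.0)
        assert pct == pytest.approx(100.0 * len(kept) / len(possible))

    def test_empty_merged_zero(self):
        pct, red = completeness([], get_point_group("1"), CELL, 3.0)
        assert pct == 0.0


class TestShellStats:
    def test_one_shell_equals_overall(self, small_scan):
        _, ds, _ = small_scan
        pg = get_point_group("1")
        table = shell_stats(ds, pg, CELL, 1, 3.0)
        shell, overall = table.iloc[0], table.iloc[-1]
        for col in ("n_unique", "completeness", "redundancy", "rsplit", "cc_half"):
            assert shell[col] == pytest.approx(overall[col], nan_ok=True)

    def test_shell_n_unique_sums_to_overall(self, small_scan):
        _, ds, _ = small_scan
        pg = get_point_group("1")
        table = shell_stats(ds, pg, CELL, 5, 3.0)
        assert table.iloc[:-1]["n_unique"].sum() >= table.iloc[-1]["n_unique"]
        in_range = table.iloc[:-1]["n_unique"].sum()
        merged = merge(ds, pg)
        n_in = sum(1 for m in merged if d_spacing(*m.hkl_asu, CELL) >= 3.0)
        assert in_range == n_in

    def test_shell_membership_matches_brute_force(self, small_scan):
        _, ds, _ = small_scan
        pg = get_point_group("1")
        n_shells, d_min = 4, 3.0
        table = shell_stats(ds, pg, CELL, n_shells, d_min)
        merged = merge(ds, pg)
        edges = np.linspace(0.0, 1.0 / d_min**3, n_shells + 1)
        for i in range(n_shells):
            lo, hi = edges[i], edges[i + 1]
            n = sum(
                1
                for m in merged
                if lo <= 1.0 / d_spacing(*m.hkl_asu, CELL) ** 3 < hi
                or (i == n_shells - 1 and 1.0 / d_spacing(*m.hkl_asu, CELL) ** 3 == hi)
            )
            assert table.iloc[i]["n_unique"] == n


class TestPowerSlices:
    def _ds(self, limits):
        chunks = []
        for i, lim in enumerate(limits):
            xtal = CrystalRecord(CELL, Orientation(np.eye(3)), lim, [])
            chunks.append(Chunk(i, f"i{i}", f"//{i}", 5, [xtal]))
        return StreamDataset(chunks=chunks)

    def test_two_parts_hand_values(self):
        table = diffraction_power_slices(self._ds([2.0, 3.0, 4.0, 5.0]), 2)
        assert table.iloc[0]["mean_resolution"] == 2.5
        assert table.iloc[0]["best_resolution"] == 2.0
        assert table.iloc[1]["mean_resolution"] == 4.5
        assert table.iloc[1]["best_resolution"] == 4.0

    def test_single_part_is_global(self):
        table = diffraction_power_slices(self._ds([2.0, 3.0, 4.0]), 1)
        assert table.iloc[0]["mean_resolution"] == 3.0
        assert table.iloc[0]["best_resolution"] == 2.0

    def test_four_parts_match_recomputation(self, small_scan):
        _, ds, _ = small_scan
        table = diffraction_power_slices(ds, 4)
        from incellproc.stream_io import iter_crystals, split_into_parts

        for row, part in zip(table.itertuples(), split_into_parts(ds, 4)):
            limits = [x.resolution_limit for _, _, x in iter_crystals(part)]
            assert row.n_crystals == len(limits)
            if limits:
                assert row.mean_resolution == pytest.approx(np.mean(limits))
                assert row.best_resolution == pytest.approx(min(limits))

    def test_empty_part_flagged(self):
        ds = self._ds([2.0])
        ds.chunks.append(Chunk(1, "i1", "//1", 0, []))
        with pytest.warns(UserWarning, match="no crystals"):
            table = diffraction_power_slices(ds, 2)
        assert math.isnan(table.iloc[1]["mean_resolution"])
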