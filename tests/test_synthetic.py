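"""Synthetic world: determinism, scenario consistency, niche truth, sampling."""

import numpy as np
import pytest

from nicheshift import GridSpec
from nicheshift.errors import CannotSampleError, ConfigurationError
from nicheshift.grid import RasterLayer
from nicheshift.synthetic import (
    NicheParams,
    generate_env_stack,
    generate_shipping,
    generate_zones,
    sample_occurrences,
    true_suitability,
)

SPEC = GridSpec(0.0, 0.0, 0.5, 60, 80)


class TestEnvStack:
    def test_zero_delta_scenario_identical_to_current(self):
        stacks = generate_env_stack(SPEC, n_vars=4,
                                    warming_deltas={"flat": 0.0}, seed=7)
        for name in stacks["current"].names:
            np.testing.assert_array_equal(stacks["flat"][name].values,
                                          stacks["current"][name].values)

    def test_same_seed_bit_identical(self):
        a = generate_env_stack(SPEC, n_vars=5, warming_deltas={"w": 2.0}, seed=11)
        b = generate_env_stack(SPEC, n_vars=5, warming_deltas={"w": 2.0}, seed=11)
        for tag in a:
            for name in a[tag].names:
                np.testing.assert_array_equal(a[tag][name].values,
                                              b[tag][name].values)

    def test_warming_moves_isotherm_by_delta_over_slope(self):
        # noise-free linear gradient T = 30 - 0.5 lat: the 20-degree isotherm
        # sits at lat 20 now and at lat 24 after +2 warming
        spec = GridSpec(0.0, 0.0, 0.5, 100, 4)
        stacks = generate_env_stack(spec, n_vars=2, warming_deltas={"w": 2.0},
                                    seed=0, temp_noise_sd=0.0)
        lat = spec.lat_centers()

        def isotherm(stack, t=20.0):
            # T decreases with latitude, so T is ascending down the rows
            col = stack["temperature"].values[:, 0]
            return float(np.interp(t, col, lat))

        assert isotherm(stacks["current"]) == pytest.approx(20.0, abs=0.26)
        assert isotherm(stacks["w"]) == pytest.approx(24.0, abs=0.26)

    def test_scenario_consistency_non_temperature_layers_shared(self):
        stacks = generate_env_stack(SPEC, n_vars=5,
                                    warming_deltas={"w": 1.5}, seed=3)
        for name in stacks["current"].names:
            cur = stacks["current"][name].values
            fut = stacks["w"][name].values
            if name == "temperature":
                np.testing.assert_allclose(fut - cur, 1.5)
            else:
                np.testing.assert_array_equal(fut, cur)

    def test_invalid_spec_and_nvars(self):
        with pytest.raises(Exception):
            generate_env_stack(GridSpec(0, 0, 0.5, -1, 10), n_vars=3, seed=0)
        with pytest.raises(ConfigurationError):
            generate_env_stack(SPEC, n_vars=1, seed=0)


class TestTrueSuitability:
    def test_optimum_scores_one_and_one_sigma_scores_exp_half(self):
        spec = GridSpec(0, 0, 1.0, 1, 3)
        stack_layers = {
            "a": RasterLayer(spec, np.array([[2.0, 2.0, 3.0]]), name="a"),
            "b": RasterLayer(spec, np.array([[5.0, 5.0, 5.0]]), name="b"),
        }
        from nicheshift.grid import EnvStack
        stack = EnvStack(spec, stack_layers)
        niche = NicheParams("x", mu={"a": 2.0, "b": 5.0},
                            sigma={"a": 1.0, "b": 2.0})
        s = true_suitability(niche, stack).values[0]
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(1.0)
        assert s[2] == pytest.approx(np.exp(-0.5))  # one sigma off in "a"

    def test_values_in_unit_interval_and_decreasing_from_optimum(self):
        stacks = generate_env_stack(SPEC, n_vars=3, seed=5)
        niche = NicheParams("x", mu={"temperature": 22.0}, sigma={"temperature": 1.0})
        s = true_suitability(niche, stacks["current"])
        vals = s.valid_values()
        assert np.all((vals > 0) & (vals <= 1))

    def test_missing_variable_errors(self):
        stacks = generate_env_stack(SPEC, n_vars=2, seed=5)
        niche = NicheParams("x", mu={"no_such": 0.0}, sigma={"no_such": 1.0})
        with pytest.raises(ConfigurationError):
            true_suitability(niche, stacks["current"])


class TestSampleOccurrences:
    def test_degenerate_support_puts_all_points_in_that_cell(self):
        spec = GridSpec(0, 0, 1.0, 4, 4)
        vals = np.zeros((4, 4))
        vals[1, 2] = 1.0
        truth = RasterLayer(spec, vals)
        occ = sample_occurrences(truth, 50, seed=1)
        rows, cols, inside = spec.cells_of(occ.lons, occ.lats)
        assert inside.all()
        assert set(zip(rows, cols)) == {(1, 2)}

    def test_contaminant_counts_by_construction(self):
        spec = GridSpec(0, 0, 1.0, 10, 10)
        vals = np.ones((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, 8:] = True  # pretend-land for the land contaminant class
        truth = RasterLayer(spec, np.where(mask, np.nan, vals), mask)
        occ = sample_occurrences(
            truth, 100,
            error_rates={"duplicate": 0.1, "zero_coord": 0.02, "land": 0.05},
            seed=2)
        assert len(occ) == 117
        flags, counts = np.unique(occ.flags, return_counts=True)
        got = dict(zip(flags, counts))
        assert got == {"clean": 100, "duplicate": 10, "zero_coord": 2, "land": 5}
        # duplicates are exact copies of clean rows
        dup = occ.table[occ.flags == "duplicate"]
        clean = occ.table[occ.flags == "clean"]
        merged = dup.merge(clean, on=["lon", "lat"], how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_all_zero_truth_cannot_sample(self):
        truth = RasterLayer(GridSpec(0, 0, 1.0, 3, 3), np.zeros((3, 3)))
        with pytest.raises(CannotSampleError):
            sample_occurrences(truth, 10, seed=0)

    def test_fixed_seed_reproducible(self):
        stacks = generate_env_stack(SPEC, n_vars=3, seed=5)
        niche = NicheParams("x", mu={"temperature": 22.0}, sigma={"temperature": 1.0})
        truth = true_suitability(niche, stacks["current"])
        a = sample_occurrences(truth, 80, {"duplicate": 0.1}, seed=9)
        b = sample_occurrences(truth, 80, {"duplicate": 0.1}, seed=9)
        assert a.table.equals(b.table)
        assert (a.flags == b.flags).all()

    def test_occurrence_density_tracks_suitability(self):
        # law-of-large-numbers check: clean points concentrate where truth is high
        stacks = generate_env_stack(SPEC, n_vars=3, seed=5)
        niche = NicheParams("x", mu={"temperature": 20.0, "chlorophyll": 5.0},
                            sigma={"temperature": 2.0, "chlorophyll": 3.0})
        truth = true_suitability(niche, stacks["current"])
        occ = sample_occurrences(truth, 500, seed=4)
        rows, cols, inside = SPEC.cells_of(occ.lons, occ.lats)
        s_at = truth.values[rows, cols]
        cell_vals = truth.valid_values()
        assert (cell_vals > 0.8).any() and (cell_vals < 0.2).any()
        assert (s_at > 0.8).mean() > (s_at < 0.2).mean()


class TestZones:
    def test_mpa_fraction_zero_gives_empty_mask(self):
        zones = generate_zones(SPEC, mpa_fraction=0.0, n_eez=3, seed=1)
        assert zones.mpa.values.sum() == 0

    def test_mpa_cell_count_matches_fraction_within_one_cell(self):
        zones = generate_zones(SPEC, mpa_fraction=0.25, n_eez=3, seed=1)
        n_sea = int((zones.land.values == 0).sum())
        n_mpa = int(zones.mpa.values.sum())
        assert abs(n_mpa - 0.25 * n_sea) <= 1

    def test_mpa_and_eez_only_on_sea(self):
        zones = generate_zones(SPEC, mpa_fraction=0.3, n_eez=4, seed=2)
        land = zones.land.values != 0
        assert not (zones.mpa.values[land] != 0).any()
        assert not (zones.eez.values[land] != 0).any()
        assert set(np.unique(zones.eez.values[~land])) <= set(range(0, 5))


class TestShipping:
    def test_no_lanes_gives_zero_field(self):
        ship = generate_shipping(SPEC, n_lanes=0, seed=0)
        assert (ship.values == 0).all()

    def test_nonnegative_zero_on_land_and_reproducible(self):
        zones = generate_zones(SPEC, 0.1, 3, seed=3)
        a = generate_shipping(SPEC, n_lanes=5, seed=3, land=zones.land)
        b = generate_shipping(SPEC, n_lanes=5, seed=3, land=zones.land)
        assert (a.values >= 0).all()
        assert (a.values[zones.land.values != 0] == 0).all()
        np.testing.assert_array_equal(a.values, b.values)

    def test_heavy_tail_mass_concentrated(self):
        ship = generate_shipping(SPEC, n_lanes=4, seed=5)
        vals = np.sort(ship.values.ravel())[::-1]
        top10 = vals[: vals.size // 10].sum()
        assert top10 / vals.sum() > 0.5  # lanes concentrate most of the density
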