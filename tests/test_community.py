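"""Light competition, cover assignment and annual community simulation."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import constant_signals
from tests.test_niche import make_species
from vegniche.community import (
    CommunityState,
    SimulationOptions,
    assign_relative_cover,
    covers_to_frame,
    light_at_height,
    plant_strength,
    read_covers,
    simulate_community,
    step_community,
    write_covers,
)
from vegniche.drivers import SyntheticDriverConfig, generate_synthetic_drivers
from vegniche.niche import ParameterTable


def random_table(rng, n_species=5, identical_niches=False):
    """Random viable table around the constant-driver regime."""
    species = []
    for i in range(n_species):
        if identical_niches:
            opts = {"pH": 4.3, "N": 1.2, "moisture": 0.55, "light": 0.12}
        else:
            opts = {
                "pH": 4.3 + rng.uniform(-0.5, 0.5),
                "N": max(0.0, 1.2 + rng.uniform(-0.8, 0.8)),
                "moisture": float(np.clip(0.55 + rng.uniform(-0.2, 0.2), 0, 1)),
                "light": float(np.clip(0.12 + rng.uniform(-0.08, 0.15), 0, 1)),
            }
        species.append(make_species(
            f"sp{i}", opts=opts,
            shading_height=float(rng.choice([0.1, 0.3, 0.6, 1.0, 1.5])),
            rooting_depth=float(rng.choice([0.1, 0.2, 0.3])),
        ))
    return ParameterTable(tuple(species))


class TestLightAtHeight:
    def setup_method(self):
        self.tall = make_species("tall", shading_height=1.5)
        self.short = make_species("short", shading_height=0.2)
        self.table = ParameterTable((self.tall, self.short))

    def test_no_taller_plants_light_unchanged(self):
        state = CommunityState({"tall": 0.5, "short": 0.5})
        assert light_at_height(self.tall, state, self.table, 0.4) == pytest.approx(0.4)

    def test_full_taller_cover_formula(self):
        state = CommunityState({"tall": 1.0, "short": 0.0})
        out = light_at_height(self.short, state, self.table, 0.4,
                              shading_efficiency=0.75)
        assert out == pytest.approx(0.4 * (1 - 0.75))  # = 0.1

    def test_equal_heights_do_not_shade(self):
        a = make_species("a", shading_height=0.5)
        b = make_species("b", shading_height=0.5)
        table = ParameterTable((a, b))
        state = CommunityState({"a": 0.7, "b": 0.3})
        assert light_at_height(a, state, table, 0.3) == pytest.approx(0.3)
        assert light_at_height(b, state, table, 0.3) == pytest.approx(0.3)


class TestStrengthAndCover:
    def test_strength_is_identity(self):
        assert plant_strength(0.0) == 0.0
        assert plant_strength(1.0) == 1.0
        assert plant_strength(0.42) == pytest.approx(2 * plant_strength(0.21))

    def test_dominance_exponent(self):
        assert plant_strength(0.5, dominance_exponent=2.0) == pytest.approx(0.25)

    def test_equal_strengths_share_equally(self):
        state = assign_relative_cover({"a": 3.0, "b": 3.0, "c": 3.0})
        assert all(c == pytest.approx(1 / 3) for c in state.covers.values())

    def test_proportional_normalization(self):
        state = assign_relative_cover({"a": 2.0, "b": 1.0, "c": 1.0})
        assert state.covers == pytest.approx({"a": 0.5, "b": 0.25, "c": 0.25})

    def test_zero_strength_zero_cover(self):
        state = assign_relative_cover({"a": 1.0, "b": 0.0})
        assert state.covers["b"] == 0.0
        assert state.viable

    def test_all_zero_flagged_not_error(self):
        state = assign_relative_cover({"a": 0.0, "b": 0.0})
        assert not state.viable
        assert all(c == 0.0 for c in state.covers.values())


class TestStepCommunity:
    def test_inertia_blends_toward_target(self, constant_drivers):
        series, profile = constant_drivers
        # one species shut out by its temperature window -> target (0, 1)
        dead = make_species("dead", tmin=20.0, tmax=30.0)  # drivers sit at 10 C
        alive = make_species("alive")
        table = ParameterTable((dead, alive))
        old = CommunityState({"dead": 1.0, "alive": 0.0})
        out = step_community(old, table, profile, series, (2000, 6), inertia=0.5)
        assert out.covers == pytest.approx({"dead": 0.5, "alive": 0.5})
        full = step_community(old, table, profile, series, (2000, 6), inertia=1.0)
        assert full.covers == pytest.approx({"dead": 0.0, "alive": 1.0})

    def test_fixed_point_unchanged_at_lambda_one(self, constant_drivers):
        series, profile = constant_drivers
        table = ParameterTable((make_species("a"), make_species("b")))
        state = CommunityState({"a": 0.5, "b": 0.5})
        out = step_community(state, table, profile, series, (2000, 6), inertia=1.0)
        assert out.covers == pytest.approx(state.covers, abs=1e-12)

    def test_single_species_cover_one(self, constant_drivers):
        series, profile = constant_drivers
        table = ParameterTable((make_species("only"),))
        state = CommunityState({"only": 1.0})
        out = step_community(state, table, profile, series, (2000, 7))
        assert out.covers["only"] == pytest.approx(1.0)


class TestSimulateCommunity:
    def test_identical_species_split_evenly(self, constant_drivers):
        series, profile = constant_drivers
        table = ParameterTable((make_species("a"), make_species("b")))
        states = simulate_community(table, series, profile)
        for st in states:
            assert st.covers == pytest.approx({"a": 0.5, "b": 0.5}, abs=1e-9)

    def test_stationary_under_constant_drivers(self, constant_drivers, rng):
        series, profile = constant_drivers
        table = random_table(rng)
        states = simulate_community(table, series, profile)
        first, second = states[0], states[1]
        for name in table.names:
            assert second.covers[name] == pytest.approx(first.covers[name], abs=1e-5)

    def test_covers_normalized_every_year(self, noisy_drivers, rng):
        series, profile = noisy_drivers
        table = random_table(rng, n_species=6)
        states = simulate_community(table, series, profile)
        for st in states:
            assert sum(st.covers.values()) == pytest.approx(1.0, abs=1e-12)

    def test_competition_release(self, constant_drivers, rng):
        # removing a species never decreases any remaining species' cover
        series, profile = constant_drivers
        table = random_table(rng, n_species=5)
        full = simulate_community(table, series, profile)[-1]
        removed = table.names[int(rng.integers(len(table)))]
        reduced = ParameterTable(tuple(sp for sp in table if sp.name != removed))
        part = simulate_community(reduced, series, profile)[-1]
        for name in reduced.names:
            assert part.covers[name] >= full.covers[name] - 1e-9

    def test_zero_shading_equalizes_identical_niches(self, constant_drivers, rng):
        series, profile = constant_drivers
        table = random_table(rng, n_species=4, identical_niches=True)
        opts = SimulationOptions(shading_efficiency=0.0)
        final = simulate_community(table, series, profile, opts=opts)[-1]
        assert all(c == pytest.approx(0.25, abs=1e-9) for c in final.covers.values())

    def test_nonviable_community_flagged(self, constant_drivers):
        series, profile = constant_drivers
        table = ParameterTable((make_species("frozen", tmin=25.0, tmax=35.0),))
        states = simulate_community(table, series, profile)
        assert not states[-1].viable

    def test_iteration_cap_flags_unconverged(self, constant_drivers, rng):
        series, profile = constant_drivers
        table = random_table(rng, n_species=4)
        opts = SimulationOptions(fp_tol=1e-14, fp_max_iter=1)
        states = simulate_community(table, series, profile, opts=opts)
        assert not states[0].converged

    def test_reference_run_regression(self):
        """Frozen trajectory of the packaged example community on seed-1
        synthetic drivers (guards against silent behavioural drift)."""
        from vegniche.fixtures import example_parameter_table

        cfg = SyntheticDriverConfig(start_year=2000, n_years=3, seed=1)
        series = generate_synthetic_drivers(cfg)
        final = simulate_community(
            example_parameter_table(), series, cfg.profile
        )[-1]
        expected = {
            "Fern tall": 0.2001585,
            "Fern low": 0.4040796,
            "Shrub tall": 0.0029092,
            "Herb shade": 0.3783129,
            "Herb light": 0.0000108,
            "Seedling broad": 0.0145290,
        }
        assert final.covers == pytest.approx(expected, abs=2e-7)


class TestCoverIO:
    def test_roundtrip(self, tmp_path, constant_drivers, rng):
        series, profile = constant_drivers
        table = random_table(rng)
        states = simulate_community(table, series, profile)
        path = tmp_path / "covers.csv"
        write_covers(states, path)
        back = read_covers(path)
        assert [st.time for st in back] == [st.time for st in states]
        for a, b in zip(states, back):
            assert b.covers == pytest.approx(a.covers, abs=1e-12)

    def test_frame_is_sorted(self, constant_drivers, rng):
        series, profile = constant_drivers
        states = simulate_community(random_table(rng), series, profile)
        df = covers_to_frame(states)
        assert list(df.columns) == ["year", "species", "cover_frac"]
        assert df.equals(df.sort_values(["year", "species"]).reset_index(drop=True))
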