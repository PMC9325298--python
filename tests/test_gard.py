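"""GARD flux arithmetic, homeostasis scoring, simplex enumeration, screening."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micellekin.gard import (
    GardModel,
    accretion_flux,
    binary_homeostasis_point,
    enumerate_simplex,
    homeostasis_similarity,
    screen_reproducers,
)


def _random_model(rng, s=5):
    return GardModel(
        species=[f"S{i}" for i in range(s)],
        env_conc=rng.uniform(0.001, 0.01, s),
        k_entry=rng.uniform(10, 100, s),
        k_exit=rng.uniform(0.01, 0.3, s),
        beta_entry=rng.uniform(-0.5, 0.5, (s, s)),
        beta_exit=rng.uniform(-0.5, 0.5, (s, s)),
    )


class TestAccretionFlux:
    def test_balanced_terms_zero_flux(self):
        m = GardModel(species=["A", "B"], env_conc=0.004, k_entry=25.0, k_exit=0.1)
        assert np.allclose(accretion_flux([0.5, 0.5], m), 0.0)

    def test_single_species(self):
        m = GardModel(species=["A"], env_conc=0.004, k_entry=50.0, k_exit=0.05)
        assert accretion_flux([1.0], m) == pytest.approx(0.004 * 50.0 - 0.05)

    def test_matches_term_by_term_evaluation(self):
        """Vectorised flux equals a literal per-species evaluation of the
        accretion equation to 1e-12 on random 5-species models."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            m = _random_model(rng)
            f = rng.dirichlet(np.ones(5))
            got = accretion_flux(f, m)
            for i in range(5):
                entry = m.env_conc[i] * m.k_entry[i] * (
                    1.0 + sum(f[j] * m.beta_entry[i, j] for j in range(5))
                )
                exit_ = m.k_exit[i] * (1.0 + sum(f[j] * m.beta_exit[i, j] for j in range(5)))
                assert got[i] == pytest.approx(entry - exit_, abs=1e-12)

    def test_exit_scaling_mode(self):
        m = GardModel(
            species=["A", "B"], env_conc=0.004, k_entry=25.0, k_exit=0.1,
            exit_scaled_by_composition=True,
        )
        f = np.array([0.25, 0.75])
        assert np.allclose(accretion_flux(f, m), 0.004 * 25.0 - 0.1 * f)


class TestHomeostasisSimilarity:
    def test_parallel_flux(self):
        f = np.array([0.3, 0.7])
        assert homeostasis_similarity(f, 3 * f) == pytest.approx(1.0)

    def test_orthogonal_flux(self):
        assert homeostasis_similarity([1.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_antiparallel_flux(self):
        f = np.array([0.5, 0.5])
        assert homeostasis_similarity(f, -f) == pytest.approx(-1.0)

    def test_zero_flux_undefined(self):
        assert math.isnan(homeostasis_similarity([0.5, 0.5], [0.0, 0.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1e-6, 1e6))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4))
        flux = rng.normal(size=4)
        if np.linalg.norm(flux) == 0:
            return
        h1 = homeostasis_similarity(f, flux)
        h2 = homeostasis_similarity(f, c * flux)
        assert h1 == pytest.approx(h2, abs=1e-9)
        assert -1.0 - 1e-12 <= h1 <= 1.0 + 1e-12


class TestSimplexEnumeration:
    def test_two_types_half_step(self):
        grid = enumerate_simplex(2, 0.5)
        assert sorted(map(tuple, grid)) == [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]

    def test_single_type(self):
        assert enumerate_simplex(1, 0.05).tolist() == [[1.0]]

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("step", [0.5, 0.25, 0.1, 0.05])
    def test_count_matches_stars_and_bars(self, n, step):
        m = round(1 / step)
        grid = enumerate_simplex(n, step)
        assert len(grid) == math.comb(m + n - 1, n - 1)
        assert len({tuple(np.round(r, 9)) for r in grid}) == len(grid)
        assert np.allclose(grid.sum(axis=1), 1.0)

    def test_five_types_five_percent(self):
        grid = enumerate_simplex(5, 0.05)
        assert len(grid) == 10_626  # C(24, 4)

    def test_non_integral_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_simplex(3, 0.3)


class TestScreening:
    def test_best_62_reproducers_cover_point_58_percent(self):
        grid = enumerate_simplex(5, 0.05)
        assert 100 * 62 / len(grid) == pytest.approx(0.58, abs=0.005)

    def test_zero_beta_equal_rates_maximise_h_at_environment_proportions(self):
        """Without kinetic effects the flux is proportional to the outside
        concentrations, so H peaks at the environment-proportional grid
        composition."""
        conc = np.array([0.1, 0.15, 0.2, 0.25, 0.3]) * 0.004
        m = GardModel(species=list("ABCDE"), env_conc=conc, k_entry=50.0, k_exit=0.0)
        result = screen_reproducers(m, step=0.05)
        best = result.grid[np.nanargmax(result.h_values)]
        assert np.allclose(best, conc / conc.sum(), atol=1e-9)

    def test_constant_flux_sole_perfect_reproducer(self):
        # flux is composition-independent and points at (0.6, 0.4)
        m = GardModel(
            species=["A", "B"], env_conc=1.0, k_entry=np.array([0.6, 0.4]), k_exit=0.0
        )
        result = screen_reproducers(m, step=0.2, threshold=1.0 - 1e-9)
        assert result.n_reproducers == 1
        assert np.allclose(result.grid[result.reproducer_mask][0], [0.6, 0.4])
        assert result.h_values[result.reproducer_mask][0] == pytest.approx(1.0)

    def test_centroid_of_top_one_is_best_composition(self):
        rng = np.random.default_rng(5)
        m = _random_model(rng, 3)
        result = screen_reproducers(m, step=0.1, threshold=-1.0, top_k=1)
        best = result.grid[np.nanargmax(result.h_values)]
        assert np.allclose(result.centroid, best)

    def test_zero_flux_everywhere_flagged(self):
        m = GardModel(species=["A", "B"], env_conc=0.004, k_entry=25.0, k_exit=0.1)
        result = screen_reproducers(m, step=0.5)
        assert result.n_reproducers == 0
        assert result.centroid is None
        assert result.n_zero_flux == len(result.grid)

    def test_equimolar_distance_percentile_range(self):
        rng = np.random.default_rng(11)
        m = _random_model(rng, 4)
        result = screen_reproducers(m, step=0.1, threshold=0.0)
        if result.n_reproducers:
            assert 0.0 <= result.equimolar_distance_percentile <= 100.0


class TestBinaryHomeostasisPoint:
    def test_symmetric_rates_meet_at_half(self):
        f_b, valid = binary_homeostasis_point(0.2, 0.2, -0.5, -0.5)
        assert f_b == pytest.approx(0.5)
        assert valid

    def test_matches_grid_search_oracle(self):
        """The closed-form intersection agrees with a two-stage grid search
        minimising |rate_A - rate_B| to 1e-6, over random valid parameters."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            k_a, k_b = rng.uniform(0.05, 0.5, 2)
            b_ab, b_ba = rng.uniform(-0.9, -0.1, 2)
            f_b, valid = binary_homeostasis_point(k_a, k_b, b_ab, b_ba)
            if not valid:
                continue

            def gap(f):
                return np.abs(k_a * (1 + f * b_ab) - k_b * (1 + (1 - f) * b_ba))

            coarse = np.linspace(0, 1, 10_001)
            f0 = coarse[np.argmin(gap(coarse))]
            fine = np.linspace(max(0, f0 - 2e-4), min(1, f0 + 2e-4), 40_001)
            f_star = fine[np.argmin(gap(fine))]
            assert abs(f_b - f_star) <= 1e-6

    def test_example_parameters(self):
        f_b, valid = binary_homeostasis_point(0.2, 0.3, -0.6, -0.5)
        gap = abs(0.2 * (1 + f_b * -0.6) - 0.3 * (1 + (1 - f_b) * -0.5))
        assert gap < 1e-12
        assert valid

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="intersection"):
            binary_homeostasis_point(0.2, 0.2, 0.0, 0.0)
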