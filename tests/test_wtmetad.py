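import math

import numpy as np
import pytest

from dimerfes.constants import kT
from dimerfes.grids import Axis
from dimerfes.wtmetad import (
    BiasGrid,
    Hill,
    default_dimer_axes,
    fes_from_bias,
    fes_time_average,
    grid_from_hills,
    read_hills,
    write_hills,
)

GAMMA = 5.0


def fresh_grid(**kw):
    kw.setdefault("bias_factor", GAMMA)
    return BiasGrid(default_dimer_axes(), **kw)


class TestHillHeightLaw:
    def test_first_hill_is_full_height(self):
        grid = fresh_grid()
        hill = grid.deposit_hill((0.55, 0.0))
        assert hill.height == 1.0

    def test_height_decays_by_e_at_gamma_kt(self):
        """At accumulated bias (gamma-1) kT the next hill is w0/e."""
        grid = fresh_grid()
        grid.values[:] = (GAMMA - 1.0) * kT(300.0)
        hill = grid.deposit_hill((0.55, 0.0))
        assert hill.height == pytest.approx(1.0 / math.e, rel=1e-12)

    def test_height_vanishes_under_large_bias(self):
        grid = fresh_grid()
        grid.values[:] = 500.0
        assert grid.deposit_hill((0.55, 0.0)).height < 1e-20

    def test_heights_non_increasing_when_revisiting(self):
        grid = fresh_grid()
        heights = [grid.deposit_hill((0.55, 0.0)).height for _ in range(10)]
        assert all(h2 <= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_bias_factor_must_exceed_one(self):
        with pytest.raises(ValueError, match="bias_factor"):
            BiasGrid(default_dimer_axes(), bias_factor=1.0)


class TestBiasEvaluation:
    def test_empty_grid_is_zero_everywhere(self):
        grid = fresh_grid()
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = (rng.uniform(0, 2.2), rng.uniform(-np.pi, np.pi))
            assert grid.bias_at(s) == 0.0

    def test_single_hill_peaks_at_own_center(self):
        grid = fresh_grid()
        center = (grid.axes[0].nodes[80], grid.axes[1].nodes[100])
        hill = grid.deposit_hill(center)
        assert grid.bias_at(center) == pytest.approx(hill.height, abs=1e-3)

    def test_grid_matches_explicit_hill_summation(self):
        """Interpolated grid bias equals the direct sum over the hill list
        (fine validation grid, where discretization sits below 1e-3)."""
        grid = BiasGrid(
            default_dimer_axes(dist_spacing=0.00125, torsion_spacing=0.005),
            bias_factor=GAMMA,
        )
        rng = np.random.default_rng(2)
        centers = np.column_stack(
            [rng.uniform(0.3, 1.9, 60), rng.uniform(-np.pi, np.pi, 60)]
        )
        for c in centers:
            grid.deposit_hill(c)
        hills = grid.hills
        pts = np.column_stack(
            [rng.uniform(0.3, 1.9, 1000), rng.uniform(-np.pi, np.pi, 1000)]
        )
        for p in pts:
            direct = 0.0
            for h in hills:
                dd = p[0] - h.center[0]
                dt = p[1] - h.center[1]
                dt -= 2 * np.pi * np.round(dt / (2 * np.pi))
                direct += h.height * math.exp(
                    -0.5 * ((dd / h.widths[0]) ** 2 + (dt / h.widths[1]) ** 2)
                )
            assert grid.bias_at(p) == pytest.approx(direct, abs=1e-3)

    def test_values_monotone_nondecreasing_in_time(self):
        grid = fresh_grid()
        rng = np.random.default_rng(3)
        prev = grid.values.copy()
        for _ in range(15):
            grid.deposit_hill((rng.uniform(0.3, 1.9), rng.uniform(-np.pi, np.pi)))
            assert np.all(grid.values >= prev - 1e-15)
            prev = grid.values.copy()

    def test_out_of_range_clamps_with_warning(self):
        grid = fresh_grid()
        grid.deposit_hill((2.15, 0.0))
        with pytest.warns(UserWarning, match="clamp"):
            v = grid.bias_at((2.4, 0.0))
        assert v == pytest.approx(grid.bias_at((2.2, 0.0)))

    def test_periodic_torsion_wraps(self):
        grid = fresh_grid()
        grid.deposit_hill((1.0, math.pi - 0.05))
        # just across the seam the bias should still be large
        assert grid.bias_at((1.0, -math.pi + 0.05)) > 0.5


class TestFESFromBias:
    def test_flat_bias_gives_flat_fes(self):
        grid = fresh_grid()
        F = fes_from_bias(grid)
        assert np.all(F.values == 0.0)

    def test_well_tempered_prefactor(self):
        """gamma = 5: a 4 kJ/mol bias spot maps to a -5 kJ/mol free-energy dip."""
        grid = fresh_grid()
        grid.values[30, 5] = 4.0
        F = fes_from_bias(grid)
        assert F.values[30, 5] - F.values[0, 0] == pytest.approx(-5.0, abs=1e-12)

    def test_linearity_in_bias(self):
        grid = fresh_grid()
        rng = np.random.default_rng(4)
        for _ in range(10):
            grid.deposit_hill((rng.uniform(0.3, 1.9), rng.uniform(-np.pi, np.pi)))
        F1 = fes_from_bias(grid).values
        grid.values *= 2.0
        F2 = fes_from_bias(grid).values
        np.testing.assert_allclose(F2 - F2[0, 0], 2 * (F1 - F1[0, 0]), atol=1e-9)

    def test_time_average_of_constant_history_matches_final(self):
        ax = Axis("s", -1.7, 1.7, 0.01)
        hills = [Hill((0.0,), (0.1,), 0.5, i * 500) for i in range(1, 5)]
        grid = grid_from_hills(hills, (ax,), bias_factor=GAMMA)
        Ffinal = fes_from_bias(grid)
        # averaging over only the last epoch reproduces the final estimate
        Favg = fes_time_average(hills, (ax,), bias_factor=GAMMA, average_fraction=0.249)
        np.testing.assert_allclose(Favg.values, Ffinal.values, atol=1e-12)


class TestHillsIO:
    def test_round_trip_random_hills(self, tmp_path):
        rng = np.random.default_rng(6)
        hills = [
            Hill(
                center=(rng.uniform(0.3, 1.9), rng.uniform(-np.pi, np.pi)),
                widths=(0.05, 0.2),
                height=rng.uniform(0.01, 1.0),
                step_index=500 * (i + 1),
            )
            for i in range(100)
        ]
        path = tmp_path / "HILLS"
        write_hills(hills, path, bias_factor=GAMMA)
        back, names, biasf = read_hills(path)
        assert names == ["dist", "torsion"]
        assert biasf == GAMMA
        assert len(back) == 100
        for a, b in zip(hills, back):
            assert a.step_index == b.step_index
            assert a.height == pytest.approx(b.height, abs=1e-9)
            np.testing.assert_allclose(a.center, b.center, atol=1e-9)
            np.testing.assert_allclose(a.widths, b.widths, atol=1e-9)

    def test_empty_hill_list_round_trips(self, tmp_path):
        path = tmp_path / "HILLS"
        write_hills([], path)
        back, _, _ = read_hills(path)
        assert back == []

    def test_plumed_style_fixture_parses(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text(
            "#! FIELDS time dist torsion sigma_dist sigma_torsion height biasf\n"
            "500 0.62 -0.41 0.05 0.2 1.0 5\n"
            "1000 0.55 0.10 0.05 0.2 0.91 5\n"
            "1500 0.48 1.90 0.05 0.2 0.77 5\n"
        )
        hills, names, biasf = read_hills(path)
        assert [h.height for h in hills] == [1.0, 0.91, 0.77]
        assert hills[2].center == (0.48, 1.90)

    def test_unknown_fields_header_rejected(self, tmp_path):
        path = tmp_path / "HILLS"
        path.write_text("#! FIELDS time x height\n1 2 3\n")
        with pytest.raises(ValueError, match="FIELDS"):
            read_hills(path)
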