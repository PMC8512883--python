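import math

import numpy as np
import pytest

from dimerfes.constants import R_GAS, kT
from dimerfes.fesutils import (
    compare_profiles,
    entropic_correction,
    extract_binding,
    frame_weights,
    read_fes,
    reweight_to_cv,
    weighted_fes_histogram,
    write_fes,
    zero_shift,
)
from dimerfes.grids import Axis, FESGrid
from dimerfes.sampling import CVTrajectory, SamplerConfig, metropolis_cv_sample
from dimerfes.synthetic import make_dip_grid, make_harmonic
from dimerfes.wtmetad import BiasGrid, Hill


def dist_axis(spacing=0.05, hi=2.2):
    return Axis("dist", 0.0, hi, spacing)


def angle_axis(n=18):
    return Axis("nangle", 0.0, math.pi / 2, (math.pi / 2) / n)


def flat_grid(value=0.0, corrected=True, shifted=True):
    axes = (dist_axis(), angle_axis())
    g = FESGrid(axes=axes, values=np.full((axes[0].n_nodes, axes[1].n_nodes), value))
    g.entropic_corrected = corrected
    g.zero_shifted = shifted
    return g


class TestEntropicCorrection:
    def test_zero_at_one_nanometer(self):
        axes = (Axis("dist", 0.5, 1.5, 0.5),)  # nodes 0.5, 1.0, 1.5
        g = FESGrid(axes=axes, values=np.zeros(3))
        out = entropic_correction(g, n_dims=3, temperature=300.0)
        assert out.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_at_two_nanometers(self):
        axes = (Axis("dist", 1.0, 2.0, 1.0),)
        g = FESGrid(axes=axes, values=np.zeros(2))
        out = entropic_correction(g, n_dims=3, temperature=300.0)
        expected = 2 * R_GAS * 300.0 * math.log(2.0)  # ~3.458
        assert out.values[1] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(3.458, abs=1e-3)

    def test_one_dimension_means_no_correction(self):
        axes = (Axis("dist", 0.5, 2.0, 0.5),)
        g = FESGrid(axes=axes, values=np.zeros(4))
        out = entropic_correction(g, n_dims=1)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_double_application_rejected(self):
        g = FESGrid(axes=(dist_axis(),), values=np.zeros(dist_axis().n_nodes))
        once = entropic_correction(g)
        with pytest.raises(ValueError, match="entropic_corrected"):
            entropic_correction(once)

    def test_nonpositive_distance_nodes_become_undefined(self):
        g = FESGrid(axes=(dist_axis(),), values=np.zeros(dist_axis().n_nodes))
        out = entropic_correction(g)
        assert np.isinf(out.values[0])  # node at r = 0


class TestZeroShift:
    def test_idempotent(self):
        rng = np.random.default_rng(1)
        g = FESGrid(axes=(dist_axis(),), values=rng.normal(size=dist_axis().n_nodes))
        once = zero_shift(g)
        twice = zero_shift(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_gauge_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=dist_axis().n_nodes)
        a = zero_shift(FESGrid(axes=(dist_axis(),), values=vals))
        b = zero_shift(FESGrid(axes=(dist_axis(),), values=vals + 17.3))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_constructed_tail_mean_removed(self):
        ax = dist_axis()
        vals = np.zeros(ax.n_nodes)
        window = (ax.nodes >= 1.6) & (ax.nodes <= 1.8)
        vals[window] = 4.2
        g = zero_shift(FESGrid(axes=(ax,), values=vals))
        assert abs(g.values[window].mean()) < 1e-9

    def test_window_outside_grid_rejected(self):
        ax = Axis("dist", 0.0, 1.0, 0.1)
        g = FESGrid(axes=(ax,), values=np.zeros(ax.n_nodes), shift_window=(1.6, 1.8))
        with pytest.raises(ValueError, match="shift window"):
            zero_shift(g)


class TestReweighting:
    def test_zero_bias_equals_plain_histogram_bitwise(self):
        """With no bias the weights are exactly 1 and F matches -kT ln(counts)."""
        rng = np.random.default_rng(3)
        n = 5000
        traj = CVTrajectory(
            time=np.arange(1, n + 1),
            cvs=rng.uniform(0.3, 2.0, n)[:, None],
            cv_names=("dist",),
            bias=np.zeros(n),
        )
        ax = dist_axis()
        F = reweight_to_cv(traj, [], (ax,), (ax,), bias_factor=5.0)
        counts, _ = np.histogram(traj.cvs[:, 0], bins=ax.edges)
        with np.errstate(divide="ignore"):
            expected = -kT(300.0) * np.log(counts.astype(float))
        np.testing.assert_array_equal(F.values, expected)

    def test_frozen_known_bias_recovers_harmonic_profile(self):
        """Sampling U+V with fixed V and reweighting by exp(beta V) returns U."""
        k = 100.0
        pot = make_harmonic(k)
        ax = Axis("s", -0.6, 0.6, 0.01)
        bias = BiasGrid((ax,), bias_factor=5.0, widths=(0.15,))
        # one frozen hill centred on the well pushes the walker outwards
        bias.add_hill(Hill((0.0,), (0.15,), 6.0, 0))

        def total(s):
            return pot(s) + bias.bias_at((s,))

        cfg = SamplerConfig(n_steps=400_000, seed=5, record_stride=2)
        traj = metropolis_cv_sample(total, cfg, bounds=(-0.6, 0.6), step_size=0.08)
        # record the bias the frames actually felt
        v = np.array([bias.bias_at((s,)) for s in traj.cvs[:, 0]])
        traj = CVTrajectory(
            time=traj.time, cvs=traj.cvs, cv_names=("s",), bias=v, meta=traj.meta
        )
        axc = Axis("s", -0.6, 0.6, 0.05)
        w = frame_weights(traj, bias.hills, (ax,), variant="final_bias")
        F = reweight_to_cv(traj, bias.hills, (axc,), (ax,), weights=w)
        sigma_eq = math.sqrt(kT(300.0) / k)
        mask = np.abs(axc.nodes) <= 2 * sigma_eq
        ref = 0.5 * k * axc.nodes**2
        diff = F.values - ref
        diff -= diff[mask].mean()
        assert np.nanmax(np.abs(diff[mask])) < 0.5

    def test_unknown_variant_rejected(self):
        traj = CVTrajectory(
            time=np.array([1, 2]),
            cvs=np.array([[0.5], [0.6]]),
            cv_names=("dist",),
            bias=np.array([0.0, 0.0]),
        )
        with pytest.raises(ValueError, match="variant"):
            frame_weights(traj, [], (dist_axis(),), variant="bogus")

    def test_uniform_weight_normalization(self):
        traj = CVTrajectory(
            time=np.array([1, 2, 3]),
            cvs=np.array([[0.5], [0.6], [0.7]]),
            cv_names=("dist",),
            bias=np.array([2.0, 2.0, 2.0]),
        )
        hills = [Hill((0.5,), (0.05,), 1.0, 0)]
        w = frame_weights(traj, hills, (dist_axis(0.01),), bias_factor=5.0)
        assert w.mean() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)  # equal bias -> equal weights


class TestExtractBinding:
    def test_single_t_shaped_dip(self):
        grid = make_dip_grid(
            (dist_axis(), angle_axis()),
            [((0.55, math.pi / 2), (0.05, 0.3), -5.0)],
        )
        s = extract_binding(grid)
        d, a, depth = s.first_shell_min
        assert d == pytest.approx(0.55, abs=1e-9)
        assert math.degrees(a) == pytest.approx(90.0, abs=1e-6)
        assert depth == pytest.approx(-5.0, abs=1e-6)
        assert s.mode_label == "T-shaped"

    def test_stacked_dip(self):
        grid = make_dip_grid(
            (dist_axis(), angle_axis()),
            [((0.45, 0.0), (0.05, 0.3), -4.0)],
        )
        assert extract_binding(grid).mode_label == "stacked"

    def test_flat_grid_reports_zero_depth_with_warning(self):
        grid = flat_grid(0.0)
        with pytest.warns(UserWarning, match="mixed"):
            s = extract_binding(grid)
        assert s.first_shell_min[2] == 0.0
        assert s.mode_label == "mixed"

    def test_deeper_second_shell_does_not_leak_into_first(self):
        grid = make_dip_grid(
            (dist_axis(), angle_axis()),
            [
                ((0.55, math.pi / 2), (0.04, 0.3), -3.0),
                ((0.95, math.pi / 2), (0.04, 0.3), -7.0),
            ],
        )
        s = extract_binding(grid)
        assert s.first_shell_min[0] == pytest.approx(0.55, abs=0.02)
        assert s.first_shell_min[2] == pytest.approx(-3.0, abs=0.1)
        assert s.second_shell_min[0] == pytest.approx(0.95, abs=0.02)
        assert s.second_shell_min[2] == pytest.approx(-7.0, abs=0.1)

    def test_uncorrected_grid_rejected(self):
        grid = flat_grid(corrected=False)
        with pytest.raises(ValueError, match="corrected"):
            extract_binding(grid)


class TestCompareProfiles:
    def make(self, depth):
        return make_dip_grid(
            (dist_axis(), angle_axis()),
            [((0.55, math.pi / 2), (0.05, 0.3), depth)],
        )

    def test_identical_profiles_not_flagged(self):
        r = compare_profiles([("a", self.make(-5.0)), ("b", self.make(-5.0))])
        assert r.flagged == []
        assert len(r.table) == 2

    def test_difference_beyond_thermal_energy_flagged(self):
        r = compare_profiles([("a", self.make(-5.0)), ("b", self.make(-10.0))])
        assert r.threshold == pytest.approx(2.494, abs=1e-3)
        assert len(r.flagged) == 1
        assert r.flagged[0][2] == pytest.approx(5.0, abs=0.05)

    def test_sub_thermal_difference_not_flagged(self):
        r = compare_profiles([("a", self.make(-5.0)), ("b", self.make(-6.0))])
        assert r.flagged == []

    def test_three_profiles_pairwise(self):
        r = compare_profiles(
            [("a", self.make(-2.0)), ("b", self.make(-5.0)), ("c", self.make(-9.0))]
        )
        assert len(r.table) == 3
        flagged_pairs = {(x, y) for x, y, _ in r.flagged}
        assert flagged_pairs == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_mismatched_axes_rejected(self):
        other = make_dip_grid(
            (dist_axis(hi=2.0), angle_axis()),
            [((0.55, math.pi / 2), (0.05, 0.3), -5.0)],
        )
        with pytest.raises(ValueError, match="axes"):
            compare_profiles([("a", self.make(-5.0)), ("b", other)])


class TestFesIO:
    def test_round_trip_2d(self, tmp_path):
        grid = make_dip_grid(
            (dist_axis(), angle_axis()),
            [((0.55, math.pi / 2), (0.05, 0.3), -5.0)],
            stderr=0.2,
        )
        path = tmp_path / "fes.dat"
        write_fes(grid, path)
        back = read_fes(path)
        np.testing.assert_allclose(back.values, grid.values, atol=1e-8)
        np.testing.assert_allclose(back.stderr, grid.stderr, atol=1e-8)
        assert back.entropic_corrected and back.zero_shifted

    def test_round_trip_1d_with_inf(self, tmp_path):
        ax = dist_axis()
        vals = np.zeros(ax.n_nodes)
        vals[0] = np.inf
        g = FESGrid(axes=(ax,), values=vals)
        path = tmp_path / "fes.dat"
        write_fes(g, path)
        back = read_fes(path)
        assert np.isinf(back.values[0])
        np.testing.assert_allclose(back.values[1:], 0.0, atol=1e-12)
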