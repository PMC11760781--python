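"""Q→B conversion, model-map rendering, CC-mean and the scaling-factor scan."""

import numpy as np
import pytest

from qscore3d import (
    AtomicModel,
    ComputationError,
    DensityGrid,
    FixtureSpec,
    InputError,
    QScoreParams,
    cc_mean,
    make_isolated_model,
    make_map,
    model_mask,
    model_q,
    q_to_bfactor,
    render_model_map,
    scan_scaling,
)
from qscore3d.models import Atom
from qscore3d.qscore import AtomQ, QScoreTable

EIGHT_PI_SQ = 8 * np.pi**2


def _fake_table(model, q_values, params=QScoreParams()):
    atoms = model.scoreable_atoms()
    return QScoreTable(
        [AtomQ(a, q, 30) for a, q in zip(atoms, q_values)], params
    )


class TestQToBFactor:
    @pytest.mark.parametrize("q,f,expected", [
        (1.0, 150.0, 0.0),
        (0.7, 150.0, 45.0),
        (0.0, 300.0, 300.0),
    ])
    def test_linear_conversion(self, q, f, expected):
        assert q_to_bfactor(q, f) == pytest.approx(expected)

    def test_negative_f_rejected(self):
        with pytest.raises(InputError):
            q_to_bfactor(0.5, -1.0)


class TestRenderModelMap:
    def _single_atom_grid(self, b=0.0, voxel=0.4, cutoff_sigmas=30.0):
        # generous cutoff: these tests probe the exact analytic profile
        model = AtomicModel([Atom("A", "LIG", 1, "C", "C", [0.0, 0.0, 0.0])])
        n = 41
        half = (n - 1) // 2 * voxel
        template = DensityGrid(np.zeros((n, n, n)), [voxel] * 3,
                               [-half, -half, -half])
        return model, render_model_map(model, template, np.array([b]),
                                       cutoff_sigmas=cutoff_sigmas)

    def test_peak_at_atom_position(self):
        model, grid = self._single_atom_grid(b=0.0)
        idx = np.unravel_index(np.argmax(grid.values), grid.shape)
        assert np.allclose(grid.voxel_to_world([idx])[0], 0.0, atol=1e-9)

    def test_zero_b_profile_matches_sigma0_gaussian(self):
        _, grid = self._single_atom_grid(b=0.0)
        xyz = grid.voxel_center_coords().reshape(-1, 3)
        r2 = (xyz**2).sum(axis=1)
        expected = grid.values.max() * np.exp(-r2 / (2 * 0.36))
        assert np.allclose(grid.values.ravel(), expected, atol=1e-6 * grid.values.max())

    def test_variance_grows_by_b_over_8pi2(self):
        """Second moment of the rendered peak: B = 8π² adds exactly 1 Å² of
        variance to the σ₀² = 0.36 Å² base."""
        for b, var_expected in ((0.0, 0.36), (EIGHT_PI_SQ, 1.36)):
            _, grid = self._single_atom_grid(b=b, voxel=0.3)
            xyz = grid.voxel_center_coords().reshape(-1, 3)
            w = grid.values.ravel()
            var = (w * (xyz[:, 0] ** 2)).sum() / w.sum()
            assert var == pytest.approx(var_expected, rel=1e-3)

    def test_mass_conservation_across_b(self):
        """Raising B spreads density without changing the atom's integral."""
        _, sharp = self._single_atom_grid(b=0.0, voxel=0.3)
        _, blurred = self._single_atom_grid(b=100.0, voxel=0.3)
        assert blurred.values.max() < sharp.values.max()
        assert blurred.values.sum() == pytest.approx(sharp.values.sum(), rel=1e-3)

    def test_negative_b_rejected(self):
        model = AtomicModel([Atom("A", "LIG", 1, "C", "C", [0, 0, 0])])
        template = DensityGrid(np.zeros((8, 8, 8)), [1, 1, 1], [-4, -4, -4])
        with pytest.raises(InputError):
            render_model_map(model, template, np.array([-5.0]))


class TestCCMean:
    def test_self_correlation_is_one(self, toy_map):
        assert cc_mean(toy_map, toy_map) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, toy_map):
        neg = DensityGrid(-toy_map.values, toy_map.voxel_size, toy_map.origin)
        assert cc_mean(toy_map, neg) == pytest.approx(-1.0)

    def test_amplitude_scaling_invariance(self, toy_model, toy_map):
        doubled = DensityGrid(2.0 * toy_map.values, toy_map.voxel_size, toy_map.origin)
        mask = model_mask(toy_map, toy_model)
        other = make_map(toy_model, FixtureSpec(b_factor=30.0))
        assert cc_mean(other, doubled, mask) == pytest.approx(
            cc_mean(other, toy_map, mask), abs=1e-12)

    def test_matches_bruteforce_voxel_loop(self, rng):
        a = DensityGrid(rng.normal(size=(6, 6, 6)), [1, 1, 1], [0, 0, 0])
        b = DensityGrid(rng.normal(size=(6, 6, 6)), [1, 1, 1], [0, 0, 0])
        got = cc_mean(a, b)
        xs = a.values.ravel().tolist()
        ys = b.values.ravel().tolist()
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        den = (sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)) ** 0.5
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_is_error(self):
        flat = DensityGrid(np.ones((4, 4, 4)), [1, 1, 1], [0, 0, 0])
        other = DensityGrid(np.arange(64, dtype=float).reshape(4, 4, 4),
                            [1, 1, 1], [0, 0, 0])
        with pytest.raises(ComputationError):
            cc_mean(flat, other)

    def test_geometry_mismatch_is_error(self):
        a = DensityGrid(np.zeros((4, 4, 4)), [1, 1, 1], [0, 0, 0])
        b = DensityGrid(np.zeros((5, 4, 4)), [1, 1, 1], [0, 0, 0])
        with pytest.raises(InputError):
            cc_mean(a, b)


class TestScanScaling:
    def _recovery_setup(self, f_true, seed=0, noise_sd=0.0):
        model = make_isolated_model(n_atoms=6, spacing=7.0)
        rng = np.random.default_rng(seed)
        q_true = rng.uniform(0.3, 0.95, 6)
        b_true = (1 - q_true) * f_true
        grid = make_map(model, FixtureSpec(pad=5.0, noise_sd=noise_sd,
                                           rng_seed=seed), b_factors=b_true)
        return model, _fake_table(model, q_true), grid

    def test_recovers_true_scaling_factor(self):
        model, table, grid = self._recovery_setup(120.0)
        scan = scan_scaling(model, table, grid)
        assert abs(scan.f_opt - 120.0) <= 10.0
        assert np.allclose(scan.b_factors, (1 - table.q_values) * scan.f_opt)

    def test_recovery_with_voxel_noise(self):
        """5% Gaussian voxel noise still localises f within two grid steps."""
        model, table, grid = self._recovery_setup(120.0, seed=1)
        grid.values += np.random.default_rng(9).normal(
            0, 0.05 * grid.values.max(), grid.shape)
        scan = scan_scaling(model, table, grid)
        assert abs(scan.f_opt - 120.0) <= 20.0

    def test_sharp_map_gives_f_zero(self):
        model = make_isolated_model(n_atoms=4, spacing=7.0)
        grid = make_map(model, FixtureSpec(pad=5.0))  # rendered with B = 0
        table = _fake_table(model, np.linspace(0.4, 0.9, 4))
        scan = scan_scaling(model, table, grid)
        assert scan.f_opt == 0.0

    def test_cc_curve_unimodal_around_optimum(self):
        for seed in range(5):
            model, table, grid = self._recovery_setup(120.0, seed=seed)
            scan = scan_scaling(model, table, grid)
            peak = int(np.argmax(scan.cc_values))
            assert np.all(np.diff(scan.cc_values[: peak + 1]) > 0)
            assert np.all(np.diff(scan.cc_values[peak:]) < 0)

    def test_optimal_b_beats_zero_b(self):
        model, table, grid = self._recovery_setup(240.0, seed=3)
        scan = scan_scaling(model, table, grid)
        assert scan.cc_values[np.argmax(scan.f_grid == scan.f_opt)] > scan.cc_values[0]

    def test_undefined_q_filled_with_median(self):
        model = make_isolated_model(n_atoms=3, spacing=7.0)
        grid = make_map(model, FixtureSpec(pad=5.0))
        atoms = model.scoreable_atoms()
        table = QScoreTable(
            [AtomQ(atoms[0], 0.4, 30), AtomQ(atoms[1], np.nan, 2),
             AtomQ(atoms[2], 0.8, 30)],
            QScoreParams(),
        )
        scan = scan_scaling(model, table, grid, f_range=(0, 50), f_step=10)
        assert scan.q_used[1] == pytest.approx(0.6)  # median of {0.4, 0.8}
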