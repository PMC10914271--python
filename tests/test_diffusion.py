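import numpy as np
import pytest
from scipy import integrate, special

from mswsim.diffusion import (
    DrugField,
    PkParams,
    VesselLayout,
    exp_decay_field,
    read_field,
    solve_pde,
    steady_state_1d,
    steady_state_2d,
    superpose_sources,
    transient_1d_oracle,
    transient_2d_oracle,
    write_field,
)


class TestSteadyState1D:
    def test_point_values(self):
        p = PkParams(D=1.0, gamma=1.0, k=4.0)
        assert steady_state_1d(p, 0.0) == pytest.approx(2.0)
        assert steady_state_1d(p, 1.0) == pytest.approx(2.0 * np.exp(-1.0))

    def test_symmetry(self):
        p = PkParams(D=2.0, gamma=0.5, k=3.0)
        x = np.linspace(0, 10, 50)
        assert np.allclose(steady_state_1d(p, x), steady_state_1d(p, -x))

    def test_mass_balance(self):
        # clearance integrates the profile back to the source input k
        p = PkParams(D=0.7, gamma=0.3, k=5.0)
        total, _ = integrate.quad(lambda x: p.gamma * steady_state_1d(p, x), -np.inf, np.inf)
        assert total == pytest.approx(p.k, rel=1e-8)

    def test_gamma_zero_rejected(self):
        with pytest.raises(ValueError):
            steady_state_1d(PkParams(D=1.0, gamma=0.0, k=1.0), 0.0)


class TestSteadyState2D:
    def test_matches_hankel_integral_oracle(self):
        # independent evaluation of the radial inverse-transform integral
        p = PkParams(D=1.3, gamma=0.8, k=2 * np.pi, vessel_radius=0.01)
        for r in (0.5, 1.0, 3.0):
            oracle, _ = integrate.quad(
                lambda rho: p.k * rho * special.j0(r * rho) / (2 * np.pi * (p.D * rho**2 + p.gamma)),
                0,
                2000.0,
                limit=2000,
            )
            assert steady_state_2d(p, r) == pytest.approx(oracle, rel=1e-4)

    def test_bessel_value(self):
        p = PkParams(D=1.0, gamma=1.0, k=2 * np.pi, vessel_radius=0.01)
        assert steady_state_2d(p, 1.0) == pytest.approx(0.42102443824070823, rel=1e-10)

    def test_vessel_cap_and_monotonicity(self):
        p = PkParams(D=1.0, gamma=1.0, k=1.0, vessel_radius=0.5)
        r = np.linspace(0, 10, 300)
        u = steady_state_2d(p, r)
        inside = r < 0.5
        assert np.allclose(u[inside], steady_state_2d(p, 0.5))
        beyond = u[~inside]
        assert np.all(np.diff(beyond) < 0)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            steady_state_2d(PkParams(), -0.1)

    def test_mass_balance_on_grid(self):
        # gamma * sum(u * cell area) ~ k for a fine large grid
        p = PkParams(D=1.0, gamma=1.0, k=3.0, vessel_radius=0.025)
        h = 0.05
        half = 30.0
        ax = np.arange(-half, half + h / 2, h)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        u = steady_state_2d(p, np.hypot(xx, yy))
        mass = p.gamma * u.sum() * h * h
        assert mass == pytest.approx(p.k, rel=0.01)


class TestTransientOracle:
    def test_zero_at_t0(self):
        p = PkParams(D=1.0, gamma=1.0, k=4.0)
        assert transient_1d_oracle(p, 1.3, 0.0) == 0.0

    def test_large_t_converges_to_steady_state(self):
        p = PkParams(D=1.0, gamma=1.0, k=4.0)
        for x in (0.0, 0.5, 1.0, 2.0):
            assert abs(transient_1d_oracle(p, x, 50.0) - steady_state_1d(p, x)) < 1e-6

    def test_monotone_approach(self):
        p = PkParams(D=1.0, gamma=0.5, k=2.0)
        xs = np.array([0.0, 0.7, 1.5])
        sups = []
        for t in (0.5, 2.0, 8.0, 32.0):
            vals = np.array([transient_1d_oracle(p, x, t) for x in xs])
            steady = steady_state_1d(p, xs)
            assert np.all(vals > 0) and np.all(vals < steady)
            sups.append(np.max(steady - vals))
        assert all(a > b for a, b in zip(sups[:-1], sups[1:]))

    def test_2d_oracle_converges_to_bessel_kernel(self):
        p = PkParams(D=1.0, gamma=1.0, k=2 * np.pi, vessel_radius=1e-6)
        assert transient_2d_oracle(p, 1.0, 60.0) == pytest.approx(
            steady_state_2d(p, 1.0), rel=1e-4
        )


class TestPdeSolver:
    def test_no_vessels_stays_zero(self):
        layout = VesselLayout(positions=[(5, 5)], strengths=[0.0])
        f = solve_pde(layout, PkParams(D=1.0, gamma=0.1), (11, 11), n_steps=50)
        assert np.all(f.values == 0)

    def test_stability_guard(self):
        layout = VesselLayout(positions=[(5, 5)], strengths=[1.0])
        with pytest.raises(ValueError, match="unstable"):
            solve_pde(layout, PkParams(D=1.0, gamma=0.1), (11, 11), dt=0.3, n_steps=1)

    def test_strong_absorption_localizes_drug(self):
        layout = VesselLayout(positions=[(15, 15)], strengths=[1.0])
        f = solve_pde(layout, PkParams(D=0.1, gamma=2.0), (31, 31), steady_tol=1e-12)
        assert f.values[15, 15] == 1.0
        assert f.values[15, 20] < 1e-3  # confined near the vessel
        assert f.values.sum() < 10.0

    def test_steady_state_matches_bessel_profile(self):
        # numerical clamped-vessel steady state has the K0 radial shape
        p = PkParams(D=1.0, gamma=0.02, k=1.0)
        layout = VesselLayout(positions=[(60, 60)], strengths=[1.0])
        f = solve_pde(layout, p, (121, 121), steady_tol=1e-10)
        ii, jj = np.meshgrid(np.arange(121), np.arange(121), indexing="ij")
        r = np.hypot(ii - 60, jj - 60)
        annulus = (r >= 6) & (r <= 20)
        prof = special.k0(np.sqrt(p.gamma / p.D) * r[annulus])
        amp = (f.values[annulus] / prof).mean()
        rel = np.abs(f.values[annulus] - amp * prof) / (amp * prof)
        assert rel.max() < 0.05
        assert np.corrcoef(np.log(f.values[annulus]), np.log(prof))[0, 1] > 0.99

    def test_positivity_preserved(self):
        layout = VesselLayout(positions=[(10, 10)], strengths=[5.0])
        f = solve_pde(layout, PkParams(D=1.0, gamma=0.5), (21, 21), n_steps=200)
        assert np.all(f.values >= 0)


class TestExpDecayField:
    def test_half_life_definition(self):
        layout = VesselLayout(positions=[(50, 25), (50, 75)])
        f = exp_decay_field(layout, k=10.0, L=4.0, grid_shape=(100, 100))
        assert f.values[50, 25] == 10.0  # at the vessel
        assert f.values[50, 29] == pytest.approx(5.0)  # d = L -> k/2
        assert f.values[50, 33] == pytest.approx(2.5)  # d = 2L -> k/4

    def test_nearest_vessel_rule(self):
        layout = VesselLayout(positions=[(0, 0), (0, 10)])
        f = exp_decay_field(layout, k=1.0, L=2.0, grid_shape=(1, 11))
        assert f.values[0, 5] == pytest.approx(2.0 ** (-5 / 2))
        assert np.allclose(f.values[0], f.values[0, ::-1])  # mirror symmetry

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exp_decay_field(VesselLayout(positions=[(0, 0)]), 1.0, 0.0, (5, 5))
        with pytest.raises(ValueError):
            VesselLayout(positions=[])


class TestSuperposition:
    def test_single_source_equals_kernel(self):
        p = PkParams(D=1.0, gamma=0.1, k=2.0)
        layout = VesselLayout(positions=[(10, 10)])
        f = superpose_sources(layout, p, (21, 21))
        ii, jj = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        expected = steady_state_2d(p, np.hypot(ii - 10, jj - 10))
        assert np.allclose(f.values, expected)

    def test_mirror_symmetry(self):
        p = PkParams(D=1.0, gamma=0.1, k=1.0)
        layout = VesselLayout(positions=[(10, 5), (10, 15)])
        f = superpose_sources(layout, p, (21, 21))
        assert np.allclose(f.values, f.values[:, ::-1])

    def test_matches_per_site_direct_sum(self):
        # independent per-site loop over sources
        p = PkParams(D=0.8, gamma=0.3, k=1.5)
        layout = VesselLayout(positions=[(3, 4), (11, 2), (7, 13)], strengths=[1.0, 2.0, 0.5])
        f = superpose_sources(layout, p, (15, 15))
        for i in range(0, 15, 3):
            for j in range(0, 15, 4):
                expected = sum(
                    steady_state_2d(
                        PkParams(D=p.D, gamma=p.gamma, k=s * p.k, vessel_radius=p.vessel_radius),
                        float(np.hypot(i - vi, j - vj)),
                    )
                    for (vi, vj), s in zip(layout.positions, layout.strengths)
                )
                assert f.values[i, j] == pytest.approx(expected)

    def test_linearity(self):
        p = PkParams(D=1.0, gamma=0.2, k=1.0)
        a = superpose_sources(VesselLayout(positions=[(5, 5)]), p, (15, 15))
        b = superpose_sources(VesselLayout(positions=[(9, 9)]), p, (15, 15))
        ab = superpose_sources(VesselLayout(positions=[(5, 5), (9, 9)]), p, (15, 15))
        assert np.allclose(ab.values, a.values + b.values)


def test_field_round_trip(tmp_path):
    values = np.random.default_rng(0).random((6, 7))
    f = DrugField(values=values, spacing=2.0, unit="uM")
    write_field(f, tmp_path / "f.csv", tmp_path / "f.yaml")
    back = read_field(tmp_path / "f.csv", tmp_path / "f.yaml")
    assert np.allclose(back.values, values)
    assert back.spacing == 2.0 and back.unit == "uM"


def test_drug_field_validation():
    with pytest.raises(ValueError):
        DrugField(values=np.array([[1.0, -0.1]]))
    with pytest.raises(ValueError):
        DrugField(values=np.array([[np.inf]]))
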