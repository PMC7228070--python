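"""Stiffness fitting, energy decomposition, equipartition, persistence."""

import numpy as np
import pytest

from torsionmelt import (
    GeneratorSpec,
    HelicalTrajectory,
    elastic_energy_series,
    equipartition_report,
    fit_stiffness,
    half_split_dof_energy,
    long_range_coupling_score,
    per_step_energy,
    sample_restrained,
    sample_unrestrained,
    twist_covariance_map,
    twist_persistence_length,
)
from torsionmelt.constants import kbt
from torsionmelt.elastic import StiffnessModel


@pytest.fixture(scope="module")
def default_traj():
    return sample_unrestrained(GeneratorSpec(n_frames=5000, seed=11))


@pytest.fixture(scope="module")
def default_model(default_traj):
    return fit_stiffness(default_traj)


class TestFitStiffness:
    def test_dimension_is_three_dofs_per_step(self, default_model):
        assert default_model.stiffness.shape == (129, 129)
        assert default_model.covariance.shape == (129, 129)

    def test_stiffness_times_covariance_is_thermal_identity(self, default_model):
        kt = kbt(default_model.temperature)
        prod = default_model.stiffness @ default_model.covariance
        np.testing.assert_allclose(prod, kt * np.eye(129), atol=1e-8)

    def test_recovers_known_stiffness_from_large_sample(self):
        spec = GeneratorSpec(n_steps=10, n_frames=50_000, seed=3)
        k_true = spec.stiffness_matrix()
        model = fit_stiffness(sample_unrestrained(spec))
        err = np.linalg.norm(model.stiffness - k_true) / np.linalg.norm(k_true)
        assert err < 0.05

    def test_error_shrinks_with_more_frames(self):
        spec = GeneratorSpec(n_steps=8, seed=5)
        k_true = spec.stiffness_matrix()
        errs = []
        for frames in (1000, 8000, 64_000):
            m = fit_stiffness(sample_unrestrained(
                GeneratorSpec(n_steps=8, seed=5, n_frames=frames)))
            errs.append(np.linalg.norm(m.stiffness - k_true) / np.linalg.norm(k_true))
        assert errs[0] > errs[1] > errs[2]

    def test_singular_covariance_reports_offending_mode(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 4))
        traj = HelicalTrajectory(
            twist=np.repeat(base, 50, axis=0),
            roll=rng.normal(size=(50, 4)),
            tilt=rng.normal(size=(50, 4)),
        )
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            fit_stiffness(traj)

    def test_warns_below_dim_plus_one_frames(self):
        # with fewer frames than dofs the covariance is rank-deficient, so
        # the conditioning warning is followed by the singularity error
        traj = sample_unrestrained(GeneratorSpec(n_steps=43, n_frames=100, seed=1))
        with pytest.warns(UserWarning, match="frames"):
            with pytest.raises(np.linalg.LinAlgError):
                fit_stiffness(traj)


class TestEnergyDecomposition:
    @pytest.fixture()
    def random_model(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(12, 12))
        k = a @ a.T + 12 * np.eye(12)
        cov = kbt(300.0) * np.linalg.inv(k)
        labels = tuple(f"{p}:{s}" for s in range(1, 5) for p in ("twist", "roll", "tilt"))
        return StiffnessModel(labels, rng.normal(size=12), cov, k, 300.0)

    def test_zero_displacement_gives_zero_everywhere(self, random_model):
        e = per_step_energy(random_model, random_model.mean[None, :])
        np.testing.assert_allclose(e, 0.0, atol=1e-15)

    def test_half_split_sums_exactly_to_quadratic_form(self, random_model):
        rng = np.random.default_rng(8)
        values = random_model.mean + rng.normal(size=(30, 12))
        total = random_model.energy(values)
        np.testing.assert_allclose(
            half_split_dof_energy(random_model, values).sum(axis=1), total, rtol=1e-12
        )
        np.testing.assert_allclose(
            per_step_energy(random_model, values).sum(axis=1), total, rtol=1e-12
        )

    def test_diagonal_stiffness_localizes_energy(self):
        k = np.diag(np.full(6, 2.0))
        cov = kbt(300.0) * np.linalg.inv(k)
        labels = tuple(f"{p}:{s}" for s in (1, 2) for p in ("twist", "roll", "tilt"))
        model = StiffnessModel(labels, np.zeros(6), cov, k, 300.0)
        dw = np.zeros((1, 6))
        dw[0, 4] = 1.5  # roll of step 2
        e = per_step_energy(model, dw)
        assert e[0, 0] == 0.0
        assert e[0, 1] == pytest.approx(0.5 * 2.0 * 1.5**2)


class TestEquipartition:
    def test_each_dof_holds_half_kbt_from_own_gaussian(self, default_traj, default_model):
        report = equipartition_report(default_traj, default_model)
        grand = report["mean_energy_kbt"].mean()
        se = report["mean_energy_kbt"].std() / np.sqrt(len(report))
        assert grand == pytest.approx(0.5, abs=max(3 * se, 0.01))

    def test_restraint_breaks_equipartition_between_unequal_oscillators(self):
        from torsionmelt import two_oscillator_demo

        res = two_oscillator_demo(k1=1.0, k2=4.0, restraint_k=2.0, n_frames=40_000, seed=2)
        assert abs(res.analytic_e1 - res.analytic_e2) > 0.1 * res.kbt
        # while the virial stays kBT for every coordinate
        np.testing.assert_allclose(res.sampled_virial, res.kbt, rtol=0.05)


class TestPersistenceLength:
    def test_direct_formula_evaluation(self):
        # contour 14.62 nm and cumulative-twist variance 0.132 rad^2
        n_steps = 43
        rise = np.full((2, n_steps), 3.4)
        # two frames at +/- d have sample variance 2 d^2 (ddof=1)
        d = np.degrees(np.sqrt(0.132 / 2.0))
        twist = np.full((2, n_steps), 34.5)
        twist[0, 0] += d
        twist[1, 0] -= d
        traj = HelicalTrajectory(
            twist=twist, roll=np.zeros((2, n_steps)), tilt=np.zeros((2, n_steps)),
            rise=rise,
        )
        est = twist_persistence_length(traj)
        assert est.contour_nm == pytest.approx(14.62)
        assert est.twist_variance_rad2 == pytest.approx(0.132, rel=1e-12)
        assert est.persistence_nm == pytest.approx(110.7576, abs=1e-3)

    def test_invariant_to_constant_twist_offset(self):
        traj = sample_unrestrained(GeneratorSpec(n_steps=6, n_frames=500, seed=4))
        p0 = twist_persistence_length(traj).persistence_nm
        shifted = HelicalTrajectory(
            twist=traj.twist + 5.0, roll=traj.roll, tilt=traj.tilt, rise=traj.rise
        )
        assert twist_persistence_length(shifted).persistence_nm == pytest.approx(p0)

    def test_doubling_twist_variance_halves_persistence(self):
        rng = np.random.default_rng(9)
        twist = rng.normal(34.5, 3.0, size=(4000, 5))
        rise = np.full_like(twist, 3.4)
        zeros = np.zeros_like(twist)
        base = HelicalTrajectory(twist=twist, roll=zeros, tilt=zeros, rise=rise)
        widened = HelicalTrajectory(
            twist=34.5 + np.sqrt(2) * (twist - 34.5), roll=zeros, tilt=zeros, rise=rise
        )
        assert twist_persistence_length(widened).persistence_nm == pytest.approx(
            twist_persistence_length(base).persistence_nm / 2
        )

    def test_recovers_the_generator_target(self):
        spec = GeneratorSpec(n_frames=100_000, seed=6)
        est = twist_persistence_length(sample_unrestrained(spec))
        a = spec.twist_selector()
        var_deg2 = float(a @ spec.covariance_matrix() @ a)
        p_analytic = (spec.n_steps * 0.34) / (var_deg2 * (np.pi / 180.0) ** 2)
        assert est.persistence_nm == pytest.approx(p_analytic, rel=0.05)
        assert 100.0 < p_analytic < 125.0  # realistic torsional stiffness regime


class TestCovarianceMap:
    def test_nearest_neighbour_model_shows_no_long_range_coupling(self, default_traj):
        cov = twist_covariance_map(default_traj)
        assert cov.shape == (43, 43)
        assert long_range_coupling_score(cov) < 0.05

    def test_global_restraint_induces_long_range_coupling(self, default_traj):
        restrained = sample_restrained(
            GeneratorSpec(n_frames=5000, seed=11, restraint_k=0.005,
                          target_total_twist=43 * 34.37 - 99.0)
        )
        s_free = long_range_coupling_score(twist_covariance_map(default_traj))
        s_res = long_range_coupling_score(twist_covariance_map(restrained))
        assert s_res > s_free

    def test_degenerate_frames_give_zero_map(self):
        row = np.linspace(30, 40, 5)
        traj = HelicalTrajectory(
            twist=np.tile(row, (3, 1)), roll=np.zeros((3, 5)), tilt=np.zeros((3, 5))
        )
        np.testing.assert_allclose(twist_covariance_map(traj), 0.0, atol=1e-12)


class TestCouplingScore:
    def test_identity_scores_zero(self):
        assert long_range_coupling_score(np.eye(6)) == 0.0

    def test_constant_correlation_scores_its_rho(self):
        c = np.full((8, 8), 0.5) + 0.5 * np.eye(8)
        assert long_range_coupling_score(c) == pytest.approx(0.5)

    def test_rejects_non_square_input(self):
        with pytest.raises(ValueError):
            long_range_coupling_score(np.ones((3, 4)))


def test_energy_series_profiles_and_block_errors(default_traj, default_model):
    series = elastic_energy_series(default_model, default_traj, n_blocks=10)
    assert series.energies.shape == (default_traj.n_frames, 43)
    np.testing.assert_allclose(
        series.mean_profile, series.energies.mean(axis=0), rtol=1e-12
    )
    assert series.smoothed_profile.shape == (43,)
    assert np.all(series.block_standard_errors >= 0)
    assert series.n_blocks == 10
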