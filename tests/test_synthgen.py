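import numpy as np
import pytest

from mechanotrace import (
    FixtureConfig,
    bell_rate,
    gen_harmonic_dimer,
    gen_ideal_gas,
    gen_membrane_protein_fixture,
    gen_pn_traces,
    gen_unbinding_times,
)
from mechanotrace.errors import InvalidParameterError, MinimumImageError
from mechanotrace.units import KT_BODY_PN_NM, PN_NM_PER_U_NM2_PS2


class TestIdealGas:
    def test_equipartition_mean_kinetic_energy(self):
        """Per-particle mean kinetic energy matches (3/2) kT within sampling error."""
        traj = gen_ideal_gas(2000, 310.15, (10, 10, 10), n_frames=60, seed=4)
        ke = []
        for f in traj:
            ke.append(0.5 * traj.topology.masses @ np.sum(f.velocities**2, axis=1))
        mean_ke = np.mean(ke) / traj.topology.n_particles * PN_NM_PER_U_NM2_PS2
        assert mean_ke == pytest.approx(1.5 * KT_BODY_PN_NM, rel=0.01)

    def test_zero_temperature_gives_zero_velocities(self):
        traj = gen_ideal_gas(100, 0.0, (5, 5, 5), seed=0)
        assert np.all(traj.frames[0].velocities == 0.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            gen_ideal_gas(0, 300.0, (5, 5, 5))
        with pytest.raises(InvalidParameterError):
            gen_ideal_gas(10, -1.0, (5, 5, 5))
        with pytest.raises(InvalidParameterError):
            gen_ideal_gas(10, 300.0, (5, -5, 5))

    def test_seeded_determinism(self):
        a = gen_ideal_gas(50, 300.0, (5, 5, 5), n_frames=3, seed=9)
        b = gen_ideal_gas(50, 300.0, (5, 5, 5), n_frames=3, seed=9)
        assert np.array_equal(a.positions_array(), b.positions_array())
        assert np.array_equal(a.frames[0].velocities, b.frames[0].velocities)


class TestHarmonicDimer:
    def test_minimum_image_ambiguity_rejected(self):
        with pytest.raises(MinimumImageError):
            gen_harmonic_dimer(separation=3.0, box=(5, 5, 5))

    def test_static_single_frame_with_zero_velocities(self, dimer):
        assert len(dimer) == 1
        assert np.all(dimer.frames[0].velocities == 0.0)
        d = dimer.frames[0].separation(0, 1)
        assert np.linalg.norm(d) == pytest.approx(1.5)


class TestFixture:
    def test_planted_counts_match_config(self, small_fixture):
        _, truth, config = small_fixture
        assert truth.n_tight() == config.n_tight == 10
        assert truth.n_short_inserted() == config.n_short_inserted == 8
        assert truth.hbond_counts == {"cytoplasmic": 40, "periplasmic": 21}

    def test_bound_intervals_within_span(self, small_fixture):
        _, truth, _ = small_fixture
        for ivals in truth.bound_intervals.values():
            for t0, t1 in ivals:
                assert 0.0 <= t0 <= t1 <= truth.span_ns

    def test_bound_lipid_pn_mean_near_median(self, small_fixture):
        traj, truth, config = small_fixture
        from mechanotrace import pn_distance_traces

        _, nearest = pn_distance_traces(traj)
        tight = [r for r, v in truth.tight.items() if v]
        pooled = np.concatenate([nearest[r] for r in tight])
        assert pooled.mean() == pytest.approx(config.pn_median, rel=0.01)

    def test_zero_planted_count_supported(self):
        config = FixtureConfig(n_tight=0, n_short_inserted=0, n_frames=5, lipids_per_leaflet=45)
        _, truth = gen_membrane_protein_fixture(config, seed=2)
        assert truth.n_tight() == 0

    def test_overfull_planting_rejected(self):
        with pytest.raises(InvalidParameterError):
            FixtureConfig(hbond_cytoplasmic=60, lipids_per_leaflet=50)
        with pytest.raises(InvalidParameterError):
            FixtureConfig(n_short_inserted=11)

    def test_seeded_determinism(self):
        config = FixtureConfig(n_frames=3)
        a, _ = gen_membrane_protein_fixture(config, seed=5)
        b, _ = gen_membrane_protein_fixture(config, seed=5)
        assert np.array_equal(a.positions_array(), b.positions_array())


class TestPNTraces:
    def test_full_occupancy_tiny_sigma_is_constant(self):
        traces = gen_pn_traces(n_traces=2, sigma=1e-12, occupancy=1.0, n_frames=500, seed=0)
        assert np.allclose(traces.distances, 0.4)
        assert traces.bound.all()

    def test_zero_occupancy_never_within_bond_range(self):
        traces = gen_pn_traces(n_traces=3, occupancy=0.0, n_frames=2000, seed=1)
        assert not traces.bound.any()
        assert traces.distances.min() > 0.35

    def test_pooled_fwhm_matches_gaussian_width(self):
        """50k bound frames give FWHM = 2 sqrt(2 ln 2) sigma ~ 26 pm."""
        from mechanotrace import distribution_fwhm

        traces = gen_pn_traces(n_traces=1, occupancy=1.0, n_frames=50_000, seed=1)
        fwhm_pm = distribution_fwhm(traces.pooled_bound_distances()) * 1e3
        assert fwhm_pm == pytest.approx(26.0, abs=1.0)

    def test_partial_occupancy_mixes_states(self):
        traces = gen_pn_traces(n_traces=4, occupancy=0.5, n_frames=20_000, seed=3)
        frac = traces.bound.mean()
        assert 0.4 < frac < 0.6


class TestUnbindingTimes:
    def test_rate_closed_forms(self):
        """Bell-law rates at the tabulated pulling forces."""
        assert bell_rate(910.0, 441.0, 35.0, 310.15) == pytest.approx(3.86, rel=0.01)
        assert bell_rate(530.0, 441.0, 35.0, 310.15) == pytest.approx(0.172, rel=0.01)
        # exponent at 910 pN
        assert 910.0 * 35.0e-3 / KT_BODY_PN_NM == pytest.approx(7.44, abs=0.01)

    def test_zero_force_sample_mean_is_tau0(self):
        ds = gen_unbinding_times(forces=[0.0], tau0=10.0, xbeta=35.0, n_lipids=100, n_reps=10, seed=6)[0]
        se = ds.times.std(ddof=1) / np.sqrt(len(ds.times))
        assert abs(ds.times.mean() - 10.0) <= 3 * se

    @pytest.mark.parametrize("force", [530.0, 910.0])
    def test_sample_mean_within_three_se_of_inverse_rate(self, force):
        ds = gen_unbinding_times(forces=[force], n_lipids=100, n_reps=10, seed=8)[0]
        k = bell_rate(force, 441.0, 35.0, 310.15)
        se = ds.times.std(ddof=1) / np.sqrt(len(ds.times))
        assert abs(ds.times.mean() - 1.0 / k) <= 3 * se

    def test_negative_force_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_unbinding_times(forces=[-10.0])
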