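import numpy as np
import pytest

from mechanotrace import (
    Frame,
    HBondCriteria,
    Topology,
    Trajectory,
    classify_tightly_bound,
    com_distance_variance,
    count_hbonded_lipids_by_side,
    detect_hbonds,
    detect_unbinding_events,
    distribution_fwhm,
    lipid_volumes,
    pn_distance_traces,
    pore_diameter,
)
from mechanotrace.errors import InvalidParameterError


def _topo(roles, elements, sides=None, resids=None, monomers=None, radii=None, **kw):
    n = len(roles)
    return Topology(
        masses=np.ones(n),
        radii=np.zeros(n) if radii is None else np.asarray(radii, float),
        elements=np.asarray(elements),
        resids=np.arange(n) if resids is None else np.asarray(resids),
        monomers=np.full(n, -1) if monomers is None else np.asarray(monomers),
        sides=np.full(n, "none") if sides is None else np.asarray(sides),
        roles=np.asarray(roles),
        **kw,
    )


class TestPNDistanceTraces:
    def test_static_pair_constant_distance(self):
        topo = _topo(["lipid-head-P", "lysine-N"], ["P", "N"], resids=[1, 0])
        frame = Frame(0.0, [[0, 0, 0], [0, 0, 0.4]], box=[5, 5, 5])
        traces, nearest = pn_distance_traces(Trajectory(topo, [frame, Frame(1.0, [[0, 0, 0], [0, 0, 0.4]], box=[5, 5, 5])]))
        assert np.allclose(traces[0].distances, 0.4)
        assert np.allclose(nearest[1], 0.4)

    def test_minimum_image_across_boundary(self):
        topo = _topo(["lipid-head-P", "lysine-N"], ["P", "N"], resids=[1, 0])
        frame = Frame(0.0, [[0.1, 0, 0], [4.9, 0, 0]], box=[5, 5, 5])
        _, nearest = pn_distance_traces(Trajectory(topo, [frame]))
        assert nearest[1][0] == pytest.approx(0.2)

    def test_empty_selection_rejected(self):
        topo = _topo(["lipid-head-P", "lipid-head-P"], ["P", "P"], resids=[1, 2])
        frame = Frame(0.0, np.zeros((2, 3)), box=[5, 5, 5])
        with pytest.raises(InvalidParameterError):
            pn_distance_traces(Trajectory(topo, [frame]))

    def test_fixture_bound_lipids_average_point_four(self, small_fixture):
        traj, truth, config = small_fixture
        _, nearest = pn_distance_traces(traj)
        for rid, tight in truth.tight.items():
            if tight:
                assert nearest[rid].mean() == pytest.approx(0.4, abs=0.01)


class TestDetectHbonds:
    def _geometry(self, d):
        topo = _topo(
            ["lysine-N", "lipid-head-N-acceptor-O"], ["N", "O"],
            sides=["cytoplasmic", "cytoplasmic"], resids=[0, 7],
        )
        frame = Frame(0.0, [[1, 1, 1], [1, 1, 1 + d]], box=[5, 5, 5])
        return frame, topo

    def test_within_cutoff_detected(self):
        frame, topo = self._geometry(0.30)
        bonds = detect_hbonds(frame, topo)
        assert len(bonds) == 1 and bonds[0].is_lysine and bonds[0].lipid_resid == 7

    def test_beyond_cutoff_not_detected(self):
        frame, topo = self._geometry(0.40)
        assert detect_hbonds(frame, topo) == []

    def test_clamp_flag_for_double_oxygen_bond(self):
        topo = _topo(
            ["lysine-N", "lipid-head-N-acceptor-O", "lipid-head-N-acceptor-O"],
            ["N", "O", "O"], sides=["cytoplasmic"] * 3, resids=[0, 7, 7],
        )
        frame = Frame(0.0, [[1, 1, 1], [1, 1, 1.3], [1, 1.3, 1]], box=[5, 5, 5])
        bonds = detect_hbonds(frame, topo)
        assert len(bonds) == 2 and all(b.clamp for b in bonds)

    def test_angle_criterion_applies_with_explicit_hydrogens(self):
        # donor N with one H pointing at the acceptor (angle ~0) vs away (angle 180)
        topo = _topo(
            ["lysine-N", "solvent", "lipid-head-N-acceptor-O"], ["N", "H", "O"],
            sides=["cytoplasmic", "none", "cytoplasmic"], resids=[0, 0, 7],
            bonds=[[0, 1]], bond_k=[1.0], bond_r0=[0.1],
        )
        toward = Frame(0.0, [[1, 1, 1], [1, 1, 1.1], [1, 1, 1.3]], box=[5, 5, 5])
        away = Frame(0.0, [[1, 1, 1], [1, 1, 0.9], [1, 1, 1.3]], box=[5, 5, 5])
        assert len(detect_hbonds(toward, topo)) == 1
        assert detect_hbonds(away, topo) == []


class TestCensus:
    def test_fixture_recovers_planted_counts(self, small_fixture):
        traj, truth, _ = small_fixture
        df, summary = count_hbonded_lipids_by_side(traj)
        assert summary["mean_cytoplasmic"] == pytest.approx(40, rel=0.05)
        assert summary["mean_periplasmic"] == pytest.approx(21, rel=0.05)
        assert summary["lysine_mediated_fraction"] == pytest.approx(0.85, abs=0.02)

    def test_counts_zero_when_nothing_in_range(self):
        topo = _topo(
            ["lysine-N", "lipid-head-N-acceptor-O"], ["N", "O"],
            sides=["cytoplasmic", "periplasmic"], resids=[0, 7],
        )
        frame = Frame(0.0, [[1, 1, 1], [3, 3, 3]], box=[8, 8, 8])
        df, summary = count_hbonded_lipids_by_side(Trajectory(topo, [frame]))
        assert summary["mean_cytoplasmic"] == 0 and summary["mean_periplasmic"] == 0

    def test_particle_order_invariance(self, small_fixture):
        traj, _, _ = small_fixture
        sub = Trajectory(traj.topology, traj.frames[:5], traj.frame_spacing)
        _, s1 = count_hbonded_lipids_by_side(sub)
        perm = np.random.default_rng(0).permutation(traj.topology.n_particles)
        topo = traj.topology
        topo2 = Topology(
            masses=topo.masses[perm], radii=topo.radii[perm], elements=topo.elements[perm],
            resids=topo.resids[perm], monomers=topo.monomers[perm], sides=topo.sides[perm],
            roles=topo.roles[perm],
        )
        frames2 = [Frame(f.time, f.positions[perm], f.box) for f in traj.frames[:5]]
        _, s2 = count_hbonded_lipids_by_side(Trajectory(topo2, frames2))
        assert s1 == s2


class TestClassifier:
    def test_fixture_recovery_and_tail_identity(self, small_fixture):
        traj, truth, config = small_fixture
        records = classify_tightly_bound(traj)
        assert len(records) == config.n_tight
        by_monomer = {}
        for r in records:
            by_monomer[r.monomer] = by_monomer.get(r.monomer, 0) + 1
        assert all(v == 2 for v in by_monomer.values())
        assert sum(r.inserted_tail == "short" for r in records) == config.n_short_inserted
        for r in records:
            assert truth.tight[r.lipid_resid]
            assert truth.inserted_tail[r.lipid_resid] == r.inserted_tail

    def test_occupancy_below_threshold_excluded(self, small_fixture):
        traj, _, config = small_fixture
        # demanding full occupancy of the insertion keeps the planted lipids;
        # an impossible threshold excludes everything
        assert len(classify_tightly_bound(traj, occupancy_threshold=1.0)) == config.n_tight
        with pytest.raises(InvalidParameterError):
            classify_tightly_bound(traj, occupancy_threshold=1.5)

    def test_planted_recovery_across_seeds(self):
        """Sensitivity and specificity >= 0.95 over several fixture seeds."""
        from mechanotrace import FixtureConfig, gen_membrane_protein_fixture

        config = FixtureConfig(n_frames=60)
        sens, spec = [], []
        for seed in range(1, 6):
            traj, truth = gen_membrane_protein_fixture(config, seed=seed)
            found = {r.lipid_resid for r in classify_tightly_bound(traj)}
            planted = {r for r, t in truth.tight.items() if t}
            others = set(truth.lipid_resids) - planted
            sens.append(len(found & planted) / len(planted))
            spec.append(1 - len(found & others) / len(others))
        assert min(sens) >= 0.95 and min(spec) >= 0.95


class TestLipidVolumes:
    def test_single_particle_owns_whole_box(self):
        topo = _topo(["solvent"], ["C"], resids=[3], radii=[0.2])
        frame = Frame(0.0, [[2.5, 2.5, 2.5]], box=[5, 5, 5])
        vols = lipid_volumes(frame, topo, resolution=0.25)
        assert vols[3] == pytest.approx(125.0)

    def test_symmetric_pair_splits_evenly(self):
        topo = _topo(["solvent", "solvent"], ["C", "C"], resids=[0, 1], radii=[0.2, 0.2])
        frame = Frame(0.0, [[1.25, 2.5, 2.5], [3.75, 2.5, 2.5]], box=[5, 5, 5])
        vols = lipid_volumes(frame, topo, resolution=0.125)
        sample = 0.125**3
        assert abs(vols[0] - 62.5) <= 62.5 * 1e-6 + sample
        assert vols[0] + vols[1] == pytest.approx(125.0)

    def test_power_bisector_position(self):
        # d=1, r1^2 - r2^2 = 0.2 -> plane at (d^2 + r1^2 - r2^2)/(2d) = 0.6 from particle 1
        r1, r2 = np.sqrt(0.3), np.sqrt(0.1)
        topo = _topo(["solvent", "solvent"], ["C", "C"], resids=[0, 1], radii=[r1, r2])
        frame = Frame(0.0, [[2.0, 2.5, 2.5], [3.0, 2.5, 2.5]], box=[5, 5, 5])
        vols = lipid_volumes(frame, topo, resolution=0.05)
        # bisector between the particles at x = 2.0 + 0.6 = 2.6; through the
        # periodic image (d = 4) the far bisector sits at x = -0.025, so
        # particle 0 owns a slab of width 2.625 of the 5 nm axis
        frac0 = vols[0] / 125.0
        assert frac0 == pytest.approx(2.625 / 5.0, abs=0.05 / 5.0 + 1e-9)

    def test_volume_conservation_on_fixture(self, small_fixture):
        traj, _, _ = small_fixture
        vols = lipid_volumes(traj.frames[0], traj.topology, resolution=0.2)
        box_volume = float(np.prod(traj.frames[0].box))
        assert vols.sum() == pytest.approx(box_volume, rel=1e-12)


class TestMobilityAndWidths:
    def test_static_trajectory_zero_variance(self):
        topo = _topo(
            ["protein", "lipid-head-P"], ["C", "P"], resids=[0, 1],
        )
        frames = [Frame(float(t), [[1, 1, 1], [3, 1, 1]], box=[6, 6, 6]) for t in range(4)]
        var = com_distance_variance(Trajectory(topo, frames), np.array([0]))
        assert var[1] == 0.0

    def test_iid_fluctuations_recover_spread(self, rng):
        s = 0.3
        topo = _topo(["protein", "lipid-head-P"], ["C", "P"], resids=[0, 1])
        frames = [
            Frame(float(t), [[3, 3, 3], [3 + 2.0 + rng.normal(0, s), 3, 3]], box=[10, 10, 10])
            for t in range(4000)
        ]
        var = com_distance_variance(Trajectory(topo, frames), np.array([0]))
        assert var[1] == pytest.approx(s**2, rel=0.1)

    def test_random_walker_exceeds_bound_lipid(self, rng):
        topo = _topo(["protein", "lipid-head-P", "lipid-head-P"], ["C", "P", "P"], resids=[0, 1, 2])
        walk = 2.0 + np.cumsum(rng.normal(0, 0.05, 500))
        frames = [
            Frame(float(t), [[5, 5, 5], [5 + 2.0 + rng.normal(0, 0.02), 5, 5], [5 + walk[t], 5, 5]], box=[30, 30, 30])
            for t in range(500)
        ]
        var = com_distance_variance(Trajectory(topo, frames), np.array([0]))
        assert var[2] > var[1]

    def test_single_frame_variance_rejected(self):
        topo = _topo(["protein", "lipid-head-P"], ["C", "P"], resids=[0, 1])
        traj = Trajectory(topo, [Frame(0.0, [[1, 1, 1], [2, 1, 1]], box=[5, 5, 5])])
        with pytest.raises(InvalidParameterError):
            com_distance_variance(traj, np.array([0]))

    def test_fwhm_gaussian_and_degenerate(self, rng):
        samples = rng.normal(0.4, 0.01104, 50_000)
        assert distribution_fwhm(samples) * 1e3 == pytest.approx(26.0, abs=1.0)
        assert distribution_fwhm(np.full(500, 0.4)) == 0.0
        with pytest.raises(InvalidParameterError):
            distribution_fwhm(np.arange(10))

    def test_fwhm_triangular_closed_form(self, rng):
        a = 2.0
        samples = rng.triangular(-a, 0, a, 100_000)
        assert distribution_fwhm(samples) == pytest.approx(a, rel=0.05)

    def test_fwhm_bias_small_across_widths(self, rng):
        for sigma_pm in (5.0, 20.0, 50.0):
            samples = rng.normal(0, sigma_pm, 10_000)
            expected = 2 * np.sqrt(2 * np.log(2)) * sigma_pm
            assert abs(distribution_fwhm(samples) - expected) / expected <= 0.04


class TestPoreDiameter:
    def _ring(self, pts):
        topo = _topo(["protein"] * 5, ["C"] * 5, monomers=np.arange(5))
        frame = Frame(0.0, pts, box=[10, 10, 10])
        return frame, topo

    def test_regular_ring_diameter(self):
        ang = 2 * np.pi * np.arange(5) / 5
        pts = np.column_stack([5 + np.cos(ang), 5 + np.sin(ang), np.full(5, 5.0)])
        frame, topo = self._ring(pts)
        assert pore_diameter(frame, np.arange(5), topo) == pytest.approx(2.0)

    def test_coincident_points_give_zero(self):
        frame, topo = self._ring(np.tile([5.0, 5.0, 5.0], (5, 1)))
        assert pore_diameter(frame, np.arange(5), topo) == 0.0

    def test_displaced_vertex_increases_by_two_fifths_delta(self):
        ang = 2 * np.pi * np.arange(5) / 5
        delta = 0.05
        radii = np.array([1 + delta] + [1.0] * 4)
        pts = np.column_stack([5 + radii * np.cos(ang), 5 + radii * np.sin(ang), np.full(5, 5.0)])
        frame, topo = self._ring(pts)
        base = 2.0
        assert pore_diameter(frame, np.arange(5), topo) - base == pytest.approx(2 * delta / 5, rel=0.05)

    def test_wrong_site_count_rejected(self):
        ang = 2 * np.pi * np.arange(5) / 5
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(5)]) + 5
        frame, topo = self._ring(pts)
        with pytest.raises(InvalidParameterError):
            pore_diameter(frame, np.arange(4), topo)


class TestUnbindingDetection:
    def test_step_trace_event_at_jump(self):
        times = np.arange(0, 4000, 10.0)  # ps
        d = np.where(times < 2000, 3.0, 6.0)
        assert detect_unbinding_events(d, times, jump_threshold=1.0) == pytest.approx(2.0)

    def test_flat_trace_censored(self):
        times = np.arange(0, 1000, 10.0)
        assert detect_unbinding_events(np.full_like(times, 3.0), times) is None

    def test_short_spike_ignored_under_persistence(self):
        times = np.arange(0, 2000, 10.0)
        d = np.full_like(times, 3.0)
        spike = (times >= 1000) & (times < 1050)  # 50 ps spike
        d[spike] = 6.0
        assert detect_unbinding_events(d, times, persistence_ps=100.0) is None
        d2 = np.where(times >= 1000, 6.0, 3.0)
        assert detect_unbinding_events(d2, times, persistence_ps=100.0) == pytest.approx(1.0)
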