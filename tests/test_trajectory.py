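"""Trajectory-metric tests: minimum distances, dissociation classifier,
MSD/diffusion, radial density and hydrogen bonds."""

import numpy as np
import pytest

from gelmesh.geometry import brute_force_min_image_distance
from gelmesh.synthetic import (gen_brownian, gen_dissociation_scenario,
                               gen_hbond_triplet)
from gelmesh.trajectory import (DiffusionEstimate, EmptySelectionError,
                                HBondTopologyError, MsdCurve, Trajectory,
                                UndefinedFractionError, WrapAmbiguityError,
                                dissociated_fraction, fit_diffusion,
                                hydrogen_bonds, hydrogen_bonds_frame,
                                min_distance_series, msd, radial_density)


def _toy_traj(drug_frames, polymer_xyz=(50.0, 50.0, 50.0), box=100.0):
    """One single-atom drug molecule + one polymer atom."""
    frames = np.asarray(drug_frames, float)
    n = len(frames)
    coords = np.stack([np.vstack([f, polymer_xyz]) for f in frames])
    return Trajectory(times=np.arange(n, dtype=float),
                      coordinates=coords, boxes=np.full((n, 3), box),
                      groups={"drug": np.array([0]), "polymer": np.array([1])},
                      mol_ids=np.array([0, 1]))


class TestMinDistanceSeries:
    def test_constant_distance(self):
        traj = _toy_traj([(54.0, 50, 50)] * 3)
        series = min_distance_series(traj)
        assert series == pytest.approx(np.full((1, 3), 4.0))

    def test_two_frame_toy(self):
        traj = _toy_traj([(53.0, 50, 50), (57.0, 50, 50)])
        series = min_distance_series(traj)
        assert series.ravel() == pytest.approx([3.0, 7.0])
        assert series.mean() == pytest.approx(5.0)

    def test_periodic_boundary_matches_brute_force(self):
        rng = np.random.default_rng(11)
        box = 15.0
        n_frames, n_drug, n_poly = 3, 4, 20
        coords = rng.uniform(-5, 20, size=(n_frames, n_drug + n_poly, 3))
        traj = Trajectory(times=np.arange(n_frames, dtype=float),
                          coordinates=coords, boxes=np.full((n_frames, 3), box),
                          groups={"drug": np.arange(n_drug),
                                  "polymer": np.arange(n_drug, n_drug + n_poly)},
                          mol_ids=np.concatenate([np.arange(n_drug),
                                                  np.full(n_poly, n_drug)]))
        series = min_distance_series(traj)
        for k in range(n_frames):
            for m in range(n_drug):
                brute = min(brute_force_min_image_distance(
                    coords[k, m], coords[k, j], np.full(3, box))
                    for j in range(n_drug, n_drug + n_poly))
                assert series[m, k] == pytest.approx(brute, abs=1e-9)

    def test_empty_group_raises(self):
        traj = _toy_traj([(54.0, 50, 50)])
        traj.groups["polymer"] = np.array([], int)
        with pytest.raises(EmptySelectionError):
            min_distance_series(traj)


class TestDissociatedFraction:
    @pytest.mark.parametrize("n_free, expected", [(11, 22.0), (0, 0.0), (6, 12.0)])
    def test_constructed_scenarios(self, n_free, expected):
        traj = gen_dissociation_scenario(n_total=50, n_free=n_free, seed=2)
        frac, labels = dissociated_fraction(traj, cutoff=5.0)
        assert frac == expected
        assert (labels == traj.ground_truth["labels"]).all()

    def test_exactly_at_cutoff_counts_as_associated(self):
        traj = gen_dissociation_scenario(n_total=10, n_free=5, margin=0.0, seed=3)
        frac, _ = dissociated_fraction(traj, cutoff=5.0)
        assert frac == 0.0

    def test_no_drug_raises(self):
        traj = _toy_traj([(54.0, 50, 50)])
        traj.groups["drug"] = np.array([], int)
        with pytest.raises(UndefinedFractionError):
            dissociated_fraction(traj)

    @pytest.mark.parametrize("seed", range(4))
    def test_granularity_is_two_percent_at_fifty_molecules(self, seed):
        rng = np.random.default_rng(seed)
        traj = gen_dissociation_scenario(n_total=50, n_free=int(rng.integers(0, 51)),
                                         seed=seed)
        frac, _ = dissociated_fraction(traj, cutoff=5.0)
        assert frac % 2.0 == 0.0


class TestMsd:
    def test_stationary_particles_have_zero_msd(self):
        traj = gen_brownian(0.0, n_mol=5, n_steps=50, seed=0)
        curve = msd(traj)
        assert curve.msd == pytest.approx(np.zeros_like(curve.msd), abs=1e-8)
        assert abs(curve.msd[0]) < 1e-8

    def test_ballistic_motion_is_quadratic(self):
        n, v = 41, 0.3
        t = np.arange(n, dtype=float)
        coords = np.zeros((n, 2, 3))
        coords[:, 0, 0] = v * t
        coords[:, 1, :] = 5.0  # static decoy
        traj = Trajectory(times=t, coordinates=coords, boxes=np.full((n, 3), 100.0),
                          groups={"drug": np.array([0]), "polymer": np.array([1])},
                          mol_ids=np.array([0, 1]), unwrapped=True)
        curve = msd(traj, max_lag=t[-1])
        assert curve.msd == pytest.approx((v * curve.lags) ** 2, rel=1e-9)

    def test_brownian_msd_tracks_einstein_line(self):
        d_gen = 2.0
        traj = gen_brownian(d_gen, n_mol=100, dt=1.0, n_steps=2000, seed=4)
        curve = msd(traj)
        # compare at moderate lags where thousands of origins average;
        # relative sampling error ~ sqrt(2/3 * lag/(n_mol*span)) < 4%
        sel = (curve.lags >= 100) & (curve.lags <= 500)
        expected = 6.0 * d_gen * 1e-3 * curve.lags[sel]
        assert np.abs(curve.msd[sel] / expected - 1).max() < 0.12

    def test_wrapped_coordinates_rejected(self):
        traj = gen_dissociation_scenario(n_total=5, n_free=1, seed=0)
        with pytest.raises(WrapAmbiguityError):
            msd(traj)

    def test_origin_stride_agrees_with_fft_route(self):
        traj = gen_brownian(1.0, n_mol=3, n_steps=40, seed=1)
        fft_curve = msd(traj, max_lag=20.0)
        naive = msd(traj, max_lag=20.0, origin_stride=1)
        # origin_stride=1 uses the same estimator; explicit strided loop:
        strided = msd(traj, max_lag=20.0, origin_stride=2)
        assert fft_curve.msd == pytest.approx(naive.msd)
        assert strided.msd[0] == 0.0
        assert strided.n_origins[0] == 21


class TestFitDiffusion:
    def test_exact_einstein_line_recovers_d(self):
        lags = np.arange(101, dtype=float)
        d_true = 0.92  # 1e-7 cm^2/s -> slope 6 * 0.92e-3 Å^2/ps
        curve = MsdCurve(lags=lags, msd=6.0 * d_true * 1e-3 * lags,
                         n_origins=np.full(101, 100))
        est = fit_diffusion(curve)
        assert est.D == pytest.approx(d_true, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_flat_curve_gives_zero(self):
        curve = MsdCurve(lags=np.arange(20.0), msd=np.full(20, 3.0),
                         n_origins=np.full(20, 10))
        est = fit_diffusion(curve, window=(0.0, 19.0))
        assert est.D == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_slope_conversion(self):
        # slope 6 Å^2/ps across lags 0,1,2 -> D = 1 Å^2/ps = 1000e-7 cm^2/s
        curve = MsdCurve(lags=np.array([0.0, 1.0, 2.0]),
                         msd=np.array([0.0, 6.0, 12.0]),
                         n_origins=np.array([3, 2, 1]))
        est = fit_diffusion(curve, window=(0.0, 2.0))
        assert est.slope == pytest.approx(6.0)
        assert est.D == pytest.approx(1000.0)

    def test_negative_slope_warns(self):
        curve = MsdCurve(lags=np.arange(10.0), msd=-np.arange(10.0),
                         n_origins=np.full(10, 5))
        with pytest.warns(UserWarning):
            est = fit_diffusion(curve, window=(0.0, 9.0))
        assert est.D < 0


class TestRigidMotionInvariance:
    def test_msd_invariant_under_global_rotation_translation(self):
        traj = gen_brownian(1.5, n_mol=4, n_steps=60, seed=6)
        base = msd(traj)
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
        moved = Trajectory(times=traj.times,
                           coordinates=traj.coordinates @ rot.T + 7.0,
                           boxes=traj.boxes, groups=traj.groups,
                           mol_ids=traj.mol_ids, unwrapped=True)
        assert msd(moved).msd == pytest.approx(base.msd, rel=1e-6, abs=1e-8)


class TestRadialDensity:
    def test_single_radius_occupies_one_bin(self):
        traj = gen_dissociation_scenario(n_total=20, n_free=0, margin=1.0,
                                         n_frames=3, seed=1)
        # molecules sit at 4 ± 0.25 Å; a 3 Å bin catches them all in [3, 6)
        rd = radial_density(traj, bin_width=3.0, window=(0.0, traj.times[-1]))
        occupied = np.flatnonzero(rd.counts > 0)
        assert len(occupied) == 1
        assert rd.bin_edges[occupied[0]] == 3.0

    def test_counts_conserve_drug_molecules(self):
        traj = gen_dissociation_scenario(n_total=30, n_free=10, n_frames=5, seed=2)
        rd = radial_density(traj, bin_width=0.5, window=(0.0, traj.times[-1]))
        assert rd.counts.sum() == pytest.approx(30.0)

    def test_uniform_shell_density_is_flat(self):
        rng = np.random.default_rng(8)
        n = 4000
        r = (rng.uniform(10.0 ** 3, 20.0 ** 3, n)) ** (1 / 3)  # uniform in shell
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = (50.0 + r[:, None] * dirs)[None]
        coords = np.concatenate([coords, np.full((1, 1, 3), 50.0)], axis=1)
        traj = Trajectory(times=[0.0], coordinates=coords,
                          boxes=np.full((1, 3), 100.0),
                          groups={"drug": np.arange(n), "polymer": np.array([n])},
                          mol_ids=np.concatenate([np.arange(n), [n]]))
        rd = radial_density(traj, bin_width=2.0, window=(0.0, 0.0))
        shell_bins = (rd.bin_edges[:-1] >= 10.0) & (rd.bin_edges[1:] <= 20.0)
        dens = rd.density[shell_bins]
        expected = n / (4 / 3 * np.pi * (20.0 ** 3 - 10.0 ** 3))
        # Poisson error: each bin holds ~n/5 molecules -> rel sd ~ 3.5%
        assert np.abs(dens / expected - 1).max() < 0.15


class TestHydrogenBonds:
    @pytest.mark.parametrize("dDA, angle, expected", [
        (2.9, 10.0, 1),
        (2.9, 40.0, 0),   # just beyond the angular cutoff
        (3.6, 10.0, 0),   # beyond the distance cutoff
        (3.5, 35.0, 1),   # closed boundary on both criteria
        (2.9, 90.0, 0),
    ])
    def test_geometric_criteria(self, dDA, angle, expected):
        pos, box, topo = gen_hbond_triplet(dDA, angle)
        counts = hydrogen_bonds_frame(pos, box, topo["donors"], topo["hydrogens"],
                                      topo["donor_of_hydrogen"], topo["acceptors"])
        assert counts.get("all", 0) == expected

    def test_orphan_hydrogen_raises(self):
        pos, box, topo = gen_hbond_triplet(2.9, 10.0)
        with pytest.raises(HBondTopologyError):
            hydrogen_bonds_frame(pos, box, topo["donors"], topo["hydrogens"],
                                 {}, topo["acceptors"])

    def test_categorized_counts_over_trajectory(self):
        pos, box, topo = gen_hbond_triplet(2.9, 10.0)
        coords = np.repeat(pos[None], 3, axis=0)
        traj = Trajectory(times=np.arange(3, dtype=float), coordinates=coords,
                          boxes=np.tile(box, (3, 1)),
                          groups={"polymer": np.array([0, 1]), "drug": np.array([2])},
                          mol_ids=np.array([0, 0, 1]),
                          hbond_topology=topo)
        res = hydrogen_bonds(traj, window=(0.0, 2.0))
        assert res.counts == {"polymer-drug": 1.0}
        assert res.per_frame["polymer-drug"].tolist() == [1.0, 1.0, 1.0]
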