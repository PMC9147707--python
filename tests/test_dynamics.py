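"""Local diffusion estimator, block filter, site merging, residence times."""

import numpy as np
import pytest

from ionatmos.core import TrajectoryEnsemble
from ionatmos.dynamics import (
    DiffusionMap,
    block_consistency_filter,
    local_diffusion_map,
    merge_sites,
    residence_times,
)
from ionatmos.geometry import GridSpec
from ionatmos.synthetic import (
    SlabMobility,
    SyntheticScene,
    free_scene,
    simulate_ion_cloud,
)

from conftest import make_static_traj, single_cylinder_scene


def brownian_traj(rng, D, n_ions, n_frames, box, dt=1.0):
    steps = rng.normal(0, np.sqrt(2 * D * dt), (n_frames - 1, n_ions, 3))
    start = rng.uniform(0, 1, (1, n_ions, 3)) * np.asarray(box)
    path = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    return TrajectoryEnsemble(np.mod(path, box), np.asarray(box, float), dt,
                              {"na": np.arange(n_ions)})


class TestLocalDiffusionMap:
    def test_frozen_ion_gives_zero(self):
        box = (10.0, 10.0, 10.0)
        traj = make_static_traj([[5.0, 5.0, 5.0]], box, dt=1.0, n_frames=30,
                                groups={"na": np.array([0])})
        grid = GridSpec((5.0, 5.0, 5.0), 1.0, (1, 1, 1), box)
        dm = local_diffusion_map(traj, "na", grid, min_events=1)
        assert dm.D[0] == 0.0
        assert dm.n_events[0] == 28

    def test_uniform_brownian_median_recovery(self, rng):
        D = 0.15
        traj = brownian_traj(rng, D, 150, 8000, (15.0, 15.0, 15.0))
        grid = GridSpec((4.0, 4.0, 4.0), 2.0, (4, 4, 4), (15.0, 15.0, 15.0))
        dm = local_diffusion_map(traj, "na", grid)
        med = np.nanmedian(dm.D[dm.reported])
        assert abs(med - D) / D < 0.10

    def test_two_zone_ordering_preserved(self):
        box = (24.0, 12.0, 12.0)
        sc = SyntheticScene(
            box_lengths=box, cylinder_centers=(0.0, 0.0), cylinder_radius=0.0,
            surface_charge_positions=np.zeros((0, 3)),
            surface_charges=np.zeros(0), ion_counts={"na": 150},
            mobility_map=SlabMobility(6.0, 4.0, 0.06, 0.21, smoothing=1.0),
            frame_interval=1.0, n_frames=4000, seed=5,
        )
        traj = simulate_ion_cloud(sc)
        slow = GridSpec((4.0, 4.0, 4.0), 2.0, (3, 3, 3), box)
        fast = GridSpec((16.0, 4.0, 4.0), 2.0, (3, 3, 3), box)
        dslow = local_diffusion_map(traj, "na", slow)
        dfast = local_diffusion_map(traj, "na", fast)
        assert dslow.reported.all() and dfast.reported.all()
        assert np.nanmax(dslow.D) < np.nanmin(dfast.D)

    @pytest.mark.parametrize("D", [0.05, 0.1, 0.2])
    def test_estimator_unbiased_on_force_free_motion(self, D):
        rng = np.random.default_rng(int(D * 1000))
        traj = brownian_traj(rng, D, 200, 3000, (12.0, 12.0, 12.0))
        grid = GridSpec((6.0, 6.0, 6.0), 1.0, (1, 1, 1), (12.0, 12.0, 12.0))
        # unbiasedness holds for any t1 < t2 commensurate with the frames
        dm = local_diffusion_map(traj, "na", grid, t1=1.0, t2=3.0)
        n = dm.n_events[0]
        se = np.sqrt(2.0 * 1.8 / n) * D  # conservative overlap-corrected SE
        assert abs(dm.D[0] - D) < 4 * se

    def test_time_rescaling_invariance(self, rng):
        traj = brownian_traj(rng, 0.1, 50, 2000, (10.0, 10.0, 10.0))
        grid = GridSpec((5.0, 5.0, 5.0), 1.0, (1, 1, 1), (10.0, 10.0, 10.0))
        d1 = local_diffusion_map(traj, "na", grid)
        slow = TrajectoryEnsemble(traj.positions, traj.box, traj.dt * 2,
                                  traj.groups)
        d2 = local_diffusion_map(slow, "na", grid, t1=2.0, t2=4.0)
        assert d2.D[0] == pytest.approx(d1.D[0] / 2.0, rel=1e-12)

    def test_coarse_frames_rejected(self, rng):
        traj = brownian_traj(rng, 0.1, 5, 50, (10.0, 10.0, 10.0), dt=2.0)
        grid = GridSpec.from_box((10.0, 10.0, 10.0), 2.0)
        with pytest.raises(ValueError, match="coarser"):
            local_diffusion_map(traj, "na", grid)

    def test_abs_mode_per_event_biases_upward(self, rng):
        traj = brownian_traj(rng, 0.1, 100, 1500, (10.0, 10.0, 10.0))
        grid = GridSpec((5.0, 5.0, 5.0), 1.0, (1, 1, 1), (10.0, 10.0, 10.0))
        of_mean = local_diffusion_map(traj, "na", grid, abs_mode="of_mean")
        per_event = local_diffusion_map(traj, "na", grid, abs_mode="per_event")
        assert per_event.D[0] > of_mean.D[0]


def fake_map(grid, occupied, value=0.1):
    n = grid.n_points
    events = np.where(occupied, 5, 0)
    D = np.where(occupied, value, np.nan)
    return DiffusionMap(grid, D, events)


class TestBlockFilter:
    def setup_method(self):
        self.grid = GridSpec.from_box((6.0, 6.0, 6.0), 1.0)

    def test_exact_retention_thresholds(self):
        n = self.grid.n_points
        occ9 = np.ones(n, bool)
        occ6 = np.zeros(n, bool)
        maps = []
        for k in range(9):
            occupied = occ9 if k < 6 else occ6
            # point 0 occupied in all nine, point 1 in exactly six
            occ = np.zeros(n, bool)
            occ[0] = True
            occ[1] = k < 6
            maps.append(fake_map(self.grid, occ))
        res = block_consistency_filter(maps, overlap_frac=0.7)
        assert res.retained[0]
        assert not res.retained[1]  # 6/9 < 0.7 -> dropped

    def test_retention_matches_binomial_tail(self, rng):
        n = self.grid.n_points  # 216 points
        reps = 20
        rates = []
        for r in range(reps):
            maps = [fake_map(self.grid, rng.random(n) < 0.5) for _ in range(9)]
            rates.append(block_consistency_filter(maps).retained.mean())
        # P(X >= 7), X ~ Binom(9, 0.5) = 46/512
        p = 46.0 / 512.0
        mc_se = np.sqrt(p * (1 - p) / (n * reps))
        assert abs(np.mean(rates) - p) < 4 * mc_se

    def test_monotone_in_overlap_fraction(self, rng):
        maps = [fake_map(self.grid, rng.random(self.grid.n_points) < 0.7)
                for _ in range(9)]
        prev = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            kept = block_consistency_filter(maps, frac).retained
            if prev is not None:
                assert np.all(kept <= prev)
            prev = kept

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_consistency_filter([fake_map(self.grid, np.ones(216, bool))])


class TestMergeSites:
    def test_two_close_points_merge_at_weighted_mean(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        s = merge_sites(pos, [0.1, 0.3], [1.0, 1.0])
        assert len(s) == 1
        assert np.allclose(s.positions[0], [0.5, 0, 0])
        assert s.values[0] == pytest.approx(0.2)
        assert s.weights[0] == 2.0

    def test_separated_points_unchanged(self, rng):
        pos = rng.uniform(0, 30, (20, 3))
        while True:
            from scipy.spatial.distance import pdist
            if pdist(pos).min() >= 3.0:
                break
            pos = rng.uniform(0, 40, (20, 3))
        s = merge_sites(pos, np.arange(20.0), np.ones(20))
        assert len(s) == 20
        assert np.allclose(np.sort(s.values), np.arange(20.0))

    def test_jittered_cluster_collapses_to_center(self, rng):
        center = np.array([5.0, 5.0, 5.0])
        pos = center + rng.normal(0, 0.4, (20, 3))
        s = merge_sites(pos, np.full(20, 0.1), np.ones(20))
        assert len(s) == 1
        assert np.linalg.norm(s.positions[0] - pos.mean(axis=0)) < 0.5

    def test_weight_conservation_and_hull(self, rng):
        pos = rng.uniform(0, 10, (40, 3))
        w = rng.uniform(0.5, 5.0, 40)
        s = merge_sites(pos, rng.uniform(0, 1, 40), w)
        assert s.weights.sum() == pytest.approx(w.sum())
        for k, contribs in enumerate(s.contributors):
            sub = pos[contribs]
            assert np.all(s.positions[k] >= sub.min(axis=0) - 1e-9)
            assert np.all(s.positions[k] <= sub.max(axis=0) + 1e-9)

    def test_final_separation_exceeds_threshold(self, rng):
        from scipy.spatial.distance import pdist
        pos = rng.uniform(0, 12, (60, 3))
        s = merge_sites(pos, rng.uniform(0, 1, 60), np.ones(60))
        if len(s) > 1:
            assert pdist(s.positions).min() > 2.8


class TestResidenceTimes:
    def test_consecutive_visit_duration(self):
        box = (10.0, 10.0, 10.0)
        pos = np.full((80, 1, 3), 8.0)
        pos[:50] = [5.0, 5.0, 5.0]
        traj = TrajectoryEnsemble(pos, np.asarray(box), 0.1,
                                  {"na": np.array([0])})
        rt = residence_times(traj, "na", np.array([[5.0, 5.0, 5.0]]))
        assert rt.max_residence_ps[0] == pytest.approx(5.0)

    def test_gap_tolerance_bridges_single_frame_exit(self):
        box = (10.0, 10.0, 10.0)
        pos = np.full((21, 1, 3), 5.0)
        pos[10] = [8.0, 8.0, 8.0]  # one-frame excursion
        traj = TrajectoryEnsemble(pos, np.asarray(box), 0.1,
                                  {"na": np.array([0])})
        rt = residence_times(traj, "na", np.array([[5.0, 5.0, 5.0]]),
                             gap_tolerance=2)
        assert rt.n_visits[0] == 1
        assert rt.max_residence_ps[0] == pytest.approx(2.1)
        rt0 = residence_times(traj, "na", np.array([[5.0, 5.0, 5.0]]),
                              gap_tolerance=0)
        assert rt0.n_visits[0] == 2

    def test_empty_site_set_rejected(self):
        traj = make_static_traj([[1.0, 1.0, 1.0]], (5, 5, 5),
                                groups={"na": np.array([0])})
        with pytest.raises(ValueError):
            residence_times(traj, "na", np.zeros((0, 3)))

    def test_well_sites_outlast_bulk_sites(self, trapped_scene_pair):
        """Trapped counterions reside at charge-well sites far longer than
        free ions pass through equivalent bulk sites."""
        _, trr = trapped_scene_pair
        box = trr.box
        na0 = trr.group_positions("na")[-1]  # final, settled positions
        well_sites = na0[:6]
        free = simulate_ion_cloud(free_scene(box=(20.0, 20.0, 20.0), D=0.21,
                                             n_ions=60, n_frames=2500,
                                             frame_interval=1.0, seed=4))
        bulk_sites = free.group_positions("na")[0][:12]
        rt_well = residence_times(trr, "na", well_sites)
        rt_bulk = residence_times(free, "na", bulk_sites)
        wm = rt_well.mean_residence_ps.dropna()
        bm = rt_bulk.mean_residence_ps.dropna()
        gap = wm.mean() - bm.mean()
        spread = np.sqrt(wm.var() / len(wm) + bm.var() / len(bm))
        assert gap > 3 * spread
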