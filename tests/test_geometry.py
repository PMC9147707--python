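"""Zone partitioning, helical centers, groove delimitation and RMSD/RMSF."""

import numpy as np
import pytest

from ionatmos.core import TrajectoryEnsemble
from ionatmos.geometry import (
    GROOVE_CODES,
    ZONE_CODES,
    GridSpec,
    HelicalFrame,
    HelixSpec,
    ZoneMask,
    assign_zones,
    compute_helical_centers,
    groove_mask,
    rmsd_rmsf,
)
from ionatmos.synthetic import simulate_ion_cloud

from conftest import make_static_traj, single_cylinder_scene


def cylinder_surface_atoms(cx, cy, lz, radius=10.0, n_phi=24, n_z=6):
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    z = np.linspace(0.5, lz - 0.5, n_z)
    pts = [
        (cx + radius * np.cos(p), cy + radius * np.sin(p), zz)
        for zz in z
        for p in phi
    ]
    return np.asarray(pts)


class TestHelicalCenters:
    def test_constructed_cylinders_recover_separation(self):
        box = (40.0, 30.0, 20.0)
        a1 = cylinder_surface_atoms(8.0, 15.0, 20.0, radius=6.0)
        a2 = cylinder_surface_atoms(30.4, 15.0, 20.0, radius=6.0)
        pos = np.concatenate([a1, a2])
        groups = {
            "dna1": np.arange(len(a1)),
            "dna2": np.arange(len(a1), len(a1) + len(a2)),
        }
        traj = make_static_traj(pos, box, groups=groups)
        hf = compute_helical_centers(traj, "dna1", "dna2")
        assert hf.d == pytest.approx(22.4, abs=1e-9)

    def test_single_frame_single_slab_is_centroid(self):
        pos = np.array([[1.0, 2.0, 5.0], [3.0, 6.0, 5.0], [5.0, 4.0, 5.0]])
        traj = make_static_traj(pos, (10, 10, 10), n_frames=1,
                                groups={"a": np.arange(3), "b": np.arange(3)})
        hf = compute_helical_centers(traj, "a", "b")
        assert np.allclose(hf.c1[0, 0], pos[:, :2].mean(axis=0))

    def test_empty_selection_rejected(self):
        traj = make_static_traj(np.zeros((2, 3)), (5, 5, 5),
                                groups={"a": np.arange(2)})
        with pytest.raises(ValueError):
            compute_helical_centers(traj, "a", np.array([], dtype=int))

    def test_jittered_scene_mean_separation(self):
        # flexible anchors fluctuate frame to frame; the time-mean center
        # separation stays within 0.1 Å of the nominal construction
        from ionatmos.io import RunConfig
        from ionatmos.pipeline import build_scene

        cfg = RunConfig.from_dict({"scene": {"n_frames": 400}})
        tr = simulate_ion_cloud(build_scene(cfg, "flexible", seed=5))
        hf = compute_helical_centers(tr, "dna1", "dna2")
        per_frame = hf.per_frame_d()
        assert per_frame.std() > 0.01
        assert abs(per_frame.mean() - 22.4) < 0.1
        assert abs(hf.d - 22.4) < 0.1


class TestAssignZones:
    def setup_method(self):
        self.box = (40.0, 30.0, 6.0)
        self.hf = HelicalFrame.from_static_centers((4.0, 15.0), (26.4, 15.0))

    def test_point_at_center_and_inside_radius(self):
        grid = GridSpec((4.0, 15.0, 1.0), 5.0, (2, 1, 1), self.box)
        zm = assign_zones(grid, self.hf)
        # first point at c1 itself, second at in-plane distance 5 < R_DNA
        assert zm.labels[0] == ZONE_CODES["inside1"]
        assert zm.labels[1] == ZONE_CODES["inside1"]

    def test_midpoint_ownership_rule(self):
        # c1x = 4, c2x = 26.4 -> midpoint 15.2; exterior probes at y = c_y
        grid = GridSpec((15.1, 15.0, 1.0), 0.2, (2, 1, 1), self.box)
        zm = assign_zones(grid, self.hf)
        assert zm.labels[0] == ZONE_CODES["interface"]
        assert zm.labels[1] == ZONE_CODES["interface"]
        assert zm.owner[0] == 1  # x = 15.1 < midpoint
        assert zm.owner[1] == 2  # x = 15.3 > midpoint
        tie = GridSpec((15.2, 15.0, 1.0), 1.0, (1, 1, 1), self.box)
        assert assign_zones(tie, self.hf).owner[0] == 1

    def test_labels_partition_grid(self):
        grid = GridSpec.from_box(self.box, 1.0)
        zm = assign_zones(grid, self.hf)
        assert sum(zm.counts().values()) == grid.n_points

    def test_mirror_swap_symmetry(self):
        box = (40.0, 30.0, 4.0)
        grid = GridSpec((0.25, 0.5, 0.5), 0.5, (80, 60, 8), box)
        hf = HelicalFrame.from_static_centers((8.0, 15.0), (32.0, 15.0))
        hm = HelicalFrame.from_static_centers((32.0, 15.0), (8.0, 15.0))
        zm = assign_zones(grid, hf)
        zmirror = assign_zones(grid, hm)
        # geometry is symmetric about x = 20, so exchanging the duplex
        # labels is the mirrored configuration: labels swap 1<->2 exactly
        # (no grid point sits on the midpoint plane)
        lab = zm.labels.reshape(80, 60, 8)
        labm = zmirror.labels.reshape(80, 60, 8)
        swap = {ZONE_CODES["inside1"]: ZONE_CODES["inside2"],
                ZONE_CODES["inside2"]: ZONE_CODES["inside1"],
                ZONE_CODES["interface"]: ZONE_CODES["interface"],
                ZONE_CODES["noninterface1"]: ZONE_CODES["noninterface2"],
                ZONE_CODES["noninterface2"]: ZONE_CODES["noninterface1"]}
        expected = np.vectorize(swap.get)(labm)
        assert np.array_equal(lab, expected)

    def test_degenerate_separation_rejected(self):
        hf = HelicalFrame.from_static_centers((4.0, 15.0), (26.4, 15.0))
        hf.d = -1.0
        grid = GridSpec.from_box(self.box, 2.0)
        with pytest.raises(ValueError):
            assign_zones(grid, hf)


class TestGrooveMask:
    def test_sector_rule_matches_bracketing_phosphate_oracle(self):
        box = (40.0, 40.0, 34.0)
        grid = GridSpec.from_box(box, 1.0)
        hf = HelicalFrame.from_static_centers((20.0, 20.0), (120.0, 20.0))
        hs = HelixSpec()
        labels = groove_mask(hf, hs, grid, shell=(10.0, 14.0))
        pts = grid.points()
        idx = np.flatnonzero(labels > 0)
        assert idx.size > 1000
        # oracle: the two backbone crossings bracketing the point in z at
        # its azimuth; the narrow (~11.3 Å) gap bounded below by strand 2
        # and above by strand 1 is the minor groove
        reps, strand = [], []
        for zoff in (-34.0, 0.0, 34.0):
            for s, (p, _) in enumerate(
                zip(hs.phosphate_positions((20.0, 20.0), box[2]), (1, 2))
            ):
                q = p.copy()
                q[:, 2] += zoff
                reps.append(q)
                strand.append(np.full(len(q), s + 1))
        phos = np.vstack(reps)
        strand = np.concatenate(strand)
        theta = np.arctan2(phos[:, 1] - 20, phos[:, 0] - 20)
        omega = np.deg2rad(hs.twist) / hs.rise
        P = pts[idx]
        phi = np.arctan2(P[:, 1] - 20, P[:, 0] - 20)
        dphi = np.mod(phi[:, None] - theta[None, :] + np.pi, 2 * np.pi) - np.pi
        zc = phos[None, :, 2] + dphi / omega
        dz = zc - P[:, 2:3]
        ib = np.argmax(np.where(dz <= 0, dz, -np.inf), axis=1)
        ia = np.argmin(np.where(dz > 0, dz, np.inf), axis=1)
        oracle = np.where((strand[ib] == 2) & (strand[ia] == 1),
                          GROOVE_CODES["minor"], GROOVE_CODES["major"])
        assert np.mean(oracle == labels[idx]) >= 0.95

    def test_bulk_point_unlabeled(self):
        box = (60.0, 60.0, 10.0)
        hf = HelicalFrame.from_static_centers((30.0, 30.0), (130.0, 30.0))
        grid = GridSpec((50.0, 30.0, 5.0), 1.0, (1, 1, 1), box)  # 20 Å out
        labels = groove_mask(hf, HelixSpec(), grid)
        assert labels[0] == GROOVE_CODES["none"]

    def test_missing_helix_spec_warns_all_none(self):
        box = (40.0, 40.0, 10.0)
        grid = GridSpec.from_box(box, 2.0)
        hf = HelicalFrame.from_static_centers((20.0, 20.0), (60.0, 20.0))
        with pytest.warns(UserWarning):
            labels = groove_mask(hf, None, grid)
        assert np.all(labels == GROOVE_CODES["none"])

    def test_rotating_duplex_rotates_its_mask(self):
        box = (40.0, 40.0, 34.0)
        # grid symmetric under 180-degree rotation about the duplex axis
        grid = GridSpec((7.75, 7.75, 0.5), 0.5, (50, 50, 34), box)
        hf = HelicalFrame.from_static_centers((20.0, 20.0), (220.0, 20.0))
        base = groove_mask(hf, HelixSpec(), grid, shell=(10.0, 14.0))
        rot = groove_mask(hf, HelixSpec(rotation2=180.0), grid, shell=(10.0, 14.0))
        # duplex 1 here: rotation2 must not change duplex-1 labels
        assert np.array_equal(base, rot)
        rot1 = groove_mask(hf, HelixSpec(phase1=180.0, phase2=300.0), grid,
                           shell=(10.0, 14.0))
        arr = base.reshape(50, 50, 34)
        arr_rot = rot1.reshape(50, 50, 34)[::-1, ::-1, :]
        assert np.array_equal(arr, arr_rot)


class TestRmsdRmsf:
    def test_reference_repeated_gives_zero(self, rng):
        ref = rng.uniform(0, 10, (7, 3))
        traj = make_static_traj(ref, (10, 10, 10), n_frames=4,
                                groups={"a": np.arange(7)})
        rmsd, rmsf = rmsd_rmsf(traj, "a", ref)
        assert np.allclose(rmsd, 0) and np.allclose(rmsf, 0)

    def test_single_displaced_atom_scaling(self):
        n = 16
        ref = np.zeros((n, 3))
        moved = ref.copy()
        moved[0, 0] = 2.0
        traj = make_static_traj(moved, (10, 10, 10), n_frames=3,
                                groups={"a": np.arange(n)})
        rmsd, _ = rmsd_rmsf(traj, "a", ref)
        assert np.allclose(rmsd, 2.0 / np.sqrt(n))

    def test_isotropic_jitter_rmsf_limit(self, rng):
        sigma, n_frames, n_atoms = 0.7, 4000, 30
        ref = np.full((n_atoms, 3), 5.0)
        frames = ref[None] + rng.normal(0, sigma, (n_frames, n_atoms, 3))
        traj = TrajectoryEnsemble(frames, np.array([20.0, 20.0, 20.0]), 0.1,
                                  {"a": np.arange(n_atoms)})
        _, rmsf = rmsd_rmsf(traj, "a", ref)
        se = sigma * np.sqrt(3) / np.sqrt(2 * n_frames)
        assert np.all(np.abs(rmsf - sigma * np.sqrt(3)) < 5 * se)

    def test_atom_count_mismatch_rejected(self):
        traj = make_static_traj(np.zeros((4, 3)), (5, 5, 5),
                                groups={"a": np.arange(4)})
        with pytest.raises(ValueError):
            rmsd_rmsf(traj, "a", np.zeros((3, 3)))


class TestZoneMaskIO:
    def test_roundtrip(self, tmp_path):
        box = (12.0, 12.0, 6.0)
        grid = GridSpec.from_box(box, 1.0)
        hf = HelicalFrame.from_static_centers((3.0, 6.0), (9.0, 6.0), R_DNA=2.0)
        zm = assign_zones(grid, hf)
        zm.save(tmp_path / "mask.vox.gz")
        back = ZoneMask.load(tmp_path / "mask.vox.gz")
        assert back.grid == grid
        assert np.array_equal(back.labels, zm.labels)
        assert np.array_equal(back.owner, zm.owner)
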