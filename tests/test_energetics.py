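"""Ewald per-particle energies and LJ decomposition."""

import numpy as np
import pytest

from ionatmos.core import TrajectoryEnsemble
from ionatmos.energetics import (
    COULOMB,
    ChargeSystem,
    EwaldConvergenceError,
    LJParameterSet,
    ewald_per_particle_energy,
    ewald_total_energy,
    lj_decomposition,
    lj_group_pair_energy,
    voxel_energy_map,
)
from ionatmos.geometry import GridSpec
from ionatmos.synthetic import toy_charge_lattice


def evjen_madelung(n: int = 8) -> float:
    """Direct summation of the NaCl Madelung constant with Evjen weights.

    Charges on the integer lattice within [-n, n]^3 receive weight 1/2 per
    coordinate lying on the cube boundary, which makes the conditionally
    convergent sum converge rapidly.
    """
    i, j, k = np.meshgrid(*[np.arange(-n, n + 1)] * 3, indexing="ij")
    r = np.sqrt(i**2 + j**2 + k**2)
    sign = np.where((i + j + k) % 2 == 0, 1.0, -1.0)
    w = np.ones_like(r)
    for ax in (i, j, k):
        w *= np.where(np.abs(ax) == n, 0.5, 1.0)
    with np.errstate(divide="ignore"):
        terms = sign * w / r
    terms[r == 0] = 0.0
    return -terms.sum()  # positive constant ~1.7476


class TestEwald:
    def test_isolated_pair_approaches_bare_coulomb(self):
        pos = np.array([[50.0, 50.0, 50.0], [53.0, 50.0, 50.0]])
        sys2 = ChargeSystem(pos, [1.0, -1.0], [200.0] * 3, ["a", "b"])
        e = ewald_per_particle_energy(sys2, "a", "b", self_images=True)
        assert e[0] == pytest.approx(-COULOMB / 3.0, rel=1e-3)

    @pytest.mark.parametrize("cells,a", [(1, 4.0), (2, 4.0), (1, 2.5)])
    def test_rocksalt_matches_direct_sum_madelung(self, cells, a):
        lat = toy_charge_lattice("rocksalt", cells, a)
        per_pair = ewald_total_energy(lat) / (len(lat.charges) / 2)
        oracle = -evjen_madelung(10) * COULOMB / a
        assert per_pair == pytest.approx(oracle, rel=1e-4)

    def test_alpha_independence_at_converged_kspace(self):
        lat = toy_charge_lattice("rocksalt", 1, 4.0)
        idx = np.arange(8)
        base_alpha = 3.8 / 4.0
        e1 = ewald_per_particle_energy(lat, idx, idx, alpha=base_alpha)
        e2 = ewald_per_particle_energy(lat, idx, idx, alpha=2 * base_alpha)
        assert np.max(np.abs(e1 - e2)) < 1e-3

    def test_partner_partition_additivity(self, rng):
        # random neutral system; energies against a partition of the
        # partner groups reproduce the energy against their union
        n = 12
        pos = rng.uniform(0, 20, (n, 3))
        q = rng.normal(size=n)
        q -= q.mean()
        labels = np.array(["dna1"] * 4 + ["dna2"] * 4 + ["na"] * 4)
        sys_ = ChargeSystem(pos, q, [20.0] * 3, labels)
        subj = sys_.group("na")
        total = ewald_per_particle_energy(sys_, "na", ("dna1", "dna2", "na"))
        parts = (
            ewald_per_particle_energy(sys_, "na", "dna1")
            + ewald_per_particle_energy(sys_, "na", "dna2")
            + ewald_per_particle_energy(sys_, "na", "na")
        )
        assert np.max(np.abs(total - parts)) / np.max(np.abs(total)) < 1e-8

    def test_non_neutral_system_rejected(self):
        sys_ = ChargeSystem(np.zeros((1, 3)), [1.0], [10.0] * 3, ["na"])
        with pytest.raises(ValueError, match="net charge"):
            ewald_per_particle_energy(sys_, "na", "na")

    def test_insufficient_kmax_reported(self):
        lat = toy_charge_lattice("rocksalt", 1, 4.0)
        with pytest.raises(EwaldConvergenceError):
            ewald_per_particle_energy(lat, np.arange(8), np.arange(8),
                                      alpha=1.5, kmax=1)


class TestLJ:
    def setup_method(self):
        self.params = LJParameterSet(
            types={"na": (0.1, 1.2), "cl": (0.2, 1.8), "dna": (0.15, 2.0)}
        )

    def test_pair_minimum_is_minus_epsilon(self):
        eps, rmin = self.params.pair("na", "cl")
        pos = np.array([[1.0, 1.0, 1.0], [1.0 + rmin, 1.0, 1.0]])
        e = lj_group_pair_energy(pos, np.array(["na", "cl"], dtype=object),
                                 np.array([50.0] * 3), self.params,
                                 np.array([0]), np.array([1]))
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_zero_crossing_at_sigma(self):
        eps, rmin = self.params.pair("na", "na")
        sigma = rmin / 2.0 ** (1.0 / 6.0)
        pos = np.array([[1.0, 1.0, 1.0], [1.0 + sigma, 1.0, 1.0]])
        e = lj_group_pair_energy(pos, np.array(["na", "na"], dtype=object),
                                 np.array([50.0] * 3), self.params,
                                 np.array([0]), np.array([1]))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_override_changes_only_its_group_pair(self, rng):
        pos = rng.uniform(0, 12, (30, 3))
        types = np.array(["na"] * 10 + ["cl"] * 10 + ["dna"] * 10, dtype=object)
        groups = {"na": np.arange(10), "cl": np.arange(10, 20),
                  "dna": np.arange(20, 30)}
        box = np.array([12.0] * 3)
        base = lj_decomposition(pos, types, groups, box, self.params)
        eps, rmin = self.params.pair("na", "cl")
        halved = LJParameterSet(self.params.types,
                                {("na", "cl"): (eps / 2.0, rmin)})
        mod = lj_decomposition(pos, types, groups, box, halved)
        b = base.set_index("pair")["E_LJ"]
        m = mod.set_index("pair")["E_LJ"]
        assert m["cl-na"] == pytest.approx(b["cl-na"] / 2.0, rel=1e-12)
        for pair in b.index:
            if pair not in ("cl-na", "total"):
                assert m[pair] == b[pair]

    def test_translation_invariance_with_wrapping(self, rng):
        pos = rng.uniform(0, 15, (20, 3))
        types = np.array(["na"] * 20, dtype=object)
        box = np.array([15.0] * 3)
        idx = np.arange(20)
        e0 = lj_group_pair_energy(pos, types, box, self.params, idx, idx)
        shifted = np.mod(pos + np.array([7.3, -4.1, 11.9]), box)
        e1 = lj_group_pair_energy(shifted, types, box, self.params, idx, idx)
        assert e1 == pytest.approx(e0, rel=1e-10)

    def test_missing_type_parameters_named(self):
        with pytest.raises(KeyError, match="mg"):
            self.params.pair("na", "mg")

    def test_parameter_file_roundtrip(self, tmp_path):
        p = tmp_path / "lj.par"
        p.write_text(
            "# demo parameters\n"
            "type na 0.0469 1.41075\n"
            "type cl 0.15 2.27\n"
            "pair na cl 0.0839 3.23\n"
        )
        params = LJParameterSet.from_file(p)
        assert params.pair("cl", "na") == (0.0839, 3.23)
        assert params.pair("na", "na") == (0.0469, 2.8215)


class TestVoxelEnergyMap:
    def test_single_frame_matches_per_particle_energy(self):
        box = np.array([20.0, 20.0, 20.0])
        pos = np.array([[5.0, 5.0, 5.0], [9.0, 5.0, 5.0], [14.0, 12.0, 5.0]])
        q = np.array([-1.0, 1.0, 0.0])
        traj = TrajectoryEnsemble(pos[None], box, 0.1,
                                  {"dna1": np.array([0]), "na": np.array([1]),
                                   "x": np.array([2])})
        grid = GridSpec.from_box(box, 1.0)
        emap, esd = voxel_energy_map(
            traj, {"dna1": -1.0, "na": 1.0}, grid,
            partner_groups=("dna1",),
        )
        sys_ = ChargeSystem(pos[:2], q[:2], box, np.array(["dna1", "na"]))
        direct = ewald_per_particle_energy(sys_, "na", "dna1")
        flat, _ = grid.voxel_index(pos[1][None])
        assert emap.values[flat[0]] == pytest.approx(direct[0], rel=1e-10)
        assert np.isnan(emap.values[0])  # unvisited voxel is missing, not 0

    def test_energy_minimum_colocates_with_density_peak(self, trapped_scene_pair):
        """The radial electrostatic-energy minimum of the counterions sits
        at the same shell (±1) as their density maximum."""
        from ionatmos.density import radial_profile, voxel_number_density
        from ionatmos.geometry import HelicalFrame, assign_zones

        _, trr = trapped_scene_pair
        box = trr.box
        grid = GridSpec.from_box(box, 1.0)
        hf = HelicalFrame.from_static_centers(
            (box[0] / 2, box[1] / 2), (box[0] / 2 + 60.0, box[1] / 2), R_DNA=10.0
        )
        zones = assign_zones(grid, hf)
        dens = voxel_number_density(trr, "na", grid)
        emap, _ = voxel_energy_map(
            trr, {"dna1": -1.0, "na": 1.0}, grid, frame_stride=100,
        )
        dprof = radial_profile(dens, hf, zones, "noninterface", 1, r_max=16.0)
        eprof = radial_profile(emap, hf, zones, "noninterface", 1, r_max=16.0)
        r_peak = dprof.r_mid[np.nanargmax(dprof.value.fillna(-np.inf))]
        r_min = eprof.r_mid[np.nanargmin(eprof.value.fillna(np.inf))]
        assert abs(r_peak - r_min) <= 0.5 + 1e-9
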