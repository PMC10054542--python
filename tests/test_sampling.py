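import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from implimem import (
    MembraneGeometry,
    Particle,
    ParticleSystem,
    build_enm,
    depth_profile,
    energy_scan,
    insertion_metrics,
    membrane_profile,
    minimize,
    planar_depth,
    run_monte_carlo,
    total_energy,
)
from implimem.sampling import BOLTZMANN_KCAL

from .conftest import random_bead_system


def single_bead(z=0.0, etr=-0.05, sasa=60.0):
    return ParticleSystem(
        [Particle(0, [0.0, 0.0, z], radius=2.3, sasa=sasa, etr_per_area=etr)],
        "one-bead",
    )


class TestMonteCarlo:
    def test_identical_seed_identical_trajectory(self, hydrophobic_helix):
        t1 = run_monte_carlo(hydrophobic_helix, steps=500, seed=11, record_every=5)
        t2 = run_monte_carlo(hydrophobic_helix, steps=500, seed=11, record_every=5)
        assert t1.n_accepted == t2.n_accepted
        d1, d2 = t1.to_dataframe(), t2.to_dataframe()
        assert np.array_equal(d1["e_imp"].to_numpy(), d2["e_imp"].to_numpy())
        assert np.array_equal(d1["depth"].to_numpy(), d2["depth"].to_numpy())
        t3 = run_monte_carlo(hydrophobic_helix, steps=500, seed=12, record_every=5)
        assert not np.array_equal(
            d1["e_imp"].to_numpy(), t3.to_dataframe()["e_imp"].to_numpy()
        )

    def test_low_temperature_never_accepts_uphill(self, amphipathic_helix):
        traj = run_monte_carlo(
            amphipathic_helix, temperature=1e-6, steps=800, seed=2, record_every=1
        )
        e = traj.to_dataframe()["e_imp"].to_numpy()
        acc = traj.to_dataframe()["accepted"].to_numpy()
        de = np.diff(e)
        assert np.all(de[acc[1:]] <= 1e-12)

    def test_high_temperature_accepts_almost_everything(self, hydrophobic_helix):
        traj = run_monte_carlo(
            hydrophobic_helix, temperature=1e7, steps=1000, seed=3
        )
        assert traj.acceptance_fraction > 0.99

    def test_stored_energies_match_reevaluation(self, hydrophobic_helix, geom):
        traj = run_monte_carlo(hydrophobic_helix, steps=300, seed=5, record_every=30)
        base = hydrophobic_helix.positions
        work = hydrophobic_helix.copy()
        for frame in traj.frames:
            work.positions = frame.pose.apply(base)
            again = total_energy(work, planar_depth, geom)
            assert again.e_imp == pytest.approx(frame.energy.e_imp, abs=1e-9)

    def test_invalid_arguments(self, hydrophobic_helix):
        with pytest.raises(ValueError):
            run_monte_carlo(hydrophobic_helix, temperature=-1.0, steps=10)
        with pytest.raises(ValueError):
            run_monte_carlo(hydrophobic_helix, steps=0)

    def test_visit_frequencies_follow_boltzmann(self, geom):
        """Single-bead walker in the membrane: occupancy ratio of a core bin
        vs an interface bin matches the Boltzmann integral within 3 SE."""
        bead = single_bead(z=0.0, etr=-0.05)
        temperature = 150.0
        traj = run_monte_carlo(
            bead, temperature=temperature, steps=100_000, seed=9, record_every=10
        )
        z = traj.to_dataframe()["depth"].to_numpy()

        beta = 1.0 / (BOLTZMANN_KCAL * temperature)

        def energy_at(zz):
            c = membrane_profile(zz, geom)
            return 60.0 * (0.05 + geom.a_lip) * c  # -S*etr*C + a_lip*S*C

        grid = np.linspace(-30.0, 30.0, 6001)
        w = np.exp(-beta * energy_at(grid))
        bin_a = (grid >= -5.0) & (grid <= 5.0)
        bin_b = ((grid >= 10.0) & (grid <= 15.0)) | ((grid <= -10.0) & (grid >= -15.0))
        expected = w[bin_a].sum() / w[bin_b].sum()

        in_a = (z >= -5.0) & (z <= 5.0)
        in_b = ((z >= 10.0) & (z <= 15.0)) | ((z <= -10.0) & (z >= -15.0))
        assert in_b.sum() > 50
        observed = in_a.sum() / in_b.sum()
        # standard error via 10 block ratios
        blocks_a = np.array_split(in_a, 10)
        blocks_b = np.array_split(in_b, 10)
        ratios = [a.sum() / max(b.sum(), 1) for a, b in zip(blocks_a, blocks_b)]
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(observed - expected) < 3 * max(se, 0.05 * expected)


class TestEquilibration:
    """The physical contract of the model: hydrophobic helices bury in the
    acyl core, amphipathic helices sit at the headgroup interface."""

    @staticmethod
    def grid_scan_minimum(system, geom):
        best = (np.inf, None, None)
        base = system.positions - system.center_of_mass()
        work = system.copy()
        for roll in range(0, 360, 30):
            for tilt_deg in range(0, 95, 5):
                rot = Rotation.from_euler("zy", [roll, tilt_deg], degrees=True)
                rp = rot.apply(base)
                for z in np.arange(-25.0, 25.01, 0.5):
                    work.positions = rp + [0.0, 0.0, z]
                    e = total_energy(work, planar_depth, geom).e_imp
                    if e < best[0]:
                        best = (e, z, tilt_deg)
        return best

    def test_helices_settle_where_the_landscape_says(
        self, hydrophobic_helix, amphipathic_helix, geom
    ):
        _, z_hyd, _ = self.grid_scan_minimum(hydrophobic_helix, geom)
        _, z_amp, _ = self.grid_scan_minimum(amphipathic_helix, geom)
        assert abs(z_hyd) < geom.z0 - geom.beta          # core minimum
        assert geom.z0 - geom.beta < abs(z_amp) < geom.z0 + geom.beta  # interface

        hyd_means, amp_means = [], []
        for seed in range(1, 6):
            th = run_monte_carlo(
                hydrophobic_helix, steps=50_000, seed=seed, record_every=50
            ).to_dataframe()
            ta = run_monte_carlo(
                amphipathic_helix, steps=50_000, seed=seed, record_every=50
            ).to_dataframe()
            hyd_means.append(th["depth"].iloc[len(th) // 2 :].abs().mean())
            amp_means.append(ta["depth"].iloc[len(ta) // 2 :].abs().mean())
        assert all(h < geom.z0 - geom.beta for h in hyd_means)
        for a in amp_means:
            assert abs(a - abs(z_amp)) < 4.0   # interfacial band around the scan minimum
        # hydrophobic buries deeper than amphipathic, both inside the membrane
        assert np.mean(hyd_means) < np.mean(amp_means) < geom.z0 + geom.beta


class TestMinimize:
    def test_energy_never_increases(self, amphipathic_helix, geom):
        start = total_energy(amphipathic_helix, planar_depth, geom).e_imp
        res = minimize(amphipathic_helix, planar_depth, geom)
        assert res.energy.e_imp <= start

    def test_single_hydrophobic_particle_reaches_core_plateau(self, geom):
        """Descent from the interface drives the bead into the acyl core,
        reaching the plateau energy of the z=0 minimum."""
        bead = single_bead(z=geom.z0, etr=-0.05)
        res = minimize(bead, planar_depth, geom, step_size=0.5)
        e_at_center = total_energy(single_bead(0.0, etr=-0.05), planar_depth, geom).e_imp
        assert abs(res.pose.depth) < geom.z0 - geom.beta
        assert res.energy.e_imp == pytest.approx(e_at_center, abs=1e-6)

    def test_agrees_with_exhaustive_scan(self, hydrophobic_helix, geom):
        scan = energy_scan(
            hydrophobic_helix, planar_depth, geom, scan_range=(-30.0, 30.0), step=0.5
        )
        z_scan = scan.loc[scan["e_imp"].idxmin(), "coordinate"]
        res = minimize(hydrophobic_helix, planar_depth, geom)
        assert abs(res.pose.depth - z_scan) <= 0.5


class TestElasticNetwork:
    def test_zero_energy_and_force_at_build_geometry(self, rng):
        s = random_bead_system(rng, n=20, spread=8.0)
        enm = build_enm(s, cutoff=9.0)
        assert enm.energy(s.positions) == 0.0
        assert np.allclose(enm.forces(s.positions), 0.0)

    def test_pair_within_cutoff_gives_one_spring(self):
        s = ParticleSystem(
            [Particle(0, [0, 0, 0], radius=2.0), Particle(1, [5, 0, 0], radius=2.0)]
        )
        assert len(build_enm(s, cutoff=9.0).pairs) == 1
        assert len(build_enm(s, cutoff=4.0).pairs) == 0

    def test_forces_sum_to_zero(self, rng):
        s = random_bead_system(rng, n=25, spread=8.0)
        enm = build_enm(s, cutoff=9.0)
        deformed = s.positions + rng.normal(0.0, 0.4, size=(25, 3))
        f = enm.forces(deformed)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)
        assert enm.energy(deformed) > 0.0

    def test_energy_invariant_under_rigid_motion(self, rng):
        s = random_bead_system(rng, n=15, spread=8.0)
        enm = build_enm(s, cutoff=9.0)
        deformed = s.positions + rng.normal(0.0, 0.3, size=(15, 3))
        e0 = enm.energy(deformed)
        rot = Rotation.random(rng=np.random.default_rng(4))
        moved = rot.apply(deformed) + np.array([3.0, -7.0, 11.0])
        assert enm.energy(moved) == pytest.approx(e0, abs=1e-9)

    def test_spring_energy_quadratic(self):
        s = ParticleSystem(
            [Particle(0, [0, 0, 0], radius=2.0), Particle(1, [5, 0, 0], radius=2.0)]
        )
        enm = build_enm(s, cutoff=9.0, stiffness=2.0)
        stretched = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        assert enm.energy(stretched) == pytest.approx(0.5 * 2.0 * 1.0**2)


class TestInsertionMetrics:
    def test_axis_aligned_cases(self, rng):
        s = random_bead_system(rng, n=2)
        s.positions = np.array([[0.0, 0.0, -5.0], [0.0, 0.0, 5.0]])
        depth, tilt, roll = insertion_metrics(s, planar_depth, (0, 1))
        assert depth == pytest.approx(0.0)
        assert tilt == pytest.approx(0.0)
        s.positions = np.array([[0.0, 0.0, 7.0], [8.0, 0.0, 7.0]])
        depth, tilt, _ = insertion_metrics(s, planar_depth, (0, 1))
        assert depth == pytest.approx(7.0)
        assert tilt == pytest.approx(90.0)

    def test_constructed_pose_closed_form(self, rng):
        """Rotating a vertical pair by a known angle yields exactly that tilt."""
        s = random_bead_system(rng, n=2)
        for angle in (10.0, 35.0, 60.0, 85.0):
            rot = Rotation.from_euler("y", angle, degrees=True)
            s.positions = rot.apply(np.array([[0.0, 0.0, -6.0], [0.0, 0.0, 6.0]]))
            _, tilt, _ = insertion_metrics(s, planar_depth, (0, 1))
            assert tilt == pytest.approx(angle, abs=1e-9)

    def test_degenerate_vector_errors(self, rng):
        s = random_bead_system(rng, n=2)
        s.positions = np.zeros((2, 3))
        with pytest.raises(ValueError):
            insertion_metrics(s, planar_depth, (0, 1))


class TestDepthProfile:
    def test_static_profile_is_instantaneous_depths(self, hydrophobic_helix, geom):
        prof = depth_profile(hydrophobic_helix, planar_depth, geom)
        z = hydrophobic_helix.positions[:, 2]
        assert prof.mean_depth == pytest.approx(z, abs=1e-12)

    def test_transmembrane_helix_profile_is_affine(self, geom):
        """A vertical ideal helix shows ~1.5 A/residue slope in depth."""
        from implimem import make_fixture

        helix = make_fixture("hydrophobic_helix", 20, seed=0)
        prof = depth_profile(helix, planar_depth, geom)
        slope = np.polyfit(np.arange(20), prof.mean_depth, 1)[0]
        assert slope == pytest.approx(1.5, abs=0.01)

    def test_deviation_against_itself_is_zero(self, hydrophobic_helix, geom):
        prof = depth_profile(hydrophobic_helix, planar_depth, geom)
        ref = dict(zip(prof.residues, prof.mean_depth))
        again = depth_profile(hydrophobic_helix, planar_depth, geom, reference=ref)
        assert np.allclose(again.deviation, 0.0)

    def test_trajectory_window_average(self, hydrophobic_helix, geom):
        traj = run_monte_carlo(hydrophobic_helix, steps=200, seed=1, record_every=20)
        prof = depth_profile(
            hydrophobic_helix, planar_depth, geom, trajectory=traj, window=slice(-3, None)
        )
        assert len(prof.residues) == 18
        with pytest.raises(ValueError, match="empty"):
            depth_profile(
                hydrophobic_helix, planar_depth, geom,
                trajectory=traj, window=slice(99, 99),
            )


class TestEnergyScan:
    def test_symmetric_fixture_symmetric_scan(self, geom):
        bead = single_bead(0.0)
        scan = energy_scan(bead, planar_depth, geom, scan_range=(-30.0, 30.0), step=1.0)
        e = scan["e_imp"].to_numpy()
        assert e == pytest.approx(e[::-1], abs=1e-12)

    def test_aqueous_range_is_flat(self, hydrophobic_helix, geom):
        scan = energy_scan(
            hydrophobic_helix, planar_depth, geom, scan_range=(200.0, 240.0), step=1.0
        )
        e = scan["e_imp"].to_numpy()
        assert e.max() - e.min() < 1e-6

    def test_breakdown_columns_consistent(self, amphipathic_helix, geom):
        scan = energy_scan(amphipathic_helix, planar_depth, geom, step=2.0)
        assert np.allclose(scan["e_imp"], scan["e_int"] + scan["e_lip"])
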