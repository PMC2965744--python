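"""P2 order parameter against the effective normal; angle distributions."""

import numpy as np
import pytest

from dropletmetrics.model import Trajectory
from dropletmetrics.orientation import (AxisDefinition, angle_distribution,
                                        conformation_map, effective_normal,
                                        order_parameter, order_parameter_profile)
from dropletmetrics.synth import SyntheticSpec, build_trajectory, sample_orientations
from tests.conftest import single_frame, two_bead_molecules


def _shell_molecules(n: int, mode: str, seed: int = 0, radius: float = 4.0):
    """Antipodal pairs of 2-bead CHOL molecules on a sphere; axes radial or
    tangent.  The antipodal symmetry pins the particle COM exactly at the
    origin, so the effective normal equals the placement direction."""
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n // 2, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    dirs = np.concatenate([d, -d])
    if mode == "radial":
        axes = dirs
    elif mode == "tangent":
        helper = np.zeros_like(dirs)
        helper[np.arange(len(dirs)), np.argmin(np.abs(dirs), axis=1)] = 1.0
        axes = np.cross(dirs, helper)
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    com = dirs * radius
    pos = np.stack([com - 0.3 * axes, com + 0.3 * axes], axis=1)  # R4, R1
    top, x = two_bead_molecules(pos, species="CHOL")
    return single_frame(top, x)


CHOL_AXIS = AxisDefinition("CHOL", "R4", "R1")


class TestEffectiveNormal:
    def test_unit_radial_direction(self):
        np.testing.assert_allclose(effective_normal([0, 0, 0], [0, 0, 2]), [0, 0, 1])
        np.testing.assert_allclose(effective_normal([0, 0, 0], [3, 4, 0]), [0.6, 0.8, 0])

    def test_midpoint_at_com_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            effective_normal([0, 0, 0], [0, 0, 0])


class TestOrderParameterProfile:
    def test_radial_axes_give_plus_one(self):
        traj = _shell_molecules(200, "radial")
        prof = order_parameter_profile(traj, CHOL_AXIS, min_count=1)
        occupied = prof.count > 0
        np.testing.assert_allclose(prof.S[occupied], 1.0, atol=1e-10)

    def test_tangent_axes_give_minus_half(self):
        traj = _shell_molecules(200, "tangent")
        prof = order_parameter_profile(traj, CHOL_AXIS, min_count=1)
        occupied = prof.count > 0
        np.testing.assert_allclose(prof.S[occupied], -0.5, atol=1e-10)

    def test_isotropic_field_is_near_zero(self):
        n = 100_000
        v, _ = sample_orientations(n, 0.0, seed=11)
        S = order_parameter(v[:, 2])
        assert abs(S) < 3 / np.sqrt(n)

    @pytest.mark.parametrize("S_target", [-0.4, 0.0, 0.3, 0.7, 0.95])
    def test_recovery_across_targets(self, S_target):
        if S_target == 0.0:
            v, _ = sample_orientations(100_000, 1e-9, seed=13)
        else:
            v, _ = sample_orientations(100_000, S_target, seed=13)
        assert order_parameter(v[:, 2]) == pytest.approx(S_target, abs=0.02)

    def test_droplet_surface_recovery(self):
        """A droplet generated with surface S_target=0.6 yields a profile
        whose surface-shell average recovers 0.6 within 0.02."""
        spec = SyntheticSpec(S_target=0.6, n_frames=450, seed=21)
        traj = build_trajectory(spec)
        prof = order_parameter_profile(traj, AxisDefinition("POPC", "C4A", "NC3"))
        sel = (prof.bin_centers >= 4.0) & (prof.count > 0)
        S_mean = np.average(prof.S[sel], weights=prof.count[sel])
        assert S_mean == pytest.approx(0.6, abs=0.02)

    def test_low_count_bins_flagged(self):
        traj = _shell_molecules(10, "radial")
        prof = order_parameter_profile(traj, CHOL_AXIS, min_count=50)
        assert not prof.reliable[prof.count > 0].any()


def _four_bead_ce(n_mol: int, ring_axes: np.ndarray, chain_axes: np.ndarray,
                  com: np.ndarray):
    """CE-like molecules with explicit ring (R4->R1) and chain (C1->C4) axes."""
    from dropletmetrics.model import Topology

    names = np.tile(np.array(["R4", "R1", "C1", "C4"], dtype=object), n_mol)
    pos = np.empty((n_mol, 4, 3))
    pos[:, 0] = com - 0.3 * ring_axes
    pos[:, 1] = com + 0.3 * ring_axes
    pos[:, 2] = com
    pos[:, 3] = com + 0.6 * chain_axes
    top = Topology(
        bead_names=names,
        molecule_ids=np.repeat(np.arange(n_mol), 4),
        species=np.array(["CE"] * 4 * n_mol, dtype=object),
        moieties=np.array(["sterol_ring", "sterol_ring", "oleate_chain",
                           "oleate_chain"] * n_mol, dtype=object),
        residue_indices=np.full(4 * n_mol, -1),
        residue_names=np.array([""] * 4 * n_mol, dtype=object),
        hydro_classes=np.array([""] * 4 * n_mol, dtype=object),
        chain_labels=np.array([""] * 4 * n_mol, dtype=object),
    )
    return single_frame(top, pos.reshape(-1, 3))


class TestAngleDistribution:
    def test_parallel_and_antiparallel_extremes(self):
        axes = np.tile([0.0, 0.0, 1.0], (8, 1))
        com = np.tile([0.0, 0.0, 4.0], (8, 1))
        com[:4, 0] = np.linspace(-1, 1, 4)   # break exact COM degeneracy
        traj = _four_bead_ce(8, axes, axes, com)
        edges, p, _ = angle_distribution(traj, AxisDefinition("CE", "R4", "R1"),
                                         AxisDefinition("CE", "C1", "C4"), bins_deg=18)
        assert p[0] == pytest.approx(1.0)
        traj2 = _four_bead_ce(8, axes, -axes, com)
        _, p2, _ = angle_distribution(traj2, AxisDefinition("CE", "R4", "R1"),
                                      AxisDefinition("CE", "C1", "C4"), bins_deg=18)
        assert p2[-1] == pytest.approx(1.0)

    def test_isotropic_pairs_follow_sine_density(self):
        rng = np.random.default_rng(17)
        n = 60_000
        a = rng.normal(size=(n, 3)); a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = rng.normal(size=(n, 3)); b /= np.linalg.norm(b, axis=1, keepdims=True)
        com = rng.normal(size=(n, 3)) * 0.1 + [0, 0, 4.0]
        traj = _four_bead_ce(n, a, b, com)
        edges, p, _ = angle_distribution(traj, AxisDefinition("CE", "R4", "R1"),
                                         AxisDefinition("CE", "C1", "C4"), bins_deg=18)
        centers = np.deg2rad(0.5 * (edges[:-1] + edges[1:]))
        expected = np.sin(centers) / np.sin(centers).sum()
        np.testing.assert_allclose(p, expected, atol=0.006)

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(23)
        n = 500
        a = rng.normal(size=(n, 3)); a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = rng.normal(size=(n, 3)); b /= np.linalg.norm(b, axis=1, keepdims=True)
        com = rng.normal(size=(n, 3)) + [0, 0, 5.0]
        traj = _four_bead_ce(n, a, b, com)
        _, p, _ = angle_distribution(traj, AxisDefinition("CE", "R4", "R1"),
                                     AxisDefinition("CE", "C1", "C4"))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=1).as_matrix()
        rot = Trajectory(traj.topology, traj.times, traj.coords @ R.T)
        _, p_rot, _ = angle_distribution(rot, AxisDefinition("CE", "R4", "R1"),
                                         AxisDefinition("CE", "C1", "C4"))
        np.testing.assert_allclose(p, p_rot, atol=1e-12)


class TestConformationMap:
    def test_fixed_conformation_occupies_single_cell(self):
        theta, phi = np.deg2rad(30), np.deg2rad(120)
        n = 16
        ring = np.array([np.sin(theta), 0, np.cos(theta)])
        # chain at angle phi from the ring axis, in the x-z plane
        perp = np.array([np.cos(theta), 0, -np.sin(theta)])
        chain = np.cos(phi) * ring + np.sin(phi) * perp
        # antipodal mirror molecules pin the particle COM at the origin and
        # leave both angles unchanged (normal flips with the placement)
        com = np.vstack([np.tile([0.0, 0.0, 4.0], (n // 2, 1)),
                         np.tile([0.0, 0.0, -4.0], (n // 2, 1))])
        rings = np.vstack([np.tile(ring, (n // 2, 1)), np.tile(-ring, (n // 2, 1))])
        chains = np.vstack([np.tile(chain, (n // 2, 1)), np.tile(-chain, (n // 2, 1))])
        traj = _four_bead_ce(n, rings, chains, com)
        cmap = conformation_map(traj, bins_deg=36)
        assert cmap.prob.sum() == pytest.approx(1.0)
        i, j = np.unravel_index(np.argmax(cmap.prob), cmap.prob.shape)
        t_center = 0.5 * (cmap.theta_edges[i] + cmap.theta_edges[i + 1])
        p_center = 0.5 * (cmap.phi_edges[j] + cmap.phi_edges[j + 1])
        # angles sit on a bin edge; allow the cell on either side
        assert abs(t_center - 30) <= 2.5 + 1e-9
        assert abs(p_center - 120) <= 2.5 + 1e-9
        assert cmap.prob[i, j] == pytest.approx(1.0)

    def test_generator_chain_angle_recovered(self, droplet_traj):
        """CE molecules built with a 120 deg ring-chain angle put the phi
        marginal's mass at 120 deg."""
        cmap = conformation_map(droplet_traj, bins_deg=36)
        phi_marginal = cmap.prob.sum(axis=0)
        j = int(np.argmax(phi_marginal))
        p_center = 0.5 * (cmap.phi_edges[j] + cmap.phi_edges[j + 1])
        assert abs(p_center - 120) <= 2.5 + 1e-9

    def test_empty_region_filter_raises(self, droplet_traj):
        with pytest.raises(ValueError, match="surface"):
            # CE lives in the core of the generated droplet
            conformation_map(droplet_traj, region_filter="surface")
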