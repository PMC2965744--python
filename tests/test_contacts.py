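"""Annular lipids, contact lifetimes with the tolerance rule, profiles, RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropletmetrics.contacts import (annular_states, annular_summary,
                                     contact_lifetimes, intergroup_contacts,
                                     merge_interruptions, moiety_contact_fractions,
                                     pairs_within, residue_contact_profile, rmsf,
                                     ContactRecord)
from dropletmetrics.model import Trajectory
from dropletmetrics.synth import telegraph_contacts
from tests.conftest import (brute_merge, brute_pairs, concat_topologies,
                            protein_beads, single_frame, two_bead_molecules)


def _lipid_near_protein(distance: float):
    """One CHOL molecule with its nearest bead at the given distance from a
    one-residue protein."""
    prot = protein_beads(np.array([[0.0, 0.0, 0.0]]), ["TRP"])
    chol, chol_x = two_bead_molecules(
        np.array([[[distance, 0, 0], [distance + 0.6, 0, 0]]]), species="CHOL")
    top = concat_topologies([chol, prot])
    coords = np.concatenate([chol_x, np.zeros((1, 3))])
    return Trajectory(top, np.array([0.0, 0.1]), np.tile(coords, (2, 1, 1)))


class TestAnnularStates:
    @pytest.mark.parametrize("d,expected", [(0.79, True), (0.81, False), (0.8, False)])
    def test_strict_cutoff_boundary(self, d, expected):
        rec = annular_states(_lipid_near_protein(d), "CHOL", cutoff_nm=0.8)
        assert bool(rec.annular.all()) is expected

    def test_counts_match_all_pairs_oracle(self, droplet_traj):
        f = 0
        top = droplet_traj.topology
        prot = top.beads_of("PROTEIN")
        for sp in ("CHOL", "PPC"):
            rec = annular_states(droplet_traj, sp)
            mids = top.molecules_of(sp)
            lipid_beads = np.concatenate(
                [np.arange(top.molecule_slice(m).start, top.molecule_slice(m).stop)
                 for m in mids])
            pairs = brute_pairs(droplet_traj.coords[f, lipid_beads],
                                droplet_traj.coords[f, prot], 0.8)
            bead_mol = np.repeat(np.arange(mids.size),
                                 [top.molecule_slice(m).stop - top.molecule_slice(m).start
                                  for m in mids])
            expected = np.zeros(mids.size, dtype=bool)
            for i, _ in pairs:
                expected[bead_mol[i]] = True
            np.testing.assert_array_equal(rec.annular[f], expected)

    def test_no_protein_is_an_error(self):
        top, x = two_bead_molecules(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="protein"):
            annular_states(single_frame(top, x), "CHOL")


class TestAnnularSummary:
    def test_all_contact_record(self):
        rec = ContactRecord("CHOL", np.arange(49), np.ones((5, 49), bool), 0.8, 0.1)
        count, frac = annular_summary(rec)
        assert count == 49 and frac == 1.0

    def test_alternating_frames_give_half(self):
        ann = np.zeros((10, 4), dtype=bool)
        ann[::2] = True
        rec = ContactRecord("CE", np.arange(4), ann, 0.8, 0.1)
        _, frac = annular_summary(rec)
        assert frac == pytest.approx(0.5)

    def test_telegraph_stationary_fraction(self):
        m = telegraph_contacts(80.0, 80.0, 0.1, 400_000, 6, seed=3)
        rec = ContactRecord("CHOL", np.arange(6), m, 0.8, 0.1)
        _, frac = annular_summary(rec)
        assert frac == pytest.approx(0.5, abs=0.02)


class TestLifetimeToleranceRule:
    def test_short_gap_is_unbroken(self):
        series = np.array([1, 1, 0, 0, 0, 0, 0, 1, 1], dtype=bool)
        merged = merge_interruptions(series, tolerance_frames=10)
        assert merged.all()          # one contact interval spanning all 9 frames

    def test_gap_of_exactly_tolerance_breaks(self):
        series = np.array([1, 1] + [0] * 10 + [1, 1], dtype=bool)
        merged = merge_interruptions(series, tolerance_frames=10)
        np.testing.assert_array_equal(merged, series)   # two separate intervals

    def test_interior_gap_merging_with_padding(self):
        series = np.array([0] * 12 + [1, 1] + [0] * 5 + [1, 1] + [0] * 12, bool)
        st_ = contact_lifetimes(series, dt_ns=0.1, tolerance_frames=10)
        np.testing.assert_allclose(st_.on_dwells_ns, [0.9])   # 9 merged frames
        # the leading/trailing off-runs touch the ends: censored, not merged
        assert np.isnan(st_.mean_off_ns)
        np.testing.assert_allclose(np.sort(st_.censored_off_ns), [1.2, 1.2])

    def test_tolerance_one_equals_no_merging(self):
        rng = np.random.default_rng(4)
        s = rng.random(500) < 0.5
        np.testing.assert_array_equal(merge_interruptions(s, 1), s)
        np.testing.assert_array_equal(merge_interruptions(s, 0), s)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=200), st.integers(0, 12))
    def test_merge_matches_brute_force_oracle(self, series, tol):
        s = np.array(series, dtype=bool)
        np.testing.assert_array_equal(merge_interruptions(s, tol),
                                      brute_merge(s, tol))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_lifetime_monotone_in_tolerance(self, seed):
        m = telegraph_contacts(3.0, 3.0, 0.1, 2000, 2, seed=seed)
        means = []
        for tol in (0, 3, 8, 15):
            st_ = contact_lifetimes(m, dt_ns=0.1, tolerance_frames=tol)
            if st_.on_dwells_ns.size:
                means.append(st_.mean_on_ns)
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_telegraph_recovery_and_oracle_agreement(self):
        m = telegraph_contacts(146.0, 175.0, 0.1, 1_000_000, 6, seed=29)
        st0 = contact_lifetimes(m, dt_ns=0.1, tolerance_frames=0)
        assert st0.mean_on_ns == pytest.approx(146.0, rel=0.05)
        assert st0.mean_off_ns == pytest.approx(175.0, rel=0.05)
        st10 = contact_lifetimes(m, dt_ns=0.1, tolerance_frames=10)
        from tests.conftest import brute_dwells
        on = []
        for j in range(m.shape[1]):
            for val, ns, cens in brute_dwells(brute_merge(m[:, j], 10), 0.1):
                if val and not cens:
                    on.append(ns)
        assert st10.mean_on_ns == pytest.approx(np.mean(on), abs=1e-9)
        assert len(st10.on_dwells_ns) == len(on)


class TestResidueProfile:
    def test_normalisation_per_residue_multiplicity(self):
        """One CHOL bead in contact with one of four Trp residues scores
        0.25 per frame for Trp."""
        seq = ["TRP", "TRP", "TRP", "TRP", "SER"]
        pos = np.array([[0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0], [12, 0, 0.0]])
        prot = protein_beads(pos, seq)
        chol, chol_x = two_bead_molecules(np.array([[[0.5, 0, 0], [1.5, 0, 0]]]),
                                          species="CHOL")
        top = concat_topologies([chol, prot])
        traj = single_frame(top, np.concatenate([chol_x, pos]))
        df = residue_contact_profile(traj, "CHOL").set_index("residue_name")
        assert df.loc["TRP", "contacts_per_residue_per_frame"] == pytest.approx(0.25)
        assert df.loc["SER", "contacts_per_residue_per_frame"] == 0.0

    def test_matches_all_pairs_oracle(self, droplet_traj):
        top = droplet_traj.topology
        df = residue_contact_profile(droplet_traj, "CHOL")
        # oracle on frame-summed pair counts for one residue type
        prot = top.beads_of("PROTEIN")
        lipid = top.beads_of("CHOL")
        rn = df.residue_name.iloc[0]
        total = 0
        for f in range(droplet_traj.n_frames):
            pairs = brute_pairs(droplet_traj.coords[f, lipid],
                                droplet_traj.coords[f, prot], 0.8)
            total += sum(1 for _, j in pairs if top.residue_names[prot[j]] == rn)
        mult = int(df.set_index("residue_name").loc[rn, "n_in_sequence"])
        expected = total / mult / droplet_traj.n_frames
        assert df.set_index("residue_name").loc[
            rn, "contacts_per_residue_per_frame"] == pytest.approx(expected, abs=1e-9)


class TestMoietyFractions:
    def test_single_moiety_contact_is_100_percent(self):
        prot = protein_beads(np.zeros((1, 3)), ["PHE"])
        chol, chol_x = two_bead_molecules(
            np.array([[[0.5, 0, 0], [5.0, 0, 0]]]), species="CHOL",
            names=("R1", "C1"))
        # R1 -> sterol_ring (in contact), C1 far away
        top = concat_topologies([chol, prot])
        top.moieties[top.bead_names == "C1"] = "sterol_tail"
        traj = single_frame(top, np.concatenate([chol_x, np.zeros((1, 3))]))
        df = moiety_contact_fractions(traj)
        assert df.contact_pct.tolist() == [100.0]
        assert df.moiety.tolist() == ["sterol_ring"]

    def test_even_split(self):
        prot = protein_beads(np.zeros((1, 3)), ["PHE"])
        chol, chol_x = two_bead_molecules(
            np.array([[[0.5, 0, 0], [-0.5, 0, 0]]]), species="CHOL",
            names=("R1", "C1"))
        top = concat_topologies([chol, prot])
        top.moieties[top.bead_names == "C1"] = "sterol_tail"
        traj = single_frame(top, np.concatenate([chol_x, np.zeros((1, 3))]))
        df = moiety_contact_fractions(traj).set_index("moiety")
        assert df.loc["sterol_ring", "contact_pct"] == pytest.approx(50.0)
        assert df.loc["sterol_tail", "contact_pct"] == pytest.approx(50.0)

    def test_rows_sum_to_100_per_species(self, droplet_traj):
        df = moiety_contact_fractions(droplet_traj)
        sums = df.groupby("species").contact_pct.sum()
        np.testing.assert_allclose(sums, 100.0)


class TestIntergroupContacts:
    def test_pair_inside_and_outside_cutoff(self):
        top, x = two_bead_molecules(np.array([[[0, 0, 0], [0.5, 0, 0]]]))
        traj = single_frame(top, x)
        assert intergroup_contacts(traj, [0], [1])[0] == 1
        top2, x2 = two_bead_molecules(np.array([[[0, 0, 0], [0.9, 0, 0]]]))
        assert intergroup_contacts(single_frame(top2, x2), [0], [1])[0] == 0

    def test_random_fixture_matches_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 2.0, size=(100, 3))
        top, _ = two_bead_molecules(pts.reshape(50, 2, 3), species="TG",
                                    names=("C1A", "C2A"))
        traj = single_frame(top, pts)
        a, b = np.arange(50), np.arange(50, 100)
        got = intergroup_contacts(traj, a, b, cutoff_nm=0.8)[0]
        assert got == len(brute_pairs(pts[a], pts[b], 0.8))

    def test_empty_group_rejected(self, droplet_traj):
        with pytest.raises(ValueError, match="non-empty"):
            intergroup_contacts(droplet_traj, np.array([], dtype=int), [0])

    def test_overlap_requires_opt_in(self, droplet_traj):
        with pytest.raises(ValueError, match="overlap"):
            intergroup_contacts(droplet_traj, [0, 1], [1, 2])


class TestRmsf:
    def _static(self, n_frames=5):
        pos = np.array([[i * 0.35, 0, 0] for i in range(10)])
        top = protein_beads(pos, ["ALA"] * 10)
        coords = np.tile(pos, (n_frames, 1, 1))
        return Trajectory(top, np.arange(n_frames) * 0.1, coords), pos

    def test_static_structure_is_zero(self):
        traj, _ = self._static()
        out = rmsf(traj)
        np.testing.assert_allclose(out["A"].rmsf_nm, 0.0, atol=1e-10)

    def test_isotropic_jitter_analytic_value(self):
        rng = np.random.default_rng(71)
        sigma = 0.05
        pos = np.array([[i * 2.0, 0, 0] for i in range(12)])
        top = protein_beads(pos, ["ALA"] * 12)
        coords = pos[None] + rng.normal(scale=sigma, size=(10_000, 12, 3))
        traj = Trajectory(top, np.arange(10_000) * 0.1, coords)
        out = rmsf(traj, align=False)
        assert out["A"].rmsf_nm.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_rigid_rotation_removed_by_alignment(self):
        pos = np.array([[i * 0.35, (i % 3) * 0.2, 0] for i in range(10)])
        top = protein_beads(pos, ["LEU"] * 10)
        F = 30
        coords = np.empty((F, 10, 3))
        for f in range(F):
            a = 0.05 * f
            R = np.array([[np.cos(a), -np.sin(a), 0],
                          [np.sin(a), np.cos(a), 0], [0, 0, 1]])
            coords[f] = pos @ R.T
        traj = Trajectory(top, np.arange(F) * 0.1, coords)
        out = rmsf(traj, align=True)
        np.testing.assert_allclose(out["A"].rmsf_nm, 0.0, atol=1e-8)
        unaligned = rmsf(traj, align=False)
        assert unaligned["A"].rmsf_nm.mean() > 0.1

    def test_alignment_needs_three_beads(self):
        pos = np.zeros((2, 3))
        top = protein_beads(pos, ["ALA", "GLY"])
        traj = Trajectory(top, np.array([0.0, 0.1]), np.tile(pos, (2, 1, 1)))
        with pytest.raises(ValueError, match="3 beads"):
            rmsf(traj, align=True)
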