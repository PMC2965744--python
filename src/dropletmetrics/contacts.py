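"""Lipid-protein contacts, annular statistics, lifetimes and protein RMSF.

Contact conventions follow the analysis protocol for CG lipoproteins:

* intermolecular contacts use a 0.8 nm bead-bead cutoff, strict inequality
  (distance < cutoff; the boundary itself is a measure-zero set);
* an *annular* lipid has any bead within 0.8 nm (8 Å) of any protein bead in
  a given frame;
* a contact's lifetime tolerates interruptions: if the separation exceeds the
  cutoff temporarily for *fewer than* ``tolerance_frames`` frames (default 10
  frames = 0.1 ns at a 0.01 ns sampling), the coupling counts as unbroken.

Neighbor searches are KD-tree accelerated and, by contract, agree exactly
with a brute-force all-pairs scan (strict inequality both sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import LIPID_SPECIES, Topology, Trajectory

DEFAULT_CUTOFF_NM = 0.8
DEFAULT_TOLERANCE_FRAMES = 10


def pairs_within(coords_a: np.ndarray, coords_b: np.ndarray, cutoff_nm: float,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i into a, j into b) with distance strictly < cutoff."""
    ta, tb = cKDTree(coords_a), cKDTree(coords_b)
    m = ta.sparse_distance_matrix(tb, max_distance=cutoff_nm, output_type="coo_matrix")
    keep = m.data < cutoff_nm
    return m.row[keep], m.col[keep]


@dataclass
class ContactRecord:
    """Per-(lipid, frame) annular state for one species."""

    species: str
    lipid_molecule_ids: np.ndarray        # (M,)
    annular: np.ndarray                   # (F, M) bool
    cutoff_nm: float
    dt_ns: float

    @property
    def n_frames(self) -> int:
        return self.annular.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.annular.shape[1]


def annular_states(trajectory: Trajectory, species: str,
                   cutoff_nm: float = DEFAULT_CUTOFF_NM) -> ContactRecord:
    """Per frame, a lipid is annular iff its minimum bead-bead distance to any
    protein bead is strictly below the cutoff."""
    top = trajectory.topology
    prot = top.beads_of("PROTEIN")
    if prot.size == 0:
        raise ValueError("no protein beads in topology; annular states undefined")
    mids = top.molecules_of(species)
    if mids.size == 0:
        raise ValueError(f"no molecules of species {species!r}")
    lipid_beads = np.concatenate([np.arange(top.molecule_slice(m).start,
                                            top.molecule_slice(m).stop) for m in mids])
    bead_mol = np.concatenate([np.full(top.molecule_slice(m).stop - top.molecule_slice(m).start, k)
                               for k, m in enumerate(mids)])
    F = trajectory.n_frames
    out = np.zeros((F, mids.size), dtype=bool)
    for f in range(F):
        tree = cKDTree(trajectory.coords[f, prot])
        d, _ = tree.query(trajectory.coords[f, lipid_beads], k=1)
        hit = d < cutoff_nm
        if hit.any():
            out[f, np.unique(bead_mol[hit])] = True
    dt = trajectory.dt_ns if F > 1 else 0.0
    return ContactRecord(species, mids, out, cutoff_nm, dt)


def annular_summary(record: ContactRecord) -> tuple[float, float]:
    """Time-averaged annular count and fraction for the record's species."""
    if record.annular.size == 0:
        raise ValueError("empty contact record")
    per_frame = record.annular.sum(axis=1)
    mean_count = float(per_frame.mean())
    return mean_count, mean_count / record.n_lipids


@dataclass
class LifetimeStats:
    """Contact / non-contact dwell statistics after tolerance merging.

    Intervals touching either trajectory end are censored: their true length
    is unknown, so they are excluded from the default means and reported
    separately (means including them are also given).
    """

    mean_on_ns: float
    mean_off_ns: float
    on_dwells_ns: np.ndarray
    off_dwells_ns: np.ndarray
    censored_on_ns: np.ndarray
    censored_off_ns: np.ndarray
    tolerance_frames: int
    mean_on_incl_censored_ns: float
    mean_off_incl_censored_ns: float


def _runs(series: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean series as (value, start, length)."""
    s = np.asarray(series, dtype=bool)
    starts = np.r_[0, np.flatnonzero(s[1:] != s[:-1]) + 1]
    lengths = np.diff(np.r_[starts, len(s)])
    return [(bool(s[st]), int(st), int(ln)) for st, ln in zip(starts, lengths)]


def merge_interruptions(series: np.ndarray, tolerance_frames: int) -> np.ndarray:
    """Fill interior off-gaps strictly shorter than the tolerance.

    Only gaps flanked by contact on both sides are merged (leading/trailing
    off-runs have no surrounding contact to keep unbroken).  ``tolerance_frames
    <= 1`` is a no-op: a strictly-shorter-than-1 gap would be empty.
    """
    s = np.asarray(series, dtype=bool).copy()
    runs = _runs(s)
    for idx, (val, start, length) in enumerate(runs):
        if (not val and 0 < idx < len(runs) - 1 and length < tolerance_frames):
            s[start:start + length] = True
    return s


def contact_lifetimes(record: ContactRecord | np.ndarray, dt_ns: float | None = None,
                      tolerance_frames: int = DEFAULT_TOLERANCE_FRAMES) -> LifetimeStats:
    """Dwell-time statistics of contact series under the tolerance rule.

    Accepts a :class:`ContactRecord` or a raw boolean matrix ``(F, M)`` with
    an explicit frame interval.  Off-gaps strictly shorter than
    ``tolerance_frames`` are considered unbroken contact; dwell times are the
    merged run lengths times the frame interval.
    """
    if isinstance(record, ContactRecord):
        mat = record.annular
        dt = record.dt_ns
    else:
        mat = np.asarray(record, dtype=bool)
        if dt_ns is None:
            raise ValueError("dt_ns required with a raw boolean matrix")
        dt = dt_ns
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 frames for lifetimes")

    on, off, c_on, c_off = [], [], [], []
    for j in range(mat.shape[1]):
        merged = merge_interruptions(mat[:, j], tolerance_frames)
        runs = _runs(merged)
        for idx, (val, start, length) in enumerate(runs):
            censored = idx == 0 or idx == len(runs) - 1
            target = (c_on if censored else on) if val else (c_off if censored else off)
            target.append(length * dt)

    on_a, off_a = np.asarray(on), np.asarray(off)
    c_on_a, c_off_a = np.asarray(c_on), np.asarray(c_off)
    mean = lambda a: float(a.mean()) if a.size else float("nan")
    return LifetimeStats(
        mean_on_ns=mean(on_a), mean_off_ns=mean(off_a),
        on_dwells_ns=on_a, off_dwells_ns=off_a,
        censored_on_ns=c_on_a, censored_off_ns=c_off_a,
        tolerance_frames=tolerance_frames,
        mean_on_incl_censored_ns=mean(np.r_[on_a, c_on_a]),
        mean_off_incl_censored_ns=mean(np.r_[off_a, c_off_a]))


def residue_contact_profile(trajectory: Trajectory, species: str = "CHOL",
                            cutoff_nm: float = DEFAULT_CUTOFF_NM,
                            ) -> pd.DataFrame:
    """Mean lipid-protein contacts per residue *type*, normalised per residue.

    For every frame, (lipid bead, protein bead) pairs within the cutoff are
    aggregated by the protein residue type and divided by that type's
    multiplicity in the sequence; the result is averaged over frames.
    Includes a hydrophobic/hydrophilic roll-up column.
    """
    top = trajectory.topology
    prot = top.beads_of("PROTEIN")
    if prot.size == 0:
        raise ValueError("no protein beads")
    missing = sorted({top.residue_names[i] for i in prot if top.hydro_classes[i] == ""})
    if missing:
        raise ValueError(f"residues lacking hydro_class: {missing}")
    lipid = top.beads_of(species)
    if lipid.size == 0:
        raise ValueError(f"no beads of species {species!r}")

    res_table = top.protein_residue_table()
    multiplicity = res_table["residue_name"].value_counts()
    hydro_of = dict(zip(res_table["residue_name"], res_table["hydro_class"]))

    prot_resname = top.residue_names[prot]
    counts: dict[str, float] = {rn: 0.0 for rn in multiplicity.index}
    for f in range(trajectory.n_frames):
        _, pj = pairs_within(trajectory.coords[f, lipid], trajectory.coords[f, prot],
                             cutoff_nm)
        for rn, c in zip(*np.unique(prot_resname[pj], return_counts=True)):
            counts[rn] += float(c)
    rows = []
    for rn in multiplicity.index:
        per_res = counts[rn] / multiplicity[rn] / trajectory.n_frames
        rows.append((rn, int(multiplicity[rn]), hydro_of[rn], per_res))
    df = pd.DataFrame(rows, columns=["residue_name", "n_in_sequence", "hydro_class",
                                     "contacts_per_residue_per_frame"])
    return df.sort_values("contacts_per_residue_per_frame", ascending=False,
                          ignore_index=True)


def moiety_contact_fractions(trajectory: Trajectory,
                             cutoff_nm: float = DEFAULT_CUTOFF_NM) -> pd.DataFrame:
    """Percentage of lipid-protein bead contacts per lipid moiety.

    Rows are (species, moiety, pct); within each species the percentages sum
    to 100 (species with zero contacts are omitted).
    """
    top = trajectory.topology
    prot = top.beads_of("PROTEIN")
    if prot.size == 0:
        raise ValueError("no protein beads")
    lipid_mask = np.isin(top.species, LIPID_SPECIES)
    lipid = np.flatnonzero(lipid_mask)
    if np.any(top.moieties[lipid] == "other"):
        bad = np.flatnonzero(lipid_mask & (top.moieties == "other"))
        raise ValueError(f"unlabeled lipid beads (moiety 'other'): ids {bad[:10].tolist()}")
    key = [(top.species[i], top.moieties[i]) for i in lipid]
    totals: dict[tuple[str, str], float] = {}
    for f in range(trajectory.n_frames):
        li, _ = pairs_within(trajectory.coords[f, lipid], trajectory.coords[f, prot],
                             cutoff_nm)
        for i, c in zip(*np.unique(li, return_counts=True)):
            totals[key[i]] = totals.get(key[i], 0.0) + float(c)
    per_species: dict[str, float] = {}
    for (sp, _), v in totals.items():
        per_species[sp] = per_species.get(sp, 0.0) + v
    rows = [(sp, moi, 100.0 * v / per_species[sp])
            for (sp, moi), v in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["species", "moiety", "contact_pct"])


def intergroup_contacts(trajectory: Trajectory, group_a: np.ndarray,
                        group_b: np.ndarray, cutoff_nm: float = DEFAULT_CUTOFF_NM,
                        allow_overlap: bool = False) -> np.ndarray:
    """Per-frame count of bead pairs (a in A, b in B) strictly within cutoff."""
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("contact groups must be non-empty")
    if not allow_overlap and np.intersect1d(a, b).size:
        raise ValueError("groups overlap; pass allow_overlap=True if intended")
    out = np.empty(trajectory.n_frames, dtype=np.int64)
    for f in range(trajectory.n_frames):
        ai, bj = pairs_within(trajectory.coords[f, a], trajectory.coords[f, b], cutoff_nm)
        if allow_overlap:
            same = a[ai] == b[bj]
            out[f] = ai.size - int(same.sum())
        else:
            out[f] = ai.size
    return out


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition of P onto Q: returns (R, tP, tQ) with
    aligned = (P - tP) @ R + tQ."""
    tP, tQ = P.mean(axis=0), Q.mean(axis=0)
    H = (P - tP).T @ (Q - tQ)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return R, tP, tQ


def rmsf(trajectory: Trajectory, align: bool = True) -> dict[str, pd.DataFrame]:
    """Per-residue RMSF (nm) of protein backbone beads, per chain.

    With ``align=True`` (default) every frame's backbone selection is rigidly
    superposed onto the first frame before measuring fluctuations — the
    droplet tumbles freely, and unaligned RMSF would measure rotation, not
    flexibility.  RMSFᵢ = sqrt(⟨||xᵢ(t) − ⟨xᵢ⟩||²⟩).
    """
    top = trajectory.topology
    if trajectory.n_frames < 2:
        raise ValueError("need >= 2 frames for RMSF")
    bb = np.flatnonzero((top.species == "PROTEIN") & (top.moieties == "backbone"))
    if bb.size == 0:
        raise ValueError("no protein backbone beads")
    if align and bb.size < 3:
        raise ValueError("alignment needs >= 3 beads (rotation underdetermined)")
    X = trajectory.coords[:, bb, :].copy()
    if align:
        ref = X[0]
        for f in range(1, X.shape[0]):
            R, tP, tQ = kabsch_rotation(X[f], ref)
            X[f] = (X[f] - tP) @ R + tQ
    mean = X.mean(axis=0)
    per_bead = np.sqrt(((X - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    out: dict[str, pd.DataFrame] = {}
    for ch in sorted(set(top.chain_labels[bb])):
        sel = top.chain_labels[bb] == ch
        out[ch] = pd.DataFrame({
            "residue_index": top.residue_indices[bb][sel].astype(int),
            "residue_name": top.residue_names[bb][sel],
            "rmsf_nm": per_bead[sel]}).sort_values("residue_index", ignore_index=True)
    return out
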