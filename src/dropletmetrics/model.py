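"""Data model for coarse-grained lipoprotein particles.

A droplet is described by a :class:`Topology` (static per-bead annotation:
molecule membership, lipid species, moiety, protein residue information) and a
:class:`Trajectory` (ordered frames of bead coordinates).

Internal unit convention: lengths in nm, times in ns.  Trajectory times are
*effective* times — coarse-grained simulation time multiplied by 4 to map CG
dynamics onto real dynamics — whenever ``time_scale_applied`` is set.

Bead ids are dense ``0..N-1`` and beads of one molecule are stored
contiguously, sorted by ``molecule_id``; this permits fast per-molecule
reductions with ``np.add.reduceat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: recognised lipid/solvent species plus protein
SPECIES = ("POPC", "PPC", "CHOL", "CE", "TG", "PROTEIN", "WATER")
LIPID_SPECIES = ("POPC", "PPC", "CHOL", "CE", "TG")

MOIETIES = (
    "headgroup", "glycerol", "sn1_chain", "sn2_chain", "sn3_chain",
    "sterol_ring", "sterol_tail", "ester", "oleate_chain",
    "backbone", "sidechain", "other",
)

HYDRO_CLASSES = ("hydrophobic", "hydrophilic")

#: residues counted as hydrophobic for SASA / contact roll-ups.  Tyr and His
#: are amphipathic aromatics kept in the hydrophilic class (their interfacial
#: hydrophobicity rivals Phe, but the two-class split follows the standard
#: convention); the table is editable via ``dropletmetrics/data``.
DEFAULT_HYDROPHOBIC = frozenset({"TRP", "PHE", "VAL", "LEU", "ILE", "MET", "ALA"})


class TopologyError(ValueError):
    """Inconsistent or malformed topology."""


class WrapError(ValueError):
    """A molecule looks wrapped across periodic boundaries."""


@dataclass
class Topology:
    """Static per-bead annotation of a CG particle.

    All arrays have length ``n_beads`` and are indexed by bead id.

    Parameters
    ----------
    bead_names : array of str
        CG bead names (e.g. ``NC3``, ``ROH``, ``BB``).
    molecule_ids : array of int
        Dense molecule index; constant species within a molecule.
    species : array of str
        One of :data:`SPECIES` per bead.
    moieties : array of str
        Moiety label for lipid beads (``other`` where not applicable);
        ``backbone``/``sidechain`` for protein beads.
    residue_indices : array of int
        Protein residue index within its chain (0-based); ``-1`` elsewhere.
    residue_names : array of str
        Three-letter residue names for protein beads; ``""`` elsewhere.
    hydro_classes : array of str
        ``hydrophobic``/``hydrophilic`` for protein beads; ``""`` elsewhere.
    chain_labels : array of str
        Protein chain label (``A``, ``B``, ...); ``""`` for non-protein beads.
    """

    bead_names: np.ndarray
    molecule_ids: np.ndarray
    species: np.ndarray
    moieties: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    hydro_classes: np.ndarray
    chain_labels: np.ndarray

    def __post_init__(self) -> None:
        as_obj = lambda a: np.asarray(a, dtype=object)
        self.bead_names = as_obj(self.bead_names)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.species = as_obj(self.species)
        self.moieties = as_obj(self.moieties)
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64)
        self.residue_names = as_obj(self.residue_names)
        self.hydro_classes = as_obj(self.hydro_classes)
        self.chain_labels = as_obj(self.chain_labels)
        self.validate()
        self._build_index()

    # -- construction helpers -------------------------------------------------

    def validate(self) -> None:
        n = len(self.bead_names)
        for name in ("molecule_ids", "species", "moieties", "residue_indices",
                     "residue_names", "hydro_classes", "chain_labels"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if n == 0:
            raise TopologyError("empty topology")
        bad = set(self.species) - set(SPECIES)
        if bad:
            raise TopologyError(f"unknown species: {sorted(bad)}")
        bad = set(self.moieties) - set(MOIETIES)
        if bad:
            raise TopologyError(f"unknown moieties: {sorted(bad)}")
        mids = self.molecule_ids
        if np.any(np.diff(mids) < 0):
            raise TopologyError("beads must be sorted by molecule_id")
        uniq = np.unique(mids)
        if uniq[0] != 0 or uniq[-1] != len(uniq) - 1:
            raise TopologyError("molecule ids must be dense 0..M-1")
        # species constant within a molecule
        first = np.r_[True, np.diff(mids) > 0]
        mol_species = self.species[first]
        for b in range(n):
            if self.species[b] != mol_species[mids[b]]:
                raise TopologyError(f"bead {b}: species varies within molecule {mids[b]}")
        prot = self.species == "PROTEIN"
        if np.any(prot & (self.residue_indices < 0)):
            raise TopologyError("protein beads must carry residue_index")
        if np.any(prot & (self.residue_names == "")):
            raise TopologyError("protein beads must carry residue_name")
        if np.any(prot & (self.hydro_classes == "")):
            raise TopologyError("protein beads must carry hydro_class")

    def _build_index(self) -> None:
        mids = self.molecule_ids
        first = np.r_[True, np.diff(mids) > 0]
        self._mol_starts = np.flatnonzero(first)
        self._mol_counts = np.diff(np.r_[self._mol_starts, len(mids)])
        self._mol_species = self.species[first]

    # -- queries --------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def n_molecules(self) -> int:
        return len(self._mol_starts)

    @property
    def molecule_species(self) -> np.ndarray:
        """Species of each molecule (length ``n_molecules``)."""
        return self._mol_species

    def molecule_slice(self, molecule_id: int) -> slice:
        if not 0 <= molecule_id < self.n_molecules:
            raise KeyError(f"unknown molecule id {molecule_id}")
        s = self._mol_starts[molecule_id]
        return slice(s, s + self._mol_counts[molecule_id])

    def molecules_of(self, species: str) -> np.ndarray:
        """Molecule ids of one species."""
        return np.flatnonzero(self._mol_species == species)

    def beads_of(self, species: str) -> np.ndarray:
        """Bead ids of one species."""
        return np.flatnonzero(self.species == species)

    def species_census(self) -> dict[str, int]:
        """Molecule counts per species (protein counted per chain)."""
        out: dict[str, int] = {}
        for sp in SPECIES:
            c = int(np.sum(self._mol_species == sp))
            if c:
                out[sp] = c
        return out

    def protein_residue_table(self) -> "pd.DataFrame":
        """One row per protein residue: chain, residue_index, name, class."""
        import pandas as pd

        prot = np.flatnonzero(self.species == "PROTEIN")
        if prot.size == 0:
            return pd.DataFrame(columns=["chain", "residue_index", "residue_name", "hydro_class"])
        key = list(zip(self.chain_labels[prot], self.residue_indices[prot]))
        seen: dict[tuple, int] = {}
        rows = []
        for i, k in zip(prot, key):
            if k not in seen:
                seen[k] = 1
                rows.append((self.chain_labels[i], int(self.residue_indices[i]),
                             self.residue_names[i], self.hydro_classes[i]))
        return pd.DataFrame(rows, columns=["chain", "residue_index", "residue_name", "hydro_class"])


@dataclass
class Trajectory:
    """Ordered frames of bead coordinates in nm with effective times in ns."""

    topology: Topology
    times: np.ndarray                      # (n_frames,) ns, strictly increasing
    coords: np.ndarray                     # (n_frames, n_beads, 3) nm
    box: np.ndarray | None = None          # optional (n_frames, 3, 3) nm
    time_scale_applied: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if self.coords.shape[1] != self.topology.n_beads:
            raise ValueError(
                f"bead count mismatch: topology has {self.topology.n_beads} beads, "
                f"frames have {self.coords.shape[1]}")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt_ns(self) -> float:
        """Frame interval, assuming a uniform grid."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame interval")
        return float(self.times[1] - self.times[0])

    def check_wrap(self, max_extent_nm: float = 5.0, frame_index: int = 0,
                   include_protein: bool = False) -> None:
        """Reject molecules whose internal extent suggests a wrapped image.

        Coordinates are treated as whole-molecule (unwrapped); the droplet is
        compact and far from the box walls, so any bead-bead span beyond
        ``max_extent_nm`` within one molecule flags a wrapping artefact.
        Protein chains are skipped by default: a belt protein legitimately
        spans the whole particle diameter.
        """
        x = self.coords[frame_index]
        top = self.topology
        for m in range(top.n_molecules):
            if not include_protein and top.molecule_species[m] == "PROTEIN":
                continue
            xm = x[top.molecule_slice(m)]
            span = xm.max(axis=0) - xm.min(axis=0)
            if np.any(span > max_extent_nm):
                raise WrapError(
                    f"molecule {m} spans {span.max():.2f} nm > {max_extent_nm} nm; "
                    "likely wrapped across periodic boundaries")


def molecule_com(trajectory: Trajectory, molecule_id: int, frame_index: int,
                 weights: np.ndarray | str = "uniform") -> np.ndarray:
    """Center of mass of one molecule in one frame (nm).

    ``weights`` is ``"uniform"`` (default; the CG bead masses are not part of
    the trajectory contract) or an explicit per-bead mass vector for the
    molecule.
    """
    sl = trajectory.topology.molecule_slice(molecule_id)
    x = trajectory.coords[frame_index, sl]
    if isinstance(weights, str):
        if weights != "uniform":
            raise ValueError(f"unknown weighting {weights!r}")
        return x.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError("mass vector length does not match molecule size")
    return (x * w[:, None]).sum(axis=0) / w.sum()


def molecule_com_series(trajectory: Trajectory, molecule_ids: Sequence[int] | np.ndarray,
                        ) -> np.ndarray:
    """Uniform-weight COM of each listed molecule in every frame.

    Returns ``(n_frames, n_molecules, 3)``.  Uses contiguous bead storage for
    a vectorised segmented reduction.
    """
    top = trajectory.topology
    mids = np.asarray(molecule_ids, dtype=np.int64)
    starts = top._mol_starts[mids]
    counts = top._mol_counts[mids]
    # gather all beads of the requested molecules, molecule-contiguous
    idx = np.concatenate([np.arange(s, s + c) for s, c in zip(starts, counts)])
    seg = np.r_[0, np.cumsum(counts)[:-1]]
    x = trajectory.coords[:, idx, :]                        # (F, B, 3)
    sums = np.add.reduceat(x, seg, axis=1)                  # (F, M, 3)
    return sums / counts[None, :, None]


def particle_com(trajectory: Trajectory, include: Iterable[str] = LIPID_SPECIES,
                 ) -> np.ndarray:
    """Per-frame center of the particle (nm), uniform bead weights.

    By default the reference COM is computed over lipid beads only — water is
    excluded always, protein by default — matching the analysis convention of
    measuring distances "from the center of mass of the particle".
    """
    top = trajectory.topology
    mask = np.isin(top.species, list(include))
    if not mask.any():
        raise ValueError(f"no beads in species selection {sorted(set(include))}")
    return trajectory.coords[:, mask, :].mean(axis=1)
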