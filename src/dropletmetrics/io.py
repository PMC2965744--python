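"""Readers and writers for standard CG structure/trajectory formats.

File parsing is delegated to MDAnalysis (GRO/PDB structures, XTC/DCD
trajectories); this module converts to the package's internal contract:
lengths in nm, times in ns, species/moiety annotation resolved through the
editable mapping table shipped in ``dropletmetrics/data/bead_map.txt``.

Effective time: MARTINI CG dynamics map onto real dynamics after multiplying
simulation time by 4; ``read_trajectory(..., apply_time_scale=True)`` applies
that factor on ingest and records it on the Trajectory.
"""

from __future__ import annotations

import fnmatch
import warnings
from importlib import resources
from pathlib import Path

import numpy as np

from .model import Topology, Trajectory, DEFAULT_HYDROPHOBIC

TIME_SCALE_FACTOR = 4.0


class ParseError(ValueError):
    """File could not be parsed under the named dialect."""


class UnknownNameError(KeyError):
    """A residue or bead name has no entry in the mapping table."""


def _data_text(name: str) -> str:
    return resources.files("dropletmetrics.data").joinpath(name).read_text()


class BeadMap:
    """Residue-name -> species and (species, bead-name) -> moiety mapping.

    Loaded from a plain-text table; bead-name keys are fnmatch globs, first
    match wins.  Ship-your-own tables cover non-default CG naming schemes.
    """

    def __init__(self, species_map: dict[str, str], moiety_rules: list[tuple[str, str, str]],
                 hydro_map: dict[str, str] | None = None):
        self.species_map = species_map
        self.moiety_rules = moiety_rules
        self.hydro_map = hydro_map or load_hydrophobicity()

    @classmethod
    def from_text(cls, text: str, hydro_map: dict[str, str] | None = None) -> "BeadMap":
        species_map: dict[str, str] = {}
        moiety_rules: list[tuple[str, str, str]] = []
        section = None
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]").lower()
                continue
            parts = line.split()
            if section == "species" and len(parts) == 2:
                species_map[parts[0]] = parts[1]
            elif section == "moiety" and len(parts) == 3:
                moiety_rules.append((parts[0], parts[1], parts[2]))
            else:
                raise ParseError(f"malformed mapping line: {raw!r}")
        return cls(species_map, moiety_rules, hydro_map)

    @classmethod
    def default(cls) -> "BeadMap":
        return cls.from_text(_data_text("bead_map.txt"))

    def species_of(self, resname: str) -> str:
        try:
            return self.species_map[resname]
        except KeyError:
            raise UnknownNameError(
                f"residue name {resname!r} has no species assignment in the mapping table")

    def moiety_of(self, species: str, bead_name: str) -> str:
        for sp, pattern, moiety in self.moiety_rules:
            if sp == species and fnmatch.fnmatchcase(bead_name, pattern):
                return moiety
        raise UnknownNameError(
            f"bead name {bead_name!r} of species {species} has no moiety assignment")


def load_hydrophobicity() -> dict[str, str]:
    """Editable residue -> hydrophobic/hydrophilic table."""
    out: dict[str, str] = {}
    for raw in _data_text("hydrophobicity.txt").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            res, cls_ = line.split()
            out[res] = cls_
    return out


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _topology_from_universe(u, bead_map: BeadMap) -> Topology:
    n = len(u.atoms)
    bead_names = np.array([a.name for a in u.atoms], dtype=object)
    resnames = [r.resname for r in u.residues]
    resids = [r.resid for r in u.residues]

    species_per_res = [bead_map.species_of(rn) for rn in resnames]

    # molecule assignment: each non-protein residue is one molecule; runs of
    # consecutive protein residues form one chain, broken on a resid decrease
    # (chains restart numbering) or on an intervening non-protein residue.
    mol_of_res = np.empty(len(resnames), dtype=np.int64)
    chain_of_res = [""] * len(resnames)
    mol = -1
    chain_ord = 0
    prev_protein = False
    prev_resid = None
    for i, sp in enumerate(species_per_res):
        if sp == "PROTEIN":
            new_chain = not prev_protein or (prev_resid is not None and resids[i] <= prev_resid)
            if new_chain:
                mol += 1
                chain_ord += 1
            chain_of_res[i] = chr(ord("A") + chain_ord - 1)
            prev_protein = True
        else:
            mol += 1
            prev_protein = False
        mol_of_res[i] = mol
        prev_resid = resids[i]

    molecule_ids = np.empty(n, dtype=np.int64)
    species = np.empty(n, dtype=object)
    moieties = np.empty(n, dtype=object)
    residue_indices = np.full(n, -1, dtype=np.int64)
    residue_names = np.full(n, "", dtype=object)
    hydro_classes = np.full(n, "", dtype=object)
    chain_labels = np.full(n, "", dtype=object)

    res_index_in_chain: dict[int, int] = {}
    counters: dict[str, int] = {}
    for ri, res in enumerate(u.residues):
        ch = chain_of_res[ri]
        if species_per_res[ri] == "PROTEIN":
            res_index_in_chain[ri] = counters.get(ch, 0)
            counters[ch] = res_index_in_chain[ri] + 1

    for a in u.atoms:
        ri = a.residue.ix
        i = a.ix
        sp = species_per_res[ri]
        molecule_ids[i] = mol_of_res[ri]
        species[i] = sp
        moieties[i] = bead_map.moiety_of(sp, bead_names[i])
        if sp == "PROTEIN":
            rn = resnames[ri]
            residue_indices[i] = res_index_in_chain[ri]
            residue_names[i] = rn
            try:
                hydro_classes[i] = bead_map.hydro_map[rn]
            except KeyError:
                raise UnknownNameError(f"residue {rn!r} has no hydrophobicity class")
            chain_labels[i] = chain_of_res[ri]

    return Topology(bead_names, molecule_ids, species, moieties,
                    residue_indices, residue_names, hydro_classes, chain_labels)


def read_structure(path: str | Path, dialect: str | None = None,
                   bead_map: BeadMap | None = None) -> tuple[Topology, np.ndarray]:
    """Read a GRO or PDB structure; return topology + single frame (nm).

    MDAnalysis reports positions in Å; they are converted to nm on ingest
    (GRO files store nm natively, PDB stores Å — both arrive here in nm).
    """
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).upper()
    if dialect not in ("GRO", "PDB"):
        raise ValueError(f"unsupported structure dialect {dialect!r}")
    mda = _import_mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=dialect)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise ParseError(f"could not parse {path} as {dialect}: {exc}") from exc
    bead_map = bead_map or BeadMap.default()
    top = _topology_from_universe(u, bead_map)
    coords = u.atoms.positions.astype(float) / 10.0  # Å -> nm
    return top, coords


def read_trajectory(topology: Topology, path: str | Path, dialect: str | None = None,
                    apply_time_scale: bool = False) -> Trajectory:
    """Read an XTC or DCD coordinate trajectory against a known topology.

    Frame times are converted ps -> ns and multiplied by
    :data:`TIME_SCALE_FACTOR` iff ``apply_time_scale``.
    """
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).upper()
    if dialect not in ("XTC", "DCD"):
        raise ValueError(f"unsupported trajectory dialect {dialect!r}")
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_beads, trajectory=True)
        try:
            u.load_new(str(path), format=dialect)
        except Exception as exc:  # includes bead-count mismatches from readers
            raise ParseError(f"could not read {path} as {dialect}: {exc}") from exc
        n_file = u.trajectory.n_atoms
        if n_file != topology.n_beads:
            raise ValueError(
                f"bead count mismatch: topology has {topology.n_beads} beads, "
                f"trajectory file has {n_file}")
        frames, times = [], []
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float) / 10.0)
            times.append(ts.time / 1000.0)  # ps -> ns
    coords = np.stack(frames)
    times_arr = np.asarray(times)
    if apply_time_scale:
        times_arr = times_arr * TIME_SCALE_FACTOR
    order = np.argsort(times_arr, kind="stable")
    return Trajectory(topology, times_arr[order], coords[order],
                      time_scale_applied=apply_time_scale)


def _universe_from(topology: Topology, coords: np.ndarray):
    mda = _import_mda()
    top = topology
    # residue structure: lipids/water one residue per molecule; protein one
    # residue per (chain, residue_index)
    res_key = []
    for i in range(top.n_beads):
        if top.species[i] == "PROTEIN":
            res_key.append(("P", top.chain_labels[i], int(top.residue_indices[i])))
        else:
            res_key.append(("M", int(top.molecule_ids[i]), 0))
    uniq: dict[tuple, int] = {}
    atom_resindex = np.empty(top.n_beads, dtype=np.int64)
    res_names, res_ids = [], []
    next_resid_nonprot = 0
    chain_resid: dict[str, int] = {}
    for i, k in enumerate(res_key):
        if k not in uniq:
            uniq[k] = len(uniq)
            if k[0] == "P":
                res_names.append(top.residue_names[i])
                chain_resid[k[1]] = chain_resid.get(k[1], 0) + 1
                res_ids.append(chain_resid[k[1]])
            else:
                sp = top.species[i]
                res_names.append("W" if sp == "WATER" else sp)
                next_resid_nonprot += 1
                res_ids.append(next_resid_nonprot)
        atom_resindex[i] = uniq[k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(top.n_beads, n_residues=len(uniq),
                               atom_resindex=atom_resindex, trajectory=True)
        u.add_TopologyAttr("names", list(top.bead_names))
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", res_ids)
        u.atoms.positions = np.asarray(coords) * 10.0  # nm -> Å
    return u


def write_structure(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write a single frame as GRO or PDB (dialect from extension)."""
    u = _universe_from(topology, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as XTC or DCD (dialect from extension); times ns -> ps.

    Stored times are the trajectory's own (effective if scaled); a reader
    applying the time scale again would double-scale, so scaled trajectories
    should be read back with ``apply_time_scale=False``.
    """
    mda = _import_mda()
    u = _universe_from(trajectory.topology, trajectory.coords[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.topology.n_beads) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coords[f] * 10.0
                u.trajectory.ts.time = trajectory.times[f] * 1000.0
                u.trajectory.ts.frame = f
                w.write(u.atoms)
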