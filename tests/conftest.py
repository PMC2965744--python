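"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from dropletmetrics.model import Topology, Trajectory
from dropletmetrics.synth import SyntheticSpec, build_trajectory


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent of the package
# implementations they check)
# ---------------------------------------------------------------------------

def brute_pairs(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float,
                ) -> set[tuple[int, int]]:
    """All-pairs strict-inequality neighbor scan."""
    out = set()
    for i, a in enumerate(coords_a):
        for j, b in enumerate(coords_b):
            if np.sqrt(((a - b) ** 2).sum()) < cutoff:
                out.add((i, j))
    return out


def brute_merge(series, tolerance: int):
    """Naive gap-merging: interior off-gaps strictly shorter than tolerance
    become contact."""
    s = list(bool(v) for v in series)
    n = len(s)
    i = 0
    out = s[:]
    while i < n:
        if not s[i]:
            j = i
            while j < n and not s[j]:
                j += 1
            gap = j - i
            interior = i > 0 and j < n
            if interior and gap < tolerance:
                for k in range(i, j):
                    out[k] = True
            i = j
        else:
            i += 1
    return np.array(out, dtype=bool)


def brute_dwells(series, dt: float):
    """(value, length_ns, censored) tuples of a boolean series."""
    s = list(bool(v) for v in series)
    runs = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            runs.append((s[start], (i - start) * dt, start == 0 or i == len(s)))
            start = i
    return runs


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def droplet_spec() -> SyntheticSpec:
    """Default study composition, short trajectory for structure/contact tests."""
    return SyntheticSpec(n_frames=60, seed=123)


@pytest.fixture(scope="session")
def droplet_traj(droplet_spec) -> Trajectory:
    return build_trajectory(droplet_spec)


def two_bead_molecules(positions: np.ndarray, species: str = "CHOL",
                       names=("R4", "R1")) -> tuple[Topology, np.ndarray]:
    """Topology of n two-bead molecules; positions has shape (n, 2, 3)."""
    n = positions.shape[0]
    moi = "sterol_ring" if species in ("CHOL", "CE") else "other"
    top = Topology(
        bead_names=np.tile(np.array(names, dtype=object), n),
        molecule_ids=np.repeat(np.arange(n), 2),
        species=np.array([species] * 2 * n, dtype=object),
        moieties=np.array([moi] * 2 * n, dtype=object),
        residue_indices=np.full(2 * n, -1),
        residue_names=np.array([""] * 2 * n, dtype=object),
        hydro_classes=np.array([""] * 2 * n, dtype=object),
        chain_labels=np.array([""] * 2 * n, dtype=object),
    )
    return top, positions.reshape(-1, 3)


def protein_beads(positions: np.ndarray, residue_names: list[str],
                  hydro: dict[str, str] | None = None) -> Topology:
    """Single-chain protein topology, one BB bead per residue."""
    from dropletmetrics.model import DEFAULT_HYDROPHOBIC

    n = positions.shape[0]
    hydro = hydro or {}
    classes = [hydro.get(r, "hydrophobic" if r in DEFAULT_HYDROPHOBIC else "hydrophilic")
               for r in residue_names]
    return Topology(
        bead_names=np.array(["BB"] * n, dtype=object),
        molecule_ids=np.zeros(n, dtype=int),
        species=np.array(["PROTEIN"] * n, dtype=object),
        moieties=np.array(["backbone"] * n, dtype=object),
        residue_indices=np.arange(n),
        residue_names=np.array(residue_names, dtype=object),
        hydro_classes=np.array(classes, dtype=object),
        chain_labels=np.array(["A"] * n, dtype=object),
    )


def concat_topologies(tops: list[Topology]) -> Topology:
    """Stack topologies, renumbering molecules densely."""
    fields = {}
    offset = 0
    mids = []
    for t in tops:
        mids.append(t.molecule_ids + offset)
        offset += t.n_molecules
    cat = lambda name: np.concatenate([getattr(t, name) for t in tops])
    return Topology(cat("bead_names"), np.concatenate(mids), cat("species"),
                    cat("moieties"), cat("residue_indices"), cat("residue_names"),
                    cat("hydro_classes"), cat("chain_labels"))


def single_frame(top: Topology, coords: np.ndarray) -> Trajectory:
    return Trajectory(top, np.array([0.0]), coords[None, :, :])
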