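"""Orientational order against the effective radial normal.

The *effective normal* of a molecule is the unit vector from the particle's
center of mass to the midpoint of the molecular axis — the local radial
direction that plays the role of the director.  Order is quantified by the
second Legendre polynomial,

    S = ⟨ P2(cos θ) ⟩ = ⟨ (3 cos²θ − 1) / 2 ⟩ ,

where θ is the angle between the molecular axis and the effective normal.
S = 1 for perfectly radial axes, 0 for isotropic ones and −0.5 for axes lying
tangent to the surface; the negative surface values reported for cholesteryl
ester rings are only meaningful under this P2 form.

Axes are treated as *directed* vectors (the sterol axis has a defined
hydroxyl/ester end), so angles span the full [0°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import LIPID_SPECIES, Trajectory, particle_com
from .radial import DEFAULT_BOUNDARIES


@dataclass(frozen=True)
class AxisDefinition:
    """A molecular axis: named tail bead -> named head bead of one species.

    For CHOL the default runs from the ring start (the bead attached to the
    short tail chain) to the ring bead adjacent to the hydroxyl; the exact
    bead naming is a topology choice, hence editable here.
    """

    species: str
    tail_bead: str
    head_bead: str


def _bead_of(topology, molecule_ids: np.ndarray, name: str) -> np.ndarray:
    """Index of the named bead within each listed molecule."""
    out = np.empty(len(molecule_ids), dtype=np.int64)
    for i, m in enumerate(molecule_ids):
        sl = topology.molecule_slice(m)
        hits = np.flatnonzero(topology.bead_names[sl] == name)
        if hits.size != 1:
            raise ValueError(
                f"bead {name!r} occurs {hits.size} times in molecule {m} "
                f"({topology.molecule_species[m]}); axis beads must be unique")
        out[i] = sl.start + hits[0]
    return out


def axis_vectors(trajectory: Trajectory, axis_def: AxisDefinition,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis vectors and midpoints for every molecule of the species.

    Returns (molecule_ids, vectors (F, M, 3), midpoints (F, M, 3)).
    """
    top = trajectory.topology
    mids = top.molecules_of(axis_def.species)
    if mids.size == 0:
        raise ValueError(f"no molecules of species {axis_def.species!r}")
    tail = _bead_of(top, mids, axis_def.tail_bead)
    head = _bead_of(top, mids, axis_def.head_bead)
    vec = trajectory.coords[:, head, :] - trajectory.coords[:, tail, :]
    mid = 0.5 * (trajectory.coords[:, head, :] + trajectory.coords[:, tail, :])
    return mids, vec, mid


def effective_normal(particle_center: np.ndarray, axis_midpoint: np.ndarray,
                     ) -> np.ndarray:
    """Unit vector(s) from the particle COM to the axis midpoint(s).

    Raises when a midpoint coincides with the COM (normal undefined).
    """
    d = np.asarray(axis_midpoint, dtype=float) - np.asarray(particle_center, dtype=float)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("effective normal undefined: axis midpoint at the particle COM")
    return d / norm


@dataclass
class OrderProfile:
    """Radial P2 profile: S(r) with per-bin sample counts.

    Bins with fewer than ``min_count`` samples are flagged unreliable.
    """

    bin_edges: np.ndarray
    S: np.ndarray
    count: np.ndarray
    min_count: int = 50

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def reliable(self) -> np.ndarray:
        return self.count >= self.min_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.bin_centers, "S": self.S,
                             "n": self.count, "reliable": self.reliable})


def _cos_to_normal(trajectory: Trajectory, axis_def: AxisDefinition,
                   com_species=LIPID_SPECIES) -> tuple[np.ndarray, np.ndarray]:
    """cos(theta) against the effective normal and midpoint radii, flattened."""
    _, vec, mid = axis_vectors(trajectory, axis_def)
    centers = particle_com(trajectory, include=com_species)
    normal = effective_normal(centers[:, None, :], mid)
    vnorm = np.linalg.norm(vec, axis=2)
    if np.any(vnorm < 1e-12):
        raise ValueError("zero-length molecular axis encountered")
    cos_t = np.einsum("fmk,fmk->fm", vec, normal) / vnorm
    radii = np.linalg.norm(mid - centers[:, None, :], axis=2)
    return cos_t.ravel(), radii.ravel()


def order_parameter_profile(trajectory: Trajectory, axis_def: AxisDefinition,
                            bin_width_nm: float = 0.1, min_count: int = 50,
                            com_species=LIPID_SPECIES) -> OrderProfile:
    """S(r) = ⟨P2(cos θ)⟩ binned by the radial distance of the axis midpoint."""
    cos_t, radii = _cos_to_normal(trajectory, axis_def, com_species)
    p2 = 0.5 * (3 * cos_t**2 - 1)
    edges = np.arange(0.0, radii.max() + bin_width_nm, bin_width_nm)
    which = np.digitize(radii, edges) - 1
    nbins = len(edges) - 1
    count = np.bincount(which, minlength=nbins)[:nbins]
    ssum = np.bincount(which, weights=p2, minlength=nbins)[:nbins]
    with np.errstate(invalid="ignore"):
        S = np.where(count > 0, ssum / np.maximum(count, 1), np.nan)
    return OrderProfile(edges, S, count, min_count)


def order_parameter(cos_theta: np.ndarray) -> float:
    """Ensemble P2 order parameter of a set of cos(theta) samples."""
    return float(np.mean(0.5 * (3 * np.asarray(cos_theta)**2 - 1)))


def angle_distribution(trajectory: Trajectory, vector_a: AxisDefinition,
                       vector_b: AxisDefinition | str, bins_deg: int = 90,
                       com_species=LIPID_SPECIES,
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalised histogram of angles between two segments, in [0°, 180°].

    ``vector_b`` may be another axis of the *same* molecules or the string
    ``"effective_normal"``.  Zero-length vectors are excluded; their number is
    returned as the third element.  Probabilities sum to one.
    """
    _, va, mid = axis_vectors(trajectory, vector_a)
    if isinstance(vector_b, str):
        if vector_b != "effective_normal":
            raise ValueError(f"unknown vector spec {vector_b!r}")
        centers = particle_com(trajectory, include=com_species)
        vb = effective_normal(centers[:, None, :], mid)
    else:
        if vector_b.species != vector_a.species:
            raise ValueError("both segments must belong to the same species")
        _, vb, _ = axis_vectors(trajectory, vector_b)
    na = np.linalg.norm(va, axis=2)
    nb = np.linalg.norm(vb, axis=2)
    ok = (na > 1e-12) & (nb > 1e-12)
    n_excluded = int((~ok).sum())
    cos_t = np.einsum("fmk,fmk->fm", va, vb)[ok] / (na[ok] * nb[ok])
    ang = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    edges = np.linspace(0.0, 180.0, bins_deg + 1)
    h, _ = np.histogram(ang, bins=edges)
    p = h / h.sum() if h.sum() else h.astype(float)
    return edges, p, n_excluded


@dataclass
class ConformationMap:
    """Joint (θ, φ) histogram: axis-vs-normal angle against ring-vs-chain angle."""

    theta_edges: np.ndarray
    phi_edges: np.ndarray
    prob: np.ndarray          # (n_theta, n_phi), sums to 1
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        tc = 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])
        pc = 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])
        t, p = np.meshgrid(tc, pc, indexing="ij")
        return pd.DataFrame({"theta_deg": t.ravel(), "phi_deg": p.ravel(),
                             "prob": self.prob.ravel()})


def conformation_map(trajectory: Trajectory,
                     ring_axis: AxisDefinition = AxisDefinition("CE", "R4", "R1"),
                     chain_axis: AxisDefinition = AxisDefinition("CE", "C1", "C4"),
                     region_filter: str | None = None,
                     boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
                     bins_deg: int = 36, com_species=LIPID_SPECIES) -> ConformationMap:
    """Joint distribution of (ring-vs-normal θ, ring-vs-chain φ) for CE.

    ``region_filter`` restricts samples by the radial region of the ring-axis
    midpoint ("core", "intermediate" or "surface" under the half-open
    boundary convention); ``None`` keeps everything.
    """
    _, vr, mid = axis_vectors(trajectory, ring_axis)
    _, vc, _ = axis_vectors(trajectory, chain_axis)
    centers = particle_com(trajectory, include=com_species)
    normal = effective_normal(centers[:, None, :], mid)
    nr = np.linalg.norm(vr, axis=2)
    nc = np.linalg.norm(vc, axis=2)
    cos_t = np.einsum("fmk,fmk->fm", vr, normal) / nr
    cos_p = np.einsum("fmk,fmk->fm", vr, vc) / (nr * nc)
    theta = np.degrees(np.arccos(np.clip(cos_t, -1, 1)))
    phi = np.degrees(np.arccos(np.clip(cos_p, -1, 1)))
    if region_filter is not None:
        r1, r2 = boundaries
        radii = np.linalg.norm(mid - centers[:, None, :], axis=2)
        label = np.where(radii < r1, "core", np.where(radii < r2, "intermediate", "surface"))
        keep = label == region_filter
        if not keep.any():
            raise ValueError(f"region filter {region_filter!r} selects no samples")
        theta, phi = theta[keep], phi[keep]
    t_edges = np.linspace(0, 180, bins_deg + 1)
    p_edges = np.linspace(0, 180, bins_deg + 1)
    h, _, _ = np.histogram2d(theta.ravel(), phi.ravel(), bins=(t_edges, p_edges))
    prob = h / h.sum()
    return ConformationMap(t_edges, p_edges, prob, int(h.sum()))
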