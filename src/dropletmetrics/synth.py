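"""Synthetic droplet topologies and trajectories with known ground truth.

The generator emulates the study system — a spheroidal droplet of ~480 lipids
(260 POPC / 10 PPC / 122 CE / 49 CHOL / 39 TG) wrapped by two apolipoprotein
chains — with *prescribed* structure and dynamics, so that every estimator in
the package can be validated by parameter recovery:

* species-specific radial placement (hydrophobic CE/TG in the core ball,
  phospholipids on the surface shell, CHOL split between the two);
* per-shell orientational order realised by sampling molecular axes from a
  Maier-Saupe-type angular density with the concentration parameter solved to
  hit a target P2 order parameter;
* 2D Brownian motion on the sphere for surface species and 3D Brownian motion
  in the core ball with prescribed diffusion coefficients;
* two-state (contact / non-contact) telegraph processes with exponential
  dwell times for lifetime analysis.

None of this is a physical force field: beads are rigid template offsets
around a molecular axis, and frames are statistically — not mechanically —
coupled.  That is exactly what makes closed-form recovery targets possible.

Units: nm, ns.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .model import Topology, Trajectory, DEFAULT_HYDROPHOBIC

__all__ = [
    "SyntheticSpec", "sample_orientations", "order_to_concentration",
    "brownian_on_sphere", "brownian_in_ball", "telegraph_contacts",
    "build_droplet", "build_trajectory",
]

#: Default molecular composition: the realistic human-serum HDL mixture used
#: throughout (counts per species; two protein chains handled separately).
DEFAULT_COMPOSITION = {"POPC": 260, "PPC": 10, "CE": 122, "CHOL": 49, "TG": 39}

#: amino acids present in human apoA-I (Ile and Cys are absent)
_APOA1_ALPHABET = ("ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS",
                   "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                   "TYR", "VAL")


@dataclass
class SyntheticSpec:
    """Ground-truth parameters of a synthetic droplet.

    Defaults mirror the study conditions: composition 260/10/122/49/39 + 2
    protein chains; core/surface shell boundaries at 3.0 and 4.0 nm with a
    4.5 nm particle radius; surface (2D) diffusion ~1e-3 nm^2/ns as for fluid
    phospholipid layers and core (3D) diffusion slower by a factor of 10;
    contact/non-contact dwell means 146/175 ns as reported for the
    CHOL-protein coupling; 0.1 ns frames.
    """

    composition: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    n_protein_chains: int = 2
    residues_per_chain: int = 243
    shell_radii: tuple[float, float] = (3.0, 4.0)
    particle_radius: float = 4.5
    D2_true: float = 1.0e-3         # nm^2/ns, surface species
    D3_true: float = 1.0e-4         # nm^2/ns, core species
    S_target: float = 0.7           # surface-shell P2 target (core isotropic)
    chol_surface_fraction: float = 0.85
    ce_chain_angle_deg: float = 120.0
    dwell_on_ns: float = 146.0
    dwell_off_ns: float = 175.0
    dt_ns: float = 0.1
    n_frames: int = 2000
    protein_jitter_nm: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if any(c < 0 for c in self.composition.values()):
            raise ValueError("composition counts must be >= 0")
        r1, r2 = self.shell_radii
        if not (0 < r1 < r2 < self.particle_radius + 1e-12):
            raise ValueError("shell radii must satisfy 0 < r1 < r2 <= particle_radius")
        if self.D2_true <= 0 or self.D3_true <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if not -0.5 < self.S_target < 1.0:
            raise ValueError("S_target must lie in (-0.5, 1)")
        if self.dwell_on_ns <= 0 or self.dwell_off_ns <= 0:
            raise ValueError("dwell means must be > 0")
        if self.dt_ns <= 0 or self.n_frames < 1:
            raise ValueError("need dt_ns > 0 and n_frames >= 1")


# ---------------------------------------------------------------------------
# orientation sampling with a prescribed order parameter
# ---------------------------------------------------------------------------

_LAMBDA_BRACKET = (-200.0, 200.0)
_U_GRID = np.linspace(0.0, 1.0, 20001)


def _order_of_concentration(lam: float) -> float:
    """S(lambda) for the angular density f(u) ∝ exp(lambda u^2), u=cos(theta)."""
    w = np.exp(lam * (_U_GRID**2 - (1.0 if lam > 0 else 0.0)))
    num = np.trapezoid(0.5 * (3 * _U_GRID**2 - 1) * w, _U_GRID)
    den = np.trapezoid(w, _U_GRID)
    return float(num / den)


def order_to_concentration(S_target: float) -> float:
    """Solve the Maier-Saupe concentration lambda with E[P2(cos theta)] = S_target.

    Bracketed root-find on lambda in [-200, 200]; |S| targets very close to
    the degenerate boundaries (-0.5, 1) fall outside the bracket and raise.
    """
    if not -0.5 < S_target < 1.0:
        raise ValueError(f"S_target={S_target} outside the open interval (-0.5, 1)")
    if S_target == 0.0:
        return 0.0
    lo, hi = _LAMBDA_BRACKET
    S_lo, S_hi = _order_of_concentration(lo), _order_of_concentration(hi)
    if not S_lo < S_target < S_hi:
        raise ValueError(
            f"S_target={S_target} unreachable within lambda bracket {_LAMBDA_BRACKET} "
            f"(achievable range ~[{S_lo:.3f}, {S_hi:.3f}]); the distribution is "
            "degenerate at the boundaries")
    return float(brentq(lambda l: _order_of_concentration(l) - S_target, lo, hi,
                        xtol=1e-10, rtol=1e-12))


def _cos_theta_inverse_cdf(lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid inverse CDF of u=cos(theta) under f(u) ∝ exp(lambda u^2) on [0,1]."""
    w = np.exp(lam * (_U_GRID**2 - (1.0 if lam > 0 else 0.0)))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(_U_GRID))])
    cdf /= cdf[-1]
    return cdf, _U_GRID


def sample_orientations(n: int, S_target: float, seed: int) -> tuple[np.ndarray, float]:
    """Draw ``n`` unit axes about +z with E[P2(cos theta)] = ``S_target``.

    Polar angles follow density ∝ exp(lambda cos^2 theta) sin(theta) with
    lambda solved so the ensemble P2 equals the target; azimuths are uniform.
    u = cos(theta) is drawn on [0, 1] (directed hemisphere toward the pole),
    which leaves S unchanged relative to the full symmetric density and makes
    theta concentrate at 0 as S_target -> 1.

    Returns the (n, 3) unit vectors and the lambda used.
    """
    lam = order_to_concentration(S_target)
    rng = np.random.default_rng(seed)
    cdf, grid = _cos_theta_inverse_cdf(lam)
    u = np.interp(rng.random(n), cdf, grid)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u]), lam


# ---------------------------------------------------------------------------
# Brownian ground-truth dynamics
# ---------------------------------------------------------------------------

def _uniform_sphere_dirs(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sphere_walk(start: np.ndarray, radii: np.ndarray, D: np.ndarray, dt: float,
                 n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Tangent-plane Gaussian steps re-projected to each walker's sphere."""
    n = start.shape[0]
    out = np.empty((n_steps + 1, n, 3))
    x = start.copy()
    out[0] = x
    sigma = np.sqrt(2.0 * D * dt)              # per tangent axis
    for k in range(1, n_steps + 1):
        nhat = x / np.linalg.norm(x, axis=1, keepdims=True)
        # tangent basis: e1 ⟂ nhat via a non-parallel helper axis
        helper = np.zeros_like(nhat)
        helper[np.arange(n), np.argmin(np.abs(nhat), axis=1)] = 1.0
        e1 = np.cross(nhat, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(nhat, e1)
        g = rng.normal(size=(n, 2)) * sigma[:, None]
        x = x + g[:, :1] * e1 + g[:, 1:] * e2
        x = x / np.linalg.norm(x, axis=1, keepdims=True) * radii[:, None]
        out[k] = x
    return out


def brownian_on_sphere(R: float, D: float, dt: float, n_steps: int, n_walkers: int,
                       seed: int, start: np.ndarray | None = None) -> np.ndarray:
    """2D Brownian COM paths on a sphere of radius ``R`` (nm).

    Each step displaces a walker within its local tangent plane by an
    isotropic 2D Gaussian with variance 2 D dt per tangent axis (total
    4 D dt), then re-projects to radius R.  Valid while the RMS step stays
    small against curvature: requires sqrt(4 D dt) <= 0.2 R.

    Returns coordinates of shape ``(n_steps + 1, n_walkers, 3)``.
    """
    step = np.sqrt(4.0 * D * dt)
    if step > 0.2 * R:
        raise ValueError(
            f"step size sqrt(4 D dt)={step:.4g} nm exceeds 0.2 R={0.2*R:.4g} nm; "
            "reduce dt or D (tangent-plane stepping needs steps small vs curvature)")
    rng = np.random.default_rng(seed)
    if start is None:
        start = _uniform_sphere_dirs(rng, n_walkers) * R
    radii = np.full(n_walkers, float(R))
    return _sphere_walk(np.asarray(start, dtype=float), radii,
                        np.full(n_walkers, float(D)), dt, n_steps, rng)


def brownian_in_ball(R: float, D: float, dt: float, n_steps: int, n_walkers: int,
                     seed: int, start: np.ndarray | None = None) -> np.ndarray:
    """3D Brownian COM paths inside a reflecting ball of radius ``R`` (nm).

    Isotropic Gaussian steps with variance 2 D dt per axis; excursions past
    the boundary are reflected radially (r -> 2R - r), exact to first order in
    the step size; requires sqrt(6 D dt) <= 0.2 R.

    Returns coordinates of shape ``(n_steps + 1, n_walkers, 3)``.
    """
    step = np.sqrt(6.0 * D * dt)
    if step > 0.2 * R:
        raise ValueError(
            f"step size sqrt(6 D dt)={step:.4g} nm exceeds 0.2 R={0.2*R:.4g} nm; "
            "reduce dt or D")
    rng = np.random.default_rng(seed)
    if start is None:
        start = _uniform_sphere_dirs(rng, n_walkers) * R * rng.random(n_walkers)[:, None] ** (1 / 3)
    x = np.asarray(start, dtype=float).copy()
    out = np.empty((n_steps + 1, n_walkers, 3))
    out[0] = x
    sigma = np.sqrt(2.0 * D * dt)
    for k in range(1, n_steps + 1):
        x = x + rng.normal(size=x.shape) * sigma
        r = np.linalg.norm(x, axis=1)
        over = r > R
        if over.any():
            x[over] *= ((2 * R - r[over]) / r[over])[:, None]
        out[k] = x
    return out


# ---------------------------------------------------------------------------
# telegraph (two-state) contact processes
# ---------------------------------------------------------------------------

def telegraph_contacts(mean_on_ns: float, mean_off_ns: float, dt: float,
                       n_frames: int, n_lipids: int, seed: int) -> np.ndarray:
    """Boolean contact matrix ``(n_frames, n_lipids)`` from a telegraph process.

    Each lipid alternates between contact ("on") and non-contact ("off")
    states with independent exponential dwell times of the given means,
    sampled on the frame grid ``t_k = k dt``.  Initial states are drawn from
    the stationary law (P(on) = mean_on / (mean_on + mean_off)); exponential
    memorylessness then makes the whole sampled process stationary, so the
    marginal on-fraction converges to that ratio as n_frames grows.
    """
    if mean_on_ns <= 0 or mean_off_ns <= 0:
        raise ValueError("dwell means must be > 0")
    rng = np.random.default_rng(seed)
    T = n_frames * dt
    t = np.arange(n_frames) * dt
    out = np.empty((n_frames, n_lipids), dtype=bool)
    p_on = mean_on_ns / (mean_on_ns + mean_off_ns)
    means = np.array([mean_off_ns, mean_on_ns])
    for j in range(n_lipids):
        state0 = bool(rng.random() < p_on)
        # draw enough dwells to exceed T, extending if a draw falls short
        dwells = []
        total, s = 0.0, int(state0)
        while total < T:
            block = rng.exponential(means[np.arange(s, s + 64) % 2])
            dwells.append(block)
            total += block.sum()
            s += 64
        switches = np.cumsum(np.concatenate(dwells))
        k = np.searchsorted(switches, t, side="right")
        out[:, j] = (k % 2 == 0) == state0
    return out


# ---------------------------------------------------------------------------
# bead templates and droplet assembly
# ---------------------------------------------------------------------------

def _template(species: str, ce_chain_angle_deg: float = 120.0,
              ) -> tuple[list[str], list[str], np.ndarray]:
    """Bead names, moieties and axis-frame offset coefficients for a species.

    Offsets are coefficients ``(a_u, a_v, a_w)`` on the molecule's orthonormal
    frame (u = molecular axis, tail -> head).  Geometry is schematic (rigid
    ~0.25 nm spacing), sufficient for COM, axis and contact statistics.
    """
    if species == "POPC":
        names = ["NC3", "PO4", "GL1", "GL2",
                 "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"]
        moi = ["headgroup", "headgroup", "glycerol", "glycerol"] + \
              ["sn1_chain"] * 4 + ["sn2_chain"] * 4
        off = [(0.90, 0, 0), (0.65, 0, 0), (0.40, 0.10, 0), (0.40, -0.10, 0),
               (0.15, 0.12, 0), (-0.10, 0.12, 0), (-0.35, 0.12, 0), (-0.60, 0.12, 0),
               (0.15, -0.12, 0), (-0.10, -0.12, 0), (-0.35, -0.12, 0), (-0.60, -0.12, 0)]
    elif species == "PPC":
        names = ["NC3", "PO4", "GL1", "C1A", "C2A", "C3A", "C4A"]
        moi = ["headgroup", "headgroup", "glycerol"] + ["sn1_chain"] * 4
        off = [(0.90, 0, 0), (0.65, 0, 0), (0.40, 0, 0),
               (0.15, 0, 0), (-0.10, 0, 0), (-0.35, 0, 0), (-0.60, 0, 0)]
    elif species == "CHOL":
        names = ["ROH", "R1", "R2", "R3", "R4", "C1", "C2"]
        moi = ["sterol_ring"] * 5 + ["sterol_tail"] * 2
        off = [(0.50, 0, 0), (0.30, 0, 0), (0.10, 0.10, 0), (-0.10, 0.10, 0),
               (-0.30, 0, 0), (-0.55, 0, 0), (-0.80, 0, 0)]
    elif species == "CE":
        phi = np.deg2rad(ce_chain_angle_deg)
        c_u, c_v = np.cos(phi), np.sin(phi)
        names = ["ES", "R1", "R2", "R3", "R4", "C1", "C2", "C3", "C4"]
        moi = ["ester"] + ["sterol_ring"] * 4 + ["oleate_chain"] * 4
        off = [(0.55, 0, 0), (0.30, 0, 0), (0.10, 0.10, 0), (-0.10, 0.10, 0),
               (-0.30, 0, 0)]
        off += [(0.55 + 0.25 * k * c_u, 0.25 * k * c_v, 0) for k in range(1, 5)]
    elif species == "TG":
        dirs = [(1.0, 0.0), (-0.5, np.sqrt(3) / 2), (-0.5, -np.sqrt(3) / 2)]
        names = ["GL", "ES1", "ES2", "ES3"]
        moi = ["glycerol"] + ["ester"] * 3
        off = [(0.0, 0.0, 0.0)] + [(0.20 * du, 0.20 * dv, 0.0) for du, dv in dirs]
        for ci, suffix in enumerate("ABC"):
            du, dv = dirs[ci]
            names += [f"C{k}{suffix}" for k in range(1, 5)]
            moi += [f"sn{ci+1}_chain"] * 4
            off += [((0.20 + 0.25 * k) * du, (0.20 + 0.25 * k) * dv, 0.0)
                    for k in range(1, 5)]
    elif species == "WATER":
        names, moi, off = ["W"], ["other"], [(0.0, 0.0, 0.0)]
    else:
        raise ValueError(f"no bead template for species {species!r}")
    off = np.asarray(off, dtype=float)
    # center so the uniform-weight bead COM coincides with the placement COM:
    # orientation resampling then provably never displaces the molecule COM,
    # keeping the prescribed Brownian COM paths exact ground truth
    return names, moi, off - off.mean(axis=0)


#: default molecular-axis bead pairs (tail bead, head bead) per species; for
#: CHOL/CE the axis runs from the ring start (attached to the short chain) to
#: the bead adjacent to the hydroxyl/ester, for phospholipids from the end of
#: the sn-1 chain to the choline bead.  Editable per analysis call.
DEFAULT_AXES = {
    "POPC": ("C4A", "NC3"),
    "PPC": ("C4A", "NC3"),
    "CHOL": ("R4", "R1"),
    "CE": ("R4", "R1"),
}
#: CE oleate-chain segment (first -> last chain bead)
CE_CHAIN_SEGMENT = ("C1", "C4")

# minimum per-molecule footprints used by the crude packing check
_MIN_CORE_VOLUME_NM3 = 0.30
_MIN_SURFACE_AREA_NM2 = 0.30


def _tangent_basis(nhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros_like(nhat)
    helper[np.arange(len(nhat)), np.argmin(np.abs(nhat), axis=1)] = 1.0
    e1 = np.cross(nhat, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    return e1, np.cross(nhat, e1)


def _axes_about(nhat: np.ndarray, cos_theta: np.ndarray, rng: np.random.Generator,
                ) -> np.ndarray:
    """Unit axes at polar angle arccos(u) from each local direction nhat."""
    e1, e2 = _tangent_basis(nhat)
    phi = rng.uniform(0, 2 * np.pi, len(nhat))
    s = np.sqrt(np.clip(1 - cos_theta**2, 0, None))
    return (cos_theta[:, None] * nhat
            + (s * np.cos(phi))[:, None] * e1 + (s * np.sin(phi))[:, None] * e2)


class _Placement:
    """Ground-truth COM radii/directions and per-molecule dynamic class."""

    def __init__(self) -> None:
        self.com: list[np.ndarray] = []
        self.kind: list[str] = []          # "surface" | "core" | "static"
        self.species: list[str] = []


def _place_molecules(spec: SyntheticSpec, rng: np.random.Generator) -> _Placement:
    r1, r2 = spec.shell_radii
    R = spec.particle_radius
    comp = spec.composition
    n_chol_surf = int(round(comp.get("CHOL", 0) * spec.chol_surface_fraction))
    n_core = comp.get("TG", 0) + comp.get("CE", 0) + comp.get("CHOL", 0) - n_chol_surf
    n_surf = comp.get("POPC", 0) + comp.get("PPC", 0) + n_chol_surf
    if n_core * _MIN_CORE_VOLUME_NM3 > 4 / 3 * np.pi * r1**3:
        raise ValueError(
            f"{n_core} core molecules cannot pack into a {r1} nm core ball; "
            "increase particle_radius / shell radii")
    if n_surf * _MIN_SURFACE_AREA_NM2 > 4 * np.pi * r2**2:
        raise ValueError(
            f"{n_surf} surface molecules cannot pack onto a {r2} nm shell; "
            "increase particle_radius")

    pl = _Placement()

    def surface_com(n: int) -> np.ndarray:
        d = _uniform_sphere_dirs(rng, n)
        radii = rng.uniform(r2, R, n)
        return d * radii[:, None]

    def core_com(n: int) -> np.ndarray:
        d = _uniform_sphere_dirs(rng, n)
        radii = r1 * rng.random(n) ** (1 / 3)
        return d * radii[:, None]

    for sp in ("POPC", "PPC", "CHOL", "CE", "TG"):
        n = comp.get(sp, 0)
        if n == 0:
            continue
        if sp in ("POPC", "PPC"):
            coms, kinds = surface_com(n), ["surface"] * n
        elif sp == "CHOL":
            ns = int(round(n * spec.chol_surface_fraction))
            coms = np.concatenate([surface_com(ns), core_com(n - ns)]) if n - ns \
                else surface_com(ns)
            kinds = ["surface"] * ns + ["core"] * (n - ns)
        else:
            coms, kinds = core_com(n), ["core"] * n
        for c, k in zip(coms, kinds):
            pl.com.append(c)
            pl.kind.append(k)
            pl.species.append(sp)
    return pl


def _protein_chain_coords(spec: SyntheticSpec, chain: int, sequence: list[str],
                          ) -> tuple[list[str], list[str], np.ndarray]:
    """Backbone + sidechain beads of one chain on a great-circle surface band.

    Each chain winds once around the particle at latitude ±lat; backbone beads
    sit at the particle radius, sidechain beads 0.3 nm inward so that surface
    lipids can reach contact range.
    """
    R = spec.particle_radius
    lat = 0.10 * (1 if chain % 2 == 0 else -1)
    nres = len(sequence)
    ang = 2 * np.pi * (np.arange(nres) + 0.5 * chain) / nres
    names, moi, coords = [], [], []
    for i, a in enumerate(ang):
        zhat = np.array([np.cos(a) * np.cos(lat), np.sin(a) * np.cos(lat), np.sin(lat)])
        names.append("BB")
        moi.append("backbone")
        coords.append(zhat * R)
        if sequence[i] != "GLY":
            names.append("SC1")
            moi.append("sidechain")
            coords.append(zhat * (R - 0.30))
    return names, moi, np.asarray(coords)


def build_droplet(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Assemble a droplet topology and its initial frame (coords in nm).

    TG/CE molecule COMs are uniform in the core ball, POPC/PPC on the surface
    shell, CHOL split by ``chol_surface_fraction``; surface molecular axes are
    drawn about the outward radial direction with the target order parameter,
    core axes isotropically.  Protein chains sit on great-circle bands.  The
    protein sequence is a *synthetic* seeded draw over the 18 amino acids
    present in human apoA-I, not a real sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pl = _place_molecules(spec, rng)
    lam = order_to_concentration(spec.S_target)
    cdf, grid = _cos_theta_inverse_cdf(lam)

    hydro = {res: ("hydrophobic" if res in DEFAULT_HYDROPHOBIC else "hydrophilic")
             for res in _APOA1_ALPHABET}

    bead_names: list[str] = []
    moieties: list[str] = []
    molecule_ids: list[int] = []
    species_arr: list[str] = []
    residue_indices: list[int] = []
    residue_names: list[str] = []
    hydro_classes: list[str] = []
    chain_labels: list[str] = []
    coords: list[np.ndarray] = []

    coms = np.asarray(pl.com)
    nmol = len(pl.com)
    nhat = coms / np.linalg.norm(coms, axis=1, keepdims=True)
    u_surface = np.interp(rng.random(nmol), cdf, grid)
    u_core = rng.random(nmol)              # isotropic: cos(theta) uniform on [0,1]
    cos_t = np.where(np.asarray(pl.kind) == "surface", u_surface, u_core)
    axes = _axes_about(nhat, cos_t, rng)
    e1, _ = _tangent_basis(axes)

    mol = 0
    for m in range(nmol):
        sp = pl.species[m]
        names, moi, off = _template(sp, spec.ce_chain_angle_deg)
        u = axes[m]
        v = e1[m]
        w = np.cross(u, v)
        xyz = coms[m] + off[:, 0:1] * u + off[:, 1:2] * v + off[:, 2:3] * w
        k = len(names)
        bead_names += names
        moieties += moi
        molecule_ids += [mol] * k
        species_arr += [sp] * k
        residue_indices += [-1] * k
        residue_names += [""] * k
        hydro_classes += [""] * k
        chain_labels += [""] * k
        coords.append(xyz)
        mol += 1

    for c in range(spec.n_protein_chains):
        seq = [str(_APOA1_ALPHABET[i])
               for i in rng.integers(0, len(_APOA1_ALPHABET), spec.residues_per_chain)]
        names, moi, xyz = _protein_chain_coords(spec, c, seq)
        label = chr(ord("A") + c)
        ridx = []
        rnam = []
        i = -1
        for nm in names:
            if nm == "BB":
                i += 1
            ridx.append(i)
            rnam.append(seq[i])
        k = len(names)
        bead_names += names
        moieties += moi
        molecule_ids += [mol] * k
        species_arr += ["PROTEIN"] * k
        residue_indices += ridx
        residue_names += rnam
        hydro_classes += [hydro[r] for r in rnam]
        chain_labels += [label] * k
        coords.append(xyz)
        mol += 1

    top = Topology(np.array(bead_names, dtype=object), np.array(molecule_ids),
                   np.array(species_arr, dtype=object), np.array(moieties, dtype=object),
                   np.array(residue_indices), np.array(residue_names, dtype=object),
                   np.array(hydro_classes, dtype=object), np.array(chain_labels, dtype=object))
    return top, np.concatenate(coords)


def build_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Generate a full synthetic trajectory with known dynamics.

    Surface-placed molecules follow 2D Brownian motion on their own sphere at
    ``D2_true``; core molecules follow 3D Brownian motion in the core ball at
    ``D3_true``.  Molecular orientations are resampled independently every
    frame (fast rotational decorrelation), so orientation statistics gain
    n_molecules x n_frames independent samples.  Protein beads get small
    Gaussian positional jitter.  Times are effective times on a uniform
    ``dt_ns`` grid.
    """
    spec.validate()
    top, x0 = build_droplet(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    pl_rng = np.random.default_rng(spec.seed)
    pl = _place_molecules(spec, pl_rng)     # same draw order as build_droplet

    nmol_lipid = len(pl.com)
    kinds = np.asarray(pl.kind)
    coms0 = np.asarray(pl.com)
    F = spec.n_frames
    r1, _ = spec.shell_radii

    com_paths = np.empty((F, nmol_lipid, 3))
    surf = np.flatnonzero(kinds == "surface")
    core = np.flatnonzero(kinds == "core")
    if surf.size:
        radii = np.linalg.norm(coms0[surf], axis=1)
        com_paths[:, surf, :] = _sphere_walk(
            coms0[surf], radii, np.full(surf.size, spec.D2_true),
            spec.dt_ns, F - 1, rng)
    if core.size:
        path = brownian_in_ball(r1, spec.D3_true, spec.dt_ns, F - 1, core.size,
                                seed=int(rng.integers(2**31)), start=coms0[core])
        com_paths[:, core, :] = path

    lam = order_to_concentration(spec.S_target)
    cdf, grid = _cos_theta_inverse_cdf(lam)

    # per-species template offsets, gathered once
    templates = {sp: _template(sp, spec.ce_chain_angle_deg)[2]
                 for sp in set(pl.species)}
    sizes = np.array([templates[sp].shape[0] for sp in pl.species])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n_lipid_beads = int(sizes.sum())

    coords = np.empty((F, top.n_beads, 3))
    prot_slice = slice(n_lipid_beads, top.n_beads)
    species_order = list(pl.species)

    # assemble lipid beads frame by frame (vectorised over molecules per species)
    by_species = {sp: np.flatnonzero(np.asarray(species_order) == sp)
                  for sp in set(species_order)}
    for f in range(F):
        com_f = com_paths[f]
        nhat = com_f / np.maximum(np.linalg.norm(com_f, axis=1, keepdims=True), 1e-12)
        u_surf = np.interp(rng.random(nmol_lipid), cdf, grid)
        u_core = rng.random(nmol_lipid)
        cos_t = np.where(kinds == "surface", u_surf, u_core)
        axes = _axes_about(nhat, cos_t, rng)
        v_basis, _ = _tangent_basis(axes)
        w_basis = np.cross(axes, v_basis)
        for sp, mids in by_species.items():
            off = templates[sp]                      # (k, 3)
            u = axes[mids]
            xyz = (com_f[mids][:, None, :]
                   + off[None, :, 0:1] * u[:, None, :]
                   + off[None, :, 1:2] * v_basis[mids][:, None, :]
                   + off[None, :, 2:3] * w_basis[mids][:, None, :])
            # molecules of one species are placed as a contiguous bead block
            s0 = starts[mids[0]]
            coords[f, s0:s0 + xyz.shape[0] * xyz.shape[1]] = xyz.reshape(-1, 3)
        coords[f, prot_slice] = x0[prot_slice] + rng.normal(
            scale=spec.protein_jitter_nm, size=(top.n_beads - n_lipid_beads, 3))

    times = np.arange(F) * spec.dt_ns
    return Trajectory(top, times, coords)
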