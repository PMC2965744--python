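# Methods

This note documents the models, conventions and numerical choices behind
`dropletmetrics`, and what the synthetic-data validation does and does not
establish about real trajectories.

## Data model and units

Everything internal is in nm and ns.  Readers convert on ingest (MDAnalysis
reports Å and ps).  Trajectory times may carry the ×4 effective-time scaling
that maps CG (MARTINI-type) dynamics onto real dynamics; the flag
`time_scale_applied` records it, and writers emit the stored times, so a
scaled trajectory must not be re-scaled on re-reading.

Beads are annotated by molecule, species (POPC, PPC, CHOL, CE, TG, PROTEIN,
WATER), lipid moiety and — for protein — residue index/name/hydrophobicity
class.  Species and moiety assignment is table-driven
(`data/bead_map.txt`, fnmatch patterns, first match wins), never hard-coded
in parsing, because bead naming varies across CG topologies.  Bead ids are
dense 0..N−1 with molecules stored contiguously; this is what makes the
segmented per-molecule COM reductions cheap.

Coordinates are assumed whole-molecule (unwrapped): the droplet is compact
and far from the box walls.  A wrap guard rejects any lipid whose internal
extent exceeds 5 nm (configurable) as a likely periodic image; protein
chains are exempt by default because a double-belt protein genuinely spans
the particle diameter.

Molecular COMs use uniform bead weights by default (bead masses are not
part of the trajectory contract); an explicit mass vector is accepted.  The
particle reference COM is computed over lipid beads only — water always
excluded, protein excluded by default — and is configurable on every call.

## Radial structure

Densities are time-averaged counts per spherical-shell volume
(4π/3)(r₊³−r₋³); the default 0.1 nm bin resolves the ~1 nm intermediate
shell.  By construction Σ density·shell-volume returns the species census
exactly, which the tests assert.  Region labels use the half-open
convention r < r₁ core, r₁ ≤ r < r₂ intermediate, r ≥ r₂ surface with
defaults (3.0, 4.0) nm — the inner edge of the ordered intermediate shell
sits at 3 nm in particles of this size.  Composition mol% includes the
protein chains in the denominator by default; that convention reproduces
the standard HDL composition table (53.9/2.1/25.3/10.2/8.1 for
260/10/122/49/39 + 2 chains), while the lipid-only denominator gives e.g.
POPC 54.2%.

## Orientational order

The order parameter is the second Legendre polynomial
S = ⟨(3cos²θ−1)/2⟩ of the angle between a molecular axis and the effective
normal (particle COM → axis midpoint).  P2 is the only form consistent with
tangentially ordered species reaching S ≈ −0.5 at the surface.  Radial
binning uses the axis midpoint — consistent with the effective-normal
definition — not the molecule COM.  Axes are directed (the sterol axis has
a defined hydroxyl end), so angle histograms span [0°, 180°]; bead pairs
defining each axis are configuration, with defaults running from the ring
start to the hydroxyl-adjacent bead for CHOL/CE and from the sn-1 chain end
to the choline bead for the phospholipids.  Bins with fewer than 50 samples
are flagged unreliable.

## Diffusion

Jump lengths are COM displacement magnitudes over a lag that must be an
integer multiple of the frame interval, pooled over all overlapping frame
pairs.  The two free-diffusion propagator densities (2D and 3D Gaussians in
the radial variable) are least-squares fitted to the normalised histogram
(60 bins, moment-based initial guess ⟨r²⟩ = 2dDτ); the lower-residual model
supplies D and the dimensionality.  Design points:

* Surface jumps are chord (3D Euclidean) displacements, not geodesics; the
  generator precondition √(4Ddt) ≤ 0.2R keeps the curvature bias under 1%.
* Region-filtered estimates assign each pair by the molecule's region at
  the pair's start frame; molecules crossing regions during the lag are not
  excluded.  This is the simplest reproducible rule and is a choice of this
  package.
* The D(τ) plateau flag requires < 10% variation over the final half of the
  lag grid (default: ≤10 log-spaced lags from one frame up to ~100 ns, the
  long-time window).  Ballistic drift (r = vτ) grows linearly and fails the
  flag.
* Dimension normalisation multiplies by 2·d (the MSD-slope convention), so
  2D surface and 3D core coefficients are comparable; an identity scale is
  available.  1 nm²/ns = 10⁻⁵ cm²/s.

## Contacts, lifetimes, RMSF

All cutoffs are strict inequalities (a bead *within* 0.8 nm means
d < 0.8 nm); the boundary set has measure zero, and the 0.79/0.81 nm
behavior is pinned by tests.  KD-tree searches are contract-tested for
exact agreement with a brute-force all-pairs oracle.

Lifetimes follow the tolerance rule: an interior non-contact gap strictly
shorter than `tolerance_frames` (default 10) leaves the coupling unbroken;
tolerance ≤ 1 is provably a no-op.  Dwell times are merged run lengths ×
frame interval.  Intervals touching either trajectory end are censored:
their true length is unknown, so they are excluded from the default means
and reported separately, with means-including-censored also available.

Per-residue contact profiles divide pair counts by the residue type's
multiplicity in the sequence ("normalised per residue"); a
hydrophobic/hydrophilic roll-up uses the editable class table (Trp, Phe,
Val, Leu, Ile, Met, Ala hydrophobic; Tyr and His stay hydrophilic despite
their interfacial amphipathy, which is worth remembering when reading the
roll-up).

RMSF aligns each frame's protein backbone onto the first frame by
least-squares (Kabsch) superposition before measuring fluctuations about
the mean structure — the droplet tumbles freely, and unaligned RMSF would
measure rotation, not flexibility.  Alignment needs ≥ 3 beads.

## SASA

Shrake–Rupley with a deterministic Fibonacci-lattice point set (default 960
points per bead).  Probe radius 0.56 nm: the atomistic 0.14 nm water probe
scaled by the 4:1 CG water mapping.  Bead radii default to 0.235 nm (half
the standard 0.47 nm CG bead diameter) and are overridable per bead name;
no published per-bead radius table exists for this use, so the absolute
areas — and therefore the hydrophobic/hydrophilic percentage split on real
particles — should be treated as convention-dependent.  Occluders default
to all non-water beads (lipids bury the protein face they wrap); the
selection only chooses whose area is reported.  A point exactly on another
sphere's surface counts as buried, so coincident beads have zero area.

## Synthetic generator

The generator emulates the study conditions, not the physics:

* Composition defaults to 260/10/122/49/39 lipids + 2 chains of 243
  residues.  The protein sequence is a seeded random draw over the 18 amino
  acids present in human apoA-I (no Ile/Cys) — synthetic, not a real
  sequence.
* Placement: TG/CE COMs uniform in the 3 nm core ball; POPC/PPC on the
  4.0–4.5 nm shell; CHOL split 85% surface / 15% core; chains wound once
  around great-circle bands at ±0.10 rad latitude with sidechain beads
  0.3 nm inboard.  A crude packing check rejects impossible radii.
* Orientations: axes are drawn about the local radial direction from the
  density f(u) ∝ exp(λu²), u = cos θ ∈ [0,1], with λ solved by bracketed
  root-finding (λ ∈ [−200, 200], quadrature-checked) so that E[P2] hits the
  target S.  The Maier–Saupe form is a modelling choice; any density with
  the right P2 would serve.  Orientations are resampled independently every
  frame (instant rotational decorrelation), which (a) gives
  n_molecules × n_frames independent samples for order statistics and
  (b) is made harmless for diffusion by centering every bead template on
  its COM, so re-orientation never displaces the molecule COM.
* Dynamics: surface molecules take tangent-plane Gaussian steps
  (variance 2Ddt per axis) re-projected to their sphere — valid while
  √(4Ddt) ≤ 0.2R, which bounds the curvature bias below fitting tolerance —
  and core molecules take free 3D steps with radial reflection at the core
  boundary.  Defaults D₂ = 10⁻³ nm²/ns (fluid-membrane scale) and
  D₃ = 10⁻⁴ nm²/ns (slower by the core/surface factor of 10).
* Contacts: independent two-state telegraph processes with exponential
  dwells (defaults 146/175 ns, the reported CHOL–protein contact and
  non-contact lifetimes), sampled on the frame grid from a stationary
  start; exponential memorylessness makes the sampled process exactly
  stationary.

What passing recovery tests shows: the estimators are correct on data that
satisfies their own assumptions (free diffusion, exponential dwells,
rotationally uncorrelated frames, rigid templates).  What it does not show:
behavior under crowding, correlated rotation–translation, anomalous
diffusion, non-exponential dwells, or deformable molecules — all present in
real CG trajectories.  The published multi-microsecond HDL trajectory is
not deposited, so its headline numbers are used only as generator inputs
(dwell means, composition), never as assertions.

## Problem sizes

Default validation sizes, chosen to keep every statistical check several
standard errors inside its tolerance: Brownian fixtures of 100 walkers ×
10⁴ steps (~10⁶ jumps per fit); 10⁵ orientation samples per target;
telegraph fixtures of 10⁶ frames (6–20 processes, ~2×10³–10⁴ dwells);
droplet fixtures of 60–450 frames at 0.1 ns.  The full pipeline on the
default 482-molecule droplet runs in well under a minute per 60 frames on
one CPU, dominated by SASA frames.

## Known limitations

* Ellipsoidal shape metrics (moments of inertia) and SAXS-comparable
  electron densities are out of scope.
* The propagator fit assumes free diffusion within a region; the
  intermediate shell mixes 2D and 3D character and its D should be read as
  an effective coefficient.
* Lifetime means are sensitive to censoring on short trajectories; compare
  the censored-included means before interpreting.
* GRO round-trips quantise coordinates to 10⁻³ nm; XTC to ~10⁻³ nm as well.
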