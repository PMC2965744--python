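# dropletmetrics

Analysis toolkit for coarse-grained (CG) trajectories of spheroidal
lipid-droplet particles — most directly, high density lipoprotein (HDL): a
~10 nm particle with a hydrophobic core of cholesteryl esters (CE) and
triglycerides (TG), a surface of phospholipids (POPC, lyso-PC) and free
cholesterol (CHOL), wrapped by two apolipoprotein A-I chains in a double
belt.  It is written for structural bioinformaticians and molecular
modellers who have a CG structure + trajectory (GRO/PDB + XTC/DCD) of such a
particle and want the standard battery of droplet analyses, plus a
synthetic-trajectory generator that validates every estimator by parameter
recovery without running any molecular dynamics.

## What it computes

* **Radial structure** — per-species number-density profiles
  `ρ(r) = ⟨N(r)⟩ / [4π/3 (r₊³−r₋³)]` about the particle center of mass,
  composition accounting (counts and mol%), radius of gyration, and
  core / intermediate / surface region labels (default boundaries 3.0 and
  4.0 nm, half-open bins).
* **Orientational order** — the P2 order parameter
  `S = ⟨(3cos²θ − 1)/2⟩` of a molecular axis against the *effective normal*
  (the unit vector from the particle COM to the axis midpoint): S = 1 radial,
  0 isotropic, −0.5 tangential.  Also 1-D angle distributions and the joint
  CE conformation map (ring-vs-normal θ against ring-vs-oleate-chain φ).
* **Diffusion** — jump-length distributions of molecular COM displacements
  over a lag τ, least-squares fitted by the free-diffusion propagators
  `P₂d(r) = r/(2Dτ)·exp(−r²/4Dτ)` and
  `P₃d(r) = 4πr²(4πDτ)^(−3/2)·exp(−r²/4Dτ)`;
  the lower-residual model fixes the dimensionality (2D surface vs 3D core)
  and its D is reported, with a D(τ) plateau diagnostic for the long-time
  limit and 2·d·D dimension normalisation.
* **Contacts** — annular lipids (any bead within 0.8 nm of any protein
  bead), contact lifetimes under the tolerance rule (an interruption
  strictly shorter than 10 frames leaves the coupling unbroken),
  per-residue-type contact profiles, per-moiety contact fractions,
  group-group contact counts, and per-residue backbone RMSF after rigid-body
  superposition.
* **SASA** — Shrake–Rupley solvent-accessible surface area with the
  CG-converted 0.56 nm probe (0.14 nm × the 4:1 water mapping), split by
  residue hydrophobicity class.
* **Synthetic data** — droplets with the realistic HDL composition
  (260 POPC / 10 PPC / 122 CE / 49 CHOL / 39 TG + 2 chains), prescribed
  per-shell order parameters, prescribed 2D/3D diffusion coefficients, and
  exponential contact dwell processes — known ground truth for every
  estimator above.

Trajectory times are *effective* times: CG simulation time × 4, applied on
ingest when requested.

## Worked example

```bash
cat > cfg.yaml <<EOF
seed: 7
output_dir: out
synthetic: {n_frames: 60}
analyses: [density, order, diffusion, contacts, lifetimes, sasa]
lags_ns: [0.5, 1.0, 2.0]
min_jumps: 200
EOF
dropletmetrics run --config cfg.yaml
```

This generates a synthetic droplet (60 frames, 0.1 ns apart) and writes one
TSV per analysis plus `out/manifest.json`.  `out/diffusion.tsv` prints:

```
species	dimension	D_nm2_per_ns	D_scaled_2dD	plateau
POPC	2	0.0010147729	0.0040590915	True
PPC	2	0.00094629249	0.00378517	True
CHOL	2	0.00089999109	0.0035999644	True
CE	3	9.0105222e-05	0.00054063133	True
TG	3	9.823478e-05	0.00058940868	True
```

The generator placed POPC/PPC/CHOL on the surface shell with
D₂ = 1.0×10⁻³ nm²/ns and CE/TG in the core with D₃ = 1.0×10⁻⁴ nm²/ns: the
fits recover the prescribed coefficients, select the correct dimensionality
(2D at the lipid–water interface, 3D in the core — the core is slower by a
factor of 10), and flag the flat D(τ) plateau.  `out/contacts.tsv` reports
the time-averaged annular count and fraction per species, and
`out/density.tsv` the radial profiles in nm⁻³ (CE/TG density vanishes
outside 3 nm, POPC density vanishes inside 4 nm).

The same analyses run on real data by pointing the config at files instead:

```yaml
structure: hdl.gro
trajectory: hdl.xtc
apply_time_scale: true
```

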