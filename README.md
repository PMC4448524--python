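# crowdmd

Analysis of molecular-dynamics trajectories of **multiple copies of a
globular protein at millimolar concentration** — the regime where
protein–protein encounter, recognition and (possibly reversible) binding can
be watched directly.  The package targets the standard observables of such
studies: when do two copies meet, through which residues, how do their
relative orientations and electric dipoles behave on approach, how fast do
the copies diffuse, and what oligomeric species populate the box over time.

It is written for structural-bioinformatics / biomolecular-simulation users
who have multi-chain trajectories (multi-model PDB; per-atom charges via
PQR) and want desk-scale, reproducible analyses — plus a synthetic
rigid-body trajectory generator with exact ground truth, so every estimator
in the pipeline can be validated without any external data.

## What it computes

For every pair of protein copies (chains) per frame:

- **COM distance** `d(t)` between centers of mass, minimum-image under the
  periodic cubic box.  A maximally compact dimer of identical globules sits
  near the *gyration diameter* `2·Rg`.
- **Orientation angle** `θ(t) = arccos((tr R − 1)/2)` of the optimal (Kabsch)
  rotation `R` superposing one COM-centered copy onto the other;
  180° is a perfect C2-symmetric dimer.
- **Dipole angle** between molecular dipoles `μ = Σᵢ qᵢ(rᵢ − r̄)` (Debye).
- **Contact count**: heavy atoms of each copy within 4 Å of heavy atoms of
  the other (atoms counted once per side).

On top of these: per-residue contact-frequency profiles with running
residue averages and profile comparison (Pearson r, peak overlap);
binding/dissociation **event detection** with persistence filtering;
**oligomer-state classification** (monomer / dimer / linear vs compact
trimer / n-mer) from the inter-chain contact graph; translational
**diffusion coefficients** from time-origin-averaged MSD (`MSD(τ) = 6Dτ`);
PCA **conformational landscapes** `−k_BT ln(Nᵢ/N₀)` over Cα covariance
modes; and continuum **dipole–dipole electrostatics**

    E(r, θ) = μₐ μ_b (1 − 3cos²θ) / (4π ε₀ D r³),   |F| = 3|E|/r,

with the Arrhenius conversion `τ = exp(ΔG/RT)/k₀` from dissociation
barriers to timescales.

## Worked example

Simulate the default study system — three copies of a compact 70-residue
pseudo-protein (~560 heavy atoms, 250 D dipole) in a periodic 100 Å box,
i.e. ~5 mM, with one binding event scripted at 20 ns — then analyze it:

```sh
python analysis/01_simulate_encounters.py
python analysis/02_analyze_encounters.py
```

which prints (trajectory files under `scratch/`, tables under
`results/encounters/`):

```
  scripted binding ['A', 'B']: scheduled 20.0 ns, docked at 42.8 ns
analysis in results/encounters
  box concentration: 4.98 mM
  gyration diameter: 18.6 Å
  chain A: D = 1.47e-11 m²/s (R² 0.996)
  chain B: D = 1.78e-11 m²/s (R² 0.999)
  chain C: D = 2.56e-11 m²/s (R² 0.997)
  bind events: 1, unbind events: 0
```

Three copies in a (100 Å)³ box are 4.98 mM; the free copy (C) diffuses near
the generator's input `D = 3×10⁻¹¹ m²/s` while the scripted pair (A, B) is
slowed by its deterministic approach and docking; the event detector finds
exactly the one scripted binding.  The electrostatics driver

```sh
python analysis/05_electrostatics.py
```

prints the force a pair of protein-sized dipoles exerts across typical
encounter geometries:

```
  300 D dipoles at 135°, 50 Å: 0.277 pN (attractive)
  200 D dipoles at 70°, 35 Å: 0.665 pN magnitude
  ΔG = 20.0 kcal/mol → τ = 3.71e+08 s
```

i.e. tenths of a piconewton already at 50 Å separation — enough to bias the
diffusion of a ~10 kDa protein — and dissociation timescales that leap from
milliseconds to years as the barrier grows from 5 to 20 kcal/mol at a 1 µs⁻¹
attempt frequency.

The remaining drivers build replica contact profiles
(`03_contact_profiles.py`) and a PCA landscape from a synthetic two-mode
ensemble (`04_landscape.py`).  The same functionality is exposed as a CLI
(`crowdmd simulate|analyze|landscape|electro|events`).

## Layout

- `src/crowdmd/` — library: `io`, `geometry`, `contacts`, `electrostatics`,
  `landscape`, `events`, `synthetic`, `pipeline`, `cli`, `constants`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite (unit, property and end-to-end acceptance tests).
- `docs/methods.md` — models, conventions, parameter choices, limitations.
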