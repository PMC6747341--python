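# iondyn

Post-simulation analysis of molecular-dynamics trajectories of metal-binding
proteins, built around the questions raised by MMP-2 (matrix
metalloproteinase-2), a Zn²⁺-dependent collagenase with catalytic (Cat),
fibronectin (Fib) and hemopexin (Hpx) domains joined by a short linker and
five crystallographically assigned divalent cations (2 Zn²⁺, 3 Ca²⁺).
Given a structure, a nonbonded parameter table and a trajectory, the package
answers, stage by stage:

* **How stable is each domain?** Superposition RMSD, per-residue RMSF,
  radius of gyration R_g, inter-domain center-of-mass distances, minimum
  periodic-image distance, and the Schlitter quasi-harmonic configurational
  entropy S(t) whose plateau marks equilibration.
* **What conformational families are sampled?** Backbone ϕ/ψ dihedrals are
  embedded as (cos θ, sin θ) and analysed by principal components (dPCA);
  the first two components are binned into a free-energy landscape
  ΔG = −RT ln(ρ_xy/ρ_max), and k-means (with SSE, average silhouette width
  S_AVG and silhouette coefficient SC diagnostics) extracts families whose
  lowest-ΔG members are exported as PDB representatives.
* **Which domains move together?** The Cα covariance matrix yields the
  dynamic cross-correlation matrix (DCCM) of Pearson coefficients
  c_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) and a Cartesian PCA with per-component
  RMSF profiles and variance fractions.
* **How are the ions hydrated?** Ion–water-oxygen radial distribution
  functions g(r), hydration-shell occupancy probabilities, coordination
  numbers CN = 4πρ₀∫g(r)r²dr, and Shrake–Rupley solvent-accessible surface
  areas.
* **How strongly are the ions bound, and by which residues?** Pairwise
  Lennard-Jones + Coulomb interaction energies
  (σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_iε_j), f = 138.935458 kJ mol⁻¹ nm e⁻²),
  continuum-solvation terms, the interaction entropy
  −TΔS = RT ln⟨e^{βΔE}⟩ with bootstrap standard errors, Tukey-fence
  ([Q1 − k·IQR, Q3 + k·IQR]) outlier calling of per-residue contributions,
  and coordination-geometry classification (linear … octahedral) by
  angle-RMSD against ideal templates.

A first-class synthetic-data module generates trajectories with *planted*
ground truth — multi-state dihedral dynamics with known populations,
rigid domains with known correlation signs, an ion in a pocket with exactly
known energies (computed by a deliberately naive loop that serves as the
oracle for the vectorised pipeline), and hydration shells with known
occupancies — so every stage is verified by parameter recovery without any
simulation data.

Internal units follow the GROMACS convention: nm, kJ/mol, ns, elementary
charges, K.

## Worked example

An ion sampled by Metropolis Monte Carlo at 310 K in a four-site charged
pocket, analysed by the energetics stage:

```python
import numpy as np
from iondyn import SyntheticSpec, select
from iondyn.synthetic import gen_ion_pocket
from iondyn.energetics import (interaction_energy, interaction_entropy,
                               bootstrap_se, assign_geometry)

spec = SyntheticSpec("ion_pocket", n_frames=1000, seed=1,
                     params={"sampling": "metropolis", "temperature": 310.0})
system, traj, oracle = gen_ion_pocket(spec)
ions = select(system, "domain ion")
sites = select(system, "domain Cat")
series = interaction_energy(traj, system, ions, sites)
print(f"mean E_int  = {series.total.mean():.2f} +/- "
      f"{bootstrap_se(series.total, n_boot=5000, seed=1):.2f} kJ/mol")
print(f"-T dS       = {interaction_entropy(series, 310.0):.3f} kJ/mol")
print(f"oracle gap  = {np.abs(series.total - oracle).max():.2e} kJ/mol")
geo = assign_geometry(traj.coords[-1], int(ions[0]), system)
print(f"coordination: {geo.label} (angle RMSD {geo.angle_rmsd:.1f} deg, "
      f"{geo.ligand_atoms.size} ligands)")
```

prints

```
mean E_int  = -2223.96 +/- 0.09 kJ/mol
-T dS       = 2.175 kJ/mol
oracle gap  = 9.09e-13 kJ/mol
coordination: tetrahedral (angle RMSD 5.6 deg, 4 ligands)
```

The divalent ion is strongly bound (electrostatics dominate), the entropic
penalty from energy fluctuations is small and positive as Jensen's
inequality requires, the vectorised energy pipeline agrees with the
generator's independent naive-loop oracle to 1e-13 kJ/mol, and the ion sits
tetrahedrally inside its four coordinating sites.

The same analyses are available from the shell:

```bash
iondyn synth ion_pocket --n-frames 1000 --seed 1 --out pocket
iondyn energy pocket/ion_pocket.pdb --trajectory pocket/ion_pocket.xtc \
       --params pocket/ion_pocket.params.tsv
iondyn run -c config.yaml      # full pipeline, all stages
```

## Layout

| module | contents |
| --- | --- |
| `iondyn.model_io` | `MolecularSystem`, `Trajectory`, parameter tables, domain configs, selections, PDB/XTC/DCD IO |
| `iondyn.synthetic` | scenario generators with planted ground truth |
| `iondyn.geometry` | RMSD/RMSF/R_g/COM/periodic-image observables |
| `iondyn.conformation` | dihedrals, dPCA, free-energy landscape, k-means families, Schlitter entropy |
| `iondyn.dynamics` | covariance, DCCM, Cartesian PCA |
| `iondyn.solvation` | RDF, shell occupancies, coordination numbers, SASA |
| `iondyn.energetics` | interaction energies, solvation terms, interaction entropy, bootstrap, Tukey fences, coordination geometry |
| `iondyn.crystal` | single-structure (crystal) reference report |
| `iondyn.pipeline` | one-config orchestration with provenance |

See `docs/methods.md` for the models, conventions, defaults and known
limitations.
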