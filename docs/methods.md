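# Methods

This note records the models implemented in `iondyn`, the conventions and
defaults they use, what the synthetic generators do and do not emulate, and
the design choices made where more than one reasonable definition exists.
No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

GROMACS conventions throughout: lengths nm, energies kJ/mol, times ns (ps at
file boundaries), charges in units of e, temperatures K. The Coulomb
prefactor is 1/(4πε₀) = 138.935458 kJ mol⁻¹ nm e⁻²; the molar gas constant
R = 8.314462618×10⁻³ kJ mol⁻¹ K⁻¹; the default temperature is 310 K
(physiological). Residue numbering is 1-based author numbering from the PDB;
domain ranges are inclusive on both ends.

## Systems, parameters, domains

A `MolecularSystem` carries per-atom name, element, residue, chain, mass,
partial charge q, and Lennard-Jones σ/ε. Parameters come from a plain-text
TSV table keyed by (residue name, atom name), with `*` atom-name wildcards
and per-element fallbacks; His protonation variants (HSD/HSE/HSP/HID/HIE)
alias to HIS at lookup. The shipped table covers the divalent-cation model
used for Zn²⁺ (σ = 0.226466454151 nm, ε = 0.01381916624 kJ/mol) and Ca²⁺
(σ = 0.293818397243 nm, ε = 0.44320568080 kJ/mol), water oxygen, and
generic LJ values per element; it deliberately does *not* assign protein
partial charges — a force-field-complete table (or the scenario-specific
table emitted next to every synthetic bundle) must be supplied when
electrostatics beyond the ions matter. Monoatomic HETATM residues named
like ions are labelled `ion` and get formal charges (+2 for Zn²⁺/Ca²⁺).

Domain labels are assigned by residue ranges in declaration order, so the
MMP-2 default lists the fibronectin insert (Fib 217–393) before the
catalytic range (Cat 110–445): `domain Cat` then means "Cat without Fib",
and the union is the selection `domain Cat or domain Fib`. Lnk is 446–460,
Hpx 461–660.

File IO (PDB, multi-model PDB, XTC, DCD) goes through mdtraj; XTC limits
round-trip coordinate precision to about 10⁻³ nm, DCD (float32) to about
10⁻⁵ nm.

## Geometry observables

Superposition is weighted Kabsch (SVD with a determinant correction, proper
rotations only, so mirror images keep a positive RMSD); collinear point sets
are rejected. The RMSD/RMSF reference is the iteratively converged average
structure (frames are refit to the running mean until it moves < 10⁻⁶ nm
RMS; two passes normally suffice). Ion RMSF is measured after superposing on
the protein Cα trace (`fit_selection`), i.e. the ion's excursion in the
protein frame. Note that fitting absorbs six rigid-body degrees of freedom:
for N identical isotropic atoms the measured RMSF is √((3N−6)/3N) of the
unfitted value, which the tests account for.

R_g is mass-weighted by default (a Cα-only, unit-weight variant is a
parameter choice). COM distances are computed on unwrapped coordinates — a
domain split across the periodic boundary has no meaningful COM, so no
wrapping is applied. The minimum periodic-image distance searches all 26
neighbouring lattice translations with a KD-tree.

Configurational entropy uses Schlitter's quasi-harmonic upper bound
S ≤ ½ R ln det[1 + (k_B T e²/ħ²) M^{1/2} C M^{1/2}] on the mass-weighted
Cα covariance; the +identity keeps the determinant finite for singular
covariances, so a static ensemble gives exactly S = 0. Computed on growing
windows [t₀, t], the first window after which S changes by < 1% over three
consecutive windows is taken as the equilibration time (overridable with a
fixed cutoff; downstream stages use only frames with t ≥ cutoff).

## Dihedral PCA and free-energy landscape

Backbone ϕ(i) = C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1)
are computed with the standard atan2 torsion formula (verified against
mdtraj); chain-terminal residues and residues flanking chain breaks are
skipped. Each angle enters PCA as the pair (cos θ, sin θ), which removes
the ±π wrap — the analysis is invariant to adding 2π to any angle. Only
ϕ/ψ are used (no ω or sidechain torsions).

The landscape is ΔG = −RT ln(ρ_xy/ρ_max) on a grid (default 100×100 over
the projection range padded 1%); empty bins are +∞ (ΔG is undefined at
ρ = 0), and the most populated bin has ΔG = 0 by construction.

Families come from scikit-learn k-means (k-means++ starts, best of
n_init = 50 by SSE, fixed seed). Silhouettes are exact up to 5000 points
and computed on a seeded subsample beyond that (the exact computation is
quadratic). S_AVG is the mean silhouette width at a given k; the silhouette
coefficient SC is defined as the maximum of S_AVG over a k-scan, a common
usage where the term is otherwise ambiguous. Each family's representative
is the member frame in the family's lowest-ΔG occupied bin (ties go to the
frame nearest the centroid), exported as PDB.

## Domain-movement analysis

The 3N×3N Cα covariance is computed after superposition onto the mean
structure by default, removing the six rigid-body degrees of freedom;
the six near-zero eigenvalues are excluded from the "internal" variance
fraction denominator (both internal and total fractions are reported).
Scenarios with *planted* rigid-body motion must use `superpose=False`,
since fitting would remove exactly the planted signal.

The DCCM is the Pearson coefficient of displacement vectors,
c_ij = tr C_ij/√(tr C_ii · tr C_jj) ∈ [−1, 1]; atoms with zero fluctuation
are flagged in a `defined` mask and their rows zeroed rather than
propagating NaNs; an entirely static input is an error. The quaternion
(GeoStaS-style) variant is out of scope. Cartesian PCA reports per-component
trajectory projections and the RMSF of single-component reconstructions
(std of the projection times the eigenvector's per-atom norm).

## Ion hydration

g(r) is the standard shell-volume-normalised RDF with minimum-image
distances in an orthorhombic box, reference density ρ₀ = N_target/⟨V_box⟩
and r_max capped at half the smallest box edge. Per-frame neighbour counts
per bin are kept on the profile, which makes three quantities exact rather
than quadrature-dependent:

* the coordination number CN(r) = 4πρ₀∫₀ʳ g r′² dr′ is integrated
  analytically over shell volumes (g is piecewise-constant per bin), which
  reproduces direct per-frame counting;
* the "statistical density" of a hydration shell is reported as the
  probability that at least one solvent molecule occupies the shell in a
  sampled frame. The literal cumulative integral ∫ g dr is not
  dimensionless and cannot be that probability; it is still exposed as
  `rdf_integral` for completeness, but the prose meaning is implemented.

Default shell boundaries follow the divalent-cation hydration profiles
(troughs 0.31/0.50 nm for Zn²⁺, 0.31/0.55 nm for Ca²⁺); an extrema detector
(`find_shells`) recovers them from the profile for other systems.

SASA is Shrake–Rupley via mdtraj (960 sphere points, probe 0.14 nm,
Bondi-style radii, per-element overrides available), computed on the solute
only so targets are shielded by the full protein/ion context.

## Energetics

The MM interaction energy is the cutoff-free gas-phase pairwise sum
E = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + Σ f q_i q_j/r with arithmetic-mean
σ_ij and geometric-mean ε_ij; pair distances below 10⁻⁴ nm are an error.
The per-residue decomposition assigns each pair term to the protein atom's
residue and sums exactly to the total.

Interaction entropy: −TΔS = RT ln⟨e^{βΔE}⟩ with ΔE = E − ⟨E⟩ and
β = 1/(RT) on molar energies (so RT ln⟨·⟩ is dimensionally consistent),
evaluated through a log-sum-exp shift that cannot overflow. Jensen's
inequality guarantees −TΔS ≥ 0, with equality only for constant series;
for Gaussian fluctuations of variance σ², −TΔS → βσ²/2. Standard errors
come from frame bootstrap (default n = 5000, seeded).

Continuum solvation replaces a finite-difference Poisson–Boltzmann solve
(out of scope) with a deliberately simple, clearly labelled Born-style
approximation: the polar binding term is the fraction of the ion's free
solvent exposure lost in the complex times the magnitude of the Born
transfer energy −(f/2)q²(1/ε_in − 1/ε_w)/a with ε_in = 4, ε_w = 80 and a
configurable Born radius (default 0.11 nm). It is positive (a desolvation
penalty), larger for buried ions, and zero for a fully exposed ion — the
sign structure of a PB term, not its magnitude. The nonpolar term is
γ·SASA + b with γ = 2.27 kJ mol⁻¹ nm⁻², b = 3.85 kJ/mol. The report
assembles ΔE_binding = ΔE_vdw + ΔE_elec + ΔG_polar + ΔG_nonpolar and
ΔG_binding = ΔE_binding + (−TΔS), each with bootstrap SE.

Tukey fences are [Q1 − k·IQR, Q3 + k·IQR] with linear-interpolation
(type-7) quartiles — the definition must be fixed explicitly since the
fence formula alone does not; k = 1.5 flags outliers, k = 3.0 extreme
outliers; values at or beyond a fence are flagged, except values lying
within [Q1, Q3] themselves (which only matters in the degenerate IQR = 0
case). Note that for the set {1,…,8} the k = 1.5 fences are −2.5 and 11.5.

Coordination geometry compares the sorted ligand–ion–ligand angle set of
all N/O ligands within 0.35 nm against ideal templates (linear, trigonal
pyramidal, tetrahedral, square planar, seesaw, trigonal bipyramidal,
octahedral), including parent geometries with one vacant position; lowest
angle-RMSD wins, ties prefer the exact-ligand-count template, and a best
RMSD above 20° (or fewer than 2 ligands) is "not-coordinated". Because a
seesaw is angle-identical to a trigonal bipyramid with an equatorial
vacancy, four ligands at those angles are reported as seesaw; services
that use bond-valence information may label the same site as a vacant
trigonal bipyramid.

## Synthetic generators — what they emulate and what they do not

All generators are seeded (`numpy` Generator); identical spec + seed gives
byte-identical output, and `write_scenario` emits the ground truth (and an
exact parameter table) beside the PDB/XTC bundle.

* `dihedral_states`: a polyalanine-like backbone built by natural-extension
  (NeRF) from per-state mean ϕ/ψ with wrapped-normal jitter (default sd
  10°), states drawn i.i.d. with the requested populations (default
  90/10, an α-helical and an extended basin, 8 residues). It plants basin
  populations and geometry, not kinetics: there are no barrier crossings in
  time, no correlated transitions, no sidechains.
* `domain_motion`: rigid blobs of Cα beads (10/domain) displaced along a
  common axis by a shared Gaussian signal with per-domain sign (+/−) or an
  independent signal, plus isotropic per-atom noise (defaults: amplitude
  0.1 nm, noise 0.01 nm — correlation magnitudes ≈ A²/(A²+3σ²) ≈ 0.97).
  It plants the correlation sign matrix; it has no internal domain
  deformation and no rotational modes.
* `ion_pocket`: one divalent ion among fixed charged LJ sites (default four
  −0.5 e sites at tetrahedral vertices, 0.25 nm), positions from a Gaussian
  or from Metropolis sampling of the exact pair energy at T; overlaps
  (r < 0.05 nm) are rejected and resampled. The per-frame energy is
  computed by a naive scalar double loop, kept deliberately independent of
  the vectorised energetics module, and returned as the oracle.
* `hydration_shells`: solvent-oxygen points on concentric shells with
  controlled (possibly fractional → Bernoulli) occupancy and small radial
  jitter, plus an optional uniform ideal-gas background, around a central
  ion in a cubic periodic box. Absent shell molecules are parked outside a
  configurable radius (default 0.45·L) to keep the atom count constant, so
  g(r) beyond that radius is not meaningful in fractional-occupancy
  scenarios. There are no water–water interactions and no orientational
  structure.

Passing parameter-recovery tests on these scenarios therefore demonstrates
the correctness of the estimators under their stated statistical
assumptions — not force-field realism, sampling convergence, or any
property of real MD data.

## Problem sizes and numerical choices

The verification battery uses sizes chosen to make the statistical
tolerances meaningful at interactive runtimes: 100 000 frames for the
Gaussian interaction-entropy limit (5% tolerance), 50 000 frames for the
90/10 landscape gap (10%) and cluster purity (≥ 99%), 10 000 frames for
DCCM block recovery (±0.1), 1000 frames for the energy-oracle comparison
(10⁻¹⁰ relative), and 1000 random datasets for the Tukey oracle. FEL grids
default to 100×100; the two-state recovery bins at 30×30 so the modal bin
of each basin holds enough counts that top-bin Poisson noise stays well
inside the 10% band. Numerical tie-breaks and degenerate-input behaviours (static
ensembles, zero-fluctuation atoms, IQR = 0, overlap rejection) are each
fixed and tested explicitly.

## Crystal-structure reference

`iondyn.crystal.crystal_report` reproduces the static observables of the
processed MMP-2 structure (PDB 1CK7): pro-peptide residues 31–109 removed,
Cα R_g, Cat–Hpx and Fib–Hpx COM distances, ion–ligand distances for the
crystallographic coordination sites, and per-ion geometry labels. The PDB
file is not redistributed; the corresponding tests require `data/1CK7.pdb`
and fail with an explanatory message when it is absent (e.g. in offline
environments).

## Known limitations

* The polar solvation term is a Born-style surrogate; absolute ΔG_polar
  magnitudes are not comparable to Poisson–Boltzmann results.
* The shipped parameter table has no protein partial charges; protein–ion
  electrostatics on real structures require a user-supplied table.
* RDFs assume orthorhombic boxes (the synthetic box is cubic); triclinic
  minimum-image is not implemented in the pair search.
* Geometry classification uses angles only; it cannot distinguish
  arrangements that differ only in bond-valence or vacancy placement.
* No DSSP, no hydrogen-bond analysis, no normal-mode or quasi-harmonic
  entropy beyond Schlitter, no PB solver, no polarizable force fields.
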