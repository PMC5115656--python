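# Methods

## Scope and model

`kynox` post-processes converged electronic-structure results into
antioxidant descriptors; everything upstream of a `SpeciesRecord` (geometry
optimization, Hessians, solvation, single points) is out of scope. All
energies are held internally in kcal/mol; serialized inputs may declare
hartree, eV or kJ/mol per record and are converted on read through a single
registry that pivots through kcal/mol (eV is defined as
hartree/27.211386245988, so chained conversions compose exactly).

### Thermochemistry

The bond dissociation enthalpy is assembled from total energies of the
whole molecule, its H-abstracted radical, and the free H atom; the
corrected value adds H_T, the same combination of thermal enthalpy
corrections at 298.15 K. The adiabatic ionization potential is keyed on a
charge difference of +1 between parent and electron-abstracted form rather
than on absolute charges, which covers the convention that the
"electron-abstracted form" of an anionic (ionized-carboxyl) parent is the
neutral molecule. Descriptor rows never mix theory levels or phases; the
assembler resolves record labels at one level/phase and leaves absent
ingredients as absent fields, never zeros.

δ_SD, the spin-delocalization descriptor, is the standard deviation of the
per-atom Mulliken spin densities. The population convention (divide by N)
is the default because the atom set of a radical is complete, not a sample;
the sample convention and a heavy-atoms-only restriction are selectable.
O\* and C_PARA atoms are identified by caller-supplied indices — assigning
them chemically is the user's job; the package does no ring perception.

The PCET charge descriptors use the radical-specific oxygen combination:
dQ(O) = Q(O₂) + Q(O₃) − Q(O₁) for a peroxy radical (two acceptor oxygens)
and Q(O₂) − Q(O₁) for a phenoxyl-type radical; Δ quantities are TS minus
reagent complex.

### Kinetics

ΔG_TS−R in the corrected barrier is the difference of thermal free-energy
*corrections*, not of full free energies: the corrected barrier is the
electronic barrier plus that difference, which is the reading under which
the packaged rate constants reproduce. The rate model is conventional TST
with a Wigner factor. Two deliberately "conventional" constants are
defaults with physical alternatives selectable per call:

| parameter | default | physical alternative | why the default |
|---|---|---|---|
| Wigner coefficient (cm·K) | 1.44 | hc/k_B = 1.4388 | bit-compatibility with the conventional rounded literal |
| standard-state factor | 24.3 | 24.465 (ideal-gas molar volume at 298.15 K, L/mol) | same |

k_B = 1.380649×10⁻²³ J/K and h = 6.62607015×10⁻³⁴ J·s are the SI defining
constants; R = 1.98720425×10⁻³ kcal/(mol·K); T defaults to 298.15 K. Rates
are bimolecular (M⁻¹s⁻¹) only. `system_rate` supports the hybrid recipe in
which electronic energies come from large-basis single points while
ΔG_TS−R and ν_i are carried over from the optimization level; the result
carries a provenance note naming the mix.

### Range-separation tuning

J²(μ) is built from per-μ (neutral, cation, anion) triples:
IP(N) = E(cation) − E(neutral), IP(N+1) = E(neutral) − E(anion), with
E_HOMO(N) from the neutral and E_HOMO(N+1) from the anion. Splines use the
**not-a-knot** boundary condition. This was a genuinely open choice (only
"spline interpolation" is conventional); not-a-knot is the standard
interpolation default and reproduces cubic — hence parabolic — sample
curves exactly, which a natural spline (zero end second derivatives) does
not. Missing grid points may only be interpolated, never extrapolated, and
are flagged. The minimum is located by dense evaluation at 10⁻⁴ resolution
followed by bounded scalar refinement to ~10⁻⁶; when refinement does not
strictly improve on the best grid point the grid point wins, which also
breaks flat-curve ties toward the smallest μ.

### Geometry

"O…H…O length" is the donor-to-acceptor O–O distance (the tabulated
2.4–2.9 Å magnitudes are O–O separations); the O–H + H–O path sum is
available by composing `distance` calls. Torsions are IUPAC right-handed
dihedrals mapped to [0°, 360°) so that near-eclipsed negative dihedrals
report as ~350° rather than ~−9°. Note the signed dihedral is *invariant*
under reversing the atom chain (both plane normals negate); it negates
under mirror reflection. Plane angles are folded to [0°, 90°]. RMSD uses
atom order as the correspondence, unit weights, and proper-rotation
(Kabsch) superposition via SVD; residuals are evaluated explicitly after
applying the rotation to avoid the cancellation error of closed-form
residual norms. Raw (non-superposed) RMSD is a flag away, since whether a
published RMSD was superposed is often unstated.

### Statistics

Pearson p-values come from the exact t-transform with n−2 degrees of
freedom, two-sided. Exclusion of outlier compounds from validation sets is
always an explicit argument, never a heuristic. Rank orderings merge values
within a relative tie tolerance (default 3%); the tolerance is configurable
because "approximately equal" in comparative tables is a judgment call —
the packaged gas-phase rates of 3HAA and L-3HOK differ by a factor 1.31 and
merge only at a wider tolerance. Summary ± values default to the sample
convention.

The consistency checker (`reproduce_tables`) re-derives every derivable
cell of the packaged tables: HOMO–LUMO gaps from printed orbital energies,
corrected barriers from printed parts, ΔE_TS−P from ΔE_TS−R − ΔE_P−R, and
rate constants from printed barriers and frequencies (refined-level rates
reuse the optimization-level frequency, per the hybrid recipe).
Discrepancies are reported, never raised. The sum tolerance defaults to
1.5×10⁻³ kcal/mol — the half-ulp budget of three cells printed to three
decimals — so pure print rounding never flags, while genuine
inconsistencies do (the checker finds eight, including one corrected
barrier that differs from the sum of its printed parts by 0.2 kcal/mol and
one rate constant whose printed exponent is off by one).

## Synthetic data

The generators emulate the *statistical structure* of quantum-chemistry
outputs by inverse construction: target descriptor values are chosen first
and absolute energies drawn around them, because the pipeline consumes only
differences (absolute scales are gauge freedom). Defaults encode the study
conditions:

* thermal corrections to the BDE are drawn from N(−6.645, 0.260) kcal/mol,
  the tight cluster characteristic of O–H homolysis in this compound class;
* the free H atom's thermal enthalpy correction is fixed at 1.481 kcal/mol
  (5/2 RT at 298.15 K, the ideal-gas atom value);
* ΔG_TS−R corrections are drawn from N(−2.0, 0.6) kcal/mol, the range of
  the hydrogen-transfer pathways in the packaged tables;
* tuning curves are parabolas (μ − μ*)²·curvature with seeded smooth noise
  ≤ 10⁻⁶ (exactly flat when curvature is zero); orbital energies are derived
  from the *stored* rounded total energies so the planted J² is exact in
  floating point;
* geometry fixtures are constructed analytically from the target
  descriptors (law-of-cosines O–H–O triangle, internal-coordinate placement
  of the torsion atom, normal-rotation construction of the second ring
  plane) and then moved by a seeded random rigid motion.

One `numpy.random.Generator` seeded per call drives all draws; identical
seeds give byte-identical serialized output. What the generators do *not*
emulate: real potential-energy surfaces, conformer ensembles, basis-set or
functional behavior, or correlated noise between descriptors. Passing tests
therefore demonstrate that the algebra, spline work, geometry and
statistics are correct on data with known truth — not that any particular
chemistry is reproduced beyond the packaged study tables.

## Numerical choices and degenerate inputs

Unit conversions are exact linear maps; round-trips hold to 1e-12 relative.
Validation rejects non-finite coordinates, element/nuclear-charge
mismatches, nonzero spin density on singlets (>1e-6), non-positive
imaginary-frequency magnitudes, and level/phase mixing inside any single
descriptor. Zero-length bond-angle arms, collinear plane triples, and
degenerate dihedrals raise rather than return NaN. Spline work requires at
least four curve points. The packaged printed tables are protected by a
SHA-256 checksum verified at load.

## Problem sizes

The test suite runs planted-truth recovery over 100 seeds across the four
generators plus property tests at a few dozen examples each; the whole
suite completes in a few seconds on one CPU, and the acceptance script is a
handful of closed-form evaluations.

## Known limitations

* No parsing of native quantum-chemistry log files; an adapter mapping a
  third-party parser's output onto `SpeciesRecord` is the intended route.
* CSV carries scalar fields only; records with atom lists require JSON.
* No unimolecular (s⁻¹) rate mode, no variational TST, no Eckart or
  small-curvature tunneling.
* The printed μ-opt values of the descriptor table cannot be recomputed
  from the package's inputs (they require the underlying per-μ energies,
  which are not printed); they are carried as fixture metadata only.
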