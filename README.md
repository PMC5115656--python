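# kynox

Antioxidant thermochemistry and hydrogen-transfer kinetics computed from
structured quantum-chemistry results, built around the redox chemistry of
kynurenines — the tryptophan catabolites (3-hydroxykynurenine, 3-hydroxy-
anthranilic acid, xanthurenic acid, …) whose pro- and antioxidant balance is
implicated in neurodegenerative disease.

`kynox` is a post-processing library: it consumes per-species summaries of
electronic-structure output (total energies, thermal corrections, frontier
orbital energies, imaginary frequencies, Mulliken populations, Cartesian
coordinates) and computes the descriptors by which radical-scavenging
activity is compared. It runs no electronic-structure calculation itself.

## What it computes

**Hydrogen and electron donation.** For a phenolic antioxidant ArO–H with
total energies E and thermal enthalpy corrections H:

    BDE     = E(ArO•) + E(H•) − E(ArOH)          homolytic O–H bond enthalpy
    BDE_COR = BDE + H_T,  H_T = H(ArO•) + H(H•) − H(ArOH)
    IP      = E(ArOH•⁺) − E(ArOH)                adiabatic ionization potential

plus the frontier-orbital quantities (HOMO–LUMO gap E_HOMO − E_LUMO, the
Koopmans residual IP − (−E_HOMO)), the spin-delocalization descriptor δ_SD
(standard deviation of per-atom Mulliken spin density of the radical), and
the PCET charge descriptors Q(H), ΔQ(H), dQ(O), Δ(dQ)_TS−R of
hydrogen-transfer transition structures.

**Kinetics.** Conventional transition-state theory with Wigner tunneling
for the bimolecular H transfer ArOH + •OR → ArO• + HOR:

    k(T) = I · (k_B T / h) · exp(−ΔE_COR / RT) · 24.3 · A(T)
    A(T) = 1 + (1/24) (1.44 ν_i / T)²

with ΔE_COR = ΔE_TS−R + ΔG_TS−R (electronic barrier plus the difference of
thermal free-energy corrections), ν_i the TS imaginary frequency in cm⁻¹,
and 24.3 the 1 atm → 1 M standard-state factor.

**Range-separation tuning.** The Koopmans residual
J²(μ) = [E_HOMO^μ(N) + IP^μ(N)]² + [E_HOMO^μ(N+1) + IP^μ(N+1)]² built from
per-μ neutral/cation/anion energies, spline interpolation of missing grid
points, and location of the optimal μ on the spline.

**Geometry.** O…O distance through the transferred H, O–H–O angle, ring
plane angle, C–O…O–C torsion on [0°, 360°), and Kabsch-superposed RMSD
between conformations.

**Statistics and reproduction.** Pearson correlations with exact t-based
p-values, mean ± sd summaries, rank orderings with tie tolerance, and a
consistency checker that re-derives every derivable cell of the packaged
study tables and reports printed-vs-recomputed discrepancies.

A seeded synthetic-data module generates species records, reaction systems,
tuning curves and coordinate sets with planted ground truth, so the whole
pipeline is testable without any electronic-structure code.

## Worked example

```python
from kynox import paper_fixture, rate_constant

cells = paper_fixture().table3["Ph-O*"]["3HAA"]["II_gas"]
out = rate_constant(cells["dE_TS-R/COR"], cells["nu_i"])
print(f"A(T) = {out.tunneling_factor:.3f},  k(T) = {out.rate:.3e} 1/(M s)")
```

prints

```
A(T) = 2.632,  k(T) = 1.443e+14 1/(M s)
```

i.e. with its corrected barrier of 0.600 kcal/mol and tunneling factor 2.63,
3-hydroxyanthranilic acid donates its phenolic H to a phenoxyl radical at
~1.4 × 10¹⁴ M⁻¹s⁻¹ — three to four orders of magnitude faster than the
xanthurenic-acid tautomers, which is the thermochemical basis of its high
scavenging activity. The `examples/` directory holds one short script per
capability (descriptors, rates, tuning, geometry, table consistency); each
prints the numbers it computes and a line on what they mean.

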