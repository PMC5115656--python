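"""Bond dissociation enthalpy and ionization potential from species records.

Builds a small synthetic set of quantum-chemistry species records with
planted energetics (values chosen near the hydroxykynurenine range) and
assembles the standard antioxidant descriptor table from them.
"""

from kynox import RecipeEntry, build_descriptor_table, generate_species_set

# (label, O-H BDE, adiabatic IP, HOMO-LUMO gap), kcal/mol
targets = [
    ("L-3HOK-like", 73.166, 165.428, -92.118),
    ("phenol-like", 106.511, 190.455, -137.362),
]
records, truth = generate_species_set(seed=42, spec=targets)
rows = build_descriptor_table(
    records,
    [RecipeEntry(label, label, f"{label}*", f"{label}+")
     for label, *_ in targets])

print(f"{'compound':<12} {'BDE':>8} {'BDE_COR':>8} {'IP':>8} {'H-L gap':>9}")
for row in rows:
    print(f"{row.label:<12} {row.bde:>8.3f} {row.bde_cor:>8.3f} "
          f"{row.ip:>8.3f} {row.hl_gap:>9.3f}")
print("\nLower O-H BDE and IP mean easier H-atom and electron donation: the "
      "aminophenol-like compound is the far better radical scavenger; "
      "BDE_COR folds in the ~ -6.6 kcal/mol thermal correction at 298 K.")
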