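"""Species-record data model and I/O.

A :class:`SpeciesRecord` is one chemical species at one theory level and
phase: total energy, thermal corrections, frontier-orbital energies, the
transition-structure imaginary frequency, and optionally per-atom Cartesian
coordinates with Mulliken charges and spin densities.  These records are the
sole input of every downstream computation; nothing in the package reads raw
quantum-chemistry logs.

Energies are stored in kcal/mol.  Serialized documents may declare a
different unit per record via an ``energy_unit`` tag; values are converted
on read.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

from .constants import convert_energy

__all__ = [
    "AtomRecord",
    "SpeciesRecord",
    "ReactionSystem",
    "PHASES",
    "LEVELS",
    "read_species_records",
    "write_species_records",
    "read_xyz_block",
]

PHASES = frozenset({"gas", "water"})
LEVELS = frozenset({"I", "II", "III", "III(LC-BLYP)", "IV", "V"})

# Element symbols for the nuclear charges that occur in organic antioxidant
# structures (H through Kr covers every species handled here).
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr"
).split()
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

_ENERGY_FIELDS = ("energy", "h_corr", "g_corr", "e_homo", "e_lumo")


@dataclass
class AtomRecord:
    """One atom: element, Cartesian coordinates (A), Mulliken populations."""

    element: str
    x: float
    y: float
    z: float
    nuclear_charge: int | None = None
    mulliken_charge: float | None = None
    mulliken_spin: float | None = None

    def __post_init__(self) -> None:
        if self.element not in SYMBOL_TO_Z:
            raise ValueError(f"unknown element symbol: {self.element!r}")
        if self.nuclear_charge is None:
            self.nuclear_charge = SYMBOL_TO_Z[self.element]
        elif SYMBOL_TO_Z[self.element] != self.nuclear_charge:
            raise ValueError(
                f"element {self.element!r} does not match nuclear charge "
                f"{self.nuclear_charge}"
            )
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"non-finite coordinate in atom {self.element}")

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class SpeciesRecord:
    """One species at one theory level and phase, energies in kcal/mol."""

    label: str
    energy: float
    charge: int = 0
    multiplicity: int = 1
    level: str = "II"
    phase: str = "gas"
    h_corr: float | None = None
    g_corr: float | None = None
    e_homo: float | None = None
    e_lumo: float | None = None
    nu_imag: float | None = None
    atoms: list[AtomRecord] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"{self.label}: phase {self.phase!r} not in {sorted(PHASES)}"
            )
        if self.level not in LEVELS:
            raise ValueError(
                f"{self.label}: level {self.level!r} not in {sorted(LEVELS)}"
            )
        if self.multiplicity < 1:
            raise ValueError(f"{self.label}: multiplicity must be positive")
        if self.nu_imag is not None and not self.nu_imag > 0:
            raise ValueError(
                f"{self.label}: imaginary frequency must be stored as a "
                f"positive magnitude, got {self.nu_imag}"
            )
        if self.multiplicity == 1 and self.atoms:
            for i, atom in enumerate(self.atoms):
                if atom.mulliken_spin is not None and abs(atom.mulliken_spin) > 1e-6:
                    raise ValueError(
                        f"{self.label}: singlet species carries nonzero spin "
                        f"density {atom.mulliken_spin} on atom {i}"
                    )

    def require(self, *fields: str) -> None:
        """Raise if any named optional field is absent."""
        for name in fields:
            if getattr(self, name) is None:
                raise ValueError(f"record {self.label!r} lacks field {name!r}")


@dataclass
class ReactionSystem:
    """Reagent complex, transition structure, and product complex of one
    hydrogen-transfer pathway."""

    name: str
    radical: str  # "phenoxyl" | "methyl_peroxy" | "other"
    reagents: SpeciesRecord
    ts: SpeciesRecord
    products: SpeciesRecord
    degeneracy: int = 1

    def __post_init__(self) -> None:
        if self.radical not in {"phenoxyl", "methyl_peroxy", "other"}:
            raise ValueError(f"unknown radical kind: {self.radical!r}")
        if self.ts.nu_imag is None:
            raise ValueError(
                f"{self.name}: transition structure lacks an imaginary frequency"
            )
        if self.degeneracy < 1:
            raise ValueError(f"{self.name}: degeneracy must be >= 1")
        for s in (self.ts, self.products):
            if (s.level, s.phase) != (self.reagents.level, self.reagents.phase):
                raise ValueError(
                    f"{self.name}: species {s.label!r} level/phase "
                    f"({s.level}, {s.phase}) differs from reagents "
                    f"({self.reagents.level}, {self.reagents.phase})"
                )


# ---------------------------------------------------------------------------
# serialization

def _atom_to_dict(a: AtomRecord) -> dict:
    d = {"element": a.element, "nuclear_charge": a.nuclear_charge,
         "x": a.x, "y": a.y, "z": a.z}
    if a.mulliken_charge is not None:
        d["mulliken_charge"] = a.mulliken_charge
    if a.mulliken_spin is not None:
        d["mulliken_spin"] = a.mulliken_spin
    return d


def _record_to_dict(r: SpeciesRecord) -> dict:
    d: dict = {
        "label": r.label, "charge": r.charge, "multiplicity": r.multiplicity,
        "level": r.level, "phase": r.phase, "energy": r.energy,
    }
    for name in ("h_corr", "g_corr", "e_homo", "e_lumo", "nu_imag"):
        v = getattr(r, name)
        if v is not None:
            d[name] = v
    if r.atoms is not None:
        d["atoms"] = [_atom_to_dict(a) for a in r.atoms]
    if r.extra:
        d["extra"] = dict(r.extra)
    return d


_SCALAR_KEYS = {"label", "charge", "multiplicity", "level", "phase", "energy",
                "h_corr", "g_corr", "e_homo", "e_lumo", "nu_imag"}


def _record_from_dict(d: dict) -> SpeciesRecord:
    label = d.get("label", "<unlabelled>")
    unit = d.get("energy_unit", "kcal_per_mol")
    known = {k: d[k] for k in _SCALAR_KEYS if k in d and d[k] is not None}
    extra = dict(d.get("extra", {}))
    for k, v in d.items():
        if k not in _SCALAR_KEYS and k not in {"atoms", "extra", "energy_unit"}:
            extra[k] = v
    for name in ("charge", "multiplicity"):
        if name in known:
            try:
                known[name] = int(known[name])
            except (TypeError, ValueError):
                raise ValueError(f"record {label!r}: malformed field {name!r}: "
                                 f"{known[name]!r}") from None
    for name in _ENERGY_FIELDS + ("nu_imag",):
        if name in known:
            try:
                known[name] = float(known[name])
            except (TypeError, ValueError):
                raise ValueError(f"record {label!r}: malformed field {name!r}: "
                                 f"{known[name]!r}") from None
    if unit != "kcal_per_mol":
        for name in _ENERGY_FIELDS:
            if name in known:
                known[name] = convert_energy(known[name], unit, "kcal_per_mol")
    atoms = None
    if "atoms" in d and d["atoms"] is not None:
        atoms = [AtomRecord(**a) for a in d["atoms"]]
    if "energy" not in known:
        raise ValueError(f"record {label!r}: missing required field 'energy'")
    return SpeciesRecord(atoms=atoms, extra=extra, **known)


def _open(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_species_records(source, format: str = "json") -> list[SpeciesRecord]:
    """Read species records from a path or stream.

    JSON documents are a list of species objects (atoms supported); CSV
    carries scalar fields only, one record per row, with a mandatory header.
    A per-record ``energy_unit`` tag (``hartree``, ``eV``, ``kJ_per_mol``,
    ``kcal_per_mol``) converts all energy-like fields on read.
    """
    fh, close = _open(source, "r")
    try:
        if format == "json":
            doc = json.load(fh)
            if not isinstance(doc, list):
                raise ValueError("JSON species document must be a list")
            return [_record_from_dict(d) for d in doc]
        if format == "csv":
            reader = csv.DictReader(fh)
            records = []
            for row in reader:
                d = {k: v for k, v in row.items() if v not in (None, "")}
                records.append(_record_from_dict(d))
            return records
        raise ValueError(f"unknown format: {format!r}")
    finally:
        if close:
            fh.close()


def write_species_records(records: Iterable[SpeciesRecord], sink,
                          format: str = "json") -> None:
    """Write records so that ``read_species_records`` recovers them
    field-for-field.  CSV cannot carry atom lists; writing a record with
    atoms in CSV format raises."""
    records = list(records)
    fh, close = _open(sink, "w")
    try:
        if format == "json":
            json.dump([_record_to_dict(r) for r in records], fh, indent=1)
        elif format == "csv":
            if any(r.atoms for r in records):
                raise ValueError("CSV format carries scalar fields only; "
                                 "use JSON for records with atoms")
            cols = ["label", "charge", "multiplicity", "level", "phase",
                    "energy", "h_corr", "g_corr", "e_homo", "e_lumo", "nu_imag"]
            writer = csv.writer(fh)
            writer.writerow(cols)
            for r in records:
                writer.writerow(["" if getattr(r, c) is None else
                                 repr(getattr(r, c)) if isinstance(getattr(r, c), float)
                                 else getattr(r, c) for c in cols])
        else:
            raise ValueError(f"unknown format: {format!r}")
    finally:
        if close:
            fh.close()


def read_xyz_block(source) -> list[AtomRecord]:
    """Parse a coordinate block of ``name  nuclear_charge  x  y  z`` lines.

    Whitespace-delimited; blank lines and a leading atom-count/comment pair
    (plain XYZ convention) are tolerated.  The nuclear charge must match the
    element symbol.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        # plain-XYZ header lines: a bare count, or a comment after it
        if len(parts) == 1 and parts[0].isdigit() and not atoms:
            continue
        if len(parts) != 5:
            if not atoms and not parts[0] in SYMBOL_TO_Z:
                continue  # comment line of a plain-XYZ header
            raise ValueError(
                f"line {lineno}: expected 'name charge x y z', got {line!r}"
            )
        name, q, xs, ys, zs = parts
        symbol = name.rstrip("0123456789")
        if symbol not in SYMBOL_TO_Z:
            raise ValueError(f"line {lineno}: unknown element in {name!r}")
        try:
            z_nuc = float(q)
            coords = tuple(float(v) for v in (xs, ys, zs))
        except ValueError:
            raise ValueError(f"line {lineno}: malformed number in {line!r}") from None
        if int(round(z_nuc)) != SYMBOL_TO_Z[symbol]:
            raise ValueError(
                f"line {lineno}: nuclear charge {q} does not match element "
                f"{symbol!r} (expected {SYMBOL_TO_Z[symbol]})"
            )
        atoms.append(AtomRecord(symbol, *coords))
    return atoms
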