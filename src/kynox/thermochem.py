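"""Antioxidant thermochemistry descriptors.

Implements the standard gas/solution descriptors of hydrogen- and
electron-donating ability computed from total energies and thermal
corrections of the whole molecule, its H-abstracted radical, the free H
atom, and the one-electron-abstracted form:

* homolytic O-H bond dissociation enthalpy
  ``BDE = E_RAD + E_H - E_W`` and its thermally corrected variant
  ``BDE_COR = BDE + H_T`` with ``H_T = H_RAD + H_H - H_W``;
* adiabatic ionization potential ``IP = E_CAT - E_W`` (for anionic parents
  the "cation" is the neutral form — the operation keys on the charge
  difference, not the absolute charge);
* frontier-orbital quantities: HOMO-LUMO gap and the Koopmans residual
  ``IP - (-E_HOMO)``;
* spin-delocalization descriptors (standard deviation of per-atom Mulliken
  spin density) and the PCET charge descriptors Q(H), dQ(H), dQ(O),
  d(dQ)_TS-R of hydrogen-transfer transition structures.

All energies in kcal/mol, charges and spin densities in e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import ReactionSystem, SpeciesRecord

__all__ = [
    "DescriptorRow",
    "ChargeDescriptors",
    "RecipeEntry",
    "bde",
    "thermal_correction",
    "bde_cor",
    "ip",
    "homo_lumo_gap",
    "koopmans_delta",
    "spin_delocalization",
    "charge_descriptors",
    "build_descriptor_table",
]


@dataclass
class DescriptorRow:
    """One compound's descriptors at one level/phase (absent fields are
    ``None``, never zero)."""

    label: str
    level: str
    phase: str
    bde: float | None = None
    h_t: float | None = None
    bde_cor: float | None = None
    ip: float | None = None
    e_homo: float | None = None
    e_lumo: float | None = None
    hl_gap: float | None = None
    koopmans_delta: float | None = None
    delta_sd: float | None = None
    sd_ostar: float | None = None
    sd_cpara: float | None = None

    def __post_init__(self) -> None:
        if None not in (self.bde, self.h_t, self.bde_cor):
            if abs(self.bde_cor - (self.bde + self.h_t)) > 1e-9:
                raise ValueError(
                    f"{self.label}: bde_cor != bde + h_t "
                    f"({self.bde_cor} vs {self.bde + self.h_t})"
                )
        if None not in (self.e_homo, self.e_lumo, self.hl_gap):
            if abs(self.hl_gap - (self.e_homo - self.e_lumo)) > 1e-9:
                raise ValueError(f"{self.label}: hl_gap != e_homo - e_lumo")


@dataclass
class ChargeDescriptors:
    """PCET charge descriptors of a hydrogen-transfer transition structure."""

    q_h: float
    delta_q_h: float
    dq_o: float
    delta_dq_ts_r: float


def _check_same_frame(*records: SpeciesRecord) -> None:
    level, phase = records[0].level, records[0].phase
    for r in records[1:]:
        if (r.level, r.phase) != (level, phase):
            raise ValueError(
                f"records {records[0].label!r} and {r.label!r} mix "
                f"level/phase ({level},{phase}) vs ({r.level},{r.phase})"
            )


def bde(whole: SpeciesRecord, radical: SpeciesRecord,
        h_atom: SpeciesRecord) -> float:
    """Homolytic bond dissociation enthalpy E_RAD + E_H - E_W (kcal/mol)."""
    _check_same_frame(whole, radical, h_atom)
    return radical.energy + h_atom.energy - whole.energy


def thermal_correction(whole: SpeciesRecord, radical: SpeciesRecord,
                       h_atom: SpeciesRecord) -> float:
    """Thermal correction to the BDE: H_RAD + H_H - H_W (kcal/mol)."""
    for r in (whole, radical, h_atom):
        r.require("h_corr")
    _check_same_frame(whole, radical, h_atom)
    return radical.h_corr + h_atom.h_corr - whole.h_corr


def bde_cor(bde_value: float, h_t: float) -> float:
    """Thermally corrected bond dissociation enthalpy BDE + H_T."""
    return bde_value + h_t


def ip(parent: SpeciesRecord, electron_abstracted: SpeciesRecord) -> float:
    """Adiabatic ionization potential E_CAT - E_W (kcal/mol).

    ``electron_abstracted`` must carry total charge ``parent.charge + 1``;
    for an anionic parent it is therefore the neutral form.
    """
    if electron_abstracted.charge != parent.charge + 1:
        raise ValueError(
            f"electron-abstracted form {electron_abstracted.label!r} must "
            f"carry charge {parent.charge + 1}, got {electron_abstracted.charge}"
        )
    _check_same_frame(parent, electron_abstracted)
    return electron_abstracted.energy - parent.energy


def homo_lumo_gap(species: SpeciesRecord) -> float:
    """HOMO-LUMO gap E_HOMO - E_LUMO (negative by this sign convention)."""
    species.require("e_homo", "e_lumo")
    return species.e_homo - species.e_lumo


def koopmans_delta(ip_value: float, e_homo: float) -> float:
    """Residual of Koopmans' theorem, IP - (-E_HOMO); zero when the theorem
    holds exactly."""
    return ip_value + e_homo


def spin_delocalization(radical: SpeciesRecord,
                        named_atoms: dict[str, int] | None = None,
                        *, convention: str = "population",
                        heavy_only: bool = False) -> dict:
    """Spin-delocalization descriptors of a radical.

    Returns ``{"delta_sd": sd, "sd_by_role": {role: spin}}`` where
    ``delta_sd`` is the standard deviation of the per-atom Mulliken spin
    densities — a dispersion measure over the complete atom set, so the
    population convention is the default (``convention="sample"`` selects
    the n-1 normalization).  ``heavy_only=True`` restricts the dispersion
    to non-hydrogen atoms.
    """
    if radical.atoms is None:
        raise ValueError(f"record {radical.label!r} carries no atoms")
    spins = []
    for i, atom in enumerate(radical.atoms):
        if atom.mulliken_spin is None:
            raise ValueError(
                f"record {radical.label!r}: atom {i} lacks Mulliken spin density"
            )
        if heavy_only and atom.element == "H":
            continue
        spins.append(atom.mulliken_spin)
    spins = np.asarray(spins, dtype=float)
    if convention == "population":
        delta_sd = float(spins.std(ddof=0))
    elif convention == "sample":
        delta_sd = float(spins.std(ddof=1))
    else:
        raise ValueError(f"unknown convention: {convention!r}")
    sd_by_role = {}
    for role, idx in (named_atoms or {}).items():
        if not 0 <= idx < len(radical.atoms):
            raise ValueError(
                f"role {role!r}: atom index {idx} out of range for "
                f"{radical.label!r} ({len(radical.atoms)} atoms)"
            )
        spin = radical.atoms[idx].mulliken_spin
        if spin is None:
            raise ValueError(f"role {role!r}: atom {idx} lacks spin density")
        sd_by_role[role] = spin
    return {"delta_sd": delta_sd, "sd_by_role": sd_by_role}


def _mapped_charge(species: SpeciesRecord, atom_map: dict[str, int],
                   role: str) -> float:
    if role not in atom_map:
        raise ValueError(
            f"{species.label!r}: role {role!r} missing from atom map"
        )
    idx = atom_map[role]
    if species.atoms is None or not 0 <= idx < len(species.atoms):
        raise ValueError(f"{species.label!r}: atom index {idx} out of range")
    q = species.atoms[idx].mulliken_charge
    if q is None:
        raise ValueError(
            f"{species.label!r}: atom {idx} (role {role!r}) lacks a Mulliken charge"
        )
    return q


def _dq_o(species: SpeciesRecord, atom_map: dict[str, int],
          radical: str) -> float:
    # O1: donor oxygen of the antioxidant; O2 (and O3 for peroxy radicals):
    # acceptor oxygens of the radical.
    q_o1 = _mapped_charge(species, atom_map, "O1")
    q_o2 = _mapped_charge(species, atom_map, "O2")
    if radical == "methyl_peroxy":
        q_o3 = _mapped_charge(species, atom_map, "O3")
        return q_o2 + q_o3 - q_o1
    return q_o2 - q_o1


def charge_descriptors(system: ReactionSystem,
                       atom_map: dict[str, dict[str, int]]) -> ChargeDescriptors:
    """PCET charge descriptors from the Mulliken charges of the reagent
    complex and the transition structure.

    ``atom_map`` maps ``"reagents"`` and ``"ts"`` to role->atom-index maps
    with roles ``H``, ``O1``, ``O2`` (plus ``O3`` for a peroxy radical).
    ``dq_o`` is Q(O2)+Q(O3)-Q(O1) for a peroxy radical and Q(O2)-Q(O1) for a
    phenoxyl-type radical; delta fields are TS-minus-reagents differences.
    """
    for key in ("reagents", "ts"):
        if key not in atom_map:
            raise ValueError(f"atom_map lacks entry for {key!r}")
    q_h_ts = _mapped_charge(system.ts, atom_map["ts"], "H")
    q_h_r = _mapped_charge(system.reagents, atom_map["reagents"], "H")
    dq_ts = _dq_o(system.ts, atom_map["ts"], system.radical)
    dq_r = _dq_o(system.reagents, atom_map["reagents"], system.radical)
    return ChargeDescriptors(
        q_h=q_h_ts,
        delta_q_h=q_h_ts - q_h_r,
        dq_o=dq_ts,
        delta_dq_ts_r=dq_ts - dq_r,
    )


@dataclass
class RecipeEntry:
    """How to assemble one descriptor row: which record labels are the
    whole molecule, the H-abstracted radical, and the electron-abstracted
    form of one compound."""

    compound: str
    whole: str
    radical: str | None = None
    cation: str | None = None
    radical_roles: dict[str, int] = field(default_factory=dict)


def _resolve(records: list[SpeciesRecord], label: str | None,
             level: str, phase: str) -> SpeciesRecord | None:
    if label is None:
        return None
    hits = [r for r in records
            if r.label == label and (r.level, r.phase) == (level, phase)]
    if not hits:
        return None
    if len(hits) > 1:
        raise ValueError(
            f"label {label!r} at level {level}/{phase} is ambiguous: "
            f"{len(hits)} records match"
        )
    return hits[0]


def build_descriptor_table(records: list[SpeciesRecord],
                           recipe: list[RecipeEntry | tuple],
                           *, level: str = "II", phase: str = "gas",
                           h_label: str = "H") -> list[DescriptorRow]:
    """Assemble descriptor rows from a record pool.

    Every referenced label must resolve uniquely at the given level/phase.
    Ingredients that are absent leave the corresponding descriptors absent
    (``None``); the free H atom is looked up under ``h_label``.
    """
    rows = []
    for entry in recipe:
        if isinstance(entry, tuple):
            entry = RecipeEntry(*entry)
        whole = _resolve(records, entry.whole, level, phase)
        if whole is None:
            raise ValueError(
                f"recipe entry {entry.compound!r}: whole-molecule label "
                f"{entry.whole!r} not found at level {level}/{phase}"
            )
        radical = _resolve(records, entry.radical, level, phase)
        cation = _resolve(records, entry.cation, level, phase)
        h_atom = _resolve(records, h_label, level, phase)
        row = DescriptorRow(label=entry.compound, level=level, phase=phase,
                            e_homo=whole.e_homo, e_lumo=whole.e_lumo)
        if whole.e_homo is not None and whole.e_lumo is not None:
            row.hl_gap = homo_lumo_gap(whole)
        if radical is not None and h_atom is not None:
            row.bde = bde(whole, radical, h_atom)
            if None not in (whole.h_corr, radical.h_corr, h_atom.h_corr):
                row.h_t = thermal_correction(whole, radical, h_atom)
                row.bde_cor = bde_cor(row.bde, row.h_t)
        if cation is not None:
            row.ip = ip(whole, cation)
            if whole.e_homo is not None:
                row.koopmans_delta = koopmans_delta(row.ip, whole.e_homo)
        if radical is not None and radical.atoms is not None and all(
                a.mulliken_spin is not None for a in radical.atoms):
            sd = spin_delocalization(radical, entry.radical_roles or None)
            row.delta_sd = sd["delta_sd"]
            row.sd_ostar = sd["sd_by_role"].get("O*")
            row.sd_cpara = sd["sd_by_role"].get("C_PARA")
        rows.append(row)
    return rows
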