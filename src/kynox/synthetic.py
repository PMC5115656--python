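"""Seeded generators of species records, reaction systems, tuning curves
and coordinate sets with planted ground truth.

The pipeline consumes only energy *differences* and relative geometry, so
the generators work by inverse construction: the target descriptor values
are chosen first and absolute energies (or a random rigid motion) are then
drawn around them, leaving the planted truth exactly recoverable.  One
explicit seeded generator drives every draw; identical seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import AtomRecord, ReactionSystem, SpeciesRecord

__all__ = [
    "PlantedTruth",
    "generate_species_set",
    "generate_reaction_system",
    "generate_tuning_curve",
    "generate_geometry_fixture",
]

# Thermal enthalpy correction of a free atom at 298.15 K, 5/2 RT, kcal/mol.
H_ATOM_THERMAL = 1.481

# The study-wide thermal correction to the BDE clusters tightly; the
# generator draws it from that distribution (mean, sd in kcal/mol).
BDE_THERMAL_MEAN = -6.645
BDE_THERMAL_SD = 0.260


@dataclass
class PlantedTruth:
    seed: int
    targets: dict = field(default_factory=dict)


def generate_species_set(seed: int,
                         spec: list[tuple[str, float, float, float]],
                         *, level: str = "II", phase: str = "gas"
                         ) -> tuple[list[SpeciesRecord], PlantedTruth]:
    """Generate whole/radical/cation records (plus one free H atom) whose
    energy differences realize the given (label, bde, ip, hl_gap) targets
    exactly.

    The gap target follows the package's sign convention (E_HOMO - E_LUMO,
    negative for closed-shell organics).
    """
    rng = np.random.default_rng(seed)
    e_h = float(rng.uniform(-320.0, -300.0))
    records = [SpeciesRecord(label="H", energy=e_h, multiplicity=2,
                             level=level, phase=phase,
                             h_corr=H_ATOM_THERMAL)]
    truth = PlantedTruth(seed=seed)
    for label, target_bde, target_ip, target_gap in spec:
        e_w = float(rng.uniform(-9e4, -4e4))
        h_w = float(rng.uniform(60.0, 120.0))
        h_t = float(rng.normal(BDE_THERMAL_MEAN, BDE_THERMAL_SD))
        e_homo = float(rng.uniform(-160.0, -100.0))
        whole = SpeciesRecord(
            label=label, energy=e_w, level=level, phase=phase, h_corr=h_w,
            e_homo=e_homo, e_lumo=e_homo - target_gap)
        radical = SpeciesRecord(
            label=f"{label}*", energy=e_w + target_bde - e_h,
            multiplicity=2, level=level, phase=phase,
            h_corr=h_w + h_t - H_ATOM_THERMAL)
        cation = SpeciesRecord(
            label=f"{label}+", energy=e_w + target_ip, charge=1,
            multiplicity=2, level=level, phase=phase)
        records += [whole, radical, cation]
        truth.targets[label] = {"bde": target_bde, "ip": target_ip,
                                "hl_gap": target_gap, "h_t": h_t,
                                "bde_cor": target_bde + h_t}
    return records, truth


def generate_reaction_system(seed: int, target_de_cor: float,
                             target_nu: float, target_de_p_r: float,
                             *, radical: str = "phenoxyl",
                             level: str = "II", phase: str = "gas"
                             ) -> tuple[ReactionSystem, PlantedTruth]:
    """Generate a reagent/TS/product triple realizing the corrected
    barrier, imaginary frequency, and reaction energy targets exactly."""
    if not target_nu > 0:
        raise ValueError("imaginary-frequency target must be positive")
    rng = np.random.default_rng(seed)
    e_r = float(rng.uniform(-9e4, -4e4))
    g_r = float(rng.uniform(60.0, 120.0))
    dg = float(rng.normal(-2.0, 0.6))  # range of hydrogen-transfer pathways
    reagents = SpeciesRecord(label="R", energy=e_r, multiplicity=2,
                             level=level, phase=phase, g_corr=g_r)
    ts = SpeciesRecord(label="TS", energy=e_r + target_de_cor - dg,
                       multiplicity=2, level=level, phase=phase,
                       g_corr=g_r + dg, nu_imag=target_nu)
    products = SpeciesRecord(label="P", energy=e_r + target_de_p_r,
                             multiplicity=2, level=level, phase=phase,
                             g_corr=g_r + float(rng.normal(0.0, 0.5)))
    system = ReactionSystem(name=f"planted-{seed}", radical=radical,
                            reagents=reagents, ts=ts, products=products)
    truth = PlantedTruth(seed=seed, targets={
        "de_ts_r_cor": target_de_cor, "nu_imag": target_nu,
        "de_p_r": target_de_p_r, "dg_ts_r": dg,
        "de_ts_r": target_de_cor - dg,
    })
    return system, truth


def generate_tuning_curve(seed: int, mu_star: float, curvature: float,
                          grid: list[float] | None = None
                          ) -> tuple[list[tuple], PlantedTruth]:
    """Generate per-mu (mu, neutral, cation, anion) triples whose J^2
    curve is ``curvature * (mu - mu_star)^2`` plus seeded smooth noise
    below 1e-6."""
    from .tuning import MU_GRID_DEFAULT
    if grid is None:
        grid = MU_GRID_DEFAULT
    if not grid[0] <= mu_star <= grid[-1]:
        raise ValueError("mu_star must lie inside the grid range")
    rng = np.random.default_rng(seed)
    phase_shift = float(rng.uniform(0, 2 * np.pi))
    records = []
    for mu in grid:
        j2 = curvature * (mu - mu_star) ** 2
        if curvature > 0:  # zero curvature means an exactly flat curve
            j2 += 5e-7 * (1 + np.sin(2 * np.pi * mu + phase_shift))  # <= 1e-6
        residual = float(np.sqrt(j2))
        # put the whole residual in the N-electron term; the N+1 term is
        # Koopmans-compliant.  Orbital energies are derived from the stored
        # (rounded) total energies so the planted J^2 is exact in floats.
        e_neutral = float(rng.uniform(-7e4, -6e4))
        ip_n = float(rng.uniform(150.0, 200.0))
        ip_n1 = float(rng.uniform(10.0, 60.0))
        cation = SpeciesRecord(label="N-1", energy=e_neutral + ip_n,
                               charge=1, multiplicity=2)
        anion = SpeciesRecord(label="N+1", energy=e_neutral - ip_n1,
                              charge=-1, multiplicity=2, e_homo=0.0)
        neutral = SpeciesRecord(
            label="N", energy=e_neutral,
            e_homo=residual - (cation.energy - e_neutral))
        anion.e_homo = -(e_neutral - anion.energy)
        records.append((mu, neutral, cation, anion))
    truth = PlantedTruth(seed=seed, targets={"mu_star": mu_star,
                                             "curvature": curvature})
    return records, truth


def _rigid_motion(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    # random rotation via QR of a Gaussian matrix, determinant forced to +1
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10.0, 10.0, size=3)
    return coords @ q.T + t


def generate_geometry_fixture(seed: int, targets: dict
                              ) -> tuple[list[AtomRecord], dict[str, int],
                                         PlantedTruth]:
    """Construct a coordinate set whose O...O length, O-H-O angle, ring
    plane angle, and C-O...O-C torsion equal the given targets, then apply
    a seeded random rigid motion.

    ``targets`` keys: ``oho_length`` (A), ``oho_angle``, ``plane_angle``,
    ``torsion`` (degrees).  Returns (atoms, role map, planted truth).
    """
    L = float(targets["oho_length"])
    theta = np.radians(float(targets["oho_angle"]))
    alpha = np.radians(float(targets["plane_angle"]))
    tau = np.radians(float(targets["torsion"]))
    if L <= 0:
        raise ValueError("oho_length must be positive")
    if not 0 < theta <= np.pi:
        raise ValueError("oho_angle must be in (0, 180]")
    if not 0 <= alpha <= np.pi / 2:
        raise ValueError("plane_angle must be in [0, 90]")

    # H at the origin; O1 and O2 symmetric about the bisector, separated by
    # L with the O1-H-O2 angle theta (law of cosines for the arm length).
    arm = L / np.sqrt(2.0 * (1.0 - np.cos(theta))) if theta < np.pi else L / 2
    half = theta / 2
    o1 = np.array([arm * np.sin(half), arm * np.cos(half), 0.0])
    o2 = np.array([-arm * np.sin(half), arm * np.cos(half), 0.0])
    h = np.zeros(3)

    # C1 bonded to O1, placed out of the O1-O2 axis so no triple is collinear
    axis = (o2 - o1) / np.linalg.norm(o2 - o1)
    ref = np.array([0.0, 0.0, 1.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    c1 = o1 - 1.36 * (0.8 * axis - 0.6 * perp)

    # C2 via torsion construction about the O1->O2 axis: standard internal
    # coordinate placement with bond 1.36 A and O1-O2-C2 angle 115 deg
    ang = np.radians(115.0)
    b1 = o1 - c1
    b2 = o2 - o1
    b2n = b2 / np.linalg.norm(b2)
    n_ref = np.cross(b1, b2)
    n_ref /= np.linalg.norm(n_ref)
    m_ref = np.cross(n_ref, b2n)
    d = 1.36 * (-np.cos(ang) * b2n
                + np.sin(ang) * (np.cos(tau) * m_ref - np.sin(tau) * n_ref))
    c2 = o2 + d

    # Ring plane 1: triangle through C1 in the plane spanned by b2n/perp1
    n1 = np.cross(b2n, c1 - o1)
    n1 /= np.linalg.norm(n1)
    u1 = np.cross(n1, b2n)
    c3a = c1 + 1.4 * b2n + 1.2 * u1
    c5a = c1 - 1.4 * b2n + 1.2 * u1
    # Ring plane 2: through C2, normal rotated from n1 by alpha about b2n
    n2 = np.cos(alpha) * n1 + np.sin(alpha) * np.cross(b2n, n1)
    n2 /= np.linalg.norm(n2)
    v1 = np.cross(n2, b2n)
    v1 /= np.linalg.norm(v1)
    c3b = c2 + 1.4 * b2n + 1.2 * v1
    c5b = c2 - 1.4 * b2n + 1.2 * v1

    coords = np.vstack([o1, h, o2, c1, c2, c3a, c5a, c3b, c5b])
    rng = np.random.default_rng(seed)
    coords = _rigid_motion(rng, coords)
    elements = ["O", "H", "O", "C", "C", "C", "C", "C", "C"]
    atoms = [AtomRecord(el, *xyz) for el, xyz in zip(elements, coords)]
    roles = {"O1": 0, "H": 1, "O2": 2, "C1": 3, "C2": 4,
             "C1A": 3, "C3A": 5, "C5A": 6, "C1B": 4, "C3B": 7, "C5B": 8}
    truth = PlantedTruth(seed=seed, targets=dict(targets))
    return atoms, roles, truth
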