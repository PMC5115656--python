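"""Geometric descriptors of antioxidant-radical complexes.

Distances, bond angles, the angle between two ring planes, the C-O...O-C
dihedral reported on [0, 360), and the Kabsch-superposed RMSD used to
compare optimized endpoint structures with reaction-path endpoints.  All
descriptors operate on Cartesian coordinates in Angstrom and are invariant
under rigid motions of the full coordinate set.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .species import AtomRecord

__all__ = [
    "GeometryReport",
    "distance",
    "bond_angle",
    "plane_angle",
    "torsion",
    "kabsch_rmsd",
    "geometry_report",
]


def _pos(a: AtomRecord | np.ndarray) -> np.ndarray:
    if isinstance(a, AtomRecord):
        return np.array(a.position, dtype=float)
    return np.asarray(a, dtype=float)


def distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(_pos(a) - _pos(b)))


def bond_angle(a: AtomRecord, vertex: AtomRecord, b: AtomRecord) -> float:
    """Angle at ``vertex`` in degrees, in [0, 180]."""
    u = _pos(a) - _pos(vertex)
    v = _pos(b) - _pos(vertex)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("bond angle undefined for a zero-length arm")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _normal(p1, p2, p3) -> np.ndarray:
    n = np.cross(_pos(p2) - _pos(p1), _pos(p3) - _pos(p1))
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("collinear atoms do not define a plane")
    return n / norm


def plane_angle(plane1: tuple, plane2: tuple) -> float:
    """Angle between the planes of two atom triples, folded to [0, 90] deg."""
    n1 = _normal(*plane1)
    n2 = _normal(*plane2)
    cos = np.clip(abs(np.dot(n1, n2)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def torsion(c1: AtomRecord, o1: AtomRecord, o2: AtomRecord,
            c2: AtomRecord) -> float:
    """Right-handed dihedral of the four atoms, mapped to [0, 360) degrees."""
    p = [_pos(a) for a in (c1, o1, o2, c2)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    if np.linalg.norm(b2) < 1e-12:
        raise ValueError("central atoms coincide: dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear atom triple: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(angle % 360.0)


def kabsch_rmsd(structure1: list[AtomRecord], structure2: list[AtomRecord],
                superpose: bool = True) -> float:
    """RMSD between two conformations of the same structure, in Angstrom.

    Atom order defines the correspondence; element sequences must match.
    By default the structures are first superposed by the optimal rigid
    motion (rotation + translation, no reflection); ``superpose=False``
    gives the raw coordinate RMSD.
    """
    if len(structure1) != len(structure2):
        raise ValueError(
            f"atom counts differ: {len(structure1)} vs {len(structure2)}"
        )
    for i, (a, b) in enumerate(zip(structure1, structure2)):
        if a.element != b.element:
            raise ValueError(
                f"element mismatch at atom {i}: {a.element} vs {b.element}"
            )
    x = np.array([a.position for a in structure1], dtype=float)
    y = np.array([a.position for a in structure2], dtype=float)
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem restricted to
    # proper rotations (Kabsch); residuals are evaluated explicitly rather
    # than via the returned rssd, which loses precision to cancellation
    rot, _ = Rotation.align_vectors(xc, yc)
    diff = xc - rot.apply(yc)
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


class GeometryReport(dict):
    """Descriptor bundle of one complex: O...O length through the
    transferred H, O-H-O angle, ring-plane angle, and C-O...O-C torsion."""


def geometry_report(atoms: list[AtomRecord], roles: dict[str, int]) -> GeometryReport:
    """Evaluate the four standard descriptors from a role->atom-index map.

    Required roles: ``O1``, ``H``, ``O2``; optionally ``C1A, C3A, C5A`` and
    ``C1B, C3B, C5B`` (ring triples) for the plane angle, and ``C1``, ``C2``
    for the C1-O1-O2-C2 torsion.  Absent roles leave the descriptor out.
    """
    def at(role):
        return atoms[roles[role]]

    for role in ("O1", "H", "O2"):
        if role not in roles:
            raise ValueError(f"required role {role!r} missing")
    report = GeometryReport(
        oho_length=distance(at("O1"), at("O2")),
        oho_angle=bond_angle(at("O1"), at("H"), at("O2")),
    )
    if all(r in roles for r in ("C1A", "C3A", "C5A", "C1B", "C3B", "C5B")):
        report["plane_angle"] = plane_angle(
            (at("C1A"), at("C3A"), at("C5A")),
            (at("C1B"), at("C3B"), at("C5B")),
        )
    if all(r in roles for r in ("C1", "C2")):
        report["torsion"] = torsion(at("C1"), at("O1"), at("O2"), at("C2"))
    return report
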