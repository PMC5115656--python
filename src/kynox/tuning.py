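"""Range-separation parameter tuning for long-range-corrected functionals.

The optimal range-separation parameter mu of an LC functional is the
minimizer of the Koopmans residual

    J^2(mu) = [E_HOMO^mu(N) + IP^mu(N)]^2 + [E_HOMO^mu(N+1) + IP^mu(N+1)]^2

where IP^mu(N) = E^mu(cation) - E^mu(neutral) and IP^mu(N+1) =
E^mu(neutral) - E^mu(anion).  J^2 is sampled on a mu grid (conventionally
0.05 ... 0.90 in 0.05 steps), missing points are filled by cubic spline
interpolation, and the minimum is located on the spline.  Splines use the
not-a-knot boundary condition, the standard interpolation default, which
reproduces cubic (hence parabolic) sample curves exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .species import SpeciesRecord

__all__ = [
    "TuningPoint",
    "TuningCurve",
    "j_squared",
    "build_curve",
    "interpolate_missing",
    "find_optimal_mu",
]

MU_GRID_DEFAULT = [round(0.05 * k, 2) for k in range(1, 19)]  # 0.05 ... 0.90


def j_squared(e_homo_n: float, ip_n: float,
              e_homo_n1: float, ip_n1: float) -> float:
    """Sum of the two squared Koopmans residuals (kcal^2/mol^2)."""
    return (e_homo_n + ip_n) ** 2 + (e_homo_n1 + ip_n1) ** 2


@dataclass
class TuningPoint:
    """J^2 and its ingredients at one mu."""

    mu: float
    e_homo_n: float
    ip_n: float
    e_homo_n1: float
    ip_n1: float
    interpolated: bool = False

    @property
    def j2(self) -> float:
        return j_squared(self.e_homo_n, self.ip_n, self.e_homo_n1, self.ip_n1)


@dataclass
class TuningCurve:
    """J^2(mu) samples ordered by strictly increasing mu."""

    points: list[TuningPoint]
    mu_opt: float | None = None
    interpolated_mus: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        mus = [p.mu for p in self.points]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise ValueError("tuning-curve mus must be strictly increasing")

    @property
    def mus(self) -> np.ndarray:
        return np.array([p.mu for p in self.points])

    @property
    def j2_values(self) -> np.ndarray:
        return np.array([p.j2 for p in self.points])

    def spline(self) -> CubicSpline:
        if len(self.points) < 4:
            raise ValueError(
                f"spline work needs >= 4 curve points, got {len(self.points)}"
            )
        return CubicSpline(self.mus, self.j2_values, bc_type="not-a-knot")


def build_curve(per_mu_records: list[tuple[float, SpeciesRecord,
                                           SpeciesRecord, SpeciesRecord]]
                ) -> TuningCurve:
    """Build a J^2(mu) curve from per-mu (neutral, cation, anion) triples.

    IP(N) = E(cation) - E(neutral); IP(N+1) = E(neutral) - E(anion);
    E_HOMO(N) from the neutral and E_HOMO(N+1) from the anion.
    """
    if not per_mu_records:
        raise ValueError("empty input: a tuning curve needs >= 4 points")
    points = []
    for mu, neutral, cation, anion in per_mu_records:
        q = neutral.charge
        if (cation.charge, anion.charge) != (q + 1, q - 1):
            raise ValueError(
                f"mu={mu}: expected charges ({q}+1, {q}-1) for cation/anion, "
                f"got ({cation.charge}, {anion.charge})"
            )
        neutral.require("e_homo")
        anion.require("e_homo")
        points.append(TuningPoint(
            mu=mu,
            e_homo_n=neutral.e_homo,
            ip_n=cation.energy - neutral.energy,
            e_homo_n1=anion.e_homo,
            ip_n1=neutral.energy - anion.energy,
        ))
    points.sort(key=lambda p: p.mu)
    return TuningCurve(points=points)


def interpolate_missing(curve: TuningCurve,
                        missing_mus: list[float]) -> TuningCurve:
    """Fill J^2 at interior mus by cubic spline interpolation.

    Interpolated points are flagged and never alter known points.  The two
    Koopmans residuals cannot be disentangled from J^2 alone, so the spline
    value is stored in the first residual with the second zero.
    """
    spline = curve.spline()
    lo, hi = curve.mus[0], curve.mus[-1]
    new_points = list(curve.points)
    added = []
    for mu in missing_mus:
        if not lo <= mu <= hi:
            raise ValueError(
                f"mu={mu} outside the known range [{lo}, {hi}]: refusing to "
                "extrapolate"
            )
        if any(abs(p.mu - mu) < 1e-12 for p in new_points):
            continue
        j2 = float(spline(mu))
        new_points.append(TuningPoint(mu=mu, e_homo_n=np.sqrt(max(j2, 0.0)),
                                      ip_n=0.0, e_homo_n1=0.0, ip_n1=0.0,
                                      interpolated=True))
        added.append(mu)
    new_points.sort(key=lambda p: p.mu)
    return TuningCurve(points=new_points, mu_opt=curve.mu_opt,
                       interpolated_mus=sorted(curve.interpolated_mus + added))


def find_optimal_mu(curve: TuningCurve, grid_step: float = 1e-4) -> float:
    """Global minimizer of the cubic-spline interpolant of J^2(mu).

    Dense evaluation at ``grid_step`` resolution brackets the minimum; a
    bounded scalar minimization refines it to ~1e-6.  Ties break toward
    smaller mu.
    """
    spline = curve.spline()
    lo, hi = float(curve.mus[0]), float(curve.mus[-1])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    values = spline(grid)
    best = int(np.argmin(values))  # argmin returns the first == smallest mu
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    if a == b:
        return float(grid[best])
    res = minimize_scalar(spline, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-6})
    mu_star = float(res.x)
    # keep the grid point unless refinement strictly improves: this both
    # protects boundary minima and breaks flat ties toward smaller mu
    if spline(grid[best]) <= res.fun:
        mu_star = float(grid[best])
    return min(max(mu_star, lo), hi)
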