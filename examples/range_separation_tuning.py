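"""Tuning the range-separation parameter of an LC functional.

Generates per-mu neutral/cation/anion energy triples whose Koopmans
residual J^2(mu) has a planted minimum, drops two grid points (mimicking
SCF convergence failures), restores them by spline interpolation, and
locates the optimal mu on the spline.
"""

from kynox import (build_curve, find_optimal_mu, generate_tuning_curve,
                   interpolate_missing)
from kynox.tuning import MU_GRID_DEFAULT

grid = [m for m in MU_GRID_DEFAULT if m not in (0.10, 0.15)]
records, truth = generate_tuning_curve(seed=7, mu_star=0.21, curvature=4.0,
                                       grid=grid)
curve = build_curve(records)
curve = interpolate_missing(curve, [0.10, 0.15])
mu_opt = find_optimal_mu(curve)

print("mu      J^2 (kcal^2/mol^2)")
for p in curve.points[:6]:
    tag = " (interpolated)" if p.interpolated else ""
    print(f"{p.mu:.2f}   {p.j2:10.5f}{tag}")
print(f"...\noptimal mu = {mu_opt:.4f} (planted {truth.targets['mu_star']})")
print("J^2 measures how far -E_HOMO sits from the ionization potential for "
      "the N and N+1 electron systems; its minimizer is the mu at which the "
      "functional best satisfies Koopmans' theorem, here ~0.21 as planted — "
      "the aminophenol antioxidants tune to mu ~ 0.20.")
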