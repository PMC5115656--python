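"""Statistical layer: Pearson correlations, mean +/- sd summaries, rank
orderings with tie tolerance, and the printed-table consistency checker."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinetics import rate_constant

__all__ = [
    "CorrelationResult",
    "pearson_r",
    "mean_sd",
    "rank_order",
    "reproduce_tables",
]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def pearson_r(x, y, excluded: list[str] | None = None) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value from the
    t-transform with n-2 degrees of freedom.

    ``excluded`` is a bookkeeping list of labels dropped upstream (e.g. a
    compound excluded from a validation set); it is carried through to the
    result, not acted on.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need >= 3 points for a correlation with a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=int(x.size),
                             p_two_sided=float(res.pvalue),
                             excluded=list(excluded or []))


def mean_sd(values, convention: str = "sample") -> dict:
    """Arithmetic mean and standard deviation (sample n-1 by default,
    ``convention="population"`` for n).  For a single value the sample sd
    is absent (None)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    mean = float(values.mean())
    if convention == "sample":
        sd = None if values.size == 1 else float(values.std(ddof=1))
    elif convention == "population":
        sd = float(values.std(ddof=0))
    else:
        raise ValueError(f"unknown convention: {convention!r}")
    return {"mean": mean, "sd": sd}


def rank_order(values: dict[str, float], direction: str = "ascending",
               tie_tol: float = 0.03) -> list[list[str]]:
    """Sort labels by value; values within ``tie_tol`` relative of each
    other merge into tied groups (the "~" of comparative rankings).

    Returns a list of groups, each a list of labels, ordered in
    ``direction``; singleton groups are single-label lists.
    """
    if direction not in {"ascending", "descending"}:
        raise ValueError(f"unknown direction: {direction!r}")
    for label, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite value for {label!r}")
    items = sorted(values.items(), key=lambda kv: kv[1],
                   reverse=(direction == "descending"))
    groups: list[list[str]] = []
    last_value: float | None = None
    for label, v in items:
        denom = max(abs(v), abs(last_value)) if last_value is not None else 1.0
        if (last_value is not None and denom > 0
                and abs(v - last_value) / denom <= tie_tol):
            groups[-1].append(label)
        else:
            groups.append([label])
        last_value = v
    return groups


def reproduce_tables(fixture, rate_rtol: float = 0.005,
                     sum_tol: float = 1.5e-3) -> dict:
    """Recompute every derivable cell of the printed tables and report
    printed-vs-recomputed discrepancies.

    * HOMO-LUMO gaps of the descriptor tables are re-derived from the
      printed orbital energies;
    * corrected barriers are re-summed from the printed electronic barrier
      and thermal free-energy correction;
    * the TS-to-product drop is checked against dE_TS-R - dE_P-R;
    * rate constants are recomputed from the printed corrected barrier and
      imaginary frequency (level II frequencies are used for the refined
      columns, per the study's hybrid recipe).

    Discrepancies are reported, never raised.  Returns
    ``{"tables": {name: DataFrame}, "discrepancies": [dict, ...]}``.
    """
    from .tables import StudyTables  # local import to avoid a cycle

    if not isinstance(fixture, StudyTables):
        raise TypeError("fixture must be a StudyTables instance")
    discrepancies: list[dict] = []

    def flag(table, row, column, printed, recomputed, tol):
        if abs(recomputed - printed) > tol:
            discrepancies.append({
                "table": table, "row": row, "column": column,
                "printed": printed, "recomputed": recomputed,
            })

    # ---- Table 1: H-L gaps per level ------------------------------------
    t1_rows = []
    for label, levels in fixture.table1.items():
        out = {"compound": label}
        for level, cells in levels.items():
            if {"E_HOMO", "E_LUMO", "H-L gap"} <= cells.keys():
                gap = cells["E_HOMO"] - cells["E_LUMO"]
                out[f"hl_gap_{level}"] = gap
                flag("table1", label, f"H-L gap ({level})",
                     cells["H-L gap"], gap, sum_tol)
            if {"BDE", "BDE_COR"} <= cells.keys():
                out[f"h_t_{level}"] = cells["BDE_COR"] - cells["BDE"]
        t1_rows.append(out)

    # ---- Table 2: H-L gaps per phase ------------------------------------
    t2_rows = []
    for label, phases in fixture.table2.items():
        out = {"compound": label}
        for phase, cells in phases.items():
            if {"E_HOMO", "E_LUMO", "H-L gap"} <= cells.keys():
                gap = cells["E_HOMO"] - cells["E_LUMO"]
                out[f"hl_gap_{phase}"] = gap
                flag("table2", label, f"H-L gap ({phase})",
                     cells["H-L gap"], gap, sum_tol)
        t2_rows.append(out)

    # ---- Table 3: barrier sums, TS-P identity, rates --------------------
    t3_rows = []
    for radical, compounds in fixture.table3.items():
        for label, blocks in compounds.items():
            lvl2 = blocks.get("II_gas")
            if lvl2 is None:
                continue
            out = {"radical": radical, "compound": label}
            cor = lvl2["dE_TS-R"] + lvl2["dG_TS-R"]
            out["de_cor_resummed"] = cor
            flag("table3", f"{radical}/{label}", "dE_TS-R/COR (II gas)",
                 lvl2["dE_TS-R/COR"], cor, sum_tol)
            ts_p = lvl2["dE_TS-R"] - lvl2["dE_P-R"]
            flag("table3", f"{radical}/{label}", "dE_TS-P (II gas)",
                 lvl2["dE_TS-P"], ts_p, sum_tol)
            k = rate_constant(lvl2["dE_TS-R/COR"], lvl2["nu_i"]).rate
            out["k_recomputed"] = k
            if abs(k - lvl2["k"]) > rate_rtol * lvl2["k"]:
                discrepancies.append({
                    "table": "table3", "row": f"{radical}/{label}",
                    "column": "k(T) (II gas)", "printed": lvl2["k"],
                    "recomputed": k,
                })
            # refined-level columns reuse the level II frequency
            for key in ("IV_gas", "IV_water"):
                blk = blocks.get(key)
                if blk and "k" in blk and "dE_TS-R/COR" in blk:
                    k4 = rate_constant(blk["dE_TS-R/COR"], lvl2["nu_i"]).rate
                    if abs(k4 - blk["k"]) > rate_rtol * blk["k"]:
                        discrepancies.append({
                            "table": "table3", "row": f"{radical}/{label}",
                            "column": f"k(T) ({key})", "printed": blk["k"],
                            "recomputed": k4,
                        })
            t3_rows.append(out)

    tables = {
        "table1": pd.DataFrame(t1_rows),
        "table2": pd.DataFrame(t2_rows),
        "table3": pd.DataFrame(t3_rows),
        "table6": pd.DataFrame(
            [{"radical": k, **v} for k, v in fixture.table6.items()]
        ),
    }
    return {"tables": tables, "discrepancies": discrepancies}
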