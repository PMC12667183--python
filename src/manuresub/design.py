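"""Fertilizer-substitution treatment design.

The trial compares a conventional all-chemical nitrogen regime (CK) with
four regimes in which 25/50/75/100 % of the nitrogen dose is supplied as
dairy manure instead.  Chemical P and K stay fixed; manure carries a small
additional amount of P and K proportional to its N content.  The five
canonical treatment rows ship as a packaged lookup table (their printed
values carry rounding that exact arithmetic would not reproduce); plans for
intermediate substitution rates are interpolated linearly in manure N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "NPK",
    "FertilizerPlan",
    "CANONICAL_RATES",
    "TOTAL_N_NOMINAL",
    "TOTAL_N_PRINTED",
    "canonical_table",
    "plan_for_rate",
    "validate_plan",
]

#: Nominal control N dose, kg ha^-1 yr^-1 (the protocol figure).
TOTAL_N_NOMINAL = 187.5
#: N dose as printed in the treatment table (rounded to 3 significant digits).
#: Both are reported because the source documents disagree at this rounding.
TOTAL_N_PRINTED = 187.0

CHEM_P = 42.6
CHEM_K = 62.2
# Manure P and K per unit manure N, from the 100 % substitution row.
MANURE_P_PER_N = 1.66 / 187.0
MANURE_K_PER_N = 5.81 / 187.0

CANONICAL_RATES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: total.X must equal chemical.X + manure.X within this printed-rounding slack
ROUNDING_TOL = 0.2


@dataclass(frozen=True)
class NPK:
    """Nutrient rates in kg ha^-1 yr^-1."""

    N: float
    P: float
    K: float

    def __add__(self, other: "NPK") -> "NPK":
        return NPK(self.N + other.N, self.P + other.P, self.K + other.K)


@dataclass(frozen=True)
class FertilizerPlan:
    """Per-treatment chemical and manure N-P-K application rates."""

    substitution_rate: float
    chemical: NPK
    manure: NPK
    total: NPK
    label: str = field(default="", compare=False)

    def to_dict(self) -> dict:
        return {
            "substitution_rate": self.substitution_rate,
            "label": self.label,
            **{f"chem_{x}": getattr(self.chemical, x) for x in "NPK"},
            **{f"manure_{x}": getattr(self.manure, x) for x in "NPK"},
            **{f"total_{x}": getattr(self.total, x) for x in "NPK"},
        }


def canonical_table() -> pd.DataFrame:
    """The five canonical treatment rows as a DataFrame (packaged data)."""
    with resources.files("manuresub.data").joinpath("fertilizer_table.csv").open() as fh:
        return pd.read_csv(fh)


def _plan_from_row(row: pd.Series) -> FertilizerPlan:
    return FertilizerPlan(
        substitution_rate=float(row["substitution_rate"]),
        chemical=NPK(row["chem_N"], row["chem_P"], row["chem_K"]),
        manure=NPK(row["manure_N"], row["manure_P"], row["manure_K"]),
        total=NPK(row["total_N"], row["total_P"], row["total_K"]),
        label=str(row["treatment"]),
    )


def plan_for_rate(rate: float) -> FertilizerPlan:
    """Fertilizer plan for a manure-N substitution fraction in [0, 1].

    The five canonical rates return the printed treatment-table row
    verbatim.  Other rates split the nominal 187.5 kg N ha^-1 yr^-1 dose
    linearly between chemical and manure N, with manure P and K scaled by
    the manure-N fraction of the full-substitution row.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0, 1], got {rate}")
    table = canonical_table()
    for _, row in table.iterrows():
        if abs(row["substitution_rate"] - rate) < 1e-12:
            return _plan_from_row(row)
    manure_n = rate * TOTAL_N_NOMINAL
    chemical = NPK(TOTAL_N_NOMINAL - manure_n, CHEM_P, CHEM_K)
    manure = NPK(manure_n, manure_n * MANURE_P_PER_N, manure_n * MANURE_K_PER_N)
    return FertilizerPlan(
        substitution_rate=rate,
        chemical=chemical,
        manure=manure,
        total=chemical + manure,
        label=f"{rate:.0%}",
    )


def validate_plan(plan: FertilizerPlan, tol: float = ROUNDING_TOL) -> list[str]:
    """Check plan invariants; return a list of human-readable violations.

    An empty list means the plan is consistent: all rates non-negative and
    each total equal to chemical + manure within ``tol`` (printed rounding).
    """
    violations: list[str] = []
    for part in ("chemical", "manure", "total"):
        npk = getattr(plan, part)
        for x in "NPK":
            value = getattr(npk, x)
            if value < 0:
                violations.append(f"{part}.{x} is negative ({value})")
    for x in "NPK":
        total = getattr(plan.total, x)
        parts = getattr(plan.chemical, x) + getattr(plan.manure, x)
        if abs(total - parts) > tol:
            violations.append(
                f"total.{x} = {total} differs from chemical+manure = {parts}"
                f" by {abs(total - parts):.3g}"
            )
    return violations
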