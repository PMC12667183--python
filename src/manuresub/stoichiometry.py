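"""Ecoenzymatic stoichiometry vectors from hydrolase activity panels.

Six hydrolases proxy microbial nutrient acquisition: BG, CB and XYL target
carbon, NAG and LAP nitrogen, and ALP (acid phosphatase) phosphorus.  Two
activity ratios summarise relative investment:

    x = C / (C + ALP)          with C = BG + CB + XYL   (C vs P)
    y = C / (C + LAP + NAG)                              (C vs N)

The vector length sqrt(x^2 + y^2) grows with relative carbon demand; the
vector angle is the planar angle of the point (x, y) from the positive
x-axis in degrees (spreadsheet two-argument arctangent convention with the
C-vs-P ratio as the x-coordinate).  Under that convention an angle above
45 deg indicates phosphorus demand, below 45 deg nitrogen demand; the
interpretation is the conventional reading, not asserted here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EnzymePanel",
    "StoichVector",
    "ENZYME_NAMES",
    "ENZYME_ALIASES",
    "stoich_vector",
    "vector_length",
    "vector_angle",
    "panel_from_dataset",
]

#: Canonical enzyme names; aliases map synonymous field notations onto them.
ENZYME_NAMES = ("BG", "CB", "XYL", "NAG", "LAP", "ALP")
ENZYME_ALIASES = {"ACP": "ALP", "CE": "CB", "BX": "XYL"}

C_ENZYMES = ("BG", "CB", "XYL")
N_ENZYMES = ("NAG", "LAP")


@dataclass(frozen=True)
class EnzymePanel:
    """Activities of the six hydrolases for one sample, nmol g^-1 h^-1."""

    BG: float
    CB: float
    XYL: float
    NAG: float
    LAP: float
    ALP: float

    def __post_init__(self):
        for name in ENZYME_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"enzyme activity {name} must be >= 0")

    @classmethod
    def from_mapping(cls, values: dict) -> "EnzymePanel":
        """Build a panel from a name->activity mapping, resolving aliases."""
        canon = {}
        for key, val in values.items():
            name = ENZYME_ALIASES.get(key, key)
            if name in ENZYME_NAMES:
                canon[name] = float(val)
        missing = [n for n in ENZYME_NAMES if n not in canon]
        if missing:
            raise KeyError(f"missing enzyme activities: {missing}")
        return cls(**canon)


@dataclass(frozen=True)
class StoichVector:
    """C-vs-P and C-vs-N acquisition ratios with length and angle."""

    x: float  # C/(C+ALP), dimensionless in (0, 1]
    y: float  # C/(C+LAP+NAG), dimensionless in (0, 1]
    length: float  # sqrt(x^2 + y^2), in (0, sqrt(2)]
    angle: float  # degrees in (0, 90)
    length_squared: float  # diagnostic: x^2 + y^2 without the square root


def stoich_vector(panel: EnzymePanel) -> StoichVector:
    """Compute the stoichiometry vector for one enzyme panel.

    Raises ``ValueError`` when the C-acquisition sum BG+CB+XYL is zero,
    which leaves both ratios undefined.
    """
    c = sum(getattr(panel, e) for e in C_ENZYMES)
    if c <= 0:
        raise ValueError("C-acquisition sum BG+CB+XYL must be > 0")
    x = c / (c + panel.ALP)
    y = c / (c + panel.LAP + panel.NAG)
    sq = x * x + y * y
    # atan2 with the C-vs-P ratio as the x-coordinate: more phosphatase
    # pulls x down and the angle above 45 degrees.
    angle = math.degrees(math.atan2(y, x))
    return StoichVector(x=x, y=y, length=math.sqrt(sq), angle=angle, length_squared=sq)


def vector_length(panel: EnzymePanel) -> float:
    """Stoichiometry vector length sqrt(x^2 + y^2), dimensionless."""
    return stoich_vector(panel).length


def vector_angle(panel: EnzymePanel) -> float:
    """Stoichiometry vector angle in degrees, in (0, 90)."""
    return stoich_vector(panel).angle


def panel_from_dataset(dataset) -> pd.DataFrame:
    """One stoichiometry vector per (treatment, replicate, depth) sample.

    ``dataset`` is a :class:`~manuresub.synthetic.TrialDataset` or any
    object with a long-format ``records`` table.  Samples missing any of
    the six enzymes are skipped with a warning.

    Returns a DataFrame with columns treatment, replicate, depth, x, y,
    length, angle.
    """
    wide = dataset.to_wide()
    rows = []
    for key, row in wide.iterrows():
        values = {}
        for name in ENZYME_NAMES:
            if name in row.index and pd.notna(row[name]):
                values[name] = row[name]
        if not values:
            continue  # sample carries no enzyme data at all (e.g. plot level)
        if len(values) < len(ENZYME_NAMES):
            missing = sorted(set(ENZYME_NAMES) - set(values))
            warnings.warn(
                f"sample {key}: missing enzyme(s) {missing}; skipped", stacklevel=2
            )
            continue
        vec = stoich_vector(EnzymePanel(**values))
        rows.append(
            {
                "treatment": key[0],
                "replicate": key[1],
                "depth": key[2],
                "x": vec.x,
                "y": vec.y,
                "length": vec.length,
                "angle": vec.angle,
            }
        )
    return pd.DataFrame(rows)
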