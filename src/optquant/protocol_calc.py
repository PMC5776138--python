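"""Bench calculators for the EdU staining protocol.

Scales the 3 mL click-chemistry staining-solution recipe (PBS, ascorbic
acid, Tris, Alexa Fluor azide, copper sulfate) to arbitrary batch volumes,
and computes stock molarity from powder mass, solvent volume and molar
mass (EdU: 252.23 g/mol, so 50 mg in 20 mL is ~10 mM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

__all__ = [
    "EDU_MOLAR_MASS_G_PER_MOL",
    "REFERENCE_RECIPE_UL",
    "Recipe",
    "scale_recipe",
    "stock_molarity",
]

EDU_MOLAR_MASS_G_PER_MOL = 252.23

#: Reference composition for 3 mL of EdU staining solution, in uL.
REFERENCE_RECIPE_UL: Tuple[Tuple[str, float], ...] = (
    ("1X-PBS (pH 7.4)", 2241.0),
    ("0.5 M L-ascorbic acid", 600.0),
    ("2 M Tris buffer (pH 8.5)", 150.0),
    ("100 mM Alexa Fluor azide", 6.0),
    ("1 M copper(II) sulfate", 3.0),
)
_REFERENCE_TOTAL_UL = 3000.0


@dataclass(frozen=True)
class Recipe:
    """A staining-solution recipe: ordered components plus total, in uL."""

    components: Tuple[Tuple[str, float], ...]
    total_ul: float

    def volume(self, name: str) -> float:
        for comp, vol in self.components:
            if comp == name:
                return vol
        raise KeyError(f"no component named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows: List[dict] = [
            {"reagent": name, "volume_ul": vol} for name, vol in self.components
        ]
        rows.append({"reagent": "Total volume", "volume_ul": self.total_ul})
        return pd.DataFrame(rows)


def scale_recipe(total_volume_ml: float) -> Recipe:
    """Scale the 3 mL reference recipe proportionally.

    Component volumes are reported to 0.1 uL (pipettable precision), so
    after rounding the components sum to the total within 0.5 uL.
    """
    if not total_volume_ml > 0:
        raise ValueError(f"total volume must be > 0, got {total_volume_ml}")
    factor = total_volume_ml * 1000.0 / _REFERENCE_TOTAL_UL
    components = tuple(
        (name, round(vol * factor, 1)) for name, vol in REFERENCE_RECIPE_UL
    )
    return Recipe(components=components, total_ul=total_volume_ml * 1000.0)


def stock_molarity(
    mass_mg: float,
    volume_ml: float,
    molar_mass_g_per_mol: float = EDU_MOLAR_MASS_G_PER_MOL,
) -> float:
    """Stock concentration in mM from powder mass and solvent volume.

    mM = mass_mg / (molar_mass_g_per_mol x volume_ml) x 1000.
    """
    if mass_mg <= 0 or volume_ml <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("mass, volume and molar mass must all be > 0")
    return mass_mg / (molar_mass_g_per_mol * volume_ml) * 1000.0
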