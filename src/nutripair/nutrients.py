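"""Nutrient vocabulary shared across the package.

Eight nutrients are tracked per food item: total energy plus the three
macronutrients, sugar, fiber, and the two micronutrients (cholesterol,
sodium) that consumer-app databases report least reliably.  Units are
fixed per nutrient: kcal for energy, grams for macronutrients/sugar/fiber,
milligrams for cholesterol and sodium.
"""

from __future__ import annotations

from enum import Enum


class Nutrient(str, Enum):
    ENERGY = "energy"
    CARBOHYDRATE = "carbohydrate"
    FAT = "fat"
    PROTEIN = "protein"
    FIBER = "fiber"
    SUGAR = "sugar"
    CHOLESTEROL = "cholesterol"
    SODIUM = "sodium"

    def __str__(self) -> str:  # plain value in messages and file headers
        return self.value


UNITS: dict[Nutrient, str] = {
    Nutrient.ENERGY: "kcal",
    Nutrient.CARBOHYDRATE: "g",
    Nutrient.FAT: "g",
    Nutrient.PROTEIN: "g",
    Nutrient.FIBER: "g",
    Nutrient.SUGAR: "g",
    Nutrient.CHOLESTEROL: "mg",
    Nutrient.SODIUM: "mg",
}

NUTRIENTS: tuple[Nutrient, ...] = tuple(Nutrient)

#: Default association measure per nutrient for cross-method correlation.
#: Daily intakes of energy, macronutrients, sugar and fiber are close to
#: normal, so Pearson is used; cholesterol and sodium are heavy-tailed and
#: get Spearman rank correlation.
DEFAULT_ASSOC: dict[Nutrient, str] = {
    n: ("spearman" if n in (Nutrient.CHOLESTEROL, Nutrient.SODIUM) else "pearson")
    for n in NUTRIENTS
}

PHASES = ("T1", "T2")


def ref_col(nutrient: Nutrient) -> str:
    """CSV column holding the reference-database value for *nutrient*."""
    return f"ref_{nutrient.value}"


def app_col(nutrient: Nutrient) -> str:
    """CSV column holding the consumer-app value for *nutrient*."""
    return f"app_{nutrient.value}"


REF_COLUMNS = [ref_col(n) for n in NUTRIENTS]
APP_COLUMNS = [app_col(n) for n in NUTRIENTS]
NUTRIENT_COLUMNS = REF_COLUMNS + APP_COLUMNS


def parse_nutrient(name: str) -> Nutrient:
    """Map a nutrient name to its enum member, raising a clear error."""
    try:
        return Nutrient(name.strip().lower())
    except ValueError:
        valid = ", ".join(n.value for n in NUTRIENTS)
        raise ValueError(f"unknown nutrient {name!r}; expected one of: {valid}") from None
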