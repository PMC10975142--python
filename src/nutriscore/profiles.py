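"""Products and nutrient profiles.

A :class:`NutrientProfile` holds the declared composition of a product
per 100 g (solids) or 100 mL (drinkables), exactly as printed on a
nutrition table: energy, total sugar, saturated fatty acids, salt,
protein, fiber, the fruits/vegetables/legumes share, non-nutritive
sweetener presence, and the three fortificants tracked for plant-based
alternatives (iron, calcium, vitamin B12).

Missing declarations are imputed to zero — a nutrient a manufacturer
does not declare is treated as absent — via :func:`impute_missing`,
which records what it filled so the imputation is auditable.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Category",
    "NutrientProfile",
    "Product",
    "ImputationResult",
    "impute_missing",
    "protein_energy_percent",
    "sum_fvl",
    "KJ_PER_KCAL",
    "NUTRIENT_FIELDS",
]

KJ_PER_KCAL = 4.184

#: nutrient fields that are imputed to zero when absent
NUTRIENT_FIELDS = (
    "sugar_g",
    "sfa_g",
    "salt_g",
    "protein_g",
    "fiber_g",
    "fvl_percent",
    "iron_mg",
    "calcium_mg",
    "vitb12_ug",
)

# relative tolerance for declared kJ/kcal agreement; label values are
# rounded independently, so exact 4.184 conversion cannot be assumed
ENERGY_REL_TOL = 0.10
ENERGY_ABS_TOL_KCAL = 5.0


class Category(str, Enum):
    """Product categories of the plant-based alternative inventory."""

    meat_alt = "meat_alt"
    fish_alt = "fish_alt"
    coldcuts_alt = "coldcuts_alt"
    milk_alt = "milk_alt"
    dessert_alt = "dessert_alt"
    cheese_alt = "cheese_alt"
    #: reserved category for exercising the beverage label scale, where
    #: only waters may receive label A; never produced by the generator
    water = "water"


#: categories declared per 100 mL rather than per 100 g
_PER_ML = {Category.milk_alt, Category.water}


class NutrientProfile(BaseModel):
    """Declared composition per 100 g or 100 mL."""

    model_config = ConfigDict(frozen=True)

    energy_kj: float = Field(ge=0)
    energy_kcal: float = Field(ge=0)
    sugar_g: float = Field(default=0.0, ge=0)
    sfa_g: float = Field(default=0.0, ge=0)
    salt_g: float = Field(default=0.0, ge=0)
    protein_g: float = Field(default=0.0, ge=0)
    fiber_g: float = Field(default=0.0, ge=0)
    fvl_percent: float = Field(default=0.0, ge=0, le=100)
    nns_present: bool = False
    iron_mg: float = Field(default=0.0, ge=0)
    calcium_mg: float = Field(default=0.0, ge=0)
    vitb12_ug: float = Field(default=0.0, ge=0)
    basis: Literal["100g", "100ml"] = "100g"

    @model_validator(mode="after")
    def _energy_consistent(self) -> "NutrientProfile":
        expected = self.energy_kj / KJ_PER_KCAL
        tol = max(ENERGY_ABS_TOL_KCAL, ENERGY_REL_TOL * max(expected, self.energy_kcal))
        if abs(self.energy_kcal - expected) > tol:
            raise ValueError(
                f"inconsistent energy declaration: {self.energy_kj} kJ "
                f"vs {self.energy_kcal} kcal (expected ~{expected:.0f} kcal)"
            )
        return self


class Product(BaseModel):
    """A shelf product: identifier, category and nutrient profile."""

    model_config = ConfigDict(frozen=True)

    id: str
    name: str = ""
    category: Category
    is_water: bool = False
    profile: NutrientProfile

    @model_validator(mode="after")
    def _water_flag(self) -> "Product":
        if self.is_water and self.category is not Category.water:
            raise ValueError("is_water is only legal for the reserved water category")
        return self


class ImputationResult(BaseModel):
    """Outcome of :func:`impute_missing`: the profile plus an audit log."""

    profile: NutrientProfile
    imputed_fields: tuple[str, ...]


def _parse_number(field: str, raw: object) -> float:
    if isinstance(raw, bool):
        raise ValueError(f"{field}: boolean is not a nutrient amount")
    if isinstance(raw, (int, float)):
        value = float(raw)
    else:
        text = str(raw).strip()
        try:
            value = float(text)
        except ValueError:
            raise ValueError(f"{field}: unparseable numeric value {raw!r}") from None
    if math.isnan(value):
        raise ValueError(f"{field}: NaN is not a valid declared amount")
    if value < 0:
        raise ValueError(f"{field}: negative value {value!r}")
    return value


def _is_missing(raw: object) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and math.isnan(raw):
        return True
    return isinstance(raw, str) and raw.strip() == ""


def impute_missing(
    raw_record: Mapping[str, object],
    *,
    basis: Literal["100g", "100ml"] | None = None,
) -> ImputationResult:
    """Build a complete :class:`NutrientProfile` from a partial record.

    Absent nutrient fields are set to exactly 0 and listed in the
    returned imputation log; present fields pass through unchanged.  At
    least one energy declaration (kJ or kcal) must be present; the
    missing unit is derived at 1 kcal = 4.184 kJ.

    ``basis`` defaults to per-100 mL for milk alternatives and waters
    (when a ``category`` key is present) and per-100 g otherwise.

    Raises
    ------
    ValueError
        On a negative or unparseable numeric value (the offending field
        is named), or when both energy declarations are absent.
    """
    imputed: list[str] = []
    values: dict[str, object] = {}

    kj_raw = raw_record.get("energy_kj")
    kcal_raw = raw_record.get("energy_kcal")
    kj_missing, kcal_missing = _is_missing(kj_raw), _is_missing(kcal_raw)
    if kj_missing and kcal_missing:
        raise ValueError("energy_kj/energy_kcal: at least one energy declaration required")
    if not kj_missing:
        values["energy_kj"] = _parse_number("energy_kj", kj_raw)
    if not kcal_missing:
        values["energy_kcal"] = _parse_number("energy_kcal", kcal_raw)
    if kj_missing:
        values["energy_kj"] = values["energy_kcal"] * KJ_PER_KCAL  # type: ignore[operator]
    if kcal_missing:
        values["energy_kcal"] = values["energy_kj"] / KJ_PER_KCAL  # type: ignore[operator]

    for field in NUTRIENT_FIELDS:
        raw = raw_record.get(field)
        if _is_missing(raw):
            values[field] = 0.0
            imputed.append(field)
        else:
            values[field] = _parse_number(field, raw)

    nns_raw = raw_record.get("nns_present")
    if _is_missing(nns_raw):
        values["nns_present"] = False
        imputed.append("nns_present")
    elif isinstance(nns_raw, str):
        lowered = nns_raw.strip().lower()
        if lowered in {"true", "1", "yes", "present"}:
            values["nns_present"] = True
        elif lowered in {"false", "0", "no", "absent"}:
            values["nns_present"] = False
        else:
            raise ValueError(f"nns_present: unparseable boolean {nns_raw!r}")
    else:
        values["nns_present"] = bool(nns_raw)

    if basis is None:
        category = raw_record.get("category")
        try:
            basis = "100ml" if Category(category) in _PER_ML else "100g"
        except ValueError:
            basis = "100g"
    values["basis"] = basis

    return ImputationResult(
        profile=NutrientProfile(**values),  # type: ignore[arg-type]
        imputed_fields=tuple(imputed),
    )


class ProteinEnergyUndefined(ValueError):
    """Protein E% is undefined when the declared energy is zero."""


def protein_energy_percent(profile: NutrientProfile) -> float:
    """Share of total energy supplied by protein, in percent.

    Protein contributes 4 kcal per gram, so the share is
    ``protein_g * 4 / energy_kcal * 100``.

    Raises
    ------
    ProteinEnergyUndefined
        If ``energy_kcal`` is 0 — the ratio is undefined and silently
        returning 0 would conflate "no protein" with "no energy".
    """
    if profile.energy_kcal <= 0:
        raise ProteinEnergyUndefined(
            "protein E% undefined for a product declaring 0 kcal"
        )
    return profile.protein_g * 4.0 / profile.energy_kcal * 100.0


def sum_fvl(
    components: Iterable[tuple[str, float]],
    *,
    version: Literal["old", "new"] = "new",
    ingredient_classes: Mapping[str, str] | None = None,
) -> float:
    """Fruits/vegetables/legumes percentage from per-ingredient shares.

    Qualifying shares are summed and capped at 100.  Fruits, vegetables
    and legumes qualify under both algorithm versions; nuts and
    rapeseed/walnut/olive oils qualify only under the old one.
    Ingredient class membership comes from ``ingredient_classes``
    (ingredient name, lower-cased, to class name); unlisted ingredients
    do not qualify.  The default map is the bundled configuration.
    """
    if ingredient_classes is None:
        from .registry import load_fvl_ingredient_classes

        ingredient_classes = load_fvl_ingredient_classes()
    qualifying = {"fruit", "vegetable", "legume"}
    if version == "old":
        qualifying |= {"nut", "qualifying_oil"}
    elif version != "new":
        raise ValueError(f"unknown algorithm version {version!r}")

    total = 0.0
    for ingredient, percent in components:
        if percent < 0:
            raise ValueError(f"{ingredient}: negative ingredient share {percent!r}")
        if ingredient_classes.get(ingredient.strip().lower()) in qualifying:
            total += float(percent)
    return min(total, 100.0)
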