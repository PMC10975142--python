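"""FSAm-NPS totals and Nutri-Score letters for products.

The FSAm-NPS score is the sum of negative points (energy density,
sugars, saturated fatty acids, salt, plus a sweetener penalty for
beverages under the new algorithm) minus the counted positive points
(protein, fiber, fruits/vegetables/legumes).  Whether protein counts
depends on the algorithm's aggregation rule; the breakdown records the
decision so alternative readings of the rule stay testable.

Routing: every product category is scored as a general food, except
milk alternatives, which the old algorithm treats as general foods and
the new algorithm as beverages — the single routing change responsible
for the largest label shifts in this product segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .profiles import Category, NutrientProfile, Product
from .registry import (
    NEGATIVE_COMPONENTS,
    POSITIVE_COMPONENTS,
    AlgorithmRegistry,
    AlgorithmSpec,
    LabelScale,
    load_registry,
)

__all__ = [
    "ScoreBreakdown",
    "route_product",
    "compute_fsam_nps",
    "assign_label",
    "score_product",
    "score_table",
    "breakdowns_to_frame",
]

Version = Literal["old", "new"]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component points and the resulting score and label."""

    product_id: str
    version: Version
    product_class: str
    component_points: Mapping[str, int]
    negative_points: int
    positive_points: int          # counted positives only
    protein_counted: bool
    total: int
    label: str
    color: str


def route_product(product: Product, version: Version, *, registry: AlgorithmRegistry | None = None) -> AlgorithmSpec:
    """Resolve the algorithm spec a product is scored under.

    Milk alternatives are general foods under the old algorithm and
    beverages under the new one; waters (reserved test category) are
    beverages under both; every other category is a general food.
    """
    registry = registry or load_registry()
    if version not in ("old", "new"):
        raise ValueError(f"unknown algorithm version {version!r}")
    category = Category(product.category)
    if category is Category.water:
        product_class = "beverages"
    elif category is Category.milk_alt:
        product_class = "beverages" if version == "new" else "general_foods"
    else:
        product_class = "general_foods"
    return registry.get(version, product_class)


def _protein_counted(rule: str, negative: int, fvl_points: int, fvl_max: int) -> bool:
    if rule == "always":
        return True
    if rule == "never":
        return False
    if rule == "n_lt_11":
        return negative < 11
    if rule == "n_lt_11_or_max_fvl":
        return negative < 11 or fvl_points == fvl_max
    raise ValueError(f"unknown protein rule {rule!r}")


def compute_fsam_nps(
    profile: NutrientProfile,
    spec: AlgorithmSpec,
    *,
    is_water: bool = False,
    product_id: str = "",
    protein_rule: str | None = None,
) -> ScoreBreakdown:
    """Score one nutrient profile under one algorithm spec.

    ``protein_rule`` overrides the spec's aggregation rule (``always``,
    ``never``, ``n_lt_11``, ``n_lt_11_or_max_fvl``) — useful for
    probing how the protein-counting conditional shapes a score.
    """
    points: dict[str, int] = {}
    for comp in NEGATIVE_COMPONENTS:
        points[comp] = spec.negative[comp].score(getattr(profile, comp))
    if spec.nns_points:
        points["nns"] = spec.nns_points if profile.nns_present else 0
    negative = sum(points[c] for c in NEGATIVE_COMPONENTS) + points.get("nns", 0)

    for comp in POSITIVE_COMPONENTS:
        points[comp] = spec.positive[comp].score(getattr(profile, comp))

    rule = protein_rule if protein_rule is not None else spec.protein_rule
    counted = _protein_counted(
        rule, negative, points["fvl_percent"], spec.positive["fvl_percent"].max_points
    )
    positive = points["fiber_g"] + points["fvl_percent"]
    if counted:
        positive += points["protein_g"]

    total = negative - positive
    label = assign_label(total, spec.label_scale, is_water=is_water)
    return ScoreBreakdown(
        product_id=product_id,
        version=spec.version,
        product_class=spec.product_class,
        component_points=points,
        negative_points=negative,
        positive_points=positive,
        protein_counted=counted,
        total=total,
        label=label,
        color=LabelScale.color(label),
    )


def assign_label(total: int, scale: LabelScale, *, is_water: bool = False) -> str:
    """Letter for an FSAm-NPS total under a label scale.

    Cut-offs are inclusive as published.  On beverage scales label A is
    reserved for waters: a non-water beverage gets at best B no matter
    how low its score, and a water gets A regardless of its score.
    """
    if not float(total).is_integer():
        raise ValueError(f"FSAm-NPS totals are integers, got {total!r}")
    return scale.letter(int(total), is_water=is_water)


def score_product(
    product: Product,
    version: Version,
    *,
    registry: AlgorithmRegistry | None = None,
    protein_rule: str | None = None,
) -> ScoreBreakdown:
    """Route and score a single product under one algorithm version."""
    spec = route_product(product, version, registry=registry)
    return compute_fsam_nps(
        product.profile,
        spec,
        is_water=product.is_water,
        product_id=product.id,
        protein_rule=protein_rule,
    )


def score_table(
    products: Iterable[Product],
    version: Version,
    *,
    registry: AlgorithmRegistry | None = None,
    protein_rule: str | None = None,
) -> tuple[list[ScoreBreakdown], list[tuple[str, str]]]:
    """Score a batch of products, collecting per-product errors.

    Returns the breakdowns in input order and a list of
    ``(product_id, message)`` pairs for products that failed to score;
    a bad product never aborts the batch.
    """
    registry = registry or load_registry()
    breakdowns: list[ScoreBreakdown] = []
    errors: list[tuple[str, str]] = []
    for product in products:
        try:
            breakdowns.append(
                score_product(product, version, registry=registry, protein_rule=protein_rule)
            )
        except (ValueError, KeyError) as exc:
            errors.append((product.id, str(exc)))
    return breakdowns, errors


def breakdowns_to_frame(breakdowns: Iterable[ScoreBreakdown]) -> pd.DataFrame:
    """Tidy DataFrame view of a batch of score breakdowns."""
    rows = []
    for b in breakdowns:
        row = {
            "product_id": b.product_id,
            "version": b.version,
            "product_class": b.product_class,
            "negative_points": b.negative_points,
            "positive_points": b.positive_points,
            "protein_counted": b.protein_counted,
            "total": b.total,
            "label": b.label,
            "color": b.color,
        }
        row.update({f"pts_{k}": v for k, v in b.component_points.items()})
        rows.append(row)
    return pd.DataFrame(rows)
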