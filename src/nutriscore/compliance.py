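"""Dutch dietary-guideline compliance for plant-based alternatives.

The Wheel of Five gives directional composition criteria a product must
meet to count as a full replacement for its animal-based counterpart:
meat alternatives are judged on protein energy share, saturated fat,
salt, iron and vitamin B12; milk alternatives additionally on sugar and
calcium.  Compliance depends only on composition, never on which
Nutri-Score algorithm labelled the product; the pipeline then tabulates
the share of compliant products within each label group.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
import yaml

from .profiles import Product, protein_energy_percent
from .scoring import ScoreBreakdown

__all__ = [
    "Criterion",
    "CriteriaSet",
    "load_criteria",
    "check_product",
    "compliance_by_label",
]


@dataclass(frozen=True)
class Criterion:
    """One directional threshold, inclusive at the boundary."""

    metric: str
    op: Literal["ge", "le"]
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"{self.metric}: threshold must be positive")
        if self.op not in ("ge", "le"):
            raise ValueError(f"{self.metric}: op must be 'ge' or 'le'")

    def passes(self, value: float) -> bool:
        return value >= self.threshold if self.op == "ge" else value <= self.threshold

    @property
    def label(self) -> str:
        sign = ">=" if self.op == "ge" else "<="
        return f"{self.metric} {sign} {self.threshold:g}"


@dataclass(frozen=True)
class CriteriaSet:
    """Guideline criteria for one product category."""

    category: str
    criteria: tuple[Criterion, ...]


def _data_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("nutriscore") / "data" / "criteria.yaml"))


@lru_cache(maxsize=8)
def load_criteria(path: str | Path | None = None) -> dict[str, CriteriaSet]:
    """Criteria sets keyed by category (bundled configuration by default)."""
    src = Path(path) if path is not None else _data_path()
    raw = yaml.safe_load(src.read_text())
    return {
        category: CriteriaSet(
            category=category,
            criteria=tuple(
                Criterion(metric=c["metric"], op=c["op"], threshold=float(c["threshold"]))
                for c in items
            ),
        )
        for category, items in raw.items()
    }


def _metric_value(product: Product, metric: str) -> float:
    if metric == "protein_epct":
        # a product declaring 0 kcal supplies no protein energy; for
        # criteria purposes its protein energy share is 0%
        if product.profile.energy_kcal <= 0:
            return 0.0
        return protein_energy_percent(product.profile)
    try:
        return float(getattr(product.profile, metric))
    except AttributeError:
        raise ValueError(f"criterion metric {metric!r} not resolvable from the profile") from None


def check_product(product: Product, criteria: CriteriaSet) -> dict[str, bool]:
    """Evaluate every criterion for one product (inclusive thresholds)."""
    return {c.label: c.passes(_metric_value(product, c.metric)) for c in criteria.criteria}


def compliance_by_label(
    products: Iterable[Product],
    breakdowns: Iterable[ScoreBreakdown],
    criteria: CriteriaSet,
    *,
    labels: tuple[str, ...] = ("A", "B", "C", "D", "E"),
) -> pd.DataFrame:
    """Share of products meeting each criterion, per label group.

    Products are matched to breakdowns by product id; only products of
    the criteria set's category enter the tabulation.  Empty label
    groups are absent from the output rather than reported as 0%.

    Returns a tidy frame with columns ``label``, ``n``, ``criterion``,
    ``n_pass``, ``pct_pass``.
    """
    by_id: Mapping[str, Product] = {p.id: p for p in products}
    groups: dict[str, list[dict[str, bool]]] = {}
    for b in breakdowns:
        product = by_id.get(b.product_id)
        if product is None or product.category.value != criteria.category:
            continue
        if b.label in labels:
            groups.setdefault(b.label, []).append(check_product(product, criteria))

    rows = []
    for label in labels:
        checks = groups.get(label)
        if not checks:
            continue
        n = len(checks)
        for criterion in criteria.criteria:
            n_pass = sum(c[criterion.label] for c in checks)
            rows.append(
                {
                    "label": label,
                    "n": n,
                    "criterion": criterion.label,
                    "n_pass": n_pass,
                    "pct_pass": 100.0 * n_pass / n,
                }
            )
    return pd.DataFrame(rows, columns=["label", "n", "criterion", "n_pass", "pct_pass"])
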