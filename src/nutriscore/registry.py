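"""Loading and validation of the bundled algorithm configuration.

The band tables, label scales, guideline criteria and FVL ingredient
classes ship as human-readable YAML under ``nutriscore/data``.  This
module parses them into validated objects and caches the result; pass a
path to any loader to swap in an edited configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import yaml

from .bands import BandTable

__all__ = [
    "LabelScale",
    "AlgorithmSpec",
    "AlgorithmRegistry",
    "load_registry",
    "load_anchors",
    "load_fvl_ingredient_classes",
    "NEGATIVE_COMPONENTS",
    "POSITIVE_COMPONENTS",
]

Version = Literal["old", "new"]
ProductClass = Literal["general_foods", "beverages"]
ProteinRule = Literal["always", "never", "n_lt_11", "n_lt_11_or_max_fvl"]

NEGATIVE_COMPONENTS = ("energy_kj", "sugar_g", "sfa_g", "salt_g")
POSITIVE_COMPONENTS = ("protein_g", "fiber_g", "fvl_percent")

_LETTERS = ("A", "B", "C", "D", "E")
_COLORS = {
    "A": "dark green",
    "B": "light green",
    "C": "yellow",
    "D": "orange",
    "E": "red",
}

# range checked by the label-partition validator; comfortably wider than
# any feasible FSAm-NPS total
_PARTITION_RANGE = range(-60, 101)


@dataclass(frozen=True)
class LabelScale:
    """Ordered score cut-offs mapping an FSAm-NPS total to a letter.

    ``cutoffs`` maps each letter to an inclusive ``(min, max)`` range,
    ``None`` meaning unbounded.  Beverage scales reserve label A for
    waters: they carry no numeric A range and ``water_only_a`` is true.
    """

    cutoffs: Mapping[str, tuple[int | None, int | None]]
    water_only_a: bool

    def __post_init__(self) -> None:
        letters = set(self.cutoffs)
        expected = set(_LETTERS) - ({"A"} if self.water_only_a else set())
        if letters != expected:
            raise ValueError(f"label scale letters {letters} != expected {expected}")
        for score in _PARTITION_RANGE:
            hits = [let for let in self.cutoffs if self._in_range(let, score)]
            if len(hits) != 1:
                raise ValueError(
                    f"label scale does not partition the integers at {score}: {hits}"
                )

    def _in_range(self, letter: str, total: int) -> bool:
        lo, hi = self.cutoffs[letter]
        return (lo is None or total >= lo) and (hi is None or total <= hi)

    def letter(self, total: int, *, is_water: bool = False) -> str:
        """Letter for a total score; waters force A on beverage scales."""
        if self.water_only_a and is_water:
            return "A"
        for let in _LETTERS:
            if let in self.cutoffs and self._in_range(let, int(total)):
                return let
        raise AssertionError("partition validator guarantees a match")

    @staticmethod
    def color(letter: str) -> str:
        return _COLORS[letter]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One (version, product class) bundle of band tables and rules."""

    version: Version
    product_class: ProductClass
    negative: Mapping[str, BandTable]
    positive: Mapping[str, BandTable]
    protein_rule: ProteinRule
    label_scale: LabelScale
    nns_points: int = 0

    def __post_init__(self) -> None:
        if set(self.negative) != set(NEGATIVE_COMPONENTS):
            raise ValueError(f"negative components {set(self.negative)} incomplete")
        if set(self.positive) != set(POSITIVE_COMPONENTS):
            raise ValueError(f"positive components {set(self.positive)} incomplete")
        if self.nns_points and self.product_class != "beverages":
            raise ValueError("NNS penalty applies to beverages only")

    @property
    def max_negative(self) -> int:
        return sum(t.max_points for t in self.negative.values()) + self.nns_points

    @property
    def max_positive(self) -> int:
        return sum(t.max_points for t in self.positive.values())

    @property
    def score_range(self) -> tuple[int, int]:
        """Feasible (min, max) FSAm-NPS total for this spec."""
        return (-self.max_positive, self.max_negative)


@dataclass(frozen=True)
class AlgorithmRegistry:
    """All four (version, product class) algorithm specs plus a checksum."""

    specs: Mapping[tuple[str, str], AlgorithmSpec]
    checksum: str

    def get(self, version: Version, product_class: ProductClass) -> AlgorithmSpec:
        try:
            return self.specs[(version, product_class)]
        except KeyError:
            raise KeyError(f"no algorithm spec for ({version}, {product_class})") from None


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nutriscore") / "data" / name))


def _parse_spec(version: str, product_class: str, raw: Mapping) -> AlgorithmSpec:
    negative = {
        comp: BandTable(comp, "negative", tuple(cfg["thresholds"]), tuple(cfg["points"]))
        for comp, cfg in raw["negative"].items()
    }
    positive = {
        comp: BandTable(comp, "positive", tuple(cfg["thresholds"]), tuple(cfg["points"]))
        for comp, cfg in raw["positive"].items()
    }
    scale_raw = raw["label_scale"]
    cutoffs = {
        letter: (rng[0], rng[1]) for letter, rng in scale_raw["cutoffs"].items()
    }
    scale = LabelScale(cutoffs=cutoffs, water_only_a=bool(scale_raw["water_only_a"]))
    return AlgorithmSpec(
        version=version,  # type: ignore[arg-type]
        product_class=product_class,  # type: ignore[arg-type]
        negative=negative,
        positive=positive,
        protein_rule=raw["protein_rule"],
        label_scale=scale,
        nns_points=int(raw.get("nns_points", 0)),
    )


def _checksum(raw: Mapping) -> str:
    canonical = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


@lru_cache(maxsize=8)
def load_registry(path: str | Path | None = None) -> AlgorithmRegistry:
    """Parse the band-table configuration (bundled file by default)."""
    src = Path(path) if path is not None else _data_path("algorithms.yaml")
    raw = yaml.safe_load(src.read_text())
    specs = {
        (version, product_class): _parse_spec(version, product_class, spec_raw)
        for version, classes in raw.items()
        for product_class, spec_raw in classes.items()
    }
    return AlgorithmRegistry(specs=specs, checksum=_checksum(raw))


@lru_cache(maxsize=8)
def load_anchors(path: str | Path | None = None) -> dict:
    """Published min/max anchor summary per (version, class, component)."""
    src = Path(path) if path is not None else _data_path("anchors.yaml")
    return yaml.safe_load(src.read_text())


@lru_cache(maxsize=8)
def load_fvl_ingredient_classes(path: str | Path | None = None) -> dict[str, str]:
    """Flat ingredient -> class map for the FVL component."""
    src = Path(path) if path is not None else _data_path("fvl_ingredients.yaml")
    raw = yaml.safe_load(src.read_text())
    return {
        str(name).strip().lower(): cls
        for cls, names in raw.items()
        for name in names
    }
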