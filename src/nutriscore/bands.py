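"""Band tables: the atom of the FSAm-NPS point system.

A band table maps a nutrient amount to an integer point level through an
ordered sequence of thresholds.  Both algorithm versions (2017 and
2022/2023) are built entirely from such tables; only the thresholds and
point levels differ.  The boundary convention is centralised in
:meth:`BandTable.score` so that every component of every version shares
it:

* values at or below the first threshold (the published "<= min" anchor)
  score 0 points;
* values at or above the last threshold (the published ">= max" anchor)
  score the component maximum;
* interior bands are left-open / right-closed: a value equal to an
  interior threshold falls in the band below it.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Literal

__all__ = ["BandTable", "uniform_band_table"]

Direction = Literal["negative", "positive"]


@dataclass(frozen=True)
class BandTable:
    """Ordered thresholds mapping a nutrient value to component points.

    Parameters
    ----------
    component
        Name of the nutrient field this table scores (e.g. ``salt_g``).
    direction
        ``"negative"`` for unfavourable components (energy, sugar,
        saturated fat, salt), ``"positive"`` for favourable ones
        (protein, fiber, fruits/vegetables/legumes).
    thresholds
        Strictly increasing nutrient values; ``thresholds[0]`` is the
        0-point anchor and ``thresholds[-1]`` the max-point anchor.
    points
        Non-decreasing point level per band, one more entry than
        thresholds; must start at 0.  Uniformly graded components use
        ``0..max_points``; the FVL component uses e.g. ``[0, 1, 2, 5]``.
    """

    component: str
    direction: Direction
    thresholds: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "points", tuple(int(p) for p in self.points))
        if len(self.points) != len(self.thresholds) + 1:
            raise ValueError(
                f"{self.component}: need len(points) == len(thresholds) + 1, "
                f"got {len(self.points)} points for {len(self.thresholds)} thresholds"
            )
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"{self.component}: thresholds must be strictly increasing")
        if self.points[0] != 0:
            raise ValueError(f"{self.component}: lowest band must score 0")
        if any(b < a for a, b in zip(self.points, self.points[1:])):
            raise ValueError(f"{self.component}: points must be non-decreasing")
        if self.direction not in ("negative", "positive"):
            raise ValueError(f"{self.component}: bad direction {self.direction!r}")

    @property
    def max_points(self) -> int:
        return self.points[-1]

    def score(self, value: float) -> int:
        """Point level of the band containing ``value``.

        Raises
        ------
        ValueError
            If ``value`` is negative (nutrient amounts cannot be).
        """
        if value < 0:
            raise ValueError(f"{self.component}: negative value {value!r}")
        if value >= self.thresholds[-1]:
            return self.points[-1]
        # band index = number of thresholds strictly below value
        return self.points[bisect_left(self.thresholds, value)]


def uniform_band_table(
    component: str,
    direction: Direction,
    min_anchor: float,
    max_anchor: float,
    max_points: int,
) -> BandTable:
    """Fallback table with thresholds evenly spaced between the anchors.

    The step is ``(max - min) / (max_points - 1)``, which reproduces the
    official 2017 grids for energy, saturated fat, salt and protein
    exactly and approximates components whose official interior
    thresholds are rounded or non-uniform.  Intended for exploring
    alternative grids or anchor-only specifications; the shipped
    configuration carries the official thresholds.
    """
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    if not max_anchor > min_anchor:
        raise ValueError("max_anchor must exceed min_anchor")
    step = (max_anchor - min_anchor) / (max_points - 1) if max_points > 1 else None
    if step is None:
        thresholds = [min_anchor]
        pts = [0, 1]
    else:
        thresholds = [min_anchor + k * step for k in range(max_points)]
        thresholds[-1] = max_anchor  # guard against float drift
        pts = list(range(max_points + 1))
    return BandTable(component, direction, tuple(thresholds), tuple(pts))
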