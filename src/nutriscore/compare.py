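"""Old-versus-new algorithm comparison.

Scores are heavily non-normal across supermarket categories, so every
summary is a median with 25th/75th percentiles and every test is
nonparametric: a Shapiro–Wilk screen documents the non-normality, the
Wilcoxon signed-rank test compares paired per-product scores between
algorithm versions within a category, and the Mann–Whitney U test
compares the composition of the (independent) groups of products that
hold label A or B under each version.  All tests are two-sided at
alpha = 0.05 with no multiple-testing correction.

Zero paired differences are discarded before the signed-rank test
(Wilcoxon's original convention); the exact null distribution is used
for small samples without ties and the tie-corrected normal
approximation otherwise.  Both choices are configurable through
:class:`StatOptions` and recorded in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import Product, protein_energy_percent
from .scoring import ScoreBreakdown

__all__ = [
    "StatOptions",
    "quartiles",
    "normality_screen",
    "summarize_scores",
    "label_shift",
    "compare_ab_subsets",
]

ALPHA = 0.05
EXACT_N_MAX = 25

LETTERS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class StatOptions:
    """Statistical policy knobs, recorded alongside every result."""

    method: Literal["auto", "exact", "approx"] = "auto"
    zero_method: Literal["wilcox", "pratt", "zsplit"] = "wilcox"
    alpha: float = ALPHA


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(25th, 50th, 75th) percentiles, linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quartiles of an empty sample are undefined")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q25), float(q50), float(q75)


def _fmt_median_iqr(values: Sequence[float]) -> str:
    q25, q50, q75 = quartiles(values)
    return f"{q50:g} ({q25:g}-{q75:g})"


def normality_screen(values: Sequence[float]) -> dict:
    """Shapiro–Wilk screen for a sample.

    Downstream summaries use medians regardless of the outcome; the
    screen only documents why.  Samples of fewer than 3 values or
    constant samples are flagged as degenerate and carry no p-value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        return {"n": int(arr.size), "statistic": None, "p": None, "note": "skipped: n < 3"}
    if np.ptp(arr) == 0:
        return {"n": int(arr.size), "statistic": None, "p": None, "note": "degenerate: constant sample"}
    stat, p = stats.shapiro(arr)
    return {"n": int(arr.size), "statistic": float(stat), "p": float(p), "note": ""}


def _wilcoxon_method(diffs: np.ndarray, options: StatOptions) -> str:
    if options.method == "exact":
        return "exact"
    if options.method == "approx":
        return "approx"
    nonzero = diffs[diffs != 0]
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if 0 < nonzero.size <= EXACT_N_MAX and not has_ties:
        return "exact"
    return "approx"


def summarize_scores(
    scores_old: Mapping[str, int],
    scores_new: Mapping[str, int],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Per-category score summary with the paired signed-rank test.

    Parameters
    ----------
    scores_old, scores_new
        FSAm-NPS totals keyed by product id; every product must be
        scored under both versions (pairing is by id).
    categories
        Product category keyed by product id.

    Returns one row per category: ``n``, median and quartiles per
    version, the signed-rank statistic and its two-sided p-value.
    Categories with fewer than 2 pairs, or with all differences zero,
    carry no test and are flagged in ``note``.
    """
    options = StatOptions()
    ids_by_cat: dict[str, list[str]] = {}
    for pid, cat in categories.items():
        if pid in scores_old and pid in scores_new:
            ids_by_cat.setdefault(cat, []).append(pid)

    rows = []
    for cat in sorted(ids_by_cat):
        ids = ids_by_cat[cat]
        old = np.array([scores_old[i] for i in ids], dtype=float)
        new = np.array([scores_new[i] for i in ids], dtype=float)
        o25, o50, o75 = quartiles(old)
        n25, n50, n75 = quartiles(new)
        row = {
            "category": cat,
            "n": len(ids),
            "old_q25": o25, "old_median": o50, "old_q75": o75,
            "new_q25": n25, "new_median": n50, "new_q75": n75,
            "median_shift": n50 - o50,
            "statistic": np.nan,
            "p": np.nan,
            "method": "",
            "note": "",
        }
        diffs = new - old
        if len(ids) < 2:
            row["note"] = "no test: n < 2"
        elif np.all(diffs == 0):
            row["note"] = "degenerate: all paired differences zero"
        else:
            method = _wilcoxon_method(diffs, options)
            res = stats.wilcoxon(
                new, old, zero_method=options.zero_method, method=method,
                alternative="two-sided",
            )
            row["statistic"] = float(res.statistic)
            row["p"] = float(res.pvalue)
            row["method"] = method
        rows.append(row)
    return pd.DataFrame(rows)


def label_shift(
    breakdowns_by_version: Mapping[str, Sequence[ScoreBreakdown]],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Per-category label distribution per version, as percentages.

    One row per (category, version) with a column per letter, the
    combined healthy share ``pct_AB``, and — when both versions are
    present — ``ab_decline`` on the new rows: old A∪B% minus new A∪B%.
    """
    rows = []
    for version, breakdowns in breakdowns_by_version.items():
        counts: dict[str, dict[str, int]] = {}
        for b in breakdowns:
            cat = categories.get(b.product_id)
            if cat is None:
                continue
            counts.setdefault(cat, {}).setdefault(b.label, 0)
            counts[cat][b.label] += 1
        for cat in sorted(counts):
            total = sum(counts[cat].values())
            row = {"category": cat, "version": version, "n": total}
            for letter in LETTERS:
                row[f"pct_{letter}"] = 100.0 * counts[cat].get(letter, 0) / total
            row["pct_AB"] = row["pct_A"] + row["pct_B"]
            rows.append(row)
    frame = pd.DataFrame(rows)
    if {"old", "new"} <= set(breakdowns_by_version):
        ab = frame.pivot(index="category", columns="version", values="pct_AB")
        decline = (ab["old"] - ab["new"]).to_dict()
        frame["ab_decline"] = [
            decline.get(r.category, np.nan) if r.version == "new" else np.nan
            for r in frame.itertuples()
        ]
    return frame


def _protein_epct(product: Product) -> float:
    # zero-energy products supply no protein energy: share is 0%
    if product.profile.energy_kcal <= 0:
        return 0.0
    return protein_energy_percent(product.profile)


#: nutrient views available to the A/B subset comparison
_NUTRIENT_GETTERS = {
    "protein_epct": _protein_epct,
    "protein_g": lambda p: p.profile.protein_g,
    "fiber_g": lambda p: p.profile.fiber_g,
    "energy_kcal": lambda p: p.profile.energy_kcal,
    "sugar_g": lambda p: p.profile.sugar_g,
    "sfa_g": lambda p: p.profile.sfa_g,
    "salt_g": lambda p: p.profile.salt_g,
    "iron_mg": lambda p: p.profile.iron_mg,
    "calcium_mg": lambda p: p.profile.calcium_mg,
    "vitb12_ug": lambda p: p.profile.vitb12_ug,
}

DEFAULT_AB_NUTRIENTS = (
    "protein_epct", "fiber_g", "energy_kcal", "sugar_g", "sfa_g", "salt_g",
)


def compare_ab_subsets(
    products: Iterable[Product],
    breakdowns_old: Iterable[ScoreBreakdown],
    breakdowns_new: Iterable[ScoreBreakdown],
    *,
    category: str,
    nutrients: Sequence[str] = DEFAULT_AB_NUTRIENTS,
    labels: tuple[str, ...] = ("A", "B"),
    options: StatOptions | None = None,
) -> pd.DataFrame:
    """Composition of label-A and label-B holders, old versus new.

    For each requested label the group of products holding it under the
    old algorithm is compared with the (independent) group holding it
    under the new algorithm, nutrient by nutrient, with a two-sided
    Mann–Whitney U test.  A label that no product holds under one of
    the versions yields rows marked not-computable instead of a test —
    under the new algorithm no non-water beverage can hold label A, so
    the milk-alternative A comparison is structurally empty.

    Returns a tidy frame: label, nutrient, n per group, median (25-75)
    per group, U statistic, p, significance flag, computable flag.
    """
    options = options or StatOptions()
    by_id = {p.id: p for p in products}

    def group(breakdowns: Iterable[ScoreBreakdown], label: str) -> list[Product]:
        return [
            by_id[b.product_id]
            for b in breakdowns
            if b.label == label
            and b.product_id in by_id
            and by_id[b.product_id].category.value == category
        ]

    breakdowns_old = list(breakdowns_old)
    breakdowns_new = list(breakdowns_new)
    rows = []
    for label in labels:
        g_old = group(breakdowns_old, label)
        g_new = group(breakdowns_new, label)
        for nutrient in nutrients:
            getter = _NUTRIENT_GETTERS[nutrient]
            row = {
                "category": category,
                "label": label,
                "nutrient": nutrient,
                "n_old": len(g_old),
                "n_new": len(g_new),
                "old_summary": "x",
                "new_summary": "x",
                "U": np.nan,
                "p": np.nan,
                "significant": False,
                "computable": bool(g_old) and bool(g_new),
            }
            if g_old:
                row["old_summary"] = _fmt_median_iqr([getter(p) for p in g_old])
            if g_new:
                row["new_summary"] = _fmt_median_iqr([getter(p) for p in g_new])
            if row["computable"]:
                x = [getter(p) for p in g_old]
                y = [getter(p) for p in g_new]
                method = options.method if options.method != "approx" else "asymptotic"
                res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
                row["U"] = float(res.statistic)
                row["p"] = float(res.pvalue)
                row["significant"] = bool(res.pvalue < options.alpha)
            rows.append(row)
    return pd.DataFrame(rows)
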