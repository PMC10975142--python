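"""CSV readers/writers and the full-analysis orchestrator.

The product CSV schema (one header row, UTF-8, comma separator, period
decimal mark) is::

    id, name, category, energy_kj, energy_kcal, protein_g, sugar_g,
    sfa_g, salt_g, fiber_g, fvl_percent, nns_present, iron_mg,
    calcium_mg, vitb12_ug, is_water

Empty cells are missing declarations and are imputed to zero.  Dutch
source data often use comma decimal marks; such cells are rejected
row-by-row with an explicit message rather than silently mis-parsed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .compare import (
    DEFAULT_AB_NUTRIENTS,
    StatOptions,
    compare_ab_subsets,
    label_shift,
    summarize_scores,
)
from .compliance import compliance_by_label, load_criteria
from .profiles import Category, Product, impute_missing
from .registry import load_registry
from .scoring import breakdowns_to_frame, score_table
from .simulate import GeneratorConfig, default_config, generate_products

__all__ = [
    "PRODUCT_COLUMNS",
    "ReadResult",
    "read_products",
    "write_products",
    "RunConfig",
    "run_full_analysis",
]

PRODUCT_COLUMNS = (
    "id", "name", "category", "energy_kj", "energy_kcal", "protein_g",
    "sugar_g", "sfa_g", "salt_g", "fiber_g", "fvl_percent", "nns_present",
    "iron_mg", "calcium_mg", "vitb12_ug", "is_water",
)

MANDATORY_COLUMNS = ("id", "category")

_COMMA_DECIMAL = re.compile(r"^-?\d+,\d+$")

_NUMERIC_CSV_FIELDS = (
    "energy_kj", "energy_kcal", "protein_g", "sugar_g", "sfa_g",
    "salt_g", "fiber_g", "fvl_percent", "iron_mg", "calcium_mg", "vitb12_ug",
)


@dataclass
class ReadResult:
    """Validated products plus row-level rejects and the imputation log."""

    products: list[Product]
    rejects: list[tuple[str, str]] = field(default_factory=list)
    imputation_log: dict[str, tuple[str, ...]] = field(default_factory=dict)


def read_products(path: str | Path) -> ReadResult:
    """Read and validate a product CSV.

    Rows that fail validation are collected into ``rejects`` (id,
    message) without aborting the read; per-row zero-imputation is
    recorded in ``imputation_log``.

    Raises
    ------
    ValueError
        If a mandatory column (id, category) or both energy columns are
        absent from the header — nothing sensible can be read then.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if "energy_kj" not in frame.columns and "energy_kcal" not in frame.columns:
        missing.append("energy_kj|energy_kcal")
    if missing:
        raise ValueError(f"{path.name}: missing mandatory columns: {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in PRODUCT_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown columns {extra}", stacklevel=2)

    result = ReadResult(products=[])
    for idx, row in frame.iterrows():
        record = {k: v for k, v in row.items() if k in PRODUCT_COLUMNS}
        pid = str(record.get("id", "")).strip() or f"row{idx}"
        try:
            for fieldname in _NUMERIC_CSV_FIELDS:
                raw = record.get(fieldname)
                if isinstance(raw, str) and _COMMA_DECIMAL.match(raw.strip()):
                    raise ValueError(
                        f"{fieldname}: comma decimal mark in {raw!r}; "
                        "use a period decimal mark"
                    )
            imputation = impute_missing(record)
            is_water = str(record.get("is_water", "")).strip().lower() in {"true", "1", "yes"}
            product = Product(
                id=pid,
                name=str(record.get("name", "")).strip(),
                category=Category(str(record["category"]).strip()),
                is_water=is_water,
                profile=imputation.profile,
            )
        except (ValueError, KeyError) as exc:
            result.rejects.append((pid, str(exc)))
            continue
        result.products.append(product)
        if imputation.imputed_fields:
            result.imputation_log[pid] = imputation.imputed_fields
    return result


def write_products(products: Iterable[Product], path: str | Path) -> None:
    """Write products in the product CSV schema (round-trips with read)."""
    rows = []
    for p in products:
        prof = p.profile
        rows.append(
            {
                "id": p.id,
                "name": p.name,
                "category": p.category.value,
                "energy_kj": prof.energy_kj,
                "energy_kcal": prof.energy_kcal,
                "protein_g": prof.protein_g,
                "sugar_g": prof.sugar_g,
                "sfa_g": prof.sfa_g,
                "salt_g": prof.salt_g,
                "fiber_g": prof.fiber_g,
                "fvl_percent": prof.fvl_percent,
                "nns_present": prof.nns_present,
                "iron_mg": prof.iron_mg,
                "calcium_mg": prof.calcium_mg,
                "vitb12_ug": prof.vitb12_ug,
                "is_water": p.is_water,
            }
        )
    pd.DataFrame(rows, columns=PRODUCT_COLUMNS).to_csv(path, index=False)


class RunConfig(BaseModel):
    """Configuration of a full analysis run."""

    input_csv: Path | None = None
    generator: GeneratorConfig | None = None
    versions: tuple[Literal["old", "new"], ...] = ("old", "new")
    criteria_categories: tuple[str, ...] = ("meat_alt", "milk_alt")
    ab_nutrients: tuple[str, ...] = DEFAULT_AB_NUTRIENTS
    output_dir: Path = Path("nutriscore_run")
    seed: int | None = None
    stat_options: StatOptions | None = None

    model_config = {"arbitrary_types_allowed": True}


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run scoring, comparison and compliance end to end.

    Writes per-version score tables, the category summary, the
    label-shift table, A/B subset comparisons, per-category compliance
    reports, a rejects report when input rows failed, and a manifest
    (config, seed, band-table checksum) for reproducibility.  Returns
    the written paths keyed by artifact name.  A stage failure removes
    all partial outputs and re-raises with the stage named.
    """
    if not config.versions:
        raise ValueError("at least one algorithm version must be selected")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    registry = load_registry()
    stage = "load products"
    try:
        rejects: list[tuple[str, str]] = []
        if config.input_csv is not None:
            read = read_products(config.input_csv)
            products, rejects = read.products, read.rejects
        else:
            gen_cfg = config.generator or default_config()
            products = generate_products(gen_cfg, seed=config.seed)
        categories = {p.id: p.category.value for p in products}

        stage = "scoring"
        breakdowns = {}
        for version in config.versions:
            b, errs = score_table(products, version, registry=registry)
            rejects.extend(errs)
            breakdowns[version] = b
            path = out / f"scores_{version}.csv"
            breakdowns_to_frame(b).to_csv(path, index=False)
            written[f"scores_{version}"] = path

        both = {"old", "new"} <= set(config.versions)
        if both:
            stage = "category summary"
            totals = {
                v: {b.product_id: b.total for b in breakdowns[v]} for v in ("old", "new")
            }
            summary = summarize_scores(totals["old"], totals["new"], categories)
            path = out / "category_summary.csv"
            summary.to_csv(path, index=False)
            written["category_summary"] = path

        stage = "label shift"
        shift = label_shift(breakdowns, categories)
        path = out / "label_shift.csv"
        shift.to_csv(path, index=False)
        written["label_shift"] = path
        if not both:
            warnings.warn(
                "single-version run: label-shift decline and paired "
                "comparisons are omitted",
                stacklevel=2,
            )

        if both:
            stage = "A/B subset comparison"
            frames = [
                compare_ab_subsets(
                    products, breakdowns["old"], breakdowns["new"],
                    category=cat, nutrients=config.ab_nutrients,
                    options=config.stat_options,
                )
                for cat in config.criteria_categories
            ]
            path = out / "subset_comparison.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            written["subset_comparison"] = path

        stage = "compliance"
        criteria = load_criteria()
        for version in config.versions:
            frames = [
                compliance_by_label(products, breakdowns[version], criteria[cat]).assign(
                    category=cat, version=version
                )
                for cat in config.criteria_categories
                if cat in criteria
            ]
            path = out / f"compliance_{version}.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            written[f"compliance_{version}"] = path

        stage = "manifest"
        if rejects:
            path = out / "rejects.csv"
            pd.DataFrame(rejects, columns=["id", "error"]).to_csv(path, index=False)
            written["rejects"] = path
        manifest = {
            "seed": config.seed,
            "versions": list(config.versions),
            "n_products": len(products),
            "input": str(config.input_csv) if config.input_csv else "synthetic",
            "band_table_checksum": registry.checksum,
            "outputs": {k: str(v) for k, v in written.items()},
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = path
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"analysis stage '{stage}' failed: {exc}") from exc
    return written
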