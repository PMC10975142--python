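"""Synthetic product tables for the six alternative categories.

The study's supermarket database is not public, so this module
generates product tables with the statistical structure the analysis
assumes: six categories (meat, fish, cold cuts, milk, dessert, cheese
alternatives), strictly positive nutrients drawn from log-normal
families parameterised by their median and 75th percentile (the two
quantiles such inventories report), optional zero inflation for
nutrients with a point mass at zero (e.g. sugar in unsweetened drinks),
a truncated-normal fruits/vegetables/legumes share, and all-or-nothing
fortification: a product either carries the full configured fortificant
levels (iron 2.1 mg, calcium 120 mg, vitamin B12 0.38 µg per 100 g/mL)
or none of them, a Bernoulli draw per product, because fortification is
a brand-level decision.

Declared energy is floored at the energy implied by the declared
macronutrients (4 kcal/g protein and sugar, 9 kcal/g saturated fat,
2 kcal/g fiber) so no synthetic label is internally impossible.

Everything is driven by a single :class:`numpy.random.Generator` seed,
so tables are reproducible bit for bit.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .profiles import KJ_PER_KCAL, Category, NutrientProfile, Product

__all__ = [
    "QuantileSpec",
    "FVLSpec",
    "FortificationSpec",
    "CategoryConfig",
    "GeneratorConfig",
    "default_config",
    "generate_products",
    "worked_fixtures",
]

#: standard-normal 75th percentile, used to convert a (median, q75)
#: pair into log-normal parameters
_Z75 = stats.norm.ppf(0.75)

#: nutrients sampled from quantile-parameterised log-normal families
SAMPLED_NUTRIENTS = ("energy_kcal", "protein_g", "sugar_g", "sfa_g", "salt_g", "fiber_g")


class QuantileSpec(BaseModel):
    """Log-normal family pinned by its median and 75th percentile.

    ``p_zero`` mixes in a point mass at exactly 0 (share of products
    declaring none of the nutrient)."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    q75: float = Field(gt=0)
    p_zero: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "QuantileSpec":
        if self.q75 <= self.median:
            raise ValueError("q75 must exceed the median")
        return self

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.log(self.q75 / self.median) / _Z75


class FVLSpec(BaseModel):
    """Truncated-normal fruits/vegetables/legumes share on [0, 100]."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(gt=0)


class FortificationSpec(BaseModel):
    """All-or-nothing fortificant block: Bernoulli(prob) per product."""

    model_config = ConfigDict(frozen=True)

    prob: float = Field(ge=0, le=1)
    iron_mg: float = Field(default=0.0, ge=0)
    calcium_mg: float = Field(default=0.0, ge=0)
    vitb12_ug: float = Field(default=0.0, ge=0)


class CategoryConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    nutrients: dict[str, QuantileSpec]
    fvl: FVLSpec | None = None
    nns_prob: float = Field(default=0.0, ge=0, le=1)
    fortification: FortificationSpec = FortificationSpec(prob=0.0)

    @model_validator(mode="after")
    def _complete(self) -> "CategoryConfig":
        missing = set(SAMPLED_NUTRIENTS) - set(self.nutrients)
        if missing:
            raise ValueError(f"nutrient specs missing: {sorted(missing)}")
        return self


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    categories: dict[Category, CategoryConfig]
    seed: int | None = None


def _cat(
    n: int,
    energy: tuple[float, float],
    protein: tuple[float, float],
    sugar: tuple[float, float, float],
    sfa: tuple[float, float],
    salt: tuple[float, float],
    fiber: tuple[float, float],
    fvl: FVLSpec | None,
    nns_prob: float,
    fort: FortificationSpec,
) -> CategoryConfig:
    return CategoryConfig(
        n=n,
        nutrients={
            "energy_kcal": QuantileSpec(median=energy[0], q75=energy[1]),
            "protein_g": QuantileSpec(median=protein[0], q75=protein[1]),
            "sugar_g": QuantileSpec(median=sugar[0], q75=sugar[1], p_zero=sugar[2]),
            "sfa_g": QuantileSpec(median=sfa[0], q75=sfa[1]),
            "salt_g": QuantileSpec(median=salt[0], q75=salt[1]),
            "fiber_g": QuantileSpec(median=fiber[0], q75=fiber[1]),
        },
        fvl=fvl,
        nns_prob=nns_prob,
        fortification=fort,
    )


def default_config(n_per_category: int = 200, seed: int | None = None) -> GeneratorConfig:
    """Calibrated defaults for the six categories.

    Meat and milk alternatives are centred on the published category
    medians (meat ~175 kcal and ~1.1 g salt per 100 g; milk ~40 kcal
    and ~0.10 g salt per 100 mL, with fortificant levels 2.1 mg iron,
    120 mg calcium, 0.38 µg B12); fish, cold cuts, dessert and cheese
    alternatives use typical Dutch supermarket compositions.  See
    docs/methods.md for the full rationale.
    """
    meat_fort = FortificationSpec(prob=0.33, iron_mg=2.1, vitb12_ug=0.38)
    dairy_fort = FortificationSpec(prob=0.38, calcium_mg=120, vitb12_ug=0.38)
    cats = {
        Category.meat_alt: _cat(
            n_per_category, (175, 205), (14, 17), (1.5, 2.8, 0.05), (1.0, 1.5),
            (1.1, 1.35), (4.5, 6.0), FVLSpec(mean=10, sd=15), 0.0, meat_fort,
        ),
        Category.fish_alt: _cat(
            n_per_category, (185, 220), (13, 16), (1.0, 2.0, 0.10), (1.5, 2.5),
            (1.4, 1.7), (3.5, 5.0), FVLSpec(mean=5, sd=10), 0.0,
            FortificationSpec(prob=0.25, iron_mg=2.1, vitb12_ug=0.38),
        ),
        Category.coldcuts_alt: _cat(
            n_per_category, (160, 200), (15, 19), (1.5, 2.5, 0.05), (1.3, 2.2),
            (1.8, 2.1), (2.5, 3.5), FVLSpec(mean=5, sd=10), 0.0, meat_fort,
        ),
        Category.milk_alt: _cat(
            n_per_category, (40, 52), (1.5, 3.2), (2.5, 5.5, 0.25), (0.25, 0.4),
            (0.10, 0.12), (0.4, 0.7), FVLSpec(mean=3, sd=5), 0.10, dairy_fort,
        ),
        Category.dessert_alt: _cat(
            n_per_category, (90, 115), (3.5, 4.5), (8.0, 11.0, 0.10), (1.2, 2.2),
            (0.12, 0.16), (1.0, 1.8), FVLSpec(mean=3, sd=5), 0.10, dairy_fort,
        ),
        Category.cheese_alt: _cat(
            n_per_category, (280, 330), (1.0, 2.5), (0.5, 1.0, 0.30), (17, 21),
            (2.0, 2.3), (0.5, 1.0), FVLSpec(mean=2, sd=4), 0.0,
            FortificationSpec(prob=0.10, calcium_mg=120, vitb12_ug=0.38),
        ),
    }
    return GeneratorConfig(categories=cats, seed=seed)


def _sample_lognormal(rng: np.random.Generator, spec: QuantileSpec, n: int) -> np.ndarray:
    values = rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=n)
    if spec.p_zero > 0:
        values[rng.random(n) < spec.p_zero] = 0.0
    return values


def generate_products(config: GeneratorConfig, seed: int | None = None) -> list[Product]:
    """Sample a product table; deterministic for a given seed.

    ``seed`` overrides ``config.seed``.  Products are emitted in a
    fixed category order with ids ``<category>_0001`` onward.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    products: list[Product] = []
    for category in Category:
        cat_cfg = config.categories.get(category)
        if cat_cfg is None or cat_cfg.n == 0:
            continue
        n = cat_cfg.n
        draws = {
            name: _sample_lognormal(rng, cat_cfg.nutrients[name], n)
            for name in SAMPLED_NUTRIENTS
        }
        if cat_cfg.fvl is not None:
            lo = (0 - cat_cfg.fvl.mean) / cat_cfg.fvl.sd
            hi = (100 - cat_cfg.fvl.mean) / cat_cfg.fvl.sd
            fvl = stats.truncnorm.rvs(
                lo, hi, loc=cat_cfg.fvl.mean, scale=cat_cfg.fvl.sd,
                size=n, random_state=rng,
            )
        else:
            fvl = np.zeros(n)
        nns = rng.random(n) < cat_cfg.nns_prob
        fortified = rng.random(n) < cat_cfg.fortification.prob

        basis = "100ml" if category is Category.milk_alt else "100g"
        for i in range(n):
            protein = round(float(draws["protein_g"][i]), 2)
            sugar = round(float(draws["sugar_g"][i]), 2)
            sfa = round(float(draws["sfa_g"][i]), 2)
            fiber = round(float(draws["fiber_g"][i]), 2)
            salt = round(float(draws["salt_g"][i]), 2)
            # declared energy cannot fall below the macro-implied floor
            floor = 4 * protein + 4 * sugar + 9 * sfa + 2 * fiber
            kcal = round(max(float(draws["energy_kcal"][i]), floor), 1)
            profile = NutrientProfile(
                energy_kj=round(kcal * KJ_PER_KCAL, 1),
                energy_kcal=kcal,
                sugar_g=sugar,
                sfa_g=sfa,
                salt_g=salt,
                protein_g=protein,
                fiber_g=fiber,
                fvl_percent=round(float(fvl[i]), 1),
                nns_present=bool(nns[i]),
                iron_mg=cat_cfg.fortification.iron_mg if fortified[i] else 0.0,
                calcium_mg=cat_cfg.fortification.calcium_mg if fortified[i] else 0.0,
                vitb12_ug=cat_cfg.fortification.vitb12_ug if fortified[i] else 0.0,
                basis=basis,
            )
            products.append(
                Product(
                    id=f"{category.value}_{i + 1:04d}",
                    name=f"synthetic {category.value.replace('_', ' ')} {i + 1}",
                    category=category,
                    profile=profile,
                )
            )
    return products


def _fixture(
    pid: str,
    category: Category,
    kcal: float,
    *,
    name: str = "",
    is_water: bool = False,
    **nutrients: float | bool,
) -> Product:
    profile = NutrientProfile(
        energy_kj=round(kcal * KJ_PER_KCAL, 1),
        energy_kcal=kcal,
        basis="100ml" if category in (Category.milk_alt, Category.water) else "100g",
        **nutrients,  # type: ignore[arg-type]
    )
    return Product(
        id=pid, name=name or pid.replace("_", " "), category=category,
        is_water=is_water, profile=profile,
    )


def worked_fixtures() -> list[Product]:
    """Hand-written products pinned at band boundaries and criteria edges.

    A dozen products whose scores, labels and compliance verdicts can
    be checked by hand against the published grids: an all-zero food, a
    product sitting at every maximum anchor of the new general-foods
    grid, boundary products for salt/protein/fiber, a water, and a few
    realistic drinks and burgers exercising routing, the sweetener
    penalty and the fortification criteria.
    """
    return [
        _fixture("zero_food", Category.meat_alt, 0.0),
        _fixture(
            "anchor_max_new", Category.meat_alt, 800.7,
            sugar_g=51, sfa_g=10, salt_g=4, protein_g=17, fiber_g=7.4, fvl_percent=80,
        ),
        _fixture(
            "salt_edge", Category.meat_alt, 150.0,
            salt_g=1.125, protein_g=10, sfa_g=1.0, fiber_g=4.0,
        ),
        _fixture(
            "high_salt_burger", Category.meat_alt, 180.0,
            salt_g=1.3, protein_g=12, sfa_g=1.2, sugar_g=1.5, fiber_g=5.0,
        ),
        _fixture("tap_water", Category.water, 0.0, is_water=True),
        _fixture(
            "plain_soy_drink", Category.milk_alt, 38.0,
            protein_g=3.4, sugar_g=0.5, sfa_g=0.4, salt_g=0.09, fiber_g=0.6,
            calcium_mg=120, vitb12_ug=0.38,
        ),
        _fixture(
            "sweet_oat_drink", Category.milk_alt, 60.0,
            protein_g=0.8, sugar_g=6.5, sfa_g=0.3, salt_g=0.1, fiber_g=0.8,
        ),
        _fixture(
            "nns_drink", Category.milk_alt, 20.0,
            protein_g=0.5, sugar_g=0.0, salt_g=0.05, nns_present=True,
        ),
        _fixture(
            "protein_border", Category.meat_alt, 120.0,
            protein_g=8.0, fiber_g=2.0, salt_g=0.5,
        ),
        _fixture(
            "fiber_border", Category.meat_alt, 140.0,
            protein_g=5.0, fiber_g=7.4, salt_g=0.5,
        ),
        _fixture(
            "fortified_burger", Category.meat_alt, 175.0,
            protein_g=15, sugar_g=1.0, sfa_g=1.0, salt_g=1.0, fiber_g=5.0,
            iron_mg=2.1, vitb12_ug=0.38,
        ),
        _fixture(
            "unfortified_schnitzel", Category.meat_alt, 220.0,
            protein_g=8.0, sugar_g=2.0, sfa_g=2.6, salt_g=1.5, fiber_g=3.0,
        ),
    ]
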