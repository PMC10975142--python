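"""Scoring engine: component points, routing, aggregation, labels."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriscore import (
    Category,
    NutrientProfile,
    Product,
    assign_label,
    compute_fsam_nps,
    route_product,
    score_table,
)
from nutriscore.profiles import KJ_PER_KCAL


def _product(category=Category.meat_alt, *, pid="p", is_water=False, **nutrients):
    kcal = nutrients.pop("energy_kcal", 100.0)
    profile = NutrientProfile(
        energy_kj=kcal * KJ_PER_KCAL, energy_kcal=kcal, **nutrients
    )
    return Product(id=pid, category=category, is_water=is_water, profile=profile)


class TestComponentPoints:
    """Published point levels above the maximum anchors."""

    @pytest.mark.parametrize(
        "version, component, value, expected",
        [
            ("old", "energy_kj", 4000, 10),
            ("new", "salt_g", 5.0, 20),
            ("new", "salt_g", 0.1, 0),
            ("old", "sfa_g", 12, 10),
            ("new", "sugar_g", 60, 15),
        ],
    )
    def test_negative_components(self, registry, version, component, value, expected):
        assert registry.get(version, "general_foods").negative[component].score(value) == expected

    @pytest.mark.parametrize(
        "version, component, value, expected",
        [
            ("new", "protein_g", 20, 7),
            ("new", "fiber_g", 8, 5),
            ("old", "protein_g", 8.0, 5),
            ("old", "fvl_percent", 85, 5),
            ("new", "fvl_percent", 50, 1),
        ],
    )
    def test_positive_components(self, registry, version, component, value, expected):
        assert registry.get(version, "general_foods").positive[component].score(value) == expected


class TestRouting:
    def test_milk_routes_by_version(self, registry):
        milk = _product(Category.milk_alt, energy_kcal=40)
        assert route_product(milk, "old").product_class == "general_foods"
        assert route_product(milk, "new").product_class == "beverages"

    @pytest.mark.parametrize(
        "category",
        [Category.meat_alt, Category.fish_alt, Category.coldcuts_alt,
         Category.dessert_alt, Category.cheese_alt],
    )
    def test_solid_categories_are_general_foods(self, category):
        product = _product(category)
        for version in ("old", "new"):
            assert route_product(product, version).product_class == "general_foods"

    def test_cheese_not_given_a_special_scale(self, registry):
        spec = route_product(_product(Category.cheese_alt), "new")
        assert spec is registry.get("new", "general_foods")

    def test_unknown_version_rejected(self):
        with pytest.raises(ValueError):
            route_product(_product(), "2017")


class TestAggregation:
    def test_all_zero_profile_totals_zero(self, registry):
        profile = NutrientProfile(energy_kj=0, energy_kcal=0)
        b = compute_fsam_nps(profile, registry.get("old", "general_foods"))
        assert b.negative_points == 0
        assert b.positive_points == 0
        assert b.total == 0
        assert b.label == "B"

    def test_max_anchor_profile_new_foods(self, registry):
        """Every negative component at its maximum anchor: N = 10+15+10+20."""
        profile = NutrientProfile(
            energy_kj=3500, energy_kcal=3500 / KJ_PER_KCAL,
            sugar_g=60, sfa_g=12, salt_g=5, protein_g=20, fiber_g=8,
        )
        b = compute_fsam_nps(profile, registry.get("new", "general_foods"))
        assert b.negative_points == 55
        assert b.component_points["fiber_g"] == 5
        assert not b.protein_counted      # N >= 11 excludes protein
        assert b.total == 50

    def test_protein_rule_override_changes_total_arithmetically(self, registry):
        profile = NutrientProfile(
            energy_kj=3500, energy_kcal=3500 / KJ_PER_KCAL,
            sugar_g=60, sfa_g=12, salt_g=5, protein_g=20, fiber_g=8,
        )
        b = compute_fsam_nps(
            profile, registry.get("new", "general_foods"), protein_rule="always"
        )
        assert b.protein_counted
        assert b.total == 50 - 7

    def test_old_rule_max_fvl_rescues_protein(self, registry):
        """Old general foods count protein at N >= 11 when FVL is at max."""
        profile = NutrientProfile(
            energy_kj=3500, energy_kcal=3500 / KJ_PER_KCAL,
            sugar_g=50, sfa_g=12, salt_g=3, protein_g=10, fvl_percent=85,
        )
        spec = registry.get("old", "general_foods")
        b = compute_fsam_nps(profile, spec)
        assert b.negative_points >= 11
        assert b.protein_counted

    def test_nns_penalty_beverages_new_only(self, registry):
        profile = NutrientProfile(energy_kj=0, energy_kcal=0, nns_present=True, basis="100ml")
        b_new = compute_fsam_nps(profile, registry.get("new", "beverages"))
        assert b_new.component_points["nns"] == 4
        assert b_new.negative_points == 4
        b_old = compute_fsam_nps(profile, registry.get("old", "beverages"))
        assert "nns" not in b_old.component_points

    def test_totals_within_feasible_range(self, registry, synthetic_products):
        for version in ("old", "new"):
            breakdowns, errors = score_table(synthetic_products, version)
            assert not errors
            for b in breakdowns:
                spec = registry.get(version, b.product_class)  # type: ignore[arg-type]
                lo, hi = spec.score_range
                assert lo <= b.total <= hi

    @settings(max_examples=60, deadline=None)
    @given(
        kcal=st.floats(0, 900),
        sugar=st.floats(0, 80),
        sfa=st.floats(0, 40),
        salt=st.floats(0, 8),
        fiber=st.floats(0, 15),
        bump=st.floats(0.1, 5),
        version=st.sampled_from(["old", "new"]),
    )
    def test_monotone_in_negative_nutrients_and_fiber(
        self, registry, kcal, sugar, sfa, salt, fiber, bump, version
    ):
        """More salt never lowers the total; more fiber never raises it.

        Protein is exempt: raising it can flip the counting conditional.
        """
        spec = registry.get(version, "general_foods")

        def total(**kw):
            base = dict(sugar_g=sugar, sfa_g=sfa, salt_g=salt, fiber_g=fiber)
            base.update(kw)
            profile = NutrientProfile(
                energy_kj=kcal * KJ_PER_KCAL, energy_kcal=kcal, **base
            )
            return compute_fsam_nps(profile, spec).total

        assert total(salt_g=salt + bump) >= total()
        assert total(sugar_g=sugar + bump) >= total()
        assert total(fiber_g=fiber + bump) <= total()


class TestLabels:
    @pytest.mark.parametrize(
        "total, version, expected",
        [(-1, "old", "A"), (0, "old", "B"), (2, "old", "B"), (3, "old", "C"),
         (10, "old", "C"), (11, "old", "D"), (18, "old", "D"), (19, "old", "E"),
         (0, "new", "A"), (1, "new", "B"), (3, "new", "C"), (11, "new", "D"),
         (19, "new", "E")],
    )
    def test_general_foods_cutoffs(self, registry, total, version, expected):
        scale = registry.get(version, "general_foods").label_scale
        assert assign_label(total, scale) == expected

    @pytest.mark.parametrize(
        "total, version, expected",
        [(-5, "new", "B"), (2, "new", "B"), (3, "new", "C"), (6, "new", "C"),
         (7, "new", "D"), (9, "new", "D"), (10, "new", "E"),
         (1, "old", "B"), (2, "old", "C"), (5, "old", "C"), (6, "old", "D"),
         (9, "old", "D"), (10, "old", "E")],
    )
    def test_beverage_cutoffs_never_a_for_non_water(self, registry, total, version, expected):
        scale = registry.get(version, "beverages").label_scale
        assert assign_label(total, scale, is_water=False) == expected

    def test_waters_always_a_on_beverage_scales(self, registry):
        for version in ("old", "new"):
            scale = registry.get(version, "beverages").label_scale
            assert assign_label(15, scale, is_water=True) == "A"

    def test_label_partition_every_integer_has_one_letter(self, registry):
        for spec in registry.specs.values():
            scale = spec.label_scale
            for total in range(-20, 61):
                letters = [
                    let for let in "ABCDE"
                    if let in scale.cutoffs and scale._in_range(let, total)
                ]
                assert len(letters) == 1, (spec.version, spec.product_class, total)

    def test_non_integer_total_rejected(self, registry):
        scale = registry.get("old", "general_foods").label_scale
        with pytest.raises(ValueError):
            assign_label(1.5, scale)


class TestScoreTable:
    def test_empty_list(self):
        breakdowns, errors = score_table([], "old")
        assert breakdowns == [] and errors == []

    def test_milk_class_tag_differs_by_version(self):
        products = [_product(pid="a"), _product(Category.milk_alt, pid="b", energy_kcal=40)]
        old, _ = score_table(products, "old")
        new, _ = score_table(products, "new")
        assert [b.product_class for b in old] == ["general_foods", "general_foods"]
        assert [b.product_class for b in new] == ["general_foods", "beverages"]

    def test_deterministic(self, synthetic_products):
        a, _ = score_table(synthetic_products, "new")
        b, _ = score_table(synthetic_products, "new")
        assert a == b
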