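"""Membership evaluation, Mamdani inference and defuzzification numerics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from routemerit.binning import BinSpec
from routemerit.fuzzy import (
    FuzzyRule,
    FuzzyVariable,
    MembershipFunction,
    RuleBase,
    membership_degree,
    output_variable,
    three_level_variable,
    variable_from_binspec,
)


class TestMembershipFunction:
    @pytest.mark.parametrize(
        "x,expected",
        [(5.0, 1.0), (12.0, 0.0), (2.5, 0.5), (-1.0, 0.0), (7.5, 0.5)],
    )
    def test_triangle_piecewise_linear(self, x, expected):
        mf = MembershipFunction("m", (0, 5, 10))
        assert membership_degree(mf, x) == pytest.approx(expected)

    def test_trapezoid_plateau(self):
        mf = MembershipFunction("m", (0, 2, 6, 10))
        assert mf(2) == mf(4) == mf(6) == 1.0
        assert mf(1) == pytest.approx(0.5)

    def test_decreasing_vertices_rejected(self):
        with pytest.raises(ValueError):
            MembershipFunction("m", (3, 2, 5))


@pytest.fixture()
def simple_base():
    spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
    var = variable_from_binspec(spec)
    out = output_variable([12.5, 37.5, 62.5, 87.5])
    rules = [FuzzyRule((lab,), lab) for lab in var.labels()]
    return RuleBase([var], out, rules)


class TestMamdaniInference:
    def test_single_rule_centroid_is_apex(self, simple_base):
        # interior Moderate input -> only the Moderate rule fires; the clipped
        # symmetric output triangle keeps its centroid at the apex
        assert simple_base.infer([0.3]) == pytest.approx(37.5)
        assert simple_base.infer([0.4]) == pytest.approx(37.5)

    def test_out_of_universe_names_variable(self, simple_base):
        with pytest.raises(ValueError, match="'x'"):
            simple_base.infer([2.0])

    def test_arity_checked(self, simple_base):
        with pytest.raises(ValueError, match="expected 1 inputs"):
            simple_base.infer([0.1, 0.2])

    def test_unknown_consequent_rejected(self, simple_base):
        with pytest.raises(ValueError, match="unknown to output"):
            RuleBase(
                simple_base.inputs,
                simple_base.output,
                [FuzzyRule(("Weak",), "Stellar")],
            )

    def test_empty_rule_list_rejected(self, simple_base):
        with pytest.raises(ValueError, match="non-empty"):
            RuleBase(simple_base.inputs, simple_base.output, [])

    @given(st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_output_bounded_by_centroid_range(self, x):
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec)
        out = output_variable([12.5, 37.5, 62.5, 87.5])
        base = RuleBase([var], out, [FuzzyRule((lab,), lab) for lab in var.labels()])
        assert 12.5 - 1e-9 <= base.infer([x]) <= 87.5 + 1e-9

    def test_grid_doubling_changes_merit_below_tolerance(self):
        # a genuine two-category blend, scored on 1000 vs 2000 grid points
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec, preset="overlap50")
        out = output_variable([12.5, 37.5, 62.5, 87.5])
        rules = [FuzzyRule((lab,), lab) for lab in var.labels()]
        coarse = RuleBase([var], out, rules, defuzz="grid", grid_points=1000)
        fine = RuleBase([var], out, rules, defuzz="grid", grid_points=2000)
        for x in (0.2, 0.45, 0.6, 0.9):
            assert abs(coarse.infer([x]) - fine.infer([x])) < 1e-3

    def test_exact_centroid_matches_fine_grid(self):
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec, preset="overlap50")
        out = output_variable([12.5, 37.5, 62.5, 87.5])
        rules = [FuzzyRule((lab,), lab) for lab in var.labels()]
        exact = RuleBase([var], out, rules, defuzz="exact")
        grid = RuleBase([var], out, rules, defuzz="grid", grid_points=200001)
        for x in (0.2, 0.45, 0.6, 0.9):
            assert exact.infer([x]) == pytest.approx(grid.infer([x]), abs=1e-5)


class TestVariableConstruction:
    def test_range_preset_supports_meet_at_boundaries(self):
        spec = BinSpec("x", -1.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec, preset="range")
        # sentinel carries full Weak membership, maximum full Excellent
        assert var.memberships(-1.0)["Weak"] == 1.0
        assert var.memberships(1.0)["Excellent"] == 1.0
        # strictly interior points belong to exactly one category
        mus = var.memberships(0.3)
        assert sum(v > 0 for v in mus.values()) == 1

    def test_boundary_crisp_fallback(self):
        spec = BinSpec("x", -1.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec, preset="range")
        mus = var.memberships(0.5)  # exactly on the Moderate/Good boundary
        assert mus == {"Weak": 0.0, "Moderate": 1.0, "Good": 0.0, "Excellent": 0.0}

    def test_overlap50_is_partition_of_unity(self):
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        var = variable_from_binspec(spec, preset="overlap50")
        for x in np.linspace(0.15, 0.85, 17):
            assert sum(var.memberships(x).values()) == pytest.approx(1.0)

    def test_three_level_collapses_degenerate_bins(self):
        spec = BinSpec("b", 0.0, 0.0, 0.0, 0.0275, 0.177)
        var = three_level_variable(spec)
        assert var.labels() == ("Weak", "Good", "Excellent")
        assert var.memberships(0.0)["Weak"] == 1.0
        assert var.memberships(0.177)["Excellent"] == 1.0

    def test_unknown_preset_rejected(self):
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        with pytest.raises(ValueError, match="preset"):
            variable_from_binspec(spec, preset="zigzag")


def test_full_factorial_enumerates_cartesian_product():
    spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
    inputs = [
        FuzzyVariable(f"x{i}", v.universe, v.functions, v.binspec)
        for i, v in enumerate([variable_from_binspec(spec)] * 3)
    ]
    out = output_variable([12.5, 37.5, 62.5, 87.5])
    base = RuleBase.full_factorial(inputs, out, lambda combo: combo[0])
    assert len(base.rules) == 4**3
    assert len({r.antecedent for r in base.rules}) == 4**3


def test_score_table_preserves_order_and_handles_empty(simple_base):
    import pandas as pd

    records = pd.DataFrame({"x": [0.9, 0.1, 0.4]})
    scored = simple_base.score_table(records)
    assert list(scored.index) == [0, 1, 2]
    assert scored["merit"].between(0, 100).all()
    empty = simple_base.score_table(pd.DataFrame({"x": []}))
    assert empty.empty
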