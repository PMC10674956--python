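"""Rule-consequent calibration against worked examples and synthetic truth."""

import numpy as np
import pandas as pd
import pytest

from routemerit import fixtures
from routemerit.binning import BinSpec
from routemerit.calibrate import (
    CalibrationError,
    MeritModel,
    majority_consequent,
)
from routemerit.fuzzy import FuzzyRule, RuleBase, output_variable, variable_from_binspec


class TestWorkedExamples:
    """The printed merit tables are the calibration ground truth."""

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Glycine", 90.33333333),
            ("Inosine", 37.5),
            ("Citric acid", 90.33333333),
            ("cis-Aconitic acid", 37.5),
            ("L-Phenylalanine", 62.5),
            ("L-Lysine", 90.33333333),
        ],
    )
    def test_anchor_rows_reproduced(self, metabolite_fit, table7, name, expected):
        row = table7[table7.metabolite == name]
        merit = metabolite_fit.predict(row)["merit"].iloc[0]
        assert merit == pytest.approx(expected, abs=1e-3)

    def test_output_centroids_anchored_on_degenerate_merits(self, metabolite_fit):
        c = metabolite_fit.centroids
        assert c["Moderate"] == pytest.approx(37.5)
        assert c["Good"] == pytest.approx(62.5)
        assert c["Excellent"] == pytest.approx(90.33333333)
        assert all(metabolite_fit.anchored.values())

    def test_sentinel_rows_scored_not_rejected(self, metabolite_fit, table7):
        # metabolites absent from one network layer still get a merit
        absent = table7[(table7.w1 == -1) | (table7.w3 == -1)]
        merits = metabolite_fit.predict(absent)["merit"]
        assert merits.between(0, 100).all()

    def test_mgdin_absence_is_penalized_more_than_mmin_absence(
        self, metabolite_fit, table7
    ):
        # Calcium (absent from MMIN, excellent in MGDIN) scores high;
        # Maltotriose (moderate in MMIN, absent from MGDIN) scores low.
        pred = metabolite_fit.predict(table7).set_index(table7.metabolite)["merit"]
        assert pred["Calcium"] > 85
        assert pred["Maltotriose"] < 20

    def test_residual_report_complete(self, metabolite_fit):
        res = metabolite_fit.residuals
        assert len(res) == 55
        assert res["fitted"].between(0, 100).all()
        assert metabolite_fit.rmse < 5.0
        assert "category_w1" in res.columns

    def test_summary_mentions_key_quantities(self, metabolite_fit):
        text = metabolite_fit.summary()
        assert "RMSE" in text and "256" in text and "range" in text

    def test_homogeneous_interior_set(self, metabolite_fit):
        names = set(
            metabolite_fit.homogeneous_interior()["metabolite"]
        )
        # sentinel rows and boundary-sitting rows are excluded by construction
        assert names == {
            "Glycine",
            "Inosine",
            "Citric acid",
            "cis-Aconitic acid",
            "L-Phenylalanine",
            "L-Lysine",
            "L-Arginine",
        }


class TestRouteModel:
    def test_calibrates_and_reports_residuals(self, route_fit):
        assert len(route_fit.residuals) == 33
        assert route_fit.rmse < 10.0

    def test_degenerate_betweenness_has_three_functions(self, route_fit):
        names = {v.name: v for v in route_fit.rule_base.inputs}
        assert names["betweenness_impact"].labels() == ("Weak", "Good", "Excellent")

    def test_abc_transporters_residual_reported_not_asserted(self, route_fit, table9):
        row = table9[table9.pathway == "ABC transporters"]
        fitted = route_fit.predict(row)["merit"].iloc[0]
        printed = row["merit"].iloc[0]
        assert np.isfinite(fitted)
        resid = route_fit.residuals.loc[
            route_fit.residuals.pathway == "ABC transporters", "residual"
        ].iloc[0]
        assert resid == pytest.approx(fitted - printed)


class TestSyntheticRecovery:
    """Exact consequent recovery from a known random rule base."""

    def test_consequents_recovered_by_per_rule_search(self):
        rng = np.random.default_rng(4)
        spec = BinSpec("x", 0.0, 0.25, 0.5, 0.75, 1.0)
        labels = ("Weak", "Moderate", "Good", "Excellent")
        variables = [
            variable_from_binspec(BinSpec(f"x{i}", 0.0, 0.25, 0.5, 0.75, 1.0))
            for i in range(2)
        ]
        out = output_variable([10.0, 37.5, 62.5, 90.0])
        # random truth respecting the homogeneity constraint
        truth = {}
        for a in labels:
            for b in labels:
                truth[(a, b)] = a if a == b else labels[int(rng.integers(4))]
        base = RuleBase(
            variables, out, [FuzzyRule(k, v) for k, v in truth.items()]
        )
        # one example strictly inside every category cell -> unique activation
        mids = {"Weak": 0.1, "Moderate": 0.375, "Good": 0.625, "Excellent": 0.9}
        rows = [
            {"x0": mids[a], "x1": mids[b], "merit": base.infer([mids[a], mids[b]])}
            for a in labels
            for b in labels
        ]
        fit = MeritModel(
            pd.DataFrame(rows),
            input_columns=["x0", "x1"],
            binspecs={f"x{i}": BinSpec(f"x{i}", 0.0, 0.25, 0.5, 0.75, 1.0) for i in range(2)},
        ).fit()
        fitted = {
            r.antecedent: r.consequent for r in fit.rule_base.rules
        }
        recovered = sum(fitted[k] == truth[k] for k in truth)
        assert recovered == len(truth)
        assert fit.max_abs_residual < 1e-9

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MeritModel(pd.DataFrame(), input_columns=["x"])


def test_majority_consequent_votes_and_tiebreaks():
    assert majority_consequent(("Weak", "Weak", "Good", "Weak")) == "Weak"
    # 2-2 tie goes to the lower category with equal weights
    assert majority_consequent(("Weak", "Weak", "Good", "Good")) == "Weak"
    # weighted votes can flip the tie
    assert (
        majority_consequent(("Weak", "Weak", "Good", "Good"), (1, 1, 2, 2)) == "Good"
    )


def test_preset_selection_prefers_lower_rmse():
    best = MeritModel.select_preset(
        lambda preset: fixtures.metabolite_merit_model(preset)
    )
    assert best.model.preset == "range"
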