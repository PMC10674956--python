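"""Calibration of merit rule bases against worked examples.

The published merit tables print, for every record, the four indicator values
and the merit the original fuzzy system produced -- but not the rule
consequents, which lived in a supplementary file.  Calibration reconstructs
them: the input membership geometry is fixed from the quartile bin ranges, the
output-category centroids are anchored on the *degenerate* examples (records
whose four indicators all fall in one category, which a Mamdani system maps
exactly to that category's centroid), and each rule's consequent is chosen by
exhaustive per-rule search minimizing the squared error of the fitted system
against the printed merits.  Rules with a homogeneous antecedent (all inputs
in category X) are constrained to conclude X.

The API follows the estimator/results convention: build a :class:`MeritModel`
from a table of examples, call :meth:`~MeritModel.fit`, inspect the returned
:class:`MeritModelResults` (rule base, residuals, ``summary()``).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import ASCENDING_LABELS, BinSpec, assign_category, quartile_boundaries
from .fuzzy import (
    FuzzyRule,
    FuzzyVariable,
    RuleBase,
    output_variable,
    three_level_variable,
    variable_from_binspec,
)

logger = logging.getLogger(__name__)

#: fallback output centroids when a category has no degenerate example
DEFAULT_CENTROIDS = (12.5, 37.5, 62.5, 87.5)

_QUALITY = {label: i for i, label in enumerate(ASCENDING_LABELS)}


class CalibrationError(RuntimeError):
    """Raised when the constraint set cannot be satisfied; carries the conflicts."""

    def __init__(self, message: str, conflicts: pd.DataFrame | None = None):
        super().__init__(message)
        self.conflicts = conflicts


def _mode_or_median(values: Sequence[float]) -> float:
    """Most frequent value (ties -> smallest); median when all values are unique."""
    rounded = [round(float(v), 9) for v in values]
    counts = Counter(rounded)
    top = max(counts.values())
    if top > 1:
        return min(v for v, c in counts.items() if c == top)
    return float(np.median(rounded))


def majority_consequent(
    antecedent: tuple[str, ...], weights: Sequence[float] | None = None
) -> str:
    """Weighted majority vote over antecedent quality labels; ties go low."""
    weights = list(weights) if weights is not None else [1.0] * len(antecedent)
    votes: dict[int, float] = {}
    for cat, w in zip(antecedent, weights):
        votes[_QUALITY[cat]] = votes.get(_QUALITY[cat], 0.0) + w
    best = max(votes.values())
    return ASCENDING_LABELS[min(q for q, v in votes.items() if v == best)]


class MeritModel:
    """Mamdani merit system with calibratable rule consequents.

    Parameters
    ----------
    examples:
        Table with one column per input indicator plus a ``merit`` column of
        printed target merits.
    binspecs:
        One :class:`~routemerit.binning.BinSpec` per input column.  When
        omitted, quartile boundaries are recomputed from the example columns
        themselves under the default convention.
    preset:
        Input membership geometry (``"range"`` or ``"overlap50"``); see
        :func:`routemerit.fuzzy.variable_from_binspec`.
    three_level:
        Names of input columns whose two lowest bins are degenerate and which
        therefore carry only Weak/Good/Excellent functions.
    heuristic_weights:
        Per-input voting weights for the consequents of rules never activated
        by an example (default: equal weights).
    """

    def __init__(
        self,
        examples: pd.DataFrame,
        input_columns: Sequence[str],
        binspecs: Mapping[str, BinSpec] | None = None,
        target_column: str = "merit",
        preset: str = "range",
        output_shape: str = "triangular",
        three_level: Sequence[str] = (),
        heuristic_weights: Sequence[float] | None = None,
        defuzz: str = "exact",
    ) -> None:
        if examples.empty:
            raise ValueError("examples table is empty")
        self.examples = examples.reset_index(drop=True)
        self.input_columns = list(input_columns)
        self.target_column = target_column
        self.preset = preset
        self.output_shape = output_shape
        self.heuristic_weights = heuristic_weights
        if binspecs is None:
            binspecs = {
                c: quartile_boundaries(self.examples[c].to_numpy(), name=c)
                for c in self.input_columns
            }
        self.binspecs = dict(binspecs)
        self.variables: list[FuzzyVariable] = [
            three_level_variable(self.binspecs[c], preset)
            if c in set(three_level)
            else variable_from_binspec(self.binspecs[c], preset)
            for c in self.input_columns
        ]
        self.defuzz = defuzz

    # ------------------------------------------------------------------ fit
    def fit(self, max_passes: int = 10) -> "MeritModelResults":
        df = self.examples
        targets = df[self.target_column].to_numpy(dtype=float)

        # crisp category of every input of every example
        crisp = pd.DataFrame(
            {
                c: [assign_category(v, self.binspecs[c]) for v in df[c]]
                for c in self.input_columns
            }
        )

        # --- anchor output centroids on degenerate (homogeneous) examples
        anchor_rows: dict[str, list[float]] = {c: [] for c in ASCENDING_LABELS}
        for i in range(len(df)):
            cats = set(crisp.iloc[i])
            if len(cats) == 1:
                anchor_rows[next(iter(cats))].append(targets[i])
        centroids = []
        anchored = {}
        for j, label in enumerate(ASCENDING_LABELS):
            vals = anchor_rows[label]
            c = _mode_or_median(vals) if vals else DEFAULT_CENTROIDS[j]
            anchored[label] = bool(vals)
            centroids.append(c)
        if sorted(centroids) != centroids or len(set(centroids)) != 4:
            conflicts = pd.DataFrame(
                [(label, v) for label in ASCENDING_LABELS for v in anchor_rows[label]],
                columns=["category", "printed_merit"],
            )
            raise CalibrationError(
                f"anchored output centroids are not increasing: {centroids}",
                conflicts,
            )
        output = output_variable(centroids, shape=self.output_shape)
        out_mfs = {mf.label: mf for mf in output.functions}

        # --- full-factorial rule keys and per-example activations
        keys = list(product(*(v.labels() for v in self.variables)))
        key_index = {k: i for i, k in enumerate(keys)}
        fired: list[list[tuple[int, float]]] = []
        for i in range(len(df)):
            mus = [
                var.memberships(float(df.iloc[i][c]))
                for var, c in zip(self.variables, self.input_columns)
            ]
            row_fired = []
            for k in keys:
                alpha = min(mu[cat] for mu, cat in zip(mus, k))
                if alpha > 0.0:
                    row_fired.append((key_index[k], alpha))
            if not row_fired:
                raise CalibrationError(
                    f"example {i} activates no rule under preset {self.preset!r}"
                )
            fired.append(row_fired)

        # --- initial consequents: homogeneity constraint + majority heuristic
        consequents: list[str] = []
        pinned: list[bool] = []
        for k in keys:
            if len(set(k)) == 1:
                consequents.append(k[0])
                pinned.append(True)
            else:
                consequents.append(majority_consequent(k, self.heuristic_weights))
                pinned.append(False)

        def predict_row(i: int) -> float:
            levels: dict[str, float] = {}
            for ridx, alpha in fired[i]:
                lab = consequents[ridx]
                levels[lab] = max(levels.get(lab, 0.0), alpha)
            clipped = [(out_mfs[lab], a) for lab, a in levels.items()]
            from .fuzzy import _exact_centroid  # local import to avoid cycle at top

            return _exact_centroid(clipped, output.universe)

        rows_by_rule: dict[int, list[int]] = {}
        for i, rf in enumerate(fired):
            for ridx, _ in rf:
                rows_by_rule.setdefault(ridx, []).append(i)

        # --- iterated exhaustive per-rule search (one pass suffices when each
        # example activates a single rule; more passes handle overlap presets)
        for _ in range(max_passes):
            changed = False
            for ridx, rows in sorted(rows_by_rule.items()):
                if pinned[ridx]:
                    continue
                best_label, best_sse = consequents[ridx], None
                for label in ASCENDING_LABELS:
                    consequents[ridx] = label
                    sse = sum((predict_row(i) - targets[i]) ** 2 for i in rows)
                    if best_sse is None or sse < best_sse - 1e-12:
                        best_label, best_sse = label, sse
                if best_label != consequents[ridx]:
                    changed = True
                consequents[ridx] = best_label
            if not changed:
                break

        rule_base = RuleBase(
            self.variables,
            output,
            [FuzzyRule(k, c) for k, c in zip(keys, consequents)],
            defuzz=self.defuzz,
        )
        fitted = np.array([predict_row(i) for i in range(len(df))])
        residuals = df.copy()
        residuals["fitted"] = fitted
        residuals["residual"] = fitted - targets
        for c in self.input_columns:
            residuals[f"category_{c}"] = crisp[c]
        data_rules = {keys[r] for r in rows_by_rule}
        return MeritModelResults(
            model=self,
            rule_base=rule_base,
            centroids=dict(zip(ASCENDING_LABELS, centroids)),
            anchored=anchored,
            residuals=residuals,
            n_data_rules=len(data_rules),
        )

    @staticmethod
    def select_preset(
        make_model, presets: Sequence[str] = ("range", "overlap50")
    ) -> "MeritModelResults":
        """Fit under each membership preset and keep the lowest-RMSE fit."""
        fits = []
        for preset in presets:
            try:
                fits.append(make_model(preset).fit())
            except CalibrationError as exc:
                logger.warning("preset %r failed to calibrate: %s", preset, exc)
        if not fits:
            raise CalibrationError("no membership preset produced a valid fit")
        return min(fits, key=lambda r: r.rmse)


@dataclass
class MeritModelResults:
    """Fitted rule base with residual diagnostics."""

    model: MeritModel
    rule_base: RuleBase
    centroids: dict[str, float]
    anchored: dict[str, bool]
    residuals: pd.DataFrame
    n_data_rules: int

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals["residual"] ** 2)))

    @property
    def max_abs_residual(self) -> float:
        return float(self.residuals["residual"].abs().max())

    def predict(self, records: pd.DataFrame) -> pd.DataFrame:
        """Score records; values beyond the calibration domain saturate into
        the nearest edge category."""
        return self.rule_base.score_table(
            records, self.model.input_columns, clamp=True
        )

    def homogeneous_interior(self) -> pd.DataFrame:
        """Examples whose four inputs are non-sentinel and strictly inside one
        category's open bin interval (the rows a Mamdani system must map to a
        pure category centroid)."""
        df = self.model.examples
        keep = []
        for i in range(len(df)):
            cats = []
            interior = True
            for c in self.model.input_columns:
                v = float(df.iloc[i][c])
                spec = self.model.binspecs[c]
                if v == -1 or v in spec.boundaries:
                    interior = False
                    break
                cats.append(assign_category(v, spec))
            if interior and len(set(cats)) == 1:
                keep.append(i)
        return self.residuals.iloc[keep]

    def summary(self) -> str:
        res = self.residuals["residual"]
        lines = [
            "Merit rule-base calibration",
            "=" * 43,
            f"examples:            {len(self.residuals)}",
            f"rules:               {len(self.rule_base.rules)}"
            f" ({self.n_data_rules} activated by data)",
            f"membership preset:   {self.model.preset}",
            f"output centroids:    "
            + ", ".join(f"{k}={v:.8g}" for k, v in self.centroids.items()),
            f"anchored categories: "
            + ", ".join(k for k, v in self.anchored.items() if v),
            f"RMSE:                {self.rmse:.4f}",
            f"max |residual|:      {self.max_abs_residual:.4f}",
            f"exact fits (<1e-3):  {(res.abs() < 1e-3).sum()}",
        ]
        worst = self.residuals.reindex(
            self.residuals["residual"].abs().sort_values(ascending=False).index
        ).head(5)
        id_cols = [
            c for c in worst.columns
            if worst[c].dtype == object and not c.startswith("category_")
        ]
        lines.append("worst residuals:")
        for _, row in worst.iterrows():
            ident = str(row[id_cols[0]]) if id_cols else "?"
            lines.append(
                f"  {ident:<30s} printed={row[self.model.target_column]:<12.6g}"
                f" fitted={row['fitted']:<12.6g} resid={row['residual']:+.4f}"
            )
        return "\n".join(lines)
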