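"""Mamdani fuzzy inference: membership functions, rule bases, defuzzification.

The engine follows the classic Mamdani recipe: rule activation by the minimum
of the antecedent membership degrees, implication by clipping the consequent
membership function at the activation level, aggregation of clipped sets by
pointwise maximum, and centroid defuzzification.  Because every membership
function here is piecewise linear, the centroid of the aggregate is computed
*exactly* by segment-wise integration between breakpoints; a uniform-grid
approximation is available for cross-checking (``method="grid"``).

Input variables are built from :class:`~routemerit.binning.BinSpec` quartile
boundaries.  The default ``"range"`` geometry gives each category a triangle
over exactly its own bin range (apex at the range midpoint, outer categories
anchored at the domain ends), so category supports do not overlap; the
``"overlap50"`` geometry instead places apexes at bin midpoints with feet at
the neighbouring apexes (a partition of unity).  The geometry choice is a
calibration preset, selected by residuals against worked examples, never
hard-coded as truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import ASCENDING_LABELS, SENTINEL, BinSpec, assign_category

logger = logging.getLogger(__name__)

PRESETS = ("range", "overlap50")


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular (3 vertices) or trapezoidal (4 vertices) membership function."""

    label: str
    vertices: tuple[float, ...]

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.vertices)
        if len(v) not in (3, 4):
            raise ValueError("membership function needs 3 or 4 vertices")
        if any(b < a for a, b in zip(v, v[1:])):
            raise ValueError(f"vertices of {self.label!r} must be non-decreasing: {v}")
        object.__setattr__(self, "vertices", v)

    @property
    def shape(self) -> str:
        return "triangular" if len(self.vertices) == 3 else "trapezoidal"

    def _abcd(self) -> tuple[float, float, float, float]:
        if len(self.vertices) == 3:
            a, b, c = self.vertices
            return a, b, b, c
        return self.vertices  # type: ignore[return-value]

    def __call__(self, x: float) -> float:
        a, b, c, d = self._abcd()
        if x < a or x > d:
            return 0.0
        if b <= x <= c:
            return 1.0
        if x < b:  # rising edge; a == b handled above
            return (x - a) / (b - a)
        return (d - x) / (d - c)

    def clipped_breakpoints(self, alpha: float) -> list[tuple[float, float]]:
        """Breakpoints ``(x, mu)`` of ``min(alpha, mf)``, in ascending x."""
        a, b, c, d = self._abcd()
        pts: list[tuple[float, float]] = [(a, min(alpha, 1.0) if a == b else 0.0)]
        if b > a:
            pts.append((a + (b - a) * alpha, alpha))
        pts.append((b, min(alpha, 1.0)))
        if c > b:
            pts.append((c, min(alpha, 1.0)))
        if d > c:
            pts.append((d - (d - c) * alpha, alpha))
        pts.append((d, min(alpha, 1.0) if c == d else 0.0))
        return pts


@dataclass(frozen=True)
class FuzzyVariable:
    """A named linguistic variable: a universe and ordered membership functions."""

    name: str
    universe: tuple[float, float]
    functions: tuple[MembershipFunction, ...]
    binspec: BinSpec | None = None

    def labels(self) -> tuple[str, ...]:
        return tuple(mf.label for mf in self.functions)

    def memberships(self, x: float) -> dict[str, float]:
        if not (self.universe[0] <= x <= self.universe[1]):
            raise ValueError(
                f"input {x} outside universe {self.universe} of variable {self.name!r}"
            )
        mu = {mf.label: mf(x) for mf in self.functions}
        if all(v == 0.0 for v in mu.values()) and self.binspec is not None:
            # x sits exactly on a shared boundary of two non-overlapping
            # categories; fall back to the crisp bin assignment.
            cat = assign_category(x, self.binspec)
            logger.debug(
                "input %s of %r has zero membership everywhere; crisp fallback to %r",
                x, self.name, cat,
            )
            mu[cat] = 1.0
        return mu


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedent categories (one per input; ``None`` is a wildcard) -> consequent."""

    antecedent: tuple[str | None, ...]
    consequent: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("rule weight must be in (0, 1]")


class RuleBase:
    """A Mamdani system: input variables, an output variable and rules."""

    def __init__(
        self,
        inputs: Sequence[FuzzyVariable],
        output: FuzzyVariable,
        rules: Sequence[FuzzyRule],
        defuzz: str = "exact",
        grid_points: int = 1001,
    ) -> None:
        if not rules:
            raise ValueError("rule list must be non-empty")
        out_labels = set(output.labels())
        for rule in rules:
            if len(rule.antecedent) != len(inputs):
                raise ValueError("rule arity does not match the number of inputs")
            for var, cat in zip(inputs, rule.antecedent):
                if cat is not None and cat not in var.labels():
                    raise ValueError(
                        f"antecedent category {cat!r} unknown to variable {var.name!r}"
                    )
            if rule.consequent not in out_labels:
                raise ValueError(f"consequent {rule.consequent!r} unknown to output")
        self.inputs = tuple(inputs)
        self.output = output
        self.rules = list(rules)
        self.defuzz = defuzz
        self.grid_points = int(grid_points)

    # ------------------------------------------------------------------ build
    @classmethod
    def full_factorial(
        cls,
        inputs: Sequence[FuzzyVariable],
        output: FuzzyVariable,
        consequent_fn,
        **kw,
    ) -> "RuleBase":
        """One rule per combination of input categories (4 inputs x 4 cats = 256)."""
        rules = [
            FuzzyRule(tuple(combo), consequent_fn(tuple(combo)))
            for combo in product(*(v.labels() for v in inputs))
        ]
        return cls(inputs, output, rules, **kw)

    # -------------------------------------------------------------- inference
    def activations(self, x: Sequence[float]) -> list[tuple[FuzzyRule, float]]:
        """Min-AND activation level of every rule with nonzero firing strength."""
        if len(x) != len(self.inputs):
            raise ValueError(
                f"expected {len(self.inputs)} inputs, got {len(x)}"
            )
        mus = [var.memberships(float(v)) for var, v in zip(self.inputs, x)]
        fired = []
        for rule in self.rules:
            alpha = rule.weight * min(
                (mu[cat] for mu, cat in zip(mus, rule.antecedent) if cat is not None),
                default=1.0,
            )
            if alpha > 0.0:
                fired.append((rule, alpha))
        return fired

    def infer(self, x: Sequence[float]) -> float:
        """Merit score: centroid of the max-aggregated clipped consequents."""
        fired = self.activations(x)
        if not fired:
            raise ValueError(f"no rule fires for input {tuple(x)}")
        levels: dict[str, float] = {}
        for rule, alpha in fired:
            levels[rule.consequent] = max(levels.get(rule.consequent, 0.0), alpha)
        clipped = [
            (mf, levels[mf.label])
            for mf in self.output.functions
            if levels.get(mf.label, 0.0) > 0.0
        ]
        if self.defuzz == "grid":
            return _grid_centroid(clipped, self.output.universe, self.grid_points)
        return _exact_centroid(clipped, self.output.universe)

    def score_table(
        self,
        records: pd.DataFrame,
        columns: Sequence[str] | None = None,
        clamp: bool = False,
    ) -> pd.DataFrame:
        """Vectorized :meth:`infer` over a record table.

        Returns a frame with one merit per record plus the crisp category each
        input fell into, for audit.  Record order is preserved.  With
        ``clamp=True`` inputs beyond a variable's universe saturate into the
        nearest edge (the semantics for scoring data outside the calibration
        domain); sentinels are never clamped.
        """
        columns = list(columns if columns is not None else (v.name for v in self.inputs))
        out_rows = []
        for idx, row in records.iterrows():
            x = [float(row[c]) for c in columns]
            if clamp:
                x = [
                    v if v == -1.0 else min(max(v, var.universe[0]), var.universe[1])
                    for var, v in zip(self.inputs, x)
                ]
            try:
                merit = self.infer(x)
            except ValueError as exc:
                raise ValueError(f"record {idx}: {exc}") from exc
            cats = {
                f"category_{var.name}": (
                    assign_category(v, var.binspec) if var.binspec is not None else ""
                )
                for var, v in zip(self.inputs, x)
            }
            out_rows.append({"merit": merit, **cats})
        return pd.DataFrame(out_rows, index=records.index)

    # ------------------------------------------------------------------ io
    def rules_frame(self) -> pd.DataFrame:
        names = [v.name for v in self.inputs]
        recs = [
            {**{n: (c if c is not None else "*") for n, c in zip(names, r.antecedent)},
             "consequent": r.consequent, "weight": r.weight}
            for r in self.rules
        ]
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# defuzzification helpers
# ---------------------------------------------------------------------------

def _aggregate(clipped: list[tuple[MembershipFunction, float]], x: float) -> float:
    return max((min(alpha, mf(x)) for mf, alpha in clipped), default=0.0)


def _exact_centroid(
    clipped: list[tuple[MembershipFunction, float]],
    universe: tuple[float, float],
) -> float:
    """Exact centroid of ``max_i min(alpha_i, mf_i)`` on the universe.

    The aggregate is piecewise linear; its breakpoints are the clipped-MF
    vertices plus pairwise intersections of the MF edges.  Between consecutive
    breakpoints the trapezoid rule is exact.
    """
    lo, hi = universe
    xs: set[float] = {lo, hi}
    segments = []
    for mf, alpha in clipped:
        pts = mf.clipped_breakpoints(alpha)
        xs.update(p[0] for p in pts)
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x1 > x0:
                slope = (y1 - y0) / (x1 - x0)
                segments.append((x0, x1, slope, y0 - slope * x0))
    # pairwise intersections of linear pieces from different MFs
    for i in range(len(segments)):
        x0a, x1a, sa, ia = segments[i]
        for j in range(i + 1, len(segments)):
            x0b, x1b, sb, ib = segments[j]
            if sa == sb:
                continue
            xc = (ib - ia) / (sa - sb)
            if max(x0a, x0b) < xc < min(x1a, x1b):
                xs.add(xc)
    grid = sorted(x for x in xs if lo <= x <= hi)
    area = 0.0
    moment = 0.0
    for x0, x1 in zip(grid, grid[1:]):
        if x1 <= x0:
            continue
        m0 = _aggregate(clipped, x0)
        m1 = _aggregate(clipped, x1)
        # max of linear pieces crossing only at breakpoints -> linear inside
        w = x1 - x0
        area += 0.5 * (m0 + m1) * w
        moment += w * (m0 * (2 * x0 + x1) + m1 * (x0 + 2 * x1)) / 6.0
    if area <= 0.0:
        raise ValueError("aggregate membership has zero area")
    return moment / area


def _grid_centroid(
    clipped: list[tuple[MembershipFunction, float]],
    universe: tuple[float, float],
    n: int,
) -> float:
    x = np.linspace(universe[0], universe[1], n)
    mu = np.zeros_like(x)
    for mf, alpha in clipped:
        a, b, c, d = mf._abcd()
        rise = np.ones_like(x) if b == a else np.clip((x - a) / (b - a), 0, 1)
        fall = np.ones_like(x) if d == c else np.clip((d - x) / (d - c), 0, 1)
        mu = np.maximum(mu, np.minimum(alpha, np.minimum(rise, fall)))
    s = mu.sum()
    if s <= 0:
        raise ValueError("aggregate membership has zero area")
    return float((x * mu).sum() / s)


# ---------------------------------------------------------------------------
# building variables from bin specs
# ---------------------------------------------------------------------------

def variable_from_binspec(
    spec: BinSpec,
    preset: str = "range",
    output_shape: str = "triangular",
) -> FuzzyVariable:
    """Turn quartile boundaries into a 4-function linguistic variable.

    ``"range"``: each category's function spans exactly its bin range; the two
    outer categories peak at the domain ends (so the ``-1`` sentinel carries
    full Weak membership and the column maximum full Excellent membership) and
    the two inner categories are symmetric triangles over their range.
    Supports meet only at the shared boundaries.

    ``"overlap50"``: apexes at the bin midpoints, feet at the neighbouring
    apexes -- adjacent categories overlap and memberships sum to one between
    the outer apexes.
    """
    b = spec.boundaries
    labels = list(ASCENDING_LABELS)
    if spec.orientation == "descending":
        labels = labels[::-1]
    if preset == "range":
        mfs = [
            MembershipFunction(labels[0], (b[0], b[0], b[1])),
            MembershipFunction(labels[1], (b[1], 0.5 * (b[1] + b[2]), b[2])),
            MembershipFunction(labels[2], (b[2], 0.5 * (b[2] + b[3]), b[3])),
            MembershipFunction(labels[3], (b[3], b[4], b[4])),
        ]
    elif preset == "overlap50":
        mids = [0.5 * (b[i] + b[i + 1]) for i in range(4)]
        mfs = [
            MembershipFunction(labels[0], (b[0], mids[0], mids[1])),
            MembershipFunction(labels[1], (mids[0], mids[1], mids[2])),
            MembershipFunction(labels[2], (mids[1], mids[2], mids[3])),
            MembershipFunction(labels[3], (mids[2], mids[3], b[4])),
        ]
    else:
        raise ValueError(f"unknown membership preset {preset!r}")
    return FuzzyVariable(spec.name, (b[0], b[4]), tuple(mfs), binspec=spec)


def three_level_variable(spec: BinSpec, preset: str = "range") -> FuzzyVariable:
    """Variable with collapsed degenerate bins (e.g. betweenness impact).

    When the two lowest bin ranges are degenerate (``0 to 0``), the variable
    effectively has three categories: Weak concentrated at the degenerate
    value, Good over the next range and Excellent above.
    """
    b = spec.boundaries
    if not (b[0] == b[1] == b[2]):
        raise ValueError("three_level_variable expects two degenerate lower bins")
    mfs = (
        MembershipFunction("Weak", (b[0], b[0], b[3])),
        MembershipFunction("Good", (b[0], 0.5 * (b[0] + b[3]), b[3])),
        MembershipFunction("Excellent", (b[3], b[4], b[4])),
    )
    return FuzzyVariable(spec.name, (b[0], b[4]), mfs, binspec=spec)


def output_variable(
    centroids: Sequence[float],
    universe: tuple[float, float] = (0.0, 100.0),
    shape: str = "triangular",
    labels: Sequence[str] = ASCENDING_LABELS,
) -> FuzzyVariable:
    """Symmetric output functions centred on the calibrated category centroids.

    Symmetry about the centroid makes the defuzzified value of a single
    clipped function equal to its centroid at *every* activation level, which
    is what lets calibration anchor the centroids directly on the worked
    examples.  The common half-width is the largest value keeping every
    function symmetric inside the universe and adjacent supports disjoint.
    """
    c = [float(v) for v in centroids]
    if sorted(c) != c or len(c) != len(labels):
        raise ValueError("output centroids must be sorted, one per label")
    lo, hi = universe
    hw = min(
        min(ci - lo for ci in c),
        min(hi - ci for ci in c),
        0.5 * min(b - a for a, b in zip(c, c[1:])),
    )
    if hw <= 0:
        raise ValueError(f"cannot fit symmetric output functions around {c}")
    mfs = []
    for label, ci in zip(labels, c):
        if shape == "triangular":
            mfs.append(MembershipFunction(label, (ci - hw, ci, ci + hw)))
        else:
            mfs.append(
                MembershipFunction(label, (ci - hw, ci - hw / 2, ci + hw / 2, ci + hw))
            )
    return FuzzyVariable("merit", universe, tuple(mfs))


def membership_degree(mf: MembershipFunction, x: float) -> float:
    """Degree of membership of ``x`` in ``mf`` (total function, 0 outside support)."""
    return mf(float(x))
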