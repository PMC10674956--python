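"""Normalization, quartile binning and linguistic category assignment.

Raw network statistics (degrees, betweenness values, pathway impacts, FDRs)
are turned into four linguistic categories per indicator.  The bin boundaries
are the sample quartiles of the indicator, computed under a configurable
positional convention; the default ``"np1"`` convention places quartile ``p``
at position ``(n + 1) * p`` in the sorted sample, averaging the two bracketing
order statistics when the position is fractional.  This is the convention that
round-trips the packaged fixture tables exactly (see
:func:`calibrate_binning`).

A value of ``-1`` is a *sentinel* meaning "absent from this network layer",
which is distinct from a zero statistic.  Sentinels always fall in the lowest
category of an ascending bin spec, and whether they participate in quartile
computation is a calibration decision, not an assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENTINEL = -1.0

#: ascending category labels, worst to best
ASCENDING_LABELS = ("Weak", "Moderate", "Good", "Excellent")
#: labels used for pathway indicators in ascending-value order; for the three
#: impact indicators larger values are better (D worst .. A best), while for
#: FDR the orientation is reversed (A best at the smallest values).
GRADE_LABELS = ("D", "C", "B", "A")

QUANTILE_CONVENTIONS = ("np1", "linear", "median_inclusive", "median_exclusive")


class DegenerateInputError(ValueError):
    """All present values are zero -- nothing to normalize against."""


@dataclass(frozen=True)
class BinSpec:
    """Quartile bin boundaries for one indicator.

    ``orientation="ascending"`` means larger values map to better categories
    (Weak < Moderate < Good < Excellent); ``"descending"`` reverses the
    quality order so the smallest values are best (used for FDR).
    """

    name: str
    domain_min: float
    q1: float
    q2: float
    q3: float
    domain_max: float
    orientation: str = "ascending"
    convention: str = "np1"
    include_sentinels: bool = True

    def __post_init__(self) -> None:
        if not (self.domain_min <= self.q1 <= self.q2 <= self.q3 <= self.domain_max):
            raise ValueError(
                f"bin boundaries of {self.name!r} must be ordered within the domain: "
                f"{(self.domain_min, self.q1, self.q2, self.q3, self.domain_max)}"
            )
        if self.orientation not in ("ascending", "descending"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def boundaries(self) -> tuple[float, float, float, float, float]:
        return (self.domain_min, self.q1, self.q2, self.q3, self.domain_max)

    def labels(self) -> tuple[str, ...]:
        """Category labels in ascending *value* order."""
        if self.orientation == "ascending":
            return ASCENDING_LABELS
        return tuple(reversed(ASCENDING_LABELS))


def normalize_by_max(
    values: Mapping[str, float], absent: Iterable[str] = ()
) -> dict[str, float]:
    """Scale raw non-negative statistics by their maximum so the max maps to 1.

    Identifiers listed in ``absent`` receive the ``-1`` sentinel.  Scaling is
    by the maximum (not min-max): observed minima of real columns are nonzero
    while maxima are exactly 1, which max-scaling preserves.
    """
    absent = set(absent)
    present = {k: float(v) for k, v in values.items() if k not in absent}
    for k, v in present.items():
        if v < 0:
            raise ValueError(f"raw statistic of {k!r} is negative: {v}")
    if not present:
        raise DegenerateInputError("no present values to normalize")
    top = max(present.values())
    if top == 0:
        raise DegenerateInputError("all present values are zero")
    out = {k: v / top for k, v in present.items()}
    out.update({k: SENTINEL for k in absent})
    return out


def _positional_quantile(sorted_vals: np.ndarray, p: float, convention: str) -> float:
    """Quantile of a sorted sample under one positional convention."""
    x = sorted_vals
    n = len(x)
    if convention == "np1":
        h = (n + 1) * p
    elif convention == "linear":
        h = 1 + (n - 1) * p
    elif convention in ("median_inclusive", "median_exclusive"):
        # Tukey-style hinges: quartiles are medians of the lower/upper half,
        # including or excluding the overall median when n is odd.
        if p == 0.5:
            h = (n + 1) * 0.5
        else:
            if convention == "median_inclusive":
                m = (n + 1) // 2
            else:
                m = n // 2
            half = x[:m] if p < 0.5 else x[n - m:]
            return _positional_quantile(half, 0.5, "np1")
    else:
        raise ValueError(f"unknown quantile convention {convention!r}")
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    lo = min(max(lo, 1), n)
    hi = min(max(hi, 1), n)
    if lo == hi:
        return float(x[lo - 1])
    return float(x[lo - 1] + (h - lo) * (x[hi - 1] - x[lo - 1]))


def quartile_boundaries(
    values: Sequence[float],
    name: str = "",
    convention: str = "np1",
    include_sentinels: bool = True,
    orientation: str = "ascending",
) -> BinSpec:
    """Compute a :class:`BinSpec` from a sample of indicator values.

    ``include_sentinels`` controls whether ``-1`` entries enter the quartile
    computation; the domain always extends down to the sentinel when one is
    present so that sentinels remain assignable.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError(f"non-finite values in {name!r}")
    has_sentinel = bool((arr == SENTINEL).any())
    sample = arr if include_sentinels else arr[arr != SENTINEL]
    if sample.size < 4:
        raise ValueError(
            f"need at least 4 values to compute quartiles for {name!r}, got {sample.size}"
        )
    s = np.sort(sample)
    q1, q2, q3 = (_positional_quantile(s, p, convention) for p in (0.25, 0.5, 0.75))
    lo = float(arr.min()) if has_sentinel else float(sample.min())
    hi = float(sample.max()) if not include_sentinels else float(s.max())
    hi = max(hi, float(arr.max()))
    return BinSpec(
        name=name,
        domain_min=lo,
        q1=q1,
        q2=q2,
        q3=q3,
        domain_max=hi,
        orientation=orientation,
        convention=convention,
        include_sentinels=include_sentinels,
    )


def assign_category(value: float, spec: BinSpec) -> str:
    """Map a value to its linguistic category.

    Boundary values are assigned to the *lower* interval (a value equal to
    ``q2`` is Moderate, not Good); the bottom interval is closed on both
    sides.  The ``-1`` sentinel maps to the lowest-value category.
    """
    labels = spec.labels()
    if value == SENTINEL:
        return labels[0]
    if not (spec.domain_min <= value <= spec.domain_max):
        raise ValueError(
            f"value {value} outside domain [{spec.domain_min}, {spec.domain_max}] "
            f"of {spec.name!r}"
        )
    b = spec.boundaries
    for i in range(1, 4):
        if value <= b[i]:
            if value == b[i]:
                logger.debug(
                    "value %s of %r sits exactly on boundary %s; assigned to lower "
                    "category %r", value, spec.name, b[i], labels[i - 1]
                )
            return labels[i - 1]
    return labels[3]


def assign_grade(value: float, spec: BinSpec) -> str:
    """Like :func:`assign_category` but with A-D grades (A = best)."""
    cat = assign_category(value, spec)
    return GRADE_LABELS[ASCENDING_LABELS.index(cat)]


def calibrate_binning(
    table: pd.DataFrame,
    printed: Mapping[str, Sequence[float]],
    columns: Sequence[str] | None = None,
    atol: float = 1e-9,
) -> dict:
    """Grid-search quantile convention x sentinel policy against printed boundaries.

    ``printed`` maps column name to its three printed boundaries (q1, q2, q3).
    Returns the winning ``{"convention", "include_sentinels"}`` combination
    together with the per-column maximum absolute error of every combination.
    Raises ``ValueError`` when no combination reproduces all printed
    boundaries to within ``atol``.
    """
    columns = list(columns if columns is not None else printed.keys())
    report: dict[tuple[str, bool], float] = {}
    winner = None
    for conv, use_sent in product(QUANTILE_CONVENTIONS, (True, False)):
        worst = 0.0
        try:
            for col in columns:
                spec = quartile_boundaries(
                    table[col].to_numpy(), name=col, convention=conv,
                    include_sentinels=use_sent,
                )
                err = max(
                    abs(a - b)
                    for a, b in zip((spec.q1, spec.q2, spec.q3), printed[col])
                )
                worst = max(worst, err)
        except ValueError:
            worst = float("inf")
        report[(conv, use_sent)] = worst
        if worst <= atol and winner is None:
            winner = {"convention": conv, "include_sentinels": use_sent}
    if winner is None:
        raise ValueError(
            "no quantile convention / sentinel policy reproduces the printed "
            f"boundaries; best errors: {report}"
        )
    winner["errors"] = {f"{c}|sentinels={s}": e for (c, s), e in report.items()}
    return winner


def filter_significant(
    table: pd.DataFrame, alpha: float = 0.05, column: str = "fdr"
) -> pd.DataFrame:
    """Retain records whose FDR is strictly below ``alpha``."""
    if column not in table.columns:
        raise KeyError(f"no column {column!r} in table")
    return table[table[column] < alpha].reset_index(drop=True)
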