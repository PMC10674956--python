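"""Merit-weighted route x metabolite matrix assembly.

A metabolic route database starts as a 0/1 incidence matrix (route rows,
metabolite columns).  Each present-metabolite cell is then replaced by that
metabolite's fuzzy merit, and each route carries one fuzzy output merit of its
own.  The resulting matrix is the training table for the surrogate regressor
and the search space of the GA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class IncidenceMatrix:
    """0/1 membership of metabolites (columns) in routes (rows)."""

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.cells.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence cells must be 0 or 1")
        empty_rows = self.cells.index[vals.sum(axis=1) == 0].tolist()
        empty_cols = self.cells.columns[vals.sum(axis=0) == 0].tolist()
        if empty_rows:
            raise ValueError(f"routes without any metabolite: {empty_rows}")
        if empty_cols:
            raise ValueError(f"metabolites in no route: {empty_cols}")

    @property
    def routes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.cells.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IncidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index_label="route")


@dataclass
class RouteMatrix:
    """Incidence with merits substituted for presence, plus one output merit per route."""

    cells: pd.DataFrame
    output_merit: pd.Series

    def __post_init__(self) -> None:
        if not self.cells.index.equals(self.output_merit.index):
            raise ValueError("output_merit index must match the route rows")

    @property
    def routes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def n_routes(self) -> int:
        return len(self.cells.index)

    @property
    def n_metabolites(self) -> int:
        return len(self.cells.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out["output_merit"] = self.output_merit
        out.to_csv(path, sep="\t", index_label="route")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RouteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        if "output_merit" not in df.columns:
            raise ValueError("route matrix TSV must carry an output_merit column")
        return cls(df.drop(columns="output_merit"), df["output_merit"])


def build_route_matrix(
    incidence: IncidenceMatrix,
    metabolite_merits: Mapping[str, float],
    route_merits: Mapping[str, float],
) -> RouteMatrix:
    """Replace presence flags by metabolite merits and attach route output merits.

    ``cell(r, m) = merit(m)`` where the incidence is 1 and 0 elsewhere; row
    and column order of the incidence is preserved.
    """
    missing_m = [m for m in incidence.metabolites if m not in metabolite_merits]
    missing_r = [r for r in incidence.routes if r not in route_merits]
    if missing_m or missing_r:
        raise KeyError(
            f"missing merits for metabolites {missing_m} and routes {missing_r}"
        )
    merits = np.array([float(metabolite_merits[m]) for m in incidence.metabolites])
    cells = incidence.cells.to_numpy(dtype=float) * merits[None, :]
    out = pd.Series(
        [float(route_merits[r]) for r in incidence.routes],
        index=incidence.cells.index,
        name="output_merit",
    )
    return RouteMatrix(
        pd.DataFrame(cells, index=incidence.cells.index, columns=incidence.cells.columns),
        out,
    )


def load_cpd_mapping(path: str | Path) -> dict[str, str]:
    """2-column TSV mapping compound codes to display names (no online lookups)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["code", "name"])
    return dict(zip(df["code"], df["name"]))
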