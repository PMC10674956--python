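"""Packaged fixture tables and ready-made model constructors.

The TSVs under ``routemerit/data`` transcribe the published worked-example
tables: the metabolite bin ranges (``table6``), the 55 metabolites with their
four normalized network weights and printed merits (``table7``), the pathway
indicator bin ranges (``table8``), the 33 significant pathways with impact /
FDR indicators and printed merits (``table9``), the final 25-metabolite
selection (``table1``) and the GA parameters (``table10``).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .binning import BinSpec
from .calibrate import MeritModel

METABOLITE_WEIGHT_COLUMNS = ["w1", "w2", "w3", "w4"]
ROUTE_INDICATOR_COLUMNS = [
    "degree_impact",
    "betweenness_impact",
    "closeness_impact",
    "fdr",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("routemerit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def fixture_meta() -> dict:
    with resources.files("routemerit.data").joinpath("fixture_meta.json").open() as fh:
        return json.load(fh)


def load_table1() -> list[str]:
    """The 25 metabolites selected by the surrogate-guided GA."""
    return _read("table1.tsv")["metabolite"].tolist()


def load_table6() -> dict[str, BinSpec]:
    """Printed quartile bin ranges of the four metabolite weight variables."""
    meta = fixture_meta()["binning"]
    out = {}
    for _, row in _read("table6.tsv").iterrows():
        out[row["variable"]] = BinSpec(
            name=row["variable"],
            domain_min=float(row["weak_lo"]),
            q1=float(row["q1"]),
            q2=float(row["q2"]),
            q3=float(row["q3"]),
            domain_max=float(row["hi"]),
            orientation="ascending",
            convention=meta["convention"],
            include_sentinels=meta["include_sentinels"],
        )
    return out


def load_table7() -> pd.DataFrame:
    """55 metabolites x four normalized weights (+ printed merit)."""
    return _read("table7.tsv")


def load_table8() -> dict[str, BinSpec]:
    """Printed quartile bin ranges of the four pathway indicators."""
    meta = fixture_meta()["binning"]
    out = {}
    for _, row in _read("table8.tsv").iterrows():
        out[row["variable"]] = BinSpec(
            name=row["variable"],
            domain_min=float(row["lo"]),
            q1=float(row["q1"]),
            q2=float(row["q2"]),
            q3=float(row["q3"]),
            domain_max=float(row["hi"]),
            orientation=row["orientation"],
            convention=meta["convention"],
            include_sentinels=meta["include_sentinels"],
        )
    return out


def load_table9() -> pd.DataFrame:
    """33 significant pathways x impact/FDR indicators (+ printed merit)."""
    return _read("table9.tsv")


def load_table10() -> dict[str, float]:
    """Published binary-GA parameters."""
    df = _read("table10.tsv")
    return {row["parameter"]: float(row["value"]) for _, row in df.iterrows()}


def metabolite_merit_model(preset: str = "range") -> MeritModel:
    """Merit model 1: four normalized weights -> metabolite merit (0-100).

    MMIN degree/betweenness votes carry half the weight of MGDIN ones in the
    consequent heuristic for rules never seen in the worked examples: the
    printed examples treat absence from the metabolite-metabolite layer as
    far less damaging than absence from the metabolite-gene-disease layer.
    """
    return MeritModel(
        load_table7(),
        input_columns=METABOLITE_WEIGHT_COLUMNS,
        binspecs=load_table6(),
        preset=preset,
        output_shape="triangular",
        heuristic_weights=(1.0, 1.0, 2.0, 2.0),
    )


def route_merit_model(preset: str = "range") -> MeritModel:
    """Merit model 2: pathway impact/FDR indicators -> route output merit.

    Betweenness impact has two degenerate lower bins (``0 to 0``) and is
    represented with three membership functions; the FDR variable has reversed
    orientation (smallest values are best).  The output uses trapezoidal
    functions.
    """
    return MeritModel(
        load_table9(),
        input_columns=ROUTE_INDICATOR_COLUMNS,
        binspecs=load_table8(),
        preset=preset,
        output_shape="trapezoidal",
        three_level=("betweenness_impact",),
    )
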