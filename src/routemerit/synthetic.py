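"""Synthetic data with the statistical shape the pipeline stages assume.

The published study's route x metabolite incidence and raw network statistics
live in a supplementary file that is not part of the printed tables, so the
package ships a generator instead: scale-free interaction layers (preferential
attachment) whose degree/betweenness statistics are max-normalized into the
four weight columns (with ~10% ``-1`` absence sentinels per layer), pathway
indicators whose magnitudes mimic the printed indicator table (log-uniform
FDRs spanning 1e-27..5e-2, impacts up to ~0.7), and a Bernoulli incidence
matrix repaired to have no empty row or column.  Everything derives from one
global seed through fixed-key child streams, so adding a component never
perturbs existing ones and a bundle regenerates bit-for-bit from its
manifest.

:func:`gen_planted_optimum` rewrites a bundle around a hidden metabolite
subset with additive effects — the ground truth for surrogate/GA recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .binning import normalize_by_max, quartile_boundaries
from .routes import IncidenceMatrix

_STREAMS = {
    "graph_mmin": 0,
    "graph_mgdin": 1,
    "absence": 2,
    "indicators": 3,
    "incidence": 4,
    "planted": 5,
}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class SyntheticBundle:
    """All artifacts one pipeline run needs, plus the manifest to remake them."""

    graph: nx.Graph  # metabolite-metabolite layer
    graph_mgdin: nx.Graph  # metabolite-gene-disease layer
    weights: pd.DataFrame  # metabolite x (w1..w4), -1 sentinels
    indicators: pd.DataFrame  # route x indicator columns
    incidence: IncidenceMatrix
    seed: int
    manifest: dict
    planted: dict | None = None
    route_merits: pd.Series | None = None

    @property
    def metabolites(self) -> list[str]:
        return list(self.weights.index)

    @property
    def routes(self) -> list[str]:
        return list(self.indicators.index)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.weights.to_csv(outdir / "weights.tsv", sep="\t", index_label="metabolite")
        self.indicators.to_csv(outdir / "indicators.tsv", sep="\t", index_label="route")
        self.incidence.to_tsv(outdir / "incidence.tsv")
        nx.write_edgelist(self.graph, outdir / "graph_mmin.tsv", delimiter="\t", data=False)
        nx.write_edgelist(
            self.graph_mgdin, outdir / "graph_mgdin.tsv", delimiter="\t", data=False
        )
        if self.route_merits is not None:
            self.route_merits.to_csv(
                outdir / "route_merits.tsv", sep="\t", index_label="route", header=True
            )
        manifest = dict(self.manifest)
        if self.planted is not None:
            manifest["planted"] = {
                k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                for k, v in self.planted.items()
                if k in ("subset", "subset_size", "effect", "noise_sd", "seed")
            }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _scale_free_weights(
    names: list[str], absent: set[str], rng: np.random.Generator
) -> tuple[nx.Graph, dict[str, float], dict[str, float]]:
    present = [n for n in names if n not in absent]
    m = 2 if len(present) > 2 else 1
    g = nx.barabasi_albert_graph(len(present), m, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, dict(enumerate(present)))
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    w_deg = normalize_by_max({n: float(deg[n]) for n in present}, absent)
    w_btw = normalize_by_max({n: float(btw[n]) for n in present}, absent)
    return g, w_deg, w_btw


def gen_fixture_bundle(
    n_routes: int = 33,
    n_metabolites: int = 55,
    density: float = 0.15,
    seed: int = 0,
    absent_fraction: float = 0.1,
) -> SyntheticBundle:
    """Generate a full synthetic bundle of the published shape (33 x 55)."""
    if not (0.0 < density < 1.0):
        raise ValueError(
            f"density must lie strictly inside (0, 1); at {density} the no-empty "
            "row/column constraint cannot be satisfied sensibly"
        )
    if min(n_routes, n_metabolites) < 4:
        raise ValueError("need at least 4 routes and 4 metabolites")
    metabolites = [f"M{i:03d}" for i in range(1, n_metabolites + 1)]
    routes = [f"R{i:03d}" for i in range(1, n_routes + 1)]

    # disjoint absence sets per layer so every metabolite has one live pair
    rng_abs = _child_rng(seed, "absence")
    n_abs = int(round(absent_fraction * n_metabolites))
    shuffled = list(rng_abs.permutation(metabolites))
    absent_mmin = set(shuffled[:n_abs])
    absent_mgdin = set(shuffled[n_abs : 2 * n_abs])

    g1, w1, w2 = _scale_free_weights(metabolites, absent_mmin, _child_rng(seed, "graph_mmin"))
    g2, w3, w4 = _scale_free_weights(metabolites, absent_mgdin, _child_rng(seed, "graph_mgdin"))
    weights = pd.DataFrame(
        {
            "w1": [w1[m] for m in metabolites],
            "w2": [w2[m] for m in metabolites],
            "w3": [w3[m] for m in metabolites],
            "w4": [w4[m] for m in metabolites],
        },
        index=metabolites,
    )

    rng_ind = _child_rng(seed, "indicators")
    fdr = 10.0 ** rng_ind.uniform(np.log10(1e-27), np.log10(5e-2), size=n_routes)
    degree_impact = np.where(
        rng_ind.random(n_routes) < 0.15, 0.0, rng_ind.uniform(0.0, 0.5, size=n_routes)
    )
    betweenness_impact = np.where(
        rng_ind.random(n_routes) < 0.6, 0.0, rng_ind.uniform(0.0, 0.18, size=n_routes)
    )
    closeness_impact = rng_ind.uniform(0.06, 0.68, size=n_routes)
    indicators = pd.DataFrame(
        {
            "degree_impact": degree_impact,
            "betweenness_impact": betweenness_impact,
            "closeness_impact": closeness_impact,
            "fdr": fdr,
        },
        index=routes,
    )

    rng_inc = _child_rng(seed, "incidence")
    cells = (rng_inc.random((n_routes, n_metabolites)) < density).astype(int)
    for i in range(n_routes):  # repair, O(cells)
        if cells[i].sum() == 0:
            cells[i, rng_inc.integers(n_metabolites)] = 1
    for j in range(n_metabolites):
        if cells[:, j].sum() == 0:
            cells[rng_inc.integers(n_routes), j] = 1
    incidence = IncidenceMatrix(pd.DataFrame(cells, index=routes, columns=metabolites))

    manifest = {
        "n_routes": n_routes,
        "n_metabolites": n_metabolites,
        "density": density,
        "seed": seed,
        "absent_fraction": absent_fraction,
    }
    return SyntheticBundle(
        graph=g1,
        graph_mgdin=g2,
        weights=weights,
        indicators=indicators,
        incidence=incidence,
        seed=seed,
        manifest=manifest,
    )


def gen_planted_optimum(
    bundle: SyntheticBundle,
    subset_size: int,
    effect: float,
    noise_sd: float,
    seed: int,
) -> SyntheticBundle:
    """Plant a hidden high-merit metabolite subset with additive route effects.

    The planted metabolites' weight columns are pushed into the top quartile
    band (so their fuzzy merits land in the Excellent category), and the
    bundle's route output merits are rewritten as
    ``effect * coverage(planted) + N(0, noise_sd)`` clipped to [0, 100].
    Per-metabolite additive fitness weights (positive on the subset, negative
    elsewhere) are stored for exact-recovery checks.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_met = len(bundle.metabolites)
    if not (0 < subset_size < n_met):
        raise ValueError(f"subset_size must be in 1..{n_met - 1}")

    rng = _child_rng(seed, "planted")
    planted = sorted(rng.choice(bundle.metabolites, size=subset_size, replace=False))
    weights = bundle.weights.copy()
    for col in weights.columns:
        draws = rng.uniform(0.92, 1.0, size=subset_size)
        weights.loc[planted, col] = draws
        col_max = weights[col].max()
        weights[col] = weights[col].where(weights[col] == -1, weights[col] / col_max)
        spec = quartile_boundaries(weights[col].to_numpy(), name=col)
        low = weights.loc[planted, col] <= spec.q3
        if low.any():  # guarantee top-category placement
            weights.loc[low[low].index, col] = spec.domain_max

    inc = bundle.incidence.cells.to_numpy(dtype=float)
    mask = np.array([m in set(planted) for m in bundle.metabolites], dtype=float)
    coverage = inc @ mask / subset_size
    merits = np.clip(
        effect * coverage + rng.normal(0.0, noise_sd, size=len(coverage)), 0.0, 100.0
    )
    route_merits = pd.Series(merits, index=bundle.incidence.cells.index, name="output_merit")

    base = effect / subset_size
    pos = rng.uniform(0.5, 1.5, size=subset_size) * base
    neg = rng.uniform(0.25, 0.75, size=n_met - subset_size) * base
    fitness_weights = {}
    pi, ni = 0, 0
    for m in bundle.metabolites:
        if m in set(planted):
            fitness_weights[m] = float(pos[pi]); pi += 1
        else:
            fitness_weights[m] = -float(neg[ni]); ni += 1

    return SyntheticBundle(
        graph=bundle.graph,
        graph_mgdin=bundle.graph_mgdin,
        weights=weights,
        indicators=bundle.indicators,
        incidence=bundle.incidence,
        seed=bundle.seed,
        manifest=dict(bundle.manifest),
        planted={
            "subset": list(planted),
            "subset_size": subset_size,
            "effect": effect,
            "noise_sd": noise_sd,
            "seed": seed,
            "fitness_weights": fitness_weights,
        },
        route_merits=route_merits,
    )


def planted_fitness(bundle: SyntheticBundle) -> Callable[[np.ndarray], float]:
    """Deterministic additive fitness whose unique argmax is the planted subset."""
    if bundle.planted is None:
        raise ValueError("bundle has no planted optimum")
    w = np.array(
        [bundle.planted["fitness_weights"][m] for m in bundle.metabolites]
    )
    return lambda bits: float(np.asarray(bits, dtype=float) @ w)


def gen_from_manifest(manifest: dict) -> SyntheticBundle:
    """Rebuild a bundle bit-for-bit from its manifest."""
    manifest = dict(manifest)
    planted = manifest.pop("planted", None)
    bundle = gen_fixture_bundle(
        n_routes=manifest["n_routes"],
        n_metabolites=manifest["n_metabolites"],
        density=manifest["density"],
        seed=manifest["seed"],
        absent_fraction=manifest.get("absent_fraction", 0.1),
    )
    if planted:
        bundle = gen_planted_optimum(
            bundle,
            subset_size=planted["subset_size"],
            effect=planted["effect"],
            noise_sd=planted["noise_sd"],
            seed=planted["seed"],
        )
    return bundle
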