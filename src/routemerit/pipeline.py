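"""End-to-end orchestration: bin -> calibrate/score fuzzy models -> route matrix
-> surrogate -> GA selection.

The rule bases are always calibrated on the packaged worked-example tables
(the only source of consequent ground truth) and then applied to whichever
weight/indicator tables the run supplies -- the packaged ones, a synthetic
bundle, or user files.  A run writes per-stage outputs plus a machine-readable
report; all randomness funnels through the single global seed, and the
report's content digest is computed over a canonical core that excludes
wall-clock timings, so identical config + seed reproduce an identical digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .binning import quartile_boundaries
from .ga import GAConfig, decode_selection, run_binary_ga, surrogate_fitness
from .routes import IncidenceMatrix, build_route_matrix
from .surrogate import SurrogateConfig, train_surrogate
from .synthetic import gen_fixture_bundle

logger = logging.getLogger(__name__)

STAGES = ("binning", "metabolite_model", "route_model", "matrix", "surrogate", "ga")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration.

    ``preset="desk"`` keeps the surrogate at early-stopped desk-scale epochs;
    ``"paper"`` restores the long training schedule.  When no incidence path
    is given, a synthetic paper-shaped incidence is generated from the seed.
    """

    seed: int = 0
    outdir: str = "frm_run"
    preset: str = "desk"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    weights_path: str | None = None
    indicators_path: str | None = None
    incidence_path: str | None = None
    surrogate_epochs: int | None = None
    ga_iterations: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "frm_run")),
            preset=str(raw.get("preset", "desk")),
            weights_path=raw.get("weights"),
            indicators_path=raw.get("indicators"),
            incidence_path=raw.get("incidence"),
            surrogate_epochs=raw.get("surrogate_epochs"),
            ga_iterations=raw.get("ga_iterations"),
        )
        toggles = raw.get("stages", {})
        unknown = set(toggles) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggle(s): {sorted(unknown)}")
        cfg.stages = {s: bool(toggles.get(s, True)) for s in STAGES}
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.preset not in ("paper", "desk", "custom"):
            raise ValueError(f"unknown preset {self.preset!r}")
        for p in (self.weights_path, self.indicators_path, self.incidence_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "preset": config.preset,
        "stages": {},
        "outputs": {},
    }
    timings: dict[str, float] = {}
    artifacts: dict[str, object] = {}

    def record(path: Path) -> None:
        report["outputs"][path.name] = _digest(path)

    def stage_enabled(name: str) -> bool:
        if not config.stages.get(name, True):
            report["stages"][name] = {"status": "skipped"}
            return False
        return True

    def need(name: str, key: str):
        if key not in artifacts:
            raise DependencyError(
                f"stage {name!r} requires artifact {key!r}; enable its stage "
                "or supply the input file"
            )
        return artifacts[key]

    # ------------------------------------------------------------ inputs
    if config.weights_path:
        weights = pd.read_csv(config.weights_path, sep="\t", index_col=0)
    else:
        weights = fixtures.load_table7().set_index("metabolite")[
            fixtures.METABOLITE_WEIGHT_COLUMNS
        ]
    if config.indicators_path:
        indicators = pd.read_csv(config.indicators_path, sep="\t", index_col=0)
    else:
        indicators = fixtures.load_table9().set_index("pathway")[
            fixtures.ROUTE_INDICATOR_COLUMNS
        ]
    if config.incidence_path:
        incidence = IncidenceMatrix.from_tsv(config.incidence_path)
    else:
        bundle = gen_fixture_bundle(
            n_routes=len(indicators), n_metabolites=len(weights), seed=config.seed
        )
        incidence = IncidenceMatrix(
            pd.DataFrame(
                bundle.incidence.cells.to_numpy(),
                index=indicators.index,
                columns=weights.index,
            )
        )
        report["stages"]["inputs"] = {
            "incidence": "synthetic (no incidence file supplied)"
        }

    # ------------------------------------------------------------ binning
    if stage_enabled("binning"):
        t0 = time.perf_counter()
        specs = {
            c: quartile_boundaries(weights[c].to_numpy(), name=c)
            for c in weights.columns
        }
        ind_specs = {
            c: quartile_boundaries(
                indicators[c].to_numpy(),
                name=c,
                orientation="descending" if c == "fdr" else "ascending",
            )
            for c in indicators.columns
        }
        artifacts["binspecs"] = specs
        path = outdir / "binspecs.json"
        path.write_text(
            json.dumps(
                {
                    name: {
                        "boundaries": spec.boundaries,
                        "orientation": spec.orientation,
                        "convention": spec.convention,
                    }
                    for name, spec in {**specs, **ind_specs}.items()
                },
                indent=2,
            )
        )
        record(path)
        timings["binning"] = time.perf_counter() - t0
        report["stages"]["binning"] = {
            "status": "ok",
            "convention": fixtures.fixture_meta()["binning"]["convention"],
        }

    # ------------------------------------------------ metabolite merits
    if stage_enabled("metabolite_model"):
        t0 = time.perf_counter()
        res1 = fixtures.metabolite_merit_model().fit()
        scored = res1.predict(weights.reset_index()).set_index(weights.index)
        merits = scored["merit"]
        artifacts["metabolite_merits"] = merits
        path = outdir / "metabolite_merits.tsv"
        scored.to_csv(path, sep="\t", index_label="metabolite")
        record(path)
        timings["metabolite_model"] = time.perf_counter() - t0
        report["stages"]["metabolite_model"] = {
            "status": "ok",
            "calibration_rmse": round(res1.rmse, 6),
            "exact_fits": int((res1.residuals["residual"].abs() < 1e-3).sum()),
        }

    # ------------------------------------------------------ route merits
    if stage_enabled("route_model"):
        t0 = time.perf_counter()
        res2 = fixtures.route_merit_model().fit()
        scored = res2.predict(indicators.reset_index()).set_index(indicators.index)
        artifacts["route_merits"] = scored["merit"]
        path = outdir / "route_merits.tsv"
        scored.to_csv(path, sep="\t", index_label="route")
        record(path)
        timings["route_model"] = time.perf_counter() - t0
        report["stages"]["route_model"] = {
            "status": "ok",
            "calibration_rmse": round(res2.rmse, 6),
        }

    # ------------------------------------------------------------ matrix
    if stage_enabled("matrix"):
        t0 = time.perf_counter()
        merits = need("matrix", "metabolite_merits")
        route_merits = need("matrix", "route_merits")
        matrix = build_route_matrix(incidence, merits.to_dict(), route_merits.to_dict())
        artifacts["matrix"] = matrix
        path = outdir / "route_matrix.tsv"
        matrix.to_tsv(path)
        record(path)
        timings["matrix"] = time.perf_counter() - t0
        report["stages"]["matrix"] = {
            "status": "ok",
            "shape": [matrix.n_routes, matrix.n_metabolites],
        }

    # --------------------------------------------------------- surrogate
    if stage_enabled("surrogate"):
        t0 = time.perf_counter()
        matrix = need("surrogate", "matrix")
        if config.preset == "paper":
            scfg = SurrogateConfig.paper_preset(
                seed=config.seed, input_size=matrix.n_metabolites
            )
        else:
            scfg = SurrogateConfig(
                seed=config.seed,
                input_size=matrix.n_metabolites,
                epochs=config.surrogate_epochs or 2000,
            )
        trained = train_surrogate(matrix, scfg)
        artifacts["surrogate"] = trained
        path = outdir / "surrogate.npz"
        trained.save(path)
        record(path)
        timings["surrogate"] = time.perf_counter() - t0
        report["stages"]["surrogate"] = {
            "status": "ok",
            "best_val_loss": float(trained.best_val_loss),
            "best_epoch": trained.best_epoch,
            "epochs_run": int(len(trained.history)),
        }

    # ---------------------------------------------------------------- ga
    if stage_enabled("ga"):
        t0 = time.perf_counter()
        matrix = need("ga", "matrix")
        trained = need("ga", "surrogate")
        merit_vector = matrix.cells.to_numpy().max(axis=0)
        gcfg = GAConfig.table_preset(
            seed=config.seed,
            chromosome_length=matrix.n_metabolites,
            max_iterations=config.ga_iterations or 300,
        )
        best, history = run_binary_ga(
            surrogate_fitness(trained, merit_vector), gcfg
        )
        selection = decode_selection(best, matrix.metabolites)
        path = outdir / "ga_history.tsv"
        history.to_frame().to_csv(path, sep="\t", index=False)
        record(path)
        sel_path = outdir / "selection.json"
        sel_path.write_text(
            json.dumps(
                {
                    "selected": selection,
                    "count": len(selection),
                    "fitness": best.fitness,
                },
                indent=2,
            )
        )
        record(sel_path)
        timings["ga"] = time.perf_counter() - t0
        report["stages"]["ga"] = {
            "status": "ok",
            "selected_count": len(selection),
            "best_fitness": best.fitness,
            "evaluations": history.evaluations,
        }

    core = json.dumps(report, sort_keys=True, default=float)
    report["content_digest"] = hashlib.sha256(core.encode()).hexdigest()
    report["durations_s"] = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
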