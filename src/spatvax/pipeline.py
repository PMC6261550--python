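"""End-to-end orchestration of the district-level spatial analysis.

For each outcome the pipeline runs the full procedure: quantile classing,
global and local univariate Moran with cluster/significance labelling,
bivariate Moran against every predictor, OLS, residual Moran + LM
diagnostics, ML spatial lag and spatial error models, and AIC selection.
Artifacts are written as CSV/JSON tables and labelled GeoJSON layers.

Reproducibility: one global seed is expanded into independent per-outcome,
per-stage substreams (via ``numpy.random.SeedSequence`` keyed on the stage
and outcome names), so adding or reordering outcomes does not perturb the
permutation draws of the others, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import esda, spatmodels
from .geoweights import (
    PolygonLayer,
    build_queen_weights,
    read_polygon_layer,
    row_standardize,
    write_polygon_layer,
)
from .synthetic_data import OUTCOME_NAMES, PREDICTOR_NAMES

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "write_report_tables"]

log = logging.getLogger("spatvax.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and outcome."""


@dataclass
class PipelineConfig:
    layer_path: str
    attributes_csv: str
    id_field: str = "id"
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOME_NAMES))
    predictors: list[str] = field(default_factory=lambda: list(PREDICTOR_NAMES))
    permutations: int = 999
    alpha: float = 0.05
    quantiles: int = 5
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.outcomes:
            raise ValueError("outcome list is empty")
        if not self.predictors:
            raise ValueError("predictor list is empty")


@dataclass
class OutcomeReport:
    outcome: str
    quantiles: esda.QuantileClassing
    moran: esda.MoranResult
    lisa: esda.LisaResult
    clusters: dict
    bivariate: dict[str, esda.MoranResult]  # predictor -> result
    ols: spatmodels.OLSResult
    diagnostics: spatmodels.DiagnosticsResult
    slm: spatmodels.SpatialModelResult
    sem: spatmodels.SpatialModelResult
    comparison: spatmodels.ModelComparison


@dataclass
class PipelineReport:
    config: PipelineConfig
    ids: list[str]
    n: int
    n_dropped: int
    islands: list[str]
    outcomes: dict[str, OutcomeReport]


def _stage_seed(global_seed: int, outcome: str, stage: str) -> int:
    """Deterministic substream seed < 2^31, independent across stages."""
    ss = np.random.SeedSequence(
        entropy=global_seed,
        spawn_key=tuple(b for b in f"{outcome}/{stage}".encode()),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _load_inputs(config: PipelineConfig) -> tuple[PolygonLayer, pd.DataFrame]:
    layer = read_polygon_layer(config.layer_path, config.id_field)
    attrs = pd.read_csv(config.attributes_csv, dtype={0: str})
    idcol = attrs.columns[0]
    attrs = attrs.set_index(idcol)
    missing_units = [u for u in layer.ids if u not in attrs.index]
    if missing_units:
        raise PipelineError(f"attribute table missing units: {missing_units[:10]}")
    needed = list(config.outcomes) + list(config.predictors)
    absent = [c for c in needed if c not in attrs.columns]
    if absent:
        raise PipelineError(f"attribute table missing columns: {absent}")
    return layer, attrs.loc[layer.ids, needed]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis; see the module docstring for the stages."""
    layer, attrs = _load_inputs(config)

    # listwise deletion on the analysis columns; weights re-subset
    complete = attrs.dropna()
    n_dropped = len(attrs) - len(complete)
    if n_dropped:
        log.warning("dropping %d unit(s) with missing values", n_dropped)
    if len(complete) < 30:
        raise PipelineError(f"only {len(complete)} complete units; need >= 30")

    w_full = build_queen_weights(layer)
    if n_dropped:
        w_binary = w_full.subset(list(complete.index))
    else:
        w_binary = w_full
    # islands cannot enter the spatial regressions; drop them up front so
    # OLS, SLM and SEM share the same estimation set
    if w_binary.islands:
        log.warning("dropping %d island unit(s): %s", len(w_binary.islands), w_binary.islands[:10])
        keep = [u for u in w_binary.ids if u not in set(w_binary.islands)]
        complete = complete.loc[keep]
        w_binary = w_binary.subset(keep)
    w = row_standardize(w_binary)
    ids = list(complete.index)
    n = len(ids)

    Xmat = complete[config.predictors].to_numpy(dtype=float)
    reports: dict[str, OutcomeReport] = {}
    for outcome in config.outcomes:
        y = complete[outcome].to_numpy(dtype=float)
        try:
            quant = esda.quantile_classes(y, config.quantiles)
            moran = esda.moran_global(
                y, w, config.permutations, _stage_seed(config.seed, outcome, "moran")
            )
            lisa = esda.lisa_univariate(
                y, w, config.permutations,
                _stage_seed(config.seed, outcome, "lisa"), config.alpha,
            )
            clusters = esda.classify_clusters(lisa, config.alpha)
            bivariate = {
                pred: esda.moran_bivariate(
                    complete[pred].to_numpy(dtype=float), y, w, config.permutations,
                    _stage_seed(config.seed, outcome, f"bivariate/{pred}"),
                )
                for pred in config.predictors
            }
            ols = spatmodels.fit_ols(y, Xmat, names=config.predictors)
            diag = spatmodels.lm_diagnostics(
                ols, w, config.permutations,
                _stage_seed(config.seed, outcome, "residual-moran"),
            )
            slm = spatmodels.fit_spatial_lag(y, Xmat, w, names=config.predictors)
            sem = spatmodels.fit_spatial_error(y, Xmat, w, names=config.predictors)
            comparison = spatmodels.compare_models(ols, slm, sem)
        except Exception as exc:
            raise PipelineError(f"outcome {outcome!r}: {exc}") from exc
        reports[outcome] = OutcomeReport(
            outcome, quant, moran, lisa, clusters, bivariate, ols, diag, slm, sem, comparison
        )
        log.info(
            "outcome %s: I=%.3f, rho=%.3f, lambda=%.3f, selected=%s",
            outcome, moran.statistic, slm.spatial_param, sem.spatial_param, comparison.selected,
        )

    report = PipelineReport(
        config=config,
        ids=ids,
        n=n,
        n_dropped=n_dropped,
        islands=list(w_full.islands),
        outcomes=reports,
    )
    if config.outdir:
        write_report_tables(report, config.outdir, layer=layer)
    return report


def _fmt_cell(stat: float, p: float) -> str:
    return f"{stat:.6g} ({p:.6g})"


_CELL_RE = re.compile(r"^\s*(-?[0-9.eE+-]+)\s*\(\s*(-?[0-9.eE+-]+)\s*\)\s*$")


def parse_cell(cell: str) -> tuple[float, float]:
    """Parse a "statistic (p-value)" table cell back to numbers."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable cell {cell!r}")
    return float(m.group(1)), float(m.group(2))


def _model_rows(rep: OutcomeReport) -> pd.DataFrame:
    rows = []
    for term, est, se, st, p in zip(rep.ols.terms, rep.ols.beta, rep.ols.se, rep.ols.t, rep.ols.p):
        rows.append(("OLS", term, est, se, st, p))
    for model, fitres in (("SLM", rep.slm), ("SEM", rep.sem)):
        for term, est, se, st, p in zip(fitres.terms, fitres.beta, fitres.se, fitres.z, fitres.p):
            rows.append((model, term, est, se, st, p))
        pname = "rho" if fitres.kind == "lag" else "lambda"
        rows.append((model, pname, fitres.spatial_param, fitres.spatial_se,
                     fitres.spatial_z, fitres.spatial_p))
    df = pd.DataFrame(rows, columns=["model", "term", "estimate", "se", "stat", "p"])
    return df.round(6)


def write_report_tables(report: PipelineReport, outdir, layer: PolygonLayer | None = None) -> list[Path]:
    """Write the report artifacts; returns the list of files written.

    Per outcome: a coefficient table CSV (OLS/SLM/SEM rows), a model summary
    JSON, and — when the polygon layer is available — a GeoJSON with
    quantile class, LISA quadrant, pseudo p, cluster label and significance
    tier per unit. One shared bivariate Moran matrix CSV uses the
    "statistic (p)" cell format of the published tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    biv = pd.DataFrame(
        {
            out: {
                pred: _fmt_cell(res.statistic, res.pseudo_p)
                for pred, res in rep.bivariate.items()
            }
            for out, rep in report.outcomes.items()
        }
    )
    biv.index.name = "predictor"
    p = outdir / "bivariate_moran.csv"
    biv.to_csv(p)
    written.append(p)

    for out, rep in report.outcomes.items():
        p = outdir / f"models_{out}.csv"
        _model_rows(rep).to_csv(p, index=False)
        written.append(p)

        summary = {
            "outcome": out,
            "n": report.n,
            "global_moran": {
                "I": round(rep.moran.statistic, 6),
                "expected": round(rep.moran.expected_value, 6),
                "p_sim": rep.moran.pseudo_p,
                "permutations": rep.moran.permutations,
            },
            "clusters": {
                "hotspots": rep.clusters["hotspots"],
                "coldspots": rep.clusters["coldspots"],
                "outliers": rep.clusters["outliers"],
            },
            "models": {
                name: {
                    "loglik": round(ll, 6),
                    "AIC": round(aic, 6),
                    "fit": round(fit, 6),
                }
                for name, ll, aic, fit in (
                    ("OLS", rep.ols.loglik, rep.ols.aic, rep.ols.adj_r2),
                    ("SLM", rep.slm.loglik, rep.slm.aic, rep.slm.pseudo_r2),
                    ("SEM", rep.sem.loglik, rep.sem.aic, rep.sem.pseudo_r2),
                )
            },
            "rho": round(rep.slm.spatial_param, 6),
            "lambda": round(rep.sem.spatial_param, 6),
            "selected": rep.comparison.selected,
            "seed": report.config.seed,
            "permutations": report.config.permutations,
        }
        p = outdir / f"summary_{out}.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        written.append(p)

        if layer is not None:
            props = {}
            for k, uid in enumerate(report.ids):
                props[uid] = {
                    "quantile_class": int(rep.quantiles.classes[k]),
                    "quadrant": rep.lisa.quadrant[k],
                    "local_i": round(float(rep.lisa.local_i[k]), 6),
                    "p_sim": float(rep.lisa.pseudo_p[k]),
                    "cluster_label": rep.clusters["labels"][k],
                    "sig_tier": rep.clusters["sig_tier"][k],
                }
            keep = set(report.ids)
            sub = PolygonLayer(
                [u for u in layer.ids if u in keep],
                [nm for u, nm, _ in layer if u in keep],
                [g for u, _, g in layer if u in keep],
                crs_label=layer.crs_label,
            )
            p = outdir / f"clusters_{out}.geojson"
            write_polygon_layer(sub, p, properties=props)
            written.append(p)
    return written
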