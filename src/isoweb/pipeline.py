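"""End-to-end orchestration: TDF grid × prior grid → fits → comparison.

`run_model_grid` reproduces the study design of fitting one mixing model per
(TDF, prior) combination on identical consumer data, ranking them by
LOO/WAIC, and validating each TDF with the mixing-polygon test. Models that
fail the polygon test or do not converge are flagged in the comparison
table, never dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import data_io, mixing_model, polygon, priors, synthetic_data, tdf as tdf_mod
from .errors import ValidationError


@dataclass
class RunConfig:
    """Declarative description of one model-grid run."""

    seed: int
    consumers_path: Optional[str] = None  # default: simulate trout from the fixture
    sources_path: Optional[str] = None  # default: packaged six-source set
    biomass_path: Optional[str] = None  # default: synthetic log-uniform biomasses
    tdf_grid: tuple[str, ...] = ("calculated", "TDF2", "TDF3", "TDF4", "TDF5")
    prior_kinds: tuple[str, ...] = ("biomass", "uniform")
    chains: int = 3
    iterations: int = 30_000
    burn: int = 15_000
    thin: int = 10
    polygon_iterates: int = 1500
    n_consumers: int = 9
    method: str = "loo"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config must set a seed")
        presets = set(tdf_mod.load_tdf_presets())
        for name in self.tdf_grid:
            if name != "calculated" and name not in presets:
                raise ValidationError(f"unknown TDF preset {name!r}")
        for kind in self.prior_kinds:
            if kind not in ("uniform", "biomass"):
                raise ValidationError(f"unknown prior kind {kind!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("tdf_grid", "prior_kinds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class GridResult:
    """Artifacts of one model-grid run."""

    config: RunConfig
    comparison: pd.DataFrame
    posteriors: dict[str, mixing_model.DietPosterior]
    polygon_results: dict[str, polygon.PolygonResult]
    tdfs: dict[str, tdf_mod.TDFSpec]
    priors: dict[str, priors.DirichletPrior]
    consumers: list = field(default_factory=list)
    sources: list = field(default_factory=list)


def _load_inputs(config: RunConfig):
    if config.sources_path:
        sources = data_io.read_sources(config.sources_path)
    else:
        sources = synthetic_data.trout_diet_sources()
    if config.consumers_path:
        consumers = data_io.read_consumers(config.consumers_path)
    else:
        consumers = synthetic_data.simulated_trout_consumers(
            n=config.n_consumers, seed=config.seed
        )
    if config.biomass_path:
        biomass = data_io.read_biomass(config.biomass_path)
    else:
        biomass = synthetic_data.gen_biomass(
            [s.name for s in sources], seed=config.seed + 1
        )
    return consumers, sources, biomass


def _resolve_tdf(name: str, consumers, sources) -> tdf_mod.TDFSpec:
    if name == "calculated":
        mean = {
            "d13C": float(np.mean([c.d13C for c in consumers])),
            "d15N": float(np.mean([c.d15N for c in consumers])),
        }
        return tdf_mod.calc_tdf(mean, sources, name="calculated")
    return tdf_mod.load_tdf_presets()[name]


def run_model_grid(config: RunConfig) -> GridResult:
    """Fit every TDF × prior combination on identical data and rank them.

    The comparison table carries one row per model with the LOO/WAIC
    criterion columns plus ``polygon_pass``, ``converged`` and the config
    hash. A calculated TDF is derived from the loaded consumers' mean vs the
    loaded sources.
    """
    consumers, sources, biomass = _load_inputs(config)
    source_names = [s.name for s in sources]

    tdfs = {name: _resolve_tdf(name, consumers, sources) for name in config.tdf_grid}
    prior_map = {}
    for kind in config.prior_kinds:
        if kind == "uniform":
            prior_map[kind] = priors.uniform_prior(source_names)
        else:
            prior_map[kind] = priors.biomass_prior(source_names, biomass, neutral_fill=True)

    polygon_results = {
        name: polygon.polygon_test(
            sources, spec, consumers,
            iterates=config.polygon_iterates, seed=config.seed + 7,
        )
        for name, spec in tdfs.items()
    }

    posteriors: dict[str, mixing_model.DietPosterior] = {}
    fit_seed = config.seed
    for tdf_name, tdf_spec in tdfs.items():
        for kind in config.prior_kinds:
            model_name = f"{kind}+{tdf_name}"
            spec = mixing_model.MixingModelSpec(
                sources=sources, tdf=tdf_spec, prior=prior_map[kind], name=model_name
            )
            fit_seed += 1
            posteriors[model_name] = mixing_model.fit(
                spec, consumers,
                chains=config.chains, iterations=config.iterations,
                burn=config.burn, thin=config.thin, seed=fit_seed,
            )

    table = mixing_model.compare(list(posteriors.values()), method=config.method)
    tdf_of = {name: name.split("+", 1)[1] for name in posteriors}
    table["polygon_pass"] = [
        polygon_results[tdf_of[m]].all_pass for m in table["model"]
    ]
    table["converged"] = [posteriors[m].converged for m in table["model"]]
    table["config_hash"] = config.hash()

    return GridResult(
        config=config, comparison=table, posteriors=posteriors,
        polygon_results=polygon_results, tdfs=tdfs, priors=prior_map,
        consumers=consumers, sources=sources,
    )


# ---------------------------------------------------------------------------
# reporting

def _fmt_df(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def report(artifacts: dict) -> str:
    """Human-readable run summary; absent stages are noted, not fatal.

    Recognised keys: ``tdfs`` (name → TDFSpec), ``priors`` (name →
    DirichletPrior), ``comparison`` (DataFrame), ``posteriors`` (name →
    DietPosterior), ``polygon`` (name → PolygonResult), ``trophic`` (list of
    TrophicResult), ``topology`` (WebMetrics). A :class:`GridResult` can be
    passed directly.
    """
    if isinstance(artifacts, GridResult):
        artifacts = {
            "tdfs": artifacts.tdfs, "priors": artifacts.priors,
            "comparison": artifacts.comparison, "posteriors": artifacts.posteriors,
            "polygon": artifacts.polygon_results,
        }
    if not artifacts:
        raise ValidationError("report: no completed stages supplied")
    lines: list[str] = ["# isoweb run report", ""]

    def section(title: str, key: str, render) -> None:
        lines.append(f"## {title}")
        if key in artifacts and artifacts[key] is not None:
            render(artifacts[key])
        else:
            lines.append("(stage not run)")
        lines.append("")

    def _tdfs(tdfs):
        rows = [{"name": t.name, "dC": t.mean_dC, "sd_dC": t.sd_dC,
                 "dN": t.mean_dN, "sd_dN": t.sd_dN, "provenance": t.provenance}
                for t in tdfs.values()]
        lines.append(_fmt_df(pd.DataFrame(rows)))

    def _priors(pr):
        for name, p in pr.items():
            alpha = ", ".join(f"{a:.3f}" for a in p.alpha)
            lines.append(f"{name} ({p.kind}): alpha = [{alpha}]")

    def _cmp(table):
        lines.append(_fmt_df(table))

    def _post(posteriors):
        for name, post in posteriors.items():
            lines.append(f"{name}:")
            order = np.argsort(post.p_mean)[::-1]
            p = post.draws["p"].reshape(-1, len(post.spec.source_names))
            for i in order:
                lines.append(
                    f"  {post.spec.source_names[i]}: "
                    f"{post.p_mean[i]:.3f} ± {p[:, i].std(ddof=1):.3f}"
                )

    def _poly(results):
        for name, res in results.items():
            status = "pass" if res.all_pass else "FAIL"
            lines.append(
                f"{name}: min inclusion prob "
                f"{res.consumer_probs.min():.3f} -> {status}"
            )

    def _trophic(results):
        rows = [{"consumer": r.consumer, "TP": r.trophic_position,
                 "alpha_littoral": r.alpha_littoral, "delta_n": r.delta_n}
                for r in results]
        lines.append(_fmt_df(pd.DataFrame(rows)))

    def _topo(metrics):
        lines.append(json.dumps(metrics.to_dict(), indent=2, default=str))

    section("Trophic discrimination factors", "tdfs", _tdfs)
    section("Dirichlet priors", "priors", _priors)
    section("Model comparison", "comparison", _cmp)
    section("Diet posteriors (mean ± SD, sorted)", "posteriors", _post)
    section("Mixing-polygon validation", "polygon", _poly)
    section("Trophic positions", "trophic", _trophic)
    section("Food-web topology", "topology", _topo)
    return "\n".join(lines)
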