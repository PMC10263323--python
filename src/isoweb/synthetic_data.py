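"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators make the pipeline fully testable without field data:

* :func:`gen_mixing_dataset` draws consumers from the exact generative model
  the mixing sampler inverts (known diet p*, ILR-space consumer random
  effect, multiplicative error), so parameter recovery can be checked
  against a known truth.
* :func:`gen_foodweb` builds node-attributed 0/1 webs whose generating
  categories are recoverable by :func:`isoweb.topology.classify_nodes`, at a
  requested connectance.
* :func:`gen_biomass` draws source biomasses log-uniformly over two orders
  of magnitude, mimicking the strong skew of real standing-stock tables.

:func:`table1_fixture` returns the packaged two-lake isotope summary table
(group means ± SD with habitat-zone labels) that the worked examples and the
trout model grid run on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import BiomassRecord, FoodWebInput, IsotopeMeasurement, SourceSummary
from .errors import FeasibilityError, ValidationError
from .mixing_model import TRACERS, ilr, ilr_inv
from .tdf import TDFSpec


@dataclass
class SimulationTruth:
    """Ground truth behind one synthetic mixing dataset."""

    true_p: np.ndarray
    tdf: TDFSpec
    xi: tuple[float, float] = (1.0, 1.0)
    sigma_re: float = 0.0
    n_consumers: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_p = np.asarray(self.true_p, dtype=float)
        if abs(self.true_p.sum() - 1.0) > 1e-9 or (self.true_p < 0).any():
            raise ValidationError("true_p must be a simplex vector")
        if any(x <= 0 for x in self.xi):
            raise ValidationError("xi must be > 0")

    def provenance(self) -> dict:
        return {
            "true_p": self.true_p.tolist(),
            "tdf": self.tdf.name,
            "xi": list(self.xi),
            "sigma_re": self.sigma_re,
            "n_consumers": self.n_consumers,
            "seed": self.seed,
        }


def gen_mixing_dataset(
    truth: SimulationTruth,
    sources: Sequence[SourceSummary],
    lake: str = "synthetic",
    zone: str = "pelagic",
) -> tuple[list[IsotopeMeasurement], dict]:
    """Simulate consumers from the mixing model's own generative process.

    Per consumer j, the diet p_j perturbs ILR(true_p) with
    Normal(0, sigma_re) noise; each tracer value is then drawn from
    Normal(sum_i p_ji (mu_S + mu_TDF), sqrt(xi * sum_i p_ji^2 (sd_S^2 + sd_TDF^2))).
    Deterministic for a fixed seed. Returns the consumers and a provenance
    record of the truth parameters.
    """
    if len(truth.true_p) != len(sources):
        raise ValidationError(
            f"true_p has {len(truth.true_p)} entries for {len(sources)} sources"
        )
    rng = np.random.default_rng(truth.seed)
    n = len(sources)
    M = np.array([[s.mean(tr) + truth.tdf.mean(tr) for tr in TRACERS] for s in sources])
    V = np.array([[s.sd(tr) ** 2 + truth.tdf.sd(tr) ** 2 for tr in TRACERS] for s in sources])
    xi = np.asarray(truth.xi, dtype=float)

    z = ilr(truth.true_p)
    consumers = []
    for j in range(truth.n_consumers):
        zj = z + truth.sigma_re * rng.standard_normal(n - 1)
        pj = ilr_inv(zj, n)
        mu = pj @ M
        sd = np.sqrt(xi * (pj**2 @ V))
        vals = rng.normal(mu, sd)
        consumers.append(
            IsotopeMeasurement(
                sample_id=f"sim{j + 1}", lake=lake, zone=zone,
                taxon="synthetic consumer", group="consumer",
                d13C=float(vals[0]), d15N=float(vals[1]),
            )
        )
    return consumers, truth.provenance()


def gen_biomass(
    source_names: Sequence[str], seed: int, low: float = 1.0, high: float = 100.0
) -> list[BiomassRecord]:
    """Log-uniform biomasses (mg C m^-2) spanning ``low``..``high``."""
    rng = np.random.default_rng(seed)
    b = np.exp(rng.uniform(np.log(low), np.log(high), len(source_names)))
    return [BiomassRecord(source_name=s, biomass=float(v))
            for s, v in zip(source_names, b)]


# ---------------------------------------------------------------------------
# synthetic food webs

def gen_foodweb(
    n_basal: int,
    n_herb: int,
    n_omn: int,
    n_pred: int,
    connectance_target: Optional[float] = None,
    zones: Sequence[str] = ("littoral", "pelagic"),
    seed: int = 0,
) -> FoodWebInput:
    """Random web whose nodes classify back to their generating categories.

    Herbivores prey only on basal nodes; omnivores on at least one basal and
    one herbivore (two distinct prey levels); predators only on herbivores.
    Extra links are added uniformly among the allowed pairs until the
    realized connectance L/N^2 is as close as feasible to
    ``connectance_target`` (must land within ±20% of it, else a
    :class:`FeasibilityError`).
    """
    counts = (n_basal, n_herb, n_omn, n_pred)
    if any(c < 0 for c in counts):
        raise ValidationError("node counts must be >= 0")
    n_cons = n_herb + n_omn + n_pred
    if n_cons > 0 and n_basal < 1:
        raise FeasibilityError("consumers need at least one basal node")
    if (n_omn > 0 or n_pred > 0) and n_herb < 1:
        raise FeasibilityError("omnivores/predators need at least one herbivore")
    rng = np.random.default_rng(seed)

    names, cats = [], []
    for prefix, cnt, cat in (
        ("basal", n_basal, "basal"), ("herb", n_herb, "herbivore"),
        ("omn", n_omn, "omnivore"), ("pred", n_pred, "predator"),
    ):
        for i in range(cnt):
            names.append(f"{prefix}{i + 1}")
            cats.append(cat)
    N = len(names)
    A = np.zeros((N, N), dtype=int)
    basal_idx = [i for i, c in enumerate(cats) if c == "basal"]
    herb_idx = [i for i, c in enumerate(cats) if c == "herbivore"]

    allowed: dict[int, list[int]] = {}
    for j, cat in enumerate(cats):
        if cat == "herbivore":
            allowed[j] = list(basal_idx)
        elif cat == "omnivore":
            allowed[j] = list(basal_idx) + list(herb_idx)
        elif cat == "predator":
            allowed[j] = list(herb_idx)

    # mandatory links establishing each node's category
    for j, cat in enumerate(cats):
        if cat == "herbivore":
            A[rng.choice(basal_idx), j] = 1
        elif cat == "omnivore":
            A[rng.choice(basal_idx), j] = 1
            A[rng.choice(herb_idx), j] = 1
        elif cat == "predator":
            A[rng.choice(herb_idx), j] = 1

    l_min = int(A.sum())
    l_max = sum(len(v) for v in allowed.values())
    if connectance_target is not None:
        target_links = connectance_target * N * N
        l_goal = int(round(min(max(target_links, l_min), l_max)))
        if target_links > 0 and abs(l_goal - target_links) / target_links > 0.2:
            raise FeasibilityError(
                f"target connectance {connectance_target} infeasible for this "
                f"structure (achievable links {l_min}..{l_max})"
            )
        free = [(i, j) for j, prey in allowed.items() for i in prey if not A[i, j]]
        need = l_goal - l_min
        if need > 0:
            chosen = rng.choice(len(free), size=need, replace=False)
            for idx in chosen:
                i, j = free[idx]
                A[i, j] = 1

    zone_cycle = [zones[i % len(zones)] for i in range(N)]
    node_attrs = {
        name: {"zone": zone_cycle[i], "guild": cats[i], "species_richness": 1}
        for i, name in enumerate(names)
    }
    return FoodWebInput(node_names=names, adjacency=A, node_attrs=node_attrs)


# ---------------------------------------------------------------------------
# packaged two-lake fixture

def _fixture_frame() -> pd.DataFrame:
    ref = importlib.resources.files("isoweb.data").joinpath("table1_isotopes.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table1_fixture(lake: Optional[str] = None) -> list[SourceSummary]:
    """The packaged two-lake isotope summary table as source summaries.

    Each row carries a group's mean ± SD per tracer and its habitat zone;
    ``lake`` ('El Sol' or 'La Luna') filters to one lake. Sample sizes per
    group are not public, so ``n`` is set to 1 throughout.
    """
    df = _fixture_frame()
    if lake is not None:
        df = df[df["lake"] == lake]
        if df.empty:
            raise ValidationError(f"unknown lake {lake!r}")
    return [
        SourceSummary(
            name=row["group"], zone=row["zone"],
            mean_d13C=float(row["mean_d13C"]), sd_d13C=float(row["sd_d13C"]),
            mean_d15N=float(row["mean_d15N"]), sd_d15N=float(row["sd_d15N"]),
            n=1,
        )
        for _, row in df.iterrows()
    ]


#: the six candidate trout diet sources used throughout the worked examples
TROUT_DIET_SOURCES = (
    "Lumbriculus variegatus",
    "Tubifex tubifex",
    "Limnodrilus hoffmeisteri",
    "Physa sp.",
    "Daphnia ambigua",
    "Leptodiaptomus cuauhtemoci",
)


def trout_summary() -> SourceSummary:
    """The introduced rainbow trout's mean ± SD row from the fixture."""
    for s in table1_fixture("El Sol"):
        if s.name == "Oncorhynchus mykiss":
            return s
    raise ValidationError("fixture is missing the trout row")  # pragma: no cover


def trout_diet_sources() -> list[SourceSummary]:
    """The six-source candidate set for the trout diet models, fixture order."""
    table = {s.name: s for s in table1_fixture("El Sol")}
    return [table[name] for name in TROUT_DIET_SOURCES]


def simulated_trout_consumers(n: int = 9, seed: int = 0) -> list[IsotopeMeasurement]:
    """Individual trout drawn from the fixture's population mean ± SD.

    The raw per-fish values are unpublished; these stand-ins are normal draws
    around the printed population summary, for exercising the pipeline.
    """
    t = trout_summary()
    rng = np.random.default_rng(seed)
    return [
        IsotopeMeasurement(
            sample_id=f"Tro{i + 1}", lake="El Sol", zone="pelagic",
            taxon="Oncorhynchus mykiss", group="Oncorhynchus mykiss",
            d13C=float(rng.normal(t.mean_d13C, t.sd_d13C)),
            d15N=float(rng.normal(t.mean_d15N, t.sd_d15N)),
        )
        for i in range(n)
    ]
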