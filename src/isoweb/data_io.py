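"""Shared data model and tabular input/output.

The package exchanges all data as delimited text with an explicit header row
and decimal points (decimal commas, which appear in some source tables, are
normalized on read). Four tables are understood:

* ``consumers.csv`` — one row per analysed sample:
  ``sample_id,lake,zone,taxon,group,d13C,d15N[,cn_ratio,tissue]``
* ``sources.csv`` — per-source isotope summaries:
  ``name,zone,mean_d13C,sd_d13C,mean_d15N,sd_d15N,n``
* ``biomass.csv`` — ``source_name,biomass_mgC_m2``
* a food-web link matrix (first row/column are node names, cells 0/1) plus a
  node-attribute table ``node,zone,guild,species_richness[,category]``.

δ values are per-mil (‰) vs VPDB (carbon) and AIR (nitrogen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    ParseError,
    SchemaError,
    ValidationError,
)

ZONES = ("pelagic", "littoral", "profundal")

CATEGORIES = ("basal", "herbivore", "omnivore", "predator")


def _check_zone(zone: str) -> str:
    if zone not in ZONES:
        raise ValidationError(
            f"unknown zone {zone!r}; expected one of {ZONES}"
        )
    return zone


@dataclass
class IsotopeMeasurement:
    """A single sample's two-tracer isotope measurement with habitat labels."""

    sample_id: str
    lake: str
    zone: str
    taxon: str
    group: str
    d13C: float
    d15N: float
    cn_ratio: Optional[float] = None
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        _check_zone(self.zone)
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")


@dataclass
class SourceSummary:
    """Per-source per-tracer mean/SD/n, the mixing-model view of a food source."""

    name: str
    zone: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    n: int

    def __post_init__(self) -> None:
        _check_zone(self.zone)
        if self.sd_d13C < 0 or self.sd_d15N < 0:
            raise ValidationError(f"source {self.name}: SD must be >= 0")
        if self.n < 1:
            raise ValidationError(f"source {self.name}: n must be >= 1")

    def mean(self, tracer: str) -> float:
        return {"d13C": self.mean_d13C, "d15N": self.mean_d15N}[tracer]

    def sd(self, tracer: str) -> float:
        return {"d13C": self.sd_d13C, "d15N": self.sd_d15N}[tracer]


@dataclass
class BiomassRecord:
    """Average annual biomass of one source, in mg C per m^2."""

    source_name: str
    biomass: float

    def __post_init__(self) -> None:
        if not (self.biomass > 0):
            raise ValidationError(
                f"biomass of {self.source_name} must be > 0, got {self.biomass!r}"
            )


@dataclass
class FoodWebInput:
    """Node-attributed 0/1 trophic-link matrix.

    Entry ``adjacency[i, j] == 1`` means predator ``j`` (column) eats prey
    ``i`` (row).
    """

    node_names: list[str]
    adjacency: np.ndarray
    node_attrs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.node_names)
        if len(set(self.node_names)) != n:
            raise ValidationError("node names must be unique")
        if self.adjacency.shape != (n, n):
            raise ValidationError(
                f"adjacency must be {n}x{n}, got {self.adjacency.shape}"
            )
        if not np.isin(self.adjacency, (0, 1)).all():
            bad = self.adjacency[~np.isin(self.adjacency, (0, 1))][0]
            raise ValidationError(f"adjacency entries must be 0/1, found {bad!r}")
        self.adjacency = self.adjacency.astype(int)
        for name, attrs in self.node_attrs.items():
            sr = attrs.get("species_richness")
            if sr is not None and sr < 1:
                raise ValidationError(f"node {name}: species_richness must be >= 1")
            cat = attrs.get("category")
            if cat is not None and cat not in CATEGORIES:
                raise ValidationError(f"node {name}: unknown category {cat!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def prey_of(self, predator: str) -> list[str]:
        j = self.node_names.index(predator)
        return [self.node_names[i] for i in np.flatnonzero(self.adjacency[:, j])]


# ---------------------------------------------------------------------------
# reading

def _normalize_decimal(value):
    """Accept decimal commas ('-17,04' -> -17.04) alongside decimal points."""
    if isinstance(value, str):
        return value.strip().replace(",", ".")
    return value


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_float(value, path, row: int, col: str, optional: bool = False):
    value = _normalize_decimal(value)
    if value is None or (isinstance(value, str) and value == "") or (
        isinstance(value, float) and math.isnan(value)
    ):
        if optional:
            return None
        raise ParseError(f"{path} row {row}: missing value in column {col!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"{path} row {row}: non-numeric value {value!r} in column {col!r}"
        ) from None


def read_consumers(path) -> list[IsotopeMeasurement]:
    """Read per-sample consumer isotope measurements, preserving row order."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["sample_id", "lake", "zone", "taxon", "group", "d13C", "d15N"], path)
    out: list[IsotopeMeasurement] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        out.append(
            IsotopeMeasurement(
                sample_id=sid,
                lake=row["lake"],
                zone=row["zone"],
                taxon=row["taxon"],
                group=row["group"],
                d13C=_parse_float(row["d13C"], path, i, "d13C"),
                d15N=_parse_float(row["d15N"], path, i, "d15N"),
                cn_ratio=_parse_float(row.get("cn_ratio"), path, i, "cn_ratio", optional=True)
                if "cn_ratio" in df.columns
                else None,
                tissue=row.get("tissue") if "tissue" in df.columns else None,
            )
        )
    return out


def read_sources(path) -> list[SourceSummary]:
    """Read per-source isotope summary table."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(
        df, ["name", "zone", "mean_d13C", "sd_d13C", "mean_d15N", "sd_d15N", "n"], path
    )
    out = []
    names = set()
    for i, row in df.iterrows():
        if row["name"] in names:
            raise ValidationError(f"{path}: duplicate source name {row['name']!r}")
        names.add(row["name"])
        out.append(
            SourceSummary(
                name=row["name"],
                zone=row["zone"],
                mean_d13C=_parse_float(row["mean_d13C"], path, i, "mean_d13C"),
                sd_d13C=_parse_float(row["sd_d13C"], path, i, "sd_d13C"),
                mean_d15N=_parse_float(row["mean_d15N"], path, i, "mean_d15N"),
                sd_d15N=_parse_float(row["sd_d15N"], path, i, "sd_d15N"),
                n=int(_parse_float(row["n"], path, i, "n")),
            )
        )
    return out


def read_biomass(path) -> list[BiomassRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["source_name", "biomass_mgC_m2"], path)
    return [
        BiomassRecord(
            source_name=row["source_name"],
            biomass=_parse_float(row["biomass_mgC_m2"], path, i, "biomass_mgC_m2"),
        )
        for i, row in df.iterrows()
    ]


def read_foodweb(matrix_path, attrs_path=None) -> FoodWebInput:
    """Read a 0/1 link matrix (names in first row/column) and node attributes.

    The matrix is validated strictly: entries other than exactly 0 or 1
    (e.g. 0.5 or 2) raise :class:`ValidationError`; a non-square matrix
    raises :class:`SchemaError`.
    """
    df = pd.read_csv(matrix_path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SchemaError(
            f"{matrix_path}: matrix must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    names = [str(c) for c in df.columns]
    row_names = [str(r) for r in df.index]
    if row_names != names:
        raise SchemaError(f"{matrix_path}: row and column names differ")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))][0]
        raise ValidationError(f"{matrix_path}: non-binary entry {bad!r}")

    node_attrs: dict[str, dict] = {}
    if attrs_path is not None:
        adf = pd.read_csv(attrs_path, dtype=str)
        _require_columns(adf, ["node", "zone", "guild", "species_richness"], attrs_path)
        attr_names = set(adf["node"])
        orphans = sorted(set(names) ^ attr_names)
        if orphans:
            raise SchemaError(
                f"{attrs_path}: node names do not match matrix; orphans: {orphans}"
            )
        for i, row in adf.iterrows():
            attrs = {
                "zone": _check_zone(row["zone"]),
                "guild": row["guild"],
                "species_richness": int(
                    _parse_float(row["species_richness"], attrs_path, i, "species_richness")
                ),
            }
            if "category" in adf.columns and isinstance(row.get("category"), str):
                attrs["category"] = row["category"]
            node_attrs[row["node"]] = attrs
    return FoodWebInput(node_names=names, adjacency=values.astype(int), node_attrs=node_attrs)


# ---------------------------------------------------------------------------
# writing

def write_consumers(measurements: Iterable[IsotopeMeasurement], path) -> None:
    df = pd.DataFrame([asdict(m) for m in measurements])
    df.to_csv(path, index=False)


def write_sources(sources: Iterable[SourceSummary], path) -> None:
    df = pd.DataFrame([asdict(s) for s in sources])
    df.to_csv(path, index=False)


def write_foodweb(web: FoodWebInput, matrix_path, attrs_path=None) -> None:
    df = pd.DataFrame(web.adjacency, index=web.node_names, columns=web.node_names)
    df.to_csv(matrix_path)
    if attrs_path is not None and web.node_attrs:
        rows = []
        for name in web.node_names:
            attrs = web.node_attrs.get(name, {})
            rows.append({"node": name, **attrs})
        pd.DataFrame(rows).to_csv(attrs_path, index=False)


# ---------------------------------------------------------------------------
# summarisation

def summarize_sources(
    measurements: Sequence[IsotopeMeasurement], group_by: str = "group"
) -> list[SourceSummary]:
    """Collapse per-sample measurements into per-group mean ± SD summaries.

    SD is the sample standard deviation (n−1 denominator), 0 for singleton
    groups. The group's zone is taken from its first measurement.
    """
    if not measurements:
        raise EmptyInputError("summarize_sources: no measurements supplied")
    order: list[str] = []
    groups: dict[str, list[IsotopeMeasurement]] = {}
    for m in measurements:
        key = getattr(m, group_by)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(m)
    out = []
    for key in order:
        ms = groups[key]
        c = np.array([m.d13C for m in ms])
        n_vals = np.array([m.d15N for m in ms])
        sd_c = float(np.std(c, ddof=1)) if len(ms) > 1 else 0.0
        sd_n = float(np.std(n_vals, ddof=1)) if len(ms) > 1 else 0.0
        out.append(
            SourceSummary(
                name=key,
                zone=ms[0].zone,
                mean_d13C=float(np.mean(c)),
                sd_d13C=sd_c,
                mean_d15N=float(np.mean(n_vals)),
                sd_d15N=sd_n,
                n=len(ms),
            )
        )
    return out
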