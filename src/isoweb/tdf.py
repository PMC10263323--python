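"""Trophic discrimination factors (TDFs).

A TDF (Δδ¹³C, Δδ¹⁵N) is the systematic per-trophic-step isotopic enrichment
between a consumer's tissue and its diet. Besides published presets (shipped
in ``data/tdf_presets.yaml``), a TDF can be *calculated* for a consumer as the
mean ± SD of the differences between the consumer's mean tissue value and each
candidate source's mean, one difference per source, per tracer. Negative
carbon TDFs are legitimate: littoral grazers can carry heavier carbon than
their predator.

The candidate source set is always an explicit argument — it is an ecological
choice, never inferred from data.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .data_io import SourceSummary
from .errors import DegenerateFitError, EmptyInputError, InsufficientDataError, ValidationError


@dataclass
class TDFSpec:
    """Per-tracer trophic discrimination mean/SD."""

    name: str
    mean_dC: float
    sd_dC: float
    mean_dN: float
    sd_dN: float
    provenance: str = "published"  # "calculated" | "published"

    def __post_init__(self) -> None:
        if self.sd_dC < 0 or self.sd_dN < 0:
            raise ValidationError(f"TDF {self.name}: SD must be >= 0")
        if not (math.isfinite(self.mean_dC) and math.isfinite(self.mean_dN)):
            raise ValidationError(f"TDF {self.name}: means must be finite")
        if self.provenance not in ("calculated", "published"):
            raise ValidationError(f"TDF {self.name}: bad provenance {self.provenance!r}")

    def mean(self, tracer: str) -> float:
        return {"d13C": self.mean_dC, "d15N": self.mean_dN}[tracer]

    def sd(self, tracer: str) -> float:
        return {"d13C": self.sd_dC, "d15N": self.sd_dN}[tracer]


def _consumer_mean(consumer_mean) -> tuple[float, float]:
    if isinstance(consumer_mean, Mapping):
        return float(consumer_mean["d13C"]), float(consumer_mean["d15N"])
    c, n = consumer_mean
    return float(c), float(n)


def calc_tdf(consumer_mean, sources: Sequence[SourceSummary], name: str = "calculated") -> TDFSpec:
    """Empirical TDF: mean ± sample SD of (consumer − source) differences.

    Parameters
    ----------
    consumer_mean
        Mapping ``{"d13C": ..., "d15N": ...}`` or a ``(d13C, d15N)`` pair of
        the consumer's mean tissue values (‰).
    sources
        Candidate diet sources; each contributes one difference per tracer,
        equally weighted regardless of its sample size.
    """
    if not sources:
        raise EmptyInputError("calc_tdf: no sources supplied")
    c13, c15 = _consumer_mean(consumer_mean)
    diff_c = np.array([c13 - s.mean_d13C for s in sources])
    diff_n = np.array([c15 - s.mean_d15N for s in sources])
    sd_c = float(np.std(diff_c, ddof=1)) if len(sources) > 1 else 0.0
    sd_n = float(np.std(diff_n, ddof=1)) if len(sources) > 1 else 0.0
    return TDFSpec(
        name=name,
        mean_dC=float(np.mean(diff_c)),
        sd_dC=sd_c,
        mean_dN=float(np.mean(diff_n)),
        sd_dN=sd_n,
        provenance="calculated",
    )


def calc_tdf_by_zone(consumer_mean, sources: Sequence[SourceSummary]) -> dict[str, TDFSpec]:
    """One calculated TDF per habitat zone present among the sources."""
    if not sources:
        raise EmptyInputError("calc_tdf_by_zone: no sources supplied")
    zones: dict[str, list[SourceSummary]] = {}
    for s in sources:
        zones.setdefault(s.zone, []).append(s)
    return {
        zone: calc_tdf(consumer_mean, zone_sources, name=f"calculated_{zone}")
        for zone, zone_sources in zones.items()
    }


def tdf_source_regression(
    source_values: Sequence[float], tdf_values: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS regression of per-source TDF on the source isotope value.

    Returns ``(slope, intercept, r_squared, p_value)``. At least 3 points and
    non-zero variance in the predictor are required.
    """
    x = np.asarray(source_values, dtype=float)
    y = np.asarray(tdf_values, dtype=float)
    if x.size != y.size:
        raise ValidationError("tdf_source_regression: x and y lengths differ")
    if x.size < 3:
        raise InsufficientDataError(
            f"tdf_source_regression: need >= 3 points, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError("tdf_source_regression: zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def load_tdf_presets() -> dict[str, TDFSpec]:
    """Published TDF presets (TDF1–TDF5) shipped with the package."""
    ref = importlib.resources.files("isoweb.data").joinpath("tdf_presets.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {
        key: TDFSpec(name=key, provenance=entry.pop("provenance", "published"), **entry)
        for key, entry in raw.items()
    }
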