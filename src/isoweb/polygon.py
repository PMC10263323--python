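"""Monte-Carlo mixing-polygon (in-polygon) validation.

A two-tracer mixing model can only explain a consumer that lies inside the
convex hull of its TDF-corrected sources. The test simulates the hull: each
iterate draws every source vertex from Normal(μ_S + μ_TDF, √(σ_S² + σ_TDF²))
independently per tracer, builds the convex hull of the drawn vertices, and
records which consumers fall inside. A consumer's inclusion probability is
the fraction of iterates containing it; by the published convention a
consumer passes when that probability is ≥ 0.05 (it sits inside the 95%
mixing region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .data_io import IsotopeMeasurement, SourceSummary
from .errors import GeometryError
from .tdf import TDFSpec

_TRACERS = ("d13C", "d15N")


@dataclass
class PolygonResult:
    consumer_ids: list[str]
    consumer_probs: np.ndarray
    iterates: int
    pass_95: np.ndarray
    hulls: Optional[list[np.ndarray]] = None

    def as_rows(self) -> list[dict]:
        return [
            {"consumer_id": cid, "probability": float(p), "pass_95": bool(ok)}
            for cid, p, ok in zip(self.consumer_ids, self.consumer_probs, self.pass_95)
        ]

    @property
    def all_pass(self) -> bool:
        return bool(self.pass_95.all())


def point_in_hull(point, vertices, tol: float = 1e-9) -> bool:
    """True iff ``point`` lies inside or on the convex hull of ``vertices``.

    The boundary counts as inside. Collinear vertex sets degrade to a
    point-on-segment test. Fewer than 3 vertices is a geometry error.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError(f"a polygon needs >= 3 vertices, got {pts.shape[0]}")
    p = np.asarray(point, dtype=float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return _point_on_degenerate(p, pts, tol)
    # hull.equations: rows [a, b, c] with a*x + b*y + c <= 0 inside
    return bool((pts[hull.vertices].shape[0] >= 3) and
                (hull.equations[:, :-1] @ p + hull.equations[:, -1] <= tol).all())


def _point_on_degenerate(p: np.ndarray, pts: np.ndarray, tol: float) -> bool:
    """Membership test when all vertices are collinear (or coincident)."""
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.allclose(lo, hi, atol=tol):
        return bool(np.allclose(p, lo, atol=tol))
    d = hi - lo
    t = np.dot(p - lo, d) / np.dot(d, d)
    closest = lo + np.clip(t, 0.0, 1.0) * d
    return bool(np.linalg.norm(p - closest) <= max(tol, 1e-9 * np.linalg.norm(d)))


def _tdf_for_source(
    source: SourceSummary, tdf: Union[TDFSpec, Mapping[str, TDFSpec]]
) -> TDFSpec:
    if isinstance(tdf, Mapping):
        try:
            return tdf[source.zone]
        except KeyError:
            raise GeometryError(
                f"no TDF configured for zone {source.zone!r} (source {source.name})"
            ) from None
    return tdf


def polygon_test(
    sources: Sequence[SourceSummary],
    tdf: Union[TDFSpec, Mapping[str, TDFSpec]],
    consumers: Sequence[IsotopeMeasurement],
    iterates: int = 1500,
    seed: int | None = None,
    keep_hulls: bool = False,
) -> PolygonResult:
    """Per-consumer inclusion probability in the simulated mixing polygon.

    ``tdf`` is a single :class:`TDFSpec` or a zone→TDFSpec mapping (the
    per-source TDF is then looked up by the source's zone). TDF uncertainty
    enters each vertex SD in quadrature with the source SD. ``seed`` is
    required for reproducibility.
    """
    if len(sources) < 3:
        raise GeometryError(f"polygon test needs >= 3 sources, got {len(sources)}")
    if iterates < 1:
        raise GeometryError("iterates must be >= 1")
    if seed is None:
        raise ValueError("polygon_test: a seed is required")
    rng = np.random.default_rng(seed)

    mu = np.empty((len(sources), 2))
    sd = np.empty((len(sources), 2))
    for i, s in enumerate(sources):
        t = _tdf_for_source(s, tdf)
        for k, tracer in enumerate(_TRACERS):
            mu[i, k] = s.mean(tracer) + t.mean(tracer)
            sd[i, k] = np.hypot(s.sd(tracer), t.sd(tracer))

    pts = np.array([[c.d13C, c.d15N] for c in consumers])
    inside = np.zeros(len(consumers), dtype=int)
    hulls: list[np.ndarray] = []
    for _ in range(iterates):
        vertices = rng.normal(mu, sd)
        if keep_hulls:
            hulls.append(vertices)
        for ci in range(len(consumers)):
            if point_in_hull(pts[ci], vertices):
                inside[ci] += 1
    probs = inside / iterates
    return PolygonResult(
        consumer_ids=[c.sample_id for c in consumers],
        consumer_probs=probs,
        iterates=iterates,
        pass_95=probs >= 0.05,
        hulls=hulls if keep_hulls else None,
    )
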