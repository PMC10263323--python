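"""Food-web topology metrics from a binary trophic-link matrix.

The web is an n×n 0/1 adjacency with predators as columns and prey as rows.
Nodes are ecological groups; several species may aggregate into one node, so
species richness S is carried as per-node metadata and summed, while N counts
nodes. Derived metrics:

* L — number of realized links (count of 1-entries, self-links included)
* D1 = L/S and D2 = L/N — linkage densities per species and per node
* Lp = N² — potential directed links; C = L/N² — directed connectance
* basal/herbivore/omnivore/predator node fractions
* integer trophic levels: level(basal) = 1, level(consumer) = 1 + max(level
  of its prey)
* littoral/pelagic sub-network link counts plus the coupling links between
  them (profundal is grouped with littoral as the benthic compartment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import FoodWebInput
from .errors import MissingDataError

#: guild labels recognised for the node-count columns
_GUILD_BUCKETS = {
    "phytoplankton": "basal_guild",
    "zooplankton": "zooplankton",
    "bmi": "bmi",
    "benthic_macroinvertebrate": "bmi",
    "fish": "fish",
}


@dataclass
class WebMetrics:
    """Derived topology metrics of one food web."""

    S: Optional[int]
    N: int
    L: int
    D1: Optional[float]
    D2: float
    Lp: int
    C: float
    fractions: dict[str, float]
    counts: dict[str, int]
    trophic_levels: int
    sublinks: Optional[dict[str, int]] = None
    node_categories: dict[str, str] = field(default_factory=dict)
    node_levels: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "S": self.S, "N": self.N, "L": self.L,
            "D1 (L/S)": self.D1, "D2 (L/N)": self.D2,
            "Lp (N^2)": self.Lp, "C (L/N^2)": self.C,
            "fractions": self.fractions, "counts": self.counts,
            "trophic_levels": self.trophic_levels, "sublinks": self.sublinks,
        }


def metrics_from_counts(S: int, N: int, L: int) -> dict[str, float]:
    """Derived cells (D1, D2, Lp, C) from printed S, N, L totals alone."""
    return {"D1": L / S, "D2": L / N, "Lp": N * N, "C": L / (N * N)}


def _prey_sets(web: FoodWebInput) -> list[set[int]]:
    A = web.adjacency
    return [set(np.flatnonzero(A[:, j]).tolist()) for j in range(web.n_nodes)]


def node_levels(web: FoodWebInput) -> dict[str, int]:
    """Integer trophic level per node.

    Basal nodes (no prey) sit at level 1; a consumer sits one above its
    highest prey. Self-links are ignored for the level recursion (a cannibal's
    level is set by its other prey). Any remaining cycle among consumers
    triggers a fallback to shortest-path-to-basal + 1, with a warning.
    """
    n = web.n_nodes
    prey = _prey_sets(web)
    level: list[Optional[int]] = [None] * n
    for j in range(n):
        if not prey[j]:
            level[j] = 1
    changed = True
    while changed:
        changed = False
        for j in range(n):
            if level[j] is not None:
                continue
            deps = prey[j] - {j}
            if deps and all(level[i] is not None for i in deps):
                level[j] = 1 + max(level[i] for i in deps)
                changed = True
            elif not deps:  # pure self-loop consumer
                level[j] = 2
                changed = True
    unresolved = [j for j in range(n) if level[j] is None]
    if unresolved:
        warnings.warn(
            "cycle detected among consumers; falling back to "
            "shortest-path-to-basal + 1 for "
            + ", ".join(web.node_names[j] for j in unresolved)
        )
        basal = {j for j in range(n) if not prey[j]}
        for j in unresolved:
            # BFS downwards along prey links to the nearest basal node
            frontier, seen, depth = {j}, {j}, 0
            found = None
            while frontier and found is None:
                depth += 1
                nxt = set()
                for u in frontier:
                    for v in prey[u] - {u}:
                        if v in basal:
                            found = depth
                            break
                        if v not in seen:
                            seen.add(v)
                            nxt.add(v)
                    if found is not None:
                        break
                frontier = nxt
            level[j] = (found + 1) if found is not None else 2
    return {web.node_names[j]: level[j] for j in range(n)}


def classify_nodes(web: FoodWebInput) -> dict[str, str]:
    """Assign each node to basal / herbivore / omnivore / predator.

    * basal — no prey
    * herbivore — preys only on basal nodes
    * omnivore — prey spans ≥ 2 distinct integer trophic levels
    * predator — preys on ≥ 1 non-basal node and on no basal node

    An explicit ``category`` node attribute overrides the inference.
    """
    levels = node_levels(web)
    prey = _prey_sets(web)
    out: dict[str, str] = {}
    for j, name in enumerate(web.node_names):
        override = web.node_attrs.get(name, {}).get("category")
        if override is not None:
            out[name] = override
            continue
        deps = prey[j] - {j}
        if not prey[j]:
            out[name] = "basal"
            continue
        prey_levels = {levels[web.node_names[i]] for i in deps}
        if len(prey_levels) >= 2:
            out[name] = "omnivore"
        elif prey_levels == {1}:
            out[name] = "herbivore"
        else:
            out[name] = "predator"
    return out


def trophic_level_count(web: FoodWebInput) -> int:
    """Number of distinct integer trophic levels occupied."""
    return len(set(node_levels(web).values()))


def _zone_bucket(zone: str) -> str:
    return "pelagic" if zone == "pelagic" else "littoral"


def compute_metrics(web: FoodWebInput) -> WebMetrics:
    """All topology metrics of a node-attributed web.

    Species richness S requires a ``species_richness`` attribute on every
    node; sub-network link counts require a ``zone`` on every node (omitted
    with a warning otherwise).
    """
    A = web.adjacency
    N = web.n_nodes
    L = int(A.sum())

    have_richness = all(
        "species_richness" in web.node_attrs.get(name, {}) for name in web.node_names
    )
    if web.node_names and not have_richness:
        raise MissingDataError(
            "species richness missing on some nodes; S unavailable"
        )
    S = int(sum(web.node_attrs[name]["species_richness"] for name in web.node_names)) if N else 0

    categories = classify_nodes(web)
    levels = node_levels(web)
    fractions = {
        cat: (sum(1 for c in categories.values() if c == cat) / N if N else 0.0)
        for cat in ("basal", "herbivore", "omnivore", "predator")
    }

    counts = {"basal": sum(1 for c in categories.values() if c == "basal"),
              "zooplankton": 0, "bmi": 0, "fish": 0}
    for name in web.node_names:
        guild = str(web.node_attrs.get(name, {}).get("guild", "")).lower()
        bucket = _GUILD_BUCKETS.get(guild)
        if bucket in counts:
            counts[bucket] += 1

    sublinks: Optional[dict[str, int]] = None
    have_zones = N > 0 and all(
        "zone" in web.node_attrs.get(name, {}) for name in web.node_names
    )
    if have_zones:
        sublinks = {"littoral": 0, "pelagic": 0, "coupling": 0}
        zones = [_zone_bucket(web.node_attrs[name]["zone"]) for name in web.node_names]
        rows, cols = np.nonzero(A)
        for i, j in zip(rows, cols):
            if zones[i] == zones[j]:
                sublinks[zones[i]] += 1
            else:
                sublinks["coupling"] += 1
    elif N:
        warnings.warn("zone missing on some nodes; sub-network link counts omitted")

    return WebMetrics(
        S=S, N=N, L=L,
        D1=(L / S if S else None), D2=(L / N if N else 0.0),
        Lp=N * N, C=(L / (N * N) if N else 0.0),
        fractions=fractions, counts=counts,
        trophic_levels=len(set(levels.values())) if N else 0,
        sublinks=sublinks,
        node_categories=categories, node_levels=levels,
    )
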