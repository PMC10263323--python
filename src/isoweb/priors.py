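"""Dirichlet priors over diet proportions.

Two prior kinds are supported for the mixing model:

* *uniform* ("generalist"): every source equally likely a priori, αᵢ = 1.
* *biomass*-informed: αᵢ proportional to the source's standing biomass
  (mg C m⁻²), rescaled so that Σα equals the number of sources. Keeping the
  total concentration Σα identical to the uniform prior makes the biomass
  prior shift only the prior *means* E[pᵢ] = αᵢ/Σα, not the overall prior
  strength — a deliberately gentle way to inject biomass information.

A source with unknown biomass can be given a *neutral* fill equal to the mean
of the known biomasses, so its prior mean matches the average source rather
than biasing its contribution either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_io import BiomassRecord
from .errors import MissingDataError, ValidationError


@dataclass
class DirichletPrior:
    """Dirichlet(α) over the simplex of diet proportions."""

    source_names: list[str]
    alpha: np.ndarray
    kind: str  # "uniform" | "biomass"

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.alpha) != len(self.source_names):
            raise ValidationError("alpha length must match source_names")
        if not (self.alpha > 0).all():
            raise ValidationError("all alpha must be > 0")

    @property
    def mean(self) -> np.ndarray:
        """Prior expectation of the diet proportions."""
        return self.alpha / self.alpha.sum()

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "source_names": self.source_names,
             "alpha": self.alpha.tolist()},
            indent=2,
        )


def uniform_prior(source_names: Sequence[str], alpha_each: float = 1.0) -> DirichletPrior:
    """Uninformative prior αᵢ = 1 (so Σα = n and E[pᵢ] = 1/n).

    ``alpha_each`` exposes the alternative reading αᵢ = 1/n for users who want
    a weaker prior; the default is the conventional αᵢ = 1.
    """
    n = len(source_names)
    if n < 2:
        raise ValidationError(f"a mixture needs >= 2 sources, got {n}")
    return DirichletPrior(
        source_names=list(source_names),
        alpha=np.full(n, float(alpha_each)),
        kind="uniform",
    )


def biomass_prior(
    source_names: Sequence[str],
    biomass: Sequence[BiomassRecord],
    neutral_fill: bool = False,
) -> DirichletPrior:
    """Biomass-informed prior αᵢ = bᵢ · n / Σb.

    Scaling by n/Σb standardizes the hyperparameters so Σα = n exactly,
    matching the total concentration of the uniform prior. With
    ``neutral_fill``, any source lacking a biomass record is assigned the
    arithmetic mean of the known biomasses before standardization.
    """
    n = len(source_names)
    if n < 2:
        raise ValidationError(f"a mixture needs >= 2 sources, got {n}")
    table = {}
    for rec in biomass:
        table[rec.source_name] = rec.biomass
    known = [table[s] for s in source_names if s in table]
    b = np.empty(n)
    for i, s in enumerate(source_names):
        if s in table:
            b[i] = table[s]
        elif neutral_fill:
            if not known:
                raise MissingDataError("neutral_fill needs at least one known biomass")
            b[i] = float(np.mean(known))
        else:
            raise MissingDataError(f"no biomass record for source {s!r}")
    if not (b > 0).all():
        raise ValidationError("all biomasses must be > 0")
    alpha = b * n / b.sum()
    return DirichletPrior(source_names=list(source_names), alpha=alpha, kind="biomass")
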