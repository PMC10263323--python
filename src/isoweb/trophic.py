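"""Trophic position and food-chain length from δ¹⁵N.

Nitrogen enriches by a roughly constant amount Δn (‰) per trophic step, so a
consumer's continuous trophic position follows from its δ¹⁵N relative to a
baseline organism of known trophic level λ. When a consumer draws on two
isotopically distinct baselines (littoral vs pelagic), the fraction α of the
littoral baseline is first inferred from δ¹³C, which passes up food chains
nearly unchanged:

    α  = (δ¹³C_consumer − δ¹³C_base2) / (δ¹³C_base1 − δ¹³C_base2), clipped to [0,1]
    TP = λ + (δ¹⁵N_consumer − [α·δ¹⁵N_base1 + (1−α)·δ¹⁵N_base2]) / Δn

Food-chain length is the maximum TP over the web's top consumers. Common Δn
choices: 3.4 ‰ (literature consensus) or an empirically calculated consumer
TDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import EmptyInputError, ValidationError

#: conventional per-step nitrogen enrichment (permil)
DELTA_N_LITERATURE = 3.4


@dataclass
class Baseline:
    """A baseline organism with assumed trophic level λ (≥ 1)."""

    name: str
    d13C: float
    d15N: float
    lam: float = 2.0

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValidationError(f"baseline {self.name}: lambda must be >= 1")


@dataclass
class TrophicResult:
    consumer: str
    trophic_position: float
    delta_n: float
    alpha_littoral: float | None = None
    baselines: tuple[str, ...] = ()


def _consumer_values(consumer) -> tuple[str, float, float]:
    if hasattr(consumer, "d13C"):
        name = getattr(consumer, "sample_id", getattr(consumer, "group", "consumer"))
        return name, consumer.d13C, consumer.d15N
    name, c13, c15 = consumer
    return name, float(c13), float(c15)


def trophic_position_two_source(
    consumer, base1: Baseline, base2: Baseline, delta_n: float
) -> TrophicResult:
    """Two-baseline trophic position; base1 is the littoral end-member.

    ``consumer`` is an object with ``d13C``/``d15N`` attributes or a
    ``(name, d13C, d15N)`` triple.
    """
    if delta_n <= 0:
        raise ValidationError(f"delta_n must be > 0, got {delta_n}")
    if base1.d13C == base2.d13C:
        raise ValidationError("baselines have identical d13C; mixing fraction undefined")
    if base1.lam != base2.lam:
        raise ValidationError("baselines must share the same lambda")
    name, c13, c15 = _consumer_values(consumer)
    alpha = (c13 - base2.d13C) / (base1.d13C - base2.d13C)
    alpha = min(1.0, max(0.0, alpha))
    base_n = alpha * base1.d15N + (1 - alpha) * base2.d15N
    tp = base1.lam + (c15 - base_n) / delta_n
    return TrophicResult(
        consumer=name,
        trophic_position=tp,
        delta_n=delta_n,
        alpha_littoral=alpha,
        baselines=(base1.name, base2.name),
    )


def trophic_position_single(consumer, base: Baseline, delta_n: float) -> TrophicResult:
    """Single-baseline trophic position TP = λ + (δ¹⁵N_c − δ¹⁵N_base)/Δn."""
    if delta_n <= 0:
        raise ValidationError(f"delta_n must be > 0, got {delta_n}")
    name, _, c15 = _consumer_values(consumer)
    tp = base.lam + (c15 - base.d15N) / delta_n
    return TrophicResult(
        consumer=name, trophic_position=tp, delta_n=delta_n, baselines=(base.name,)
    )


def primary_consumer_baseline(
    consumer_d15N: float, source_d15N: Sequence[float], delta_n: float
) -> float:
    """Trophic level of a primary consumer over the mean δ¹⁵N of its sources.

    TL = 1 + (δ¹⁵N_consumer − mean source δ¹⁵N)/Δn.
    """
    if delta_n <= 0:
        raise ValidationError(f"delta_n must be > 0, got {delta_n}")
    vals = list(source_d15N)
    if not vals:
        raise EmptyInputError("primary_consumer_baseline: no sources supplied")
    return 1.0 + (consumer_d15N - sum(vals) / len(vals)) / delta_n


def food_chain_length(results: Sequence[TrophicResult]) -> float:
    """Maximum trophic position over the supplied top consumers."""
    if not results:
        raise EmptyInputError("food_chain_length: no trophic results supplied")
    return max(r.trophic_position for r in results)
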