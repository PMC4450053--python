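"""Population-genetic quantities of GC-biased gene conversion (haploid).

The strength of gBGC relative to drift is summarised by the population-scaled
coefficient

    B = 2 * Ne * r * L * b0

with Ne the effective population size, r the recombination (conversion
initiation) rate per bp per generation, L the mean conversion tract length
and b0 = 2*pGC - 1 the repair/transmission bias, pGC being the probability
that the GC allele is transmitted at a GC/AT heterozygous site covered by a
conversion tract.

gBGC acts like genic selection of coefficient B: relative to a neutral
allele, the fixation probability of a new GC mutation is scaled by
kappa(B) = B / (1 - exp(-B)) and that of an AT mutation by kappa(-B). With a
mutational bias lambda (GC->AT rate over AT->GC rate), the equilibrium GC
content is GC* = 1 / (1 + lambda * exp(-B)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class GBGCParameters:
    """Parameters of the gBGC model; B and b0 are derived on construction."""

    ne: float
    r: float
    tract_length: float
    p_gc: float
    lambda_mut: float = 1.0

    def __post_init__(self) -> None:
        if self.ne < 0 or self.r < 0 or self.tract_length < 0:
            raise InputError("Ne, r and tract length must be non-negative")
        if not 0.0 <= self.p_gc <= 1.0:
            raise InputError(f"p_gc must lie in [0, 1], got {self.p_gc}")
        if self.lambda_mut <= 0:
            raise InputError("lambda_mut must be positive")

    @property
    def b0(self) -> float:
        return b0_from_pgc(self.p_gc)

    @property
    def B(self) -> float:
        return gbgc_coefficient(self)


def b0_from_pgc(p_gc: float) -> float:
    """Repair bias b0 = 2*pGC - 1 (0 under Mendelian transmission)."""
    if not 0.0 <= p_gc <= 1.0:
        raise InputError(f"p_gc must lie in [0, 1], got {p_gc}")
    return 2.0 * p_gc - 1.0


def gbgc_coefficient(p: GBGCParameters) -> float:
    """Population-scaled gBGC coefficient B = 2*Ne*r*L*b0 (haploid)."""
    return 2.0 * p.ne * p.r * p.tract_length * p.b0


def fixation_bias_factor(B: float) -> float:
    """kappa(B) = B / (1 - exp(-B)), continuously extended to kappa(0) = 1.

    Multiplies the AT->GC substitution rate; kappa(-B) multiplies GC->AT.
    A short series expansion is used near B = 0 to avoid cancellation.
    """
    if not math.isfinite(B):
        raise InputError("B must be finite")
    if abs(B) < 1e-5:
        # B/(1-e^-B) = 1 + B/2 + B^2/12 + O(B^4)
        return 1.0 + B / 2.0 + B * B / 12.0
    return B / (-math.expm1(-B))


def equilibrium_gc(lambda_mut: float, B: float) -> float:
    """Stationary GC content GC* = 1 / (1 + lambda * exp(-B)).

    Derived from detailed balance of the two-state (GC vs AT) substitution
    process with AT->GC rate proportional to kappa(B) and GC->AT to
    lambda * kappa(-B), using kappa(B)/kappa(-B) = exp(B).
    """
    if lambda_mut <= 0:
        raise InputError("lambda_mut must be positive")
    return 1.0 / (1.0 + lambda_mut * math.exp(-B))
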