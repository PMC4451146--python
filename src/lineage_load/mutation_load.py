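"""Mutational-load calculus.

Closed-form arithmetic linking the germline deleterious mutation rate to the
per-generation reduction in mean fitness under relaxed selection,

    Delta_R = U * hs_mean,

where U is the expected number of new deleterious mutations per diploid
genome per generation (U = 2 * mu * L * f for per-site rate mu over L sites
of which a fraction f is functionally deleterious) and hs_mean is the mean
selection coefficient against a deleterious heterozygous mutation.

A second route infers Delta_R from an observed fitness decline: if the
cumulative decline in survivorship across the three preceding ancestral
generations is split equally among them (as expected for de novo mutations),
each generation contributes delta = cumulative / 3; and since the de novo
mutation count rises by roughly one third between paternal ages 30 and 40,
the loads at the two ages satisfy Delta_old = (4/3) * Delta_young while
their difference equals delta, pinning down both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "LoadParameters",
    "LoadEstimate",
    "FitnessDeclineSpec",
    "deleterious_rate",
    "load_reduction",
    "per_generation_decline",
    "load_from_age_effect",
    "implied_mean_hs",
    "DEFAULT_LOAD_RATIO",
    "MUTATIONS_PER_YEAR",
]

#: Extra de novo point mutations per year of paternal age (~20 per decade).
MUTATIONS_PER_YEAR: float = 2.0

#: Ratio of mutation load between paternal ages 40 and 30: the de novo count
#: rises by roughly one third over that decade.
DEFAULT_LOAD_RATIO: float = 4.0 / 3.0


@dataclass(frozen=True)
class LoadParameters:
    """Inputs of the U = 2*mu*L*f calculation.

    mu : per-site per-generation point mutation rate
    L : number of sites considered (e.g. 3e7 coding sites, 3.2e9 genome)
    f : fraction of mutations at those sites that are deleterious
    hs_mean : mean heterozygous selection coefficient, dimensionless
    """

    mu: float
    L: float
    f: float
    hs_mean: float

    def __post_init__(self) -> None:
        if self.mu < 0 or self.L < 0:
            raise ValueError("mu and L must be non-negative")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if not 0.0 <= self.hs_mean <= 1.0:
            raise ValueError(f"hs_mean must be in [0, 1], got {self.hs_mean}")

    def estimate(self) -> "LoadEstimate":
        U = deleterious_rate(self.mu, self.L, self.f)
        return LoadEstimate(U=U, delta_R=load_reduction(U, self.hs_mean))


@dataclass(frozen=True)
class LoadEstimate:
    U: float
    delta_R: float

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.delta_R < 0:
            raise ValueError("delta_R must be non-negative")
        if self.delta_R > 1:
            warnings.warn(f"delta_R = {self.delta_R:.3g} exceeds 1; interpret with caution", stacklevel=3)


@dataclass(frozen=True)
class FitnessDeclineSpec:
    """An observed cumulative fitness decline split over n generations.

    ``load_ratio`` is Delta_R(older age) / Delta_R(younger age), 4/3 by
    default for the 30-to-40 paternal-age contrast.
    """

    cumulative_decline: float
    n_generations: int = 3
    load_ratio: float = DEFAULT_LOAD_RATIO

    def __post_init__(self) -> None:
        if not 0.0 <= self.cumulative_decline <= 1.0:
            raise ValueError("cumulative_decline must be a fraction in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be at least 1")

    @property
    def delta_per_generation(self) -> float:
        return per_generation_decline(self.cumulative_decline, self.n_generations)


def deleterious_rate(mu: float, L: float, f: float) -> float:
    """Deleterious mutations per diploid genome per generation: U = 2*mu*L*f."""
    if mu < 0 or L < 0 or f < 0:
        raise ValueError("mu, L and f must be non-negative")
    return 2.0 * mu * L * f


def load_reduction(U: float, hs_mean: float) -> float:
    """Per-generation fitness reduction Delta_R = U * hs_mean."""
    if U < 0 or hs_mean < 0:
        raise ValueError("U and hs_mean must be non-negative")
    return U * hs_mean


def per_generation_decline(cumulative: float, n_generations: int) -> float:
    """Equal split of a cumulative decline across generations."""
    if n_generations < 1:
        raise ValueError("n_generations must be at least 1")
    return cumulative / n_generations


def load_from_age_effect(spec: FitnessDeclineSpec) -> tuple[float, float]:
    """Per-generation load at the younger and older paternal age.

    Solves the pair

        Delta_old = load_ratio * Delta_young
        Delta_old - Delta_young = delta_per_generation

    i.e. ``Delta_young = delta / (load_ratio - 1)``.  With the default ratio
    4/3, ``Delta_young`` equals three times the per-generation decline, which
    for a decline split over three generations is the cumulative decline
    itself.
    """
    if spec.load_ratio <= 1.0:
        raise ValueError(f"load_ratio must exceed 1 (no solution otherwise), got {spec.load_ratio}")
    delta = spec.delta_per_generation
    young = delta / (spec.load_ratio - 1.0)
    old = spec.load_ratio * young
    return young, old


def implied_mean_hs(delta_per_generation: float, extra_deleterious_mutations: float) -> float:
    """Mean selection coefficient implied by a fitness decline per extra mutation.

    If moving the paternal age contrast adds ``extra_deleterious_mutations``
    new deleterious mutations and costs ``delta_per_generation`` fitness,
    the implied mean heterozygous selection coefficient is their ratio.
    """
    if extra_deleterious_mutations <= 0:
        raise ValueError("extra_deleterious_mutations must be positive")
    return delta_per_generation / extra_deleterious_mutations
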