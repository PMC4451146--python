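"""Weighted mean age of male ancestors (WMAMA).

The statistic summarises, for a focal individual (the proband), the ages at
which the male ancestors of the last three generations fathered the proband's
lineage: the father's age at the proband's birth, each grandfather's age at
the birth of the relevant parent, and each great-grandfather's age at the
birth of the relevant grandparent.  Because the expected fraction of the
genome inherited from an ancestor halves every generation, ages are weighted
by the coefficient of relationship r (0.5, 0.25, 0.125 for generations 1-3)
and the weighted mean is renormalised over whichever ancestors are known:

    m = sum(a_i * r_i) / sum(r_i)

Under an age-dependent germline point-mutation rate, m is proportional (up to
an affine transform) to the expected number of de novo mutations the proband
carries from those three generations, which is what makes it a useful
exposure for fitness analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "RELATEDNESS_BY_GENERATION",
    "AncestorAge",
    "AncestorAgeSet",
    "WMAMAResult",
    "compute_wmama",
    "expected_signal_shares",
    "quartile_summary",
]

#: Coefficient of relationship between proband and a male ancestor g
#: generations back: father 0.5, grandfather 0.25, great-grandfather 0.125.
RELATEDNESS_BY_GENERATION: dict[int, float] = {1: 0.5, 2: 0.25, 3: 0.125}

#: Maximum number of male ancestors at each generation (1 father,
#: 2 grandfathers, 4 great-grandfathers).
MAX_PER_GENERATION: dict[int, int] = {1: 1, 2: 2, 3: 4}

Variant = Literal["full", "exclude_father", "father_only"]


@dataclass(frozen=True)
class AncestorAge:
    """One known male ancestor with his age at fathering the lineage."""

    ancestor_id: str
    generation: int
    age: float

    @property
    def relatedness(self) -> float:
        return RELATEDNESS_BY_GENERATION[self.generation]


@dataclass
class AncestorAgeSet:
    """The known male ancestors of one proband, up to great-grandfathers.

    ``missing_by_generation`` counts ancestors whose identity or birth year
    is unknown, so that ``len(entries at g) + missing[g]`` equals the full
    complement (1, 2 or 4) whenever the lineage above is traceable.
    """

    proband_id: str
    entries: list[AncestorAge] = field(default_factory=list)
    missing_by_generation: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.generation not in RELATEDNESS_BY_GENERATION:
                raise ValueError(f"generation must be 1-3, got {e.generation}")
            if not e.age > 0:
                raise ValueError(f"age at fathering must be positive, got {e.age}")
        for g, cap in MAX_PER_GENERATION.items():
            n = sum(1 for e in self.entries if e.generation == g)
            if n > cap:
                raise ValueError(f"at most {cap} ancestors allowed at generation {g}, got {n}")

    def at_generation(self, g: int) -> list[AncestorAge]:
        return [e for e in self.entries if e.generation == g]

    @property
    def father(self) -> AncestorAge | None:
        gen1 = self.at_generation(1)
        return gen1[0] if gen1 else None

    def has_baseline(self) -> bool:
        """Father and both grandfathers known (the cohort eligibility rule)."""
        return len(self.at_generation(1)) == 1 and len(self.at_generation(2)) == 2


@dataclass(frozen=True)
class WMAMAResult:
    """The computed statistic plus provenance."""

    proband_id: str
    m: float
    variant: Variant
    n_used: int
    weight_sum: float


def compute_wmama(ancestors: AncestorAgeSet, variant: Variant = "full") -> WMAMAResult:
    """Compute the relatedness-weighted mean age of male ancestors.

    Parameters
    ----------
    ancestors
        Known male ancestors with ages at fathering.  Unknown ancestors are
        simply absent: they drop out of both the numerator and denominator,
        i.e. the weights renormalise over what is known.
    variant
        ``full`` uses all entries; ``exclude_father`` drops generation 1
        (used to ask whether grandfathers/great-grandfathers carry signal
        beyond paternal age); ``father_only`` reduces to paternal age.

    Returns
    -------
    WMAMAResult
        ``m`` in years, always within ``[min(a_i), max(a_i)]`` of the ages
        used; ``weight_sum`` is the sum of coefficients of relationship.
    """
    if variant == "full":
        used = list(ancestors.entries)
    elif variant == "exclude_father":
        used = [e for e in ancestors.entries if e.generation > 1]
    elif variant == "father_only":
        used = [e for e in ancestors.entries if e.generation == 1]
        if not used:
            raise ValueError(f"father unknown for proband {ancestors.proband_id!r}; cannot compute father_only variant")
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if not used:
        raise ValueError(f"no known ancestors left for proband {ancestors.proband_id!r} under variant {variant!r}")

    wsum = sum(e.relatedness for e in used)
    m = sum(e.age * e.relatedness for e in used) / wsum
    return WMAMAResult(proband_id=ancestors.proband_id, m=m, variant=variant, n_used=len(used), weight_sum=wsum)


#: Raw per-generation signal weights. The variance contributed by a
#: generation's ages halves each generation back (the number of ancestors
#: doubles while each individual weight halves and variance scales with the
#: squared weight times the count), giving fathers : grandfathers :
#: great-grandfathers = 1 : 0.5 : 0.25.
SIGNAL_WEIGHTS: dict[int, float] = {1: 1.0, 2: 0.5, 3: 0.25}


def expected_signal_shares(known: Iterable[int]) -> dict[str, object]:
    """Expected share of the ancestral-age signal carried by each generation.

    With per-generation weights 1 : 0.5 : 0.25 over whichever generations are
    present, the normalised generation-1 share is the fraction of signal lost
    when the father's age is removed from the statistic: 1/1.75 = 57% when
    all three generations are known, 1/1.5 = 67% with father and
    grandfathers only.

    Returns a dict with ``shares`` (generation -> share), ``father_loss``
    (the generation-1 share, 0.0 if generation 1 absent) and
    ``father_loss_percent_truncated`` (integer percent, truncated).
    """
    gens = sorted(set(known))
    if not gens:
        raise ValueError("at least one generation must be present")
    if not set(gens) <= set(SIGNAL_WEIGHTS):
        raise ValueError(f"generations must be within {{1,2,3}}, got {gens}")
    total = sum(SIGNAL_WEIGHTS[g] for g in gens)
    shares = {g: SIGNAL_WEIGHTS[g] / total for g in gens}
    father_loss = shares.get(1, 0.0)
    return {
        "shares": shares,
        "father_loss": father_loss,
        "father_loss_percent_truncated": math.floor(father_loss * 100),
    }


def quartile_summary(cohort: pd.DataFrame, outcome_column: str, wmama_column: str = "wmama") -> pd.DataFrame:
    """Per-quartile mean and standard error of an outcome.

    Rows are binned by empirical quartile cut-points of the WMAMA column
    (linear-interpolation quantiles); values tied with a cut-point fall in
    the lower quartile.  Returns one row per quartile with the lower
    threshold (NaN for the first quartile), mean outcome, its standard error
    and the bin count.
    """
    m = cohort[wmama_column].to_numpy(dtype=float)
    if np.unique(m).size < 4:
        raise ValueError("quartiles undefined: need at least 4 distinct WMAMA values")
    cuts = np.quantile(m, [0.25, 0.5, 0.75])
    # side='left' so values equal to a cut-point stay in the lower quartile
    quartile = np.searchsorted(cuts, m, side="left") + 1
    rows = []
    y = cohort[outcome_column].to_numpy(dtype=float)
    for q in (1, 2, 3, 4):
        mask = quartile == q
        n = int(mask.sum())
        mean = float(y[mask].mean()) if n else float("nan")
        se = float(y[mask].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "quartile": q,
                "lower_threshold": float(cuts[q - 2]) if q > 1 else float("nan"),
                "mean_outcome": mean,
                "se": se,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
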