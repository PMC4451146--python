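"""Forward-time synthetic pedigree generator.

Generates a strictly monogamous, multi-generation population in which
deleterious de novo mutation counts rise linearly with paternal age, are
transmitted with Mendelian halving at each meiosis, and penalise survival to
age 15 multiplicatively.  The output has the statistical structure the
association analyses assume — a pedigree with ancestor ages, demographic
covariates (parish, social class, twin status, maternal age, birth year) and
fitness outcomes — together with a per-individual truth table of latent
mutation counts for validation.

Model sketch, per child:

* paternal age drawn from a truncated normal (default mean 33, sd 6);
* de novo deleterious count ~ Poisson((lambda_ref + beta*(age-30)) * f_del)
  from the father plus an age-independent Poisson maternal contribution;
* inherited count = Binomial(k_father, 1/2) + Binomial(k_mother, 1/2);
* survival to 15 with probability s0 * (1-hs)^k, shifted on the logit scale
  by parish, class, twin and maternal-age effects;
* non-survivors never marry or reproduce, so selection purges mutations.

The defaults emulate a pre-industrial high-mortality population: roughly
40% of children die before 15, ~60 de novo point mutations at paternal age
30 rising by ~20 per decade (one-third more at 40 than at 30), 5% of them
deleterious.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import IndividualRecord, Pedigree

__all__ = [
    "CovariateEffects",
    "SimulationConfig",
    "SimulatedCohort",
    "SimulationError",
    "sample_de_novo_count",
    "transmit_mutations",
    "survival_probability",
    "simulate_population",
    "cohort_from_truth",
    "logistic_cohort",
]


class SimulationError(RuntimeError):
    pass


def _logit(p: float | np.ndarray) -> float | np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CovariateEffects:
    """Nuisance covariate effects on the logit of survival to 15.

    Parish intercepts are drawn once per run from N(0, parish_sd^2); class
    effects are relative to the rich reference; maternal age acts per year
    centred at its mean.
    """

    parish_sd: float = 0.4
    class_middle: float = 0.05
    class_poor: float = -0.3
    twin: float = -1.0
    maternal_age: float = -0.01


@dataclass(frozen=True)
class AgeLaw:
    """Truncated normal age-at-parenthood distribution."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        # resample the few out-of-support draws rather than clipping, to
        # avoid probability mass piling on the bounds
        bad = (x < self.lo) | (x > self.hi)
        while bad.any():
            x[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = (x < self.lo) | (x > self.hi)
        return x


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults are the study conditions."""

    n_founder_couples: int = 150
    n_generations: int = 5  # founders + 4 descendant generations
    paternal_age_law: AgeLaw = field(default_factory=lambda: AgeLaw(33.0, 6.0, 18.0, 60.0))
    maternal_age_law: AgeLaw = field(default_factory=lambda: AgeLaw(29.0, 5.0, 16.0, 45.0))
    lambda_ref: float = 60.0  # expected de novo point mutations at paternal age 30
    beta: float = 2.0  # extra point mutations per year of paternal age (~20/decade)
    f_del: float = 0.05  # deleterious fraction of point mutations
    maternal_denovo_points: float = 15.0  # age-independent maternal point mutations
    hs: float = 0.04  # survival penalty per deleterious mutation
    s0: float = 0.62  # survival to 15 of a mutation-free individual
    marriage_base: float = 0.85
    female_marriage_wmama_slope: float = 0.0  # logit-scale, per WMAMA year
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    n_parishes: int = 7
    mean_children: float = 5.5  # completed family size of a married couple
    spouse_gap_mean: float = 4.0  # husband older than wife, on average (years)
    spouse_gap_sd: float = 3.0
    twin_rate: float = 0.03
    emigration_rate: float = 0.05
    founding_year: float = 1690.0
    class_probs: tuple[float, float, float] = (0.25, 0.45, 0.30)  # rich/middle/poor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_del", "hs", "s0", "marriage_base", "twin_rate", "emigration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_generations < 2:
            raise ValueError("n_generations must be at least 2")
        lo = self.lambda_ref + self.beta * (self.paternal_age_law.lo - 30.0)
        hi = self.lambda_ref + self.beta * (self.paternal_age_law.hi - 30.0)
        if min(lo, hi) < 0:
            raise ValueError("de novo mean is negative somewhere on the paternal age support")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")


@dataclass
class SimulatedCohort:
    """Pedigree plus the generative truth table (one row per individual)."""

    pedigree: Pedigree | None
    truth: pd.DataFrame
    config: SimulationConfig

    def probands(self) -> pd.DataFrame:
        """Truth rows of the final generation."""
        return self.truth[self.truth["generation"] == self.truth["generation"].max()]


def sample_de_novo_count(father_age: float | np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Paternal-age-dependent de novo deleterious mutation count.

    Poisson with mean ``(lambda_ref + beta*(father_age - 30)) * f_del``.
    """
    mean = (config.lambda_ref + config.beta * (np.asarray(father_age, dtype=float) - 30.0)) * config.f_del
    if np.any(mean < 0):
        raise ValueError("negative de novo mean: lambda_ref/beta misconfigured for this age")
    return rng.poisson(mean)


def transmit_mutations(parent_count: int | np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian halving: Binomial(parent_count, 1/2) mutations transmitted."""
    return rng.binomial(np.asarray(parent_count), 0.5)


def survival_probability(
    k_total_del: int | np.ndarray,
    config: SimulationConfig,
    covariate_logit_shift: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Survival to 15: s0 * (1-hs)^k, covariates shifting the logit.

    The multiplicative mutation penalty is applied first; any covariate
    shift then acts on the logit of that probability.  The result is clamped
    to (0, 1).
    """
    k = np.asarray(k_total_del, dtype=float)
    if np.any(k < 0):
        raise ValueError("mutation count must be non-negative")
    base = config.s0 * np.power(1.0 - config.hs, k)
    base = np.clip(base, 1e-9, 1.0 - 1e-9)
    p = _expit(_logit(base) + np.asarray(covariate_logit_shift, dtype=float))
    return np.clip(p, 0.0, 1.0)


class _GenerationArrays:
    """Column arrays for one generation of individuals."""

    __slots__ = (
        "ids", "sex_male", "birth", "parish", "social", "twin", "first_born",
        "father_row", "mother_row", "father_age", "maternal_age",
        "k", "k_denovo", "k_inherited", "survived", "married", "marriage_year",
        "death", "emigration", "g1", "g2", "g3", "n_children",
    )

    def __init__(self, n: int):
        self.ids = np.empty(n, dtype=object)
        self.sex_male = np.zeros(n, dtype=bool)
        self.birth = np.zeros(n, dtype=float)
        self.parish = np.zeros(n, dtype=np.int64)
        self.social = np.zeros(n, dtype=np.int64)
        self.twin = np.zeros(n, dtype=bool)
        self.first_born = np.zeros(n, dtype=bool)
        self.father_row = np.full(n, -1, dtype=np.int64)
        self.mother_row = np.full(n, -1, dtype=np.int64)
        self.father_age = np.full(n, np.nan)
        self.maternal_age = np.full(n, np.nan)
        self.k = np.zeros(n, dtype=np.int64)
        self.k_denovo = np.zeros(n, dtype=np.int64)
        self.k_inherited = np.zeros(n, dtype=np.int64)
        self.survived = np.ones(n, dtype=bool)
        self.married = np.zeros(n, dtype=bool)
        self.marriage_year = np.full(n, np.nan)
        self.death = np.full(n, np.nan)
        self.emigration = np.full(n, np.nan)
        # ancestral ages-at-fathering carried down the pedigree so the true
        # WMAMA is available without re-traversal
        self.g1 = np.full(n, np.nan)
        self.g2 = np.full((n, 2), np.nan)
        self.g3 = np.full((n, 4), np.nan)
        self.n_children = np.full(n, np.nan)

    def __len__(self) -> int:
        return len(self.ids)


def _true_wmama(g1: np.ndarray, g2: np.ndarray, g3: np.ndarray) -> np.ndarray:
    ages = np.column_stack([g1, g2, g3])
    w = np.array([0.5, 0.25, 0.25, 0.125, 0.125, 0.125, 0.125])
    known = ~np.isnan(ages)
    num = np.nansum(ages * w, axis=1)
    den = (known * w).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _pair_within_parish(
    gen: _GenerationArrays, seeking: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Monogamous pairing within parish.

    Each male seeks a wife born ``spouse_gap_mean`` years after him (with
    ``spouse_gap_sd`` dispersion); males sorted by that target birth year
    are matched against females sorted by actual birth year, which keeps
    husbands a few years older than wives on average so that implied
    maternal ages centre on the configured maternal age law."""
    pairs: list[tuple[int, int]] = []
    for p in range(config.n_parishes):
        males = np.flatnonzero(seeking & gen.sex_male & (gen.parish == p))
        females = np.flatnonzero(seeking & ~gen.sex_male & (gen.parish == p))
        n = min(len(males), len(females))
        # the surplus of the more numerous sex stays unmarried at random
        # (taking the tail of the sorted list would systematically leave the
        # latest-born unmarried and fabricate a birth-year effect)
        if len(males) > n:
            males = rng.choice(males, size=n, replace=False)
        if len(females) > n:
            females = rng.choice(females, size=n, replace=False)
        target = gen.birth[males] + rng.normal(config.spouse_gap_mean, config.spouse_gap_sd, size=n)
        males = males[np.argsort(target, kind="stable")]
        females = females[np.argsort(gen.birth[females], kind="stable")]
        pairs.extend(zip(males.tolist(), females.tolist()))
    return pairs


def simulate_population(config: SimulationConfig, build_pedigree: bool = True) -> SimulatedCohort:
    """Run the forward simulation; fully reproducible from ``config.seed``.

    ``build_pedigree=False`` skips materialising per-individual records
    (useful for repeated calibration runs that only need the truth table;
    the random stream, and hence the truth table, is unaffected).

    Raises :class:`SimulationError`, naming the generation, if the breeding
    pool empties before ``n_generations`` generations are produced.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_setup, *gen_seeds = ss.spawn(config.n_generations + 1)
    rng0 = np.random.default_rng(rng_setup)
    eff = config.covariate_effects
    parish_effects = rng0.normal(0.0, eff.parish_sd, size=config.n_parishes)
    class_effects = np.array([0.0, eff.class_middle, eff.class_poor])

    generations: list[_GenerationArrays] = []

    # founders: generation 0, mutation-free married couples
    nf = config.n_founder_couples
    founders = _GenerationArrays(2 * nf)
    founders.sex_male[:nf] = True
    founders.parish[:nf] = rng0.integers(0, config.n_parishes, size=nf)
    founders.parish[nf:] = founders.parish[:nf]
    founders.social[:nf] = rng0.choice(3, size=nf, p=config.class_probs)
    founders.social[nf:] = founders.social[:nf]
    founders.birth[:nf] = config.founding_year + rng0.uniform(-5.0, 5.0, size=nf)
    founders.birth[nf:] = founders.birth[:nf] + rng0.normal(config.spouse_gap_mean, config.spouse_gap_sd, size=nf)
    founders.married[:] = True
    founders.marriage_year = np.maximum(founders.birth[np.r_[0:nf, 0:nf]], founders.birth) + 20.0
    for i in range(2 * nf):
        founders.ids[i] = f"G0-{i:05d}"
    generations.append(founders)
    couple_rows: list[tuple[int, int]] = [(i, nf + i) for i in range(nf)]

    for g in range(1, config.n_generations):
        rng = np.random.default_rng(gen_seeds[g - 1])
        prev = generations[-1]
        if not couple_rows:
            raise SimulationError(f"population extinct: no breeding couples to found generation {g}")
        fa_rows = np.array([c[0] for c in couple_rows])
        mo_rows = np.array([c[1] for c in couple_rows])
        n_kids = rng.poisson(config.mean_children, size=len(couple_rows))
        total = int(n_kids.sum())
        if total == 0:
            raise SimulationError(f"population extinct: no births in generation {g}")

        cur = _GenerationArrays(total)
        child_couple = np.repeat(np.arange(len(couple_rows)), n_kids)
        cur.father_row = fa_rows[child_couple]
        cur.mother_row = mo_rows[child_couple]
        fb, mb = prev.birth[cur.father_row], prev.birth[cur.mother_row]

        pa = config.paternal_age_law.sample(total, rng)
        birth = fb + pa
        # keep the implied maternal age inside its own support
        lo = np.maximum(mb + config.maternal_age_law.lo, fb + config.paternal_age_law.lo)
        hi = np.minimum(mb + config.maternal_age_law.hi, fb + config.paternal_age_law.hi)
        hi = np.maximum(hi, lo)
        cur.birth = np.clip(birth, lo, hi)
        cur.father_age = cur.birth - fb
        cur.maternal_age = cur.birth - mb

        order = np.lexsort((cur.birth, child_couple))
        first = np.zeros(total, dtype=bool)
        # first row of each couple block after sorting by birth year
        _, block_start = np.unique(child_couple[order], return_index=True)
        first[order[block_start]] = True
        cur.first_born = first

        cur.sex_male = rng.random(total) < 0.5
        cur.twin = rng.random(total) < config.twin_rate
        cur.parish = prev.parish[cur.father_row]
        cur.social = prev.social[cur.father_row]

        cur.k_inherited = transmit_mutations(prev.k[cur.father_row], rng) + transmit_mutations(prev.k[cur.mother_row], rng)
        cur.k_denovo = sample_de_novo_count(cur.father_age, config, rng) + rng.poisson(
            config.maternal_denovo_points * config.f_del, size=total
        )
        cur.k = cur.k_inherited + cur.k_denovo

        cur.g1 = cur.father_age
        cur.g2 = np.column_stack([prev.g1[cur.father_row], prev.g1[cur.mother_row]])
        cur.g3 = np.column_stack([prev.g2[cur.father_row], prev.g2[cur.mother_row]])

        shift = (
            parish_effects[cur.parish]
            + class_effects[cur.social]
            + eff.twin * cur.twin
            + eff.maternal_age * (cur.maternal_age - config.maternal_age_law.mean)
        )
        p_surv = survival_probability(cur.k, config, shift)
        cur.survived = rng.random(total) < p_surv
        cur.death = np.where(
            cur.survived,
            cur.birth + np.clip(rng.normal(60.0, 15.0, size=total), 15.5, 95.0),
            cur.birth + rng.uniform(0.0, 15.0, size=total),
        )
        emigrates = rng.random(total) < config.emigration_rate
        emi_year = cur.birth + rng.uniform(1.0, 40.0, size=total)
        # emigrants are lost to follow-up: death unobserved after emigration
        cur.emigration = np.where(emigrates, emi_year, np.nan)
        lost = emigrates & (emi_year < cur.death)
        cur.death[lost] = np.nan

        # marriage intent: survivors only; optional female WMAMA penalty
        wm = _true_wmama(cur.g1, cur.g2, cur.g3)
        wm_centred = np.where(np.isnan(wm), 0.0, wm - config.paternal_age_law.mean)
        intent_logit = _logit(config.marriage_base) + np.where(
            ~cur.sex_male, config.female_marriage_wmama_slope * wm_centred, 0.0
        )
        seeking = cur.survived & (rng.random(total) < _expit(intent_logit)) & ~lost

        for i in range(total):
            cur.ids[i] = f"G{g}-{i:05d}"
        generations.append(cur)

        pairs = _pair_within_parish(cur, seeking, config, rng)
        for m, f in pairs:
            cur.married[m] = cur.married[f] = True
            wed = max(cur.birth[m], cur.birth[f]) + rng.uniform(18.0, 25.0)
            cur.marriage_year[m] = cur.marriage_year[f] = wed
            # a wife takes her husband's class and parish at marriage
            cur.social[f] = cur.social[m]
        couple_rows = pairs

    # children counts and death-year consistency for reproducing generations
    last = config.n_generations - 1
    for g, gen in enumerate(generations):
        if g < last:
            counts = np.zeros(len(gen), dtype=np.int64)
            if g + 1 < len(generations):
                nxt = generations[g + 1]
                np.add.at(counts, nxt.father_row, 1)
                np.add.at(counts, nxt.mother_row, 1)
                # a parent must outlive (or at least reach) the last birth
                last_birth = np.full(len(gen), -np.inf)
                np.maximum.at(last_birth, nxt.father_row, nxt.birth)
                np.maximum.at(last_birth, nxt.mother_row, nxt.birth)
                has_kids = counts > 0
                gen.death[has_kids] = np.fmax(gen.death[has_kids], last_birth[has_kids] + 0.5)
            gen.n_children = np.where(gen.married, counts.astype(float), np.nan)
            gen.n_children[~gen.married] = 0.0
        else:
            # final generation never had the chance to reproduce
            gen.n_children = np.where(gen.married, np.nan, 0.0)

    pedigree = _to_pedigree(generations) if build_pedigree else None
    return SimulatedCohort(pedigree=pedigree, truth=_to_truth(generations), config=config)


_CLASS_NAMES = ("rich", "middle", "poor")


def _to_pedigree(generations: list[_GenerationArrays]) -> Pedigree:
    ped = Pedigree(records={})
    prev: _GenerationArrays | None = None
    for gen in generations:
        for i in range(len(gen)):
            fid = prev.ids[gen.father_row[i]] if prev is not None and gen.father_row[i] >= 0 else None
            mid = prev.ids[gen.mother_row[i]] if prev is not None and gen.mother_row[i] >= 0 else None
            ped.add(
                IndividualRecord(
                    id=gen.ids[i],
                    sex="male" if gen.sex_male[i] else "female",
                    father_id=fid,
                    mother_id=mid,
                    birth_year=float(gen.birth[i]),
                    death_year=None if math.isnan(gen.death[i]) else float(gen.death[i]),
                    emigration_year=None if math.isnan(gen.emigration[i]) else float(gen.emigration[i]),
                    parish=f"parish{gen.parish[i] + 1}",
                    social_class=_CLASS_NAMES[gen.social[i]],
                    twin=bool(gen.twin[i]),
                    first_born=bool(gen.first_born[i]),
                    married=bool(gen.married[i]),
                    marriage_year=None if math.isnan(gen.marriage_year[i]) else float(gen.marriage_year[i]),
                    n_children=None if math.isnan(gen.n_children[i]) else int(gen.n_children[i]),
                    maternal_age_at_birth=None if math.isnan(gen.maternal_age[i]) else float(gen.maternal_age[i]),
                )
            )
        prev = gen
    ped.validate()
    return ped


def _to_truth(generations: list[_GenerationArrays]) -> pd.DataFrame:
    frames = []
    prev: _GenerationArrays | None = None
    for g, gen in enumerate(generations):
        if prev is None:
            father_ids = mother_ids = np.full(len(gen), None, dtype=object)
        else:
            father_ids = prev.ids[gen.father_row]
            mother_ids = prev.ids[gen.mother_row]
        frames.append(
            pd.DataFrame(
                {
                    "id": gen.ids,
                    "generation": g,
                    "father_id": father_ids,
                    "mother_id": mother_ids,
                    "sex": np.where(gen.sex_male, "male", "female"),
                    "birth_year": gen.birth,
                    "father_age": gen.father_age,
                    "maternal_age": gen.maternal_age,
                    "k_denovo_del": gen.k_denovo,
                    "k_inherited_del": gen.k_inherited,
                    "k_total_del": gen.k,
                    "survived15": gen.survived,
                    "married": gen.married,
                    "n_children": gen.n_children,
                    "parish": [f"parish{p + 1}" for p in gen.parish],
                    "social_class": [_CLASS_NAMES[s] for s in gen.social],
                    "twin": gen.twin,
                    "first_born": gen.first_born,
                    "emigration_year": gen.emigration,
                    "death_year": gen.death,
                    "wmama_true": _true_wmama(gen.g1, gen.g2, gen.g3),
                }
            )
        )
        prev = gen
    return pd.concat(frames, ignore_index=True)


def cohort_from_truth(
    cohort: "SimulatedCohort",
    outcome: str = "survival15",
    generations: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Analysis table straight from the truth table (no pedigree traversal).

    Convenience for calibration studies: selects the requested generations
    (final generation by default), keeps rows with a defined true WMAMA and
    maternal age, and renames columns to the analysis layout used by
    :func:`lineage_load.associations.fit_model`.  The production path goes
    through :func:`lineage_load.pedigree.build_cohort`; the two agree on
    shared probands (asserted in the test-suite).
    """
    truth = cohort.truth
    if generations is None:
        generations = [int(truth["generation"].max())]
    sub = truth[truth["generation"].isin(generations)].copy()
    sub = sub[sub["wmama_true"].notna() & sub["maternal_age"].notna()]
    if outcome == "survival15":
        y = sub["survived15"].astype(int)
    elif outcome == "marriage":
        sub = sub[sub["survived15"]]
        y = sub["married"].astype(int)
    elif outcome == "longevity":
        sub = sub[sub["survived15"] & sub["death_year"].notna()]
        y = (sub["death_year"] - sub["birth_year"] - 15.0).clip(lower=0).astype(int)
    elif outcome == "lbs":
        sub = sub[sub["married"] & sub["n_children"].notna()]
        y = sub["n_children"].astype(int)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    out = pd.DataFrame(
        {
            "proband_id": sub["id"],
            "outcome": y,
            "wmama": sub["wmama_true"],
            "father_age": sub["father_age"],
            "maternal_age": sub["maternal_age"],
            "parish": sub["parish"],
            "social_class": sub["social_class"],
            "twin": sub["twin"].astype(int),
            "first_born": sub["first_born"].astype(int),
            "sex": sub["sex"],
            "birth_year": sub["birth_year"],
            "mother_id": sub["mother_id"],
            "death_age": sub["death_year"] - sub["birth_year"],
            "k_total_del": sub["k_total_del"],
        }
    ).reset_index(drop=True)
    return out


def logistic_cohort(
    n: int,
    intercept: float,
    slope: float,
    seed: int,
    wmama_mean: float = 33.0,
    wmama_sd: float = 2.5,
    covariate_effects: Mapping[str, float] | None = None,
    n_parishes: int = 7,
) -> pd.DataFrame:
    """Analysis table sampled directly from a known logistic model.

    Unlike :func:`simulate_population`, which generates outcomes through the
    mutation mechanism, this draws a binary outcome straight from
    ``logit(p) = intercept + slope * wmama + covariate effects`` with an
    exposure distribution matching the ancestral-age statistic's realistic
    spread.  Used for parameter-recovery and coverage studies where the true
    coefficient must be known exactly.

    ``covariate_effects`` maps design-column names (e.g. ``twin``,
    ``social_class[poor]``, ``parish[parish3]``, ``maternal_age``) to
    logit-scale coefficients; unnamed columns have zero effect.
    """
    rng = np.random.default_rng(seed)
    eff = dict(covariate_effects or {})
    w = rng.normal(wmama_mean, wmama_sd, size=n)
    parish = rng.integers(0, n_parishes, size=n)
    social = rng.choice(np.array(["rich", "middle", "poor"]), size=n, p=[0.25, 0.45, 0.30])
    twin = rng.random(n) < 0.03
    first_born = rng.random(n) < 0.3
    sex = rng.random(n) < 0.5
    maternal_age = rng.normal(29.0, 5.0, size=n)
    birth_year = rng.uniform(1700.0, 1900.0, size=n)
    mother_id = rng.integers(0, max(n // 3, 1), size=n)

    eta = intercept + slope * w
    for p in range(n_parishes):
        eta = eta + eff.get(f"parish[parish{p + 1}]", 0.0) * (parish == p)
    for cls in ("middle", "poor"):
        eta = eta + eff.get(f"social_class[{cls}]", 0.0) * (social == cls)
    eta = eta + eff.get("twin", 0.0) * twin
    eta = eta + eff.get("first_born", 0.0) * first_born
    eta = eta + eff.get("sex[female]", 0.0) * ~sex
    eta = eta + eff.get("maternal_age", 0.0) * maternal_age
    y = rng.random(n) < _expit(eta)

    return pd.DataFrame(
        {
            "proband_id": [f"d{i}" for i in range(n)],
            "outcome": y.astype(int),
            "wmama": w,
            "father_age": w,
            "maternal_age": maternal_age,
            "parish": [f"parish{p + 1}" for p in parish],
            "social_class": social,
            "twin": twin.astype(int),
            "first_born": first_born.astype(int),
            "sex": np.where(sex, "male", "female"),
            "birth_year": birth_year,
            "mother_id": [f"m{m}" for m in mother_id],
        }
    )
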