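"""Monte-Carlo calibration studies for the simulator + inference stack.

Each routine runs many independently seeded replicates and summarises how
the estimators behave under a known truth: type-I error / confidence
interval coverage under a neutral simulator (hs = 0), sign recovery of the
ancestral-age effect under selection, uniformity of permutation p-values,
and recovery of a known outcome-probability decline between WMAMA 30 and
40.  Replicate seeds are derived deterministically from ``base_seed``.

Problem sizes default to a few thousand probands per replicate and 100
replicates, which keeps each full study in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .associations import ModelSpec, fit_model, permutation_test, translate_effect
from .synthetic_data import SimulationConfig, cohort_from_truth, logistic_cohort, simulate_population

__all__ = [
    "null_calibration",
    "power_calibration",
    "slope_recovery",
    "decline_recovery",
    "FOUNDERS_2K",
    "FOUNDERS_4K",
]

#: Founder-couple counts that yield roughly 2,000 / 4,000 final-generation
#: probands (the neutral run at hs = 0 loses fewer children, so it needs
#: fewer founders; calibrated once on the default demography).
FOUNDERS_2K = 190
FOUNDERS_4K = 830

_SPEC = ModelSpec(outcome="survival15")


def _seeds(base_seed: int, n: int) -> list[int]:
    # keep derived seeds well below 2**31
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31 - 1)]


def null_calibration(
    n_seeds: int = 100,
    n_founder_couples: int = FOUNDERS_2K,
    base_seed: int = 0,
    n_permutations: int = 99,
) -> dict:
    """Neutral-simulator calibration: hs = 0, so WMAMA has no causal path
    to survival.

    Returns CI coverage of zero, the fraction of |z| < 1.96, the
    permutation p-values and their Kolmogorov-Smirnov distance from
    uniform.
    """
    covered = 0
    calm = 0
    pvals = []
    ns = []
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(n_founder_couples=n_founder_couples, hs=0.0, seed=seed)
        sim = simulate_population(config, build_pedigree=False)
        cohort = cohort_from_truth(sim)
        ns.append(len(cohort))
        res = fit_model(cohort, _SPEC)
        lo, hi = res.exposure_ci
        covered += lo <= 0.0 <= hi
        calm += abs(res.exposure_coefficient / res.bse[_SPEC.exposure]) < 1.96
        pvals.append(permutation_test(cohort, _SPEC, n_permutations=n_permutations, seed=seed))
    pvals = np.asarray(pvals)
    ks = stats.kstest(pvals, "uniform")
    return {
        "n_seeds": n_seeds,
        "mean_n": float(np.mean(ns)),
        "ci_coverage_of_zero": covered / n_seeds,
        "fraction_abs_z_below_1p96": calm / n_seeds,
        "permutation_pvalues": pvals,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def power_calibration(
    n_seeds: int = 100,
    n_founder_couples: int = FOUNDERS_4K,
    base_seed: int = 1,
) -> dict:
    """Sign recovery under selection: default simulator (hs = 0.04).

    Returns the fraction of replicates whose fitted WMAMA slope on survival
    to 15 is negative, plus the slope distribution.
    """
    slopes = []
    ns = []
    for seed in _seeds(base_seed, n_seeds):
        config = SimulationConfig(n_founder_couples=n_founder_couples, seed=seed)
        sim = simulate_population(config, build_pedigree=False)
        cohort = cohort_from_truth(sim)
        ns.append(len(cohort))
        res = fit_model(cohort, _SPEC, robust=False)
        slopes.append(res.exposure_coefficient)
    slopes = np.asarray(slopes)
    return {
        "n_seeds": n_seeds,
        "mean_n": float(np.mean(ns)),
        "fraction_negative": float(np.mean(slopes < 0)),
        "slope_mean": float(slopes.mean()),
        "slope_sd": float(slopes.std(ddof=1)),
    }


def slope_recovery(
    true_slope: float = -0.036,
    n: int = 4000,
    n_seeds: int = 100,
    base_seed: int = 2,
    p_at_30: float = 0.62,
) -> dict:
    """CI coverage of a known logit slope in directly generated cohorts.

    The intercept is set so the survival probability at WMAMA 30 equals
    ``p_at_30``; the outcome is drawn straight from the logistic model, so
    the estimand is exact.
    """
    intercept = float(np.log(p_at_30 / (1 - p_at_30)) - 30.0 * true_slope)
    covered = 0
    for seed in _seeds(base_seed, n_seeds):
        cohort = logistic_cohort(n, intercept, true_slope, seed=seed)
        res = fit_model(cohort, _SPEC)
        lo, hi = res.exposure_ci
        covered += lo <= true_slope <= hi
    return {"n_seeds": n_seeds, "n": n, "true_slope": true_slope, "ci_coverage": covered / n_seeds}


def decline_recovery(
    true_relative_decline: float = 0.135,
    n: int = 4000,
    n_seeds: int = 100,
    base_seed: int = 3,
    p_at_30: float = 0.62,
    ci_draws: int = 1000,
) -> dict:
    """Recovery of a known relative survival decline between WMAMA 30 and 40.

    Solves for the logistic slope whose predicted probabilities at the two
    exposure values differ by the stated relative decline, generates
    cohorts from that model, and checks how often each run's 95% interval
    for the translated decline contains the truth.
    """
    logit = lambda p: float(np.log(p / (1 - p)))
    p_at_40 = p_at_30 * (1 - true_relative_decline)
    slope = (logit(p_at_40) - logit(p_at_30)) / 10.0
    intercept = logit(p_at_30) - 30.0 * slope
    covered = 0
    declines = []
    for seed in _seeds(base_seed, n_seeds):
        cohort = logistic_cohort(n, intercept, slope, seed=seed)
        res = fit_model(cohort, _SPEC)
        tr = translate_effect(res, ci_draws=ci_draws, seed=seed)
        declines.append(tr.relative_decline)
        lo, hi = tr.relative_decline_ci
        covered += lo <= true_relative_decline <= hi
    return {
        "n_seeds": n_seeds,
        "n": n,
        "true_relative_decline": true_relative_decline,
        "true_slope": slope,
        "ci_coverage": covered / n_seeds,
        "mean_recovered_decline": float(np.mean(declines)),
    }
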