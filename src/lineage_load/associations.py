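"""Fitness association analyses.

Four outcomes are modelled against the weighted mean age of male ancestors
(WMAMA): survival to 15 and probability of marriage as binomial-logit GLMs,
adult longevity (years lived past 15) and lifetime breeding success as
Poisson-log GLMs.  Inference uses maximum likelihood with cluster-robust
standard errors on maternal identity, supplemented by permutation tests that
shuffle the exposure within parish strata.  A discrete-time (person-year)
logistic hazard model approximates proportional-hazards regression of
childhood mortality risk; for annual records and small per-year hazards the
two coincide to first order.

Coefficients on the link scale are translated into the decline in the
predicted outcome probability between WMAMA 30 and 40, the scale on which
ancestral-age effects are usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "EffectTranslation",
    "FitError",
    "fit_model",
    "backward_prune",
    "discrete_time_hazard",
    "permutation_test",
    "translate_effect",
    "compare_models",
]

BINOMIAL_OUTCOMES = {"survival15", "marriage", "hazard"}
POISSON_OUTCOMES = {"longevity", "lbs"}

#: Default covariate set mirroring the demographic nuisance structure:
#: parish, social class, twin status, birth order, maternal age, sex and
#: 25-year birth-year bins.
DEFAULT_COVARIATES = (
    "parish",
    "social_class",
    "twin",
    "first_born",
    "maternal_age",
    "sex",
    "birth_year_bins",
)


class FitError(RuntimeError):
    """Model could not be fitted (separation, rank deficiency, no data)."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``covariates`` may contain: parish, social_class, twin, first_born,
    maternal_age, maternal_age_sq, sex, birth_year_bins.  ``interactions``
    lists covariate names whose dummies are crossed with the exposure.
    ``cluster`` names the grouping column for robust standard errors.
    """

    outcome: str
    exposure: str = "wmama"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cluster: str | None = "mother_id"
    interactions: tuple[str, ...] = ()

    @property
    def family_name(self) -> str:
        if self.outcome in BINOMIAL_OUTCOMES:
            return "binomial-logit"
        if self.outcome in POISSON_OUTCOMES:
            return "poisson-log"
        raise ValueError(f"unknown outcome {self.outcome!r}")

    def family(self) -> sm.families.Family:
        return sm.families.Binomial() if self.family_name == "binomial-logit" else sm.families.Poisson()


@dataclass
class AssociationResult:
    """A converged fit with link-scale coefficients and provenance."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    n_rows: int
    loglik: float
    aic: float
    term_blocks: dict[str, list[str]]
    covariate_means: pd.Series
    cov_params: pd.DataFrame
    permutation_p: float | None = None
    pearson_dispersion: float | None = None

    @property
    def exposure_coefficient(self) -> float:
        return float(self.params[self.spec.exposure])

    @property
    def exposure_ci(self) -> tuple[float, float]:
        row = self.conf_int.loc[self.spec.exposure]
        return float(row["lower"]), float(row["upper"])

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "lower": self.conf_int["lower"], "upper": self.conf_int["upper"]}
        )


_BIN_WIDTH = 25.0  # birth-year bins, e.g. 1701-1725


def _birth_year_bin(year: pd.Series) -> pd.Series:
    return (np.floor((year - 1.0) / _BIN_WIDTH) * _BIN_WIDTH + 1).astype(int).astype(str)


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, pd.DataFrame, dict[str, list[str]]]:
    """Response vector, design matrix and term -> column map.

    Categorical references: first parish in sorted order, the ``rich``
    social class, singleton, not first-born, male, earliest birth-year bin.
    """
    needed = {spec.exposure, "outcome"} | {c for c in spec.covariates if c not in ("maternal_age_sq", "birth_year_bins")}
    needed.discard("birth_year")
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise FitError(f"cohort lacks required column(s): {', '.join(sorted(missing))}")
    if cohort[sorted(needed)].isna().any().any():
        bad = [c for c in sorted(needed) if cohort[c].isna().any()]
        raise FitError(f"missing values in analysis column(s): {', '.join(bad)}")
    if len(cohort) < 2:
        raise FitError(f"insufficient data: {len(cohort)} row(s)")

    y = cohort["outcome"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(cohort))}
    blocks: dict[str, list[str]] = {"const": ["const"]}

    def add_dummies(term: str, series: pd.Series, reference: str | None = None) -> None:
        levels = sorted(series.astype(str).unique())
        if reference is None:
            reference = levels[0]
        elif reference in levels:
            levels.remove(reference)
            levels.insert(0, reference)
        names = []
        for lev in levels[1:] if len(levels) > 1 else []:
            name = f"{term}[{lev}]"
            cols[name] = (series.astype(str) == lev).to_numpy(dtype=float)
            names.append(name)
        blocks[term] = names

    for cov in spec.covariates:
        if cov == "parish":
            add_dummies("parish", cohort["parish"])
        elif cov == "social_class":
            add_dummies("social_class", cohort["social_class"], reference="rich")
        elif cov == "sex":
            add_dummies("sex", cohort["sex"], reference="male")
        elif cov == "birth_year_bins":
            add_dummies("birth_year_bins", _birth_year_bin(cohort["birth_year"]))
        elif cov == "maternal_age_sq":
            cols["maternal_age_sq"] = (cohort["maternal_age"].to_numpy(dtype=float)) ** 2
            blocks["maternal_age_sq"] = ["maternal_age_sq"]
        elif cov in ("twin", "first_born", "maternal_age"):
            cols[cov] = cohort[cov].to_numpy(dtype=float)
            blocks[cov] = [cov]
        else:
            raise FitError(f"unknown covariate {cov!r}")

    exposure = cohort[spec.exposure].to_numpy(dtype=float)
    cols[spec.exposure] = exposure
    blocks[spec.exposure] = [spec.exposure]

    for term in spec.interactions:
        if term not in blocks:
            raise FitError(f"interaction partner {term!r} not among fitted covariates")
        names = []
        for base_col in blocks[term]:
            name = f"{spec.exposure}:{base_col}"
            cols[name] = exposure * cols[base_col]
            names.append(name)
        blocks[f"{spec.exposure}:{term}"] = names

    X = pd.DataFrame(cols, index=cohort.index)
    return y, X, blocks


def _drop_degenerate_levels(y: np.ndarray, X: pd.DataFrame, blocks: dict[str, list[str]], binomial: bool) -> pd.DataFrame:
    """Merge categorical levels whose outcome is constant into the reference.

    A binomial level with all-0 or all-1 outcomes would be fitted to +/-
    infinity (complete separation); dropping the dummy keeps the fit finite
    at the cost of pooling that level with the reference.
    """
    if not binomial:
        return X
    drop = []
    for term, names in blocks.items():
        for name in names:
            col = X[name].to_numpy()
            if set(np.unique(col)) <= {0.0, 1.0} and col.any():
                sub = y[col == 1.0]
                if sub.min() == sub.max() and len(sub) < len(y):
                    drop.append(name)
    if drop:
        warnings.warn(f"degenerate categorical level(s) merged into reference: {', '.join(drop)}", stacklevel=3)
        X = X.drop(columns=drop)
        for names in blocks.values():
            for name in drop:
                if name in names:
                    names.remove(name)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(arr / scale, mode="r")
    diag = np.abs(np.diag(r))
    bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
    if bad:
        raise FitError(f"rank-deficient design; collinear column(s): {', '.join(map(str, bad))}")


def fit_model(cohort: pd.DataFrame, spec: ModelSpec, robust: bool = True) -> AssociationResult:
    """Maximum-likelihood GLM fit with (optionally) cluster-robust errors.

    Binomial outcomes use a logit link, count outcomes a log link.  With
    ``robust=True`` and a ``cluster`` column in the spec, standard errors
    are clustered on it (maternal identity by default), absorbing the
    within-family correlation that a random intercept would model.
    """
    y, X, blocks = build_design(cohort, spec)
    binomial = spec.family_name == "binomial-logit"
    X = _drop_degenerate_levels(y, X, blocks, binomial)
    _check_rank(X)

    model = sm.GLM(y, X, family=spec.family())
    kwargs: dict = {}
    if robust and spec.cluster is not None:
        if spec.cluster not in cohort.columns:
            raise FitError(f"cluster column {spec.cluster!r} not in cohort")
        groups = pd.Categorical(cohort[spec.cluster]).codes
        if len(np.unique(groups)) > 1:
            kwargs = {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    try:
        res = model.fit(maxiter=200, **kwargs)
    except Exception as exc:  # statsmodels raises several flavours here
        raise FitError(f"GLM fit failed for outcome {spec.outcome!r}: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"GLM fit diverged for outcome {spec.outcome!r} (non-finite coefficients); possible separation")

    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    means = X.mean(axis=0)
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    return AssociationResult(
        spec=spec,
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        n_rows=len(cohort),
        loglik=float(res.llf),
        aic=float(res.aic),
        term_blocks=blocks,
        covariate_means=means,
        cov_params=res.cov_params(),
        pearson_dispersion=dispersion,
    )


def backward_prune(cohort: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05) -> ModelSpec:
    """Drop nuisance covariates whose confidence interval covers zero.

    Iteratively removes the weakest covariate block whose coefficients all
    have 95% CIs covering zero; the exposure is never removed, and maternal
    age is retained whenever it was significant in the model *before* the
    exposure entered (so that its confounding role is preserved even if the
    exposure absorbs its significance).
    """
    protected = {spec.exposure, "const"}
    if "maternal_age" in spec.covariates:
        # significance of maternal age before the exposure enters: fit the
        # covariates-only model (exposure column dropped from the design)
        y, X, blocks = build_design(cohort, spec)
        X0 = X.drop(columns=blocks[spec.exposure])
        X0 = _drop_degenerate_levels(y, X0, {k: list(v) for k, v in blocks.items() if k != spec.exposure}, spec.family_name == "binomial-logit")
        res0 = sm.GLM(y, X0, family=spec.family()).fit(maxiter=200)
        ci0 = res0.conf_int()
        if "maternal_age" in X0.columns:
            lo, hi = ci0.loc["maternal_age"]
            if lo > 0 or hi < 0:
                protected.add("maternal_age")

    current = spec
    while True:
        result = fit_model(cohort, current)
        removable: list[tuple[float, str]] = []
        for term in current.covariates:
            if term in protected or term not in result.term_blocks:
                continue
            names = [n for n in result.term_blocks[term] if n in result.params.index]
            if not names:
                removable.append((0.0, term))
                continue
            covers = all(result.conf_int.loc[n, "lower"] <= 0 <= result.conf_int.loc[n, "upper"] for n in names)
            if covers:
                zmax = max(abs(result.params[n] / result.bse[n]) for n in names)
                removable.append((zmax, term))
        if not removable:
            return current
        _, weakest = min(removable)
        current = replace(current, covariates=tuple(c for c in current.covariates if c != weakest))


def expand_person_years(cohort: pd.DataFrame, max_age: int = 15) -> pd.DataFrame:
    """One row per proband per life-year up to death or ``max_age``.

    Requires a ``death_age`` column (NaN = survived past ``max_age``).
    Adds ``age`` (the year lived) and replaces ``outcome`` with the
    per-year death indicator.
    """
    if "death_age" not in cohort.columns:
        raise FitError("person-year expansion needs a 'death_age' column")
    death = cohort["death_age"].to_numpy(dtype=float)
    years = np.where(np.isnan(death), max_age, np.minimum(np.ceil(death + 1e-9), max_age)).astype(int)
    years = np.maximum(years, 1)
    idx = np.repeat(np.arange(len(cohort)), years)
    expanded = cohort.iloc[idx].reset_index(drop=True)
    age = np.concatenate([np.arange(n) for n in years])
    expanded["age"] = age
    died_here = np.zeros(len(expanded), dtype=float)
    last = np.cumsum(years) - 1
    dies = ~np.isnan(death) & (death < max_age)
    died_here[last[dies]] = 1.0
    expanded["outcome"] = died_here
    if len(expanded) == 0:
        raise FitError("empty person-year expansion")
    return expanded


def discrete_time_hazard(cohort: pd.DataFrame, spec: ModelSpec | None = None, max_age: int = 15) -> AssociationResult:
    """Person-year logistic hazard of death before ``max_age``.

    Each life-year is a Bernoulli death trial; the baseline hazard is a
    step function of age (single-year dummies).  The exponentiated exposure
    coefficient is the per-year mortality hazard ratio per unit of
    exposure.  Degenerate data (no deaths at all) raise :class:`FitError`.
    """
    if spec is None:
        spec = ModelSpec(outcome="hazard")
    expanded = expand_person_years(cohort, max_age=max_age)
    if expanded["outcome"].sum() == 0:
        raise FitError("no deaths observed; hazard model undefined")

    y, X, blocks = build_design(expanded, spec)
    # piecewise-constant baseline: 3-year age bands keep the design small
    band = (expanded["age"] // 3).astype(int).astype(str)
    names = []
    for lev in sorted(band.unique())[1:]:
        name = f"age_band[{lev}]"
        X[name] = (band == lev).to_numpy(dtype=float)
        names.append(name)
    blocks["age_band"] = names
    X = _drop_degenerate_levels(y, X, blocks, binomial=True)
    _check_rank(X)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:
        raise FitError(f"hazard fit failed: {exc}") from exc
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return AssociationResult(
        spec=spec,
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        n_rows=len(cohort),
        loglik=float(res.llf),
        aic=float(res.aic),
        term_blocks=blocks,
        covariate_means=X.mean(axis=0),
        cov_params=res.cov_params(),
    )


def permutation_test(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_permutations: int = 999,
    seed: int = 0,
    strata: str = "parish",
) -> float:
    """Permutation p-value for the exposure coefficient.

    Shuffling the raw exposure would break its correlation with nuisance
    covariates (the ancestral-age statistic co-moves with maternal age and
    birth year), which makes the naive test anti-conservative.  Instead the
    exposure is first residualised on the other design columns; the
    residuals are then shuffled within strata (parishes by default) and
    added back to the fitted part, so permuted exposures keep the covariate
    structure while severing any exposure-outcome link beyond it
    (Kennedy-style residual permutation).

    p = (1 + #{|b_perm| >= |b_obs|}) / (n_permutations + 1); deterministic
    given the seed.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    y, X, blocks = build_design(cohort, spec)
    X = _drop_degenerate_levels(y, X, blocks, spec.family_name == "binomial-logit")
    _check_rank(X)
    family = spec.family()
    res_obs = sm.GLM(y, X, family=family).fit(maxiter=200)
    b_obs = abs(float(res_obs.params[spec.exposure]))

    rng = np.random.default_rng(seed)
    exp_col = X.columns.get_loc(spec.exposure)
    Xmat = X.to_numpy().copy()
    exposure = Xmat[:, exp_col].copy()
    others = np.delete(Xmat, exp_col, axis=1)
    coef, *_ = np.linalg.lstsq(others, exposure, rcond=None)
    fitted_part = others @ coef
    residuals = exposure - fitted_part

    groups = pd.Categorical(cohort[strata]).codes if strata in cohort.columns else np.zeros(len(cohort), dtype=int)
    group_rows = [np.flatnonzero(groups == g) for g in np.unique(groups)]
    start = res_obs.params.to_numpy()

    hits = 0
    for _ in range(n_permutations):
        perm = residuals.copy()
        for rows in group_rows:
            perm[rows] = perm[rng.permutation(rows)]
        Xmat[:, exp_col] = fitted_part + perm
        res_p = sm.GLM(y, Xmat, family=family).fit(maxiter=100, start_params=start)
        if abs(float(res_p.params[exp_col])) >= b_obs:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


@dataclass(frozen=True)
class EffectTranslation:
    """Link-scale coefficient translated to outcome-probability declines."""

    reference_wmama: float
    comparison_wmama: float
    p_ref: float
    p_cmp: float
    absolute_decline: float
    relative_decline: float
    relative_decline_ci: tuple[float, float] | None = None


def _profile_row(result: AssociationResult, profile: Mapping[str, float] | None) -> pd.Series:
    """Prediction row: reference categories (dummies at 0), continuous
    covariates at their cohort mean, overridable via ``profile``."""
    row = pd.Series(0.0, index=result.params.index)
    row["const"] = 1.0
    for cont in ("maternal_age", "maternal_age_sq"):
        if cont in row.index:
            row[cont] = float(result.covariate_means[cont])
    if profile:
        for k, v in profile.items():
            if k not in row.index:
                raise KeyError(f"profile names unknown column {k!r}")
            row[k] = v
    return row


def translate_effect(
    result: AssociationResult,
    reference: float = 30.0,
    comparison: float = 40.0,
    covariate_profile: Mapping[str, float] | None = None,
    ci_draws: int = 0,
    seed: int = 0,
) -> EffectTranslation:
    """Predicted outcome-probability decline between two exposure values.

    Only meaningful for binomial fits.  The relative decline is
    ``(p_ref - p_cmp) / p_ref``; the absolute decline is the difference in
    probability points.  With ``ci_draws > 0`` a 95% interval for the
    relative decline is obtained by sampling coefficient vectors from their
    asymptotic normal distribution.
    """
    if result.spec.family_name != "binomial-logit":
        raise ValueError("effect translation is defined for binomial fits only")
    if result.spec.exposure not in result.params.index:
        raise KeyError(f"exposure {result.spec.exposure!r} absent from fit")

    row = _profile_row(result, covariate_profile)

    def predict(params: np.ndarray, exposure_value: float) -> float | np.ndarray:
        x = row.copy()
        x[result.spec.exposure] = exposure_value
        eta = params @ x.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    beta = result.params.to_numpy()
    p_ref = float(predict(beta, reference))
    p_cmp = float(predict(beta, comparison))
    absolute = p_ref - p_cmp
    relative = absolute / p_ref if p_ref > 0 else np.nan

    ci = None
    if ci_draws > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(beta, result.cov_params.to_numpy(), size=ci_draws)
        pr = np.asarray(predict(draws, reference))
        pc = np.asarray(predict(draws, comparison))
        rel = (pr - pc) / pr
        ci = (float(np.quantile(rel, 0.025)), float(np.quantile(rel, 0.975)))

    return EffectTranslation(
        reference_wmama=reference,
        comparison_wmama=comparison,
        p_ref=p_ref,
        p_cmp=p_cmp,
        absolute_decline=absolute,
        relative_decline=relative,
        relative_decline_ci=ci,
    )


def compare_models(cohort: pd.DataFrame, specs: Sequence[ModelSpec], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """AIC comparison of candidate specifications on identical rows.

    Used for interaction screening (exposure x parish / class / sex): the
    spec with the lowest AIC wins.  All specs must address the same cohort.
    """
    if labels is None:
        labels = [",".join(s.interactions) if s.interactions else "base" for s in specs]
    rows = []
    for label, spec in zip(labels, specs):
        result = fit_model(cohort, spec, robust=False)
        if result.n_rows != len(cohort):
            raise FitError("specs fitted on differing row sets")
        rows.append({"model": label, "aic": result.aic, "loglik": result.loglik, "n_params": len(result.params)})
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
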