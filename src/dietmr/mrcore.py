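"""One-sample Mendelian randomisation with a Cox second stage.

Stage 1 regresses the dietary trait on its weighted allele score (plus
covariates) to obtain genetically predicted exposure values; stage 2 fits
an age-scale Cox proportional-hazards model of the outcome on those
fitted values, so the reported effect is a hazard ratio per unit of
exposure.  Pleiotropy diagnostics operate on per-instrument summary
estimates: MR-Egger's intercept tests directional pleiotropy, MR-PRESSO's
simulation-based global test detects heterogeneity, flags outlying
instruments and quantifies the distortion their removal causes.
Multivariable MR jointly instruments groups of correlated exposures, and
subgroup runs repeat the estimator by sex and cancer subsite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ivbuild import InstrumentDiagnostics, check_strength, f_statistic
from .survival import fit_cox

__all__ = [
    "EffectEstimate",
    "EggerResult",
    "PressoReport",
    "first_stage",
    "second_stage_cox",
    "two_stage_cox",
    "wald_ratio",
    "ivw_estimate",
    "mr_egger",
    "mr_presso",
    "multivariable_mr",
    "subgroup_run",
]


@dataclass
class EffectEstimate:
    """A hazard ratio with its 95% CI and provenance."""

    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    method: str
    trait: str = ""
    outcome: str = "crc"
    subgroup: str = "all"
    increment: str = "1 unit"
    f_stat: float | None = None
    p_pleiotropy: float | None = None
    n: int = 0
    events: int = 0

    @classmethod
    def from_loghr(cls, log_hr: float, se: float, **kw) -> "EffectEstimate":
        return cls(
            hr=float(np.exp(log_hr)),
            ci_low=float(np.exp(log_hr - 1.96 * se)),
            ci_high=float(np.exp(log_hr + 1.96 * se)),
            log_hr=float(log_hr),
            se=float(se),
            **kw,
        )


@dataclass
class EggerResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    intercept_p: float
    n_instruments: int


@dataclass
class PressoReport:
    global_p: float
    outlier_ids: list
    outlier_p: pd.Series
    distortion_p: float | None
    corrected_slope: float | None
    corrected_se: float | None
    n_sim: int
    seed: int


@dataclass
class FirstStageResult:
    fitted: np.ndarray
    diagnostics: InstrumentDiagnostics
    residuals: np.ndarray
    params: pd.Series


def first_stage(trait, score, covariates: pd.DataFrame | None = None) -> FirstStageResult:
    """Regress the exposure on its allele score; return fitted exposures.

    Fitted values are produced for every sample with a non-missing score
    (and covariates); the instrument-strength diagnostics carry the score
    coefficient, its SE and F = (beta/se)^2.
    """
    y = np.asarray(trait, float)
    s = np.asarray(score, float)
    if np.ptp(s[np.isfinite(s)]) == 0:
        raise ValueError("constant allele score")
    X = pd.DataFrame({"score": s})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], float)
    X = sm.add_constant(X, has_constant="add")
    fit_mask = np.isfinite(y) & np.all(np.isfinite(X.to_numpy()), axis=1)
    res = sm.OLS(y[fit_mask], X[fit_mask]).fit()
    pred_mask = np.all(np.isfinite(X.to_numpy()), axis=1)
    fitted = np.full(len(y), np.nan)
    fitted[pred_mask] = res.predict(X[pred_mask])
    diag = f_statistic(res.params["score"], res.bse["score"], n=int(fit_mask.sum()))
    residuals = np.full(len(y), np.nan)
    residuals[fit_mask] = y[fit_mask] - fitted[fit_mask]
    return FirstStageResult(fitted=fitted, diagnostics=diag, residuals=residuals, params=res.params)


def second_stage_cox(
    fitted,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    trait: str = "",
    outcome_label: str = "crc",
    subgroup: str = "all",
    increment: str = "1 unit",
    f_stat: float | None = None,
) -> EffectEstimate:
    """Age-scale Cox fit of the outcome on genetically predicted exposure.

    SE is the model-based Cox SE (no first-stage correction); see
    :func:`two_stage_cox` for a bootstrap that propagates stage-1 noise.
    """
    df = pd.DataFrame(
        {
            "entry_age": outcome["entry_age"].to_numpy(float),
            "exit_age": outcome["exit_age"].to_numpy(float),
            "event": (outcome["event"].to_numpy() > 0).astype(int),
            "xhat": np.asarray(fitted, float),
        }
    )
    covar_cols = []
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], float)
            covar_cols.append(c)
    fit = fit_cox(df, "xhat", covar_cols)
    return EffectEstimate.from_loghr(
        fit["log_hr"],
        fit["se"],
        method="2SLS-Cox",
        trait=trait,
        outcome=outcome_label,
        subgroup=subgroup,
        increment=increment,
        f_stat=f_stat,
        n=fit["n"],
        events=fit["events"],
    )


def two_stage_cox(
    trait,
    score,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_f: float = 10.0,
    allow_weak: bool = False,
    bootstrap: int = 0,
    seed: int = 0,
    trait_label: str = "",
    **labels,
) -> EffectEstimate:
    """Full one-sample 2SLS-Cox estimate for one trait.

    With ``bootstrap > 0`` the SE (and CI) are replaced by a nonparametric
    bootstrap over individuals that refits both stages, propagating
    first-stage uncertainty; the naive model-based SE is retained in
    ``EffectEstimate.se`` metadata only when bootstrap is off.
    """
    fs = first_stage(trait, score, covariates)
    check_strength(fs.diagnostics, min_f=min_f, allow_weak=allow_weak)
    est = second_stage_cox(
        fs.fitted, outcome, covariates, trait=trait_label, f_stat=fs.diagnostics.f_stat, **labels
    )
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(outcome)
        reps = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, n)
            try:
                fs_b = first_stage(
                    np.asarray(trait, float)[idx],
                    np.asarray(score, float)[idx],
                    covariates.iloc[idx].reset_index(drop=True) if covariates is not None else None,
                )
                est_b = second_stage_cox(
                    fs_b.fitted,
                    outcome.iloc[idx].reset_index(drop=True),
                    covariates.iloc[idx].reset_index(drop=True) if covariates is not None else None,
                )
                reps.append(est_b.log_hr)
            except Exception:
                continue
        if len(reps) >= 10:
            se_b = float(np.std(reps, ddof=1))
            est = EffectEstimate.from_loghr(
                est.log_hr,
                se_b,
                method=est.method,
                trait=est.trait,
                outcome=est.outcome,
                subgroup=est.subgroup,
                increment=est.increment,
                f_stat=est.f_stat,
                n=est.n,
                events=est.events,
            )
    return est


def wald_ratio(beta_out: float, beta_exp: float, se_out: float = np.nan, se_exp: float = 0.0):
    """Single-instrument ratio estimate beta_out / beta_exp with delta SE."""
    if beta_exp == 0:
        raise ValueError("exposure effect is zero: ratio undefined")
    est = beta_out / beta_exp
    se = np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4)
    return float(est), float(se)


def ivw_estimate(beta_exp, beta_out, se_out) -> tuple[float, float]:
    """Inverse-variance-weighted estimate (WLS through the origin)."""
    be, bo = np.asarray(beta_exp, float), np.asarray(beta_out, float)
    w = 1.0 / np.asarray(se_out, float) ** 2
    denom = (w * be**2).sum()
    b = (w * be * bo).sum() / denom
    return float(b), float(1.0 / np.sqrt(denom))


def mr_egger(beta_exp, se_exp, beta_out, se_out) -> EggerResult:
    """MR-Egger: weighted regression of outcome effects on exposure effects.

    Effect alleles are re-oriented so all exposure effects are
    non-negative (required for the intercept to identify directional
    pleiotropy); weights are 1/se_out^2 and the intercept p-value uses a
    t distribution on k - 2 df.
    """
    be = np.asarray(beta_exp, float).copy()
    bo = np.asarray(beta_out, float).copy()
    so = np.asarray(se_out, float)
    k = len(be)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = be < 0
    be[flip] *= -1
    bo[flip] *= -1
    X = sm.add_constant(be)
    res = sm.WLS(bo, X, weights=1.0 / so**2).fit()
    tstat = res.params[0] / res.bse[0]
    p_int = float(2 * stats.t.sf(abs(tstat), df=k - 2))
    return EggerResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        intercept_p=p_int,
        n_instruments=k,
    )


def _loo_slopes(be, bo, w):
    """Leave-one-out IVW slopes for every instrument (vectorized)."""
    s1 = (w * be * bo).sum()
    s2 = (w * be**2).sum()
    return (s1 - w * be * bo) / (s2 - w * be**2)


def mr_presso(
    beta_exp,
    se_exp,
    beta_out,
    se_out,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoReport:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares of the IVW fit (each instrument's
    residual taken against its leave-one-out prediction) is compared with
    a parametric simulation null in which exposure and outcome effects are
    redrawn from their sampling distributions; per-instrument residuals
    give Bonferroni-adjusted outlier p-values, and the distortion test
    compares the estimate after outlier removal with a null of removing
    random instrument subsets of the same size.  Fully seeded.
    """
    be = np.asarray(beta_exp, float)
    bo = np.asarray(beta_out, float)
    see = np.asarray(se_exp, float)
    seo = np.asarray(se_out, float)
    k = len(be)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim below 100 gives an unusable null; increase it")
    rng = np.random.default_rng(seed)
    w = 1.0 / seo**2
    loo = _loo_slopes(be, bo, w)
    obs_res2 = w * (bo - loo * be) ** 2
    rss_obs = obs_res2.sum()
    # parametric null: redraw effects around the LOO predictions
    be_sim = rng.normal(be, see, size=(n_sim, k))
    bo_sim = rng.normal(loo * be, seo, size=(n_sim, k))
    s1 = (w * be_sim * bo_sim).sum(axis=1, keepdims=True)
    s2 = (w * be_sim**2).sum(axis=1, keepdims=True)
    loo_sim = (s1 - w * be_sim * bo_sim) / (s2 - w * be_sim**2)
    sim_res2 = w * (bo_sim - loo_sim * be_sim) ** 2
    rss_sim = sim_res2.sum(axis=1)
    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (1 + n_sim))
    # per-instrument outlier test, Bonferroni over k
    p_var = (1 + (sim_res2 >= obs_res2[None, :]).sum(axis=0)) / (1 + n_sim)
    outlier_p = pd.Series(np.minimum(p_var * k, 1.0))
    outliers = list(np.flatnonzero(outlier_p.to_numpy() < outlier_alpha))
    distortion_p = None
    corrected_slope = corrected_se = None
    if outliers:
        keep = np.setdiff1d(np.arange(k), outliers)
        if len(keep) >= 2:
            b_all, _ = ivw_estimate(be, bo, seo)
            corrected_slope, corrected_se = ivw_estimate(be[keep], bo[keep], seo[keep])
            obs_dist = 100.0 * (b_all - corrected_slope) / abs(corrected_slope)
            n_out = len(outliers)
            dists = []
            for _ in range(n_sim):
                drop = rng.choice(k, n_out, replace=False)
                sub = np.setdiff1d(np.arange(k), drop)
                b_sub, _ = ivw_estimate(be[sub], bo[sub], seo[sub])
                dists.append(100.0 * (b_all - b_sub) / abs(b_sub))
            dists = np.asarray(dists)
            distortion_p = float((1 + (np.abs(dists) >= abs(obs_dist)).sum()) / (1 + n_sim))
    return PressoReport(
        global_p=global_p,
        outlier_ids=outliers,
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        corrected_slope=corrected_slope,
        corrected_se=corrected_se,
        n_sim=n_sim,
        seed=seed,
    )


def _correlation_groups(traits, score_cor, rg, r_score=0.10, r_g=0.30):
    """Connected components of the trait graph linked by either rule."""
    parent = {t: t for t in traits}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            linked = False
            if score_cor is not None and abs(score_cor.loc[a, b]) > r_score:
                linked = True
            if rg is not None and abs(rg.loc[a, b]) > r_g:
                linked = True
            if linked:
                union(a, b)
    groups: dict[str, list[str]] = {}
    for t in traits:
        groups.setdefault(find(t), []).append(t)
    return list(groups.values())


def multivariable_mr(
    traits_df: pd.DataFrame,
    scores_df: pd.DataFrame,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    score_cor: pd.DataFrame | None = None,
    rg: pd.DataFrame | None = None,
    r_score: float = 0.10,
    r_g: float = 0.30,
    max_condition: float = 1e8,
) -> tuple[list[EffectEstimate], list[list[str]]]:
    """Multivariable MR over groups of correlated exposures.

    Traits are grouped when their allele scores correlate (|r| > 0.10) or
    their genetic correlation is high (|r_g| > 0.30); within each group of
    two or more, stage 1 regresses every trait on ALL group scores jointly
    and stage 2 fits one Cox model on all fitted exposures simultaneously,
    giving direct effects.  Singleton groups are skipped.  A condition
    number gate rejects collinear fitted-exposure designs.
    """
    traits = list(traits_df.columns)
    if len(traits) < 2:
        raise ValueError("multivariable MR needs at least 2 traits")
    if score_cor is None:
        score_cor = scores_df.corr()
    groups = _correlation_groups(traits, score_cor, rg, r_score, r_g)
    results: list[EffectEstimate] = []
    for group in groups:
        if len(group) < 2:
            continue
        S = scores_df[group].to_numpy(float)
        X = sm.add_constant(
            np.hstack([S] + ([covariates.to_numpy(float)] if covariates is not None else []))
        )
        fitted = {}
        for t in group:
            y = traits_df[t].to_numpy(float)
            m = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
            res = sm.OLS(y[m], X[m]).fit()
            fv = np.full(len(y), np.nan)
            pm = np.all(np.isfinite(X), axis=1)
            fv[pm] = res.predict(X[pm])
            fitted[t] = fv
        F = np.column_stack([fitted[t] for t in group])
        ok = np.all(np.isfinite(F), axis=1)
        cond = np.linalg.cond(F[ok] - F[ok].mean(axis=0))
        if cond > max_condition:
            raise ValueError(
                f"collinear fitted exposures in group {group} (condition number {cond:.2e})"
            )
        df = pd.DataFrame(
            {
                "entry_age": outcome["entry_age"].to_numpy(float),
                "exit_age": outcome["exit_age"].to_numpy(float),
                "event": (outcome["event"].to_numpy() > 0).astype(int),
            }
        )
        for t in group:
            df[f"xhat_{t}"] = fitted[t]
        covar_cols = []
        if covariates is not None:
            for c in covariates.columns:
                df[c] = covariates[c].to_numpy(float)
                covar_cols.append(c)
        for t in group:
            others = [f"xhat_{o}" for o in group if o != t]
            fit = fit_cox(df, f"xhat_{t}", others + covar_cols)
            results.append(
                EffectEstimate.from_loghr(
                    fit["log_hr"],
                    fit["se"],
                    method="MVMR",
                    trait=t,
                    n=fit["n"],
                    events=fit["events"],
                )
            )
    return results, groups


SUBSITE_CODES = {"crc": None, "colon": 1, "rectal": 2}


def subgroup_run(
    trait,
    score,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    sexes: tuple[str, ...] = ("all", "men", "women"),
    subsites: tuple[str, ...] = ("crc", "colon", "rectal"),
    allow_weak: bool = True,
    **kw,
) -> list[EffectEstimate]:
    """Repeat the 2SLS-Cox estimator by sex and cancer subsite.

    Sex codes follow the cohort convention 0 = men, 1 = women.  For a
    subsite analysis the competing subsite's events are treated as
    censored at their event age.  Empty subgroups or subgroups without
    events raise.
    """
    trait = np.asarray(trait, float)
    score = np.asarray(score, float)
    results = []
    for sex_label in sexes:
        if sex_label == "all":
            m = np.ones(len(outcome), bool)
        elif sex_label == "men":
            m = outcome["sex"].to_numpy() == 0
        elif sex_label == "women":
            m = outcome["sex"].to_numpy() == 1
        else:
            raise ValueError(f"unknown sex subgroup {sex_label!r}")
        if m.sum() == 0:
            raise ValueError(f"empty subgroup {sex_label!r}")
        for site in subsites:
            out = outcome.loc[m].copy().reset_index(drop=True)
            code = SUBSITE_CODES[site]
            if code is not None:
                out["event"] = (out["event"] == code).astype(int)
            if (out["event"] > 0).sum() == 0:
                raise ValueError(f"no events in subgroup {sex_label}/{site}")
            est = two_stage_cox(
                trait[m],
                score[m],
                out,
                covariates.loc[m].reset_index(drop=True) if covariates is not None else None,
                allow_weak=allow_weak,
                outcome_label=site,
                subgroup=sex_label,
                **kw,
            )
            results.append(est)
    return results


def results_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Flatten effect estimates into the standard results table."""
    return pd.DataFrame(
        [
            {
                "trait": e.trait,
                "outcome": e.outcome,
                "subgroup": e.subgroup,
                "method": e.method,
                "hr": e.hr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "f_stat": e.f_stat,
                "p_pleiotropy": e.p_pleiotropy,
                "n": e.n,
                "events": e.events,
            }
            for e in estimates
        ]
    )
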