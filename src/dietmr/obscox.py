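"""Observational Cox association arm.

Univariate and multivariable age-scale Cox models of colorectal-cancer
risk on each dietary trait, with the conventional lifestyle adjustment
set.  This is the comparison arm for the MR estimates: under residual
confounding the observational hazard ratio is biased while the
instrumented estimate is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mrcore import EffectEstimate
from .survival import fit_cox

__all__ = ["CovariateSpec", "cox_fit", "confounder_screen"]

DEFAULT_ADJUSTMENTS = (
    "sex",
    "family_history",
    "income",
    "smoking",
    "alcohol",
    "bmi",
    "physical_activity",
)


@dataclass
class CovariateSpec:
    """Adjustment set for the multivariable observational model.

    Alcohol is dropped from the adjustment set when alcohol itself is the
    exposure.  ``increment`` labels the exposure scale of the reported HR
    (1 time/week, 100 mL/day, 1 serving/day, 1 cup/day).
    """

    adjustments: tuple[str, ...] = DEFAULT_ADJUSTMENTS
    increment: str = "1 unit"

    def for_exposure(self, exposure: str) -> list[str]:
        return [c for c in self.adjustments if c != exposure]


def cox_fit(
    exposure_name: str,
    exposure,
    outcome: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    spec: CovariateSpec | None = None,
    mode: str = "multivariable",
) -> EffectEstimate:
    """Observational age-scale Cox HR for one dietary exposure.

    ``mode='univariate'`` fits the exposure alone; ``'multivariable'``
    adds the adjustment set (complete case over exposure + covariates).
    Delayed entry at enrolment age; Efron ties.
    """
    spec = spec or CovariateSpec()
    df = pd.DataFrame(
        {
            "entry_age": outcome["entry_age"].to_numpy(float),
            "exit_age": outcome["exit_age"].to_numpy(float),
            "event": (outcome["event"].to_numpy() > 0).astype(int),
            exposure_name: np.asarray(exposure, float),
        }
    )
    covar_cols: list[str] = []
    if mode == "multivariable":
        if covariates is None:
            raise ValueError("multivariable mode requires a covariate table")
        for c in spec.for_exposure(exposure_name):
            if c in covariates.columns:
                df[c] = covariates[c].to_numpy(float)
                covar_cols.append(c)
    elif mode != "univariate":
        raise ValueError("mode must be 'univariate' or 'multivariable'")
    fit = fit_cox(df, exposure_name, covar_cols)
    return EffectEstimate.from_loghr(
        fit["log_hr"],
        fit["se"],
        method="observational",
        trait=exposure_name,
        increment=spec.increment,
        n=fit["n"],
        events=fit["events"],
    )


def confounder_screen(
    candidates: pd.DataFrame,
    outcome: pd.DataFrame,
    p_threshold: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Select adjustment covariates by univariate Cox screening.

    Each candidate is fit alone against the outcome; those with Wald
    p below the threshold are retained.  Returns the selected names and a
    decision log (candidate, log-HR, p, selected).
    """
    rows = []
    selected = []
    base = pd.DataFrame(
        {
            "entry_age": outcome["entry_age"].to_numpy(float),
            "exit_age": outcome["exit_age"].to_numpy(float),
            "event": (outcome["event"].to_numpy() > 0).astype(int),
        }
    )
    for c in candidates.columns:
        df = base.copy()
        df[c] = candidates[c].to_numpy(float)
        try:
            fit = fit_cox(df, c, [])
            keep = fit["p"] < p_threshold
            rows.append({"candidate": c, "log_hr": fit["log_hr"], "p": fit["p"], "selected": keep})
            if keep:
                selected.append(c)
        except ValueError as exc:
            rows.append({"candidate": c, "log_hr": np.nan, "p": np.nan, "selected": False, "note": str(exc)})
    return selected, pd.DataFrame(rows)
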