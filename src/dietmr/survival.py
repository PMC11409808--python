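"""Thin Cox proportional-hazards wrapper (age time scale, delayed entry).

All Cox fits in the package go through :func:`fit_cox`: lifelines'
partial-likelihood fitter with age as the time axis, left truncation at
enrolment age, and Efron handling of tied event ages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = ["fit_cox"]


def fit_cox(
    df: pd.DataFrame,
    exposure: str,
    covariates: list[str] | None = None,
    duration_col: str = "exit_age",
    event_col: str = "event",
    entry_col: str = "entry_age",
) -> dict:
    """Fit an age-scale Cox model and return the exposure coefficient.

    ``df`` must contain entry/exit ages, a 0/1 event column, the exposure
    and any covariate columns; rows with missing values are dropped
    (complete case).  Returns log-HR, SE, Wald p, HR with 95% CI, and the
    analyzed sample/event counts.
    """
    covariates = covariates or []
    cols = [entry_col, duration_col, event_col, exposure] + list(covariates)
    d = df[cols].dropna()
    if d[event_col].sum() < 1:
        raise ValueError("no events among complete cases")
    if np.ptp(d[exposure].to_numpy(float)) == 0:
        raise ValueError(f"exposure {exposure!r} is constant on analyzable rows")
    cph = CoxPHFitter()
    cph.fit(
        d,
        duration_col=duration_col,
        event_col=event_col,
        entry_col=entry_col,
        show_progress=False,
    )
    log_hr = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    return {
        "log_hr": log_hr,
        "se": se,
        "p": float(cph.summary.loc[exposure, "p"]),
        "hr": float(np.exp(log_hr)),
        "ci_low": float(np.exp(log_hr - 1.96 * se)),
        "ci_high": float(np.exp(log_hr + 1.96 * se)),
        "n": int(len(d)),
        "events": int(d[event_col].sum()),
        "model": cph,
    }
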