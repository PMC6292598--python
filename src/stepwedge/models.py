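"""Fixed-effect formulations and intervention-effect contrasts.

Nine candidate mean models for the stepped-wedge analysis, in three blocks:

* no time:          M1  y = b0 + d*x
* continuous time:  M2  + tau*t
                    M3  + tau*t + omega*x*t
                    M4  + tau*t + psi*d_exposure
                    M5  tau*t + psi*d_exposure (no step term)
                    M6  + tau*t + psi*d_exposure + zeta*t^2
* categorical time: M7  + kappa_t                      (Hussey-Hughes)
                    M8  + kappa_t + phi_t * x, t = 3..n-1
                    M9  kappa_t + xi_d (no step term)

Categorical calendar time uses t = 1 as the reference level (kappa_1 = 0)
and categorical exposure uses d = 0 (xi_0 = 0). Two identifiability
constraints are structural in the standard design: M8's interaction
columns exist only for t = 3..n-1 (at t = 2 the step term already carries
the single treated cluster's effect, and at t = n there is no concurrent
control), and M9 carries no separate step term because treatment is
completely nested within positive exposure.

Both estimands are linear contrasts c'beta of the fitted fixed effects:
the effect at six months of exposure, and the time-averaged effect over
the study's exposure levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lme import FitResult, _check_full_rank, fit_ml
from .scenarios import TrialDataset, VarianceComponents

__all__ = [
    "FORMULATIONS",
    "ModelFormulation",
    "EffectEstimate",
    "design_matrix",
    "contrast",
    "estimate_effect",
    "fit_formulation",
]

ESTIMANDS = ("six_month", "time_averaged")


@dataclass(frozen=True)
class ModelFormulation:
    id: str
    time_kind: str  # none | continuous | categorical
    has_step: bool
    terms: tuple  # extra-term labels beyond intercept/step


FORMULATIONS = {
    "M1": ModelFormulation("M1", "none", True, ()),
    "M2": ModelFormulation("M2", "continuous", True, ("cal_time",)),
    "M3": ModelFormulation("M3", "continuous", True, ("cal_time", "treat_x_time")),
    "M4": ModelFormulation("M4", "continuous", True, ("cal_time", "exposure")),
    "M5": ModelFormulation("M5", "continuous", False, ("cal_time", "exposure")),
    "M6": ModelFormulation(
        "M6", "continuous", True, ("cal_time", "exposure", "cal_time_sq")
    ),
    "M7": ModelFormulation("M7", "categorical", True, ("kappa",)),
    "M8": ModelFormulation("M8", "categorical", True, ("kappa", "phi")),
    "M9": ModelFormulation("M9", "categorical", False, ("kappa", "xi")),
}


def _get_formulation(formulation) -> ModelFormulation:
    if isinstance(formulation, ModelFormulation):
        return formulation
    try:
        return FORMULATIONS[formulation]
    except KeyError:
        raise ValueError(
            f"unknown formulation {formulation!r}; expected M1..M9"
        ) from None


def design_matrix(
    formulation, dataset: TrialDataset, restrict_identifiability: bool = True
):
    """Build the fixed-effect design matrix for one formulation.

    Returns ``(X, names)`` with X of full column rank. With
    ``restrict_identifiability=False`` the structural constraints are
    dropped (M8 gets interaction columns for every treated time step, M9
    gets a step-effect column); on stepped-wedge data those matrices are
    rank deficient and a rank error naming the aliased columns is raised.
    """
    f = _get_formulation(formulation)
    df = dataset.df
    t = df["time"].to_numpy(dtype=float)
    x = df["treated"].to_numpy(dtype=float)
    d = df["exposure"].to_numpy(dtype=float)
    n = int(df["time"].max())

    cols = [np.ones(len(df))]
    names = ["intercept"]
    if f.has_step or (f.id == "M9" and not restrict_identifiability):
        cols.append(x)
        names.append("treat")
    if "cal_time" in f.terms:
        cols.append(t)
        names.append("cal_time")
    if "treat_x_time" in f.terms:
        cols.append(x * t)
        names.append("treat_x_time")
    if "exposure" in f.terms:
        cols.append(d)
        names.append("exposure")
    if "cal_time_sq" in f.terms:
        cols.append(t**2)
        names.append("cal_time_sq")
    if "kappa" in f.terms:
        for tt in range(2, n + 1):  # t = 1 is the reference level
            cols.append((t == tt).astype(float))
            names.append(f"kappa_t{tt}")
    if "phi" in f.terms:
        lo, hi = (3, n - 1) if restrict_identifiability else (2, n)
        for tt in range(lo, hi + 1):
            cols.append(((t == tt) & (x == 1)).astype(float))
            names.append(f"phi_t{tt}")
    if "xi" in f.terms:
        for dd in range(1, n):  # d = 0 is the reference level
            cols.append((d == dd).astype(float))
            names.append(f"xi_d{dd}")

    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def contrast(formulation, estimand: str, n_steps: int = 13) -> pd.Series:
    """Weights c such that c'beta is the requested intervention estimand.

    six_month: effect after six steps of exposure (for the calendar-
    interaction models, the effect six steps into the study). time_averaged:
    the effect averaged over the study — at the median calendar step for M3,
    over the mean of the interaction terms for M8, over exposure levels
    d = 1..n-1 for M9; for the continuous-exposure models six steps is the
    median exposure, so the two estimands coincide.
    """
    if estimand not in ESTIMANDS:
        raise ValueError(f"unknown estimand {estimand!r}; expected one of {ESTIMANDS}")
    f = _get_formulation(formulation)
    n = n_steps
    six = estimand == "six_month"
    if f.id in ("M1", "M2", "M7"):
        w = {"treat": 1.0}
    elif f.id == "M3":
        w = {"treat": 1.0, "treat_x_time": 6.0 if six else (n + 1) / 2.0}
    elif f.id in ("M4", "M6"):
        w = {"treat": 1.0, "exposure": 6.0}
    elif f.id == "M5":
        w = {"exposure": 6.0}
    elif f.id == "M8":
        if six:
            w = {"treat": 1.0, "phi_t6": 1.0}
        else:
            ts = range(3, n)
            w = {"treat": 1.0, **{f"phi_t{tt}": 1.0 / len(ts) for tt in ts}}
    else:  # M9
        if six:
            w = {"xi_d6": 1.0}
        else:
            ds = range(1, n)
            w = {f"xi_d{dd}": 1.0 / len(ds) for dd in ds}
    return pd.Series(w, dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    """A Wald interval for one intervention-effect contrast (HoNOS units)."""

    estimand: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    level: float = 0.95


def estimate_effect(
    fit: FitResult,
    c: pd.Series | dict,
    level: float = 0.95,
    estimand: str = "custom",
    reference: str = "normal",
) -> EffectEstimate:
    """Estimate c'beta with its Wald standard error and interval.

    ``reference`` selects the normal (z) reference — matching contrast
    machinery such as multcomp on an ML fit — or ``"t"`` with
    n_obs - n_fixed residual degrees of freedom.
    """
    c = pd.Series(c, dtype=float)
    missing = [name for name in c.index if name not in fit.beta.index]
    if missing:
        raise ValueError(f"contrast names not in fitted parameters: {missing}")
    cv = pd.Series(0.0, index=fit.beta.index)
    cv[c.index] = c
    est = float(cv @ fit.beta)
    var = float(cv @ fit.vcov_beta.to_numpy() @ cv)
    se = float(np.sqrt(max(var, 0.0)))
    if reference == "t":
        df = fit.n_obs - len(fit.beta)
        q = stats.t.ppf(0.5 + level / 2.0, df)
        p = 2.0 * stats.t.sf(abs(est / se), df) if se > 0 else np.nan
    else:
        q = stats.norm.ppf(0.5 + level / 2.0)
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return EffectEstimate(
        estimand=estimand,
        estimate=est,
        se=se,
        ci_low=est - q * se,
        ci_high=est + q * se,
        p=float(p) if se > 0 else float("nan"),
        level=level,
    )


def fit_formulation(
    dataset: TrialDataset,
    formulation,
    structure: str = "CS",
    start: VarianceComponents | None = None,
) -> FitResult:
    """Fit one formulation x covariance structure to a trial dataset by ML."""
    f = _get_formulation(formulation)
    X, names = design_matrix(f, dataset)
    df = dataset.df
    return fit_ml(
        X,
        df["y"].to_numpy(dtype=float),
        df["cluster_id"].to_numpy(),
        df["subject_id"].to_numpy(),
        df["time"].to_numpy(dtype=float),
        structure=structure,
        start=start,
        names=names,
        formulation=f.id,
    )
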