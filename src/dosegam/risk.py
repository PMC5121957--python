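"""Counterfactual relative-risk inference from fitted dose-response models.

A fitted model predicts each cell's mean ``mu`` and the counterfactual mean
``mu_0`` obtained by resetting the dose covariate to its zero-dose value
(0 for dose models; ecdf(dose)(0) for ecdos models) while holding every
other covariate and all coefficients fixed.  Relative Risk is
``RR = mu / mu_0`` and Excess Relative Risk ``ERR = RR - 1``.  Confidence
intervals come from the posterior variance of the linear-predictor
difference (including covariances).

Reporting follows the cohort-analysis conventions: 90% intervals whose
bounds are the lower/upper 95% confidence limits (LCL95%, UCL95%),
"borderline" when 0.98 ≤ LCL95% ≤ 1, and cellwise significance indicators
I = [LCL95% > 1], J = [UCL95% < 1] summarized over dose/covariate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EXPOSURE_DATE, CohortTable
from .pgam import FittedModel, posterior_interval

__all__ = [
    "RiskEstimate",
    "SignificanceSummary",
    "counterfactual_rr",
    "rr_curve",
    "rr_surface",
    "attributable_fraction_and_sir",
    "significance_regions",
    "err_ratio_vs_linear",
]

REGIONS = ("D0", "D05", "S05", "T05", "ST")


@dataclass(frozen=True)
class RiskEstimate:
    dose: float
    rr: float
    lcl: float
    ucl: float
    level: float
    fixed: dict

    @property
    def err(self) -> float:
        return self.rr - 1.0

    @property
    def borderline(self) -> bool:
        return 0.98 <= self.lcl <= 1.0


@dataclass
class SignificanceSummary:
    """Per-region proportions of cases/py with significant RR elevation (I)
    or depression (J)."""

    cases_I: dict
    py_I: dict
    cases_J: dict
    py_J: dict


def _baseline_value(fit: FittedModel) -> float:
    dc = fit.meta.get("dose_cov")
    if dc == "ecdos":
        sd = fit.meta.get("ecdf_doses")
        if sd is None:
            raise ValueError("ecdos model carries no stored dose ecdf")
        return float(np.searchsorted(sd, 0.0, side="right") / len(sd))
    return 0.0


def _delta_eta_contrast(fit: FittedModel, cells: pd.DataFrame) -> np.ndarray:
    """Contrast rows for eta - eta_0 (dose covariate reset)."""
    dc = fit.meta.get("dose_cov")
    X = fit.design.design_for(cells)
    if dc is None:
        return np.zeros_like(X)
    cells0 = cells.copy()
    cells0[dc] = _baseline_value(fit)
    X0 = fit.design.design_for(cells0)
    return X - X0


def counterfactual_rr(fit: FittedModel, table: CohortTable,
                      level: float = 0.90) -> pd.DataFrame:
    """Per-cell RR with CIs, relative to the zero-dose counterfactual."""
    cells = table.df
    C = _delta_eta_contrast(fit, cells)
    est, lo, hi = posterior_interval(fit, C, level=level)
    out = cells[["dose", "py", "obs"]].copy()
    for extra in ("since", "agex"):
        if extra in cells:
            out[extra] = cells[extra]
    out["rr"] = np.exp(est)
    out["lcl"] = np.exp(lo)
    out["ucl"] = np.exp(hi)
    return out


def prediction_cells(fit: FittedModel, doses, fixed: dict) -> pd.DataFrame:
    """Synthetic single cells (py=1, reference factor levels) on a dose grid.

    ``fixed`` gives the attained age plus one timescale (``since`` or
    ``agex``); the remaining covariates are derived consistently
    (since = year - exposure date, birth = year - age).  The factor levels
    cancel in RR, so the reference stratum is used.
    """
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    age = float(fixed["age"])
    if "since" in fixed:
        since = float(fixed["since"])
    elif "agex" in fixed:
        since = age - float(fixed["agex"])
    else:
        raise ValueError("fixed covariates must include 'since' or 'agex'")
    year = EXPOSURE_DATE + since
    cells = pd.DataFrame({
        "dose": doses,
        "py": 1.0,
        "age": age,
        "logage": np.log(age),
        "since": since,
        "agex": age - since,
        "year": year,
        "birth": year - age,
    })
    for fac, levels in fit.design.factor_levels.items():
        cells[fac] = levels[0]
    if fit.meta.get("dose_cov") == "ecdos":
        sd = fit.meta.get("ecdf_doses")
        if sd is None:
            raise ValueError("ecdos model carries no stored dose ecdf")
        cells["ecdos"] = np.searchsorted(sd, doses, side="right") / len(sd)
    return cells


def rr_curve(fit: FittedModel, doses, fixed: dict,
             level: float = 0.90) -> list[RiskEstimate]:
    """RR and CIs along a dose grid (mGy) at fixed covariates."""
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    dmax = fit.meta.get("dose_max")
    if dmax is not None and np.any(doses > dmax):
        raise ValueError(
            f"grid dose exceeds the subcohort's maximum dose ({dmax:.3g} mGy)"
        )
    cells = prediction_cells(fit, doses, fixed)
    C = _delta_eta_contrast(fit, cells)
    est, lo, hi = posterior_interval(fit, C, level=level)
    return [
        RiskEstimate(dose=float(d), rr=float(np.exp(e)), lcl=float(np.exp(l)),
                     ucl=float(np.exp(h)), level=level, fixed=dict(fixed))
        for d, e, l, h in zip(doses, est, lo, hi)
    ]


def rr_surface(fit: FittedModel, doses, covar: str, covar_grid,
               fixed: dict, level: float = 0.90) -> dict:
    """RR over a (dose x covariate) grid with significance shading classes.

    Classes: 'sig-up' (LCL > 1), 'up' (RR > 1, not significant), 'down'
    (RR ≤ 1, not significant), 'sig-down' (UCL < 1) — a partition.
    """
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    grid = np.atleast_1d(np.asarray(covar_grid, dtype=float))
    rr = np.empty((doses.size, grid.size))
    lcl = np.empty_like(rr)
    ucl = np.empty_like(rr)
    for j, v in enumerate(grid):
        fx = dict(fixed)
        fx[covar] = float(v)
        ests = rr_curve(fit, doses, fx, level=level)
        rr[:, j] = [e.rr for e in ests]
        lcl[:, j] = [e.lcl for e in ests]
        ucl[:, j] = [e.ucl for e in ests]
    classes = np.full(rr.shape, "down", dtype=object)
    classes[rr > 1] = "up"
    classes[lcl > 1] = "sig-up"
    classes[ucl < 1] = "sig-down"
    return {"dose": doses, covar: grid, "rr": rr, "lcl": lcl, "ucl": ucl,
            "classes": classes}


def attributable_fraction_and_sir(fit: FittedModel,
                                  table: CohortTable) -> tuple[float, float]:
    """(AF, SIR) = (1 - Σmu_0/Σmu, Σmu/Σmu_0) from the fitted model."""
    C = _delta_eta_contrast(fit, table.df)
    mu = fit.mu
    mu0 = mu * np.exp(-(C @ fit.beta))
    sir = float(mu.sum() / mu0.sum())
    return 1.0 - 1.0 / sir, sir


def significance_regions(fit: FittedModel, table: CohortTable,
                         level: float = 0.90) -> SignificanceSummary:
    """Proportions of cases and person-years with I=1 (LCL > 1) and J=1
    (UCL < 1) over the dose/covariate regions D0, D0.5, S0.5, T0.5, S∩T."""
    per = counterfactual_rr(fit, table, level=level)
    df = table.df
    dose = df["dose"].to_numpy(float)
    since = df["since"].to_numpy(float)
    agex = df["agex"].to_numpy(float)
    masks = {
        "D0": dose > 0,
        "D05": dose > 0.5,
        "S05": (since < 35) & (dose > 0.5),
        "T05": (agex > 35) & (dose > 0.5),
        "ST": (since < 35) & (agex > 35) & (dose > 0.5),
    }
    I = (per["lcl"].to_numpy() > 1.0)
    J = (per["ucl"].to_numpy() < 1.0)
    obs = df["obs"].to_numpy(float)
    py = df["py"].to_numpy(float)

    def prop(w, ind, m):
        tot = w[m].sum()
        return float(w[m & ind].sum() / tot) if tot > 0 else 0.0

    return SignificanceSummary(
        cases_I={r: prop(obs, I, m) for r, m in masks.items()},
        py_I={r: prop(py, I, m) for r, m in masks.items()},
        cases_J={r: prop(obs, J, m) for r, m in masks.items()},
        py_J={r: prop(py, J, m) for r, m in masks.items()},
    )


def err_ratio_vs_linear(err_model: float, err_per_gy: float,
                        target_mgy: float) -> tuple[float, float]:
    """Compare a model ERR at a target dose with linear extrapolation.

    ``err_per_gy`` is the slope of an external linear ERR model (per Gy);
    the extrapolated ERR at ``target_mgy`` is slope × target/1000 and the
    ratio is model/extrapolated.
    """
    if err_per_gy == 0:
        raise ZeroDivisionError("zero linear slope: extrapolated ERR undefined")
    extrapolated = err_per_gy * target_mgy / 1000.0
    return extrapolated, err_model / extrapolated
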