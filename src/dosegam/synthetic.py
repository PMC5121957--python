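"""Synthetic grouped-cohort generator emulating the A-bomb survivor
incidence data's structure, so the whole modelling pipeline is testable
without the restricted-access download.

Cells are strata of (city x urban/rural x dose category x age-at-exposure
band x calendar period), plus a zero-dose Not-In-City (NIC) stratum.
Person-years are allocated so the dose distribution reproduces the cohort's
hallmark skew (the bulk of follow-up below 20 mGy, with stated fractions
below 20 and 100 mGy with and without NIC), doses are drawn right-skewed
within each category so the marginal distribution is multimodal across
category cutpoints, baseline incidence is log-linear in log attained age
with a birth-cohort trend and city/residence effects, and case counts are
Poisson with an embeddable true excess-relative-risk curve:

    obs ~ Pois( py * baseline(age, birth, city, residence) * (1 + ERR(dose)) )
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import EXPOSURE_DATE, CohortTable

__all__ = ["SyntheticCohortConfig", "generate", "calibration_report"]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the generated cohort.

    Defaults target roughly 2,000 cells and 5,000 expected cases with the
    dose-skew fractions the source cohort exhibits (>70% of person-years
    below 20 mGy including NIC, >60% excluding it; >84%/>79% below 100 mGy).
    """

    #: dose category cutpoints, mGy (zero-dose cells form their own category)
    cutpoints: tuple[float, ...] = (0.0, 5.0, 20.0, 40.0, 60.0, 80.0, 100.0,
                                    150.0, 250.0, 500.0)
    #: share of total person-years in the zero-dose NIC stratum
    nic_py_fraction: float = 0.25
    #: in-city person-year shares per dose category (zero-dose first)
    category_py_shares: tuple[float, ...] = (0.15, 0.30, 0.20, 0.10, 0.07,
                                             0.05, 0.04, 0.03, 0.03, 0.03)
    total_py: float = 2.5e6
    expected_cases: float = 5000.0
    #: city person-year split and multiplicative rate effects
    city_shares: tuple[float, float] = (0.65, 0.35)  # hiroshima, nagasaki
    urban_share: float = 0.75
    log_city_effect: float = -0.05   # nagasaki vs hiroshima
    log_rural_effect: float = -0.10  # rural vs urban
    log_city_rural_interaction: float = -0.15  # extra effect, rural nagasaki
    #: baseline log-rate: slope on log attained age (incidence ~ age^5) and
    #: linear birth-cohort trend per year
    logage_slope: float = 5.0
    birth_trend: float = 0.01
    #: age-at-exposure bands (years) and calendar periods (mid-years)
    agex_bands: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    period_years: tuple[float, ...] = (1960.0, 1965.0, 1970.0, 1975.0, 1980.0,
                                       1985.0, 1990.0, 1995.0)
    #: within-category dose clump position draw: Beta(a, b), right-skewed
    dose_beta: tuple[float, float] = (1.2, 3.0)
    #: within-clump jitter (fraction of the category width); the grouped
    #: public data clumps py-weighted mean doses tightly by stratum
    dose_jitter: float = 0.03
    py_lognorm_sigma: float = 1.0
    sex: str = "female"
    #: embedded true ERR curve (None = null)
    curve: object = None
    seed: int = 0

    def __post_init__(self):
        if len(self.category_py_shares) != len(self.cutpoints):
            raise ValueError("need one py share per dose category")
        if abs(sum(self.category_py_shares) - 1.0) > 1e-8:
            raise ValueError("category py shares must sum to 1")
        if not 0.0 <= self.nic_py_fraction < 1.0:
            raise ValueError("nic_py_fraction must be in [0, 1)")
        if min(self.period_years) - EXPOSURE_DATE < 12.4:
            raise ValueError("calendar periods must start at least 12.4 years "
                             "after exposure")


def _category_bounds(cfg: SyntheticCohortConfig) -> list[tuple[float, float]]:
    cp = list(cfg.cutpoints)
    bounds = [(0.0, 0.0)]  # zero-dose category
    for lo, hi in zip(cp[:-1], cp[1:]):
        bounds.append((lo, hi))
    return bounds[: len(cfg.category_py_shares)]


def generate(cfg: SyntheticCohortConfig) -> CohortTable:
    """Generate a grouped cohort table from the configuration (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    bounds = _category_bounds(cfg)
    ncat = len(bounds)
    cities = ["hiroshima", "nagasaki"]
    dists = ["urban", "rural"]
    rows = []
    dist_levels = dists + (["NIC"] if cfg.nic_py_fraction > 0 else [])
    for ci, city in enumerate(cities):
        for dist in dist_levels:
            cats = range(ncat) if dist != "NIC" else [0]
            for cat in cats:
                lo, hi = bounds[cat]
                # the public grouped data clumps py-weighted mean doses by
                # stratum within each dose category: one right-skewed clump
                # location per (city, residence, category), tight jitter
                a, b = cfg.dose_beta
                clump = rng.beta(a, b)
                for bi in range(len(cfg.agex_bands) - 1):
                    ax_lo, ax_hi = cfg.agex_bands[bi], cfg.agex_bands[bi + 1]
                    for year in cfg.period_years:
                        agex = rng.uniform(ax_lo, ax_hi)
                        since = year - EXPOSURE_DATE
                        age = agex + since
                        if dist == "NIC" or hi == lo:
                            dose = 0.0
                        else:
                            u = np.clip(clump + cfg.dose_jitter
                                        * rng.standard_normal(), 0.005, 0.995)
                            dose = lo + (hi - lo) * u
                        raw_py = rng.lognormal(0.0, cfg.py_lognorm_sigma)
                        rows.append({
                            "city": city, "distcat": dist, "cat": cat,
                            "dose": dose, "agex": agex, "since": since,
                            "age": age, "year": year, "raw_py": raw_py,
                            "city_share": cfg.city_shares[ci],
                        })
    df = pd.DataFrame(rows)

    # allocate person-years: NIC gets its fraction; in-city py follows the
    # configured category shares exactly, split between cities
    nic = df["distcat"] == "NIC"
    incity_py = cfg.total_py * (1.0 - cfg.nic_py_fraction)
    nic_py = cfg.total_py * cfg.nic_py_fraction
    py = np.empty(len(df))
    for ci, city in enumerate(cities):
        in_c = (df["city"] == city).to_numpy()
        m = in_c & nic.to_numpy()
        if m.any():
            w = df.loc[m, "raw_py"].to_numpy()
            py[m] = nic_py * cfg.city_shares[ci] * w / w.sum()
        for cat in range(ncat):
            m = in_c & ~nic.to_numpy() & (df["cat"] == cat).to_numpy()
            if not m.any():
                continue
            urb = (df["distcat"] == "urban").to_numpy()
            target = incity_py * cfg.city_shares[ci] * cfg.category_py_shares[cat]
            for dmask, share in ((m & urb, cfg.urban_share),
                                 (m & ~urb, 1.0 - cfg.urban_share)):
                w = df.loc[dmask, "raw_py"].to_numpy()
                py[dmask] = target * share * w / w.sum()
    df["py"] = py

    # baseline rate, intercept calibrated to the expected case total
    log_rel = (
        cfg.logage_slope * (np.log(df["age"]) - np.log(70.0))
        + cfg.birth_trend * (df["year"] - df["age"] - 1920.0)
        + np.where(df["city"] == "nagasaki", cfg.log_city_effect, 0.0)
        + np.where(df["distcat"] == "rural", cfg.log_rural_effect, 0.0)
        + np.where((df["city"] == "nagasaki") & (df["distcat"] == "rural"),
                   cfg.log_city_rural_interaction, 0.0)
    )
    rel = np.exp(log_rel)
    rate0 = cfg.expected_cases / float(np.sum(df["py"] * rel))
    mu0 = df["py"].to_numpy() * rate0 * rel
    if cfg.curve is not None:
        err = cfg.curve(df["dose"].to_numpy())
        if np.any(1.0 + err <= 0):
            raise ValueError("true curve gives non-positive relative risk")
        mu = mu0 * (1.0 + err)
    else:
        mu = mu0
    obs = rng.poisson(mu)

    out = pd.DataFrame({
        "py": df["py"], "obs": obs, "dose": df["dose"], "age": df["age"],
        "agex": df["agex"], "year": df["year"], "since": df["since"],
        "birth": df["year"] - df["age"], "logage": np.log(df["age"]),
        "city": df["city"], "distcat": df["distcat"], "sex": cfg.sex,
    })
    table = CohortTable(df=out.reset_index(drop=True),
                        meta={"config": cfg, "mu0": mu0, "dose_column": "dose"})
    table.validate()
    return table


def calibration_report(table: CohortTable) -> dict:
    """Summary of the quantities used to judge likeness to the source
    cohort: py fractions below 20/100 mGy (with/without NIC), NIC share,
    dose deciles, totals."""
    df = table.df
    py = df["py"].to_numpy(float)
    dose = df["dose"].to_numpy(float)
    nic = (df["distcat"].astype(str) == "NIC").to_numpy()
    tot = py.sum()
    in_city = py[~nic].sum()
    rep = {
        "n_cells": int(len(df)),
        "total_py": float(tot),
        "total_cases": int(df["obs"].sum()),
        "nic_py_share": float(py[nic].sum() / tot) if tot else 0.0,
        "py_frac_lt20_incl_nic": float(py[dose < 20].sum() / tot),
        "py_frac_lt100_incl_nic": float(py[dose < 100].sum() / tot),
        "py_frac_lt20_excl_nic": float(py[(dose < 20) & ~nic].sum() / in_city)
        if in_city else 0.0,
        "py_frac_lt100_excl_nic": float(py[(dose < 100) & ~nic].sum() / in_city)
        if in_city else 0.0,
        "dose_deciles": np.quantile(dose, np.linspace(0.1, 0.9, 9)).tolist(),
    }
    return rep
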