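"""The dose-response model catalogue and selection rules.

The catalogue augments a baseline model

    P0:  offset(log py) + (city + distcat)^2 + ti(logage) + ti(birth)
         + ti(logage, birth)

with dose terms built either on raw dose (d-variants) or on its ecdf
transform ecdos (e-variants), and optionally with a timescale interaction
on age-at-exposure (``a``) or time-since-exposure (``s``):

    P1: + dose covariate (log-linear)          P2: + ti(dcov)
    P3: + ti(dcov) + ti(dcov, logage)          P4a/P4s: + ti(dcov) + ti(dcov, agex|since)
    P5a/P5s: + ti(dcov) + ti(dcov, logage) + ti(agex|since) + ti(dcov, agex|since)

Q-models are the quasipoisson twins with Pearson-estimated scale.  Smooths
are cubic regression splines with basis dimension 10 by default, and the
fitting criterion is marginal likelihood (ML).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .cohort import CohortTable
from .pgam import (DesignMatrix, Fac, FittedModel, Lin, Ti, anova_compare,
                   criterion_value, estimate_scale_quasi, fit_at_lambda,
                   optimize_smoothing)

__all__ = ["ModelSpec", "build_spec", "catalogue", "build_design",
           "fit_model", "fit_ladder", "select_poisson", "select_quasi_pair"]

_NAME_RE = re.compile(r"^([PQ])([0-5])(a|s)?(e|d)?$")


@dataclass(frozen=True)
class ModelSpec:
    """A catalogue model: family, dose covariate, timescale and term list."""

    name: str
    family: str  # poisson | quasipoisson
    dose_cov: str | None  # "ecdos" | "dose" | None
    timescale: str | None  # "agex" | "since" | None
    terms: tuple = ()
    k: int = 10
    min_sp: float | None = None
    selection_method: str | None = None

    def term_set(self) -> frozenset:
        return frozenset(self.terms)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return self.term_set() <= other.term_set()

    def to_yaml(self) -> str:
        def enc(t):
            return {"kind": type(t).__name__,
                    "vars": list(getattr(t, "vars", [getattr(t, "var", None)])),
                    "k": getattr(t, "k", None),
                    "min_sp": getattr(t, "min_sp", None)}
        return yaml.safe_dump({
            "name": self.name, "family": self.family, "dose_cov": self.dose_cov,
            "timescale": self.timescale, "k": self.k, "min_sp": self.min_sp,
            "terms": [enc(t) for t in self.terms],
        }, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        return build_spec(d["name"], k=d["k"], min_sp=d["min_sp"])


def catalogue() -> list[str]:
    names = ["P0", "Q0"]
    for fam in "PQ":
        for lvl in "12":
            for dc in "ed":
                names.append(f"{fam}{lvl}{dc}")
        for dc in "ed":
            names.append(f"{fam}3{dc}")
        for lvl in "45":
            for ts in "as":
                for dc in "ed":
                    names.append(f"{fam}{lvl}{ts}{dc}")
    return names


def build_spec(name: str, k: int = 10, min_sp: float | None = None) -> ModelSpec:
    """Construct the named catalogue model (error lists valid names)."""
    m = _NAME_RE.match(name)
    if not m or name not in catalogue():
        raise ValueError(f"unknown model {name!r}; catalogue: {', '.join(catalogue())}")
    fam = "poisson" if m.group(1) == "P" else "quasipoisson"
    level = int(m.group(2))
    ts = {"a": "agex", "s": "since", None: None}[m.group(3)]
    dc = {"e": "ecdos", "d": "dose", None: None}[m.group(4)]
    base = (
        Fac(("city", "distcat")),
        Ti(("logage",), k=k, min_sp=min_sp),
        Ti(("birth",), k=k, min_sp=min_sp),
        Ti(("logage", "birth"), k=k, min_sp=min_sp),
    )
    extra: tuple = ()
    if level == 1:
        extra = (Lin(dc),)
    elif level == 2:
        extra = (Ti((dc,), k=k, min_sp=min_sp),)
    elif level == 3:
        extra = (Ti((dc,), k=k, min_sp=min_sp), Ti((dc, "logage"), k=k, min_sp=min_sp))
    elif level == 4:
        extra = (Ti((dc,), k=k, min_sp=min_sp), Ti((dc, ts), k=k, min_sp=min_sp))
    elif level == 5:
        extra = (Ti((dc,), k=k, min_sp=min_sp), Ti((dc, "logage"), k=k, min_sp=min_sp),
                 Ti((ts,), k=k, min_sp=min_sp), Ti((dc, ts), k=k, min_sp=min_sp))
    return ModelSpec(name=name, family=fam, dose_cov=dc, timescale=ts,
                     terms=base + extra, k=k, min_sp=min_sp)


def build_design(table: CohortTable, spec: ModelSpec) -> DesignMatrix:
    df = table.df
    if spec.dose_cov == "ecdos" and "ecdos" not in df.columns:
        raise ValueError(f"{spec.name} needs the ecdos transform; run ecdos_transform first")
    terms = list(spec.terms)
    # factor terms degenerate gracefully when a level is absent (e.g. NIC
    # excluded, or a single-sex table); a sex factor is added when needed
    if "sex" in df.columns and df["sex"].astype(str).nunique() > 1:
        terms[0] = Fac(("city", "distcat", "sex"))
    return DesignMatrix(df, terms, offset="py")


def fit_model(table: CohortTable, spec: ModelSpec, method: str = "ML",
              lam0=None, design: DesignMatrix | None = None) -> FittedModel:
    """Fit one catalogue model to a cohort table."""
    design = design if design is not None else build_design(table, spec)
    y = table.df["obs"].to_numpy(dtype=float)
    try:
        if spec.family == "quasipoisson":
            fit = estimate_scale_quasi(design, y, method=method,
                                       min_sp=spec.min_sp, lam0=lam0)
        else:
            fit = optimize_smoothing(design, y, method=method,
                                     min_sp=spec.min_sp, lam0=lam0)
    except RuntimeError as e:
        raise RuntimeError(f"model {spec.name}: {e}") from e
    fit.meta.update(
        spec=spec,
        dose_cov=spec.dose_cov,
        ecdf_doses=table.meta.get("ecdf_doses"),
        dose_max=float(table.df["dose"].max()),
    )
    return fit


def fit_ladder(table: CohortTable, names, method: str = "ML",
               k: int = 10, min_sp=None) -> dict[str, FittedModel]:
    """Fit a list of catalogue models; returns name -> FittedModel."""
    fits = {}
    for name in names:
        spec = build_spec(name, k=k, min_sp=min_sp)
        fits[name] = fit_model(table, spec, method=method)
    return fits


def score_table(fits: dict[str, FittedModel]) -> pd.DataFrame:
    rows = []
    for name, f in fits.items():
        rows.append({"model": name, "score": f.score, "edf": f.edf,
                     "deviance": f.dev, "phi": f.phi, "family": f.family})
    return pd.DataFrame(rows)


def _aic(fit: FittedModel) -> float:
    return fit.dev / fit.phi + 2.0 * fit.edf


def select_poisson(fits: dict[str, FittedModel], method: int = 1,
                   alpha: float = 0.05) -> str:
    """Choose a preferred model among Poisson fits.

    method 1: lowest ML score (ties go to the lower-edf model).
    method 2: lowest AIC (deviance/φ + 2·edf) — a configurable stand-in.
    method 3: walk each nested chain forward, keeping an extension only when
    the deviance-difference test rejects at ``alpha`` — also a stand-in.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to select")
    fams = {f.family for f in fits.values()}
    if len(fams) > 1:
        raise ValueError("cannot mix families in one selection")
    if method == 1:
        return min(fits, key=lambda n: (round(fits[n].score, 10), fits[n].edf))
    if method == 2:
        return min(fits, key=lambda n: (round(_aic(fits[n]), 10), fits[n].edf))
    if method == 3:
        order = sorted(fits, key=lambda n: (fits[n].edf, n))
        best = order[0]
        for name in order[1:]:
            spec_b = fits[best].meta["spec"]
            spec_n = fits[name].meta["spec"]
            if spec_b.is_nested_in(spec_n):
                if anova_compare(fits[best], fits[name])["p"] < alpha:
                    best = name
        return best
    if method == 4:
        return min(fits, key=lambda n: (round(fits[n].score, 10), fits[n].edf))
    raise ValueError("selection method must be 1, 2, 3 or 4")


def select_quasi_pair(fit_e: FittedModel, fit_d: FittedModel,
                      tol: float = 1e-6) -> str:
    """Prefer the ecdos or dose covariate between quasipoisson twins.

    Each model is rescored at the scale optimized for the other member of
    the pair; the preference holds only if the same model wins at both
    common scales, otherwise 'ambiguous'.
    """
    def rescored(fit, phi):
        d = fit.design
        y = fit.y
        f = optimize_smoothing(d, y, family="quasipoisson", method=fit.method or "ML",
                               phi=phi, lam0=fit.lam, beta0=fit.beta)
        return f.score

    s_e_at_d = rescored(fit_e, fit_d.phi)
    s_d_at_d = rescored(fit_d, fit_d.phi)
    s_e_at_e = rescored(fit_e, fit_e.phi)
    s_d_at_e = rescored(fit_d, fit_e.phi)
    win_at_d = "e" if s_e_at_d < s_d_at_d - tol else ("d" if s_d_at_d < s_e_at_d - tol else "tie")
    win_at_e = "e" if s_e_at_e < s_d_at_e - tol else ("d" if s_d_at_e < s_e_at_e - tol else "tie")
    if win_at_d == win_at_e and win_at_d in ("e", "d"):
        return "ecdos" if win_at_d == "e" else "dose"
    if "tie" in (win_at_d, win_at_e) and win_at_d != win_at_e:
        w = win_at_d if win_at_e == "tie" else win_at_e
        if w in ("e", "d"):
            return "ambiguous"
    return "ambiguous"
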