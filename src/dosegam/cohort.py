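"""Grouped person-years cohort tables: loading, subcohorts, the ecdf dose
transform, and descriptive statistics.

A *cohort table* is a pandas DataFrame of grouped strata ("cells"), one row
per cell, with person-years ``py``, incident case counts ``obs``,
py-weighted mean covariates (``dose`` in mGy, attained ``age``, age at
exposure ``agex``, calendar ``year``), derived covariates (``logage``,
``birth = year - age``, ``since = year - exposure date``), and the factors
``city`` (hiroshima/nagasaki), ``distcat`` (urban/rural/NIC) and ``sex``.
The Not-In-City (NIC) stratum carries zero flash dose by definition.

The ``ecdos`` covariate is the empirical cumulative distribution function of
dose evaluated at each cell's dose — the proportion of cells with dose less
than or equal to it — computed *within the current (sub)table*, so it must
be (re)computed after any filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortTable",
    "SubcohortSpec",
    "read_cohort",
    "subcohort",
    "ecdos_transform",
    "ecdos_value",
    "ecdos_quantile",
    "weighted_mean_dose",
    "mid_covariate",
    "round_to_5",
]

EXPOSURE_DATE = 1945.6  # mid-1945 bombing date on the decimal-year scale
REQUIRED = ("py", "obs", "dose", "age", "agex", "year", "city", "distcat", "sex")

#: named subcohort dose ceilings, mGy: A = 0-20, B = 0-100, C = 0-500;
#: superscript + includes the NIC stratum, - excludes it
CEILINGS = {"A": 20.0, "B": 100.0, "C": 500.0, "J": 4000.0}


@dataclass(frozen=True)
class SubcohortSpec:
    """Filter defining a modelling subcohort.

    Membership is always judged on the colon-dose column (``ceiling_col``),
    whatever organ dose drives the outcome model, matching the convention
    that the named ranges are defined from colon dose for every cancer site.
    """

    ceiling: float = 100.0  # strict upper bound, mGy
    include_nic: bool = True
    sex: str | None = None
    dose_column: str = "dose"
    ceiling_col: str = "dose"

    def __post_init__(self):
        if self.ceiling <= 0:
            raise ValueError("dose ceiling must be positive")

    @classmethod
    def from_name(cls, name: str, **kw) -> "SubcohortSpec":
        """Named ranges 'A+', 'A-', 'B+', 'B-', 'C+', 'C-' (and 'J+-')."""
        letter, sign = name[0].upper(), name[1:]
        if letter not in CEILINGS or sign not in {"+", "-"}:
            raise ValueError(f"unknown subcohort name {name!r}")
        return cls(ceiling=CEILINGS[letter], include_nic=(sign == "+"), **kw)


@dataclass
class CohortTable:
    """A grouped cohort table plus the spec that produced it."""

    df: pd.DataFrame
    spec: SubcohortSpec | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        for c in REQUIRED:
            if c not in self.df.columns:
                raise ValueError(f"cohort table lacks mandatory column '{c}'")
        if (self.df["py"] <= 0).any():
            raise ValueError("person-years must be strictly positive in every cell")
        if (self.df["obs"] < 0).any() or (self.df["dose"] < 0).any():
            raise ValueError("negative case count or dose")
        nic = self.df["distcat"].astype(str) == "NIC"
        if (self.df.loc[nic, "dose"] > 0).any():
            raise ValueError("NIC cells must carry zero dose")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def total_py(self) -> float:
        return float(self.df["py"].sum())

    @property
    def total_obs(self) -> int:
        return int(self.df["obs"].sum())


DEFAULT_COLMAP = {c: c for c in REQUIRED}


def _load_colmap(colmap) -> dict:
    if colmap is None:
        return dict(DEFAULT_COLMAP)
    if isinstance(colmap, (str, bytes)) or hasattr(colmap, "read"):
        with open(colmap) as fh:
            colmap = yaml.safe_load(fh)
    out = dict(DEFAULT_COLMAP)
    out.update(colmap)
    return out


def read_cohort(
    path,
    dose_column: str = "dose",
    rbe=None,
    colmap=None,
    unknown_dose_col: str | None = None,
    gamma_col: str | None = None,
    neutron_col: str | None = None,
    dose_scale: float = 1.0,
    distcat_codes: dict | None = None,
    city_codes: dict | None = None,
) -> CohortTable:
    """Read a grouped cohort CSV into a validated :class:`CohortTable`.

    ``colmap`` maps canonical names (py, obs, dose, ...) to the file's
    column names (dict or YAML path), so other grouped-data dialects can be
    read.  Cells flagged in ``unknown_dose_col`` (truthy/nonzero), or with
    missing dose, are excluded.  Doses in Gy are brought to mGy with
    ``dose_scale=1000``; if separate gamma/neutron components are given,
    ``dose = dose_scale * (Dγ + rbe(Dn)·Dn)`` with ``rbe`` a constant or a
    function of the neutron dose (default constant 10).
    """
    cm = _load_colmap(colmap)
    raw = pd.read_csv(path)
    need = {k: v for k, v in cm.items() if k != "dose" or (gamma_col is None)}
    for canon, col in need.items():
        if col not in raw.columns:
            raise ValueError(f"input file lacks mandatory column '{col}' (for '{canon}')")
    df = pd.DataFrame({k: raw[v] for k, v in cm.items() if v in raw.columns})

    if gamma_col is not None:
        if neutron_col is None:
            raise ValueError("gamma_col given without neutron_col")
        rbe = 10.0 if rbe is None else rbe
        dn = raw[neutron_col].astype(float)
        w = rbe(dn) if callable(rbe) else float(rbe)
        df["dose"] = dose_scale * (raw[gamma_col].astype(float) + w * dn)
    else:
        df["dose"] = df["dose"].astype(float) * dose_scale
        if rbe is not None and callable(rbe):
            warnings.warn("rbe function ignored: no separate neutron column",
                          stacklevel=2)

    if unknown_dose_col is not None and unknown_dose_col in raw.columns:
        flag = raw[unknown_dose_col].astype(float).to_numpy() != 0
        df = df.loc[~flag]
    df = df.loc[df["dose"].notna()].reset_index(drop=True)

    if city_codes:
        df["city"] = df["city"].map(lambda v: city_codes.get(v, v))
    if distcat_codes:
        df["distcat"] = df["distcat"].map(lambda v: distcat_codes.get(v, v))

    if (df["py"] <= 0).any():
        raise ValueError("non-positive person-years in input cells")
    df["logage"] = np.log(df["age"].astype(float))
    df["birth"] = df["year"].astype(float) - df["age"].astype(float)
    df["since"] = df["year"].astype(float) - EXPOSURE_DATE
    table = CohortTable(df=df, meta={"dose_column": dose_column, "source": str(path)})
    table.validate()
    return table


def subcohort(table: CohortTable, spec: SubcohortSpec) -> CohortTable:
    """Restrict a table by sex, colon-dose ceiling (strict <) and NIC status."""
    df = table.df
    mask = df[spec.ceiling_col].astype(float) < spec.ceiling
    if not spec.include_nic:
        mask &= df["distcat"].astype(str) != "NIC"
    if spec.sex is not None:
        mask &= df["sex"].astype(str) == str(spec.sex)
    out = df.loc[mask].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("subcohort filter produced an empty table", stacklevel=2)
    return CohortTable(df=out, spec=spec, meta=dict(table.meta))


def ecdos_transform(table: CohortTable, dose_col: str = "dose") -> CohortTable:
    """Attach ``ecdos``, the within-table ecdf of dose at each cell's dose.

    ecdos(cell) is the proportion of cells (unweighted) whose dose is ≤ the
    cell's dose; ties share a value, max is 1 and the minimum is positive
    whenever zero-dose cells exist.  Re-application is idempotent on the
    same table; after further filtering it must be recomputed.
    """
    if len(table) == 0:
        raise ValueError("cannot compute the ecdf of an empty table")
    d = table.df[dose_col].to_numpy(dtype=float)
    sorted_d = np.sort(d)
    ec = np.searchsorted(sorted_d, d, side="right") / d.size
    df = table.df.copy()
    df["ecdos"] = ec
    meta = dict(table.meta)
    meta["ecdf_doses"] = sorted_d
    return CohortTable(df=df, spec=table.spec, meta=meta)


def ecdos_value(table: CohortTable, dose) -> np.ndarray | float:
    """Evaluate the table's dose ecdf at arbitrary doses (mGy)."""
    sorted_d = table.meta.get("ecdf_doses")
    if sorted_d is None:
        sorted_d = np.sort(table.df["dose"].to_numpy(dtype=float))
    out = np.searchsorted(sorted_d, np.asarray(dose, dtype=float), side="right") / len(sorted_d)
    return float(out) if np.isscalar(dose) else out


def ecdos_quantile(table: CohortTable, q) -> np.ndarray | float:
    """Inverse transform: smallest observed dose with ecdf ≥ q."""
    sorted_d = table.meta.get("ecdf_doses")
    if sorted_d is None:
        sorted_d = np.sort(table.df["dose"].to_numpy(dtype=float))
    n = len(sorted_d)
    idx = np.clip(np.ceil(np.asarray(q, dtype=float) * n).astype(int) - 1, 0, n - 1)
    out = sorted_d[idx]
    return float(out) if np.isscalar(q) else out


def weighted_mean_dose(table: CohortTable, dose_col: str = "dose") -> float:
    """Person-year-weighted mean dose, Σ(py·dose)/Σpy, in mGy."""
    py = table.df["py"].to_numpy(dtype=float)
    d = table.df[dose_col].to_numpy(dtype=float)
    return float(np.sum(py * d) / np.sum(py))


def mid_covariate(table: CohortTable, covariate: str) -> float:
    """Covariate value below which half the cases occur.

    Returns the smallest observed value v such that the fraction of cases
    with covariate < v reaches 0.5 (so exactly at a boundary the larger
    value is reported).
    """
    df = table.df
    total = df["obs"].sum()
    if total <= 0:
        raise ValueError("no cases in table")
    grp = df.loc[df["obs"] > 0].groupby(covariate)["obs"].sum().sort_index()
    below = grp.cumsum().shift(fill_value=0) / total
    ok = below.index[below >= 0.5]
    return float(ok[0]) if len(ok) else float(grp.index[-1])


def round_to_5(x: float) -> int:
    """Reporting helper: round to the nearest 5 years."""
    return int(5 * round(float(x) / 5.0))
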