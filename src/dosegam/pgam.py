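"""Penalized Poisson / quasipoisson regression for grouped cohort cells.

Fits log-link models ``obs_j ~ Pois(mu_j)``, ``log mu_j = offset_j + X_j b``
by minimizing the penalized deviance ``Dev(b) + bᵀ S(λ) b``, where ``S`` is a
block-diagonal sum of spline curvature penalties, each block weighted by its
own smoothing parameter.  Smoothing parameters are chosen by minimizing a
Laplace-approximate marginal likelihood (ML, the default, or REML) or GCV
over log-smoothing-parameters.  Inference uses the Bayesian posterior
covariance ``V_b = (XᵀWX + S)⁻¹ φ``.

The quasipoisson family keeps the Poisson mean model but estimates the
scale φ as the fixed point of Pearson χ² / dfres under refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .splines import BasisBlock, crs_basis, tensor_product

__all__ = [
    "Lin",
    "Fac",
    "Ti",
    "DesignMatrix",
    "FittedModel",
    "poisson_deviance",
    "fit_at_lambda",
    "optimize_smoothing",
    "estimate_scale_quasi",
    "posterior_interval",
    "leverage_and_cooks",
    "exclude_high_cooks",
    "anova_compare",
]

LAMBDA_LO = 1e-8
LAMBDA_HI = 1e9
PHI_LO = 1e-4


# ---------------------------------------------------------------------------
# term descriptors and design assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lin:
    """Unsmoothed (log-linear) parametric term."""

    var: str


@dataclass(frozen=True)
class Fac:
    """Factor main effects with all first-order interactions: (f1+f2+...)^2."""

    vars: tuple[str, ...]


@dataclass(frozen=True)
class Ti:
    """Interaction-only smooth: ti(x) main-effect smooth or ti(x, z) tensor."""

    vars: tuple[str, ...]
    k: int = 10
    min_sp: float | None = None
    knots: tuple[float, ...] | None = None  # explicit knots for 1-d smooths


class DesignMatrix:
    """Assembled design: intercept, factors, parametric and smooth blocks.

    Holds everything needed to refit at new smoothing parameters or to
    evaluate the linear predictor on new cells.
    """

    def __init__(self, df: pd.DataFrame, terms: Sequence, offset: str = "py"):
        n = len(df)
        self.terms = list(terms)
        self.offset_var = offset
        py = np.asarray(df[offset], dtype=float)
        if np.any(py <= 0):
            raise ValueError("offset person-years must be strictly positive")
        self.offset = np.log(py)
        cols: list[np.ndarray] = [np.ones((n, 1))]
        names = ["(Intercept)"]
        self.layout: list[dict] = [{"term": "intercept", "sl": slice(0, 1)}]
        self.penalties: list[dict] = []  # {"sl": slice, "S": matrix, "min_sp": float}
        self.factor_levels: dict[str, list] = {}
        pos = 1
        for t in self.terms:
            if isinstance(t, Fac):
                X, fnames = self._factor_block(df, t)
            elif isinstance(t, Lin):
                X = np.asarray(df[t.var], dtype=float)[:, None]
                fnames = [t.var]
            elif isinstance(t, Ti):
                X, fnames = self._smooth_block(df, t, pos)
            else:  # pragma: no cover
                raise TypeError(f"unknown term {t!r}")
            sl = slice(pos, pos + X.shape[1])
            self.layout.append({"term": t, "sl": sl, "names": fnames})
            cols.append(X)
            pos += X.shape[1]
        self.X = np.hstack(cols)
        self.colnames = None
        self.n, self.p = self.X.shape
        self.nlam = len(self.penalties)
        self._blocks: dict[int, BasisBlock] = getattr(self, "_blocks", {})

    # -- block builders ----------------------------------------------------

    def _factor_block(self, df: pd.DataFrame, t: Fac):
        dummies = {}
        for v in t.vars:
            col = df[v]
            levels = sorted(pd.unique(col.astype(str)))
            self.factor_levels[v] = levels
            D = np.zeros((len(df), max(len(levels) - 1, 0)))
            for i, lev in enumerate(levels[1:]):
                D[:, i] = (col.astype(str) == lev).to_numpy(dtype=float)
            dummies[v] = (D, [f"{v}[{lev}]" for lev in levels[1:]])
        cols, names = [], []
        for v in t.vars:
            D, nm = dummies[v]
            cols.append(D)
            names += nm
        for i, v1 in enumerate(t.vars):
            for v2 in t.vars[i + 1:]:
                D1, n1 = dummies[v1]
                D2, n2 = dummies[v2]
                inter = (D1[:, :, None] * D2[:, None, :]).reshape(len(df), -1)
                cols.append(inter)
                names += [f"{a}:{b}" for a in n1 for b in n2]
        X = np.hstack(cols) if cols else np.zeros((len(df), 0))
        # drop all-zero interaction columns (unobserved level combinations)
        keep = (np.abs(X).sum(axis=0) > 0)
        return X[:, keep], [n for n, k in zip(names, keep) if k]

    def _smooth_block(self, df: pd.DataFrame, t: Ti, pos: int):
        if not hasattr(self, "_blocks"):
            self._blocks = {}
        if not hasattr(self, "penalty_groups"):
            self.penalty_groups = []
        if len(t.vars) == 1:
            v = t.vars[0]
            blk = crs_basis(df[v].to_numpy(dtype=float), k=t.k,
                            knots=t.knots, name=v)
        elif len(t.vars) == 2:
            margins = [
                crs_basis(df[v].to_numpy(dtype=float), k=t.k, name=v)
                for v in t.vars
            ]
            blk = tensor_product(margins[0], margins[1])
        else:
            raise ValueError("ti terms support one or two covariates")
        self._blocks[pos] = blk
        sl = slice(pos, pos + blk.ncol)
        i0 = len(self.penalties)
        for S in blk.penalties:
            self.penalties.append(
                {"sl": sl, "S": S, "min_sp": t.min_sp if t.min_sp else LAMBDA_LO}
            )
        # eigen-structure for fast log-pseudo-determinants: single blocks are
        # plain spectra; a tensor's two kron penalties share the eigenbasis
        # Qa x Qb, so eigenvalues of l1*Sa(x)I + l2*I(x)Sb are l1*a_i + l2*b_j
        if len(blk.penalties) == 1:
            self.penalty_groups.append(
                {"idx": [i0], "eigs": np.linalg.eigvalsh(blk.penalties[0])}
            )
        else:
            Sa = blk.margins[0].Z.T @ blk.margins[0].S @ blk.margins[0].Z
            Sb = blk.margins[1].Z.T @ blk.margins[1].S @ blk.margins[1].Z
            self.penalty_groups.append(
                {"idx": [i0, i0 + 1],
                 "alpha": np.linalg.eigvalsh(0.5 * (Sa + Sa.T)),
                 "beta": np.linalg.eigvalsh(0.5 * (Sb + Sb.T))}
            )
        names = [f"ti({','.join(t.vars)}).{i}" for i in range(blk.ncol)]
        return blk.X, names

    # -- penalties and prediction -----------------------------------------

    def total_penalty(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lmb, pen in zip(lam, self.penalties):
            sl = pen["sl"]
            S[sl, sl] += lmb * pen["S"]
        return S

    def penalty_rank(self, lam: np.ndarray) -> tuple[float, int]:
        """(log pseudo-determinant, rank) of the total penalty, accumulated
        over its diagonal blocks from precomputed spectra."""
        logdet, rank = 0.0, 0
        for g in getattr(self, "penalty_groups", []):
            if len(g["idx"]) == 1:
                ev = lam[g["idx"][0]] * g["eigs"]
            else:
                l1, l2 = lam[g["idx"][0]], lam[g["idx"][1]]
                ev = (l1 * g["alpha"][:, None] + l2 * g["beta"][None, :]).ravel()
            tol = max(ev.max(), 0.0) * 1e-10 if ev.size else 0.0
            pos = ev[ev > tol]
            logdet += float(np.log(pos).sum())
            rank += int(pos.size)
        return logdet, rank

    def penalty_logdet_grad(self, lam: np.ndarray) -> np.ndarray:
        """d log|S(λ)|_+ / dλ per smoothing parameter, from block spectra."""
        g = np.zeros(self.nlam)
        for grp in getattr(self, "penalty_groups", []):
            if len(grp["idx"]) == 1:
                j = grp["idx"][0]
                ev = grp["eigs"]
                tol = max(ev.max(), 0.0) * 1e-10
                g[j] = float((ev > tol).sum()) / lam[j]
            else:
                j1, j2 = grp["idx"]
                ev = lam[j1] * grp["alpha"][:, None] + lam[j2] * grp["beta"][None, :]
                tol = max(ev.max(), 0.0) * 1e-10
                pos = ev > tol
                g[j1] = float(np.sum(np.where(pos, grp["alpha"][:, None] / np.where(pos, ev, 1.0), 0.0)))
                g[j2] = float(np.sum(np.where(pos, grp["beta"][None, :] / np.where(pos, ev, 1.0), 0.0)))
        return g

    def lower_bounds(self) -> np.ndarray:
        return np.array([p["min_sp"] for p in self.penalties])

    def design_for(self, newdata: pd.DataFrame) -> np.ndarray:
        """Evaluate the model columns on new cells (no offset applied)."""
        n = len(newdata)
        cols = [np.ones((n, 1))]
        for entry in self.layout[1:]:
            t = entry["term"]
            if isinstance(t, Fac):
                sub = []
                dummies = {}
                for v in t.vars:
                    levels = self.factor_levels[v]
                    col = newdata[v].astype(str)
                    bad = set(col) - set(levels)
                    if bad:
                        raise ValueError(f"unknown level(s) {bad} for factor {v}")
                    D = np.zeros((n, max(len(levels) - 1, 0)))
                    for i, lev in enumerate(levels[1:]):
                        D[:, i] = (col == lev).to_numpy(dtype=float)
                    dummies[v] = D
                for v in t.vars:
                    sub.append(dummies[v])
                for i, v1 in enumerate(t.vars):
                    for v2 in t.vars[i + 1:]:
                        D1, D2 = dummies[v1], dummies[v2]
                        sub.append((D1[:, :, None] * D2[:, None, :]).reshape(n, -1))
                X = np.hstack(sub) if sub else np.zeros((n, 0))
                # replicate construction-time column dropping
                width = entry["sl"].stop - entry["sl"].start
                if X.shape[1] != width:
                    keep_names = entry["names"]
                    all_names = self._factor_names(t)
                    keep = [all_names.index(nm) for nm in keep_names]
                    X = X[:, keep]
                cols.append(X)
            elif isinstance(t, Lin):
                cols.append(np.asarray(newdata[t.var], dtype=float)[:, None])
            elif isinstance(t, Ti):
                blk = self._blocks[entry["sl"].start]
                cols.append(blk.design({v: newdata[v].to_numpy(dtype=float)
                                        for v in t.vars}))
        return np.hstack(cols)

    def _factor_names(self, t: Fac) -> list[str]:
        per = {v: [f"{v}[{lev}]" for lev in self.factor_levels[v][1:]]
               for v in t.vars}
        names = []
        for v in t.vars:
            names += per[v]
        for i, v1 in enumerate(t.vars):
            for v2 in t.vars[i + 1:]:
                names += [f"{a}:{b}" for a in per[v1] for b in per[v2]]
        return names


# ---------------------------------------------------------------------------
# deviance and the inner penalized fit
# ---------------------------------------------------------------------------

def poisson_deviance(obs, mu) -> float:
    """-2 Σ [obs·log(mu) - mu - I_obs·(obs·log(obs) - obs)]."""
    obs = np.asarray(obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(mu <= 0):
        raise ValueError("fitted means must be positive")
    term = obs * np.log(mu) - mu
    pos = obs > 0
    term[pos] -= obs[pos] * np.log(obs[pos]) - obs[pos]
    return float(-2.0 * term.sum())


@dataclass
class FittedModel:
    """A converged penalized fit with everything needed for inference."""

    design: DesignMatrix
    y: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    family: str
    phi: float
    mu: np.ndarray
    eta: np.ndarray
    dev: float
    edf: float
    score: float | None = None
    method: str | None = None
    converged: bool = True
    iterations: int = 0
    meta: dict = field(default_factory=dict)
    _chol: tuple | None = None
    _XtWX: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def dfres(self) -> float:
        return self.n - self.edf

    @property
    def pearson(self) -> float:
        return float(np.sum((self.y - self.mu) ** 2 / self.mu))

    @property
    def Vb(self) -> np.ndarray:
        """Bayesian posterior covariance (XᵀWX + S)⁻¹ φ."""
        return cho_solve(self._chol, np.eye(self.design.p)) * self.phi

    def predict_eta(self, newdata: pd.DataFrame, offset: bool = False) -> np.ndarray:
        X = self.design.design_for(newdata)
        eta = X @ self.beta
        if offset:
            eta = eta + np.log(np.asarray(newdata[self.design.offset_var], float))
        return eta

    def to_json(self) -> str:
        out = {
            "family": self.family,
            "phi": self.phi,
            "coefficients": self.beta.tolist(),
            "lambda": self.lam.tolist(),
            "deviance": self.dev,
            "edf": self.edf,
            "dfres": self.dfres,
            "score": self.score,
            "method": self.method,
            "knots": {
                f"ti({','.join(e['term'].vars)})": [m.knots.tolist()
                                                    for m in self.design._blocks[e["sl"].start].margins]
                for e in self.design.layout[1:]
                if isinstance(e["term"], Ti)
            },
        }
        return json.dumps(out, indent=1)


def fit_at_lambda(
    design: DesignMatrix,
    y,
    lam,
    family: str = "poisson",
    phi: float = 1.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
    polish: bool = True,
) -> FittedModel:
    """Penalized IRLS at fixed smoothing parameters.

    Minimizes Dev(b) + bᵀS(λ)b with the offset coefficient fixed at 1;
    step-halving guards against divergence.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative counts")
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam.size != design.nlam:
        raise ValueError(f"expected {design.nlam} smoothing parameters, got {lam.size}")
    X, off = design.X, design.offset
    S = design.total_penalty(lam)
    if beta0 is None:
        mu = y + np.mean(y) * 0.1 + 0.1
        eta = np.log(mu)
        beta = np.zeros(design.p)
        beta[0] = np.log(max(y.sum(), 0.5) / np.exp(off).sum())
        eta = off + X @ beta
        mu = np.exp(eta)
    else:
        beta = beta0.copy()
        eta = off + X @ beta
        mu = np.exp(np.clip(eta, -300, 300))
    pdev = poisson_deviance(y, mu) + beta @ S @ beta
    chol = None
    XtWX = None
    for it in range(1, max_iter + 1):
        w = mu
        z = (eta - off) + (y - mu) / mu
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + S
        try:
            chol = cho_factor(A + np.eye(design.p) * 1e-12 * max(A.diagonal().max(), 1.0))
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"singular penalized system at iteration {it}") from e
        beta_new = cho_solve(chol, X.T @ (w * z))
        step = 1.0
        for _ in range(40):
            b_try = beta + step * (beta_new - beta)
            eta_try = off + X @ b_try
            if eta_try.max() > 300:
                step *= 0.5
                continue
            mu_try = np.exp(eta_try)
            pdev_try = poisson_deviance(y, np.maximum(mu_try, 1e-300)) + b_try @ S @ b_try
            if np.isfinite(pdev_try) and pdev_try <= pdev + 1e-11 * (abs(pdev) + 1.0):
                break
            step *= 0.5
        else:
            # no step reduces the penalized deviance any further: the current
            # point is the minimum to within rounding
            break
        delta = abs(pdev - pdev_try)
        beta, eta, mu, pdev = b_try, eta_try, mu_try, pdev_try
        if delta < tol * (abs(pdev) + tol):
            break
    else:
        raise RuntimeError(
            f"penalized IRLS failed to converge in {max_iter} iterations "
            f"(last penalized deviance {pdev:.6g})"
        )
    # polish: plain Newton steps until the penalized score equation is tight
    # (this is what makes sum(mu) = sum(obs) hold with intercept and offset)
    gtol = 1e-7 * max(1.0, y.sum())
    for _ in range(10 if polish else 0):
        g = X.T @ (y - mu) - S @ beta
        gmax = np.max(np.abs(g))
        if gmax < gtol:
            break
        w = mu
        A = X.T @ (X * w[:, None]) + S
        chol = cho_factor(A + np.eye(design.p) * 1e-12 * max(A.diagonal().max(), 1.0))
        b_new = beta + cho_solve(chol, g)
        eta_new = off + X @ b_new
        mu_new = np.exp(np.clip(eta_new, -300, 300))
        g_new = X.T @ (y - mu_new) - S @ b_new
        if np.max(np.abs(g_new)) >= gmax:  # polish no longer improving
            break
        beta, eta, mu = b_new, eta_new, mu_new
    g = X.T @ (y - mu) - S @ beta
    if polish and np.max(np.abs(g)) > 1e-3 * max(1.0, y.sum()):
        raise RuntimeError(
            f"penalized IRLS stalled with score-equation sup-norm "
            f"{np.max(np.abs(g)):.3g} after {it} iterations"
        )
    # final curvature at the solution
    w = mu
    XtWX = X.T @ (X * w[:, None])
    A = XtWX + S
    chol = cho_factor(A + np.eye(design.p) * 1e-12 * max(A.diagonal().max(), 1.0))
    edf = float(np.trace(cho_solve(chol, XtWX)))
    dev = poisson_deviance(y, mu)
    return FittedModel(
        design=design, y=y, beta=beta, lam=lam, family=family, phi=phi,
        mu=mu, eta=eta, dev=dev, edf=edf, iterations=it,
        _chol=chol, _XtWX=XtWX,
    )


# ---------------------------------------------------------------------------
# smoothing parameter selection criteria
# ---------------------------------------------------------------------------

def criterion_value(fit: FittedModel, method: str = "ML") -> float:
    """Score used for smoothing-parameter selection (lower is better).

    ML/REML: negative Laplace-approximate log marginal likelihood of the
    penalized model, with a flat prior over the penalty null space (constant
    terms in the data dropped).  GCV: n·Dev/(n-edf)².
    """
    d = fit.design
    if method.upper() == "GCV":
        return float(d.n * fit.dev / (d.n - fit.edf) ** 2)
    phi = fit.phi
    pdev = fit.dev + fit.beta @ d.total_penalty(fit.lam) @ fit.beta
    logdetS, r = d.penalty_rank(fit.lam)
    logdetA = 2.0 * np.sum(np.log(np.diag(fit._chol[0])))
    Mp = d.p - r
    return float(
        pdev / (2.0 * phi)
        + 0.5 * (logdetA - logdetS)
        - 0.5 * r * np.log(phi)
        - 0.5 * Mp * np.log(2.0 * np.pi * phi)
    )


def criterion_grad(fit: FittedModel, method: str = "ML") -> np.ndarray:
    """Exact gradient of the ML/REML criterion over log smoothing parameters.

    Differentiates through the penalized score equation (canonical log
    link): dβ̂/dρ_j = -λ_j A⁻¹ S_j β̂ with A = XᵀWX + S, which also gives the
    weight-dependence of log|A| via the diagonal of X A⁻¹ Xᵀ.
    """
    d = fit.design
    lam = fit.lam
    phi = fit.phi
    X, w = d.X, fit.mu
    B = cho_solve(fit._chol, X.T)  # p x n
    hdiag = np.einsum("ij,ji->i", X, B)
    gld = d.penalty_logdet_grad(lam)
    g = np.zeros(d.nlam)
    for j, pen in enumerate(d.penalties):
        sl = pen["sl"]
        pb = sl.stop - sl.start
        Sb = np.zeros(d.p)
        Sb[sl] = pen["S"] @ fit.beta[sl]
        v = cho_solve(fit._chol, Sb)
        # tr(A^-1 S_j) from the block columns of A^-1
        E = np.zeros((d.p, pb))
        E[sl, :] = np.eye(pb)
        Ainv_cols = cho_solve(fit._chol, E)
        tr_term = float(np.einsum("ij,ji->", Ainv_cols[sl, :], pen["S"]))
        u = -lam[j] * (X @ v)  # d eta / d rho_j
        dW_term = 0.5 * float(np.sum(w * u * hdiag))
        g[j] = lam[j] * (
            float(fit.beta[sl] @ Sb[sl]) / (2.0 * phi)
            + 0.5 * tr_term
            - 0.5 * gld[j]
        ) + dW_term
    return g


def _fellner_schall(design, y, lam, lo, family, phi, beta0,
                    max_iter=30, step_tol=0.02):
    """Generalized Fellner-Schall smoothing-parameter updates.

    λ_j <- λ_j · [d log|S|_+/dλ_j − tr(A⁻¹ S_j)] / [βᵀ S_j β / φ], which has
    the REML stationary point as its fixed point; used as a cheap warm-up
    before polishing the requested criterion.
    """
    beta = beta0
    p = design.p
    for _ in range(max_iter):
        try:
            fit = fit_at_lambda(design, y, lam, family=family, phi=phi,
                                beta0=beta, polish=False)
        except RuntimeError:
            return lam, beta
        beta = fit.beta
        gld = design.penalty_logdet_grad(lam)
        ratios = np.ones(design.nlam)
        for j, pen in enumerate(design.penalties):
            sl = pen["sl"]
            E = np.zeros((p, sl.stop - sl.start))
            E[sl, :] = np.eye(sl.stop - sl.start)
            Ainv_cols = cho_solve(fit._chol, E)
            tr_term = float(np.trace(Ainv_cols[sl, :] @ pen["S"]))
            num = max(gld[j] - tr_term, 1e-10)
            den = max(float(beta[sl] @ pen["S"] @ beta[sl]) / phi, 1e-12)
            ratios[j] = num / den
        lam_new = np.clip(lam * np.clip(ratios, 0.05, 20.0), lo, LAMBDA_HI)
        move = np.max(np.abs(np.log(lam_new / np.maximum(lam, 1e-300))))
        lam = lam_new
        if move < step_tol:
            break
    return lam, beta


def optimize_smoothing(
    design: DesignMatrix,
    y,
    family: str = "poisson",
    method: str = "ML",
    phi: float = 1.0,
    min_sp: float | np.ndarray | None = None,
    lam0: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-6,
) -> FittedModel:
    """Outer optimization of the selection criterion over log smoothing
    parameters (quasi-Newton with finite-difference gradients)."""
    y = np.asarray(y, dtype=float)
    if design.nlam == 0:
        fit = fit_at_lambda(design, y, [], family=family, phi=phi, beta0=beta0)
        fit.score = criterion_value(fit, method)
        fit.method = method
        return fit
    lo = design.lower_bounds()
    if min_sp is not None:
        lo = np.maximum(lo, np.atleast_1d(np.asarray(min_sp, float)))
    lam = np.clip(np.atleast_1d(lam0 if lam0 is not None else np.ones(design.nlam)),
                  lo, LAMBDA_HI)
    beta_ws = beta0
    if method.upper() in ("ML", "REML"):
        # Fellner-Schall multiplicative warm-up: one inner fit per update,
        # no criterion derivatives needed; lands near the optimum cheaply
        lam, beta_ws = _fellner_schall(design, y, lam, lo, family, phi, beta_ws,
                                       max_iter=8 if lam0 is not None else 30)
    x0 = np.log(np.maximum(lam, lo))
    state = {"beta": beta_ws}
    use_grad = method.upper() in ("ML", "REML")

    def _inner(rho: np.ndarray):
        lam = np.exp(np.clip(rho, np.log(LAMBDA_LO), np.log(LAMBDA_HI)))
        try:
            f = fit_at_lambda(design, y, lam, family=family, phi=phi,
                              beta0=state["beta"], polish=False)
        except RuntimeError:
            try:
                f = fit_at_lambda(design, y, lam, family=family, phi=phi,
                                  polish=False)
            except RuntimeError:
                return None
        state["beta"] = f.beta
        return f

    def loss(rho: np.ndarray) -> float:
        f = _inner(rho)
        return 1e12 if f is None else criterion_value(f, method)

    def loss_and_grad(rho: np.ndarray):
        f = _inner(rho)
        if f is None:
            return 1e12, np.zeros_like(rho)
        return criterion_value(f, method), criterion_grad(f, method)

    bounds = [(np.log(l), np.log(LAMBDA_HI)) for l in lo]
    if use_grad:
        res = optimize.minimize(
            loss_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol * 1e-4, "gtol": 1e-6, "maxiter": 200},
        )
    else:
        res = optimize.minimize(
            loss, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol * 1e-3, "gtol": 1e-5, "eps": 1e-3,
                     "maxiter": 100, "maxls": 12},
        )
    lam = np.exp(res.x)
    at_bound = np.any(np.isclose(res.x, [b[0] for b in bounds])) or np.any(
        np.isclose(res.x, np.log(LAMBDA_HI))
    )
    if at_bound:
        warnings.warn("smoothing parameter at its bound (flat criterion)",
                      RuntimeWarning, stacklevel=2)
    fit = fit_at_lambda(design, y, lam, family=family, phi=phi, beta0=state["beta"])
    fit.score = criterion_value(fit, method)
    fit.method = method
    return fit


def estimate_scale_quasi(
    design: DesignMatrix,
    y,
    method: str = "ML",
    min_sp=None,
    lam0=None,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> FittedModel:
    """Quasipoisson fit with φ the fixed point of Pearson χ²/dfres."""
    phi = 1.0
    fit = None
    history = []
    for _ in range(max_iter):
        fit = optimize_smoothing(
            design, y, family="quasipoisson", method=method, phi=phi,
            min_sp=min_sp, lam0=fit.lam if fit is not None else lam0,
            beta0=fit.beta if fit is not None else None,
        )
        phi_new = max(fit.pearson / fit.dfres, PHI_LO)
        history.append(abs(phi_new - phi))
        if abs(phi_new - phi) < tol:
            phi = phi_new
            break
        if len(history) > 6 and history[-1] > history[-3] > history[-5]:
            warnings.warn("oscillating scale iteration; returning best-so-far",
                          RuntimeWarning, stacklevel=2)
            break
        phi = phi_new
    fit.phi = phi
    fit.score = criterion_value(fit, method)
    return fit


# ---------------------------------------------------------------------------
# inference and diagnostics
# ---------------------------------------------------------------------------

def posterior_interval(fit: FittedModel, contrast: np.ndarray, level: float = 0.90):
    """Normal-theory interval for a linear functional Cβ on the link scale.

    Returns (estimate, lcl, ucl) arrays; exponentiate for RR-type quantities.
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != fit.design.p:
        raise ValueError(
            f"contrast has {C.shape[1]} columns but the model has {fit.design.p} terms"
        )
    est = C @ fit.beta
    half = cho_solve(fit._chol, C.T)
    var = np.einsum("ij,ji->i", C, half) * fit.phi
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, est - z * se, est + z * se


def leverage_and_cooks(fit: FittedModel):
    """Per-cell leverage (diagonal of the influence matrix; sums to edf) and
    Cook's distance from standardized Pearson residuals."""
    X = fit.design.X
    w = fit.mu
    B = cho_solve(fit._chol, (X * w[:, None]).T)  # p x n
    h = np.einsum("ij,ji->i", X, B)
    h = np.clip(h, 0.0, 1.0 - 1e-12)
    rp = (fit.y - fit.mu) / np.sqrt(fit.phi * fit.mu)
    cd = rp**2 * h / (max(fit.edf, 1e-12) * (1.0 - h) ** 2)
    return h, cd


def exclude_high_cooks(df: pd.DataFrame, fit: FittedModel, q: float = 5.0) -> pd.DataFrame:
    """Drop the top q% of cells by Cook's distance (q=0 returns df unchanged)."""
    if q <= 0:
        return df
    _, cd = leverage_and_cooks(fit)
    cut = np.quantile(cd, 1.0 - q / 100.0)
    return df.loc[np.asarray(cd) < cut].reset_index(drop=True)


def anova_compare(nested: FittedModel, fuller: FittedModel) -> dict:
    """Deviance-difference test between nested penalized fits.

    χ² reference for Poisson; F with the fuller model's Pearson scale for
    quasipoisson.  Models must be fitted to the same response.
    """
    if nested.n != fuller.n or not np.array_equal(nested.y, fuller.y):
        raise ValueError("models are not fitted to the same data")
    ddf = fuller.edf - nested.edf
    ddev = nested.dev - fuller.dev
    if ddf <= 1e-8 or ddev <= 0:
        return {"statistic": max(ddev, 0.0), "df": max(ddf, 0.0), "p": 1.0}
    if fuller.family == "quasipoisson":
        phi = fuller.phi
        F = (ddev / ddf) / phi
        p = float(stats.f.sf(F, ddf, fuller.dfres))
        return {"statistic": F, "df": ddf, "p": p, "phi": phi}
    p = float(stats.chi2.sf(ddev, ddf))
    return {"statistic": ddev, "df": ddf, "p": p}
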