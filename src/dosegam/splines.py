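"""Cardinal cubic regression spline bases, curvature penalties, tensor products.

The basis used throughout is the natural ("cardinal") cubic regression
spline: ``k`` knots are placed on the covariate (by default at equally
spaced quantiles of its unique values), and basis function *i* is the
natural cubic interpolating spline taking the value 1 at knot *i* and 0
at the others.  Coefficients are therefore the function values at the
knots, and the quadratic curvature penalty ``∫ f''(x)² dx`` has the
closed form ``βᵀ D B⁻¹ D β`` in this parameterization.  The null space
of the penalty is the span of constants and linears, so as the
smoothing parameter grows the smooth degenerates to a straight line.

Main-effect and interaction ("ti"-style) blocks are produced by
applying a sum-to-zero centering constraint per margin, so that an
interaction tensor product excludes the marginal main effects and
``ti(x) + ti(x, z)`` decomposes main effect and interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BasisBlock", "crs_basis", "tensor_product"]


def _crs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band matrices of the natural cubic spline construction.

    Returns (D, B, F) where the interior second derivatives of the
    interpolant with values beta are ``B⁻¹ D beta`` and F stacks that map
    to all k knots (natural end conditions: zero curvature at the ends).
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F = np.zeros((k, k))
    F[1:-1] = np.linalg.solve(B, D)
    return D, B, F


def _crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluate the k cardinal basis functions at x (linear extrapolation)."""
    x = np.asarray(x, dtype=float)
    k = knots.size
    X = np.zeros((x.size, k))
    h = np.diff(knots)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    inside = (x >= knots[0]) & (x <= knots[-1])

    xi = x[inside]
    ji = j[inside]
    hj = h[ji]
    lo = knots[ji]
    hi = knots[ji + 1]
    am = (hi - xi) / hj
    ap = (xi - lo) / hj
    cm = ((hi - xi) ** 3 / hj - hj * (hi - xi)) / 6.0
    cp = ((xi - lo) ** 3 / hj - hj * (xi - lo)) / 6.0
    rows = np.zeros((xi.size, k))
    rows[np.arange(xi.size), ji] = am
    rows[np.arange(xi.size), ji + 1] = ap
    rows += cm[:, None] * F[ji] + cp[:, None] * F[ji + 1]
    X[inside] = rows

    # beyond the boundary knots a natural spline is linear
    for side, idx in ((x < knots[0], 0), (x > knots[-1], k - 2)):
        if not side.any():
            continue
        hj = h[idx]
        lo, hi = knots[idx], knots[idx + 1]
        x0 = lo if idx == 0 else hi
        # value and first derivative of the basis at the boundary knot
        val = np.zeros(k)
        val[idx if idx == 0 else idx + 1] = 1.0
        der = np.zeros(k)
        der[idx] = -1.0 / hj
        der[idx + 1] = 1.0 / hj
        if idx == 0:  # at x = lo
            der += (-(3.0 * hj**2 / hj - hj) / 6.0) * F[idx] + (-hj / 6.0) * F[idx + 1]
        else:  # at x = hi
            der += (hj / 6.0) * F[idx] + ((3.0 * hj**2 / hj - hj) / 6.0) * F[idx + 1]
        X[side] = val[None, :] + (x[side] - x0)[:, None] * der[None, :]
    return X


@dataclass
class _Margin:
    """One covariate margin: knots plus its interpolation map."""

    name: str
    knots: np.ndarray
    F: np.ndarray
    S: np.ndarray  # raw k x k curvature penalty
    Z: np.ndarray  # k x (k-1) centering constraint null basis

    def design(self, x: np.ndarray, centered: bool = True) -> np.ndarray:
        X = _crs_design(x, self.knots, self.F)
        return X @ self.Z if centered else X


@dataclass
class BasisBlock:
    """A design block with one curvature penalty per smoothing parameter.

    ``X`` holds the evaluated (and constrained) columns at the
    construction data; ``penalties`` are symmetric PSD matrices of the
    same dimension as the column count, each taking its own smoothing
    parameter in the total penalty.
    """

    names: tuple[str, ...]
    X: np.ndarray
    penalties: list[np.ndarray]
    margins: list[_Margin] = field(default_factory=list)
    k: tuple[int, ...] = ()
    centered: bool = True

    @property
    def ncol(self) -> int:
        return self.X.shape[1]

    def design(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluate the block's columns at new covariate values."""
        mats = [m.design(np.asarray(values[m.name], dtype=float)) for m in self.margins]
        out = mats[0]
        for M in mats[1:]:
            out = (out[:, :, None] * M[:, None, :]).reshape(out.shape[0], -1)
        return out


def default_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Equally spaced quantiles of the unique covariate values."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(
            f"only {ux.size} distinct covariate values for a basis of dimension "
            f"{k}; lower k to at most {ux.size}"
        )
    probs = np.linspace(0.0, 1.0, k)
    knots = np.quantile(ux, probs)
    return np.unique(knots)


def _build_margin(x: np.ndarray, k: int, knots=None, name: str = "x") -> _Margin:
    x = np.asarray(x, dtype=float)
    if k < 3:
        raise ValueError("basis dimension k must be at least 3")
    if knots is None:
        kn = default_knots(x, k)
        if kn.size < k:
            raise ValueError(
                "quantile knots collapsed to fewer than k distinct locations; lower k"
            )
    else:
        kn = np.unique(np.asarray(knots, dtype=float))
        if kn.size != len(knots):
            raise ValueError("explicit knots must be distinct")
        if kn.size < 3:
            raise ValueError("need at least 3 knots")
    D, B, F = _crs_matrices(kn)
    S = D.T @ np.linalg.solve(B, D)
    S = 0.5 * (S + S.T)
    X = _crs_design(x, kn, F)
    # sum-to-zero constraint over the construction data, absorbed through a
    # Householder null-space basis so the constrained block keeps k-1 columns
    c = X.sum(axis=0)[:, None]
    Q, _ = np.linalg.qr(c, mode="complete")
    Z = Q[:, 1:]
    return _Margin(name=name, knots=kn, F=F, S=S, Z=Z)


def crs_basis(x, k: int = 10, knots=None, name: str = "x") -> BasisBlock:
    """Centered cubic-regression-spline main-effect block.

    The returned block has ``k - 1`` columns (one lost to the sum-to-zero
    constraint; the constant is carried by the model intercept) and a single
    curvature penalty whose null space is the centered linear trend.
    """
    m = _build_margin(x, k, knots=knots, name=name)
    X = m.design(np.asarray(x, dtype=float), centered=True)
    S = m.Z.T @ m.S @ m.Z
    return BasisBlock(
        names=(name,), X=X, penalties=[0.5 * (S + S.T)], margins=[m], k=(m.knots.size,)
    )


def raw_crs_design(x, k: int = 10, knots=None):
    """Uncentered cardinal design and penalty (basis i is 1 at knot i).

    Mostly useful for inspecting the cardinal property and for tests; the
    model-facing blocks are the centered ones.
    """
    m = _build_margin(x, k, knots=knots)
    return m.design(np.asarray(x, dtype=float), centered=False), m.S, m.knots


def tensor_product(a: BasisBlock, b: BasisBlock) -> BasisBlock:
    """Interaction-only tensor product of two centered marginal blocks.

    Columns are the row-wise products of the centered margins, giving
    ``(k_a - 1)(k_b - 1)`` columns; two penalty blocks (one per margin,
    each with its own smoothing parameter) penalize curvature along each
    margin while leaving the bilinear term unpenalized.
    """
    if a.X.shape[0] != b.X.shape[0]:
        raise ValueError("tensor margins must be built on the same cells")
    if len(a.margins) != 1 or len(b.margins) != 1:
        raise ValueError("tensor_product combines two univariate margins")
    ma, mb = a.margins[0], b.margins[0]
    Xa, Xb = a.X, b.X
    X = (Xa[:, :, None] * Xb[:, None, :]).reshape(Xa.shape[0], -1)
    Sa = a.penalties[0]
    Sb = b.penalties[0]
    pa, pb = Sa.shape[0], Sb.shape[0]
    P1 = np.kron(Sa, np.eye(pb))
    P2 = np.kron(np.eye(pa), Sb)
    return BasisBlock(
        names=(ma.name, mb.name),
        X=X,
        penalties=[P1, P2],
        margins=[ma, mb],
        k=(ma.knots.size, mb.knots.size),
    )
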