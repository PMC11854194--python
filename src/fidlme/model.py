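"""Data model and deterministic linear-algebra kernels for fiducial LME.

The mixed model is

    y_i = x_i beta + z_i gamma_i + e_i,   gamma_i ~ N_q(0, D),  e_i ~ N(0, sigma^2 I),

for subjects i = 1..m with D = diag(sigma_1^2, ..., sigma_q^2).  Writing the
random-effect standard deviations as a coefficient vector delta on the
columns z_i diag(U_i), with U_i standardized latent effects, turns the model
into an ordinary regression given U = u:

    y = X beta + Z_u delta + e = X_u theta + e,    X_u = (X, Z_u).

This module holds the design container and the kernels the sampler needs:
stacking X_u for a given u, and the least-squares/projection quantities
(GLS estimate, residual sum of squares, a factor of (X_u'X_u)^{-1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "LMEDesign",
    "ParamState",
    "ProjectionQuantities",
    "build_design",
    "stack_xu",
    "projection_quantities",
]


class DesignError(ValueError):
    """Raised when a design table or its column-role mapping is invalid."""


@dataclass(frozen=True)
class LMEDesign:
    """Stacked per-subject design blocks for a single-grouping-level LME.

    Rows are ordered by subject (first appearance in the source table) and,
    within a subject, by original row order.  ``group_index`` maps each row
    to its 0-based subject index; ``group_sizes[i]`` is n_i.
    """

    y: np.ndarray               # (n,)
    X: np.ndarray               # (n, p) fixed-effect covariates
    Z: np.ndarray               # (n, q) random-effect covariates
    group_sizes: np.ndarray     # (m,) int
    group_index: np.ndarray     # (n,) int, non-decreasing
    fixed_names: tuple = ()
    random_names: tuple = ()
    group_labels: tuple = ()

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        sizes = np.asarray(self.group_sizes, dtype=int)
        idx = np.asarray(self.group_index, dtype=int)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "group_sizes", sizes)
        object.__setattr__(self, "group_index", idx)
        n = y.shape[0]
        if sizes.size < 1 or np.any(sizes < 1):
            raise DesignError("every subject must contribute at least one row")
        if sizes.sum() != n or X.shape[0] != n or Z.shape[0] != n or idx.shape[0] != n:
            raise DesignError("block sizes do not add up to the number of rows")
        if Z.shape[1] < 1:
            raise DesignError("at least one random-effect column is required (q >= 1)")
        if n <= X.shape[1] + Z.shape[1]:
            raise DesignError(
                f"need n > p + q for positive residual degrees of freedom; "
                f"got n={n}, p={X.shape[1]}, q={Z.shape[1]}"
            )
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
            raise DesignError("design contains non-finite values")

    @property
    def m(self) -> int:
        return int(self.group_sizes.size)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    @property
    def q(self) -> int:
        return int(self.Z.shape[1])

    @property
    def dof(self) -> int:
        """Residual degrees of freedom n - p - q of the conditional fit."""
        return self.n - self.p - self.q

    @cached_property
    def balanced(self) -> bool:
        return bool(np.all(self.group_sizes == self.group_sizes[0]))

    def block(self, i: int):
        """Return (y_i, x_i, z_i) for subject i."""
        starts = np.concatenate([[0], np.cumsum(self.group_sizes)])
        sl = slice(starts[i], starts[i + 1])
        return self.y[sl], self.X[sl], self.Z[sl]

    @cached_property
    def _blocks3d(self):
        ni = int(self.group_sizes[0])
        return (
            self.y.reshape(self.m, ni),
            self.X.reshape(self.m, ni, self.p),
            self.Z.reshape(self.m, ni, self.q),
        )

    def blocks3d(self):
        """Stacked (m, n_i, .) views of y, X, Z; balanced designs only."""
        if not self.balanced:
            raise DesignError("blocks3d requires equal group sizes")
        return self._blocks3d


@dataclass(frozen=True)
class ParamState:
    """One point eta = (beta, delta, sigma^2) in the parameter space.

    ``delta`` is signed: the fiducial density is symmetric under
    delta_j -> -delta_j and the chain may occupy either sign; the implied
    random-effect covariance is D = diag(delta_j^2) regardless.
    """

    beta: np.ndarray
    delta: np.ndarray
    sigma2: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        object.__setattr__(self, "delta", np.atleast_1d(np.asarray(self.delta, dtype=float)))
        object.__setattr__(self, "sigma2", float(self.sigma2))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class ProjectionQuantities:
    """Least-squares quantities of y on an augmented design X_u.

    ``chol_inv`` is a matrix S with S S' = (X_u'X_u)^{-1} (lower Cholesky
    factor when X_u has full column rank, a pseudo-inverse factor with
    ``rank`` columns otherwise); ``gls`` is the minimum-norm least-squares
    solution and ``rss`` the residual sum of squares y'(I - P_u)y.
    """

    gls: np.ndarray
    rss: float
    chol_inv: np.ndarray
    rank: int
    full_rank: bool = field(default=True)


def build_design(
    table: pd.DataFrame,
    response: str,
    group: str,
    fixed: tuple = (),
    random: tuple = (),
    fixed_intercept: bool = True,
    random_intercept: bool = False,
) -> LMEDesign:
    """Assemble an :class:`LMEDesign` from a long-format table.

    Columns are ordered intercept-first within the fixed and random parts,
    then in the order given, so coefficient indices map deterministically to
    covariates.  Subjects are ordered by first appearance.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    needed = [response, group, *fixed, *random]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise DesignError(f"missing columns in input table: {missing}")
    for c in [response, *fixed, *random]:
        if not np.issubdtype(np.asarray(table[c]).dtype, np.number):
            raise DesignError(f"column {c!r} is not numeric")
    if table.shape[0] == 0:
        raise DesignError("input table is empty")

    codes, labels = pd.factorize(table[group])  # first-appearance order
    order = np.argsort(codes, kind="stable")
    tab = table.iloc[order]
    codes = codes[order]
    sizes = np.bincount(codes)
    if np.any(sizes == 0):
        raise DesignError("empty group encountered")

    n = tab.shape[0]
    xcols = [np.ones(n)] if fixed_intercept else []
    xnames = ["(Intercept)"] if fixed_intercept else []
    for c in fixed:
        xcols.append(np.asarray(tab[c], dtype=float))
        xnames.append(c)
    zcols = [np.ones(n)] if random_intercept else []
    znames = ["(Intercept)"] if random_intercept else []
    for c in random:
        zcols.append(np.asarray(tab[c], dtype=float))
        znames.append(c)
    if not zcols:
        raise DesignError("random part is empty: give random columns or random_intercept=True")
    if not xcols:
        raise DesignError("fixed part is empty: give fixed columns or fixed_intercept=True")

    return LMEDesign(
        y=np.asarray(tab[response], dtype=float),
        X=np.column_stack(xcols),
        Z=np.column_stack(zcols),
        group_sizes=sizes,
        group_index=codes,
        fixed_names=tuple(xnames),
        random_names=tuple(znames),
        group_labels=tuple(labels),
    )


def stack_xu(design: LMEDesign, u: np.ndarray) -> np.ndarray:
    """Stack the augmented design X_u = (X, Z_u) with z_{u,i} = z_i diag(U_i).

    ``u`` is the (m, q) matrix of latent standardized effects; the random
    columns of block i are z_i scaled columnwise by U_i.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (design.m, design.q):
        raise DesignError(f"u has shape {u.shape}, expected {(design.m, design.q)}")
    zu = design.Z * u[design.group_index]
    return np.concatenate([design.X, zu], axis=1)


def _tri_inv_lower(l: np.ndarray) -> np.ndarray:
    """Invert a small lower-triangular matrix via LAPACK trtri."""
    from scipy.linalg.lapack import dtrtri

    linv, info = dtrtri(l, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("triangular inversion failed")
    return linv


def projection_quantities(xu: np.ndarray, y: np.ndarray) -> ProjectionQuantities:
    """GLS estimate, residual sum of squares and an inverse-Gram factor.

    Rank is detected from the eigenvalues of the symmetrized Gram matrix
    with tolerance k * eps * s_max on the singular value scale.  Full-rank
    designs use the lower Cholesky factor of (X_u'X_u)^{-1}; rank-deficient
    ones fall back to the minimum-norm solution through the pseudo-inverse.
    """
    xu = np.asarray(xu, dtype=float)
    y = np.asarray(y, dtype=float)
    nrow, k = xu.shape
    if y.shape[0] != nrow:
        raise DesignError("response length does not match design rows")
    a = xu.T @ xu
    a = 0.5 * (a + a.T)
    b = xu.T @ y
    # fast path: well-conditioned Gram matrix, Cholesky certifies full rank
    diag = np.diag(a)
    if np.all(diag > 0):
        try:
            l = np.linalg.cholesky(a)
            ldiag = np.diag(l)
            if ldiag.min() > np.sqrt(max(nrow, k) * np.finfo(float).eps) * ldiag.max():
                linv = _tri_inv_lower(l)
                ainv = linv.T @ linv
                s = np.linalg.cholesky(0.5 * (ainv + ainv.T))
                gls = ainv @ b
                resid = y - xu @ gls
                return ProjectionQuantities(
                    gls=gls, rss=float(resid @ resid), chol_inv=s, rank=k, full_rank=True
                )
        except np.linalg.LinAlgError:
            pass
    w, v = np.linalg.eigh(a)
    svals = np.sqrt(np.clip(w, 0.0, None))
    smax = svals[-1] if svals.size else 0.0
    # eigenvalues carry Gram-formation roundoff of order eps*smax^2, so the
    # detectable singular-value floor is sqrt(eps)*smax, not eps*smax
    tol = np.sqrt(max(nrow, k) * np.finfo(float).eps) * smax
    keep = svals > tol
    rank = int(keep.sum())
    if rank == k:
        ainv = (v / w) @ v.T
        ainv = 0.5 * (ainv + ainv.T)
        s = np.linalg.cholesky(ainv)
        gls = ainv @ b
        full = True
    else:
        vk = v[:, keep]
        s = vk / svals[keep]          # S S' = (X_u'X_u)^+
        gls = s @ (s.T @ b)           # minimum-norm least squares
        full = False
    resid = y - xu @ gls
    rss = float(resid @ resid)
    return ProjectionQuantities(gls=gls, rss=rss, chol_inv=s, rank=rank, full_rank=full)
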