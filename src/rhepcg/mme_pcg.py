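"""Matrix-free mixed-model equations and their Jacobi-preconditioned CG solver.

The SNP-BLUP mixed-model equations are

    [ X'X      X'Z*        ] [theta]   [ X'y  ]
    [ Z*'X     Z*'Z* + lam ] [  u  ] = [ Z*'y ]

with X the intercept incidence (a column of ones) and Z* = Z / sqrt(m)
the standardized design rescaled so that SNP-BLUP is algebraically
identical to GBLUP with G = ZZ'/m and lam = sigma_e2 / sigma_g2.  The
coefficient matrix is applied as factored matrix-vector products with X
and Z only — it is never assembled, and no n x n or (m+1) x (m+1) array
exists anywhere in this module.

The solver is textbook preconditioned conjugate gradient with the Jacobi
preconditioner M = diag(A); the true residual is recomputed periodically
to guard against drift of the recurred residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np

from .core import StandardizedDesign, VarianceComponents
from .rhe import H2_MIN, H2_MAX

__all__ = [
    "MMEOperator",
    "MMESolution",
    "apply_operator",
    "pcg_solve",
    "fit_rhepcg",
    "predict_from_solution",
]

#: iterations between true-residual recomputations
_TRUE_RESIDUAL_EVERY = 50


class MMEOperator:
    """Symmetric positive-definite MME coefficient operator, applied matrix-free.

    Parameters
    ----------
    design : StandardizedDesign
        Supplies X (intercept incidence) and Z; the marker block uses
        Z* = Z/sqrt(m).
    lam : float
        Ridge added to the marker block; must be positive, which makes the
        operator SPD.
    """

    def __init__(self, design: StandardizedDesign, lam: float):
        if lam <= 0:
            raise ValueError("ridge parameter lam must be positive")
        self.design = design
        self.lam = float(lam)
        self._scale = 1.0 / np.sqrt(design.m)
        self.dim = design.m + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.dim, self.dim)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return apply_operator(self, v)

    __matmul__ = matvec

    def diagonal(self) -> np.ndarray:
        """diag(A) for the Jacobi preconditioner.

        diag(X'X) = n; diag(Z*'Z*)_j = (sum_i z_ij^2)/m + lam, which is
        n/m + lam under divisor-n scaling.  One vectorized column pass —
        exact for any design, including reference-standardized ones.
        """
        Z = self.design.Z
        d = np.empty(self.dim)
        d[0] = self.design.n
        d[1:] = (Z * Z).sum(axis=0) / self.design.m + self.lam
        return d

    def rhs(self) -> np.ndarray:
        """Right-hand side b = [X'y, Z*'y]."""
        y = self.design.y
        if y is None:
            raise ValueError("design carries no phenotype vector")
        b = np.empty(self.dim)
        b[0] = float(y.sum())
        b[1:] = (self.design.Z.T @ y) * self._scale
        return b


def apply_operator(op: MMEOperator, v: np.ndarray) -> np.ndarray:
    """Compute A @ v via the factored products, O(nm) work, O(n+m) memory."""
    v = np.asarray(v, dtype=float)
    if v.shape != (op.dim,):
        raise ValueError(f"expected vector of length {op.dim}, got {v.shape}")
    Z, s = op.design.Z, op._scale
    a = v[0] + (Z @ v[1:]) * s          # X v0 + Z* v1  (X is all ones)
    out = np.empty_like(v)
    out[0] = float(a.sum())             # X'a
    out[1:] = (Z.T @ a) * s + op.lam * v[1:]
    return out


@dataclass(frozen=True)
class MMESolution:
    """Solution of the mixed-model equations with solver diagnostics."""

    theta_hat: float
    u_hat: np.ndarray
    iterations: int
    rel_residual: float
    converged: bool
    h2_used: Optional[float] = None


class PCGNumericalError(RuntimeError):
    """The operator behaved non-SPD during CG (p'Ap <= 0)."""


def pcg_solve(
    op: MMEOperator,
    b: np.ndarray,
    tol: float = 1e-8,
    max_iter: Optional[int] = None,
    x0: Optional[np.ndarray] = None,
    jacobi: bool = True,
) -> MMESolution:
    """Solve A x = b by Jacobi-preconditioned conjugate gradient.

    Terminates when the relative residual ||b - Ax|| / ||b|| drops below
    ``tol`` (converged) or at ``max_iter`` (best iterate, not converged).
    ``jacobi=False`` disables the preconditioner (M = I), useful for
    measuring how much the diagonal scaling helps.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("right-hand side must be finite")
    if max_iter is None:
        max_iter = 10 * op.dim

    minv = 1.0 / op.diagonal() if jacobi else np.ones(op.dim)
    x = np.zeros(op.dim) if x0 is None else np.asarray(x0, dtype=float).copy()
    r = b - op.matvec(x) if x.any() else b.copy()
    b_norm = float(np.linalg.norm(b))
    if b_norm == 0.0:
        return MMESolution(0.0, np.zeros(op.dim - 1), 0, 0.0, True)

    z = minv * r
    p = z.copy()
    rz = float(r @ z)
    rel = float(np.linalg.norm(r)) / b_norm
    it = 0
    while rel > tol and it < max_iter:
        Ap = op.matvec(p)
        pAp = float(p @ Ap)
        if pAp <= 0.0:
            raise PCGNumericalError(
                f"p'Ap = {pAp} <= 0 at iteration {it}: operator is not SPD"
            )
        alpha = rz / pAp
        x += alpha * p
        it += 1
        if it % _TRUE_RESIDUAL_EVERY == 0:
            r = b - op.matvec(x)        # guard against recurrence drift
        else:
            r -= alpha * Ap
        z = minv * r
        rz_new = float(r @ z)
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
        rel = float(np.linalg.norm(r)) / b_norm

    # final true residual for honest diagnostics
    rel = float(np.linalg.norm(b - op.matvec(x))) / b_norm
    return MMESolution(
        theta_hat=float(x[0]),
        u_hat=x[1:].copy(),
        iterations=it,
        rel_residual=rel,
        converged=bool(rel <= tol),
    )


def fit_rhepcg(
    design: StandardizedDesign,
    components: VarianceComponents,
    tol: float = 1e-8,
    max_iter: Optional[int] = None,
) -> MMESolution:
    """Build the MME from estimated variance components and solve by PCG.

    The ridge is lam = sigma_e2 / sigma_g2 on the Z/sqrt(m) scale, i.e. the
    GBLUP-equivalent shrinkage for G = ZZ'/m.
    """
    h2 = components.h2
    if h2 <= H2_MIN or h2 >= H2_MAX:
        warnings.warn(
            f"h2 = {h2:.4g} sits at the clamp boundary; the variance-component "
            "estimate is uninformative and predictions are heavily shrunk",
            stacklevel=2,
        )
    lam = components.ratio
    op = MMEOperator(design, lam)
    sol = pcg_solve(op, op.rhs(), tol=tol, max_iter=max_iter)
    return MMESolution(
        theta_hat=sol.theta_hat,
        u_hat=sol.u_hat,
        iterations=sol.iterations,
        rel_residual=sol.rel_residual,
        converged=sol.converged,
        h2_used=h2,
    )


def predict_from_solution(
    sol: MMESolution, design_cand: StandardizedDesign
) -> np.ndarray:
    """Predicted genotypic values theta + Z*_cand u for candidates already
    standardized on the training scale (reference standardization)."""
    s = 1.0 / np.sqrt(design_cand.m)
    return sol.theta_hat + (design_cand.Z @ sol.u_hat) * s
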