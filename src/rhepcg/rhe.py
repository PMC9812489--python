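"""Randomized Haseman-Elston regression for heritability, matrix-free.

The moment estimator solves the 2x2 system

    [ tr(G^2)  tr(G) ] [sigma_g2]   [ y'Gy ]
    [ tr(G)      n   ] [sigma_e2] = [ y'y  ]

with G = ZZ'/m the genomic relationship matrix, which is never formed.
Under divisor-n column scaling tr(G) = n exactly.  tr(G^2) is the only
expensive term and is estimated by the Hutchinson randomized trace
estimator with S standard-normal probe vectors (S = 5 by default), at
O(nmS) cost and O(n + m) extra memory.  y'Gy = ||Z'y||^2 / m costs one
O(nm) pass and is computed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StandardizedDesign, VarianceComponents

__all__ = ["HEFit", "estimate_trace_omega2", "rhe_fit"]

#: Heritability clamp bounds: the MME ridge lambda = sigma_e2/sigma_g2 must
#: stay finite and nonzero, so h2 is kept off the boundaries.
H2_MIN, H2_MAX = 1e-3, 1.0 - 1e-3


@dataclass(frozen=True)
class HEFit:
    """Result of one randomized HE regression."""

    components: VarianceComponents
    sigma_y2: float
    trace_omega2_hat: float
    yT_omega_y: float
    S: int
    clamped: bool


def estimate_trace_omega2(
    Z: np.ndarray, S: int, rng: np.random.Generator
) -> float:
    """Hutchinson estimate of tr[(ZZ'/m)^2] from S random probes.

    For each probe w ~ N(0, I_n) the quadratic form w'G^2 w = ||Z(Z'w)||^2/m^2
    is unbiased for tr(G^2); the estimate is the probe average.  Only two
    matrix-vector products per probe; no n x n matrix is ever materialized.
    """
    if S < 1:
        raise ValueError("probe count S must be >= 1")
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    total = 0.0
    for _ in range(S):
        w = rng.standard_normal(n)
        v = Z.T @ w          # m
        u = Z @ v            # n  -> u = ZZ'w
        total += float(u @ u)
    return total / (S * m * m)


def rhe_fit(
    design: StandardizedDesign,
    S: int = 5,
    rng: np.random.Generator | None = None,
) -> HEFit:
    """Estimate variance components by randomized HE regression.

    Solves the two-moment system in closed form with tr(G) = n exact,
    tr(G^2) randomized, and y'Gy computed exactly as ||Z'y||^2/m.
    sigma_g2 is clamped to [0, sigma_y2] and h2 to [1e-3, 1 - 1e-3]
    (negative moment estimates can occur when there is no genetic signal).
    """
    if rng is None:
        rng = np.random.default_rng()
    Z, y = design.Z, design.y
    if y is None:
        raise ValueError("design carries no phenotype vector")
    n, m = Z.shape
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")

    tr_omega = float(n)
    tr_omega2 = estimate_trace_omega2(Z, S, rng)
    Zty = Z.T @ y
    y_omega_y = float(Zty @ Zty) / m
    yty = float(y @ y)
    sigma_y2 = (yty - n * float(y.mean()) ** 2) / (n - 1)

    det = tr_omega2 * n - tr_omega**2
    if abs(det) < 1e-8 * max(1.0, tr_omega2 * n):
        raise ValueError(
            "degenerate relatedness: tr(G^2) ~ tr(G)^2/n, the HE system is singular"
        )
    sigma_g2 = (n * y_omega_y - tr_omega * yty) / det
    sigma_e2 = (tr_omega2 * yty - tr_omega * y_omega_y) / det

    clamped = False
    if sigma_g2 < 0.0:
        sigma_g2, clamped = 0.0, True
    if sigma_g2 > sigma_y2:
        sigma_g2, clamped = sigma_y2, True
    if sigma_e2 < 0.0:
        sigma_e2, clamped = 0.0, True

    tot = sigma_g2 + sigma_e2
    h2 = sigma_g2 / tot if tot > 0 else 0.0
    if h2 < H2_MIN:
        h2, clamped = H2_MIN, True
    elif h2 > H2_MAX:
        h2, clamped = H2_MAX, True
    # keep the reported components consistent with the clamped h2
    if tot <= 0:
        tot = sigma_y2
    sigma_g2_r = h2 * tot
    sigma_e2_r = (1.0 - h2) * tot

    comps = VarianceComponents(
        sigma_g2=sigma_g2_r, sigma_e2=sigma_e2_r, h2=h2, method="RHE"
    )
    return HEFit(
        components=comps,
        sigma_y2=sigma_y2,
        trace_omega2_hat=tr_omega2,
        yT_omega_y=y_omega_y,
        S=S,
        clamped=clamped,
    )
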