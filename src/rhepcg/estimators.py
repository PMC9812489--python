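"""Scikit-learn style estimators for genomic prediction.

:class:`RHEPCGRegressor` — heritability by randomized Haseman-Elston
regression, marker effects by matrix-free preconditioned conjugate
gradient on the SNP-BLUP mixed-model equations; never forms or inverts
the genomic relationship matrix.

:class:`GBLUPRegressor` — the conventional baseline: dense GRM, profile
REML variance components, direct BLUP through the train-candidate
relationship block.

Both take a raw allele-dosage matrix X (individuals x markers) and a
phenotype vector y, standardize internally on the training statistics,
and predict genotypic values on the raw phenotype scale, so they compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import gblup_ref, mme_pcg, rhe
from .core import StandardizedDesign, VarianceComponents, standardize
from .simulate import substream

__all__ = ["RHEPCGRegressor", "GBLUPRegressor"]


class _GenomicRegressorBase(RegressorMixin, BaseEstimator):
    """Shared standardization and prediction plumbing."""

    def _standardize_fit(self, X, y, standardize_phenotype):
        X, y = check_X_y(X, y, dtype=np.float64, y_numeric=True)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training individuals")
        design = standardize(
            X, y, standardize_phenotype=standardize_phenotype
        )
        self.n_features_in_ = X.shape[1]
        return design

    def _candidate_design(self, X) -> StandardizedDesign:
        check_is_fitted(self, "design_")
        X = check_array(X, dtype=np.float64)
        return standardize(X, reference=self.design_)

    def _back_transform(self, pred_std: np.ndarray) -> np.ndarray:
        return self.design_.y_mean + self.design_.y_scale * pred_std


class RHEPCGRegressor(_GenomicRegressorBase):
    """Genomic prediction without inverting the genomic relationship matrix.

    Heritability is estimated by IBS-based randomized Haseman-Elston
    regression (Hutchinson trace probes), then the SNP-BLUP mixed-model
    equations are solved by Jacobi-preconditioned conjugate gradient using
    only matrix-vector products with the standardized design.  Total cost
    is O(nm) per CG iteration and O(n + m) memory beyond the design itself.

    Parameters
    ----------
    n_probes : int, default=5
        Random probes S for the trace estimator tr[(ZZ'/m)^2].
    h2 : float or None, default=None
        Fixed heritability override; when None it is estimated by RHE.
    tol : float, default=1e-8
        Relative-residual convergence tolerance of the CG solve.
    max_iter : int or None, default=None
        CG iteration cap; None means 10 * (m + 1).
    standardize_phenotype : bool, default=True
        Center/scale y before fitting; predictions are always returned on
        the raw phenotype scale.
    random_state : int or None, default=None
        Seed for the trace-probe substream.

    Attributes
    ----------
    h2_ : float
        Heritability used in the mixed-model equations.
    sigma_g2_, sigma_e2_ : float
        Variance components on the G = ZZ'/m scale (standardized-y units).
    u_hat_ : ndarray of shape (m,)
        Marker effects on the Z/sqrt(m) training scale.
    theta_hat_ : float
        Intercept estimate (standardized-y units).
    n_iter_ : int
        CG iterations used.
    converged_ : bool
        Whether the relative residual reached ``tol``.

    Examples
    --------
    >>> from rhepcg.simulate import SimulationConfig, simulate_population
    >>> pop = simulate_population(SimulationConfig(n_train=300, n_cand=50,
    ...                           h2=0.5, n_markers=400, seed=0))
    >>> Xt = pop.genotypes.matrix[pop.train_idx]
    >>> yt = pop.phenotypes[pop.train_idx]
    >>> model = RHEPCGRegressor(random_state=0).fit(Xt, yt)
    >>> ghat = model.predict(pop.genotypes.matrix[pop.cand_idx])
    """

    def __init__(
        self,
        n_probes: int = 5,
        h2: Optional[float] = None,
        tol: float = 1e-8,
        max_iter: Optional[int] = None,
        standardize_phenotype: bool = True,
        random_state: Optional[int] = None,
    ):
        self.n_probes = n_probes
        self.h2 = h2
        self.tol = tol
        self.max_iter = max_iter
        self.standardize_phenotype = standardize_phenotype
        self.random_state = random_state

    def fit(self, X, y):
        design = self._standardize_fit(X, y, self.standardize_phenotype)
        if self.h2 is not None:
            h2 = float(np.clip(self.h2, rhe.H2_MIN, rhe.H2_MAX))
            sy2 = float(np.var(design.y, ddof=1))
            comps = VarianceComponents(
                sigma_g2=h2 * sy2, sigma_e2=(1 - h2) * sy2, h2=h2, method="TRUE"
            )
        else:
            rng = substream(
                0 if self.random_state is None else int(self.random_state),
                "rhe-probes",
            )
            comps = rhe.rhe_fit(design, S=self.n_probes, rng=rng).components
        sol = mme_pcg.fit_rhepcg(
            design, comps, tol=self.tol, max_iter=self.max_iter
        )
        self.design_ = design
        self.h2_ = comps.h2
        self.sigma_g2_ = comps.sigma_g2
        self.sigma_e2_ = comps.sigma_e2
        self.u_hat_ = sol.u_hat
        self.theta_hat_ = sol.theta_hat
        self.n_iter_ = sol.iterations
        self.converged_ = sol.converged
        return self

    def predict(self, X):
        design_c = self._candidate_design(X)
        sol = mme_pcg.MMESolution(
            theta_hat=self.theta_hat_,
            u_hat=self.u_hat_,
            iterations=self.n_iter_,
            rel_residual=0.0,
            converged=self.converged_,
        )
        return self._back_transform(mme_pcg.predict_from_solution(sol, design_c))


class GBLUPRegressor(_GenomicRegressorBase):
    """Conventional GBLUP: profile REML on the dense GRM, then direct BLUP.

    Pays the O(n^3) eigendecomposition of G = ZZ'/m once per fit; serves
    as the exact reference for :class:`RHEPCGRegressor`, whose predictions
    coincide with GBLUP's when both use the same variance ratio.

    Parameters
    ----------
    h2 : float or None, default=None
        Fixed heritability override; when None it is estimated by REML.
    standardize_phenotype : bool, default=True
        Center/scale y before fitting.

    Attributes
    ----------
    h2_, sigma_g2_, sigma_e2_ : float
        REML (or fixed) variance components.
    loglik_ : float or None
        Restricted log-likelihood at the optimum (None when h2 is fixed).
    boundary_ : bool
        REML optimum hit the h2 search boundary.
    """

    def __init__(
        self,
        h2: Optional[float] = None,
        standardize_phenotype: bool = True,
    ):
        self.h2 = h2
        self.standardize_phenotype = standardize_phenotype

    def fit(self, X, y):
        design = self._standardize_fit(X, y, self.standardize_phenotype)
        grm = gblup_ref.build_grm(design)
        if self.h2 is not None:
            h2 = float(np.clip(self.h2, 1e-4, 1 - 1e-4))
            sy2 = float(np.var(design.y, ddof=1))
            comps = VarianceComponents(
                sigma_g2=h2 * sy2, sigma_e2=(1 - h2) * sy2, h2=h2, method="TRUE"
            )
            self.loglik_ = None
            self.boundary_ = False
        else:
            fit = gblup_ref.reml_fit(grm, design.y)
            comps = fit.components
            self.loglik_ = fit.loglik
            self.boundary_ = fit.boundary
        self.design_ = design
        self.grm_ = grm
        self.h2_ = comps.h2
        self.sigma_g2_ = comps.sigma_g2
        self.sigma_e2_ = comps.sigma_e2
        self.components_ = comps
        return self

    def predict(self, X):
        design_c = self._candidate_design(X)
        res = gblup_ref.gblup_predict(
            self.grm_, self.components_, self.design_.y, design_c, self.design_
        )
        return self._back_transform(res.predicted)
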