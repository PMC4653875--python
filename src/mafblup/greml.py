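"""Restricted maximum likelihood for GBLUP models, and breeding-value prediction.

The model is y = 1 mu + sum_c u_c + e with u_c ~ N(0, G_c sigma_c^2) and
e ~ N(0, I sigma_e^2); one genomic component gives the single-GRM model, two
(low-/high-MAF partition) give the two-component model.  Heritability is the
genomic share of the variance components:

    h1^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2)
    h2^2 = (sigma_uL^2 + sigma_uH^2) / (sigma_uL^2 + sigma_uH^2 + sigma_e^2)

Estimation is average-information (AI) REML with EM-REML fallback steps:
an AI proposal that would lower the restricted likelihood is step-halved and,
failing that, replaced by the (monotone) EM update, so the likelihood path is
non-decreasing.  Components are bounded below at a small fraction of Var(y);
a fit pinned at that boundary, or sitting on a flat ridge (singular AI
matrix), is flagged as degenerate.

The restricted log-likelihood uses the Harville form with all constants,

    l_R = -1/2 [ (n-p) ln 2pi - ln|X'X| + ln|V| + ln|X'V^-1 X| + y'Py ],

which equals the exact log-density of any orthonormal set of error contrasts,
so AIC = 2v - 2 l_R is comparable across models fitted to the same data.

Organisation follows the Model/Results convention: :class:`GREML` holds the
data and likelihood machinery, :meth:`GREML.fit` returns a
:class:`GREMLResults` carrying estimates, diagnostics, ``summary()`` and
``predict()``; ``reml_fit`` / ``profile_loglik`` / ``aic`` / ``predict_gebv``
are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "GREML",
    "GREMLResults",
    "GebvResult",
    "DegenerateFitWarning",
    "reml_fit",
    "profile_loglik",
    "aic",
    "predict_gebv",
    "gblup_predict",
]

_LN2PI = np.log(2.0 * np.pi)


class DegenerateFitWarning(UserWarning):
    """A variance component hit its boundary or the likelihood is flat."""


def _as_matrix(g) -> np.ndarray:
    return np.asarray(getattr(g, "matrix", g), dtype=float)


class GREML:
    """Variance-component model for a phenotype vector and one or two GRMs.

    Parameters
    ----------
    y : (n,) phenotypes (one record per animal; fixed effects are the mean)
    grms : Grm/array or sequence of them (1 = single, 2 = MAF-partitioned)
    """

    def __init__(self, y, grms, animal_ids=None):
        self.y = np.asarray(y, dtype=float).ravel()
        if not isinstance(grms, (list, tuple)):
            grms = [grms]
        self.grm_objects = list(grms)
        self.grms = [_as_matrix(g) for g in grms]
        self.n = self.y.size
        if not 1 <= len(self.grms) <= 2:
            raise ValueError("provide one or two genomic relationship matrices")
        for G in self.grms:
            if G.shape != (self.n, self.n):
                raise ValueError(f"GRM shape {G.shape} does not match n={self.n}")
        if np.var(self.y) <= 0:
            raise ValueError("phenotype variance must be positive")
        self.animal_ids = list(animal_ids) if animal_ids is not None else None
        self.n_components = len(self.grms)
        self.model = "single" if self.n_components == 1 else "two_component"

    # -- restricted likelihood --------------------------------------------
    def loglik(self, variances) -> float:
        """Exact restricted log-likelihood at (sigma_1^2[, sigma_2^2], sigma_e^2)."""
        theta = np.asarray(variances, dtype=float).ravel()
        if theta.size != self.n_components + 1:
            raise ValueError(
                f"expected {self.n_components + 1} variances, got {theta.size}"
            )
        if np.any(theta < 0) or not np.any(theta > 0):
            raise ValueError("variances must be >= 0 and not all zero")
        ll, *_ = self._likelihood_parts(theta)
        return ll

    def _likelihood_parts(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, G in zip(theta[:-1], self.grms):
            V += t * G
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except (LinAlgError, np.linalg.LinAlgError) as e:
            raise LinAlgError(f"total covariance matrix is singular: {e}") from None
        logdetV = 2.0 * float(np.log(np.diag(cf[0])).sum())
        ones = np.ones(n)
        Vi1 = cho_solve(cf, ones, check_finite=False)
        s = float(ones @ Vi1)  # 1'V^-1 1
        Viy = cho_solve(cf, self.y, check_finite=False)
        mu = float(ones @ Viy) / s
        Py = Viy - Vi1 * mu
        yPy = float(self.y @ Py)
        ll = -0.5 * ((n - 1) * _LN2PI - np.log(n) + logdetV + np.log(s) + yPy)
        return ll, cf, Vi1, s, Py, mu

    def _derivatives(self, theta):
        """Score vector and average-information matrix at theta."""
        ll, cf, Vi1, s, Py, mu = self._likelihood_parts(theta)
        n = self.n
        Vi = cho_solve(cf, np.eye(n), check_finite=False)
        P = Vi - np.outer(Vi1, Vi1) / s
        Gs = self.grms + [np.eye(n)]
        k = len(Gs)
        score = np.empty(k)
        trPG = np.empty(k)
        t_vecs = []
        for c, G in enumerate(Gs):
            trPG[c] = float(np.sum(P * G))
            t = G @ Py
            t_vecs.append(t)
            score[c] = -0.5 * (trPG[c] - float(Py @ t))
        AI = np.empty((k, k))
        Pt = [P @ t for t in t_vecs]
        for c in range(k):
            for d in range(c, k):
                AI[c, d] = AI[d, c] = 0.5 * float(t_vecs[c] @ Pt[d])
        return ll, score, AI, trPG, Py, t_vecs, mu

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start=None,
        maxiter: int = 100,
        tol_loglik: float = 1e-6,
        tol_param: float = 1e-8,
        floor_frac: float = 1e-8,
    ) -> "GREMLResults":
        """Maximize the restricted likelihood by safeguarded AI-REML."""
        if self.n < 30:
            raise ValueError(f"REML needs at least 30 animals, got {self.n}")
        vy = float(np.var(self.y))
        k = self.n_components + 1
        theta = (
            np.asarray(start, dtype=float).copy()
            if start is not None
            else np.full(k, vy / k)
        )
        if theta.shape != (k,) or np.any(theta <= 0):
            raise ValueError("start must give a positive value per variance component")
        floor = floor_frac * vy
        scale = vy

        ll_path = []
        converged = False
        flat_ridge = False
        n_iter = 0
        ll = -np.inf
        for it in range(1, maxiter + 1):
            n_iter = it
            ll, score, AI, trPG, Py, t_vecs, mu = self._derivatives(theta)
            ll_path.append(ll)

            em_theta = np.maximum(
                theta + theta**2 * np.array(
                    [float(Py @ t) - tr for t, tr in zip(t_vecs, trPG)]
                ) / self.n,
                floor,
            )
            if it == 1:
                proposal = em_theta
            else:
                cond = np.linalg.cond(AI)
                if not np.isfinite(cond) or cond > 1e10:
                    flat_ridge = True
                    delta = np.linalg.lstsq(AI, score, rcond=None)[0]
                else:
                    delta = np.linalg.solve(AI, score)
                proposal = np.maximum(theta + delta, floor)
                ll_prop = self._safe_loglik(proposal)
                halvings = 0
                while ll_prop < ll - 1e-10 and halvings < 8:
                    delta *= 0.5
                    proposal = np.maximum(theta + delta, floor)
                    ll_prop = self._safe_loglik(proposal)
                    halvings += 1
                if ll_prop < ll - 1e-10:
                    proposal = em_theta
            ll_new = self._safe_loglik(proposal)
            if ll_new < ll - 1e-10:  # even EM cannot improve: flat optimum
                proposal = theta
                ll_new = ll
            d_theta = float(np.max(np.abs(proposal - theta)))
            theta = proposal
            if it > 1 and (abs(ll_new - ll) < tol_loglik or d_theta < tol_param * scale):
                converged = True
                ll = ll_new
                break
            ll = ll_new
        ll_path.append(ll)

        at_boundary = bool(np.any(theta <= floor * (1 + 1e-9)))
        degenerate = at_boundary or flat_ridge
        if degenerate:
            reason = "boundary variance component" if at_boundary else "flat likelihood ridge"
            warnings.warn(
                f"degenerate REML fit ({reason}); heritability may be unidentified",
                DegenerateFitWarning,
                stacklevel=2,
            )
        if not converged:
            warnings.warn(
                f"REML did not converge in {maxiter} iterations", UserWarning, stacklevel=2
            )
        _, _, _, _, _, mu = self._likelihood_parts(theta)
        return GREMLResults(
            model_obj=self,
            params=theta,
            mu=mu,
            loglik=float(ll),
            converged=converged,
            degenerate=degenerate,
            n_iter=n_iter,
            loglik_path=np.asarray(ll_path),
        )

    def _safe_loglik(self, theta) -> float:
        try:
            return self._likelihood_parts(theta)[0]
        except LinAlgError:
            return -np.inf


@dataclass
class GebvResult:
    """Predicted breeding values with their model provenance."""

    animal_ids: list
    gebv: np.ndarray
    model: str
    grm_kind: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"animal_id": self.animal_ids, "gebv": self.gebv})


class GREMLResults:
    """REML estimates, restricted likelihood, AIC, heritability, prediction."""

    def __init__(self, model_obj, params, mu, loglik, converged, degenerate, n_iter, loglik_path):
        self.model_obj = model_obj
        self.params = np.asarray(params, dtype=float)
        self.mu = float(mu)
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.degenerate = bool(degenerate)
        self.n_iter = int(n_iter)
        self.loglik_path = loglik_path
        self.model = model_obj.model
        if self.model == "single":
            self.component_names = ["sigma_u2", "sigma_e2"]
        else:
            self.component_names = ["sigma_uL2", "sigma_uH2", "sigma_e2"]

    # -- derived quantities -------------------------------------------------
    @property
    def sigma_e2(self) -> float:
        return float(self.params[-1])

    @property
    def genomic_variance(self) -> float:
        return float(self.params[:-1].sum())

    @property
    def h2(self) -> float:
        tot = self.genomic_variance + self.sigma_e2
        return float(self.genomic_variance / tot) if tot > 0 else np.nan

    @property
    def v(self) -> int:
        """Number of variance components (2 for single, 3 for two-component)."""
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.v - 2.0 * self.loglik

    def varcomp(self) -> dict:
        return dict(zip(self.component_names, self.params))

    # -- prediction ----------------------------------------------------------
    def predict(self, grms_full, ref_indices, test_indices, y_ref=None) -> GebvResult:
        """BLUP of breeding values for test animals from reference phenotypes.

        ``grms_full`` are GRM(s) over the full sample (reference + test), of
        the same kind(s) the model was fitted with; ``ref_indices`` /
        ``test_indices`` index rows of those matrices.
        """
        y_ref = self.model_obj.y if y_ref is None else np.asarray(y_ref, dtype=float)
        res = gblup_predict(
            y_ref,
            grms_full,
            ref_indices,
            test_indices,
            self.params[:-1],
            self.sigma_e2,
            mu=self.mu,
        )
        kinds = [getattr(g, "kind", "matrix") for g in
                 (grms_full if isinstance(grms_full, (list, tuple)) else [grms_full])]
        return GebvResult(
            animal_ids=res.animal_ids, gebv=res.gebv, model=self.model,
            grm_kind="+".join(kinds),
        )

    def summary(self) -> str:
        lines = [
            "GREML fit" + ("" if self.converged else " (NOT CONVERGED)"),
            f"  model:        {self.model} ({self.v} variance components)",
            f"  n animals:    {self.model_obj.n}",
        ]
        for name, value in self.varcomp().items():
            lines.append(f"  {name:<12}  {value:12.4f}")
        lines += [
            f"  mu            {self.mu:12.4f}",
            f"  h2            {self.h2:12.4f}",
            f"  logLik        {self.loglik:12.4f}",
            f"  AIC           {self.aic:12.4f}",
            f"  iterations    {self.n_iter:6d}",
        ]
        if self.degenerate:
            lines.append("  warning: degenerate fit (boundary or flat ridge)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def reml_fit(y, grms, animal_ids=None, **options) -> GREMLResults:
    """Fit the single- or two-component GBLUP model by AI-REML."""
    return GREML(y, grms, animal_ids=animal_ids).fit(**options)


def profile_loglik(y, grms, components) -> float:
    """Exact restricted log-likelihood at the given variance components."""
    return GREML(y, grms).loglik(components)


def aic(fit: GREMLResults) -> float:
    """Akaike information criterion, 2v - 2 lnL, v = number of variance components."""
    return fit.aic


def gblup_predict(
    y_ref,
    grms_full,
    ref_indices,
    test_indices,
    var_components,
    sigma_e2: float,
    mu: float | None = None,
    animal_ids=None,
) -> GebvResult:
    """Conditional-expectation BLUP with fixed variance components.

    u_hat(test) = sum_c sigma_c^2 G_c[test, ref] V^-1 (y_ref - mu), with
    V = sum_c sigma_c^2 G_c[ref, ref] + sigma_e^2 I.
    """
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if not isinstance(grms_full, (list, tuple)):
        grms_full = [grms_full]
    mats = [_as_matrix(g) for g in grms_full]
    var_components = np.atleast_1d(np.asarray(var_components, dtype=float))
    if len(var_components) != len(mats):
        raise ValueError("one variance component per GRM required")
    ref = np.asarray(ref_indices, dtype=int)
    test = np.asarray(test_indices, dtype=int)
    if np.intersect1d(ref, test).size:
        raise ValueError("reference and test indices must be disjoint")
    if y_ref.size != ref.size:
        raise ValueError("y_ref length must match reference indices")
    n_ref = ref.size
    V = sigma_e2 * np.eye(n_ref)
    for s2, G in zip(var_components, mats):
        V += s2 * G[np.ix_(ref, ref)]
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except (LinAlgError, np.linalg.LinAlgError) as e:
        raise LinAlgError(f"singular reference covariance: {e}") from None
    ones = np.ones(n_ref)
    if mu is None:
        Vi1 = cho_solve(cf, ones, check_finite=False)
        mu = float(ones @ cho_solve(cf, y_ref, check_finite=False)) / float(ones @ Vi1)
    alpha = cho_solve(cf, y_ref - mu, check_finite=False)
    gebv = np.zeros(test.size)
    for s2, G in zip(var_components, mats):
        gebv += s2 * (G[np.ix_(test, ref)] @ alpha)
    ids = (
        [animal_ids[i] for i in test]
        if animal_ids is not None
        else [int(i) for i in test]
    )
    model = "single" if len(mats) == 1 else "two_component"
    kinds = "+".join(getattr(g, "kind", "matrix") for g in grms_full)
    return GebvResult(animal_ids=ids, gebv=gebv, model=model, grm_kind=kinds)


def predict_gebv(fit: GREMLResults, y_ref, grms_full, ref_indices, test_indices) -> GebvResult:
    """GEBV for masked test animals given a reference-population fit."""
    return fit.predict(grms_full, ref_indices, test_indices, y_ref=y_ref)
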