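"""Genomic relationship matrix and single-component REML heritability.

The GRM uses the allele-frequency-standardized cross-product
``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with ``Z`` the per-marker
mean-centered dosage matrix (missing dosages mean-imputed per marker,
monomorphic markers excluded). Narrow-sense heritability is then estimated
under ``y ~ N(X b, sigma2_g G + sigma2_e I)`` by restricted maximum
likelihood with average-information (AI) updates and an
expectation-maximization fallback whenever an AI step leaves the parameter
space or decreases the restricted likelihood.

Numerically the solver works in the eigenbasis of the GRM: one symmetric
eigendecomposition turns every V-solve into diagonal arithmetic, so
iterations are cheap even at a few thousand individuals. Components are
clamped at 1e-8; convergence is |delta logL| < 1e-6 (at most 200
iterations). The standard error of h2 comes from the inverse AI matrix via
the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

COMPONENT_FLOOR = 1e-8

#: effects selected for the association model that must stay out of the REML
#: fixed design: the GRM already models family structure, and fitting sire as
#: a fixed effect would absorb the between-family genetic variance and bias
#: h2 downward.
REML_EXCLUDED_EFFECTS = ("sire",)


@dataclass
class GRM:
    ids: np.ndarray
    matrix: np.ndarray
    m: int  # markers used


@dataclass
class HeritabilityEstimate:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se: float
    converged: bool
    n_iterations: int
    loglik: float


def build_grm(geno: GenotypeMatrix, chunk: int = 4096) -> GRM:
    """Allele-frequency-standardized GRM from post-QC dosages."""
    n, m = geno.dosage.shape
    G = np.zeros((n, n))
    denom = 0.0
    used = 0
    for start in range(0, m, chunk):
        D = np.asarray(geno.dosage[:, start : start + chunk], dtype=float)
        col_mean = np.nanmean(D, axis=0)
        isnan = np.isnan(D)
        if isnan.any():
            D = np.where(isnan, col_mean, D)
        p = col_mean / 2.0
        poly = (p > 0) & (p < 1)
        if not poly.all():
            D = D[:, poly]
            p = p[poly]
        Z = D - 2.0 * p
        G += Z @ Z.T
        denom += float(2.0 * np.sum(p * (1.0 - p)))
        used += int(poly.sum())
    if used == 0:
        raise ValueError("no polymorphic markers for GRM")
    if used < m:
        logger.info("GRM: excluded %d monomorphic markers", m - used)
    G /= denom
    return GRM(ids=geno.ids.copy(), matrix=G, m=used)


def _trace_P(a, vinv, XtVX_inv, Xr):
    """tr(P diag(a)) with P the REML projection matrix, in the eigenbasis."""
    t1 = float(np.sum(vinv * a))
    W = Xr * (vinv * a * vinv)[:, None]
    t2 = float(np.trace(XtVX_inv @ (Xr.T @ W)))
    return t1 - t2


def reml_h2(
    y,
    X,
    grm: GRM,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HeritabilityEstimate:
    """AI-REML estimate of (sigma2_g, sigma2_e) and h2 for one trait.

    ``y`` and the fixed-effect design ``X`` (with intercept) must be aligned
    with ``grm.ids``; rows with missing values should be removed (and the
    GRM subset) beforehand. Non-convergence returns the last estimate with
    ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if grm.matrix.shape[0] != n:
        raise ValueError("GRM not aligned with phenotype vector")
    lam, U = np.linalg.eigh(grm.matrix)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X
    k = X.shape[1]

    # start from an even split of the OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = float(np.var(y - X @ beta0, ddof=k))
    theta = np.array([resid_var / 2.0, resid_var / 2.0])  # (sigma2_g, sigma2_e)

    def restricted_loglik(th):
        v = th[0] * lam + th[1]
        if np.any(v <= 0):
            return -np.inf, None
        vinv = 1.0 / v
        XtVX = Xr.T @ (Xr * vinv[:, None])
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf, None
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ (Xr.T @ (yr * vinv))
        r = yr - Xr @ beta
        Py = r * vinv
        ypy = float(r @ Py)
        ll = -0.5 * (float(np.sum(np.log(v))) + logdet_xvx + ypy)
        return ll, (v, vinv, XtVX_inv, Py)

    ll, aux = restricted_loglik(theta)
    n_iter = 0
    converged = False
    ai = np.eye(2)
    for n_iter in range(1, max_iter + 1):
        v, vinv, XtVX_inv, Py = aux
        a_g, a_e = lam, np.ones(n)
        # scores
        yPAPy_g = float(np.sum(Py * Py * a_g))
        yPAPy_e = float(np.sum(Py * Py * a_e))
        tr_g = _trace_P(a_g, vinv, XtVX_inv, Xr)
        tr_e = _trace_P(a_e, vinv, XtVX_inv, Xr)
        score = 0.5 * np.array([yPAPy_g - tr_g, yPAPy_e - tr_e])

        # average information
        def apply_P(vec):
            tmp = vec * vinv
            return tmp - (Xr * vinv[:, None]) @ (XtVX_inv @ (Xr.T @ tmp))

        u_g = a_g * Py
        u_e = a_e * Py
        Pu_g = apply_P(u_g)
        Pu_e = apply_P(u_e)
        ai = 0.5 * np.array(
            [
                [float(u_g @ Pu_g), float(u_g @ Pu_e)],
                [float(u_e @ Pu_g), float(u_e @ Pu_e)],
            ]
        )
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(ai) @ score
        proposal = theta + delta
        new_ll, new_aux = (-np.inf, None)
        if np.all(proposal > 0):
            new_ll, new_aux = restricted_loglik(proposal)
        if new_ll < ll - 1e-10:
            # EM fallback: guaranteed-ascent update
            em = theta + theta**2 / n * np.array(
                [yPAPy_g - tr_g, yPAPy_e - tr_e]
            )
            proposal = np.maximum(em, COMPONENT_FLOOR)
            new_ll, new_aux = restricted_loglik(proposal)
            if new_ll < ll - 1e-10 or new_aux is None:
                break  # cannot improve
        proposal = np.maximum(proposal, COMPONENT_FLOOR)
        change = abs(new_ll - ll)
        theta, ll, aux = proposal, new_ll, new_aux
        if change < tol:
            converged = True
            break

    sigma2_g, sigma2_e = float(theta[0]), float(theta[1])
    total = sigma2_g + sigma2_e
    h2 = sigma2_g / total if total > 0 else np.nan
    try:
        cov = np.linalg.pinv(ai)
        grad = np.array([sigma2_e, -sigma2_g]) / total**2
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.nan
    logger.info(
        "REML: h2=%.3f (sg2=%.4g, se2=%.4g) %s in %d iterations",
        h2, sigma2_g, sigma2_e,
        "converged" if converged else "NOT converged", n_iter,
    )
    return HeritabilityEstimate(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2=h2,
        se=se,
        converged=converged,
        n_iterations=n_iter,
        loglik=float(ll),
    )
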