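"""Maximum-likelihood variance components under y ~ N(0, Gσg² + Iσe²).

Rotating phenotypes by the eigenvectors of G diagonalizes the covariance:
with ``ỹ = U'y`` the log-likelihood is a sum of n independent normal terms
with variances ``λ_i σg² + σe²``.  One eigendecomposition therefore prices
likelihood evaluations at O(n) each, and the two-component MLE reduces to a
1-D search: parameterize by heritability h² = σg²/(σg²+σe²), profile out
the total variance in closed form, and Brent-optimize h² on (0, 1).

Phenotypes are mean-centered before fitting; there is no fixed-effect
design in the likelihood.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.optimize

from .geno_io import GenotypeMatrix, PhenotypeVector
from .grm import GRM, EigenGRM, drop_markers_grm, eigen_grm

__all__ = ["VarComp", "loglik", "fit_ml", "refit_with_marker_removed"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class VarComp:
    """Genomic and residual variance components with fit diagnostics.

    ``lambda_ratio`` is the variance ratio σe²/σg² used by the mixed-model
    equations; ``boundary`` flags an optimum pinned at h² ≈ 0 or 1.
    """

    sigma_g2: float
    sigma_e2: float
    h2: float
    lambda_ratio: float
    loglik: float = np.nan
    se_g2: float | None = None
    se_e2: float | None = None
    converged: bool = True
    boundary: bool = False
    n_iter: int = 0

    @classmethod
    def from_components(cls, sigma_g2: float, sigma_e2: float, **kw) -> "VarComp":
        if sigma_g2 < 0 or sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        tot = sigma_g2 + sigma_e2
        if tot <= 0:
            raise ValueError("sigma_g2 + sigma_e2 must be positive")
        h2 = sigma_g2 / tot
        ratio = sigma_e2 / sigma_g2 if sigma_g2 > 0 else np.inf
        return cls(sigma_g2, sigma_e2, h2, ratio, **kw)

    @classmethod
    def from_h2(cls, h2: float, total_var: float = 1.0, **kw) -> "VarComp":
        if not 0 <= h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        return cls.from_components(h2 * total_var, (1.0 - h2) * total_var, **kw)


def _spectral_terms(
    e: EigenGRM, y: PhenotypeVector | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotated phenotypes and eigenvalues, with the mean direction deflated.

    Phenotypes are mean-centered, so the data carry no information along
    the constant vector.  When G is built from column-centered markers the
    constant vector is a null eigenvector of G (G·1 = 0) and the rotated
    datum in that direction is identically zero; keeping its likelihood
    term would let σe² → 0 drive the log-likelihood to +∞ (a spurious
    boundary supremum at h² = 1).  Components with both a (numerically)
    zero eigenvalue and zero rotated datum are therefore excluded — the
    likelihood of centered data on the orthogonal complement of the mean,
    the same treatment as profiling out a fixed intercept.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    yv = yv - yv.mean()
    ytil = e.U.T @ yv
    lam_tol = 1e-9 * max(float(e.lam[0]), 1e-300)
    y_tol = 1e-9 * max(float(np.abs(ytil).max(initial=0.0)), 1e-300)
    degenerate = (e.lam <= lam_tol) & (np.abs(ytil) <= y_tol)
    keep = ~degenerate
    return ytil[keep], e.lam[keep]


def loglik(e: EigenGRM, y: PhenotypeVector | np.ndarray, vc: VarComp) -> float:
    """Gaussian log-likelihood via the spectral rotation.

    Equals the dense N(0, Gσg² + Iσe²) log-density of the mean-centered
    phenotypes whenever V is positive definite with no degenerate mean
    direction; costs O(n) after the decomposition.  For GRMs built from
    centered markers the constant null direction is excluded (see
    ``_spectral_terms``).
    """
    ytil, lam = _spectral_terms(e, y)
    w = lam * vc.sigma_g2 + vc.sigma_e2
    if np.any(w <= 0):
        raise ValueError("non-positive eigen-variance lambda_i*sigma_g2 + sigma_e2")
    return float(-0.5 * (np.log(w).sum() + (ytil**2 / w).sum() + ytil.size * _LOG2PI))


def _profile_nll(h2: float, lam: np.ndarray, ytil2: np.ndarray) -> float:
    # total-variance MLE is closed-form given h2; returns -2/2*loglik up to sign
    w = h2 * lam + (1.0 - h2)
    s2 = float(np.mean(ytil2 / w))
    n = lam.size
    return 0.5 * (n * np.log(s2) + np.log(w).sum() + n + n * _LOG2PI)


def fit_ml(
    e: EigenGRM,
    y: PhenotypeVector | np.ndarray,
    h2_tol: float = 1e-8,
    se: bool = True,
) -> VarComp:
    """Two-component ML fit by bounded 1-D profile search over h².

    Given h², V = σ²·(h²Λ + (1−h²)I) in the rotated basis and the total
    variance MLE is ``σ̂² = (1/n)Σ ỹ_i²/w_i`` with ``w_i = h²λ_i + 1 − h²``.
    The profile is optimized by Brent search on [1e−6, 1−1e−6]; boundary
    optima are returned (flagged) rather than erroring.  Standard errors
    come from the observed information: a central finite-difference Hessian
    of the (σg², σe²) log-likelihood.
    """
    if e.n < 3:
        raise ValueError("need at least 3 observations to fit two components")
    if np.ptp(e.lam) < 1e-12 * max(abs(e.lam[0]), 1.0):
        raise ValueError(
            "all eigenvalues equal (G proportional to I): h2 is unidentifiable"
        )
    ytil, lam = _spectral_terms(e, y)
    ytil2 = ytil**2
    if ytil2.sum() <= 0:
        raise ValueError("phenotype has zero variance")
    lo, hi = 1e-6, 1.0 - 1e-6
    res = scipy.optimize.minimize_scalar(
        _profile_nll,
        bounds=(lo, hi),
        args=(lam, ytil2),
        method="bounded",
        options={"xatol": h2_tol},
    )
    # the bounded search can stall short of a boundary optimum; compare ends
    candidates = [(float(res.x), float(res.fun))]
    for h2c in (lo, hi):
        candidates.append((h2c, _profile_nll(h2c, lam, ytil2)))
    h2_hat, _ = min(candidates, key=lambda t: t[1])
    w = h2_hat * lam + (1.0 - h2_hat)
    s2 = float(np.mean(ytil2 / w))
    sigma_g2 = h2_hat * s2
    sigma_e2 = (1.0 - h2_hat) * s2
    boundary = h2_hat <= lo + 1e-9 or h2_hat >= hi - 1e-9
    vc = VarComp.from_components(
        sigma_g2,
        sigma_e2,
        converged=bool(res.success),
        boundary=boundary,
        n_iter=int(getattr(res, "nit", 0) or getattr(res, "nfev", 0)),
    )
    vc.loglik = loglik(e, y, vc)
    if se and not boundary:
        vc.se_g2, vc.se_e2 = _observed_info_se(lam, ytil2, sigma_g2, sigma_e2)
    return vc


def _observed_info_se(
    lam: np.ndarray, ytil2: np.ndarray, sigma_g2: float, sigma_e2: float
) -> tuple[float | None, float | None]:
    def ll(theta: np.ndarray) -> float:
        w = lam * theta[0] + theta[1]
        if np.any(w <= 0):
            return -np.inf
        return float(-0.5 * (np.log(w).sum() + (ytil2 / w).sum()))

    theta = np.array([sigma_g2, sigma_e2])
    h = 1e-4 * np.maximum(np.abs(theta), 1e-8)
    H = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            ea = np.eye(2)[a] * h[a]
            eb = np.eye(2)[b] * h[b]
            H[a, b] = (
                ll(theta + ea + eb) - ll(theta + ea - eb)
                - ll(theta - ea + eb) + ll(theta - ea - eb)
            ) / (4.0 * h[a] * h[b])
    info = -H
    try:
        cov = scipy.linalg.inv(info)
    except scipy.linalg.LinAlgError:
        return None, None
    d = np.diag(cov)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None, None
    return float(np.sqrt(d[0])), float(np.sqrt(d[1]))


def refit_with_marker_removed(
    grm: GRM,
    g: GenotypeMatrix,
    y: PhenotypeVector | np.ndarray,
    j: int,
    base: VarComp | None = None,
) -> tuple[VarComp, float]:
    """Re-estimate variance components with marker j excluded from G.

    Builds ``G[-j]`` by the exact per-marker subtraction, re-decomposes,
    and refits.  Returns the marker-out fit and ``|σ̂g² − σ̂g²[-j]|``
    relative to ``base`` (fitted on the full G when not supplied) — the
    quantity that measures how safe the constant-variance-components
    assumption behind the marker-out invariance is for this marker.
    """
    e_full = eigen_grm(grm)
    if base is None:
        base = fit_ml(e_full, y, se=False)
    grm_mj = drop_markers_grm(grm, g, [j])
    vc_mj = fit_ml(eigen_grm(grm_mj), y, se=False)
    return vc_mj, abs(base.sigma_g2 - vc_mj.sigma_g2)
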