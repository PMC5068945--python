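"""Single- and multi-marker association scans with a genomic relationship
matrix in the covariance structure.

The scan estimators:

* OLS single-marker regression (SMR): ``β̂_j = x_j'y / x_j'x_j`` with a
  Student-t test on n−1 residual degrees of freedom.
* GLS SMR: ``β̂_j = x_j'V⁻¹y / x_j'V⁻¹x_j`` with ``V = Gσg² + Iσe²``; one
  factorization of V is reused across all p markers.  The naive variance
  ``(x_j'V⁻¹x_j)⁻¹`` treats marker j as random inside G; when the marker is
  instead treated as fixed *and removed* from G, the corrected variance is
  ``(x_j'V⁻¹x_j)⁻¹ − σg²·scale_c``.  Both are reported.
* Mixed-model equations (Henderson): joint solve for fixed regressions and
  GBLUP of genomic values; algebraically identical to GLS + the direct
  ("strong-arm") BLUP ``ĝ = σg² G V⁻¹ (y − Xβ̂)``.
* m-marker GLS multiple regression with the fixed-and-removed covariance
  correction ``(X'V⁻¹X)⁻¹ − I·σg²·scale_c``.
* PC-adjusted scans: leading eigenvectors of G enter as fixed covariates,
  with G either left intact or depleted of those eigenvectors.

A key identity holds throughout: GLS estimates and BLUPs are invariant to
whether the tested marker's own contribution is removed from G (the
covariance edit cancels exactly), whereas removing *eigenvectors* from G
does change the estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .geno_io import GenotypeMatrix, PhenotypeVector, allele_freq
from .grm import GRM, EigenGRM
from .downdate import PhenoCov, rank1_downdate_inv, lowrank_downdate_inv
from .varcomp import VarComp

__all__ = [
    "ScanTable",
    "BlupResult",
    "MmrResult",
    "MmeResult",
    "smv",
    "ols_scan",
    "gls_scan",
    "markerout_variance",
    "mmr_gls",
    "mme_solve",
    "blup_strongarm",
    "pc_adjusted_scan",
    "whiten_gls",
]

SCAN_COLUMNS = [
    "marker_id", "beta", "se", "stat", "p_value", "r2", "smv", "significant",
]


@dataclasses.dataclass
class ScanTable:
    """Per-marker scan results.

    ``table`` has one row per marker with columns ``marker_id, beta, se,
    stat, p_value, r2, smv, significant`` (GLS scans add ``se_markerout``,
    the fixed-and-removed corrected standard error).  Monomorphic markers
    carry NaN estimates, are never significant, and do not count toward the
    Bonferroni denominator ``n_tested``.
    """

    table: pd.DataFrame
    method: str
    alpha: float
    n_tested: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / max(self.n_tested, 1)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


@dataclasses.dataclass
class BlupResult:
    """GBLUP of marker-captured additive genomic values and the residual
    (phenotype minus fixed fit) it was computed from."""

    g_hat: np.ndarray
    residual: np.ndarray


@dataclasses.dataclass
class MmrResult:
    """Joint m-marker GLS regression."""

    beta: np.ndarray
    cov_naive: np.ndarray        # (X'V⁻¹X)⁻¹
    cov_corrected: np.ndarray    # (X'V⁻¹X)⁻¹ − I·c_sigma
    se: np.ndarray
    stat: np.ndarray
    p_value: np.ndarray
    r2: float


@dataclasses.dataclass
class MmeResult:
    """Henderson mixed-model-equation solve."""

    beta: np.ndarray
    blup: BlupResult
    c_beta_beta: np.ndarray      # fixed-block of the inverted coefficient matrix
    z: np.ndarray | None         # β̂ / (σe √cββ) when σe² supplied


def smv(q: float, beta: float, inbred: bool = False) -> float:
    """Single-marker variance ``2q(1−q)β²`` (``q(1−q)β²`` for inbreds).

    A linkage-equilibrium, single-locus assessment of the variance a marker
    contributes; crude, but the standard SMR summary.
    """
    factor = 1.0 if inbred else 2.0
    return factor * q * (1.0 - q) * beta * beta


def _freqs(g: GenotypeMatrix) -> np.ndarray:
    return np.array([allele_freq(g, j) for j in range(g.p)])


def _smv_column(g: GenotypeMatrix, beta: np.ndarray) -> np.ndarray:
    inbred = g.ploidy_code == "binary01"
    q = _freqs(g)
    return np.array(
        [smv(q[j], b, inbred=inbred) if np.isfinite(b) else np.nan
         for j, b in enumerate(beta)]
    )


def _mono_mask(g: GenotypeMatrix) -> np.ndarray:
    if g.monomorphic is not None:
        return g.monomorphic.astype(bool)
    return np.all(np.abs(g.values - g.values.mean(axis=0)) < 1e-12, axis=0)


def _finish_table(
    g: GenotypeMatrix,
    beta: np.ndarray,
    se: np.ndarray,
    stat: np.ndarray,
    p: np.ndarray,
    r2: np.ndarray,
    mono: np.ndarray,
    method: str,
    alpha: float,
    extra: dict | None = None,
) -> ScanTable:
    for arr in (beta, se, stat, p, r2):
        arr[mono] = np.nan
    n_tested = int((~mono).sum())
    thresh = alpha / max(n_tested, 1)
    significant = np.where(mono, False, p < thresh)
    data = {
        "marker_id": g.marker_ids,
        "beta": beta,
        "se": se,
        "stat": stat,
        "p_value": p,
        "r2": r2,
        "smv": _smv_column(g, beta),
        "significant": significant.astype(bool),
    }
    if extra:
        for k, v in extra.items():
            v = np.asarray(v, dtype=float)
            v[mono] = np.nan
            data[k] = v
    return ScanTable(pd.DataFrame(data), method, alpha, n_tested)


def ols_scan(g: GenotypeMatrix, y: PhenotypeVector, alpha: float = 0.05) -> ScanTable:
    """OLS single-marker regression over all markers.

    Requires centered markers and uses mean-centered phenotypes, so each
    regression is slope-only with n−1 residual degrees of freedom.  R² is
    the fraction of the corrected phenotype sum of squares explained.
    """
    if not g.centered:
        raise ValueError("ols_scan requires centered markers")
    yv = y.values - y.values.mean()
    X = g.values
    n = g.n
    mono = _mono_mask(g)
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = X.T @ yv
    syy = float(yv @ yv)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - sxy**2 / sxx
        sigma_e2 = rss / (n - 1)
        se = np.sqrt(sigma_e2 / sxx)
        stat = beta / se
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.nan)
    p = 2.0 * scipy.stats.t.sf(np.abs(stat), df=n - 1)
    return _finish_table(g, beta, se, stat, p, r2, mono, "OLS", alpha)


def whiten_gls(
    g: GenotypeMatrix, y: PhenotypeVector, pc: PhenoCov
) -> tuple[np.ndarray, np.ndarray]:
    """Transform (y, X) by the symmetric inverse square root of V.

    OLS on the transformed data reproduces GLS estimates and standard
    errors, which is how GLS scans can be run through stock least-squares
    code.  Returns ``(y*, X*)`` with ``y* = V^{-1/2} y``, ``X* = V^{-1/2} X``.
    """
    lam, U = scipy.linalg.eigh(pc.V)
    if lam[0] <= 0:
        raise ValueError("V must be positive definite to whiten")
    W = (U / np.sqrt(lam)) @ U.T
    return W @ y.values, W @ g.values


def gls_scan(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    pc: PhenoCov,
    alpha: float = 0.05,
) -> ScanTable:
    """GLS single-marker regression under V = Gσg² + Iσe².

    One cached inverse of V serves every marker.  ``se`` is the naive
    ``√(x'V⁻¹x)⁻¹`` used for the normal test statistic; ``se_markerout``
    is the corrected standard error when the tested marker is treated as
    fixed and removed from G, ``√((x'V⁻¹x)⁻¹ − σg²·scale_c)``.  R² is
    computed on the whitened scale.
    """
    if not g.centered:
        raise ValueError("gls_scan requires centered markers")
    X = g.values
    yv = y.values
    mono = _mono_mask(g)
    Viy = pc.solve(yv)
    ViX = pc.Vinv @ X
    den = np.einsum("ij,ij->j", X, ViX)
    num = X.T @ Viy
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / den
        var_naive = 1.0 / den
        se = np.sqrt(var_naive)
        stat = beta / se
        var_out = var_naive - pc.marker_c
        se_out = np.sqrt(np.where(var_out > 0, var_out, np.nan))
    p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    # whitened-scale R² (slope-only regression of y* on x*)
    ystar, Xstar = whiten_gls(g, y, pc)
    yc = ystar - ystar.mean()
    syy = float(yc @ yc)
    sxy = Xstar.T @ yc
    sxx = np.einsum("ij,ij->j", Xstar, Xstar)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.nan)
    return _finish_table(
        g, beta, se, stat, p, r2, mono, "GLS", alpha,
        extra={"se_markerout": se_out},
    )


def markerout_variance(pc: PhenoCov, x: np.ndarray, c_sigma: float) -> float:
    """Variance of the GLS estimator when marker x is fixed-and-removed.

    Computes ``(1/s²)·x'V⁻¹ V[-j] V⁻¹ x`` with ``s = x'V⁻¹x`` and
    ``V[-j] = V − c_sigma·xx'`` — the honest variance of ``β̂_j`` given that
    x no longer contributes ``c_sigma·xx'`` to the covariance.  Reduces
    algebraically to ``1/s − c_sigma``.
    """
    x = np.asarray(x, dtype=float).ravel()
    t = pc.solve(x)
    s = float(x @ t)
    if s <= 0:
        raise ValueError("degenerate marker: x'V^-1 x is not positive")
    V_mj = pc.V - c_sigma * np.outer(x, x)
    return float(t @ V_mj @ t) / (s * s)


def mmr_gls(
    Xm: np.ndarray,
    y: PhenotypeVector | np.ndarray,
    pc: PhenoCov,
    c_sigma: float = 0.0,
    cond_limit: float = 1e10,
) -> MmrResult:
    """Joint GLS regression on m markers with the marker-out covariance.

    ``β̂ = (X'V⁻¹X)⁻¹ X'V⁻¹y``; the fixed-and-removed covariance is
    ``(X'V⁻¹X)⁻¹ − I·c_sigma``.  With V = I and c_sigma = 0 this is plain
    OLS multiple regression.  Collinear columns are refused, naming a null
    space direction.
    """
    Xm = np.asarray(Xm, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    ViX = pc.Vinv @ Xm
    A = Xm.T @ ViX
    A = 0.5 * (A + A.T)
    w, Q = scipy.linalg.eigh(A)
    if w[0] <= w[-1] / cond_limit:
        null = Q[:, 0]
        raise ValueError(
            f"collinear marker columns: null-space direction {np.round(null, 4)}"
        )
    cov_naive = (Q / w) @ Q.T
    beta = cov_naive @ (Xm.T @ pc.solve(yv))
    cov_corr = cov_naive - np.eye(Xm.shape[1]) * c_sigma
    se = np.sqrt(np.diag(cov_naive))
    stat = beta / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    # model R² on the whitened scale
    lam, U = scipy.linalg.eigh(pc.V)
    W = (U / np.sqrt(lam)) @ U.T
    ystar = W @ yv
    resid = ystar - (W @ Xm) @ beta
    yc = ystar - ystar.mean()
    syy = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else np.nan
    return MmrResult(beta, cov_naive, cov_corr, se, stat, p, r2)


def mme_solve(
    W: np.ndarray,
    y: PhenotypeVector | np.ndarray,
    grm_inv: np.ndarray,
    lambda_g: float,
    sigma_e2: float | None = None,
) -> MmeResult:
    """Henderson mixed-model equations for fixed regressions plus GBLUP.

    Solves::

        [ W'W      W'            ] [β̂]   [W'y]
        [ W        I + G⁻¹ λg    ] [ĝ] = [ y ]

    given the variance ratio λg = σe²/σg² and an inverse GRM (obtainable
    once, with marker removals handled by Woodbury downdates of G⁻¹).  The
    fixed-block of the inverted coefficient matrix, ``cββ``, scaled by σe²,
    is the sampling variance of β̂; the z statistic is returned when σe² is
    supplied.  β̂ equals the GLS estimator and ĝ the direct BLUP.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n, k = W.shape
    if lambda_g <= 0:
        raise ValueError("lambda_g must be positive")
    coef = np.empty((k + n, k + n))
    coef[:k, :k] = W.T @ W
    coef[:k, k:] = W.T
    coef[k:, :k] = W
    coef[k:, k:] = np.eye(n) + grm_inv * lambda_g
    rhs = np.concatenate([W.T @ yv, yv])
    try:
        C = scipy.linalg.inv(coef)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular mixed-model coefficient matrix") from exc
    sol = C @ rhs
    beta, g_hat = sol[:k], sol[k:]
    cbb = C[:k, :k]
    z = None
    if sigma_e2 is not None:
        z = beta / (np.sqrt(sigma_e2) * np.sqrt(np.diag(cbb)))
    resid = yv - W @ beta
    return MmeResult(beta, BlupResult(g_hat, resid), cbb, z)


def blup_strongarm(
    grm: GRM,
    pc: PhenoCov,
    y: PhenotypeVector | np.ndarray,
    fitted_fixed: np.ndarray,
) -> BlupResult:
    """Direct GBLUP ``ĝ = σg² G V⁻¹ (y − fitted_fixed)``.

    Works for rank-deficient G (no inverse of G needed) and is invariant to
    removing the tested marker from both G and V.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    resid = yv - np.asarray(fitted_fixed, dtype=float)
    g_hat = pc.sigma_g2 * (grm.matrix @ pc.solve(resid))
    return BlupResult(g_hat, resid)


def pc_adjusted_scan(
    g: GenotypeMatrix,
    y: PhenotypeVector,
    e: EigenGRM,
    n_pc: int,
    vc: VarComp,
    mode: str = "keep_G",
    alpha: float = 0.05,
) -> ScanTable:
    """SMR scan with the leading ``n_pc`` eigenvectors of G as fixed covariates.

    Per marker, the design is ``W = [x_j, U_1, …, U_{n_pc}]`` fit by GLS.
    ``mode="keep_G"`` uses V = Gσg² + Iσe² unmodified (the common practice);
    ``mode="remove_from_G"`` first strips the fitted eigenvectors'
    contribution ``σg²·Σ λ_i U_i U_i'`` from V via a low-rank downdate, so
    the covariates no longer appear on both sides of the model.  The two
    modes give different estimates — eigenvector removal, unlike marker
    removal, is not an invariance.  Variance components are used as given;
    re-estimating them on the edited G is the caller's decision.
    """
    if not 0 <= n_pc < e.n:
        raise ValueError("need 0 <= n_pc < n")
    if mode not in ("keep_G", "remove_from_G"):
        raise ValueError(f"unknown mode {mode!r}")
    pc_cov = PhenoCov.from_grm(e.parent, vc.sigma_g2, vc.sigma_e2)
    U_fixed = e.U[:, :n_pc]
    if mode == "remove_from_G" and n_pc > 0:
        scores = U_fixed * np.sqrt(e.lam[:n_pc])  # columns U_i √λ_i
        pc_cov = lowrank_downdate_inv(pc_cov, scores, vc.sigma_g2)
    X = g.values
    yv = y.values
    mono = _mono_mask(g)
    Vinv = pc_cov.Vinv
    ViU = Vinv @ U_fixed
    Viy = Vinv @ yv
    ViX = Vinv @ X
    UtViU = U_fixed.T @ ViU
    UtViy = U_fixed.T @ Viy
    p_markers = g.p
    beta = np.full(p_markers, np.nan)
    se = np.full(p_markers, np.nan)
    for j in range(p_markers):
        if mono[j]:
            continue
        xj = X[:, j]
        A = np.empty((n_pc + 1, n_pc + 1))
        A[0, 0] = xj @ ViX[:, j]
        A[0, 1:] = xj @ ViU
        A[1:, 0] = A[0, 1:]
        A[1:, 1:] = UtViU
        b = np.concatenate([[xj @ Viy], UtViy])
        try:
            Ainv = scipy.linalg.inv(A)
        except scipy.linalg.LinAlgError:
            continue
        theta = Ainv @ b
        beta[j] = theta[0]
        se[j] = np.sqrt(max(Ainv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    r2 = np.full(p_markers, np.nan)
    method = f"GLS+{n_pc}PC({'intact' if mode == 'keep_G' else 'removed'})"
    return _finish_table(g, beta, se, stat, p, r2, mono, method, alpha)
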