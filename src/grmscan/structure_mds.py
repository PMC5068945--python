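"""Multidimensional scaling of genotype distances, with STRESS.

Classical (Torgerson) MDS double-centers the squared Euclidean distances
and embeds on the leading eigenvectors; its eigenvalue decay is the scree
diagnostic for how many axes of population structure the panel carries.
Nonmetric MDS preserves only the rank order of distances and is minimized
here by SMACOF majorization with pool-adjacent-violators isotonic
regression (Kruskal stress-1).

STRESS — the square root of the sum of squared observed-minus-fitted
distances over the sum of squared observed distances — is the fit
criterion; values below roughly 5–10% indicate the dimension suffices.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .geno_io import GenotypeMatrix

__all__ = [
    "DistanceSet",
    "MdsResult",
    "pairwise_distances",
    "classical_mds",
    "stress",
    "nonmetric_mds",
    "stress_scan",
]


@dataclasses.dataclass
class DistanceSet:
    """Condensed (upper-triangle) Euclidean distances among n objects."""

    n: int
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float).ravel()
        expected = self.n * (self.n - 1) // 2
        if self.d.size != expected:
            raise ValueError(
                f"expected {expected} condensed distances for n={self.n}, got {self.d.size}"
            )
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "DistanceSet":
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.ndim == 1 or coords.shape[1] == 0:
            coords = coords.reshape(len(coords), -1)
        return cls(coords.shape[0], pdist(coords))


@dataclasses.dataclass
class MdsResult:
    """A K-dimensional configuration and its goodness of fit."""

    coords: np.ndarray
    K: int
    eigvals: np.ndarray | None
    stress: float
    converged: bool = True
    n_iter: int = 0

    @property
    def eigval_fractions(self) -> np.ndarray | None:
        """Positive eigenvalues as fractions of their sum (scree heights)."""
        if self.eigvals is None:
            return None
        pos = self.eigvals[self.eigvals > 0]
        return pos / pos.sum()


def pairwise_distances(g: GenotypeMatrix) -> DistanceSet:
    """Euclidean distances between genotype rows: n(n−1)/2 pairs.

    Column centering shifts every row equally, so the distances are the
    same for raw and centered dosages.
    """
    return DistanceSet(g.n, pdist(g.values))


def stress(d_obs: DistanceSet | np.ndarray, d_fit: DistanceSet | np.ndarray) -> float:
    """STRESS = sqrt( Σ(d_obs − d_fit)² / Σ d_obs² ).

    0 for a perfect fit, 1 for an all-zero fitted configuration.
    """
    do = d_obs.d if isinstance(d_obs, DistanceSet) else np.asarray(d_obs, dtype=float)
    df = d_fit.d if isinstance(d_fit, DistanceSet) else np.asarray(d_fit, dtype=float)
    if do.shape != df.shape:
        raise ValueError("observed and fitted distance sets differ in length")
    denom = float(do @ do)
    if denom <= 0:
        raise ValueError("all observed distances are zero")
    diff = do - df
    return float(np.sqrt((diff @ diff) / denom))


def classical_mds(D: DistanceSet, K: int) -> MdsResult:
    """Torgerson classical scaling.

    Double-centers the squared distances, ``B = −½ J D² J``, and embeds on
    the top-K eigenvectors scaled by √eigenvalue.  Dimensions with
    non-positive eigenvalues are zeroed with a warning.  The reported
    STRESS compares configuration distances with the observed ones
    directly (no monotone transform).
    """
    n = D.n
    if not 1 <= K < n:
        raise ValueError("need 1 <= K < n")
    D2 = squareform(D.d) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    lam, U = scipy.linalg.eigh(B)
    lam, U = lam[::-1].copy(), U[:, ::-1].copy()
    coords = np.zeros((n, K))
    eig_tol = 1e-12 * max(float(np.abs(lam).max(initial=0.0)), 1e-300)
    for k in range(K):
        if lam[k] > eig_tol:
            coords[:, k] = U[:, k] * np.sqrt(lam[k])
        else:
            warnings.warn(
                f"classical MDS dimension {k} has non-positive eigenvalue "
                f"{lam[k]:.3g}; coordinate zeroed",
                stacklevel=2,
            )
    fit = DistanceSet.from_coords(coords)
    return MdsResult(coords, K, lam, stress(D, fit))


def _kruskal_stress1(d_conf: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(d_conf @ d_conf)
    if denom <= 0:
        return np.inf
    diff = d_conf - disparities
    return float(np.sqrt((diff @ diff) / denom))


def _guttman_transform(X: np.ndarray, d_conf: np.ndarray, disp: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_conf > 0, disp / d_conf, 0.0)
    R = squareform(ratio)
    B = -R
    np.fill_diagonal(B, R.sum(axis=1))
    return (B @ X) / n


def nonmetric_mds(
    D: DistanceSet,
    K: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    n_restarts: int = 4,
    extra_inits: list[np.ndarray] | None = None,
) -> MdsResult:
    """Kruskal nonmetric MDS by SMACOF majorization.

    Each iteration fits disparities by isotonic regression of configuration
    distances on the observed rank order (scaled so Σd̂² = Σd²), then
    updates the configuration by the Guttman transform; stress-1 is
    non-increasing.  Restarts: the classical-MDS solution plus
    ``n_restarts − 1`` seeded random configurations (plus any
    ``extra_inits``), keeping the lowest-stress result.  Deterministic
    given ``seed``.
    """
    n = D.n
    if not 1 <= K < n:
        raise ValueError("need 1 <= K < n")
    order = np.argsort(D.d, kind="stable")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    scale = max(D.d.max(initial=0.0), 1.0)
    inits: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inits.append(classical_mds(D, K).coords)
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(rng.normal(scale=scale / np.sqrt(n), size=(n, K)))
    if extra_inits:
        inits.extend(np.asarray(x, dtype=float).reshape(n, K) for x in extra_inits)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    ranks = np.arange(D.d.size, dtype=float)
    best: MdsResult | None = None
    for X0 in inits:
        X = X0.copy()
        prev = np.inf
        converged = False
        it = 0
        s = np.inf
        for it in range(1, max_iter + 1):
            d_conf = pdist(X)
            disp_sorted = iso.fit_transform(ranks, d_conf[order])
            disp = np.empty_like(disp_sorted)
            disp[order] = disp_sorted
            ss = float(disp @ disp)
            if ss > 0:
                disp *= np.sqrt(float(d_conf @ d_conf) / ss)
            s = _kruskal_stress1(d_conf, disp)
            if prev - s < tol:
                converged = True
                break
            prev = s
            X = _guttman_transform(X, d_conf, disp)
        cand = MdsResult(X, K, None, s, converged, it)
        if best is None or cand.stress < best.stress:
            best = cand
    assert best is not None
    return best


def stress_scan(
    D: DistanceSet,
    K_max: int,
    method: str = "nonmetric",
    seed: int = 0,
) -> list[tuple[int, float]]:
    """STRESS as a function of embedding dimension, K = 1..K_max.

    For nonmetric scans, the K-dimensional solution (padded with a zero
    column) seeds the K+1 run, which guarantees the curve is non-increasing
    up to solver tolerance.
    """
    out: list[tuple[int, float]] = []
    prev_coords: np.ndarray | None = None
    for K in range(1, K_max + 1):
        if method == "classical":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = classical_mds(D, K)
        elif method == "nonmetric":
            extra = None
            if prev_coords is not None:
                extra = [np.column_stack([prev_coords, np.zeros(D.n)])]
            res = nonmetric_mds(D, K, seed=seed, extra_inits=extra)
            prev_coords = res.coords
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append((K, res.stress))
    return out
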