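"""Sherman–Morrison–Woodbury downdates of covariance inverses.

A single-marker GWAS that removes the tested marker from G needs the
inverse of ``V[-j] = V - σg²·scale_c·x_j x_j'`` for every j.  Inverting p
dense n×n matrices is hopeless at sequence scale; the Woodbury identity
turns each removal into a rank-one (or rank-m) correction of one base
inverse:

    (V - c·xx')⁻¹ = V⁻¹ + c·t t' / (1 - c·x't),   t = V⁻¹x.

The same identity, with c = scale_c, serves G⁻¹ downdates for the
mixed-model-equation path.  Every downdate checks its capacitance
(1 - c·x'V⁻¹x, or the matrix analogue) and refuses removals that would
leave the matrix indefinite, rather than returning a near-singular inverse.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .grm import GRM

__all__ = [
    "DowndateError",
    "PhenoCov",
    "woodbury_downdated_inverse",
    "rank1_downdate_inv",
    "lowrank_downdate_inv",
    "eig_downdate_then_marker",
]

#: relative tolerance of the positive-definiteness (capacitance) check
PD_TOL = 1e-10


class DowndateError(ValueError):
    """Raised when a requested removal would make the matrix indefinite."""


def woodbury_downdated_inverse(
    A_inv: np.ndarray, X: np.ndarray, c: float, pd_tol: float = PD_TOL
) -> np.ndarray:
    """Inverse of ``A - c·XX'`` from ``A⁻¹``.

    ``X`` may be an n-vector (rank-one) or an n×m matrix.  The capacitance
    ``I - c·X'A⁻¹X`` must stay positive definite within ``pd_tol``
    (relative to ``X'A⁻¹X``), otherwise :class:`DowndateError` is raised.
    """
    A_inv = np.asarray(A_inv, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if c < 0:
        raise ValueError("downdate weight c must be non-negative")
    if c == 0 or X.shape[1] == 0:
        return A_inv.copy()
    T = A_inv @ X  # n×m, the paper-style t_j columns
    S = X.T @ T  # X'A⁻¹X
    cap = np.eye(X.shape[1]) - c * S
    cap = 0.5 * (cap + cap.T)
    scale = max(float(np.abs(c * S).max(initial=0.0)), 1.0)
    eigs = scipy.linalg.eigvalsh(cap)
    if eigs[0] <= pd_tol * scale:
        raise DowndateError(
            "downdate not positive definite: capacitance eigenvalue "
            f"{eigs[0]:.3g} (scale {scale:.3g})"
        )
    out = A_inv + c * T @ scipy.linalg.solve(cap, T.T, assume_a="pos")
    return 0.5 * (out + out.T)


@dataclasses.dataclass
class PhenoCov:
    """Phenotypic covariance ``V = G σg² + I σe²`` with a cached inverse.

    ``marker_c = σg² · scale_c`` is the weight of one marker column inside
    V, i.e. the ``c`` to pass when removing a marker.  ``edits`` records
    applied downdates for provenance.
    """

    V: np.ndarray
    Vinv: np.ndarray
    sigma_g2: float
    sigma_e2: float
    scale_c: float = 1.0
    edits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.Vinv = np.asarray(self.Vinv, dtype=float)
        if self.V.shape != self.Vinv.shape or self.V.shape[0] != self.V.shape[1]:
            raise ValueError("V and Vinv must be square and congruent")

    @classmethod
    def from_grm(cls, grm: GRM, sigma_g2: float, sigma_e2: float) -> "PhenoCov":
        if sigma_g2 < 0 or sigma_e2 <= 0:
            raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0 for a PD covariance")
        V = grm.matrix * sigma_g2 + np.eye(grm.n) * sigma_e2
        cho = scipy.linalg.cho_factor(V)
        Vinv = scipy.linalg.cho_solve(cho, np.eye(grm.n))
        return cls(V, 0.5 * (Vinv + Vinv.T), sigma_g2, sigma_e2, grm.scale_c)

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def marker_c(self) -> float:
        return self.sigma_g2 * self.scale_c

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self.Vinv @ b


def rank1_downdate_inv(pc: PhenoCov, x: np.ndarray, c: float) -> PhenoCov:
    """Covariance after removing one marker: ``V - c·xx'`` with its inverse.

    For a marker column x of the centered genotype matrix, ``c`` is
    ``pc.marker_c`` (= σg²·scale_c).  One matrix–vector product and an
    outer-product correction; no new factorization.
    """
    x = np.asarray(x, dtype=float).ravel()
    Vinv_new = woodbury_downdated_inverse(pc.Vinv, x, c)
    V_new = pc.V - c * np.outer(x, x)
    return PhenoCov(
        V_new, Vinv_new, pc.sigma_g2, pc.sigma_e2, pc.scale_c,
        pc.edits + (f"rank1(c={c:.6g})",),
    )


def lowrank_downdate_inv(pc: PhenoCov, Xm: np.ndarray, c: float) -> PhenoCov:
    """Covariance after removing m markers jointly: ``V - c·Xm Xm'``.

    A singular capacitance matrix means the removal is not admissible
    (for G-downdates this is the n ≤ p − m rank condition failing).
    """
    Xm = np.asarray(Xm, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    Vinv_new = woodbury_downdated_inverse(pc.Vinv, Xm, c)
    V_new = pc.V - c * (Xm @ Xm.T)
    return PhenoCov(
        0.5 * (V_new + V_new.T), Vinv_new, pc.sigma_g2, pc.sigma_e2, pc.scale_c,
        pc.edits + (f"lowrank(m={Xm.shape[1]}, c={c:.6g})",),
    )


def eig_downdate_then_marker(
    pc: PhenoCov,
    pcs: list[np.ndarray],
    sigma_g2: float,
    x_j: np.ndarray,
    c: float,
) -> PhenoCov:
    """Remove eigenvector contributions from V, then a tested marker.

    ``pcs`` are PC score vectors ``U_i √λ_i`` (see ``grm.pc_scores``); their
    genomic share ``σg²·Σ pc_i pc_i'`` is removed in one low-rank downdate,
    after which the marker removal reuses the edited inverse.  Equivalent to
    directly inverting ``V − σg²·Σ pc pc' − c·x_j x_j'`` but with a single
    base inversion for the whole scan.
    """
    if pcs:
        pc = lowrank_downdate_inv(pc, np.column_stack(pcs), sigma_g2)
    return rank1_downdate_inv(pc, x_j, c)
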