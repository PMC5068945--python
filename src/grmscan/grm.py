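"""Genomic relationship matrices: construction, scaling, spectra, and edits.

The GRM is ``G = XX'`` over centered marker columns, optionally scaled to
``XX'/(p d̄)`` where ``d̄`` is the mean diagonal of ``XX'/p`` (so the mean
diagonal of the scaled G is 1 and variance components are on the phenotypic
scale).  The scaling constant is frozen at build time: removing marker j
subtracts ``scale_c · x_j x_j'`` rather than recomputing ``d̄``, which is
exactly the per-marker contribution the covariance downdates assume.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .geno_io import GenotypeMatrix

__all__ = [
    "GRM",
    "EigenGRM",
    "build_grm",
    "drop_markers_grm",
    "eigen_grm",
    "drop_eigvecs_grm",
    "pc_scores",
    "write_grm",
    "read_grm",
]


@dataclasses.dataclass
class GRM:
    """Symmetric PSD relationship matrix with its per-marker weight.

    ``scale_c`` is the weight of one marker's outer product inside
    ``matrix``: 1 for the raw G, ``1/(p d̄)`` for the mean-diagonal scaling.
    ``source_markers`` tracks which marker columns currently contribute;
    ``removed_eigs`` which eigenvector indices (0-based, descending
    eigenvalue order) have been subtracted.
    """

    matrix: np.ndarray
    scale_c: float
    sample_ids: list[str]
    source_markers: tuple[str, ...]
    removed_eigs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match GRM order")
        asym = np.abs(self.matrix - self.matrix.T).max(initial=0.0)
        if asym > 1e-10 * max(1.0, np.abs(self.matrix).max(initial=0.0)):
            raise ValueError(f"GRM is not symmetric (max asymmetry {asym:.3g})")
        if self.scale_c <= 0:
            raise ValueError("scale_c must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class EigenGRM:
    """Full spectral decomposition ``G = U diag(lam) U'``, descending."""

    U: np.ndarray
    lam: np.ndarray
    parent: GRM

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.U.shape[0] != self.U.shape[1] or self.lam.size != self.U.shape[0]:
            raise ValueError("eigenvector/eigenvalue shapes inconsistent")
        if np.any(np.diff(self.lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n(self) -> int:
        return self.lam.size


def build_grm(g: GenotypeMatrix, scaling: str = "raw") -> GRM:
    """Form G from a centered genotype matrix.

    ``scaling="raw"`` gives ``G = XX'`` (scale_c = 1); ``"mean_diag"``
    gives ``G = XX'/(p d̄)`` with ``d̄`` the mean diagonal of ``XX'/p``,
    so that ``mean(diag(G)) = 1``.
    """
    if not g.centered:
        raise ValueError("build_grm requires centered markers")
    if g.p == 0:
        raise ValueError("cannot build a GRM from zero markers")
    X = g.values
    raw = X @ X.T
    if scaling == "raw":
        matrix, scale_c = raw, 1.0
    elif scaling == "mean_diag":
        dbar = raw.trace() / (g.n * g.p)
        if dbar <= 0:
            raise ValueError("mean diagonal of XX'/p is zero; all markers monomorphic?")
        scale_c = 1.0 / (g.p * dbar)
        matrix = raw * scale_c
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    matrix = 0.5 * (matrix + matrix.T)
    return GRM(matrix, scale_c, list(g.sample_ids), tuple(g.marker_ids))


def _resolve_marker_indices(grm: GRM, g: GenotypeMatrix, drop) -> np.ndarray:
    ids = list(drop)
    if all(isinstance(d, (int, np.integer)) for d in ids):
        idx = np.asarray(ids, dtype=int)
        names = [g.marker_ids[i] for i in idx]
    else:
        names = [str(d) for d in ids]
        lookup = {m: i for i, m in enumerate(g.marker_ids)}
        idx = np.asarray([lookup[m] for m in names], dtype=int)
    present = set(grm.source_markers)
    for m in names:
        if m not in present:
            raise ValueError(f"marker {m!r} is not in the GRM source set")
    return idx


def drop_markers_grm(grm: GRM, g: GenotypeMatrix, drop) -> GRM:
    """Remove markers' contributions: ``G - scale_c · X_drop X_drop'``.

    ``drop`` is a set of column indices or marker IDs present in the GRM's
    source set; ``g`` must be the same centered matrix the GRM was built
    from (the coding consistency the invariance results require).  The
    scaling constant is left untouched.
    """
    idx = _resolve_marker_indices(grm, g, drop)
    Xd = g.values[:, idx]
    matrix = grm.matrix - grm.scale_c * (Xd @ Xd.T)
    dropped = {g.marker_ids[i] for i in idx}
    remaining = tuple(m for m in grm.source_markers if m not in dropped)
    return GRM(
        0.5 * (matrix + matrix.T),
        grm.scale_c,
        list(grm.sample_ids),
        remaining,
        grm.removed_eigs,
    )


def eigen_grm(grm: GRM, psd_tol: float = 1e-8) -> EigenGRM:
    """Full symmetric eigendecomposition with PSD clipping.

    Eigenvalues in ``[-psd_tol·λ₁, 0]`` are set to 0; anything more
    negative raises, since a genuinely indefinite G signals an upstream
    construction error.
    """
    lam, U = scipy.linalg.eigh(grm.matrix)
    lam, U = lam[::-1].copy(), U[:, ::-1].copy()
    lam1 = max(lam[0], 0.0)
    floor = -psd_tol * max(lam1, 1e-12)
    if lam[-1] < floor:
        raise ValueError(
            f"GRM is not PSD: smallest eigenvalue {lam[-1]:.3g} below tolerance {floor:.3g}"
        )
    lam[lam < 0] = 0.0
    return EigenGRM(U, lam, grm)


def drop_eigvecs_grm(e: EigenGRM, drop) -> GRM:
    """Subtract eigenvector contributions: ``G - Σ_{i∈drop} U_i U_i' λ_i``.

    ``drop`` holds 0-based indices into the descending eigenvalue order, so
    ``{0, 1}`` removes the two leading (population-structure) axes.
    """
    idx = sorted(int(i) for i in set(drop))
    for i in idx:
        if not 0 <= i < e.n:
            raise ValueError(f"eigenvector index {i} out of range")
    keep = np.ones(e.n, dtype=bool)
    keep[idx] = False
    Uk = e.U[:, keep]
    matrix = (Uk * e.lam[keep]) @ Uk.T
    parent = e.parent
    return GRM(
        0.5 * (matrix + matrix.T),
        parent.scale_c,
        list(parent.sample_ids),
        parent.source_markers,
        tuple(sorted(set(parent.removed_eigs) | set(idx))),
    )


def pc_scores(e: EigenGRM, i: int) -> np.ndarray:
    """Principal-component score vector ``U_i √λ_i``.

    With this scaling ``Σ_i pc_i pc_i' = G``, so removing ``σg²·pc_i pc_i'``
    from V is exactly removing eigenvector i's share of genomic covariance.
    """
    if not 0 <= i < e.n:
        raise ValueError(f"eigenvector index {i} out of range")
    return e.U[:, i] * np.sqrt(e.lam[i])


def write_grm(grm: GRM, path: str | Path, sep: str = ",") -> None:
    """Export G as a square CSV with sample-ID header and index."""
    pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep=sep
    )


def read_grm(path: str | Path, scale_c: float = 1.0, sep: str = ",") -> GRM:
    """Import a square GRM CSV written by :func:`write_grm`.

    The per-marker weight cannot be recovered from the matrix alone and
    must be supplied if marker downdates are to follow.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GRM(df.to_numpy(dtype=float), scale_c, [str(s) for s in df.index], ())
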