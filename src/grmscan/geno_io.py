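"""Genotype and phenotype I/O, validation, centering, and allele frequencies.

Genotypes are held as an ``n x p`` real dosage matrix (individuals by
markers).  Two codings are supported: ``diploid012`` (0/1/2 copies of the
reference allele, SNP-style) and ``binary01`` (presence/absence, as for
dominant DArT markers or fully inbred lines).  Centering subtracts the
column mean marker-by-marker, the standard preprocessing before building a
genomic relationship matrix G = XX'.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "center_markers",
    "uncenter_markers",
    "allele_freq",
    "align_phenotypes",
]

#: maximum dosage per coding; also the allele-count divisor for frequencies
PLOIDY_MAX = {"diploid012": 2.0, "binary01": 1.0}

MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "."}


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the dosage coding contract."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix with sample/marker identifiers and centering state.

    Parameters
    ----------
    values
        ``n x p`` float array.  Raw dosages before centering; deviations
        from the column mean afterwards.
    sample_ids, marker_ids
        Row and column labels, in file order.
    ploidy_code
        ``"diploid012"`` or ``"binary01"``.
    centered
        Whether :func:`center_markers` has been applied.
    col_means
        Original column means; populated by :func:`center_markers` and kept
        so that allele frequencies and un-centering remain available.
    monomorphic
        Boolean mask of zero-variance markers (set at centering time).
    """

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    ploidy_code: str = "diploid012"
    centered: bool = False
    col_means: np.ndarray | None = None
    monomorphic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("ID lengths do not match matrix shape")
        if self.ploidy_code not in PLOIDY_MAX:
            raise ValueError(f"unknown ploidy_code {self.ploidy_code!r}")
        if np.isnan(self.values).any():
            raise ValueError("genotype matrix contains missing values")
        if self.centered:
            if self.col_means is None:
                raise ValueError("centered matrix must carry col_means")
            colmean = self.values.mean(axis=0)
            if p and np.abs(colmean).max() > 1e-10:
                raise ValueError("centered flag set but column means are not 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class PhenotypeVector:
    """A single quantitative trait, aligned to genotype sample order."""

    values: np.ndarray
    sample_ids: list[str]
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise ValueError("phenotype IDs do not match value length")
        if np.isnan(self.values).any():
            raise ValueError("phenotype vector contains missing values")

    @property
    def n(self) -> int:
        return self.values.size


def _parse_cell(raw: str) -> float:
    token = raw.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise GenotypeFormatError(f"non-numeric dosage {raw!r}") from None


def read_genotypes(
    path: str | Path,
    sep: str = ",",
    ploidy_code: str = "diploid012",
    missing_policy: str = "mean_impute",
) -> GenotypeMatrix:
    """Read a samples-by-markers dosage CSV/TSV.

    The file must have a header row of marker IDs and sample IDs in the
    first column.  Dosages must lie in {0,1,2} (``diploid012``) or {0,1}
    (``binary01``).  Missing cells (empty, ``NA``, ``.``) are imputed with
    the marker mean under ``missing_policy="mean_impute"`` or rejected under
    ``"fail"``.  Non-numeric or out-of-range entries raise
    :class:`GenotypeFormatError` naming the offending sample and marker.
    """
    if missing_policy not in ("mean_impute", "fail"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if ploidy_code not in PLOIDY_MAX:
        raise ValueError(f"unknown ploidy_code {ploidy_code!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    marker_ids = [str(m) for m in df.columns]
    n, p = df.shape
    values = np.empty((n, p), dtype=float)
    allowed = set(range(int(PLOIDY_MAX[ploidy_code]) + 1))
    for jcol, marker in enumerate(marker_ids):
        col = df.iloc[:, jcol].to_numpy()
        for irow, raw in enumerate(col):
            try:
                v = _parse_cell(raw)
            except GenotypeFormatError as exc:
                raise GenotypeFormatError(
                    f"{exc} at sample {sample_ids[irow]!r}, marker {marker!r}"
                ) from None
            if not np.isnan(v) and v not in allowed:
                raise GenotypeFormatError(
                    f"dosage {v} out of range for {ploidy_code} at sample "
                    f"{sample_ids[irow]!r}, marker {marker!r}"
                )
            values[irow, jcol] = v
        missing = np.isnan(values[:, jcol])
        if missing.any():
            if missing_policy == "fail":
                raise GenotypeFormatError(
                    f"missing dosage at marker {marker!r} with missing_policy='fail'"
                )
            if missing.all():
                raise GenotypeFormatError(f"marker {marker!r} is entirely missing")
            values[missing, jcol] = values[~missing, jcol].mean()
    return GenotypeMatrix(values, sample_ids, marker_ids, ploidy_code)


def write_genotypes(g: GenotypeMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a dosage matrix in the dialect :func:`read_genotypes` reads."""
    pd.DataFrame(g.values, index=g.sample_ids, columns=g.marker_ids).to_csv(path, sep=sep)


def read_phenotypes(path: str | Path, sep: str = ",") -> PhenotypeVector:
    """Read a two-column (sample id, value) phenotype file with header."""
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs at least two columns (id, value)")
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    return PhenotypeVector(values, list(df.iloc[:, 0]), trait_name=str(df.columns[1]))


def write_phenotypes(y: PhenotypeVector, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame({"id": y.sample_ids, y.trait_name: y.values}).to_csv(
        path, sep=sep, index=False
    )


def center_markers(g: GenotypeMatrix) -> GenotypeMatrix:
    """Center each marker column to mean zero.

    Column means are stored on the result so the operation is invertible and
    allele frequencies remain computable.  Monomorphic (zero-variance)
    columns become all-zero and are flagged; they are kept so that G built
    from the full matrix is reproducible, but scans skip them.
    """
    if g.centered:
        raise ValueError("genotype matrix is already centered")
    col_means = g.values.mean(axis=0)
    centered = g.values - col_means
    mono = np.all(np.abs(centered) < 1e-12, axis=0)
    centered[:, mono] = 0.0
    return GenotypeMatrix(
        centered,
        list(g.sample_ids),
        list(g.marker_ids),
        g.ploidy_code,
        centered=True,
        col_means=col_means,
        monomorphic=mono,
    )


def uncenter_markers(g: GenotypeMatrix) -> GenotypeMatrix:
    """Add the stored column means back, recovering original dosages."""
    if not g.centered:
        raise ValueError("genotype matrix is not centered")
    return GenotypeMatrix(
        g.values + g.col_means,
        list(g.sample_ids),
        list(g.marker_ids),
        g.ploidy_code,
        centered=False,
    )


def allele_freq(g: GenotypeMatrix, j: int) -> float:
    """Reference-allele frequency of marker ``j`` from original dosages.

    ``q = mean/2`` for diploid 0/1/2 coding and ``q = mean`` for binary 0/1
    coding; computed from stored column means when the matrix is centered.
    """
    mean = g.col_means[j] if g.centered else float(g.values[:, j].mean())
    return float(mean) / PLOIDY_MAX[g.ploidy_code]


def align_phenotypes(g: GenotypeMatrix, y: PhenotypeVector) -> PhenotypeVector:
    """Reorder a phenotype vector to genotype sample order, by ID.

    Raises ``ValueError`` on any ID mismatch or duplicate — no silent
    subsetting or reordering beyond the exact one-to-one match.
    """
    if len(set(y.sample_ids)) != len(y.sample_ids):
        raise ValueError("duplicate sample IDs in phenotype vector")
    pos = {s: i for i, s in enumerate(y.sample_ids)}
    missing = [s for s in g.sample_ids if s not in pos]
    extra = sorted(set(y.sample_ids) - set(g.sample_ids))
    if missing or extra:
        raise ValueError(
            f"sample ID mismatch: {len(missing)} genotyped samples lack phenotypes "
            f"(first: {missing[:3]}), {len(extra)} phenotypes lack genotypes "
            f"(first: {extra[:3]})"
        )
    order = [pos[s] for s in g.sample_ids]
    return PhenotypeVector(y.values[order], list(g.sample_ids), y.trait_name)
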