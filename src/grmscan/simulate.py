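"""Structured synthetic genotypes and phenotypes.

The generator emulates the two population structures the method's case
studies exhibit: a small number of well-separated strata ("wheat-like",
two groups that the first MDS coordinate separates cleanly) and a diffuse
many-family structure ("Arabidopsis-like").  Subpopulation k draws marker j
from Binomial(2, q_jk) (or Bernoulli for binary coding), with the q_jk
jittered around a common base frequency by the ``divergence`` knob.

Phenotypes follow the generative model the scans assume:

    y = X_f β_fixed + g + e,   g ~ N(0, G σg²),   e ~ N(0, I σe²),

with g drawn through the spectral factor of G.  All randomness flows
through explicit seeds into ``numpy.random.default_rng`` (PCG64); there is
no global RNG state.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geno_io import GenotypeMatrix, PhenotypeVector, center_markers
from .grm import GRM, eigen_grm
from .varcomp import VarComp

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]


@dataclasses.dataclass
class SimConfig:
    """Generator settings.

    Defaults give a stratified diploid panel of 300 individuals by 1000
    markers in two groups of moderate divergence with h² = 0.5 — large
    enough that variance-component recovery and structure diagnostics are
    well-posed, small enough for desk-scale runs.
    """

    n: int = 300
    p: int = 1000
    n_subpops: int = 2
    divergence: float = 0.3
    h2_true: float = 0.5
    total_var: float = 1.0
    beta_fixed: dict[int, float] | None = None
    ploidy_code: str = "diploid012"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p <= 0 or self.n_subpops < 1:
            raise ValueError("n, p must be positive and n_subpops >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")


def _subpop_labels(n: int, k: int) -> np.ndarray:
    """Contiguous, near-equal group assignment."""
    return np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a stratified dosage matrix, deterministic given ``cfg.seed``.

    Base frequencies are Uniform(0.1, 0.9) per marker; each subpopulation's
    frequency is jittered by Uniform(−divergence/2, +divergence/2) and
    clipped to [0.02, 0.98].  Divergence 0 gives a homogeneous panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    base = rng.uniform(0.1, 0.9, size=cfg.p)
    jitter = rng.uniform(
        -cfg.divergence / 2.0, cfg.divergence / 2.0, size=(cfg.n_subpops, cfg.p)
    )
    freqs = np.clip(base[None, :] + jitter, 0.02, 0.98)
    labels = _subpop_labels(cfg.n, cfg.n_subpops)
    q = freqs[labels, :]  # n×p per-cell success probabilities
    trials = 2 if cfg.ploidy_code == "diploid012" else 1
    values = rng.binomial(trials, q).astype(float)
    sample_ids = [f"s{labels[i]}_{i:04d}" for i in range(cfg.n)]
    marker_ids = [f"m{j:05d}" for j in range(cfg.p)]
    return GenotypeMatrix(values, sample_ids, marker_ids, cfg.ploidy_code)


def simulate_phenotypes(
    g: GenotypeMatrix,
    grm: GRM,
    vc: VarComp,
    beta_fixed: dict[int, float] | None = None,
    seed: int = 0,
    trait_name: str = "sim_trait",
) -> PhenotypeVector:
    """Draw y = X_f β_fixed + g + e for a given GRM and variance components.

    The genomic term is drawn through the spectral factor
    ``U diag(√λ) z σg``, so its covariance is exactly ``G σg²`` even when G
    is rank-deficient.  Fixed effects index columns of ``g`` (centered
    dosages if ``g`` is centered).
    """
    if vc.sigma_g2 < 0 or vc.sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    n = grm.n
    y = np.zeros(n)
    if beta_fixed:
        for j, beta in beta_fixed.items():
            y += g.values[:, j] * beta
    if vc.sigma_g2 > 0:
        e = eigen_grm(grm)
        # zero out numerical-noise eigenvalues so rank-deficient G yields
        # draws exactly inside its column space
        lam = np.where(e.lam < 1e-12 * max(e.lam[0], 1e-300), 0.0, e.lam)
        z = rng.standard_normal(n)
        y += e.U @ (np.sqrt(lam) * z) * np.sqrt(vc.sigma_g2)
    else:
        rng.standard_normal(n)  # keep the residual stream stable across σg²
    y += rng.standard_normal(n) * np.sqrt(vc.sigma_e2)
    return PhenotypeVector(y, list(g.sample_ids), trait_name)


def simulate_dataset(
    cfg: SimConfig, scaling: str = "mean_diag"
) -> tuple[GenotypeMatrix, GenotypeMatrix, GRM, PhenotypeVector, VarComp]:
    """One-call generator: raw genotypes, centered copy, GRM, phenotype.

    The true variance components split ``cfg.total_var`` by ``cfg.h2_true``
    on the scale of the requested GRM scaling (mean-diagonal-1 by default,
    matching how the variance-component machinery is meant to be used).
    """
    from .grm import build_grm  # local import avoids a cycle at module load

    raw = simulate_genotypes(cfg)
    centered = center_markers(raw)
    grm = build_grm(centered, scaling=scaling)
    vc_true = VarComp.from_h2(cfg.h2_true, cfg.total_var)
    y = simulate_phenotypes(
        centered, grm, vc_true, beta_fixed=cfg.beta_fixed, seed=cfg.seed
    )
    return raw, centered, grm, y, vc_true
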