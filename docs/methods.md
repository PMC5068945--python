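# Methods

## Model and estimators

All scans work under the single-marker mixed model
`y = x_j β_j + g + e` with `g ~ N(0, Gσg²)`, `e ~ N(0, Iσe²)`,
`V = Gσg² + Iσe²`. Markers are centered column-by-column before any GRM is
built; phenotypes are mean-centered where a mean is not otherwise modeled.
Two GRM scalings are supported: raw `G = XX′` (`scale_c = 1`) and the
mean-diagonal form `G = XX′/(p·d̄)` with `d̄` the mean diagonal of `XX′/p`
(`scale_c = 1/(p·d̄)`, mean diag(G) = 1, variance components on the
phenotypic scale). The scaling constant is frozen at build time; removing
marker j from G subtracts exactly `scale_c·x_j x_j′`, never recomputing
`d̄`. This is what makes the removal identities below hold verbatim — the
per-marker contribution to V is the constant `c = σg²·scale_c`.

### Marker-removal invariance

`(V − c·x_j x_j′)⁻¹ = V⁻¹ + c·t_j t_j′/(1 − c·x_j′t_j)` with `t_j = V⁻¹x_j`
(rank-one Woodbury), and the rank-m analogue with capacitance matrix
`I − c·X_m′V⁻¹X_m`. Substituting into the GLS estimator shows
`β̂_j` computed with `V[-j]` equals `β̂_j` computed with V, exactly; the
same holds for the joint m-marker estimator and for
`ĝ = σg²·G·V⁻¹(y − x_jβ̂_j)` under the paired edit (G[-j], V[-j]). The test
suite verifies all three at 1e−8 over hundreds of seeded instances, for
both scalings and h² ∈ {0.1, 0.25, 0.5}. What is *not* invariant is the
sampling variance: treating marker j as fixed-and-removed gives
`Var(β̂_j) = (x_j′V⁻¹x_j)⁻¹ − c`, strictly below the naive
`(x_j′V⁻¹x_j)⁻¹`. Scan tables carry both (`se` and `se_markerout`).

### Eigenvector removal

With `G = UΛU′` and PC score vectors `U_i√λ_i`, stripping eigenvectors
from G means subtracting `σg²·Σ λ_i U_i U_i′` from V (one low-rank
downdate). A finding worth stating precisely, because it sharpens the usual
"removal matters" intuition: if the removed eigenvectors are **also fitted
as fixed covariates** and variance components are held fixed, the tested
marker's GLS estimate and standard error are exactly invariant to the
removal — the Woodbury correction of `(W′V⁻¹W)⁻¹` lives entirely in the
PC-coefficient block (same cancellation as marker removal, since the
removed span lies inside the fixed design). Removal matters through a
different channel: the variance components. The structure axes can carry a
large share of marked genetic variance, so refitting (σg², σe²) on the
depleted G can change ĥ² drastically (our structured test panel drops from
0.77 to 0.34 after removing the top eigenvector), and the scan estimates
move with the re-estimated components. Accordingly `pc_adjusted_scan` takes
the components as given, and the CLI re-estimates them on the depleted G by
default (`--freeze-vc` to override).

### Mixed-model equations, whitening

`mme_solve` builds the Henderson system for an arbitrary fixed design plus
a genomic random effect given `λg = σe²/σg²` and G⁻¹ (obtainable once, with
marker removals as Woodbury downdates of G⁻¹; the capacitance turning
singular signals the rank condition n ≤ p − m failing). It reproduces
GLS + direct BLUP whenever G is invertible, which the suite asserts at
1e−8. `whiten_gls` exposes the symmetric-inverse-square-root transform
`y* = V^{-1/2}y, X* = V^{-1/2}X` under which stock OLS reproduces GLS
estimates and standard errors; GLS R² values are computed on this whitened
scale.

## Variance components

The likelihood of `y ~ N(0, Gσg² + Iσe²)` is evaluated in the eigenbasis of
G: with `ỹ = U′y`, it is a sum of independent terms with variances
`λ_iσg² + σe²`. One subtlety is handled explicitly: phenotypes are
mean-centered, and when G comes from column-centered markers the constant
vector is a null eigenvector of G (`G·1 = 0`), so the rotated datum in that
direction is identically zero. Keeping its term would let σe² → 0 drive the
log-likelihood to +∞ (a spurious boundary maximum at h² = 1). Components
with both a numerically zero eigenvalue and zero rotated datum are
therefore excluded — the likelihood of centered data on the orthogonal
complement of the mean, equivalent to profiling out a fixed intercept. On
matrices with no such degenerate direction the spectral value equals the
dense multivariate-normal log-density to 1e−8 (tested).

`fit_ml` parameterizes by `h² = σg²/(σg²+σe²)`: given h², the total
variance MLE is closed-form (`σ̂² = n⁻¹Σ ỹ_i²/w_i`, `w_i = h²λ_i + 1 − h²`),
and the 1-D profile is minimized by bounded Brent search on
[1e−6, 1 − 1e−6] with tolerance 1e−8, comparing against both endpoints so
boundary solutions are returned (flagged) rather than missed. A 1-D profile
has no starting-value ambiguity, so the marker-out refits
(`refit_with_marker_removed`) need no documented start. Standard errors
come from the observed information — a central finite-difference Hessian of
the (σg², σe²) log-likelihood with steps `1e−4·estimate` — and are omitted
at boundary optima, where the quadratic approximation is meaningless.
Identity-proportional G (all eigenvalues equal) is rejected as
unidentifiable. Parameter recovery is exercised at n = 300, p = 1000,
h² = 0.5 over 50 seeded replicates (mean ĥ² within 0.05 of truth, ~10 s);
problem sizes throughout the suite (n ≤ 500, p ≤ 1000) were chosen as the
smallest at which these statistical checks are stable.

## Simulator

`simulate_genotypes` draws subpopulation k's dosage at marker j from
Binomial(2, q_jk) (Bernoulli for presence/absence coding), with base
frequencies Uniform(0.1, 0.9) and per-subpopulation jitter
±divergence/2 clipped to [0.02, 0.98]. Two well-separated strata
(divergence ≈ 0.3–0.5) emulate a stratified inbred-panel topology whose
first MDS coordinate splits the groups; divergence 0 gives a homogeneous
panel. This is a deliberately simple dispersion model — not a calibrated
F_ST or coalescent model, with no linkage disequilibrium, no selection and
no family pedigree — so passing tests demonstrate the linear-algebraic and
statistical machinery, not robustness to realistic LD structure.
`simulate_phenotypes` draws `g` through the spectral factor
`U diag(√λ) z σg` (exact covariance `Gσg²` even for rank-deficient G,
with numerical-noise eigenvalues zeroed at 1e−12·λ₁) and adds
`N(0, σe²)` noise; all randomness flows through explicit PCG64 seeds.
Defaults (n = 300, p = 1000, two subpopulations, divergence 0.3,
h² = 0.5) are the conditions under which recovery and structure
diagnostics are well-posed at desk scale.

## MDS

Classical scaling double-centers squared Euclidean distances
(`B = −½JD²J`) and embeds on the top-K eigenvectors; eigenvalues within
1e−12 of zero (or negative — non-Euclidean distortion) zero their
coordinate with a warning, and negative eigenvalues are dropped from the
fraction-of-variation denominator. Nonmetric MDS minimizes Kruskal
stress-1 by SMACOF majorization: disparities from pool-adjacent-violators
isotonic regression on the observed rank order (scaled so `Σd̂² = Σd²`),
configuration updates by the Guttman transform, tolerance 1e−7 on stress
change, max 300 iterations, 4 restarts (classical init + 3 seeded random)
keeping the best. `stress_scan` additionally seeds the K+1 run with the
K-solution padded by a zero column, making the reported STRESS curve
non-increasing in K up to solver tolerance. Classical results report
raw-distance STRESS (no monotone transform); nonmetric results report
stress-1 — both so the 5–10 % adequacy rule can be applied, and the API
documents which is which.

## Numerical choices and edge cases

* Downdates refuse capacitances below 1e−10 (relative) rather than return
  near-singular inverses (`DowndateError`).
* Monomorphic markers are kept in X (so G is reproducible) but carry NaN
  scan rows and are excluded from the Bonferroni denominator, which is
  α / (number of polymorphic markers tested), α = 0.05 by default.
* OLS tests use Student-t with n − 1 df (centered data, slope only);
  GLS/MME statistics are referred to the standard normal.
* Eigenvalues of G in [−1e−8·λ₁, 0] are clipped to zero; anything lower is
  treated as a construction error.
* Eigenvalue ties: downstream quantities are basis-invariant (projections
  and sums of outer products), so no eigenvector canonicalization is
  attempted.
* Missing genotypes are mean-imputed per marker before centering (a
  strict `fail` mode is available); sample alignment between genotype and
  phenotype files is by ID with a deterministic error on mismatch.

## Limitations

Single-trait, single-random-effect models only; no REML with general
fixed-effect designs, no binary-trait likelihoods, no LOCO schemes (the
supported data model carries no map positions), and no small-sample exact
p-values. The simulator's lack of LD means per-marker power figures on
synthetic panels do not transfer to dense real genotypes.
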