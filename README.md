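# grmscan

GWAS single- and multi-marker scans with a genomic relationship matrix
(GRM) in the covariance structure, for quantitative-genetics analysts
working with plant or animal panels (inbred line collections, accession
panels, breeding populations) where relatedness and population structure
confound naive association tests.

## The model

Phenotypes follow a mixed linear model per tested marker *j*:

```
y = x_j β_j + g + e,    g ~ N(0, G σg²),    e ~ N(0, I σe²)
```

where `x_j` is the centered dosage column, `G = XX′` (optionally scaled to
`XX′/(p·d̄)` so its mean diagonal is 1) is the marker-based relationship
matrix, and `V = Gσg² + Iσe²` is the phenotypic covariance. The package
provides:

* **OLS and GLS single-marker regression** — `β̂_j = x_j′V⁻¹y / x_j′V⁻¹x_j`
  with one factorization of V reused across all p markers; Bonferroni
  significance, per-marker R² and single-marker variance `2q(1−q)β²`.
* **Woodbury downdates** — `(V − c·xx′)⁻¹ = V⁻¹ + c·tt′/(1 − c·x′t)` and
  its rank-m generalization, so "marker(s) removed from G" and
  "eigenvectors removed from G" analyses cost a single base inversion.
  A central guarantee, verified to 1e−8 across hundreds of random
  instances: **GLS estimates and GBLUP are invariant to whether the tested
  marker is included in G** (at fixed variance components), so a scan never
  needs p rebuilt relationship matrices. The corrected sampling variance
  when a marker is treated as fixed-and-removed, `(x′V⁻¹x)⁻¹ − σg²·c`, is
  reported alongside the naive one.
* **Mixed-model equations and GBLUP** — Henderson solve for fixed
  regressions plus `ĝ`, identical to GLS + `ĝ = σg² G V⁻¹(y − x_jβ̂_j)`.
* **Spectral ML variance components** — with `G = UΛU′`, the rotated
  likelihood is diagonal, so `(σ̂g², σ̂e²)` come from a 1-D profile search
  over heritability `h² = σg²/(σg² + σe²)` with closed-form total variance;
  standard errors from observed information.
* **PC-adjusted scans** — leading eigenvectors of G as fixed covariates,
  with G kept intact or depleted of those eigenvectors (variance components
  re-estimated on the depleted G; unlike marker removal, this changes the
  answers).
* **MDS structure diagnostics** — classical (Torgerson) and nonmetric
  (SMACOF/isotonic) multidimensional scaling of genotype distances with the
  STRESS criterion (≤ 5–10 % ≈ adequate dimension).
* **A structured simulator** — stratified Binomial genotypes plus
  `y = Xβ + g + e` phenotypes, fully seeded, for end-to-end testing without
  external data.

## Worked example

```python
import numpy as np
from grmscan import *

cfg = SimConfig(n=200, p=800, n_subpops=2, divergence=0.3, h2_true=0.5, seed=42)
raw, g, grm, y, _ = simulate_dataset(cfg)        # centered X, G with mean diag 1

fit = fit_ml(eigen_grm(grm), y)                  # spectral ML
# sigma_g2 = 0.494 +/- 0.178
# sigma_e2 = 0.394 +/- 0.149
# h2       = 0.556

pc = PhenoCov.from_grm(grm, fit.sigma_g2, fit.sigma_e2)
scan = gls_scan(g, y, pc)                        # one inversion, 800 markers
scan.table.head(3)
#  marker_id      beta       se      stat  p_value       r2      smv
#     m00000  0.137102 0.118231  1.159609 0.246208 0.006757 0.006398
#     m00001 -0.103068 0.105645 -0.975607 0.329259 0.004783 0.005253
#     m00002 -0.186571 0.103129 -1.809101 0.070435 0.016446 0.015622

# marker-removal invariance: same estimate from V and from V[-j]
xj = g.values[:, 0]
pc_mj = rank1_downdate_inv(pc, xj, pc.marker_c)
b_in  = (xj @ pc.solve(y.values)) / (xj @ pc.solve(xj))
b_out = (xj @ pc_mj.solve(y.values)) / (xj @ pc_mj.solve(xj))
# b_in = b_out = 0.1371020725   (|diff| = 2.8e-17)
```

The heritability estimate brackets the simulated truth (0.5); no marker
reaches Bonferroni significance because the generated trait is purely
polygenic — `g` spreads variance over all markers, so single-marker shares
(`r2`, `smv` of order 0.5–1.5 %) sit far below the 0.05/800 threshold.
Eigenvector removal, by contrast, is *not* an invariance: on a strongly
stratified panel (`divergence=0.5, seed=444`), removing the top eigenvector
of G and refitting drops ĥ² from 0.767 to 0.335, because the structure axis
itself carries marked genetic variance.

The same workflows are available from the shell:

```bash
grmscan simulate --n 200 --p 800 --seed 42 --out-prefix demo
grmscan gwas --geno demo_geno.csv --pheno demo_pheno.csv --method gls --out scan.csv
grmscan varcomp --geno demo_geno.csv --pheno demo_pheno.csv --out vc.csv
grmscan mds --geno demo_geno.csv --k 2 --out mds.csv
```

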