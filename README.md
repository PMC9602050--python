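# shaher

Decomposition of the shared genetic background of correlated traits from
GWAS summary statistics.

## The problem

Sets of genetically correlated traits (anthropometric measures, psychiatric
conditions, lipid concentrations, ...) typically share part of their genetic
architecture: some causal variants act on every trait in the set with
collinear effects (*shared genetic factors*, SGF), while the rest act in
trait-specific ways (*unshared genetic factors*, UGF). `shaher` separates
these two components using nothing but per-trait GWAS summary statistics
plus the matrices of genetic and phenotypic correlations between the traits
— no individual-level genotypes or phenotypes are required.

For K standardized traits with heritabilities h²_i, the correlation-component
model is

    U_phen = H·U_gen·H + E·U_env·E        H = diag(h_i),  E = diag(√(1−h²_i))
    U_gen  = w·wᵀ + D·U_unsh·D            D = diag(√(1−w²_i))

where w²_i is the proportion of trait i's heritability explained by SGF
(w_i signed by the direction of the shared effect). The framework:

1. **SGI screen** — checks that a shared genetic impact can exist at all:
   U_gen positive definite, every |r_ij| above a threshold (default 0.2),
   and the sign pattern of U_gen consistent with a rank-one factor.
2. **MaxSH** — estimates w by least-squares fit of the rank-one model to
   the off-diagonal of U_gen, then builds the **SGIT** (shared genetic
   impact trait), the linear combination α ᵀy maximizing the proportion of
   genetic variance explained by SGF:

       α = U_phen⁻¹·H·w / √(wᵀ·H·U_phen⁻¹·H·w)

   and per-trait **UGITs** (unshared genetic impact traits)
   UGIT_i = y_i − c_i·SGIT with c_i = cov_gen(y_i, SGIT)/h²_SGIT, encoded by
   the columns of Γ = I − α·cᵀ. Every UGIT is genetically uncorrelated with
   SGIT by construction.
3. **sumCOT** — produces GWAS summary statistics for SGIT and the UGITs by
   combining the per-SNP Z-scores of the original GWASs with the α/γ
   coefficients, propagating standard errors through the phenotypic
   correlation matrix (which absorbs sample overlap), and assigning
   effective sample sizes.
4. **Post-processing** — distance clumping (5×10⁻⁸, ±500 kb), novel-locus
   calls, locus overlap matrices and trait-count profiles.

A simulation engine validates the estimation stage against the GIP1
baseline (first principal component of the genetic covariance matrix), and
an individual-level cohort simulator provides end-to-end oracles for the
summary-level arithmetic.

## Worked example

```python
import numpy as np
from shaher.core import CorrelationMatrix, TraitPanel, compose_ugen, compose_uphen
from shaher.maxsh import run_maxsh

w  = np.array([0.6, 0.8, 0.9])          # true shared loadings
h2 = np.array([0.5, 0.5, 0.5])
ugen  = compose_ugen(w, CorrelationMatrix.identity(3))
uphen = compose_uphen(ugen, CorrelationMatrix.identity(3), h2)
panel = TraitPanel(("a", "b", "c"), h2, ugen, uphen)
print(run_maxsh(panel, with_gip=True).describe())
```

prints

```
SGI screen: PASS
  positive definite:        True
  min |off-diagonal|:       0.48 (threshold 0.2)
  rank-one sign pattern:    True
  sign vector:              +++

Per-trait decomposition:
  trait	h2	w	w2	shared_h2	unshared_h2
  a	0.5000	+0.6000	0.3600	0.1800	0.3200
  b	0.5000	+0.8000	0.6400	0.3200	0.1800
  c	0.5000	+0.9000	0.8100	0.4050	0.0950
  loss: 1.6538e-18

SGIT: h2_total=0.6763 h2_shared=0.5782 Q=0.8549
UGIT[a]: h2_total=0.3557 h2_shared=0.0025
UGIT[b]: h2_total=0.2475 h2_shared=0.0003
UGIT[c]: h2_total=0.2273 h2_shared=0.0028
GIP1: h2_total=0.6842 h2_shared=0.5660

Residual SGI screen on UGIT genetic correlations (expected FAIL): FAIL
```

The estimated loadings recover the generating values exactly (loss ~ 1e-18);
trait `c` has 81% of its heritability explained by the shared factor. The
SGIT captures more shared heritability (0.578) than the GIP1 baseline
(0.566), and Q = 0.855 says 85.5% of SGIT's genetic variance is shared.
The final screen confirms that no shared impact remains among the UGITs.

## Command line

```bash
shaher check-sgi --ugen ugen.tsv                 # exit 0 / 3 (no SGI)
shaher maxsh --ugen ugen.tsv --uphen uphen.tsv --h2 h2.tsv --out out/
shaher sumcot --stats a.tsv --stats b.tsv --stats c.tsv \
              --coeffs 0.4,0.4,0.3 --uphen uphen.tsv --out combined.tsv
shaher shaher --ugen ugen.tsv --uphen uphen.tsv --h2 h2.tsv \
              --stats a.tsv --stats b.tsv --stats c.tsv --out run/
shaher simulate --grid grid.yaml --reps 1000 --seed 1 --out scenarios.tsv
shaher fixtures --k 4 --seed 7 --out fixture/   # synthetic test panel
shaher clump --stats sgit.tsv --out loci.tsv
```

Summary statistics are tab-delimited with columns
`rsid chr pos ea oa eaf beta se z p n mlog10p` (common dialect synonyms are
accepted on input); matrices and heritability vectors are labeled
tab-delimited tables.

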