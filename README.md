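# dpprs — nonparametric Bayesian polygenic risk scores from summary statistics

`dpprs` estimates joint SNP effect sizes for polygenic risk scores (PRS)
using only GWAS **summary statistics** and a reference genotype panel — no
individual-level training data and no validation cohort for parameter
tuning. It is aimed at statistical geneticists building PRS from published
GWAS results.

## The model

With standardized genotypes and phenotype, marginal GWAS effects
$\hat\beta$ within an LD block relate to the joint effects $\beta$ through

$$\hat\beta \mid \beta \sim N(R\beta,\; R/N),$$

where $R$ is the LD (correlation) matrix estimated from a reference panel.
Instead of a fixed parametric prior on effect sizes, each $\beta_i \sim
N(0,\sigma^2_i)$ with the variance drawn from a Dirichlet process,
truncated to $K$ components via stick breaking:

$$\beta_i \sim \sum_{k=1}^{K} p_k\,N(0,\sigma^2_k),\qquad
p_k = V_k \prod_{m<k}(1-V_m),\quad V_k \sim \mathrm{Beta}(1,\alpha),$$

with $\sigma^2_1$ pinned to an exact point mass at zero (Bayesian variable
selection) and the base distribution the square of a Uniform$(0,u)$ draw.
This infinite normal mixture adapts to sparse (few causal SNPs) and
infinitesimal (all SNPs causal) architectures alike. Effects are
overparametrized as $\beta_i = \eta\gamma_i$ for faster MCMC mixing, and
the posterior is explored by a blocked Gibbs sampler that is exact across
approximately independent LD blocks.

Two robustness devices handle real-world summary statistics. When SNPs
were measured on partially different individuals, the covariance of
$\hat\beta$ is $R \circ H$ with $H_{ii}=1/N_i$,
$H_{ij}=N_{s,ij}/(N_iN_j)$ (shared sample count $N_{s,ij}$) — available as
the `overlap` likelihood. When overlap bookkeeping is unknown (the usual
case for meta-analyses), the `regularized` likelihood uses covariance
$(R + Na\,I)/N$ on the rescaled input $\hat\beta/c$, shrinking the
implied cross-SNP correlation to $R_{ij}/(1+Na)$; $c$ corrects deflation
from double genomic control.

The LD reference itself is built by a single-scan partitioner that cuts
the genome wherever no SNP pair within the scan window crosses the cut
with $r^2 > 0.1$, then shrinks each block's sample correlation matrix
linearly toward the identity.

## Worked example

Everything below is generated on the fly — the package ships its own
simulator for panels, effect-size scenarios, phenotypes and summary
statistics.

```python
import numpy as np
from dpprs import (ScenarioConfig, simulate_effects, direct_sumstats,
                   LDReference, LikelihoodSpec, DPPrior, MCMCConfig, run_mcmc)
from dpprs.simulate import ar1_correlation, simulate_panel, simulate_phenotype

rng = np.random.default_rng(42)
R = [ar1_correlation(40, 0.5) for _ in range(50)]           # 2000 SNPs, 50 LD blocks
beta = simulate_effects(ScenarioConfig(scenario="custom", M=2000, h2=0.5,
                                       n_causal=20), rng)
ss = direct_sumstats(R, beta, N=20_000, rng=rng)            # ~ N(R beta, R/N)
ldref = LDReference.from_matrices(R)

res = run_mcmc(ldref, ss, spec=LikelihoodSpec(mode="plain"), prior=DPPrior(),
               cfg=MCMCConfig(n_iter=1000, burn_in=200, seed=1))
print(res.summary())
```

```
Dirichlet-process PRS results
============================================================
SNPs                                                    2000
LD blocks                                                 50
Likelihood                                             plain
Input scale c                                              1
Components (K)                                          1000
Iterations (kept)                                 1000 (800)
Seed                                                       1
------------------------------------------------------------
Posterior mean h2 (diagnostic)                        0.3020
Occupied clusters (final)                                  2
SNPs with P(nonzero) > 0.5                                18
Max |posterior mean effect|                        3.278e-01
============================================================
```

The sampler finds 18 of the 20 causal SNPs with posterior inclusion above
one half and needs only 2 occupied mixture components for this two-group
(null/causal) architecture; the heritability diagnostic tracks the
realized $\beta^\top R \beta$ of this particular effect draw (0.30 here —
the 20 sampled effects carry less squared weight than their expectation
0.5; the phenotype simulator rescales realized heritability to exactly
0.5, which is why prediction below still reaches ~0.5). Scoring a fresh
simulated cohort:

```python
X, _, _ = simulate_panel(2000, [40] * 50, rho=0.5, rng=rng)
y, beta_true = simulate_phenotype(X, beta, 0.5, rng)
r2 = np.corrcoef(res.predict(X), y)[0, 1] ** 2
print(f"correlation with true effects: "
      f"{np.corrcoef(res.posterior_mean, beta)[0,1]:.3f}")
print(f"prediction R2 in a fresh cohort: {r2:.3f}")
```

```
correlation with true effects: 0.997
prediction R2 in a fresh cohort: 0.498
```

## Command line

The same pipeline from a shell (`dpprs` is installed as a console
script): QC → LD reference → fit → score.

```bash
dpprs simulate --out sim --m 2000 --n 20000 --n-ref 2000 --scenario 1B --seed 1
dpprs ldref    --bed sim/panel --out ld --r2 0.1 --window 1Mb --shrink auto
dpprs fit      --ss sim/sumstats.tsv --ldref ld --out effects.tsv \
               --likelihood regularized --an 0.1 --iter 1000 --seed 1
dpprs score    --bed sim/panel --effects effects.tsv --out prs.tsv
```

Each subcommand writes a JSON run manifest; reruns with the same seed are
byte-identical.

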