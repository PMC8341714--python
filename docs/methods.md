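# Methods

## Model

Let $\hat\beta$ be per-SNP marginal GWAS effects on the standardized
scale (genotypes and phenotype standardized; if a file carries z-scores,
$\hat\beta_i = z_i/\sqrt{N_i}$; per-allele effects are converted with
$\sqrt{2f(1-f)}$). Within an LD block with reference correlation matrix
$R$,

$$\hat\beta \mid \beta \sim N(R\beta, \mathrm{Cov}),$$

with three covariance models:

| mode | Cov | when |
|---|---|---|
| `plain` | $R/N$ | all SNPs measured on the same cohort, matched panel |
| `overlap` | $R \circ H$, $H_{ii}=1/N_i$, $H_{ij}=N_{s,ij}/(N_iN_j)$ | per-pair shared sample counts known |
| `regularized` | $(R + Na\,I)/N$ applied to $\hat\beta/c$ | overlap unknown (default), double-GC deflation |

`regularized` with $Na=0,c=1$ is numerically identical to `plain`. The
implied correlation of marginal effects under `regularized` is
$R_{ij}/(1+Na)$, a single-knob surrogate for the attenuation that
per-SNP cohort differences produce.

The prior is a truncated Dirichlet-process scale mixture of normals with
an exact point mass: $\beta_i = \eta\gamma_i$,
$\gamma_i \sim \sum_{k=0}^{K-1} p_k N(0,\sigma^2_k)$, $\sigma^2_0 = 0$
fixed, stick-breaking weights $p_k$ with $V_k \sim \mathrm{Beta}(1,\alpha)$,
$\alpha \sim \mathrm{Gamma}(a_\alpha, b_\alpha)$, and base distribution
$\sigma_k \sim \mathrm{Uniform}(0,u)$ on the standard-deviation scale
(so $\sigma_k^2$ is a squared uniform — heavier near zero than an
inverse gamma and bounded, avoiding the informativeness problems of the
conjugate choice). The expansion parameter $\eta \sim N(0, v_\eta)$ is a
pure mixing device; only $\beta=\eta\gamma$ is identified or reported.

## Gibbs sampler

One sweep updates, in fixed order: per block (parallelizable — blocks
are conditionally independent given globals) a sequential scan over SNPs
drawing the component assignment with $\gamma_i$ integrated out and then
$\gamma_i$ from its conjugate normal; then component variances, sticks,
$\alpha$, $\eta$. The likelihood enters only through precomputed
per-block quantities $B = RAR$, $v = RA(\hat\beta/c)$ (with $A$ the
inverse covariance kernel) and a scalar working sample size $\tilde N$
(the median per-SNP $N$ in the block — robust to outlying reported
sizes while the raw per-SNP $N$ still drives QC). The block
log-likelihood is $\tilde N(\beta^\top v - \tfrac12\beta^\top B\beta)$
up to a constant; a unit test verifies this against dense
multivariate-normal log-densities for all three modes.

For SNP $i$, with residual signal
$\rho_i = v_i - \eta\sum_{j\ne i}B_{ij}\gamma_j$ and
$\lambda_k = \tilde N\eta^2B_{ii} + 1/\sigma^2_k$,
$m_k = \tilde N\eta\rho_i/\lambda_k$:

$$\log w_0 = \log p_0,\qquad
\log w_k = \log p_k - \tfrac12\log(\sigma^2_k\lambda_k)
          + \tfrac12\lambda_k m_k^2 .$$

Weights are normalized by max subtraction. Components whose weight is
provably below $e^{-37}$ of the running maximum (using the bound
$\tfrac12\lambda_k m_k^2 \le \tfrac12(\tilde N\eta\rho_i)^2/(\tilde N\eta^2B_{ii})$
and $\sigma^2_k\lambda_k \ge 1$) are skipped — a deterministic, lossless
pruning that makes the $K{=}1000$ default cheap.

The variance conditional for an occupied component is
$\propto (\sigma^2)^{-(n_k+1)/2}\exp(-S_k/2\sigma^2)$ on $(0,u^2]$
($S_k$ the sum of squared member $\gamma$'s): in the precision it is a
Gamma with shape $(n_k-1)/2$, rate $S_k/2$, truncated below at $1/u^2$,
drawn by inverse CDF on the upper tail for numerical precision. The
shape degenerates to 0 for singleton clusters; there the (still proper)
density is inverted through the exponential integral $E_1$ with a
bracketed root search. Empty components are refreshed from the base
distribution.

Sticks: $V_k \sim \mathrm{Beta}(1+n_k,\ \alpha+\sum_{m>k}n_m)$,
$V_{K-1}=1$. Concentration:
$\alpha \sim \mathrm{Gamma}(a_\alpha+K-1,\ b_\alpha-\sum_{k<K-1}\log(1-V_k))$
with each $\log(1-V_k)$ floored at $-30$. Expansion parameter: conjugate
normal with precision $\sum_b \tilde N_b\gamma_b^\top B_b\gamma_b + 1/v_\eta$.

**Randomness.** A master seed spawns one `SeedSequence` substream per
block plus one global substream. Per sweep, each block's uniform and
normal variates are pre-drawn from its own substream and handed to a
numba kernel (GIL released), so thread count cannot change results;
reruns with the same seed are byte-identical. A pure-Python scan with
identical draw semantics backs the kernel and is cross-checked in tests.

**Initialization and divergence guard.** The chain starts at the null
model ($z=0$, $\gamma=0$, $\eta=1$, $\alpha=1$). If any $|\beta|$
exceeds $10^3$ the run aborts with a `DivergenceError` recommending the
regularized likelihood — the characteristic failure of the plain
likelihood under panel/cohort mismatch.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| $K$ (truncation) | 1000 | occupied components are observed to number far below this in both regimes; configurable |
| $u$ (base bound, sd scale) | 1.0 | standardized per-SNP effects are $\ll 1$; effectively uninformative while keeping the truncated conditional proper |
| $a_\alpha, b_\alpha$ | 0.1, 0.1 | weakly informative concentration hyperprior |
| $v_\eta$ | 1.0 | weakly informative; $\eta$ is a mixing device |
| iterations / burn-in | 1000 / 200 | posterior means stabilize well before 1000 sweeps at these problem sizes |
| $Na$ | 0.1 (fit CLI default) | customary robustness level for meta-analysed real traits; 0 for matched simulations |
| $c$ | 1.0 | only lowered when double genomic control demonstrably deflated the input |
| $r^2$ partition threshold | 0.1 | the level at which cross-block correlation becomes ignorable for the block likelihood |
| scan window | max(256 SNPs, 1 Mb) | the scale at which LD is non-negligible in European-ancestry panels |
| max block size | 1024 | bounds the per-block $O(m^3)$ precomputation |
| shrinkage intensity | "auto", floored at 0.05 for $n_\mathrm{ref}\le1000$ | variance-minimizing linear shrinkage; the floor guarantees comfortable positive definiteness for small panels |

LD shrinkage is linear toward the identity,
$(1-\lambda)R + \lambda I$, with "auto"
$\lambda = \sum_{i\ne j}\widehat{\mathrm{Var}}(r_{ij}) / \sum_{i\ne j} r_{ij}^2$
using $\widehat{\mathrm{Var}}(r) = (1-r^2)^2/n$. This is a deliberate
design choice: it preserves the two properties the sampler needs —
positive definiteness (eigenvalues $\ge \lambda$) and damping of
reference-panel noise — with one transparent parameter. Published
empirical-Bayes LD estimators based on genetic-map distances are a
documented alternative the package does not implement.

## QC conventions

In order: drop non-ACGT/INDEL records, drop strand-ambiguous (A/T, G/C)
pairs, drop SNPs with $N$ below 0.67 × the 90th percentile of $N$
(nearest-rank percentile — deterministic at ties), drop the MHC
(chr6:28–34 Mb) when positions are available. For binary traits the
per-SNP $N$ should be the effective sample size
$4N_\mathrm{case}N_\mathrm{control}/(N_\mathrm{case}+N_\mathrm{control})$
(`effective_sample_size`). Allele alignment against the panel flips
signs for swapped pairs and drops anything else; strand-complement
rescue is deliberately not attempted since ambiguous SNPs are already
gone. The panel-side MAF filter defaults to 0.01 (0.05 mirrors common
simulation QC).

## Simulator: what it emulates, what it does not

Genotypes are continuous standardized Gaussians with exact block-diagonal
correlation (AR(1) decay $\rho^{|i-j|}$ or exchangeable within blocks) —
precisely the structure the likelihood assumes, which makes the
generator the right instrument for validating the sampler: any failure
is attributable to the method, not the data. Optional thresholding to
0/1/2 dosages at Hardy–Weinberg quantiles adds hard-call realism (note
thresholding attenuates LD by a known factor — the simulator reports the
true post-thresholding correlations only for the continuous path).
Phenotypes follow $y = X\beta + \epsilon$ with the realized genetic
variance fraction pinned exactly to $h^2$ (the convention of fixed-h²
simulation tools); an expectation-only mode exists for theory checks.

Summary statistics come either from explicit marginal regressions on
configurable per-SNP individual subsets (`marginal_gwas` — this is what
reproduces sample-overlap structure, including misreported $N$), or
directly from $N(R\beta, R/N)$ (`direct_sumstats`), which is orders of
magnitude faster and exact for sampler tests. A replication experiment
in the test suite confirms that regression-based summary statistics
reproduce the $R/N$ covariance under full overlap and the Hadamard
$R\circ H$ covariance under partial overlap.

What the simulator does **not** model: recombination-map LD, allele
frequency spectra, haplotype resampling from real panels, case-control
liability sampling, imputation error. Passing tests therefore
demonstrate correctness of the inference machinery under its own
assumptions, not end-to-end performance on real GWAS.

## Study sizes used by tests and scripts/acceptance.py

Genome-scale runs (hundreds of thousands of SNPs) are replaced by
desk-scale problems chosen to preserve the quantities being tested:
M = 2000 SNPs in 50 AR(1) blocks ($\rho=0.5$), N = 20,000,
$h^2 = 0.5$, 20 causal SNPs for the sparse architecture and all-causal
for the infinitesimal one; oracle comparisons use 5-SNP blocks where
dense enumeration ($2^5$ inclusion patterns × Gaussian integrals) is
exact; the cohort-mismatch experiment regresses half the SNPs on an 80%
subsample of 20,000 individuals while misreporting the full N, mirroring
the bookkeeping that breaks plain-likelihood methods. Monte-Carlo
comparisons use batch-means standard errors (50 batches).

## Degenerate inputs and numerical conventions

* Monomorphic panel columns standardize to zero (and should be removed
  by the MAF filter).
* Covariance kernels are factorized by Cholesky; a single automatic
  $10^{-6}$ ridge retry guards round-off on serialized blocks, logged as
  a warning and counted in the run report.
* Forced partition cuts (blocks at `max_block_size`) choose the cut
  position minimizing the maximum crossing $r^2$, preferring the latest
  position on ties (fewest blocks); cuts whose residual crossing $r^2$
  exceeds the threshold are logged and reported.
* `sample_alpha` guards $\log(1-V)$ at $-30$; stick weights are computed
  in log space.
* The divergence guard bound ($10^3$ on $|\beta|$) is far outside any
  plausible standardized effect, so it only trips on genuine
  misspecification.
* Posterior effects are reported on the $\hat\beta/c$ standardized
  scale; no un-scaling by $c$ is applied after fitting (documented
  choice — $c$ corrects an artifact of the input, not of the output).

## Known limitations

* The DP mixture is exchangeable across SNPs: no functional annotation,
  no allele-frequency-dependent architecture.
* One population, one LD reference; no trans-ethnic modelling.
* The heritability trace is a convergence diagnostic, not an estimator
  with standard errors; `nonzero_freq` is not a calibrated posterior
  inclusion probability.
* `overlap` mode forms and factorizes the full per-block covariance —
  fine at desk scale, quadratic in block size.
* Validation-cohort covariate regression (age, sex, PCs) is left to
  downstream analysis; `score` produces raw standardized-genotype PRS.
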