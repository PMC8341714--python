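"""Synthetic cohorts with the statistical structure the sampler assumes.

The generator covers the effect-size architectures used to benchmark
summary-statistics PRS methods:

* spike-and-slab (scenarios "1A"/"1B"/"1C"): each effect is nonzero with
  probability pi = 1e-4 / 1e-3 / 1e-2 and then N(0, h2/(M pi));
* a point mass plus three normals ("4"): mixture weights
  pi = (1e-4, 1e-4, 1e-2) over variances (1, 0.1, 0.01) * sigma2 with
  sigma2 solved so the expected total heritability equals h2;
* infinitesimal ("5"): every effect N(0, h2/M).

All scenarios satisfy E[sum beta^2] = h2 analytically.

Genotypes are continuous standardized Gaussians with block-diagonal
correlation (AR(1)-decay rho^|i-j| or exchangeable within blocks, zero
across) — exactly the assumptions the likelihood makes, which is what the
sampler tests need; optional thresholding to 0/1/2 dosages at
Hardy-Weinberg quantiles adds hard-call realism. ``marginal_gwas`` runs
per-SNP marginal regressions on configurable individual subsets
(reproducing sample-overlap structure), and ``direct_sumstats`` samples
marginal effects straight from their sampling distribution
N(R beta, R/N) — orders of magnitude faster when no individual-level data
are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .sumstats import SummaryStats

_SCENARIO_PI = {"1A": 1e-4, "1B": 1e-3, "1C": 1e-2}


@dataclass
class ScenarioConfig:
    """Effect-size scenario parameters.

    ``pi`` overrides the scenario default sparsity; ``n_causal`` (exactly
    that many causal SNPs, chosen at random) is a desk-scale alternative
    to a Bernoulli rate.
    """

    scenario: str = "1B"
    M: int = 2000
    h2: float = 0.5
    pi: float | None = None
    n_causal: int | None = None
    c_scales: tuple = (1.0, 0.1, 0.01)
    pi_vec: tuple = (1e-4, 1e-4, 1e-2)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.h2 < 1):
            raise ConfigError("h2 must be in (0, 1)")
        if self.scenario not in {"1A", "1B", "1C", "4", "5", "custom"}:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "4" and sum(self.pi_vec) > 1:
            raise ConfigError("scenario-4 mixture weights exceed 1")


@dataclass
class SimulatedCohort:
    """Individual-level data for one simulated study."""

    X: np.ndarray                 # (n, M) standardized genotypes
    beta: np.ndarray              # true joint effects (standardized scale)
    y: np.ndarray                 # standardized phenotype
    R_blocks: list                # true block correlation matrices
    meta: pd.DataFrame
    h2: float
    cohort_of_snp: np.ndarray | None = None  # mismatch experiments


def default_meta(M: int, chrom: int = 1, spacing: int = 5000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(M)],
            "chrom": chrom,
            "pos": np.arange(1, M + 1) * spacing,
            "a1": "A",
            "a2": "G",
        }
    )


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def exchangeable_correlation(m: int, rho: float) -> np.ndarray:
    return np.full((m, m), rho) + (1 - rho) * np.eye(m)


def simulate_panel(
    n: int,
    block_sizes,
    rho: float = 0.5,
    model: str = "ar1",
    rng: np.random.Generator | None = None,
    maf: float | np.ndarray | None = None,
    discretize: bool = False,
):
    """Standardized genotypes with true block-diagonal correlation.

    Returns ``(X, R_blocks, meta)``. With ``discretize=True`` the latent
    Gaussians are thresholded to dosages 0/1/2 at Hardy-Weinberg quantiles
    for allele frequency ``maf`` and re-standardized.
    """
    rng = rng or np.random.default_rng()
    if not (0 <= rho < 1):
        raise ConfigError("rho must be in [0, 1)")
    cols = []
    R_blocks = []
    for m in block_sizes:
        if model == "ar1":
            # AR recursion: exact rho^|i-j| correlation, O(n m)
            x = np.empty((n, m))
            x[:, 0] = rng.standard_normal(n)
            innov = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                x[:, j] = rho * x[:, j - 1] + innov * rng.standard_normal(n)
            R_blocks.append(ar1_correlation(m, rho))
        elif model == "exchangeable":
            f = rng.standard_normal(n)[:, None]
            x = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((n, m))
            R_blocks.append(exchangeable_correlation(m, rho))
        else:
            raise ConfigError(f"unknown correlation model {model!r}")
        cols.append(x)
    X = np.concatenate(cols, axis=1)
    M = X.shape[1]
    if discretize:
        f = np.broadcast_to(
            np.asarray(maf if maf is not None else 0.3, dtype=float), (M,)
        )
        # genotype = (latent > q1) + (latent > q2): HWE probabilities
        q2 = stats.norm.ppf(1.0 - f * f)            # P(2) = f^2
        q1 = stats.norm.ppf((1.0 - f) ** 2)         # P(0) = (1-f)^2
        X = (X > q1).astype(float) + (X > q2)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    return X, R_blocks, default_meta(M)


def simulate_effects(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw true effects for a scenario; E[sum beta^2] = h2 by construction."""
    M, h2 = cfg.M, cfg.h2
    beta = np.zeros(M)
    if cfg.scenario in _SCENARIO_PI or (
        cfg.scenario == "custom" and (cfg.pi is not None or cfg.n_causal is not None)
    ):
        pi = cfg.pi if cfg.pi is not None else _SCENARIO_PI.get(cfg.scenario)
        if cfg.n_causal is not None:
            idx = rng.choice(M, size=cfg.n_causal, replace=False)
            var = h2 / cfg.n_causal
        else:
            if pi is None or not (0 < pi <= 1):
                raise ConfigError("sparse scenario needs pi in (0, 1] or n_causal")
            mask = rng.random(M) < pi
            idx = np.where(mask)[0]
            var = h2 / (M * pi)
        beta[idx] = rng.normal(0.0, np.sqrt(var), size=len(idx))
    elif cfg.scenario == "4":
        pis = np.asarray(cfg.pi_vec, dtype=float)
        cs = np.asarray(cfg.c_scales, dtype=float)
        sigma2 = h2 / (M * float(pis @ cs))
        u = rng.random(M)
        edges = np.concatenate([[0.0], np.cumsum(pis)])
        for comp in range(len(pis)):
            sel = (u >= edges[comp]) & (u < edges[comp + 1])
            beta[sel] = rng.normal(0.0, np.sqrt(cs[comp] * sigma2), size=int(sel.sum()))
    elif cfg.scenario == "5":
        beta = rng.normal(0.0, np.sqrt(h2 / M), size=M)
    else:
        raise ConfigError(f"scenario {cfg.scenario!r} needs pi or n_causal")
    return beta


def simulate_phenotype(
    X: np.ndarray,
    beta: np.ndarray,
    h2: float,
    rng: np.random.Generator,
    exact: bool = True,
):
    """Phenotype y = X beta + eps, standardized.

    With ``exact=True`` (the convention of fixed-h2 simulation tools) the
    genetic values are rescaled so the realized sample variance fraction
    is exactly h2 and the noise is orthogonalized against them; the
    returned ``beta_realized`` is the correspondingly rescaled truth.
    With ``exact=False`` eps ~ N(0, var(X beta)(1-h2)/h2) and only the
    expectation is controlled.
    """
    g = X @ beta
    vg = g.var()
    n = X.shape[0]
    if h2 == 0 or vg == 0:
        if np.any(beta) and h2 == 0:
            import warnings

            warnings.warn("h2 = 0 with nonzero effects: phenotype is pure noise")
        e = rng.standard_normal(n)
        y = (e - e.mean()) / e.std()
        return y, np.zeros_like(beta)
    if exact:
        scale = np.sqrt(h2 / vg)
        gs = g * scale
        e = rng.standard_normal(n)
        e = e - e.mean()
        gc = g - g.mean()
        e = e - (e @ gc) / (gc @ gc) * gc  # exactly uncorrelated noise
        e = e / e.std() * np.sqrt(1.0 - h2)
        y = gs + e
        y = y - y.mean()
        return y, beta * scale
    eps = rng.normal(0.0, np.sqrt(vg * (1.0 - h2) / h2), size=n)
    y = g + eps
    s = y.std()
    y = (y - y.mean()) / s
    return y, beta / s


def marginal_gwas(
    X: np.ndarray,
    y: np.ndarray,
    meta: pd.DataFrame | None = None,
    subset_of_snp: np.ndarray | None = None,
    subsets: dict | None = None,
    reported_n=None,
) -> SummaryStats:
    """Per-SNP marginal regression summary statistics.

    Parameters
    ----------
    subset_of_snp, subsets
        Per-SNP group labels and a mapping group -> row indices; each
        SNP's regression runs on its group's individuals (standardizing X
        and y within the subset). Default: the full sample for every SNP.
    reported_n
        ``None`` records the true per-SNP regression sample size;
        a scalar or array misreports N (the bookkeeping mismatch that
        breaks the plain likelihood when cohorts differ per SNP).
    """
    n, M = X.shape
    if meta is None:
        meta = default_meta(M)
    beta_hat = np.empty(M)
    n_used = np.empty(M)
    if subset_of_snp is None:
        ys = (y - y.mean()) / y.std()
        Xs = X - X.mean(axis=0)
        sd = Xs.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = Xs / sd
        beta_hat = (Xs.T @ ys) / n
        n_used[:] = n
    else:
        groups = {}
        for g, rows in subsets.items():
            rows = np.asarray(rows)
            if len(rows) < 2:
                raise InputError(f"subset {g!r} has fewer than 2 individuals")
            yg = y[rows]
            yg = (yg - yg.mean()) / yg.std()
            groups[g] = (rows, yg)
        for g in np.unique(subset_of_snp):
            rows, yg = groups[g]
            sel = subset_of_snp == g
            Xg = X[np.ix_(rows, np.where(sel)[0])]
            Xg = Xg - Xg.mean(axis=0)
            sd = Xg.std(axis=0)
            sd[sd == 0] = 1.0
            Xg = Xg / sd
            beta_hat[sel] = (Xg.T @ yg) / len(rows)
            n_used[sel] = len(rows)
    if reported_n is not None:
        n_rep = np.broadcast_to(np.asarray(reported_n, dtype=float), (M,)).copy()
    else:
        n_rep = n_used
    zscores = beta_hat * np.sqrt(n_rep)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(zscores)), 1e-300, 1.0)
    df = meta.copy()
    df["beta_hat"] = beta_hat
    df["n"] = n_rep
    df["pval"] = pvals
    return SummaryStats(df)


def direct_sumstats(
    R_blocks,
    beta: np.ndarray,
    N: float,
    rng: np.random.Generator,
    meta: pd.DataFrame | None = None,
) -> SummaryStats:
    """Sample marginal effects directly from N(R beta, R/N), block-wise."""
    M = len(beta)
    if meta is None:
        meta = default_meta(M)
    beta_hat = np.empty(M)
    s = 0
    for R in R_blocks:
        m = len(R)
        L = np.linalg.cholesky(R)
        mean = R @ beta[s : s + m]
        beta_hat[s : s + m] = mean + (L @ rng.standard_normal(m)) / np.sqrt(N)
        s += m
    if s != M:
        raise InputError("R blocks do not cover the effect vector")
    zscores = beta_hat * np.sqrt(N)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(zscores)), 1e-300, 1.0)
    df = meta.copy()
    df["beta_hat"] = beta_hat
    df["n"] = float(N)
    df["pval"] = pvals
    return SummaryStats(df)


def simulate_study(
    cfg: ScenarioConfig,
    n_train: int,
    block_sizes,
    rho: float = 0.5,
    model: str = "ar1",
    exact_h2: bool = True,
    discretize: bool = False,
    maf: float = 0.3,
) -> SimulatedCohort:
    """Full individual-level study: genotypes, effects, phenotype."""
    rng = np.random.default_rng(cfg.seed)
    if sum(block_sizes) != cfg.M:
        raise ConfigError("block sizes must sum to M")
    X, R_blocks, meta = simulate_panel(
        n_train, block_sizes, rho=rho, model=model, rng=rng,
        discretize=discretize, maf=maf,
    )
    beta = simulate_effects(cfg, rng)
    y, beta_real = simulate_phenotype(X, beta, cfg.h2, rng, exact=exact_h2)
    return SimulatedCohort(
        X=X, beta=beta_real, y=y, R_blocks=R_blocks, meta=meta, h2=cfg.h2
    )


def mismatch_sumstats(
    cohort: SimulatedCohort,
    subsample_fraction: float = 0.8,
    affected_fraction: float = 0.5,
    misreport: bool = True,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Summary statistics with per-SNP cohort mismatch.

    A random ``affected_fraction`` of SNPs get their marginal regression
    computed on the first ``subsample_fraction`` of individuals while
    (with ``misreport=True``) still reporting the full sample size — the
    situation in which the plain likelihood overstates the correlation of
    marginal effects between mixed pairs by 1/sqrt(subsample_fraction)
    relative to truth.
    """
    rng = rng or np.random.default_rng(0)
    n, M = cohort.X.shape
    n_sub = int(round(subsample_fraction * n))
    affected = rng.random(M) < affected_fraction
    subset_of_snp = np.where(affected, 1, 0)
    subsets = {0: np.arange(n), 1: np.arange(n_sub)}
    reported = float(n) if misreport else None
    ss = marginal_gwas(
        cohort.X, cohort.y, cohort.meta,
        subset_of_snp=subset_of_snp, subsets=subsets, reported_n=reported,
    )
    cohort.cohort_of_snp = subset_of_snp
    return ss
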