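"""Blocked Gibbs sampler for the truncated Dirichlet-process mixture prior.

Model, per SNP i: beta_i = eta * gamma_i, gamma_i ~ sum_k p_k N(0, sigma2_k)
with sigma2_0 = 0 fixed (exact point mass: Bayesian variable selection),
stick-breaking weights p_k = V_k prod_{m<k} (1 - V_m), V_k ~ Beta(1, alpha),
and component variances drawn from the square of a Uniform(0, u) draw on
the standard-deviation scale. The multiplicative overparametrization
beta = eta * gamma is a parameter-expansion device that improves mixing;
only beta is identified and reported.

The likelihood enters through per-block quadratics (B, v, ntilde) from
:mod:`dpprs.likelihood`; blocks are conditionally independent given the
global parameters, so the per-block scans can run in parallel. Randomness
is organised as one substream per block plus one global substream, all
spawned from the master seed, making results independent of thread count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats, optimize

from .errors import ConfigError, NumericalError

_LOG_SKIP = 37.0
_LOG1M_V_FLOOR = -30.0  # guard for log(1 - V) with V ~ 1


@dataclass
class DPPrior:
    """Hyperparameters of the truncated DP mixture prior.

    Parameters
    ----------
    K : int
        Truncation level (number of mixture components including the null).
    u : float
        Upper bound of the Uniform(0, u) base distribution on the
        standard-deviation scale; component variances live in (0, u^2].
    alpha_shape, alpha_rate : float
        Gamma hyperprior on the concentration parameter alpha.
    eta_prior_var : float
        Prior variance of the expansion parameter eta ~ N(0, eta_prior_var).
    fixed_sigma2, fixed_weights, fix_eta
        Diagnostic controls that freeze parts of the model (used by oracle
        tests and oracle fits with known hyperparameters); all None/False
        for a normal run.
    """

    K: int = 1000
    u: float = 1.0
    alpha_shape: float = 0.1
    alpha_rate: float = 0.1
    eta_prior_var: float = 1.0
    fixed_sigma2: np.ndarray | None = None
    fixed_weights: np.ndarray | None = None
    fix_eta: bool = False

    def __post_init__(self):
        if self.K < 2:
            raise ConfigError("K must be >= 2")
        if self.u <= 0:
            raise ConfigError("u must be > 0")
        if self.fixed_sigma2 is not None:
            self.fixed_sigma2 = np.asarray(self.fixed_sigma2, dtype=float)
            if self.fixed_sigma2.shape[0] != self.K or self.fixed_sigma2[0] != 0:
                raise ConfigError("fixed_sigma2 must have length K with [0] == 0")
        if self.fixed_weights is not None:
            self.fixed_weights = np.asarray(self.fixed_weights, dtype=float)
            if self.fixed_weights.shape[0] != self.K or not math.isclose(
                self.fixed_weights.sum(), 1.0, abs_tol=1e-9
            ):
                raise ConfigError("fixed_weights must have length K and sum to 1")


@dataclass
class MCMCConfig:
    n_iter: int = 1000
    burn_in: int = 200
    thin: int = 1
    seed: int = 0
    n_threads: int = 1

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ConfigError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")


@dataclass
class DPState:
    """Full MCMC state."""

    z: np.ndarray        # per-SNP component assignment
    gamma: np.ndarray    # per-SNP expanded effect
    eta: float
    sigma2: np.ndarray   # per-component variance, sigma2[0] == 0
    V: np.ndarray        # stick proportions, V[K-1] == 1
    p: np.ndarray        # component weights
    logp: np.ndarray
    alpha: float

    @property
    def beta(self) -> np.ndarray:
        return self.eta * self.gamma

    @property
    def K(self) -> int:
        return self.sigma2.shape[0]


def stick_weights(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weights p_k = V_k prod_{m<k}(1 - V_m) and their logs."""
    with np.errstate(divide="ignore"):
        log1mV = np.log1p(-np.clip(V, 0.0, 1.0))
        logp = np.log(V) + np.concatenate(([0.0], np.cumsum(log1mV[:-1])))
    p = np.exp(logp)
    return p, logp


def init_state(n_snps: int, prior: DPPrior, rng: np.random.Generator) -> DPState:
    """Null-model initialization: all SNPs in the point-mass component."""
    K = prior.K
    if prior.fixed_sigma2 is not None:
        sigma2 = prior.fixed_sigma2.copy()
    else:
        sigma2 = np.concatenate(([0.0], rng.uniform(0, prior.u, K - 1) ** 2))
    if prior.fixed_weights is not None:
        p = prior.fixed_weights.copy()
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        V = np.full(K, np.nan)
    else:
        V = rng.beta(1.0, 1.0, K)  # alpha starts at 1
        V[K - 1] = 1.0
        p, logp = stick_weights(V)
    return DPState(
        z=np.zeros(n_snps, dtype=np.int64),
        gamma=np.zeros(n_snps),
        eta=1.0,
        sigma2=sigma2,
        V=V,
        p=p,
        logp=logp,
        alpha=1.0,
    )


# ---------------------------------------------------------------------------
# per-SNP / per-block updates


def sample_assignment_and_gamma(
    i, B, v, ntilde, eta, logp, sigma2, gamma, u, zdraw, r=None
):
    """Reference (pure Python) update for one SNP; mirrors the numba kernel.

    ``u`` and ``zdraw`` are the pre-drawn Uniform(0,1) and N(0,1) variates.
    Returns (z_i, gamma_i). ``r`` may pass a precomputed B @ gamma row sum.
    """
    K = logp.shape[0]
    a = ntilde * eta * eta * B[i, i]
    if r is None:
        ri = float(B[i] @ gamma)
    else:
        ri = r[i]
    rho = v[i] - eta * (ri - B[i, i] * gamma[i])
    t = ntilde * eta * rho
    gain = 0.5 * t * t / a if a > 0.0 else 0.0
    lw = np.empty(K)
    lw[0] = logp[0]
    mx = lw[0]
    for k in range(1, K):
        if logp[k] + gain < mx - _LOG_SKIP:
            lw[k] = -np.inf
            continue
        lam = a + 1.0 / sigma2[k]
        mk = t / lam
        val = logp[k] - 0.5 * math.log(sigma2[k] * lam) + 0.5 * lam * mk * mk
        lw[k] = val
        if val > mx:
            mx = val
    if not np.isfinite(mx):
        raise NumericalError(f"non-finite assignment weights at SNP {i}")
    w = np.where(np.isneginf(lw), 0.0, np.exp(lw - mx))
    tot = w.sum()
    target = u * tot
    acc = 0.0
    knew = 0
    for k in range(K):
        acc += w[k]
        if acc >= target:
            knew = k
            break
    if knew == 0:
        gnew = 0.0
    else:
        lam = a + 1.0 / sigma2[knew]
        gnew = t / lam + zdraw / math.sqrt(lam)
    return knew, gnew


def block_scan_python(B, v, ntilde, eta, logp, sigma2, z, gamma, u01, zstd):
    """Sequential scan over a block; same contract as the numba kernel."""
    m = B.shape[0]
    r = B @ gamma
    for i in range(m):
        knew, gnew = sample_assignment_and_gamma(
            i, B, v, ntilde, eta, logp, sigma2, gamma, u01[i], zstd[i], r=r
        )
        gold = gamma[i]
        z[i] = knew
        if gnew != gold:
            gamma[i] = gnew
            r += B[:, i] * (gnew - gold)


# ---------------------------------------------------------------------------
# global updates


def _trunc_invgamma(nk: int, S: float, u2: float, uquant: float) -> float:
    """Inverse-CDF draw from the cluster-variance conditional.

    Density on sigma2 = x: x^{-(nk+1)/2} exp(-S / 2x) on (0, u^2]; in the
    precision t = 1/x this is Gamma(shape (nk-1)/2, rate S/2) truncated to
    t >= 1/u^2. The shape is 0 at nk = 1, where the (still proper, because
    the support is bounded below) density is inverted through the
    exponential integral E1.
    """
    a = (nk - 1) / 2.0
    b = max(S / 2.0, 1e-300)
    tmin = 1.0 / u2
    if a > 0:
        upper = stats.gamma.sf(tmin, a, scale=1.0 / b)  # P(T > tmin)
        if upper <= 0:
            # all usable mass below tmin: return the boundary
            return u2
        # map uquant in [0,1) across the truncated upper tail
        t = stats.gamma.isf(upper * (1.0 - uquant), a, scale=1.0 / b)
    else:
        # survival S(t) = E1(b t) / E1(b tmin)
        e_lo = special.exp1(b * tmin)
        if e_lo <= 0 or not np.isfinite(e_lo):
            return u2
        targ = e_lo * (1.0 - uquant)

        def f(logt):
            return special.exp1(b * math.exp(logt)) - targ

        lo = math.log(tmin)
        hi = lo
        for _ in range(200):
            hi += 2.0
            if f(hi) <= 0:
                break
        if f(lo) < 0:  # uquant ~ 0 edge
            return u2
        logt = optimize.brentq(f, lo, hi, xtol=1e-12)
        t = math.exp(logt)
    t = max(t, tmin)
    return 1.0 / t


def sample_cluster_variances(
    z: np.ndarray, gamma: np.ndarray, prior: DPPrior, rng: np.random.Generator
) -> np.ndarray:
    """Draw sigma2_k for k >= 1; empty components from the base distribution."""
    K = prior.K
    u2 = prior.u ** 2
    counts = np.bincount(z, minlength=K)
    S = np.bincount(z, weights=gamma ** 2, minlength=K)
    sigma2 = np.empty(K)
    sigma2[0] = 0.0
    uq = rng.random(K - 1)
    for k in range(1, K):
        if counts[k] > 0:
            sigma2[k] = _trunc_invgamma(int(counts[k]), float(S[k]), u2, uq[k - 1])
        else:
            sigma2[k] = (prior.u * uq[k - 1]) ** 2
    if np.any(sigma2[1:] <= 0) or np.any(sigma2[1:] > u2 * (1 + 1e-12)):
        raise AssertionError("cluster variance left the base support (0, u^2]")
    return np.minimum(sigma2, u2)


def sample_sticks(
    counts: np.ndarray, alpha: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """V_k ~ Beta(1 + n_k, alpha + sum_{m>k} n_m); V_{K-1} = 1."""
    K = counts.shape[0]
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    V = rng.beta(1.0 + counts, alpha + tail)
    V[K - 1] = 1.0
    p, logp = stick_weights(V)
    return V, p, logp


def sample_alpha(V: np.ndarray, prior: DPPrior, rng: np.random.Generator) -> float:
    """alpha ~ Gamma(shape + K - 1, rate - sum_{k<K-1} log(1 - V_k))."""
    K = V.shape[0]
    with np.errstate(divide="ignore"):
        terms = np.log1p(-V[: K - 1])
    terms = np.maximum(terms, _LOG1M_V_FLOOR)
    shape = prior.alpha_shape + K - 1
    rate = prior.alpha_rate - terms.sum()
    return float(rng.gamma(shape, 1.0 / rate))


def sample_eta(
    quads, gamma: np.ndarray, prior: DPPrior, rng: np.random.Generator
) -> float:
    """Conjugate normal update of the expansion parameter eta.

    Likelihood terms are linear/quadratic in eta:
    precision = sum_b ntilde_b gamma_b' B_b gamma_b + 1/eta_prior_var,
    mean = s2 * sum_b ntilde_b gamma_b' v_b.
    """
    prec = 1.0 / prior.eta_prior_var
    lin = 0.0
    for (s, e), B, v, nt in zip(quads.bounds, quads.B, quads.v, quads.ntilde):
        g = gamma[s:e]
        if np.any(g):
            prec += nt * float(g @ (B @ g))
            lin += nt * float(g @ v)
    s2 = 1.0 / prec
    return float(rng.normal(s2 * lin, math.sqrt(s2)))


# ---------------------------------------------------------------------------
# sweeps


def gibbs_sweep(
    quads,
    state: DPState,
    prior: DPPrior,
    block_rngs,
    global_rng,
    n_threads: int = 1,
    use_numba: bool = True,
):
    """One full iteration: per-block scans, then global conditionals.

    The scans mutate ``state.z`` / ``state.gamma`` in place; they are
    conditionally independent across blocks given the global parameters,
    so thread-level parallelism never changes the result (each block
    consumes only its own pre-drawn variates).
    """
    if use_numba:
        from ._kernels import block_scan as scan
    else:
        scan = block_scan_python

    draws = []
    for rng_b, (s, e) in zip(block_rngs, quads.bounds):
        m = e - s
        draws.append((rng_b.random(m), rng_b.standard_normal(m)))

    def run_block(b):
        s, e = quads.bounds[b]
        u01, zstd = draws[b]
        scan(
            quads.B[b],
            quads.v[b],
            quads.ntilde[b],
            state.eta,
            state.logp,
            state.sigma2,
            state.z[s:e],
            state.gamma[s:e],
            u01,
            zstd,
        )

    if n_threads > 1 and len(quads.bounds) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=n_threads) as ex:
            list(ex.map(run_block, range(len(quads.bounds))))
    else:
        for b in range(len(quads.bounds)):
            run_block(b)

    if prior.fixed_sigma2 is None:
        state.sigma2 = sample_cluster_variances(state.z, state.gamma, prior, global_rng)
    if prior.fixed_weights is None:
        counts = np.bincount(state.z, minlength=prior.K).astype(float)
        state.V, state.p, state.logp = sample_sticks(counts, state.alpha, global_rng)
        state.alpha = sample_alpha(state.V, prior, global_rng)
    if not prior.fix_eta:
        state.eta = sample_eta(quads, state.gamma, prior, global_rng)
    return state
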