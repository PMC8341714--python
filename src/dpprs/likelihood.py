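"""Likelihood variants linking marginal GWAS effects to joint effects.

With standardized genotypes and phenotype, the marginal effects beta_hat
within an LD block are multivariate normal around ``R beta``. Three
covariance models are supported:

``plain``
    Cov = R / N. Exact when every SNP was measured on the same N
    individuals and the reference R matches the GWAS cohort.
``overlap``
    Cov = R o H (Hadamard), H_ii = 1/N_i, H_ij = N_s,ij / (N_i N_j) with
    N_s,ij the number of individuals shared between the two SNPs' cohorts.
    Exact under partial sample overlap (e.g. multi-array meta-analyses).
``regularized``
    Cov = (R + aN I) / N applied to beta_hat / c. The implied correlation
    between marginal effects is R_ij / (1 + aN): a one-knob robust
    surrogate for unknown overlap structure, which also guards against
    double genomic control deflation through the input scaling c.
    aN = 0, c = 1 reduces exactly to ``plain``.

The sampler never sees these covariances directly; it consumes, per block,
B = R A R and v = R A (beta_hat / c) with A the inverse covariance kernel,
so that the log-likelihood is N~ (beta' v - beta' B beta / 2) + const.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ConfigError, InputError, NumericalError

logger = logging.getLogger(__name__)

MODES = ("plain", "regularized", "overlap")


@dataclass
class LikelihoodSpec:
    """Which likelihood is in force, and its parameters.

    Parameters
    ----------
    mode : {"regularized", "plain", "overlap"}
    aN : float
        Regularizer on the covariance kernel (regularized mode); the
        product "N times a". 0.1 is the customary real-data default.
    c : float
        Input scaling: beta_hat is divided by c before fitting (corrects
        deflation from double genomic control).
    overlap_labels : array of per-SNP cohort/array labels (overlap mode).
    overlap_ns : dict mapping (label_i, label_j) -> shared sample count.
        Symmetrized automatically; same-label pairs default to
        min(N_i, N_j) when not listed.
    """

    mode: str = "regularized"
    aN: float = 0.1
    c: float = 1.0
    overlap_labels: np.ndarray | None = None
    overlap_ns: dict | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"likelihood mode must be one of {MODES}")
        if self.aN < 0:
            raise ConfigError("aN must be >= 0")
        if self.c <= 0:
            raise ConfigError("c must be > 0")
        if self.mode == "overlap" and (
            self.overlap_labels is None or self.overlap_ns is None
        ):
            raise ConfigError("overlap mode requires overlap_labels and overlap_ns")

    def shared_n(self, label_i, label_j, n_i: float, n_j: float) -> float:
        if label_i == label_j and (label_i, label_j) not in self.overlap_ns:
            return min(n_i, n_j)
        key = (
            (label_i, label_j)
            if (label_i, label_j) in self.overlap_ns
            else (label_j, label_i)
        )
        ns = float(self.overlap_ns.get(key, 0.0))
        if ns > min(n_i, n_j):
            raise InputError(
                f"shared count {ns} exceeds min sample size for labels "
                f"({label_i}, {label_j})"
            )
        return ns


def overlap_entry(n_i: float, n_j: float, n_s: float) -> float:
    """Entry of the overlap covariance multiplier H for a SNP pair.

    1/N_i on the diagonal; N_s / (N_i N_j) off it. Full overlap
    (N_s = N_i = N_j = N) recovers the plain 1/N scale; disjoint cohorts
    (N_s = 0) make marginal effects uncorrelated given the true effects.
    """
    if n_i <= 0 or n_j <= 0:
        raise InputError("sample sizes must be positive")
    if n_s > min(n_i, n_j):
        raise InputError("shared count cannot exceed either sample size")
    if n_s < 0:
        raise InputError("shared count cannot be negative")
    return n_s / (n_i * n_j)


def effective_correlation(r_ij: float, aN: float) -> float:
    """Correlation of marginal effects implied by the regularized model:
    R_ij / (1 + aN)."""
    return r_ij / (1.0 + aN)


def rescale_input(beta_hat: np.ndarray, c: float) -> np.ndarray:
    """Divide marginal effects by the deflation constant c."""
    if c <= 0:
        raise ConfigError("c must be > 0")
    return np.asarray(beta_hat, dtype=float) / c


@dataclass
class BlockQuadratics:
    """Per-block quantities consumed by the Gibbs sampler.

    For each block b: ``B[b]`` (m x m, symmetric PSD), ``v[b]`` (m,),
    ``ntilde[b]`` (scalar working sample size), plus the reference
    correlation ``R[b]`` kept for the heritability diagnostic. The
    block log-likelihood is ntilde * (beta' v - beta' B beta / 2) + const.
    """

    B: list
    v: list
    ntilde: list
    R: list
    bounds: list
    ridge_retries: int = 0

    @property
    def n_snps(self) -> int:
        return sum(len(x) for x in self.v)


def _spd_inverse_apply(kernel: np.ndarray, rhs: np.ndarray, context: str):
    """Solve kernel @ X = rhs via Cholesky, with a single 1e-6 ridge retry."""
    try:
        cho = scipy.linalg.cho_factor(kernel, lower=True)
        return scipy.linalg.cho_solve(cho, rhs), 0
    except np.linalg.LinAlgError:
        pass
    except scipy.linalg.LinAlgError:  # pragma: no cover - alias on some scipy
        pass
    logger.warning("Cholesky failed for %s; retrying with 1e-6 ridge", context)
    kernel = kernel + 1e-6 * np.eye(len(kernel))
    try:
        cho = scipy.linalg.cho_factor(kernel, lower=True)
        return scipy.linalg.cho_solve(cho, rhs), 1
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise NumericalError(f"covariance kernel not positive definite ({context})") from exc


def build_block_quadratics(ldref, ss, spec: LikelihoodSpec) -> BlockQuadratics:
    """Precompute (B, v, ntilde) per block for the active likelihood.

    Requires ``ss`` aligned to ``ldref`` SNP order (same ids, same effect
    alleles). The working sample size ntilde is the median per-SNP N in
    the block.
    """
    if len(ss) != ldref.n_snps or not np.array_equal(
        ss.df["snp_id"].to_numpy(), ldref.meta["snp_id"].to_numpy()
    ):
        raise InputError("summary statistics are not aligned to the LD reference")
    beta = rescale_input(ss.beta_hat, spec.c)
    nvec = ss.n
    labels = (
        np.asarray(spec.overlap_labels) if spec.overlap_labels is not None else None
    )
    if labels is not None and len(labels) != len(ss):
        raise InputError("overlap_labels length does not match SNP count")

    Bs, vs, ns, retries = [], [], [], 0
    for (s, e), R in zip(ldref.partition.bounds, ldref.blocks):
        b = beta[s:e]
        nt = float(np.median(nvec[s:e]))
        if spec.mode == "plain":
            B, v = R.copy(), b.copy()
        elif spec.mode == "regularized":
            kernel = R + spec.aN * np.eye(len(R))
            rhs = np.concatenate([R, b[:, None]], axis=1)
            sol, r = _spd_inverse_apply(kernel, rhs, f"block [{s},{e})")
            retries += r
            A_R, A_b = sol[:, :-1], sol[:, -1]
            B = R @ A_R
            B = 0.5 * (B + B.T)
            v = R @ A_b
        else:  # overlap: exact Eq-(5) covariance, rescaled so ntilde cancels
            nb = nvec[s:e]
            lb = labels[s:e]
            m = e - s
            H = np.empty((m, m))
            for i in range(m):
                H[i, i] = 1.0 / nb[i]
                for j in range(i + 1, m):
                    ns_ij = spec.shared_n(lb[i], lb[j], nb[i], nb[j])
                    H[i, j] = H[j, i] = overlap_entry(nb[i], nb[j], ns_ij)
            C = R * H
            rhs = np.concatenate([R, b[:, None]], axis=1)
            sol, r = _spd_inverse_apply(C, rhs, f"block [{s},{e}) overlap")
            retries += r
            B = (R @ sol[:, :-1]) / nt
            B = 0.5 * (B + B.T)
            v = (R @ sol[:, -1]) / nt
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(v))):
            raise NumericalError(f"non-finite quadratics in block [{s},{e})")
        Bs.append(B)
        vs.append(v)
        ns.append(nt)
    return BlockQuadratics(
        B=Bs, v=vs, ntilde=ns, R=list(ldref.blocks), bounds=list(ldref.partition.bounds),
        ridge_retries=retries,
    )
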