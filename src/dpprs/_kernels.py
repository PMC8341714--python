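"""Numba kernel for the within-block assignment/effect scan.

All randomness is pre-drawn in numpy (one uniform and one standard normal
per SNP per sweep, from that block's dedicated substream) and passed in,
so results are bit-reproducible regardless of thread count and the kernel
can run with the GIL released.
"""

import math

import numpy as np
from numba import njit

_NEG_INF = -np.inf
# relative log-weight below which a component's contribution is provably
# negligible (exp(-37) ~ 8.5e-17, below double epsilon relative to the max)
_LOG_SKIP = 37.0


@njit(cache=True, nogil=True)
def block_scan(B, v, ntilde, eta, logp, sigma2, z, gamma, u01, zstd):
    """One sequential pass over a block's SNPs.

    Updates ``z`` (component assignments) and ``gamma`` in place. For SNP i
    with residual signal rho_i = v_i - eta * sum_{j != i} B_ij gamma_j, the
    component posterior uses gamma integrated out:

        log w_0 = log p_0
        log w_k = log p_k - log(sigma2_k * lambda_k)/2 + lambda_k m_k^2 / 2,
        lambda_k = ntilde eta^2 B_ii + 1/sigma2_k,  m_k = ntilde eta rho_i / lambda_k

    then gamma_i = 0 (k = 0) or a draw from N(m_k, 1/lambda_k).
    """
    m = B.shape[0]
    K = logp.shape[0]
    r = B @ gamma
    lw = np.empty(K)
    for i in range(m):
        a = ntilde * eta * eta * B[i, i]
        rho = v[i] - eta * (r[i] - B[i, i] * gamma[i])
        t = ntilde * eta * rho
        gain = 0.5 * t * t / a if a > 0.0 else 0.0
        lw[0] = logp[0]
        mx = lw[0]
        for k in range(1, K):
            # sound skip: lw[k] <= logp[k] + gain, and mx only grows
            if logp[k] + gain < mx - _LOG_SKIP:
                lw[k] = _NEG_INF
                continue
            lam = a + 1.0 / sigma2[k]
            mk = t / lam
            val = logp[k] - 0.5 * math.log(sigma2[k] * lam) + 0.5 * lam * mk * mk
            lw[k] = val
            if val > mx:
                mx = val
        tot = 0.0
        for k in range(K):
            if lw[k] == _NEG_INF:
                lw[k] = 0.0
            else:
                lw[k] = math.exp(lw[k] - mx)
                tot += lw[k]
        target = u01[i] * tot
        acc = 0.0
        knew = 0
        for k in range(K):
            acc += lw[k]
            if acc >= target:
                knew = k
                break
        gold = gamma[i]
        if knew == 0:
            gnew = 0.0
        else:
            lam = a + 1.0 / sigma2[knew]
            gnew = t / lam + zstd[i] / math.sqrt(lam)
        z[i] = knew
        if gnew != gold:
            gamma[i] = gnew
            for jj in range(m):
                r[jj] += B[jj, i] * (gnew - gold)
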