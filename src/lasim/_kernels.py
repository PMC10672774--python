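"""Numba-compiled observation-level likelihood kernel.

The binomial-probit log-likelihood and its gradients with respect to the
per-pair (mu, log sigma) and the adrenaline slope are accumulated in one
fused loop; this is the hot path of the NUTS gradient.  Falls back to a
numpy implementation when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False


def _py_obs_loglik_grad(mu, sigma, adr, obs_pair, obs_t, obs_vadr, score, miss,
                        log_binom, n_pairs):
    from scipy.special import log_ndtr

    c = 100.0 - (1.0 - adr * obs_vadr) * obs_t
    sig = sigma[obs_pair]
    z = (c - mu[obs_pair]) / sig
    la = log_ndtr(-z)
    lb = log_ndtr(z)
    lpdf = -0.5 * z * z - _LOG_SQRT_2PI
    logp = float(np.sum(log_binom + score * la + miss * lb))
    g_z = -score * np.exp(lpdf - la) + miss * np.exp(lpdf - lb)
    g_mu = np.bincount(obs_pair, weights=-g_z / sig, minlength=n_pairs)
    g_lsig = np.bincount(obs_pair, weights=-g_z * z, minlength=n_pairs)
    g_adr = float(np.sum(g_z * obs_vadr * obs_t / sig))
    return logp, g_mu, g_lsig, g_adr


if _HAVE_NUMBA:

    @numba.njit(cache=True, inline="always")
    def _log_tail(a: float) -> float:
        """log Phi(-a) for a >= 0 (log of the small upper tail)."""
        if a < 30.0:
            return math.log(0.5 * math.erfc(a / _SQRT2))
        # asymptotic Mills-ratio expansion beyond erfc's useful range
        z2 = a * a
        z4 = z2 * z2
        return (
            -0.5 * z2
            - _LOG_SQRT_2PI
            - math.log(a)
            + math.log1p(-1.0 / z2 + 3.0 / z4 - 15.0 / (z4 * z2))
        )

    @numba.njit(cache=True)
    def _nb_obs_loglik_grad(mu, sigma, adr, obs_pair, obs_t, obs_vadr, score, miss,
                            log_binom, n_pairs):
        logp = 0.0
        g_mu = np.zeros(n_pairs)
        g_lsig = np.zeros(n_pairs)
        g_adr = 0.0
        for o in range(obs_t.size):
            p = obs_pair[o]
            c = 100.0 - (1.0 - adr * obs_vadr[o]) * obs_t[o]
            sig = sigma[p]
            z = (c - mu[p]) / sig
            # one small-tail evaluation; the complementary side via log1p
            if z >= 0.0:
                la = _log_tail(z)       # log Phi(-z), the small side
                lb = math.log1p(-math.exp(la))
            else:
                lb = _log_tail(-z)      # log Phi(z), the small side
                la = math.log1p(-math.exp(lb))
            lpdf = -0.5 * z * z - _LOG_SQRT_2PI
            s = score[o]
            m = miss[o]
            logp += log_binom[o] + s * la + m * lb
            g_z = 0.0
            if s != 0.0:
                g_z -= s * math.exp(lpdf - la)
            if m != 0.0:
                g_z += m * math.exp(lpdf - lb)
            g_mu[p] += -g_z / sig
            g_lsig[p] += -g_z * z
            g_adr += g_z * obs_vadr[o] * obs_t[o] / sig
        return logp, g_mu, g_lsig, g_adr

    obs_loglik_grad = _nb_obs_loglik_grad
else:  # pragma: no cover
    obs_loglik_grad = _py_obs_loglik_grad
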