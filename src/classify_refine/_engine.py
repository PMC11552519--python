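"""Flat-array session-likelihood kernel used by the fitting loop.

MAP fitting evaluates the session likelihood tens of thousands of times,
so the trial loop is implemented over pre-extracted arrays and JIT
compiled with numba when available (falling back to the same code in pure
NumPy).  The object-level API in ``agent_models``/``response_models``
remains the reference implementation; ``tests`` assert the two paths
agree to 1e-10.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["session_loglik_kernel", "_HAVE_NUMBA"]

_LOG_FLOOR = 1e-12
_CLAMP = 1e-6


@njit(cache=True)
def _channel_loglik(value: float, bin_idx: int, alpha: float,
                    bins: np.ndarray) -> float:
    d2min = np.inf
    for j in range(bins.shape[0]):
        d = bins[j] - value
        if d * d < d2min:
            d2min = d * d
    z = 0.0
    w_obs = 0.0
    for j in range(bins.shape[0]):
        d = bins[j] - value
        w = np.exp(-alpha * (d * d - d2min))  # stabilised softmax
        z += w
        if j == bin_idx:
            w_obs = w
    p = w_obs / z
    if p < _LOG_FLOOR:
        p = _LOG_FLOOR
    return np.log(p)


@njit(cache=True)
def _biased(value: float, poc: float) -> float:
    v = value
    if v < _CLAMP:
        v = _CLAMP
    elif v > 1.0 - _CLAMP:
        v = 1.0 - _CLAMP
    z = np.log(v / (1.0 - v)) + poc
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def session_loglik_kernel(
    prior0: np.ndarray,      # (n_s,) joint state prior at block start
    pf0: np.ndarray,         # (n_s,) initial policy-fairness per state
    hi_w: np.ndarray,        # (n_s,) HI attribution weight per state
    si_w: np.ndarray,        # (n_s,) SI attribution weight per state
    learn: bool,             # classify-refine count refinement on/off
    aEv: float, omega: float, lam: float, alpha: float, poc: float,
    outcomes: np.ndarray,    # (T,) 1 = fair, 0 = unfair
    exp_bin: np.ndarray,     # (T,) snapped report bin indices
    hi_bin: np.ndarray,
    si_bin: np.ndarray,
    nonwhite: np.ndarray,    # (T,) 1 if the trial's dictator is nonwhite
    block_start: np.ndarray, # (B+1,) trial offsets delimiting blocks
    bins: np.ndarray,        # (n_bins,) response scale
    use_exp: bool, use_hi: bool, use_si: bool,
):
    """Session log-likelihood; returns (loglik, failing_trial or -1)."""
    n_s = prior0.shape[0]
    base_f = np.empty(n_s)
    base_u = np.empty(n_s)
    for s in range(n_s):
        base_f[s] = aEv * pf0[s]
        base_u[s] = aEv * (1.0 - pf0[s])
    cf = base_f.copy()
    cu = base_u.copy()
    prior = prior0.copy()
    post = np.empty(n_s)
    phat = np.empty(n_s)

    total = 0.0
    for b in range(block_start.shape[0] - 1):
        if learn:
            if b == 0:
                for s in range(n_s):
                    cf[s] = base_f[s]
                    cu[s] = base_u[s]
            else:
                for s in range(n_s):
                    cf[s] = base_f[s] + lam * (cf[s] - base_f[s])
                    cu[s] = base_u[s] + lam * (cu[s] - base_u[s])
        for s in range(n_s):
            prior[s] = prior0[s]

        for t in range(block_start[b], block_start[b + 1]):
            if learn:
                for s in range(n_s):
                    phat[s] = cf[s] / (cf[s] + cu[s])
            else:
                for s in range(n_s):
                    phat[s] = pf0[s]

            if use_exp:
                pred = 0.0
                for s in range(n_s):
                    pred += prior[s] * phat[s]
                total += _channel_loglik(pred, exp_bin[t], alpha, bins)

            z = 0.0
            fair = outcomes[t] == 1
            for s in range(n_s):
                lik = phat[s] if fair else 1.0 - phat[s]
                post[s] = prior[s] * lik
                z += post[s]
            if not z > 0.0:
                return -np.inf, t
            for s in range(n_s):
                post[s] /= z

            if use_hi or use_si:
                hi_v = 0.0
                si_v = 0.0
                for s in range(n_s):
                    hi_v += post[s] * hi_w[s]
                    si_v += post[s] * si_w[s]
                if nonwhite[t] == 1 and poc != 0.0:
                    hi_v = _biased(hi_v, poc)
                    si_v = _biased(si_v, poc)
                if use_hi:
                    total += _channel_loglik(hi_v, hi_bin[t], alpha, bins)
                if use_si:
                    total += _channel_loglik(si_v, si_bin[t], alpha, bins)

            if learn:
                for s in range(n_s):
                    if fair:
                        cf[s] += post[s]
                    else:
                        cu[s] += post[s]
                    cf[s] = base_f[s] + omega * (cf[s] - base_f[s])
                    cu[s] = base_u[s] + omega * (cu[s] - base_u[s])

            for s in range(n_s):
                prior[s] = post[s]

    if not np.isfinite(total):
        return -np.inf, 0
    return total, -1
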