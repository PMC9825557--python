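"""Wiener diffusion (drift-diffusion) first-passage-time core.

The two-alternative decision process is a driftless-scale Brownian motion
``dX = v dt + dW`` between absorbing boundaries 0 and ``a``, started at
``z * a`` (``0 < z < 1``), with the diffusion coefficient fixed to 1 so that
``v``, ``a`` are expressed on that scale.  The upper boundary codes
orientation to the fearful face.  A response is emitted ``t0`` seconds after
the accumulator is absorbed (non-decision time).

The defective first-passage density is evaluated with the classical
small-time / large-time series expansions, switching automatically to
whichever representation needs fewer terms at the requested accuracy.  All
evaluation routines are vectorised over trials *and* parameter sets, which
is what makes ensemble MCMC over hierarchical drift-diffusion models
affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WienerParams",
    "choice_prob_upper",
    "wfpt_density",
    "wfpt_logpdf",
    "wfpt_loglik",
    "wfpt_loglik_sum",
    "simulate_ddm",
]

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco

# absolute truncation error tolerated when evaluating the standardized series
_SERIES_EPS = 1e-12
_MAX_TERMS = 120


@dataclass(frozen=True)
class WienerParams:
    """Drift-diffusion parameter set for one condition/participant.

    v : drift rate, evidence per second, positive toward the upper (fear)
        boundary.
    a : boundary separation (> 0).
    z : relative start point in (0, 1); 0.5 is unbiased.
    t0 : non-decision time in seconds (>= 0).
    """

    v: float
    a: float
    z: float
    t0: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.v, self.a, self.z, self.t0]).all():
            raise ValueError("WienerParams must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"start point z must lie in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")


def choice_prob_upper(p: WienerParams) -> float:
    """Probability that the accumulator is absorbed at the upper boundary.

    Closed form for Brownian motion with drift between two absorbing
    boundaries; reduces to ``z`` exactly when ``v == 0`` (martingale
    identity).
    """
    return float(_prob_upper(np.asarray(p.v), np.asarray(p.a), np.asarray(p.z)))


def _prob_upper(v: np.ndarray, a: np.ndarray, z: np.ndarray) -> np.ndarray:
    v, a, z = np.broadcast_arrays(v, a, z)
    va = 2.0 * v * a
    out = np.empty(np.shape(va), dtype=float)
    small = np.abs(va) < 1e-9
    # limit v -> 0 is z; first-order correction keeps the function smooth
    out[small] = z[small] + 0.5 * va[small] * z[small] * (1.0 - z[small])
    nv = ~small
    out[nv] = np.expm1(-va[nv] * z[nv]) / np.expm1(-va[nv])
    return out


def _nterms_small(tau: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the small-time expansion (per element)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 2.0 * eps * np.sqrt(2.0 * np.pi * tau)
        k = 2.0 + np.sqrt(np.maximum(-2.0 * tau * np.log(np.minimum(arg, 1.0 - 1e-16)), 0.0))
    return np.ceil(np.maximum(k, np.sqrt(tau) + 1.0)).astype(int)


def _nterms_large(tau: np.ndarray, eps: float) -> np.ndarray:
    """Terms needed by the large-time expansion (per element)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = np.pi * tau * eps
        k = np.sqrt(np.maximum(-2.0 * np.log(np.minimum(arg, 1.0 - 1e-16)), 0.0) / (np.pi**2 * tau))
    return np.ceil(np.maximum(k, 1.0 / (np.pi * np.sqrt(tau)))).astype(int)


def _f1(tau: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Standardized lower-boundary density f(tau | v=0, a=1, start=w)."""
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(w, dtype=float)
    tau, w = np.broadcast_arrays(tau, w)
    out = np.zeros(tau.shape, dtype=float)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]
    ww = w[pos]
    ks = np.minimum(_nterms_small(t, _SERIES_EPS), _MAX_TERMS)
    kl = np.minimum(_nterms_large(t, _SERIES_EPS), _MAX_TERMS)
    use_small = ks < kl
    val = np.zeros(t.shape, dtype=float)
    if use_small.any():
        ts, wsm = t[use_small], ww[use_small]
        kmax = int(ks[use_small].max())
        acc = np.zeros(ts.shape)
        for k in range(-kmax, kmax + 1):
            u = wsm + 2.0 * k
            acc += u * np.exp(-(u * u) / (2.0 * ts))
        val[use_small] = acc / np.sqrt(2.0 * np.pi * ts**3)
    if (~use_small).any():
        tl, wl = t[~use_small], ww[~use_small]
        kmax = int(kl[~use_small].max())
        acc = np.zeros(tl.shape)
        for k in range(1, kmax + 1):
            acc += k * np.exp(-(k * k) * np.pi**2 * tl / 2.0) * np.sin(k * np.pi * wl)
        val[~use_small] = np.pi * acc
    out[pos] = np.maximum(val, 0.0)
    return out


def _f1_small(tau: np.ndarray, w: np.ndarray, kmax: int) -> np.ndarray:
    acc = np.zeros(np.broadcast(tau, w).shape)
    for k in range(-kmax, kmax + 1):
        u = w + 2.0 * k
        acc = acc + u * np.exp(-(u * u) / (2.0 * tau))
    return acc / np.sqrt(2.0 * np.pi * tau**3)


def _f1_large(tau: np.ndarray, w: np.ndarray, kmax: int) -> np.ndarray:
    acc = np.zeros(np.broadcast(tau, w).shape)
    for k in range(1, kmax + 1):
        acc = acc + k * np.exp(-(k * k) * np.pi**2 * tau / 2.0) * np.sin(k * np.pi * w)
    return np.pi * acc


def wfpt_density(t, p: WienerParams, boundary: str = "upper"):
    """Defective first-passage density at latency ``t`` (seconds).

    Zero for ``t <= t0``; integrates over (t0, inf) to the boundary's hit
    probability.  ``t`` may be a scalar or array.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t_arr = np.asarray(t, dtype=float)
    upper = np.full(t_arr.shape, boundary == "upper")
    out = np.exp(wfpt_logpdf(t_arr, upper, p.v, p.a, p.z, p.t0))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def wfpt_logpdf(t, upper, v, a, z, t0) -> np.ndarray:
    """Vectorised log defective density; broadcasts all arguments.

    ``upper`` is boolean: True for upper-boundary (fear) absorptions.  The
    upper-boundary density is obtained from the lower one via the exact
    mirror symmetry (v, z) -> (-v, 1 - z).
    """
    t, upper, v, a, z, t0 = np.broadcast_arrays(
        np.asarray(t, dtype=float), np.asarray(upper, dtype=bool),
        np.asarray(v, dtype=float), np.asarray(a, dtype=float),
        np.asarray(z, dtype=float), np.asarray(t0, dtype=float),
    )
    veff = np.where(upper, -v, v)
    weff = np.where(upper, 1.0 - z, z)
    dt = t - t0
    tau = np.where(dt > 0, dt, np.nan) / a**2
    with np.errstate(invalid="ignore"):
        f1 = _f1(np.nan_to_num(tau, nan=-1.0), weff)
    logf = np.where(
        dt > 0,
        np.log(np.maximum(f1, 1e-300)) - 2.0 * np.log(a) - veff * a * weff
        - veff**2 * np.where(dt > 0, dt, 0.0) / 2.0,
        -np.inf,
    )
    return logf


def wfpt_loglik(trials, p: WienerParams) -> float:
    """Joint log-likelihood of (choice, latency) pairs under one parameter set.

    ``trials``: iterable of ``(choice, latency_s)`` with choice ``'fear'``
    (upper boundary) or ``'neutral'`` (lower), or an ``(upper, t)`` pair of
    arrays.  Latencies at or below ``t0`` contribute ``-inf``.
    """
    trials = list(trials)
    if len(trials) == 0:
        raise ValueError("empty trial list")
    choices = np.array([c for c, _ in trials])
    lat = np.array([float(t) for _, t in trials])
    if choices.dtype.kind in "UO":
        upper = choices == "fear"
    else:
        upper = choices.astype(bool)
    return float(np.sum(wfpt_logpdf(lat, upper, p.v, p.a, p.z, p.t0)))


@_njit(cache=True, fastmath=True)
def _loglik_sum_kernel(t, upper, v, a, z, t0, eps):  # pragma: no cover - jitted
    nw, n = v.shape
    out = np.empty(nw)
    pi = np.pi
    for j in range(nw):
        total = 0.0
        for i in range(n):
            dt = t[i] - t0[j, i]
            if dt <= 0.0:
                total = -np.inf
                break
            aa = a[j, i]
            if upper[i]:
                veff = -v[j, i]
                w = 1.0 - z[j, i]
            else:
                veff = v[j, i]
                w = z[j, i]
            tau = dt / (aa * aa)
            arg = 2.0 * eps * np.sqrt(2.0 * pi * tau)
            ks = 2.0 + (np.sqrt(-2.0 * tau * np.log(arg)) if arg < 1.0 else 0.0)
            sq = np.sqrt(tau)
            if ks < sq + 1.0:
                ks = sq + 1.0
            argl = pi * tau * eps
            kl = (np.sqrt(-2.0 * np.log(argl) / (pi * pi * tau)) if argl < 1.0 else 0.0)
            if kl < 1.0 / (pi * sq):
                kl = 1.0 / (pi * sq)
            if ks < kl:
                K = int(np.ceil(ks))
                if K > 120:
                    K = 120
                s = 0.0
                for k in range(-K, K + 1):
                    u = w + 2.0 * k
                    s += u * np.exp(-u * u / (2.0 * tau))
                f1 = s / np.sqrt(2.0 * pi * tau**3)
            else:
                K = int(np.ceil(kl))
                if K > 120:
                    K = 120
                s = 0.0
                for k in range(1, K + 1):
                    s += k * np.exp(-k * k * pi * pi * tau / 2.0) * np.sin(k * pi * w)
                f1 = pi * s
            if f1 < 1e-300:
                f1 = 1e-300
            total += np.log(f1) - 2.0 * np.log(aa) - veff * aa * w - veff * veff * dt / 2.0
        out[j] = total
    return out


def wfpt_loglik_sum(t: np.ndarray, upper: np.ndarray, v: np.ndarray, a: np.ndarray,
                    z: np.ndarray, t0: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Summed log-likelihood per parameter column.

    ``t`` and ``upper`` are per-trial (length n); ``v, a, z, t0`` are
    (n, m) matrices of per-trial parameter values for m candidate parameter
    sets.  Returns length-m sums — the sampler's hot path.
    """
    t = np.ascontiguousarray(t, dtype=np.float64)
    upper = np.ascontiguousarray(upper, dtype=np.bool_)
    mats = [np.ascontiguousarray(np.broadcast_to(m_, (len(t), v.shape[1])).T,
                                 dtype=np.float64) for m_ in (v, a, z, t0)]
    if _HAVE_NUMBA:
        return _loglik_sum_kernel(t, upper, *mats, eps)
    return wfpt_logpdf(t[:, None], upper[:, None], v, a, z, t0).sum(axis=0)


def simulate_ddm(p: WienerParams, n: int, seed=None, method: str = "exact_hybrid",
                 dt: float = 1e-4, t_max: float = 20.0):
    """Draw ``n`` (choice, rt) pairs from the diffusion process.

    method 'euler' integrates sample paths with step ``dt``; 'exact_hybrid'
    draws the boundary from the closed-form hitting probability and the
    latency by inverse-CDF sampling of the conditional first-passage
    density on a dense grid.  Returns ``(choices, rts)`` where choices are
    1 for upper (fear) and 0 for lower, rts in seconds (> t0).
    """
    if n <= 0:
        raise ValueError(f"number of trials must be positive, got {n}")
    rng = np.random.default_rng(seed)
    if method == "euler":
        return _simulate_euler(p, n, rng, dt, t_max)
    if method == "exact_hybrid":
        return _simulate_hybrid(p, n, rng)
    raise ValueError(f"unknown method {method!r}")


def _simulate_euler(p: WienerParams, n: int, rng, dt: float, t_max: float):
    """Euler-Maruyama with Brownian-bridge boundary-crossing correction:
    without it, first-passage times carry an O(sqrt(dt)) late-hitting bias
    from within-step excursions beyond the boundary."""
    x = np.full(n, p.z * p.a)
    t_hit = np.zeros(n)
    choice = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    sqdt = np.sqrt(dt)
    nsteps = int(np.ceil(t_max / dt))
    for step in range(1, nsteps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x0 = x[idx]
        x1 = x0 + p.v * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x1 >= p.a
        hit_lo = x1 <= 0.0
        inside = ~(hit_up | hit_lo)
        if inside.any():
            u0, u1 = p.a - x0[inside], p.a - x1[inside]
            p_up = np.exp(-2.0 * u0 * u1 / dt)
            p_lo = np.exp(-2.0 * x0[inside] * x1[inside] / dt)
            r = rng.random(int(inside.sum()))
            bridge_up = r < p_up
            bridge_lo = (~bridge_up) & (r < p_up + p_lo)
            hit_up[np.flatnonzero(inside)[bridge_up]] = True
            hit_lo[np.flatnonzero(inside)[bridge_lo]] = True
        x[idx] = x1
        done = hit_up | hit_lo
        if done.any():
            d = idx[done]
            t_hit[d] = step * dt
            choice[d] = hit_up[done].astype(int)
            active[d] = False
    if active.any():  # censor stragglers at t_max toward the drift side
        t_hit[active] = t_max
        choice[active] = int(p.v >= 0)
    return choice, p.t0 + t_hit


def _tail_rate(p: WienerParams) -> float:
    # slowest decay mode of the FPT density
    return np.pi**2 / (2.0 * p.a**2) + p.v**2 / 2.0


def _simulate_hybrid(p: WienerParams, n: int, rng):
    pu = choice_prob_upper(p)
    upper = rng.random(n) < pu
    # grid long enough that the neglected tail mass is < 1e-9
    t_hi = max(1.0, 25.0 / _tail_rate(p))
    grid = np.linspace(1e-6, t_hi, 8192)
    rts = np.empty(n)
    for is_up, nn in ((True, int(upper.sum())), (False, int(n - upper.sum()))):
        if nn == 0:
            continue
        dens = np.exp(wfpt_logpdf(grid + p.t0, is_up, p.v, p.a, p.z, p.t0))
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        u = rng.random(nn)
        rts[upper == is_up] = np.interp(u, cdf, grid)
    return upper.astype(int), p.t0 + rts
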