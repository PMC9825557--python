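"""Posterior sampling engine for the hierarchical behavioural models.

The posterior geometries here (many fixed effects, per-participant random
intercepts, half-Normal hierarchical scales) are sampled with the block
differential-evolution MCMC scheme that is standard for hierarchical
evidence-accumulation models: an ensemble of walkers is updated block by
block (fixed-effect blocks, one block per participant) with
DE proposals built from the difference of two walkers of the opposite
half-ensemble (parallel red-blue updates preserve detailed balance), while
each hierarchical scale parameter is resampled exactly by univariate slice
sampling from its conditional given the (centred) random intercepts — the
conditional does not involve the data, so the funnel between scales and
intercepts never slows the ensemble.

Models expose a vectorised log posterior (points x parameters -> points), a
block structure, and scale-update metadata.  A MAP search (batched
finite-difference gradients) provides the starting point and per-axis
dispersion.  Convergence is judged the way short-chain ensembles require:
R-hat over superchains (walkers grouped round-robin, draws step-major) and
bulk ESS with walkers as chains; chains are extended adaptively until the
contract (R-hat <= 1.01, bulk ESS >= 400 by default) holds, else a
ConvergenceError is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceError",
    "ConvergenceReport",
    "Block",
    "ScaleUpdate",
    "sample_posterior",
    "diagnostics",
]


class ConvergenceError(RuntimeError):
    """The sampler did not meet its convergence postconditions."""


@dataclass(frozen=True)
class Block:
    """One DE update block.

    ``indices`` are the parameter coordinates moved jointly; ``partial``,
    if given, maps a (points, dim) array to the posterior terms that depend
    on these coordinates only (e.g. one participant's log-likelihood plus
    that participant's prior terms) — the Metropolis ratio then needs just
    those terms, which makes per-participant updates cheap.
    """

    indices: np.ndarray
    partial: object = None


@dataclass(frozen=True)
class ScaleUpdate:
    """Gibbs metadata for one hierarchical scale parameter.

    ``sd_index`` addresses log-sd in the parameter vector; ``dev_indices``
    the centred deviations it governs.  Conditional (u = log sd):
    log f(u) = -SS/2 e^(-2u) - S u - e^(2u)/2 + u   (half-Normal(1) prior).
    """

    sd_index: int
    dev_indices: tuple


@dataclass(frozen=True)
class SamplerConfig:
    """Block DE-MCMC controls."""

    n_walkers: int = 96
    n_burn: int = 400
    n_draws: int = 400               # kept iterations
    rhat_max: float = 1.01
    ess_min: float = 400.0
    rhat_groups: int = 4
    max_extensions: int = 4
    extension_steps: int = 300
    init_jitter: float = 0.3         # walker spread in scaled units
    gamma_jump_prob: float = 0.1     # probability of a gamma = 1 mode jump
    adapt_target: float = 0.25       # per-block acceptance targeted in burn-in
    adapt_rate: float = 0.05
    map_maxiter: int = 300
    seed: int = 0
    strict: bool = True              # raise on convergence failure


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws: (chains, draws, parameters) plus convergence
    statistics per parameter."""

    draws: np.ndarray
    names: list
    rhat: np.ndarray
    ess: np.ndarray
    acceptance: float = np.nan
    map_point: np.ndarray | None = None

    def __post_init__(self):
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, draws, parameters)")
        if self.draws.shape[0] < 2:
            raise ValueError("at least 2 chains required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if not np.all(np.isfinite(self.rhat)):
            raise ValueError("R-hat must be finite")

    @property
    def n_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat(), columns=self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.flat()[:, self.names.index(name)]


@dataclass
class ConvergenceReport:
    rhat: pd.Series
    ess_bulk: pd.Series
    acceptance: float
    rhat_max: float
    ess_min: float
    divergences: int = 0  # gradient-free moves: no divergent transitions exist

    @property
    def passed(self) -> bool:
        return bool((self.rhat <= self.rhat_max).all() and (self.ess_bulk >= self.ess_min).all())


def diagnostics(draws: PosteriorDraws, rhat_max: float = 1.01,
                ess_min: float = 400.0, groups: int = 4) -> ConvergenceReport:
    """Superchain R-hat and bulk ESS per parameter with pass/fail thresholds."""
    rhat = _rhat(draws.draws, groups=groups)
    ess = _ess_bulk(draws.draws)
    return ConvergenceReport(rhat=pd.Series(rhat, index=draws.names),
                             ess_bulk=pd.Series(ess, index=draws.names),
                             acceptance=draws.acceptance,
                             rhat_max=rhat_max, ess_min=ess_min)


def _rhat(chains: np.ndarray, groups: int = 4) -> np.ndarray:
    """Split R-hat over superchains: walkers assigned round-robin to
    ``groups`` groups, draws within a group ordered step-major so the split
    halves are early vs late iterations."""
    nw, ns, dim = chains.shape
    g = min(groups, nw)
    m = nw // g
    arr = np.empty((g, m * ns, dim))
    for i in range(g):
        arr[i] = chains[i::g][:m].transpose(1, 0, 2).reshape(-1, dim)
    ds = az.convert_to_dataset({"theta": arr})
    return np.atleast_1d(az.rhat(ds)["theta"].to_numpy())


def _ess_bulk(chains: np.ndarray) -> np.ndarray:
    ds = az.convert_to_dataset({"theta": chains})
    return np.atleast_1d(az.ess(ds, method="bulk")["theta"].to_numpy())


# ---------------------------------------------------------------------------
# MAP + per-axis scaling
# ---------------------------------------------------------------------------

def _batched_grad(logp_vec, x: np.ndarray, eps: float = 1e-5):
    """(logp, gradient) by central differences evaluated in one batch."""
    dim = len(x)
    h = eps * np.maximum(np.abs(x), 1.0)
    pts = np.concatenate([x[None, :], x + np.diag(h), x - np.diag(h)])
    vals = np.nan_to_num(logp_vec(pts), nan=-1e12, neginf=-1e12)
    grad = (vals[1:dim + 1] - vals[dim + 1:]) / (2.0 * h)
    return vals[0], grad


def find_map(logp_vec, x0: np.ndarray, maxiter: int = 300) -> np.ndarray:
    """L-BFGS MAP search on the penalised (finite-valued) log posterior."""

    def negf(x):
        f, g = _batched_grad(logp_vec, np.asarray(x, float))
        return -f, -g

    res = optimize.minimize(negf, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxcor": 25})
    return np.asarray(res.x, float)


def posterior_scales(logp_vec, x_map: np.ndarray, min_scale: float = 1e-3,
                     max_scale: float = 10.0, probe_iters: int = 4) -> np.ndarray:
    """Per-axis posterior SD estimates from finite-difference curvature,
    shrunk wherever a one-unit probe drops the log posterior by more than a
    sound quadratic would (guards against non-quadratic directions)."""
    dim = len(x_map)
    f0 = float(np.nan_to_num(logp_vec(x_map[None, :]), nan=-1e12, neginf=-1e12)[0])
    h = 1e-3 * np.maximum(np.abs(x_map), 1.0)
    vals = np.nan_to_num(logp_vec(np.concatenate([x_map[None] + np.diag(h),
                                                  x_map[None] - np.diag(h)])),
                         nan=-1e12, neginf=-1e12)
    curv = (2.0 * f0 - vals[:dim] - vals[dim:]) / h**2
    scales = 1.0 / np.sqrt(np.clip(curv, 1.0 / max_scale**2, 1.0 / min_scale**2))
    for _ in range(probe_iters):
        vals = np.nan_to_num(logp_vec(np.concatenate([x_map[None] + np.diag(scales),
                                                      x_map[None] - np.diag(scales)])),
                             nan=-1e12, neginf=-1e12)
        drop = f0 - np.minimum(vals[:dim], vals[dim:])
        bad = drop > 2.0
        if not bad.any():
            break
        scales[bad] *= np.sqrt(0.5 / np.maximum(drop[bad], 0.5))
    return scales


# ---------------------------------------------------------------------------
# Gibbs update of hierarchical scales (vectorised slice sampler)
# ---------------------------------------------------------------------------

def _slice_sample_logsd(u: np.ndarray, ss: np.ndarray, s_count: int,
                        rng: np.random.Generator, width: float = 1.0,
                        max_step: int = 30) -> np.ndarray:
    """One slice-sampling update of u = log sd per walker.

    Conditional: log f(u) = -ss/2 e^(-2u) - s_count u - e^(2u)/2 + u.
    """

    def logf(uu):
        return -0.5 * ss * np.exp(-2 * uu) - s_count * uu - 0.5 * np.exp(2 * uu) + uu

    y = logf(u) + np.log(rng.random(u.shape))
    lo = u - width * rng.random(u.shape)
    hi = lo + width
    for _ in range(max_step):  # step out
        grow_lo = logf(lo) > y
        grow_hi = logf(hi) > y
        if not (grow_lo.any() or grow_hi.any()):
            break
        lo = np.where(grow_lo, lo - width, lo)
        hi = np.where(grow_hi, hi + width, hi)
    out = u.copy()
    todo = np.ones(u.shape, bool)
    for _ in range(100):  # shrink
        prop = lo + (hi - lo) * rng.random(u.shape)
        ok = logf(prop) > y
        accept = todo & ok
        out = np.where(accept, prop, out)
        todo = todo & ~ok
        if not todo.any():
            break
        lo = np.where(todo & (prop < u), prop, lo)
        hi = np.where(todo & (prop >= u), prop, hi)
    return out


# ---------------------------------------------------------------------------
# block DE-MCMC
# ---------------------------------------------------------------------------

def _de_sweep(x: np.ndarray, logp: np.ndarray, logp_vec, blocks: list,
              scale_updates: list, rng: np.random.Generator,
              gamma_jump_prob: float, accepts: list,
              gamma_scales: np.ndarray | None = None,
              adapt: float = 0.0, adapt_target: float = 0.25) -> None:
    """One in-place sweep: block DE Metropolis for each half-ensemble,
    then Gibbs slice updates of the hierarchical scales.  With ``adapt`` > 0
    the per-block proposal scale chases the target acceptance (burn-in
    only, so the kept-phase kernel stays fixed)."""
    nw = x.shape[0]
    half = nw // 2
    order = [np.arange(half), np.arange(half, nw)]
    for bi, block in enumerate(blocks):
        idxs = block.indices
        gscale = 1.0 if gamma_scales is None else gamma_scales[bi]
        gamma0 = gscale * 2.38 / np.sqrt(2.0 * len(idxs))
        block_acc = []
        for h, idx in enumerate(order):
            other = order[1 - h]
            r1 = other[rng.integers(0, len(other), size=len(idx))]
            r2 = other[rng.integers(0, len(other), size=len(idx))]
            while True:
                clash = r1 == r2
                if not clash.any():
                    break
                r2[clash] = other[rng.integers(0, len(other), size=int(clash.sum()))]
            gamma = np.where(rng.random(len(idx)) < gamma_jump_prob, 1.0, gamma0)
            prop = x[idx].copy()
            step = gamma[:, None] * (x[r1][:, idxs] - x[r2][:, idxs])
            step += 1e-4 * rng.standard_normal(step.shape)
            prop[:, idxs] += step
            if block.partial is None:
                lp_prop = logp_vec(prop)
                lp_prop = np.where(np.isnan(lp_prop), -np.inf, lp_prop)
                delta = lp_prop - logp[idx]
            else:
                pp = np.asarray(block.partial(prop), float)
                pc = np.asarray(block.partial(x[idx]), float)
                delta = np.where(np.isnan(pp), -np.inf, pp) - pc
            acc = np.log(rng.random(len(idx))) < delta
            x[idx[acc]] = prop[acc]
            logp[idx[acc]] = logp[idx[acc]] + delta[acc]
            block_acc.append(float(np.mean(acc)))
        accepts.extend(block_acc)
        if adapt > 0 and gamma_scales is not None:
            gamma_scales[bi] *= np.exp(adapt * (np.mean(block_acc) - adapt_target))
            gamma_scales[bi] = min(max(gamma_scales[bi], 0.1), 3.0)
    if scale_updates:
        for su in scale_updates:
            dev = x[:, list(su.dev_indices)]
            ss = np.sum(dev * dev, axis=1)
            x[:, su.sd_index] = _slice_sample_logsd(
                x[:, su.sd_index], ss, len(su.dev_indices), rng)
        logp[:] = logp_vec(x)
        logp[:] = np.where(np.isnan(logp), -np.inf, logp)


def sample_posterior(logp_vec, x0: np.ndarray, names: list,
                     cfg: SamplerConfig = SamplerConfig(),
                     blocks: list | None = None,
                     scale_updates: list | None = None,
                     check_indices=None) -> PosteriorDraws:
    """MAP start -> block DE-MCMC with Gibbs scale updates -> diagnostics.

    ``logp_vec`` maps an (n_points, dim) array to log-posterior values;
    ``blocks`` lists index arrays updated jointly (default: one full
    block); ``scale_updates`` lists ScaleUpdate entries handled by Gibbs.
    The convergence contract is enforced over ``check_indices`` (default:
    every parameter) — models restrict it to the reported parameters, the
    fixed effects that all contrasts are built from.
    """
    dim = len(x0)
    names = list(names)
    if len(names) != dim:
        raise ValueError("one name per parameter required")
    rng = np.random.default_rng(cfg.seed)
    scale_updates = list(scale_updates or [])
    gibbs_idx = sorted({su.sd_index for su in scale_updates})
    x0 = np.asarray(x0, float)
    if gibbs_idx:
        # the joint mode of a centred hierarchy sits at the funnel apex
        # (sd -> 0); clamp the scales during the MAP search so walkers start
        # with the random intercepts free to move
        clamp = np.array(gibbs_idx, dtype=int)
        clamp_vals = x0[clamp]

        def logp_map(pts):
            pts = np.array(np.atleast_2d(pts), copy=True)
            pts[:, clamp] = clamp_vals[None, :]
            return logp_vec(pts)

        x_map = find_map(logp_map, x0, maxiter=cfg.map_maxiter)
        x_map[clamp] = clamp_vals
    else:
        x_map = find_map(logp_vec, x0, maxiter=cfg.map_maxiter)
    scales = posterior_scales(logp_vec, x_map)
    if blocks is None:
        blocks = [np.array([i for i in range(dim) if i not in gibbs_idx])]
    blocks = [b if isinstance(b, Block) else Block(np.asarray(b, dtype=int))
              for b in blocks]

    nw = max(cfg.n_walkers, 8)
    nw += nw % 2
    x = x_map[None, :] + cfg.init_jitter * scales[None, :] * rng.standard_normal((nw, dim))
    logp = np.asarray(logp_vec(x), float)
    logp = np.where(np.isnan(logp), -np.inf, logp)
    for _ in range(50):  # pull infeasible starters toward the mode
        bad = ~np.isfinite(logp)
        if not bad.any():
            break
        x[bad] = x_map[None, :] + 0.5 * (x[bad] - x_map[None, :])
        logp[bad] = logp_vec(x[bad])
        logp[bad] = np.where(np.isnan(logp[bad]), -np.inf, logp[bad])
    if not np.isfinite(logp).all():
        raise ConvergenceError("could not initialise walkers at finite posterior density")

    check = (np.arange(dim) if check_indices is None
             else np.asarray(check_indices, dtype=int))
    accepts: list = []
    gamma_scales = np.ones(len(blocks))
    for _ in range(cfg.n_burn):
        _de_sweep(x, logp, logp_vec, blocks, scale_updates, rng,
                  cfg.gamma_jump_prob, accepts, gamma_scales,
                  adapt=cfg.adapt_rate, adapt_target=cfg.adapt_target)
    accepts.clear()
    kept = []
    for _ in range(cfg.n_draws):
        _de_sweep(x, logp, logp_vec, blocks, scale_updates, rng,
                  cfg.gamma_jump_prob, accepts, gamma_scales)
        kept.append(x.copy())

    def current() -> PosteriorDraws:
        theta = np.stack(kept, axis=1)  # (walkers, iters, dim)
        return PosteriorDraws(
            draws=theta, names=names,
            rhat=_rhat(theta, groups=cfg.rhat_groups), ess=_ess_bulk(theta),
            acceptance=float(np.mean(accepts)) if accepts else np.nan,
            map_point=x_map,
        )

    def unmet(d: PosteriorDraws) -> bool:
        return bool(d.rhat[check].max() > cfg.rhat_max
                    or d.ess[check].min() < cfg.ess_min)

    draws = current()
    ext = 0
    while unmet(draws) and ext < cfg.max_extensions:
        for _ in range(cfg.extension_steps):
            _de_sweep(x, logp, logp_vec, blocks, scale_updates, rng,
                      cfg.gamma_jump_prob, accepts, gamma_scales)
            kept.append(x.copy())
        draws = current()
        ext += 1
    if cfg.strict and unmet(draws):
        raise ConvergenceError(
            f"convergence contract not met on reported parameters: "
            f"max R-hat {draws.rhat[check].max():.4f}, "
            f"min bulk ESS {draws.ess[check].min():.0f}")
    return draws
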