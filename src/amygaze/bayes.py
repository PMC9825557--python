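"""Hierarchical Bayesian models of saccadic latency and choice.

Three response families are fitted to the QC-filtered trial table:

* shifted lognormal  — latency with location ``mu`` varying over
  Instruction x Disruption x Emotion (full factorial) plus a Hemifield
  confound, and log-linked spread ``sigma`` and shift ``delta`` (the
  earliest possible response);
* Bernoulli          — fear-choice rate ``theta`` (logit link) varying over
  Instruction x Disruption x binarized Latency plus Hemifield;
* Wiener diffusion   — joint (choice, latency) likelihood with drift ``v``
  and start point ``z`` varying over Instruction x Disruption(3) x
  Hemifield, and boundary ``a`` / non-decision time ``t0`` (log links) over
  Instruction x Disruption presence.

All factors are sum-to-zero (deviation) coded, so marginalising the
Hemifield confound is equal-weight averaging and main effects stay
interpretable under imbalance.  Participants contribute random intercepts
(non-centred, half-Normal scale priors).  Posterior summaries are means,
95% credible intervals (2.5/97.5 percentiles) and P(effect), the posterior
mass on the side of zero matching the estimated direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sampling import (Block, ConvergenceError, ConvergenceReport, PosteriorDraws,
                        SamplerConfig, ScaleUpdate, diagnostics, sample_posterior)
from .wiener import wfpt_loglik_sum

__all__ = [
    "ContrastResult",
    "ShiftedLognormalModel",
    "BernoulliChoiceModel",
    "WienerDDMModel",
    "median_split",
    "fit_model",
    "contrast",
    "summarize_contrast",
    "planned_contrast_suite",
    "diagnostics",
    "ConvergenceError",
    "ConvergenceReport",
    "PosteriorDraws",
    "SamplerConfig",
]

INSTRUCTIONS = ("Yield", "Oppose")
DISRUPTIONS = ("None", "Ipsi", "Contra")
HEMIFIELDS = ("L", "R")
EMOTIONS = ("fear", "neutral")
LATCLASSES = ("Early", "Late")
PRESENCE = ("None", "Present")


# ---------------------------------------------------------------------------
# design coding
# ---------------------------------------------------------------------------

def _sum_code(values, levels) -> np.ndarray:
    """Deviation coding: k-1 columns, last level coded -1 everywhere."""
    values = np.asarray(values)
    k = len(levels)
    X = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = np.where(values == lev, 1.0, 0.0)
    X[values == levels[-1], :] = -1.0
    return X


def factorial_matrix(factors: list) -> tuple:
    """Full-factorial sum-coded design matrix with intercept.

    ``factors``: list of (name, values, levels).  Returns (X, column names).
    """
    coded = [(name, _sum_code(vals, levels)) for name, vals, levels in factors]
    n = len(coded[0][1]) if coded else 0
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for r in range(1, len(coded) + 1):
        for combo in itertools.combinations(range(len(coded)), r):
            idx_sets = [range(coded[i][1].shape[1]) for i in combo]
            for js in itertools.product(*idx_sets):
                col = np.ones(n)
                for i, j in zip(combo, js):
                    col = col * coded[i][1][:, j]
                cols.append(col[:, None])
                names.append(":".join(f"{coded[i][0]}[{j}]" for i, j in zip(combo, js)))
    return np.concatenate(cols, axis=1), names


def _cell_matrix(level_sets: list) -> tuple:
    """Design rows for every factor-level combination (same coding)."""
    cells = list(itertools.product(*[levels for _, levels in level_sets]))
    frame = {name: [c[i] for c in cells] for i, (name, _) in enumerate(level_sets)}
    factors = [(name, np.asarray(frame[name]), levels) for name, levels in level_sets]
    X, names = factorial_matrix(factors)
    return X, cells, names


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(table: pd.DataFrame,
                 cell_factors=("instruction", "disruption", "hemifield_fear"),
                 latency_col: str = "latency_ms") -> pd.DataFrame:
    """Binarize latency within each factorial cell: strictly below the cell
    median is 'Early', at or above it 'Late' (deterministic tie rule), so
    the split stays orthogonal to the other factors.
    """
    out = table.copy()
    out["latency_class"] = pd.NA
    valid = out[latency_col].notna()
    for key, idx in out[valid].groupby(list(cell_factors)).groups.items():
        lat = out.loc[idx, latency_col].to_numpy(float)
        if len(lat) == 0:
            raise ValueError(f"empty factorial cell {key}")
        med = np.median(lat)
        out.loc[idx, "latency_class"] = np.where(lat < med, "Early", "Late")
    cells = out[valid].groupby(list(cell_factors)).size()
    expected = np.prod([len(set(out[f])) for f in cell_factors])
    if len(cells) < expected:
        raise ValueError("some factorial cells contain no valid latencies")
    return out


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    mean: float
    ci_low: float
    ci_high: float
    p_effect: float
    scale: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("credible interval must bracket the mean")


def summarize_contrast(values: np.ndarray, scale: str = "") -> ContrastResult:
    """Mean, 95% CI and P(effect) of per-draw contrast values.

    P(effect) is the posterior mass strictly on the side of zero matching
    the sign of the posterior mean (0.5 when the mean is exactly zero)."""
    values = np.asarray(values, float)
    mean = float(values.mean())
    lo, hi = np.percentile(values, [2.5, 97.5])
    if mean > 0:
        p = float(np.mean(values > 0))
    elif mean < 0:
        p = float(np.mean(values < 0))
    else:
        p = 0.5
    return ContrastResult(mean=mean, ci_low=float(lo), ci_high=float(hi),
                          p_effect=p, scale=scale)


def contrast(cell_draws: pd.DataFrame, weights: dict, scale: str = "") -> ContrastResult:
    """Linear combination of per-draw cell predictions.

    ``cell_draws``: draws x cells frame whose columns are condition tuples
    with the Hemifield confound already marginalised (equal-weight average
    over its levels).  Referencing a hemifield level directly is an error.
    """
    vals = np.zeros(len(cell_draws))
    for cell, w in weights.items():
        key = cell if not isinstance(cell, list) else tuple(cell)
        if any(str(part) in HEMIFIELDS for part in np.atleast_1d(key)):
            raise ValueError("contrasts must not reference the hemifield confound")
        vals = vals + w * cell_draws[key].to_numpy()
    return summarize_contrast(vals, scale=scale)


def _laterality_weights(cells, value_fn) -> dict:
    out = {}
    for c in cells:
        w = value_fn(c)
        if w:
            out[c] = w
    return out


# ---------------------------------------------------------------------------
# model base
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _hier_logprior(b: np.ndarray, log_sd: np.ndarray) -> np.ndarray:
    """Centred random-intercept prior: b_s ~ N(0, sd^2), sd ~ half-Normal(1)
    sampled on the log scale (Jacobian included)."""
    sd = np.exp(np.clip(log_sd, -15, 5))
    return (-0.5 * np.sum(b * b, axis=1) / sd**2 - b.shape[1] * np.log(sd)
            - 0.5 * sd**2 + log_sd)


class _HierarchicalModel(BaseEstimator):
    """Shared fit machinery: parameter layout, priors on unconstrained
    scales, Laplace-preconditioned ensemble sampling, cell predictions."""

    def __init__(self, sampler: SamplerConfig | None = None, prior_scale: float = 1.0):
        self.sampler = sampler
        self.prior_scale = prior_scale

    # subclass hooks -------------------------------------------------------
    _layout: list  # [(name, size), ...] set by _prepare

    def _prepare(self, table: pd.DataFrame) -> None:
        raise NotImplementedError

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _initial_point(self) -> np.ndarray:
        raise NotImplementedError

    # shared ---------------------------------------------------------------
    def _slices(self):
        out, i = {}, 0
        for name, size in self._layout:
            out[name] = slice(i, i + size)
            i += size
        self._dim = i
        return out

    def _idx(self, name: str) -> np.ndarray:
        sl = self._sl[name]
        return np.arange(sl.start, sl.stop)

    def _blocks(self) -> list:
        """DE update blocks: one per fixed-effect group, one per participant
        (all of that participant's random intercepts move together)."""
        raise NotImplementedError

    def _scale_updates(self) -> list:
        raise NotImplementedError

    def _names(self):
        names = []
        for name, size in self._layout:
            names.extend([name] if size == 1 else [f"{name}[{j}]" for j in range(size)])
        return names

    def _reported_indices(self) -> np.ndarray:
        """Fixed effects and intercepts: the parameters contrasts use."""
        idx = []
        for name, _ in self._layout:
            if not (name.startswith("eta") or name.startswith("log_sd")):
                idx.extend(range(self._sl[name].start, self._sl[name].stop))
        return np.asarray(idx)

    def fit(self, table: pd.DataFrame, y=None):
        self._prepare(table)
        cfg = self.sampler or SamplerConfig()
        self.draws_ = sample_posterior(self._log_prob, self._initial_point(),
                                       self._names(), cfg,
                                       blocks=self._blocks(),
                                       scale_updates=self._scale_updates(),
                                       check_indices=self._reported_indices())
        self.report_ = diagnostics(self.draws_, cfg.rhat_max, cfg.ess_min)
        return self

    def _theta(self) -> np.ndarray:
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        return self.draws_.flat()

    def contrast(self, weights: dict, scale: str = "") -> ContrastResult:
        return contrast(self.cell_draws(), weights, scale=scale)


def _check_valid_table(table: pd.DataFrame, need_latency: bool = True) -> pd.DataFrame:
    req = {"participant", "instruction", "disruption", "hemifield_fear", "choice"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    if "qc_flag" in table.columns:
        table = table[table["qc_flag"] == "valid"]
    elif "qc_true" in table.columns:
        table = table[table["qc_true"] == "valid"]
    if need_latency:
        table = table[table["latency_ms"].notna()]
    if len(table) == 0:
        raise ValueError("no valid trials")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# shifted lognormal latency model
# ---------------------------------------------------------------------------

class ShiftedLognormalModel(_HierarchicalModel):
    """Hierarchical shifted-lognormal latency model.

    latency_s ~ delta + LogNormal(mu, sigma) with
    mu    = X_factorial(Instr x Disr x Emotion) beta + hemifield confound
            + participant intercept,
    sigma = exp(log sigma0 + participant intercept),
    delta = ub_s * logistic(q0 + participant intercept), a smooth bounded
            link with ub_s = 0.95 x the participant's fastest valid latency
            (keeps the shift below every observed latency without a hard
            likelihood wall).
    """

    scale = "ms"

    def _prepare(self, table: pd.DataFrame) -> None:
        table = _check_valid_table(table)
        self.table_ = table
        lat = table["latency_ms"].to_numpy(float) / 1000.0
        if np.any(lat <= 0):
            raise ValueError("latencies must be positive")
        self._lat = lat
        subj_levels = sorted(table["participant"].unique())
        self._subj = np.searchsorted(subj_levels, table["participant"].to_numpy())
        self._n_subj = len(subj_levels)
        self._minlat = np.array([lat[self._subj == s].min() for s in range(self._n_subj)])
        X, names = factorial_matrix([
            ("instruction", table["instruction"].to_numpy(), INSTRUCTIONS),
            ("disruption", table["disruption"].to_numpy(), DISRUPTIONS),
            ("emotion", table["choice"].to_numpy(), EMOTIONS),
        ])
        hemi = _sum_code(table["hemifield_fear"].to_numpy(), HEMIFIELDS)
        self._X = np.concatenate([X, hemi], axis=1)
        self._beta_names = names + ["hemifield[0]"]
        p = self._X.shape[1]
        s = self._n_subj
        self._ub = 0.95 * self._minlat
        self._layout = [("beta_mu", p), ("log_sigma0", 1), ("q_delta0", 1),
                        ("eta_mu", s), ("eta_sigma", s), ("eta_delta", s),
                        ("log_sd_mu", 1), ("log_sd_sigma", 1), ("log_sd_delta", 1)]
        self._sl = self._slices()

    def _initial_point(self) -> np.ndarray:
        x = np.zeros(self._dim)
        sl = self._sl
        delta0 = 0.5 * self._minlat.min()
        x[sl["beta_mu"].start] = np.log(max(np.mean(self._lat) - delta0, 0.05))
        x[sl["log_sigma0"]] = np.log(0.35)
        x[sl["q_delta0"]] = 0.0  # delta at roughly half its upper bound
        x[sl["log_sd_mu"]] = x[sl["log_sd_sigma"]] = x[sl["log_sd_delta"]] = np.log(0.1)
        return x

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        sl = self._sl
        beta = theta[:, sl["beta_mu"]]
        ls0 = theta[:, sl["log_sigma0"]][:, 0]
        q0 = theta[:, sl["q_delta0"]][:, 0]
        b_mu = theta[:, sl["eta_mu"]]        # centred deviations
        b_sig = theta[:, sl["eta_sigma"]]
        b_del = theta[:, sl["eta_delta"]]
        mu = self._X @ beta.T + b_mu.T[self._subj]              # (n, W)
        sigma = np.exp(np.clip(ls0[None, :] + b_sig.T[self._subj], -10, 3))
        delta_subj = self._ub[:, None] * _inv_logit(q0[None, :] + b_del.T)  # (S, W)
        delta = delta_subj[self._subj]
        t = self._lat[:, None] - delta
        ok = t > 0
        logt = np.log(np.where(ok, t, 1.0))
        ll = np.where(ok,
                      -logt - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                      - (logt - mu) ** 2 / (2 * sigma**2),
                      -np.inf).sum(axis=0)
        ps = self.prior_scale
        lp = -0.5 * ((beta[:, 0] - np.log(0.25)) / ps) ** 2
        lp += -0.5 * np.sum((beta[:, 1:] / ps) ** 2, axis=1)
        lp += -0.5 * ((ls0 + 1.0) / ps) ** 2 - 0.5 * (q0 / (1.5 * ps)) ** 2
        for nm, b in (("log_sd_mu", b_mu), ("log_sd_sigma", b_sig),
                      ("log_sd_delta", b_del)):
            lp += _hier_logprior(b, theta[:, sl[nm]][:, 0])
        return ll + lp

    def _subject_partial(self, s: int):
        """Posterior terms touched by participant s's random intercepts."""
        mask = self._subj == s
        X = self._X[mask]
        lat = self._lat[mask]
        ub = self._ub[s]
        sl = self._sl

        def partial(theta):
            theta = np.atleast_2d(theta)
            bm = theta[:, sl["eta_mu"].start + s]
            bs = theta[:, sl["eta_sigma"].start + s]
            bd = theta[:, sl["eta_delta"].start + s]
            mu = X @ theta[:, sl["beta_mu"]].T + bm[None, :]
            sigma = np.exp(np.clip(theta[:, sl["log_sigma0"]][:, 0][None, :] + bs[None, :],
                                   -10, 3))
            delta = ub * _inv_logit(theta[:, sl["q_delta0"]][:, 0] + bd)[None, :]
            t = lat[:, None] - delta
            ok = t > 0
            logt = np.log(np.where(ok, t, 1.0))
            ll = np.where(ok, -logt - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                          - (logt - mu) ** 2 / (2 * sigma**2), -np.inf).sum(axis=0)
            for b, nm in ((bm, "log_sd_mu"), (bs, "log_sd_sigma"), (bd, "log_sd_delta")):
                sd = np.exp(np.clip(theta[:, sl[nm]][:, 0], -15, 5))
                ll += -0.5 * (b / sd) ** 2
            return ll

        return partial

    def _blocks(self) -> list:
        ix = self._idx
        blocks = [ix("beta_mu"), np.concatenate([ix("log_sigma0"), ix("q_delta0")])]
        for s in range(self._n_subj):
            blocks.append(Block(np.array([self._sl["eta_mu"].start + s,
                                          self._sl["eta_sigma"].start + s,
                                          self._sl["eta_delta"].start + s]),
                                partial=self._subject_partial(s)))
        # ridge blocks: each location intercept moves jointly with its
        # random intercepts, so proposals can travel along the
        # intercept-vs-deviation-mean ridge
        blocks.append(np.concatenate([[self._sl["beta_mu"].start], ix("eta_mu")]))
        blocks.append(np.concatenate([ix("log_sigma0"), ix("eta_sigma")]))
        blocks.append(np.concatenate([ix("q_delta0"), ix("eta_delta")]))
        # the location/spread/shift intercepts trade off along a common
        # nonlinear ridge of the shifted-lognormal likelihood
        blocks.append(np.concatenate([[self._sl["beta_mu"].start],
                                      ix("log_sigma0"), ix("q_delta0")]))
        return blocks

    def _scale_updates(self) -> list:
        return [ScaleUpdate(self._sl[f"log_sd_{nm}"].start,
                            tuple(self._idx(f"eta_{nm}")))
                for nm in ("mu", "sigma", "delta")]

    # predictions ----------------------------------------------------------
    def cell_draws(self) -> pd.DataFrame:
        """Posterior-predictive mean latency (ms) per Instruction x
        Disruption x Emotion cell at the average participant, hemifield
        marginalised by equal-weight averaging."""
        theta = self._theta()
        sl = self._sl
        beta = theta[:, sl["beta_mu"]]
        sigma = np.exp(theta[:, sl["log_sigma0"]][:, 0])
        delta = self._ub.min() * _inv_logit(theta[:, sl["q_delta0"]][:, 0])
        Xc, cells, _ = _cell_matrix([
            ("instruction", INSTRUCTIONS), ("disruption", DISRUPTIONS),
            ("emotion", EMOTIONS),
        ])
        # hemifield column marginalises to zero under sum coding
        mu = beta[:, :Xc.shape[1]] @ Xc.T
        mean_ms = 1000.0 * (delta[:, None] + np.exp(mu + (sigma**2 / 2)[:, None]))
        return pd.DataFrame(mean_ms, columns=pd.Index(cells))

    def planned_contrasts(self) -> dict:
        cd = self.cell_draws()
        cells = list(cd.columns)
        res = {}
        w = {}
        for c in cells:
            instr, disr, emo = c
            w[c] = (1 / 8 if disr != "None" else -1 / 4)
        res["disruption_presence"] = contrast(cd, w, scale=self.scale)
        res["yield_laterality"] = contrast(cd, {
            c: (1 / 2 if c[1] == "Contra" else -1 / 2)
            for c in cells if c[0] == "Yield" and c[1] != "None"
        }, scale=self.scale)
        res["yield_laterality_x_emotion"] = contrast(cd, {
            c: (1.0 if c[1] == "Contra" else -1.0) * (1.0 if c[2] == "fear" else -1.0)
            for c in cells if c[0] == "Yield" and c[1] != "None"
        }, scale=self.scale)
        res["instruction_x_laterality_x_emotion"] = contrast(cd, {
            c: ((1.0 if c[0] == "Yield" else -1.0)
                * (1.0 if c[1] == "Contra" else -1.0)
                * (1.0 if c[2] == "fear" else -1.0))
            for c in cells if c[1] != "None"
        }, scale=self.scale)
        return res


# ---------------------------------------------------------------------------
# Bernoulli choice model
# ---------------------------------------------------------------------------

class BernoulliChoiceModel(_HierarchicalModel):
    """Hierarchical logistic model of fear-face preference theta over
    Instruction x Disruption x binarized Latency (plus hemifield confound
    and participant intercepts)."""

    scale = "rate"

    def _prepare(self, table: pd.DataFrame) -> None:
        table = _check_valid_table(table)
        if "latency_class" not in table.columns or table["latency_class"].isna().any():
            table = median_split(table)
        self.table_ = table
        self._y = (table["choice"] == "fear").to_numpy(float)
        subj_levels = sorted(table["participant"].unique())
        self._subj = np.searchsorted(subj_levels, table["participant"].to_numpy())
        self._n_subj = len(subj_levels)
        X, names = factorial_matrix([
            ("instruction", table["instruction"].to_numpy(), INSTRUCTIONS),
            ("disruption", table["disruption"].to_numpy(), DISRUPTIONS),
            ("latency", table["latency_class"].to_numpy(), LATCLASSES),
        ])
        hemi = _sum_code(table["hemifield_fear"].to_numpy(), HEMIFIELDS)
        self._X = np.concatenate([X, hemi], axis=1)
        self._layout = [("beta", self._X.shape[1]), ("eta", self._n_subj), ("log_sd", 1)]
        self._sl = self._slices()

    def _initial_point(self) -> np.ndarray:
        x = np.zeros(self._dim)
        x[self._sl["log_sd"]] = np.log(0.1)
        return x

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        sl = self._sl
        beta = theta[:, sl["beta"]]
        b = theta[:, sl["eta"]]
        lin = self._X @ beta.T + b.T[self._subj]                # (n, W)
        sign = np.where(self._y[:, None] > 0.5, 1.0, -1.0)
        ll = -_softplus(-sign * lin).sum(axis=0)
        ps = self.prior_scale
        lp = -0.5 * np.sum((beta / ps) ** 2, axis=1)
        lp += _hier_logprior(b, theta[:, sl["log_sd"]][:, 0])
        return ll + lp

    def _subject_partial(self, s: int):
        mask = self._subj == s
        X = self._X[mask]
        sign = np.where(self._y[mask] > 0.5, 1.0, -1.0)[:, None]
        sl = self._sl

        def partial(theta):
            theta = np.atleast_2d(theta)
            b = theta[:, sl["eta"].start + s]
            lin = X @ theta[:, sl["beta"]].T + b[None, :]
            ll = -_softplus(-sign * lin).sum(axis=0)
            sd = np.exp(np.clip(theta[:, sl["log_sd"]][:, 0], -15, 5))
            return ll - 0.5 * (b / sd) ** 2

        return partial

    def _blocks(self) -> list:
        blocks = [self._idx("beta")]
        for s in range(self._n_subj):
            blocks.append(Block(np.array([self._sl["eta"].start + s]),
                                partial=self._subject_partial(s)))
        blocks.append(np.concatenate([[self._sl["beta"].start], self._idx("eta")]))
        return blocks

    def _scale_updates(self) -> list:
        return [ScaleUpdate(self._sl["log_sd"].start, tuple(self._idx("eta")))]

    def cell_draws(self) -> pd.DataFrame:
        """Fear-preference rate per Instruction x Disruption x Latency cell
        at the average participant (hemifield marginalised)."""
        theta = self._theta()
        beta = theta[:, self._sl["beta"]]
        Xc, cells, _ = _cell_matrix([
            ("instruction", INSTRUCTIONS), ("disruption", DISRUPTIONS),
            ("latency", LATCLASSES),
        ])
        rate = _inv_logit(beta[:, :Xc.shape[1]] @ Xc.T)
        return pd.DataFrame(rate, columns=pd.Index(cells))

    def planned_contrasts(self) -> dict:
        cd = self.cell_draws()
        cells = list(cd.columns)
        res = {
            "latency_main": contrast(cd, {
                c: (1 / 6 if c[2] == "Early" else -1 / 6) for c in cells
            }, scale=self.scale),
            "disruption_presence": contrast(cd, {
                c: (1 / 8 if c[1] != "None" else -1 / 4) for c in cells
            }, scale=self.scale),
            "yield_laterality_x_latency": contrast(cd, {
                c: ((1.0 if c[1] == "Contra" else -1.0)
                    * (1.0 if c[2] == "Early" else -1.0))
                for c in cells if c[0] == "Yield" and c[1] != "None"
            }, scale=self.scale),
            "instruction_x_laterality_x_latency": contrast(cd, {
                c: ((1.0 if c[0] == "Yield" else -1.0)
                    * (1.0 if c[1] == "Contra" else -1.0)
                    * (1.0 if c[2] == "Early" else -1.0))
                for c in cells if c[1] != "None"
            }, scale=self.scale),
        }
        return res


# ---------------------------------------------------------------------------
# hierarchical drift-diffusion model
# ---------------------------------------------------------------------------

class WienerDDMModel(_HierarchicalModel):
    """Joint hierarchical drift-diffusion model of (choice, latency).

    v and z vary over Instruction x Disruption(None/Ipsi/Contra) x
    Hemifield (full factorial); a and t0 (log links) over Instruction x
    Disruption presence.  Fear choices map to the upper boundary.
    Participant random intercepts on every parameter's link scale; t0
    bounded above by 0.95 x each participant's fastest valid latency.
    """

    scale = "native"

    def _prepare(self, table: pd.DataFrame) -> None:
        table = _check_valid_table(table)
        self.table_ = table
        self._lat = table["latency_ms"].to_numpy(float)[:, None] / 1000.0
        self._upper = (table["choice"] == "fear").to_numpy()[:, None]
        subj_levels = sorted(table["participant"].unique())
        self._subj = np.searchsorted(subj_levels, table["participant"].to_numpy())
        self._n_subj = len(subj_levels)
        lat = self._lat[:, 0]
        self._minlat = np.array([lat[self._subj == s].min() for s in range(self._n_subj)])
        self._Xvz, self._vz_names = factorial_matrix([
            ("instruction", table["instruction"].to_numpy(), INSTRUCTIONS),
            ("disruption", table["disruption"].to_numpy(), DISRUPTIONS),
            ("hemifield", table["hemifield_fear"].to_numpy(), HEMIFIELDS),
        ])
        presence = np.where(table["disruption"].to_numpy() == "None", "None", "Present")
        self._Xat, self._at_names = factorial_matrix([
            ("instruction", table["instruction"].to_numpy(), INSTRUCTIONS),
            ("presence", presence, PRESENCE),
        ])
        # t0 is bounded by the fastest response among the trials it applies
        # to: the minimum latency within each (participant, instruction,
        # presence) group
        grp = pd.DataFrame({
            "s": self._subj, "i": table["instruction"].to_numpy(), "p": presence,
            "lat": lat,
        })
        self._minlat_group = grp.groupby(["s", "i", "p"])["lat"].transform("min").to_numpy()
        p_vz, p_at, s = self._Xvz.shape[1], self._Xat.shape[1], self._n_subj
        self._layout = [("beta_v", p_vz), ("beta_z", p_vz),
                        ("beta_a", p_at), ("beta_t0", p_at),
                        ("eta_v", s), ("eta_z", s), ("eta_a", s), ("eta_t0", s),
                        ("log_sd_v", 1), ("log_sd_z", 1), ("log_sd_a", 1), ("log_sd_t0", 1)]
        self._sl = self._slices()

    def _initial_point(self) -> np.ndarray:
        x = np.zeros(self._dim)
        sl = self._sl
        x[sl["beta_a"].start] = 0.0                       # a ~ 1
        x[sl["beta_t0"].start] = np.log(0.6 * self._minlat.min())
        for nm in ("log_sd_v", "log_sd_z", "log_sd_a", "log_sd_t0"):
            x[sl[nm]] = np.log(0.1)
        return x

    def _param_fields(self, theta: np.ndarray):
        sl = self._sl
        v = self._Xvz @ theta[:, sl["beta_v"]].T + theta[:, sl["eta_v"]].T[self._subj]
        zl = self._Xvz @ theta[:, sl["beta_z"]].T + theta[:, sl["eta_z"]].T[self._subj]
        la = self._Xat @ theta[:, sl["beta_a"]].T + theta[:, sl["eta_a"]].T[self._subj]
        lt = self._Xat @ theta[:, sl["beta_t0"]].T + theta[:, sl["eta_t0"]].T[self._subj]
        return v, _inv_logit(zl), np.exp(np.clip(la, -5, 3)), np.exp(np.clip(lt, -12, 1))

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        sl = self._sl
        v, z, a, t0 = self._param_fields(theta)
        z = np.clip(z, 1e-6, 1 - 1e-6)
        ll = wfpt_loglik_sum(self._lat[:, 0], self._upper[:, 0], v, a, z, t0)
        bad = (t0 > 0.95 * self._minlat_group[:, None]).any(axis=0)
        ll = np.where(bad, -np.inf, ll)
        ps = self.prior_scale
        lp = -0.5 * np.sum((theta[:, sl["beta_v"]] / ps) ** 2, axis=1)
        lp += -0.5 * np.sum((theta[:, sl["beta_z"]] / ps) ** 2, axis=1)
        ba = theta[:, sl["beta_a"]].copy()
        bt = theta[:, sl["beta_t0"]].copy()
        bt[:, 0] -= np.log(0.18)
        lp += -0.5 * np.sum((ba / (0.5 * ps)) ** 2, axis=1)
        lp += -0.5 * np.sum((bt / (0.5 * ps)) ** 2, axis=1)
        for nm in ("v", "z", "a", "t0"):
            lp += _hier_logprior(theta[:, sl[f"eta_{nm}"]],
                                 theta[:, sl[f"log_sd_{nm}"]][:, 0])
        return ll + lp

    def _subject_partial(self, s: int):
        mask = self._subj == s
        Xvz = self._Xvz[mask]
        Xat = self._Xat[mask]
        lat = self._lat[mask, 0]
        upper = self._upper[mask, 0]
        mlg = self._minlat_group[mask]
        sl = self._sl

        def partial(theta):
            theta = np.atleast_2d(theta)
            es = {nm: theta[:, sl[f"eta_{nm}"].start + s] for nm in ("v", "z", "a", "t0")}
            v = Xvz @ theta[:, sl["beta_v"]].T + es["v"][None, :]
            z = np.clip(_inv_logit(Xvz @ theta[:, sl["beta_z"]].T + es["z"][None, :]),
                        1e-6, 1 - 1e-6)
            a = np.exp(np.clip(Xat @ theta[:, sl["beta_a"]].T + es["a"][None, :], -5, 3))
            t0 = np.exp(np.clip(Xat @ theta[:, sl["beta_t0"]].T + es["t0"][None, :], -12, 1))
            ll = wfpt_loglik_sum(lat, upper, v, a, z, t0)
            bad = (t0 > 0.95 * mlg[:, None]).any(axis=0)
            ll = np.where(bad, -np.inf, ll)
            for nm in ("v", "z", "a", "t0"):
                sd = np.exp(np.clip(theta[:, sl[f"log_sd_{nm}"]][:, 0], -15, 5))
                ll += -0.5 * (es[nm] / sd) ** 2
            return ll

        return partial

    def _blocks(self) -> list:
        ix = self._idx
        blocks = [ix("beta_v"), ix("beta_z"), ix("beta_a"), ix("beta_t0"),
                  np.concatenate([ix("beta_v"), ix("beta_z")]),
                  np.concatenate([ix("beta_a"), ix("beta_t0")])]
        for s in range(self._n_subj):
            blocks.append(Block(np.array([self._sl[f"eta_{nm}"].start + s
                                          for nm in ("v", "z", "a", "t0")]),
                                partial=self._subject_partial(s)))
        for nm in ("v", "z", "a", "t0"):
            blocks.append(np.concatenate([[self._sl[f"beta_{nm}"].start],
                                          ix(f"eta_{nm}")]))
        return blocks

    def _scale_updates(self) -> list:
        return [ScaleUpdate(self._sl[f"log_sd_{nm}"].start,
                            tuple(self._idx(f"eta_{nm}")))
                for nm in ("v", "z", "a", "t0")]

    # predictions ----------------------------------------------------------
    def cell_draws(self, param: str = "z") -> pd.DataFrame:
        """Native-scale parameter per condition cell at the average
        participant.  v/z cells: Instruction x Disruption, hemifield
        marginalised; a/t0 cells: Instruction x Disruption presence."""
        theta = self._theta()
        sl = self._sl
        if param in ("v", "z"):
            Xc, cells, _ = _cell_matrix([
                ("instruction", INSTRUCTIONS), ("disruption", DISRUPTIONS),
            ])
            # hemifield columns marginalise to zero under sum coding; the
            # cell matrix above simply omits them
            full_Xc, full_cells, _ = _cell_matrix([
                ("instruction", INSTRUCTIONS), ("disruption", DISRUPTIONS),
                ("hemifield", HEMIFIELDS),
            ])
            beta = theta[:, sl[f"beta_{param}"]]
            pred_full = beta @ full_Xc.T
            # average the two hemifield levels per (instruction, disruption)
            out = {}
            for i, c in enumerate(cells):
                cols = [j for j, fc in enumerate(full_cells) if fc[:2] == c]
                out[c] = pred_full[:, cols].mean(axis=1)
            vals = pd.DataFrame(out)
            if param == "z":
                vals = pd.DataFrame(_inv_logit(vals.to_numpy()), columns=vals.columns)
            return vals
        if param in ("a", "t0"):
            Xc, cells, _ = _cell_matrix([
                ("instruction", INSTRUCTIONS), ("presence", PRESENCE),
            ])
            beta = theta[:, sl[f"beta_{param}"]]
            return pd.DataFrame(np.exp(beta @ Xc.T), columns=pd.Index(cells))
        raise ValueError(f"unknown parameter {param!r}")

    def planned_contrasts(self) -> dict:
        res = {}
        for param in ("v", "z"):
            cd = self.cell_draws(param)
            cells = list(cd.columns)
            res[f"{param}_yield_laterality"] = contrast(cd, {
                c: (1.0 if c[1] == "Contra" else -1.0)
                for c in cells if c[0] == "Yield" and c[1] != "None"
            }, scale=param)
            res[f"{param}_instruction_x_laterality"] = contrast(cd, {
                c: ((1.0 if c[0] == "Oppose" else -1.0)
                    * (1.0 if c[1] == "Contra" else -1.0))
                for c in cells if c[1] != "None"
            }, scale=param)
        for param, unit in (("a", "a"), ("t0", "s")):
            cd = self.cell_draws(param)
            cells = list(cd.columns)
            res[f"{param}_instruction_main"] = contrast(cd, {
                c: (1 / 2 if c[0] == "Oppose" else -1 / 2) for c in cells
            }, scale=unit)
            res[f"{param}_disruption_main"] = contrast(cd, {
                c: (1 / 2 if c[1] == "Present" else -1 / 2) for c in cells
            }, scale=unit)
            res[f"{param}_instruction_x_disruption"] = contrast(cd, {
                c: ((1.0 if c[0] == "Oppose" else -1.0)
                    * (1.0 if c[1] == "Present" else -1.0)) for c in cells
            }, scale=unit)
        return res


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------

_FAMILIES = {
    "latency": ShiftedLognormalModel,
    "shifted_lognormal": ShiftedLognormalModel,
    "choice": BernoulliChoiceModel,
    "bernoulli": BernoulliChoiceModel,
    "ddm": WienerDDMModel,
    "wiener": WienerDDMModel,
}


def fit_model(table: pd.DataFrame, family: str = "latency",
              sampler: SamplerConfig | None = None, **kwargs):
    """Fit one of the three response-family models; returns the fitted
    estimator (draws in ``.draws_``, convergence report in ``.report_``)."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {sorted(_FAMILIES)}")
    return _FAMILIES[family](sampler=sampler, **kwargs).fit(table)


def planned_contrast_suite(models: dict) -> dict:
    """The planned posterior contrasts of every fitted model, as
    {model: {contrast name: ContrastResult}}.  Latency contrasts are in ms
    (posterior-predictive mean differencing), choice contrasts in rate
    units, drift-diffusion contrasts on each parameter's native scale."""
    out = {}
    for name, model in models.items():
        if model is None:
            raise ValueError(f"missing model {name!r}")
        out[name] = model.planned_contrasts()
    return out
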