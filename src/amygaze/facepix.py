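"""Pixelwise fixed-effects inference on face difference images.

Each trial contributes an attended-minus-neglected difference image; an
ordinary least-squares model with Disruption (None, Ipsi, Contra) and
binarized Latency (Early, Late) cells plus an orientation-side confound is
fitted independently at every pixel.  Family-wise error over pixels is
controlled with a permutation max-statistic null (labels exchanged within
condition blocks), inference restricted to an upper-face mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["StatMap", "PixelwiseGLM", "fit_pixelwise_glm", "fwe_threshold"]


@dataclass
class StatMap:
    """Per-pixel test statistic with its degrees of freedom."""

    stat: np.ndarray
    stat_type: str            # 't' or 'F'
    df: tuple                 # (df1, df2) for F, (df,) for t
    contrast: str = ""
    p_fwe: np.ndarray | None = None
    threshold: float | None = None
    peaks: list = field(default_factory=list)

    def __post_init__(self):
        if self.stat_type == "F" and np.nanmin(self.stat) < 0:
            raise ValueError("F statistics must be non-negative")


def _cell_design(labels: pd.DataFrame):
    """Cell-means design: one indicator per Disruption x Latency cell plus a
    centred orientation-side confound column."""
    disr_levels = list(pd.unique(labels["disruption"]))
    lat_levels = ["Early", "Late"]
    cells = [(d, l) for d in disr_levels for l in lat_levels]
    X = np.zeros((len(labels), len(cells) + 1))
    for j, (d, l) in enumerate(cells):
        X[:, j] = ((labels["disruption"] == d) & (labels["latency_class"] == l)).to_numpy(float)
    side = (labels["side"] == "R").to_numpy(float)
    X[:, -1] = side - side.mean()
    return X, cells, disr_levels


def _glm_stats(Y: np.ndarray, X: np.ndarray, contrasts: dict):
    """OLS per pixel; returns per-contrast stat images and error df.

    ``contrasts`` maps name -> (C, kind) with C of shape (q, p).
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Y                       # p x npx
    resid = Y - X @ beta
    dfe = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dfe
    out = {}
    for name, (C, kind) in contrasts.items():
        C = np.atleast_2d(np.asarray(C, float))
        q = C.shape[0]
        cb = C @ beta                     # q x npx
        M = np.linalg.inv(C @ xtx_inv @ C.T)
        if kind == "t":
            se = np.sqrt(sigma2 / M[0, 0])
            out[name] = (cb[0] / np.maximum(se, 1e-300), ("t", (dfe,)))
        else:
            quad = np.einsum("qj,qr,rj->j", cb, M, cb)
            F = quad / (q * np.maximum(sigma2, 1e-300))
            out[name] = (np.maximum(F, 0.0), ("F", (q, dfe)))
    return out


class PixelwiseGLM(BaseEstimator):
    """Fixed-effects pixelwise GLM over Disruption x Latency cells.

    ``fit`` computes, per pixel, the omnibus F over the three per-disruption
    Early-minus-Late contrasts, the Disruption x Latency interaction F, and
    one Early-minus-Late t map per disruption level.  Fitted attributes:
    ``maps_`` (name -> StatMap), ``cells_``, ``design_``.
    """

    def __init__(self, min_per_cell: int = 2):
        self.min_per_cell = min_per_cell

    def fit(self, images: np.ndarray, labels: pd.DataFrame):
        images = np.asarray(images, float)
        if images.ndim != 3:
            raise ValueError("images must be a (trials, height, width) stack")
        if len(images) != len(labels):
            raise ValueError("one label row per image required")
        counts = labels.groupby(["disruption", "latency_class"]).size()
        if (counts < self.min_per_cell).any() or len(counts) < 2:
            raise ValueError(f"need >= {self.min_per_cell} images per design cell")
        X, cells, disr_levels = _cell_design(labels)
        self.shape_ = images.shape[1:]
        Y = images.reshape(len(images), -1)
        contrasts = self._contrasts(cells, disr_levels)
        stats = _glm_stats(Y, X, contrasts)
        self.maps_ = {
            name: StatMap(stat=s.reshape(self.shape_), stat_type=k[0], df=k[1], contrast=name)
            for name, (s, k) in stats.items()
        }
        self.design_ = X
        self.cells_ = cells
        self.labels_ = labels.reset_index(drop=True)
        self.images_ = images
        return self

    def _contrasts(self, cells, disr_levels):
        p = len(cells) + 1
        contrasts = {}
        rows = []
        for d in disr_levels:
            c = np.zeros(p)
            c[cells.index((d, "Early"))] = 1.0
            c[cells.index((d, "Late"))] = -1.0
            rows.append(c)
            contrasts[f"early_minus_late[{d}]"] = (c[None, :], "t")
        contrasts["omnibus_early_late"] = (np.array(rows), "F")
        if len(disr_levels) > 1:
            inter = []
            ref = rows[0]
            for c in rows[1:]:
                inter.append(c - ref)
            contrasts["disruption_x_latency"] = (np.array(inter), "F")
        return contrasts

    def permutation_fwe(self, map_name: str, mask: np.ndarray, n_perm: int = 1000,
                        alpha: float = 0.05, seed: int = 0) -> StatMap:
        """Max-statistic permutation FWE for one fitted map.

        Early/Late labels are permuted within Disruption x side blocks (the
        exchangeable units are trials within a condition), the model refitted
        and the maximum |t| or F over the mask collected to form the null.
        """
        if not hasattr(self, "maps_"):
            raise ValueError("fit the model first")
        return fwe_threshold(self, map_name, mask, n_perm=n_perm, alpha=alpha, seed=seed)


def fit_pixelwise_glm(images: np.ndarray, labels: pd.DataFrame) -> dict:
    """Functional wrapper: returns the fitted map dictionary."""
    return PixelwiseGLM().fit(images, labels).maps_


def fwe_threshold(model: PixelwiseGLM, map_name: str, mask: np.ndarray,
                  n_perm: int = 1000, alpha: float = 0.05, seed: int = 0) -> StatMap:
    """Permutation max-statistic FWE control for ``model.maps_[map_name]``.

    Returns a new StatMap with per-pixel FWE-corrected p (inside the mask),
    the alpha-level threshold, and the suprathreshold peak list.  Pixels
    outside the mask are never suprathreshold.
    """
    if mask.shape != model.shape_:
        raise ValueError("mask shape must match the images")
    if not mask.any():
        raise ValueError("empty mask")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = model.labels_
    blocks = labels.groupby(["disruption", "side"]).groups
    if max(len(ix) for ix in blocks.values()) < 2:
        raise ValueError("too few exchangeable trials within blocks")
    observed = model.maps_[map_name]
    is_t = observed.stat_type == "t"
    obs = np.abs(observed.stat) if is_t else observed.stat
    rng = np.random.default_rng(seed)
    Y = model.images_.reshape(len(model.images_), -1)[:, mask.ravel()]
    # rebuild the cell design directly from permuted label arrays
    disr = labels["disruption"].to_numpy()
    lab0 = labels["latency_class"].to_numpy()
    side_col = model.design_[:, -1]
    block_ix = [np.asarray(ix) for ix in blocks.values()]
    cells = model.cells_
    disr_levels = list(dict.fromkeys(d for d, _ in cells))
    contrast = model._contrasts(cells, disr_levels)[map_name]
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        lab = lab0.copy()
        for ix in block_ix:
            lab[ix] = lab[ix[rng.permutation(len(ix))]]
        Xp = np.empty((len(lab), len(cells) + 1))
        for j, (d, l) in enumerate(cells):
            Xp[:, j] = (disr == d) & (lab == l)
        Xp[:, -1] = side_col
        s, _ = _glm_stats(Y, Xp, {map_name: contrast})[map_name]
        null_max[b] = np.abs(s).max() if is_t else s.max()
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    p_fwe = np.full(model.shape_, np.nan)
    pvals = (1.0 + (null_max[None, :] >= obs[mask][:, None]).sum(axis=1)) / (n_perm + 1.0)
    p_fwe[mask] = pvals
    supra = mask & (obs > threshold)
    peaks = []
    if supra.any():
        order = np.argsort(obs[supra])[::-1]
        coords = np.argwhere(supra)[order]
        for y, x in coords[:10]:
            peaks.append({"pixel": (int(y), int(x)), "stat": float(obs[y, x]),
                          "p_fwe": float(p_fwe[y, x])})
    return StatMap(stat=observed.stat, stat_type=observed.stat_type, df=observed.df,
                   contrast=map_name, p_fwe=p_fwe, threshold=threshold, peaks=peaks)
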