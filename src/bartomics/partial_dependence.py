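"""Partial dependence on the probit scale with Bayesian credible bands.

The partial dependence of a feature (or pair) is the model's probit prediction
with that feature clamped to a value, averaged over the training distribution
of all other features.  Averaging is done inside each posterior draw, so every
evaluation point carries a full set of posterior probit values from which 0.95
credible intervals are formed.  Risk surfaces are reported as log-odds of the
probability at the posterior-mean probit, log(Phi(f)/(1 - Phi(f))): 0 means
case and control are equally likely, positive values mean elevated risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

from . import _mcmc
from .bart import BartPosterior
from .cohort import FeatureTable

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))


def _log_odds(mean_probit: np.ndarray) -> np.ndarray:
    p = ndtr(mean_probit)
    return np.log(p) - np.log1p(-p)


@dataclass
class PDSurface:
    """Partial-dependence evaluations with per-point posterior draws.

    1D: ``eval_points`` has shape (k, 1) holding raw feature values (with
    ``quantiles`` recording the grid's quantile levels when applicable).
    2D: ``eval_points`` has shape (k, 2), a flattened regular grid, with
    ``grid_shape`` recording the (n0, n1) axis lengths.
    """

    feature_ids: list
    eval_points: np.ndarray  # (k, 1) or (k, 2) raw feature values
    probit_draws: np.ndarray  # (k, n_draws)
    quantiles: Optional[np.ndarray] = None
    grid_shape: Optional[Tuple[int, int]] = None

    def __post_init__(self):
        for ax in range(self.eval_points.shape[1]):
            axis_vals = (self.eval_points[:, ax] if self.grid_shape is None
                         else np.unique(self.eval_points[:, ax]))
            if np.any(np.diff(axis_vals) < 0):
                raise ValueError("evaluation grid must be increasing per axis")
        if not np.isfinite(self.probit_draws).all():
            raise ValueError("probit draws must be finite")

    @property
    def mean_probit(self) -> np.ndarray:
        return self.probit_draws.mean(axis=1)

    def credible_interval(self, level: float = 0.95):
        lo = (1.0 - level) / 2.0
        return (np.quantile(self.probit_draws, lo, axis=1),
                np.quantile(self.probit_draws, 1.0 - lo, axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        """log-odds of the probability at the posterior-mean probit; exactly 0
        where the mean probit is 0 (equal risk)."""
        return _log_odds(self.mean_probit)

    def log_odds_grid(self) -> np.ndarray:
        if self.grid_shape is None:
            raise ValueError("not a 2D surface")
        return self.log_odds.reshape(self.grid_shape)


def _pd_eval(posterior: BartPosterior, table: FeatureTable, fidx, fvals):
    X = np.ascontiguousarray(table.values[:, [table.column(f)
                                              for f in posterior.feature_ids]]
                             if table.feature_ids != posterior.feature_ids
                             else table.values)
    f0 = int(fidx[0])
    f1 = int(fidx[1]) if len(fidx) > 1 else -1
    draws = _mcmc._pd_average(
        posterior.node_feature, posterior.node_threshold, posterior.node_value,
        posterior.node_left, posterior.node_right, posterior.tree_offsets,
        posterior.n_draws, posterior.m, X, f0, f1,
        np.ascontiguousarray(fvals, dtype=float), posterior.offset)
    return draws


def pd_1d(posterior: BartPosterior, table: FeatureTable, feature: str,
          quantiles: Sequence[float] = DEFAULT_QUANTILES,
          values: Optional[Sequence[float]] = None) -> PDSurface:
    """1D partial dependence at empirical feature quantiles.

    For each quantile q, the feature is clamped to its empirical q-quantile in
    every training sample and predictions are averaged within each posterior
    draw.  Pass ``values`` to evaluate at explicit raw feature values instead.
    """
    j = posterior.feature_ids.index(feature) if feature in posterior.feature_ids \
        else _raise_unknown(feature)
    col = table.values[:, table.column(feature)]
    if values is not None:
        pts = np.asarray(values, dtype=float)
        qs = None
    else:
        qs = np.asarray(quantiles, dtype=float)
        if ((qs < 0) | (qs > 1)).any():
            raise ValueError("quantiles must lie in [0, 1]")
        pts = np.quantile(col, qs)
    fvals = pts.reshape(-1, 1)
    draws = _pd_eval(posterior, table, [j], np.column_stack([pts, pts * 0]))
    return PDSurface(feature_ids=[feature], eval_points=fvals,
                     probit_draws=draws, quantiles=qs)


def _raise_unknown(feature):
    raise KeyError(f"unknown feature: {feature!r}")


def pd_2d(posterior: BartPosterior, table: FeatureTable,
          pair: Tuple[str, str], grid_size: int = 20) -> PDSurface:
    """2D partial dependence on a regular grid spanning observed ranges.

    Both features are clamped to each grid point in all training samples;
    predictions are averaged per draw.  Grid corners sit exactly on the
    observed feature minima/maxima.  The ``log_odds`` summary colours the
    surface: 0 means equal risk.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    ja, jb = (posterior.feature_ids.index(f) if f in posterior.feature_ids
              else _raise_unknown(f) for f in pair)
    axes = []
    for f in pair:
        col = table.values[:, table.column(f)]
        lo, hi = float(col.min()), float(col.max())
        if lo == hi:
            raise ValueError(f"feature {f!r} has a degenerate (constant) range")
        axes.append(np.linspace(lo, hi, grid_size))
    g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
    fvals = np.column_stack([g0.ravel(), g1.ravel()])
    draws = _pd_eval(posterior, table, [ja, jb], fvals)
    return PDSurface(feature_ids=list(pair), eval_points=fvals,
                     probit_draws=draws, grid_shape=(grid_size, grid_size))


def surface_frame(surface: PDSurface, level: float = 0.95):
    """Tidy table of a PD surface: eval point(s), mean probit, credible bounds
    and log-odds, ready for any plotting layer."""
    import pandas as pd

    lo, hi = surface.credible_interval(level)
    data = {}
    for ax, fid in enumerate(surface.feature_ids):
        data[fid] = surface.eval_points[:, ax]
    if surface.quantiles is not None:
        data["quantile"] = surface.quantiles
    data["mean_probit"] = surface.mean_probit
    data["lo"] = lo
    data["hi"] = hi
    data["log_odds"] = surface.log_odds
    return pd.DataFrame(data)
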