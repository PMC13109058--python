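"""Allele-frequency trajectories and epoch-wise selection inference.

The model is a discrete-generation Wright-Fisher population of effective
size ``Ne`` diploids.  Selection acts deterministically on the expected
frequency before binomial sampling:

    p' = p (1 + s) / (1 + p s)        (genic selection)

Trajectory posteriors are computed on a frequency grid with a hidden Markov
model: one-generation transition operators built from the binomial WF
kernel, a uniform prior at the oldest time, and a binomial emission for the
present-day sample count.  Selection is piecewise-constant over epochs of
generations before present (default boundaries 0, 50, 100, 150; s = 0
beyond the last boundary).

Conventions
-----------
* Time is measured in generations before present; index 0 is the present.
* A transition from generation ``t+1`` (older) to ``t`` (younger) uses the
  selection coefficient of the epoch containing the *younger* generation
  ``t``.
* Effect sizes are per derived-allele copy; the population-average polygenic
  score Z(t) = sum_i beta_i p_i(t) is on the allele-frequency scale (not
  doubled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_GENERATION_TIME = 28.0  # years per generation
DEFAULT_NE = 10_000


class ConfigurationError(ValueError):
    """Invalid epoch/grid configuration."""


@dataclass
class EpochSelectionModel:
    """Piecewise-constant selection over epochs of generations before present.

    ``boundaries`` are strictly increasing from 0; ``s_per_epoch[i]``
    applies to generations in ``[boundaries[i], boundaries[i+1])``; beyond
    the last boundary s is fixed at 0.
    """

    boundaries: tuple = (0, 50, 100, 150)
    s_per_epoch: tuple = (0.0, 0.0, 0.0)
    Ne: int = DEFAULT_NE
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ConfigurationError(
                "epoch boundaries must be strictly increasing from 0")
        if len(self.s_per_epoch) != len(b) - 1:
            raise ConfigurationError(
                f"need one s per epoch interval: {len(b) - 1} intervals, "
                f"{len(self.s_per_epoch)} coefficients")
        if np.any(np.abs(np.asarray(self.s_per_epoch)) >= 1):
            raise ConfigurationError("|s| must be < 1")

    def s_at(self, t: int) -> float:
        """Selection coefficient governing the transition into generation t."""
        b = self.boundaries
        for i in range(len(b) - 1):
            if b[i] <= t < b[i + 1]:
                return float(self.s_per_epoch[i])
        return 0.0

    @classmethod
    def constant(cls, s: float, horizon: int, Ne: int = DEFAULT_NE,
                 generation_time: float = DEFAULT_GENERATION_TIME
                 ) -> "EpochSelectionModel":
        return cls(boundaries=(0, horizon), s_per_epoch=(s,), Ne=Ne,
                   generation_time=generation_time)


@dataclass
class Trajectory:
    """Per-generation allele frequency, optionally with a grid posterior.

    ``times`` are generations before present, increasing into the past;
    ``freq[t]`` is the (point or posterior-mean) frequency at ``times[t]``.
    ``posterior`` (optional) has one row per time over ``grid``.
    """

    times: np.ndarray
    freq: np.ndarray
    snp_id: str | None = None
    posterior: np.ndarray | None = None
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative, increasing into the past")
        if self.posterior is not None:
            rows = self.posterior.sum(axis=1)
            if np.any(np.abs(rows - 1) > 1e-9):
                raise ValueError("posterior rows must sum to 1")


@dataclass
class PSTrajectory:
    """Population-average polygenic score Z(t) over a common time grid."""

    times: np.ndarray
    z: np.ndarray
    contributing_snps: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z(t) must be a finite series")


@dataclass
class WFHMMConfig:
    """Frequency grid and prior for the Wright-Fisher HMM."""

    grid_size: int = 101
    prior: str = "uniform"  # prior over the grid at the oldest time

    def __post_init__(self) -> None:
        if self.grid_size < 3:
            raise ConfigurationError("grid must have at least 3 points")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_size)


def selection_update(p, s):
    """Deterministic one-generation expected frequency under genic selection."""
    p = np.asarray(p, dtype=float)
    return p * (1.0 + s) / (1.0 + p * s)


def wf_transition(cfg: WFHMMConfig, Ne: int, s: float) -> np.ndarray:
    """One-generation transition matrix (past row -> present column).

    Row ``i`` places the mass of Binomial(2 Ne, p') onto the grid, where
    ``p'`` is the post-selection expected frequency for grid point ``i``;
    the binomial count space is aggregated into bins whose edges are the
    midpoints between grid points.  Boundary states 0 and 1 are absorbing.
    """
    if abs(s) >= 1:
        raise ConfigurationError("|s| must be < 1")
    grid = cfg.grid
    n = 2 * Ne
    p_next = selection_update(grid, s)
    # count-space bin edges at midpoints between grid points
    mid = (grid[:-1] + grid[1:]) / 2.0 * n
    edges = np.floor(mid).astype(np.int64)  # bin j holds counts (e[j-1], e[j]]
    cdf = stats.binom.cdf(edges[None, :], n, p_next[:, None])
    T = np.empty((cfg.grid_size, cfg.grid_size))
    T[:, 0] = cdf[:, 0]
    T[:, 1:-1] = np.diff(cdf, axis=1)
    T[:, -1] = 1.0 - cdf[:, -1]
    T[0, :] = 0.0
    T[0, 0] = 1.0
    T[-1, :] = 0.0
    T[-1, -1] = 1.0
    return T


def _epoch_transitions(model: EpochSelectionModel, cfg: WFHMMConfig,
                       horizon: int) -> dict[float, np.ndarray]:
    s_values = {model.s_at(t) for t in range(horizon)}
    return {s: wf_transition(cfg, model.Ne, s) for s in s_values}


def trajectory_posterior(k: int, n: int, model: EpochSelectionModel,
                         cfg: WFHMMConfig | None = None,
                         horizon: int | None = None,
                         snp_id: str | None = None) -> Trajectory:
    """Posterior allele-frequency trajectory given a present-day count.

    Forward-backward smoothing on the frequency grid: uniform prior at the
    oldest generation (``horizon``), epoch-wise WF transitions toward the
    present, and a Binomial(n, p) emission for observing ``k`` derived of
    ``n`` sampled haplotypes at generation 0.
    """
    if not 0 <= k <= n:
        raise ValueError(f"derived count k={k} outside 0..n={n}")
    cfg = cfg or WFHMMConfig()
    if horizon is None:
        horizon = int(model.boundaries[-1])
    if horizon < model.boundaries[-1]:
        raise ConfigurationError("horizon must reach the last epoch boundary")
    grid = cfg.grid
    trans = _epoch_transitions(model, cfg, horizon)
    emission = stats.binom.pmf(k, n, grid)

    # forward pass, oldest -> present: alpha[t] = P(state at t | prior)
    alpha = np.empty((horizon + 1, cfg.grid_size))
    alpha[horizon] = np.full(cfg.grid_size, 1.0 / cfg.grid_size)
    for t in range(horizon - 1, -1, -1):
        a = alpha[t + 1] @ trans[model.s_at(t)]
        alpha[t] = a / a.sum()
    # backward pass: beta[t] = P(observation | state at t)
    beta = np.empty_like(alpha)
    beta[0] = emission
    for t in range(1, horizon + 1):
        b = trans[model.s_at(t - 1)] @ beta[t - 1]
        m = b.max()
        beta[t] = b / (m if m > 0 else 1.0)
    post = alpha * beta
    norm = post.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise RuntimeError("zero posterior mass; observation incompatible")
    post /= norm
    mean = post @ grid
    return Trajectory(times=np.arange(horizon + 1), freq=mean, snp_id=snp_id,
                      posterior=post, grid=grid)


def hmm_loglik(k: int, n: int, model: EpochSelectionModel,
               cfg: WFHMMConfig, horizon: int) -> float:
    """Marginal log-likelihood of the present-day count under the HMM."""
    grid = cfg.grid
    trans = _epoch_transitions(model, cfg, horizon)
    a = np.full(cfg.grid_size, 1.0 / cfg.grid_size)
    logc = 0.0
    for t in range(horizon - 1, -1, -1):
        a = a @ trans[model.s_at(t)]
        tot = a.sum()
        logc += np.log(tot)
        a /= tot
    lik = float(a @ stats.binom.pmf(k, n, grid))
    return logc + (np.log(lik) if lik > 0 else -np.inf)


def _path_epoch_loglik(freq: np.ndarray, times: np.ndarray, Ne: int,
                       t_lo: float, t_hi: float,
                       s_grid: np.ndarray) -> np.ndarray:
    """Log-likelihood over ``s_grid`` of the path transitions into [t_lo, t_hi).

    The path is treated as observed counts ``k_t = round(2 Ne freq_t)``;
    each transition contributes log Binomial(k_child; 2 Ne, p'(k_parent)).
    """
    n = 2 * Ne
    k = np.rint(np.asarray(freq) * n).astype(np.int64)
    # transitions into child generation t (times ascending into the past)
    child = np.nonzero((times[:-1] >= t_lo) & (times[:-1] < t_hi))[0]
    if child.size == 0:
        return np.zeros(s_grid.size)
    p_parent = k[child + 1] / n
    k_child = k[child]
    p_prime = selection_update(p_parent[None, :], s_grid[:, None])
    np.clip(p_prime, 0.0, 1.0, out=p_prime)
    ll = stats.binom.logpmf(k_child[None, :], n, p_prime)
    return ll.sum(axis=1)


def estimate_epoch_s(observed, boundaries, cfg: WFHMMConfig | None = None,
                     s_grid: np.ndarray | None = None,
                     Ne: int = DEFAULT_NE) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood selection coefficient per epoch by grid search.

    ``observed`` is either a :class:`Trajectory` (a fully observed
    frequency path, likelihood formed from its WF transitions) or a tuple
    ``(k, n, horizon)`` of a present-day sample count, in which case the
    grid HMM marginal likelihood is maximized (coordinate ascent over
    epochs when there is more than one).

    Returns ``(s_hat per epoch, log-likelihood surface of shape
    (n_epochs, len(s_grid)))``.  A flat surface (monomorphic observation)
    yields NaN estimates.
    """
    cfg = cfg or WFHMMConfig()
    if s_grid is None:
        s_grid = np.round(np.arange(-0.05, 0.0505, 0.0005), 6)
    s_grid = np.asarray(s_grid, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    n_epochs = len(boundaries) - 1

    if isinstance(observed, Trajectory):
        surfaces = np.empty((n_epochs, s_grid.size))
        for e in range(n_epochs):
            surfaces[e] = _path_epoch_loglik(observed.freq, observed.times,
                                             Ne, boundaries[e],
                                             boundaries[e + 1], s_grid)
        s_hat = np.empty(n_epochs)
        for e in range(n_epochs):
            surf = surfaces[e]
            if np.allclose(surf, surf[0]):
                logger.warning("flat likelihood in epoch %d (monomorphic "
                               "observation); estimate undefined", e)
                s_hat[e] = np.nan
            else:
                s_hat[e] = s_grid[int(np.argmax(surf))]
        return s_hat, surfaces

    k, n, horizon = observed
    s_cur = np.zeros(n_epochs)
    surfaces = np.empty((n_epochs, s_grid.size))
    n_passes = 2 if n_epochs > 1 else 1
    for _ in range(n_passes):
        for e in range(n_epochs):
            for j, s in enumerate(s_grid):
                trial = s_cur.copy()
                trial[e] = s
                model = EpochSelectionModel(tuple(boundaries), tuple(trial),
                                            Ne=Ne)
                surfaces[e, j] = hmm_loglik(k, n, model, cfg, int(horizon))
            if np.allclose(surfaces[e], surfaces[e, 0]):
                s_cur[e] = np.nan
            else:
                s_cur[e] = s_grid[int(np.argmax(surfaces[e]))]
    return s_cur, surfaces


def ps_trajectory(trajectories: list[Trajectory],
                  betas: np.ndarray) -> PSTrajectory:
    """Population-average polygenic score Z(t) = sum_i beta_i p_i(t).

    All trajectories must share an identical time grid (no silent
    interpolation); ``betas`` are per derived-allele effect sizes aligned
    with ``trajectories``.
    """
    if len(trajectories) == 0:
        raise ValueError("no trajectories given")
    betas = np.asarray(betas, dtype=float)
    if betas.size != len(trajectories):
        raise ValueError("one beta per trajectory required")
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if tr.times.shape != t0.shape or np.any(tr.times != t0):
            raise ValueError("trajectories do not share a common time grid")
    z = np.zeros(t0.size)
    for tr, b in zip(trajectories, betas):
        z += b * tr.freq
    return PSTrajectory(times=t0, z=z, contributing_snps=len(trajectories))


def generations_to_years(g, generation_time: float = DEFAULT_GENERATION_TIME):
    """Convert generations before present to years (default 28 yr/gen)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("generations must be non-negative")
    out = g * generation_time
    return float(out) if out.ndim == 0 else out


def ps_model_comparison(bmi, age, ps, age_cutoffs=(None, 55, 50, 45),
                        min_n: int = 4) -> pd.DataFrame:
    """Compare age-only, PS-only, and age+PS OLS models of a trait.

    For each age-defined subset (``cutoff=None`` keeps everyone, otherwise
    individuals with ``age < cutoff``), fits the three ordinary
    least-squares models and reports n, adjusted R^2 and AIC.  Subsets
    smaller than ``min_n`` are skipped with a log entry.
    """
    import statsmodels.api as sm

    bmi = np.asarray(bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    ps = np.asarray(ps, dtype=float)
    rows = []
    for cutoff in age_cutoffs:
        mask = np.ones(bmi.size, dtype=bool) if cutoff is None else age < cutoff
        n = int(mask.sum())
        if n < min_n:
            logger.info("subset age<%s has n=%d < %d; skipped", cutoff, n, min_n)
            continue
        y = bmi[mask]
        designs = {
            "age_only": age[mask][:, None],
            "ps_only": ps[mask][:, None],
            "age_and_ps": np.column_stack([age[mask], ps[mask]]),
        }
        for name, X in designs.items():
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            rows.append({
                "subset": "all" if cutoff is None else f"age<{cutoff:g}",
                "n": n, "model": name,
                "r2": fit.rsquared, "r2_adj": fit.rsquared_adj,
                "aic": fit.aic,
            })
    return pd.DataFrame(rows)
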