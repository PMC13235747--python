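"""Bias-adjusted Bayesian penalized B-spline model for U5MR and IMR.

The logarithm of the true mortality rate is a penalized B-spline curve
``log f(t) = sum_j alpha_j B_j(t)`` with a difference penalty (random-walk
prior) on the coefficients.  Each observation is the true rate times an
error multiplier:

    log(obs_i) = log f(t_i) + b_{source(i)} + eps_i,
    eps_i ~ Normal(0, se_i^2 (log scale) + sigma^2_{source(i)})

where ``b`` are average systematic biases per source type (one reference
source — vital registration when present — is fixed at zero to identify
them) and ``sigma`` are per-source-type non-sampling standard deviations.
No covariates enter the mean.

Posterior sampling is by a Gibbs sweep written on numpy/scipy: the
coefficient/bias block is conjugate Gaussian given the variances, the
penalty precision is conjugate gamma given the coefficients, and the
non-sampling standard deviations take Metropolis steps on the log scale
under half-normal priors.  Split-chain potential-scale-reduction
diagnostics are attached to every fit.

Beyond the last data year, trajectories are extended to the common
reference year with an equally weighted combination of the country's own
recent trend (per posterior draw) and the broader global trend.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from u5m.data_model import ConfigError, MortalityObservation
from u5m.splines import SplineBasis, build_basis

_VAR_FLOOR = 1e-8


@dataclass
class B3Config:
    """Model settings: spline geometry, prior scales, MCMC budget."""

    knot_spacing: float = 2.5
    degree: int = 3
    penalty_order: int = 2
    tau_prior: tuple = (1.0, 0.01)     # gamma(shape, rate) on penalty precision
    bias_prior_sd: float = 0.1         # log-scale prior sd of source biases
    nonsampling_prior_scale: float = 0.15  # half-normal scale for sigma_s
    mh_step: float = 0.4               # log-scale MH step for sigma_s
    n_chains: int = 2
    n_warmup: int = 500
    n_draws: int = 500                 # retained draws per chain
    seed: int = 0
    reference_source: str = "VR"
    extrapolation_window: int = 10     # trailing years defining "recent trend"
    reference_year: int = 2024
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if min(self.knot_spacing, self.bias_prior_sd,
               self.nonsampling_prior_scale) <= 0:
            raise ConfigError("scales must be positive")
        if self.n_draws < 1 or self.n_chains < 1:
            raise ConfigError("need at least one chain and one draw")


@dataclass
class PosteriorTrajectories:
    """Posterior draws of an annual rate trajectory (per 1000).

    ``draws`` has shape ``(n_draws, n_years)``; ``fitted`` marks years in
    the observed period (False = extrapolated).
    """

    country_id: str
    indicator: str
    years: np.ndarray
    draws: np.ndarray
    fitted: np.ndarray = None
    crisis_adjusted: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        if self.fitted is None:
            self.fitted = np.ones(self.years.size, bool)
        if self.draws.shape[1] != self.years.size:
            raise ValueError("draws and years misaligned")
        if np.any(~np.isfinite(self.draws)) or np.any(self.draws <= 0):
            raise ValueError("trajectories must be positive and finite")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def interval(self, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        a = (1.0 - level) / 2.0 * 100.0
        lo, hi = np.percentile(self.draws, [a, 100.0 - a], axis=0)
        return lo, hi

    def at(self, year: int) -> np.ndarray:
        idx = np.nonzero(self.years == int(year))[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in trajectory")
        return self.draws[:, idx[0]]


def _difference_matrix(n: int, order: int) -> np.ndarray:
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar.

    ``chains``: (n_chains, n_iter).  Each chain is split in half, giving
    2*n_chains sequences.
    """
    n_chains, n_iter = chains.shape
    half = n_iter // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def _as_observation_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = [
        {
            "country_id": o.country_id, "series_id": o.series_id,
            "source_type": o.source_type, "indicator": o.indicator,
            "ref_year": o.ref_year, "value": o.value, "se": o.se,
            "included": o.included,
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


class B3SplineModel(BaseEstimator):
    """Penalized-spline mortality trend estimator with source-bias adjustment.

    scikit-learn style: all hyper-parameters in ``__init__``; fitted state
    in trailing-underscore attributes after :meth:`fit`.

    Examples
    --------
    >>> model = B3SplineModel(n_warmup=200, n_draws=200, seed=1)
    >>> traj = model.fit(observations, indicator="U5MR").trajectories_
    """

    def __init__(
        self,
        knot_spacing: float = 2.5,
        degree: int = 3,
        penalty_order: int = 2,
        tau_prior: tuple = (1.0, 0.01),
        bias_prior_sd: float = 0.1,
        nonsampling_prior_scale: float = 0.15,
        mh_step: float = 0.4,
        n_chains: int = 2,
        n_warmup: int = 500,
        n_draws: int = 500,
        seed: int = 0,
        reference_source: str = "VR",
        reference_year: int = 2024,
        rhat_threshold: float = 1.05,
    ):
        self.knot_spacing = knot_spacing
        self.degree = degree
        self.penalty_order = penalty_order
        self.tau_prior = tau_prior
        self.bias_prior_sd = bias_prior_sd
        self.nonsampling_prior_scale = nonsampling_prior_scale
        self.mh_step = mh_step
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.reference_source = reference_source
        self.reference_year = reference_year
        self.rhat_threshold = rhat_threshold

    # -- fitting ------------------------------------------------------------

    def fit(self, observations, indicator: str = "U5MR",
            fix_bias_to_zero: bool = False):
        """Fit to the included observations of one country and indicator."""
        df = _as_observation_frame(observations)
        if len(df) == 0:
            raise ValueError(
                "no included observations: use the extrapolation-only path "
                "(expected-ratio or donor trend) for this country"
            )
        if "included" in df.columns:
            df = df[df["included"]]
        df = df[df["indicator"] == indicator]
        if len(df) == 0:
            raise ValueError(
                "no included observations: use the extrapolation-only path "
                "(expected-ratio or donor trend) for this country"
            )
        df = df.sort_values("ref_year").reset_index(drop=True)

        t_obs = df["ref_year"].to_numpy(float)
        y = np.log(df["value"].to_numpy(float))
        se_log = (df["se"] / df["value"]).to_numpy(float)
        sources = df["source_type"].to_numpy(object)

        # grid of mid-year points over the observed period
        y_lo = int(math.floor(t_obs.min()))
        y_hi = int(math.ceil(t_obs.max() - 0.5))
        grid_years = np.arange(y_lo, y_hi + 1)
        grid_mid = grid_years + 0.5
        span_lo = min(t_obs.min(), grid_mid.min())
        span_hi = max(t_obs.max(), grid_mid.max())
        basis = build_basis(np.array([span_lo, span_hi]),
                            knot_spacing=self.knot_spacing, degree=self.degree)
        b_obs = basis.evaluate(t_obs)
        b_grid = basis.evaluate(grid_mid)
        k = basis.n_basis

        src_levels = list(dict.fromkeys(sources))  # stable order
        if fix_bias_to_zero or len(src_levels) == 1:
            # a single source type cannot be separated from the level
            free_sources: list[str] = []
        elif self.reference_source in src_levels:
            # reference source (VR meeting coverage rules) anchors the level
            free_sources = [s for s in src_levels if s != self.reference_source]
        else:
            # no anchor available: all biases shrunk to the mean-zero prior,
            # which leaves the level weakly identified but propagates the
            # bias uncertainty into the posterior
            free_sources = list(src_levels)
        z = np.zeros((len(df), len(free_sources)))
        for j, s in enumerate(free_sources):
            z[:, j] = (sources == s).astype(float)
        x = np.hstack([b_obs, z])
        d = x.shape[1]

        dmat = _difference_matrix(k, self.penalty_order)
        pen = dmat.T @ dmat
        rank_pen = k - self.penalty_order
        a_tau, b_tau = self.tau_prior

        prior_prec_bias = np.full(len(free_sources), self.bias_prior_sd ** -2)

        all_draws = []
        monitor_idx = np.linspace(0, grid_mid.size - 1,
                                  min(5, grid_mid.size)).astype(int)
        monitors = []  # per chain: (n_iter, n_monitor)
        sigma_draws_all = []
        bias_draws_all = []

        for chain in range(self.n_chains):
            rng = np.random.default_rng(
                [max(0, int(self.seed)), chain,
                 zlib.crc32(indicator.encode()) % (2 ** 31)])
            tau = a_tau / b_tau
            sigma = {s: self.nonsampling_prior_scale for s in src_levels}
            theta = np.zeros(d)
            theta[:k] = np.median(y)

            keep_f, keep_sig, keep_b, keep_mon = [], [], [], []
            n_iter = self.n_warmup + self.n_draws
            src_masks = {s: sources == s for s in src_levels}
            for it in range(n_iter):
                var = se_log ** 2 + np.array(
                    [sigma[s] ** 2 for s in sources]) + _VAR_FLOOR
                w = 1.0 / var
                q = (x * w[:, None]).T @ x
                q[:k, :k] += tau * pen + 1e-6 * np.eye(k)
                if free_sources:
                    q[k:, k:] += np.diag(prior_prec_bias)
                rhs = (x * w[:, None]).T @ y
                c, low = linalg.cho_factor(q, lower=True)
                mean = linalg.cho_solve((c, low), rhs)
                zdraw = rng.standard_normal(d)
                theta = mean + linalg.solve_triangular(
                    c, zdraw, lower=True, trans="T")

                alpha = theta[:k]
                quad = float(alpha @ pen @ alpha)
                tau = rng.gamma(a_tau + 0.5 * rank_pen,
                                1.0 / (b_tau + 0.5 * quad))

                resid = y - x @ theta
                for s in src_levels:
                    mask = src_masks[s]
                    if not mask.any():
                        continue
                    cur = sigma[s]
                    prop = cur * math.exp(rng.normal(0.0, self.mh_step))
                    r = resid[mask]
                    se2 = se_log[mask] ** 2

                    def logpost(sg: float) -> float:
                        v = se2 + sg ** 2 + _VAR_FLOOR
                        ll = -0.5 * np.sum(np.log(v) + r ** 2 / v)
                        lp = -0.5 * (sg / self.nonsampling_prior_scale) ** 2
                        return ll + lp + math.log(sg)  # log-scale Jacobian

                    if math.log(rng.random() + 1e-300) < (
                            logpost(prop) - logpost(cur)):
                        sigma[s] = prop

                if it >= self.n_warmup:
                    logf = b_grid @ alpha
                    keep_f.append(logf)
                    keep_sig.append([sigma[s] for s in src_levels])
                    keep_b.append(theta[k:].copy())
                    keep_mon.append(logf[monitor_idx])

            all_draws.append(np.exp(np.array(keep_f)))
            sigma_draws_all.append(np.array(keep_sig))
            bias_draws_all.append(np.array(keep_b))
            monitors.append(np.array(keep_mon))

        draws = np.concatenate(all_draws, axis=0)
        mon = np.stack(monitors)  # (chains, iters, n_monitor)
        rhats = [_split_rhat(mon[:, :, j]) for j in range(mon.shape[2])]
        rhat_max = float(np.nanmax(rhats)) if rhats else np.nan
        converged = bool(np.isnan(rhat_max) or rhat_max < self.rhat_threshold)

        sigma_draws = np.concatenate(sigma_draws_all, axis=0)
        bias_draws = np.concatenate(bias_draws_all, axis=0)

        self.basis_ = basis
        self.grid_years_ = grid_years
        self.source_levels_ = src_levels
        self.free_sources_ = free_sources
        self.bias_ = {
            s: float(np.median(bias_draws[:, j]))
            for j, s in enumerate(free_sources)
        }
        self.bias_draws_ = bias_draws
        self.sigma_ = {
            s: float(np.median(sigma_draws[:, j]))
            for j, s in enumerate(src_levels)
        }
        self.rhat_max_ = rhat_max
        self.converged_ = converged
        self.trajectories_ = PosteriorTrajectories(
            country_id=str(df["country_id"].iloc[0]),
            indicator=indicator,
            years=grid_years,
            draws=draws,
            fitted=np.ones(grid_years.size, bool),
            metadata={
                "rhat_max": rhat_max, "converged": converged,
                "seed": self.seed, "bias": dict(self.bias_),
                "sigma": dict(self.sigma_),
                "last_data_year": float(t_obs.max()),
            },
        )
        if not converged:
            import warnings
            warnings.warn(
                f"B3 fit for {self.trajectories_.country_id}/{indicator}: "
                f"split-Rhat {rhat_max:.3f} exceeds {self.rhat_threshold}",
                stacklevel=2)
        return self


def fit_b3(observations, config: Optional[B3Config] = None,
           indicator: str = "U5MR", **overrides) -> PosteriorTrajectories:
    """Functional wrapper over :class:`B3SplineModel`."""
    config = config or B3Config()
    model = B3SplineModel(
        knot_spacing=config.knot_spacing, degree=config.degree,
        penalty_order=config.penalty_order, tau_prior=config.tau_prior,
        bias_prior_sd=config.bias_prior_sd,
        nonsampling_prior_scale=config.nonsampling_prior_scale,
        mh_step=config.mh_step, n_chains=config.n_chains,
        n_warmup=config.n_warmup, n_draws=config.n_draws, seed=config.seed,
        reference_source=config.reference_source,
        reference_year=config.reference_year,
        rhat_threshold=config.rhat_threshold,
    )
    model.set_params(**overrides)
    return model.fit(observations, indicator=indicator).trajectories_


# ---------------------------------------------------------------------------
# Extrapolation to the common reference year
# ---------------------------------------------------------------------------

def _trailing_arr(draws: np.ndarray, years: np.ndarray, window: int
                  ) -> np.ndarray:
    """Per-draw ARR over the trailing window of a trajectory."""
    last = years.size - 1
    first = max(0, last - window)
    span = years[last] - years[first]
    if span <= 0:
        return np.zeros(draws.shape[0])
    return np.log(draws[:, first] / draws[:, last]) / span


def extrapolate(
    trajectories: PosteriorTrajectories,
    last_data_year: float,
    global_arr,
    window: int = 10,
    reference_year: int = 2024,
) -> PosteriorTrajectories:
    """Extend trajectories to the reference year.

    Each draw's annual log-decline beyond the last data year is the equal
    weighting ``0.5 x (that draw's ARR over the trailing window) + 0.5 x
    (global ARR)``.  ``global_arr`` may be a scalar or a mapping from year
    to ARR.  If the last data year already reaches the reference year, the
    input is returned unchanged.
    """
    if global_arr is None:
        raise ValueError("missing global trend")
    last_grid_year = int(trajectories.years[-1])
    if last_data_year >= reference_year or last_grid_year >= reference_year:
        return trajectories
    country_arr = _trailing_arr(trajectories.draws, trajectories.years, window)
    new_years = np.arange(last_grid_year + 1, reference_year + 1)
    ext = np.empty((trajectories.n_draws, new_years.size))
    level = trajectories.draws[:, -1].copy()
    for j, year in enumerate(new_years):
        g = (global_arr.get(int(year)) if isinstance(global_arr, Mapping)
             else float(global_arr))
        if g is None:
            raise ValueError(f"missing global trend for year {year}")
        slope = 0.5 * country_arr + 0.5 * g
        level = level * np.exp(-slope)
        ext[:, j] = level
    return PosteriorTrajectories(
        country_id=trajectories.country_id,
        indicator=trajectories.indicator,
        years=np.concatenate([trajectories.years, new_years]),
        draws=np.concatenate([trajectories.draws, ext], axis=1),
        fitted=np.concatenate([
            trajectories.fitted, np.zeros(new_years.size, bool)]),
        crisis_adjusted=trajectories.crisis_adjusted,
        metadata=dict(trajectories.metadata),
    )


def compute_global_trend(
    trajectories: Mapping[str, PosteriorTrajectories],
    births: Mapping[str, pd.Series],
    window: int = 10,
) -> dict:
    """Birth-weighted global rate series and its trailing-window ARR.

    Uses posterior medians per country; the global rate in a year is the
    birth-weighted mean of country rates over countries covering that year.
    Returns ``{"years", "rate", "arr"}``.
    """
    if not trajectories:
        raise ValueError("need at least one country")
    years_sets = [set(t.years.tolist()) for t in trajectories.values()]
    common = sorted(set.intersection(*years_sets))
    if not common:
        raise ValueError("no common years across countries")
    years = np.array(common, int)
    num = np.zeros(years.size)
    den = np.zeros(years.size)
    for cid, traj in trajectories.items():
        med = traj.median()
        idx = np.searchsorted(traj.years, years)
        b = births[cid]
        wt = np.array([
            float(b.loc[y]) if y in b.index else float(b.iloc[-1])
            for y in years
        ])
        num += wt * med[idx]
        den += wt
    rate = num / den
    last = years.size - 1
    first = max(0, last - window)
    span = years[last] - years[first]
    arr_val = float(np.log(rate[first] / rate[last]) / span) if span > 0 else 0.0
    return {"years": years, "rate": rate, "arr": arr_val}


def cap_imr_at_u5mr(
    imr: PosteriorTrajectories, u5mr: PosteriorTrajectories
) -> PosteriorTrajectories:
    """Enforce IMR <= U5MR per draw-year by truncation (no swapping).

    IMR and U5MR are fitted independently by the same machinery; this
    post-hoc cap restores the logical ordering where posterior noise
    violates it.  Draw counts must match (pairs are matched by index).
    """
    common = sorted(set(imr.years.tolist()) & set(u5mr.years.tolist()))
    years = np.array(common, int)
    i_idx = np.searchsorted(imr.years, years)
    u_idx = np.searchsorted(u5mr.years, years)
    n = min(imr.n_draws, u5mr.n_draws)
    capped = np.minimum(imr.draws[:n][:, i_idx], u5mr.draws[:n][:, u_idx])
    return PosteriorTrajectories(
        country_id=imr.country_id, indicator="IMR", years=years,
        draws=capped, fitted=imr.fitted[i_idx],
        crisis_adjusted=imr.crisis_adjusted, metadata=dict(imr.metadata),
    )
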