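"""Neonatal mortality estimation via the expected-ratio x multiplier model.

Rather than smoothing neonatal observations directly, the model works on
the ratio ``R = NMR / (U5MR - NMR)``, which maps any positive R to a
neonatal rate strictly between zero and the U5MR.  For each country-year

    R(t) = expected_ratio(U5MR(t)) x m(t)

where the expected ratio is a deterministic global relation (log R linear
in log U5MR above a low-mortality plateau, non-increasing in U5MR) and the
country multiplier ``log m(t)`` is a first-order random walk centred at
zero, fitted to the country's neonatal observations.  With no neonatal
data the multiplier is exactly one and the country follows the expected
ratio.  No separate extrapolation is applied: neonatal rates beyond the
last datum inherit the extrapolated U5MR through the expected ratio and
the last multiplier state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from u5m.b3 import PosteriorTrajectories, _as_observation_frame
from u5m.data_model import ConfigError

_VAR_FLOOR = 1e-8


@dataclass
class RatioModelConfig:
    """Expected-ratio curve parameters and multiplier smoothing settings.

    Defaults calibrated so the implied NMR/U5MR share matches the global
    pattern (about 0.46 at U5MR 37 per 1000, about 0.39 at U5MR 94).
    """

    intercept: float = 0.95        # a in log R = a + b log U5MR
    slope: float = -0.31           # b <= 0: ratio falls as U5MR rises
    plateau_u5mr: float = 10.0     # per 1000; constant ratio below this
    innovation_sd_scale: float = 0.05   # half-normal scale for RW innovation sd
    level_sd: float = 0.5          # prior sd of the initial log-multiplier
    obs_sd_scale: float = 0.1      # half-normal scale for extra obs noise
    mh_step: float = 0.4
    n_chains: int = 2
    n_warmup: int = 400
    n_draws: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_u5mr <= 0:
            raise ConfigError("plateau threshold must be positive")
        if self.slope > 0:
            raise ConfigError("expected-ratio slope must be non-positive")


@dataclass
class RatioTrajectory:
    """Draws of R(t) = NMR / (U5MR - NMR); R > 0 iff 0 < NMR < U5MR."""

    country_id: str
    years: np.ndarray
    draws: np.ndarray  # (n_draws, n_years)

    def __post_init__(self) -> None:
        if np.any(self.draws <= 0):
            raise ValueError("ratio draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def expected_ratio(u5mr, config: Optional[RatioModelConfig] = None):
    """Expected R as a monotone non-increasing function of U5MR (per 1000)."""
    config = config or RatioModelConfig()
    u5mr = np.asarray(u5mr, dtype=float)
    if np.any(u5mr <= 0):
        raise ValueError("u5mr must be positive")
    u = np.maximum(u5mr, config.plateau_u5mr)
    out = np.exp(config.intercept + config.slope * np.log(u))
    return float(out) if out.ndim == 0 else out


def fit_expected_ratio(
    u5mr: np.ndarray, ratio: np.ndarray, plateau_u5mr: float = 10.0
) -> RatioModelConfig:
    """Calibrate the global relation by least squares on log-log pairs.

    Only pairs above the plateau threshold inform the line.  This is the
    pluggable calibration step for the global relation; the returned config
    can be passed anywhere a :class:`RatioModelConfig` is accepted.
    """
    u5mr = np.asarray(u5mr, float)
    ratio = np.asarray(ratio, float)
    mask = u5mr > plateau_u5mr
    if mask.sum() < 2:
        raise ValueError("need at least two pairs above the plateau")
    a = np.vstack([np.ones(mask.sum()), np.log(u5mr[mask])]).T
    coef, *_ = np.linalg.lstsq(a, np.log(ratio[mask]), rcond=None)
    slope = min(0.0, float(coef[1]))
    return RatioModelConfig(intercept=float(coef[0]), slope=slope,
                            plateau_u5mr=plateau_u5mr)


class NmrRatioModel(BaseEstimator):
    """Bayesian country-multiplier model for the neonatal ratio.

    Observations enter as log ratios with delta-method sampling error; the
    multiplier's log follows a first-order random walk centred at zero with
    a half-normal prior on the innovation sd.  Fitted attributes:
    ``ratio_trajectory_``, ``multiplier_median_``, ``innovation_sd_``.
    """

    def __init__(self, intercept: float = 0.95, slope: float = -0.31,
                 plateau_u5mr: float = 10.0, innovation_sd_scale: float = 0.05,
                 level_sd: float = 0.5, obs_sd_scale: float = 0.1,
                 mh_step: float = 0.4, n_chains: int = 2, n_warmup: int = 400,
                 n_draws: int = 400, seed: int = 0):
        self.intercept = intercept
        self.slope = slope
        self.plateau_u5mr = plateau_u5mr
        self.innovation_sd_scale = innovation_sd_scale
        self.level_sd = level_sd
        self.obs_sd_scale = obs_sd_scale
        self.mh_step = mh_step
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed

    def _config(self) -> RatioModelConfig:
        return RatioModelConfig(
            intercept=self.intercept, slope=self.slope,
            plateau_u5mr=self.plateau_u5mr,
            innovation_sd_scale=self.innovation_sd_scale,
            level_sd=self.level_sd, obs_sd_scale=self.obs_sd_scale,
            mh_step=self.mh_step, n_chains=self.n_chains,
            n_warmup=self.n_warmup, n_draws=self.n_draws, seed=self.seed)

    def fit(self, nmr_observations, u5mr_trajectories: PosteriorTrajectories):
        """Fit the multiplier random walk to neonatal observations.

        ``nmr_observations`` may be empty (or None): the multiplier is then
        identically one and the country follows the expected-ratio curve.
        Observations implying NMR >= U5MR are excluded with a warning.
        """
        cfg = self._config()
        years = np.asarray(u5mr_trajectories.years, int)
        u5_med = u5mr_trajectories.median()
        e_ratio = expected_ratio(u5_med, cfg)
        n_years = years.size
        n_total = cfg.n_chains * cfg.n_draws

        df = (_as_observation_frame(nmr_observations)
              if nmr_observations is not None else pd.DataFrame())
        if len(df):
            if "included" in df.columns:
                df = df[df["included"]]
            df = df[df["indicator"] == "NMR"].reset_index(drop=True)

        if len(df) == 0:
            z_draws = np.zeros((n_total, n_years))
            self.innovation_sd_ = 0.0
            self.n_obs_used_ = 0
        else:
            yi = np.clip(np.floor(df["ref_year"].to_numpy(float)).astype(int)
                         - years[0], 0, n_years - 1)
            u5_at = u5_med[yi]
            nmr_val = df["value"].to_numpy(float)
            se = df["se"].to_numpy(float)
            ok = nmr_val < u5_at
            if not ok.all():
                import warnings
                warnings.warn(
                    f"{(~ok).sum()} neonatal observation(s) implying "
                    "NMR >= U5MR excluded", stacklevel=2)
            yi, u5_at, nmr_val, se = yi[ok], u5_at[ok], nmr_val[ok], se[ok]
            self.n_obs_used_ = int(ok.sum())
            if self.n_obs_used_ == 0:
                z_draws = np.zeros((n_total, n_years))
                self.innovation_sd_ = 0.0
            else:
                r_obs = nmr_val / (u5_at - nmr_val)
                # delta method: d log R / d nmr = 1/nmr + 1/(u5 - nmr)
                se_log = se * (1.0 / nmr_val + 1.0 / (u5_at - nmr_val))
                resid_target = np.log(r_obs) - np.log(e_ratio[yi])
                z_draws, delta_med = self._sample_rw(
                    resid_target, se_log, yi, n_years, cfg)
                self.innovation_sd_ = delta_med

        ratio_draws = e_ratio[None, :] * np.exp(z_draws)
        self.multiplier_median_ = np.exp(np.median(z_draws, axis=0))
        self.ratio_trajectory_ = RatioTrajectory(
            country_id=u5mr_trajectories.country_id, years=years,
            draws=ratio_draws)
        return self

    def _sample_rw(self, target: np.ndarray, se_log: np.ndarray,
                   obs_idx: np.ndarray, n_years: int,
                   cfg: RatioModelConfig) -> tuple[np.ndarray, float]:
        """Gibbs sampling of the log-multiplier random walk.

        Conjugate GMRF draw of the state vector given the variance
        parameters; log-scale Metropolis steps for the innovation sd and
        the extra observation sd.
        """
        d1 = np.diff(np.eye(n_years), axis=0)
        rw = d1.T @ d1
        keep = []
        deltas = []
        for chain in range(cfg.n_chains):
            rng = np.random.default_rng([max(0, int(cfg.seed)), 101, chain])
            delta = cfg.innovation_sd_scale
            extra = cfg.obs_sd_scale / 2.0
            z = np.zeros(n_years)
            for it in range(cfg.n_warmup + cfg.n_draws):
                var = se_log ** 2 + extra ** 2 + _VAR_FLOOR
                w = 1.0 / var
                q = rw / max(delta ** 2, _VAR_FLOOR)
                q += np.eye(n_years) / cfg.level_sd ** 2 / n_years
                np.add.at(q, (obs_idx, obs_idx), w)
                rhs = np.zeros(n_years)
                np.add.at(rhs, obs_idx, w * target)
                c, low = linalg.cho_factor(q, lower=True)
                mean = linalg.cho_solve((c, low), rhs)
                z = mean + linalg.solve_triangular(
                    c, rng.standard_normal(n_years), lower=True, trans="T")

                # MH on innovation sd (half-normal prior)
                def logpost_delta(dl: float) -> float:
                    quad = float(z @ rw @ z)
                    v = max(dl ** 2, _VAR_FLOOR)
                    ll = -0.5 * (n_years - 1) * math.log(v) - 0.5 * quad / v
                    return ll - 0.5 * (dl / cfg.innovation_sd_scale) ** 2 \
                        + math.log(dl)

                prop = delta * math.exp(rng.normal(0.0, cfg.mh_step))
                if math.log(rng.random() + 1e-300) < (
                        logpost_delta(prop) - logpost_delta(delta)):
                    delta = prop

                resid = target - z[obs_idx]

                def logpost_extra(sg: float) -> float:
                    v = se_log ** 2 + sg ** 2 + _VAR_FLOOR
                    ll = -0.5 * np.sum(np.log(v) + resid ** 2 / v)
                    return ll - 0.5 * (sg / cfg.obs_sd_scale) ** 2 \
                        + math.log(sg)

                prop = extra * math.exp(rng.normal(0.0, cfg.mh_step))
                if math.log(rng.random() + 1e-300) < (
                        logpost_extra(prop) - logpost_extra(extra)):
                    extra = prop

                if it >= cfg.n_warmup:
                    keep.append(z.copy())
                    deltas.append(delta)
        return np.array(keep), float(np.median(deltas))


def fit_country_multiplier(
    nmr_observations,
    u5mr_trajectories: PosteriorTrajectories,
    config: Optional[RatioModelConfig] = None,
) -> RatioTrajectory:
    """Functional wrapper over :class:`NmrRatioModel`."""
    cfg = config or RatioModelConfig()
    model = NmrRatioModel(
        intercept=cfg.intercept, slope=cfg.slope,
        plateau_u5mr=cfg.plateau_u5mr,
        innovation_sd_scale=cfg.innovation_sd_scale, level_sd=cfg.level_sd,
        obs_sd_scale=cfg.obs_sd_scale, mh_step=cfg.mh_step,
        n_chains=cfg.n_chains, n_warmup=cfg.n_warmup, n_draws=cfg.n_draws,
        seed=cfg.seed)
    return model.fit(nmr_observations, u5mr_trajectories).ratio_trajectory_


def derive_nmr(
    u5mr_trajectories: PosteriorTrajectories,
    ratio_trajectories: RatioTrajectory,
) -> PosteriorTrajectories:
    """NMR = U5MR x R / (1 + R), per draw-year; guarantees 0 < NMR < U5MR.

    Draw counts must match up to cycling: if the ratio has fewer draws they
    are tiled to the U5MR draw count.
    """
    if not np.array_equal(np.asarray(u5mr_trajectories.years, int),
                          np.asarray(ratio_trajectories.years, int)):
        raise ValueError("year grids of U5MR and ratio trajectories differ")
    r = ratio_trajectories.draws
    n = u5mr_trajectories.n_draws
    if r.shape[0] != n:
        reps = int(np.ceil(n / r.shape[0]))
        r = np.tile(r, (reps, 1))[:n]
    nmr = u5mr_trajectories.draws * r / (1.0 + r)
    return PosteriorTrajectories(
        country_id=u5mr_trajectories.country_id, indicator="NMR",
        years=u5mr_trajectories.years, draws=nmr,
        fitted=u5mr_trajectories.fitted,
        crisis_adjusted=u5mr_trajectories.crisis_adjusted,
        metadata=dict(u5mr_trajectories.metadata),
    )
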