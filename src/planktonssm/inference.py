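"""Hierarchical Bayesian estimation of the state-space predator-prey model.

The model: per-lake latent plankton trajectories follow the deterministic
discrete Lotka-Volterra map of :mod:`planktonssm.dynamics`, with rates tied
to standardized covariates through link functions (consumption linear in
temperature, log growth rate linear in phosphorus load, two mortality
levels by fish presence). Observations are normal around the latent states
with standard deviations ``sigma_x`` and ``sigma_y``. Estimated quantities
are the link coefficients, the mortality levels, the shared energy
efficiency, the observation sds, and the per-lake initial states.

Sampling is adaptive random-walk Metropolis-within-Gibbs: the nine global
parameters are updated one at a time plus one correlated joint proposal
built from the empirical covariance accumulated in burn-in, and the
initial-state vectors are updated with independent per-lake proposals
(valid because lakes are conditionally independent given the globals).
Because the deterministic-trajectory likelihood is rugged, each chain runs
several tempered replicas with adjacent-pair swap moves (replica exchange)
and retains only the cold one. Proposal scales adapt toward a 44%
acceptance rate during burn-in only, so retained chains are Markovian.
Constrained parameters are handled by rejection: any proposal off the
support has log-posterior minus infinity.

Convergence is assessed with the split form of the potential scale
reduction factor R-hat (each chain halved before the between/within
comparison; no rank normalization), and posterior summaries report means,
equal-tailed 95% intervals (linear-interpolation quantiles), the fraction
of posterior mass below zero, split R-hat and effective sample size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._core import lake_logliks
from .dynamics import standardize
from .params import HyperParams

logger = logging.getLogger(__name__)

__all__ = [
    "LakeData",
    "Prior",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "log_likelihood",
    "log_posterior",
    "fit_mcmc",
    "grid_posterior",
    "rhat",
    "split_rhat",
    "effective_sample_size",
    "summarize_posterior",
]

_NEG_INF = float("-inf")
_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data container


@dataclass
class LakeData:
    """Aligned observation matrices and covariates, ready for the sampler.

    ``st`` and ``sp`` are the standardized temperature and phosphorus load,
    computed over exactly the lake set being fitted (so excluding a lake
    changes the standardization, as it would in the original analysis).
    """

    lake_ids: list[str]
    fish: np.ndarray  # (L,) bool
    st: np.ndarray  # (L,)
    sp: np.ndarray  # (L,)
    obs_x: np.ndarray  # (L, T)
    obs_y: np.ndarray  # (L, T)

    @property
    def n_lakes(self) -> int:
        return len(self.lake_ids)

    @property
    def n_times(self) -> int:
        return self.obs_x.shape[1]

    @classmethod
    def from_frames(
        cls,
        lakes: pd.DataFrame,
        series: pd.DataFrame,
        exclude_lakes: Sequence[str] = (),
    ) -> "LakeData":
        excl = {str(e) for e in exclude_lakes}
        lakes = lakes[~lakes["lake_id"].astype(str).isin(excl)].reset_index(drop=True)
        if len(lakes) < 2:
            raise ValueError("need at least 2 lakes after exclusions")
        ids = [str(i) for i in lakes["lake_id"]]
        series = series[series["lake_id"].astype(str).isin(set(ids))]
        wide_x = series.pivot_table(index="lake_id", columns="time_index", values="chla_obs")
        wide_y = series.pivot_table(index="lake_id", columns="time_index", values="zoop_obs")
        if wide_x.isna().any().any() or wide_y.isna().any().any():
            raise ValueError("series table is not a complete lake x time grid")
        wide_x = wide_x.loc[[i for i in ids]]
        wide_y = wide_y.loc[[i for i in ids]]
        return cls(
            lake_ids=ids,
            fish=lakes["fish_present"].to_numpy(dtype=bool),
            st=standardize(lakes["temp_c"].to_numpy(dtype=float)),
            sp=standardize(lakes["tot_p"].to_numpy(dtype=float)),
            obs_x=np.ascontiguousarray(wide_x.to_numpy(dtype=float)),
            obs_y=np.ascontiguousarray(wide_y.to_numpy(dtype=float)),
        )

    @classmethod
    def from_dataset(cls, dataset, exclude_lakes: Sequence[str] = ()) -> "LakeData":
        lakes, series = dataset.to_frames()
        return cls.from_frames(lakes, series, exclude_lakes=exclude_lakes)


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class Prior:
    """One scalar prior: family name plus its parameters.

    Families: ``normal(mu, sd)``, ``uniform(lo, hi)``, ``halfnormal(scale)``,
    ``lognormal(mu_log, sd_log)``, and ``fixed(value)`` which pins a
    parameter (the sampler then never updates it — used for conditional
    subproblems and oracle comparisons). Off-support values get log-density
    -inf.
    """

    family: str
    params: tuple[float, ...]

    def logpdf(self, v):
        v = np.asarray(v, dtype=float)
        if self.family == "fixed":
            (value,) = self.params
            out = np.where(np.isclose(v, value, rtol=1e-12, atol=1e-300), 0.0, _NEG_INF)
        elif self.family == "normal":
            mu, sd = self.params
            out = -0.5 * ((v - mu) / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI
        elif self.family == "uniform":
            lo, hi = self.params
            out = np.where((v >= lo) & (v <= hi), -math.log(hi - lo), _NEG_INF)
        elif self.family == "halfnormal":
            (scale,) = self.params
            out = np.where(
                v > 0,
                math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale) - 0.5 * (v / scale) ** 2,
                _NEG_INF,
            )
        elif self.family == "lognormal":
            mu, sd = self.params
            with np.errstate(divide="ignore", invalid="ignore"):
                lv = np.log(v)
            out = np.where(
                v > 0,
                -0.5 * ((lv - mu) / sd) ** 2 - lv - math.log(sd) - 0.5 * _LOG_2PI,
                _NEG_INF,
            )
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, scale_shrink: float = 1.0):
        """Draw one value, optionally with the spread shrunk (used to start
        chains overdispersed yet at finite-scale parameter values)."""
        if self.family == "fixed":
            return self.params[0]
        if self.family == "normal":
            mu, sd = self.params
            return rng.normal(mu, sd * scale_shrink)
        if self.family == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi)
        if self.family == "halfnormal":
            (scale,) = self.params
            return abs(rng.normal(0.0, scale * scale_shrink))
        if self.family == "lognormal":
            mu, sd = self.params
            return math.exp(rng.normal(mu, sd * scale_shrink))
        raise ValueError(f"unknown prior family {self.family!r}")


@dataclass
class PriorSpec:
    """Priors for every estimated quantity, keyed by parameter name.

    Initial-state priors use the names ``x1[<lake_id>]`` / ``y1[<lake_id>]``.
    """

    priors: dict[str, Prior]

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.priors

    @classmethod
    def default(cls, data: LakeData) -> "PriorSpec":
        """Weakly informative defaults: normal(0, 10) link coefficients,
        uniform(0, 1) mortalities and efficiency, half-normal observation
        sds scaled to the data spread, and lognormal initial states centered
        on the first observation of each lake."""
        priors = {
            "alpha_c": Prior("normal", (0.0, 10.0)),
            "beta_c": Prior("normal", (0.0, 10.0)),
            "alpha_psi": Prior("normal", (0.0, 10.0)),
            "beta_psi": Prior("normal", (0.0, 10.0)),
            "m_fish": Prior("uniform", (0.0, 1.0)),
            "m_nofish": Prior("uniform", (0.0, 1.0)),
            "e": Prior("uniform", (0.0, 1.0)),
            "sigma_x": Prior("halfnormal", (max(float(np.std(data.obs_x)), 1e-3),)),
            "sigma_y": Prior("halfnormal", (max(float(np.std(data.obs_y)), 1e-3),)),
        }
        for j, lake in enumerate(data.lake_ids):
            priors[f"x1[{lake}]"] = Prior(
                "lognormal", (math.log(max(data.obs_x[j, 0], 1e-6)), 1.0)
            )
            priors[f"y1[{lake}]"] = Prior(
                "lognormal", (math.log(max(data.obs_y[j, 0], 1e-6)), 1.0)
            )
        return cls(priors)

    def to_dict(self) -> dict:
        return {k: {"family": p.family, "params": list(p.params)} for k, p in self.priors.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls({k: Prior(v["family"], tuple(v["params"])) for k, v in d.items()})


# ---------------------------------------------------------------------------
# likelihood / posterior


def _derived_rates(data: LakeData, g: np.ndarray):
    """Per-lake (c, psi, m) vectors from the global parameter vector."""
    c = g[0] + g[1] * data.st
    psi = np.exp(g[2] + g[3] * data.sp)
    m = np.where(data.fish, g[4], g[5])
    return c, psi, m


def _loglik_vector(data: LakeData, g: np.ndarray, x1: np.ndarray, y1: np.ndarray) -> np.ndarray:
    c, psi, m = _derived_rates(data, g)
    return lake_logliks(
        c, psi, m, g[6], x1, y1, data.obs_x, data.obs_y, g[7], g[8]
    )


def log_likelihood(data: LakeData, theta: HyperParams) -> float:
    """Log-likelihood of the observations under ``theta``.

    Invalid parameter values return -inf (not an exception) so samplers can
    probe support boundaries.
    """
    if theta.x1 is None or theta.y1 is None:
        raise ValueError("theta must carry per-lake initial states x1, y1")
    if len(theta.x1) != data.n_lakes or len(theta.y1) != data.n_lakes:
        raise ValueError("initial-state vectors do not match the number of lakes")
    if not theta.is_valid():
        return _NEG_INF
    g = theta.globals_vector()
    return float(
        _loglik_vector(data, g, np.asarray(theta.x1, float), np.asarray(theta.y1, float)).sum()
    )


def _log_prior(data: LakeData, theta: HyperParams, priors: PriorSpec) -> float:
    total = 0.0
    for name, value in zip(HyperParams.GLOBAL_NAMES, theta.globals_vector()):
        total += float(priors[name].logpdf(value))
        if total == _NEG_INF:
            return _NEG_INF
    for prefix, arr in (("x1", theta.x1), ("y1", theta.y1)):
        for lake, v in zip(data.lake_ids, arr):
            total += float(priors[f"{prefix}[{lake}]"].logpdf(v))
            if total == _NEG_INF:
                return _NEG_INF
    return total


def log_posterior(data: LakeData, theta: HyperParams, priors: PriorSpec) -> float:
    """Unnormalized log posterior: log-likelihood plus log prior; -inf off
    the support."""
    lp = _log_prior(data, theta, priors)
    if lp == _NEG_INF:
        return _NEG_INF
    ll = log_likelihood(data, theta)
    return ll + lp


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class MCMCConfig:
    """Sampler settings. ``n_iter`` counts all iterations including burn-in;
    retained draws number ``(n_iter - n_burnin) // thin`` per chain."""

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 8_000
    thin: int = 2
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44
    init_attempts: int = 200
    # replica exchange: each chain runs n_temps coupled replicas whose
    # likelihood is raised to powers on a geometric ladder from 1 down to
    # min_temp, with adjacent-pair swap proposals every iteration; only the
    # cold (power 1) replica is retained. The hot replicas let the sampler
    # cross between the local modes of the rugged deterministic-trajectory
    # likelihood. n_temps=1 recovers plain Metropolis-within-Gibbs.
    n_temps: int = 4
    min_temp: float = 0.02

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for R-hat")

    @classmethod
    def paper_protocol(cls, seed: int = 0) -> "MCMCConfig":
        """The original survey's protocol: 3 chains, 250k iterations,
        100k burn-in, thinning 3."""
        return cls(n_chains=3, n_iter=250_000, n_burnin=100_000, thin=3, seed=seed)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: array (chain, draw, parameter) plus names."""

    draws: np.ndarray
    names: list[str]
    config: MCMCConfig
    seed: int

    def get(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chain, draw)."""
        try:
            k = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, :, k]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_long_frame(self) -> pd.DataFrame:
        C, N, P = self.draws.shape
        chain = np.repeat(np.arange(C), N * P)
        it = np.tile(np.repeat(np.arange(N), P), C)
        par = np.tile(np.array(self.names, dtype=object), C * N)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "parameter": par, "value": self.draws.reshape(-1)}
        )


_HARD_SUPPORT = {
    # index in the global vector -> (low, high), enforced besides the prior
    4: (0.0, 1.0),  # m_fish
    5: (0.0, 1.0),  # m_nofish
    6: (1e-12, 1.0),  # e
    7: (1e-12, np.inf),  # sigma_x
    8: (1e-12, np.inf),  # sigma_y
}


def _init_chain(data: LakeData, priors: PriorSpec, rng, attempts: int):
    """Overdispersed initialization from (spread-shrunk) prior draws,
    retried until the log-posterior is finite."""
    for _ in range(attempts):
        g = np.array(
            [priors[name].sample(rng, scale_shrink=0.1) for name in HyperParams.GLOBAL_NAMES]
        )
        for k, (lo, hi) in _HARD_SUPPORT.items():
            g[k] = min(max(g[k], lo + 1e-9), hi if np.isfinite(hi) else g[k])
        x1 = np.array([priors[f"x1[{l}]"].sample(rng, scale_shrink=0.3) for l in data.lake_ids])
        y1 = np.array([priors[f"y1[{l}]"].sample(rng, scale_shrink=0.3) for l in data.lake_ids])
        ll = _loglik_vector(data, g, x1, y1)
        if np.isfinite(ll).all():
            theta = HyperParams.from_globals_vector(g, x1, y1)
            if np.isfinite(_log_prior(data, theta, priors)):
                return g, x1, y1, ll
    raise RuntimeError(
        "could not find a finite log-posterior initialization; "
        "check priors and data alignment"
    )


class _Replica:
    """Mutable state of one tempered replica."""

    __slots__ = ("g", "x1", "y1", "ll", "pg", "px", "py", "s_g", "s_x1", "s_y1",
                 "acc_g", "acc_x1", "acc_y1", "g_hist", "joint_chol", "s_joint",
                 "acc_joint", "n_joint")

    def __init__(self, g, x1, y1, ll, pg, px, py):
        self.g, self.x1, self.y1 = g, x1, y1
        self.ll, self.pg, self.px, self.py = ll, pg, px, py
        self.s_g = np.full(9, 0.1)
        self.s_g[4:7] = 0.05  # mortalities and efficiency live on [0, 1]
        self.s_x1 = 0.25 * np.maximum(x1, 0.05)
        self.s_y1 = 0.25 * np.maximum(y1, 0.05)
        self.acc_g = np.zeros(9)
        self.acc_x1 = np.zeros(len(x1))
        self.acc_y1 = np.zeros(len(y1))
        # adaptive joint proposal over the globals (empirical-covariance
        # random walk), for traversing ridge-shaped posteriors
        self.g_hist: list[np.ndarray] = []
        self.joint_chol = None
        self.s_joint = 1.0
        self.acc_joint = 0.0
        self.n_joint = 0

    def swap_state(self, other: "_Replica") -> None:
        for f in ("g", "x1", "y1", "ll", "pg", "px", "py"):
            a, b = getattr(self, f), getattr(other, f)
            setattr(self, f, b)
            setattr(other, f, a)


def _lognormal_lp(v, mu, sd):
    out = np.full_like(v, _NEG_INF)
    pos = v > 0
    lv = np.log(v[pos])
    out[pos] = -0.5 * ((lv - mu[pos]) / sd[pos]) ** 2 - lv - np.log(sd[pos]) - 0.5 * _LOG_2PI
    return out


def fit_mcmc(data: LakeData, priors: Optional[PriorSpec] = None,
             config: Optional[MCMCConfig] = None) -> PosteriorDraws:
    """Sample the posterior with adaptive Metropolis-within-Gibbs, with
    replica exchange across a temperature ladder for mode hopping.

    Reproducible given ``config.seed``; chains run sequentially on
    independent random streams and only cold-replica draws are retained.
    """
    if data.n_lakes < 1 or data.n_times < 1:
        raise ValueError("data must contain at least one lake and one time point")
    if priors is None:
        priors = PriorSpec.default(data)
    if config is None:
        config = MCMCConfig()

    L = data.n_lakes
    names = list(HyperParams.GLOBAL_NAMES)
    names += [f"x1[{l}]" for l in data.lake_ids] + [f"y1[{l}]" for l in data.lake_ids]
    n_kept = (config.n_iter - config.n_burnin + config.thin - 1) // config.thin
    all_draws = np.empty((config.n_chains, n_kept, len(names)))

    global_priors = [priors[n] for n in HyperParams.GLOBAL_NAMES]
    g_fixed = np.array([p.family == "fixed" for p in global_priors])

    def _ln_params(prefix):
        mu = np.zeros(L)
        sd = np.ones(L)
        fixed = np.zeros(L, dtype=bool)
        for j, l in enumerate(data.lake_ids):
            p = priors[f"{prefix}[{l}]"]
            if p.family == "fixed":
                fixed[j] = True
            elif p.family == "lognormal":
                mu[j], sd[j] = p.params
            else:
                raise ValueError(
                    f"initial-state priors must be lognormal or fixed, got {p.family}"
                )
        return mu, sd, fixed

    x1_mu, x1_sd, x1_fixed = _ln_params("x1")
    y1_mu, y1_sd, y1_fixed = _ln_params("y1")

    K = config.n_temps
    betas = np.geomspace(1.0, config.min_temp, K) if K > 1 else np.array([1.0])

    def try_joint(rep: _Replica, beta: float, rng) -> None:
        """Correlated random-walk proposal over all nine globals at once."""
        g = rep.g
        prop = g + rep.s_joint * (rep.joint_chol @ rng.normal(size=9))
        prop[g_fixed] = g[g_fixed]
        for k, (lo, hi) in _HARD_SUPPORT.items():
            if not lo <= prop[k] <= hi:
                return
        p_new = np.array([float(p.logpdf(v)) for p, v in zip(global_priors, prop)])
        if not np.isfinite(p_new.sum()):
            return
        new_ll = _loglik_vector(data, prop, rep.x1, rep.y1)
        delta = beta * (new_ll.sum() - rep.ll.sum()) + p_new.sum() - rep.pg.sum()
        rep.n_joint += 1
        if math.log(rng.random()) < delta:
            rep.g[:] = prop
            rep.ll = new_ll
            rep.pg = p_new
            rep.acc_joint += 1

    def sweep(rep: _Replica, beta: float, rng) -> None:
        g, x1, y1 = rep.g, rep.x1, rep.y1
        cur_sum = rep.ll.sum()
        for k in range(9):
            if g_fixed[k]:
                continue
            old = g[k]
            g[k] = old + rep.s_g[k] * rng.normal()
            lo, hi = _HARD_SUPPORT.get(k, (-np.inf, np.inf))
            if not lo <= g[k] <= hi:
                g[k] = old
                continue
            p_new = float(global_priors[k].logpdf(g[k]))
            if p_new == _NEG_INF:
                g[k] = old
                continue
            new_ll = _loglik_vector(data, g, x1, y1)
            delta = beta * (new_ll.sum() - cur_sum) + p_new - rep.pg[k]
            if math.log(rng.random()) < delta:
                rep.ll = new_ll
                cur_sum = new_ll.sum()
                rep.pg[k] = p_new
                rep.acc_g[k] += 1
            else:
                g[k] = old

        # independent per-lake proposals for the initial-state vectors
        prop = x1 + rep.s_x1 * rng.normal(size=L)
        prop[x1_fixed] = x1[x1_fixed]
        p_new = _lognormal_lp(prop, x1_mu, x1_sd)
        new_ll = _loglik_vector(data, g, np.maximum(prop, 1e-300), y1)
        acc = np.log(rng.random(size=L)) < beta * (new_ll - rep.ll) + p_new - rep.px
        if acc.any():
            x1[acc] = prop[acc]
            rep.ll[acc] = new_ll[acc]
            rep.px[acc] = p_new[acc]
            rep.acc_x1[acc] += 1

        prop = y1 + rep.s_y1 * rng.normal(size=L)
        prop[y1_fixed] = y1[y1_fixed]
        p_new = _lognormal_lp(prop, y1_mu, y1_sd)
        new_ll = _loglik_vector(data, g, x1, np.maximum(prop, 1e-300))
        acc = np.log(rng.random(size=L)) < beta * (new_ll - rep.ll) + p_new - rep.py
        if acc.any():
            y1[acc] = prop[acc]
            rep.ll[acc] = new_ll[acc]
            rep.py[acc] = p_new[acc]
            rep.acc_y1[acc] += 1

        if rep.joint_chol is not None:
            try_joint(rep, beta, rng)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for ci in range(config.n_chains):
        rng = np.random.default_rng(seeds[ci])
        reps = []
        for _ in range(K):
            g, x1, y1, ll = _init_chain(data, priors, rng, config.init_attempts)
            pg = np.array([float(p.logpdf(v)) for p, v in zip(global_priors, g)])
            reps.append(
                _Replica(g, x1, y1, ll, pg,
                         _lognormal_lp(x1, x1_mu, x1_sd), _lognormal_lp(y1, y1_mu, y1_sd))
            )

        n_swap_prop = 0
        n_swap_acc = 0
        kept = 0
        for it in range(config.n_iter):
            for r, beta in zip(reps, betas):
                sweep(r, beta, rng)

            if K > 1:
                # alternate even/odd adjacent pairs for detailed balance
                for i in range(it % 2, K - 1, 2):
                    a, b = reps[i], reps[i + 1]
                    log_ratio = (betas[i] - betas[i + 1]) * (b.ll.sum() - a.ll.sum())
                    n_swap_prop += 1
                    if math.log(rng.random()) < log_ratio:
                        a.swap_state(b)
                        n_swap_acc += 1

            in_burnin = it < config.n_burnin
            if in_burnin:
                for r in reps:
                    r.g_hist.append(r.g.copy())
                    if len(r.g_hist) > 4000:
                        del r.g_hist[: len(r.g_hist) - 4000]
                if (it + 1) % config.adapt_interval == 0:
                    n = config.adapt_interval
                    for r in reps:
                        r.s_g *= np.exp(r.acc_g / n - config.target_accept)
                        r.s_x1 *= np.exp(r.acc_x1 / n - config.target_accept)
                        r.s_y1 *= np.exp(r.acc_y1 / n - config.target_accept)
                        r.acc_g[:] = 0
                        r.acc_x1[:] = 0
                        r.acc_y1[:] = 0
                        if r.n_joint:
                            r.s_joint *= math.exp(r.acc_joint / r.n_joint - 0.25)
                            r.acc_joint = 0.0
                            r.n_joint = 0
                if (it + 1) % (config.adapt_interval * 10) == 0 and len(r.g_hist) >= 500:
                    for r in reps:
                        hist = np.asarray(r.g_hist[-2000:])
                        cov = np.cov(hist.T) + 1e-12 * np.eye(9)
                        try:
                            r.joint_chol = np.linalg.cholesky(cov) * (2.38 / math.sqrt(9))
                        except np.linalg.LinAlgError:
                            pass

            if not in_burnin and (it - config.n_burnin) % config.thin == 0:
                cold = reps[0]
                all_draws[ci, kept, :9] = cold.g
                all_draws[ci, kept, 9 : 9 + L] = cold.x1
                all_draws[ci, kept, 9 + L :] = cold.y1
                kept += 1
        logger.info(
            "chain %d finished: %d retained draws, swap acceptance %.2f",
            ci, kept, n_swap_acc / max(n_swap_prop, 1),
        )

    return PosteriorDraws(draws=all_draws, names=names, config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# oracle and diagnostics


def grid_posterior(
    data: LakeData,
    priors: PriorSpec,
    free_param: str,
    grid: np.ndarray,
    fixed: HyperParams,
) -> np.ndarray:
    """Normalized posterior masses of one free parameter on a grid.

    Every other parameter is held at its value in ``fixed``. Masses use
    trapezoid weights and sum to one; used as an independent check of the
    MCMC marginals.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a sorted 1-d array, length >= 3")
    logp = np.empty(len(grid))
    for i, v in enumerate(grid):
        theta = fixed.copy()
        if free_param in HyperParams.GLOBAL_NAMES:
            setattr(theta, free_param, float(v))
        elif free_param.startswith(("x1[", "y1[")):
            prefix, lake = free_param[:2], free_param[3:-1]
            arr = getattr(theta, prefix).copy()
            arr[data.lake_ids.index(lake)] = v
            setattr(theta, prefix, arr)
        else:
            raise KeyError(f"unknown parameter {free_param!r}")
        logp[i] = log_posterior(data, theta, priors)
    if np.all(np.isneginf(logp)):
        raise ValueError("log-posterior is -inf on the whole grid")
    w = np.empty(len(grid))
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    mass = np.exp(logp - np.nanmax(logp[np.isfinite(logp)])) * w
    return mass / mass.sum()


def rhat(draws: PosteriorDraws, param: str) -> float:
    """Split R-hat: each chain is halved, then the classic between/within
    variance ratio is computed over the 2C half-chains."""
    chains = draws.get(param)
    return split_rhat(chains)


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor for an array (chain, draw)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        if B == 0:
            warnings.warn("zero within- and between-chain variance; R-hat set to 1")
            return 1.0
        return float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size via arviz (standard implementation)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains, dtype=float)))


def summarize_posterior(draws: PosteriorDraws, params: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Posterior summary table in the survey's reporting style.

    One row per parameter: mean, equal-tailed 95% interval (2.5%/97.5%
    linear-interpolation quantiles), fraction of draws below zero, split
    R-hat and effective sample size.
    """
    if draws.draws.size == 0:
        raise ValueError("no retained draws to summarize")
    if params is None:
        params = draws.names
    rows = []
    for name in params:
        chains = draws.get(name)
        flat = chains.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        try:
            rh = split_rhat(chains)
            ess = effective_sample_size(chains)
        except ValueError:  # too few draws for the diagnostics
            rh = float("nan")
            ess = float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "prob_below_zero": float((flat < 0).mean()),
                "rhat": rh,
                "ess": ess,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
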