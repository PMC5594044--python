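"""Posterior sampling and convergence diagnostics.

The sampler is an adaptive Hamiltonian Monte Carlo implementation in the
No-U-Turn style: trajectory length chosen by the doubling/U-turn criterion
with slice acceptance, step size tuned by dual averaging toward a target
acceptance statistic, and a diagonal mass matrix estimated in doubling
warmup windows. It consumes a single contract — the joint log density and
its gradient on the unconstrained scale — so the model code stays
sampler-agnostic. Warmup draws are discarded and never enter the returned
posterior; no thinning is applied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DesignInfo, ModelData
from .model import ModelSpec, ParamLayout, log_posterior_and_grad, pointwise_log_lik

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "PosteriorDraws", "fit", "fit_map", "diagnostics",
           "save_draws", "load_draws"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings: 3 chains of 2000 iterations, half warmup, by default."""

    chains: int = 3
    iterations: int = 2000
    warmup: int = None
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10

    def __post_init__(self):
        warmup = self.warmup if self.warmup is not None else self.iterations // 2
        object.__setattr__(self, "warmup", warmup)
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 < self.warmup < self.iterations):
            raise ValueError("warmup must be positive and smaller than iterations")

    def to_dict(self):
        return {"chains": self.chains, "iterations": self.iterations,
                "warmup": self.warmup, "seed": self.seed,
                "target_accept": self.target_accept,
                "max_treedepth": self.max_treedepth}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class PosteriorDraws:
    """Retained posterior samples plus the pointwise log-likelihood matrix.

    ``thetas`` stacks post-warmup draws from all chains on the unconstrained
    scale; ``loglik`` holds the per-observation log-likelihood of every draw,
    the raw material for WAIC.
    """

    thetas: np.ndarray          # (S, dim)
    chain: np.ndarray           # (S,)
    loglik: np.ndarray          # (S, n)
    spec: ModelSpec
    layout: ParamLayout
    design_info: DesignInfo = None
    stats: dict = field(default_factory=dict)

    @property
    def S(self) -> int:
        return self.thetas.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if self.S else 0

    def parameter_sets(self):
        """Iterate over draws as structured :class:`ParameterSet` objects."""
        for s in range(self.S):
            yield self.layout.unpack(self.thetas[s])

    def names(self) -> list:
        return self.layout.names(self.design_info)

    def to_arviz(self):
        """Posterior as an arviz InferenceData (one variable per parameter)."""
        import arviz as az
        C = self.n_chains
        per = self.S // C
        arr = self.thetas[: C * per].reshape(C, per, -1)
        data = {name: arr[:, :, j] for j, name in enumerate(self.names())}
        return az.convert_to_inference_data(data)


def _leapfrog(theta, p, grad, eps, inv_mass, logp_grad):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    lp, g = logp_grad(theta)
    p = p + 0.5 * eps * g
    return theta, p, lp, g


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p, inv_mass * p))


class _NutsChain:
    """One NUTS chain with dual-averaging step size and windowed mass updates."""

    def __init__(self, logp_grad, theta0, rng, target_accept, max_treedepth):
        self.f = logp_grad
        self.rng = rng
        self.delta = target_accept
        self.max_depth = max_treedepth
        self.theta = np.asarray(theta0, dtype=float)
        self.lp, self.grad = self.f(self.theta)
        if not np.isfinite(self.lp):
            raise ValueError("non-finite log density at the initial point")
        self.inv_mass = np.ones_like(self.theta)
        self.eps = self._find_initial_step()
        self._da_reset()
        self.divergences = 0

    # --- dual averaging (Hoffman & Gelman 2014) ---
    def _da_reset(self):
        self.mu = math.log(10 * self.eps)
        self.h_bar = 0.0
        self.log_eps_bar = math.log(self.eps)
        self.da_count = 0

    def _da_update(self, accept_stat):
        self.da_count += 1
        t0, gamma, kappa = 10.0, 0.05, 0.75
        w = 1.0 / (self.da_count + t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.delta - accept_stat)
        log_eps = self.mu - math.sqrt(self.da_count) / gamma * self.h_bar
        eta = self.da_count ** (-kappa)
        self.log_eps_bar = eta * log_eps + (1 - eta) * self.log_eps_bar
        self.eps = math.exp(log_eps)

    def _find_initial_step(self):
        eps = 0.1
        p = self.rng.standard_normal(self.theta.size) / np.sqrt(self.inv_mass)
        h0 = self.lp - _kinetic(p, self.inv_mass)
        theta1, p1, lp1, _ = _leapfrog(self.theta, p, self.grad, eps,
                                       self.inv_mass, self.f)
        h1 = lp1 - _kinetic(p1, self.inv_mass) if np.isfinite(lp1) else -np.inf
        direction = 1 if (h1 - h0) > math.log(0.5) else -1
        for _ in range(50):
            eps *= 2.0 ** direction
            theta1, p1, lp1, _ = _leapfrog(self.theta, p, self.grad, eps,
                                           self.inv_mass, self.f)
            h1 = lp1 - _kinetic(p1, self.inv_mass) if np.isfinite(lp1) else -np.inf
            if direction == 1 and (h1 - h0) <= math.log(0.5):
                break
            if direction == -1 and (h1 - h0) >= math.log(0.5):
                break
        return eps

    # --- recursive tree doubling with slice acceptance ---
    def _build_tree(self, theta, p, grad, log_u, direction, depth, h0):
        if depth == 0:
            theta1, p1, lp1, g1 = _leapfrog(theta, p, grad,
                                            direction * self.eps,
                                            self.inv_mass, self.f)
            h1 = lp1 - _kinetic(p1, self.inv_mass) if np.isfinite(lp1) else -np.inf
            n_keep = int(log_u <= h1)
            diverged = (h0 - h1) > _MAX_ENERGY_ERROR or not np.isfinite(h1)
            if diverged:
                self._diverged = True
            accept = min(1.0, math.exp(min(0.0, h1 - h0)))
            return (theta1, p1, g1, theta1, p1, g1, theta1, lp1, g1,
                    n_keep, not diverged, accept, 1)
        (tm, pm, gm, tp, pp, gp, tprop, lpprop, gprop, n1, ok, a1, na1) = \
            self._build_tree(theta, p, grad, log_u, direction, depth - 1, h0)
        if ok:
            if direction == -1:
                (tm, pm, gm, _, _, _, tprop2, lpprop2, gprop2, n2, ok2, a2,
                 na2) = self._build_tree(tm, pm, gm, log_u, direction,
                                         depth - 1, h0)
            else:
                (_, _, _, tp, pp, gp, tprop2, lpprop2, gprop2, n2, ok2, a2,
                 na2) = self._build_tree(tp, pp, gp, log_u, direction,
                                         depth - 1, h0)
            if n2 and self.rng.random() < n2 / max(n1 + n2, 1):
                tprop, lpprop, gprop = tprop2, lpprop2, gprop2
            dt = tp - tm
            no_uturn = (np.dot(dt, self.inv_mass * pm) >= 0
                        and np.dot(dt, self.inv_mass * pp) >= 0)
            ok = ok2 and no_uturn
            n1 += n2
            a1 += a2
            na1 += na2
        return tm, pm, gm, tp, pp, gp, tprop, lpprop, gprop, n1, ok, a1, na1

    def step(self):
        self._diverged = False
        p0 = self.rng.standard_normal(self.theta.size) / np.sqrt(self.inv_mass)
        h0 = self.lp - _kinetic(p0, self.inv_mass)
        log_u = h0 + math.log(self.rng.random() + 1e-300)
        tm = tp = self.theta
        pm = pp = p0
        gm = gp = self.grad
        n_keep, depth, ok = 1, 0, True
        accept_sum, accept_n = 0.0, 0
        while ok and depth < self.max_depth:
            direction = 1 if self.rng.random() < 0.5 else -1
            if direction == -1:
                (tm, pm, gm, _, _, _, tprop, lpprop, gprop, n2, ok2, a2,
                 na2) = self._build_tree(tm, pm, gm, log_u, direction,
                                         depth, h0)
            else:
                (_, _, _, tp, pp, gp, tprop, lpprop, gprop, n2, ok2, a2,
                 na2) = self._build_tree(tp, pp, gp, log_u, direction,
                                         depth, h0)
            accept_sum += a2
            accept_n += na2
            if ok2 and n2 and self.rng.random() < min(1.0, n2 / n_keep):
                self.theta = tprop
                self.lp = lpprop
                self.grad = gprop
            n_keep += n2
            dt = tp - tm
            ok = (ok2 and np.dot(dt, self.inv_mass * pm) >= 0
                  and np.dot(dt, self.inv_mass * pp) >= 0)
            depth += 1
        if self._diverged:
            self.divergences += 1
        return accept_sum / max(accept_n, 1)

    def run(self, iterations, warmup):
        dim = self.theta.size
        draws = np.empty((iterations - warmup, dim))
        # Stan-like schedule: settle step size, then doubling variance
        # windows for the mass matrix, then a final step-size buffer.
        init_buf = max(1, int(0.15 * warmup))
        term_buf = max(1, int(0.10 * warmup))
        window_start = init_buf
        window_len = 25
        welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
        next_window_end = min(window_start + window_len, warmup - term_buf)
        for it in range(iterations):
            accept_stat = self.step()
            if it < warmup:
                self._da_update(accept_stat)
                if window_start <= it < warmup - term_buf:
                    welford_n += 1
                    delta = self.theta - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (self.theta - welford_mean)
                    if it + 1 == next_window_end and welford_n > 5:
                        var = welford_m2 / (welford_n - 1)
                        # regularize toward unit scale as Stan does
                        w = welford_n / (welford_n + 5.0)
                        self.inv_mass = w * var + (1 - w) * 1e-3
                        welford_n, welford_mean[:] = 0, 0.0
                        welford_m2[:] = 0.0
                        window_len *= 2
                        window_start = it + 1
                        next_window_end = min(window_start + window_len,
                                              warmup - term_buf)
                        self.eps = math.exp(self.log_eps_bar)
                        self._da_reset()
                if it + 1 == warmup:
                    self.eps = math.exp(self.log_eps_bar)
                    self.div_warmup = self.divergences
                    self.divergences = 0
            else:
                draws[it - warmup] = self.theta
        return draws


def fit(data: ModelData, spec: ModelSpec = None, config: SamplerConfig = None,
        prior_only: bool = False) -> PosteriorDraws:
    """Sample the posterior of the multinomial mixed model.

    Deterministic given ``config.seed``. A poorly mixing run is still
    returned, with the problem visible in :func:`diagnostics`; only
    structural errors (empty data, dimension mismatches) raise.

    ``prior_only`` drops the likelihood term, so the draws target the prior
    — useful for checking the prior implementation against its quantiles.
    """
    if data.n == 0:
        raise ValueError("cannot fit a model to zero observations")
    spec = spec or ModelSpec.from_model_data(data)
    config = config or SamplerConfig()
    layout = ParamLayout(spec)

    def logp_grad(theta):
        return log_posterior_and_grad(theta, data, spec, layout,
                                      include_lik=not prior_only)

    all_draws, chain_ids, div_counts, step_sizes = [], [], [], []
    for c in range(config.chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        theta0 = 0.1 * rng.standard_normal(layout.dim)
        for f in spec.re_factors:  # start scales near a moderate value
            t_sl, _, _ = layout.factor_slices[f.name]
            theta0[t_sl] = math.log(0.5) + 0.1 * rng.standard_normal(spec.D)
        chain = _NutsChain(logp_grad, theta0, rng, config.target_accept,
                           config.max_treedepth)
        draws = chain.run(config.iterations, config.warmup)
        all_draws.append(draws)
        chain_ids.append(np.full(draws.shape[0], c))
        div_counts.append(chain.divergences)
        step_sizes.append(chain.eps)
        logger.info("chain %d: %d draws, step size %.4g, %d divergences",
                    c, draws.shape[0], chain.eps, chain.divergences)

    thetas = np.vstack(all_draws)
    loglik = np.empty((thetas.shape[0], data.n))
    for s in range(thetas.shape[0]):
        loglik[s] = pointwise_log_lik(layout.unpack(thetas[s]), data)

    return PosteriorDraws(
        thetas=thetas,
        chain=np.concatenate(chain_ids),
        loglik=loglik,
        spec=spec,
        layout=layout,
        design_info=data.design_info,
        stats={"divergences": div_counts, "step_size": step_sizes,
               "config": config.to_dict(), "prior_only": prior_only},
    )


def fit_map(data: ModelData, spec: ModelSpec = None, n_restarts: int = 1,
            seed: int = 0):
    """Posterior mode by L-BFGS on the unconstrained scale.

    A fast deterministic surrogate for invariance checks; MCMC remains the
    estimation method of record.
    """
    from scipy.optimize import minimize

    spec = spec or ModelSpec.from_model_data(data)
    layout = ParamLayout(spec)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        theta0 = 0.01 * rng.standard_normal(layout.dim)
        res = minimize(
            lambda th: tuple(-x for x in
                             log_posterior_and_grad(th, data, spec, layout)),
            theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return layout.unpack(best.x), -best.fun, layout


def diagnostics(draws: PosteriorDraws, rhat_max: float = 1.01,
                ess_min: float = 100.0) -> dict:
    """Split R-hat, effective sample size, and divergence report.

    Parameters whose R-hat exceeds ``rhat_max`` or whose bulk ESS falls
    below ``ess_min`` are flagged; the verdict is "adequately mixed" only
    when nothing is flagged and no divergences occurred.
    """
    import arviz as az

    names = draws.names()
    report = {"divergences": int(sum(draws.stats.get("divergences", [0])))}
    idata = draws.to_arviz()
    ess = az.ess(idata)
    report["ess"] = {v: float(ess[v].values) for v in names}
    if draws.n_chains >= 2:
        rhat = az.rhat(idata)
        report["rhat"] = {v: float(rhat[v].values) for v in names}
    else:
        logger.warning("single chain: split R-hat omitted")
        report["rhat"] = None
    flagged = [v for v, e in report["ess"].items() if e < ess_min]
    if report["rhat"] is not None:
        flagged += [v for v, r in report["rhat"].items()
                    if np.isfinite(r) and r > rhat_max]
    report["flagged"] = sorted(set(flagged))
    report["adequately_mixed"] = (not report["flagged"]
                                  and report["divergences"] == 0)
    report["verdict"] = ("adequately mixed" if report["adequately_mixed"]
                         else f"{len(report['flagged'])} flagged parameters, "
                              f"{report['divergences']} divergences")
    return report


def save_draws(draws: PosteriorDraws, prefix) -> None:
    """Persist draws as CSV (one row per draw) plus JSON metadata."""
    df = pd.DataFrame(draws.thetas, columns=draws.names())
    df.insert(0, "chain", draws.chain)
    df.to_csv(f"{prefix}_draws.csv", index=False)
    pd.DataFrame(draws.loglik).to_csv(f"{prefix}_loglik.csv", index=False)
    meta = {
        "spec": draws.spec.to_dict(),
        "stats": draws.stats,
        "design_info": (draws.design_info.to_dict()
                        if draws.design_info is not None else None),
    }
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_draws(prefix) -> PosteriorDraws:
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    spec = ModelSpec.from_dict(meta["spec"])
    layout = ParamLayout(spec)
    df = pd.read_csv(f"{prefix}_draws.csv")
    chain = df.pop("chain").to_numpy(dtype=np.int64)
    loglik = pd.read_csv(f"{prefix}_loglik.csv").to_numpy(dtype=float)
    design_info = (DesignInfo.from_dict(meta["design_info"])
                   if meta.get("design_info") else None)
    return PosteriorDraws(
        thetas=df.to_numpy(dtype=float), chain=chain, loglik=loglik,
        spec=spec, layout=layout, design_info=design_info,
        stats=meta.get("stats", {}),
    )
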