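"""WAIC model comparison and posterior summary tables.

WAIC is reported on the deviance scale, -2(lppd - p_waic), so lower values
indicate models expected to predict better out of sample; p_waic (the sum of
pointwise posterior variances of the log-likelihood) plays the role of the
effective number of parameters. Model weights follow the Akaike convention
exp(-delta/2), normalized across the candidate set, and the standard error
of each delta uses the paired pointwise difference so that correlation
between models' pointwise scores is respected.

Credible intervals throughout are equal-tailed percentile intervals; the
defaults are 96% for coefficient flagging and 89% for predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import correlation_from_block

__all__ = ["WAICResult", "waic", "compare", "summarize_params", "re_summary"]


@dataclass
class WAICResult:
    waic: float
    se: float
    p_waic: float
    lppd: float
    pointwise: np.ndarray  # per-observation waic contributions, length n

    @property
    def n(self) -> int:
        return self.pointwise.shape[0]


def waic(loglik: np.ndarray) -> WAICResult:
    """Widely Applicable Information Criterion from an S x n log-lik matrix.

    lppd_i = log mean_s exp(l_si) (via log-sum-exp), p_i = Var_s(l_si),
    waic_i = -2 (lppd_i - p_i); the total is the sum over observations and
    the SE is sqrt(n Var_i(waic_i)) (0 when n = 1).
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik must be a 2-D (draws x observations) matrix")
    S, n = ll.shape
    if S < 2:
        raise ValueError("need at least 2 draws to estimate p_waic")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite entries in the log-likelihood matrix")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = np.var(ll, axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return WAICResult(
        waic=float(waic_i.sum()),
        se=se,
        p_waic=float(p_i.sum()),
        lppd=float(lppd_i.sum()),
        pointwise=waic_i,
    )


def compare(results, names=None) -> pd.DataFrame:
    """WAIC comparison table: delta vs the best model, paired SE, weights.

    All results must come from the same observations (aligned pointwise
    vectors); the best model sits in the first row with delta 0, and the
    weights sum to one.
    """
    results = list(results)
    if names is None:
        names = [f"model_{i}" for i in range(len(results))]
    ns = {r.n for r in results}
    if len(ns) != 1:
        raise ValueError(f"models were scored on different n: {sorted(ns)}")
    n = ns.pop()
    waics = np.array([r.waic for r in results])
    best = int(np.argmin(waics))
    delta = waics - waics[best]
    d_se = np.zeros(len(results))
    for m, r in enumerate(results):
        if m != best and n > 1:
            diff = r.pointwise - results[best].pointwise
            d_se[m] = np.sqrt(n * np.var(diff, ddof=1))
    # subtracting the min keeps the exponentials stable; weights are invariant
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    df = pd.DataFrame(
        {
            "waic": waics,
            "se": [r.se for r in results],
            "p_waic": [r.p_waic for r in results],
            "d_waic": delta,
            "d_se": d_se,
            "weight": w,
        },
        index=pd.Index(names, name="model"),
    )
    return df.sort_values("waic")


def _interval(x: np.ndarray, level: float):
    if not (0 < level < 1):
        raise ValueError("interval level must be in (0, 1)")
    alpha = (1 - level) / 2
    return np.quantile(x, alpha, axis=0), np.quantile(x, 1 - alpha, axis=0)


def _summary_frame(samples: np.ndarray, names, level: float) -> pd.DataFrame:
    lower, upper = _interval(samples, level)
    return pd.DataFrame(
        {
            "mean": samples.mean(axis=0),
            "sd": samples.std(axis=0, ddof=1) if samples.shape[0] > 1 else 0.0,
            "lower": lower,
            "upper": upper,
            "excludes_zero": (lower > 0) | (upper < 0),
        },
        index=pd.Index(names, name="parameter"),
    )


def _constrained_samples(draws, include=("beta", "sigma", "rho")):
    """Named posterior samples of interpretable quantities.

    beta entries come straight off the draw matrix; sigma and each pairwise
    correlation are transformed per draw (so rho summaries are posterior
    summaries of the correlation, not correlations of posterior means).
    """
    spec = draws.spec
    info = draws.design_info
    cats = ([info.ethogram.categories[k] for k in spec.nonref]
            if info is not None else [str(k) for k in spec.nonref])
    cols = (list(info.column_names) if info is not None
            else [str(p) for p in range(spec.P)])
    names, columns = [], []
    if "beta" in include:
        b = draws.thetas[:, draws.layout.beta].reshape(draws.S, spec.D, spec.P)
        for j, c in enumerate(cats):
            for p, col in enumerate(cols):
                names.append(f"beta[{c},{col}]")
                columns.append(b[:, j, p])
    for f in spec.re_factors:
        t_sl, y_sl, _ = draws.layout.factor_slices[f.name]
        if "sigma" in include:
            sig = np.exp(draws.thetas[:, t_sl])
            for j, c in enumerate(cats):
                names.append(f"sigma[{f.name},{c}]")
                columns.append(sig[:, j])
        if "rho" in include and y_sl is not None:
            from .model import corr_free_to_chol
            rho = np.empty((draws.S, spec.D, spec.D))
            for s in range(draws.S):
                L, _ = corr_free_to_chol(draws.thetas[s, y_sl], spec.D)
                rho[s] = correlation_from_block(None, L)
            for a in range(spec.D):
                for b_ in range(a + 1, spec.D):
                    names.append(f"rho[{f.name},{cats[a]},{cats[b_]}]")
                    columns.append(rho[:, b_, a])
    return names, np.column_stack(columns) if columns else np.empty((draws.S, 0))


def summarize_params(draws, level: float = 0.96,
                     include=("beta", "sigma", "rho")) -> pd.DataFrame:
    """Posterior mean, SD, percentile interval, and zero-exclusion flag.

    The default 96% level matches the convention of flagging coefficients
    whose credible interval excludes zero.
    """
    names, samples = _constrained_samples(draws, include)
    return _summary_frame(samples, names, level)


def re_summary(draws, factor: str, level: float = 0.96) -> dict:
    """Random-effect scale and cross-category correlation summaries.

    Returns ``{"sigma": DataFrame, "rho": DataFrame or None, "rho_matrix":
    (mean matrix, sd matrix) or None}`` for the requested factor. Each
    pairwise correlation is computed per posterior draw from the Cholesky
    factor and then summarized.
    """
    spec = draws.spec
    factor_names = [f.name for f in spec.re_factors]
    if factor not in factor_names:
        raise KeyError(f"factor {factor!r} not in model (have {factor_names})")
    fspec = spec.re_factors[factor_names.index(factor)]
    info = draws.design_info
    cats = ([info.ethogram.categories[k] for k in spec.nonref]
            if info is not None else [str(k) for k in spec.nonref])
    t_sl, y_sl, _ = draws.layout.factor_slices[factor]
    sig = np.exp(draws.thetas[:, t_sl])
    out = {"sigma": _summary_frame(sig, cats, level)}
    if fspec.full_covariance and y_sl is not None:
        from .model import corr_free_to_chol
        rho = np.empty((draws.S, spec.D, spec.D))
        for s in range(draws.S):
            L, _ = corr_free_to_chol(draws.thetas[s, y_sl], spec.D)
            rho[s] = correlation_from_block(None, L)
        names, cols = [], []
        for a in range(spec.D):
            for b in range(a + 1, spec.D):
                names.append(f"rho[{cats[a]},{cats[b]}]")
                cols.append(rho[:, b, a])
        out["rho"] = _summary_frame(np.column_stack(cols), names, level)
        out["rho_matrix"] = (rho.mean(axis=0),
                             rho.std(axis=0, ddof=1) if draws.S > 1
                             else np.zeros((spec.D, spec.D)))
    else:
        out["rho"] = None
        out["rho_matrix"] = None
    return out
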