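"""The multilevel multinomial (baseline-category logit) behavior model.

For an ethogram of K categories with reference category r, the model places
K-1 log-odds equations

    log(pi_k / pi_r) = x' beta_k + sum_f v_f[group_f, k]

over the non-reference categories k, where each random-effect factor f
(individual, household, month, ...) contributes a group-specific deviation
vector v_g distributed MVN(0, Omega_f) across the K-1 equations. The
covariance Omega_f = diag(sigma) R diag(sigma) is what carries the
behavioral trade-off structure: a negative off-diagonal correlation means
groups doing relatively more of one behavior do relatively less of another
(both relative to the reference).

Sampling uses the non-centered parameterization v_g = diag(sigma) L z_g with
z_g ~ N(0, I) and L the Cholesky factor of the correlation matrix R, which
decorrelates the hierarchical geometry for HMC. All densities are evaluated
on the unconstrained scale (log sigma; tanh-based free coordinates for L)
with the appropriate Jacobian terms, and analytic gradients are provided for
every block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, logsumexp

__all__ = [
    "PriorConfig",
    "REFactorSpec",
    "ModelSpec",
    "REBlock",
    "ParameterSet",
    "ParamLayout",
    "linear_predictors",
    "category_log_probs",
    "pointwise_log_lik",
    "transform_noncentered",
    "correlation_from_block",
    "log_prior",
    "log_posterior_and_grad",
    "corr_free_to_chol",
    "corr_chol_to_free",
    "lkj_cholesky_log_norm",
]


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors centered at zero.

    Intercepts Normal(0, 5); slopes Normal(0, 1); random-effect scales
    half-Cauchy(0, 2); correlation Cholesky factors LKJ(eta=2). Zero is the
    prior mode for every parameter, including correlations, so posteriors
    away from zero reflect evidence in the data.
    """

    intercept_scale: float = 5.0
    slope_scale: float = 1.0
    sigma_scale: float = 2.0
    lkj_eta: float = 2.0

    def to_dict(self):
        return {
            "intercept_scale": self.intercept_scale,
            "slope_scale": self.slope_scale,
            "sigma_scale": self.sigma_scale,
            "lkj_eta": self.lkj_eta,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass(frozen=True)
class REFactorSpec:
    """One crossed random-effect factor (e.g. individual, household, month).

    ``full_covariance`` estimates the full (K-1)x(K-1) correlation matrix;
    switch it off for factors with few groups, where the correlations are
    weakly identified, to fall back to independent scales.
    """

    name: str
    group_count: int
    full_covariance: bool = True

    def __post_init__(self):
        if self.group_count < 1:
            raise ValueError(f"factor {self.name!r} needs at least one group")


@dataclass(frozen=True)
class ModelSpec:
    K: int
    reference_index: int
    P: int
    re_factors: tuple = ()
    priors: PriorConfig = field(default_factory=PriorConfig)
    intercept_col: int = 0  # design column receiving the intercept prior; -1 for none

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if not (0 <= self.reference_index < self.K):
            raise ValueError("reference_index out of range")
        object.__setattr__(self, "re_factors", tuple(self.re_factors))

    @property
    def D(self) -> int:
        """Number of contrast equations, K - 1."""
        return self.K - 1

    @property
    def nonref(self) -> np.ndarray:
        """Category codes owning a contrast equation, in order."""
        return np.array([k for k in range(self.K) if k != self.reference_index])

    @classmethod
    def from_model_data(cls, data, priors: PriorConfig = None, full_covariance=True,
                        intercept_col: int = None) -> "ModelSpec":
        counts = data.group_counts()
        if intercept_col is None:
            intercept_col = (
                data.design_info.column_names.index("intercept")
                if "intercept" in data.design_info.column_names
                else -1
            )
        return cls(
            K=data.K,
            reference_index=data.design_info.ethogram.reference_index,
            P=data.P,
            re_factors=tuple(
                REFactorSpec(name, counts[name], full_covariance)
                for name in data.factor_indices
            ),
            priors=priors or PriorConfig(),
            intercept_col=intercept_col,
        )

    def to_dict(self):
        return {
            "K": self.K,
            "reference_index": self.reference_index,
            "P": self.P,
            "re_factors": [
                {"name": f.name, "group_count": f.group_count,
                 "full_covariance": f.full_covariance}
                for f in self.re_factors
            ],
            "priors": self.priors.to_dict(),
            "intercept_col": self.intercept_col,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            K=d["K"],
            reference_index=d["reference_index"],
            P=d["P"],
            re_factors=tuple(REFactorSpec(**f) for f in d["re_factors"]),
            priors=PriorConfig.from_dict(d["priors"]),
            intercept_col=d.get("intercept_col", 0),
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class REBlock:
    """Realized random-effect block for one factor."""

    sigma: np.ndarray  # (D,)
    L: np.ndarray      # (D, D) lower Cholesky of the correlation matrix
    z: np.ndarray      # (G, D) standard-normal innovations
    v: np.ndarray      # (G, D) realized effects, diag(sigma) L z_g per group


@dataclass
class ParameterSet:
    """One point in parameter space: fixed effects plus RE blocks."""

    beta: np.ndarray   # (D, P)
    re: dict = field(default_factory=dict)  # factor name -> REBlock


# ---------------------------------------------------------------------------
# correlation Cholesky transform (unconstrained -> unit-row lower triangular)
# ---------------------------------------------------------------------------

def _n_corr_free(D: int) -> int:
    return D * (D - 1) // 2


def corr_free_to_chol(y: np.ndarray, D: int, want_grad: bool = False):
    """Map free coordinates to the Cholesky factor of a correlation matrix.

    Row i of L is built from i free values via z = tanh(y):
    L[i,j] = z_ij * sqrt(1 - sum_{l<j} L[i,l]^2), diagonal completing the
    unit row norm. Returns (L, log_jac) where log_jac is the log absolute
    determinant of the y -> L map; with ``want_grad`` also returns dL/dy
    (D, D, m) and d log_jac / dy (m,).
    """
    m = _n_corr_free(D)
    y = np.asarray(y, dtype=float)
    if y.shape != (m,):
        raise ValueError(f"expected {m} free correlation parameters, got {y.shape}")
    L = np.zeros((D, D))
    L[0, 0] = 1.0
    log_jac = 0.0
    dL = np.zeros((D, D, m)) if want_grad else None
    djac = np.zeros(m) if want_grad else None
    pos = 0
    for i in range(1, D):
        idx = list(range(pos, pos + i))
        z = np.tanh(y[idx])
        s = 0.0
        ds = np.zeros(m) if want_grad else None
        for j in range(i):
            w = math.sqrt(max(1.0 - s, 1e-300))
            zj = z[j]
            L[i, j] = zj * w
            log_jac += math.log1p(-zj * zj) + 0.5 * math.log(max(1.0 - s, 1e-300))
            if want_grad:
                dz = np.zeros(m)
                dz[idx[j]] = 1.0 - zj * zj  # d tanh
                dw = -0.5 / w * ds
                dL[i, j] = dz * w + zj * dw
                djac += (-2.0 * zj / (1.0 - zj * zj)) * dz - 0.5 / (1.0 - s) * ds
                ds = ds + 2.0 * L[i, j] * dL[i, j]
            s += L[i, j] ** 2
        L[i, i] = math.sqrt(max(1.0 - s, 1e-300))
        if want_grad:
            dL[i, i] = -0.5 / L[i, i] * ds
        pos += i
    if want_grad:
        return L, log_jac, dL, djac
    return L, log_jac


def corr_chol_to_free(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_free_to_chol` (for initialization and round trips)."""
    L = np.asarray(L, dtype=float)
    D = L.shape[0]
    y = []
    for i in range(1, D):
        s = 0.0
        for j in range(i):
            w = math.sqrt(max(1.0 - s, 1e-300))
            z = np.clip(L[i, j] / w, -1 + 1e-12, 1 - 1e-12)
            y.append(np.arctanh(z))
            s += L[i, j] ** 2
    return np.asarray(y)


def lkj_cholesky_log_norm(D: int, eta: float) -> float:
    """Log normalizing constant of the LKJ density det(R)^(eta-1).

    The density of the correlation Cholesky factor over its free lower
    triangle is exp(this constant) at L = I.
    """
    log_c = 0.0
    for k in range(1, D):
        dk = D - k
        a = eta + (dk - 1) / 2.0
        log_c -= (2 * eta - 2 + dk) * dk * math.log(2.0) + dk * betaln(a, a)
    return log_c


def _lkj_cholesky_logpdf(L: np.ndarray, eta: float):
    """Log density of a unit-row lower Cholesky under LKJ(eta), with d/d diag(L)."""
    D = L.shape[0]
    diag = np.diag(L)
    expo = np.array([2 * eta - 2 + D - (i + 1) for i in range(D)], dtype=float)
    expo[0] = 0.0  # L[0,0] = 1 always
    lp = lkj_cholesky_log_norm(D, eta) + float(np.sum(expo[1:] * np.log(diag[1:])))
    ddiag = np.zeros(D)
    ddiag[1:] = expo[1:] / diag[1:]
    return lp, ddiag


# ---------------------------------------------------------------------------
# flat parameter vector layout
# ---------------------------------------------------------------------------

@dataclass
class ParamLayout:
    """Slices of the unconstrained parameter vector for a :class:`ModelSpec`.

    Order: beta (D*P), then per factor: log sigma (D), correlation free
    coordinates (D(D-1)/2 if full covariance), innovations z (G*D).
    """

    spec: ModelSpec
    beta: slice = None
    factor_slices: dict = None  # name -> (t_slice, y_slice or None, z_slice)
    dim: int = 0

    def __post_init__(self):
        spec = self.spec
        D = spec.D
        off = D * spec.P
        self.beta = slice(0, off)
        self.factor_slices = {}
        for f in spec.re_factors:
            t = slice(off, off + D)
            off += D
            if f.full_covariance and D > 1:
                y = slice(off, off + _n_corr_free(D))
                off = y.stop
            else:
                y = None
            z = slice(off, off + f.group_count * D)
            off = z.stop
            self.factor_slices[f.name] = (t, y, z)
        self.dim = off

    def unpack(self, theta: np.ndarray) -> ParameterSet:
        spec = self.spec
        D = spec.D
        beta = theta[self.beta].reshape(D, spec.P)
        re = {}
        for f in spec.re_factors:
            t_sl, y_sl, z_sl = self.factor_slices[f.name]
            sigma = np.exp(theta[t_sl])
            if y_sl is not None:
                L, _ = corr_free_to_chol(theta[y_sl], D)
            else:
                L = np.eye(D)
            z = theta[z_sl].reshape(f.group_count, D)
            v = transform_noncentered(z, sigma, L)
            re[f.name] = REBlock(sigma=sigma, L=L, z=z, v=v)
        return ParameterSet(beta=beta, re=re)

    def pack(self, params: ParameterSet) -> np.ndarray:
        spec = self.spec
        theta = np.zeros(self.dim)
        theta[self.beta] = np.asarray(params.beta, dtype=float).ravel()
        for f in spec.re_factors:
            t_sl, y_sl, z_sl = self.factor_slices[f.name]
            blk = params.re[f.name]
            theta[t_sl] = np.log(blk.sigma)
            if y_sl is not None:
                theta[y_sl] = corr_chol_to_free(blk.L)
            theta[z_sl] = np.asarray(blk.z, dtype=float).ravel()
        return theta

    def names(self, design_info=None) -> list:
        """Flattened parameter names aligned with the theta vector.

        Categories are labeled by their 0-based ethogram code (skipping the
        reference); design columns by index, or by name when ``design_info``
        is given.
        """
        spec = self.spec
        cats = [str(k) for k in spec.nonref]
        cols = [str(p) for p in range(spec.P)]
        if design_info is not None:
            cats = [design_info.ethogram.categories[k] for k in spec.nonref]
            cols = list(design_info.column_names)
        out = [f"beta[{c},{p}]" for c in cats for p in cols]
        for f in spec.re_factors:
            _, y_sl, _ = self.factor_slices[f.name]
            out += [f"log_sigma[{f.name},{c}]" for c in cats]
            if y_sl is not None:
                out += [
                    f"corr_free[{f.name},{i}]"
                    for i in range(y_sl.stop - y_sl.start)
                ]
            out += [f"z[{f.name},{g},{c}]" for g in range(f.group_count) for c in cats]
        return out


# ---------------------------------------------------------------------------
# model kernels
# ---------------------------------------------------------------------------

def transform_noncentered(z: np.ndarray, sigma: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Realize correlated effects v_g = diag(sigma) L z_g for each group row.

    With z_g ~ N(0, I) the result is MVN(0, diag(sigma) L L' diag(sigma)).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.shape[0] != L.shape[1] or not np.allclose(L, np.tril(L)):
        raise ValueError("L must be square lower-triangular")
    if z.shape[1] != L.shape[0] or sigma.shape != (L.shape[0],):
        raise ValueError("dimension mismatch between z, sigma, and L")
    return (z @ L.T) * sigma


def correlation_from_block(sigma: np.ndarray, L: np.ndarray = None,
                           omega: np.ndarray = None) -> np.ndarray:
    """Correlation matrix R of a random-effect block.

    Either from the Cholesky factor (R = L L') or from a covariance matrix
    (R_jk = Omega_jk / (sigma_j sigma_k)); both routes agree by construction.
    """
    if omega is not None:
        sigma = np.sqrt(np.diag(omega))
        return omega / np.outer(sigma, sigma)
    if L is None:
        raise ValueError("provide L or omega")
    return L @ L.T


def _augment_logits(eta: np.ndarray, reference_index: int) -> np.ndarray:
    """Insert the fixed zero reference logit into eta (works on 1-D or 2-D)."""
    eta = np.asarray(eta, dtype=float)
    return np.insert(eta, reference_index, 0.0, axis=-1)


def linear_predictors(params: ParameterSet, X: np.ndarray,
                      factor_indices: dict = None) -> np.ndarray:
    """eta (n, K-1): fixed-effect part plus each factor's group deviation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.beta.shape[1]:
        raise ValueError(
            f"design has {X.shape[1]} columns but beta expects {params.beta.shape[1]}"
        )
    eta = X @ params.beta.T
    for name, blk in params.re.items():
        if factor_indices is None or name not in factor_indices:
            raise ValueError(f"no index vector supplied for factor {name!r}")
        eta = eta + blk.v[factor_indices[name]]
    return eta


def category_log_probs(eta: np.ndarray, reference_index: int) -> np.ndarray:
    """log pi over all K categories from the K-1 contrast predictors.

    The reference logit is fixed at 0; normalization is the softmax computed
    via max-subtracted log-sum-exp, so exp of the result sums to one.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictors")
    logits = _augment_logits(eta, reference_index)
    return logits - logsumexp(logits, axis=-1, keepdims=True)


def pointwise_log_lik(params: ParameterSet, data) -> np.ndarray:
    """Per-observation log-likelihood under the categorical distribution."""
    eta = linear_predictors(params, data.X, data.factor_indices)
    logp = category_log_probs(eta, data.design_info.ethogram.reference_index)
    return logp[np.arange(data.n), data.y]


def _beta_prior_scales(spec: ModelSpec) -> np.ndarray:
    scales = np.full(spec.P, spec.priors.slope_scale)
    if 0 <= spec.intercept_col < spec.P:
        scales[spec.intercept_col] = spec.priors.intercept_scale
    return scales


def log_prior(params: ParameterSet, spec: ModelSpec) -> float:
    """Joint log prior (unconstrained-space Jacobians excluded).

    Normal priors on beta, half-Cauchy on the RE scales, LKJ on correlation
    Cholesky factors, standard normal on the innovations z. Returns -inf for
    sigma <= 0.
    """
    scales = _beta_prior_scales(spec)
    lp = float(
        np.sum(-0.5 * (params.beta / scales) ** 2
               - np.log(scales) - 0.5 * math.log(2 * math.pi))
    )
    c = spec.priors.sigma_scale
    for f in spec.re_factors:
        blk = params.re[f.name]
        if np.any(blk.sigma <= 0):
            return -np.inf
        lp += float(np.sum(math.log(2.0 / (math.pi * c))
                           - np.log1p((blk.sigma / c) ** 2)))
        if f.full_covariance and spec.D > 1:
            lp += _lkj_cholesky_logpdf(blk.L, spec.priors.lkj_eta)[0]
        lp += float(np.sum(-0.5 * blk.z ** 2 - 0.5 * math.log(2 * math.pi)))
    return lp


def log_posterior_and_grad(theta: np.ndarray, data, spec: ModelSpec,
                           layout: ParamLayout = None, include_lik: bool = True):
    """Unconstrained-space log density (likelihood + priors + Jacobians) and
    its gradient.

    This is the single contract the sampler consumes. The log-sigma and
    correlation transforms contribute their Jacobian terms so that the
    density integrates to one over the unconstrained space.
    """
    layout = layout or ParamLayout(spec)
    D, P = spec.D, spec.P
    theta = np.asarray(theta, dtype=float)
    grad = np.zeros_like(theta)
    beta = theta[layout.beta].reshape(D, P)

    factor_state = {}
    eta = data.X @ beta.T if include_lik else None
    for f in spec.re_factors:
        t_sl, y_sl, z_sl = layout.factor_slices[f.name]
        t = theta[t_sl]
        sigma = np.exp(t)
        if y_sl is not None:
            L, log_jac, dL, djac = corr_free_to_chol(theta[y_sl], D, want_grad=True)
        else:
            L, log_jac, dL, djac = np.eye(D), 0.0, None, None
        z = theta[z_sl].reshape(f.group_count, D)
        A = L * sigma[:, None]          # diag(sigma) @ L
        factor_state[f.name] = (t, sigma, L, log_jac, dL, djac, z, A)
        if include_lik:
            v = z @ A.T
            eta = eta + v[data.factor_indices[f.name]]

    lp = 0.0
    if include_lik:
        n = data.n
        nonref = spec.nonref
        logits = np.zeros((n, spec.K))
        logits[:, nonref] = eta
        mx = logits.max(axis=1)
        np.exp(logits - mx[:, None], out=logits)
        sumexp = logits.sum(axis=1)
        lse = mx + np.log(sumexp)
        rows = np.arange(n)
        # logits buffer now holds exp(shifted); recover pi in place
        logits /= sumexp[:, None]
        eta_y = np.zeros(n)
        in_nonref = data.y != spec.reference_index
        col_of = np.full(spec.K, -1)
        col_of[nonref] = np.arange(spec.D)
        eta_y[in_nonref] = eta[rows[in_nonref], col_of[data.y[in_nonref]]]
        lp += float(eta_y.sum() - lse.sum())
        g_logits = -logits
        g_logits[rows, data.y] += 1.0
        g_eta = g_logits[:, nonref]
        grad[layout.beta] = (g_eta.T @ data.X).ravel()
    else:
        g_eta = None

    # beta prior
    scales = _beta_prior_scales(spec)
    lp += float(np.sum(-0.5 * (beta / scales) ** 2
                       - np.log(scales) - 0.5 * math.log(2 * math.pi)))
    grad[layout.beta] += (-beta / scales ** 2).ravel()

    c = spec.priors.sigma_scale
    for f in spec.re_factors:
        t_sl, y_sl, z_sl = layout.factor_slices[f.name]
        t, sigma, L, log_jac, dL, djac, z, A = factor_state[f.name]

        if include_lik:
            idx = data.factor_indices[f.name]
            g_v = np.empty((f.group_count, D))
            for k in range(D):
                g_v[:, k] = np.bincount(idx, weights=g_eta[:, k],
                                        minlength=f.group_count)
            g_z_lik = g_v @ A
            g_A = g_v.T @ z                     # (D, D)
            g_L = g_A * sigma[:, None]
            g_sigma = np.sum(g_A * L, axis=1)
        else:
            g_z_lik = 0.0
            g_L = np.zeros((D, D))
            g_sigma = np.zeros(D)

        # half-Cauchy prior on sigma plus log-sigma Jacobian (+t per entry)
        lp += float(np.sum(math.log(2.0 / (math.pi * c))
                           - np.log1p((sigma / c) ** 2) + t))
        g_t = sigma * g_sigma - 2.0 * sigma ** 2 / (c ** 2 + sigma ** 2) + 1.0
        grad[t_sl] = g_t

        # LKJ prior on L plus transform Jacobian, chained to free coordinates
        if y_sl is not None:
            lkj_lp, lkj_ddiag = _lkj_cholesky_logpdf(L, spec.priors.lkj_eta)
            lp += lkj_lp + log_jac
            g_L_total = g_L + np.diag(lkj_ddiag)
            grad[y_sl] = np.einsum("ab,abm->m", g_L_total, dL) + djac

        # standard normal innovations
        lp += float(np.sum(-0.5 * z ** 2 - 0.5 * math.log(2 * math.pi)))
        grad[z_sl] = (g_z_lik - z).ravel()

    return lp, grad
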