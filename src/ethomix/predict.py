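"""Posterior predictions over covariate scenarios, and contrasts between them.

For every posterior draw and every scenario, the fixed-effect design row is
multiplied by that draw's coefficients and pushed through the softmax to give
the K category probabilities. Random effects enter according to the
scenario's mode: ``fixed_only`` (the default) sets them to zero, ``unit``
adds the stored deviations of named groups, and ``marginal_new_unit`` draws
fresh deviations from that draw's covariance — a prediction for an unseen
group.

Inference about differences between scenarios works on the posterior
distribution of per-draw differences, never on whether two marginal
prediction intervals overlap: overlapping intervals do not imply the absence
of a distinguishable difference, because they carry uncertainty from all
parameters rather than from the contrast of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import category_log_probs, transform_noncentered

__all__ = ["Scenario", "PredictionDraws", "link_mn", "summarize_predictions",
           "contrast"]

RE_MODES = ("fixed_only", "unit", "marginal_new_unit")


@dataclass
class Scenario:
    """One covariate setting on the original (unstandardized) scale.

    ``covariates`` must supply every continuous and categorical term of the
    design; standardization is applied internally from the training record.
    ``unit`` maps factor names to group labels for ``unit`` mode.
    """

    covariates: dict
    re_mode: str = "fixed_only"
    unit: dict = field(default_factory=dict)
    label: str = None

    def __post_init__(self):
        if self.re_mode not in RE_MODES:
            raise ValueError(f"re_mode must be one of {RE_MODES}")


@dataclass
class PredictionDraws:
    """S x scenarios x K posterior probability draws (each slice a simplex)."""

    probs: np.ndarray
    scenario_labels: list
    categories: list

    @property
    def S(self) -> int:
        return self.probs.shape[0]

    def scenario_index(self, key) -> int:
        if isinstance(key, (int, np.integer)):
            return int(key)
        return self.scenario_labels.index(key)

    def category_index(self, key) -> int:
        if isinstance(key, (int, np.integer)):
            return int(key)
        if key not in self.categories:
            raise KeyError(f"unknown category {key!r} (have {self.categories})")
        return self.categories.index(key)


def link_mn(draws, scenarios, rng=None) -> PredictionDraws:
    """Per-draw softmax predictions for a list of scenarios.

    ``draws`` must carry design information (fitting through
    :func:`ethomix.data.build_design` provides it). ``rng`` (or a seed) is
    required only by ``marginal_new_unit`` scenarios.
    """
    info = draws.design_info
    if info is None:
        raise ValueError("draws carry no design information; cannot build scenarios")
    spec = draws.spec
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    scenarios = list(scenarios)
    X = np.stack([info.design_row(sc.covariates) for sc in scenarios])
    if X.shape[1] != spec.P:
        raise ValueError(f"scenario rows have {X.shape[1]} columns, model has {spec.P}")

    factor_names = [f.name for f in spec.re_factors]
    unit_groups = {}
    for j, sc in enumerate(scenarios):
        if sc.re_mode == "unit":
            if not sc.unit:
                raise ValueError(f"scenario {j}: unit mode needs group ids")
            for fac, label in sc.unit.items():
                if fac not in factor_names:
                    raise KeyError(f"unknown factor {fac!r}")
                levels = info.factor_levels.get(fac, [])
                if str(label) not in levels:
                    raise KeyError(f"unknown group {label!r} for factor {fac!r}")
                unit_groups[(j, fac)] = levels.index(str(label))

    out = np.empty((draws.S, len(scenarios), spec.K))
    for s, params in enumerate(draws.parameter_sets()):
        eta = X @ params.beta.T  # (n_scen, D)
        for j, sc in enumerate(scenarios):
            if sc.re_mode == "fixed_only":
                continue
            if sc.re_mode == "unit":
                for fac, _ in sc.unit.items():
                    eta[j] = eta[j] + params.re[fac].v[unit_groups[(j, fac)]]
            else:  # marginal_new_unit: fresh draw from this draw's covariance
                for blk in params.re.values():
                    z_new = rng.standard_normal(spec.D)
                    eta[j] = eta[j] + transform_noncentered(
                        z_new, blk.sigma, blk.L)[0]
        out[s] = np.exp(category_log_probs(eta, spec.reference_index))

    labels = [sc.label or f"scenario_{j}" for j, sc in enumerate(scenarios)]
    return PredictionDraws(
        probs=out,
        scenario_labels=labels,
        categories=list(info.ethogram.categories),
    )


def summarize_predictions(pd_: PredictionDraws, level: float = 0.89) -> pd.DataFrame:
    """Tidy table of posterior means and percentile intervals per scenario x category."""
    if not (0 < level < 1):
        raise ValueError("interval level must be in (0, 1)")
    alpha = (1 - level) / 2
    mean = pd_.probs.mean(axis=0)
    lower = np.quantile(pd_.probs, alpha, axis=0)
    upper = np.quantile(pd_.probs, 1 - alpha, axis=0)
    rows = []
    for j, lab in enumerate(pd_.scenario_labels):
        for k, cat in enumerate(pd_.categories):
            rows.append({"scenario": lab, "category": cat,
                         "mean": mean[j, k], "lower": lower[j, k],
                         "upper": upper[j, k]})
    return pd.DataFrame(rows)


def contrast(pd_: PredictionDraws, scenario_a, scenario_b, category,
             level: float = 0.89) -> dict:
    """Posterior distribution of pi_k(a) - pi_k(b) for one category.

    Differences are taken within each posterior draw and the resulting
    distribution is summarized (mean, percentile interval, and the posterior
    probability that the difference is positive).
    """
    a = pd_.scenario_index(scenario_a)
    b = pd_.scenario_index(scenario_b)
    k = pd_.category_index(category)
    diff = pd_.probs[:, a, k] - pd_.probs[:, b, k]
    alpha = (1 - level) / 2
    return {
        "category": pd_.categories[k],
        "scenario_a": pd_.scenario_labels[a],
        "scenario_b": pd_.scenario_labels[b],
        "mean": float(diff.mean()),
        "lower": float(np.quantile(diff, alpha)),
        "upper": float(np.quantile(diff, 1 - alpha)),
        "pr_positive": float(np.mean(diff > 0)),
        "draws": diff,
    }
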