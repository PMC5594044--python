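"""Synthetic scan-sampling data with known generating parameters.

The generator emulates the structure of household-based scan sampling:
individuals nested in households, observed at 30-minute scans on sampling
days spread over monthly periods, with each household visited at most once
per day. Covariates mirror the usual mix — an individual-level age, household
wealth and size, weekday/Saturday/Sunday calendar labels, time of day as a
fraction of 24 h, and a monthly rainfall level — and outcomes are drawn from
the same multinomial mixed model the package fits, so every downstream stage
can be tested against a recorded ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (Ethogram, Formula, ModelData, ObservationTable,
                   build_design, standardize_covariates)
from .model import category_log_probs, transform_noncentered

logger = logging.getLogger(__name__)

__all__ = ["SimDesign", "TruthRecord", "SimResult", "generate_design",
           "sample_truth", "sample_lkj", "simulate_behaviors",
           "simulate_dataset", "recovery_report", "desk_design",
           "field_design", "default_formula", "default_ethogram",
           "rare_category_truth"]

_DAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
         "Saturday", "Sunday")

_BEHAVIORS = ("foraging", "traveling", "grooming", "vigilance", "digging",
              "carrying", "tool_use", "guarding", "provisioning", "playing",
              "courtship", "building", "tending")


def default_ethogram(K: int) -> Ethogram:
    """K-category ethogram with a non-work/inactive reference last."""
    if K - 1 > len(_BEHAVIORS):
        labels = tuple(f"behavior_{j + 1}" for j in range(K - 1))
    else:
        labels = _BEHAVIORS[: K - 1]
    return Ethogram(labels + ("resting",), reference="resting")


def default_formula() -> Formula:
    """The standard 10-column design: intercept, age + age^2, wealth, house
    size, Saturday/Sunday dummies (weekday baseline), time of day + squared,
    rainfall."""
    return Formula(
        continuous={"age": 2, "wealth": 1, "house_size": 1,
                    "time_of_day": 2, "rainfall": 1},
        categorical={"day_of_week": ["Saturday", "Sunday"]},
    )


@dataclass(frozen=True)
class SimDesign:
    """Study design of a simulated scan-sampling campaign.

    Defaults are desk-scale (20 individuals in 10 households over 6 monthly
    periods, 5 households visited per sampling day, 7 scans per day at
    30-minute spacing), which yields roughly 3000 scan records. The
    field-scale preset (:func:`field_design`) matches a 45-individual,
    25-household, 12-month campaign.
    """

    n_individuals: int = 20
    n_households: int = 10
    n_periods: int = 6
    days_per_period: int = 7
    households_per_day: int = 5  # None = every household, still once per day
    day_start: float = 8.0      # hours; first scan
    day_end: float = 11.0       # hours; no scan scheduled later than this
    scan_interval_min: float = 30.0
    K: int = 5

    def __post_init__(self):
        if self.day_end < self.day_start:
            raise ValueError("day_end is earlier than day_start")
        if self.n_households < 1 or self.n_individuals < self.n_households:
            # round-robin assignment below guarantees non-empty households
            raise ValueError("need at least one individual per household")
        if self.K < 2:
            raise ValueError("K must be at least 2")

    @property
    def scan_times(self) -> np.ndarray:
        step = self.scan_interval_min / 60.0
        n = int(np.floor((self.day_end - self.day_start) / step + 1e-9)) + 1
        return self.day_start + step * np.arange(n)

    def to_dict(self):
        return {k: getattr(self, k) for k in (
            "n_individuals", "n_households", "n_periods", "days_per_period",
            "households_per_day", "day_start", "day_end",
            "scan_interval_min", "K")}


def desk_design(**overrides) -> SimDesign:
    return SimDesign(**overrides)


def field_design(**overrides) -> SimDesign:
    """45 individuals in 25 households, 12 months, dawn-to-dusk scans."""
    kw = dict(n_individuals=45, n_households=25, n_periods=12,
              days_per_period=7, households_per_day=6,
              day_start=6.0, day_end=18.0, K=14)
    kw.update(overrides)
    return SimDesign(**kw)


def generate_design(design: SimDesign, seed: int = 0) -> pd.DataFrame:
    """Observation-table skeleton (no outcomes), deterministic given the seed.

    Each sampling day draws households without replacement, so no household
    appears more than once per day; all residents of a visited household are
    recorded at every scan of that day.
    """
    rng = np.random.default_rng(seed)
    H, N = design.n_households, design.n_individuals
    household_of = np.arange(N) % H  # round-robin: every household non-empty
    members = {h: np.flatnonzero(household_of == h) for h in range(H)}

    age = np.clip(rng.normal(31.0, 15.0, size=N), 15.0, None)
    wealth = rng.normal(8.6, 0.9, size=H)
    house_size = rng.poisson(7.0, size=H) + 1
    rain_shape = (222.0 / 112.0) ** 2
    rainfall = rng.gamma(rain_shape, 222.0 / rain_shape, size=design.n_periods)

    per_day = design.households_per_day
    if per_day is None or per_day >= H:
        per_day = H
    times = design.scan_times
    rows = []
    day_id = 0
    for m in range(design.n_periods):
        # sampling days are spread across the month: cycle the week with a
        # random phase and a stride coprime to 7, so 7 days/period cover
        # every weekday exactly once
        dow_offset = int(rng.integers(7))
        for d in range(design.days_per_period):
            dow = _DAYS[(dow_offset + 4 * d) % 7]
            visited = rng.choice(H, size=per_day, replace=False)
            for h in visited:
                for i in members[h]:
                    for t in times:
                        rows.append((i, h, m, day_id, dow, t / 24.0,
                                     age[i], wealth[h], house_size[h],
                                     rainfall[m]))
            day_id += 1
    df = pd.DataFrame(rows, columns=[
        "individual", "household", "month", "day", "day_of_week",
        "time_of_day", "age", "wealth", "house_size", "rainfall"])
    logger.info("generated skeleton: %d rows, %d individuals, %d households, "
                "%d periods", len(df), N, H, design.n_periods)
    return df


def sample_lkj(D: int, eta: float, rng) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) by the partial-correlation vine."""
    if D == 1:
        return np.eye(1)
    P = np.zeros((D, D))
    R = np.eye(D)
    for k in range(D - 1):
        for i in range(k + 1, D):
            alpha = eta + (D - 2 - k) / 2.0
            p = 2.0 * rng.beta(alpha, alpha) - 1.0
            P[k, i] = p
            for l in range(k - 1, -1, -1):
                p = (p * np.sqrt((1 - P[l, i] ** 2) * (1 - P[l, k] ** 2))
                     + P[l, i] * P[l, k])
            R[k, i] = R[i, k] = p
    return R


def _validate_corr(R: np.ndarray, D: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (D, D) or not np.allclose(R, R.T):
        raise ValueError("correlation matrix must be symmetric (K-1)x(K-1)")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(R) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-10:
        raise ValueError(f"correlation matrix is not PSD (min eigenvalue {evals.min():.3g})")
    return R


@dataclass
class TruthRecord:
    """Generating parameters of a synthetic dataset, for recovery tests."""

    beta: np.ndarray              # (K-1, P)
    re: dict                      # factor -> {"sigma": (K-1,), "corr": (K-1,K-1)}
    reference_index: int
    seed: int = None
    true_pi: np.ndarray = None    # (n, K), filled by simulate_behaviors
    re_values: dict = field(default_factory=dict)  # factor -> realized v (G, K-1)

    @property
    def D(self) -> int:
        return self.beta.shape[0]

    def to_dict(self):
        return {
            "beta": np.asarray(self.beta).tolist(),
            "re": {f: {"sigma": np.asarray(b["sigma"]).tolist(),
                       "corr": np.asarray(b["corr"]).tolist()}
                   for f, b in self.re.items()},
            "reference_index": self.reference_index,
            "seed": self.seed,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d):
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            re={f: {"sigma": np.asarray(b["sigma"], dtype=float),
                    "corr": np.asarray(b["corr"], dtype=float)}
                for f, b in d["re"].items()},
            reference_index=int(d["reference_index"]),
            seed=d.get("seed"),
        )


def sample_truth(K: int, P: int, factors=("individual",), seed: int = 0,
                 values: dict = None, reference_index: int = None,
                 intercept_sd: float = 1.0, slope_sd: float = 0.5,
                 sigma_range=(0.3, 1.2), lkj_eta: float = 2.0) -> TruthRecord:
    """Draw (or accept verbatim) generating parameters.

    ``values`` may pin any of ``beta`` ((K-1) x P), per-factor ``sigma``
    ({factor: vector}) and ``corr`` ({factor: matrix}); anything not pinned
    is drawn: intercepts N(0, intercept_sd), slopes N(0, slope_sd), scales
    Uniform over ``sigma_range``, correlations LKJ(lkj_eta). Supplied
    correlation matrices are checked for symmetry, unit diagonal, and PSD.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    values = values or {}
    rng = np.random.default_rng(seed)
    D = K - 1
    if "beta" in values:
        beta = np.asarray(values["beta"], dtype=float)
        if beta.shape != (D, P):
            raise ValueError(f"beta must be ({D}, {P}), got {beta.shape}")
    else:
        beta = rng.normal(0.0, slope_sd, size=(D, P))
        beta[:, 0] = rng.normal(0.0, intercept_sd, size=D)
    re = {}
    for f in factors:
        sigma = values.get("sigma", {}).get(f)
        if sigma is None:
            sigma = rng.uniform(*sigma_range, size=D)
        else:
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != (D,) or np.any(sigma < 0):
                raise ValueError(f"sigma for {f!r} must be {D} non-negative values")
        corr = values.get("corr", {}).get(f)
        if corr is None:
            corr = sample_lkj(D, lkj_eta, rng)
        corr = _validate_corr(corr, D)
        re[f] = {"sigma": sigma, "corr": corr}
    return TruthRecord(beta=beta, re=re, seed=seed,
                       reference_index=(K - 1 if reference_index is None
                                        else reference_index))


def rare_category_truth(K: int, P: int, factors=("individual",),
                        seed: int = 0, rare_intercept: float = -6.5) -> TruthRecord:
    """Truth with one category so rare (pi < 0.005) that its posterior is
    prior-dominated — a stress preset for the rare-behavior caveat."""
    truth = sample_truth(K, P, factors, seed=seed)
    truth.beta[0, 0] = rare_intercept
    return truth


@dataclass
class SimResult:
    table: ObservationTable
    model_data: ModelData
    truth: TruthRecord


def simulate_behaviors(skeleton: pd.DataFrame, truth: TruthRecord,
                       formula: Formula = None, ethogram: Ethogram = None,
                       seed: int = 0, factors=None) -> SimResult:
    """Draw outcomes on a skeleton from the model at the recorded truth.

    The skeleton's continuous covariates are z-scored, the design matrix is
    built exactly as for fitting, each group of each factor receives one
    correlated random draw v_g ~ MVN(0, diag(sigma) R diag(sigma)), and each
    row's category is a single categorical draw from softmax(eta). True
    per-row probabilities are stored on the returned truth record.
    """
    rng = np.random.default_rng(seed)
    formula = formula or default_formula()
    D = truth.D
    K = D + 1
    ethogram = ethogram or default_ethogram(K)
    if ethogram.K != K:
        raise ValueError(f"ethogram has {ethogram.K} categories, truth implies {K}")
    factors = list(factors if factors is not None else truth.re.keys())
    if set(factors) != set(truth.re.keys()):
        raise ValueError("factors do not match the truth record")

    df = skeleton.copy()
    df["outcome"] = ethogram.categories[0]  # placeholder until outcomes drawn
    table = ObservationTable(df, ethogram)
    table, record = standardize_covariates(table, list(formula.continuous))
    data = build_design(table, formula, factors, standardization=record)
    if truth.beta.shape[1] != data.P:
        raise ValueError(
            f"truth beta has {truth.beta.shape[1]} columns, design has {data.P}")

    eta = data.X @ truth.beta.T
    re_values = {}
    for f in factors:
        blk = truth.re[f]
        G = len(data.design_info.factor_levels[f])
        L = np.linalg.cholesky(blk["corr"] + 1e-12 * np.eye(D))
        z = rng.standard_normal((G, D))
        v = transform_noncentered(z, blk["sigma"], L)
        re_values[f] = v
        eta = eta + v[data.factor_indices[f]]

    logp = category_log_probs(eta, ethogram.reference_index)
    pi = np.exp(logp)
    u = rng.random((len(pi), 1))
    codes = (pi.cumsum(axis=1) < u).sum(axis=1)
    outcomes = [ethogram.categories[c] for c in codes]

    df = table.df.copy()
    df["outcome"] = outcomes
    out_table = ObservationTable(df, ethogram)
    out_data = build_design(out_table, formula, factors, standardization=record)
    truth.true_pi = pi
    truth.re_values = re_values
    return SimResult(table=out_table, model_data=out_data, truth=truth)


def simulate_dataset(design: SimDesign = None, seed: int = 0,
                     formula: Formula = None, factors=("individual",),
                     truth: TruthRecord = None, truth_values: dict = None) -> SimResult:
    """End-to-end convenience: skeleton + truth + outcomes in one call."""
    design = design or SimDesign()
    formula = formula or default_formula()
    skeleton = generate_design(design, seed=seed)
    if truth is None:
        P = len(formula.column_names())
        truth = sample_truth(design.K, P, factors, seed=seed + 1,
                             values=truth_values)
    return simulate_behaviors(skeleton, truth, formula,
                              default_ethogram(design.K), seed=seed + 2,
                              factors=factors)


def recovery_report(truth: TruthRecord, draws, level: float = 0.89):
    """Coverage of the generating parameters by posterior credible intervals.

    Returns a tidy table (parameter, truth, posterior mean, interval,
    covered) and coverage rates computed separately over beta, sigma, and
    rho entries.
    """
    from .summarize import _constrained_samples, _summary_frame

    spec = draws.spec
    if spec.D != truth.D or spec.P != truth.beta.shape[1]:
        raise ValueError("truth record does not match the fitted model spec")
    names, samples = _constrained_samples(draws)
    frame = _summary_frame(samples, names, level)

    info = draws.design_info
    cats = ([info.ethogram.categories[k] for k in spec.nonref]
            if info is not None else [str(k) for k in spec.nonref])
    cols = (list(info.column_names) if info is not None
            else [str(p) for p in range(spec.P)])
    truth_map = {}
    for j, c in enumerate(cats):
        for p, col in enumerate(cols):
            truth_map[f"beta[{c},{col}]"] = truth.beta[j, p]
    for f in spec.re_factors:
        if f.name not in truth.re:
            raise ValueError(f"truth record lacks factor {f.name!r}")
        blk = truth.re[f.name]
        for j, c in enumerate(cats):
            truth_map[f"sigma[{f.name},{c}]"] = blk["sigma"][j]
        for a in range(spec.D):
            for b in range(a + 1, spec.D):
                truth_map[f"rho[{f.name},{cats[a]},{cats[b]}]"] = blk["corr"][b, a]

    frame = frame.loc[[n for n in frame.index if n in truth_map]].copy()
    frame["truth"] = [truth_map[n] for n in frame.index]
    tol = 1e-9 * (1.0 + frame["truth"].abs())  # guards degenerate posteriors
    frame["covered"] = ((frame["lower"] - tol <= frame["truth"])
                        & (frame["truth"] <= frame["upper"] + tol))
    coverage = {}
    for kind in ("beta", "sigma", "rho"):
        mask = frame.index.str.startswith(kind + "[")
        coverage[kind] = float(frame.loc[mask, "covered"].mean()) if mask.any() else None
    return frame, coverage
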