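"""Reading, validating, and preparing scan-sampling observation tables.

The unit of analysis is one scan record: the behavioral category exhibited by
one individual at one predetermined instant, together with the cluster
memberships (individual, household, month) and covariates that enter the
model. This module turns such long-format tables into the dense design
structures (outcome codes, fixed-effect matrix, random-effect factor indices)
the model and sampler consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Ethogram",
    "ObservationTable",
    "StandardizationRecord",
    "Formula",
    "DesignInfo",
    "ModelData",
    "read_observations",
    "write_observations",
    "collapse_categories",
    "standardize_covariates",
    "describe_covariates",
    "build_design",
]


@dataclass(frozen=True)
class Ethogram:
    """Catalogue of mutually exclusive behavioral categories.

    One category serves as the reference ("pivot"): its logit is fixed at
    zero and the K-1 model equations contrast every other category against
    it. By default the reference is the last category listed.
    """

    categories: tuple
    reference: str = None

    def __post_init__(self):
        cats = tuple(str(c) for c in self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 2:
            raise ValueError(f"an ethogram needs at least 2 categories, got {len(cats)}")
        if len(set(cats)) != len(cats):
            raise ValueError("ethogram category labels must be unique")
        ref = self.reference if self.reference is not None else cats[-1]
        if ref not in cats:
            raise ValueError(f"reference category {ref!r} is not in the ethogram")
        object.__setattr__(self, "reference", ref)

    @property
    def K(self) -> int:
        return len(self.categories)

    @property
    def reference_index(self) -> int:
        """0-based position of the reference category."""
        return self.categories.index(self.reference)

    @property
    def nonreference(self) -> tuple:
        """Category labels excluding the reference, in ethogram order."""
        return tuple(c for c in self.categories if c != self.reference)

    def codes(self, labels) -> np.ndarray:
        """Map category labels to 0-based integer codes in ethogram order."""
        lookup = {c: i for i, c in enumerate(self.categories)}
        out = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            try:
                out[i] = lookup[str(lab)]
            except KeyError:
                raise ValueError(
                    f"outcome label {lab!r} at row {i} is not in the ethogram "
                    f"(categories: {list(self.categories)})"
                ) from None
        return out

    def to_dict(self) -> dict:
        return {"categories": list(self.categories), "reference": self.reference}

    @classmethod
    def from_dict(cls, d: dict) -> "Ethogram":
        return cls(tuple(d["categories"]), d.get("reference"))


@dataclass
class ObservationTable:
    """Long-format scan records: one row per individual per scan.

    ``df`` must contain an ``outcome`` column whose values are ethogram
    labels; any other columns (cluster IDs, covariates, timestamp metadata)
    are carried through untouched.
    """

    df: pd.DataFrame
    ethogram: Ethogram

    def __post_init__(self):
        if "outcome" not in self.df.columns:
            raise ValueError("observation table must have an 'outcome' column")
        if self.df["outcome"].isna().any():
            bad = int(self.df["outcome"].isna().sum())
            raise ValueError(f"{bad} rows have a missing outcome")
        # raises with label and row on unknown outcomes
        self.ethogram.codes(self.df["outcome"].tolist())

    @property
    def n(self) -> int:
        return len(self.df)

    def category_counts(self) -> pd.Series:
        """Per-category scan counts in ethogram order (zeros included)."""
        counts = self.df["outcome"].value_counts()
        return pd.Series(
            [int(counts.get(c, 0)) for c in self.ethogram.categories],
            index=list(self.ethogram.categories),
            name="count",
        )


def read_observations(path, ethogram: Ethogram, schema: dict = None) -> ObservationTable:
    """Read a CSV of scan observations and validate it against an ethogram.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    ethogram
        The category catalogue outcomes are checked against.
    schema
        Optional map from canonical column names (``outcome``,
        ``individual``, ...) to the column names used in the file. Columns
        not mentioned keep their file names.
    """
    df = pd.read_csv(path)
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s) {missing} in {path}")
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    if "outcome" not in df.columns:
        raise ValueError(f"missing required column 'outcome' in {path}")
    table = ObservationTable(df.reset_index(drop=True), ethogram)
    counts = table.category_counts()
    seen = int((counts > 0).sum())
    logger.info(
        "read %d observations (%d of %d categories seen): %s",
        table.n, seen, ethogram.K, counts.to_dict(),
    )
    return table


def write_observations(table: ObservationTable, path) -> None:
    table.df.to_csv(path, index=False)


def collapse_categories(table: ObservationTable, mapping: dict):
    """Merge ethogram categories (e.g. rare behaviors) under new labels.

    ``mapping`` sends old labels to new ones; unmapped labels are kept as
    they are. The new ethogram preserves the order of first appearance of
    each target label; counts are conserved. User-directed only — no
    automatic rarity threshold is applied.

    Returns the relabeled table and the new ethogram.
    """
    old = table.ethogram
    full_map = {c: mapping.get(c, c) for c in old.categories}
    new_cats = []
    for c in old.categories:
        t = full_map[c]
        if t not in new_cats:
            new_cats.append(t)
    if len(new_cats) < 2:
        raise ValueError(
            f"collapsing produces {len(new_cats)} categories; at least 2 are required"
        )
    new_ref = full_map[old.reference]
    new_ethogram = Ethogram(tuple(new_cats), new_ref)
    df = table.df.copy()
    df["outcome"] = df["outcome"].map(full_map)
    return ObservationTable(df, new_ethogram), new_ethogram


@dataclass
class StandardizationRecord:
    """Per-covariate mean and SD used for z-scoring.

    Retained so prediction grids supplied on the original scale can be
    standardized exactly as the training data were.
    """

    stats: dict = field(default_factory=dict)  # name -> (mean, sd)

    def transform(self, name: str, values):
        if name not in self.stats:
            raise KeyError(f"no standardization recorded for covariate {name!r}")
        mean, sd = self.stats[name]
        return (np.asarray(values, dtype=float) - mean) / sd

    def to_dict(self) -> dict:
        return {k: {"mean": m, "sd": s} for k, (m, s) in self.stats.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls({k: (float(v["mean"]), float(v["sd"])) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StandardizationRecord":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def standardize_covariates(table: ObservationTable, names):
    """z-score the named covariates over observation rows (SD with n-1).

    Returns a new table whose named columns hold the standardized values,
    plus the :class:`StandardizationRecord` for reuse on prediction grids.
    """
    df = table.df.copy()
    stats = {}
    for name in names:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not in table")
        x = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"covariate {name!r} has zero variance; cannot z-score")
        df[name] = (x - mean) / sd
        stats[name] = (mean, sd)
    return ObservationTable(df, table.ethogram), StandardizationRecord(stats)


def describe_covariates(table: ObservationTable, names, individual_col: str = None) -> pd.DataFrame:
    """Covariate means/SDs over observation rows and, optionally, over individuals.

    Scan data repeat individuals, so row-wise and individual-wise summaries
    can differ; both are reported.
    """
    rows = {}
    for name in names:
        x = pd.to_numeric(table.df[name], errors="raise")
        entry = {"mean_rows": x.mean(), "sd_rows": x.std(ddof=1)}
        if individual_col is not None:
            per_ind = table.df.groupby(individual_col)[name].mean()
            entry["mean_individuals"] = per_ind.mean()
            entry["sd_individuals"] = per_ind.std(ddof=1)
        rows[name] = entry
    return pd.DataFrame(rows).T


@dataclass
class Formula:
    """Fixed-effect specification: polynomial continuous terms and 0/1 dummies.

    ``continuous`` maps a covariate name to its polynomial order (1 = linear,
    2 = linear + squared; the square is of the stored — typically
    standardized — value). ``categorical`` maps a column name to the list of
    non-baseline levels that each get a 0/1 dummy column (the baseline level
    is implicit, e.g. weekday when Saturday/Sunday get dummies).
    """

    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    intercept: bool = True

    def column_names(self):
        cols = ["intercept"] if self.intercept else []
        for name, order in self.continuous.items():
            for p in range(1, int(order) + 1):
                cols.append(name if p == 1 else f"{name}^{p}")
        for name, levels in self.categorical.items():
            for lev in levels:
                cols.append(f"{name}[{lev}]")
        return cols

    def to_dict(self) -> dict:
        return {
            "continuous": dict(self.continuous),
            "categorical": {k: list(v) for k, v in self.categorical.items()},
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Formula":
        return cls(
            continuous=dict(d.get("continuous", {})),
            categorical={k: list(v) for k, v in d.get("categorical", {}).items()},
            intercept=bool(d.get("intercept", True)),
        )


@dataclass
class DesignInfo:
    """Everything needed to rebuild a design row for a new scenario."""

    formula: Formula
    standardization: StandardizationRecord
    column_names: list
    factor_levels: dict  # factor name -> list of original group labels
    ethogram: Ethogram

    def to_dict(self) -> dict:
        return {
            "formula": self.formula.to_dict(),
            "standardization": self.standardization.to_dict(),
            "column_names": list(self.column_names),
            "factor_levels": {k: list(v) for k, v in self.factor_levels.items()},
            "ethogram": self.ethogram.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignInfo":
        return cls(
            formula=Formula.from_dict(d["formula"]),
            standardization=StandardizationRecord.from_dict(d["standardization"]),
            column_names=list(d["column_names"]),
            factor_levels={k: list(v) for k, v in d["factor_levels"].items()},
            ethogram=Ethogram.from_dict(d["ethogram"]),
        )

    def design_row(self, covariates: dict) -> np.ndarray:
        """Build one fixed-effect design row from original-scale covariates."""
        vals = []
        if self.formula.intercept:
            vals.append(1.0)
        for name, order in self.formula.continuous.items():
            if name not in covariates:
                raise KeyError(f"scenario is missing covariate {name!r}")
            x = float(covariates[name])
            if name in self.standardization.stats:
                z = float(self.standardization.transform(name, [x])[0])
            else:
                z = x
            for p in range(1, int(order) + 1):
                vals.append(z ** p)
        for name, levels in self.formula.categorical.items():
            if name not in covariates:
                raise KeyError(f"scenario is missing categorical covariate {name!r}")
            val = str(covariates[name])
            for lev in levels:
                vals.append(1.0 if val == str(lev) else 0.0)
        return np.asarray(vals, dtype=float)


@dataclass
class ModelData:
    """Model-ready arrays: outcome codes, design matrix, factor indices.

    ``y`` holds 0-based category codes in ethogram order; ``factor_indices``
    holds dense 0-based group codes per random-effect factor, with the
    original labels retained in ``design_info.factor_levels``.
    """

    y: np.ndarray
    X: np.ndarray
    factor_indices: dict
    design_info: DesignInfo

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        K = self.design_info.ethogram.K
        if self.y.min(initial=0) < 0 or (self.n and self.y.max() >= K):
            raise ValueError("outcome codes out of bounds")
        for name, idx in self.factor_indices.items():
            idx = np.asarray(idx, dtype=np.int64)
            G = len(self.design_info.factor_levels[name])
            if idx.shape != (self.n,) or (self.n and (idx.min() < 0 or idx.max() >= G)):
                raise ValueError(f"factor {name!r} indices out of bounds")
            self.factor_indices[name] = idx

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.design_info.ethogram.K

    @property
    def P(self) -> int:
        return self.X.shape[1]

    def group_counts(self) -> dict:
        return {k: len(v) for k, v in self.design_info.factor_levels.items()}


def build_design(
    table: ObservationTable,
    formula: Formula,
    factors=(),
    standardization: StandardizationRecord = None,
) -> ModelData:
    """Assemble the fixed-effect matrix and random-effect index maps.

    Continuous covariates are used as stored (standardize first with
    :func:`standardize_covariates`); polynomial columns are powers of the
    stored value, so a squared term is the square of the z-scored variable.
    Rows with missing covariate or factor values are dropped with a logged
    count. Cluster IDs are densely re-indexed to 0..G-1 with the original
    labels retained.
    """
    df = table.df
    needed = list(formula.continuous) + list(formula.categorical) + list(factors)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns {missing_cols} not in table")
    keep = np.ones(len(df), dtype=bool)
    for c in needed:
        keep &= df[c].notna().to_numpy()
    if not keep.all():
        logger.warning("dropping %d rows with missing covariate/factor values", int((~keep).sum()))
    df = df.loc[keep].reset_index(drop=True)

    for name, levels in formula.categorical.items():
        present = set(df[name].astype(str))
        baseline = present - {str(l) for l in levels}
        if not baseline:
            raise ValueError(
                f"categorical term {name!r}: no baseline level left in the data "
                f"(all observed levels have dummy columns)"
            )

    cols = []
    if formula.intercept:
        cols.append(np.ones(len(df)))
    for name, order in formula.continuous.items():
        z = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
        for p in range(1, int(order) + 1):
            cols.append(z ** p)
    for name, levels in formula.categorical.items():
        vals = df[name].astype(str).to_numpy()
        for lev in levels:
            cols.append((vals == str(lev)).astype(float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))

    # duplicate columns make the design rank-deficient by construction
    colnames = formula.column_names()
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if np.array_equal(X[:, i], X[:, j]):
                raise ValueError(
                    f"design columns {colnames[i]!r} and {colnames[j]!r} are identical"
                )

    factor_indices, factor_levels = {}, {}
    for name in factors:
        codes, uniques = pd.factorize(df[name], sort=True)
        factor_indices[name] = codes.astype(np.int64)
        factor_levels[name] = [str(u) for u in uniques]

    info = DesignInfo(
        formula=formula,
        standardization=standardization or StandardizationRecord(),
        column_names=colnames,
        factor_levels=factor_levels,
        ethogram=table.ethogram,
    )
    y = table.ethogram.codes(df["outcome"].tolist())
    return ModelData(y=y, X=X, factor_indices=factor_indices, design_info=info)
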