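"""Feature-by-sample matrices and the preprocessing they undergo.

The joint matrix holds two kinds of biomolecule features — genes (expression)
and metabolites (abundance) — over a cohort of samples labelled control or
treatment.  Before any statistical learning step the matrix is taken through
minimum-value imputation (metabolite missing values only), a natural-log
transform, and per-feature z-score standardization so that features measured
on wildly different scales compete on equal footing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENE = "gene"
METABOLITE = "metabolite"
CONTROL = "control"
TREATMENT = "treatment"

#: strings accepted as missing on read; missing cells are written empty
NA_SENTINELS = ("", "NA", "NaN", "nan")


@dataclass
class FeatureMatrix:
    """A features x samples abundance matrix with per-feature kind and
    per-sample condition labels.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns; missing entries are NaN and are only legal for metabolite rows.
    """

    values: pd.DataFrame
    feature_kind: pd.Series  # feature id -> {gene, metabolite}
    condition: pd.Series  # sample id -> {control, treatment}

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing_cond = [s for s in self.values.columns if s not in self.condition.index]
        if missing_cond:
            raise ValueError(f"samples missing a condition label: {missing_cond}")
        bad = set(self.condition.loc[list(self.values.columns)]) - {CONTROL, TREATMENT}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        missing_kind = [f for f in self.values.index if f not in self.feature_kind.index]
        if missing_kind:
            raise ValueError(f"features missing a kind: {missing_kind}")
        self.feature_kind = self.feature_kind.loc[list(self.values.index)]
        self.condition = self.condition.loc[list(self.values.columns)]

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def kind_ids(self, kind: str) -> list[str]:
        return list(self.feature_kind.index[self.feature_kind == kind])

    def condition_samples(self, label: str) -> list[str]:
        return list(self.condition.index[self.condition == label])

    def subset_features(self, ids) -> "FeatureMatrix":
        ids = [f for f in ids if f in self.values.index]
        return FeatureMatrix(
            self.values.loc[ids].copy(), self.feature_kind.loc[ids].copy(), self.condition.copy()
        )

    def subset_samples(self, ids) -> "FeatureMatrix":
        ids = [s for s in ids if s in self.values.columns]
        return FeatureMatrix(
            self.values[ids].copy(), self.feature_kind.copy(), self.condition.loc[ids].copy()
        )


@dataclass
class WelchResult:
    """Welch two-sample t-test of one feature, treatment vs control."""

    feature_id: str
    t_statistic: float
    df: float  # Welch–Satterthwaite degrees of freedom
    p_value: float
    mean_control: float
    mean_treatment: float


# -- I/O ----------------------------------------------------------------------


def read_feature_matrix(matrix_path, condition_path, kind_path=None) -> FeatureMatrix:
    """Read a feature matrix CSV plus its sample-condition map.

    The matrix CSV has feature ids in the first column and sample ids as the
    header; empty cells and ``NA`` are missing.  The condition CSV has columns
    ``sample_id,condition`` and must cover every sample in the matrix.  Feature
    kinds come either from a ``feature_id,kind`` CSV or, absent one, from an id
    prefix convention (ids starting with ``m`` are metabolites).
    """
    values = pd.read_csv(
        matrix_path, index_col=0, na_values=list(NA_SENTINELS), keep_default_na=False
    )
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)
    values = values.astype(float)

    cond = pd.read_csv(condition_path, index_col=0).iloc[:, 0].astype(str)
    cond.index = cond.index.astype(str)

    if kind_path is not None:
        kind = pd.read_csv(kind_path, index_col=0).iloc[:, 0].astype(str)
        kind.index = kind.index.astype(str)
    else:
        kind = pd.Series(
            [METABOLITE if str(f).startswith("m") else GENE for f in values.index],
            index=values.index,
        )
    return FeatureMatrix(values, kind, cond)


def write_feature_matrix(m: FeatureMatrix, matrix_path, condition_path=None, kind_path=None) -> None:
    m.values.to_csv(matrix_path, index_label="feature_id", na_rep="")
    if condition_path is not None:
        m.condition.rename("condition").to_csv(condition_path, index_label="sample_id")
    if kind_path is not None:
        m.feature_kind.rename("kind").to_csv(kind_path, index_label="feature_id")


def write_welch_results(results: list[WelchResult], path) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "t": r.t_statistic,
                "df": r.df,
                "p": r.p_value,
                "mean_control": r.mean_control,
                "mean_treatment": r.mean_treatment,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


# -- preprocessing ------------------------------------------------------------


def impute_min(m: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing entry with the minimum observed value of its row.

    Mirrors the minimum-observed-value-per-compound rule used for metabolomics
    panels where non-detection means at-or-below the detection floor.  Rows
    with no observed value at all carry no information and are dropped with a
    logged warning.  Idempotent.
    """
    values = m.values.copy()
    all_missing = values.index[values.isna().all(axis=1)]
    for fid in all_missing:
        logger.warning("impute_min: dropping all-missing feature %r", fid)
    values = values.drop(index=all_missing)
    row_min = values.min(axis=1)
    values = values.apply(lambda row: row.fillna(row_min[row.name]), axis=1) if len(values) else values
    return FeatureMatrix(values, m.feature_kind.drop(index=all_missing), m.condition.copy())


def log_transform(m: FeatureMatrix) -> FeatureMatrix:
    """Natural log, elementwise.  All values must be strictly positive."""
    bad = np.argwhere((m.values.to_numpy() <= 0) | np.isnan(m.values.to_numpy()))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"log_transform: nonpositive or missing value for feature "
            f"{m.values.index[i]!r} in sample {m.values.columns[j]!r}"
        )
    return FeatureMatrix(np.log(m.values), m.feature_kind.copy(), m.condition.copy())


def welch_test(m: FeatureMatrix) -> list[WelchResult]:
    """Per-feature Welch two-sample t-test (treatment minus control).

    Uses the unequal-variance t statistic with Welch–Satterthwaite degrees of
    freedom and a two-sided p-value.  A feature with zero variance in both
    groups has an undefined p; it is reported with NaN statistics and a
    warning rather than dropped.
    """
    ctrl = m.condition_samples(CONTROL)
    trt = m.condition_samples(TREATMENT)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("welch_test needs >= 2 samples per condition")
    out: list[WelchResult] = []
    for fid, row in m.values.iterrows():
        x, y = row[trt].to_numpy(float), row[ctrl].to_numpy(float)
        mx, my = float(np.mean(x)), float(np.mean(y))
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        if vx == 0 and vy == 0:
            logger.warning("welch_test: zero variance in both groups for %r", fid)
            out.append(WelchResult(str(fid), math.nan, math.nan, math.nan, my, mx))
            continue
        res = stats.ttest_ind(x, y, equal_var=False)
        se2 = vx / len(x) + vy / len(y)
        df = se2**2 / ((vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1))
        out.append(WelchResult(str(fid), float(res.statistic), float(df), float(res.pvalue), my, mx))
    return out


def zscore_standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Center each row to mean 0 and scale to sample (n-1) standard deviation 1.

    Constant rows have no scale and are dropped with a logged warning, keeping
    messy real-world inputs flowing instead of aborting the run.
    """
    arr = m.values.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("zscore_standardize: impute missing values first")
    sd = arr.std(axis=1, ddof=1)
    constant = m.values.index[sd == 0]
    for fid in constant:
        logger.warning("zscore_standardize: dropping constant feature %r", fid)
    keep = sd > 0
    arr = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    values = pd.DataFrame(arr, index=m.values.index[keep], columns=m.values.columns)
    return FeatureMatrix(values, m.feature_kind.drop(index=constant), m.condition.copy())
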