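"""Metabolic-fork detection via treatment-interaction ratio models.

A metabolic fork is a small network motif in which one precursor is routed to
two competing fates; under a treatment that shifts the balance between the
fates, the relationship between a downstream metabolite A and the ratio of
two others, B/C, changes slope.  Operationally a candidate triplet (A, B, C)
is scored with the ordinary-least-squares model

    A ~ intercept + (B/C) + condition + (B/C) x condition

with condition coded 0 for control and 1 for treatment, so the interaction
coefficient is exactly the treatment slope minus the control slope.  Its
two-sided t-test p-value (n - 4 residual degrees of freedom) is the selection
statistic; the Pearson correlation cor(A, B/C) — overall and within each
condition — is reported alongside as the descriptive form of the triplet.

The fit is written out explicitly from the normal equations rather than
delegated to a regression framework: the model is the point of the module,
and the closed form keeps every reported quantity (slopes, SEs, p) auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix_io import CONTROL, TREATMENT, FeatureMatrix

DEFAULT_ALPHA = 0.05
DENOM_EPSILON = 1e-12
ADJUST_METHODS = ("none", "benjamini-hochberg")


@dataclass(frozen=True)
class Triplet:
    """Ordered metabolite triplet (A, B, C); orientation matters, since
    cor(A, B/C) and cor(A, C/B) probe different fork geometries."""

    A_id: str
    B_id: str
    C_id: str

    def __post_init__(self) -> None:
        if len({self.A_id, self.B_id, self.C_id}) != 3:
            raise ValueError(f"triplet members must be distinct: {self}")

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.A_id, self.B_id, self.C_id)


@dataclass
class ForkFit:
    triplet: Triplet
    slope_control: float = math.nan
    slope_treatment: float = math.nan
    interaction_estimate: float = math.nan  # slope_treatment - slope_control
    interaction_se: float = math.nan
    interaction_p: float = math.nan
    cor_overall: float = math.nan
    cor_control: float = math.nan
    cor_treatment: float = math.nan
    n_control: int = 0
    n_treatment: int = 0
    adjusted_p: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def enumerate_triplets(candidate_A, candidate_B, candidate_C) -> list[Triplet]:
    """All ordered (A, B, C) combinations with distinct members, deduplicated,
    in sorted deterministic order."""
    a, b, c = sorted(set(candidate_A)), sorted(set(candidate_B)), sorted(set(candidate_C))
    for name, s in (("A", a), ("B", b), ("C", c)):
        if not s:
            raise ValueError(f"candidate set for role {name} is empty")
    seen = set()
    out = []
    for t in product(a, b, c):
        if len(set(t)) == 3 and t not in seen:
            seen.add(t)
            out.append(Triplet(*t))
    return out


def ratio_series(m: FeatureMatrix, B_id: str, C_id: str, epsilon: float = DENOM_EPSILON) -> pd.Series:
    """Per-sample B/C on the post-imputation abundance scale.

    Raises ValueError if any denominator value is at or below ``epsilon``;
    callers screening many triplets catch this and flag the triplet instead
    of aborting.
    """
    b = m.values.loc[B_id]
    c = m.values.loc[C_id]
    if b.isna().any() or c.isna().any():
        raise ValueError(f"ratio {B_id}/{C_id}: missing values; impute first")
    if (c <= epsilon).any():
        raise ValueError(f"degenerate-denominator: {C_id} has values <= {epsilon}")
    return b / c


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def fork_fit(m: FeatureMatrix, t: Triplet, epsilon: float = DENOM_EPSILON) -> ForkFit:
    """Fit the interaction model for one triplet.

    Design matrix columns: intercept, ratio, condition indicator, and their
    product.  Solved by least squares; the interaction coefficient's standard
    error comes from the unbiased residual variance times the corresponding
    diagonal of (X'X)^-1, and its p-value from the t distribution with n - 4
    degrees of freedom.  Degenerate situations are carried as flags:
    ``degenerate-denominator`` (C touches zero), ``collinear`` (rank-deficient
    design), ``saturated`` (zero residual variance, p undefined).
    """
    fit = ForkFit(triplet=t)
    cond01 = (m.condition == TREATMENT).astype(float).to_numpy()
    fit.n_control = int((cond01 == 0).sum())
    fit.n_treatment = int((cond01 == 1).sum())
    if fit.n_control < 3 or fit.n_treatment < 3:
        fit.flags.append("too-few-samples")
        return fit
    try:
        ratio = ratio_series(m, t.B_id, t.C_id, epsilon=epsilon).to_numpy(float)
    except ValueError:
        fit.flags.append("degenerate-denominator")
        return fit
    a = m.values.loc[t.A_id].to_numpy(float)
    if np.isnan(a).any():
        fit.flags.append("missing-response")
        return fit

    X = np.column_stack([np.ones_like(ratio), ratio, cond01, ratio * cond01])
    n, p = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(X) < p:
        fit.flags.append("collinear")
        return fit
    beta = np.linalg.solve(xtx, X.T @ a)
    resid = a - X @ beta
    rss = float(resid @ resid)

    fit.slope_control = float(beta[1])
    fit.slope_treatment = float(beta[1] + beta[3])
    fit.interaction_estimate = float(beta[3])
    fit.cor_overall = _safe_corr(a, ratio)
    fit.cor_control = _safe_corr(a[cond01 == 0], ratio[cond01 == 0])
    fit.cor_treatment = _safe_corr(a[cond01 == 1], ratio[cond01 == 1])

    df = n - p
    sigma2 = rss / df
    # exact fit: slope estimates are meaningful but the t-test is undefined
    scale = float(a @ a) if float(a @ a) > 0 else 1.0
    if sigma2 <= 1e-24 * scale:
        fit.flags.append("saturated")
        return fit
    cov = sigma2 * np.linalg.inv(xtx)
    fit.interaction_se = float(np.sqrt(cov[3, 3]))
    tstat = fit.interaction_estimate / fit.interaction_se
    fit.interaction_p = float(2.0 * stats.t.sf(abs(tstat), df))
    return fit


def screen_forks(
    m: FeatureMatrix,
    triplets: list[Triplet],
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "benjamini-hochberg",
    epsilon: float = DENOM_EPSILON,
) -> list[ForkFit]:
    """Fit every triplet and rank by interaction p-value (ascending; ties and
    failed fits ordered by triplet id).  Significance is judged on the raw p
    at ``alpha``; Benjamini–Hochberg adjusted p-values are attached for
    multiplicity-aware reading but do not change the significant set.
    """
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {ADJUST_METHODS}, got {adjust!r}")
    fits = [fork_fit(m, t, epsilon=epsilon) for t in triplets]
    valid = [f for f in fits if not math.isnan(f.interaction_p)]
    if adjust == "benjamini-hochberg" and valid:
        adj = multipletests([f.interaction_p for f in valid], method="fdr_bh")[1]
        for f, q in zip(valid, adj):
            f.adjusted_p = float(q)
    fits.sort(
        key=lambda f: (
            math.isnan(f.interaction_p),
            f.interaction_p if not math.isnan(f.interaction_p) else 0.0,
            f.triplet.as_tuple(),
        )
    )
    return fits


def significant_forks(fits: list[ForkFit], alpha: float = DEFAULT_ALPHA) -> list[ForkFit]:
    return [f for f in fits if not math.isnan(f.interaction_p) and f.interaction_p < alpha]


_TABLE_COLUMNS = [
    "A", "B", "C", "slope_control", "slope_treatment", "interaction_estimate",
    "interaction_se", "interaction_p", "adjusted_p", "cor_overall", "cor_control",
    "cor_treatment", "n_control", "n_treatment", "flags",
]


def fork_table(fits: list[ForkFit]) -> pd.DataFrame:
    if not fits:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    return pd.DataFrame(
        [
            {
                "A": f.triplet.A_id,
                "B": f.triplet.B_id,
                "C": f.triplet.C_id,
                "slope_control": f.slope_control,
                "slope_treatment": f.slope_treatment,
                "interaction_estimate": f.interaction_estimate,
                "interaction_se": f.interaction_se,
                "interaction_p": f.interaction_p,
                "adjusted_p": f.adjusted_p,
                "cor_overall": f.cor_overall,
                "cor_control": f.cor_control,
                "cor_treatment": f.cor_treatment,
                "n_control": f.n_control,
                "n_treatment": f.n_treatment,
                "flags": ";".join(f.flags),
            }
            for f in fits
        ]
    )


def write_fork_table(fits: list[ForkFit], path) -> None:
    fork_table(fits).to_csv(path, index=False)
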