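"""Linear regressions and covariation-free sum-of-squares partitioning.

When LMA is regressed on its components LVA and LD (or LVA on the tissue
VAs), part of the explained variability is shared between correlated
predictors.  To attribute variance without that covariation the total sum
of squares is decomposed as

    SS_total = sum_j SS_unique(j) + SS_covariation + SS_error

where SS_unique(j) = SS_model(full) - SS_model(full without predictor j)
is the increment in model sum of squares attributable to predictor j alone,
and the pooled covariation term absorbs everything the predictors explain
jointly.  This is the regression form of the ANOVA sum-of-squares
decomposition and coincides with commonality analysis with the shared
(common) components pooled into a single term.  Percentages are each SS
over SS_total, so every partition closes to 100%.

Significance tiers follow the field convention: *** P < 0.001,
** P < 0.01, * P < 0.05, + (marginal) 0.05 < P < 0.10, ns otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .traits import SpeciesTraitRecord, records_to_frame

logger = logging.getLogger("lmadecomp")

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "+"))


def significance_tier(p: float) -> str:
    """Map a two-sided p-value to its display tier (ns / + / * / ** / ***)."""
    if not np.isfinite(p):
        return "ns"
    for threshold, label in TIER_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


@dataclass
class RegressionResult:
    """An ordinary least squares fit with per-predictor tests.

    ``slopes`` and ``p_values`` are keyed by predictor name; ``tier`` is the
    tier of the overall model F-test (equal to the slope test for a single
    predictor).
    """

    slopes: dict[str, float]
    intercept: float
    r_squared: float
    p_values: dict[str, float]
    n: int
    tier: str
    model_p: float

    @property
    def slope(self) -> float:
        """The slope, for single-predictor fits."""
        if len(self.slopes) != 1:
            raise ValueError("slope is only defined for single-predictor fits")
        return next(iter(self.slopes.values()))

    @property
    def p_value(self) -> float:
        if len(self.p_values) != 1:
            raise ValueError("p_value is only defined for single-predictor fits")
        return next(iter(self.p_values.values()))


@dataclass
class VariancePartition:
    """Covariation-free SS shares for one response and a set of predictors."""

    response: str
    factors: tuple[str, ...]
    ss_total: float
    ss_error: float
    ss_unique: dict[str, float]
    ss_covariation: float
    pct_unique: dict[str, float]
    pct_covariation: float
    pct_error: float

    def closure(self) -> float:
        """Sum of all percentage shares; 100 up to floating-point error."""
        return sum(self.pct_unique.values()) + self.pct_covariation + self.pct_error

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-component table for CSV export."""
        rows = [
            {"response": self.response, "component": f, "ss": self.ss_unique[f],
             "pct": self.pct_unique[f]}
            for f in self.factors
        ]
        rows.append({"response": self.response, "component": "covariation",
                     "ss": self.ss_covariation, "pct": self.pct_covariation})
        rows.append({"response": self.response, "component": "error",
                     "ss": self.ss_error, "pct": self.pct_error})
        return pd.DataFrame(rows)


def _design(X, names: Sequence[str] | None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("number of names does not match number of predictors")
    return X, list(names)


def _listwise(y, X):
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    return y[mask], X[mask]


def fit_ols(y, X, names: Sequence[str] | None = None) -> RegressionResult:
    """Least-squares fit of y on one or more predictors, with an intercept.

    Missing values are removed listwise.  A rank-deficient design is
    rejected with the offending columns named.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(X, names)
    y, X = _listwise(y, X)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete observations, got {n}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    model_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # zero-variance response
        r2 = 0.0
    return RegressionResult(
        slopes=dict(zip(names, map(float, fit.params[1:]))),
        intercept=float(fit.params[0]),
        r_squared=r2,
        p_values={
            name: (float(p) if np.isfinite(p) else 1.0)
            for name, p in zip(names, fit.pvalues[1:])
        },
        n=n,
        tier=significance_tier(model_p),
        model_p=model_p,
    )


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # a column is implicated if dropping it restores full rank
    rank = np.linalg.matrix_rank(design)
    bad = []
    for j in range(1, design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(names[j - 1])
    return bad or names


def _model_ss(y: np.ndarray, X: np.ndarray | None) -> float:
    """Model sum of squares of the OLS fit of y on X (with intercept)."""
    y = y - y.mean()
    if X is None or X.shape[1] == 0:
        return 0.0
    design = sm.add_constant(X, has_constant="add")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    return float(y @ y - resid @ resid)


def _partition(y, terms: dict[str, np.ndarray], response: str) -> VariancePartition:
    y = np.asarray(y, dtype=float)
    names = list(terms)
    M = np.column_stack([terms[t] for t in names])
    mask = np.isfinite(y) & np.all(np.isfinite(M), axis=1)
    y, M = y[mask], M[mask]
    n, k = M.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} complete observations, got {n}")
    design = sm.add_constant(M, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        raise ValueError("response has zero variance; partition undefined")
    ss_model_full = _model_ss(y, M)
    ss_error = ss_total - ss_model_full

    ss_unique = {}
    for j, name in enumerate(names):
        reduced = np.delete(M, j, axis=1)
        ss_unique[name] = ss_model_full - _model_ss(y, reduced)
        if ss_unique[name] < 0 and abs(ss_unique[name]) > 1e-12 * ss_total:
            logger.warning(
                "%s: negative unique SS for %s (%.4g) -- suppression; reported as-is",
                response, name, ss_unique[name],
            )
    ss_cov = ss_model_full - sum(ss_unique.values())

    return VariancePartition(
        response=response,
        factors=tuple(names),
        ss_total=ss_total,
        ss_error=ss_error,
        ss_unique=ss_unique,
        ss_covariation=ss_cov,
        pct_unique={f: 100.0 * ss / ss_total for f, ss in ss_unique.items()},
        pct_covariation=100.0 * ss_cov / ss_total,
        pct_error=100.0 * ss_error / ss_total,
    )


def decompose_two_factor(
    y, x1, x2,
    include_interaction: bool = False,
    names: tuple[str, str] = ("x1", "x2"),
    response: str = "y",
) -> VariancePartition:
    """Partition var(y) into unique, shared and error components of two factors.

    With ``include_interaction`` the product term enters the full model as a
    third component with its own unique share.  The interaction is off by
    default: the decompositions of LMA into LVA and LD, and of LVA into the
    tissues, report main components only.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    terms: dict[str, np.ndarray] = {names[0]: x1, names[1]: x2}
    if include_interaction:
        terms[f"{names[0]}:{names[1]}"] = x1 * x2
    return _partition(y, terms, response)


def decompose_multi(
    y, X, names: Sequence[str] | None = None, response: str = "y"
) -> VariancePartition:
    """Leave-one-out SS partition of y over k >= 2 additive predictors."""
    X, names = _design(X, names)
    if X.shape[1] < 2:
        raise ValueError("decompose_multi needs at least two predictors")
    terms = {name: X[:, j] for j, name in enumerate(names)}
    return _partition(y, terms, response)


# ---------------------------------------------------------------------------
# soil-water-gradient regressions
# ---------------------------------------------------------------------------

GROUPS = ("all", "deciduous", "evergreen")


def select_group(records: Sequence[SpeciesTraitRecord], group: str) -> list[SpeciesTraitRecord]:
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if group == "all":
        return list(records)
    return [r for r in records if r.habit == group]


def gradient_regressions(
    records: Sequence[SpeciesTraitRecord],
    group: str = "all",
    traits: Sequence[str] = ("lma_g_m2", "ld_g_ml", "lva_ml_m2"),
) -> dict[str, RegressionResult]:
    """Simple regressions of each trait against site soil water content.

    Run for all species together or for the deciduous and evergreen species
    separately; the marginal (+) tier flags 0.05 < P < 0.10 relationships.
    """
    subset = select_group(records, group)
    if len(subset) < 4:
        raise ValueError(f"group {group!r} has {len(subset)} species; need >= 4")
    frame = records_to_frame(subset)
    if frame["swc_l_m2"].isna().all():
        raise ValueError("no soil water content values available")
    out = {}
    for trait in traits:
        if trait not in frame.columns:
            raise ValueError(f"unknown trait column {trait!r}")
        out[trait] = fit_ols(frame[trait].to_numpy(), frame["swc_l_m2"].to_numpy(),
                             names=["swc_l_m2"])
    return out


def regression_table(
    records: Sequence[SpeciesTraitRecord],
    responses: Sequence[str],
    predictor: str,
) -> pd.DataFrame:
    """Per-group sign / R2 / tier table for simple regressions (Table-1 layout)."""
    rows = []
    for group in GROUPS:
        subset = select_group(records, group)
        if len(subset) < 4:
            continue
        frame = records_to_frame(subset)
        for resp in responses:
            pair = frame[[resp, predictor]].dropna()
            if len(pair) < 4:
                continue
            res = fit_ols(pair[resp].to_numpy(), pair[predictor].to_numpy(),
                          names=[predictor])
            rows.append({
                "group": group,
                "response": resp,
                "predictor": predictor,
                "sign": "+" if res.slope >= 0 else "-",
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "tier": res.tier,
                "n": res.n,
            })
    return pd.DataFrame(rows)
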