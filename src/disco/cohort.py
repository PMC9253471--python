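"""Cohort-level tabular statistics.

Variable standardisation, disability-change (EDSS) classification, serum
NfL outlier handling, the GD-T2LV association, and the cross-sectional
multiple linear models relating the global disconnectome and T2 lesion
volume to serum NfL and clinical covariates at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from patsy import dmatrices

__all__ = [
    "zscore",
    "classify_edss_change",
    "remove_nfl_outliers",
    "gd_t2lv_association",
    "fit_cross_sectional",
    "CROSS_SECTIONAL_FORMULA",
]

#: Continuous covariates entering models z-scored.
CONTINUOUS = ("snfl", "disease_duration", "age")

#: Reference levels: no treatment, Barcelona, male sex, CIS phenotype.
CROSS_SECTIONAL_FORMULA = (
    "{response} ~ z_snfl + z_disease_duration + z_age"
    " + C(sex, Treatment('M'))"
    " + C(phenotype, Treatment('CIS'))"
    " + C(treatment, Treatment('none'))"
    " + C(center, Treatment('Barcelona'))"
)


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardise")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd


def add_zscored(table: pd.DataFrame, columns=CONTINUOUS) -> pd.DataFrame:
    """Return a copy of ``table`` with ``z_<col>`` columns appended."""
    out = table.copy()
    for col in columns:
        out[f"z_{col}"] = zscore(out[col].to_numpy())
    return out


_EDSS_GRID = np.arange(0.0, 10.5, 0.5)


def _check_edss(value: float, name: str) -> float:
    v = float(value)
    if not np.isclose(_EDSS_GRID, v).any():
        raise ValueError(f"{name} EDSS {value} is not on the 0-10 half-point grid")
    return v


def classify_edss_change(baseline: float, followup: float) -> str:
    """Classify disability change between two visits.

    Worsening: increase >= 1.0 from a baseline of 0.0-5.0, or >= 0.5 from
    a baseline of 5.5 and above. Improving: decrease >= 1.0 from 0.0-5.0,
    or >= 0.5 from above 5.0. Stable: baseline <= 5.0 with a change of at
    most half a point either way. Grid cells these rules leave uncovered
    (e.g. an unchanged score of 5.5+) are returned as ``"unclassified"``
    rather than silently binned.
    """
    b = _check_edss(baseline, "baseline")
    f = _check_edss(followup, "follow-up")
    delta = f - b
    if (b <= 5.0 and delta >= 1.0) or (b >= 5.5 and delta >= 0.5):
        return "worsening"
    if (b <= 5.0 and delta <= -1.0) or (b > 5.0 and delta <= -0.5):
        return "improving"
    if b <= 5.0 and abs(delta) <= 0.5:
        return "stable"
    return "unclassified"


def remove_nfl_outliers(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Drop serum NfL values more than ``k`` SDs above the mean.

    One-sided and single-pass: the cutoff ``mean + k*SD`` is computed once
    on the full input; low values are never removed. (Re-running on the
    kept values may remove more — by design this rule is applied once.)
    Returns ``(kept_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    cutoff = x.mean() + k * x.std(ddof=1)
    removed = np.flatnonzero(x > cutoff)
    kept = np.delete(x, removed)
    return kept, removed


@dataclass
class GdT2lvAssociation:
    r: float
    r_p: float
    coef: np.ndarray  # (intercept, linear, quadratic) of gd on t2lv
    n: int


def gd_t2lv_association(records: pd.DataFrame) -> GdT2lvAssociation:
    """Pearson correlation of GD with T2LV plus a quadratic fit of GD on T2LV."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    gd = records["gd"].to_numpy(dtype=float)
    t2lv = records["t2lv"].to_numpy(dtype=float)
    if gd.std() == 0 or t2lv.std() == 0:
        raise ValueError("degenerate variance in gd or t2lv")
    r, p = scipy.stats.pearsonr(gd, t2lv)
    X = np.column_stack([np.ones_like(t2lv), t2lv, t2lv**2])
    coef, *_ = np.linalg.lstsq(X, gd, rcond=None)
    return GdT2lvAssociation(r=float(r), r_p=float(p), coef=coef, n=len(records))


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
    return sorted(names[i] for i in piv[rank:])


def fit_cross_sectional(records: pd.DataFrame, response: str = "gd") -> pd.DataFrame:
    """Baseline multiple linear model of GD or T2LV on NfL and covariates.

    Ordinary least squares with z-scored continuous variables and dummy
    coding (reference levels: male sex, CIS phenotype, no treatment,
    Barcelona center). Returns a coefficient table with estimate, SE, t,
    95% CI and two-sided p per term.
    """
    if response not in ("gd", "t2lv"):
        raise ValueError("response must be 'gd' or 't2lv'")
    data = records[records["timepoint"] == 0] if "timepoint" in records else records
    data = add_zscored(data)
    y, X = dmatrices(
        CROSS_SECTIONAL_FORMULA.format(response=response), data, return_type="dataframe"
    )
    if len(data) <= X.shape[1]:
        raise ValueError(f"n={len(data)} does not exceed {X.shape[1]} design columns")
    aliased = _aliased_columns(X.to_numpy(), list(X.columns))
    if aliased:
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    ).set_index("term")
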