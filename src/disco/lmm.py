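"""Longitudinal linear mixed models for the disconnectome-biomarker analysis.

The core model relates a per-visit imaging response (global disconnectome
or T2 lesion volume) to serum NfL and clinical covariates over two visits:

    y_it = b0 + b1 * zNfL_it + b2 * time_t + [b3 * zNfL_it * time_t]
           + covariates + u_i [+ v_c] + e_it

with a subject random intercept u_i always present, and center entering
either as fixed dummy terms (default) or as a second random intercept v_c
(subjects nested in centers). Continuous covariates are z-scored across
the analysed rows; timepoint is coded 0/1 (baseline / follow-up), so the
NfL x timepoint interaction reads as the change in the NfL slope at
follow-up.

Fitting is restricted maximum likelihood via statsmodels MixedLM, with
Wald normal-approximation inference per fixed effect. A robust variant
refits the model by iteratively reweighted least squares with Huber
weights on standardised residuals, downweighting extreme observations;
on clean data it agrees with the conventional fit, and as the Huber
constant grows it converges to it exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices

from .cohort import add_zscored

__all__ = ["LmmSpec", "LmmFit", "fit_lmm", "fit_lmm_interaction", "fit_robust_lmm"]


@dataclass(frozen=True)
class LmmSpec:
    """Model specification for the longitudinal fits.

    ``center`` is one of ``"fixed"`` (dummy-coded center terms, the
    default), ``"random"`` (center random intercept with subjects nested
    inside centers) or ``"none"``.
    """

    response: str = "gd"
    interaction: bool = False
    center: str = "fixed"
    include_covariates: bool = True

    def __post_init__(self) -> None:
        if self.response not in ("gd", "t2lv"):
            raise ValueError("response must be 'gd' or 't2lv'")
        if self.center not in ("fixed", "random", "none"):
            raise ValueError("center must be 'fixed', 'random' or 'none'")

    def formula(self) -> str:
        terms = ["z_snfl", "timepoint"]
        if self.interaction:
            terms.append("z_snfl:timepoint")
        if self.include_covariates:
            terms += [
                "z_disease_duration",
                "z_age",
                "C(sex, Treatment('M'))",
                "C(phenotype, Treatment('CIS'))",
                "C(treatment, Treatment('none'))",
            ]
        if self.center == "fixed":
            terms.append("C(center, Treatment('Barcelona'))")
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class LmmFit:
    """Fixed-effect table plus variance components for one mixed-model fit."""

    params: pd.DataFrame  # estimate, se, t, ci_low, ci_high, p per fixed term
    variance_components: dict
    converged: bool
    method: str
    n_obs: int
    n_subjects: int
    n_iter: int | None = None
    singular: bool = False
    loglike: float | None = None

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


#: Canonical fixed-term aliases for the headline effects.
TERM_NFL = "z_snfl"
TERM_TIME = "timepoint"
TERM_INTERACTION = "z_snfl:timepoint"


def _fit_mixedlm(model: sm.MixedLM):
    """REML fit with optimizer fallback; some optimizers can hit singular
    information matrices on near-boundary variance parameters."""
    last: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last = exc
    raise last


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    data = add_zscored(records)
    data["timepoint"] = data["timepoint"].astype(int)
    return data


def _fe_table(fe_params, bse, pvalues, alpha: float = 0.05) -> pd.DataFrame:
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    est = np.asarray(fe_params, dtype=float)
    se = np.asarray(bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t": t,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
            "p": np.asarray(pvalues, dtype=float),
        },
        index=list(fe_params.index),
    )


def fit_lmm(records: pd.DataFrame, spec: LmmSpec | None = None) -> LmmFit:
    """REML linear mixed model with subject (and optionally center) intercepts.

    Non-convergence and boundary (singular) variance estimates are
    flagged on the returned fit, not raised.
    """
    spec = spec or LmmSpec()
    data = _prepare(records)
    if spec.interaction and data["timepoint"].nunique() < 2:
        raise ValueError("NfL x timepoint interaction needs at least two timepoints")
    kwargs: dict = {"groups": "subject_id", "re_formula": "1"}
    if spec.center == "random":
        # subjects are nested in centers: center is the grouping factor,
        # the subject intercept becomes a variance component
        kwargs = {
            "groups": "center",
            "re_formula": "1",
            "vc_formula": {"subject": "0 + C(subject_id)"},
        }
    _check_design(spec, data)
    model = sm.MixedLM.from_formula(spec.formula(), data, **kwargs)
    result = _fit_mixedlm(model)
    vc = {"sigma2": float(result.scale)}
    try:
        vc["tau_subject" if spec.center != "random" else "tau_center"] = float(
            np.asarray(result.cov_re).ravel()[0]
        )
    except (IndexError, ValueError):
        pass
    if spec.center == "random" and result.vcomp.size:
        vc["tau_subject"] = float(result.vcomp[0])
    singular = any(v <= 1e-10 for k, v in vc.items() if k != "sigma2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits: sqrt of tiny negatives
        table = _fe_table(
            result.fe_params, result.bse_fe, result.pvalues[: len(result.fe_params)]
        )
    return LmmFit(
        params=table,
        variance_components=vc,
        converged=bool(result.converged),
        method="REML-ML",
        n_obs=int(model.nobs),
        n_subjects=int(data["subject_id"].nunique()),
        singular=singular,
        loglike=float(result.llf),
    )


def _check_design(spec: LmmSpec, data: pd.DataFrame) -> None:
    _, X = dmatrices(spec.formula(), data, return_type="dataframe")
    degenerate = [
        c for c in X.columns
        if c != "Intercept" and float(np.ptp(X[c].to_numpy())) == 0.0
    ]
    if degenerate:
        raise ValueError(
            f"design columns with no variation: {degenerate}; "
            "drop the corresponding terms or supply richer data"
        )


def fit_lmm_interaction(records: pd.DataFrame, spec: LmmSpec | None = None) -> LmmFit:
    """Convenience wrapper adding the NfL x timepoint interaction term."""
    base = spec or LmmSpec()
    return fit_lmm(
        records,
        LmmSpec(
            response=base.response,
            interaction=True,
            center=base.center,
            include_covariates=base.include_covariates,
        ),
    )


def fit_robust_lmm(
    records: pd.DataFrame,
    spec: LmmSpec | None = None,
    huber_c: float = 2.5,
    max_iter: int = 8,
    tol: float = 2e-3,
) -> LmmFit:
    """Huber-weighted IRLS refit of the mixed model.

    Starting from the conventional REML fit, observations with large
    standardised residuals (relative to a MAD scale estimate) are
    downweighted by the Huber function w = min(1, c/|r|), the rows of the
    response, fixed-effect design and random-intercept design are scaled
    by sqrt(w), and the model is refit; this repeats to convergence of
    the fixed effects. The default tolerance matches the precision to
    which the reweighted solution is defined (the adaptive scale makes
    the iterates jitter at the 1e-3 level under heavy contamination).
    With ``huber_c`` = inf all weights are 1 and the result equals the
    conventional fit. Center must enter as a fixed effect (or not at
    all) in this variant.
    """
    spec = spec or LmmSpec()
    if spec.center == "random":
        raise NotImplementedError(
            "robust refit supports center as a fixed effect only"
        )
    data = _prepare(records)
    if spec.interaction and data["timepoint"].nunique() < 2:
        raise ValueError("NfL x timepoint interaction needs at least two timepoints")
    y_df, X_df = dmatrices(spec.formula(), data, return_type="dataframe")
    y = y_df.to_numpy().ravel()
    X = X_df.to_numpy()
    groups = data.loc[X_df.index, "subject_id"].to_numpy()
    names = list(X_df.columns)

    w = np.ones_like(y)
    beta_prev = None
    result = None
    n_iter = 0
    converged_irls = False
    for n_iter in range(1, max_iter + 1):
        sw = np.sqrt(w)
        model = sm.MixedLM(y * sw, X * sw[:, None], groups=groups, exog_re=sw[:, None])
        result = _fit_mixedlm(model)
        beta = np.asarray(result.fe_params, dtype=float)
        resid = y - X @ beta - _blup_per_group(result, groups)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad if mad > 0 else np.std(resid) or 1.0
        r = resid / scale
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, huber_c / np.maximum(np.abs(r), 1e-12))
        if beta_prev is not None and np.max(np.abs(beta - beta_prev)) < tol:
            converged_irls = True
            break
        beta_prev = beta

    fe = pd.Series(np.asarray(result.fe_params, dtype=float), index=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = _fe_table(fe, result.bse_fe, result.pvalues[: len(names)])
    vc = {"sigma2": float(result.scale),
          "tau_subject": float(np.asarray(result.cov_re).ravel()[0])}
    return LmmFit(
        params=table,
        variance_components=vc,
        converged=bool(result.converged) and converged_irls,
        method="robust-IRLS",
        n_obs=len(y),
        n_subjects=int(pd.unique(groups).size),
        n_iter=n_iter,
        singular=vc["tau_subject"] <= 1e-10,
        loglike=float(result.llf),
    )


def _blup_per_group(result, groups: np.ndarray) -> np.ndarray:
    """Predicted random intercept per observation, 0 for degenerate fits."""
    try:
        re = result.random_effects
    except (ValueError, np.linalg.LinAlgError):
        return np.zeros(len(groups))
    out = np.zeros(len(groups))
    for i, g in enumerate(groups):
        eff = re.get(g)
        if eff is not None and len(eff):
            out[i] = float(np.asarray(eff)[0])
    return out
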