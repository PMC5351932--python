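"""Cross-cohort pooling and the cross-region mixed model.

Cohort-level results are combined by fixed-effects inverse-variance
meta-analysis in two flavors: directly from (estimate, SE) pairs, or from
covariate-adjusted group summaries (mean difference with its large-sample
SE, then the same pooling).  Fixed rather than random effects: with only
two cohorts the between-study variance cannot be usefully estimated.

The cross-region model is a linear mixed model with random intercepts for
donor and for brain region (REML variance components via statsmodels), a
Wald z test on the exposure, and cerebellum excluded by default since its
methylome is globally distinct from the cerebral regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortEstimate",
    "GroupSummary",
    "MetaResult",
    "MixedFit",
    "welch_from_summary",
    "meta_fixed",
    "meta_from_groups",
    "adjusted_group_summaries",
    "fit_cross_region",
]


@dataclass(frozen=True)
class CohortEstimate:
    cohort: str
    estimate: float
    se: float


@dataclass(frozen=True)
class GroupSummary:
    """Per-cohort group summaries: cases (1) vs controls (0)."""

    cohort: str
    mean1: float
    sd1: float
    n1: int
    mean0: float
    sd0: float
    n0: int


@dataclass
class MetaResult:
    estimate: float
    se: float
    z: float
    p: float
    components: List[CohortEstimate]
    cochran_q: float


@dataclass
class MixedFit:
    estimate: float  # exposure effect, percentage points
    se: float
    z: float
    p: float
    var_donor: float
    var_region: float
    var_resid: float
    converged: bool
    status: str = "ok"


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean0: float, sd0: float, n0: int
) -> dict:
    """Welch two-sample t-test from group summary statistics.

    Degenerate inputs (both SDs zero) return p = 1 when the means agree
    and p = 0 (flagged) when they differ.
    """
    if sd1 < 0 or sd0 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs n >= 2")
    diff = mean1 - mean0
    v1, v0 = sd1**2 / n1, sd0**2 / n0
    if v1 + v0 == 0.0:
        if diff == 0.0:
            return {"difference": 0.0, "t": 0.0, "df": np.nan, "p": 1.0,
                    "status": "degenerate"}
        return {"difference": diff, "t": np.inf, "df": np.nan, "p": 0.0,
                "status": "degenerate"}
    t = diff / np.sqrt(v1 + v0)
    df = (v1 + v0) ** 2 / (v1**2 / (n1 - 1) + v0**2 / (n0 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"difference": float(diff), "t": float(t), "df": float(df),
            "p": float(p), "status": "ok"}


def meta_fixed(inputs: Sequence[CohortEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of cohort estimates.

    theta = sum(w_i theta_i)/sum(w_i) with w_i = 1/se_i^2;
    se = (sum w_i)^(-1/2); two-sided normal p on z = theta/se.
    """
    if len(inputs) == 0:
        raise ValueError("need at least one cohort")
    est = np.array([c.estimate for c in inputs], dtype=float)
    se = np.array([c.se for c in inputs], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    theta = float(np.sum(w * est) / np.sum(w))
    se_comb = float(1.0 / np.sqrt(np.sum(w)))
    z = theta / se_comb
    p = 2.0 * stats.norm.sf(abs(z))
    q = float(np.sum(w * (est - theta) ** 2))
    return MetaResult(
        estimate=theta, se=se_comb, z=float(z), p=float(p),
        components=list(inputs), cochran_q=q,
    )


def meta_from_groups(inputs: Sequence[GroupSummary]) -> MetaResult:
    """Fixed-effects pooling of per-cohort mean differences.

    Each cohort contributes MD = mean1 - mean0 with large-sample
    SE = sqrt(sd1^2/n1 + sd0^2/n0); cohorts with a group of fewer than
    two samples are dropped with a warning.
    """
    comps = []
    for g in inputs:
        if g.n1 < 2 or g.n0 < 2:
            warnings.warn(f"cohort {g.cohort!r} dropped: group n < 2")
            continue
        se = np.sqrt(g.sd1**2 / g.n1 + g.sd0**2 / g.n0)
        if se <= 0:
            warnings.warn(f"cohort {g.cohort!r} dropped: zero-variance groups")
            continue
        comps.append(CohortEstimate(g.cohort, g.mean1 - g.mean0, float(se)))
    if not comps:
        raise ValueError("no usable cohorts")
    return meta_fixed(comps)


def adjusted_group_summaries(
    y: np.ndarray,
    covariates: np.ndarray,
    is_case: np.ndarray,
    cohort: str = "",
) -> GroupSummary:
    """Covariate-adjusted group summaries for one cohort.

    The outcome is residualized on the covariates only (intercept
    included, diagnosis excluded), the grand mean is re-added so values
    remain on the beta scale, and group means/SDs are taken over the
    adjusted values with the group structure retained.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    adjusted = y - X @ coef + y.mean()
    a1, a0 = adjusted[is_case], adjusted[~is_case]
    return GroupSummary(
        cohort=cohort,
        mean1=float(a1.mean()), sd1=float(a1.std(ddof=1)), n1=int(len(a1)),
        mean0=float(a0.mean()), sd0=float(a0.std(ddof=1)), n0=int(len(a0)),
    )


def fit_cross_region(
    long: pd.DataFrame,
    exposure: str = "diagnosis",
    covariates: Sequence[str] = ("sex", "age", "neuronal_prop", "cohort"),
    exclude_regions: Sequence[str] = ("CER",),
    maxiter: int = 200,
) -> MixedFit:
    """Cross-region mixed model for one probe.

    ``long`` has one row per sample with columns: beta, the exposure
    (diagnosis or prs), the covariates, donor, region.  Random
    intercepts for donor and region capture repeated measures; fixed
    effects follow the EWAS covariate set plus brain bank.  The exposure
    effect is reported in percentage points with a Wald z test.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = long.copy()
    df = df[~df["region"].isin(exclude_regions)]
    if df["region"].nunique() < 2:
        raise ValueError("need >= 2 regions after exclusion")
    if exposure == "diagnosis":
        df["_exposure"] = (df["diagnosis"] == "case").astype(float)
    else:
        df["_exposure"] = pd.to_numeric(df[exposure])
    terms = ["_exposure"]
    for c in covariates:
        if c not in df.columns:
            continue
        if df[c].nunique() < 2:
            continue  # constant column: no information, breaks the design
        if df[c].dtype == object:
            terms.append(f"C({c})")
        else:
            terms.append(c)
    df = df.dropna(subset=["beta"] + [c for c in covariates if c in df.columns])
    formula = "beta ~ " + " + ".join(terms)
    vc = {"donor": "0 + C(donor)", "region": "0 + C(region)"}
    df["_group"] = 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula, df, groups="_group", vc_formula=vc, re_formula="0"
            )
            fit = model.fit(reml=True, maxiter=maxiter)
        est = float(fit.params["_exposure"])
        se = float(fit.bse["_exposure"])
        z = est / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        vcomp = fit.vcs if hasattr(fit, "vcs") else None
        var_donor = float(fit.vcomp[0]) if len(fit.vcomp) > 0 else 0.0
        var_region = float(fit.vcomp[1]) if len(fit.vcomp) > 1 else 0.0
        return MixedFit(
            estimate=est * 100.0, se=se * 100.0, z=float(z), p=float(p),
            var_donor=max(var_donor, 0.0), var_region=max(var_region, 0.0),
            var_resid=float(fit.scale), converged=bool(fit.converged),
            status="ok" if fit.converged else "not_converged",
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        return MixedFit(
            estimate=np.nan, se=np.nan, z=np.nan, p=np.nan,
            var_donor=np.nan, var_region=np.nan, var_resid=np.nan,
            converged=False, status=f"failed: {exc}",
        )
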