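"""Probe-wise epigenome-wide association and diagnostics.

Each probe's beta values are regressed on an exposure (diagnosis, coded
control = 0 / case = 1, or polygenic score) plus covariates by ordinary
least squares, with a two-sided t-test on the exposure coefficient.
Effect sizes are reported as percentage-point methylation differences
(coefficient x 100); positive diagnosis estimates mean hypermethylation
in cases.  The probe loop is a single batched least-squares solve when
the design is shared across probes, so genome-scale and permutation runs
stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import compute_pcs
from .types import BetaMatrix, MalformedInputError, SampleSheet

__all__ = [
    "ModelSpec",
    "InflationEstimate",
    "build_design",
    "fit_probe",
    "run_ewas",
    "genomic_inflation",
    "pc_sensitivity",
    "global_mean_test",
]


@dataclass
class ModelSpec:
    """What to regress on what: exposure, covariates, sample restriction."""

    exposure: str = "diagnosis"  # 'diagnosis' or 'prs'
    covariates: Tuple[str, ...] = ("age", "sex", "neuronal_prop")
    region: Optional[str] = None
    cohort: Optional[str] = None
    n_pcs: int = 0
    use_mvalues: bool = False

    def __post_init__(self) -> None:
        if self.exposure not in ("diagnosis", "prs"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.exposure in self.covariates:
            raise ValueError("exposure may not appear among covariates")
        # neuronal proportion is not an admissible covariate for cerebellum
        if self.region == "CER" and "neuronal_prop" in self.covariates:
            self.covariates = tuple(
                c for c in self.covariates if c != "neuronal_prop"
            )


@dataclass
class InflationEstimate:
    lambda_: float
    qq: pd.DataFrame  # observed vs expected -log10 p

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise ValueError("lambda must be positive")


def _encode_column(sheet: SampleSheet, name: str) -> np.ndarray:
    t = sheet.table
    if name == "diagnosis":
        return (t["diagnosis"] == "case").to_numpy(dtype=float)
    if name == "sex":
        return (t["sex"] == "M").to_numpy(dtype=float)
    if name == "cohort":
        codes, _ = pd.factorize(t["cohort"])
        return codes.astype(float)
    if name in t.columns:
        return pd.to_numeric(t[name], errors="coerce").to_numpy(dtype=float)
    raise MalformedInputError(f"covariate {name!r} absent from sample sheet")


def build_design(
    sheet: SampleSheet,
    spec: ModelSpec,
    pcs: Optional[pd.DataFrame] = None,
) -> Tuple[np.ndarray, pd.Index, List[str]]:
    """Design matrix [intercept, exposure, covariates...]; complete cases only.

    Returns the matrix, the retained sample index, and column names.
    """
    t = sheet.table
    mask = np.ones(len(t), dtype=bool)
    if spec.region is not None:
        mask &= (t["region"] == spec.region).to_numpy()
    if spec.cohort is not None:
        mask &= (t["cohort"] == spec.cohort).to_numpy()
    sub = SampleSheet(t.loc[mask])
    cols = [np.ones(len(sub.table))]
    names = ["intercept", spec.exposure]
    cols.append(_encode_column(sub, spec.exposure))
    for c in spec.covariates:
        cols.append(_encode_column(sub, c))
        names.append(c)
    X = np.column_stack(cols)
    keep = np.isfinite(X).all(axis=1)
    X = X[keep]
    samples = sub.table.index[keep]
    if pcs is not None:
        k = spec.n_pcs
        P = pcs.loc[samples].to_numpy(dtype=float)[:, :k]
        X = np.column_stack([X, P])
        names += [f"PC{i+1}" for i in range(k)]
    return X, samples, names


def _ols_exposure(
    Y: np.ndarray, X: np.ndarray, exposure_col: int = 1
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Batched OLS of many outcomes on one design.

    Y is probes x samples, X is samples x terms.  Returns exposure
    estimate, se, t statistic, p, and residual df (common to all rows).
    """
    n, k = X.shape
    df = n - k
    if df < 1:
        raise MalformedInputError(f"not enough samples ({n}) for {k} model terms")
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    H = XtX_inv @ X.T  # k x n
    B = Y @ H.T  # probes x k
    resid = Y - B @ X.T
    sse = np.einsum("ij,ij->i", resid, resid)
    sigma2 = sse / df
    var_e = sigma2 * XtX_inv[exposure_col, exposure_col]
    se = np.sqrt(np.maximum(var_e, 0.0))
    est = B[:, exposure_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return est, se, tstat, p, df


def fit_probe(
    y: np.ndarray, X: np.ndarray, exposure_col: int = 1
) -> dict:
    """OLS fit of one probe; returns estimate (%), se (%), stat, p, n, df.

    Rank-deficient designs yield a flagged result instead of raising.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    y, Xc = y[keep], X[keep]
    n, k = Xc.shape
    if n < k + 1:
        return {
            "estimate": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
            "n": int(n), "df": np.nan, "status": "too_few_samples",
        }
    if np.linalg.matrix_rank(Xc) < k:
        return {
            "estimate": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
            "n": int(n), "df": np.nan, "status": "rank_deficient",
        }
    est, se, tstat, p, df = _ols_exposure(y[None, :], Xc, exposure_col)
    return {
        "estimate": float(est[0]) * 100.0,
        "se": float(se[0]) * 100.0,
        "stat": float(tstat[0]),
        "p": float(np.clip(p[0], np.nextafter(0, 1), 1.0)),
        "n": int(n),
        "df": float(df),
        "status": "ok",
    }


def run_ewas(
    beta: BetaMatrix,
    sheet: SampleSheet,
    spec: Optional[ModelSpec] = None,
    pcs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Probe-wise association table for the given model.

    Output columns: estimate (%), se (%), stat, p, n, df, status; one row
    per probe, in the probe order of the input matrix.
    """
    spec = spec or ModelSpec()
    if len(beta.probe_ids) == 0:
        raise MalformedInputError("empty probe set")
    X, samples, _ = build_design(sheet, spec, pcs=pcs)
    if len(samples) < 10:
        raise MalformedInputError(
            f"only {len(samples)} complete-case samples; need >= 10"
        )
    sub = beta.values.loc[:, samples]
    Y = sub.to_numpy(dtype=float)
    if spec.use_mvalues:
        eps = 1e-6
        Y = np.log2(np.clip(Y, eps, 1 - eps) / (1 - np.clip(Y, eps, 1 - eps)))
    out = pd.DataFrame(
        index=beta.probe_ids,
        columns=["estimate", "se", "stat", "p", "n", "df", "status"],
    )
    complete = np.isfinite(Y).all(axis=1)
    if complete.any():
        est, se, tstat, p, df = _ols_exposure(Y[complete], X)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        idx = beta.probe_ids[complete]
        out.loc[idx, "estimate"] = est * 100.0
        out.loc[idx, "se"] = se * 100.0
        out.loc[idx, "stat"] = tstat
        out.loc[idx, "p"] = p
        out.loc[idx, "n"] = X.shape[0]
        out.loc[idx, "df"] = float(df)
        out.loc[idx, "status"] = "ok"
    for i in np.flatnonzero(~complete):
        res = fit_probe(Y[i], X)
        out.iloc[i] = [
            res["estimate"], res["se"], res["stat"], res["p"],
            res["n"], res["df"], res["status"],
        ]
    for c in ("estimate", "se", "stat", "p", "df"):
        out[c] = out[c].astype(float)
    out["n"] = out["n"].astype("Int64")
    return out


def genomic_inflation(p_values: Sequence[float]) -> InflationEstimate:
    """Genomic inflation factor lambda from the median association p-value.

    lambda = qchisq(1 - median p; 1) / qchisq(0.5; 1).  Also returns
    observed vs expected -log10 p pairs for QQ plotting.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need >= 100 p-values for a stable inflation estimate")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    med = np.median(p)
    lam = stats.chi2.isf(med, df=1) / stats.chi2.ppf(0.5, df=1)
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    qq = pd.DataFrame({"expected": exp, "observed": obs})
    return InflationEstimate(lambda_=float(lam), qq=qq)


def pc_sensitivity(
    beta: BetaMatrix,
    sheet: SampleSheet,
    spec: Optional[ModelSpec] = None,
    k_max: int = 10,
) -> pd.Series:
    """Stability of exposure estimates as top-k methylation PCs are added.

    For k = 1..k_max the model is refit with the top-k principal
    components appended; reported is the Pearson correlation of per-probe
    exposure estimates against the PC-free base model.
    """
    spec = spec or ModelSpec()
    base = run_ewas(beta, sheet, spec)
    ok = base["status"] == "ok"
    X, samples, _ = build_design(sheet, spec)
    pcs = compute_pcs(beta.values.loc[:, samples], k_max)
    corr = {}
    for k in range(1, k_max + 1):
        spec_k = ModelSpec(
            exposure=spec.exposure,
            covariates=spec.covariates,
            region=spec.region,
            cohort=spec.cohort,
            n_pcs=k,
            use_mvalues=spec.use_mvalues,
        )
        res = run_ewas(beta, sheet, spec_k, pcs=pcs)
        a = base.loc[ok, "estimate"].to_numpy(dtype=float)
        b = res.loc[ok, "estimate"].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        if keep.sum() < 3 or np.std(a[keep]) == 0 or np.std(b[keep]) == 0:
            corr[k] = np.nan
        else:
            corr[k] = float(np.corrcoef(a[keep], b[keep])[0, 1])
    return pd.Series(corr, name="estimate_correlation")


def global_mean_test(beta: BetaMatrix, sheet: SampleSheet) -> dict:
    """Case vs control comparison of array-wide mean methylation.

    Per-sample means (%) are compared by a two-sided two-sample t-test.
    """
    diag = sheet.table.loc[beta.sample_ids, "diagnosis"]
    means = beta.values.mean(axis=0) * 100.0
    case = means[(diag == "case").to_numpy()]
    ctl = means[(diag == "control").to_numpy()]
    if len(case) < 2 or len(ctl) < 2:
        raise MalformedInputError("need >= 2 samples per diagnosis group")
    if np.allclose(case.mean(), ctl.mean()) and np.ptp(means.to_numpy()) == 0:
        p = 1.0
    else:
        _, p = stats.ttest_ind(case, ctl, equal_var=False)
    return {
        "case_mean_pct": round(float(case.mean()), 2),
        "control_mean_pct": round(float(ctl.mean()), 2),
        "p": float(p),
        "n_case": int(len(case)),
        "n_control": int(len(ctl)),
    }
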