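"""Model covariates: neuronal proportion, methylation age, principal components.

Neuronal proportion is a two-class constrained projection onto reference
neuron/glia methylation profiles — the closed-form least-squares mixing
weight, clamped to [0, 1].  Cell deconvolution of this kind is unsuitable
for cerebellum (dominated by NeuN-negative neurons), so the pipeline skips
the neuronal covariate for cerebellum samples by configuration.

Methylation age uses user-supplied clock coefficients (never bundled) and
the standard clock age transform anchored at adult age 20: the linear
predictor maps through a log calibration below adulthood and a linear one
above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import json
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceProfiles",
    "ClockModel",
    "ClockResult",
    "estimate_neuronal_proportion",
    "estimate_neuronal_proportions",
    "dnam_age",
    "age_transform",
    "age_acceleration_test",
    "compute_pcs",
]


@dataclass
class ReferenceProfiles:
    """Mean reference beta per probe for the neuron and glia classes."""

    neuron: pd.Series
    glia: pd.Series

    def __post_init__(self) -> None:
        if not self.neuron.index.equals(self.glia.index):
            raise ValueError("neuron and glia profiles must cover the same probes")
        for name, s in (("neuron", self.neuron), ("glia", self.glia)):
            v = s.to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} reference values must lie in [0,1]")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceProfiles":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(neuron=df["neuron"].astype(float), glia=df["glia"].astype(float))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"neuron": self.neuron, "glia": self.glia}).rename_axis(
            "probe_id"
        ).to_csv(path, sep="\t")


@dataclass
class ClockModel:
    """Epigenetic clock: intercept, per-probe coefficients, adult-age anchor."""

    intercept: float
    coefficients: pd.Series
    adult_age: float = 20.0
    imputation_means: Optional[pd.Series] = None

    @classmethod
    def from_tsv(cls, path, header_json=None) -> "ClockModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = {}
        if header_json is not None:
            meta = json.loads(Path(header_json).read_text())
        means = df["mean"].astype(float) if "mean" in df.columns else None
        return cls(
            intercept=float(meta.get("intercept", 0.0)),
            coefficients=df["coefficient"].astype(float),
            adult_age=float(meta.get("adult_age", 20.0)),
            imputation_means=means,
        )


@dataclass
class ClockResult:
    dnam_ages: pd.Series
    spearman_rho: float
    spearman_p: float
    acceleration: pd.Series
    group_difference: float
    group_p: float


def estimate_neuronal_proportion(x: pd.Series, refs: ReferenceProfiles) -> float:
    """Least-squares neuron mixing weight of a bulk profile, clamped to [0,1].

    Solves min_p || x - p*mu_neuron - (1-p)*mu_glia ||^2 in closed form:
    p = <x - mu_g, mu_n - mu_g> / ||mu_n - mu_g||^2.
    """
    probes = refs.neuron.index.intersection(x.index)
    if len(probes) < 2:
        raise ValueError("need >= 2 reference probes present in the sample")
    mu_n = refs.neuron.loc[probes].to_numpy(dtype=float)
    mu_g = refs.glia.loc[probes].to_numpy(dtype=float)
    d = mu_n - mu_g
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("reference profiles identical; proportion unidentifiable")
    p = float((x.loc[probes].to_numpy(dtype=float) - mu_g) @ d / denom)
    return min(1.0, max(0.0, p))


def estimate_neuronal_proportions(beta_values: pd.DataFrame, refs: ReferenceProfiles) -> pd.Series:
    """Per-sample neuronal proportions for a probes x samples table."""
    return pd.Series(
        {
            s: estimate_neuronal_proportion(beta_values[s], refs)
            for s in beta_values.columns
        },
        name="neuronal_prop",
    )


def age_transform(age: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Forward clock transform: chronological age -> linear-predictor scale."""
    age = np.asarray(age, dtype=float)
    return np.where(
        age <= adult_age,
        np.log(age + 1) - np.log(adult_age + 1),
        (age - adult_age) / (adult_age + 1),
    )


def _inverse_age_transform(L: np.ndarray, adult_age: float) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    return np.where(
        L <= 0,
        (1 + adult_age) * np.exp(L) - 1,
        (1 + adult_age) * L + adult_age,
    )


def dnam_age(betas: pd.Series, clock: ClockModel) -> float:
    """Methylation-predicted age of one sample from clock coefficients."""
    probes = clock.coefficients.index
    present = probes.isin(betas.index)
    x = pd.Series(index=probes, dtype=float)
    x[probes[present]] = betas.loc[probes[present]].astype(float)
    if (~present).any():
        if clock.imputation_means is None:
            missing = probes[~present].tolist()
            raise ValueError(f"clock probes missing without imputation means: {missing[:10]}")
        x[probes[~present]] = clock.imputation_means.loc[probes[~present]]
    L = clock.intercept + float(clock.coefficients @ x)
    return float(_inverse_age_transform(np.array(L), clock.adult_age))


def age_acceleration_test(
    dnam_ages: pd.Series,
    chronological: pd.Series,
    diagnosis: pd.Series,
    method: str = "residual",
) -> ClockResult:
    """Test for differential epigenetic aging between cases and controls.

    Acceleration is the residual of methylation age regressed on
    chronological age (``method='residual'``, default) or the raw
    difference (``method='difference'``); the group contrast is a
    two-sided two-sample t-test.
    """
    idx = dnam_ages.index
    chron = chronological.loc[idx].to_numpy(dtype=float)
    dn = dnam_ages.to_numpy(dtype=float)
    diag = diagnosis.loc[idx]
    for g in ("case", "control"):
        if (diag == g).sum() < 3:
            raise ValueError(f"need >= 3 samples in group {g!r}")
    if np.ptp(chron) == 0 or np.ptp(dn) == 0:
        warnings.warn("constant ages: Spearman correlation undefined")
        rho, rho_p = np.nan, np.nan
    else:
        rho, rho_p = stats.spearmanr(dn, chron)
    if method == "residual":
        slope, intercept = np.polyfit(chron, dn, 1)
        accel = dn - (slope * chron + intercept)
    elif method == "difference":
        accel = dn - chron
    else:
        raise ValueError(f"unknown acceleration method {method!r}")
    a_case = accel[(diag == "case").to_numpy()]
    a_ctl = accel[(diag == "control").to_numpy()]
    if np.allclose(accel, accel[0]):
        diff, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a_case, a_ctl, equal_var=False)
        diff = float(a_case.mean() - a_ctl.mean())
    return ClockResult(
        dnam_ages=dnam_ages,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        acceleration=pd.Series(accel, index=idx, name="acceleration"),
        group_difference=diff,
        group_p=float(p),
    )


def compute_pcs(beta_values: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal component scores of samples over probes.

    The probes x samples table is centered per probe; scores are the
    right singular vectors scaled by singular values.  Sign convention:
    the largest-magnitude loading of each component is positive, so
    results are deterministic across runs and orderings.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n_probes, n_samples = beta_values.shape
    if k >= min(n_probes, n_samples):
        raise ValueError(f"k={k} must be < min(probes, samples)={min(n_probes, n_samples)}")
    X = beta_values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(k):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    scores = (Vt[:k].T * s[:k])
    return pd.DataFrame(
        scores, index=beta_values.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
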