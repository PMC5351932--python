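"""Sample/probe quality control and between-sample normalization.

The filter rules mirror a wateRmelon-style ``pfilter`` at the beta level:
samples failing detection in more than 1% of probes are removed; probes
failing detection in at least 1% of samples, or with low beadcount in 5%
of samples, are removed; flagged probe classes (SNP control probes, sex
chromosomes, cross-hybridizing, SNP-proximal) are excluded.  Boundary
semantics are exactly as stated: "more than" is strict, "at least" is
inclusive.

True dasen normalization operates on raw type-I/type-II intensities;
intensities are outside this pipeline's data level, so the stand-in is
between-sample quantile normalization stratified by probe design type,
which preserves dasen's essential contract (type-stratified distribution
alignment across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .types import BetaMatrix, MalformedInputError, ProbeManifest, SampleSheet

__all__ = [
    "QcReport",
    "filter_samples_by_detection",
    "filter_probes",
    "exclude_flagged_probes",
    "quantile_normalize_by_type",
    "check_sex",
    "run_qc",
]


@dataclass
class QcReport:
    removed_samples: Dict[str, str] = field(default_factory=dict)
    removed_probes: Dict[str, str] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "removed_probes": self.removed_probes,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_probes_before": self.n_probes_before,
            "n_probes_after": self.n_probes_after,
        }


def filter_samples_by_detection(
    beta: BetaMatrix, p_cut: float = 0.01, max_failed_fraction: float = 0.01
) -> Tuple[pd.Index, QcReport]:
    """Retain samples whose fraction of failed probes is <= the cut.

    A sample is removed iff the fraction of probes with detection
    p > ``p_cut`` strictly exceeds ``max_failed_fraction``.
    """
    if beta.detection_p is None:
        raise MalformedInputError("detection-p layer required for sample filtering")
    frac = (beta.detection_p.to_numpy() > p_cut).mean(axis=0)
    removed = beta.sample_ids[frac > max_failed_fraction]
    retained = beta.sample_ids.difference(removed, sort=False)
    report = QcReport(
        removed_samples={
            s: f"detection p > {p_cut} in {f:.2%} of probes"
            for s, f in zip(beta.sample_ids, frac)
            if s in set(removed)
        },
        n_samples_before=len(beta.sample_ids),
        n_samples_after=len(retained),
        n_probes_before=len(beta.probe_ids),
        n_probes_after=len(beta.probe_ids),
    )
    return retained, report


def filter_probes(
    beta: BetaMatrix,
    det_cut: float = 0.05,
    det_fraction: float = 0.01,
    bead_cut: int = 3,
    bead_fraction: float = 0.05,
) -> Tuple[pd.Index, QcReport]:
    """Retain probes passing detection and beadcount criteria.

    A probe is removed iff detection p > ``det_cut`` in at least
    ``det_fraction`` of samples (inclusive), OR beadcount < ``bead_cut``
    in ``bead_fraction`` of samples (inclusive).
    """
    if beta.detection_p is None:
        raise MalformedInputError("detection-p layer required for probe filtering")
    det_frac = (beta.detection_p.to_numpy() > det_cut).mean(axis=1)
    fail_det = det_frac >= det_fraction
    if beta.beadcount is not None:
        bead_frac = (beta.beadcount.to_numpy() < bead_cut).mean(axis=1)
        fail_bead = bead_frac >= bead_fraction
    else:
        fail_bead = np.zeros(len(beta.probe_ids), dtype=bool)
    fail = fail_det | fail_bead
    removed_probes = {}
    for i in np.flatnonzero(fail):
        reasons = []
        if fail_det[i]:
            reasons.append(f"detection p > {det_cut} in {det_frac[i]:.2%} of samples")
        if fail_bead[i]:
            reasons.append(f"beadcount < {bead_cut} in {bead_fraction:.0%}+ of samples")
        removed_probes[beta.probe_ids[i]] = "; ".join(reasons)
    retained = beta.probe_ids[~fail]
    report = QcReport(
        removed_probes=removed_probes,
        n_samples_before=len(beta.sample_ids),
        n_samples_after=len(beta.sample_ids),
        n_probes_before=len(beta.probe_ids),
        n_probes_after=len(retained),
    )
    return retained, report


def exclude_flagged_probes(
    manifest: ProbeManifest,
    probe_ids: Iterable[str],
    flag_classes: Iterable[str] = (
        "control_snp",
        "sex_chromosome",
        "cross_hybridizing",
        "snp_proximal",
    ),
) -> pd.Index:
    """Drop probes carrying any of the configured exclusion flags."""
    flagged = set(manifest.probes_with_flags(flag_classes))
    probe_ids = pd.Index(probe_ids)
    return probe_ids[~probe_ids.isin(flagged)]


def quantile_normalize_by_type(beta: BetaMatrix, manifest: ProbeManifest) -> BetaMatrix:
    """Between-sample quantile normalization stratified by probe type.

    Within each probe design type, every sample's values are replaced by
    the rank-matched mean-of-sorted reference distribution; ties map to
    the interpolated reference at the average rank.  Within-sample,
    within-type rank order is preserved exactly.
    """
    if beta.values.shape[1] < 2:
        raise MalformedInputError("quantile normalization needs >= 2 samples")
    values = beta.values.copy()
    ptype = manifest.table.loc[values.index, "probe_type"]
    for t in ("I", "II"):
        rows = values.index[ptype == t]
        if len(rows) < 2:
            if len(rows) > 0:
                warnings.warn(f"probe type {t} has < 2 probes; left unnormalized")
            continue
        block = values.loc[rows].to_numpy(dtype=float)
        n = block.shape[0]
        order = np.sort(block, axis=0)
        reference = order.mean(axis=1)
        # map each value to the reference via its (average, tie-aware) rank
        from scipy.stats import rankdata

        normalized = np.empty_like(block)
        grid = np.arange(1, n + 1, dtype=float)
        for j in range(block.shape[1]):
            ranks = rankdata(block[:, j], method="average")
            normalized[:, j] = np.interp(ranks, grid, reference)
        values.loc[rows] = normalized
    return BetaMatrix(
        values=values, detection_p=beta.detection_p, beadcount=beta.beadcount
    )


def check_sex(
    beta: BetaMatrix, manifest: ProbeManifest, sheet: SampleSheet
) -> List[str]:
    """Flag samples whose predicted sex disagrees with the reported sex.

    Prediction is a 1-D two-cluster split of mean sex-chromosome
    methylation: samples are thresholded at the midpoint of the two
    group means (initialized from reported labels); the lower-methylation
    cluster is assigned the sex with the lower observed mean.  Mismatches
    are reported, never removed.
    """
    sex_probes = manifest.probes_with_flags(["sex_chromosome"])
    sex_probes = sex_probes[sex_probes.isin(beta.probe_ids)]
    if len(sex_probes) == 0:
        warnings.warn("no sex-chromosome probes present; sex check skipped")
        return []
    means = beta.values.loc[sex_probes].mean(axis=0)
    reported = sheet.table.loc[means.index, "sex"]
    mu = means.groupby(reported.to_numpy()).mean()
    if len(mu) < 2 or np.isclose(mu.max(), mu.min()):
        warnings.warn("sex-chromosome methylation not separable; sex check skipped")
        return []
    threshold = (mu.iloc[0] + mu.iloc[1]) / 2
    low_sex = mu.idxmin()
    high_sex = mu.idxmax()
    predicted = np.where(means < threshold, low_sex, high_sex)
    return list(means.index[predicted != reported.to_numpy()])


def run_qc(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    config=None,
) -> Tuple[BetaMatrix, SampleSheet, QcReport]:
    """Full QC chain: sample filter, probe filters, flag exclusion, normalization."""
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    report = QcReport(
        n_samples_before=len(beta.sample_ids), n_probes_before=len(beta.probe_ids)
    )
    samples, s_rep = filter_samples_by_detection(
        beta, cfg.sample_det_p, cfg.sample_det_fraction
    )
    report.removed_samples.update(s_rep.removed_samples)
    beta = beta.subset(samples=samples)
    probes, p_rep = filter_probes(
        beta, cfg.probe_det_p, cfg.probe_det_fraction, cfg.bead_cut, cfg.bead_fraction
    )
    report.removed_probes.update(p_rep.removed_probes)
    beta = beta.subset(probes=probes)
    kept = exclude_flagged_probes(manifest, beta.probe_ids)
    for p in beta.probe_ids.difference(kept):
        report.removed_probes[p] = "flagged probe class"
    beta = beta.subset(probes=kept)
    beta = quantile_normalize_by_type(beta, manifest)
    report.n_samples_after = len(beta.sample_ids)
    report.n_probes_after = len(beta.probe_ids)
    sheet = sheet.subset(beta.sample_ids)
    return beta, sheet, report
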