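"""Genotype QC, LD pruning, polygenic scoring, mQTL scan, enrichment.

The genotype filters mirror a PLINK-style protocol: sample missingness
> 5%, SNP missingness > 1%, Hardy-Weinberg exact p < 1E-3 and MAF < 5%,
applied in that order.  Hardy-Weinberg uses the exact conditional
(Levene-Haldane) test.  Polygenic scores are dosage-weighted sums over
the score file's SNPs with allele-mismatch dosages flipped.  mQTL
scanning is an additive per-pair regression of methylation on dosage
with the EWAS covariate set.  GWAS-region enrichment of differentially
methylated positions uses Fisher's exact test (two-sided,
sum-of-smaller-probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import BetaMatrix, GenotypeSet, MalformedInputError, SampleSheet, ScoreFile

__all__ = [
    "PrsResult",
    "GenotypeQcReport",
    "hwe_exact",
    "qc_genotypes",
    "ld_prune",
    "compute_prs",
    "prs_group_test",
    "mqtl_scan",
    "enrichment_fisher",
    "probes_in_regions",
]


@dataclass
class PrsResult:
    scores: pd.Series
    mode: str
    n_snps_scored: int
    n_flipped: int
    n_unmatched: int
    flagged_samples: List[str] = field(default_factory=list)


@dataclass
class GenotypeQcReport:
    removed_samples: Dict[str, str] = field(default_factory=dict)
    removed_snps: Dict[str, str] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (Levene-Haldane conditional).

    Sums, over heterozygote counts compatible with the observed allele
    margin, the conditional probabilities no larger than the observed
    configuration's.  Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-allele count by construction below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # conditional log-probability of h heterozygotes given margins
    hs = np.arange(rare % 2, rare + 1, 2)

    def logprob(h: np.ndarray) -> np.ndarray:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    lp = logprob(hs)
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hs == n_Aa)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _hard_calls(dosage: np.ndarray, call_threshold: float = 0.1) -> np.ndarray:
    """Round dosages to genotypes; values farther than the threshold from
    an integer become missing."""
    g = np.round(dosage)
    g[np.abs(dosage - g) > call_threshold] = np.nan
    g[~np.isfinite(dosage)] = np.nan
    return g


def qc_genotypes(
    genos: GenotypeSet,
    sample_miss: float = 0.05,
    snp_miss: float = 0.01,
    hwe_cut: float = 1.0e-03,
    maf_cut: float = 0.05,
    sheet: Optional[SampleSheet] = None,
) -> Tuple[GenotypeSet, GenotypeQcReport]:
    """PLINK-style genotype filters in the stated order.

    Samples with > ``sample_miss`` missing data first, then SNPs with
    > ``snp_miss`` missing values, Hardy-Weinberg exact p < ``hwe_cut``
    (on hard calls) or minor allele frequency < ``maf_cut``.  When a
    sample sheet is given, per-SNP statistics are computed on one column
    per donor (genotypes are replicated across a donor's samples and
    would otherwise distort the exact test); the filters still apply to
    every column.
    """
    report = GenotypeQcReport(
        n_samples_before=len(genos.sample_ids), n_snps_before=len(genos.snp_ids)
    )
    donor_cols = None
    if sheet is not None:
        shared = genos.sample_ids[genos.sample_ids.isin(sheet.sample_ids)]
        donor_cols = (
            sheet.table.loc[shared]
            .rename_axis("sample_id")
            .reset_index()
            .drop_duplicates("donor_id")["sample_id"]
            .tolist()
        )
    D = genos.dosage.to_numpy(dtype=float)
    miss_s = (~np.isfinite(D)).mean(axis=0)
    bad_samples = miss_s > sample_miss
    for s, m in zip(genos.sample_ids[bad_samples], miss_s[bad_samples]):
        report.removed_samples[s] = f"missingness {m:.2%}"
    genos = genos.subset(samples=genos.sample_ids[~bad_samples])

    if donor_cols is not None:
        donor_cols = [c for c in donor_cols if c in set(genos.sample_ids)]
        D = genos.dosage.loc[:, donor_cols].to_numpy(dtype=float)
    else:
        D = genos.dosage.to_numpy(dtype=float)
    miss = (~np.isfinite(D)).mean(axis=1)
    keep = np.ones(len(genos.snp_ids), dtype=bool)
    for i in np.flatnonzero(miss > snp_miss):
        keep[i] = False
        report.removed_snps[genos.snp_ids[i]] = f"missingness {miss[i]:.2%}"

    calls = _hard_calls(D)
    for i in np.flatnonzero(keep):
        g = calls[i][np.isfinite(calls[i])]
        n_aa = int((g == 0).sum())  # effect-allele dosage 0
        n_Aa = int((g == 1).sum())
        n_AA = int((g == 2).sum())
        total = n_aa + n_Aa + n_AA
        if total == 0:
            keep[i] = False
            report.removed_snps[genos.snp_ids[i]] = "no callable genotypes"
            continue
        p_hwe = hwe_exact(n_AA, n_Aa, n_aa)
        if p_hwe < hwe_cut:
            keep[i] = False
            report.removed_snps[genos.snp_ids[i]] = f"HWE p {p_hwe:.2e}"
            continue
        af = (2 * n_AA + n_Aa) / (2 * total)
        maf = min(af, 1 - af)
        if maf < maf_cut:
            keep[i] = False
            report.removed_snps[genos.snp_ids[i]] = f"MAF {maf:.3f}"
    if not keep.any():
        raise MalformedInputError("all SNPs removed by genotype QC")
    genos = genos.subset(snps=genos.snp_ids[keep])
    report.n_samples_after = len(genos.sample_ids)
    report.n_snps_after = len(genos.snp_ids)
    return genos, report


def ld_prune(
    genos: GenotypeSet, window_bp: int = 1500, r2_cut: float = 0.20
) -> pd.Index:
    """Greedy positional LD pruning: drop the later SNP of any pair
    within ``window_bp`` whose dosage r^2 exceeds the cut."""
    smap = genos.snp_map.sort_values(["chrom", "pos"], kind="stable")
    D = genos.dosage.loc[smap.index].to_numpy(dtype=float)
    pos = smap["pos"].to_numpy()
    chrom = smap["chrom"].to_numpy()
    n = len(smap)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        j = i + 1
        while j < n and chrom[j] == chrom[i] and pos[j] - pos[i] <= window_bp:
            if keep[j]:
                a, b = D[i], D[j]
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                    r = np.corrcoef(a[ok], b[ok])[0, 1]
                    if r * r > r2_cut:
                        keep[j] = False
            j += 1
    retained = smap.index[keep]
    return genos.snp_ids[genos.snp_ids.isin(retained)]


def compute_prs(
    genos: GenotypeSet, score: ScoreFile, mode: str = "sum"
) -> PrsResult:
    """Dosage-weighted polygenic score per sample.

    Score SNPs are matched by id; when the score file's effect allele is
    the map's other allele the dosage is flipped (2 - d); unmatched SNPs
    are skipped with a count.  ``mode='sum'`` gives the weighted dosage
    sum; ``mode='mean'`` divides by the per-sample count of non-missing
    scored SNPs.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    matched = score.snp_ids.intersection(genos.snp_ids)
    n_unmatched = len(score.snp_ids) - len(matched)
    if len(matched) == 0:
        raise MalformedInputError("no score SNPs present in the genotype set")
    D = genos.dosage.loc[matched].to_numpy(dtype=float)
    eff_score = score.table.loc[matched, "effect_allele"].to_numpy()
    eff_map = genos.snp_map.loc[matched, "effect_allele"].to_numpy()
    oth_map = genos.snp_map.loc[matched, "other_allele"].to_numpy()
    flip = eff_score == oth_map
    bad = ~flip & (eff_score != eff_map)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} score SNPs with alleles matching neither map allele; skipped"
        )
        keep = ~bad
        D, flip = D[keep], flip[keep]
        matched = matched[keep]
    D = np.where(flip[:, None], 2.0 - D, D)
    w = score.table.loc[matched, "weight"].to_numpy(dtype=float)
    contrib = D * w[:, None]
    finite = np.isfinite(contrib)
    totals = np.where(finite, contrib, 0.0).sum(axis=0)
    counts = finite.sum(axis=0)
    flagged = [s for s, c in zip(genos.sample_ids, counts) if c == 0]
    if mode == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            totals = np.where(counts > 0, totals / counts, np.nan)
    else:
        totals = np.where(counts > 0, totals, np.nan)
    return PrsResult(
        scores=pd.Series(totals, index=genos.sample_ids, name="prs"),
        mode=mode,
        n_snps_scored=len(matched),
        n_flipped=int(flip.sum()),
        n_unmatched=n_unmatched,
        flagged_samples=flagged,
    )


def prs_group_test(scores: pd.Series, diagnosis: pd.Series) -> dict:
    """Two-sided two-sample t-test of polygenic scores, cases vs controls."""
    diag = diagnosis.loc[scores.index]
    case = scores[(diag == "case").to_numpy()].dropna()
    ctl = scores[(diag == "control").to_numpy()].dropna()
    if len(case) < 2 or len(ctl) < 2:
        raise ValueError("need >= 2 scored samples per group")
    if scores.dropna().nunique() == 1:
        return {"case_mean": float(case.mean()), "control_mean": float(ctl.mean()),
                "t": 0.0, "p": 1.0, "status": "degenerate"}
    t, p = stats.ttest_ind(case, ctl, equal_var=False)
    return {
        "case_mean": float(case.mean()),
        "control_mean": float(ctl.mean()),
        "t": float(t),
        "p": float(p),
        "n_case": int(len(case)),
        "n_control": int(len(ctl)),
        "status": "ok",
    }


def mqtl_scan(
    beta: BetaMatrix,
    genos: GenotypeSet,
    sheet: SampleSheet,
    covariates: Sequence[str] = ("age", "sex", "neuronal_prop"),
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    threshold: float = 3.69e-13,
    relaxed: float = 1.0e-10,
) -> pd.DataFrame:
    """Additive methylation-QTL scan.

    For each (SNP, probe) pair, methylation is regressed on the dosage
    plus covariates; the per-allele effect is reported in percentage
    points.  Pairs below ``threshold`` are marked significant, pairs
    below ``relaxed`` are marked separately.  By default all SNP x probe
    pairs are scanned.
    """
    from .ewas import _ols_exposure

    samples = beta.sample_ids.intersection(genos.sample_ids)
    if len(samples) < 10:
        raise MalformedInputError("need >= 10 samples shared by betas and genotypes")
    sub_sheet = sheet.table.loc[samples]
    cov_cols = [np.ones(len(samples))]
    for c in covariates:
        if c == "sex":
            cov_cols.append((sub_sheet["sex"] == "M").to_numpy(dtype=float))
        elif c in sub_sheet.columns:
            col = pd.to_numeric(sub_sheet[c], errors="coerce").to_numpy(dtype=float)
            if np.isfinite(col).all():
                cov_cols.append(col)
    C = np.column_stack(cov_cols)
    Y_all = beta.values.loc[:, samples].to_numpy(dtype=float)
    probe_index = {p: i for i, p in enumerate(beta.probe_ids)}
    snp_list = (
        pd.unique([s for s, _ in pairs]) if pairs is not None else genos.snp_ids
    )
    pair_map: Optional[Dict[str, List[str]]] = None
    if pairs is not None:
        pair_map = {}
        for s, p in pairs:
            pair_map.setdefault(s, []).append(p)
    rows = []
    for snp in snp_list:
        dos = genos.dosage.loc[snp, samples].to_numpy(dtype=float)
        ok = np.isfinite(dos)
        if np.nanstd(dos[ok]) == 0 or ok.sum() < C.shape[1] + 2:
            continue  # monomorphic or too few calls in-sample
        X = np.column_stack([C[ok, :1], dos[ok], C[ok, 1:]])
        if pair_map is not None:
            probe_rows = [probe_index[p] for p in pair_map[snp] if p in probe_index]
        else:
            probe_rows = None
        Y = Y_all[probe_rows][:, ok] if probe_rows is not None else Y_all[:, ok]
        complete = np.isfinite(Y).all(axis=1)
        if not complete.any():
            continue
        est, se, tstat, p, df = _ols_exposure(Y[complete], X, exposure_col=1)
        probe_ids = (
            np.asarray([beta.probe_ids[i] for i in probe_rows])[complete]
            if probe_rows is not None
            else beta.probe_ids.to_numpy()[complete]
        )
        hit = p < relaxed
        for j in np.flatnonzero(hit):
            rows.append(
                {
                    "snp_id": snp,
                    "probe_id": probe_ids[j],
                    "estimate": est[j] * 100.0,
                    "se": se[j] * 100.0,
                    "p": float(p[j]),
                    "significant": bool(p[j] < threshold),
                    "relaxed": True,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "probe_id", "estimate", "se", "p", "significant", "relaxed"],
    )


def probes_in_regions(manifest, regions: Sequence[Tuple[str, int, int]]) -> pd.Series:
    """Boolean per-probe membership in any of the (chrom, start, end)
    1-based inclusive intervals."""
    t = manifest.table
    member = np.zeros(len(t), dtype=bool)
    chrom = t["chrom"].to_numpy()
    pos = t["pos"].to_numpy()
    for c, start, end in regions:
        if start > end:
            raise ValueError(f"invalid interval {c}:{start}-{end}")
        member |= (chrom == c) & (pos >= start) & (pos <= end)
    return pd.Series(member, index=t.index, name="in_gwas_region")


def enrichment_fisher(
    in_region: pd.Series,
    is_dmp: pd.Series,
    bonferroni_cut: float = 1.25e-02,
) -> dict:
    """Fisher's exact test of DMP enrichment inside GWAS regions.

    Two-sided p by summing hypergeometric table probabilities no larger
    than the observed table's; the verdict compares p against the
    Bonferroni-corrected cut for the number of analyses performed.
    """
    a = int((in_region & is_dmp).sum())
    b = int((in_region & ~is_dmp).sum())
    c = int((~in_region & is_dmp).sum())
    d = int((~in_region & ~is_dmp).sum())
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    if is_dmp.sum() == 0:
        return {"odds_ratio": np.nan, "p": 1.0, "significant": False,
                "table": [[a, b], [c, d]]}
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = res.statistic if (b * c) > 0 else np.nan
    return {
        "odds_ratio": float(odds) if np.isfinite(odds) else np.nan,
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < bonferroni_cut),
        "table": [[a, b], [c, d]],
    }
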