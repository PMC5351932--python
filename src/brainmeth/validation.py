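"""Validation experiments: worked examples, calibration and recovery.

Each function re-runs a slice of the pipeline from scratch on inputs it
generates (or on the study's printed summary tables) and returns the
measured quantities.  The acceptance script and the acceptance tests
both drive these; nothing here caches or hard-codes a result.

Problem sizes: the permutation calibration uses 1,000 independent probes
x 60 samples with 500 permutations and 500 fresh replicates; recovery
experiments use 2,000-probe, 40-per-group datasets over 20 seeds; null
calibration uses 10,000 probes for the uniformity check and 20,000
probes x 10 seeds for the inflation factor; the end-to-end smoke runs a
20,000-probe, ~160-sample, two-cohort, four-region bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import call_dmrs, sidak_correct, stouffer_liptak
from .ewas import ModelSpec, _ols_exposure, build_design, genomic_inflation, run_ewas
from .fwer import fwer_threshold
from .genetics import enrichment_fisher, hwe_exact, mqtl_scan
from .meta import CohortEstimate, meta_fixed, welch_from_summary
from .simulate import (
    DmpEffect,
    DmrEffect,
    EffectSpec,
    MqtlEffect,
    make_design,
    make_manifest,
    simulate_beta,
    simulate_genotypes,
)
from .studydata import cohort_age_summaries

__all__ = [
    "welch_age_pvalues",
    "closed_form_errors",
    "fwer_calibration",
    "recovery_rates",
    "null_calibration",
    "pipeline_determinism",
]

_SINGLE_REGION = dict(
    regions=("PFC",), region_availability={"PFC": 1.0}, restricted_regions={}
)


def welch_age_pvalues() -> Dict[str, float]:
    """Welch tests of age-at-death recomputed from the printed summaries.

    Values are rounded to the two decimals the study table prints.
    """
    out = {}
    table = cohort_age_summaries()
    for (cohort, region), sub in table.groupby(["cohort", "region"], sort=False):
        case = sub[sub.group == "case"].iloc[0]
        ctl = sub[sub.group == "control"].iloc[0]
        res = welch_from_summary(
            case.age_mean, case.age_sd, int(case.n),
            ctl.age_mean, ctl.age_sd, int(ctl.n),
        )
        out[f"welch_age_p_{cohort.lower()}_{region.lower()}"] = round(res["p"], 2)
    return out


def closed_form_errors(seed: int = 0) -> Dict[str, float]:
    """Worst-case disagreement of each statistic with its independent oracle."""
    rng = np.random.default_rng(seed)

    meta_err = 0.0
    for _ in range(200):
        k = int(rng.integers(1, 6))
        est = rng.normal(0, 1, k)
        se = rng.uniform(0.05, 0.5, k)
        res = meta_fixed([CohortEstimate(str(i), est[i], se[i]) for i in range(k)])
        w = 1 / se**2
        meta_err = max(
            meta_err,
            abs(res.estimate - np.sum(w * est) / np.sum(w)),
            abs(res.se - np.sum(w) ** -0.5),
        )

    sl_single = max(
        abs(stouffer_liptak([p], np.ones((1, 1))) - p)
        for p in rng.uniform(0.001, 0.999, 50)
    )
    sl_perfect = max(
        abs(stouffer_liptak([p, p, p], np.ones((3, 3))) - p)
        for p in rng.uniform(0.001, 0.999, 50)
    )
    sidak_identity = max(
        abs(sidak_correct(p, 9, 9) - p) for p in rng.uniform(0.0, 1.0, 50)
    )

    fisher_err = 0.0
    for _ in range(100):
        total = int(rng.integers(8, 200))
        row1 = int(rng.integers(1, total))
        col1 = int(rng.integers(1, total))
        a_max = min(row1, col1)
        a_min = max(0, row1 + col1 - total)
        a = int(rng.integers(a_min, a_max + 1))
        table = [[a, row1 - a], [col1 - a, total - row1 - col1 + a]]
        in_region = pd.Series([True] * row1 + [False] * (total - row1))
        is_dmp = pd.Series(
            [True] * a + [False] * (row1 - a)
            + [True] * (col1 - a) + [False] * (total - row1 - col1 + a)
        )
        res = enrichment_fisher(in_region, is_dmp)
        pmf = stats.hypergeom.pmf(
            np.arange(a_min, a_max + 1), total, row1, col1
        )
        obs = stats.hypergeom.pmf(a, total, row1, col1)
        oracle = min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum())
        fisher_err = max(fisher_err, abs(res["p"] - oracle))

    from scipy.special import gammaln

    hwe_err = 0.0
    for _ in range(100):
        n = int(rng.integers(2, 200))
        n_AA = int(rng.integers(0, n + 1))
        n_Aa = int(rng.integers(0, n - n_AA + 1))
        n_aa = n - n_AA - n_Aa
        rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
        if rare == 0:
            oracle = 1.0
        else:
            hs = np.arange(rare % 2, rare + 1, 2)
            hom_r = (rare - hs) // 2
            hom_c = n - hs - hom_r
            lp = (
                gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hs + 1)
                - gammaln(hom_c + 1) + hs * np.log(2.0)
            )
            probs = np.exp(lp - lp.max())
            probs /= probs.sum()
            obs = probs[list(hs).index(n_Aa)]
            oracle = float(probs[probs <= obs * (1 + 1e-12)].sum())
        hwe_err = max(hwe_err, abs(hwe_exact(n_AA, n_Aa, n_aa) - min(1.0, oracle)))

    return {
        "meta_fixed_max_abs_err": float(meta_err),
        "stouffer_liptak_identity_max_abs_err": float(max(sl_single, sl_perfect)),
        "sidak_identity_max_abs_err": float(sidak_identity),
        "fisher_exact_max_abs_err": float(fisher_err),
        "hwe_exact_max_abs_err": float(hwe_err),
    }


def fwer_calibration(
    seed: int = 0,
    n_probes: int = 1000,
    n_donors: int = 60,
    n_perm: int = 500,
    n_seeds: int = 10,
    n_replicates: int = 500,
) -> Dict[str, float]:
    """Permutation threshold vs the analytic minimum-of-uniforms quantile.

    Independent null probes: the alpha = 0.05 quantile of the minimum of
    m uniforms is 1 - 0.95^(1/m).  Fresh-data family-wise error at the
    mean permutation threshold is measured on new null datasets.
    """
    rng = np.random.default_rng(seed)
    manifest = make_manifest(n_probes, n_chroms=1, mean_gap_bp=100_000, seed=int(rng.integers(2**31)))
    sheet = make_design(n_donors=n_donors, case_fraction=0.5, seed=int(rng.integers(2**31)), **_SINGLE_REGION)
    spec = ModelSpec(covariates=("age", "sex"))
    analytic = 1 - 0.95 ** (1 / n_probes)

    thresholds = []
    for _ in range(n_seeds):
        beta, _ = simulate_beta(
            manifest, sheet, EffectSpec(), phi_bp=0.0, seed=int(rng.integers(2**31))
        )
        res = fwer_threshold(beta, sheet, spec, n_perm=n_perm, seed=int(rng.integers(2**31)))
        thresholds.append(res.threshold)
    threshold_mean = float(np.mean(thresholds))

    X, samples, _ = build_design(sheet, spec)
    hits = 0
    for _ in range(n_replicates):
        beta, _ = simulate_beta(
            manifest, sheet, EffectSpec(), phi_bp=0.0, seed=int(rng.integers(2**31))
        )
        Y = beta.values.loc[:, samples].to_numpy(dtype=float)
        _, _, _, p, _ = _ols_exposure(Y, X)
        hits += p.min() < threshold_mean
    return {
        "fwer_perm_threshold_mean": threshold_mean,
        "fwer_analytic_threshold": float(analytic),
        "fwer_empirical_pct": 100.0 * hits / n_replicates,
    }


def _spiked_instance(seed: int):
    manifest = make_manifest(2000, n_chroms=4, mean_gap_bp=300, seed=seed)
    sheet = make_design(n_donors=80, case_fraction=0.5, seed=seed, **_SINGLE_REGION)
    t = manifest.sorted_by_position().table
    sub = t[t["chrom"] == "chr2"]
    pos = sub["pos"].to_numpy()
    start_i = next(
        i for i in range(len(sub) - 5) if np.all(np.diff(pos[i : i + 5]) <= 300)
    )
    dmr = DmrEffect("chr2", int(pos[start_i]), int(pos[start_i + 4]), 0.05)
    dmp_probe = t.index[100]
    effects = EffectSpec(dmp_effects=[DmpEffect(dmp_probe, 0.05)], dmr_effects=[dmr])
    return manifest, sheet, effects, dmp_probe, dmr


def recovery_rates(seed: int = 0, n_seeds: int = 20, n_null_seeds: int = 150) -> Dict[str, float]:
    """Spike recovery (DMP rank, DMR detection, mQTL detection) and the
    null region false-call rate."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(covariates=("age", "sex"))

    dmp_hits = dmr_hits = 0
    for i in range(n_seeds):
        s = int(rng.integers(2**31))
        manifest, sheet, effects, dmp_probe, dmr = _spiked_instance(s % 100000)
        beta, _ = simulate_beta(manifest, sheet, effects, seed=s)
        assoc = run_ewas(beta, sheet, spec)
        dmp_hits += assoc["p"].rank(method="min").loc[dmp_probe] <= 10
        regions = call_dmrs(assoc, manifest)
        dmr_hits += bool(
            (
                (regions["chrom"] == dmr.chrom)
                & (regions["start"] <= dmr.end)
                & (regions["end"] >= dmr.start)
                & (regions["p_sidak"] < 0.05)
            ).any()
        )

    null_candidates = null_sig = 0
    for i in range(n_null_seeds):
        s = int(rng.integers(2**31))
        manifest = make_manifest(2000, n_chroms=4, mean_gap_bp=300, seed=s % 100000)
        sheet = make_design(n_donors=80, case_fraction=0.5, seed=s % 99991, **_SINGLE_REGION)
        beta, _ = simulate_beta(manifest, sheet, EffectSpec(), phi_bp=0.0, seed=s)
        assoc = run_ewas(beta, sheet, spec)
        regions = call_dmrs(assoc, manifest)
        null_candidates += len(regions)
        null_sig += int((regions["p_sidak"] < 0.05).sum())

    mqtl_hits = 0
    for i in range(n_seeds):
        s = int(rng.integers(2**31))
        manifest = make_manifest(300, n_chroms=2, seed=s % 100000)
        sheet = make_design(n_donors=70, seed=s % 99991, **_SINGLE_REGION)
        probe = manifest.probe_ids[10]
        effects = EffectSpec(mqtl_effects=[MqtlEffect("rs000001", probe, 0.05)])
        genos = simulate_genotypes(
            sheet, n_snps=20, maf_range=(0.3, 0.3), effects=effects, seed=s % 99989
        )
        beta, _ = simulate_beta(manifest, sheet, effects, genotypes=genos, seed=s)
        hits = mqtl_scan(beta, genos, sheet, covariates=("age", "sex"))
        mqtl_hits += bool(
            ((hits["snp_id"] == "rs000001") & (hits["probe_id"] == probe)).any()
        )

    return {
        "dmp_top10_recovery_rate": dmp_hits / n_seeds,
        "dmr_detection_rate": dmr_hits / n_seeds,
        "dmr_null_false_call_rate": (
            null_sig / null_candidates if null_candidates else 0.0
        ),
        "dmr_null_candidate_regions": float(null_candidates),
        "dmr_null_sig_per_seed": null_sig / n_null_seeds,
        "mqtl_detection_rate": mqtl_hits / n_seeds,
    }


def null_calibration(
    seed: int = 0, n_ks_seeds: int = 5, n_lambda_seeds: int = 10
) -> Dict[str, float]:
    """Uniformity of null EWAS p-values and the inflation factor lambda.

    The uniformity statistic is the median KS p over ``n_ks_seeds``
    independent null datasets: a single KS draw is itself uniform under
    the null, so the median is the stable summary of calibration.
    """
    rng = np.random.default_rng(seed)
    spec = ModelSpec(covariates=("age", "sex"))

    manifest = make_manifest(10000, n_chroms=4, seed=int(rng.integers(100000)))
    sheet = make_design(n_donors=88, seed=int(rng.integers(100000)), **_SINGLE_REGION)
    ks_ps = []
    for _ in range(n_ks_seeds):
        beta, _ = simulate_beta(
            manifest, sheet, EffectSpec(), seed=int(rng.integers(2**31))
        )
        assoc = run_ewas(beta, sheet, spec)
        ks_ps.append(stats.kstest(assoc["p"].dropna().to_numpy(), "uniform").pvalue)
    ks_p = float(np.median(ks_ps))

    lams = []
    manifest20 = make_manifest(20000, n_chroms=4, seed=int(rng.integers(100000)))
    for _ in range(n_lambda_seeds):
        beta, _ = simulate_beta(
            manifest20, sheet, EffectSpec(), seed=int(rng.integers(2**31))
        )
        assoc = run_ewas(beta, sheet, spec)
        lams.append(genomic_inflation(assoc["p"].dropna()).lambda_)
    return {
        "ewas_null_ks_p": float(ks_p),
        "lambda_null_mean": float(np.mean(lams)),
        "lambda_null_min": float(np.min(lams)),
        "lambda_null_max": float(np.max(lams)),
    }


def _hash_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def pipeline_determinism(work_dir, seed: int = 0) -> Dict[str, float]:
    """Run the full CLI chain twice at one seed and compare output hashes.

    simulate -> qc -> ewas (per cohort) -> meta -> dmr -> fwer -> prs ->
    mqtl -> enrich on a 20,000-probe, ~160-sample two-cohort bundle.
    """
    from click.testing import CliRunner

    from .cli import main as cli_main

    work_dir = Path(work_dir)
    runner = CliRunner()
    summaries = {}
    hashes = []
    for run in ("run1", "run2"):
        root = work_dir / run
        bundle = root / "bundle"
        qc_dir = root / "qc"

        def ok(args):
            res = runner.invoke(cli_main, args, catch_exceptions=False)
            if res.exit_code != 0:
                raise RuntimeError(f"CLI failed: {args}\n{res.output}")

        ok(["simulate", "--out", str(bundle), "--n-probes", "20000",
            "--n-donors", "54", "--n-snps", "200", "--seed", str(seed)])
        ok(["qc", "--in", str(bundle), "--out", str(qc_dir)])
        for cohort in ("LNDBB", "DBCBB"):
            ok(["ewas", "--beta", str(qc_dir / "beta_norm.tsv"),
                "--samples", str(qc_dir / "samples.csv"),
                "--out", str(root / f"assoc_{cohort}.tsv"),
                "--region", "PFC", "--cohort", cohort])
        ok(["meta", "--inputs", str(root / "assoc_LNDBB.tsv"),
            "--inputs", str(root / "assoc_DBCBB.tsv"),
            "--out", str(root / "meta.tsv")])
        ok(["dmr", "--assoc", str(root / "assoc_LNDBB.tsv"),
            "--manifest", str(bundle / "manifest.tsv"),
            "--out", str(root / "regions.tsv")])
        ok(["fwer", "--beta", str(qc_dir / "beta_norm.tsv"),
            "--samples", str(qc_dir / "samples.csv"),
            "--out", str(root / "fwer.json"), "--n-perm", "100",
            "--seed", str(seed)])
        ok(["prs", "--dosages", str(bundle / "dosages.tsv"),
            "--score", str(bundle / "score.txt"),
            "--samples", str(bundle / "samples.csv"),
            "--out", str(root / "prs.tsv")])
        ok(["mqtl", "--beta", str(qc_dir / "beta_norm.tsv"),
            "--dosages", str(bundle / "dosages.tsv"),
            "--samples", str(qc_dir / "samples.csv"),
            "--out", str(root / "mqtl.tsv")])
        manifest_df = pd.read_csv(bundle / "manifest.tsv", sep="\t")
        chr1 = manifest_df[manifest_df.chrom == "chr1"]
        bed = root / "gwas_regions.bed"
        lines = []
        for k in range(0, min(len(chr1), 500), 100):
            start = int(chr1.iloc[k]["pos"])
            lines.append(f"chr1\t{start}\t{start + 5000}")
        bed.write_text("\n".join(lines) + "\n")
        ok(["enrich", "--assoc", str(root / "assoc_LNDBB.tsv"),
            "--manifest", str(bundle / "manifest.tsv"),
            "--regions", str(bed), "--out", str(root / "enrich.json")])
        hashes.append(_hash_dir(root))
        if run == "run1":
            regions = pd.read_csv(root / "regions.tsv", sep="\t")
            fwer = json.loads((root / "fwer.json").read_text())
            mqtl = pd.read_csv(root / "mqtl.tsv", sep="\t")
            summaries = {
                "pipeline_n_candidate_regions": float(len(regions)),
                "pipeline_fwer_threshold": float(fwer["threshold"]),
                "pipeline_n_mqtl_pairs": float(len(mqtl)),
            }
    return {"pipeline_deterministic": float(hashes[0] == hashes[1]), **summaries}
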