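"""Genotype QC, exact tests, polygenic scoring and mQTL scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from brainmeth.genetics import (
    compute_prs,
    enrichment_fisher,
    hwe_exact,
    ld_prune,
    mqtl_scan,
    probes_in_regions,
    prs_group_test,
    qc_genotypes,
)
from brainmeth.simulate import (
    EffectSpec,
    MqtlEffect,
    PrsConstruct,
    make_design,
    make_manifest,
    simulate_beta,
    simulate_genotypes,
)
from brainmeth.types import GenotypeSet, MalformedInputError, ScoreFile


def _genotype_set(dosages, positions=None, chrom="chr1", effect=None):
    dosages = np.asarray(dosages, dtype=float)
    n_snps, n_samples = dosages.shape
    snp_ids = pd.Index([f"rs{i}" for i in range(n_snps)], name="snp_id")
    return GenotypeSet(
        dosage=pd.DataFrame(
            dosages, index=snp_ids, columns=[f"s{j}" for j in range(n_samples)]
        ),
        snp_map=pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions if positions is not None else np.arange(n_snps) * 10_000,
                "effect_allele": effect if effect is not None else ["A"] * n_snps,
                "other_allele": "C",
            },
            index=snp_ids,
        ),
    )


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Full enumeration of the Levene-Haldane conditional distribution."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n_AA + n_Aa
    rare = min(na, nA)

    def logp(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(h + 1) - gammaln(hom_c + 1)
            + h * np.log(2.0) + gammaln(rare + 1) + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hs = np.arange(rare % 2, rare + 1, 2)
    probs = np.exp([logp(h) for h in hs])
    probs = probs / probs.sum()
    obs = probs[list(hs).index(n_Aa)]
    return probs[probs <= obs * (1 + 1e-12)].sum()


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact(50, 0, 0) == 1.0

    def test_tiny_enumeration_example(self):
        # margins allow h in {0, 2} with probabilities 1/3, 2/3
        assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_balanced_sample_is_modal(self):
        assert hwe_exact(25, 50, 25) == pytest.approx(1.0)

    def test_matches_full_enumeration_up_to_200(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(2, 200))
            n_AA = int(rng.integers(0, n + 1))
            n_Aa = int(rng.integers(0, n - n_AA + 1))
            n_aa = n - n_AA - n_Aa
            assert hwe_exact(n_AA, n_Aa, n_aa) == pytest.approx(
                _hwe_oracle(n_AA, n_Aa, n_aa), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)


class TestQcGenotypes:
    def test_clean_set_untouched(self):
        sheet = make_design(n_donors=200, seed=1)
        genos = simulate_genotypes(sheet, n_snps=30, maf_range=(0.3, 0.3), seed=2)
        # statistics on one column per donor: genotypes repeat across regions
        out, rep = qc_genotypes(genos, sheet=sheet)
        assert len(out.snp_ids) == 30 and not rep.removed_samples

    def test_low_maf_snp_removed(self):
        rng = np.random.default_rng(3)
        D = rng.binomial(2, 0.3, size=(3, 200)).astype(float)
        D[1] = rng.binomial(2, 0.02, size=200)  # MAF ~2% < 5%
        out, rep = qc_genotypes(_genotype_set(D))
        assert "rs1" in rep.removed_snps and "rs1" not in out.snp_ids

    def test_hwe_violating_snp_removed(self):
        D = np.full((2, 200), 1.0)  # all heterozygous: extreme HWE violation
        rng = np.random.default_rng(4)
        D[0] = rng.binomial(2, 0.4, size=200)
        out, rep = qc_genotypes(_genotype_set(D))
        assert "rs1" in rep.removed_snps

    def test_removals_match_brute_force(self):
        rng = np.random.default_rng(5)
        D = rng.binomial(2, rng.uniform(0.02, 0.5, size=(20, 1)), size=(20, 120)).astype(float)
        mask = rng.random(D.shape) < 0.02
        D[mask] = np.nan
        genos = _genotype_set(D)
        out, rep = qc_genotypes(genos)
        # brute-force re-evaluation of the stated rules, in order
        miss_s = np.mean(~np.isfinite(D), axis=0)
        keep_samples = miss_s <= 0.05
        D2 = D[:, keep_samples]
        expected = []
        for i in range(20):
            row = D2[i]
            if np.mean(~np.isfinite(row)) > 0.01:
                continue
            g = row[np.isfinite(row)]
            counts = [(g == 2).sum(), (g == 1).sum(), (g == 0).sum()]
            if hwe_exact(*counts) < 1e-3:
                continue
            af = (2 * counts[0] + counts[1]) / (2 * sum(counts))
            if min(af, 1 - af) < 0.05:
                continue
            expected.append(f"rs{i}")
        assert list(out.snp_ids) == expected


class TestLdPrune:
    def test_duplicated_snp_one_retained(self):
        rng = np.random.default_rng(6)
        row = rng.binomial(2, 0.3, 100).astype(float)
        genos = _genotype_set(np.vstack([row, row]), positions=[1000, 1100])
        kept = ld_prune(genos)
        assert len(kept) == 1

    def test_orthogonal_snps_all_retained(self):
        rng = np.random.default_rng(7)
        D = rng.binomial(2, 0.5, size=(6, 500)).astype(float)
        genos = _genotype_set(D, positions=np.arange(6) * 200)
        kept = ld_prune(genos)
        assert len(kept) == 6

    def test_postcondition_no_offending_pair_remains(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.3, size=(10, 150)).astype(float)
        # build LD blocks by jittering copies at nearby positions
        rows, pos = [], []
        for i in range(10):
            for k in range(3):
                noisy = base[i].copy()
                flip = rng.random(150) < 0.1
                noisy[flip] = rng.binomial(2, 0.3, flip.sum())
                rows.append(noisy)
                pos.append(i * 10_000 + k * 400)
        genos = _genotype_set(np.vstack(rows), positions=pos)
        kept = ld_prune(genos)
        keep_map = genos.snp_map.loc[kept]
        D = genos.dosage.loc[kept].to_numpy()
        for a, b in itertools.combinations(range(len(kept)), 2):
            same = keep_map.iloc[a]["chrom"] == keep_map.iloc[b]["chrom"]
            close = abs(keep_map.iloc[a]["pos"] - keep_map.iloc[b]["pos"]) <= 1500
            if same and close:
                r2 = np.corrcoef(D[a], D[b])[0, 1] ** 2
                assert r2 <= 0.20 + 1e-12


class TestComputePrs:
    def _score(self, weights, alleles=None, snps=None):
        snps = snps or [f"rs{i}" for i in range(len(weights))]
        return ScoreFile(
            pd.DataFrame(
                {
                    "effect_allele": alleles or ["A"] * len(weights),
                    "weight": weights,
                },
                index=pd.Index(snps, name="snp_id"),
            )
        )

    def test_zero_dosage_zero_score(self):
        genos = _genotype_set(np.zeros((2, 3)))
        res = compute_prs(genos, self._score([0.5, -0.2]))
        assert (res.scores == 0.0).all()

    def test_hand_arithmetic_sum_and_mean(self):
        genos = _genotype_set(np.array([[2.0], [1.0]]))
        score = self._score([0.5, -0.2])
        assert compute_prs(genos, score, mode="sum").scores.iloc[0] == pytest.approx(0.8)
        assert compute_prs(genos, score, mode="mean").scores.iloc[0] == pytest.approx(0.4)

    def test_allele_flip_identity(self):
        """Flipping the effect allele changes the score by w*(2 - 2d)."""
        d, w = 0.5, 0.3
        genos = _genotype_set(np.array([[d]]))
        direct = compute_prs(genos, self._score([w], alleles=["A"])).scores.iloc[0]
        flipped = compute_prs(genos, self._score([w], alleles=["C"])).scores.iloc[0]
        assert flipped - direct == pytest.approx(w * (2 - 2 * d))

    def test_invariant_to_snp_order_and_chunking(self):
        rng = np.random.default_rng(9)
        D = rng.binomial(2, 0.3, size=(10, 20)).astype(float)
        genos = _genotype_set(D)
        w = rng.normal(0, 0.1, 10)
        full = compute_prs(genos, self._score(list(w))).scores
        shuffled = self._score(list(w))
        shuffled = ScoreFile(shuffled.table.iloc[::-1])
        assert np.allclose(compute_prs(genos, shuffled).scores, full)
        first = compute_prs(genos, self._score(list(w[:5]), snps=[f"rs{i}" for i in range(5)])).scores
        second = compute_prs(genos, self._score(list(w[5:]), snps=[f"rs{i}" for i in range(5, 10)])).scores
        assert np.allclose(first + second, full)

    def test_unmatched_snps_counted(self):
        genos = _genotype_set(np.zeros((1, 2)))
        res = compute_prs(genos, self._score([0.1, 0.2], snps=["rs0", "zz"]))
        assert res.n_unmatched == 1


class TestPrsGroupTest:
    def test_simulated_shift_detected_majority_of_seeds(self):
        """0.8 SD case shift at n = 34 vs 40 reaches p < 0.05 in >= 80% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = pd.Series(
                np.concatenate([rng.normal(0.8, 1, 34), rng.normal(0, 1, 40)]),
                index=[f"s{i}" for i in range(74)],
            )
            diag = pd.Series(
                ["case"] * 34 + ["control"] * 40, index=scores.index
            )
            hits += prs_group_test(scores, diag)["p"] < 0.05
        assert hits >= 16

    def test_equal_means_p_one(self):
        scores = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        diag = pd.Series(["case", "case", "control", "control"], index=list("abcd"))
        assert prs_group_test(scores, diag)["p"] == pytest.approx(1.0)

    def test_null_calibrated(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            scores = pd.Series(rng.normal(0, 1, 60), index=[f"s{i}" for i in range(60)])
            diag = pd.Series(["case"] * 30 + ["control"] * 30, index=scores.index)
            ps.append(prs_group_test(scores, diag)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMqtlScan:
    def test_null_scan_yields_no_pairs(self):
        false_pairs = 0
        for seed in range(5):
            mani = make_manifest(200, n_chroms=2, seed=seed)
            sheet = make_design(
                n_donors=70, regions=("PFC",), region_availability={"PFC": 1.0},
                restricted_regions={}, seed=seed,
            )
            genos = simulate_genotypes(sheet, n_snps=30, seed=seed + 1)
            beta, _ = simulate_beta(mani, sheet, EffectSpec(), seed=seed + 2)
            hits = mqtl_scan(beta, genos, sheet, covariates=("age", "sex"))
            false_pairs += len(hits)
        assert false_pairs == 0

    def test_spiked_mqtl_detected_with_correct_sign(self):
        """0.05/allele at MAF 0.3, n = 70: relaxed threshold, >= 18/20 seeds."""
        detected, signs = 0, 0
        for seed in range(20):
            mani = make_manifest(300, n_chroms=2, seed=seed)
            sheet = make_design(
                n_donors=70, regions=("PFC",), region_availability={"PFC": 1.0},
                restricted_regions={}, seed=seed,
            )
            probe = mani.probe_ids[10]
            eff = EffectSpec(mqtl_effects=[MqtlEffect("rs000001", probe, 0.05)])
            genos = simulate_genotypes(
                sheet, n_snps=20, maf_range=(0.3, 0.3), effects=eff, seed=seed + 50
            )
            beta, _ = simulate_beta(
                mani, sheet, eff, genotypes=genos, seed=seed + 99
            )
            hits = mqtl_scan(beta, genos, sheet, covariates=("age", "sex"))
            hit = hits[(hits.snp_id == "rs000001") & (hits.probe_id == probe)]
            if len(hit):
                detected += 1
                signs += hit["estimate"].iloc[0] > 0
        assert detected >= 18
        assert signs == detected

    def test_monomorphic_snp_skipped(self):
        mani = make_manifest(50, n_chroms=1, seed=1)
        sheet = make_design(
            n_donors=30, regions=("PFC",), region_availability={"PFC": 1.0},
            restricted_regions={}, seed=1,
        )
        genos = simulate_genotypes(sheet, n_snps=3, seed=2)
        mono = genos.dosage.copy()
        mono.iloc[0] = 0.0
        genos = GenotypeSet(dosage=mono, snp_map=genos.snp_map)
        beta, _ = simulate_beta(mani, sheet, EffectSpec(), seed=3)
        hits = mqtl_scan(beta, genos, sheet, covariates=("age", "sex"))
        assert not (hits["snp_id"] == genos.snp_ids[0]).any()


class TestEnrichment:
    def test_worked_table_example(self):
        in_region = pd.Series([True] * 4 + [False] * 4)
        is_dmp = pd.Series([True, True, True, False, True, False, False, False])
        res = enrichment_fisher(in_region, is_dmp)
        assert res["table"] == [[3, 1], [1, 3]]
        assert res["p"] == pytest.approx(34 / 70, abs=1e-9)

    def test_no_dmps_p_one(self):
        res = enrichment_fisher(
            pd.Series([True, False, True]), pd.Series([False, False, False])
        )
        assert res["p"] == 1.0 and not res["significant"]

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p equals full enumeration over fixed-margin tables."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            total = int(rng.integers(8, 50))
            in_r = rng.random(total) < rng.uniform(0.2, 0.8)
            dmp = rng.random(total) < rng.uniform(0.1, 0.5)
            in_r[:1] = True  # avoid fully degenerate margins
            dmp[:1] = True
            res = enrichment_fisher(pd.Series(in_r), pd.Series(dmp))
            a = int((in_r & dmp).sum())
            row1 = int(in_r.sum())
            col1 = int(dmp.sum())
            obs = stats.hypergeom.pmf(a, total, row1, col1)
            lo, hi = max(0, row1 + col1 - total), min(row1, col1)
            p = sum(
                stats.hypergeom.pmf(x, total, row1, col1)
                for x in range(lo, hi + 1)
                if stats.hypergeom.pmf(x, total, row1, col1) <= obs * (1 + 1e-9)
            )
            assert res["p"] == pytest.approx(min(1.0, p), abs=1e-9)

    def test_probe_region_membership_inclusive(self, small_manifest):
        t = small_manifest.table
        probe = t.index[5]
        start, end = int(t.iloc[5]["pos"]), int(t.iloc[5]["pos"])
        member = probes_in_regions(small_manifest, [(t.iloc[5]["chrom"], start, end)])
        assert member.loc[probe]
        assert member.sum() == (
            (t["chrom"] == t.iloc[5]["chrom"]) & (t["pos"] == start)
        ).sum()
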