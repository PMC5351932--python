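"""Synthetic study generator.

Emulates the design of a two-cohort, four-brain-region post-mortem
methylation study: ~88 donors contribute up to four regions each (~262
samples), with hippocampus restricted to one brain bank.  Beta values are
generated on the logit scale as

    beta = invlogit(baseline + covariate terms + spiked effects + noise)

where the noise is a stationary Gaussian process per chromosome with
exponential spatial kernel exp(-d / phi) — the Markov property of the
exponential kernel on a line lets it be sampled exactly in O(n) — so the
DMR stage sees tunable distance-decaying autocorrelation while betas stay
in (0, 1).  Genotypes are donor-level Hardy-Weinberg draws replicated
across each donor's samples, optionally carrying mQTL effects on specific
probes and a polygenic-score shift between cases and controls.

Every generator is a pure function of its arguments and a seed; the
realized ground truth (spiked effects, latent neuronal proportions, ages,
true scores) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import BetaMatrix, GenotypeSet, ProbeManifest, SampleSheet, ScoreFile

__all__ = [
    "DmpEffect",
    "DmrEffect",
    "MqtlEffect",
    "PrsConstruct",
    "EffectSpec",
    "GroundTruth",
    "make_manifest",
    "make_design",
    "simulate_beta",
    "simulate_genotypes",
    "default_effects",
    "simulate_dataset",
]

_BETA_FLOOR, _BETA_CEIL = 0.02, 0.98


def make_reference_profiles(
    manifest: ProbeManifest, n_ref: int = 50, seed: int = 0
):
    """Matched neuron/glia reference methylation profiles over ``n_ref``
    unflagged probes, for the cell-composition covariate stage."""
    from .covariates import ReferenceProfiles

    rng = np.random.default_rng(seed)
    t = manifest.table
    candidates = t.index[t["flags"].map(len) == 0]
    if len(candidates) < n_ref:
        raise ValueError("not enough unflagged probes for reference profiles")
    probes = pd.Index(sorted(rng.choice(candidates, size=n_ref, replace=False)))
    mu_n = rng.uniform(0.2, 0.8, n_ref)
    sep = rng.uniform(0.15, 0.35, n_ref) * rng.choice([-1, 1], n_ref)
    mu_g = np.clip(mu_n + sep, 0.05, 0.95)
    return ReferenceProfiles(
        neuron=pd.Series(mu_n, index=probes, name="neuron"),
        glia=pd.Series(mu_g, index=probes, name="glia"),
    )


@dataclass(frozen=True)
class DmpEffect:
    probe_id: str
    delta_beta: float  # expected case-control (or per-SD-of-score) difference
    target: str = "diagnosis"  # 'diagnosis' or 'prs'


@dataclass(frozen=True)
class DmrEffect:
    chrom: str
    start: int
    end: int
    delta_beta: float
    target: str = "diagnosis"


@dataclass(frozen=True)
class MqtlEffect:
    snp_id: str
    probe_id: str
    delta_per_allele: float


@dataclass(frozen=True)
class PrsConstruct:
    causal_snps: Tuple[str, ...]
    weights: Tuple[float, ...]
    case_shift_sd: float = 0.0  # case-control score shift, in score SD units


@dataclass
class EffectSpec:
    dmp_effects: List[DmpEffect] = field(default_factory=list)
    dmr_effects: List[DmrEffect] = field(default_factory=list)
    mqtl_effects: List[MqtlEffect] = field(default_factory=list)
    prs_construct: Optional[PrsConstruct] = None

    def to_dict(self) -> dict:
        return {
            "dmp_effects": [dataclasses.asdict(e) for e in self.dmp_effects],
            "dmr_effects": [dataclasses.asdict(e) for e in self.dmr_effects],
            "mqtl_effects": [dataclasses.asdict(e) for e in self.mqtl_effects],
            "prs_construct": (
                dataclasses.asdict(self.prs_construct) if self.prs_construct else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        prs = d.get("prs_construct")
        return cls(
            dmp_effects=[DmpEffect(**e) for e in d.get("dmp_effects", [])],
            dmr_effects=[DmrEffect(**e) for e in d.get("dmr_effects", [])],
            mqtl_effects=[MqtlEffect(**e) for e in d.get("mqtl_effects", [])],
            prs_construct=(
                PrsConstruct(
                    causal_snps=tuple(prs["causal_snps"]),
                    weights=tuple(prs["weights"]),
                    case_shift_sd=prs["case_shift_sd"],
                )
                if prs
                else None
            ),
        )


@dataclass
class GroundTruth:
    """Realized simulation state, serialized alongside every dataset."""

    effects: EffectSpec
    neuronal_prop: Dict[str, float]
    ages: Dict[str, float]
    true_prs: Dict[str, float]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects.to_dict(),
            "neuronal_prop": self.neuronal_prop,
            "ages": self.ages,
            "true_prs": self.true_prs,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            effects=EffectSpec.from_dict(d["effects"]),
            neuronal_prop=d["neuronal_prop"],
            ages=d["ages"],
            true_prs=d["true_prs"],
            seed=d["seed"],
        )


def make_manifest(
    n_probes: int,
    n_chroms: int = 4,
    mean_gap_bp: float = 500.0,
    flag_fraction: float = 0.02,
    seed: int = 0,
) -> ProbeManifest:
    """Probe map with geometric inter-probe gaps and ~2% flagged probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chroms, n_probes // n_chroms)
    per_chrom[: n_probes % n_chroms] += 1
    rows = []
    for c, count in enumerate(per_chrom, start=1):
        if count == 0:
            continue
        gaps = rng.geometric(1.0 / mean_gap_bp, size=count)
        pos = np.cumsum(gaps) + 1000
        for p in pos:
            rows.append((f"chr{c}", int(p)))
    probe_ids = [f"cg{i:08d}" for i in range(len(rows))]
    chroms = [r[0] for r in rows]
    positions = [r[1] for r in rows]
    probe_type = np.where(rng.random(len(rows)) < 0.28, "I", "II")
    flags: List[frozenset] = [frozenset()] * len(rows)
    flagged = rng.random(len(rows)) < flag_fraction
    classes = ["sex_chromosome", "cross_hybridizing", "snp_proximal", "control_snp"]
    for i in np.flatnonzero(flagged):
        flags[i] = frozenset({classes[rng.integers(len(classes))]})
    table = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "probe_type": probe_type, "flags": flags},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(table)


_DEFAULT_AVAILABILITY = {"PFC": 0.86, "STR": 0.93, "HC": 0.53, "CER": 0.87}


def make_design(
    n_donors: int = 88,
    case_fraction: float = 41 / 88,
    cohorts: Sequence[str] = ("LNDBB", "DBCBB"),
    cohort_fractions: Sequence[float] = (0.58, 0.42),
    regions: Sequence[str] = ("PFC", "STR", "HC", "CER"),
    region_availability: Optional[Dict[str, float]] = None,
    restricted_regions: Optional[Dict[str, Sequence[str]]] = None,
    age_mean: float = 60.0,
    age_sd: float = 15.0,
    age_min: float = 18.0,
    male_fraction: float = 0.72,
    seed: int = 0,
) -> SampleSheet:
    """Donor/sample design table mirroring the two-brain-bank study layout.

    ``restricted_regions`` maps a region to the cohorts it is available
    from; by default hippocampus is restricted to the first cohort.
    """
    if not (0 <= case_fraction <= 1):
        raise ValueError("case_fraction must lie in [0, 1]")
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    rng = np.random.default_rng(seed)
    availability = dict(_DEFAULT_AVAILABILITY)
    if region_availability:
        availability.update(region_availability)
    if restricted_regions is None:
        restricted_regions = {"HC": (cohorts[0],)} if "HC" in regions else {}

    n_cases = int(round(case_fraction * n_donors))
    diagnosis = np.array(["case"] * n_cases + ["control"] * (n_donors - n_cases))
    rng.shuffle(diagnosis)
    cohort_idx = rng.choice(len(cohorts), size=n_donors, p=np.asarray(cohort_fractions))
    sexes = np.where(rng.random(n_donors) < male_fraction, "M", "F")
    ages = age_mean + age_sd * rng.standard_normal(n_donors)
    while (ages < age_min).any():  # truncated normal by resampling
        redo = ages < age_min
        ages[redo] = age_mean + age_sd * rng.standard_normal(redo.sum())

    rows = []
    for i in range(n_donors):
        donor = f"D{i:04d}"
        cohort = cohorts[cohort_idx[i]]
        for region in regions:
            allowed = restricted_regions.get(region)
            if allowed is not None and cohort not in allowed:
                continue
            if rng.random() > availability.get(region, 1.0):
                continue
            rows.append(
                {
                    "sample_id": f"{donor}_{region}",
                    "donor_id": donor,
                    "cohort": cohort,
                    "region": region,
                    "diagnosis": diagnosis[i],
                    "age": round(float(ages[i]), 2),
                    "sex": sexes[i],
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(table)


def _logit_offset(baseline_p: np.ndarray, delta: float) -> np.ndarray:
    """Logit-scale offset giving an expected beta shift of ``delta``."""
    shifted = baseline_p + delta
    if ((shifted < _BETA_FLOOR) | (shifted > _BETA_CEIL)).any():
        raise ValueError(
            f"expected beta outside [{_BETA_FLOOR}, {_BETA_CEIL}] after effect"
        )
    return logit(shifted) - logit(baseline_p)


def _spatial_noise(
    positions: np.ndarray, n_samples: int, phi_bp: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw of a unit-variance GP with kernel exp(-d/phi) on a line."""
    n = len(positions)
    eps = rng.standard_normal((n, n_samples))
    if phi_bp <= 0 or n == 1:
        return eps
    z = np.empty_like(eps)
    z[0] = eps[0]
    r = np.exp(-np.diff(positions) / phi_bp)
    s = np.sqrt(1.0 - r**2)
    for i in range(1, n):
        z[i] = r[i - 1] * z[i - 1] + s[i - 1] * eps[i]
    return z


def simulate_beta(
    manifest: ProbeManifest,
    sheet: SampleSheet,
    effects: Optional[EffectSpec] = None,
    genotypes: Optional[GenotypeSet] = None,
    phi_bp: float = 200.0,
    noise_sd: float = 0.3,
    mqtl_noise_sd: float = 0.1,
    age_slope: float = 0.004,
    sex_shift: float = 0.05,
    sex_chrom_shift: float = -1.0,
    neuronal_loading_sd: float = 0.3,
    cohort_shift_sd: float = 0.05,
    neuronal_mean: float = 0.40,
    neuronal_sd: float = 0.08,
    det_fail_rate: float = 0.001,
    bead_fail_rate: float = 0.001,
    reference=None,
    ref_noise_sd: float = 0.02,
    seed: int = 0,
) -> Tuple[BetaMatrix, GroundTruth]:
    """Simulate the beta matrix (plus detection-p and beadcount layers).

    Covariate terms: a common age slope (logit units per year), a small
    global sex shift plus a strong male shift on sex-chromosome-flagged
    probes, per-probe loadings on the latent neuronal proportion, and a
    per-probe additive cohort batch shift.  Spiked effects come from
    ``effects``; mQTL and score-targeted effects additionally need
    ``genotypes`` / a ``prs`` column on the sheet.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    mani = manifest.sorted_by_position()
    probes = mani.probe_ids
    samples = sheet.sample_ids
    n_p, n_s = len(probes), len(samples)
    if n_p == 0 or n_s == 0:
        raise ValueError("empty manifest or sample sheet")

    # bimodal baseline typical of CpG methylation
    comp = rng.choice(3, size=n_p, p=[0.4, 0.4, 0.2])
    mu = np.where(
        comp == 0,
        rng.normal(-2.0, 0.5, n_p),
        np.where(comp == 1, rng.normal(2.0, 0.5, n_p), rng.normal(0.0, 0.8, n_p)),
    )
    # Spiked probes draw baselines in the partially-methylated tails
    # (low for hyper-, high for hypomethylation effects), where array
    # DMPs typically sit and where a fixed beta-scale effect is large
    # relative to logit-scale noise; this also keeps shifted expected
    # betas inside the legal [0.02, 0.98] band.
    pos_map_pre = {p: i for i, p in enumerate(probes)}
    targeted: Dict[int, float] = {}
    for e in effects.dmp_effects:
        if e.probe_id in pos_map_pre:
            targeted.setdefault(pos_map_pre[e.probe_id], e.delta_beta)
    for e in effects.mqtl_effects:
        if e.probe_id in pos_map_pre:
            targeted.setdefault(pos_map_pre[e.probe_id], 2 * e.delta_per_allele)
    for e in effects.dmr_effects:
        hit = (
            (mani.table["chrom"] == e.chrom)
            & (mani.table["pos"] >= e.start)
            & (mani.table["pos"] <= e.end)
        ).to_numpy()
        for i in np.flatnonzero(hit):
            targeted.setdefault(int(i), e.delta_beta)
    for i, delta in sorted(targeted.items()):
        base = rng.uniform(0.06, 0.12)
        mu[i] = logit(base if delta >= 0 else 1.0 - base)
    baseline_p = expit(mu)

    # latent per-sample covariates
    neuronal = np.clip(
        rng.normal(neuronal_mean, neuronal_sd, n_s), 0.05, 0.95
    )
    ages = sheet.table["age"].to_numpy(dtype=float)
    is_case = (sheet.table["diagnosis"] == "case").to_numpy()
    is_male = (sheet.table["sex"] == "M").to_numpy()
    cohort_codes, cohort_levels = pd.factorize(sheet.table["cohort"])

    L = np.tile(mu[:, None], (1, n_s))
    L += age_slope * (ages - ages.mean())[None, :]
    L += sex_shift * is_male[None, :] * rng.standard_normal(n_p)[:, None]
    sex_probes = mani.table["flags"].map(lambda fl: "sex_chromosome" in fl).to_numpy()
    L[sex_probes] += sex_chrom_shift * is_male[None, :]
    loadings = neuronal_loading_sd * rng.standard_normal(n_p)
    L += loadings[:, None] * (neuronal - neuronal.mean())[None, :]
    for c in range(len(cohort_levels)):
        shift = cohort_shift_sd * rng.standard_normal(n_p)
        L[:, cohort_codes == c] += shift[:, None]

    pos_map = {p: i for i, p in enumerate(probes)}

    def _exposure_vector(target: str) -> np.ndarray:
        if target == "diagnosis":
            return is_case.astype(float)
        if target == "prs":
            if "prs" not in sheet.table.columns:
                raise ValueError("prs-targeted effect requires a 'prs' sheet column")
            prs = sheet.table["prs"].to_numpy(dtype=float)
            sd = prs.std(ddof=0)
            return (prs - prs.mean()) / (sd if sd > 0 else 1.0)
        raise ValueError(f"unknown effect target {target!r}")

    spiked: List[Tuple[int, float, str]] = []
    for e in effects.dmp_effects:
        if e.probe_id not in pos_map:
            raise ValueError(f"spiked probe {e.probe_id!r} not in manifest")
        spiked.append((pos_map[e.probe_id], e.delta_beta, e.target))
    for e in effects.dmr_effects:
        in_region = (
            (mani.table["chrom"] == e.chrom)
            & (mani.table["pos"] >= e.start)
            & (mani.table["pos"] <= e.end)
        ).to_numpy()
        if not in_region.any():
            raise ValueError(f"DMR effect {e.chrom}:{e.start}-{e.end} hits no probe")
        for i in np.flatnonzero(in_region):
            spiked.append((i, e.delta_beta, e.target))
    for i, delta, target in spiked:
        off = _logit_offset(baseline_p[i : i + 1], delta)[0]
        L[i] += off * _exposure_vector(target)

    for e in effects.mqtl_effects:
        if genotypes is None:
            raise ValueError("mQTL effects require genotypes")
        if e.probe_id not in pos_map:
            raise ValueError(f"mQTL probe {e.probe_id!r} not in manifest")
        i = pos_map[e.probe_id]
        # validate at the homozygous extreme
        _logit_offset(baseline_p[i : i + 1], 2 * e.delta_per_allele)
        per_allele = _logit_offset(baseline_p[i : i + 1], e.delta_per_allele)[0]
        dos = genotypes.dosage.loc[e.snp_id, samples].to_numpy(dtype=float)
        L[i] += per_allele * np.nan_to_num(dos, nan=np.nanmean(dos))

    # spatially correlated noise per chromosome
    chroms = mani.table["chrom"].to_numpy()
    noise = np.empty((n_p, n_s))
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        noise[idx] = _spatial_noise(
            mani.table["pos"].to_numpy()[idx], n_s, phi_bp, rng
        )
    scale = np.full(n_p, noise_sd)
    # genetically-driven probes are tightly controlled: strong cis-mQTLs
    # explain most of a probe's variance, so their residual noise is low
    for e in effects.mqtl_effects:
        if e.probe_id in pos_map:
            scale[pos_map[e.probe_id]] = mqtl_noise_sd
    L += scale[:, None] * noise

    values = pd.DataFrame(expit(L), index=probes, columns=samples)

    if reference is not None:
        # reference-probe betas follow the two-class mixture so the
        # deconvolution stage can recover the latent neuronal fraction
        ref_probes = reference.neuron.index
        ref_probes = ref_probes[ref_probes.isin(values.index)]
        mix = (
            np.outer(reference.neuron.loc[ref_probes], neuronal)
            + np.outer(reference.glia.loc[ref_probes], 1.0 - neuronal)
            + ref_noise_sd * rng.standard_normal((len(ref_probes), n_s))
        )
        values.loc[ref_probes] = np.clip(mix, 0.0, 1.0)

    det = rng.uniform(0.0, 1e-4, size=(n_p, n_s))
    fail = rng.random((n_p, n_s)) < det_fail_rate
    det[fail] = rng.uniform(0.06, 1.0, size=fail.sum())
    detection_p = pd.DataFrame(det, index=probes, columns=samples)

    bead = rng.poisson(14.0, size=(n_p, n_s)) + 1
    low = rng.random((n_p, n_s)) < bead_fail_rate
    bead[low] = rng.integers(0, 3, size=low.sum())
    beadcount = pd.DataFrame(bead, index=probes, columns=samples)

    truth = GroundTruth(
        effects=effects,
        neuronal_prop={s: float(v) for s, v in zip(samples, neuronal)},
        ages={s: float(a) for s, a in zip(samples, ages)},
        true_prs=(
            {s: float(v) for s, v in zip(samples, sheet.table["prs"])}
            if "prs" in sheet.table.columns
            else {}
        ),
        seed=seed,
    )
    return BetaMatrix(values=values, detection_p=detection_p, beadcount=beadcount), truth


def simulate_genotypes(
    sheet: SampleSheet,
    n_snps: int = 200,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    effects: Optional[EffectSpec] = None,
    chrom: str = "chr1",
    spacing_bp: int = 5000,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeSet:
    """Donor-level Hardy-Weinberg genotypes replicated across samples.

    When the effect spec carries a polygenic-score construct with a
    case-control shift of ``s`` score-SD units, causal allele frequencies
    in cases are shifted so that the expected case-control score
    difference equals ``s`` times the control-score SD.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")
    effects = effects or EffectSpec()
    prs = effects.prs_construct
    if prs is not None and len(prs.causal_snps) > n_snps:
        raise ValueError("n_snps smaller than the number of causal SNPs")
    rng = np.random.default_rng(seed)

    donors = sheet.table["donor_id"].unique()
    donor_diag = (
        sheet.table.drop_duplicates("donor_id").set_index("donor_id")["diagnosis"]
    )
    n_d = len(donors)
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    if prs is not None:
        # causal SNPs take the requested ids (prepended, deduplicated)
        causal = list(prs.causal_snps)
        rest = [s for s in snp_ids if s not in set(causal)]
        snp_ids = causal + rest[: n_snps - len(causal)]
    mafs = rng.uniform(lo, hi, size=n_snps)

    freq = np.tile(mafs[:, None], (1, n_d))
    if prs is not None and prs.case_shift_sd != 0.0:
        w = np.asarray(prs.weights, dtype=float)
        idx = np.arange(len(prs.causal_snps))
        p = mafs[idx]
        var = np.sum(w**2 * 2 * p * (1 - p))
        sd = np.sqrt(var) if var > 0 else 1.0
        delta = prs.case_shift_sd * w * p * (1 - p) / sd
        case_cols = donor_diag.loc[donors].eq("case").to_numpy()
        freq[np.ix_(idx, case_cols)] = np.clip(
            (p + delta)[:, None], 0.01, 0.99
        )

    geno = rng.binomial(2, freq).astype(float)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = np.nan

    donor_col = {d: i for i, d in enumerate(donors)}
    sample_cols = [donor_col[d] for d in sheet.table["donor_id"]]
    dosage = pd.DataFrame(
        geno[:, sample_cols], index=pd.Index(snp_ids, name="snp_id"),
        columns=sheet.sample_ids,
    )
    alleles = np.array(["A", "C", "G", "T"])
    eff = alleles[rng.integers(0, 4, n_snps)]
    oth = np.array([alleles[(np.flatnonzero(alleles == a)[0] + 1) % 4] for a in eff])
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(n_snps) + 1) * spacing_bp,
            "effect_allele": eff,
            "other_allele": oth,
        },
        index=dosage.index,
    )
    return GenotypeSet(dosage=dosage, snp_map=snp_map)


def default_effects(
    manifest: ProbeManifest,
    n_dmp: int = 5,
    n_prs_dmp: int = 3,
    n_dmr: int = 1,
    dmr_probes: int = 5,
    n_mqtl: int = 5,
    n_causal_snps: int = 20,
    delta_beta: float = 0.05,
    prs_shift_sd: float = 0.8,
    seed: int = 0,
) -> EffectSpec:
    """A study-like effect spec: spiked DMPs/DMRs, mQTLs and a PRS shift.

    Spiked probes are chosen among intermediate-methylation candidates so
    that the shifted expected beta stays inside the legal band.
    """
    rng = np.random.default_rng(seed)
    mani = manifest.sorted_by_position()
    t = mani.table
    unflagged = t.index[t["flags"].map(len) == 0]

    n_pick = n_dmp + n_prs_dmp
    picked = list(rng.choice(unflagged, size=min(n_pick, len(unflagged)), replace=False))
    dmps = [DmpEffect(p, delta_beta, "diagnosis") for p in picked[:n_dmp]]
    dmps += [DmpEffect(p, delta_beta, "prs") for p in picked[n_dmp:]]

    dmrs: List[DmrEffect] = []
    for chrom in pd.unique(t["chrom"])[:n_dmr]:
        sub = t[t["chrom"] == chrom]
        # pick a run of consecutive probes with gaps <= 300 bp
        pos = sub["pos"].to_numpy()
        for start_i in rng.permutation(max(1, len(sub) - dmr_probes)):
            window = pos[start_i : start_i + dmr_probes]
            if len(window) == dmr_probes and np.all(np.diff(window) <= 300):
                dmrs.append(
                    DmrEffect(chrom, int(window[0]), int(window[-1]), delta_beta)
                )
                break

    mqtls = [
        MqtlEffect(f"rs{900000 + i:06d}", p, delta_beta)
        for i, p in enumerate(
            rng.choice(unflagged, size=min(n_mqtl, len(unflagged)), replace=False)
        )
    ]
    weights = rng.normal(0.0, 0.1, n_causal_snps)
    prs = PrsConstruct(
        causal_snps=tuple(f"rs{800000 + i:06d}" for i in range(n_causal_snps)),
        weights=tuple(float(w) for w in weights),
        case_shift_sd=prs_shift_sd,
    )
    return EffectSpec(dmp_effects=dmps, dmr_effects=dmrs, mqtl_effects=mqtls, prs_construct=prs)


def simulate_dataset(
    n_probes: int = 20000,
    n_donors: int = 88,
    n_snps: int = 200,
    effects: Optional[EffectSpec] = None,
    seed: int = 0,
    **beta_kwargs,
) -> dict:
    """Generate a full input bundle: manifest, sheet, genotypes, betas, truth.

    The true polygenic score (from the effect spec's construct) is
    standardized and written into the sheet's ``prs`` column so that
    score-targeted methylation effects and the score-association stage
    have a common exposure.
    """
    rng = np.random.default_rng(seed)
    s_mani, s_design, s_geno, s_beta = rng.integers(0, 2**31 - 1, size=4)
    manifest = make_manifest(n_probes, seed=int(s_mani))
    sheet = make_design(n_donors=n_donors, seed=int(s_design))
    if effects is None:
        effects = default_effects(manifest, seed=seed)
    # ensure mQTL SNPs exist in the genotype panel
    mqtl_snps = [e.snp_id for e in effects.mqtl_effects]
    genotypes = simulate_genotypes(
        sheet, n_snps=n_snps, effects=effects, seed=int(s_geno)
    )
    if mqtl_snps:
        missing = [s for s in mqtl_snps if s not in genotypes.snp_ids]
        if missing:
            # rename trailing non-causal SNPs to the requested mQTL ids
            causal = (
                set(effects.prs_construct.causal_snps)
                if effects.prs_construct
                else set()
            )
            spare = [s for s in genotypes.snp_ids if s not in causal][::-1]
            if len(spare) < len(missing):
                raise ValueError(
                    "n_snps too small for the requested mQTL and score effects"
                )
            renames = dict(zip(spare[: len(missing)], missing))
            genotypes = GenotypeSet(
                dosage=genotypes.dosage.rename(index=renames),
                snp_map=genotypes.snp_map.rename(index=renames),
            )
    score = None
    if effects.prs_construct is not None:
        prs = effects.prs_construct
        w = np.asarray(prs.weights, dtype=float)
        dos = genotypes.dosage.loc[list(prs.causal_snps)].to_numpy(dtype=float)
        raw = np.nansum(dos * w[:, None], axis=0)
        sd = raw.std(ddof=0)
        table = sheet.table.copy()
        table["prs"] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        sheet = SampleSheet(table)
        score = ScoreFile(
            pd.DataFrame(
                {
                    "effect_allele": genotypes.snp_map.loc[
                        list(prs.causal_snps), "effect_allele"
                    ],
                    "weight": w,
                },
                index=pd.Index(list(prs.causal_snps), name="snp_id"),
            )
        )
    reference = make_reference_profiles(manifest, seed=int(s_mani))
    beta, truth = simulate_beta(
        manifest,
        sheet,
        effects,
        genotypes=genotypes,
        reference=reference,
        seed=int(s_beta),
        **beta_kwargs,
    )
    # derive the neuronal-proportion covariate the way the pipeline would
    from .covariates import estimate_neuronal_proportions

    table = sheet.table.copy()
    table["neuronal_prop"] = estimate_neuronal_proportions(beta.values, reference)
    sheet = SampleSheet(table)
    return {
        "manifest": manifest,
        "sheet": sheet,
        "genotypes": genotypes,
        "score": score,
        "beta": beta,
        "truth": truth,
        "reference": reference,
    }
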