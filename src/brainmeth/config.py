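"""Pipeline configuration: every tunable threshold with its default.

Defaults follow the published analysis protocol this pipeline mirrors
(array QC cut-offs, DMR grouping rule, permutation count, genotype QC and
mQTL significance thresholds).  The config serialises round-trip to YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # sample-level detection filter: drop samples with > sample_det_fraction
    # of probes at detection p > sample_det_p
    sample_det_p: float = 0.01
    sample_det_fraction: float = 0.01
    # probe-level filters: drop probes with detection p > probe_det_p in at
    # least probe_det_fraction of samples, or beadcount < bead_cut in
    # bead_fraction of samples
    probe_det_p: float = 0.05
    probe_det_fraction: float = 0.01
    bead_cut: int = 3
    bead_fraction: float = 0.05
    # DMR detection
    dmr_seed_p: float = 1.0e-03
    dmr_max_gap: int = 300
    dmr_min_probes: int = 2
    # family-wise error threshold estimation
    fwer_alpha: float = 0.05
    n_perm: int = 5000
    # genotype QC
    hwe_p: float = 1.0e-03
    maf_cut: float = 0.05
    snp_missingness: float = 0.01
    sample_missingness: float = 0.05
    # LD pruning
    ld_window_bp: int = 1500
    ld_r2_cut: float = 0.20
    # mQTL significance
    mqtl_p: float = 3.69e-13
    mqtl_p_relaxed: float = 1.0e-10
    # GWAS-region enrichment
    enrichment_dmp_p: float = 1.0e-03
    enrichment_bonferroni_p: float = 1.25e-02
    # RNG
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "sample_det_p",
            "sample_det_fraction",
            "probe_det_p",
            "probe_det_fraction",
            "bead_fraction",
            "fwer_alpha",
            "hwe_p",
            "snp_missingness",
            "sample_missingness",
            "ld_r2_cut",
            "mqtl_p",
            "mqtl_p_relaxed",
            "enrichment_dmp_p",
            "enrichment_bonferroni_p",
            "dmr_seed_p",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0 < self.maf_cut <= 0.5):
            raise ValueError(f"maf_cut={self.maf_cut} outside (0, 0.5]")
        for name in ("bead_cut", "dmr_max_gap", "dmr_min_probes", "n_perm", "ld_window_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
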