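"""Shared domain types for the methylome analysis pipeline.

All containers wrap :class:`pandas.DataFrame` objects and validate their
invariants at construction time.  Methylation levels ("beta values") are
proportions in [0, 1]; user-facing effect sizes are reported as percentage
points (coefficient x 100).  Genomic coordinates are 1-based and intervals
are inclusive of both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MalformedInputError",
    "PROBE_FLAGS",
    "REQUIRED_SHEET_COLUMNS",
    "ProbeManifest",
    "BetaMatrix",
    "SampleSheet",
    "GenotypeSet",
    "ScoreFile",
]


class MalformedInputError(ValueError):
    """Raised when an input file or table violates a documented invariant."""


#: Recognised probe exclusion flag classes.
PROBE_FLAGS = frozenset(
    {"sex_chromosome", "cross_hybridizing", "snp_proximal", "control_snp"}
)

REQUIRED_SHEET_COLUMNS = (
    "sample_id",
    "donor_id",
    "cohort",
    "region",
    "diagnosis",
    "age",
    "sex",
)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise MalformedInputError(f"duplicate {what}: {dups}")


@dataclass
class ProbeManifest:
    """Genomic annotation for array probes.

    ``table`` is indexed by probe id with columns ``chrom`` (str), ``pos``
    (1-based int), ``probe_type`` ('I' or 'II') and ``flags`` (frozenset of
    exclusion flag classes, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"chrom", "pos", "probe_type", "flags"} - set(t.columns)
        if missing:
            raise MalformedInputError(f"manifest missing columns: {sorted(missing)}")
        _check_unique(t.index, "probe id")
        if (t["pos"] < 1).any():
            bad = t.index[t["pos"] < 1][:5].tolist()
            raise MalformedInputError(f"manifest positions must be >= 1: {bad}")
        bad_type = ~t["probe_type"].isin(["I", "II"])
        if bad_type.any():
            raise MalformedInputError(
                f"unknown probe types: {t['probe_type'][bad_type].unique().tolist()}"
            )
        for pid, fl in t["flags"].items():
            unknown = set(fl) - PROBE_FLAGS
            if unknown:
                raise MalformedInputError(f"unknown flag {sorted(unknown)} on {pid}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_position(self) -> "ProbeManifest":
        return ProbeManifest(self.table.sort_values(["chrom", "pos"], kind="stable"))

    def probes_with_flags(self, classes: Iterable[str]) -> pd.Index:
        classes = set(classes)
        unknown = classes - PROBE_FLAGS
        if unknown:
            raise MalformedInputError(f"unknown flag classes: {sorted(unknown)}")
        mask = self.table["flags"].map(lambda fl: bool(classes & set(fl)))
        return self.table.index[mask]


@dataclass
class BetaMatrix:
    """Probes x samples methylation proportions with optional QC layers.

    ``detection_p`` and ``beadcount`` (if present) share the exact shape and
    labels of ``values``.
    """

    values: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    beadcount: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "probe id")
        _check_unique(v.columns, "sample id")
        arr = v.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if ((arr < 0) | (arr > 1))[finite].any():
            bad = np.argwhere(finite & ((arr < 0) | (arr > 1)))[0]
            raise MalformedInputError(
                f"beta value outside [0,1] at probe {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        for name in ("detection_p", "beadcount"):
            layer = getattr(self, name)
            if layer is None:
                continue
            if not (layer.index.equals(v.index) and layer.columns.equals(v.columns)):
                raise MalformedInputError(f"{name} layer labels do not match values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def subset(
        self,
        probes: Optional[Sequence] = None,
        samples: Optional[Sequence] = None,
    ) -> "BetaMatrix":
        def _cut(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[probes]
            if samples is not None:
                out = out.loc[:, samples]
            return out

        return BetaMatrix(
            values=_cut(self.values),
            detection_p=_cut(self.detection_p),
            beadcount=_cut(self.beadcount),
        )


@dataclass
class SampleSheet:
    """Per-sample phenotype and design record.

    ``table`` is indexed by sample id with at least the columns donor_id,
    cohort, region, diagnosis ('case'/'control'), age, sex ('M'/'F').
    Optional columns: neuronal_prop in [0,1], prs.  Extra columns are
    preserved untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(REQUIRED_SHEET_COLUMNS[1:]) - set(t.columns)
        if missing:
            raise MalformedInputError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(t.index, "sample id")
        bad_diag = ~t["diagnosis"].isin(["case", "control"])
        if bad_diag.any():
            raise MalformedInputError(
                f"diagnosis must be case/control, got "
                f"{t['diagnosis'][bad_diag].unique().tolist()}"
            )
        bad_sex = ~t["sex"].isin(["M", "F"])
        if bad_sex.any():
            raise MalformedInputError(
                f"sex must be M/F, got {t['sex'][bad_sex].unique().tolist()}"
            )
        age = pd.to_numeric(t["age"], errors="coerce")
        if age.isna().any() or (age < 0).any() or not np.isfinite(age).all():
            raise MalformedInputError("age must be finite and >= 0 for every sample")
        key = t[["donor_id", "region", "cohort"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise MalformedInputError(
                f"duplicate (donor, region, cohort) record: {dup}"
            )
        if "neuronal_prop" in t.columns:
            npp = pd.to_numeric(t["neuronal_prop"], errors="coerce")
            ok = npp.isna() | ((npp >= 0) & (npp <= 1))
            if not ok.all():
                raise MalformedInputError("neuronal_prop must lie in [0,1] or be missing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, samples: Sequence) -> "SampleSheet":
        return SampleSheet(self.table.loc[samples])


@dataclass
class GenotypeSet:
    """SNP x sample dosage matrix with a SNP map.

    ``dosage`` entries lie in [0, 2] or are missing (NaN); ``snp_map`` is
    indexed by snp id with columns chrom, pos, effect_allele, other_allele.
    """

    dosage: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosage.index, "snp id")
        _check_unique(self.dosage.columns, "sample id")
        arr = self.dosage.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if ((arr < 0) | (arr > 2))[finite].any():
            bad = np.argwhere(finite & ((arr < 0) | (arr > 2)))[0]
            raise MalformedInputError(
                f"dosage outside [0,2] at SNP {self.dosage.index[bad[0]]!r}, "
                f"sample {self.dosage.columns[bad[1]]!r}"
            )
        missing = {"chrom", "pos", "effect_allele", "other_allele"} - set(
            self.snp_map.columns
        )
        if missing:
            raise MalformedInputError(f"snp map missing columns: {sorted(missing)}")
        if not self.snp_map.index.equals(self.dosage.index):
            raise MalformedInputError("snp map index does not match dosage rows")

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.columns

    def subset(
        self,
        snps: Optional[Sequence] = None,
        samples: Optional[Sequence] = None,
    ) -> "GenotypeSet":
        dos = self.dosage
        smap = self.snp_map
        if snps is not None:
            dos = dos.loc[snps]
            smap = smap.loc[snps]
        if samples is not None:
            dos = dos.loc[:, samples]
        return GenotypeSet(dosage=dos, snp_map=smap)


@dataclass
class ScoreFile:
    """Polygenic score weight file: one effect allele and weight per SNP."""

    table: pd.DataFrame  # index snp_id; columns effect_allele, weight

    def __post_init__(self) -> None:
        missing = {"effect_allele", "weight"} - set(self.table.columns)
        if missing:
            raise MalformedInputError(f"score file missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "snp id")
        w = self.table["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise MalformedInputError("score weights must be finite")

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)
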