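"""Readers and writers for the pipeline's on-disk formats.

All tables are plain text.  Beta values, detection p-values and beadcounts
are probes-as-rows TSV; the probe manifest is a BED-like TSV (chrom, pos,
probe_id, probe_type, flags); the sample sheet is CSV; dosages are a
PLINK-traw-like TSV with SNP map columns followed by per-sample dosages;
the score file is whitespace-delimited (snp, effect allele, weight).
Missing values are written with an explicit sentinel (default ``NA``),
never 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    BetaMatrix,
    GenotypeSet,
    MalformedInputError,
    ProbeManifest,
    REQUIRED_SHEET_COLUMNS,
    SampleSheet,
    ScoreFile,
)

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_layer",
    "write_layer",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_dosages",
    "write_dosages",
    "read_score_file",
    "write_score_file",
    "write_table",
    "read_table",
]

NA_TOKEN = "NA"



def _read_matrix_tsv(path, na_token: str = NA_TOKEN) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[na_token],
        keep_default_na=False, float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_beta_matrix(
    path,
    manifest: Optional[ProbeManifest] = None,
    detection_p_path=None,
    beadcount_path=None,
    na_token: str = NA_TOKEN,
) -> BetaMatrix:
    """Read a probes x samples beta TSV, optionally with QC layers.

    When a manifest is given, probes are re-ordered to manifest order and
    probes absent from the manifest are rejected with their ids listed.
    """
    values = _read_matrix_tsv(path, na_token)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()[:5]
        raise MalformedInputError(f"duplicate probe ids in {path}: {dups}")
    det = _read_matrix_tsv(detection_p_path, na_token) if detection_p_path else None
    bead = _read_matrix_tsv(beadcount_path, na_token) if beadcount_path else None
    if manifest is not None:
        unknown = values.index.difference(manifest.probe_ids)
        if len(unknown):
            raise MalformedInputError(
                f"probes absent from manifest: {unknown.tolist()[:10]}"
            )
        order = manifest.probe_ids[manifest.probe_ids.isin(values.index)]
        values = values.loc[order]
        if det is not None:
            det = det.loc[order]
        if bead is not None:
            bead = bead.loc[order]
    return BetaMatrix(values=values, detection_p=det, beadcount=bead)


def write_beta_matrix(beta: BetaMatrix, path, na_token: str = NA_TOKEN) -> None:
    beta.values.to_csv(path, sep="\t", na_rep=na_token)


def read_layer(path, na_token: str = NA_TOKEN) -> pd.DataFrame:
    """Read a detection-p or beadcount layer (same TSV layout as betas)."""
    return _read_matrix_tsv(path, na_token)


def write_layer(layer: pd.DataFrame, path, na_token: str = NA_TOKEN) -> None:
    layer.to_csv(path, sep="\t", na_rep=na_token)


def read_manifest(path) -> ProbeManifest:
    """Read a BED-like manifest TSV: chrom, pos, probe_id, probe_type, flags.

    ``flags`` is a ';'-joined list of flag classes, '.' or empty for none.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype={"chrom": str, "probe_id": str, "probe_type": str, "flags": str},
        na_values=[],
        keep_default_na=False,
    )
    required = {"chrom", "pos", "probe_id", "probe_type", "flags"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"manifest missing columns: {sorted(missing)}")

    def parse_flags(s: str) -> frozenset:
        s = s.strip()
        if s in ("", "."):
            return frozenset()
        return frozenset(s.split(";"))

    table = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].astype(int).to_numpy(),
            "probe_type": df["probe_type"].to_numpy(),
            "flags": [parse_flags(s) for s in df["flags"]],
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path) -> None:
    t = manifest.table
    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "pos": t["pos"],
            "probe_id": t.index,
            "probe_type": t["probe_type"],
            "flags": [";".join(sorted(fl)) if fl else "." for fl in t["flags"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path, na_token: str = NA_TOKEN) -> SampleSheet:
    df = pd.read_csv(path, na_values=[na_token], keep_default_na=False)
    missing = set(REQUIRED_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"sample sheet missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, na_token: str = NA_TOKEN) -> None:
    sheet.table.rename_axis("sample_id").reset_index().to_csv(
        path, index=False, na_rep=na_token
    )


_MAP_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele")


def read_dosages(path, na_token: str = NA_TOKEN) -> GenotypeSet:
    """Read a SNPs x samples dosage TSV with leading SNP map columns."""
    df = pd.read_csv(path, sep="\t", na_values=[na_token], keep_default_na=False)
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"dosage file missing map columns: {sorted(missing)}")
    df = df.set_index("snp_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise MalformedInputError(f"duplicate snp ids: {dups}")
    snp_map = df[["chrom", "pos", "effect_allele", "other_allele"]].copy()
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    snp_map["pos"] = snp_map["pos"].astype(int)
    snp_map["effect_allele"] = snp_map["effect_allele"].astype(str).str.upper()
    snp_map["other_allele"] = snp_map["other_allele"].astype(str).str.upper()
    dosage = df.drop(columns=list(_MAP_COLUMNS[1:])).astype(float)
    dosage.columns = dosage.columns.astype(str)
    return GenotypeSet(dosage=dosage, snp_map=snp_map)


def write_dosages(genos: GenotypeSet, path, na_token: str = NA_TOKEN) -> None:
    out = pd.concat([genos.snp_map, genos.dosage], axis=1)
    out.rename_axis("snp_id").reset_index().to_csv(
        path, sep="\t", index=False, na_rep=na_token
    )


def read_score_file(path) -> ScoreFile:
    """Read a whitespace-delimited score file: snp id, effect allele, weight."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "effect_allele", "weight"],
        dtype={"snp_id": str, "effect_allele": str},
        comment="#",
    )
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["weight"] = df["weight"].astype(float)
    df = df.set_index("snp_id")
    return ScoreFile(df)


def write_score_file(score: ScoreFile, path) -> None:
    with open(path, "w") as fh:
        for snp_id, row in score.table.iterrows():
            fh.write(f"{snp_id} {row['effect_allele']} {row['weight']:.17g}\n")


def write_table(df: pd.DataFrame, path, na_token: str = NA_TOKEN, index: bool = True) -> None:
    """Write a generic result table as TSV."""
    df.to_csv(path, sep="\t", na_rep=na_token, index=index, float_format="%.10g")


def read_table(path, na_token: str = NA_TOKEN, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col=index_col, na_values=[na_token], keep_default_na=False
    )
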