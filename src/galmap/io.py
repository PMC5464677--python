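"""Readers and writers for the pipeline interchange formats.

Tables are TSV/CSV (gzip-aware by extension), sequences FASTA, annotations
GFF3.  Coordinates are 0-based half-open internally; 1-based only at the file
boundary (VCF-like SNP tables, GFF3).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import VariantMatrix

__all__ = [
    "GeneFeature",
    "read_table",
    "write_table",
    "read_allele_counts",
    "parse_annotation",
    "read_fasta",
    "write_fasta",
    "variant_matrix_to_tsv",
    "variant_matrix_from_tsv",
    "load_config",
]

CELLS_SCHEMA = {
    "well_id": str,
    "strain_id": str,
    "role": str,
    "glucose_pct": float,
    "galactose_pct": float,
    "replicate": int,
    "yfp": float,
    "marker": float,
}
COUNTS_SCHEMA = {
    "chrom": str,
    "pos": int,
    "A_on": int,
    "B_on": int,
    "A_off": int,
    "B_off": int,
}
PHENOTYPES_SCHEMA = {
    "segregant_id": str,
    "hybrid_id": str,
    "allele": str,
    "rep1": float,
    "rep2": float,
}
GROWTH_SCHEMA = {
    "time_h": float,
    "od600": float,
    "strain_id": str,
    "condition": str,
}


@dataclass(frozen=True)
class GeneFeature:
    seqid: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str
    name: Optional[str] = None


def _sep_for(path: str) -> str:
    base = path[:-3] if path.endswith(".gz") else path
    return "," if base.endswith(".csv") else "\t"


def read_table(path: str, schema: Optional[dict] = None) -> pd.DataFrame:
    """Read a TSV/CSV (optionally gzipped) and validate column types.

    A malformed value raises with the file, 1-based line number and the
    offending field named.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    if schema is None:
        return df
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = {}
    for col, typ in schema.items():
        if typ is str:
            out[col] = df[col]
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: line {row + 2}: field {col!r} has non-numeric "
                f"value {df[col].iloc[row]!r}"
            )
        if typ is int:
            frac = converted.dropna() % 1
            if (frac != 0).any():
                row = int(converted.index[(converted % 1).fillna(0) != 0][0])
                raise ValueError(
                    f"{path}: line {row + 2}: field {col!r} must be an "
                    f"integer, got {df[col].iloc[row]!r}"
                )
            out[col] = converted.astype("Int64").astype("int64")
        else:
            out[col] = converted.astype(float)
    return pd.DataFrame(out)[list(schema)]


def write_table(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_allele_counts(path: str) -> pd.DataFrame:
    return read_table(path, COUNTS_SCHEMA)


def parse_annotation(path: str, featuretype: str = "gene") -> list[GeneFeature]:
    """Gene features from GFF3, converted to 0-based half-open coordinates."""
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        if "No lines parsed" in str(exc):
            return []  # header-only / empty annotation
        raise ValueError(f"{path}: failed to parse GFF3: {exc}") from exc
    feats = []
    for f in db.features_of_type(featuretype):
        if f.end < f.start:
            raise ValueError(
                f"{path}: feature {f.id!r} has end ({f.end}) < start ({f.start})"
            )
        feats.append(
            GeneFeature(
                seqid=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                gene_id=f.attributes.get("ID", [f.id])[0],
                name=(f.attributes.get("Name") or [None])[0],
            )
        )
    return feats


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def variant_matrix_to_tsv(matrix: VariantMatrix, path: str) -> None:
    """Strains-as-rows, sites-as-columns layout with a leading reference row."""
    cols = [str(int(p)) for p in matrix.positions]
    df = pd.DataFrame(matrix.alleles, index=matrix.strains, columns=cols)
    df.loc["reference"] = list(matrix.ref)
    df = df.reindex(["reference"] + matrix.strains)
    df.index.name = "strain"
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep=_sep_for(path))


def variant_matrix_from_tsv(
    path: str,
    cds_fasta: Optional[str] = None,
    outgroup_fasta: Optional[str] = None,
) -> VariantMatrix:
    """Parse the sites-as-columns SNP table.

    Column labels are ORF-relative positions; the row labeled ``reference``
    carries the reference alleles.  The alternate allele per site is the
    (single) non-reference allele observed among strains.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, index_col=0)
    if "reference" not in df.index:
        raise ValueError(f"{path}: missing 'reference' row")
    try:
        positions = np.array([int(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: column labels must be integer positions") from exc
    ref = df.loc["reference"].to_numpy(dtype="<U1")
    strains = [s for s in df.index if s != "reference"]
    alleles = df.loc[strains].to_numpy(dtype="<U1")
    alt = np.empty(positions.size, dtype="<U1")
    for j in range(positions.size):
        non_ref = [
            a for a in alleles[:, j] if a != ref[j] and a not in ("N", "-", ".")
        ]
        alt[j] = non_ref[0] if non_ref else ref[j]
    ref_cds = None
    outgroup = None
    if cds_fasta:
        ref_cds = next(iter(read_fasta(cds_fasta).values()))
    if outgroup_fasta:
        outgroup = next(iter(read_fasta(outgroup_fasta).values()))
    return VariantMatrix(
        strains=strains,
        positions=positions,
        ref=ref,
        alt=alt,
        alleles=alleles,
        ref_cds=ref_cds,
        outgroup_cds=outgroup,
    )


def load_config(path: str) -> dict:
    """YAML or JSON configuration as a plain dict."""
    with open(path) as fh:
        if path.endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def dump_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)
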