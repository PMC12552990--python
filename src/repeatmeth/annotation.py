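"""Probe annotation manifests: genomic location, island context, platform flags.

A manifest is a DataFrame with one row per probe and the columns

``probe_id, chrom, pos, island_relation, gene, in_region,
epicv2, epicv1, m450k, m27k, qc_flags``

where ``pos`` is 1-based, ``in_region`` marks probes inside the target gene
+/- 1 kb, the four platform columns are 0/1 presence flags for successive
Illumina array generations, and ``qc_flags`` is a semicolon-joined subset of
:data:`QC_FLAGS`.

The packaged manifest :func:`load_locus_manifest` covers the 23 EPICv2 CpG
probes at the C9orf72 locus (chr9, within the gene and 1 kb flanks); probe
content shrinks to 12 (EPICv1), 5 (Methyl450K) and 2 (Methyl27K) on older
platforms.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PLATFORMS",
    "ISLAND_RELATIONS",
    "QC_FLAGS",
    "parse_qc_flags",
    "read_probe_annotation",
    "write_probe_annotation",
    "load_locus_manifest",
]

#: Platform flag columns, newest array generation first.
PLATFORMS = ("epicv2", "epicv1", "m450k", "m27k")

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")

QC_FLAGS = (
    "low_detection",
    "sex_chromosome",
    "snp_overlap",
    "cross_reactive",
    "manufacturer_flagged",
)

_REQUIRED = (
    "probe_id", "chrom", "pos", "island_relation", "gene", "in_region",
    *PLATFORMS, "qc_flags",
)


def parse_qc_flags(value) -> set[str]:
    """Parse a semicolon-joined qc_flags cell into a set (empty-safe)."""
    if isinstance(value, set):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    text = str(value).strip()
    if not text:
        return set()
    return {f.strip() for f in text.split(";") if f.strip()}


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in _REQUIRED if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation missing columns: {missing_cols}")
    if ann["probe_id"].duplicated().any():
        dups = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids in annotation: {dups[:10]}")
    if (ann["pos"] <= 0).any():
        raise ValueError("annotation positions must be positive (1-based)")
    bad_rel = set(ann["island_relation"]) - set(ISLAND_RELATIONS)
    if bad_rel:
        raise ValueError(f"unknown island_relation values: {sorted(bad_rel)}")
    for _, row in ann.iterrows():
        flags = parse_qc_flags(row["qc_flags"])
        unknown = flags - set(QC_FLAGS)
        if unknown:
            raise ValueError(
                f"unknown qc flags for {row['probe_id']}: {sorted(unknown)}"
            )
        if "sex_chromosome" in flags and str(row["chrom"]) not in ("chrX", "chrY"):
            raise ValueError(
                f"probe {row['probe_id']} flagged sex_chromosome but on "
                f"{row['chrom']}"
            )
    return ann


def read_probe_annotation(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a probe manifest from delimited text."""
    path = Path(path)
    sep = sep or ("," if path.suffix.lower() == ".csv" else "\t")
    ann = pd.read_csv(path, sep=sep, dtype={"qc_flags": str}, keep_default_na=False)
    ann["qc_flags"] = ann["qc_flags"].replace({"NA": ""})
    ann["pos"] = ann["pos"].astype(int)
    for col in ("in_region", *PLATFORMS):
        ann[col] = ann[col].astype(int).astype(bool)
    return validate_annotation(ann)


def write_probe_annotation(ann: pd.DataFrame, path, sep: str = "\t") -> None:
    out = ann.copy()
    for col in ("in_region", *PLATFORMS):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=sep, index=False)


def load_locus_manifest() -> pd.DataFrame:
    """Load the packaged 23-probe C9orf72 locus manifest.

    Positions are 1-based coordinates on chr9 carried through verbatim from
    the array manifests; island relations for probes without a published
    context are inferred from position relative to the locus CpG island.
    """
    ref = resources.files("repeatmeth.data").joinpath("c9orf72_locus.tsv")
    with resources.as_file(ref) as path:
        return read_probe_annotation(path)
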