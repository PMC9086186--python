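"""Tabular interchange: the variant-table TSV dialect, cohort tables and
FASTA loading.

The variant-table dialect is one row per call with columns
``sample_id, chrom, pos, ref, alt, geno, vtype`` (annotation appends
``region, effect, gene_id, cds``); tab-separated with a header line.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .variants import SampleVariantSet, VariantCall, make_call

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "geno", "vtype"]


def read_fasta(path: str) -> dict:
    """Load a FASTA file into {name: uppercase sequence} (soft-masked
    lowercase bases are uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def calls_to_frame(samples: Iterable[SampleVariantSet]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for c in s.calls:
            k = c.key
            rows.append((c.sample_id, k.chrom, k.pos, k.ref, k.alt, k.geno, c.vtype))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def frame_to_samples(
    df: pd.DataFrame,
    cohort: pd.DataFrame,
) -> list[SampleVariantSet]:
    """Rebuild SampleVariantSets from a variant table plus a cohort table
    (``sample_id, group, clean_bases``).  Samples with no calls are kept
    (empty sets)."""
    by_sample: dict[str, list[VariantCall]] = {sid: [] for sid in cohort["sample_id"]}
    for row in df.itertuples(index=False):
        if row.sample_id not in by_sample:
            raise ValueError(f"variant table sample {row.sample_id!r} missing from cohort table")
        by_sample[row.sample_id].append(
            make_call(row.sample_id, row.chrom, int(row.pos), row.ref, row.alt,
                      None if pd.isna(row.geno) else row.geno)
        )
    out = []
    for rec in cohort.itertuples(index=False):
        out.append(
            SampleVariantSet(
                rec.sample_id, rec.group, by_sample[rec.sample_id], int(rec.clean_bases)
            )
        )
    return out


def write_variant_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str, "geno": str},
    )


def read_cohort_table(path: str) -> pd.DataFrame:
    """Cohort configuration TSV: sample_id, group, clean_bases [, vcf]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "clean_bases"}
    if not required <= set(df.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    return df
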