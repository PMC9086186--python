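"""Bundled per-sample summary tables from a published EMS mutagenesis
screen in the bay scallop (4 untreated controls, 12 treated animals
stratified as 5 large / 5 normal / 2 small).

The tables carry, per animal: sequencing clean-base totals, the
group-specific ("unique") SNP counts with transition/transversion and
region breakdowns, codon-level SNP effect counts, and InDel counts
before and after shared-type removal.  ``headline_summary`` pushes them
through the burden-statistics layer to recompute the screen's summary
numbers (group means +- SD, rates, class percentages, fold change).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import stats

_FILES = {
    "sequencing": "scallop_sequencing.tsv",
    "snp_unique": "scallop_snp_unique.tsv",
    "snp_effects": "scallop_snp_effects.tsv",
    "indel_unique": "scallop_indel_unique.tsv",
    "indel_raw": "scallop_indel_raw.tsv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load one bundled table by short name.

    Names: ``sequencing`` (clean bases and group labels), ``snp_unique``
    (unique SNP counts, Ts/Tv, exonic/intronic, rate), ``snp_effects``
    (synonymous/nonsynonymous/stopgain/stoploss), ``indel_unique`` and
    ``indel_raw`` (InDel counts after/before shared-type removal).
    """
    if name not in _FILES:
        raise KeyError(f"unknown table {name!r}; available: {sorted(_FILES)}")
    ref = resources.files("mutburden.data") / _FILES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_cohort() -> pd.DataFrame:
    """Joined per-sample table: group, clean bases, SNP and InDel counts
    and effect classes, plus recomputed per-sample rates and class
    percentages (full precision, not the printed roundings)."""
    seq = load_table("sequencing")[["sample_id", "group", "clean_bases"]]
    snp = load_table("snp_unique")
    eff = load_table("snp_effects")
    ind = load_table("indel_unique")[["sample_id", "genome_total", "cds_total"]]
    ind = ind.rename(columns={"genome_total": "indel_number", "cds_total": "indel_cds"})
    df = seq.merge(snp, on="sample_id").merge(eff, on="sample_id").merge(ind, on="sample_id")
    df["rate_snp"] = [
        stats.mutation_rate(n, b) for n, b in zip(df["snp_number"], df["clean_bases"])
    ]
    df["rate_indel"] = [
        stats.mutation_rate(n, b) for n, b in zip(df["indel_number"], df["clean_bases"])
    ]
    df["rate_total"] = df["rate_snp"] + df["rate_indel"]
    df["pct_exonic"] = [
        stats.class_percentage(k, n) for k, n in zip(df["exonic"], df["snp_number"])
    ]
    df["pct_intronic"] = [
        stats.class_percentage(k, n) for k, n in zip(df["intronic"], df["snp_number"])
    ]
    df["pct_syn"] = [
        stats.class_percentage(k, n) for k, n in zip(df["synonymous"], df["snp_number"])
    ]
    df["pct_nonsyn"] = [
        stats.class_percentage(k, n) for k, n in zip(df["nonsynonymous"], df["snp_number"])
    ]
    df["pct_stop"] = [
        stats.class_percentage(sg + sl, n)
        for sg, sl, n in zip(df["stopgain"], df["stoploss"], df["snp_number"])
    ]
    df["pct_indel_cds"] = [
        stats.class_percentage(k, n) for k, n in zip(df["indel_cds"], df["indel_number"])
    ]
    return df


def headline_summary() -> dict:
    """Recompute the screen's summary numbers from the bundled tables.

    Returns a flat dict of group means/SDs of unique SNP and InDel
    counts, mutation rates, the treated/control fold change (raw and
    rounded), and the treated-group exonic and nonsynonymous SNP
    percentages.  All values are full precision.
    """
    df = load_cohort()
    ctrl = df[df["group"] == "control"]
    trt = df[df["group"] != "control"]

    def agg(sub: pd.DataFrame, col: str, grp: str) -> stats.GroupSummary:
        return stats.group_aggregate(sub[col].to_numpy(), grp, col)

    out: dict[str, float] = {}
    for grp, sub in (("control", ctrl), ("treated", trt)):
        for col in (
            "snp_number", "indel_number", "rate_snp", "rate_indel", "rate_total",
            "pct_exonic", "pct_syn", "pct_nonsyn", "pct_stop", "pct_indel_cds",
        ):
            g = agg(sub, col, grp)
            out[f"{grp}_mean_{col}"] = g.mean
            out[f"{grp}_sd_{col}"] = g.sd
    out["fold_change_total_rate"] = stats.fold_change(
        out["treated_mean_rate_total"], out["control_mean_rate_total"]
    )
    out["fold_change_rounded"] = stats.rounded(out["fold_change_total_rate"])
    out["control_1_rate_snp"] = stats.mutation_rate(
        int(df.loc[df.sample_id == "Control_1", "snp_number"].iloc[0]),
        int(df.loc[df.sample_id == "Control_1", "clean_bases"].iloc[0]),
    )
    return out
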