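"""End-to-end orchestration: filter -> annotate -> stats -> enrichment ->
exclusive screen, with a manifest for reproducibility.

``run_pipeline`` consumes a cohort table pointing at per-sample VCFs, a
reference FASTA and a GFF3, and writes the report bundle.  A
``from-tables`` mode feeds pre-tallied per-sample summary tables (such
as the bundled scallop screen tables) through the same burden-statistics
layer, skipping the variant-level stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__
from .annotate import (
    DEFAULT_UPSTREAM_WINDOW,
    annotate_sample,
    build_gene_index,
    read_gff3,
    validate_gene_models,
)
from .enrich import enrich, read_term_map, results_frame
from .filtering import SharedSetPolicy, filter_cohort
from .io import read_cohort_table, read_fasta, write_variant_table
from .screen import build_presence_matrix, exclusive_genes
from .stats import compare_groups, group_summary_table, sample_summary, summaries_frame
from .variants import TREATED_GROUPS, read_vcf

logger = logging.getLogger(__name__)

#: metrics compared between control and pooled treated groups
COMPARED_METRICS = ("n_snp", "n_indel", "ts_tv", "rate_snp", "rate_indel", "rate_total")


@dataclass
class RunConfig:
    cohort: str  # cohort TSV with sample_id, group, clean_bases, vcf
    fasta: str
    gff3: str
    outdir: str
    term_map: str | None = None
    shared_mode: str = "control_union"  # treated policy; controls go leave-one-out
    key_ignore_geno: bool = False
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW
    min_target_samples: int = 1
    normalize: bool = True
    denominator: str = "clean-bases"  # or "genome-size" for per-genome rates

    def validate(self) -> None:
        for p in (self.cohort, self.fasta, self.gff3, self.term_map):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle.

    Outputs: annotated variant table, per-sample summary, group summary,
    comparison table, enrichment table (when a term map is given),
    presence matrix, exclusive gene lists, and a JSON manifest.  Rerun
    with identical inputs is bit-identical.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    paths: dict[str, str] = {}

    genome = read_fasta(config.fasta)
    models = read_gff3(config.gff3)
    validate_gene_models(models, genome)
    index = build_gene_index(models, config.upstream_window)
    cohort = read_cohort_table(config.cohort)
    if "vcf" not in cohort.columns:
        raise ValueError("pipeline cohort table needs a 'vcf' column")

    base = os.path.dirname(os.path.abspath(config.cohort))
    logger.info("reading %d sample VCFs", len(cohort))
    samples = [
        read_vcf(
            rec.vcf if os.path.isabs(rec.vcf) else os.path.join(base, rec.vcf),
            rec.sample_id,
            group=rec.group, clean_bases=int(rec.clean_bases),
            reference=genome if config.normalize else None,
        )
        for rec in cohort.itertuples(index=False)
    ]

    policy = SharedSetPolicy(
        mode=config.shared_mode if config.shared_mode != "control_union" else "control_union",
        ignore_geno=config.key_ignore_geno,
    )
    unique = filter_cohort(samples, policy)
    for raw, u in zip(samples, unique):
        logger.info("filter %s: %d -> %d calls", raw.sample_id, len(raw), len(u))

    annotated = pd.concat(
        [annotate_sample(s, index, genome) for s in unique], ignore_index=True
    )
    paths["annotated"] = out("annotated_variants.tsv")
    write_variant_table(annotated, paths["annotated"])

    if config.denominator == "genome-size":
        denom = {s.sample_id: sum(len(seq) for seq in genome.values()) for s in unique}
    elif config.denominator == "clean-bases":
        denom = {s.sample_id: s.clean_bases for s in unique}
    else:
        raise ValueError("denominator must be 'clean-bases' or 'genome-size'")
    summaries = [
        sample_summary(
            annotated[annotated["sample_id"] == s.sample_id],
            denom[s.sample_id], sample_id=s.sample_id, group=s.group,
        )
        for s in unique
    ]
    per_sample = summaries_frame(summaries)
    paths["per_sample_summary"] = out("per_sample_summary.tsv")
    per_sample.to_csv(paths["per_sample_summary"], sep="\t", index=False)

    groups = group_summary_table(per_sample)
    pooled = per_sample.assign(
        group=per_sample["group"].map(lambda g: "control" if g == "control" else "treated")
    )
    groups = pd.concat([groups, group_summary_table(pooled)], ignore_index=True)
    paths["group_summary"] = out("group_summary.tsv")
    groups.to_csv(paths["group_summary"], sep="\t", index=False)

    comp_rows = []
    ctrl = per_sample[per_sample["group"] == "control"]
    trt = per_sample[per_sample["group"] != "control"]
    for metric in COMPARED_METRICS:
        r = compare_groups(
            {"control": ctrl[metric].to_numpy(), "treated": trt[metric].to_numpy()},
            metric=metric,
        )
        comp_rows.append(
            {
                "metric": metric, "test": r.test, "transform": r.transform,
                "levene_p": r.levene_p, "statistic": r.statistic,
                "p_value": r.p_value, "significant": r.significant,
            }
        )
    paths["comparisons"] = out("comparisons.tsv")
    pd.DataFrame(comp_rows).to_csv(paths["comparisons"], sep="\t", index=False)

    group_labels = dict(zip(cohort["sample_id"], cohort["group"]))
    matrix = build_presence_matrix(annotated, group_labels)
    paths["presence_matrix"] = out("presence_matrix.tsv")
    matrix.cells.astype(int).to_csv(paths["presence_matrix"], sep="\t")

    for target, fname in (("treated_large", "exclusive_large.tsv"),
                          ("treated_small", "exclusive_small.tsv")):
        excluded = [g for g in ("control", *TREATED_GROUPS) if g != target]
        genes = exclusive_genes(
            matrix, target, excluded, min_target_samples=config.min_target_samples
        )
        key = f"exclusive_{target.split('_')[1]}"
        paths[key] = out(fname)
        pd.Series(genes, name="gene_id").to_csv(paths[key], sep="\t", index=False)

    if config.term_map:
        terms = read_term_map(config.term_map)
        universe = sorted({m.gene_id for m in models})
        frames = []
        for group in ("control", *TREATED_GROUPS):
            sids = [s for s, g in group_labels.items() if g == group]
            query = sorted(
                set(
                    annotated[
                        annotated["sample_id"].isin(sids)
                        & (annotated["effect"] == "nonsynonymous")
                    ]["gene_id"]
                )
                - {""}
            )
            if not query:
                continue
            df = results_frame(enrich(query, terms, universe))
            df.insert(0, "group", group)
            frames.append(df)
        paths["enrichment"] = out("enrichment.tsv")
        pd.concat(frames, ignore_index=True).to_csv(paths["enrichment"], sep="\t", index=False)

    manifest = {
        "tool": "mutburden",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            p: _sha256(p)
            for p in [config.cohort, config.fasta, config.gff3, config.term_map]
            if p
        },
        "outputs": {k: _sha256(v) for k, v in sorted(paths.items())},
    }
    paths["manifest"] = out("manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def run_from_tables(outdir: str) -> dict:
    """Reproduce the summary statistics of the bundled scallop screen
    tables through the same burden-statistics layer (no variant-level
    stages)."""
    from .datasets import headline_summary, load_cohort

    os.makedirs(outdir, exist_ok=True)
    df = load_cohort()
    per_sample = os.path.join(outdir, "per_sample_summary.tsv")
    df.to_csv(per_sample, sep="\t", index=False)

    summary = headline_summary()
    headline = os.path.join(outdir, "headline_summary.json")
    with open(headline, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"per_sample_summary": per_sample, "headline_summary": headline}
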