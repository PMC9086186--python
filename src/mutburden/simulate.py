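"""Synthetic EMS-screening cohorts with full ground truth.

The generator emulates the study design the pipeline targets: a small
untreated control panel and a mutagenized cohort stratified by growth
phenotype (large / normal / small), all drawn from one founder
population.  Every animal carries

* *shared* variants drawn from a standing-polymorphism pool (these are
  what shared-type filtering removes), and
* *private* mutations sampled per individual under a mutational
  spectrum: per-base event rate, transition fraction (EMS treatment is
  transition-biased, raising Ts/Tv), a G:C-origin bias for transitions
  (EMS alkylates guanine), an InDel share, and a multiplicative
  depletion of events inside CDS (survivor selection against coding
  damage).

Designated "exclusive" genes model phenotype-causing loci: their CDS is
excluded from random mutation in every sample and nonsynonymous SNPs
are planted only in the samples of the designated phenotype group, so
truth-set recovery by the exclusive screen is a construction guarantee.

Pool variants default to high population frequency with a fixed
genotype class per variant, so a 4-animal control panel captures
essentially all shared types; the residual leakage of shared variants
through the panel is then negligible next to the configured private
rates.  Real cohorts segregate rarer polymorphisms and leak more.

All randomness flows from a single integer seed through spawned
``numpy`` generators; identical seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, coding_effect, write_gff3
from .variants import (
    BASES,
    SampleVariantSet,
    VariantCall,
    make_call,
    normalize_variant,
    write_vcf,
)

_STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: probability a private mutation is called heterozygous (mosaic G0 tissue)
PRIVATE_HET_PROB = 0.9


@dataclass(frozen=True)
class SpectrumConfig:
    """Mutational spectrum of one experimental arm.

    per_base_rate
        Expected private mutations per genome bp per individual.
    transition_fraction
        Probability a private SNP is a transition; the realized Ts/Tv of
        a large unique set converges to f/(1-f).
    gc_at_bias
        Probability a transition originates at a G:C site.
    indel_fraction
        Share of private events that are InDels rather than SNPs.
    indel_size_geometric_p
        Success parameter of the (>=1, capped at 10 bp) geometric InDel
        size distribution.
    coding_depletion
        Multiplicative factor (<1) on event probability inside CDS.
    """

    per_base_rate: float
    transition_fraction: float = 0.528
    gc_at_bias: float = 0.5
    indel_fraction: float = 0.166
    indel_size_geometric_p: float = 0.5
    coding_depletion: float = 0.95

    def __post_init__(self) -> None:
        if self.per_base_rate < 0:
            raise ValueError("per_base_rate must be >= 0")
        for name in (
            "transition_fraction", "gc_at_bias", "indel_fraction",
            "indel_size_geometric_p", "coding_depletion",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: Control arm: rate calibrated to ~1.3e-4 unique mutations per genome bp
#: (the spontaneous background of the study cohort scaled per bp), with the
#: control unique-set Ts/Tv of ~1.07 and InDel share ~0.24.
CONTROL_SPECTRUM = SpectrumConfig(
    per_base_rate=1.3e-4,
    transition_fraction=0.517,
    gc_at_bias=0.5,
    indel_fraction=0.24,
)

#: Treated arm: 9x the control rate, Ts/Tv ~1.12, InDel share ~0.17,
#: transitions biased toward G:C origins.
TREATED_SPECTRUM = SpectrumConfig(
    per_base_rate=9 * 1.3e-4,
    transition_fraction=0.528,
    gc_at_bias=0.7,
    indel_fraction=0.166,
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults describe a 1 Mb, 2-chromosome genome at 35% GC with 60
    multi-exon genes, a 4-control / 5+5+2-treated cohort, a shared pool
    of ~5.5e-3 polymorphic sites per bp, and treated/control private
    rates in ratio 9.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 2
    gc_content: float = 0.35
    n_genes: int = 60
    exons_per_gene: int = 3
    cds_exon_length: int = 150  # bp of CDS per exon, multiple of 3
    intron_length: int = 120
    utr_length: int = 30
    control_n: int = 4
    large_n: int = 5
    normal_n: int = 5
    small_n: int = 2
    shared_pool_rate: float = 5.5e-3
    pool_indel_fraction: float = 0.24
    pool_transition_fraction: float = 0.531
    pool_freq_range: tuple[float, float] = (0.90, 1.00)
    control_spectrum: SpectrumConfig = CONTROL_SPECTRUM
    treated_spectrum: SpectrumConfig = TREATED_SPECTRUM
    clean_bases_mean: float = 1.1e7  # ~11x coverage of the default genome
    clean_bases_sd: float = 8.8e5
    n_exclusive_large: int = 3
    n_exclusive_small: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_exon_length % 3:
            raise ValueError("cds_exon_length must be a multiple of 3")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")

    @property
    def treated_n(self) -> int:
        return self.large_n + self.normal_n + self.small_n


@dataclass(frozen=True)
class PoolVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    geno: str
    freq: float


@dataclass
class CohortResult:
    """A generated cohort plus its complete ground truth."""

    config: CohortConfig
    genome: dict
    contigs: dict  # chrom -> length
    models: list
    pool: list
    samples: list  # SampleVariantSet, cohort order
    exclusive_truth: dict  # group -> sorted gene_ids
    private_truth: pd.DataFrame  # sample_id, chrom, pos, ref, alt, geno, planted
    clean_bases: dict

    def cohort_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "clean_bases": [s.clean_bases for s in self.samples],
            }
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in _STOP_CODONS
    ]
    middle = rng.choice(codons, size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "ATG" + "".join(middle) + stop


def simulate_genome(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[dict, list]:
    """Random genome plus non-overlapping, structurally valid gene models.

    Every gene has ``exons_per_gene`` exons with terminal UTRs; its CDS
    starts with ATG, is in frame, ends in a stop codon and contains no
    internal stop, on a randomly chosen strand.  Deterministic under the
    config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    per_chrom = config.genome_length // config.n_chroms
    chroms = {f"chr{i + 1}": per_chrom for i in range(config.n_chroms)}
    arrays = {c: _random_sequence(rng, L, config.gc_content) for c, L in chroms.items()}

    k = config.exons_per_gene
    gene_span = 2 * config.utr_length + k * config.cds_exon_length + (k - 1) * config.intron_length
    min_gap = 2000  # leaves room for upstream windows between genes
    chrom_names = list(chroms)
    per_chrom_genes = {
        c: len(range(i, config.n_genes, config.n_chroms))
        for i, c in enumerate(chrom_names)
    }
    starts: dict[str, list[int]] = {}
    for c in chrom_names:
        n = per_chrom_genes[c]
        free = chroms[c] - n * gene_span - (n + 1) * min_gap
        if free < 0:
            raise ValueError(
                f"cannot pack {config.n_genes} genes of span {gene_span} bp into "
                f"{config.genome_length} bp with room for upstream windows"
            )
        # random gaps normalized to exactly fill the free space above the minimum
        raw = rng.uniform(0.5, 1.5, size=n + 1)
        extra = np.floor(raw / raw.sum() * free).astype(int)
        gaps = extra + min_gap
        pos, out = 0, []
        for i in range(n):
            pos += gaps[i]
            out.append(pos)  # 0-based start of gene span
            pos += gene_span
        starts[c] = out

    models: list[GeneModel] = []
    taken = {c: 0 for c in chrom_names}
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chroms]
        start = starts[chrom][taken[chrom]]
        taken[chrom] += 1

        gene_id = f"gene{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cds = []
        cursor = start + 1  # 1-based
        for e in range(k):
            exon_start = cursor
            seg_len = config.cds_exon_length
            if e == 0:
                cds_start = exon_start + config.utr_length
                exon_end = cds_start + seg_len - 1
                if k == 1:
                    exon_end += config.utr_length
            elif e == k - 1:
                cds_start = exon_start
                exon_end = cds_start + seg_len - 1 + config.utr_length
            else:
                cds_start = exon_start
                exon_end = cds_start + seg_len - 1
            cds.append((cds_start, cds_start + seg_len - 1))
            exons.append((exon_start, exon_end))
            cursor = exon_end + config.intron_length + 1
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            cds_segments=tuple(cds),
        )
        # write a valid CDS into the genome
        n_codons = (k * config.cds_exon_length) // 3
        transcript_cds = _random_cds(rng, n_codons)
        genomic_cds = (
            transcript_cds
            if strand == "+"
            else transcript_cds.translate(_COMPLEMENT)[::-1]
        )
        offset = 0
        for s, e in model.cds_segments:
            seg = genomic_cds[offset: offset + (e - s + 1)]
            arrays[chrom][s - 1: e] = np.frombuffer(seg.encode(), dtype="S1")
            offset += e - s + 1
        models.append(model)

    genome = {c: arr.tobytes().decode() for c, arr in arrays.items()}
    return genome, models


class _GenomeSampler:
    """Cached position machinery for drawing mutation sites."""

    def __init__(self, genome: Mapping[str, str], models: Sequence[GeneModel], masked_genes: set):
        self.chroms = list(genome)
        self.lengths = np.array([len(genome[c]) for c in self.chroms])
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total = int(self.lengths.sum())
        seq = "".join(genome[c] for c in self.chroms).encode()
        arr = np.frombuffer(seq, dtype="S1")
        self.base = arr
        is_gc = (arr == b"G") | (arr == b"C")
        self.gc_idx = np.where(is_gc)[0]
        self.at_idx = np.where(~is_gc)[0]
        self.cds_mask = np.zeros(self.total, dtype=bool)
        self.masked = np.zeros(self.total, dtype=bool)
        for m in models:
            off = self.offsets[self.chroms.index(m.chrom)]
            for s, e in m.cds_segments:
                self.cds_mask[off + s - 1: off + e] = True
                if m.gene_id in masked_genes:
                    self.masked[off + s - 1: off + e] = True

    def to_coord(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.chroms[i], int(gpos - self.offsets[i] + 1)

    def base_at(self, gpos: int) -> str:
        return self.base[gpos].decode()


def simulate_shared_pool(
    genome: Mapping[str, str],
    rate: float,
    rng: np.random.Generator,
    *,
    indel_fraction: float = 0.24,
    transition_fraction: float = 0.531,
    freq_range: tuple[float, float] = (0.90, 1.00),
    indel_size_p: float = 0.5,
    sampler: "_GenomeSampler | None" = None,
) -> list[PoolVariant]:
    """Standing polymorphisms: Poisson(rate x genome length) sites, each
    with a population carrier frequency and a fixed genotype class.
    Keys are unique by construction."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if sampler is None:
        sampler = _GenomeSampler(genome, [], set())
    n = int(rng.poisson(rate * sampler.total))
    if n == 0:
        return []
    positions = rng.choice(sampler.total, size=min(n, sampler.total), replace=False)
    positions = np.sort(positions[~sampler.masked[positions]])
    pool: list[PoolVariant] = []
    for gpos in positions:
        chrom, pos = sampler.to_coord(int(gpos))
        ref = sampler.base_at(int(gpos))
        if rng.random() < indel_fraction:
            pos, ref, alt = _random_indel(genome, chrom, pos, rng, indel_size_p)
            if ref is None:
                continue
        else:
            alt = _random_snp_alt(ref, rng, transition_fraction)
        geno = "het" if rng.random() < 0.5 else "hom_alt"
        freq = float(rng.uniform(*freq_range))
        pool.append(PoolVariant(chrom, pos, ref, alt, geno, freq))
    # de-duplicate keys after InDel normalization
    seen = set()
    out = []
    for v in pool:
        key = (v.chrom, v.pos, v.ref, v.alt, v.geno)
        if key not in seen:
            seen.add(key)
            out.append(v)
    return out


def _random_snp_alt(ref: str, rng: np.random.Generator, transition_fraction: float) -> str:
    from .variants import _TRANSITION_PARTNER

    if rng.random() < transition_fraction:
        return _TRANSITION_PARTNER[ref]
    choices = sorted(BASES - {ref, _TRANSITION_PARTNER[ref]})
    return choices[int(rng.integers(2))]


def _random_indel(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    rng: np.random.Generator,
    size_p: float,
) -> tuple[int, str | None, str | None]:
    """Anchored insertion or deletion at pos, normalized (left-aligned)."""
    seq = genome[chrom]
    size = min(int(rng.geometric(size_p)), 10)
    anchor = seq[pos - 1]
    if rng.random() < 0.5:  # insertion
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
        ref, alt = anchor, anchor + ins
    else:  # deletion
        if pos + size > len(seq):
            return pos, None, None
        ref, alt = seq[pos - 1: pos + size], anchor
    pos, ref, alt = normalize_variant(chrom, pos, ref, alt, genome)
    return pos, ref, alt


def simulate_sample(
    genome: Mapping[str, str],
    pool: Sequence[PoolVariant],
    spectrum: SpectrumConfig,
    sample_id: str,
    group: str,
    clean_bases: int,
    rng: np.random.Generator,
    sampler: _GenomeSampler,
    planted: Sequence[VariantCall] = (),
) -> tuple[SampleVariantSet, list]:
    """One individual: pool variants drawn by frequency plus private
    mutations under the spectrum.  Returns the sample and its private
    truth records (dicts with a ``planted`` flag)."""
    calls: list[VariantCall] = []
    used = set()

    for v in pool:
        if rng.random() < v.freq:
            call = make_call(sample_id, v.chrom, v.pos, v.ref, v.alt, v.geno)
            if call.key not in used:
                used.add(call.key)
                calls.append(call)

    truth = []
    n_events = int(rng.poisson(spectrum.per_base_rate * sampler.total))
    made = 0
    attempts = 0
    while made < n_events and attempts < 50 * n_events + 1000:
        attempts += 1
        is_indel = rng.random() < spectrum.indel_fraction
        is_transition = (not is_indel) and rng.random() < spectrum.transition_fraction
        if is_transition:
            idx = sampler.gc_idx if rng.random() < spectrum.gc_at_bias else sampler.at_idx
            gpos = int(idx[rng.integers(len(idx))])
        else:
            gpos = int(rng.integers(sampler.total))
        if sampler.masked[gpos]:
            continue
        if sampler.cds_mask[gpos] and rng.random() > spectrum.coding_depletion:
            continue
        chrom, pos = sampler.to_coord(gpos)
        ref = sampler.base_at(gpos)
        if is_indel:
            pos, ref, alt = _random_indel(genome, chrom, pos, rng, spectrum.indel_size_geometric_p)
            if ref is None:
                continue
        else:
            if is_transition:
                from .variants import _TRANSITION_PARTNER

                alt = _TRANSITION_PARTNER[ref]
            else:
                alt = _random_snp_alt(ref, rng, 0.0)
        geno = "het" if rng.random() < PRIVATE_HET_PROB else "hom_alt"
        call = make_call(sample_id, chrom, pos, ref, alt, geno)
        if call.key in used:
            continue
        used.add(call.key)
        calls.append(call)
        truth.append(
            {
                "sample_id": sample_id, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "geno": geno,
                "vtype": call.vtype, "planted": False,
            }
        )
        made += 1

    for call in planted:
        if call.key in used:
            continue
        used.add(call.key)
        calls.append(call)
        k = call.key
        truth.append(
            {
                "sample_id": sample_id, "chrom": k.chrom, "pos": k.pos,
                "ref": k.ref, "alt": k.alt, "geno": k.geno,
                "vtype": call.vtype, "planted": True,
            }
        )

    sample = SampleVariantSet(sample_id, group, calls, clean_bases)
    return sample, truth


def _plant_nonsyn(
    model: GeneModel,
    genome: Mapping[str, str],
    sample_id: str,
    rng: np.random.Generator,
) -> VariantCall:
    """A random nonsynonymous SNP inside a gene's CDS."""
    positions = model.cds_positions()
    for _ in range(200):
        pos = int(positions[rng.integers(len(positions))])
        ref = genome[model.chrom][pos - 1]
        for alt in rng.permutation(sorted(BASES - {ref})):
            call = make_call(sample_id, model.chrom, pos, ref, str(alt), "het")
            if coding_effect(call, model, genome) == "nonsynonymous":
                return call
    raise RuntimeError(f"could not plant a nonsynonymous SNP in {model.gene_id}")


def simulate_cohort(config: CohortConfig | None = None) -> CohortResult:
    """Generate the full cohort: genome, gene models, shared pool,
    per-sample variant sets, and ground-truth tables."""
    config = config or CohortConfig()
    ss = np.random.SeedSequence([config.seed, 0])
    (genome_seed, pool_seed, design_seed, clean_seed, sample_root) = ss.spawn(5)

    genome, models = simulate_genome(config, np.random.default_rng(genome_seed))
    contigs = {c: len(genome[c]) for c in genome}

    design_rng = np.random.default_rng(design_seed)
    n_excl = config.n_exclusive_large + config.n_exclusive_small
    excl_models = [models[i] for i in design_rng.choice(len(models), size=n_excl, replace=False)]
    large_genes = excl_models[: config.n_exclusive_large]
    small_genes = excl_models[config.n_exclusive_large:]
    masked_genes = {m.gene_id for m in excl_models}
    exclusive_truth = {
        "treated_large": sorted(m.gene_id for m in large_genes),
        "treated_small": sorted(m.gene_id for m in small_genes),
    }

    sampler = _GenomeSampler(genome, models, masked_genes)
    pool = simulate_shared_pool(
        genome,
        config.shared_pool_rate,
        np.random.default_rng(pool_seed),
        indel_fraction=config.pool_indel_fraction,
        transition_fraction=config.pool_transition_fraction,
        freq_range=config.pool_freq_range,
        sampler=sampler,
    )

    layout: list[tuple[str, str]] = []
    for i in range(config.control_n):
        layout.append((f"Control_{i + 1}", "control"))
    t = 0
    for group, n in (
        ("treated_large", config.large_n),
        ("treated_normal", config.normal_n),
        ("treated_small", config.small_n),
    ):
        for _ in range(n):
            t += 1
            layout.append((f"Treated_{t}", group))

    clean_rng = np.random.default_rng(clean_seed)
    clean = {
        sid: int(max(0.2 * config.clean_bases_mean,
                     clean_rng.normal(config.clean_bases_mean, config.clean_bases_sd)))
        for sid, _ in layout
    }

    samples = []
    truth_rows: list[dict] = []
    sample_seeds = sample_root.spawn(len(layout))
    for (sid, group), seed in zip(layout, sample_seeds):
        rng = np.random.default_rng(seed)
        spectrum = config.control_spectrum if group == "control" else config.treated_spectrum
        planted = []
        if group == "treated_large":
            planted = [_plant_nonsyn(m, genome, sid, rng) for m in large_genes]
        elif group == "treated_small":
            planted = [_plant_nonsyn(m, genome, sid, rng) for m in small_genes]
        sample, truth = simulate_sample(
            genome, pool, spectrum, sid, group, clean[sid], rng, sampler, planted
        )
        samples.append(sample)
        truth_rows.extend(truth)

    return CohortResult(
        config=config,
        genome=genome,
        contigs=contigs,
        models=models,
        pool=pool,
        samples=samples,
        exclusive_truth=exclusive_truth,
        private_truth=pd.DataFrame(
            truth_rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "geno", "vtype", "planted"],
        ),
        clean_bases=clean,
    )


def random_term_map(
    genes: Sequence[str],
    n_terms: int,
    genes_per_term: int,
    rng: np.random.Generator,
    category: str = "BP",
):
    """Random annotation terms over a gene universe (for enrichment
    exercises and null calibration)."""
    from .enrich import TermMap

    genes = list(genes)
    return [
        TermMap(
            term_id=f"T{i + 1:04d}",
            term_name=f"term {i + 1}",
            category=category,
            gene_ids=frozenset(
                np.asarray(genes)[rng.choice(len(genes), size=genes_per_term, replace=False)]
            ),
        )
        for i in range(n_terms)
    ]


def write_cohort(result: CohortResult, outdir: str) -> dict:
    """Write FASTA, GFF3, per-sample VCFs, cohort table, truth tables and
    a JSON manifest.  Returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    fasta = os.path.join(outdir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom, seq in result.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")
    paths["fasta"] = fasta

    gff = os.path.join(outdir, "genes.gff3")
    write_gff3(result.models, gff)
    paths["gff3"] = gff

    vcfs = {}
    for s in result.samples:
        p = os.path.join(outdir, f"{s.sample_id}.vcf")
        write_vcf(s, p, result.contigs)
        vcfs[s.sample_id] = p
    paths["vcfs"] = vcfs

    cohort = result.cohort_frame()
    # paths relative to the cohort table keep the bundle relocatable
    cohort["vcf"] = [os.path.basename(vcfs[s]) for s in cohort["sample_id"]]
    cohort_path = os.path.join(outdir, "cohort.tsv")
    cohort.to_csv(cohort_path, sep="\t", index=False)
    paths["cohort"] = cohort_path

    pool_path = os.path.join(outdir, "truth_pool.tsv")
    pd.DataFrame([vars(v) for v in result.pool]).to_csv(pool_path, sep="\t", index=False)
    paths["truth_pool"] = pool_path

    private_path = os.path.join(outdir, "truth_private.tsv")
    result.private_truth.to_csv(private_path, sep="\t", index=False)
    paths["truth_private"] = private_path

    excl_path = os.path.join(outdir, "truth_exclusive_genes.tsv")
    rows = [
        {"gene_id": g, "target_group": grp}
        for grp, gs in sorted(result.exclusive_truth.items())
        for g in gs
    ]
    pd.DataFrame(rows, columns=["gene_id", "target_group"]).to_csv(
        excl_path, sep="\t", index=False
    )
    paths["truth_exclusive"] = excl_path

    manifest = os.path.join(outdir, "manifest.json")
    rel = {
        k: (os.path.basename(v) if isinstance(v, str)
            else {s: os.path.basename(p) for s, p in v.items()})
        for k, v in paths.items()
    }
    with open(manifest, "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(result.config), "files": rel},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    paths["manifest"] = manifest
    return paths
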