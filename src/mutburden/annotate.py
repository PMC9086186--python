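"""Region assignment and codon-level effect classification.

Every variant gets exactly one region label with precedence
exonic > intronic > upstream > intergenic across overlapping genes.
Exonic SNPs inside a CDS additionally get a coding-effect label
(synonymous / nonsynonymous / stopgain / stoploss) obtained by building
the containing codon in transcript orientation, substituting the
alternate base and translating with the standard genetic code.  When a
SNP hits the CDS of several transcripts the most severe effect is kept
(stopgain/stoploss > nonsynonymous > synonymous).  Exonic positions
outside any CDS (UTR) are counted exonic but carry no effect label.

InDel coding consequences are not classified; InDels are only flagged
for CDS overlap of their affected reference interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .variants import SampleVariantSet, VariantCall

logger = logging.getLogger(__name__)

REGION_LABELS = ("exonic", "intronic", "upstream", "intergenic")
EFFECT_LABELS = ("synonymous", "nonsynonymous", "stopgain", "stoploss")

#: default upstream window (bp 5' of the transcription start, strand-aware)
DEFAULT_UPSTREAM_WINDOW = 1000

_SEVERITY = {"stopgain": 3, "stoploss": 3, "nonsynonymous": 2, "synonymous": 1}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneModel:
    """A transcript: strand, exons and CDS segments, 1-based inclusive."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        object.__setattr__(self, "exons", tuple(exons))
        object.__setattr__(self, "cds_segments", tuple(sorted(self.cds_segments)))
        for s, e in list(self.exons) + list(self.cds_segments):
            if s > e or s < 1:
                raise ValueError(f"bad interval ({s},{e}) in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in ascending order."""
        out: list[int] = []
        for s, e in self.cds_segments:
            out.extend(range(s, e + 1))
        return out

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in transcript orientation (reverse-complemented
        for minus-strand transcripts)."""
        seq = "".join(
            genome[self.chrom][s - 1: e].upper() for s, e in self.cds_segments
        )
        if self.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        return seq


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene models from a GFF3 file (gene/mRNA/exon/CDS features
    linked by ``Parent`` attributes).  Returns one GeneModel per mRNA."""
    mrna_gene: dict[str, str] = {}
    mrna_loc: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attrs = _parse_attributes(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = attrs["ID"]
                mrna_gene[tid] = attrs.get("Parent", tid)
                mrna_loc[tid] = (chrom, strand)
            elif ftype == "exon":
                for parent in attrs.get("Parent", "").split(","):
                    exons.setdefault(parent, []).append((int(start), int(end)))
            elif ftype == "CDS":
                for parent in attrs.get("Parent", "").split(","):
                    cds.setdefault(parent, []).append((int(start), int(end)))
    models = []
    for tid, (chrom, strand) in mrna_loc.items():
        models.append(
            GeneModel(
                gene_id=mrna_gene[tid],
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons.get(tid, [])),
                cds_segments=tuple(cds.get(tid, [])),
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (deterministic field order)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, ms in by_gene.items():
            chrom = ms[0].chrom
            strand = ms[0].strand
            lo = min(m.span[0] for m in ms)
            hi = max(m.span[1] for m in ms)
            fh.write(f"{chrom}\t.\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={gene_id}\n")
            for m in ms:
                s, e = m.span
                fh.write(
                    f"{chrom}\t.\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for s2, e2 in m.exons:
                    fh.write(
                        f"{chrom}\t.\texon\t{s2}\t{e2}\t.\t{strand}\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )
                phase = 0
                segs = m.cds_segments if strand == "+" else m.cds_segments[::-1]
                for s2, e2 in segs:
                    fh.write(
                        f"{chrom}\t.\tCDS\t{s2}\t{e2}\t.\t{strand}\t{phase}\t"
                        f"Parent={m.transcript_id}\n"
                    )
                    phase = (3 - ((e2 - s2 + 1 - phase) % 3)) % 3


def validate_gene_models(
    models: Sequence[GeneModel], genome: Mapping[str, str]
) -> list[str]:
    """Check CDS integrity (length % 3, start codon, terminal stop, no
    internal stop).  Violations are logged and returned, not raised."""
    problems = []
    for m in models:
        if m.cds_length % 3 != 0:
            problems.append(f"{m.transcript_id}: CDS length {m.cds_length} not divisible by 3")
            continue
        cds = m.cds_sequence(genome)
        prot = str(Seq(cds).translate())
        if not cds.startswith("ATG"):
            problems.append(f"{m.transcript_id}: CDS does not start with ATG")
        if not prot.endswith("*"):
            problems.append(f"{m.transcript_id}: CDS does not end in a stop codon")
        if "*" in prot[:-1]:
            problems.append(f"{m.transcript_id}: internal stop codon")
    for p in problems:
        logger.warning("gene model validation: %s", p)
    return problems


class GeneIndex:
    """Interval index over gene models for O(log n + hits) position queries."""

    def __init__(
        self,
        models: Sequence[GeneModel],
        upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    ) -> None:
        seen: set[str] = set()
        for m in models:
            if m.transcript_id in seen:
                raise ValueError(f"duplicate transcript ID {m.transcript_id!r}")
            seen.add(m.transcript_id)
        self.models = list(models)
        self.upstream_window = upstream_window
        self._span: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._cds: dict[str, IntervalTree] = {}
        self._upstream: dict[str, IntervalTree] = {}
        for m in models:
            lo, hi = m.span
            self._span.setdefault(m.chrom, IntervalTree()).addi(lo, hi + 1, m)
            for s, e in m.exons:
                self._exon.setdefault(m.chrom, IntervalTree()).addi(s, e + 1, m)
            for s, e in m.cds_segments:
                self._cds.setdefault(m.chrom, IntervalTree()).addi(s, e + 1, m)
            if m.strand == "+":
                us, ue = max(1, lo - upstream_window), lo - 1
            else:
                us, ue = hi + 1, hi + upstream_window
            if us <= ue:
                self._upstream.setdefault(m.chrom, IntervalTree()).addi(us, ue + 1, m)

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> list[GeneModel]:
        tree = trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self._hits(self._span, chrom, pos)

    def exonic_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self._hits(self._exon, chrom, pos)

    def cds_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self._hits(self._cds, chrom, pos)

    def upstream_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self._hits(self._upstream, chrom, pos)

    def cds_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._cds.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end + 1)]


def build_gene_index(
    models: Sequence[GeneModel], upstream_window: int = DEFAULT_UPSTREAM_WINDOW
) -> GeneIndex:
    return GeneIndex(models, upstream_window)


def annotate_region(call: VariantCall, index: GeneIndex) -> tuple[str, str]:
    """Region label for a call plus the gene it is attributed to (empty
    for intergenic).  Precedence: exonic > intronic > upstream."""
    chrom, pos = call.key.chrom, call.key.pos
    hits = index.exonic_at(chrom, pos)
    if hits:
        return "exonic", hits[0].gene_id
    hits = index.genes_at(chrom, pos)
    if hits:
        return "intronic", hits[0].gene_id
    hits = index.upstream_at(chrom, pos)
    if hits:
        return "upstream", hits[0].gene_id
    return "intergenic", ""


def coding_effect(
    snp: VariantCall, model: GeneModel, genome: Mapping[str, str]
) -> str:
    """Effect of a CDS SNP on the encoded protein.

    The containing codon is built in transcript orientation, the allele
    substituted (complemented on the minus strand) and both codons
    translated with the standard code.  stop->stop and aa->same-aa are
    synonymous; aa->other-aa nonsynonymous; non-stop->stop stopgain;
    stop->non-stop stoploss.
    """
    key = snp.key
    if snp.vtype != "SNP":
        raise ValueError("coding_effect is defined for SNPs only")
    positions = model.cds_positions()
    try:
        offset = positions.index(key.pos)
    except ValueError:
        raise ValueError(
            f"{key.chrom}:{key.pos} is not in the CDS of {model.transcript_id}; "
            "use annotate_region for region labels"
        )
    L = len(positions)
    if model.strand == "+":
        cds_index = offset
        ref_base, alt_base = key.ref, key.alt
    else:
        cds_index = L - 1 - offset
        ref_base = key.ref.translate(_COMPLEMENT)
        alt_base = key.alt.translate(_COMPLEMENT)
    codon_start = (cds_index // 3) * 3
    within = cds_index % 3
    codon = []
    for t in range(codon_start, codon_start + 3):
        g_off = t if model.strand == "+" else L - 1 - t
        base = genome[model.chrom][positions[g_off] - 1].upper()
        if model.strand == "-":
            base = base.translate(_COMPLEMENT)
        codon.append(base)
    if codon[within] != ref_base:
        raise ValueError(
            f"reference mismatch: codon has {codon[within]} at {key.chrom}:{key.pos}, "
            f"call says {ref_base} (transcript orientation)"
        )
    ref_codon = "".join(codon)
    mut = codon.copy()
    mut[within] = alt_base
    alt_codon = "".join(mut)
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def cds_indel_flag(indel: VariantCall, index: GeneIndex) -> bool:
    """True iff the affected reference interval [pos, pos+len(ref)-1]
    intersects any CDS segment."""
    key = indel.key
    return bool(
        index.cds_overlapping(key.chrom, key.pos, key.pos + len(key.ref) - 1)
    )


def annotate_sample(
    sample: SampleVariantSet,
    index: GeneIndex,
    genome: Mapping[str, str],
) -> pd.DataFrame:
    """Annotate every call of a sample.

    Returns the variant-table dialect extended with ``region``, ``effect``
    (empty unless a CDS SNP), ``gene_id`` and ``cds`` (InDel CDS-overlap
    flag; for SNPs true iff inside a CDS).
    """
    rows = []
    for call in sample.calls:
        k = call.key
        region, gene_id = annotate_region(call, index)
        effect = ""
        in_cds = False
        if call.vtype == "SNP":
            models = index.cds_at(k.chrom, k.pos)
            if models:
                in_cds = True
                best = ""
                for m in models:
                    eff = coding_effect(call, m, genome)
                    if not best or _SEVERITY[eff] > _SEVERITY[best]:
                        best = eff
                        gene_id = m.gene_id
                effect = best
        else:
            in_cds = cds_indel_flag(call, index)
        rows.append(
            {
                "sample_id": call.sample_id,
                "chrom": k.chrom,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "geno": k.geno,
                "vtype": call.vtype,
                "region": region,
                "effect": effect,
                "gene_id": gene_id,
                "cds": in_cds,
            }
        )
    columns = [
        "sample_id", "chrom", "pos", "ref", "alt", "geno",
        "vtype", "region", "effect", "gene_id", "cds",
    ]
    return pd.DataFrame(rows, columns=columns)
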