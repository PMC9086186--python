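"""Variant data model: keys, calls, per-sample sets, VCF ingestion.

A variant's identity throughout the pipeline is the five-field key
(chrom, pos, ref, alt, geno).  Including the genotype class in the key
means that the same substitution observed heterozygous in one animal and
homozygous in another counts as two distinct mutation *types*; this is
what makes "shared-type" removal against a control panel well defined.
The genotype class is canonicalized to two values (``het``/``hom_alt``)
so keys are comparable across callers; a ``key-ignore-geno`` mode drops
the field entirely.

Coordinates are 1-based inclusive (VCF convention) everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")

#: Valid genotype classes for a key.
GENO_CLASSES = ("het", "hom_alt")

#: Cohort group labels (untreated panel plus the three phenotype strata
#: of the treated cohort).
GROUPS = ("control", "treated_large", "treated_normal", "treated_small")

TREATED_GROUPS = ("treated_large", "treated_normal", "treated_small")

#: Purine/pyrimidine partners: the unique transition partner of each base.
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_VTYPES = ("SNP", "insertion", "deletion")


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Five-field mutation-type identity (chrom, pos, ref, alt, geno).

    ``geno`` may be ``None`` when genotype is deliberately excluded from
    the identity (``key-ignore-geno`` mode).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    geno: str | None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= BASES:
                raise ValueError(
                    f"{name} allele must be a non-empty uppercase ACGT string, "
                    f"got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        if self.geno is not None and self.geno not in GENO_CLASSES:
            raise ValueError(
                f"geno must be one of {GENO_CLASSES} or None, got {self.geno!r}"
            )

    def drop_geno(self) -> "VariantKey":
        """Key with the genotype field removed (geno-insensitive matching)."""
        if self.geno is None:
            return self
        return replace(self, geno=None)


@dataclass(frozen=True, slots=True)
class VariantCall:
    """A keyed variant call in one sample, with its structural type."""

    key: VariantKey
    vtype: str
    sample_id: str

    def __post_init__(self) -> None:
        expected = classify_variant(self.key.ref, self.key.alt)
        if self.vtype != expected:
            raise ValueError(
                f"vtype {self.vtype!r} inconsistent with alleles "
                f"{self.key.ref}>{self.key.alt} (expected {expected!r})"
            )


def make_call(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    geno: str | None,
) -> VariantCall:
    """Build a VariantCall, deriving the structural type from the alleles."""
    key = VariantKey(chrom, int(pos), ref.upper(), alt.upper(), geno)
    return VariantCall(key=key, vtype=classify_variant(key.ref, key.alt), sample_id=sample_id)


@dataclass
class SampleVariantSet:
    """One individual's variant calls plus its group label and clean-base
    denominator (total post-QC sequenced bases, the denominator of the
    per-sample mutation rate)."""

    sample_id: str
    group: str | None
    calls: list[VariantCall]
    clean_bases: int
    skip_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clean_bases <= 0:
            raise ValueError(f"clean_bases must be > 0, got {self.clean_bases}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        seen: set[VariantKey] = set()
        for call in self.calls:
            if call.key in seen:
                raise ValueError(
                    f"duplicate key in sample {self.sample_id}: {call.key}"
                )
            seen.add(call.key)

    def keys(self, *, ignore_geno: bool = False) -> set[VariantKey]:
        if ignore_geno:
            return {c.key.drop_geno() for c in self.calls}
        return {c.key for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)


def classify_variant(ref: str, alt: str) -> str:
    """Structural class of a normalized allele pair.

    SNP iff both alleles are single bases; otherwise insertion when the
    alternate is longer, deletion when the reference is longer.  Equal
    multi-base lengths (MNPs) are rejected: callers emitting them should
    decompose before keying.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    raise ValueError(f"cannot classify {ref!r}>{alt!r}: equal-length multi-base alleles")


def is_transition(ref: str, alt: str) -> bool:
    """True for the four purine<->purine / pyrimidine<->pyrimidine pairs.

    Defined for SNPs only; the eight remaining ordered base pairs are
    transversions.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"is_transition is defined for SNPs only, got {ref!r}>{alt!r}")
    return _TRANSITION_PARTNER[ref] == alt


def _apply_local(window: str, offset: int, ref: str, alt: str) -> str:
    return window[:offset] + alt + window[offset + len(ref):]


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str],
) -> tuple[int, str, str]:
    """Canonicalize an allele pair: trim shared bases, then left-align.

    Trimming removes shared suffix then prefix bases while both alleles
    stay non-empty.  Left-alignment then slides the (fixed) allele
    strings to the smallest position at which they still describe the
    same edited haplotype — the canonical representation inside repeat
    runs.  The operation is idempotent and haplotype-preserving.
    """
    seq = reference[chrom]
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}) at {chrom}:{pos}")
    if pos < 1 or pos - 1 + len(ref) > len(seq):
        raise ValueError(f"{chrom}:{pos} {ref!r} outside reference (len {len(seq)})")
    if seq[pos - 1: pos - 1 + len(ref)].upper() != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has "
            f"{seq[pos - 1: pos - 1 + len(ref)]!r}, record says {ref!r}"
        )

    # shared-suffix then shared-prefix trim, keeping >=1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if len(ref) != len(alt):
        # Slide left while an equivalent same-string representation exists.
        # Equivalence is checked on a local window (edits are local); the
        # scan tolerates repeat periods up to the edit length before stopping.
        max_gap = max(len(ref), len(alt))
        best = pos
        q = pos - 1
        misses = 0
        while q >= 1 and misses < max_gap:
            window_lo = q - 1  # 0-based start of comparison window
            window = seq[window_lo: pos - 1 + len(ref)].upper()
            if (
                window[: len(ref)] == ref
                and _apply_local(window, 0, ref, alt)
                == _apply_local(window, pos - q, ref, alt)
            ):
                best = q
                misses = 0
            else:
                misses += 1
            q -= 1
        pos = best

    return pos, ref, alt


def _canonical_geno(alleles: tuple, alt_index: int) -> str | None:
    """Map a GT allele tuple to the two-class genotype for one alt allele.

    ``None`` means the alt allele is not carried.  Phasing is ignored.
    """
    called = [a for a in alleles if a is not None]
    n_alt = sum(1 for a in called if a == alt_index)
    if n_alt == 0:
        return None
    if n_alt == len(called) and len(called) > 1:
        return "hom_alt"
    return "het"


def read_vcf(
    path: str,
    sample: str,
    *,
    group: str | None = None,
    clean_bases: int = 1,
    reference: Mapping[str, str] | None = None,
) -> SampleVariantSet:
    """Read one sample's non-reference calls from a VCF into a keyed set.

    Multiallelic records are split into biallelic (ref, alt) pairs before
    keying; a ``1/2`` genotype therefore yields one het call per carried
    alternate.  Records with a fully missing genotype, reference-only
    genotypes, and non-ACGT (symbolic) alleles are skipped and tallied in
    the returned set's ``skip_log``.  When ``reference`` is given, alleles
    are normalized (trimmed and left-aligned) before keying.

    Parameters
    ----------
    clean_bases
        Per-sample clean-base denominator from the cohort configuration;
        the VCF itself does not carry it.
    """
    skip = {"missing_genotype": 0, "ref_only": 0, "non_acgt_allele": 0, "duplicate_key": 0}
    calls: list[VariantCall] = []
    seen: set[VariantKey] = set()
    with pysam.VariantFile(path) as vcf:
        if sample not in vcf.header.samples:
            raise ValueError(
                f"sample {sample!r} not in {path}; available: "
                f"{', '.join(vcf.header.samples)}"
            )
        for rec in vcf:
            try:
                gt = rec.samples[sample].get("GT")
            except Exception as exc:  # malformed record
                raise ValueError(f"malformed VCF record near {path}:{rec.pos}: {exc}")
            if gt is None or all(a is None for a in gt):
                skip["missing_genotype"] += 1
                continue
            alts = rec.alts or ()
            emitted = False
            for i, alt in enumerate(alts, start=1):
                geno = _canonical_geno(tuple(gt), i)
                if geno is None:
                    continue
                ref = (rec.ref or "").upper()
                alt = (alt or "").upper()
                if not ref or not alt or not set(ref) <= BASES or not set(alt) <= BASES:
                    skip["non_acgt_allele"] += 1
                    continue
                pos = rec.pos
                if ref == alt:
                    skip["non_acgt_allele"] += 1
                    continue
                if reference is not None:
                    pos, ref, alt = normalize_variant(rec.chrom, pos, ref, alt, reference)
                key = VariantKey(rec.chrom, pos, ref, alt, geno)
                if key in seen:
                    skip["duplicate_key"] += 1
                    continue
                seen.add(key)
                calls.append(VariantCall(key, classify_variant(ref, alt), sample))
                emitted = True
            if not emitted and any(a == 0 for a in gt):
                skip["ref_only"] += 1
    if any(skip.values()):
        logger.info("read_vcf(%s, %s): skipped %s", path, sample, skip)
    return SampleVariantSet(sample, group, calls, clean_bases, skip_log=skip)


def write_vcf(
    sample_set: SampleVariantSet,
    path: str,
    contigs: Mapping[str, int],
) -> None:
    """Write one sample's calls as a minimal, deterministic VCF v4.2 file.

    Records are coordinate-sorted; byte output depends only on the calls
    and contig table, which makes same-seed simulator runs byte-identical.
    """
    order = {name: i for i, name in enumerate(contigs)}
    rows = sorted(
        sample_set.calls,
        key=lambda c: (order[c.key.chrom], c.key.pos, c.key.ref, c.key.alt, c.key.geno or ""),
    )
    gt = {"het": "0/1", "hom_alt": "1/1", None: "0/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_set.sample_id}\n"
        )
        for c in rows:
            k = c.key
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t{gt[k.geno]}\n"
            )


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a variant to a sequence (1-based pos); used by oracles and
    the haplotype-preservation property of normalization."""
    if seq[pos - 1: pos - 1 + len(ref)] != ref:
        raise ValueError("ref does not match sequence")
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
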