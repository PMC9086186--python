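import numpy as np
import pytest
from Bio.Seq import Seq

from mutburden.annotate import (
    GeneModel,
    annotate_region,
    annotate_sample,
    build_gene_index,
    cds_indel_flag,
    coding_effect,
    read_gff3,
    validate_gene_models,
    write_gff3,
)
from mutburden.simulate import CohortConfig, simulate_genome
from mutburden.variants import make_call


def _region_oracle(models, chrom, pos, window=1000):
    """Brute-force region classifier with the same precedence rules."""
    for m in models:
        if m.chrom == chrom and any(s <= pos <= e for s, e in m.exons):
            return "exonic"
    for m in models:
        if m.chrom == chrom and m.span[0] <= pos <= m.span[1]:
            return "intronic"
    for m in models:
        if m.chrom != chrom:
            continue
        lo, hi = m.span
        if m.strand == "+" and lo - window <= pos <= lo - 1:
            return "upstream"
        if m.strand == "-" and hi + 1 <= pos <= hi + window:
            return "upstream"
    return "intergenic"


def _effect_oracle(call, model, genome):
    """Translate the whole reference and mutant CDS and diff proteins."""
    mutant = dict(genome)
    k = call.key
    seq = mutant[k.chrom]
    assert seq[k.pos - 1] == k.ref
    mutant[k.chrom] = seq[: k.pos - 1] + k.alt + seq[k.pos:]
    p_ref = str(Seq(model.cds_sequence(genome)).translate())
    p_alt = str(Seq(model.cds_sequence(mutant)).translate())
    if p_ref == p_alt:
        return "synonymous"
    diffs = [(a, b) for a, b in zip(p_ref, p_alt) if a != b]
    a, b = diffs[0]
    if b == "*":
        return "stopgain"
    if a == "*":
        return "stoploss"
    return "nonsynonymous"


class TestGeneIndex:
    def setup_method(self):
        self.gene = GeneModel(
            "g1", "g1.t1", "c", "+", exons=((100, 200),), cds_segments=((100, 200),)
        )
        self.index = build_gene_index([self.gene])

    def test_stabbing_query_and_miss(self):
        assert self.index.genes_at("c", 150) == [self.gene]
        assert self.index.genes_at("c", 250) == []

    def test_boundaries_inclusive(self):
        assert self.index.genes_at("c", 100) == [self.gene]
        assert self.index.genes_at("c", 200) == [self.gene]

    def test_duplicate_transcripts_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_gene_index([self.gene, self.gene])

    def test_agrees_with_linear_scan_on_random_positions(self):
        genome, models = simulate_genome(CohortConfig(genome_length=200_000, n_genes=20, seed=3))
        index = build_gene_index(models)
        rng = np.random.default_rng(0)
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
            call = make_call("S", chrom, pos, "A", "G", "het")
            # region label only depends on position
            label, _gene = annotate_region(call, index)
            assert label == _region_oracle(models, chrom, pos)


class TestAnnotateRegion:
    def setup_method(self):
        self.gene = GeneModel(
            "g1", "g1.t1", "c", "+", exons=((100, 140), (170, 200)),
            cds_segments=((100, 140),),
        )
        self.index = build_gene_index([self.gene], upstream_window=1000)

    @pytest.mark.parametrize(
        "pos,expected",
        [(120, "exonic"), (160, "intronic"), (50, "upstream"), (1500, "intergenic")],
    )
    def test_precedence(self, pos, expected):
        call = make_call("S", "c", pos, "A", "G", "het")
        assert annotate_region(call, self.index)[0] == expected

    def test_unknown_chrom_is_intergenic(self):
        call = make_call("S", "other", 10, "A", "G", "het")
        assert annotate_region(call, self.index)[0] == "intergenic"

    def test_minus_strand_upstream_is_three_prime_side_in_genome_coords(self):
        minus = GeneModel("g2", "g2.t1", "c", "-", exons=((300, 400),), cds_segments=((300, 400),))
        index = build_gene_index([minus], upstream_window=50)
        call = make_call("S", "c", 420, "A", "G", "het")
        assert annotate_region(call, index)[0] == "upstream"
        call = make_call("S", "c", 260, "A", "G", "het")
        assert annotate_region(call, index)[0] == "intergenic"


class TestCodingEffect:
    # toy CDS: ATG AAA TGG TAC CCA TCA GGG TTT CAT GAA TGA, split 121-140 + 181-193
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (126, "A", "G", "synonymous"),     # AAA -> AAG (Lys)
            (129, "G", "A", "stopgain"),       # TGG -> TGA (Trp -> stop)
            (192, "G", "T", "stoploss"),       # TGA -> TTA (stop -> Leu)
            (124, "A", "G", "nonsynonymous"),  # AAA -> GAA (Lys -> Glu)
            (181, "G", "A", "synonymous"),     # codon GGG spans the intron (139,140|181)
        ],
    )
    def test_plus_strand_examples(self, toy_genome, pos, ref, alt, expected):
        genome, (plus, _minus) = toy_genome
        call = make_call("S", "chr1", pos, ref, alt, "het")
        assert coding_effect(call, plus, genome) == expected
        assert _effect_oracle(call, plus, genome) == expected

    def test_minus_strand_mirror_gives_identical_labels(self, toy_genome):
        genome, (plus, minus) = toy_genome
        L = len(genome["chr1"])
        comp = dict(zip("ACGT", "TGCA"))
        for pos, ref, alt in [(126, "A", "G"), (129, "G", "A"), (124, "A", "G"), (192, "G", "T")]:
            fwd = make_call("S", "chr1", pos, ref, alt, "het")
            rev = make_call("S", "chr2", L - pos + 1, comp[ref], comp[alt], "het")
            assert coding_effect(rev, minus, genome) == coding_effect(fwd, plus, genome)

    def test_position_outside_cds_redirects_to_region(self, toy_genome):
        genome, (plus, _) = toy_genome
        ref = genome["chr1"][109]  # pos 110: 5' UTR, exonic but outside CDS
        alt = "G" if ref != "G" else "A"
        call = make_call("S", "chr1", 110, ref, alt, "het")
        with pytest.raises(ValueError, match="annotate_region"):
            coding_effect(call, plus, genome)

    def test_agrees_with_whole_cds_diff_oracle_on_random_snps(self):
        genome, models = simulate_genome(CohortConfig(genome_length=150_000, n_genes=15, seed=5))
        rng = np.random.default_rng(1)
        for _ in range(150):
            m = models[rng.integers(len(models))]
            positions = m.cds_positions()
            pos = int(positions[rng.integers(len(positions))])
            ref = genome[m.chrom][pos - 1]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref:
                continue
            call = make_call("S", m.chrom, pos, ref, alt, "het")
            assert coding_effect(call, m, genome) == _effect_oracle(call, m, genome)


class TestCdsIndelFlag:
    def setup_method(self):
        gene = GeneModel("g1", "g1.t1", "c", "+", exons=((90, 150),), cds_segments=((100, 140),))
        self.index = build_gene_index([gene])

    def test_deletion_interval_intersects_cds(self):
        call = make_call("S", "c", 139, "AT", "A", "het")
        assert cds_indel_flag(call, self.index) is True

    def test_insertion_anchor_outside_cds(self):
        call = make_call("S", "c", 141, "A", "AT", "het")
        assert cds_indel_flag(call, self.index) is False

    def test_agrees_with_brute_force_interval_intersection(self):
        genome, models = simulate_genome(CohortConfig(genome_length=100_000, n_genes=10, seed=9))
        index = build_gene_index(models)
        rng = np.random.default_rng(2)
        segs = [(m.chrom, s, e) for m in models for s, e in m.cds_segments]
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(1, len(genome[chrom]) - 12))
            size = int(rng.integers(1, 9))
            ref = genome[chrom][pos - 1: pos + size]
            call = make_call("S", chrom, pos, ref, ref[0], "het")
            lo, hi = pos, pos + len(ref) - 1
            brute = any(c == chrom and s <= hi and lo <= e for c, s, e in segs)
            assert cds_indel_flag(call, index) == brute


class TestGff3AndValidation:
    def test_roundtrip_through_gff3(self, toy_genome, tmp_path):
        _genome, models = toy_genome
        path = tmp_path / "genes.gff3"
        write_gff3(models, str(path))
        back = read_gff3(str(path))
        assert {m.transcript_id for m in back} == {m.transcript_id for m in models}
        by_id = {m.transcript_id: m for m in back}
        for m in models:
            b = by_id[m.transcript_id]
            assert (b.chrom, b.strand, b.exons, b.cds_segments) == (
                m.chrom, m.strand, m.exons, m.cds_segments
            )

    def test_validation_passes_on_constructed_genes(self, toy_genome):
        genome, models = toy_genome
        assert validate_gene_models(models, genome) == []

    def test_validation_flags_broken_cds(self, toy_genome):
        genome, (plus, _) = toy_genome
        broken = GeneModel(
            "bad", "bad.t1", "chr1", "+", exons=plus.exons,
            cds_segments=((121, 140), (181, 192)),  # length not divisible by 3
        )
        assert validate_gene_models([broken], genome)


class TestPartitions:
    def test_region_and_effect_labels_partition_sample(self, default_cohort):
        from mutburden.filtering import filter_cohort

        genome = default_cohort.genome
        index = build_gene_index(default_cohort.models)
        sample = filter_cohort(default_cohort.samples)[4]  # a treated animal
        df = annotate_sample(sample, index, genome)
        assert len(df) == len(sample)
        assert (df["region"].isin(["exonic", "intronic", "upstream", "intergenic"])).all()
        snps = df[df["vtype"] == "SNP"]
        in_cds = snps[snps["cds"]]
        assert (in_cds["effect"] != "").all()
        # UTR SNPs: exonic but no effect label
        utr = snps[(snps["region"] == "exonic") & (~snps["cds"])]
        assert (utr["effect"] == "").all()
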