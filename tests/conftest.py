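import numpy as np
import pytest

from mutburden.annotate import GeneModel
from mutburden.simulate import CohortConfig, simulate_cohort, write_cohort

#: cohort seed used by the synthetic end-to-end fixtures
COHORT_SEED = 11


@pytest.fixture(scope="session")
def toy_genome():
    """Two tiny chromosomes with one hand-built gene each.

    chr1 carries a + strand gene (span 101-280) whose CDS is split over
    two exons; chr2 carries its reverse-complemented mirror, so effect
    labels must agree between the two strands.
    """
    rng = np.random.default_rng(7)
    background = "".join(rng.choice(list("ACGT"), size=400))
    # CDS: ATG AAA TGG TAC CCA TCA GGG TTT CAT GAA TGA  (10 aa + stop)
    cds = "ATGAAATGGTACCCATCAGGGTTTCATGAATGA"
    # + strand gene on chr1: exon1 101-140 (UTR 101-120, CDS 121-140),
    # intron 141-180, exon2 181-280 (CDS 181-193, UTR 194-280)
    seq1 = list(background)
    seg1, seg2 = cds[:20], cds[20:]
    seq1[120:140] = seg1
    seq1[180:193] = seg2
    chr1 = "".join(seq1)
    plus = GeneModel(
        gene_id="gplus", transcript_id="gplus.t1", chrom="chr1", strand="+",
        exons=((101, 140), (181, 280)), cds_segments=((121, 140), (181, 193)),
    )
    # mirror on chr2: reverse-complement of chr1
    comp = str.maketrans("ACGT", "TGCA")
    chr2 = chr1.translate(comp)[::-1]
    L = 400
    flip = lambda s, e: (L - e + 1, L - s + 1)
    minus = GeneModel(
        gene_id="gminus", transcript_id="gminus.t1", chrom="chr2", strand="-",
        exons=tuple(sorted([flip(101, 140), flip(181, 280)])),
        cds_segments=tuple(sorted([flip(121, 140), flip(181, 193)])),
    )
    genome = {"chr1": chr1, "chr2": chr2}
    return genome, [plus, minus]


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (1 Mb genome, 4 controls,
    5 + 5 + 2 treated, rate ratio 9), generated once per session."""
    return simulate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    """The default cohort written to disk (FASTA/GFF3/VCFs/truth)."""
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(default_cohort, str(out))
    return paths


@pytest.fixture(scope="session")
def pipeline_result(default_cohort, cohort_dir, tmp_path_factory):
    """Full pipeline run on the default synthetic cohort."""
    import pandas as pd

    from mutburden.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_out")
    paths = run_pipeline(
        RunConfig(
            cohort=cohort_dir["cohort"],
            fasta=cohort_dir["fasta"],
            gff3=cohort_dir["gff3"],
            outdir=str(outdir),
        )
    )
    paths["per_sample"] = pd.read_csv(paths["per_sample_summary"], sep="\t")
    return paths
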