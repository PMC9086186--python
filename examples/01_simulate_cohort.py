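"""Generate a synthetic mutagenesis cohort with ground truth.

Builds the default study design — a 1 Mb two-chromosome genome with 60
genes, 4 untreated controls and 12 treated animals (5 large / 5 normal /
2 small) whose private mutation rate is 9x the control rate — and writes
FASTA, GFF3, per-sample VCFs, the cohort table and truth tables.
"""

from mutburden import CohortConfig, simulate_cohort, write_cohort

cohort = simulate_cohort(CohortConfig(seed=1))
paths = write_cohort(cohort, "example_cohort")

print(f"pool variants (standing polymorphisms): {len(cohort.pool)}")
for s in cohort.samples[:3] + cohort.samples[-2:]:
    print(f"  {s.sample_id:<11} {s.group:<15} {len(s):>6} calls, "
          f"{s.clean_bases:,} clean bases")
print("planted exclusive genes:", cohort.exclusive_truth)
print("files:", ", ".join(sorted(k for k in paths if k != "vcfs")))
# Controls carry mostly pool variants (~5,400 calls); treated animals add
# ~1,200 private mutations each.  The planted genes are the truth set the
# exclusive screen must recover.
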