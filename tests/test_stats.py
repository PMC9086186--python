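import math

import numpy as np
import pandas as pd
import pytest

from mutburden.stats import (
    class_percentage,
    compare_groups,
    fold_change,
    group_aggregate,
    group_summary_table,
    mutation_rate,
    rounded,
    sample_summary,
)


class TestMutationRate:
    @pytest.mark.parametrize(
        "n,bases,expected",
        [
            (144157, 10730101234, 0.001343),  # Control_1 of the scallop screen
            (919124, 10041975926, 0.009153),  # Treated_1
            (0, 12345, 0.0),
        ],
    )
    def test_clean_base_normalized_percent(self, n, bases, expected):
        assert mutation_rate(n, bases) == pytest.approx(expected, abs=5e-7)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(1, 0)


def _toy_annotated():
    # 6 SNPs (4 transitions) + 2 InDels (1 in CDS)
    rows = [
        ("S", "c", 1, "A", "G", "het", "SNP", "intergenic", "", "", False),
        ("S", "c", 2, "C", "T", "het", "SNP", "intronic", "", "g1", False),
        ("S", "c", 3, "G", "A", "het", "SNP", "exonic", "synonymous", "g1", True),
        ("S", "c", 4, "T", "C", "het", "SNP", "exonic", "nonsynonymous", "g1", True),
        ("S", "c", 5, "A", "C", "het", "SNP", "upstream", "", "g1", False),
        ("S", "c", 6, "G", "T", "het", "SNP", "intergenic", "", "", False),
        ("S", "c", 7, "AT", "A", "het", "deletion", "intergenic", "", "", False),
        ("S", "c", 8, "A", "AC", "het", "insertion", "exonic", "", "g1", True),
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "geno",
                 "vtype", "region", "effect", "gene_id", "cds"],
    )


class TestSampleSummary:
    def test_hand_countable_fixture(self):
        s = sample_summary(_toy_annotated(), clean_bases=1000)
        assert s.n_snp == 6
        assert s.n_transition == 4 and s.n_transversion == 2
        assert s.ts_tv == pytest.approx(2.0)
        assert s.n_indel == 2 and s.n_indel_cds == 1
        assert s.n_exonic == 2 and s.n_intronic == 1
        assert s.n_syn == 1 and s.n_nonsyn == 1
        assert s.rate_snp == pytest.approx(0.6)
        assert s.rate_total == pytest.approx(s.rate_snp + s.rate_indel)

    def test_ts_tv_printed_precision(self):
        # Control_1 of the scallop screen: 74,612 / 69,545 -> 1.07
        assert round(74612 / 69545, 2) == 1.07

    def test_zero_transversions_gives_nan_not_crash(self):
        df = _toy_annotated()
        df = df[df["alt"].isin(["G", "T"]) & (df["vtype"] == "SNP")]
        df = df[[r in ("A", "C") for r in df["ref"]]]  # transitions only
        s = sample_summary(df, clean_bases=1000, sample_id="S")
        assert s.n_transversion == 0 and math.isnan(s.ts_tv)

    def test_matches_brute_force_recount(self):
        from mutburden.variants import is_transition

        rng = np.random.default_rng(0)
        rows = []
        for i in range(500):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            vtype = rng.choice(["SNP", "insertion", "deletion"], p=[0.8, 0.1, 0.1])
            if vtype == "insertion":
                ref, alt = ref, ref + alt
            elif vtype == "deletion":
                ref, alt = ref + alt, ref
            region = rng.choice(["exonic", "intronic", "upstream", "intergenic"])
            effect = (
                rng.choice(["synonymous", "nonsynonymous", "stopgain", "stoploss"])
                if vtype == "SNP" and region == "exonic" and rng.random() < 0.5
                else ""
            )
            rows.append(("S", "c", i + 1, ref, alt, "het", vtype, region, effect,
                         "g", bool(effect) or (vtype != "SNP" and rng.random() < 0.2)))
        df = pd.DataFrame(rows, columns=_toy_annotated().columns)
        s = sample_summary(df, clean_bases=10_000)
        snps = df[df.vtype == "SNP"]
        assert s.n_snp == len(snps)
        assert s.n_transition == sum(is_transition(r, a) for r, a in zip(snps.ref, snps.alt))
        assert s.n_exonic == (snps.region == "exonic").sum()
        assert s.n_syn == (snps.effect == "synonymous").sum()
        assert s.n_indel == (df.vtype != "SNP").sum()
        assert s.n_indel_cds == df[df.vtype != "SNP"].cds.sum()


class TestGroupAggregate:
    def test_control_snp_counts_reproduce_printed_mean_and_sd(self):
        g = group_aggregate([144157, 133641, 140421, 121144], "control", "n_snp")
        assert round(g.mean) == 134841
        assert abs(g.sd - 10115) <= 1  # printed value truncates 10115.53

    def test_identical_values(self):
        g = group_aggregate([5, 5, 5], "g", "m")
        assert g.mean == 5 and g.sd == 0

    def test_single_value_sd_undefined(self):
        assert math.isnan(group_aggregate([5], "g", "m").sd)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(10, 3, size=rng.integers(2, 12))
            g = group_aggregate(v, "g", "m")
            mean = sum(v) / len(v)
            sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (len(v) - 1))
            assert g.mean == pytest.approx(mean)
            assert g.sd == pytest.approx(sd)


class TestPercentagesAndFold:
    def test_treated_1_exonic_share(self):
        assert class_percentage(33221, 919124) == pytest.approx(3.614, abs=5e-4)

    def test_zero_numerator_and_denominator(self):
        assert class_percentage(0, 100) == 0.0
        assert math.isnan(class_percentage(1, 0))

    def test_fold_change_headline(self):
        f = fold_change(0.013721, 0.001518)
        assert f == pytest.approx(9.04, abs=0.01)
        assert rounded(f) == 9

    def test_fold_change_identity_and_errors(self):
        assert fold_change(0.4, 0.4) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_scale_invariance_of_rates_and_percentages(self):
        n, b = 1234, 10_000_000
        for factor in (3, 10):
            assert mutation_rate(n * factor, b * factor) == pytest.approx(mutation_rate(n, b))
            assert class_percentage(n * factor, b * factor) == pytest.approx(
                class_percentage(n, b)
            )


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        r = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_fully_separated_constant_groups_significant(self):
        r = compare_groups({"a": [0, 0, 0, 0], "b": [10, 10, 10, 10]})
        assert r.significant and r.p_value < 0.05

    def test_student_t_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        r = compare_groups({"a": a, "b": b})
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        if r.test == "student_t":
            assert r.statistic == pytest.approx(t)

    def test_three_groups_use_anova_and_tukey(self):
        rng = np.random.default_rng(5)
        r = compare_groups(
            {"a": rng.normal(0, 1, 6), "b": rng.normal(0, 1, 6), "c": rng.normal(3, 1, 6)}
        )
        assert r.test == "anova_tukey"
        assert r.tukey is not None and len(r.tukey) == 3

    def test_transform_recorded_when_normality_fails(self):
        rng = np.random.default_rng(6)
        a = np.exp(rng.normal(0, 1.5, 25))  # lognormal: fails raw normality
        b = np.exp(rng.normal(0.3, 1.5, 25))
        r = compare_groups({"a": a, "b": b})
        assert r.transform in ("sqrt", "log") or "normality_not_met" in r.warnings

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1], "b": [1, 2]})


class TestGroupSummaryTable:
    def test_means_by_group(self):
        df = pd.DataFrame(
            {"sample_id": list("abcd"), "group": ["x", "x", "y", "y"], "m": [1.0, 3.0, 10.0, 10.0]}
        )
        out = group_summary_table(df, ["m"])
        x = out[(out.group == "x") & (out.metric == "m")].iloc[0]
        assert x["mean"] == 2.0 and x["n"] == 2
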