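"""Per-sample and per-group mutation-burden statistics.

Rates are percentages of the per-sample clean-base total:
``rate = 100 * count / clean_bases``.  Group dispersion uses the sample
standard deviation (n-1 denominator).  Group comparisons follow a
normality- and variance-gated workflow: Shapiro-Wilk and a
Kolmogorov-Smirnov-type (Lilliefors) test per group, Levene across
groups, then Student's t (equal variances), Welch's t (unequal), or
one-way ANOVA with Tukey HSD for more than two groups; square-root or
natural-log transformations are tried only when normality fails and are
recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05

#: Columns of the per-sample summary table, in presentation order.
SUMMARY_COLUMNS = [
    "sample_id", "group", "n_snp", "n_transition", "n_transversion", "ts_tv",
    "n_exonic", "n_intronic", "n_upstream", "n_intergenic",
    "n_syn", "n_nonsyn", "n_stopgain", "n_stoploss",
    "n_indel", "n_indel_ins", "n_indel_del", "n_indel_cds",
    "clean_bases", "rate_snp", "rate_indel", "rate_total",
]


@dataclass
class SampleSummary:
    sample_id: str
    group: str | None
    n_snp: int
    n_transition: int
    n_transversion: int
    ts_tv: float  # NaN when transversion count is zero
    n_exonic: int
    n_intronic: int
    n_upstream: int
    n_intergenic: int
    n_syn: int
    n_nonsyn: int
    n_stopgain: int
    n_stoploss: int
    n_indel: int
    n_indel_ins: int
    n_indel_del: int
    n_indel_cds: int
    clean_bases: int
    rate_snp: float
    rate_indel: float
    rate_total: float


@dataclass
class GroupSummary:
    group: str
    metric: str
    mean: float
    sd: float  # sample SD (n-1); NaN when n < 2
    n: int


@dataclass
class ComparisonResult:
    metric: str
    groups: tuple[str, ...]
    shapiro_p: dict
    ks_p: dict
    levene_p: float
    transform: str  # "", "sqrt" or "log"
    test: str  # student_t | welch_t | anova_tukey
    statistic: float
    p_value: float
    significant: bool
    warnings: list = field(default_factory=list)
    tukey: pd.DataFrame | None = None


def mutation_rate(n_variants: int, clean_bases: int) -> float:
    """Mutation rate as a percentage of clean bases: 100 * n / bases."""
    if clean_bases <= 0:
        raise ValueError(f"clean_bases must be > 0, got {clean_bases}")
    if n_variants < 0:
        raise ValueError("variant count cannot be negative")
    return 100.0 * n_variants / clean_bases


def class_percentage(numerator: int, denominator: int) -> float:
    """Share of a variant class, in percent.  NaN for a zero denominator."""
    if denominator == 0:
        return math.nan
    return 100.0 * numerator / denominator


def fold_change(rate_treated_mean: float, rate_control_mean: float) -> float:
    """Ratio of treated to control mean rate."""
    if rate_control_mean <= 0:
        raise ValueError("control mean rate must be > 0")
    return rate_treated_mean / rate_control_mean


def rounded(fold: float) -> int:
    """Fold change to the nearest integer (the headline '9 times')."""
    return int(round(fold))


def sample_summary(
    annotated: pd.DataFrame,
    clean_bases: int,
    *,
    sample_id: str | None = None,
    group: str | None = None,
) -> SampleSummary:
    """Tally one sample's annotated variant table into a SampleSummary.

    ``annotated`` is the variant-table dialect with ``region``, ``effect``
    and ``cds`` columns (one row per group-specific call).
    """
    if sample_id is None:
        ids = annotated["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("annotated table must contain exactly one sample, or pass sample_id")
        sample_id = ids[0]
    else:
        annotated = annotated[annotated["sample_id"] == sample_id]

    snps = annotated[annotated["vtype"] == "SNP"]
    indels = annotated[annotated["vtype"] != "SNP"]
    from .variants import is_transition

    n_ts = int(sum(is_transition(r, a) for r, a in zip(snps["ref"], snps["alt"])))
    n_snp = len(snps)
    n_tv = n_snp - n_ts
    region = snps["region"].value_counts()
    effect = snps["effect"].value_counts()
    n_ins = int((indels["vtype"] == "insertion").sum())
    rate_snp = mutation_rate(n_snp, clean_bases)
    rate_indel = mutation_rate(len(indels), clean_bases)
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        n_snp=n_snp,
        n_transition=n_ts,
        n_transversion=n_tv,
        ts_tv=(n_ts / n_tv) if n_tv else math.nan,
        n_exonic=int(region.get("exonic", 0)),
        n_intronic=int(region.get("intronic", 0)),
        n_upstream=int(region.get("upstream", 0)),
        n_intergenic=int(region.get("intergenic", 0)),
        n_syn=int(effect.get("synonymous", 0)),
        n_nonsyn=int(effect.get("nonsynonymous", 0)),
        n_stopgain=int(effect.get("stopgain", 0)),
        n_stoploss=int(effect.get("stoploss", 0)),
        n_indel=len(indels),
        n_indel_ins=n_ins,
        n_indel_del=len(indels) - n_ins,
        n_indel_cds=int(indels["cds"].sum()),
        clean_bases=clean_bases,
        rate_snp=rate_snp,
        rate_indel=rate_indel,
        rate_total=rate_snp + rate_indel,
    )


def summaries_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries], columns=SUMMARY_COLUMNS)


def group_aggregate(values: Sequence[float], group: str, metric: str) -> GroupSummary:
    """Mean and sample SD (n-1 denominator) of one metric in one group."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean()) if n else math.nan
    sd = float(arr.std(ddof=1)) if n >= 2 else math.nan
    return GroupSummary(group=group, metric=metric, mean=mean, sd=sd, n=n)


def _normality(values: np.ndarray) -> tuple[float, float]:
    """(Shapiro-Wilk p, Lilliefors-KS p); NaN when not computable."""
    sw = math.nan
    ks = math.nan
    if values.size >= 3 and np.ptp(values) > 0:
        sw = float(sps.shapiro(values).pvalue)
    if values.size >= 4 and np.ptp(values) > 0:
        ks = float(lilliefors(values, dist="norm")[1])
    return sw, ks


def _normal_enough(groups: Mapping[str, np.ndarray]) -> bool:
    for v in groups.values():
        sw, ks = _normality(v)
        if not math.isnan(sw) and sw < ALPHA:
            return False
        if not math.isnan(ks) and ks < ALPHA:
            return False
    return True


def compare_groups(
    groups: Mapping[str, Sequence[float]], metric: str = ""
) -> ComparisonResult:
    """Two-sided group comparison at alpha = 0.05 with the gated workflow.

    Two groups: Student's t when Levene's p > 0.05, else Welch's t.
    More than two: one-way ANOVA followed by Tukey HSD.  When normality
    fails, square-root then natural-log transformations are attempted
    (when the data admit them) and recorded.
    """
    names = tuple(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    warnings: list[str] = []

    transform = ""
    if not _normal_enough(data):
        if all((v >= 0).all() for v in data.values()):
            cand = {k: np.sqrt(v) for k, v in data.items()}
            if _normal_enough(cand):
                data, transform = cand, "sqrt"
        if not transform and all((v > 0).all() for v in data.values()):
            cand = {k: np.log(v) for k, v in data.items()}
            if _normal_enough(cand):
                data, transform = cand, "log"
        if not transform:
            warnings.append("normality_not_met")

    shapiro_p: dict[str, float] = {}
    ks_p: dict[str, float] = {}
    for k, v in data.items():
        shapiro_p[k], ks_p[k] = _normality(v)
        if np.ptp(v) == 0:
            warnings.append(f"zero_variance:{k}")

    values = list(data.values())
    if all(np.ptp(v) == 0 for v in values):
        levene_p = math.nan
    else:
        levene_p = float(sps.levene(*values).pvalue)

    tukey = None
    if len(names) == 2:
        a, b = values
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate: both groups constant
            if a[0] == b[0]:
                stat, p = 0.0, 1.0
            else:
                stat, p = math.inf, 0.0
            test = "student_t"
        elif not math.isnan(levene_p) and levene_p > ALPHA:
            r = sps.ttest_ind(a, b, equal_var=True)
            stat, p, test = float(r.statistic), float(r.pvalue), "student_t"
        else:
            r = sps.ttest_ind(a, b, equal_var=False)
            stat, p, test = float(r.statistic), float(r.pvalue), "welch_t"
    else:
        r = sps.f_oneway(*values)
        stat, p, test = float(r.statistic), float(r.pvalue), "anova_tukey"
        flat = np.concatenate(values)
        labels = np.concatenate([[k] * len(data[k]) for k in names])
        res = pairwise_tukeyhsd(flat, labels, alpha=ALPHA)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )

    return ComparisonResult(
        metric=metric,
        groups=names,
        shapiro_p=shapiro_p,
        ks_p=ks_p,
        levene_p=levene_p,
        transform=transform,
        test=test,
        statistic=stat,
        p_value=p,
        significant=bool(p < ALPHA),
        warnings=warnings,
        tukey=tukey,
    )


def group_summary_table(
    summaries: pd.DataFrame,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean +- SD per group for each metric column of a summary frame."""
    if metrics is None:
        metrics = [
            c for c in summaries.columns
            if c not in ("sample_id", "group") and pd.api.types.is_numeric_dtype(summaries[c])
        ]
    rows = []
    for group, sub in summaries.groupby("group", sort=False):
        for metric in metrics:
            g = group_aggregate(sub[metric].to_numpy(), str(group), metric)
            rows.append(vars(g))
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "sd", "n"])
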