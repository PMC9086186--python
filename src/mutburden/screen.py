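"""Phenotype-exclusive gene screen.

From the group-specific, annotated variant tables a gene x sample
presence matrix is built (presence = at least one amino-acid-changing
SNP in that gene for that sample).  Genes are then extracted that are
hit in the target phenotype group (e.g. the largest animals) and in no
sample of any excluded group — the screen that singled out candidate
growth genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

#: Effects that count as presence.  Stopgain/stoploss change the protein
#: and are included by default; pass damaging=("nonsynonymous",) to restrict.
DAMAGING_EFFECTS = ("nonsynonymous", "stopgain", "stoploss")


@dataclass
class PresenceMatrix:
    """Boolean gene x sample matrix with the samples' group labels."""

    cells: pd.DataFrame  # index: gene_id (sorted); columns: sample_id
    groups: dict  # sample_id -> group label

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cells.columns)


def build_presence_matrix(
    annotated: pd.DataFrame,
    groups: Mapping[str, str],
    *,
    damaging: Sequence[str] = DAMAGING_EFFECTS,
) -> PresenceMatrix:
    """Build the matrix from a long annotated variant table.

    ``annotated`` holds the post-filter calls of all samples (columns
    ``sample_id``, ``vtype``, ``effect``, ``gene_id``).  Rows cover
    exactly the genes with at least one qualifying SNP in some sample;
    columns cover every sample in ``groups`` even if it has none.
    """
    hits = annotated[
        (annotated["vtype"] == "SNP")
        & annotated["effect"].isin(list(damaging))
        & (annotated["gene_id"] != "")
    ]
    samples = list(groups)
    table = (
        hits.groupby(["gene_id", "sample_id"]).size().unstack(fill_value=0) > 0
    )
    table = table.reindex(columns=samples, fill_value=False)
    table = table.sort_index()
    return PresenceMatrix(cells=table, groups=dict(groups))


def exclusive_genes(
    matrix: PresenceMatrix,
    target_group: str,
    excluded_groups: Sequence[str],
    *,
    min_target_samples: int = 1,
) -> list[str]:
    """Genes present in >= ``min_target_samples`` target-group samples and
    absent from every sample of each excluded group, sorted by gene ID."""
    known = set(matrix.groups.values())
    for g in [target_group, *excluded_groups]:
        if g not in known:
            raise ValueError(f"unknown group label {g!r}; cohort has {sorted(known)}")
    target_cols = [s for s, g in matrix.groups.items() if g == target_group]
    excl_cols = [s for s, g in matrix.groups.items() if g in set(excluded_groups)]
    cells = matrix.cells
    in_target = cells[target_cols].sum(axis=1) >= min_target_samples
    in_excluded = cells[excl_cols].any(axis=1) if excl_cols else pd.Series(False, index=cells.index)
    return sorted(cells.index[in_target & ~in_excluded])
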