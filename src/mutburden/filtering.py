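"""Shared-type removal against the control panel.

Treated samples keep only mutation types (five-field keys) absent from
the union of all control samples.  Control samples cannot be filtered
against a panel containing themselves, so their group-specific sets are
defined leave-one-out: each control subtracts the union of the *other*
controls.  An alternative mode subtracts the intersection of the two
group-wide unions from every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .variants import SampleVariantSet, VariantKey

MODES = ("control_union", "leave_one_out_controls", "intersection_of_group_unions")


@dataclass(frozen=True)
class SharedSetPolicy:
    """Which panel a sample's shared types are defined against."""

    mode: str = "control_union"
    ignore_geno: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")


def control_shared_set(
    controls: Sequence[SampleVariantSet], *, ignore_geno: bool = False
) -> set[VariantKey]:
    """Union of all variant keys observed in any control sample."""
    if not controls:
        raise ValueError("control panel is empty")
    shared: set[VariantKey] = set()
    for c in controls:
        shared |= c.keys(ignore_geno=ignore_geno)
    return shared


def _subtract(sample: SampleVariantSet, panel: set[VariantKey], ignore_geno: bool) -> SampleVariantSet:
    if ignore_geno:
        kept = [c for c in sample.calls if c.key.drop_geno() not in panel]
    else:
        kept = [c for c in sample.calls if c.key not in panel]
    return replace(sample, calls=kept)


def group_specific_variants(
    sample: SampleVariantSet,
    controls: Sequence[SampleVariantSet],
    policy: SharedSetPolicy | None = None,
    *,
    treated_union: set[VariantKey] | None = None,
) -> SampleVariantSet:
    """Remove shared mutation types from one sample, leaving its
    group-specific ("unique") set.  ``clean_bases`` is unchanged.

    Under the default policy a treated sample subtracts the full control
    union and a control sample subtracts the union of the other controls.
    Under ``intersection_of_group_unions`` every sample subtracts the keys
    present in both the control union and the treated union
    (``treated_union`` must then be supplied).
    """
    policy = policy or SharedSetPolicy()
    ig = policy.ignore_geno
    is_control = sample.group == "control" or any(
        c.sample_id == sample.sample_id for c in controls
    )
    if policy.mode == "intersection_of_group_unions":
        if treated_union is None:
            raise ValueError("intersection_of_group_unions requires treated_union")
        panel = control_shared_set(controls, ignore_geno=ig) & treated_union
        return _subtract(sample, panel, ig)
    if is_control:
        others = [c for c in controls if c.sample_id != sample.sample_id]
        if not others:
            return _subtract(sample, set(), ig)
        panel = control_shared_set(others, ignore_geno=ig)
        return _subtract(sample, panel, ig)
    panel = control_shared_set(controls, ignore_geno=ig)
    return _subtract(sample, panel, ig)


def filter_cohort(
    samples: Sequence[SampleVariantSet],
    policy: SharedSetPolicy | None = None,
) -> list[SampleVariantSet]:
    """Apply shared-type removal to every sample of a cohort.

    Controls are identified by their group label.
    """
    policy = policy or SharedSetPolicy()
    controls = [s for s in samples if s.group == "control"]
    if not controls:
        raise ValueError("cohort has no control samples")
    treated_union: set[VariantKey] | None = None
    if policy.mode == "intersection_of_group_unions":
        treated_union = set()
        for s in samples:
            if s.group != "control":
                treated_union |= s.keys(ignore_geno=policy.ignore_geno)
    return [
        group_specific_variants(s, controls, policy, treated_union=treated_union)
        for s in samples
    ]
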