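"""Dual-caller harmonization: merge two call sets and decompose MNPs.

The primary caller (label "A", HaplotypeCaller role) takes precedence: when
both callers report the same normalized variant key, the merged record keeps
caller A's read counts and quality metrics and is marked provenance "both".
Multi-base substitutions (MNPs, as emitted by FreeBayes-style callers) are
split into their constituent SNVs, each inheriting the parent's counts, and
re-enter the downstream filters individually.  Composite records that mix a
length change with substituted bases cannot be resolved without looking at
the reads, so they are quarantined for human review rather than guessed at.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .records import VariantObservation, genomic_sort_key


def merge_caller_results(
    calls_a: list[VariantObservation],
    calls_b: list[VariantObservation],
) -> list[VariantObservation]:
    """Union the two callers' observations by normalized variant key.

    Both lists must come from the same sample.  A-only and B-only variants
    keep their own counts; shared keys keep A's counts with provenance
    "both".  Re-merging is stable: an existing A-side record always wins.
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"cannot merge call sets from different samples: {samples}")
    merged: dict = {}
    for obs in calls_a:
        merged[obs.key] = obs
    for obs in calls_b:
        if obs.key in merged:
            if merged[obs.key].caller != "both":
                merged[obs.key] = replace(merged[obs.key], caller="both")
        else:
            merged[obs.key] = obs
    return sorted(merged.values(), key=genomic_sort_key)


def decompose_mnp(record: VariantObservation) -> list[VariantObservation]:
    """Split an equal-length multi-base substitution into per-base SNVs.

    One SNV is emitted for every aligned position where ref and alt differ,
    re-keyed at its own 1-based position; each component inherits the
    parent's read counts, quality metrics and provenance (the evidence is
    the same reads, so counts are inherited, never divided).
    """
    if len(record.ref) != len(record.alt):
        raise ValueError(
            f"not an equal-length substitution: {record.ref}>{record.alt}"
        )
    components = []
    for offset, (r, a) in enumerate(zip(record.ref, record.alt)):
        if r != a:
            components.append(
                replace(record, pos=record.pos + offset, ref=r, alt=a)
            )
    if not components:
        raise ValueError(f"not a variant: {record.ref}>{record.alt} (ref == alt)")
    return components


def is_composite_indel(record: VariantObservation) -> bool:
    """Length-changing allele pair with >1 base on both sides after
    normalization — the irreducible MNP+indel composites that the source
    protocol resolved by eye; routed to quarantine."""
    return (
        len(record.ref) != len(record.alt)
        and len(record.ref) > 1
        and len(record.alt) > 1
    )


def harmonize_sample(
    calls_a: list[VariantObservation],
    calls_b: list[VariantObservation],
) -> tuple[list[VariantObservation], list[VariantObservation]]:
    """Merge two call sets and decompose MNPs into primitive variants.

    Returns (harmonized observations, quarantined composites).  MNP
    components whose key is already present (typically because caller A
    reported the constituent SNVs directly) are folded into the existing
    record, which is promoted to provenance "both".
    """
    merged = merge_caller_results(calls_a, calls_b)
    out: dict = {}
    quarantine: list[VariantObservation] = []
    mnps: list[VariantObservation] = []
    for obs in merged:
        if obs.is_mnp:
            mnps.append(obs)
        elif is_composite_indel(obs):
            quarantine.append(obs)
        else:
            out.setdefault(obs.key, obs)
    # decompose after all primitive records are placed, so a component whose
    # SNV was also called directly folds into that record instead of
    # shadowing it
    for obs in mnps:
        for comp in decompose_mnp(obs):
            if comp.key in out:
                if out[comp.key].caller != "both":
                    out[comp.key] = replace(out[comp.key], caller="both")
            else:
                out[comp.key] = comp
    return (
        sorted(out.values(), key=genomic_sort_key),
        sorted(quarantine, key=genomic_sort_key),
    )


def write_quarantine_table(path: str, quarantined: list[VariantObservation]) -> None:
    rows = [
        {
            "sample": q.sample_id, "chrom": q.chrom, "pos": q.pos,
            "ref": q.ref, "alt": q.alt, "total_reads": q.total_reads,
            "alt_reads": q.alt_reads, "caller": q.caller,
        }
        for q in quarantined
    ]
    pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "total_reads",
                 "alt_reads", "caller"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
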