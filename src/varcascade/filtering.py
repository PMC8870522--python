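"""The somatic exclusion cascade.

Every variant is evaluated against every applicable exclusion predicate;
reasons accumulate (no short-circuiting) so the per-reason tally is a
complete audit of why each variant fell out.  A variant is retained iff its
reason set is empty.  The predicates are independent, which makes the
retained set invariant under evaluation order — a property the tests check
explicitly.

Inequality directions and strictness follow the published criteria exactly:
exclusion when QUAL < 20, FS > 60, MQ < 40, MQRankSum < -12.5, QD < 2,
QD/AF < 8.0, ReadPosRankSum < -20; synonymous consequence; 1000 Genomes
frequency > 2% (strict); ExAC or gnomAD frequency >= 0.1% (inclusive);
total reads < 20; alt-supporting reads < 4; alt-supporting reads in the
matched blood sample > 3 (strict); CADD Phred < 15 (a score of exactly 15
is kept).  Boundary values therefore pass wherever the printed inequality
is strict.

A metric or annotation that is absent triggers no exclusion: a variant
cannot fail a test that was not computed.  Excluding on absence would
silently drop secondary-caller calls that lack GATK-style annotations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Optional, Sequence

from .records import VariantKey, VariantObservation

logger = logging.getLogger(__name__)

# exclusion reason codes
QUAL_LOW = "QUAL_LOW"
FS_HIGH = "FS_HIGH"
MQ_LOW = "MQ_LOW"
MQRS_LOW = "MQRS_LOW"
QD_LOW = "QD_LOW"
QD_AF_LOW = "QD_AF_LOW"
RPRS_LOW = "RPRS_LOW"
SYNONYMOUS = "SYNONYMOUS"
POP_1000G = "POP_1000G"
POP_EXAC_GNOMAD = "POP_EXAC_GNOMAD"
DEPTH_LOW = "DEPTH_LOW"
ALT_SUPPORT_LOW = "ALT_SUPPORT_LOW"
GERMLINE_IN_BLOOD = "GERMLINE_IN_BLOOD"
CADD_LOW = "CADD_LOW"
NO_GENE_RESCUE = "NO_GENE_RESCUE"

ALL_REASONS = (
    QUAL_LOW, FS_HIGH, MQ_LOW, MQRS_LOW, QD_LOW, QD_AF_LOW, RPRS_LOW,
    SYNONYMOUS, POP_1000G, POP_EXAC_GNOMAD, DEPTH_LOW, ALT_SUPPORT_LOW,
    GERMLINE_IN_BLOOD, CADD_LOW, NO_GENE_RESCUE,
)


@dataclass(frozen=True)
class FilterThresholds:
    """All cascade cut-offs, defaults as published.

    ``qd_af_rule`` selects how the ambiguous "QD/allele frequency < 8.0"
    clause is read: ``"ratio"`` (default) compares qd / vaf against
    ``qd_af_min``; ``"off"`` disables the clause.
    """

    qual_min: float = 20.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqrs_min: float = -12.5
    qd_min: float = 2.0
    qd_af_min: float = 8.0
    qd_af_rule: str = "ratio"
    rprs_min: float = -20.0
    pop_1000g_max: float = 0.02
    pop_maf_max: float = 0.001
    depth_min: int = 20
    alt_min: int = 4
    blood_alt_max: int = 3
    cadd_min: float = 15.0

    def __post_init__(self) -> None:
        if self.qd_af_rule not in ("ratio", "off"):
            raise ValueError(f"unknown qd_af_rule: {self.qd_af_rule!r}")


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class FilterVerdict:
    """Outcome of the cascade for one variant: retained iff no reasons."""

    variant_key: VariantKey
    retained: bool
    reasons: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        assert self.retained == (not self.reasons)


# ---------------------------------------------------------------------------
# predicates — each returns the set of reasons it raises
# ---------------------------------------------------------------------------

def apply_quality_filters(
    v: VariantObservation, th: FilterThresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    q = v.quality
    reasons: set[str] = set()
    if q.qual is not None and q.qual < th.qual_min:
        reasons.add(QUAL_LOW)
    if q.fs is not None and q.fs > th.fs_max:
        reasons.add(FS_HIGH)
    if q.mq is not None and q.mq < th.mq_min:
        reasons.add(MQ_LOW)
    if q.mq_rank_sum is not None and q.mq_rank_sum < th.mqrs_min:
        reasons.add(MQRS_LOW)
    if q.qd is not None and q.qd < th.qd_min:
        reasons.add(QD_LOW)
    if (
        th.qd_af_rule == "ratio"
        and q.qd is not None
        and v.vaf > 0
        and q.qd / v.vaf < th.qd_af_min
    ):
        reasons.add(QD_AF_LOW)
    if q.read_pos_rank_sum is not None and q.read_pos_rank_sum < th.rprs_min:
        reasons.add(RPRS_LOW)
    return reasons


def apply_consequence_and_population_filters(
    v: VariantObservation, th: FilterThresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    a = v.annotation
    reasons: set[str] = set()
    if a.consequence == "synonymous":
        reasons.add(SYNONYMOUS)
    if a.af_1000g is not None and a.af_1000g > th.pop_1000g_max:
        reasons.add(POP_1000G)
    if (a.af_exac is not None and a.af_exac >= th.pop_maf_max) or (
        a.af_gnomad is not None and a.af_gnomad >= th.pop_maf_max
    ):
        reasons.add(POP_EXAC_GNOMAD)
    return reasons


def apply_read_support_filter(
    v: VariantObservation, th: FilterThresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    reasons: set[str] = set()
    if v.total_reads < th.depth_min:
        reasons.add(DEPTH_LOW)
    if v.alt_reads < th.alt_min:
        reasons.add(ALT_SUPPORT_LOW)
    return reasons


def subtract_germline(
    v: VariantObservation,
    normal_alt_reads: dict[VariantKey, int],
    th: FilterThresholds = DEFAULT_THRESHOLDS,
) -> set[str]:
    """Matched-blood germline subtraction: exclude when the same variant key
    carries more than ``blood_alt_max`` alt reads in the normal sample.
    A key absent from the blood call set raises no reason."""
    alt_in_blood = normal_alt_reads.get(v.key)
    if alt_in_blood is not None and alt_in_blood > th.blood_alt_max:
        return {GERMLINE_IN_BLOOD}
    return set()


def apply_pathogenicity_filter(
    v: VariantObservation, th: FilterThresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    cadd = v.annotation.cadd_phred
    if cadd is None:
        logger.warning("CADD score absent for %s:%d %s>%s; not excluded",
                       *v.key)
        return set()
    if cadd < th.cadd_min:
        return {CADD_LOW}
    return set()


def rescue_filter_unmatched(
    v: VariantObservation,
    matched_cohort_somatic_genes: frozenset | set,
    th: FilterThresholds = DEFAULT_THRESHOLDS,
) -> set[str]:
    """Unmatched-sample gene rescue: without a blood sample, only variants in
    genes that (1) carry somatic variants in the matched part of the cohort,
    or (2) are flagged tumor-suppressor/oncogene, are trusted as somatic."""
    a = v.annotation
    if a.is_cancer_gene:
        return set()
    if a.gene is not None and a.gene in matched_cohort_somatic_genes:
        return set()
    return {NO_GENE_RESCUE}


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

#: Default evaluation order; the retained set does not depend on it.
PREDICATE_NAMES = (
    "quality", "consequence_population", "read_support", "germline",
    "pathogenicity", "gene_rescue",
)


@dataclass
class CascadeResult:
    verdicts: list[FilterVerdict]
    tally: Counter = field(default_factory=Counter)

    @property
    def retained_keys(self) -> frozenset:
        return frozenset(v.variant_key for v in self.verdicts if v.retained)


def normal_alt_lookup(
    normal_calls: Iterable[VariantObservation],
) -> dict[VariantKey, int]:
    """Max alt-read count per key across the normal call set."""
    lookup: dict[VariantKey, int] = {}
    for obs in normal_calls:
        lookup[obs.key] = max(lookup.get(obs.key, 0), obs.alt_reads)
    return lookup


def run_cascade(
    variants: Sequence[VariantObservation],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    mode: str = "matched",
    normal_calls: Optional[Sequence[VariantObservation]] = None,
    matched_somatic_genes: Iterable[str] = (),
    predicate_order: Optional[Sequence[str]] = None,
) -> CascadeResult:
    """Evaluate every applicable predicate for every variant.

    ``mode="matched"`` applies blood-based germline subtraction and requires
    a normal call set (an empty one is legal; ``None`` is an error).
    ``mode="unmatched"`` applies the gene-rescue filter instead, against the
    somatic gene set of the already-filtered matched cohort plus cancer-gene
    flags.  ``predicate_order`` permutes evaluation order; reasons accumulate
    so the retained set is order-invariant.
    """
    if mode not in ("matched", "unmatched"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "matched" and normal_calls is None:
        raise ValueError("matched mode requires a normal call set")
    blood = normal_alt_lookup(normal_calls) if mode == "matched" else {}
    genes = frozenset(matched_somatic_genes)

    predicates: dict[str, Callable[[VariantObservation], set[str]]] = {
        "quality": lambda v: apply_quality_filters(v, thresholds),
        "consequence_population":
            lambda v: apply_consequence_and_population_filters(v, thresholds),
        "read_support": lambda v: apply_read_support_filter(v, thresholds),
        "pathogenicity": lambda v: apply_pathogenicity_filter(v, thresholds),
    }
    if mode == "matched":
        predicates["germline"] = lambda v: subtract_germline(v, blood, thresholds)
    else:
        predicates["gene_rescue"] = (
            lambda v: rescue_filter_unmatched(v, genes, thresholds)
        )

    order = list(predicate_order) if predicate_order is not None else list(
        n for n in PREDICATE_NAMES if n in predicates
    )
    unknown = [n for n in order if n not in predicates]
    if unknown:
        raise ValueError(f"unknown or inapplicable predicates: {unknown}")

    verdicts: list[FilterVerdict] = []
    tally: Counter = Counter()
    for v in variants:
        reasons: set[str] = set()
        for name in order:
            reasons |= predicates[name](v)
        tally.update(sorted(reasons))
        verdicts.append(
            FilterVerdict(variant_key=v.key, retained=not reasons,
                          reasons=frozenset(reasons))
        )
    return CascadeResult(verdicts=verdicts, tally=tally)


def thresholds_to_dict(th: FilterThresholds) -> dict:
    return asdict(th)
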