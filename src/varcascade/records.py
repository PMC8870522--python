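"""Core record types shared across the pipeline.

A variant observation is one ALT allele seen in one sample by one caller
(or by both, after harmonization).  Coordinates are 1-based VCF-style
throughout the variant path; coverage targets use 0-based half-open BED
coordinates and the two conventions meet only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: (chromosome, 1-based position, ref allele, alt allele)
VariantKey = tuple[str, int, str, str]

#: Consequence classes consumed from the annotation source.  Consequence
#: prediction itself is out of scope: one class per variant is taken as given.
CONSEQUENCE_CLASSES = (
    "missense",
    "frameshift",
    "inframe_indel",
    "disruptive_inframe_indel",
    "splice",
    "nonsense",
    "start_lost",
    "synonymous",
    "other",
)

#: Protein-altering classes; synonymous variants are dropped by the cascade.
NONSYNONYMOUS_CLASSES = frozenset(
    c for c in CONSEQUENCE_CLASSES if c not in ("synonymous", "other")
)


@dataclass(frozen=True)
class QualityMetrics:
    """Caller quality annotations; ``None`` means the caller did not emit it.

    Absence is represented explicitly and never coerced to 0 — several of
    these metrics (rank sums) are legitimately negative, and a missing metric
    must not look like a failing one.
    """

    qual: Optional[float] = None            # Phred-scaled site quality
    fs: Optional[float] = None              # Fisher strand bias (Phred)
    mq: Optional[float] = None              # RMS mapping quality
    mq_rank_sum: Optional[float] = None     # MQ rank-sum (alt vs ref reads)
    qd: Optional[float] = None              # quality / depth
    read_pos_rank_sum: Optional[float] = None  # read-position rank-sum


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotation: gene, consequence, population AFs, CADD.

    All fields optional; an empty bundle means the variant was not found in
    the annotation table (join logs a warning and the filters treat missing
    values as passing, never as failing).
    """

    gene: Optional[str] = None
    consequence: Optional[str] = None
    af_1000g: Optional[float] = None
    af_exac: Optional[float] = None
    af_gnomad: Optional[float] = None
    cadd_phred: Optional[float] = None
    is_cancer_gene: bool = False

    def __post_init__(self) -> None:
        for name in ("af_1000g", "af_exac", "af_gnomad"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


EMPTY_ANNOTATION = AnnotationBundle()


def normalize_allele_pair(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim shared suffix then shared prefix so that the two callers'
    representations of the same event collide on one key.

    (Full left-alignment needs the reference sequence; prefix/suffix
    trimming is the reference-free part and is what the callers' direct
    output requires here.)
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass
class VariantObservation:
    """One normalized ALT-allele observation in one sample.

    ``alt_reads`` is the count of reads supporting the alternate allele
    (the "minor allele count" in the filtering rules); ``vaf`` is
    alt_reads / total_reads.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_reads: int
    alt_reads: int
    quality: QualityMetrics = field(default_factory=QualityMetrics)
    caller: str = "A"              # "A" | "B" | "both"
    sample_id: str = ""
    sample_role: str = "tumor"     # "tumor" | "normal"
    annotation: AnnotationBundle = EMPTY_ANNOTATION

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.alt_reads > self.total_reads:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds total_reads "
                f"({self.total_reads}) at {self.chrom}:{self.pos}"
            )
        self.chrom, self.pos, self.ref, self.alt = normalize_allele_pair(
            self.chrom, self.pos, self.ref, self.alt
        )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_mnp(self) -> bool:
        """Equal-length multi-base substitution (decomposable into SNVs)."""
        return len(self.ref) == len(self.alt) > 1

    def with_annotation(self, annotation: AnnotationBundle) -> "VariantObservation":
        return replace(self, annotation=annotation)


def genomic_sort_key(v: VariantObservation) -> tuple:
    return (_chrom_rank(v.chrom), v.chrom, v.pos, v.ref, v.alt)


def _chrom_rank(chrom: str) -> tuple[int, int]:
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (0, int(name))
    return (1, 0)
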