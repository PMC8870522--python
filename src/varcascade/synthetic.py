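"""Synthetic tumor/normal dual-caller cohort generator with ground truth.

Emulates the inputs the filtering cascade consumes: two callers' VCFs per
tumor (a GATK-style primary caller "A" and a FreeBayes-style secondary
caller "B"), an optional matched-blood VCF, an annotation table
(population frequencies, CADD, consequence, gene, cancer-gene flag) and
per-target coverage profiles with injected copy-number events.

Three truth classes are planted per case:

* **somatic** events at a major-clone VAF or a subclonal VAF, with clean
  quality metrics and rare/absent population frequencies;
* **germline** events, present in tumor and matched blood (blood alt reads
  forced > 3 so blood subtraction must remove them); most carry common
  population frequencies, a fraction are rare "personal" variants that
  only the unmatched-sample gene-rescue rule can remove;
* **artifact** events, which violate at least one quality criterion by
  construction.

Read counts are binomial draws of alt reads given a Poisson depth and the
assigned VAF.  A configurable fraction of somatic events is emitted as a
two-base MNP in caller B only, with the constituent SNVs in caller A;
another fraction appears in caller B only.  Every emitted primitive
variant has exactly one truth row whose ``expected_surviving`` flag is
precomputed by an independent, brute-force restatement of the filtering
rules (kept deliberately separate from the cascade implementation so the
two can be compared as implementation vs oracle).

Determinism: one master seed; per-case substreams are derived from the
seed and a CRC32 of the case id, so identical (config, seed) give
byte-identical output files regardless of generation order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cna import TargetCoverageProfile
from .records import (
    AnnotationBundle,
    QualityMetrics,
    VariantObservation,
)
from .vcfio import ANNOTATION_COLUMNS, write_annotation_table, write_caller_vcf


class ConfigError(ValueError):
    """Invalid simulator configuration; the message names the field."""


CHROMS = tuple(f"chr{i}" for i in range(1, 9))
BASES = "ACGT"

#: gene pools — somatic, germline and artifact events draw from disjoint
#: pools so that cohort-level gene logic (recurrence, unmatched rescue) has
#: known truth.  The first entries of the somatic pool carry the
#: tumor-suppressor/oncogene flag.
SOMATIC_GENE_POOL = tuple(f"SOM{i:03d}" for i in range(160))
CANCER_GENES = frozenset(SOMATIC_GENE_POOL[:25])
GERMLINE_GENE_POOL = tuple(f"GER{i:03d}" for i in range(300))
ARTIFACT_GENE_POOL = tuple(f"ART{i:03d}" for i in range(100))

#: consequence mix for planted somatic events (protein-altering classes,
#: weighted toward missense as in real exomes)
SOMATIC_CONSEQUENCES = (
    ("missense", 0.66),
    ("frameshift", 0.12),
    ("splice", 0.08),
    ("inframe_indel", 0.06),
    ("nonsense", 0.05),
    ("disruptive_inframe_indel", 0.02),
    ("start_lost", 0.01),
)

TRUTH_COLUMNS = [
    "case_id", "chrom", "pos", "ref", "alt",
    "truth_class", "truth_clonality", "expected_surviving",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-shaped defaults: a cohort of 12 matched + 5 unmatched cases,
    mostly low somatic burden with a high-burden minority, ~130x depth."""

    n_matched_cases: int = 12
    n_unmatched_cases: int = 5
    somatic_low_mean: float = 7.0        # Poisson mean, low-burden cases
    somatic_high_mean: float = 40.0      # Poisson mean, high-burden cases
    high_burden_fraction: float = 0.18   # ~3 of 17 cases
    germline_per_case: int = 30
    artifact_per_case: int = 10
    major_clone_vaf: float = 0.35
    minor_clone_vaf_range: tuple[float, float] = (0.05, 0.15)
    mean_depth: float = 130.0
    mnp_fraction: float = 0.10
    caller_b_only_fraction: float = 0.10
    n_targets: int = 2000
    target_length: int = 120
    target_spacing: int = 10_000
    #: injected CNA events: (chrom, first_target_idx, last_target_idx
    #: [inclusive, chromosome-local], copy_number)
    cna_segments: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("high_burden_fraction", "mnp_fraction",
                     "caller_b_only_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.major_clone_vaf <= 1.0):
            raise ConfigError(
                f"major_clone_vaf must lie in (0, 1], got {self.major_clone_vaf}"
            )
        lo, hi = self.minor_clone_vaf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(
                f"minor_clone_vaf_range must be an ordered interval in (0, 1], "
                f"got {self.minor_clone_vaf_range}"
            )
        if self.mean_depth <= 0:
            raise ConfigError(f"mean_depth must be > 0, got {self.mean_depth}")
        for name in ("n_matched_cases", "n_unmatched_cases",
                     "germline_per_case", "artifact_per_case", "n_targets",
                     "target_length", "target_spacing"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.somatic_low_mean < 0 or self.somatic_high_mean < 0:
            raise ConfigError("somatic burden means must be >= 0")
        self._validate_segments()

    def _validate_segments(self) -> None:
        per_chrom = targets_per_chrom(self.n_targets)
        seen: dict[str, list[tuple[int, int]]] = {}
        for seg in self.cna_segments:
            chrom, i0, i1, cn = seg
            if chrom not in per_chrom:
                raise ConfigError(f"cna_segments: unknown chromosome {chrom!r}")
            if not (0 <= i0 <= i1 < per_chrom[chrom]):
                raise ConfigError(
                    f"cna_segments: target indices {i0}..{i1} out of range "
                    f"for {chrom} ({per_chrom[chrom]} targets)"
                )
            if cn < 0 or int(cn) != cn:
                raise ConfigError(f"cna_segments: copy_number must be a "
                                  f"non-negative integer, got {cn}")
            for a, b in seen.get(chrom, []):
                if i0 <= b and a <= i1:
                    raise ConfigError(
                        f"cna_segments: overlapping segments on {chrom}"
                    )
            seen.setdefault(chrom, []).append((i0, i1))


def targets_per_chrom(n_targets: int) -> dict[str, int]:
    base, extra = divmod(n_targets, len(CHROMS))
    return {c: base + (1 if i < extra else 0) for i, c in enumerate(CHROMS)}


def _case_rng(config: CohortSimConfig, case_id: str, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(case_id.encode()), stream]
    )


# ---------------------------------------------------------------------------
# the independent survival oracle
# ---------------------------------------------------------------------------

def oracle_survives(
    *,
    total_reads: int,
    alt_reads: int,
    qual: Optional[float],
    fs: Optional[float],
    mq: Optional[float],
    mq_rank_sum: Optional[float],
    qd: Optional[float],
    read_pos_rank_sum: Optional[float],
    consequence: Optional[str],
    af_1000g: Optional[float],
    af_exac: Optional[float],
    af_gnomad: Optional[float],
    cadd_phred: Optional[float],
    matched: bool,
    normal_alt_reads: Optional[int],
    gene: Optional[str],
    is_cancer_gene: bool,
    matched_somatic_genes: frozenset,
) -> bool:
    """Brute-force restatement of the retention rules, written directly from
    their printed form and independent of the cascade implementation."""
    vaf = alt_reads / total_reads if total_reads else 0.0
    if qual is not None and qual < 20:
        return False
    if fs is not None and fs > 60:
        return False
    if mq is not None and mq < 40:
        return False
    if mq_rank_sum is not None and mq_rank_sum < -12.5:
        return False
    if qd is not None and qd < 2:
        return False
    if qd is not None and vaf > 0 and qd / vaf < 8.0:
        return False
    if read_pos_rank_sum is not None and read_pos_rank_sum < -20:
        return False
    if consequence == "synonymous":
        return False
    if af_1000g is not None and af_1000g > 0.02:
        return False
    if af_exac is not None and af_exac >= 0.001:
        return False
    if af_gnomad is not None and af_gnomad >= 0.001:
        return False
    if total_reads < 20 or alt_reads < 4:
        return False
    if matched and normal_alt_reads is not None and normal_alt_reads > 3:
        return False
    if cadd_phred is not None and cadd_phred < 15:
        return False
    if not matched:
        if not is_cancer_gene and (gene is None or gene not in matched_somatic_genes):
            return False
    return True


# ---------------------------------------------------------------------------
# case simulation
# ---------------------------------------------------------------------------

@dataclass
class CaseBundle:
    """Everything the simulator emits for one case."""

    case_id: str
    matched: bool
    calls_a: list[VariantObservation]
    calls_b: list[VariantObservation]
    normal_calls: Optional[list[VariantObservation]]
    annotations: pd.DataFrame
    truth: pd.DataFrame


def _clean_quality(rng: np.random.Generator) -> dict:
    return {
        "qual": round(float(rng.uniform(100, 2000)), 1),
        "fs": round(float(rng.uniform(0, 10)), 3),
        "mq": round(float(rng.uniform(55, 60)), 2),
        "mq_rank_sum": round(float(rng.uniform(-2, 2)), 3),
        "qd": round(float(rng.uniform(10, 30)), 2),
        "read_pos_rank_sum": round(float(rng.uniform(-2, 2)), 3),
    }


_VIOLATIONS = {
    "qual": lambda rng: round(float(rng.uniform(0, 19.9)), 1),
    "fs": lambda rng: round(float(rng.uniform(60.1, 300)), 2),
    "mq": lambda rng: round(float(rng.uniform(5, 39.9)), 2),
    "mq_rank_sum": lambda rng: round(float(rng.uniform(-40, -12.6)), 3),
    "qd": lambda rng: round(float(rng.uniform(0, 1.99)), 3),
    "read_pos_rank_sum": lambda rng: round(float(rng.uniform(-60, -20.1)), 3),
}


class _SiteAllocator:
    """Hands out unused (chrom, pos) sites, optionally with a free
    neighbouring base for MNP emission."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def take(self, adjacent: bool = False) -> tuple[str, int]:
        while True:
            chrom = str(self.rng.choice(CHROMS))
            pos = int(self.rng.integers(1, 50_000_000))
            span = (pos, pos + 1) if adjacent else (pos,)
            if all((chrom, p) not in self.used for p in span):
                self.used.update((chrom, p) for p in span)
                return chrom, pos


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return str(rng.choice(choices))


def _pick_consequence(rng: np.random.Generator) -> str:
    names = [n for n, _ in SOMATIC_CONSEQUENCES]
    weights = np.array([w for _, w in SOMATIC_CONSEQUENCES])
    return str(rng.choice(names, p=weights / weights.sum()))


def simulate_case(
    config: CohortSimConfig,
    case_id: str,
    matched: bool = True,
    matched_somatic_genes: Optional[Iterable[str]] = None,
) -> CaseBundle:
    """Generate one case's dual-caller call sets, annotations and truth.

    ``matched_somatic_genes`` is the somatic gene set of the fully filtered
    matched cohort, needed to precompute ``expected_surviving`` for
    unmatched cases (``simulate_cohort`` wires it); if ``None`` the rescue
    oracle falls back to cancer-gene flags alone.
    """
    config.validate()
    rng = _case_rng(config, case_id, 0)
    sites = _SiteAllocator(rng)
    rescue_genes = frozenset(matched_somatic_genes or ())

    calls_a: list[VariantObservation] = []
    calls_b: list[VariantObservation] = []
    normal_calls: list[VariantObservation] = []
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(
        *,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        depth: int,
        alt_reads: int,
        quality: dict,
        annotation: dict,
        truth_class: str,
        truth_clonality: str,
        in_a: bool,
        in_b: bool,
        b_missing_ranksums: bool = False,
        normal_depth: Optional[int] = None,
        normal_alt: Optional[int] = None,
    ) -> None:
        qm = QualityMetrics(**quality)
        if in_a:
            calls_a.append(VariantObservation(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                total_reads=depth, alt_reads=alt_reads, quality=qm,
                caller="A", sample_id=f"{case_id}_tumor", sample_role="tumor",
            ))
        if in_b:
            b_depth = max(1, depth + int(rng.integers(-5, 6)))
            b_alt = int(np.clip(alt_reads + int(rng.integers(-2, 3)), 0, b_depth))
            b_quality = dict(quality)
            if b_missing_ranksums:
                b_quality["mq_rank_sum"] = None
                b_quality["read_pos_rank_sum"] = None
            calls_b.append(VariantObservation(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                total_reads=b_depth if not in_a else b_depth,
                alt_reads=b_alt if not in_a else b_alt,
                quality=QualityMetrics(**b_quality),
                caller="B", sample_id=f"{case_id}_tumor", sample_role="tumor",
            ))
        if matched and normal_depth is not None:
            normal_calls.append(VariantObservation(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                total_reads=normal_depth, alt_reads=normal_alt,
                quality=qm, caller="A",
                sample_id=f"{case_id}_normal", sample_role="normal",
            ))
        ann_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": annotation["gene"],
            "consequence": annotation["consequence"],
            "AF_1000G": annotation["af_1000g"],
            "AF_ExAC": annotation["af_exac"],
            "AF_gnomAD": annotation["af_gnomad"],
            "CADD_phred": annotation["cadd_phred"],
            "cancer_gene_flag": annotation["is_cancer_gene"],
        })
        # the harmonized record carries A's counts when A saw the variant,
        # and the secondary caller's otherwise
        if in_a:
            h_depth, h_alt, h_quality = depth, alt_reads, quality
        else:
            h_depth, h_alt = calls_b[-1].total_reads, calls_b[-1].alt_reads
            h_quality = b_quality
        truth_rows.append({
            "case_id": case_id, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt,
            "truth_class": truth_class, "truth_clonality": truth_clonality,
            "expected_surviving": oracle_survives(
                total_reads=h_depth, alt_reads=h_alt,
                qual=h_quality["qual"], fs=h_quality["fs"],
                mq=h_quality["mq"], mq_rank_sum=h_quality["mq_rank_sum"],
                qd=h_quality["qd"],
                read_pos_rank_sum=h_quality["read_pos_rank_sum"],
                consequence=annotation["consequence"],
                af_1000g=annotation["af_1000g"],
                af_exac=annotation["af_exac"],
                af_gnomad=annotation["af_gnomad"],
                cadd_phred=annotation["cadd_phred"],
                matched=matched,
                normal_alt_reads=normal_alt if matched else None,
                gene=annotation["gene"],
                is_cancer_gene=annotation["is_cancer_gene"],
                matched_somatic_genes=rescue_genes,
            ),
        })

    # --- somatic events --------------------------------------------------
    burden_mean = (
        config.somatic_high_mean
        if rng.random() < config.high_burden_fraction
        else config.somatic_low_mean
    )
    n_somatic = int(rng.poisson(burden_mean))
    for _ in range(n_somatic):
        is_major = rng.random() < 0.6
        vaf = (
            config.major_clone_vaf
            if is_major
            else float(rng.uniform(*config.minor_clone_vaf_range))
        )
        clonality = "major" if is_major else "minor"
        depth = max(1, int(rng.poisson(config.mean_depth)))
        alt_reads = int(rng.binomial(depth, vaf))
        quality = _clean_quality(rng)
        annotation = {
            "gene": str(rng.choice(SOMATIC_GENE_POOL)),
            "consequence": _pick_consequence(rng),
            "af_1000g": 0.0,
            "af_exac": round(float(rng.uniform(0, 5e-4)), 6)
            if rng.random() < 0.3 else 0.0,
            "af_gnomad": 0.0,
            "cadd_phred": round(float(rng.uniform(15, 40)), 2),
        }
        annotation["is_cancer_gene"] = annotation["gene"] in CANCER_GENES
        u = rng.random()
        if u < config.mnp_fraction:
            # two adjacent SNVs; caller A reports them separately, caller B
            # merges them into one MNP record
            chrom, pos = sites.take(adjacent=True)
            refs = [str(rng.choice(list(BASES))) for _ in range(2)]
            alts = [_alt_base(rng, r) for r in refs]
            for off in range(2):
                emit(
                    chrom=chrom, pos=pos + off, ref=refs[off], alt=alts[off],
                    depth=depth, alt_reads=alt_reads, quality=quality,
                    annotation=annotation, truth_class="somatic",
                    truth_clonality=clonality, in_a=True, in_b=False,
                )
            calls_b.append(VariantObservation(
                chrom=chrom, pos=pos, ref="".join(refs), alt="".join(alts),
                total_reads=depth, alt_reads=alt_reads,
                quality=QualityMetrics(**{**quality, "mq_rank_sum": None,
                                          "read_pos_rank_sum": None}),
                caller="B", sample_id=f"{case_id}_tumor", sample_role="tumor",
            ))
        elif u < config.mnp_fraction + config.caller_b_only_fraction:
            chrom, pos = sites.take()
            ref = str(rng.choice(list(BASES)))
            emit(
                chrom=chrom, pos=pos, ref=ref, alt=_alt_base(rng, ref),
                depth=depth, alt_reads=alt_reads, quality=quality,
                annotation=annotation, truth_class="somatic",
                truth_clonality=clonality, in_a=False, in_b=True,
                b_missing_ranksums=True,
            )
        else:
            chrom, pos = sites.take()
            ref = str(rng.choice(list(BASES)))
            emit(
                chrom=chrom, pos=pos, ref=ref, alt=_alt_base(rng, ref),
                depth=depth, alt_reads=alt_reads, quality=quality,
                annotation=annotation, truth_class="somatic",
                truth_clonality=clonality, in_a=True, in_b=True,
            )

    # --- germline events -------------------------------------------------
    for _ in range(config.germline_per_case):
        vaf = 1.0 if rng.random() < 0.1 else 0.5
        depth = max(1, int(rng.poisson(config.mean_depth)))
        alt_reads = int(rng.binomial(depth, vaf))
        normal_depth = max(8, int(rng.poisson(config.mean_depth)))
        normal_alt = int(np.clip(rng.binomial(normal_depth, vaf), 4,
                                 normal_depth))
        common = rng.random() < 0.7
        annotation = {
            "gene": str(rng.choice(GERMLINE_GENE_POOL)),
            "consequence": "synonymous" if rng.random() < 0.25 else "missense",
            "af_1000g": round(float(rng.uniform(0, 0.3)), 4) if common else 0.0,
            "af_exac": 0.0,
            "af_gnomad": round(float(rng.uniform(0.001, 0.5)), 4)
            if common else 0.0,
            "cadd_phred": round(float(rng.uniform(0, 40)), 2)
            if common else round(float(rng.uniform(15, 40)), 2),
            "is_cancer_gene": False,
        }
        chrom, pos = sites.take()
        ref = str(rng.choice(list(BASES)))
        emit(
            chrom=chrom, pos=pos, ref=ref, alt=_alt_base(rng, ref),
            depth=depth, alt_reads=alt_reads, quality=_clean_quality(rng),
            annotation=annotation, truth_class="germline",
            truth_clonality="not_applicable", in_a=True, in_b=True,
            normal_depth=normal_depth, normal_alt=normal_alt,
        )

    # --- artifacts -------------------------------------------------------
    for _ in range(config.artifact_per_case):
        vaf = float(rng.uniform(0.05, 0.40))
        depth = max(1, int(rng.poisson(config.mean_depth)))
        alt_reads = int(rng.binomial(depth, vaf))
        quality = _clean_quality(rng)
        n_viol = 1 + int(rng.random() < 0.3)
        for metric in rng.choice(list(_VIOLATIONS), size=n_viol, replace=False):
            quality[str(metric)] = _VIOLATIONS[str(metric)](rng)
        annotation = {
            "gene": str(rng.choice(ARTIFACT_GENE_POOL)),
            "consequence": "missense",
            "af_1000g": 0.0, "af_exac": 0.0, "af_gnomad": 0.0,
            "cadd_phred": round(float(rng.uniform(15, 40)), 2),
            "is_cancer_gene": False,
        }
        chrom, pos = sites.take()
        ref = str(rng.choice(list(BASES)))
        emit(
            chrom=chrom, pos=pos, ref=ref, alt=_alt_base(rng, ref),
            depth=depth, alt_reads=alt_reads, quality=quality,
            annotation=annotation, truth_class="artifact",
            truth_clonality="not_applicable", in_a=True, in_b=False,
        )

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).sort_values(
        ["chrom", "pos", "ref", "alt"], ignore_index=True
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).sort_values(
        ["chrom", "pos", "ref", "alt"], ignore_index=True
    )
    return CaseBundle(
        case_id=case_id,
        matched=matched,
        calls_a=calls_a,
        calls_b=calls_b,
        normal_calls=normal_calls if matched else None,
        annotations=annotations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def build_targets(config: CohortSimConfig) -> pd.DataFrame:
    rows = []
    for chrom, n in targets_per_chrom(config.n_targets).items():
        for i in range(n):
            start = i * config.target_spacing
            rows.append(
                {"chrom": chrom, "start": start,
                 "end": start + config.target_length}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_coverage(
    config: CohortSimConfig,
    case_id: str,
    segments: Optional[tuple] = None,
) -> tuple[TargetCoverageProfile, TargetCoverageProfile]:
    """Per-target tumor and normal depths; Poisson around ``mean_depth``,
    tumor scaled by copy_number/2 inside injected segments."""
    config.validate()
    if segments is None:
        segments = config.cna_segments
    else:
        replace(config, cna_segments=tuple(segments))  # validates
    rng = _case_rng(config, case_id, 7)
    targets = build_targets(config)
    normal_depth = rng.poisson(config.mean_depth, size=len(targets))
    tumor_mean = np.full(len(targets), config.mean_depth)
    chrom_local_idx = targets.groupby("chrom", sort=False).cumcount().to_numpy()
    for chrom, i0, i1, cn in segments:
        mask = (targets["chrom"] == chrom).to_numpy() & (
            (chrom_local_idx >= i0) & (chrom_local_idx <= i1)
        )
        tumor_mean[mask] = config.mean_depth * cn / 2.0
    tumor_depth = rng.poisson(tumor_mean)
    t = targets.copy()
    t["depth"] = tumor_depth
    n = targets.copy()
    n["depth"] = normal_depth
    return (
        TargetCoverageProfile(targets=t, sample_id=f"{case_id}_tumor",
                              role="tumor"),
        TargetCoverageProfile(targets=n, sample_id=f"{case_id}_normal",
                              role="normal"),
    )


# ---------------------------------------------------------------------------
# cohort assembly and serialization
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    config: CohortSimConfig
    cases: list[CaseBundle]
    matched_somatic_genes: frozenset


def simulate_cohort(config: CohortSimConfig) -> CohortBundle:
    """Matched cases first; their surviving somatic gene set feeds the
    unmatched cases' rescue-rule truth."""
    cases: list[CaseBundle] = []
    matched_genes: set[str] = set()
    for i in range(config.n_matched_cases):
        bundle = simulate_case(config, f"M{i + 1:02d}", matched=True)
        cases.append(bundle)
        surv = bundle.truth[
            bundle.truth["expected_surviving"]
            & (bundle.truth["truth_class"] == "somatic")
        ]
        keys = set(zip(surv["chrom"], surv["pos"], surv["ref"], surv["alt"]))
        ann = bundle.annotations
        for row in ann.itertuples(index=False):
            if (row.chrom, row.pos, row.ref, row.alt) in keys and row.gene:
                matched_genes.add(str(row.gene))
    for i in range(config.n_unmatched_cases):
        cases.append(
            simulate_case(
                config, f"U{i + 1:02d}", matched=False,
                matched_somatic_genes=matched_genes,
            )
        )
    return CohortBundle(
        config=config, cases=cases, matched_somatic_genes=frozenset(matched_genes)
    )


def write_case(bundle: CaseBundle, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = bundle.case_id
    paths = {
        "case_id": cid,
        "matched": bundle.matched,
        "vcf_a": str(outdir / f"{cid}_tumor_callerA.vcf"),
        "vcf_b": str(outdir / f"{cid}_tumor_callerB.vcf"),
        "annotations": str(outdir / f"{cid}_annotations.tsv"),
        "truth": str(outdir / f"{cid}_truth.tsv"),
    }
    write_caller_vcf(paths["vcf_a"], bundle.calls_a)
    write_caller_vcf(paths["vcf_b"], bundle.calls_b)
    if bundle.matched:
        paths["vcf_normal"] = str(outdir / f"{cid}_normal.vcf")
        write_caller_vcf(paths["vcf_normal"], bundle.normal_calls)
    write_annotation_table(paths["annotations"], bundle.annotations)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False,
                        lineterminator="\n")
    return paths


def write_cohort(config: CohortSimConfig, outdir: str | Path) -> Path:
    """Simulate and serialize a full cohort; returns the manifest path.

    The manifest (JSON) lists per-case file paths and is the input contract
    of the pipeline orchestrator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    manifest: dict = {"config": asdict(config), "cases": []}
    for bundle in cohort.cases:
        entry = write_case(bundle, outdir)
        if config.n_targets > 0:
            tumor_cov, normal_cov = simulate_coverage(config, bundle.case_id)
            entry["tumor_coverage"] = str(
                outdir / f"{bundle.case_id}_tumor_cov.tsv")
            entry["normal_coverage"] = str(
                outdir / f"{bundle.case_id}_normal_cov.tsv")
            tumor_cov.write(entry["tumor_coverage"])
            normal_cov.write(entry["normal_coverage"])
        manifest["cases"].append(entry)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest_path
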