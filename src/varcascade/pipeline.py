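"""End-to-end orchestration: harmonize, annotate, filter, classify, call
CNAs and summarize a cohort of cases.

Matched cases are always processed before unmatched ones, whatever the
manifest order: the unmatched gene-rescue filter needs the somatic gene set
of the fully filtered matched cohort.  The pipeline itself is free of
randomness — rerunning on identical inputs yields byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .clonality import classify_clonality
from .cna import (
    CNASegment,
    TargetCoverageProfile,
    compute_log_ratios,
    segment_and_call,
    summarize_cna,
    write_segments,
)
from .filtering import (
    DEFAULT_THRESHOLDS,
    CascadeResult,
    FilterThresholds,
    run_cascade,
    thresholds_to_dict,
)
from .harmonize import harmonize_sample, write_quarantine_table
from .records import VariantObservation, genomic_sort_key
from .summary import (
    CaseSummary,
    cohort_burden,
    coverage_qc,
    recurrent_genes,
    summarize_case,
)
from .vcfio import (
    join_annotations,
    read_annotation_table,
    read_caller_vcf,
    write_variant_table,
)

logger = logging.getLogger(__name__)


@dataclass
class CaseInput:
    case_id: str
    matched: bool
    vcf_a: str
    vcf_b: str
    vcf_normal: Optional[str] = None
    annotations: Optional[str] = None
    tumor_coverage: Optional[str] = None
    normal_coverage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.matched and self.vcf_normal is None:
            raise ValueError(
                f"case {self.case_id} is marked matched but has no normal VCF"
            )


@dataclass
class CaseResult:
    case_id: str
    matched: bool
    variants: list[VariantObservation]          # harmonized + annotated
    cascade: CascadeResult
    retained: list[VariantObservation]
    clonality: dict                              # key -> "major"|"minor"
    segments: list[CNASegment]
    quarantined: list[VariantObservation]
    qc: Optional[object] = None
    summary: Optional[CaseSummary] = None


def load_manifest(path: str | Path) -> list[CaseInput]:
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    fields = (
        "case_id", "matched", "vcf_a", "vcf_b", "vcf_normal",
        "annotations", "tumor_coverage", "normal_coverage",
    )
    return [
        CaseInput(**{k: entry.get(k) for k in fields})
        for entry in manifest["cases"]
    ]


def process_case(
    case: CaseInput,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    matched_somatic_genes: frozenset = frozenset(),
) -> CaseResult:
    calls_a = read_caller_vcf(case.vcf_a, "A", case.case_id, "tumor")
    calls_b = read_caller_vcf(case.vcf_b, "B", case.case_id, "tumor")
    variants, quarantined = harmonize_sample(calls_a, calls_b)
    if case.annotations:
        table = read_annotation_table(case.annotations)
        variants, n_missing = join_annotations(variants, table)
        if n_missing:
            logger.warning("%s: %d variants lacked annotation rows",
                           case.case_id, n_missing)
    normal_calls = (
        read_caller_vcf(case.vcf_normal, "A", case.case_id, "normal")
        if case.matched
        else None
    )
    cascade = run_cascade(
        variants,
        thresholds=thresholds,
        mode="matched" if case.matched else "unmatched",
        normal_calls=normal_calls,
        matched_somatic_genes=matched_somatic_genes,
    )
    retained_keys = cascade.retained_keys
    retained = [v for v in variants if v.key in retained_keys]
    labels = classify_clonality(retained) if retained else []
    clonality = {l.variant_key: l.label for l in labels}
    segments: list[CNASegment] = []
    qc = None
    if case.tumor_coverage and case.normal_coverage:
        tumor = TargetCoverageProfile.read(
            case.tumor_coverage, f"{case.case_id}_tumor", "tumor"
        )
        normal = TargetCoverageProfile.read(
            case.normal_coverage, f"{case.case_id}_normal", "normal"
        )
        qc = coverage_qc(tumor)
        if not qc.excluded:
            segments = segment_and_call(compute_log_ratios(tumor, normal))
    result = CaseResult(
        case_id=case.case_id, matched=case.matched, variants=variants,
        cascade=cascade, retained=retained, clonality=clonality,
        segments=segments, quarantined=quarantined, qc=qc,
    )
    result.summary = summarize_case(
        case.case_id, case.matched, retained, labels, segments
    )
    return result


def run_pipeline(
    cases: Sequence[CaseInput],
    outdir: str | Path,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Run every case through the full cascade and write the report bundle.

    Returns the cohort summary dict (also written as JSON).  Errors if
    unmatched cases are present but there is no matched case to anchor the
    gene-rescue filter — cancer-gene flags alone are accepted only when the
    annotation tables actually carry them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matched_cases = sorted(
        (c for c in cases if c.matched), key=lambda c: c.case_id
    )
    unmatched_cases = sorted(
        (c for c in cases if not c.matched), key=lambda c: c.case_id
    )
    if unmatched_cases and not matched_cases:
        if not any(c.annotations for c in unmatched_cases):
            raise ValueError(
                "unmatched cases without any matched case or cancer-gene "
                "annotations: the gene-rescue filter is undefined"
            )

    results: list[CaseResult] = []
    matched_genes: set[str] = set()
    for case in matched_cases:
        res = process_case(case, thresholds)
        results.append(res)
        matched_genes |= {
            v.annotation.gene for v in res.retained if v.annotation.gene
        }
    for case in unmatched_cases:
        results.append(
            process_case(case, thresholds, frozenset(matched_genes))
        )

    for res in results:
        _write_case_outputs(res, outdir)

    summaries = [r.summary for r in results]
    cna_summary = summarize_cna({r.case_id: r.segments for r in results
                                 if r.qc is not None})
    qc_rows = [
        {
            "case_id": r.qc.case_id,
            "mean_target_coverage": round(r.qc.mean_target_coverage, 2),
            "median_target_coverage": round(r.qc.median_target_coverage, 2),
            "fraction_above_50x": round(r.qc.fraction_above_50x, 4),
            "excluded": r.qc.excluded,
        }
        for r in results if r.qc is not None
    ]
    rec = recurrent_genes(summaries)
    rec.to_csv(outdir / "recurrent_genes.tsv", sep="\t", index=False,
               lineterminator="\n")

    report = {
        "tool_version": __version__,
        "thresholds": thresholds_to_dict(thresholds),
        "n_cases": len(results),
        "coverage_qc": qc_rows,
        "burden": {
            subset: _burden_dict(cohort_burden(summaries, subset))
            for subset in ("matched", "unmatched", "all")
        },
        "recurrent_genes": rec[rec["recurrent"]][["gene", "n_cases"]]
        .to_dict(orient="records"),
        "cna": {
            "per_case_counts": dict(sorted(
                cna_summary.per_case_counts.items())),
            "median_per_affected_case": cna_summary.median_per_affected_case,
            "count_range": list(cna_summary.count_range)
            if cna_summary.count_range else None,
            "n_cases_with_cna": cna_summary.n_cases_with_cna,
            "total_segments": cna_summary.total_segments,
        },
        "exclusion_tally": {
            r.case_id: dict(sorted(r.cascade.tally.items())) for r in results
        },
    }
    with open(outdir / "cohort_summary.json", "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_log.txt", "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write(f"varcascade {__version__}\n")
        fh.write("thresholds: "
                 + json.dumps(thresholds_to_dict(thresholds), sort_keys=True)
                 + "\n")
        for r in sorted(results, key=lambda r: r.case_id):
            fh.write(
                f"{r.case_id}\tmode={'matched' if r.matched else 'unmatched'}"
                f"\tvariants={len(r.variants)}\tretained={len(r.retained)}"
                f"\tquarantined={len(r.quarantined)}\tcna={len(r.segments)}\n"
            )
    return report


def _burden_dict(b) -> dict:
    return {
        "n_cases": b.n_cases,
        "total_variants": b.total_variants,
        "distinct_genes": b.distinct_genes,
        "median_per_case": b.median_per_case,
        "count_range": list(b.count_range) if b.count_range else None,
        "consequence_counts": dict(sorted(b.consequence_counts.items())),
        "consequence_percentages": dict(
            sorted(b.consequence_percentages.items())),
    }


def _write_case_outputs(res: CaseResult, outdir: Path) -> None:
    verdicts = {w.variant_key: w for w in res.cascade.verdicts}
    rows = []
    for v in sorted(res.variants, key=genomic_sort_key):
        verdict = verdicts[v.key]
        rows.append({
            "case": res.case_id,
            "gene": v.annotation.gene or "",
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "total_reads": v.total_reads, "alt_reads": v.alt_reads,
            "vaf": round(v.vaf, 6),
            "consequence": v.annotation.consequence or "",
            "clonality": res.clonality.get(v.key, ""),
            "filter_reasons": ";".join(sorted(verdict.reasons)),
        })
    write_variant_table(str(outdir / f"{res.case_id}_variants.tsv"), rows)
    if res.quarantined:
        write_quarantine_table(
            str(outdir / f"{res.case_id}_quarantine.tsv"), res.quarantined
        )
    if res.qc is not None:
        write_segments(str(outdir / f"{res.case_id}_segments.tsv"),
                       res.segments)
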