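"""VCF and table I/O.

Caller VCFs are read with cyvcf2; multi-allelic sites are split into one
observation per ALT allele before anything else looks at them.  Output
tables are plain TSV (UTF-8, LF) so they can be diffed and loaded anywhere.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .records import (
    EMPTY_ANNOTATION,
    AnnotationBundle,
    QualityMetrics,
    VariantKey,
    VariantObservation,
    genomic_sort_key,
)

logger = logging.getLogger(__name__)

_INFO_METRICS = {
    "fs": "FS",
    "mq": "MQ",
    "mq_rank_sum": "MQRankSum",
    "qd": "QD",
    "read_pos_rank_sum": "ReadPosRankSum",
}

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "AF_1000G", "AF_ExAC", "AF_gnomAD", "CADD_phred", "cancer_gene_flag",
]


class VcfFieldError(IOError):
    """A required depth/allele-depth field is missing from the VCF."""


def read_caller_vcf(
    path: str,
    caller_label: str,
    sample_id: str,
    sample_role: str = "tumor",
) -> list[VariantObservation]:
    """Read one caller's VCF into normalized per-ALT observations.

    Requires per-sample AD (allele depths); site depth comes from FORMAT DP
    when present, else INFO DP, else the sum of AD.  Quality metrics that the
    caller did not emit are recorded as absent, not zero.
    """
    out: list[VariantObservation] = []
    vcf = VCF(path)
    try:
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise VcfFieldError(
                    f"allele depth unavailable (no AD field) at "
                    f"{rec.CHROM}:{rec.POS} in {path}"
                )
            ad = np.asarray(ad[0])
            dp = _site_depth(rec, ad)
            qm_info = {
                attr: _info_float(rec, tag) for attr, tag in _INFO_METRICS.items()
            }
            quality = QualityMetrics(qual=rec.QUAL, **qm_info)
            for i, alt in enumerate(rec.ALT):
                alt_reads = int(ad[i + 1]) if i + 1 < len(ad) else 0
                out.append(
                    VariantObservation(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        total_reads=dp,
                        alt_reads=min(alt_reads, dp),
                        quality=quality,
                        caller=caller_label,
                        sample_id=sample_id,
                        sample_role=sample_role,
                    )
                )
    finally:
        vcf.close()
    return out


def _site_depth(rec, ad: np.ndarray) -> int:
    dp = rec.format("DP")
    if dp is not None and int(dp[0][0]) >= 0:
        return int(dp[0][0])
    info_dp = rec.INFO.get("DP")
    if info_dp is not None:
        return int(info_dp)
    return int(ad[ad > 0].sum())


def _info_float(rec, tag: str) -> Optional[float]:
    v = rec.INFO.get(tag)
    return float(v) if v is not None else None


def write_caller_vcf(path: str, observations: Iterable[VariantObservation]) -> None:
    """Write observations as a minimal single-sample VCF 4.2 text file.

    Used by the simulator and for round-tripping filtered call sets; records
    are emitted in genomic order so identical inputs give identical bytes.
    """
    obs = sorted(observations, key=genomic_sort_key)
    sample = obs[0].sample_id if obs else "SAMPLE"
    chroms = sorted({o.chrom for o in obs}, key=lambda c: (len(c), c))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for o in obs:
        q = o.quality
        info = [f"DP={o.total_reads}"]
        for attr, tag in _INFO_METRICS.items():
            val = getattr(q, attr)
            if val is not None:
                info.append(f"{tag}={_fmt(val)}")
        qual = _fmt(q.qual) if q.qual is not None else "."
        ref_reads = o.total_reads - o.alt_reads
        lines.append(
            "\t".join(
                [
                    o.chrom, str(o.pos), ".", o.ref, o.alt, qual, ".",
                    ";".join(info), "GT:AD:DP",
                    f"0/1:{ref_reads},{o.alt_reads}:{o.total_reads}",
                ]
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"annotation table {path} lacks columns: {missing}")
    return df


def write_annotation_table(path: str, df: pd.DataFrame) -> None:
    df = df[ANNOTATION_COLUMNS].sort_values(["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def annotation_lookup(table: pd.DataFrame) -> dict[VariantKey, AnnotationBundle]:
    """Index the annotation table by variant key.

    Duplicate keys are tolerated only when every annotated field agrees;
    conflicting duplicates are an input error, not something to arbitrate.
    """
    lookup: dict[VariantKey, AnnotationBundle] = {}
    for row in table.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        bundle = AnnotationBundle(
            gene=_none_if_na(row.gene),
            consequence=_none_if_na(row.consequence),
            af_1000g=_float_or_none(row.AF_1000G),
            af_exac=_float_or_none(row.AF_ExAC),
            af_gnomad=_float_or_none(row.AF_gnomAD),
            cadd_phred=_float_or_none(row.CADD_phred),
            is_cancer_gene=bool(row.cancer_gene_flag),
        )
        if key in lookup and lookup[key] != bundle:
            raise ValueError(f"conflicting duplicate annotation rows for {key}")
        lookup[key] = bundle
    return lookup


def join_annotations(
    observations: list[VariantObservation],
    table: pd.DataFrame,
) -> tuple[list[VariantObservation], int]:
    """Attach annotation bundles by (chrom, pos, ref, alt).

    Returns the annotated list and the number of observations with no row in
    the table; those carry an empty bundle and a logged warning.
    """
    lookup = annotation_lookup(table)
    annotated: list[VariantObservation] = []
    n_missing = 0
    for obs in observations:
        bundle = lookup.get(obs.key)
        if bundle is None:
            n_missing += 1
            logger.warning("no annotation for variant %s:%d %s>%s",
                           *obs.key)
            bundle = EMPTY_ANNOTATION
        annotated.append(obs.with_annotation(bundle))
    return annotated, n_missing


def _none_if_na(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)


def _float_or_none(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


# ---------------------------------------------------------------------------
# variant tables (MAF-like output)
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = [
    "case", "gene", "chrom", "pos", "ref", "alt", "total_reads", "alt_reads",
    "vaf", "consequence", "clonality", "filter_reasons",
]


def write_variant_table(path: str, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")
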