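"""Cohort summarization: coverage QC, per-case burden, consequence
breakdown, recurrence.

Percentages are rounded to the nearest integer with ties rounding up,
which is the convention the consequence-breakdown arithmetic follows
(e.g. 113/163 -> 69%, 19/163 -> 12%, 50/59 -> 85%, 1/59 -> 2%).
Recurrence is counted at case level: a gene mutated twice in one case is
not recurrent; a gene mutated once in each of two cases is.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clonality import ClonalityLabel
from .cna import CNASegment, TargetCoverageProfile
from .records import VariantObservation

#: mean-coverage floor below which a sample is dropped from analysis
MIN_MEAN_COVERAGE = 20
#: depth bar for the "fraction of target above Nx" QC statistic
QC_DEPTH_CUTOFF = 50


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CoverageQC:
    case_id: str
    mean_target_coverage: float
    median_target_coverage: float
    fraction_above_50x: float
    excluded: bool


def coverage_qc(
    profile: TargetCoverageProfile,
    min_mean_coverage: float = MIN_MEAN_COVERAGE,
    depth_cutoff: float = QC_DEPTH_CUTOFF,
) -> CoverageQC:
    """Length-weighted coverage statistics for one sample.

    A sample whose mean target coverage falls below ``min_mean_coverage``
    is flagged excluded — coverage that thin cannot support somatic calling
    at the read-support thresholds the cascade uses.
    """
    df = profile.targets
    if df.empty:
        raise ValueError(f"empty coverage profile for {profile.sample_id}")
    lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
    depths = df["depth"].to_numpy(dtype=float)
    total = lengths.sum()
    mean = float((lengths * depths).sum() / total)
    median = _weighted_median(depths, lengths)
    frac = float(lengths[depths > depth_cutoff].sum() / total)
    return CoverageQC(
        case_id=profile.sample_id,
        mean_target_coverage=mean,
        median_target_coverage=median,
        fraction_above_50x=frac,
        excluded=mean < min_mean_coverage,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if cum[idx] == half and idx + 1 < len(v):
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


# ---------------------------------------------------------------------------
# per-case and cohort burden
# ---------------------------------------------------------------------------

@dataclass
class CaseSummary:
    case_id: str
    matched: bool
    n_variants: int
    n_major: int
    n_minor: int
    consequence_counts: dict[str, int] = field(default_factory=dict)
    mutated_genes: frozenset = frozenset()
    n_cna: int = 0

    def __post_init__(self) -> None:
        self.mutated_genes = frozenset(self.mutated_genes)
        assert self.n_variants == self.n_major + self.n_minor
        assert self.n_variants == sum(self.consequence_counts.values())


def summarize_case(
    case_id: str,
    matched: bool,
    retained_variants: Sequence[VariantObservation],
    clonality_labels: Sequence[ClonalityLabel],
    cna_segments: Sequence[CNASegment] = (),
) -> CaseSummary:
    """Tally one case's retained, classified variants and CNA segments.

    Variants lacking a consequence annotation count under "other"; variants
    lacking a gene symbol contribute no gene to the mutated-gene set.
    """
    labels = {l.variant_key: l.label for l in clonality_labels}
    cons = Counter(
        v.annotation.consequence if v.annotation.consequence else "other"
        for v in retained_variants
    )
    n_major = sum(1 for v in retained_variants if labels.get(v.key) == "major")
    genes = frozenset(
        v.annotation.gene for v in retained_variants if v.annotation.gene
    )
    return CaseSummary(
        case_id=case_id,
        matched=matched,
        n_variants=len(retained_variants),
        n_major=n_major,
        n_minor=len(retained_variants) - n_major,
        consequence_counts=dict(cons),
        mutated_genes=genes,
        n_cna=len(cna_segments),
    )


@dataclass
class BurdenSummary:
    subset: str
    n_cases: int
    total_variants: int
    distinct_genes: int
    median_per_case: Optional[float]
    count_range: Optional[tuple[int, int]]
    consequence_counts: dict[str, int]
    consequence_percentages: dict[str, int]


def cohort_burden(
    case_summaries: Sequence[CaseSummary], subset: str = "all"
) -> BurdenSummary:
    """Aggregate per-case summaries over a subset (matched/unmatched/all).

    Total variants is the sum of per-case counts; distinct genes is the size
    of the union of per-case gene sets (so shared genes are counted once);
    percentages per consequence class are count / subset total x 100,
    rounded half-up.
    """
    if subset not in ("matched", "unmatched", "all"):
        raise ValueError(f"unknown subset: {subset!r}")
    selected = [
        s for s in case_summaries
        if subset == "all" or s.matched == (subset == "matched")
    ]
    counts = sorted(s.n_variants for s in selected)
    total = sum(counts)
    cons: Counter = Counter()
    genes: set = set()
    for s in selected:
        cons.update(s.consequence_counts)
        genes |= s.mutated_genes
    percentages = {
        c: round_half_up(100.0 * n / total) for c, n in sorted(cons.items())
    } if total else {}
    return BurdenSummary(
        subset=subset,
        n_cases=len(selected),
        total_variants=total,
        distinct_genes=len(genes),
        median_per_case=float(np.median(counts)) if counts else None,
        count_range=(counts[0], counts[-1]) if counts else None,
        consequence_counts=dict(cons),
        consequence_percentages=percentages,
    )


def recurrent_genes(case_summaries: Sequence[CaseSummary]) -> pd.DataFrame:
    """Genes by the number of cases in which they are mutated.

    Sorted by case count descending, then gene name; the ``recurrent``
    column marks genes hit in more than one case (per-case presence, not
    per-variant count).
    """
    counter: Counter = Counter()
    for s in case_summaries:
        counter.update(s.mutated_genes)
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "n_cases"])
    df["recurrent"] = df["n_cases"] > 1
    return df
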