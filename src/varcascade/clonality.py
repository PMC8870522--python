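"""Major/minor clonal classification of retained variants.

Within one tumor sample, the variant with the highest VAF anchors a
reference; every variant whose VAF is at least 50% of that reference is
called a major clonal variant (present in the majority of tumor cells),
the rest minor clonal (present in a subset).  When the top-VAF variant
rests on fewer than 25 reads its VAF is too noisy to anchor the cutoff
alone, so the reference becomes the mean of the two highest VAFs.

Classification runs after all filtering; only retained variants are labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import VariantKey, VariantObservation, genomic_sort_key

#: Below this read depth on the top-VAF variant, the two-variant mean is used.
LOW_DEPTH_FALLBACK = 25


@dataclass(frozen=True)
class ClonalityLabel:
    variant_key: VariantKey
    label: str                # "major" | "minor"
    reference_vaf: float      # per-sample reference the 50% is taken from
    cutoff: float             # 0.5 * reference_vaf


def classify_clonality(
    variants: Sequence[VariantObservation],
    depth_fallback: int = LOW_DEPTH_FALLBACK,
) -> list[ClonalityLabel]:
    """Label each retained variant of one sample as major or minor clonal.

    Ties at the top VAF are broken by genomic order; the depth fallback
    looks at the depth of that specific top variant.  A single-variant
    sample is its own reference and is labeled major.  Labels come back in
    input order.
    """
    if not variants:
        raise ValueError("no retained variants to classify")
    ranked = sorted(variants, key=lambda v: (-v.vaf,) + tuple(genomic_sort_key(v)))
    top = ranked[0]
    if top.total_reads < depth_fallback and len(ranked) >= 2:
        reference_vaf = (ranked[0].vaf + ranked[1].vaf) / 2.0
    else:
        reference_vaf = top.vaf
    cutoff = 0.5 * reference_vaf
    return [
        ClonalityLabel(
            variant_key=v.key,
            label="major" if v.vaf >= cutoff else "minor",
            reference_vaf=reference_vaf,
            cutoff=cutoff,
        )
        for v in variants
    ]
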