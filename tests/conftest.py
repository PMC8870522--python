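import pytest

from varcascade.records import AnnotationBundle, QualityMetrics, VariantObservation


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    total=100,
    alt_reads=30,
    sample_id="case1_tumor",
    caller="A",
    role="tumor",
    quality=None,
    annotation=None,
    **quality_kwargs,
):
    """Build a variant observation with clean defaults; quality metric
    overrides can be passed as keyword arguments (qual=, fs=, ...)."""
    if quality is None:
        base = dict(qual=500.0, fs=2.0, mq=60.0, mq_rank_sum=0.5,
                    qd=20.0, read_pos_rank_sum=0.5)
        base.update(quality_kwargs)
        quality = QualityMetrics(**base)
    if annotation is None:
        annotation = AnnotationBundle(
            gene="SOM001", consequence="missense",
            af_1000g=0.0, af_exac=0.0, af_gnomad=0.0, cadd_phred=25.0,
        )
    return VariantObservation(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        total_reads=total, alt_reads=alt_reads,
        quality=quality, caller=caller, sample_id=sample_id,
        sample_role=role, annotation=annotation,
    )


@pytest.fixture
def mkvar():
    return make_variant
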