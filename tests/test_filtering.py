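"""Exclusion-cascade semantics: boundary directions, missing-metric
behaviour, germline subtraction, rescue, order-invariance, monotonicity."""

import dataclasses
import random

import pytest

from varcascade import filtering as flt
from varcascade.filtering import (
    FilterThresholds,
    apply_consequence_and_population_filters,
    apply_pathogenicity_filter,
    apply_quality_filters,
    apply_read_support_filter,
    rescue_filter_unmatched,
    run_cascade,
    subtract_germline,
)
from varcascade.records import AnnotationBundle, QualityMetrics
from varcascade.synthetic import CohortSimConfig, simulate_case


def ann(**kw):
    base = dict(gene="SOM001", consequence="missense", af_1000g=0.0,
                af_exac=0.0, af_gnomad=0.0, cadd_phred=25.0)
    base.update(kw)
    return AnnotationBundle(**base)


# --- quality criteria ------------------------------------------------------

def test_qual_below_threshold_excludes(mkvar):
    assert apply_quality_filters(mkvar(qual=19.0)) == {flt.QUAL_LOW}


def test_all_printed_boundaries_pass_because_inequalities_are_strict(mkvar):
    # vaf = 0.25, so qd = 2.0 puts both the QD and the QD/AF clause
    # (2.0 / 0.25 = 8.0) exactly at their boundaries
    v = mkvar(total=100, alt_reads=25, qual=20.0, fs=60.0, mq=40.0,
              mq_rank_sum=-12.5, qd=2.0, read_pos_rank_sum=-20.0)
    assert apply_quality_filters(v) == set()


def test_qd_af_ratio_below_eight_excludes(mkvar):
    v = mkvar(total=100, alt_reads=50, qd=3.9)  # 3.9 / 0.5 = 7.8 < 8
    assert flt.QD_AF_LOW in apply_quality_filters(v)


def test_qd_af_rule_can_be_disabled(mkvar):
    v = mkvar(total=100, alt_reads=50, qd=3.9)
    th = FilterThresholds(qd_af_rule="off")
    assert flt.QD_AF_LOW not in apply_quality_filters(v, th)


def test_absent_metrics_never_exclude(mkvar):
    v = mkvar(quality=QualityMetrics())
    assert apply_quality_filters(v) == set()


# --- population / consequence ---------------------------------------------

@pytest.mark.parametrize(
    "bundle_kw, expected",
    [
        (dict(consequence="synonymous"), {flt.SYNONYMOUS}),
        (dict(af_1000g=0.02), set()),                 # ">2%" is strict
        (dict(af_1000g=0.021), {flt.POP_1000G}),
        (dict(af_exac=0.0009), set()),                # ">=0.1%" inclusive
        (dict(af_exac=0.001), {flt.POP_EXAC_GNOMAD}),
        (dict(af_gnomad=0.001), {flt.POP_EXAC_GNOMAD}),
        (dict(af_1000g=None, af_exac=None, af_gnomad=None), set()),
    ],
)
def test_population_and_consequence_boundaries(mkvar, bundle_kw, expected):
    v = mkvar(annotation=ann(**bundle_kw))
    assert apply_consequence_and_population_filters(v) == expected


# --- read support ----------------------------------------------------------

@pytest.mark.parametrize(
    "total, alt, expected",
    [
        (19, 10, {flt.DEPTH_LOW}),
        (20, 4, set()),                               # boundary passes
        (19, 3, {flt.DEPTH_LOW, flt.ALT_SUPPORT_LOW}),  # reasons accumulate
        (100, 3, {flt.ALT_SUPPORT_LOW}),
    ],
)
def test_read_support_boundaries(mkvar, total, alt, expected):
    assert apply_read_support_filter(mkvar(total=total, alt_reads=alt)) == expected


# --- germline subtraction ---------------------------------------------------

@pytest.mark.parametrize(
    "blood_alt, expected",
    [(4, {flt.GERMLINE_IN_BLOOD}), (3, set())],  # ">3" strict
)
def test_blood_alt_boundary(mkvar, blood_alt, expected):
    v = mkvar()
    assert subtract_germline(v, {v.key: blood_alt}) == expected


def test_variant_absent_from_blood_is_not_germline(mkvar):
    assert subtract_germline(mkvar(), {}) == set()


# --- pathogenicity ----------------------------------------------------------

@pytest.mark.parametrize(
    "cadd, expected",
    [(14.9, {flt.CADD_LOW}), (15.0, set()), (None, set())],
)
def test_cadd_cutoff_keeps_fifteen(mkvar, cadd, expected):
    v = mkvar(annotation=ann(cadd_phred=cadd))
    assert apply_pathogenicity_filter(v) == expected


# --- unmatched gene rescue ---------------------------------------------------

def test_rescue_by_matched_cohort_gene(mkvar):
    v = mkvar(annotation=ann(gene="SOM042"))
    assert rescue_filter_unmatched(v, {"SOM042"}) == set()


def test_rescue_by_cancer_gene_flag(mkvar):
    v = mkvar(annotation=dataclasses.replace(ann(gene="XYZ"),
                                             is_cancer_gene=True))
    assert rescue_filter_unmatched(v, set()) == set()


def test_no_rescue_excludes(mkvar):
    v = mkvar(annotation=ann(gene="XYZ"))
    assert rescue_filter_unmatched(v, {"SOM042"}) == {flt.NO_GENE_RESCUE}


# --- the cascade -------------------------------------------------------------

def test_matched_mode_without_normal_calls_is_an_error(mkvar):
    with pytest.raises(ValueError, match="normal call set"):
        run_cascade([mkvar()], mode="matched", normal_calls=None)


def test_zero_variants_give_zero_verdicts():
    res = run_cascade([], mode="matched", normal_calls=[])
    assert res.verdicts == [] and not res.tally


def test_every_variant_gets_exactly_one_verdict(mkvar):
    vs = [mkvar(pos=p) for p in range(100, 120)]
    res = run_cascade(vs, mode="matched", normal_calls=[])
    assert len(res.verdicts) == len(vs)
    assert sum(w.retained for w in res.verdicts) + sum(
        not w.retained for w in res.verdicts
    ) == len(vs)


def _fixture_case():
    cfg = CohortSimConfig(germline_per_case=40, artifact_per_case=20,
                          somatic_low_mean=30, high_burden_fraction=0.0,
                          seed=123)
    bundle = simulate_case(cfg, "F01", matched=True)
    from varcascade.harmonize import harmonize_sample
    from varcascade.vcfio import join_annotations
    variants, _ = harmonize_sample(bundle.calls_a, bundle.calls_b)
    variants, _ = join_annotations(variants, bundle.annotations)
    return variants, bundle.normal_calls


def test_retained_set_invariant_under_predicate_order():
    variants, normal = _fixture_case()
    order = ["quality", "consequence_population", "read_support",
             "germline", "pathogenicity"]
    baseline = run_cascade(variants, mode="matched", normal_calls=normal,
                           predicate_order=order).retained_keys
    rng = random.Random(99)
    for _ in range(50):
        perm = order[:]
        rng.shuffle(perm)
        got = run_cascade(variants, mode="matched", normal_calls=normal,
                          predicate_order=perm).retained_keys
        assert got == baseline


@pytest.mark.parametrize(
    "tighter",
    [
        dict(qual_min=30.0), dict(fs_max=40.0), dict(mq_min=50.0),
        dict(depth_min=40), dict(alt_min=8), dict(blood_alt_max=1),
        dict(cadd_min=22.0), dict(pop_1000g_max=0.001),
        dict(pop_maf_max=0.0001),
    ],
)
def test_tightening_any_threshold_never_grows_the_retained_set(tighter):
    variants, normal = _fixture_case()
    base = run_cascade(variants, mode="matched",
                       normal_calls=normal).retained_keys
    tight = run_cascade(
        variants, thresholds=FilterThresholds(**tighter),
        mode="matched", normal_calls=normal,
    ).retained_keys
    assert tight <= base


def test_quality_predicate_matches_direct_restatement_on_random_metrics():
    from hypothesis import given, settings
    from hypothesis import strategies as st

    metric = st.one_of(st.none(), st.floats(-100, 3000, allow_nan=False))

    @settings(max_examples=200, derandomize=True)
    @given(qual=metric, fs=metric, mq=metric, mqrs=metric, qd=metric,
           rprs=metric, alt=st.integers(0, 100))
    def check(qual, fs, mq, mqrs, qd, rprs, alt):
        from conftest import make_variant
        v = make_variant(
            total=100, alt_reads=alt,
            quality=QualityMetrics(qual=qual, fs=fs, mq=mq, mq_rank_sum=mqrs,
                                   qd=qd, read_pos_rank_sum=rprs),
        )
        got = apply_quality_filters(v)
        vaf = alt / 100
        expected = set()
        if qual is not None and qual < 20: expected.add(flt.QUAL_LOW)
        if fs is not None and fs > 60: expected.add(flt.FS_HIGH)
        if mq is not None and mq < 40: expected.add(flt.MQ_LOW)
        if mqrs is not None and mqrs < -12.5: expected.add(flt.MQRS_LOW)
        if qd is not None and qd < 2: expected.add(flt.QD_LOW)
        if qd is not None and vaf > 0 and qd / vaf < 8.0:
            expected.add(flt.QD_AF_LOW)
        if rprs is not None and rprs < -20: expected.add(flt.RPRS_LOW)
        assert got == expected

    check()


def test_cascade_recovers_generator_truth():
    cfg = CohortSimConfig(somatic_low_mean=20, germline_per_case=30,
                          mean_depth=100, major_clone_vaf=0.35, seed=7)
    bundle = simulate_case(cfg, "T01", matched=True)
    from varcascade.harmonize import harmonize_sample
    from varcascade.vcfio import join_annotations
    variants, _ = harmonize_sample(bundle.calls_a, bundle.calls_b)
    variants, _ = join_annotations(variants, bundle.annotations)
    res = run_cascade(variants, mode="matched",
                      normal_calls=bundle.normal_calls)
    retained = res.retained_keys
    truth = bundle.truth
    expected = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in truth.itertuples(index=False) if r.expected_surviving
    }
    assert retained == expected
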