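"""Simulator contracts: determinism, truth consistency, config validation,
and agreement between the generator's survival oracle and the cascade."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from varcascade.filtering import run_cascade
from varcascade.harmonize import harmonize_sample
from varcascade.synthetic import (
    CohortSimConfig,
    ConfigError,
    simulate_case,
    simulate_cohort,
    simulate_coverage,
    write_cohort,
)
from varcascade.vcfio import join_annotations


def _dir_digest(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir()) if p.is_file()
    }


def test_same_config_and_seed_give_byte_identical_cohorts(tmp_path):
    cfg = CohortSimConfig(n_matched_cases=2, n_unmatched_cases=1,
                          n_targets=200, seed=17)
    write_cohort(cfg, tmp_path / "a")
    write_cohort(cfg, tmp_path / "b")
    da, db = _dir_digest(tmp_path / "a"), _dir_digest(tmp_path / "b")
    # manifests embed absolute paths; every data file must be identical
    da.pop("manifest.json"), db.pop("manifest.json")
    assert da == db


def test_zero_event_config_yields_empty_call_sets_and_truth():
    cfg = CohortSimConfig(somatic_low_mean=0, somatic_high_mean=0,
                          germline_per_case=0, artifact_per_case=0, seed=1)
    bundle = simulate_case(cfg, "E01", matched=True)
    assert bundle.calls_a == [] and bundle.calls_b == []
    assert bundle.normal_calls == []
    assert bundle.truth.empty and bundle.annotations.empty


@pytest.mark.parametrize(
    "kw, field",
    [
        (dict(mnp_fraction=1.5), "mnp_fraction"),
        (dict(major_clone_vaf=0.0), "major_clone_vaf"),
        (dict(minor_clone_vaf_range=(0.3, 0.1)), "minor_clone_vaf_range"),
        (dict(mean_depth=0), "mean_depth"),
        (dict(germline_per_case=-1), "germline_per_case"),
    ],
)
def test_invalid_config_error_names_the_field(kw, field):
    with pytest.raises(ConfigError, match=field):
        CohortSimConfig(**kw)


def test_overlapping_injected_segments_are_rejected():
    with pytest.raises(ConfigError, match="overlapping"):
        CohortSimConfig(
            n_targets=400,
            cna_segments=(("chr1", 0, 20, 3), ("chr1", 10, 30, 1)),
        )


def test_every_germline_truth_record_has_blood_alt_above_three():
    cfg = CohortSimConfig(germline_per_case=50, seed=3)
    bundle = simulate_case(cfg, "G01", matched=True)
    germline_keys = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in bundle.truth.itertuples(index=False)
        if r.truth_class == "germline"
    }
    normal = {o.key: o for o in bundle.normal_calls}
    assert germline_keys  # non-vacuous
    for key in germline_keys:
        assert normal[key].alt_reads > 3


def test_every_artifact_violates_at_least_one_quality_criterion():
    cfg = CohortSimConfig(artifact_per_case=40, seed=4)
    bundle = simulate_case(cfg, "A01", matched=True)
    artifact_keys = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in bundle.truth.itertuples(index=False)
        if r.truth_class == "artifact"
    }
    by_key = {o.key: o for o in bundle.calls_a + bundle.calls_b}
    assert artifact_keys
    for key in artifact_keys:
        q = by_key[key].quality
        assert (
            (q.qual is not None and q.qual < 20)
            or (q.fs is not None and q.fs > 60)
            or (q.mq is not None and q.mq < 40)
            or (q.mq_rank_sum is not None and q.mq_rank_sum < -12.5)
            or (q.qd is not None and q.qd < 2)
            or (q.read_pos_rank_sum is not None and q.read_pos_rank_sum < -20)
        )


def _agreement(bundle, matched_genes=frozenset()):
    variants, _ = harmonize_sample(bundle.calls_a, bundle.calls_b)
    variants, _ = join_annotations(variants, bundle.annotations)
    res = run_cascade(
        variants,
        mode="matched" if bundle.matched else "unmatched",
        normal_calls=bundle.normal_calls,
        matched_somatic_genes=matched_genes,
    )
    retained = res.retained_keys
    expected = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in bundle.truth.itertuples(index=False) if r.expected_surviving
    }
    assert len(variants) == len(bundle.truth)
    return retained == expected


def test_expected_surviving_agrees_with_cascade_across_random_configs():
    rng = np.random.default_rng(31)
    for i in range(6):
        cfg = CohortSimConfig(
            somatic_low_mean=float(rng.uniform(5, 30)),
            germline_per_case=int(rng.integers(10, 60)),
            artifact_per_case=int(rng.integers(5, 25)),
            mean_depth=float(rng.uniform(40, 180)),
            mnp_fraction=float(rng.uniform(0, 0.25)),
            caller_b_only_fraction=float(rng.uniform(0, 0.25)),
            seed=int(rng.integers(0, 2**30)),
        )
        assert _agreement(simulate_case(cfg, f"R{i}", matched=True))


def test_unmatched_truth_honors_the_rescue_gene_set():
    cohort = simulate_cohort(
        CohortSimConfig(n_matched_cases=3, n_unmatched_cases=2,
                        somatic_low_mean=15, seed=9)
    )
    for bundle in cohort.cases:
        if not bundle.matched:
            assert _agreement(bundle, cohort.matched_somatic_genes)


def test_coverage_without_segments_is_ratio_one():
    cfg = CohortSimConfig(n_targets=600, mean_depth=120, seed=2)
    tumor, normal = simulate_coverage(cfg, "C01")
    ratio = tumor.targets["depth"].mean() / normal.targets["depth"].mean()
    assert abs(ratio - 1.0) < 0.05


def test_coverage_with_copy_three_segment_scales_by_half():
    cfg = CohortSimConfig(n_targets=600, mean_depth=120,
                          cna_segments=(("chr1", 0, 49, 3),), seed=2)
    tumor, normal = simulate_coverage(cfg, "C01")
    t = tumor.targets
    in_seg = t[(t["chrom"] == "chr1")].iloc[0:50]["depth"].mean()
    n_seg = normal.targets[(normal.targets["chrom"] == "chr1")].iloc[0:50][
        "depth"].mean()
    assert abs(in_seg / n_seg - 1.5) < 0.1


def test_coverage_profiles_are_seed_deterministic():
    cfg = CohortSimConfig(n_targets=300, seed=13)
    t1, n1 = simulate_coverage(cfg, "D01")
    t2, n2 = simulate_coverage(cfg, "D01")
    assert t1.targets.equals(t2.targets)
    assert n1.targets.equals(n2.targets)
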