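"""State assignment, allele consistency, genome metrics, LOH
incompatibility, and subclonal-history disambiguation."""

import numpy as np
import pytest

from chemopair import synthetic_data as sd
from chemopair.cn_states import (
    SampleStateCall,
    StateCall,
    assign_states,
    check_allele_consistency,
    detect_loh_incompatibility,
    disambiguate_subclonal_history,
    genome_metrics,
    scenario_from_state,
    _mixture_point,
)
from chemopair.purity_ploidy import SampleModel, predict_cluster_centers
from chemopair.segmentation import Segment
from helpers import lattice_segments, truth_state_calls

MODEL = SampleModel(rho=0.8, haploid_depth=20.0)
MODELS = {"pre": MODEL, "post": MODEL}


def _segment(depth, baf, ubaf=None, n_loci=200, start=0, end=1_000_000):
    ubaf = 1.0 - baf if ubaf is None else ubaf
    return Segment(
        chrom="chr1", start_locus=0, end_locus=n_loci, start=start, end=end,
        n_loci=n_loci, depth={"pre": depth, "post": depth},
        baf={"pre": baf, "post": baf}, ubaf={"pre": ubaf, "post": ubaf},
    )


def test_segment_at_center_is_clonal():
    center = {c.state: c for c in predict_cluster_centers(MODEL)}[(1, 1)]
    calls = assign_states([_segment(center.depth, center.baf)], MODELS)
    assert calls[0].pre.state == (1, 1)
    assert calls[0].pre.clonal_fraction == 1.0
    assert calls[0].pre.alt_state is None


def test_midway_segment_is_half_half_mixture():
    d, b = _mixture_point(np.array((2, 2)), np.array((3, 2)), 0.5, MODEL.rho,
                          MODEL.haploid_depth)
    calls = assign_states([_segment(d, b)], MODELS)
    call = calls[0].pre
    assert {call.state, call.alt_state} == {(2, 2), (3, 2)}
    assert call.clonal_fraction == pytest.approx(0.5, abs=0.02)


def test_small_segment_left_unassigned():
    calls = assign_states([_segment(40.0, 0.5, n_loci=3)], MODELS)
    assert not calls[0].assigned
    assert any(f.startswith("too_few_loci") for f in calls[0].flags)


def test_noiseless_truth_segments_recover_all_states(default_truth):
    truth = default_truth
    rho = truth.cellularity["pre"]
    model = SampleModel(rho=rho, haploid_depth=truth.haploid_depth)
    states = list(
        truth.truth_segments[["nA_pre", "nB_pre"]].itertuples(index=False)
    )
    segs = lattice_segments([(max(s), min(s)) for s in states], model)
    calls = assign_states(segs, {"pre": model, "post": model})
    got = [c.pre.state for c in calls]
    want = [(max(s), min(s)) for s in states]
    assert got == want
    assert all(c.pre.is_clonal for c in calls)


def _paired_call(state_pre, state_post, major_a_pre=True, major_a_post=True,
                 start=0, end=2_000_000):
    seg = _segment(50.0, 0.33, start=start, end=end)
    return StateCall(
        segment=seg,
        pre=SampleStateCall(state=state_pre, clonal_fraction=1.0,
                            alt_state=None, residual=0.0,
                            major_is_a=major_a_pre),
        post=SampleStateCall(state=state_post, clonal_fraction=1.0,
                             alt_state=None, residual=0.0,
                             major_is_a=major_a_post),
    )


def test_consistent_major_allele_not_flagged():
    calls = check_allele_consistency([_paired_call((2, 1), (2, 1))])
    assert calls[0].flags == []


def test_mirrored_major_allele_is_flagged_not_overwritten():
    call = _paired_call((2, 1), (2, 1), major_a_pre=True, major_a_post=False)
    out = check_allele_consistency([call])[0]
    assert "mirrored_major_allele" in out.flags
    assert out.state_pre == (2, 1) and out.state_post == (1, 2)


def test_balanced_states_skip_consistency_check():
    call = _paired_call((2, 2), (2, 1), major_a_pre=False)
    assert check_allele_consistency([call])[0].flags == []


def test_paired_synthetic_loh_always_same_allele(near_sync_result):
    flags = [f for c in near_sync_result["calls"] for f in c.flags]
    assert "mirrored_major_allele" not in flags


def test_genome_metrics_thresholds():
    calls = [
        _paired_call((1, 1), (1, 1), start=0, end=5_000_000),
        _paired_call((5, 0), (1, 1), start=5_000_000, end=6_000_000),
        _paired_call((1, 0), (1, 1), start=6_000_000, end=7_000_000),
    ]
    gm = genome_metrics(calls)["pre"]
    # ploidy = (2*5 + 5*1 + 1*1) / 7
    assert gm.average_ploidy == pytest.approx(16 / 7)
    # only total=5 exceeds 2x ploidy; total=1 at ratio 0.4375 is deleted,
    # total=2 at ratio 0.875 is not
    assert gm.fraction_amplified == pytest.approx(1 / 7)
    assert gm.fraction_deleted == pytest.approx(1 / 7)
    assert gm.fraction_loh == pytest.approx(2 / 7)


def test_half_ploidy_ratio_is_not_deleted_under_strict_rule():
    """A total of 1 at ploidy exactly 2 sits on the 0.5 boundary: the
    strict reading excludes it, the inclusive flag counts it."""
    calls = [
        _paired_call((2, 1), (2, 1), start=0, end=2_000_000),
        _paired_call((1, 0), (1, 0), start=2_000_000, end=4_000_000),
    ]
    # ploidy = (3*2 + 1*2) / 4 = 2.0, so the (1,0) ratio is exactly 0.5
    gm = genome_metrics(calls)["pre"]
    assert gm.average_ploidy == pytest.approx(2.0)
    assert gm.fraction_deleted == 0.0
    gm_incl = genome_metrics(calls, deleted_inclusive=True)["pre"]
    assert gm_incl.fraction_deleted == pytest.approx(0.5)


def test_metrics_invariant_to_segment_splitting():
    whole = [_paired_call((3, 1), (2, 1), start=0, end=4_000_000)]
    split = [
        _paired_call((3, 1), (2, 1), start=0, end=1_500_000),
        _paired_call((3, 1), (2, 1), start=1_500_000, end=4_000_000),
    ]
    a = genome_metrics(whole)["pre"]
    b = genome_metrics(split)["pre"]
    assert a == b


def test_sample_paired_with_itself_has_full_same_state_fraction():
    calls = [
        _paired_call((2, 1), (2, 1)),
        _paired_call((2, 0), (2, 0), start=2_000_000, end=3_000_000),
    ]
    assert genome_metrics(calls)["pre"].fraction_same_state == 1.0


def test_pre_loh_post_het_implies_shared_antecedent():
    calls = [_paired_call((2, 0), (1, 1), start=0, end=5_000_000)]
    res = detect_loh_incompatibility(calls)
    assert res.span_pre_loh_post_het == 5_000_000
    assert res.shared_antecedent


def test_identical_profiles_have_no_incompatibility():
    calls = [_paired_call((2, 0), (2, 0), start=0, end=5_000_000)]
    res = detect_loh_incompatibility(calls)
    assert not res.pre_loh_post_het and not res.post_loh_pre_het
    assert not res.shared_antecedent


def test_post_only_loh_is_compatible_with_linear_descent():
    calls = [_paired_call((1, 1), (2, 0), start=0, end=5_000_000)]
    res = detect_loh_incompatibility(calls)
    assert res.span_post_loh_pre_het == 5_000_000
    assert not res.shared_antecedent


def test_min_span_guards_against_noise():
    calls = [_paired_call((2, 0), (1, 1), start=0, end=500_000)]
    assert not detect_loh_incompatibility(calls).shared_antecedent


def test_lineage_private_loh_both_ways_yields_shared_antecedent():
    cfg = sd.scenario_config("private_loh", seed=9)
    truth = sd.simulate_patient(cfg)
    res = detect_loh_incompatibility(truth_state_calls(truth))
    assert res.shared_antecedent
    assert res.span_pre_loh_post_het >= 1_000_000
    assert res.span_post_loh_pre_het >= 1_000_000


def test_no_private_loh_means_no_antecedent_signal():
    cfg = sd.scenario_config("near_synchronous", seed=9)
    truth = sd.simulate_patient(cfg)
    assert not detect_loh_incompatibility(truth_state_calls(truth)).shared_antecedent


def test_subclonal_loss_scenario_chosen_from_three_clusters():
    rho = 0.8
    loss = scenario_from_state("subclonal_loss_from_AAABB", (3, 2), rho,
                               multiplicities=(1, 2, 3))
    gain = scenario_from_state("clonal_AABB_then_gain", (2, 2), rho,
                               multiplicities=(1, 2), subclonal_fraction=0.4)
    rng = np.random.default_rng(0)
    dp = rng.poisson(80, 300)
    comp = rng.integers(0, 3, 300)
    alt = rng.binomial(dp, np.asarray(loss.centers)[comp])
    res = disambiguate_subclonal_history(alt, dp, [loss, gain])
    assert res["chosen"] == "subclonal_loss_from_AAABB"
    assert res["observed_clusters"] == 3


def test_four_clusters_prefer_the_four_center_scenario():
    rho = 1.0
    four = scenario_from_state("clonal_gain_four_clusters", (3, 2), rho,
                               multiplicities=(1, 2, 3),
                               subclonal_fraction=0.45)
    three = scenario_from_state("subclonal_loss_three_clusters", (3, 2), rho,
                                multiplicities=(1, 2, 3))
    rng = np.random.default_rng(1)
    dp = rng.poisson(100, 400)
    comp = rng.integers(0, 4, 400)
    alt = rng.binomial(dp, np.asarray(four.centers)[comp])
    res = disambiguate_subclonal_history(alt, dp, [four, three])
    assert res["chosen"] == "clonal_gain_four_clusters"


def test_identical_center_sets_are_undetermined():
    a = scenario_from_state("a", (2, 1), 0.8)
    b = scenario_from_state("b", (2, 1), 0.8)
    rng = np.random.default_rng(2)
    dp = rng.poisson(60, 100)
    alt = rng.binomial(dp, 0.3)
    res = disambiguate_subclonal_history(alt, dp, [a, b])
    assert res["chosen"] == "undetermined"
    assert res["reason"] == "identical_predictions"


def test_too_few_snvs_are_undetermined():
    a = scenario_from_state("a", (2, 1), 0.8)
    b = scenario_from_state("b", (2, 2), 0.8)
    res = disambiguate_subclonal_history([5, 6], [20, 20], [a, b])
    assert res["chosen"] == "undetermined"
    assert res["reason"] == "too_few_snvs"
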