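"""Sharing partition, multiplicity algebra, early/late classification,
and divergence-timing inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemopair import synthetic_data as sd
from chemopair.snv_timing import (
    DivergenceReport,
    classify_timing,
    estimate_multiplicity,
    infer_divergence_timing,
    partition_sharing,
)


def _keys(pairs):
    return pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": "C", "alt": "A"} for c, p in pairs]
    )


def test_identical_call_sets_are_all_shared():
    df = _keys([("chr1", 100), ("chr1", 200), ("chr2", 50)])
    _, venn = partition_sharing(df, df.copy())
    assert venn == {"pre_only": 0, "shared": 3, "post_only": 0}


def test_disjoint_call_sets_share_nothing():
    a = _keys([("chr1", 100), ("chr1", 200)])
    b = _keys([("chr2", 100), ("chr2", 200), ("chr2", 300)])
    _, venn = partition_sharing(a, b)
    assert venn == {"pre_only": 2, "shared": 0, "post_only": 3}


def test_duplicate_keys_rejected():
    a = _keys([("chr1", 100), ("chr1", 100)])
    with pytest.raises(ValueError, match="duplicate"):
        partition_sharing(a, _keys([("chr1", 200)]))


def test_generator_venn_counts_match_configuration():
    cfg = sd.SimulationConfig(
        seed=21, n_truncal_snvs=500, n_private_snvs_per_lineage=0,
    )
    cfg.n_private_snvs_per_lineage = 0
    truth = sd.simulate_patient(cfg)
    pre = truth.snvs[truth.snvs["mult_pre"] > 0]
    post = truth.snvs[truth.snvs["mult_post"] > 0]
    _, venn = partition_sharing(pre, post)
    assert venn == {"pre_only": 0, "shared": 500, "post_only": 0}
    cfg2 = sd.SimulationConfig(
        seed=21, n_truncal_snvs=500, n_private_snvs_per_lineage=300,
    )
    t2 = sd.simulate_patient(cfg2)
    _, venn2 = partition_sharing(
        t2.snvs[t2.snvs["mult_pre"] > 0], t2.snvs[t2.snvs["mult_post"] > 0]
    )
    assert venn2 == {"pre_only": 300, "shared": 500, "post_only": 300}


@pytest.mark.parametrize(
    "vaf,rho,n_total,want",
    [
        (0.5, 1.0, 2, 1.0),
        (1.0, 1.0, 2, 2.0),
        (0.25, 0.6, 3, 0.25 * 2.6 / 0.6),
    ],
)
def test_multiplicity_values(vaf, rho, n_total, want):
    assert estimate_multiplicity(vaf, rho, n_total) == pytest.approx(want)


def test_multiplicity_rejects_zero_cellularity():
    with pytest.raises(ValueError):
        estimate_multiplicity(0.5, 0.0, 2)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.integers(1, 4),
    st.integers(1, 6),
    st.floats(0.1, 1.0),
)
def test_multiplicity_algebra_inverts_expected_vaf(m, extra, rho):
    """For noiseless SNVs the estimator returns the true multiplicity
    exactly: the algebra inverts the simulator's VAF model."""
    n_total = m + extra - 1 if m + extra - 1 >= m else m
    vaf = sd.expected_vaf(m, n_total, rho)
    assert estimate_multiplicity(vaf, rho, n_total) == pytest.approx(m, abs=1e-9)


def test_saturated_vaf_in_loh_doubled_state_is_early():
    # AA state, full cellularity: VAF 1 forces both copies mutated
    out = classify_timing([60], [60], (2, 0), 1.0)
    assert out[0] == "early"


def test_one_third_vaf_in_aab_is_late():
    out = classify_timing([20], [60], (2, 1), 1.0)
    assert out[0] == "late"


def test_low_depth_ambiguous_call_is_unclassified():
    # 3/8 sits between the m=1 and m=2 expectations with LR = 4 < 10
    out = classify_timing([3], [8], (2, 1), 1.0)
    assert out[0] == "unclassified"


def test_binomial_lr_threshold_matches_hand_computation():
    from scipy.stats import binom

    alt, dp = 3, 8
    l1 = binom.logpmf(alt, dp, 1 / 3)
    l2 = binom.logpmf(alt, dp, 2 / 3)
    assert np.exp(abs(l1 - l2)) == pytest.approx(4.0, rel=1e-9)
    # just over the threshold at higher depth
    out = classify_timing([10], [30], (2, 1), 1.0)
    assert out[0] == "late"


def test_balanced_diploid_region_never_early():
    rng = np.random.default_rng(0)
    dp = rng.poisson(60, 500)
    alt = rng.binomial(dp, rng.uniform(0, 1, 500))
    out = classify_timing(alt, dp, (1, 1), 0.8)
    assert set(out) == {"unclassified"}


def test_ineligible_state_is_unclassified():
    out = classify_timing([30], [60], (3, 2), 1.0)
    assert out[0] == "unclassified"


def test_sharing_conservation_end_to_end(near_sync_result):
    timed = near_sync_result["timed"]
    venn = timed["sharing"].value_counts()
    assert venn.sum() == len(timed)
    assert set(venn.index) <= {"shared", "pre_only", "post_only"}


def test_timing_misclassification_rate_low(near_sync_result):
    """At 50x and cellularity >= 0.5, classified SNVs match truth timing
    (early = truly multiplicity >= 2) in at least 95% of cases."""
    res = near_sync_result
    # the synthetic read table carries the true multiplicities through
    timed = res["timed"]
    assert {"mult_pre", "mult_post"} <= set(timed.columns)
    n_bad = n_classified = 0
    for s in ("pre", "post"):
        classified = timed[
            (timed[f"timing_{s}"] != "unclassified") & timed[f"called_{s}"]
        ]
        truth_timing = np.where(classified[f"mult_{s}"] >= 2, "early", "late")
        n_classified += len(classified)
        n_bad += (classified[f"timing_{s}"] != truth_timing).sum()
    assert n_classified > 200
    assert n_bad / n_classified <= 0.05


def test_no_early_calls_without_duplication(near_sync_result):
    timed = near_sync_result["timed"]
    for s in ("pre", "post"):
        diploid = timed[(timed[f"n_a_{s}"] == 1) & (timed[f"n_b_{s}"] == 1)]
        assert not (diploid[f"timing_{s}"] == "early").any()


def test_divergence_near_synchronous_recovered(near_sync_result):
    report = near_sync_result["divergence"]
    assert isinstance(report, DivergenceReport)
    assert report.verdict == "divergence near-synchronous with endoreduplication"
    assert report.f_private_early <= 0.02
    assert report.f_shared_late <= 0.02


def test_divergence_before_doubling_recovered(before_result):
    report = before_result["divergence"]
    assert report.verdict == "diversity predates copy-number change"
    assert report.f_private_early > 0.02


def test_divergence_after_doubling_recovered(after_result):
    report = after_result["divergence"]
    assert report.verdict == "copy-number change predates diversity"
    assert report.f_shared_late > 0.02
    assert report.f_private_early <= 0.02


def test_recent_divergence_flagged(recent_result):
    report = recent_result["divergence"]
    assert report.recent_divergence
    assert report.shared_fraction >= 0.9


def test_shared_antecedent_propagates(private_loh_result):
    assert private_loh_result["divergence"].shared_antecedent


def test_insufficient_informative_snvs_undetermined():
    timed = pd.DataFrame(
        {
            "sharing": ["shared"] * 5,
            "timing": ["early"] * 5,
            "timing_pre": ["early"] * 5,
            "timing_post": ["early"] * 5,
            "n_a_pre": [2] * 5,
            "n_a_post": [2] * 5,
        }
    )
    report = infer_divergence_timing(timed, min_informative=100)
    assert report.verdict == "undetermined"
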