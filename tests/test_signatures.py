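"""Catalog construction, QP deconstruction vs oracles, de novo NMF
extraction, and the cisplatin CpC C>A enrichment test."""

import numpy as np
import pandas as pd
import pytest

from chemopair import signatures as sig
from chemopair import synthetic_data as sd
from helpers import fisher_two_sided_oracle, simplex_grid_qp_oracle


class DictRef:
    """chrom -> string reference for catalog tests."""

    def __init__(self, seqs):
        self.seqs = seqs

    def __getitem__(self, chrom):
        return self.seqs[chrom]


def test_single_snv_fills_one_channel():
    snvs = pd.DataFrame(
        [{"chrom": "chr1", "pos": 2, "ref": "C", "alt": "T"}]
    )
    cat, skipped = sig.trinucleotide_catalog(snvs, DictRef({"chr1": "ACA"}))
    assert skipped == 0
    assert cat.sum() == 1
    assert cat[sig.CHANNEL_INDEX[("C>T", "A", "A")]] == 1


def test_purine_representation_folds_to_same_channel():
    # G>A in context TGT is the reverse complement of C>T in ACA
    assert sig.channel_of("G", "A", "TGT") == sig.channel_of("C", "T", "ACA")
    snvs = pd.DataFrame(
        [{"chrom": "chr1", "pos": 2, "ref": "G", "alt": "A"}]
    )
    cat, _ = sig.trinucleotide_catalog(snvs, DictRef({"chr1": "TGT"}))
    assert cat[sig.CHANNEL_INDEX[("C>T", "A", "A")]] == 1


def test_reference_mismatch_is_skipped_with_warning():
    snvs = pd.DataFrame(
        [
            {"chrom": "chr1", "pos": 2, "ref": "C", "alt": "T"},
            {"chrom": "chr1", "pos": 2, "ref": "G", "alt": "A"},
        ]
    )
    with pytest.warns(UserWarning, match="skipped"):
        cat, skipped = sig.trinucleotide_catalog(snvs, DictRef({"chr1": "ACA"}))
    assert skipped == 1
    assert cat.sum() == 1


def test_catalog_of_simulated_patient_matches_mixture(default_truth):
    """Catalog extracted from the synthetic FASTA through the standard
    code path reproduces the generating signature mixture."""
    truth = default_truth
    ref = sd.build_reference(truth)
    from chemopair.pipeline import _ArrayReference

    cat, skipped = sig.trinucleotide_catalog(truth.snvs, _ArrayReference(ref))
    assert skipped == 0
    assert cat.sum() == len(truth.snvs)
    p = np.asarray(truth.config.signature_matrix) @ np.asarray(
        truth.config.signature_weights
    )
    freq = cat / cat.sum()
    se = np.sqrt(p * (1 - p) / cat.sum())
    assert (np.abs(freq - p) <= 3 * se + 1e-9).mean() > 0.95


def test_deconstruct_single_signature_exactly():
    P = sd.default_signature_matrix(k=3)
    expo = sig.deconstruct_qp(P[:, 1] * 1e4, P)
    assert expo.weights[1] == pytest.approx(1.0, abs=1e-9)
    assert expo.residual == pytest.approx(0.0, abs=1e-9)


def test_deconstruct_noiseless_two_signature_mixture():
    P = sd.default_signature_matrix(k=2)
    c = 0.7 * P[:, 0] + 0.3 * P[:, 1]
    expo = sig.deconstruct_qp(c, P)
    assert np.allclose(expo.weights, [0.7, 0.3], atol=1e-6)


def test_deconstruct_recovers_sampled_mixture_within_two_percent():
    P = sd.default_signature_matrix(k=3)
    w = np.array([0.5, 0.3, 0.2])
    cat = sd.catalog_from_signatures(P, w, 50_000, seed=3)
    expo = sig.deconstruct_qp(cat, P)
    assert np.abs(expo.weights - w).max() <= 0.02


def test_deconstruct_matches_simplex_grid_oracle():
    P = sd.default_signature_matrix(k=3)
    cat = sd.catalog_from_signatures(P, np.array([0.6, 0.1, 0.3]), 20_000, seed=4)
    expo = sig.deconstruct_qp(cat, P, reporting_threshold=0.0)
    w_grid, _ = simplex_grid_qp_oracle(cat, P, step=0.001)
    assert np.abs(expo.weights - w_grid).max() <= 1.5e-3


def test_residual_zero_inside_simplex_hull():
    P = sd.default_signature_matrix(k=3)
    rng = np.random.default_rng(5)
    w = rng.dirichlet(np.ones(3))
    expo = sig.deconstruct_qp(P @ w, P, reporting_threshold=0.0)
    assert expo.residual <= 1e-8


def test_rank_deficient_matrix_warns():
    P = sd.default_signature_matrix(k=2)
    P3 = np.column_stack([P, P[:, 0]])
    with pytest.warns(UserWarning, match="rank-deficient"):
        expo = sig.deconstruct_qp(P[:, 0] * 100, P3)
    assert expo.rank_deficient


def test_denovo_stability_peaks_at_true_signature_count():
    rng = np.random.default_rng(6)
    P = sd.default_signature_matrix(k=3, seed=11)
    catalogs = np.vstack(
        [
            sd.catalog_from_signatures(
                P, rng.dirichlet(np.ones(3)), 20_000, seed=int(rng.integers(2**31 - 1))
            )
            for _ in range(40)
        ]
    )
    res = sig.extract_denovo(catalogs, k_range=[2, 3, 4], n_bootstrap=8, seed=0)
    per_k = res["per_k"].set_index("k")
    assert per_k.loc[3, "stability"] > 0.8
    assert per_k.loc[3, "stability"] > per_k.loc[4, "stability"]
    assert res["selected_k"] == 3


def test_denovo_k1_recovers_mean_catalog():
    rng = np.random.default_rng(7)
    P = sd.default_signature_matrix(k=1, seed=12)
    catalogs = np.vstack(
        [sd.catalog_from_signatures(P, [1.0], 30_000, seed=i) for i in range(6)]
    )
    res = sig.extract_denovo(catalogs, k_range=[1], n_bootstrap=5, seed=0)
    mean_profile = catalogs.sum(axis=0) / catalogs.sum()
    recovered = res["signatures"][0]
    cos = recovered @ mean_profile / (
        np.linalg.norm(recovered) * np.linalg.norm(mean_profile)
    )
    assert cos > 0.999
    del rng


def test_denovo_is_deterministic_under_fixed_seed():
    P = sd.default_signature_matrix(k=2, seed=13)
    rng = np.random.default_rng(8)
    catalogs = np.vstack(
        [
            sd.catalog_from_signatures(P, rng.dirichlet(np.ones(2)), 10_000, seed=i)
            for i in range(10)
        ]
    )
    a = sig.extract_denovo(catalogs, k_range=[2], n_bootstrap=5, seed=1)
    b = sig.extract_denovo(catalogs, k_range=[2], n_bootstrap=5, seed=1)
    pd.testing.assert_frame_equal(a["per_k"], b["per_k"])


def test_denovo_rejects_excessive_k():
    catalogs = np.ones((4, 96))
    with pytest.raises(ValueError, match="k must be"):
        sig.extract_denovo(catalogs, k_range=[4], n_bootstrap=2, seed=0)


def test_identical_group_profiles_give_unit_odds_ratio():
    cat = sd.catalog_from_signatures(
        sd.default_signature_matrix(k=2), [0.5, 0.5], 10_000, seed=9
    )
    res = sig.cisplatin_enrichment(
        np.vstack([cat, cat]), ["treated", "naive"]
    )
    assert res["odds_ratio"] == pytest.approx(1.0)
    assert res["p_value"] == pytest.approx(1.0)


def test_fisher_p_matches_enumeration_oracle_on_fixed_table():
    table = [[30, 970], [10, 990]]
    from scipy.stats import fisher_exact

    p = fisher_exact(table, alternative="two-sided")[1]
    assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)


def test_spiked_cpc_ca_mass_is_detected():
    """Moving 5% of mutation mass into CpC C>A channels in the treated
    group drives the enrichment p-value below 1e-4."""
    P = sd.default_signature_matrix(k=2)
    base = sd.catalog_from_signatures(P, [0.5, 0.5], 50_000, seed=10).astype(float)
    spiked = base.copy()
    spike = int(0.05 * base.sum())
    for ch in sig.CPC_CA_CHANNELS_5PRIME:
        spiked[ch] += spike / 4
    res = sig.cisplatin_enrichment(
        np.vstack([spiked, base]), ["treated", "naive"]
    )
    assert res["p_value"] < 1e-4
    assert res["odds_ratio"] > 1.0
    assert res["fraction_treated"] > res["fraction_naive"]


def test_cpc_convention_is_configurable():
    cat = np.zeros(96)
    cat[sig.CHANNEL_INDEX[("C>A", "C", "G")]] = 50  # CpC by the 5' reading
    cat[sig.CHANNEL_INDEX[("C>T", "A", "A")]] = 50
    other = np.zeros(96)
    other[sig.CHANNEL_INDEX[("C>T", "A", "A")]] = 100
    res5 = sig.cisplatin_enrichment(
        np.vstack([cat, other]), ["treated", "naive"], convention="5prime"
    )
    res3 = sig.cisplatin_enrichment(
        np.vstack([cat, other]), ["treated", "naive"], convention="3prime"
    )
    assert res5["fraction_treated"] == pytest.approx(0.5)
    assert res3["fraction_treated"] == pytest.approx(0.0)


def test_signature_matrix_round_trip(tmp_path):
    P = sd.default_signature_matrix(k=3)
    path = tmp_path / "sigs.tsv"
    sig.write_signature_matrix(path, P, ["S1", "S2", "S3"])
    back, names = sig.read_signature_matrix(path)
    assert names == ["S1", "S2", "S3"]
    assert np.allclose(back, P)
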