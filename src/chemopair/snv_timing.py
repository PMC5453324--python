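"""SNV multiplicity, timing relative to copy-number change, and the
divergence clock of a sample pair.

An SNV acquired before a gain of its carrying allele is present on every
duplicated copy (multiplicity >= 2); one acquired afterwards sits on a
single copy.  In a sample of cellularity rho with local total copy number
n_total, a clonal SNV at multiplicity m has expected VAF

    vaf = rho * m / (rho * n_total + 2 * (1 - rho))

so multiplicity is estimated by inverting this relation, and timing
(early = before the copy-number change, late = after) is decided by a
binomial likelihood-ratio test between the candidate integer
multiplicities, restricted to states where the two hypotheses are
distinguishable and the data are adequately powered.

The divergence logic: if clonal diversity predates the copy-number
changes, some lineage-private SNVs predate local gains (early private
SNVs); if the copy-number changes came first, some shared SNVs postdate
them (late shared SNVs).  Seeing neither places the divergence of the two
samples near-synchronous with the genome doubling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from chemopair.states import string_to_state

#: states in which early/late can be confidently distinguished
ELIGIBLE_STATES = frozenset(
    string_to_state(s) for s in ("AA", "AAB", "AABB", "AAA", "AAAA", "AAAAB")
)

SAMPLES = ("pre", "post")


def partition_sharing(
    pre_calls: pd.DataFrame, post_calls: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Partition SNV calls from the two samples by exact key.

    Both frames need columns chrom, pos, ref, alt.  Returns the union
    keyed frame with a ``sharing`` column and the Venn counts
    ``{"pre_only": ..., "shared": ..., "post_only": ...}``.  Duplicate
    keys within one sample are rejected.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    for name, df in (("pre", pre_calls), ("post", post_calls)):
        if df.duplicated(subset=key_cols).any():
            raise ValueError(f"duplicate SNV keys in {name} sample")
    merged = pre_calls[key_cols].merge(
        post_calls[key_cols], on=key_cols, how="outer", indicator=True
    )
    merged["sharing"] = merged["_merge"].map(
        {"left_only": "pre_only", "right_only": "post_only", "both": "shared"}
    ).astype(str)
    merged = merged.drop(columns="_merge")
    venn = merged["sharing"].value_counts().to_dict()
    for k in ("pre_only", "shared", "post_only"):
        venn.setdefault(k, 0)
    return merged, venn


def estimate_multiplicity(vaf, rho: float, n_total) -> np.ndarray:
    """Invert the VAF relation: m = vaf * (rho * n_total + 2 (1 - rho)) / rho."""
    if np.any(rho <= 0) or np.any(rho > 1):
        raise ValueError("cellularity must lie in (0, 1]")
    vaf = np.asarray(vaf, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    return vaf * (rho * n_total + 2.0 * (1.0 - rho)) / rho


def classify_timing(
    alt, dp, state: tuple[int, int], rho: float, lr_min: float = 10.0
) -> np.ndarray:
    """Early/late classification for SNVs in one copy-number state.

    Candidate multiplicities are {1, n_a} (and n_b when n_b >= 2).  The
    binomial likelihood of the alt count is computed at each candidate's
    expected VAF; the maximum-likelihood candidate wins when its
    likelihood ratio over the runner-up reaches ``lr_min``, giving
    ``late`` for multiplicity 1 and ``early`` for multiplicity >= 2.
    States outside the eligible set are ``unclassified``.
    """
    alt = np.atleast_1d(np.asarray(alt))
    dp = np.atleast_1d(np.asarray(dp))
    out = np.full(len(alt), "unclassified", dtype=object)
    if tuple(state) not in ELIGIBLE_STATES:
        return out
    n_a, n_b = state
    candidates = sorted({1, n_a} | ({n_b} if n_b >= 2 else set()))
    if len(candidates) < 2:
        return out
    denom = rho * (n_a + n_b) + 2.0 * (1.0 - rho)
    ps = np.clip([rho * m / denom for m in candidates], 1e-9, 1.0 - 1e-9)
    ok = dp > 0
    ll = np.full((len(alt), len(candidates)), -np.inf)
    ll[ok] = binom.logpmf(alt[ok, None], dp[ok, None], ps[None, :])
    order = np.argsort(ll, axis=1)
    best = order[:, -1]
    second = order[:, -2]
    lr_ok = (
        ll[np.arange(len(alt)), best] - ll[np.arange(len(alt)), second]
    ) >= np.log(lr_min)
    m_best = np.asarray(candidates)[best]
    out[ok & lr_ok & (m_best == 1)] = "late"
    out[ok & lr_ok & (m_best >= 2)] = "early"
    return out


def annotate_snvs(
    snvs: pd.DataFrame,
    calls: list,
    models: dict,
    lr_min: float = 10.0,
) -> pd.DataFrame:
    """Map SNVs onto assigned segments and time them per sample.

    ``snvs`` needs chrom, pos, ref, alt, and per-sample alt_{s}/dp_{s}
    plus called_{s} flags.  SNVs falling in unassigned or subclonal
    segments are excluded from timing (kept, flagged ``unclassified``).
    Adds per-sample state, VAF, real and rounded multiplicity, timing,
    and the combined sharing/timing columns.
    """
    df = snvs.copy().reset_index(drop=True)
    n = len(df)
    seg_idx = np.full(n, -1)
    by_chrom: dict[str, list] = {}
    for i, call in enumerate(calls):
        by_chrom.setdefault(call.segment.chrom, []).append((call.segment.start, call.segment.end, i))
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items])
        ends = np.array([e for _, e, _ in items])
        idxs = np.array([i for _, _, i in items])
        m = (df["chrom"] == chrom).to_numpy()
        pos0 = df.loc[m, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        valid = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
        tgt = np.full(m.sum(), -1)
        tgt[valid] = idxs[j[valid]]
        seg_idx[m] = tgt
    df["segment_index"] = seg_idx

    df["sharing"] = np.select(
        [df["called_pre"] & df["called_post"], df["called_pre"]],
        ["shared", "pre_only"],
        default="post_only",
    )

    for s in SAMPLES:
        rho = models[s].rho
        dp = df[f"dp_{s}"].to_numpy().astype(float)
        alt = df[f"alt_{s}"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(dp > 0, alt / np.maximum(dp, 1.0), np.nan)
        df[f"vaf_{s}"] = vaf
        states = np.full((n, 2), -1)
        clonal = np.zeros(n, dtype=bool)
        for i in range(n):
            si = seg_idx[i]
            if si < 0:
                continue
            sub = getattr(calls[si], s)
            if sub is None:
                continue
            states[i] = sub.state
            clonal[i] = sub.is_clonal
        df[f"n_a_{s}"] = states[:, 0]
        df[f"n_b_{s}"] = states[:, 1]
        tot = states.sum(axis=1).astype(float)
        mult = np.full(n, np.nan)
        okm = (tot > 0) & ~np.isnan(vaf)
        mult[okm] = estimate_multiplicity(vaf[okm], rho, tot[okm])
        df[f"multiplicity_{s}"] = mult
        df[f"multiplicity_int_{s}"] = np.where(
            np.isnan(mult), -1, np.maximum(np.round(mult), 1)
        ).astype(int)
        timing = np.full(n, "unclassified", dtype=object)
        called = df[f"called_{s}"].to_numpy()
        for st in set(map(tuple, states[clonal & called & (states[:, 0] >= 0)])):
            rows = clonal & called & (states[:, 0] == st[0]) & (states[:, 1] == st[1])
            timing[rows] = classify_timing(
                alt[rows], dp[rows].astype(int), st, rho, lr_min=lr_min
            )
        df[f"timing_{s}"] = timing

    # combined timing: carrier samples must agree (non-carrier ignored)
    def combine(row):
        votes = {
            row[f"timing_{s}"]
            for s in SAMPLES
            if row[f"called_{s}"] and row[f"timing_{s}"] != "unclassified"
        }
        if len(votes) == 1:
            return votes.pop()
        return "unclassified"

    df["timing"] = [combine(r) for _, r in df.iterrows()]
    return df


@dataclass
class DivergenceReport:
    verdict: str
    f_private_early: float
    f_shared_late: float
    n_informative: int
    shared_fraction: float
    recent_divergence: bool
    shared_antecedent: bool


def infer_divergence_timing(
    timed: pd.DataFrame,
    shared_antecedent: bool = False,
    eps: float = 0.02,
    min_informative: int = 100,
    recent_threshold: float = 0.9,
    alpha: float = 0.05,
) -> DivergenceReport:
    """Date the divergence of the two samples relative to the genome
    doubling from the timing of private vs shared SNVs in duplicated
    (major allele >= 2 copies), timing-eligible regions.

    f1 = fraction of classified lineage-private SNVs that are early;
    f2 = fraction of classified shared SNVs that are late.  ``eps`` is
    the residual misclassification rate attributed to caller noise;
    "f exceeds eps" is decided by a one-sided binomial test at level
    ``alpha`` against rate eps, so the verdict accounts for the sampling
    error of the fraction rather than comparing a point estimate to a
    hard cutoff.  Neither excess: divergence near-synchronous with
    endoreduplication.  f1 in excess: diversity predates the copy-number
    change.  f2 in excess (f1 not): the copy-number change predates
    diversity.  A shared fraction of all SNVs >= ``recent_threshold`` is
    additionally reported as recent divergence.
    """
    shared_fraction = float((timed["sharing"] == "shared").mean()) if len(timed) else 0.0

    def informative(sample, rows):
        dup = timed[f"n_a_{sample}"] >= 2
        classified = timed[f"timing_{sample}"] != "unclassified"
        return rows & dup & classified

    priv_early = priv_all = 0
    for s, label in (("pre", "pre_only"), ("post", "post_only")):
        rows = informative(s, timed["sharing"] == label)
        priv_all += int(rows.sum())
        priv_early += int((timed.loc[rows, f"timing_{s}"] == "early").sum())
    shared_rows = informative("pre", timed["sharing"] == "shared") | informative(
        "post", timed["sharing"] == "shared"
    )
    shared_rows &= timed["timing"] != "unclassified"
    shared_all = int(shared_rows.sum())
    shared_late = int((timed.loc[shared_rows, "timing"] == "late").sum())

    n_informative = priv_all + shared_all
    f1 = priv_early / priv_all if priv_all else 0.0
    f2 = shared_late / shared_all if shared_all else 0.0

    from scipy.stats import binom as _binom

    def exceeds(k, n):
        # one-sided: is the observed rate inconsistent with noise rate eps?
        return n > 0 and float(_binom.sf(k - 1, n, eps)) < alpha

    if n_informative < min_informative:
        verdict = "undetermined"
    elif exceeds(priv_early, priv_all):
        verdict = "diversity predates copy-number change"
    elif exceeds(shared_late, shared_all):
        verdict = "copy-number change predates diversity"
    else:
        verdict = "divergence near-synchronous with endoreduplication"

    return DivergenceReport(
        verdict=verdict,
        f_private_early=f1,
        f_shared_late=f2,
        n_informative=n_informative,
        shared_fraction=shared_fraction,
        recent_divergence=shared_fraction >= recent_threshold,
        shared_antecedent=shared_antecedent,
    )
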