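"""Allele-specific state assignment and paired-sample copy-number logic.

Segments are assigned to the clonal state lattice of a fitted sample model,
or to two-state subclonal mixtures when their means fall between centers.
Paired calls are then checked for allele consistency (is the same germline
allele amplified/lost in both samples?), summarised into genome-fraction
metrics, and screened for LOH incompatibility: a region that has lost
heterozygosity in one sample but retains it in the other cannot have been
inherited by the second sample from the first, because LOH is
irreversible.  Regions where the pre-chemotherapy sample shows LOH while
the post-chemotherapy sample retains heterozygosity therefore imply that
the two samples descend from a shared antecedent rather than one from the
other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from chemopair.purity_ploidy import (
    SampleModel,
    StateCenter,
    expected_baf,
    expected_depth,
    predict_cluster_centers,
    _robust_scale,
    _segment_arrays,
)
from chemopair.segmentation import SAMPLES, Segment
from chemopair.states import state_to_string


@dataclass
class SampleStateCall:
    """One sample's assignment for one segment.

    ``state`` is (n_major, n_minor); ``major_is_a`` anchors the major
    allele to germline allele 'a' from the segment's unfolded BAF.
    """

    state: tuple[int, int]
    clonal_fraction: float
    alt_state: tuple[int, int] | None
    residual: float
    major_is_a: bool

    @property
    def anchored(self) -> tuple[int, int]:
        """(copies of germline allele a, copies of germline allele b)."""
        n_maj, n_min = self.state
        return (n_maj, n_min) if self.major_is_a else (n_min, n_maj)

    @property
    def total(self) -> int:
        return self.state[0] + self.state[1]

    @property
    def is_clonal(self) -> bool:
        return self.alt_state is None

    def __str__(self):
        s = state_to_string(self.state)
        if self.alt_state is not None:
            s += f"/{state_to_string(self.alt_state)}@{self.clonal_fraction:.2f}"
        return s


@dataclass
class StateCall:
    segment: Segment
    pre: SampleStateCall | None
    post: SampleStateCall | None
    flags: list[str] = field(default_factory=list)

    @property
    def state_pre(self):
        return self.pre.anchored if self.pre is not None else None

    @property
    def state_post(self):
        return self.post.anchored if self.post is not None else None

    @property
    def assigned(self) -> bool:
        return self.pre is not None and self.post is not None

    @property
    def span(self) -> int:
        return self.segment.end - self.segment.start


@dataclass
class GenomeMetrics:
    """Genome-fraction summaries for one sample (bp-weighted over assigned
    segments).  Amplified: total copy number / ploidy > 2; deleted:
    ratio < 0.5 (strict, a single-copy loss at ploidy 2 does not count);
    LOH: minor copy number zero."""

    average_ploidy: float
    fraction_amplified: float
    fraction_deleted: float
    fraction_loh: float
    fraction_same_state: float


def _adjacent_pairs(max_cn: int):
    from chemopair.states import enumerate_states

    states = enumerate_states(max_cn, include_null=True)
    sset = set(states)
    pairs = []
    for n_a, n_b in states:
        for da, db in ((1, 0), (0, 1)):
            other = (n_a + da, n_b + db)
            other = (max(other), min(other))
            if other in sset and other != (n_a, n_b):
                pairs.append(((n_a, n_b), other))
    return pairs


def _mixture_point(s1, s2, phi, rho, d):
    """Expected (depth, mirrored BAF) of a tumor in which a fraction
    ``phi`` of tumor cells carry s2 and the rest s1."""
    t = (1 - phi) * sum(s1) + phi * sum(s2)
    nb = (1 - phi) * s1[1] + phi * s2[1]
    denom = rho * t + 2.0 * (1.0 - rho)
    return d * denom, (rho * nb + (1.0 - rho)) / denom


def assign_states(
    segments: list[Segment],
    models: dict[str, SampleModel],
    mixture_margin: float = 0.25,
    min_assign_loci: int = 5,
    phi_step: float = 0.01,
) -> list[StateCall]:
    """Assign each segment, per sample, to a clonal state or a two-state
    mixture of states adjacent by one copy step.

    A segment is clonal when its scaled distance to the nearest center is
    within ``mixture_margin`` of that center's distance to its closest
    neighboring center; otherwise the best mixture along the curve between
    adjacent centers is fitted, with the mixing fraction solved on a
    ``phi_step`` grid of tumor-cell fractions.  Segments with fewer than
    ``min_assign_loci`` loci are left unassigned.
    """
    segments = list(segments)
    calls = [StateCall(segment=s, pre=None, post=None) for s in segments]
    for sample in SAMPLES:
        model = models[sample]
        rho, d = model.rho, model.haploid_depth
        centers = predict_cluster_centers(model)
        c_depth = np.array([c.depth for c in centers])
        c_baf = np.array([c.baf for c in centers])
        depth, baf, _ = _segment_arrays(segments, sample)
        s_d = _robust_scale(depth, 0.02 * max(np.median(depth), 1e-9))
        s_b = _robust_scale(baf, 0.02)
        # distance from each center to its nearest other center
        cd = np.sqrt(
            ((c_depth[:, None] - c_depth[None, :]) / s_d) ** 2
            + ((c_baf[:, None] - c_baf[None, :]) / s_b) ** 2
        )
        np.fill_diagonal(cd, np.inf)
        nn_dist = cd.min(axis=1)
        pairs = _adjacent_pairs(model.max_cn)
        phis = np.arange(0.0, 1.0 + 1e-9, phi_step)

        for call, x_d, x_b in zip(calls, depth, baf):
            seg = call.segment
            if seg.n_loci < min_assign_loci:
                call.flags.append(f"too_few_loci_{sample}")
                continue
            r = np.sqrt(((x_d - c_depth) / s_d) ** 2 + ((x_b - c_baf) / s_b) ** 2)
            j = int(r.argmin())
            major_is_a = seg.ubaf[sample] >= 0.5
            if r[j] <= mixture_margin * nn_dist[j]:
                sub = SampleStateCall(
                    state=centers[j].state, clonal_fraction=1.0,
                    alt_state=None, residual=float(r[j]), major_is_a=major_is_a,
                )
            else:
                best = (np.inf, None, None, None)
                for s1, s2 in pairs:
                    e_d, e_b = _mixture_point(
                        np.array(s1), np.array(s2), phis, rho, d
                    )
                    rr = np.sqrt(((x_d - e_d) / s_d) ** 2 + ((x_b - e_b) / s_b) ** 2)
                    k = int(rr.argmin())
                    if rr[k] < best[0]:
                        best = (float(rr[k]), s1, s2, float(phis[k]))
                res, s1, s2, phi = best
                if phi >= 0.5:
                    s1, s2, phi = s2, s1, 1.0 - phi
                if phi <= phi_step / 2 or res >= r[j]:
                    # mixture adds nothing: fall back to nearest clonal state
                    sub = SampleStateCall(
                        state=centers[j].state, clonal_fraction=1.0,
                        alt_state=None, residual=float(r[j]),
                        major_is_a=major_is_a,
                    )
                else:
                    sub = SampleStateCall(
                        state=s1, clonal_fraction=1.0 - phi, alt_state=s2,
                        residual=res, major_is_a=major_is_a,
                    )
                    call.flags.append(f"subclonal_{sample}")
            setattr(call, sample, sub)
    return calls


def check_allele_consistency(calls: list[StateCall]) -> list[StateCall]:
    """Verify that the same germline allele is the major allele in both
    samples on each unbalanced segment.

    Each sample's anchoring is already determined from its own per-locus
    unfolded allele fractions (the per-locus evidence), so a disagreement
    is preserved as a genuinely mirrored event and flagged rather than
    overwritten.  Balanced segments carry no major allele and are skipped.
    """
    for call in calls:
        if not call.assigned:
            continue
        if call.pre.state[0] == call.pre.state[1]:
            continue
        if call.post.state[0] == call.post.state[1]:
            continue
        if call.pre.major_is_a != call.post.major_is_a:
            call.flags.append("mirrored_major_allele")
    return calls


def genome_metrics(
    calls: list[StateCall], deleted_inclusive: bool = False
) -> dict:
    """Per-sample genome-fraction metrics plus the paired same-state
    fraction, bp-weighted over assigned segments."""
    out = {}
    assigned = [c for c in calls if c.assigned]
    spans = np.array([c.span for c in assigned], dtype=float)
    total_span = spans.sum()
    same = np.array(
        [c.state_pre == c.state_post for c in assigned], dtype=float
    )
    frac_same = float((same * spans).sum() / total_span) if total_span else 0.0
    for sample in SAMPLES:
        tot = np.array(
            [getattr(c, sample).total for c in assigned], dtype=float
        )
        minor = np.array(
            [getattr(c, sample).state[1] for c in assigned], dtype=float
        )
        if total_span == 0:
            out[sample] = GenomeMetrics(0.0, 0.0, 0.0, 0.0, frac_same)
            continue
        ploidy = float((tot * spans).sum() / total_span)
        ratio = tot / ploidy if ploidy > 0 else tot * 0.0
        deleted = ratio <= 0.5 if deleted_inclusive else ratio < 0.5
        out[sample] = GenomeMetrics(
            average_ploidy=ploidy,
            fraction_amplified=float(((ratio > 2.0) * spans).sum() / total_span),
            fraction_deleted=float((deleted * spans).sum() / total_span),
            fraction_loh=float(((minor == 0) * spans).sum() / total_span),
            fraction_same_state=frac_same,
        )
    return out


@dataclass
class LohIncompatibility:
    pre_loh_post_het: list[StateCall]
    post_loh_pre_het: list[StateCall]
    span_pre_loh_post_het: int
    span_post_loh_pre_het: int
    shared_antecedent: bool


def detect_loh_incompatibility(
    calls: list[StateCall], min_span: int = 1_000_000
) -> LohIncompatibility:
    """Screen paired calls for regions of one-sided LOH.

    Returns the segments where the pre sample has lost heterozygosity
    (minor copy number zero) while the post sample retains it, and vice
    versa.  ``shared_antecedent`` is true when pre-LOH/post-het regions
    exceed ``min_span`` in aggregate (the post sample cannot then have
    evolved from the pre sample) or when both directions exceed it.
    Regions where both samples show LOH of *different* germline alleles
    count in both directions.
    """
    pre_dir, post_dir = [], []
    for call in calls:
        if not call.assigned:
            continue
        pre_loh = call.pre.state[1] == 0 and call.pre.total > 0
        post_loh = call.post.state[1] == 0 and call.post.total > 0
        if pre_loh and post_loh:
            a_pre, b_pre = call.state_pre
            a_post, b_post = call.state_post
            if (a_pre == 0) != (a_post == 0):  # different allele lost
                call.flags.append("discordant_loh_allele")
                pre_dir.append(call)
                post_dir.append(call)
        elif pre_loh and not post_loh:
            pre_dir.append(call)
        elif post_loh and not pre_loh:
            post_dir.append(call)
    span_pre = sum(c.span for c in pre_dir)
    span_post = sum(c.span for c in post_dir)
    # pre-LOH/post-het alone rules out post descending from pre; the
    # both-directions case is then implied, so the pre-direction span is
    # the operative criterion
    shared = span_pre >= min_span
    return LohIncompatibility(
        pre_loh_post_het=pre_dir,
        post_loh_pre_het=post_dir,
        span_pre_loh_post_het=span_pre,
        span_post_loh_pre_het=span_post,
        shared_antecedent=shared,
    )


@dataclass
class Scenario:
    """A candidate copy-number history predicting a set of VAF cluster
    centers for the SNVs inside a segment."""

    name: str
    centers: tuple[float, ...]


def scenario_from_state(
    name: str, state: tuple[int, int], rho: float,
    multiplicities: tuple[int, ...] | None = None,
    subclonal_fraction: float | None = None,
) -> Scenario:
    """Predicted VAF centers for SNVs at the given multiplicities in a
    clonal state (or, with ``subclonal_fraction``, an SNV cluster confined
    to that fraction of tumor cells at multiplicity 1)."""
    n_tot = sum(state)
    denom = rho * n_tot + 2.0 * (1.0 - rho)
    if multiplicities is None:
        multiplicities = tuple(sorted({1, state[0]} | ({state[1]} if state[1] >= 2 else set())))
    centers = [rho * m / denom for m in multiplicities]
    if subclonal_fraction is not None:
        centers.append(rho * subclonal_fraction / denom)
    return Scenario(name=name, centers=tuple(sorted(set(round(c, 10) for c in centers))))


def _mixture_loglik(alt, dp, centers, n_iter: int = 200, tol: float = 1e-8):
    """Binomial finite-mixture log-likelihood at fixed component centers,
    mixture weights fitted by EM."""
    from scipy.stats import binom

    alt = np.asarray(alt)
    dp = np.asarray(dp)
    p = np.clip(np.asarray(centers, dtype=float), 1e-6, 1.0 - 1e-6)
    logpmf = binom.logpmf(alt[:, None], dp[:, None], p[None, :])
    k = len(p)
    w = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    for _ in range(n_iter):
        lw = logpmf + np.log(w)
        m = lw.max(axis=1, keepdims=True)
        post = np.exp(lw - m)
        norm = post.sum(axis=1, keepdims=True)
        ll = float((m.ravel() + np.log(norm.ravel())).sum())
        post /= norm
        w = post.mean(axis=0)
        w = np.maximum(w, 1e-12)
        w /= w.sum()
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return ll, w


def disambiguate_subclonal_history(
    alt, dp, scenarios: list[Scenario], min_snvs: int = 20
) -> dict:
    """Choose among competing copy-number histories for a segment using
    the clustering of its SNV allele fractions.

    Each scenario predicts a set of VAF cluster centers; a binomial
    mixture with free weights is fitted at each center set and scenarios
    are compared by BIC (complexity penalised by the number of centers).
    Scenarios with identical predicted centers, or too few SNVs, return
    "undetermined".  The number of clusters actually populated (weight
    >= 5%) is reported against the number each scenario expects —
    e.g. a missing fourth cluster is what distinguishes a subclonal loss
    from a previously clonal state from a clonal state plus later gain.
    """
    alt = np.asarray(alt)
    dp = np.asarray(dp)
    n = len(alt)
    result = {"chosen": "undetermined", "scores": {}, "weights": {}, "n_snvs": n}
    if n < min_snvs:
        result["reason"] = "too_few_snvs"
        return result
    center_sets = {s.name: s.centers for s in scenarios}
    if len(set(center_sets.values())) < len(scenarios):
        result["reason"] = "identical_predictions"
        return result
    bics = {}
    for s in scenarios:
        ll, w = _mixture_loglik(alt, dp, s.centers)
        k = len(s.centers)
        bics[s.name] = -2.0 * ll + (k - 1) * np.log(n)
        result["weights"][s.name] = w
        result["scores"][s.name] = bics[s.name]
    ranked = sorted(bics.items(), key=lambda kv: kv[1])
    if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-9:
        result["reason"] = "tie"
        return result
    result["chosen"] = ranked[0][0]
    chosen = next(s for s in scenarios if s.name == result["chosen"])
    w = result["weights"][result["chosen"]]
    result["expected_clusters"] = len(chosen.centers)
    result["observed_clusters"] = int((w >= 0.05).sum())
    return result
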