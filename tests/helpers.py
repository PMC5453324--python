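"""Shared test utilities: truth-derived (noiseless) objects and oracles."""

from __future__ import annotations

import numpy as np

from chemopair.cn_states import SampleStateCall, StateCall
from chemopair.purity_ploidy import SampleModel, expected_baf, expected_depth
from chemopair.segmentation import Segment


def truth_state_calls(truth) -> list[StateCall]:
    """Noiseless paired state calls built directly from generator truth."""
    calls = []
    locus = 0
    for _, row in truth.truth_segments.iterrows():
        n_loci = max(int((row["end"] - row["start"]) // 1500), 1)
        seg = Segment(
            chrom=row["chrom"],
            start_locus=locus,
            end_locus=locus + n_loci,
            start=int(row["start"]),
            end=int(row["end"]),
            n_loci=n_loci,
            depth={s: float("nan") for s in ("pre", "post")},
            baf={s: float("nan") for s in ("pre", "post")},
            ubaf={s: float("nan") for s in ("pre", "post")},
        )
        locus += n_loci
        subs = {}
        for s in ("pre", "post"):
            n_a, n_b = int(row[f"nA_{s}"]), int(row[f"nB_{s}"])
            subs[s] = SampleStateCall(
                state=(max(n_a, n_b), min(n_a, n_b)),
                clonal_fraction=1.0,
                alt_state=None,
                residual=0.0,
                major_is_a=n_a >= n_b,
            )
        calls.append(StateCall(segment=seg, pre=subs["pre"], post=subs["post"]))
    return calls


def lattice_segments(states, model: SampleModel, n_loci=200, span=1_000_000,
                     rng=None, depth_sd=0.0, baf_sd=0.0) -> list[Segment]:
    """Segments placed exactly at (or jittered around) the cluster centers
    of ``model`` for the given states, mirrored for both samples."""
    rng = rng or np.random.default_rng(0)
    segs = []
    for i, (n_a, n_b) in enumerate(states):
        dep = expected_depth(n_a, n_b, model.rho, model.haploid_depth)
        baf = expected_baf(n_a, n_b, model.rho)
        dep += rng.normal(0.0, depth_sd) if depth_sd else 0.0
        baf = float(np.clip(baf + (rng.normal(0.0, baf_sd) if baf_sd else 0.0), 0, 0.5))
        segs.append(
            Segment(
                chrom="chr1", start_locus=i * n_loci, end_locus=(i + 1) * n_loci,
                start=i * span, end=(i + 1) * span, n_loci=n_loci,
                depth={"pre": dep, "post": dep},
                baf={"pre": baf, "post": baf},
                ubaf={"pre": 1.0 - baf, "post": 1.0 - baf},
            )
        )
    return segs


def running_median_oracle(values, window: int) -> np.ndarray:
    """Brute-force running median with shrinking edge windows."""
    x = np.asarray(values, dtype=float)
    half = window // 2
    return np.array(
        [np.median(x[max(0, i - half) : i + half + 1]) for i in range(len(x))]
    )


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by enumeration over the hypergeometric support
    (minimum-likelihood method)."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def simplex_grid_qp_oracle(catalog, P, step=0.001):
    """Dense grid search over the weight simplex minimising ||P w - c||;
    independent oracle for the NNLS-based deconstruction (K <= 3)."""
    c = np.asarray(catalog, dtype=float)
    c = c / c.sum()
    P = np.asarray(P, dtype=float)
    k = P.shape[1]
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        W = np.vstack([ticks, 1.0 - ticks])
    elif k == 3:
        w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
        keep = (w1 + w2) <= 1.0 + 1e-12
        W = np.vstack([w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]])
    else:
        raise ValueError("oracle supports K in {2, 3}")
    best_w, best_score = None, np.inf
    for start in range(0, W.shape[1], 50_000):
        chunk = W[:, start : start + 50_000]
        resid = P @ chunk - c[:, None]
        scores = np.einsum("ij,ij->j", resid, resid)
        j = int(scores.argmin())
        if scores[j] < best_score:
            best_score = float(scores[j])
            best_w = chunk[:, j].copy()
    return best_w, best_score
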