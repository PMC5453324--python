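"""Joint segmentation of depth and allele-fraction tracks for a sample pair.

A single segmentation is produced per patient by recursive binary
splitting.  At each candidate breakpoint a sliding-window one-way ANOVA F
statistic compares the means immediately left and right of the candidate,
on each of four channels (normalised depth and mirrored BAF for each tumor
sample, z-scored per chromosome so depth and BAF contribute comparably).
The candidate maximising the largest channel F is accepted when that F
exceeds the threshold, and the two halves are split recursively.  A
breakpoint supported by either sample therefore splits both.  The defaults
deliberately err on the side of oversegmentation; downstream state
assignment and merging absorb spurious breakpoints at little cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DEFAULT_F_THRESHOLD = 25.0
DEFAULT_WINDOW = 200
DEFAULT_MIN_SEG_LOCI = 20


@dataclass
class Segment:
    """A run of retained loci with per-sample summary statistics.

    ``start``/``end`` are 0-based half-open base-pair bounds;
    ``start_locus``/``end_locus`` index into the per-chromosome locus
    arrays.  ``depth`` is the germline-normalised tumor depth (reads, on
    the scale where a diploid region in a pure diploid tumor averages the
    germline mean depth).  ``ubaf`` is the mean unfolded fraction of reads
    carrying germline allele 'a'; ``baf`` is its fold into [0, 0.5].
    """

    chrom: str
    start_locus: int
    end_locus: int
    start: int
    end: int
    n_loci: int
    depth: dict
    baf: dict
    ubaf: dict


SAMPLES = ("pre", "post")


def build_tracks(loci: pd.DataFrame, smooth_window: int = 51) -> pd.DataFrame:
    """Per-locus channels for segmentation from a selected het-locus table.

    Tumor depth is normalised by the locus germline depth and rescaled to
    the median germline depth, removing locus-specific accessibility
    effects.  Mirrored BAF is folded per locus and the smoothed fold is
    used only for breakpoint detection; raw unfolded fractions are kept
    for segment means and allele anchoring.
    """
    from chemopair.het_loci import smooth_tracks

    out = {"chrom": loci["chrom"].to_numpy(), "pos": loci["pos"].to_numpy()}
    gdepth = loci["germline_depth"].to_numpy().astype(float)
    med_g = np.median(gdepth)
    # normalise against the *smoothed* germline depth: dividing by the raw
    # per-locus count would add 1/g noise and an upward E[1/g] bias
    g_smooth = np.empty(len(loci))
    for _, idx in loci.groupby("chrom", sort=False).indices.items():
        g_smooth[idx] = smooth_tracks(gdepth[idx], smooth_window)
    for s in SAMPLES:
        tdepth = loci[f"tumor_{s}_depth"].to_numpy().astype(float)
        talt = loci[f"tumor_{s}_alt"].to_numpy().astype(float)
        norm = tdepth / np.maximum(g_smooth, 1.0) * med_g
        with np.errstate(invalid="ignore", divide="ignore"):
            ubaf = np.where(tdepth > 0, 1.0 - talt / np.maximum(tdepth, 1.0), np.nan)
        ubaf = np.nan_to_num(ubaf, nan=0.5)
        out[f"depth_{s}"] = norm
        out[f"ubaf_{s}"] = ubaf
    df = pd.DataFrame(out)
    for s in SAMPLES:
        sm_d = np.empty(len(df))
        sm_b = np.empty(len(df))
        folded = np.minimum(df[f"ubaf_{s}"], 1.0 - df[f"ubaf_{s}"])
        for _, idx in df.groupby("chrom", sort=False).indices.items():
            sm_d[idx] = smooth_tracks(df[f"depth_{s}"].to_numpy()[idx], smooth_window)
            sm_b[idx] = smooth_tracks(folded.to_numpy()[idx], smooth_window)
        df[f"sm_depth_{s}"] = sm_d
        df[f"sm_baf_{s}"] = sm_b
    return df


def _window_f(x: np.ndarray, lo: int, hi: int, window: int, min_seg: int):
    """Windowed two-group F statistics for all candidate cuts in [lo+min_seg,
    hi-min_seg) of one channel.  Returns (candidates, F)."""
    ks = np.arange(lo + min_seg, hi - min_seg + 1)
    if len(ks) == 0:
        return ks, np.zeros(0)
    half = window // 2
    l0 = np.maximum(lo, ks - half)
    r1 = np.minimum(hi, ks + half)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n1 = (ks - l0).astype(float)
    n2 = (r1 - ks).astype(float)
    s1 = c1[ks] - c1[l0]
    s2 = c1[r1] - c1[ks]
    q1 = c2[ks] - c2[l0]
    q2 = c2[r1] - c2[ks]
    m1 = s1 / n1
    m2 = s2 / n2
    ssw = (q1 - s1 * m1) + (q2 - s2 * m2)
    dof = n1 + n2 - 2.0
    ssb = n1 * n2 / (n1 + n2) * (m1 - m2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ssb > 0, ssb * dof / np.maximum(ssw, 1e-12), 0.0)
    return ks, f


def segment_track(
    channels: np.ndarray,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    min_seg_loci: int = DEFAULT_MIN_SEG_LOCI,
) -> list[int]:
    """Breakpoints (locus indices) for an (n_loci, n_channels) array on one
    chromosome, by greedy recursive binary splitting."""
    X = np.asarray(channels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_seg_loci:
            continue
        best_f, best_k = -1.0, None
        for ch in range(X.shape[1]):
            ks, f = _window_f(X[:, ch], lo, hi, window, min_seg_loci)
            if len(f) and f.max() > best_f:
                best_f = float(f.max())
                best_k = int(ks[int(np.argmax(f))])
        if best_k is not None and best_f > f_threshold:
            breaks.append(best_k)
            stack.append((lo, best_k))
            stack.append((best_k, hi))
    return sorted(breaks)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def segment_joint(
    tracks: pd.DataFrame,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    min_seg_loci: int = DEFAULT_MIN_SEG_LOCI,
) -> list[Segment]:
    """Segment the four smoothed channels jointly; one breakpoint set per
    chromosome is applied to both samples.  Chromosomes with fewer than
    ``2 * min_seg_loci`` loci yield a single segment."""
    segments: list[Segment] = []
    for chrom, idx in tracks.groupby("chrom", sort=False).indices.items():
        sub = tracks.iloc[idx]
        X = np.column_stack(
            [_zscore(sub[f"sm_{kind}_{s}"].to_numpy())
             for s in SAMPLES for kind in ("depth", "baf")]
        )
        breaks = segment_track(
            X, f_threshold=f_threshold, window=window, min_seg_loci=min_seg_loci
        )
        bounds = [0] + breaks + [len(sub)]
        pos = sub["pos"].to_numpy()
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            depth, baf, ubaf = {}, {}, {}
            for s in SAMPLES:
                depth[s] = float(sub[f"depth_{s}"].to_numpy()[lo:hi].mean())
                u = float(sub[f"ubaf_{s}"].to_numpy()[lo:hi].mean())
                ubaf[s] = u
                baf[s] = min(u, 1.0 - u)
            segments.append(
                Segment(
                    chrom=chrom,
                    start_locus=lo,
                    end_locus=hi,
                    start=int(pos[lo]) - 1,
                    end=int(pos[hi - 1]),
                    n_loci=hi - lo,
                    depth=depth,
                    baf=baf,
                    ubaf=ubaf,
                )
            )
    return segments


def merge_segments(state_calls: list) -> list:
    """Merge maximal runs of adjacent segments assigned the same
    allele-anchored state pair in both samples.

    Accepts ``cn_states.StateCall`` objects (or anything with ``segment``,
    ``state_pre``, ``state_post`` attributes); means are recomputed as
    locus-weighted averages.  Raises on unannotated calls.
    """
    from dataclasses import replace as dc_replace

    merged: list = []
    for call in state_calls:
        if call.state_pre is None or call.state_post is None:
            raise ValueError("merge_segments requires state-annotated segments")
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.segment.chrom == call.segment.chrom
            and prev.segment.end_locus == call.segment.start_locus
            and prev.state_pre == call.state_pre
            and prev.state_post == call.state_post
        ):
            a, b = prev.segment, call.segment
            w1, w2 = a.n_loci, b.n_loci
            depth, baf, ubaf = {}, {}, {}
            for s in SAMPLES:
                depth[s] = (a.depth[s] * w1 + b.depth[s] * w2) / (w1 + w2)
                u = (a.ubaf[s] * w1 + b.ubaf[s] * w2) / (w1 + w2)
                ubaf[s] = u
                baf[s] = min(u, 1.0 - u)
            seg = Segment(
                chrom=a.chrom,
                start_locus=a.start_locus,
                end_locus=b.end_locus,
                start=a.start,
                end=b.end,
                n_loci=w1 + w2,
                depth=depth,
                baf=baf,
                ubaf=ubaf,
            )
            merged[-1] = dc_replace(prev, segment=seg)
        else:
            merged.append(call)
    return merged


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    rows = []
    for seg in segments:
        row = {
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "n_loci": seg.n_loci,
        }
        for s in SAMPLES:
            row[f"depth_{s}"] = seg.depth[s]
            row[f"baf_{s}"] = seg.baf[s]
            row[f"ubaf_{s}"] = seg.ubaf[s]
        rows.append(row)
    return pd.DataFrame(rows)
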