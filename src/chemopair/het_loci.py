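"""Germline-heterozygous locus selection and track smoothing.

Candidate sites are filtered to confidently heterozygous, well-behaved
autosomal loci: germline coverage between 16 and 90 reads, at least four
reads for each allele, per-site strand bias (fraction of forward-strand
reads) between 0.1 and 0.9, and exclusion of regions of apparent germline
copy-number variation found by segmenting the germline depth track.
Depth and allele-fraction tracks are then smoothed with a running median
before segmentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chemopair.segmentation import segment_track

DEFAULTS = {
    "min_depth": 16,
    "max_depth": 90,
    "min_allele_reads": 4,
    "strand_bias_lo": 0.1,
    "strand_bias_hi": 0.9,
}


def select_het_loci(
    candidates: pd.DataFrame,
    min_depth: int = 16,
    max_depth: int = 90,
    min_allele_reads: int = 4,
    strand_bias_lo: float = 0.1,
    strand_bias_hi: float = 0.9,
    mask_intervals: pd.DataFrame | None = None,
    gatk_prefilter: bool = False,
) -> pd.DataFrame:
    """Filter candidate loci to the retained germline-heterozygous set.

    All bounds are inclusive.  ``mask_intervals`` is an optional BED-like
    frame (chrom, start, end; 0-based half-open) of germline-CNV regions to
    exclude.  ``gatk_prefilter`` additionally requires depth >= 21,
    the stricter intersection with an upstream caller's low-coverage
    filter; off by default.
    """
    if candidates.empty:
        return candidates.copy()
    df = candidates
    depth = df["germline_depth"].to_numpy()
    alt = df["germline_alt"].to_numpy()
    ref = depth - alt
    fwd = df["strand_fwd"].to_numpy()
    rev = df["strand_rev"].to_numpy()
    total = fwd + rev
    with np.errstate(invalid="ignore", divide="ignore"):
        sb = np.where(total > 0, fwd / np.maximum(total, 1), np.nan)
    lo = max(min_depth, 21) if gatk_prefilter else min_depth
    keep = (
        (depth >= lo)
        & (depth <= max_depth)
        & (np.minimum(alt, ref) >= min_allele_reads)
        & (sb >= strand_bias_lo)
        & (sb <= strand_bias_hi)
    )
    out = df[keep]
    if mask_intervals is not None and len(mask_intervals):
        drop = np.zeros(len(out), dtype=bool)
        pos0 = out["pos"].to_numpy() - 1  # to 0-based
        for chrom, start, end in zip(
            mask_intervals["chrom"], mask_intervals["start"], mask_intervals["end"]
        ):
            drop |= (out["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
        out = out[~drop]
    return out.reset_index(drop=True)


def smooth_tracks(values, window: int = 51) -> np.ndarray:
    """Running median with shrinking windows at the edges.

    ``window`` must be odd; window 1 is the identity.  Output length equals
    input length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def mask_germline_cnv(
    loci: pd.DataFrame,
    deviation: float = 0.25,
    min_seg_loci: int = 20,
    smooth_window: int = 51,
    f_threshold: float = 25.0,
    window: int = 200,
) -> pd.DataFrame:
    """Find intervals of apparent germline copy-number variation.

    The germline depth track is smoothed and segmented with the same
    engine used for tumor segmentation; segments whose mean depth deviates
    from the chromosome median by more than ``deviation`` (fractional) are
    returned as a BED-like frame (chrom, start, end; 0-based half-open bp).
    The minimum segment length makes single-locus spikes invisible.
    """
    out = []
    for chrom, sub in loci.groupby("chrom", sort=False):
        depth = smooth_tracks(sub["germline_depth"].to_numpy(), smooth_window)
        med = np.median(depth)
        if med <= 0:
            continue
        breaks = segment_track(
            depth[:, None], f_threshold=f_threshold,
            window=window, min_seg_loci=min_seg_loci,
        )
        pos = sub["pos"].to_numpy()
        bounds = [0] + list(breaks) + [len(depth)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mean = depth[lo:hi].mean()
            if abs(mean - med) / med > deviation:
                out.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[lo]) - 1,
                        "end": int(pos[hi - 1]),
                        "mean_depth": float(mean),
                        "n_loci": hi - lo,
                    }
                )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "mean_depth", "n_loci"])
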