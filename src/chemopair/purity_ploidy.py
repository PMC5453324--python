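"""Cellularity and haploid-depth inference from segment summaries.

For a tumor sample of cellularity rho contaminated by normal cells, a
clonal allele-specific state (n_a, n_b) predicts

    depth = d * (rho * (n_a + n_b) + 2 * (1 - rho))
    BAF   = (rho * n_b + (1 - rho)) / (rho * (n_a + n_b) + 2 * (1 - rho))

where d is the haploid read depth (reads per copy per locus).  Plotting
segment (depth, mirrored BAF) means against this lattice of predicted
cluster centers identifies (rho, d); the fit here is a deterministic grid
search scored by the locus-weighted squared distance of each segment to
its nearest center, with channels scaled by robust spreads so depth and
BAF contribute comparably.  Near-tied solutions — notably the
genome-doubled counterpart of any solution, which is analytically
indistinguishable at rho = 1 — are reported rather than hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chemopair.states import enumerate_states


@dataclass
class SampleModel:
    """Per-sample cellularity and haploid depth."""

    rho: float
    haploid_depth: float
    max_cn: int = 8
    fit_score: float = float("nan")
    unidentifiable: bool = False

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise ValueError("cellularity must lie in (0, 1]")
        if self.haploid_depth <= 0:
            raise ValueError("haploid depth must be positive")


@dataclass
class StateCenter:
    state: tuple[int, int]
    depth: float
    baf: float


@dataclass
class PurityFit:
    """Ranked solutions plus (optionally) the full score surface."""

    models: list[SampleModel]
    surface: pd.DataFrame | None = None

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def __len__(self):
        return len(self.models)

    @property
    def best(self) -> SampleModel:
        return self.models[0]


def expected_baf(n_a: int, n_b: int, rho: float) -> float:
    """Expected mirrored (minor-allele) BAF of clonal state (n_a, n_b)
    at cellularity rho, including the normal-cell contribution."""
    if n_b > n_a:
        raise ValueError("require n_a >= n_b")
    denom = rho * (n_a + n_b) + 2.0 * (1.0 - rho)
    if denom == 0:
        raise ValueError("degenerate state: no DNA present")
    return (rho * n_b + (1.0 - rho)) / denom


def expected_depth(n_a: int, n_b: int, rho: float, d: float) -> float:
    """Expected read depth of clonal state (n_a, n_b) at cellularity rho
    and haploid depth d."""
    if d <= 0:
        raise ValueError("haploid depth must be positive")
    return d * (rho * (n_a + n_b) + 2.0 * (1.0 - rho))


def predict_cluster_centers(model: SampleModel) -> list[StateCenter]:
    """Predicted (depth, mirrored BAF) for every state with total copy
    number <= model.max_cn."""
    centers = []
    for n_a, n_b in enumerate_states(model.max_cn):
        centers.append(
            StateCenter(
                state=(n_a, n_b),
                depth=expected_depth(n_a, n_b, model.rho, model.haploid_depth),
                baf=expected_baf(n_a, n_b, model.rho),
            )
        )
    return centers


def _robust_scale(x: np.ndarray, floor: float) -> float:
    mad = np.median(np.abs(x - np.median(x)))
    return max(1.4826 * float(mad), floor)


def _segment_arrays(segments, sample: str):
    depth = np.array([s.depth[sample] for s in segments])
    baf = np.array([s.baf[sample] for s in segments])
    w = np.array([s.n_loci for s in segments], dtype=float)
    return depth, baf, w / w.sum()


def fit_purity_ploidy(
    segments,
    sample: str = "pre",
    max_cn: int = 8,
    rho_min: float = 0.05,
    rho_max: float = 1.0,
    rho_step: float = 0.01,
    d_span: tuple[float, float] = (0.2, 1.2),
    d_step_frac: float = 0.01,
    near_tie: float = 0.05,
    max_solutions: int = 5,
    objective: str = "distance",
    ploidy_penalty: float = 0.3,
    return_surface: bool = False,
) -> PurityFit:
    """Grid search for (rho, d) matching segment means to the state lattice.

    The d grid spans ``d_span`` times d-hat, half the locus-weighted median
    segment depth (the haploid depth a pure diploid genome would imply),
    in steps of ``d_step_frac * d-hat``.  Solutions within ``near_tie``
    (fractional) of the best score and separated from already-reported
    solutions by more than 0.05 in rho or 5% in d are all reported.

    ``objective='distance'`` (default) is the scaled squared distance;
    ``'loglik'`` swaps in a Gaussian likelihood with sampling variances
    (Poisson depth, binomial BAF) per segment.

    Because any solution admits an exactly equivalent genome-doubled
    re-scaling (states 2n at transformed rho and d), ranking applies a
    soft parsimony preference: scores are inflated by ``ploidy_penalty``
    per copy of implied average ploidy above 2, so the lowest-ploidy
    member of an equivalence class ranks first while its re-scalings
    remain visible as reported near-ties.  Set ``ploidy_penalty=0`` for
    the raw geometric ranking.
    """
    segments = list(segments)
    depth, baf, w = _segment_arrays(segments, sample)
    if len(segments) < 5:
        warnings.warn("fewer than 5 segments: purity fit may be unreliable")

    states = np.array(enumerate_states(max_cn))
    tot = states.sum(axis=1).astype(float)
    nb = states[:, 1].astype(float)

    d_hat = 0.5 * _weighted_median(depth, w)
    d_vals = np.arange(d_span[0], d_span[1] + 1e-9, d_step_frac) * d_hat
    rho_vals = np.round(np.arange(rho_min, rho_max + 1e-9, rho_step), 10)
    rho_vals = np.minimum(rho_vals[rho_vals <= rho_max + 1e-12], 1.0)

    s_d = _robust_scale(depth, 0.02 * max(np.median(depth), 1e-9))
    s_b = _robust_scale(baf, 0.02)
    n_loci = np.array([s.n_loci for s in segments], dtype=float)

    score = np.empty((len(rho_vals), len(d_vals)))
    implied_ploidy = np.empty((len(rho_vals), len(d_vals)))
    for i, rho in enumerate(rho_vals):
        mix = rho * tot + 2.0 * (1.0 - rho)  # (n_states,)
        ebaf = (rho * nb + (1.0 - rho)) / mix
        e_depth = d_vals[:, None] * mix[None, :]  # (n_d, n_states)
        dd = depth[:, None, None] - e_depth[None, :, :]  # (n_seg, n_d, n_states)
        db = baf[:, None] - ebaf[None, :]  # (n_seg, n_states)
        if objective == "distance":
            dist = (dd / s_d) ** 2 + ((db / s_b) ** 2)[:, None, :]
        elif objective == "loglik":
            var_d = np.maximum(e_depth[None, :, :] / n_loci[:, None, None], 1e-9)
            var_b = np.maximum(
                (ebaf * (1.0 - ebaf))[None, None, :]
                / (n_loci[:, None, None] * np.maximum(e_depth[None, :, :], 1.0)),
                1e-9,
            )
            dist = dd**2 / var_d + np.log(var_d) + (db**2)[:, None, :] / var_b + np.log(var_b)
        else:
            raise ValueError("objective must be 'distance' or 'loglik'")
        score[i] = np.einsum("s,sd->d", w, dist.min(axis=2))
        amin = dist.argmin(axis=2)  # (n_seg, n_d)
        implied_ploidy[i] = w @ tot[amin]

    adjusted = score * (
        1.0 + ploidy_penalty * np.maximum(implied_ploidy - 2.0, 0.0)
    )
    flat = np.argsort(adjusted, axis=None)
    best_adj = adjusted.flat[flat[0]]
    models: list[SampleModel] = []
    for j in flat:
        i, k = np.unravel_index(j, adjusted.shape)
        rho, d = float(rho_vals[i]), float(d_vals[k])
        if models and adjusted[i, k] > best_adj * (1.0 + near_tie) + 1e-12:
            break
        if any(
            abs(m.rho - rho) <= 0.05 and abs(m.haploid_depth - d) <= 0.05 * d
            for m in models
        ):
            continue
        models.append(
            SampleModel(
                rho=rho, haploid_depth=d, max_cn=max_cn,
                fit_score=float(score[i, k]),
            )
        )
        if len(models) >= max_solutions:
            break

    # unidentifiable: every segment of the best model sits nearest (1, 1)
    best = models[0]
    centers = predict_cluster_centers(best)
    c_depth = np.array([c.depth for c in centers])
    c_baf = np.array([c.baf for c in centers])
    dist = (
        (depth[:, None] - c_depth[None, :]) ** 2 / s_d**2
        + (baf[:, None] - c_baf[None, :]) ** 2 / s_b**2
    )
    nearest = dist.argmin(axis=1)
    states_list = [centers[i].state for i in nearest]
    if len(set(states_list)) == 1:
        # a single cluster (e.g. an all-(1,1) genome) carries no contrast
        # between states, so (rho, d) is not jointly constrained
        for m in models:
            m.unidentifiable = True
        warnings.warn(
            f"all segments assigned to {states_list[0]}: cellularity is "
            "unidentifiable"
        )
    if len({tuple(s) for s in states_list}) < 3:
        warnings.warn("fewer than 3 distinct states: fit may be unreliable")

    surface = None
    if return_surface:
        rr, dd_ = np.meshgrid(rho_vals, d_vals, indexing="ij")
        surface = pd.DataFrame(
            {
                "rho": rr.ravel(), "haploid_depth": dd_.ravel(),
                "score": score.ravel(), "adjusted_score": adjusted.ravel(),
                "implied_ploidy": implied_ploidy.ravel(),
            }
        )
    return PurityFit(models=models, surface=surface)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])
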