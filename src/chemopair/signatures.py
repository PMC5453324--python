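"""96-channel mutational catalogs, signature deconstruction, and the
cisplatin CpC C>A enrichment test.

Single-base substitutions are classified into 96 channels by substitution
type and flanking bases under the pyrimidine-strand convention: a mutation
reported with a purine reference base (A or G) is reverse-complemented so
the mutated base is always C or T.  Channel order is substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each
alphabetical — the standard COSMIC layout.

Deconstruction of a catalog into known signatures solves the
simplex-constrained least-squares problem

    min_w || P w - c ||^2   s.t.  w >= 0,  sum(w) = 1

where ``P`` is the 96 x K column-stochastic signature matrix and ``c`` the
catalog normalised to sum 1.  The solver is an exact active-set
nonnegative least squares on a penalty-augmented system (the sum-to-one
constraint is added as a heavily weighted extra row, then the solution is
renormalised); for well-posed problems this agrees with a dense simplex
grid search to well below reporting precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: channel tuples (substitution, 5' base, 3' base) in COSMIC order
CHANNELS: tuple[tuple[str, str, str], ...] = tuple(
    (sub, five, three) for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CHANNEL_INDEX: dict[tuple[str, str, str], int] = {c: i for i, c in enumerate(CHANNELS)}

#: channel labels in the conventional "A[C>A]A" form
CHANNEL_NAMES: tuple[str, ...] = tuple(f"{f}[{s}]{t}" for s, f, t in CHANNELS)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, context: str) -> int:
    """Channel index for a substitution ``ref>alt`` in trinucleotide ``context``.

    ``context`` is the 3-mer centered on the mutated base, on the strand on
    which ``ref`` is reported.  Purine-reference calls are folded to the
    pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in "AG":
        context = revcomp(context)
        ref, alt = revcomp(ref), revcomp(alt)
    return CHANNEL_INDEX[(f"{ref}>{alt}", context[0], context[2])]


def trinucleotide_catalog(snvs: pd.DataFrame, reference) -> tuple[np.ndarray, int]:
    """Build a 96-channel catalog from SNV calls and a reference sequence.

    Parameters
    ----------
    snvs : DataFrame with columns chrom, pos (1-based), ref, alt.
    reference : a ``pyfaidx.Fasta`` (or any mapping chrom -> sliceable,
        0-based sequence object with string conversion).

    Returns
    -------
    (counts, n_skipped) : 96-vector of channel counts summing to the number
        of valid SNVs, and the count of calls skipped because the reference
        base did not match.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_skipped = 0
    for chrom, pos, ref, alt in zip(
        snvs["chrom"], snvs["pos"], snvs["ref"], snvs["alt"]
    ):
        ctx = str(reference[str(chrom)][int(pos) - 2 : int(pos) + 1]).upper()
        if len(ctx) != 3 or ctx[1] != ref.upper():
            n_skipped += 1
            continue
        counts[channel_of(ref, alt, ctx)] += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} SNVs skipped: reference base mismatch")
    return counts, n_skipped


@dataclass
class SignatureExposure:
    """Nonnegative signature weights summing to one, with reconstruction error."""

    weights: np.ndarray
    residual: float
    names: list[str] = field(default_factory=list)
    rank_deficient: bool = False

    def as_series(self) -> pd.Series:
        names = self.names or [f"S{i + 1}" for i in range(len(self.weights))]
        return pd.Series(self.weights, index=names, name="exposure")


def deconstruct_qp(
    catalog: np.ndarray,
    signature_matrix: np.ndarray,
    names: list[str] | None = None,
    reporting_threshold: float = 0.01,
) -> SignatureExposure:
    """Deconstruct a 96-channel catalog into signature exposures.

    Exposures below ``reporting_threshold`` are zeroed and the remainder
    renormalised, mirroring common practice of suppressing trace
    assignments that are not distinguishable from noise.
    """
    c = np.asarray(catalog, dtype=float).ravel()
    P = np.asarray(signature_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != 96 or c.shape[0] != 96:
        raise ValueError("expected a 96-vector catalog and a 96 x K signature matrix")
    if c.sum() <= 0:
        raise ValueError("catalog is empty")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must sum to 1")
    rank_deficient = np.linalg.matrix_rank(P) < P.shape[1]
    if rank_deficient:
        warnings.warn("signature matrix is rank-deficient; exposures non-unique")

    c = c / c.sum()
    lam = 1e4  # weight of the sum-to-one penalty row
    A = np.vstack([P, lam * np.ones((1, P.shape[1]))])
    b = np.concatenate([c, [lam]])
    w, _ = optimize.nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("degenerate NNLS solution")
    w = w / total
    w[w < reporting_threshold] = 0.0
    if w.sum() == 0:
        raise RuntimeError("all exposures fell below the reporting threshold")
    w = w / w.sum()
    residual = float(np.linalg.norm(P @ w - c))
    return SignatureExposure(
        weights=w,
        residual=residual,
        names=list(names) if names is not None else [],
        rank_deficient=rank_deficient,
    )


def _match_components(base: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Permutation aligning rows of ``other`` to rows of ``base`` by cosine
    similarity (Hungarian assignment).  Returns labels for ``other`` rows."""
    from scipy.optimize import linear_sum_assignment

    bn = base / np.linalg.norm(base, axis=1, keepdims=True)
    on = other / np.linalg.norm(other, axis=1, keepdims=True)
    sim = on @ bn.T
    rows, cols = linear_sum_assignment(-sim)
    labels = np.empty(other.shape[0], dtype=int)
    labels[rows] = cols
    return labels


def extract_denovo(
    catalogs: np.ndarray,
    k_range: range | list[int],
    n_bootstrap: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
) -> dict:
    """De novo signature extraction by NMF with a stability/error trade-off.

    For each candidate number of signatures ``k``, catalogs are bootstrap
    resampled (multinomial per sample, preserving totals), factorised by
    multiplicative-update NMF, and the components matched across resamples
    to the full-data factorisation by cosine similarity.  Stability is the
    mean cosine-silhouette of the matched components; the reconstruction
    error is the Frobenius norm of the full-data residual.  The suggested
    ``k`` maximises stability minus the min-max-normalised error.

    Returns a dict with keys ``per_k`` (DataFrame: k, stability, error),
    ``selected_k``, ``signatures`` (k x 96, rows sum to 1), ``exposures``.
    """
    from sklearn.decomposition import NMF
    from sklearn.metrics import silhouette_score

    X = np.asarray(catalogs, dtype=float)
    if X.ndim != 2 or X.shape[1] != 96:
        raise ValueError("catalogs must be (n_samples, 96)")
    n_samples = X.shape[0]
    k_range = list(k_range)
    if any(k >= min(96, n_samples) for k in k_range):
        raise ValueError("k must be < min(96, n_samples)")
    rng = np.random.default_rng(seed)

    def fit(mat, k, rs):
        model = NMF(
            n_components=k, solver="mu", beta_loss="frobenius",
            init="random", random_state=rs, max_iter=max_iter, tol=1e-6,
        )
        W = model.fit_transform(mat)
        return model.components_, W, model.reconstruction_err_

    rows = []
    fits = {}
    for k in k_range:
        H0, W0, err = fit(X, k, int(rng.integers(2**31 - 1)))
        fits[k] = (H0, W0)
        all_comps, labels = [], []
        for _ in range(n_bootstrap):
            Xb = np.vstack(
                [rng.multinomial(int(row.sum()), row / row.sum()) for row in X]
            ).astype(float)
            Hb, _, _ = fit(Xb, k, int(rng.integers(2**31 - 1)))
            lab = _match_components(H0, Hb)
            all_comps.append(Hb)
            labels.append(lab)
        comps = np.vstack(all_comps)
        labs = np.concatenate(labels)
        if k == 1:
            ref = H0[0] / np.linalg.norm(H0[0])
            cn = comps / np.linalg.norm(comps, axis=1, keepdims=True)
            stability = float(np.mean(cn @ ref))
        else:
            stability = float(silhouette_score(comps, labs, metric="cosine"))
        rows.append({"k": k, "stability": stability, "error": err})

    per_k = pd.DataFrame(rows)
    err_span = per_k["error"].max() - per_k["error"].min()
    norm_err = (
        (per_k["error"] - per_k["error"].min()) / err_span if err_span > 0
        else per_k["error"] * 0.0
    )
    selected_k = int(per_k["k"][np.argmax(per_k["stability"] - norm_err)])
    H, W = fits[selected_k]
    sig = H / H.sum(axis=1, keepdims=True)
    expo = W * H.sum(axis=1)
    expo = expo / expo.sum(axis=1, keepdims=True)
    return {
        "per_k": per_k,
        "selected_k": selected_k,
        "signatures": sig,
        "exposures": expo,
    }


#: channels counted as the cisplatin-associated CpC C>A class (5' reading:
#: the base 5' of the mutated C is itself a C)
CPC_CA_CHANNELS_5PRIME = tuple(
    CHANNEL_INDEX[("C>A", "C", t)] for t in BASES
)
CPC_CA_CHANNELS_3PRIME = tuple(
    CHANNEL_INDEX[("C>A", f, "C")] for f in BASES
)


def cisplatin_enrichment(
    catalogs: np.ndarray,
    groups,
    treated_label="treated",
    convention: str = "5prime",
) -> dict:
    """Test enrichment of CpC C>A substitutions in a treated vs naive cohort.

    Pools catalogs within each group, builds the 2x2 table
    [CpC C>A, other] x [treated, naive], and returns the two-sided Fisher
    exact p-value, odds ratio, and per-group CpC C>A fractions.

    ``convention`` selects which neighbor of the mutated C defines the CpC
    dinucleotide: ``"5prime"`` (default; the cited cisplatin literature's
    XpC reading) or ``"3prime"``.
    """
    X = np.atleast_2d(np.asarray(catalogs, dtype=float))
    groups = np.asarray(groups)
    if X.shape[0] != groups.shape[0]:
        raise ValueError("one group label per catalog required")
    idx = (
        CPC_CA_CHANNELS_5PRIME if convention == "5prime"
        else CPC_CA_CHANNELS_3PRIME
    )
    treated = X[groups == treated_label].sum(axis=0)
    naive = X[groups != treated_label].sum(axis=0)
    if treated.sum() == 0 or naive.sum() == 0:
        raise ValueError("both groups need nonzero mutation totals")
    t_cpc = treated[list(idx)].sum()
    n_cpc = naive[list(idx)].sum()
    table = np.array(
        [
            [t_cpc, treated.sum() - t_cpc],
            [n_cpc, naive.sum() - n_cpc],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {
            "table": table, "odds_ratio": float("nan"), "p_value": 1.0,
            "fraction_treated": float(t_cpc / treated.sum()),
            "fraction_naive": float(n_cpc / naive.sum()),
            "degenerate": True,
        }
    res = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(res.statistic),
        "p_value": float(res.pvalue),
        "fraction_treated": float(t_cpc / treated.sum()),
        "fraction_naive": float(n_cpc / naive.sum()),
        "degenerate": False,
    }


def read_signature_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a tab-delimited 96 x K signature matrix with a header of
    signature names; rows must follow the COSMIC channel order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"expected 96 rows, got {df.shape[0]}")
    return df.to_numpy(dtype=float), list(df.columns)


def write_signature_matrix(path, matrix: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(matrix, index=list(CHANNEL_NAMES), columns=names).to_csv(
        path, sep="\t"
    )
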