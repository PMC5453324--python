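"""Synthetic paired tumor-normal data with known evolutionary truth.

The generator emulates the clonal history the paired analysis is built to
interrogate: a diploid germline acquires truncal SNVs and LOH, optionally
undergoes endoreduplication (whole-genome doubling, WGD), and diverges into
the two sampled lineages (the pre- and post-chemotherapy samples), each of
which may carry private SNVs and private copy-number events.  Read counts
are then drawn with Poisson depth and binomial allele sampling, diluted by
per-sample cellularity.

Timing semantics
----------------
* truncal / pre-WGD SNVs predate the doubling: in doubled genomes they sit
  at multiplicity 2 (capped by the carrying allele's copy count).
* ``divergence_relative_to_wgd``:
  - ``near_synchronous``: all lineage-private SNVs postdate the doubling
    (multiplicity 1) and no shared SNVs postdate it — divergence and
    doubling are effectively simultaneous on the mutational clock.
  - ``before``: a configurable fraction of private SNVs predate the
    doubling and therefore reach multiplicity 2.
  - ``after``: shared post-WGD SNVs exist (multiplicity 1), i.e. the
    doubled clone kept accumulating shared mutations before divergence.

All somatic SNVs are carried on germline allele 'a' and LOH events remove
allele 'b' by default, so no SNV is silently deleted by a later loss; this
keeps the class-count conservation exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from chemopair.signatures import CHANNELS

__all__ = [
    "CNEvent",
    "SimulationConfig",
    "TruthBundle",
    "simulate_patient",
    "simulate_reads",
    "catalog_from_signatures",
    "default_signature_matrix",
    "scenario_config",
    "expected_vaf",
    "expected_baf_allele_a",
    "build_reference",
]


@dataclass(frozen=True)
class CNEvent:
    """A copy-number event on one parental allele over [start, end) bp."""

    chrom: str
    start: int
    end: int
    allele: str  # 'a' or 'b'

    def __post_init__(self):
        if self.allele not in ("a", "b"):
            raise ValueError("allele must be 'a' or 'b'")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


def _default_loh() -> list[CNEvent]:
    return [
        CNEvent("chr1", 0, 1_200_000, "b"),
        CNEvent("chr2", 2_500_000, 3_500_000, "b"),
    ]


def _default_gains() -> list[CNEvent]:
    return [
        CNEvent("chr1", 2_000_000, 3_200_000, "a"),
        CNEvent("chr2", 0, 800_000, "a"),
    ]


def _default_losses() -> list[CNEvent]:
    # truncal one-copy losses after the doubling: these create the odd
    # (major, minor) states (e.g. AAB) that dominate real doubled genomes
    # and that anchor the purity fit against the exact halved-lattice
    # ambiguity of an all-even profile
    return [
        CNEvent("chr1", 3_300_000, 4_300_000, "b"),
        CNEvent("chr2", 3_600_000, 4_600_000, "b"),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one simulated patient (a trio).

    Defaults reflect the sequencing and sampling regime of the study design
    this pipeline targets: ~50x tumor depth, histological cellularity above
    70%, germline het sites every ~1.5 kb, on a 10 Mb toy genome split
    across two pseudo-chromosomes.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    het_spacing: int = 1500
    n_truncal_snvs: int = 500
    n_pre_wgd_snvs: int = 0
    n_post_wgd_shared_snvs: int = 0
    n_private_snvs_per_lineage: int = 300
    wgd: bool = True
    divergence_relative_to_wgd: str = "near_synchronous"
    loh_events: list[CNEvent] = field(default_factory=_default_loh)
    gain_events: list[CNEvent] = field(default_factory=_default_gains)
    loss_events: list[CNEvent] = field(default_factory=_default_losses)
    private_loh_pre: list[CNEvent] = field(default_factory=list)
    private_loh_post: list[CNEvent] = field(default_factory=list)
    cellularity_pre: float = 0.75
    cellularity_post: float = 0.75
    mean_depth: float = 50.0
    signature_matrix: np.ndarray | None = None  # (96, K) column-stochastic
    signature_weights: np.ndarray | None = None  # K-vector, sums to 1
    fraction_private_pre_wgd: float = 0.5  # used when divergence is 'before'
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_truncal_snvs", "n_pre_wgd_snvs", "n_post_wgd_shared_snvs",
            "n_private_snvs_per_lineage",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cellularity_pre", "cellularity_post"):
            rho = getattr(self, name)
            if not (0 < rho <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.divergence_relative_to_wgd not in (
            "before", "near_synchronous", "after",
        ):
            raise ValueError("divergence_relative_to_wgd must be one of "
                             "before/near_synchronous/after")
        if self.signature_matrix is None:
            self.signature_matrix = default_signature_matrix()
        P = np.asarray(self.signature_matrix, dtype=float)
        if P.shape[0] != 96:
            raise ValueError("signature_matrix must have 96 rows")
        if self.signature_weights is None:
            self.signature_weights = np.full(P.shape[1], 1.0 / P.shape[1])
        w = np.asarray(self.signature_weights, dtype=float)
        if (w < 0).any():
            raise ValueError("signature_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("signature_weights must sum to 1 within 1e-9")
        self.signature_weights = w
        # inconsistent truncal LOH: the same bases losing both alleles would
        # leave no DNA to sample
        for i, e1 in enumerate(self.loh_events):
            for e2 in self.loh_events[i + 1 :]:
                if (
                    e1.chrom == e2.chrom
                    and e1.allele != e2.allele
                    and e1.start < e2.end
                    and e2.start < e1.end
                ):
                    raise ValueError(
                        f"inconsistent LOH events: both alleles lost on "
                        f"{e1.chrom}:[{max(e1.start, e2.start)},"
                        f"{min(e1.end, e2.end)})"
                    )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        n = self.n_chromosomes
        base = self.genome_length // n
        return {f"chr{i + 1}": base for i in range(n)}


@dataclass
class TruthBundle:
    """Ground truth for one simulated patient."""

    config: SimulationConfig
    het_loci: pd.DataFrame      # chrom, pos (1-based), allele_a, allele_b
    truth_segments: pd.DataFrame  # chrom, start, end (0-based half-open bp),
    #                               nA_pre, nB_pre, nA_post, nB_post
    snvs: pd.DataFrame          # chrom, pos, ref, alt, context, channel,
    #                             epoch, sharing, mult_pre, mult_post
    cellularity: dict
    haploid_depth: float
    chrom_lengths: dict


def default_signature_matrix(k: int = 3, seed: int = 97) -> np.ndarray:
    """A deterministic synthetic 96 x k column-stochastic signature matrix
    with sparse, well-separated columns (Dirichlet draws, fixed seed)."""
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.full(96, 0.08), size=k).T
    return P / P.sum(axis=0)


def expected_vaf(multiplicity: float, n_total: int, rho: float) -> float:
    """Expected variant allele fraction of a clonal SNV at the given
    multiplicity in a tumor of cellularity ``rho`` and total copy number
    ``n_total`` (normal cells contribute 2 reference copies)."""
    return rho * multiplicity / (rho * n_total + 2.0 * (1.0 - rho))


def expected_baf_allele_a(n_a: int, n_b: int, rho: float) -> float:
    """Expected (unfolded) fraction of reads carrying germline allele 'a'."""
    return (rho * n_a + (1.0 - rho)) / (rho * (n_a + n_b) + 2.0 * (1.0 - rho))


def _state_lookup(truth_segments: pd.DataFrame, chrom: str):
    sub = truth_segments[truth_segments["chrom"] == chrom]
    return (
        sub["start"].to_numpy(),
        sub["end"].to_numpy(),
        sub[["nA_pre", "nB_pre", "nA_post", "nB_post"]].to_numpy(),
    )


def states_at(truth_segments: pd.DataFrame, chrom, pos) -> np.ndarray:
    """Per-position (nA_pre, nB_pre, nA_post, nB_post) for 1-based ``pos``
    arrays within one chromosome batch at a time."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = np.zeros((len(pos), 4), dtype=int)
    for c in np.unique(chrom):
        starts, ends, vals = _state_lookup(truth_segments, c)
        m = chrom == c
        idx = np.searchsorted(starts, pos[m] - 1, side="right") - 1
        if (idx < 0).any() or ((pos[m] - 1) >= ends[idx]).any():
            raise ValueError("position outside truth segments")
        out[m] = vals[idx]
    return out


def _build_truth_segments(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in config.chrom_lengths.items():
        cuts = {0, length}
        for ev in (
            config.loh_events + config.gain_events + config.loss_events
            + config.private_loh_pre + config.private_loh_post
        ):
            if ev.chrom == chrom:
                if ev.end > length:
                    raise ValueError(f"event {ev} exceeds {chrom} length")
                cuts.update((ev.start, ev.end))
        cuts = sorted(cuts)
        for start, end in zip(cuts[:-1], cuts[1:]):
            mid = (start + end) // 2

            def covered(events):
                return [
                    ev.allele for ev in events
                    if ev.chrom == chrom and ev.start <= mid < ev.end
                ]

            # ancestral (pre-WGD) state
            n = {"a": 1, "b": 1}
            for allele in covered(config.loh_events):
                n[allele] = 0
            for allele in covered(config.gain_events):
                if n[allele] > 0:
                    n[allele] += 1
            if config.wgd:
                n = {k: 2 * v for k, v in n.items()}
            for allele in covered(config.loss_events):
                n[allele] = max(0, n[allele] - 1)
            lineage = {}
            for name, priv in (
                ("pre", config.private_loh_pre),
                ("post", config.private_loh_post),
            ):
                nn = dict(n)
                for allele in covered(priv):
                    nn[allele] = 0
                lineage[name] = nn
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "nA_pre": lineage["pre"]["a"], "nB_pre": lineage["pre"]["b"],
                    "nA_post": lineage["post"]["a"], "nB_post": lineage["post"]["b"],
                }
            )
    return pd.DataFrame(rows)


def simulate_patient(config: SimulationConfig) -> TruthBundle:
    """Generate the evolutionary truth for one patient.

    Deterministic given ``config.seed``.  SNVs are placed uniformly at
    distinct non-het positions; each draws a 96-channel trinucleotide
    context from the configured signature mixture.
    """
    rng = np.random.default_rng([config.seed, 0])
    chrom_lengths = config.chrom_lengths
    chroms = list(chrom_lengths)

    # germline het loci: exponential spacing with the configured mean
    het_rows = []
    base_choices = np.array(list("ACGT"))
    for chrom, length in chrom_lengths.items():
        n_target = int(2 * length / config.het_spacing) + 10
        gaps = rng.exponential(config.het_spacing, size=n_target)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = np.unique(pos[(pos >= 2) & (pos <= length - 1)])
        a_idx = rng.integers(0, 4, size=len(pos))
        b_idx = (a_idx + rng.integers(1, 4, size=len(pos))) % 4
        het_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": pos,
                    "allele_a": base_choices[a_idx],
                    "allele_b": base_choices[b_idx],
                }
            )
        )
    het_loci = pd.concat(het_rows, ignore_index=True)

    truth_segments = _build_truth_segments(config)

    # SNV class layout
    classes = (
        [("truncal", "both", True)] * config.n_truncal_snvs
        + [("pre_wgd", "both", True)] * config.n_pre_wgd_snvs
        + [("shared_post_wgd", "both", False)] * config.n_post_wgd_shared_snvs
    )
    for lineage in ("pre", "post"):
        n_priv = config.n_private_snvs_per_lineage
        if config.divergence_relative_to_wgd == "before" and config.wgd:
            n_early = int(round(config.fraction_private_pre_wgd * n_priv))
        else:
            n_early = 0
        classes += [("private_pre_wgd", lineage, True)] * n_early
        classes += [("private_post_wgd", lineage, False)] * (n_priv - n_early)

    n_snvs = len(classes)
    het_keys = {
        (c, p) for c, p in zip(het_loci["chrom"], het_loci["pos"])
    }
    # distinct positions avoiding germline het sites and chromosome edges
    snv_chrom, snv_pos = [], []
    taken = set()
    total_len = sum(chrom_lengths.values())
    probs = np.array([chrom_lengths[c] / total_len for c in chroms])
    while len(snv_pos) < n_snvs:
        need = n_snvs - len(snv_pos)
        cs = rng.choice(len(chroms), size=2 * need + 10, p=probs)
        ps = (
            rng.random(size=len(cs))
            * (np.array([chrom_lengths[chroms[i]] for i in cs]) - 4)
        ).astype(np.int64) + 2
        for ci, p in zip(cs, ps):
            key = (chroms[ci], int(p))
            if key in taken or key in het_keys:
                continue
            taken.add(key)
            snv_chrom.append(chroms[ci])
            snv_pos.append(int(p))
            if len(snv_pos) == n_snvs:
                break
    order = np.lexsort((snv_pos, snv_chrom))

    channels = rng.choice(
        96, size=n_snvs,
        p=np.asarray(config.signature_matrix) @ np.asarray(config.signature_weights),
    )
    snv_df = pd.DataFrame(
        {
            "chrom": np.asarray(snv_chrom)[order],
            "pos": np.asarray(snv_pos)[order],
            "channel": channels,  # channel draw order independent of position
            "epoch": np.asarray([c[0] for c in classes])[order],
            "lineage": np.asarray([c[1] for c in classes])[order],
            "pre_wgd": np.asarray([c[2] for c in classes])[order],
        }
    )
    subs = np.array([CHANNELS[ch][0] for ch in snv_df["channel"]])
    snv_df["ref"] = [s[0] for s in subs]
    snv_df["alt"] = [s[2] for s in subs]
    snv_df["context"] = [
        f"{CHANNELS[ch][1]}{CHANNELS[ch][0][0]}{CHANNELS[ch][2]}"
        for ch in snv_df["channel"]
    ]

    states = states_at(truth_segments, snv_df["chrom"], snv_df["pos"])
    mult = np.zeros((len(snv_df), 2), dtype=int)  # columns: pre, post
    for j, sample in enumerate(("pre", "post")):
        carrier = (snv_df["lineage"] == "both") | (snv_df["lineage"] == sample)
        m = np.where(config.wgd & snv_df["pre_wgd"].to_numpy(), 2, 1)
        n_a = states[:, 2 * j]
        m = np.minimum(m, n_a)  # carried on allele 'a'
        mult[:, j] = np.where(carrier, m, 0)
    snv_df["mult_pre"] = mult[:, 0]
    snv_df["mult_post"] = mult[:, 1]
    snv_df["sharing"] = np.select(
        [
            (mult[:, 0] > 0) & (mult[:, 1] > 0),
            (mult[:, 0] > 0),
        ],
        ["shared", "pre_only"],
        default="post_only",
    )

    return TruthBundle(
        config=config,
        het_loci=het_loci,
        truth_segments=truth_segments,
        snvs=snv_df,
        cellularity={"pre": config.cellularity_pre, "post": config.cellularity_post},
        haploid_depth=config.mean_depth / 2.0,
        chrom_lengths=chrom_lengths,
    )


def _binomial(rng, n, p, overdispersion):
    p = np.clip(p, 0.0, 1.0)
    if overdispersion <= 0:
        return rng.binomial(n, p)
    # beta-binomial with intra-class correlation rho = overdispersion
    conc = (1.0 - overdispersion) / overdispersion
    a = np.maximum(p * conc, 1e-9)
    b = np.maximum((1.0 - p) * conc, 1e-9)
    return rng.binomial(n, rng.beta(a, b))


def simulate_reads(
    truth: TruthBundle, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw read counts for the het-locus table and the somatic SNV table.

    Germline depth ~ Poisson(mean_depth); tumor depth per sample
    ~ Poisson(d * (rho * n_total + 2 (1 - rho))) with haploid depth
    d = mean_depth / 2; allele and variant read counts are binomial at
    their expected fractions.  Deterministic given the config seed.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    d = config.mean_depth / 2.0

    loci = truth.het_loci.copy()
    n = len(loci)
    loci["germline_depth"] = rng.poisson(config.mean_depth, size=n)
    # "alt" counts germline allele 'b'
    loci["germline_alt"] = _binomial(
        rng, loci["germline_depth"].to_numpy(), 0.5, config.overdispersion
    )
    fwd = _binomial(rng, loci["germline_depth"].to_numpy(), 0.5, 0.0)
    loci["strand_fwd"] = fwd
    loci["strand_rev"] = loci["germline_depth"] - fwd

    states = states_at(truth.truth_segments, loci["chrom"], loci["pos"])
    for j, sample in enumerate(("pre", "post")):
        rho = truth.cellularity[sample]
        n_a, n_b = states[:, 2 * j], states[:, 2 * j + 1]
        tot = n_a + n_b
        depth = rng.poisson(d * (rho * tot + 2.0 * (1.0 - rho)), size=n)
        baf_a = (rho * n_a + (1.0 - rho)) / (rho * tot + 2.0 * (1.0 - rho))
        alt = _binomial(rng, depth, 1.0 - baf_a, config.overdispersion)
        loci[f"tumor_{sample}_depth"] = depth
        loci[f"tumor_{sample}_alt"] = alt

    snvs = truth.snvs.copy()
    states = states_at(truth.truth_segments, snvs["chrom"], snvs["pos"])
    for j, sample in enumerate(("pre", "post")):
        rho = truth.cellularity[sample]
        tot = states[:, 2 * j] + states[:, 2 * j + 1]
        m = snvs[f"mult_{sample}"].to_numpy()
        depth = rng.poisson(d * (rho * tot + 2.0 * (1.0 - rho)), size=len(snvs))
        vaf = rho * m / (rho * tot + 2.0 * (1.0 - rho))
        alt = _binomial(rng, depth, vaf, config.overdispersion)
        snvs[f"dp_{sample}"] = depth
        snvs[f"alt_{sample}"] = alt
        snvs[f"called_{sample}"] = m > 0
    return loci, snvs


def catalog_from_signatures(
    signature_matrix: np.ndarray,
    weights: np.ndarray,
    n_mutations: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw a 96-channel catalog of ``n_mutations`` from a signature mixture."""
    P = np.asarray(signature_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must sum to 1")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if n_mutations == 0:
        return np.zeros(96, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_mutations, P @ w)


def build_reference(truth: TruthBundle) -> dict[str, np.ndarray]:
    """Deterministic synthetic reference sequence consistent with the truth:
    random background, germline allele 'a' at het loci, and each SNV's
    trinucleotide context written at its position."""
    rng = np.random.default_rng([truth.config.seed, 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ref = {
        chrom: rng.choice(bases, size=length).copy()
        for chrom, length in truth.chrom_lengths.items()
    }
    for chrom, pos, allele in zip(
        truth.het_loci["chrom"], truth.het_loci["pos"], truth.het_loci["allele_a"]
    ):
        ref[chrom][pos - 1] = allele.encode()
    for chrom, pos, ctx in zip(
        truth.snvs["chrom"], truth.snvs["pos"], truth.snvs["context"]
    ):
        ref[chrom][pos - 2 : pos + 1] = np.frombuffer(ctx.encode(), dtype="S1")
    return ref


def scenario_config(scenario: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named evolutionary scenarios used throughout testing.

    - ``near_synchronous``: divergence at the time of WGD; no private SNVs
      at multiplicity 2, no shared post-WGD SNVs.
    - ``before``: clonal diversity predates the doubling; half the private
      SNVs reach multiplicity 2.
    - ``after``: the doubled clone accumulates shared mutations before
      divergence (shared post-WGD SNVs at multiplicity 1).
    - ``recent``: divergence long after doubling with >= 90% of SNVs shared
      and only trivial copy-number differences.
    - ``private_loh``: near-synchronous divergence plus lineage-private LOH
      in both lineages (incompatible ancestry in both directions).
    """
    base = dict(seed=seed, wgd=True)
    if scenario == "near_synchronous":
        base.update(divergence_relative_to_wgd="near_synchronous")
    elif scenario == "before":
        base.update(divergence_relative_to_wgd="before",
                    fraction_private_pre_wgd=0.5)
    elif scenario == "after":
        base.update(divergence_relative_to_wgd="after",
                    n_post_wgd_shared_snvs=400)
    elif scenario == "recent":
        base.update(
            divergence_relative_to_wgd="near_synchronous",
            n_truncal_snvs=2000,
            n_private_snvs_per_lineage=50,
        )
    elif scenario == "private_loh":
        base.update(
            divergence_relative_to_wgd="near_synchronous",
            private_loh_pre=[CNEvent("chr1", 3_600_000, 4_900_000, "b")],
            private_loh_post=[CNEvent("chr2", 1_200_000, 2_300_000, "b")],
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    base.update(overrides)
    return SimulationConfig(**base)
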