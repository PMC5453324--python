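"""End-to-end per-patient analysis: configuration and orchestration.

Stages: het-locus selection -> track building and joint segmentation ->
purity/haploid-depth fit per sample -> state assignment, allele
consistency and merging -> genome metrics and LOH incompatibility ->
SNV sharing, multiplicity and timing -> divergence report -> (optionally)
signature deconstruction of the pre-only / shared / post-only catalogs.

Fully deterministic given the seed; all outputs carry the config hash.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chemopair import cn_states, het_loci, io, segmentation, signatures, snv_timing
from chemopair import purity_ploidy, synthetic_data

log = logging.getLogger("chemopair")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All pipeline inputs and tunables, serialisable to/from YAML."""

    outdir: str | None = None
    seed: int = 0
    # synthetic mode: a named scenario and/or explicit generator overrides
    scenario: str | None = "near_synchronous"
    simulation: dict = field(default_factory=dict)
    # real mode: paths (scenario must be None)
    locus_table: str | None = None
    snv_vcf: str | None = None
    reference_fasta: str | None = None
    signature_matrix: str | None = None
    # het-locus selection
    min_depth: int = 16
    max_depth: int = 90
    min_allele_reads: int = 4
    strand_bias_lo: float = 0.1
    strand_bias_hi: float = 0.9
    gatk_prefilter: bool = False
    # smoothing / segmentation
    smooth_window: int = 51
    f_threshold: float = 25.0
    window: int = 200
    min_seg_loci: int = 20
    # purity fit / state assignment
    max_cn: int = 8
    mixture_margin: float = 0.25
    min_assign_loci: int = 5
    # timing / divergence
    lr_min: float = 10.0
    eps: float = 0.02
    min_informative: int = 100
    loh_min_span: int = 1_000_000
    # signatures
    run_signatures: bool = True

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**yaml.safe_load(text))

    def hash(self) -> str:
        # outdir is excluded: the hash identifies the analysis, not where
        # its outputs land
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return io.config_hash(d)

    def validate(self) -> None:
        synthetic = self.scenario is not None
        if not synthetic:
            if self.locus_table is None or self.snv_vcf is None:
                raise ValueError("real mode needs locus_table and snv_vcf")
            if self.run_signatures and (
                self.signature_matrix is None or self.reference_fasta is None
            ):
                raise ValueError(
                    "signatures stage enabled but signature_matrix or "
                    "reference_fasta missing"
                )
            for p in (self.locus_table, self.snv_vcf, self.reference_fasta,
                      self.signature_matrix):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)


class _ArrayReference:
    """Adapter presenting a dict of base arrays like an indexed FASTA."""

    def __init__(self, ref: dict):
        self._ref = ref

    def __getitem__(self, chrom):
        return _ArraySeq(self._ref[chrom])


class _ArraySeq:
    def __init__(self, arr):
        self._arr = arr

    def __getitem__(self, sl):
        return self._arr[sl].tobytes().decode()


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the in-memory result bundle and, when
    ``config.outdir`` is set, writes the TSV/JSON outputs."""
    config.validate()
    meta = {"config_hash": config.hash(), "seed": config.seed}
    results: dict = {"config": config, "meta": meta}

    synthetic = config.scenario is not None
    if synthetic:
        sim = synthetic_data.scenario_config(
            config.scenario, seed=config.seed, **config.simulation
        )
        truth = synthetic_data.simulate_patient(sim)
        loci_raw, snvs_raw = synthetic_data.simulate_reads(truth)
        reference = _ArrayReference(synthetic_data.build_reference(truth))
        sig_matrix = np.asarray(sim.signature_matrix)
        sig_names = [f"S{i + 1}" for i in range(sig_matrix.shape[1])]
        results["truth"] = truth
    else:
        loci_raw = io.read_table(config.locus_table)
        snvs_raw = io.read_snv_vcf(config.snv_vcf)
        reference = None
        sig_matrix = sig_names = None
        if config.reference_fasta:
            import pyfaidx

            reference = pyfaidx.Fasta(config.reference_fasta)
        if config.signature_matrix:
            sig_matrix, sig_names = signatures.read_signature_matrix(
                config.signature_matrix
            )

    mask = _stage("mask_germline_cnv")(het_loci.mask_germline_cnv)(
        loci_raw, min_seg_loci=config.min_seg_loci,
        smooth_window=config.smooth_window, f_threshold=config.f_threshold,
        window=config.window,
    )
    loci = _stage("select_het_loci")(het_loci.select_het_loci)(
        loci_raw,
        min_depth=config.min_depth, max_depth=config.max_depth,
        min_allele_reads=config.min_allele_reads,
        strand_bias_lo=config.strand_bias_lo,
        strand_bias_hi=config.strand_bias_hi,
        mask_intervals=mask if len(mask) else None,
        gatk_prefilter=config.gatk_prefilter,
    )
    results["loci"] = loci

    tracks = _stage("build_tracks")(segmentation.build_tracks)(
        loci, smooth_window=config.smooth_window
    )
    segments = _stage("segment_joint")(segmentation.segment_joint)(
        tracks, f_threshold=config.f_threshold, window=config.window,
        min_seg_loci=config.min_seg_loci,
    )
    results["segments"] = segments

    models = {}
    fits = {}
    for sample in segmentation.SAMPLES:
        fit = _stage(f"fit_purity_{sample}")(purity_ploidy.fit_purity_ploidy)(
            segments, sample=sample, max_cn=config.max_cn
        )
        fits[sample] = fit
        models[sample] = fit.best
    results["fits"] = fits
    results["models"] = models

    calls = _stage("assign_states")(cn_states.assign_states)(
        segments, models, mixture_margin=config.mixture_margin,
        min_assign_loci=config.min_assign_loci,
    )
    calls = cn_states.check_allele_consistency(calls)
    calls = segmentation.merge_segments(
        [c for c in calls if c.assigned]
    ) + [c for c in calls if not c.assigned]
    results["calls"] = calls

    metrics = _stage("genome_metrics")(cn_states.genome_metrics)(calls)
    loh = _stage("detect_loh_incompatibility")(
        cn_states.detect_loh_incompatibility
    )(calls, min_span=config.loh_min_span)
    results["metrics"] = metrics
    results["loh"] = loh

    timed = _stage("annotate_snvs")(snv_timing.annotate_snvs)(
        snvs_raw, calls, models, lr_min=config.lr_min
    )
    divergence = _stage("infer_divergence_timing")(
        snv_timing.infer_divergence_timing
    )(
        timed, shared_antecedent=loh.shared_antecedent, eps=config.eps,
        min_informative=config.min_informative,
    )
    results["timed"] = timed
    results["divergence"] = divergence

    if config.run_signatures and reference is not None and sig_matrix is not None:
        exposures = {}
        catalogs = {}
        for cls in ("pre_only", "shared", "post_only"):
            sub = timed[timed["sharing"] == cls]
            cat, _ = signatures.trinucleotide_catalog(sub, reference)
            catalogs[cls] = cat
            if cat.sum() > 0:
                exposures[cls] = signatures.deconstruct_qp(
                    cat, sig_matrix, names=sig_names
                )
        results["catalogs"] = catalogs
        results["exposures"] = exposures

    if config.outdir:
        _write_outputs(results, Path(config.outdir), meta)
    return results


def _write_outputs(results: dict, outdir: Path, meta: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(
        segmentation.segments_to_frame(results["segments"]),
        outdir / "segments.tsv", meta,
    )
    io.write_table(
        io.state_calls_frame(results["calls"]), outdir / "state_calls.tsv", meta
    )
    io.write_table(results["timed"], outdir / "timed_snvs.tsv", meta)
    io.write_json(
        {
            "meta": meta,
            "models": {
                s: dataclasses.asdict(m) for s, m in results["models"].items()
            },
            "metrics": {
                s: dataclasses.asdict(results["metrics"][s])
                for s in ("pre", "post")
            },
            "loh": {
                "span_pre_loh_post_het": results["loh"].span_pre_loh_post_het,
                "span_post_loh_pre_het": results["loh"].span_post_loh_pre_het,
                "shared_antecedent": results["loh"].shared_antecedent,
            },
        },
        outdir / "metrics.json",
    )
    io.write_json(
        {"meta": meta, **dataclasses.asdict(results["divergence"])},
        outdir / "divergence.json",
    )
    if "exposures" in results:
        rows = []
        for cls, expo in results["exposures"].items():
            for name, w in expo.as_series().items():
                rows.append({"class": cls, "signature": name, "exposure": w})
        io.write_table(pd.DataFrame(rows), outdir / "exposures.tsv", meta)
    lines = [
        f"config_hash: {meta['config_hash']}",
        f"seed: {meta['seed']}",
        "models: "
        + ", ".join(
            f"{s}: rho={m.rho:.2f} d={m.haploid_depth:.1f}"
            for s, m in results["models"].items()
        ),
        f"divergence: {results['divergence'].verdict}",
        f"shared_antecedent: {results['loh'].shared_antecedent}",
        f"shared_fraction: {results['divergence'].shared_fraction:.3f}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
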