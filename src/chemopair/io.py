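"""Readers and writers for the formats the pipeline touches.

Conventions, asserted in round-trip tests: internal intervals are 0-based
half-open; VCF positions are 1-based on the wire; BED is 0-based
half-open.  Tabular outputs carry the config hash and seed in ``#``
comment header lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(meta: dict | None) -> list[str]:
    if not meta:
        return []
    return [f"# {k}={v}" for k, v in sorted(meta.items())]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(intervals: pd.DataFrame, path, meta: dict | None = None) -> None:
    """BED3(+) from a frame with chrom, start, end (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        intervals.to_csv(fh, sep="\t", index=False, header=False)


def write_reference_fasta(reference: dict[str, np.ndarray], path, width: int = 60) -> None:
    """Write a synthetic reference (chrom -> byte array of bases) as FASTA."""
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_snv_vcf(
    snvs: pd.DataFrame,
    path,
    chrom_lengths: dict[str, int] | None = None,
    samples: tuple[str, str] = ("PRE", "POST"),
    meta: dict | None = None,
) -> None:
    """Minimal VCF 4.2 with per-sample AD (ref,alt) and DP.

    Expects columns chrom, pos (1-based), ref, alt, and per-sample
    dp_pre/alt_pre, dp_post/alt_post; ``called_*`` flags, when present,
    gate which sample genotypes are non-reference.
    """
    lines = ["##fileformat=VCFv4.2"]
    for k, v in sorted((meta or {}).items()):
        lines.append(f"##{k}={v}")
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    keys = {"PRE": "pre", "POST": "post"}
    for _, row in snvs.iterrows():
        fields = [
            str(row["chrom"]), str(int(row["pos"])), ".", row["ref"], row["alt"],
            ".", "PASS", ".", "GT:AD:DP",
        ]
        for name in samples:
            s = keys.get(name, name.lower())
            dp = int(row[f"dp_{s}"])
            alt = int(row[f"alt_{s}"])
            called = bool(row.get(f"called_{s}", alt > 0))
            gt = "0/1" if called else "0/0"
            fields.append(f"{gt}:{dp - alt},{alt}:{dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_snv_vcf(path) -> pd.DataFrame:
    """Read SNV records with per-sample AD/DP from a (two-sample) VCF.

    Multiallelic sites are split into one row per alternate allele.
    Missing AD leaves the per-sample counts as NA (such records are
    excluded from timing downstream and flagged here with ``has_ad``).
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    sample_names = list(vf.header.samples)
    rows = []
    for rec in vf:
        for ai, alt in enumerate(rec.alts or ()):
            row = {
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt,
                "has_ad": True,
            }
            for si, name in enumerate(sample_names):
                key = "pre" if si == 0 else "post"
                fmt = rec.samples[name]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                if ad is None or ad[0] is None:
                    row["has_ad"] = False
                    row[f"dp_{key}"] = dp if dp is not None else np.nan
                    row[f"alt_{key}"] = np.nan
                else:
                    row[f"dp_{key}"] = dp if dp is not None else int(sum(a or 0 for a in ad))
                    row[f"alt_{key}"] = int(ad[1 + ai] or 0)
                gt = fmt.get("GT")
                row[f"called_{key}"] = bool(gt and any(g == 1 + ai for g in gt if g is not None))
            rows.append(row)
    vf.close()
    df = pd.DataFrame(rows)
    if len(df) and df.duplicated(subset=["chrom", "pos", "ref", "alt"]).any():
        raise ValueError("duplicate SNV keys in VCF")
    return df


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if hasattr(o, "__dataclass_fields__"):
            from dataclasses import asdict

            return asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def state_calls_frame(calls) -> pd.DataFrame:
    """Tabular form of paired state calls: one row per segment with
    anchored per-sample states, clonal fractions, and flags."""
    rows = []
    for call in calls:
        seg = call.segment
        row = {
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "n_loci": seg.n_loci,
        }
        for s in ("pre", "post"):
            sub = getattr(call, s)
            if sub is None:
                row.update(
                    {f"nA_{s}": -1, f"nB_{s}": -1, f"clonal_fraction_{s}": np.nan}
                )
            else:
                a, b = sub.anchored
                row.update(
                    {
                        f"nA_{s}": a, f"nB_{s}": b,
                        f"clonal_fraction_{s}": sub.clonal_fraction,
                        f"state_{s}": str(sub),
                    }
                )
        row["flags"] = ";".join(call.flags)
        rows.append(row)
    return pd.DataFrame(rows)
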