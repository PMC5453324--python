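"""Cohort-level genomic metrics and group comparisons.

Per-sample metrics (mutation burden, ploidy, genome fractions altered)
are compared between chemotherapy-naive and chemotherapy-treated groups
with the Wilcoxon rank-sum test (exact for small cohorts without ties,
normal approximation with tie correction otherwise), gene-level
recurrence proportions with per-gene Fisher tests under
Benjamini-Hochberg adjustment, and categorical cohort outcomes with 2x2
contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

#: default callable genome size (Mb) for the mutations/Mb rate; the
#: denominator is always user-overridable and recorded in output metadata
DEFAULT_CALLABLE_MB = 2800.0

NONSYNONYMOUS = frozenset(
    {
        "missense_variant", "stop_gained", "stop_lost", "start_lost",
        "frameshift_variant", "inframe_insertion", "inframe_deletion",
        "splice_acceptor_variant", "splice_donor_variant",
    }
)


@dataclass
class SampleMetrics:
    sample: str
    group: str  # "naive" | "treated"
    snv_count: int
    indel_count: int
    average_ploidy: float
    fraction_amplified: float
    fraction_deleted: float
    fraction_loh: float
    mutations_per_mb: float
    callable_mb: float


def per_sample_metrics(
    genome_metrics,
    snv_count: int,
    indel_count: int,
    callable_mb: float = DEFAULT_CALLABLE_MB,
    sample: str = "",
    group: str = "naive",
) -> SampleMetrics:
    """Combine copy-number genome metrics with mutation counts.

    ``genome_metrics`` is a ``cn_states.GenomeMetrics``;
    mutations/Mb = (SNVs + indels) / callable_mb.
    """
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if snv_count < 0 or indel_count < 0:
        raise ValueError("counts must be nonnegative")
    return SampleMetrics(
        sample=sample,
        group=group,
        snv_count=int(snv_count),
        indel_count=int(indel_count),
        average_ploidy=genome_metrics.average_ploidy,
        fraction_amplified=genome_metrics.fraction_amplified,
        fraction_deleted=genome_metrics.fraction_deleted,
        fraction_loh=genome_metrics.fraction_loh,
        mutations_per_mb=(snv_count + indel_count) / callable_mb,
        callable_mb=callable_mb,
    )


def metrics_frame(metrics: list[SampleMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metrics])


def compare_groups(
    metrics: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    exact_max_n: int = 25,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of one metric between the
    two groups, with per-group medians and MADs.

    The exact null distribution is used when the combined sample size is
    at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.  Constant data yield p = 1.
    """
    groups = metrics[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    x = metrics.loc[metrics[group_col] == groups[0], metric].to_numpy(dtype=float)
    y = metrics.loc[metrics[group_col] == groups[1], metric].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    summary = {
        str(g): {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "mad": float(stats.median_abs_deviation(v)),
        }
        for g, v in zip(groups, (x, y))
    }
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return {
            "metric": metric, "statistic": float("nan"), "p_value": 1.0,
            "method": "degenerate (constant data)", "groups": summary,
        }
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "metric": metric,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": f"wilcoxon rank-sum ({method})",
        "groups": summary,
    }


def recurrence_table(
    variants: pd.DataFrame,
    gene_list: list[str],
    sample_groups: pd.DataFrame,
    qualifying: frozenset = NONSYNONYMOUS,
    fisher: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-group proportion of samples carrying >= 1 qualifying
    variant, with optional Fisher comparisons BH-adjusted across genes.

    ``variants`` needs columns sample, gene, consequence;
    ``sample_groups`` needs columns sample, group (two groups).  Genes
    absent from the annotation get proportion 0 and ``absent=True``.
    """
    if not gene_list:
        return pd.DataFrame(
            columns=["gene", "absent", "proportion_a", "proportion_b",
                     "group_a", "group_b", "p_value", "q_value"]
        )
    groups = sorted(sample_groups["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    qual = variants[variants["consequence"].isin(qualifying)]
    carriers = qual.groupby("gene")["sample"].agg(set).to_dict()
    members = {
        g: set(sample_groups.loc[sample_groups["group"] == g, "sample"])
        for g in groups
    }
    rows = []
    for gene in gene_list:
        hit = carriers.get(gene, set())
        counts = {g: len(hit & members[g]) for g in groups}
        ns = {g: len(members[g]) for g in groups}
        row = {
            "gene": gene,
            "absent": gene not in carriers,
            "group_a": groups[0],
            "group_b": groups[1],
            "proportion_a": counts[groups[0]] / ns[groups[0]],
            "proportion_b": counts[groups[1]] / ns[groups[1]],
        }
        if fisher:
            table = [
                [counts[groups[0]], ns[groups[0]] - counts[groups[0]]],
                [counts[groups[1]], ns[groups[1]] - counts[groups[1]]],
            ]
            row["p_value"] = float(stats.fisher_exact(table)[1])
        rows.append(row)
    out = pd.DataFrame(rows)
    if fisher and len(out):
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out


def _percent(numer: int, denom: int) -> float:
    """Percentage to one decimal place via exact rational arithmetic."""
    frac = Fraction(numer, denom) * 100
    return float(round(frac, 1))


def contingency_tests(table) -> dict:
    """Chi-square (continuity-corrected) and two-sided Fisher tests on a
    2x2 table of counts, with row proportions to one decimal percent.

    Rows are the two groups, first column the outcome of interest.
    Zero-margin tables return proportions only.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative integers")
    props = [
        _percent(int(t[i, 0]), int(t[i].sum())) if t[i].sum() else float("nan")
        for i in range(2)
    ]
    out = {
        "table": t,
        "percent_row1": props[0],
        "percent_row2": props[1],
    }
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        out["degenerate"] = True
        return out
    chi2 = stats.chi2_contingency(t, correction=True)
    fisher = stats.fisher_exact(t, alternative="two-sided")
    out.update(
        {
            "degenerate": False,
            "chi2_p": float(chi2.pvalue),
            "fisher_p": float(fisher.pvalue),
            "odds_ratio": float(fisher.statistic),
        }
    )
    return out
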