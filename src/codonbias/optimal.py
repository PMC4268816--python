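"""Optimal-codon determination from CAI-defined expression extremes.

Lacking direct expression measurements, the top and bottom 5% of genes by CAI
stand in for highly and lowly expressed gene sets. Codon usage is pooled
within each set and compared codon-by-codon with a 2x2 Pearson chi-square
(codon vs rest-of-family, high vs low pool). A codon is called *optimal* when
its usage is significantly higher in the high-expression pool (p below alpha,
default 0.01) and its pooled RSCU is higher there than in the low pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, standard_code, to_rna
from .indices import CodonCountTable, rscu

__all__ = [
    "ExpressionPartition",
    "partition_by_cai",
    "codon_chi_square",
    "determine_optimal_codons",
    "write_optimal_report_tsv",
]


@dataclass
class ExpressionPartition:
    """CAI-extreme gene sets with their pooled codon counts."""

    high_ids: list[str]
    low_ids: list[str]
    fraction: float
    pooled_high: CodonCountTable
    pooled_low: CodonCountTable


def partition_by_cai(
    indices: pd.DataFrame,
    gene_counts: dict[str, CodonCountTable],
    fraction: float = 0.05,
) -> ExpressionPartition:
    """Split genes into the top/bottom ``fraction`` by CAI (min 1 gene each).

    Ties in CAI are broken lexicographically by gene id so the partition is
    deterministic. Genes with undefined CAI are excluded from ranking.
    """
    cai_col = indices["cai"].dropna()
    missing = [g for g in cai_col.index if g not in gene_counts]
    if missing:
        raise KeyError(f"no count table for gene(s): {missing[:3]}")
    n = len(cai_col)
    if n < 2:
        raise ValueError("need at least 2 genes with defined CAI to partition")
    k = max(1, math.floor(fraction * n))
    order = sorted(cai_col.items(), key=lambda kv: (-kv[1], kv[0]))
    high_ids = [gid for gid, _ in order[:k]]
    low_ids = [gid for gid, _ in sorted(order[-k:], key=lambda kv: (kv[1], kv[0]))]
    if set(high_ids) & set(low_ids):
        raise ValueError("high and low CAI sets overlap; fraction too large")
    return ExpressionPartition(
        high_ids=high_ids,
        low_ids=low_ids,
        fraction=fraction,
        pooled_high=CodonCountTable.pooled([gene_counts[g] for g in high_ids]),
        pooled_low=CodonCountTable.pooled([gene_counts[g] for g in low_ids]),
    )


def codon_chi_square(
    codon: str,
    pooled_high: CodonCountTable,
    pooled_low: CodonCountTable,
    code: GeneticCode | None = None,
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for one codon.

    The 2x2 table is [codon, rest-of-family] x [high pool, low pool]. A zero
    margin makes the test undefined: (NaN, NaN).
    """
    code = code or standard_code()
    family = code.family_of(codon)
    a = pooled_high.get(codon)
    b = sum(pooled_high.get(c) for c in family) - a
    c_ = pooled_low.get(codon)
    d = sum(pooled_low.get(c) for c in family) - c_
    if (a + b) == 0 or (c_ + d) == 0 or (a + c_) == 0 or (b + d) == 0:
        return math.nan, math.nan
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c_, d]], correction=False)
    return float(chi2), float(p)


def determine_optimal_codons(
    partition: ExpressionPartition,
    code: GeneticCode | None = None,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-codon report over the 59 analysis codons with the optimal flag.

    ``optimal`` is True iff p < alpha (Bonferroni-adjusted across the tested
    codons when ``bonferroni``) and RSCU(high) > RSCU(low). Met/Trp are never
    part of the report.
    """
    code = code or standard_code()
    rscu_high = rscu(partition.pooled_high, code)
    rscu_low = rscu(partition.pooled_low, code)
    rows = []
    threshold = alpha
    if bonferroni:
        threshold = alpha / len(code.analysis_codons)
    for codon in code.analysis_codons:
        chi2, p = codon_chi_square(codon, partition.pooled_high, partition.pooled_low, code)
        rh, rl = rscu_high[codon], rscu_low[codon]
        optimal = (
            not math.isnan(p)
            and p < threshold
            and not math.isnan(rh)
            and not math.isnan(rl)
            and rh > rl
        )
        rows.append(
            {
                "codon": to_rna(codon),
                "amino_acid": code.codon_to_aa[codon],
                "rscu_high": rh,
                "count_high": partition.pooled_high.get(codon),
                "rscu_low": rl,
                "count_low": partition.pooled_low.get(codon),
                "chi2": chi2,
                "p": p,
                "optimal": optimal,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def write_optimal_report_tsv(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out["optimal"] = out["optimal"].astype(int)
    out.to_csv(path, sep="\t", float_format="%.6g")
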