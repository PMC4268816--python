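"""Per-gene codon-usage indices.

Implements the classical battery of codon-usage statistics:

* **RSCU** (relative synonymous codon usage): for codon *i* of an amino acid
  with an *n*-codon family, ``RSCU_i = n * g_i / sum_family(g)`` where ``g``
  are observed counts. RSCU = 1 means a codon is used exactly as often as
  expected under uniform synonymous usage.
* **ENC** (effective number of codons, Wright's estimator): per amino acid
  with family total *n* and proportions *p_i*, the codon "homozygosity" is
  ``F = (n * sum(p_i^2) - 1) / (n - 1)``; F is averaged within each degeneracy
  class and ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` (9 two-fold amino acids,
  Ile as the single three-fold, 5 four-fold, 3 six-fold). ENC runs from 20
  (one codon per amino acid) to 61 (uniform usage).
* The **expected ENC** under pure third-position composition
  ``s`` (GC3s): ``ENC_exp = 2 + s + 29 / (s^2 + (1-s)^2)``, capped at 61.
* **GC metrics**: GC fraction per codon position (GC1/GC2/GC3), the
  synonymous-position variant GC3s restricted to the 59 analysis codons, and
  GC12 = (GC1 + GC2)/2 used by the neutrality plot.
* **CAI** (codon adaptation index, Sharp & Li): relative adaptiveness
  ``w_i = RSCU_i / max_family(RSCU)`` computed on a highly-expressed reference
  set, then CAI of a gene = geometric mean of ``w`` over its analysis-codon
  occurrences.
* **GRAVY** (Kyte-Doolittle grand average of hydropathy) and **Aromo**
  (fraction of Phe/Tyr/Trp residues) of the encoded protein.

Codons containing N are excluded from all counting (both numerator and
denominator of every index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import GeneticCode, standard_code, to_rna, translate
from .io import CodingSequence, SequenceSet

__all__ = [
    "CodonCountTable",
    "CaiWeightTable",
    "GeneIndices",
    "count_codons",
    "rscu",
    "family_homozygosity",
    "enc_observed",
    "enc_expected",
    "gc_metrics",
    "cai_weights",
    "cai",
    "gravy",
    "aromo",
    "gene_indices",
    "indices_table",
    "per_gene_counts",
    "write_indices_tsv",
]

AROMATIC = frozenset("FYW")


@dataclass
class CodonCountTable:
    """Integer counts of sense codons for one gene or a pooled gene set."""

    counts: dict[str, int]
    source_ids: list[str] = field(default_factory=list)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCountTable(merged, self.source_ids + other.source_ids)

    @classmethod
    def pooled(cls, tables: list["CodonCountTable"]) -> "CodonCountTable":
        out = cls({}, [])
        for t in tables:
            out = out + t
        return out

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def count_codons(seq: CodingSequence, code: GeneticCode | None = None) -> CodonCountTable:
    """Count non-overlapping sense codons of a validated CDS.

    Codons containing N are skipped; a terminal stop is not counted; an
    internal stop or a length not divisible by 3 raises ``ValueError``.
    """
    code = code or standard_code()
    nts = seq.nucleotides
    if len(nts) % 3 != 0:
        raise ValueError(f"{seq.id}: length {len(nts)} not divisible by 3")
    stops = set(code.stop_codons)
    n_codons = len(nts) // 3
    counts: dict[str, int] = {}
    for i in range(n_codons):
        codon = nts[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        if codon in stops:
            if i == n_codons - 1:
                continue
            raise ValueError(f"{seq.id}: internal stop codon at codon {i}")
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts, [seq.id])


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> dict[str, float]:
    """RSCU per sense codon (DNA keys); NaN for codons of unobserved families."""
    code = code or standard_code()
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        total = sum(counts.get(c) for c in family)
        n = len(family)
        for c in family:
            out[c] = (n * counts.get(c) / total) if total > 0 else math.nan
    return out


def family_homozygosity(family_counts) -> float:
    """Wright's codon homozygosity F for one synonymous family.

    ``F = (n * sum(p_i^2) - 1) / (n - 1)`` with ``n`` the family total;
    NaN when n <= 1 (uninformative).
    """
    n = sum(family_counts)
    if n <= 1:
        return math.nan
    s = sum((c / n) ** 2 for c in family_counts)
    return (n * s - 1.0) / (n - 1.0)


# amino acids per degeneracy class in the standard code:
#   2-fold: F Y H Q N K D E C (9); 3-fold: I; 4-fold: V P T A G (5); 6-fold: L S R (3)
_CLASS_MULTIPLIER = {2: 9, 3: 1, 4: 5, 6: 3}


def enc_observed(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons for one count table.

    Class means of F average the amino acids of that degeneracy with defined
    F (family total >= 2). If the three-fold class (Ile) is missing, its mean
    is imputed as the average of the two- and four-fold means; if any other
    class mean is missing or zero, ENC is NaN. Values above 61 are capped.
    """
    code = code or standard_code()
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        k = len(family)
        if k == 1:
            continue
        f = family_homozygosity([counts.get(c) for c in family])
        if not math.isnan(f):
            class_f[k].append(f)
    means: dict[int, float] = {}
    for k, vals in class_f.items():
        means[k] = sum(vals) / len(vals) if vals else math.nan
    if math.isnan(means[3]):
        if math.isnan(means[2]) or math.isnan(means[4]):
            return math.nan
        means[3] = (means[2] + means[4]) / 2.0
    for k in (2, 3, 4, 6):
        if math.isnan(means[k]) or means[k] <= 0.0:
            return math.nan
    enc = 2.0 + sum(_CLASS_MULTIPLIER[k] / means[k] for k in (2, 3, 4, 6))
    return min(enc, 61.0)


def enc_expected(s: float) -> float:
    """Expected ENC when bias is due only to third-position composition s.

    ``2 + s + 29 / (s^2 + (1-s)^2)``, capped at 61. The curve is maximal near
    s = 0.5 and falls to 31 (s=0) and 32 (s=1).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction must lie in [0, 1], got {s}")
    return min(2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2), 61.0)


@dataclass
class GcMetrics:
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    gc12: float
    gc_all: float


def gc_metrics(seq: CodingSequence, code: GeneticCode | None = None) -> GcMetrics:
    """Positional GC fractions of a validated CDS.

    GC1/GC2/GC3 run over all sense codons (terminal stop trimmed); GC3s runs
    over third positions of the 59 analysis codons only (Met, Trp excluded).
    Codons containing N contribute to neither numerator nor denominator.
    """
    code = code or standard_code()
    stops = set(code.stop_codons)
    analysis = set(code.analysis_codons)
    nts = seq.nucleotides
    if len(nts) % 3 != 0:
        raise ValueError(f"{seq.id}: length not divisible by 3")
    gc = [0, 0, 0]
    n_codons_counted = 0
    gc3s_num = gc3s_den = 0
    total = len(nts) // 3
    for i in range(total):
        codon = nts[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        if codon in stops:
            if i == total - 1:
                continue
            raise ValueError(f"{seq.id}: internal stop codon at codon {i}")
        n_codons_counted += 1
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += 1
        if codon in analysis:
            gc3s_den += 1
            if codon[2] in "GC":
                gc3s_num += 1
    if n_codons_counted == 0:
        return GcMetrics(*(math.nan,) * 6)
    gc1, gc2, gc3 = (g / n_codons_counted for g in gc)
    gc3s = gc3s_num / gc3s_den if gc3s_den else math.nan
    return GcMetrics(
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc3s=gc3s,
        gc12=(gc1 + gc2) / 2.0,
        gc_all=(gc1 + gc2 + gc3) / 3.0,
    )


@dataclass
class CaiWeightTable:
    """Relative adaptiveness w per analysis codon, from a reference gene set."""

    w: dict[str, float]
    reference_ids: list[str] = field(default_factory=list)


def cai_weights(
    reference: CodonCountTable,
    code: GeneticCode | None = None,
    pseudocount: float = 0.5,
) -> CaiWeightTable:
    """Relative adaptiveness ``w_i = RSCU_i / max_family(RSCU)`` on a reference set.

    Zero-count codons receive ``pseudocount`` before RSCU so that w stays
    strictly positive (the geometric mean in CAI must remain finite). Within
    each family max w = 1 exactly. Met/Trp/stops are excluded.
    """
    code = code or standard_code()
    if reference.total_codons == 0:
        raise ValueError("empty reference set for CAI weights")
    w: dict[str, float] = {}
    for aa, family in code.families.items():
        if len(family) == 1:
            continue
        adj = [reference.get(c) if reference.get(c) > 0 else pseudocount for c in family]
        total = sum(adj)
        rscu_vals = [len(family) * a / total for a in adj]
        mx = max(rscu_vals)
        for c, r in zip(family, rscu_vals):
            w[c] = r / mx
    return CaiWeightTable(w=w, reference_ids=list(reference.source_ids))


def cai(counts: CodonCountTable, weights: CaiWeightTable) -> float:
    """Codon adaptation index: geometric mean of w over analysis-codon occurrences.

    Computed as exp of the count-weighted mean of log w; NaN for a gene with
    no analysis codons.
    """
    log_sum = 0.0
    n = 0
    for codon, cnt in counts.counts.items():
        wv = weights.w.get(codon)
        if wv is None or cnt == 0:
            continue
        log_sum += cnt * math.log(wv)
        n += cnt
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def gravy(protein: str) -> float:
    """Kyte-Doolittle grand average of hydropathy; X residues excluded; NaN if none left."""
    vals = [KYTE_DOOLITTLE[aa] for aa in protein if aa in KYTE_DOOLITTLE]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def aromo(protein: str) -> float:
    """Fraction of aromatic residues (F, Y, W); X residues excluded from the denominator."""
    residues = [aa for aa in protein if aa != "X"]
    if not residues:
        return math.nan
    return sum(aa in AROMATIC for aa in residues) / len(residues)


@dataclass
class GeneIndices:
    """The full per-gene index record."""

    id: str
    rscu: dict[str, float]
    enc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    gc12: float
    gc_all: float
    cai: float
    gravy: float
    aromo: float
    length_codons: int


def gene_indices(
    seq: CodingSequence,
    weights: CaiWeightTable,
    code: GeneticCode | None = None,
) -> GeneIndices:
    """Compute every per-gene index for one validated CDS."""
    code = code or standard_code()
    counts = count_codons(seq, code)
    gc = gc_metrics(seq, code)
    protein = translate(seq.nucleotides, code)
    return GeneIndices(
        id=seq.id,
        rscu=rscu(counts, code),
        enc=enc_observed(counts, code),
        gc1=gc.gc1,
        gc2=gc.gc2,
        gc3=gc.gc3,
        gc3s=gc.gc3s,
        gc12=gc.gc12,
        gc_all=gc.gc_all,
        cai=cai(counts, weights),
        gravy=gravy(protein),
        aromo=aromo(protein),
        length_codons=counts.total_codons,
    )


def per_gene_counts(
    seqset: SequenceSet, code: GeneticCode | None = None
) -> dict[str, CodonCountTable]:
    """Codon count tables keyed by gene id."""
    code = code or standard_code()
    return {rec.id: count_codons(rec, code) for rec in seqset}


def indices_table(
    seqset: SequenceSet,
    reference_ids: list[str] | None = None,
    code: GeneticCode | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene index DataFrame for a validated SequenceSet.

    CAI weights are derived from the pooled counts of ``reference_ids``
    (typically ribosomal-protein genes); when no reference is given the whole
    set is pooled as its own reference (self-referential CAI). Columns are the
    scalar indices followed by the 59 RSCU columns named by RNA-spelled codon
    in canonical (UCAG) order.
    """
    code = code or standard_code()
    counts = per_gene_counts(seqset, code)
    if reference_ids:
        known = [i for i in reference_ids if i in counts]
        if not known:
            raise ValueError("none of the reference ids are present in the sequence set")
        ref_pool = CodonCountTable.pooled([counts[i] for i in known])
    else:
        ref_pool = CodonCountTable.pooled(list(counts.values()))
    weights = cai_weights(ref_pool, code, pseudocount=pseudocount)

    rows = []
    for rec in seqset:
        gi = gene_indices(rec, weights, code)
        row = {
            "id": gi.id,
            "length_codons": gi.length_codons,
            "gc1": gi.gc1,
            "gc2": gi.gc2,
            "gc3": gi.gc3,
            "gc3s": gi.gc3s,
            "gc12": gi.gc12,
            "gc_all": gi.gc_all,
            "enc": gi.enc,
            "cai": gi.cai,
            "gravy": gi.gravy,
            "aromo": gi.aromo,
        }
        for codon in code.analysis_codons:
            row[to_rna(codon)] = gi.rscu[codon]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("id")


def write_indices_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")
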