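"""Synthetic CDS generator with controllable mutation bias and selection.

The generator emulates the statistical structure a transcriptome-wide
codon-usage study assumes: a set of CDSs whose per-gene third-position GC is
drawn from a wide distribution (mutational bias), an expression-level
covariate, and expression-dependent selection toward one preferred codon per
synonymous family.

Per gene, amino acids are drawn i.i.d. from a fixed composition; each amino
acid's codon is then drawn from its family with probability proportional to

    mut(codon) * sel(codon)

where ``mut`` gives G/C-ending codons weight ``t`` and A/T-ending codons
weight ``1 - t`` (``t`` the gene's GC3 target, so the within-pair odds of a
G/C ending are t/(1-t)), and ``sel`` multiplies the family's preferred codon
by ``exp(s_sel * expression)``. A start codon is prepended and a random stop
appended. With ``selection_strength = 0`` and ``t = 0.5`` everywhere the
generator is the unbiased null (all RSCU = 1 in expectation).

Everything is driven by a single integer seed; a fixed seed yields
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .io import CodingSequence, SequenceSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_preferred_codons",
    "simulate_cds_set",
    "write_ground_truth_tsv",
    "write_reference_ids",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def default_preferred_codons(code: GeneticCode | None = None) -> dict[str, str]:
    """One G/C-ending preferred codon per multi-codon family.

    The first C-ending codon of each family in canonical order (falling back
    to the first G-ending one) — a composition mirroring the G/C-ending
    optimal-codon sets typical of GC-leaning transcriptomes.
    """
    code = code or standard_code()
    preferred: dict[str, str] = {}
    for aa, family in code.families.items():
        if len(family) == 1:
            continue
        c_ending = [c for c in family if c[2] == "C"]
        g_ending = [c for c in family if c[2] == "G"]
        preferred[aa] = (c_ending or g_ending)[0]
    return preferred


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a wide-GC3, weak-selection gene set.

    ``gc3_beta`` is the Beta(a, b) law of per-gene GC3 targets (wide spread by
    default); ``gc3_fixed`` overrides it with a single shared value (the
    homogeneous-mutation regime). ``expression_beta`` is the Beta law of the
    per-gene expression covariate in [0, 1]. ``gc12_coupling`` tilts the
    amino-acid composition of GC3-rich genes toward amino acids whose codons
    are GC-rich at positions 1-2, creating a genuine GC12-GC3 dependence for
    neutrality-plot tests. ``length_expression_coupling`` in [0, 1] makes
    highly expressed genes shorter.
    """

    n_genes: int = 1000
    length_range: tuple[int, int] = (100, 400)  # internal codons, start/stop excluded
    gc3_beta: tuple[float, float] = (2.0, 2.0)
    gc3_fixed: float | None = None
    preferred_codons: dict[str, str] | None = None
    selection_strength: float = 1.0
    expression_beta: tuple[float, float] = (2.0, 5.0)
    amino_acid_frequencies: dict[str, float] | None = None
    gc12_coupling: float = 0.0
    length_expression_coupling: float = 0.0
    reference_fraction: float = 0.05
    seed: int = 0

    def validate(self, code: GeneticCode) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"degenerate length range {self.length_range}")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.gc3_fixed is not None and not 0.0 < self.gc3_fixed < 1.0:
            raise ValueError("gc3_fixed must lie strictly inside (0, 1)")
        if any(p <= 0 for p in self.gc3_beta) or any(p <= 0 for p in self.expression_beta):
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.reference_fraction <= 1.0:
            raise ValueError("reference_fraction must lie in [0, 1]")
        if self.preferred_codons:
            for aa, codon in self.preferred_codons.items():
                if aa not in code.families or codon not in code.families[aa]:
                    raise ValueError(f"preferred codon {codon} is not in the family of {aa}")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring recovery."""

    table: pd.DataFrame  # per gene: gc3_target, expression, length_codons, is_reference
    preferred_codons: dict[str, str]
    selection_strength: float
    reference_ids: list[str] = field(default_factory=list)


def _aa_gc12_scores(code: GeneticCode) -> dict[str, float]:
    scores = {}
    for aa, family in code.families.items():
        vals = [sum(b in "GC" for b in c[:2]) / 2.0 for c in family]
        scores[aa] = sum(vals) / len(vals)
    return scores


def simulate_cds_set(
    config: SyntheticConfig, code: GeneticCode | None = None
) -> tuple[SequenceSet, GroundTruth]:
    """Generate a CDS set plus its ground truth; deterministic in config.seed."""
    code = code or standard_code()
    config.validate(code)
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    preferred = dict(config.preferred_codons or default_preferred_codons(code))
    if config.amino_acid_frequencies:
        aa_order = sorted(config.amino_acid_frequencies)
        base_freq = np.array([config.amino_acid_frequencies[a] for a in aa_order], float)
    else:
        aa_order = list(_AA20)
        base_freq = np.ones(len(aa_order))
    base_freq = base_freq / base_freq.sum()
    gc12_score = _aa_gc12_scores(code)
    score_vec = np.array([gc12_score[a] for a in aa_order])
    score_vec = score_vec - score_vec.mean()

    if config.gc3_fixed is not None:
        t = np.full(n, config.gc3_fixed)
    else:
        t = rng.beta(*config.gc3_beta, size=n)
        t = np.clip(t, 1e-6, 1 - 1e-6)
    expr = rng.beta(*config.expression_beta, size=n)

    lo, hi = config.length_range
    u = rng.uniform(size=n)
    if config.length_expression_coupling > 0:
        cpl = config.length_expression_coupling
        expr_q = (pd.Series(expr).rank(method="first") - 0.5) / n
        u = (1 - cpl) * u + cpl * (1 - expr_q.to_numpy())
    lengths = (lo + np.floor(u * (hi - lo + 1)).astype(int)).clip(lo, hi)

    stops = list(code.stop_codons)
    aa_index = {a: i for i, a in enumerate(aa_order)}
    fam_codons = {aa: list(f) for aa, f in code.families.items()}
    mut_gc_mask = {
        aa: np.array([c[2] in "GC" for c in f], float) for aa, f in fam_codons.items()
    }
    pref_mask = {
        aa: np.array([c == preferred.get(aa) for c in f], float)
        for aa, f in fam_codons.items()
    }

    records: list[CodingSequence] = []
    for i in range(n):
        gid = f"gene{i:05d}"
        if config.gc12_coupling != 0.0:
            w = base_freq * np.exp(config.gc12_coupling * (t[i] - 0.5) * score_vec * 4.0)
            aa_p = w / w.sum()
        else:
            aa_p = base_freq
        L = int(lengths[i])
        aa_seq = rng.choice(len(aa_order), size=L, p=aa_p)
        codons = np.empty(L, dtype=object)
        sel_bonus = np.exp(config.selection_strength * expr[i])
        for aa in aa_order:
            pos = np.flatnonzero(aa_seq == aa_index[aa])
            if pos.size == 0:
                continue
            fam = fam_codons[aa]
            if len(fam) == 1:
                codons[pos] = fam[0]
                continue
            wts = t[i] * mut_gc_mask[aa] + (1 - t[i]) * (1 - mut_gc_mask[aa])
            wts = wts * (1.0 + (sel_bonus - 1.0) * pref_mask[aa])
            p = wts / wts.sum()
            draw = rng.choice(len(fam), size=pos.size, p=p)
            codons[pos] = [fam[j] for j in draw]
        stop = stops[rng.integers(len(stops))]
        seq = "ATG" + "".join(codons.tolist()) + stop
        records.append(CodingSequence(id=gid, nucleotides=seq))

    n_ref = max(1, round(config.reference_fraction * n)) if config.reference_fraction > 0 else 0
    order = sorted(range(n), key=lambda i: (-expr[i], records[i].id))
    reference_ids = [records[i].id for i in order[:n_ref]]

    truth_table = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "gc3_target": t,
            "expression": expr,
            "length_codons": lengths,
            "is_reference": [r.id in set(reference_ids) for r in records],
        }
    ).set_index("id")
    truth = GroundTruth(
        table=truth_table,
        preferred_codons=preferred,
        selection_strength=config.selection_strength,
        reference_ids=reference_ids,
    )
    return SequenceSet(records=records, provenance=f"synthetic(seed={config.seed})"), truth


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    out = truth.table.copy()
    out["is_reference"] = out["is_reference"].astype(int)
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_reference_ids(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        for gid in truth.reference_ids:
            fh.write(gid + "\n")
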