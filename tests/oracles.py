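"""Independent brute-force implementations used as cross-checks.

Each oracle recomputes a statistic by a different route from the package code
(explicit loops, eigendecomposition instead of SVD, Biopython translation)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq


def oracle_translate(nucleotides: str) -> str:
    """Biopython translation, X for ambiguous codons, terminal stop stripped."""
    prot = str(Seq(nucleotides).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def oracle_rscu(counts: dict[str, int], families: dict[str, tuple[str, ...]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for family in families.values():
        g = [counts.get(c, 0) for c in family]
        tot = sum(g)
        for c, gi in zip(family, g):
            out[c] = len(family) * gi / tot if tot else math.nan
    return out


def oracle_enc(counts: dict[str, int], families: dict[str, tuple[str, ...]]) -> float:
    """Wright's ENC by explicit family enumeration (spreadsheet style)."""
    per_class: dict[int, list[float]] = {}
    for family in families.values():
        k = len(family)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        per_class.setdefault(k, []).append(f_hat)
    means = {k: float(np.mean(v)) for k, v in per_class.items()}
    if 3 not in means:
        if 2 in means and 4 in means:
            means[3] = (means[2] + means[4]) / 2
        else:
            return math.nan
    for k in (2, 3, 4, 6):
        if k not in means or means[k] <= 0:
            return math.nan
    enc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(enc, 61.0)


def oracle_cai(counts: dict[str, int], w: dict[str, float]) -> float:
    logs = []
    for codon, n in counts.items():
        if codon in w:
            logs.extend([math.log(w[codon])] * n)
    if not logs:
        return math.nan
    return math.exp(sum(logs) / len(logs))


def oracle_gc_positions(cds: str, stops: set[str]) -> tuple[float, float, float]:
    """Per-position GC by a letter-count scan over sense, N-free codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in stops:
        codons = codons[:-1]
    codons = [c for c in codons if "N" not in c]
    gc = []
    for pos in range(3):
        gc.append(sum(c[pos] in "GC" for c in codons) / len(codons))
    return tuple(gc)


def oracle_ca_row_coords(matrix: np.ndarray, n_axes: int) -> np.ndarray:
    """Principal row coordinates via eigendecomposition of S S^T (not SVD)."""
    X = np.asarray(matrix, dtype=float)
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    k = min(n_axes, len(evals))
    coords = evecs[:, :k] * np.sqrt(evals[:k]) / np.sqrt(r)[:, None]
    return coords


def oracle_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-square n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
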