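"""Dataset-level codon-usage diagnostics.

Given a per-gene index table (see :func:`codonbias.indices.indices_table`)
these functions produce the classical genome-wide pictures of
mutation-selection balance:

* the **neutrality plot** (GC12 regressed on GC3 — slope near 1 means
  mutational pressure dominates all codon positions alike, near 0 means the
  first two positions are selectively constrained);
* the **ENC-GC3s profile** (observed ENC against Wright's expected curve,
  plus the deviation ratio ``(ENC_exp - ENC_obs)/ENC_exp`` histogrammed in
  0.05-wide bins);
* the **PR2 bias plot** (A3/(A3+T3) against G3/(G3+C3) over four-fold
  degenerate families; (0.5, 0.5) is the parity point expected under
  strand-symmetric mutation with no selection);
* **correspondence analysis** of the genes x 59 RSCU matrix;
* gene classification (ribosomal / hydrophobic / aromatic / other) and the
  Spearman correlation battery linking CA axis 1, GC content, ENC, CAI,
  length, GRAVY and Aromo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, standard_code, to_rna
from .indices import CodonCountTable

__all__ = [
    "NeutralityResult",
    "neutrality_analysis",
    "EncPlotResult",
    "enc_gc3_profile",
    "Pr2Result",
    "pr2_bias",
    "FOURFOLD_FAMILIES",
    "CAResult",
    "CorrespondenceAnalysis",
    "correspondence_analysis",
    "classify_genes",
    "correlation_battery",
    "CORRELATION_PAIRS",
]


# --------------------------------------------------------------------------
# neutrality plot
# --------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    slope: float
    intercept: float
    rho: float
    pvalue: float
    n: int
    points: pd.DataFrame  # columns gc3, gc12, indexed by gene id


def neutrality_analysis(indices: pd.DataFrame) -> NeutralityResult:
    """OLS fit of GC12 on GC3 plus the Spearman rank correlation.

    A constant-GC3 input has no defined slope (reported NaN with rho NaN).
    """
    pts = indices[["gc3", "gc12"]].dropna()
    if len(pts) < 3:
        raise ValueError("neutrality analysis needs at least 3 genes")
    x = pts["gc3"].to_numpy()
    y = pts["gc12"].to_numpy()
    if np.ptp(x) == 0.0:
        return NeutralityResult(np.nan, np.nan, np.nan, np.nan, len(pts), pts)
    fit = stats.linregress(x, y)
    if np.ptp(y) == 0.0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(x, y)
    return NeutralityResult(fit.slope, fit.intercept, float(rho), float(p), len(pts), pts)


# --------------------------------------------------------------------------
# ENC vs GC3s
# --------------------------------------------------------------------------

@dataclass
class EncPlotResult:
    table: pd.DataFrame  # gc3s, enc_obs, enc_exp, ratio per gene
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    @property
    def modal_bin(self) -> tuple[float, float]:
        i = int(np.argmax(self.bin_counts))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])


def enc_gc3_profile(indices: pd.DataFrame) -> EncPlotResult:
    """Observed vs expected ENC per gene and the deviation-ratio histogram.

    ``ratio = (ENC_exp - ENC_obs) / ENC_exp`` (always < 1); the histogram uses
    left-closed bins of width 0.05 spanning [-1, 1).
    """
    from .indices import enc_expected

    df = indices[["gc3s", "enc"]].dropna().rename(columns={"enc": "enc_obs"})
    df["enc_exp"] = [enc_expected(s) for s in df["gc3s"]]
    df["ratio"] = (df["enc_exp"] - df["enc_obs"]) / df["enc_exp"]
    edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.05), 10)
    counts, _ = np.histogram(df["ratio"].to_numpy(), bins=edges)
    return EncPlotResult(table=df, bin_edges=edges, bin_counts=counts)


# --------------------------------------------------------------------------
# PR2 bias
# --------------------------------------------------------------------------

# third positions are tallied over the eight four-fold degenerate families
# (the four-fold halves of Leu/Ser/Arg count as families here)
FOURFOLD_FAMILIES: dict[str, tuple[str, ...]] = {
    "Ala": ("GCT", "GCC", "GCA", "GCG"),
    "Arg4": ("CGT", "CGC", "CGA", "CGG"),
    "Gly": ("GGT", "GGC", "GGA", "GGG"),
    "Leu4": ("CTT", "CTC", "CTA", "CTG"),
    "Pro": ("CCT", "CCC", "CCA", "CCG"),
    "Ser4": ("TCT", "TCC", "TCA", "TCG"),
    "Thr": ("ACT", "ACC", "ACA", "ACG"),
    "Val": ("GTT", "GTC", "GTA", "GTG"),
}


@dataclass
class Pr2Result:
    table: pd.DataFrame  # a3, t3, g3, c3, x, y per gene
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n_skipped: int
    skipped_ids: list[str] = field(default_factory=list)


def pr2_bias(
    gene_counts: dict[str, CodonCountTable],
    code: GeneticCode | None = None,
) -> Pr2Result:
    """Parity-rule-2 coordinates x = G3/(G3+C3), y = A3/(A3+T3) per gene.

    Genes with no four-fold codons, or with a zero denominator on either
    axis, are excluded and tallied in ``n_skipped``.
    """
    rows = []
    skipped: list[str] = []
    for gid, table in gene_counts.items():
        a3 = t3 = g3 = c3 = 0
        for fam in FOURFOLD_FAMILIES.values():
            for codon in fam:
                n = table.get(codon)
                base = codon[2]
                if base == "A":
                    a3 += n
                elif base == "T":
                    t3 += n
                elif base == "G":
                    g3 += n
                else:
                    c3 += n
        if (g3 + c3) == 0 or (a3 + t3) == 0:
            skipped.append(gid)
            continue
        rows.append(
            {
                "id": gid,
                "a3": a3,
                "t3": t3,
                "g3": g3,
                "c3": c3,
                "x": g3 / (g3 + c3),
                "y": a3 / (a3 + t3),
            }
        )
    df = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["a3", "t3", "g3", "c3", "x", "y"]
    )
    mean_x = float(df["x"].mean()) if len(df) else float("nan")
    mean_y = float(df["y"].mean()) if len(df) else float("nan")
    sd_x = float(df["x"].std(ddof=1)) if len(df) > 1 else float("nan")
    sd_y = float(df["y"].std(ddof=1)) if len(df) > 1 else float("nan")
    return Pr2Result(df, mean_x, sd_x, mean_y, sd_y, len(skipped), skipped)


# --------------------------------------------------------------------------
# correspondence analysis
# --------------------------------------------------------------------------

@dataclass
class CAResult:
    gene_coords: pd.DataFrame   # genes x axes (principal coordinates)
    codon_coords: pd.DataFrame  # codons x axes (principal coordinates)
    inertia_fractions: np.ndarray  # over all computed axes, sums to 1 (or all 0)
    oriented: bool  # True when axis 1 was sign-fixed against gene GC


class CorrespondenceAnalysis:
    """Correspondence analysis of a nonnegative genes x codons matrix.

    Standard CA: with ``P`` the matrix scaled to sum 1, row masses ``r`` and
    column masses ``c``, the matrix of standardized residuals
    ``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` is decomposed by SVD; principal
    row/column coordinates are the mass-rescaled singular vectors scaled by
    the singular values, and each axis explains a fraction of the total
    chi-square inertia proportional to its squared singular value.

    Parameters
    ----------
    n_axes : number of leading axes to retain in the coordinate tables.

    Fitted attributes (after :meth:`fit`): ``row_coords_``, ``col_coords_``,
    ``inertia_fractions_``, ``total_inertia_``.
    """

    def __init__(self, n_axes: int = 4):
        self.n_axes = n_axes

    def fit(self, matrix: pd.DataFrame) -> "CorrespondenceAnalysis":
        X = matrix.to_numpy(dtype=float)
        X = np.nan_to_num(X, nan=0.0)
        if (X < 0).any():
            raise ValueError("correspondence analysis requires a nonnegative matrix")
        row_ok = X.sum(axis=1) > 0
        if not row_ok.all():
            warnings.warn(
                f"dropping {int((~row_ok).sum())} all-zero rows from CA", stacklevel=2
            )
        col_ok = X.sum(axis=0) > 0
        rows = matrix.index[row_ok]
        cols = matrix.columns[col_ok]
        X = X[np.ix_(row_ok, col_ok)]
        if X.shape[0] < 2:
            raise ValueError("correspondence analysis needs at least 2 nonzero genes")

        P = X / X.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        # discard numerically-zero axes (rank deficiency: fewer axes, no error)
        tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
        keep = sv > max(tol, 1e-12)
        U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]

        total_inertia = float((sv**2).sum())
        if total_inertia > 0:
            fractions = sv**2 / total_inertia
        else:
            fractions = np.zeros_like(sv)
        k = min(self.n_axes, sv.size)
        row_coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
        col_coords = (Vt[:k, :].T * sv[:k]) / np.sqrt(c)[:, None]
        axes = [f"axis{i + 1}" for i in range(k)]
        self.row_coords_ = pd.DataFrame(row_coords, index=rows, columns=axes)
        self.col_coords_ = pd.DataFrame(col_coords, index=cols, columns=axes)
        self.inertia_fractions_ = fractions
        self.total_inertia_ = total_inertia
        return self


def correspondence_analysis(
    rscu_matrix: pd.DataFrame,
    gene_gc: pd.Series | None = None,
    n_axes: int = 4,
) -> CAResult:
    """CA of an RSCU matrix, with axis 1 optionally oriented against gene GC.

    Missing RSCU entries (unobserved families) are imputed as 0. When
    ``gene_gc`` is given, the sign of axis 1 is fixed so that its correlation
    with gene GC content is negative (GC-rich genes plot on the left); other
    axis signs are arbitrary.
    """
    ca = CorrespondenceAnalysis(n_axes=n_axes).fit(rscu_matrix)
    genes = ca.row_coords_.copy()
    codons = ca.col_coords_.copy()
    oriented = False
    if gene_gc is not None and "axis1" in genes.columns:
        gc = gene_gc.reindex(genes.index)
        ok = gc.notna() & genes["axis1"].notna()
        if ok.sum() >= 3 and np.ptp(genes.loc[ok, "axis1"].to_numpy()) > 0:
            r = np.corrcoef(genes.loc[ok, "axis1"], gc[ok])[0, 1]
            if np.isfinite(r) and r > 0:
                genes["axis1"] *= -1.0
                codons["axis1"] *= -1.0
            oriented = True
    return CAResult(genes, codons, ca.inertia_fractions_, oriented)


# --------------------------------------------------------------------------
# gene classes and the correlation battery
# --------------------------------------------------------------------------

def classify_genes(
    indices: pd.DataFrame,
    ribosomal_ids: list[str] | None = None,
    gravy_threshold: float = 5.0,
    aromo_threshold: float = 0.15,
) -> pd.Series:
    """Label genes ribosomal / hydrophobic / aromatic / other.

    Precedence: ribosomal > hydrophobic (GRAVY strictly above the threshold) >
    aromatic (Aromo at or above the threshold) > other. Note the conventional
    GRAVY cutoff of 5 exceeds the Kyte-Doolittle attainable mean of 4.5, so
    with the default no gene can be hydrophobic; the threshold is configurable.
    """
    ribosomal_ids = ribosomal_ids or []
    unknown = [i for i in ribosomal_ids if i not in indices.index]
    if unknown:
        warnings.warn(f"{len(unknown)} ribosomal ids not in the index table", stacklevel=2)
    ribo = set(ribosomal_ids)
    labels = []
    for gid, row in indices.iterrows():
        if gid in ribo:
            labels.append("ribosomal")
        elif pd.notna(row["gravy"]) and row["gravy"] > gravy_threshold:
            labels.append("hydrophobic")
        elif pd.notna(row["aromo"]) and row["aromo"] >= aromo_threshold:
            labels.append("aromatic")
        else:
            labels.append("other")
    return pd.Series(labels, index=indices.index, name="gene_class")


CORRELATION_PAIRS: list[tuple[str, str]] = [
    ("axis1", "gc_all"),
    ("axis1", "gc3s"),
    ("axis1", "enc"),
    ("cai", "enc"),
    ("cai", "gc3s"),
    ("cai", "gc_all"),
    ("cai", "axis1"),
    ("length_codons", "axis1"),
    ("length_codons", "enc"),
    ("length_codons", "cai"),
    ("gravy", "enc"),
    ("aromo", "enc"),
]


def correlation_battery(
    indices: pd.DataFrame,
    ca: CAResult | None = None,
    pairs: list[tuple[str, str]] | None = None,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlations for the standard battery of index pairs.

    Missing values are pairwise-deleted; a pair with fewer than ``min_pairs``
    complete observations is reported with NaN rho/p.
    """
    df = indices.copy()
    if ca is not None:
        df = df.join(ca.gene_coords[["axis1"]], how="left")
    pairs = pairs if pairs is not None else CORRELATION_PAIRS
    rows = []
    for a, b in pairs:
        if a not in df.columns or b not in df.columns:
            rows.append({"var1": a, "var2": b, "rho": np.nan, "p": np.nan, "n": 0})
            continue
        sub = df[[a, b]].dropna()
        n = len(sub)
        if n < min_pairs:
            rows.append({"var1": a, "var2": b, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        rows.append({"var1": a, "var2": b, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)
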