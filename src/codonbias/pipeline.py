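"""End-to-end pipeline: filter -> indices -> diagnostics -> optimal codons.

All outputs are TSV (codons in RNA spelling), written atomically into the
output directory together with a flat key=value manifest recording thresholds,
library versions and input checksums. Outputs carry no timestamps, so a rerun
with the same inputs and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .analyses import (
    classify_genes,
    correlation_battery,
    correspondence_analysis,
    enc_gc3_profile,
    neutrality_analysis,
    pr2_bias,
)
from .genetic_code import standard_code, to_rna
from .indices import indices_table, per_gene_counts, write_indices_tsv
from .io import read_cds_fasta, validate_and_filter, write_rejection_log
from .optimal import determine_optimal_codons, partition_by_cai, write_optimal_report_tsv

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    fasta: list[str]
    out_dir: str
    reference_ids_path: str | None = None
    min_len_nt: int = 300
    cai_fraction: float = 0.05
    alpha: float = 0.01
    gravy_threshold: float = 5.0
    aromo_threshold: float = 0.15
    pseudocount: float = 0.5
    n_axes: int = 4
    seed: int = 0
    plots: bool = False
    verbosity: int = 1

    def as_manifest_items(self) -> list[tuple[str, str]]:
        return [
            ("fasta", ";".join(self.fasta)),
            ("reference_ids", self.reference_ids_path or ""),
            ("min_len_nt", str(self.min_len_nt)),
            ("cai_fraction", str(self.cai_fraction)),
            ("alpha", str(self.alpha)),
            ("gravy_threshold", str(self.gravy_threshold)),
            ("aromo_threshold", str(self.aromo_threshold)),
            ("pseudocount", str(self.pseudocount)),
            ("n_axes", str(self.n_axes)),
            ("seed", str(self.seed)),
        ]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and populate ``config.out_dir``; returns the directory.

    Raises :class:`PipelineError` (leaving no partial outputs behind) when the
    post-filter sequence set is empty.
    """
    code = standard_code()
    seqset = None
    for path in config.fasta:
        part = read_cds_fasta(path)
        seqset = part if seqset is None else _merge(seqset, part)
    if seqset is None:
        raise PipelineError("no input FASTA given")

    retained, rejections = validate_and_filter(seqset, config.min_len_nt, code)
    if len(retained) == 0:
        raise PipelineError(
            f"no CDS passed the filter (all {len(seqset)} records rejected; "
            f"min length > {config.min_len_nt} nt)"
        )

    reference_ids = None
    if config.reference_ids_path:
        reference_ids = [
            ln.strip()
            for ln in Path(config.reference_ids_path).read_text().splitlines()
            if ln.strip()
        ]

    indices = indices_table(retained, reference_ids, code, pseudocount=config.pseudocount)
    counts = per_gene_counts(retained, code)
    rscu_cols = [to_rna(c) for c in code.analysis_codons]

    neutrality = neutrality_analysis(indices)
    profile = enc_gc3_profile(indices)
    pr2 = pr2_bias(counts, code)
    ca = correspondence_analysis(
        indices[rscu_cols], gene_gc=indices["gc_all"], n_axes=config.n_axes
    )
    labels = classify_genes(
        indices, reference_ids, config.gravy_threshold, config.aromo_threshold
    )
    correlations = correlation_battery(indices, ca)
    partition = partition_by_cai(indices, counts, fraction=config.cai_fraction)
    optimal = determine_optimal_codons(partition, code, alpha=config.alpha)

    out_dir = Path(config.out_dir)
    staging = Path(tempfile.mkdtemp(prefix="codonbias_run_"))
    try:
        write_indices_tsv(indices.join(labels), staging / "indices.tsv")
        write_rejection_log(rejections, staging / "rejections.tsv")
        ca.gene_coords.to_csv(staging / "ca_genes.tsv", sep="\t", float_format="%.6g")
        ca.codon_coords.to_csv(staging / "ca_codons.tsv", sep="\t", float_format="%.6g")
        pd.DataFrame(
            {
                "axis": [f"axis{i + 1}" for i in range(len(ca.inertia_fractions))],
                "inertia_fraction": ca.inertia_fractions,
            }
        ).to_csv(staging / "ca_inertia.tsv", sep="\t", index=False, float_format="%.6g")
        pr2.table.to_csv(staging / "pr2.tsv", sep="\t", float_format="%.6g")
        with open(staging / "neutrality.tsv", "w") as fh:
            fh.write("slope\tintercept\tspearman_rho\tp\tn\n")
            fh.write(
                f"{neutrality.slope:.6g}\t{neutrality.intercept:.6g}\t"
                f"{neutrality.rho:.6g}\t{neutrality.pvalue:.6g}\t{neutrality.n}\n"
            )
        correlations.to_csv(
            staging / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
        )
        write_optimal_report_tsv(optimal, staging / "optimal_codons.tsv")
        pd.DataFrame(
            {"bin_left": profile.bin_edges[:-1], "count": profile.bin_counts}
        ).to_csv(staging / "enc_ratio_histogram.tsv", sep="\t", index=False,
                 float_format="%.6g")

        if config.plots:
            from . import plots

            plots.plot_all(indices, neutrality, profile, pr2, ca, labels, staging)

        with open(staging / "manifest.txt", "w") as fh:
            fh.write(f"codonbias_version={__version__}\n")
            fh.write(f"numpy_version={np.__version__}\n")
            fh.write(f"scipy_version={scipy.__version__}\n")
            fh.write(f"pandas_version={pd.__version__}\n")
            for key, val in config.as_manifest_items():
                fh.write(f"{key}={val}\n")
            for path in config.fasta:
                fh.write(f"sha256:{Path(path).name}={_sha256(path)}\n")
            fh.write(f"n_input={len(seqset)}\n")
            fh.write(f"n_retained={len(retained)}\n")
            fh.write(f"n_rejected={len(rejections)}\n")
            fh.write(f"n_high={len(partition.high_ids)}\n")
            fh.write(f"n_low={len(partition.low_ids)}\n")
            fh.write(f"n_optimal={int(optimal['optimal'].sum())}\n")

        out_dir.mkdir(parents=True, exist_ok=True)
        for f in sorted(staging.iterdir()):
            shutil.move(str(f), out_dir / f.name)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return out_dir


def _merge(a, b):
    from .io import SequenceSet

    return SequenceSet(records=a.records + b.records, provenance=f"{a.provenance};{b.provenance}")
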