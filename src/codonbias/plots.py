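"""Diagnostic scatter/histogram plots (optional, behind the pipeline --plots flag)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .indices import enc_expected

_CLASS_COLORS = {
    "ribosomal": "red",
    "aromatic": "gold",
    "hydrophobic": "green",
    "other": "steelblue",
}


def plot_neutrality(neutrality, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(neutrality.points["gc3"], neutrality.points["gc12"], s=6, alpha=0.5)
    if np.isfinite(neutrality.slope):
        xs = np.linspace(0, 1, 50)
        ax.plot(xs, neutrality.intercept + neutrality.slope * xs, "r-",
                label=f"slope={neutrality.slope:.3f}")
        ax.legend()
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_enc_gc3(profile, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(profile.table["gc3s"], profile.table["enc_obs"], s=6, alpha=0.5)
    xs = np.linspace(0.001, 0.999, 200)
    ax.plot(xs, [enc_expected(s) for s in xs], "g-", label="expected")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 63)
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_enc_ratio_hist(profile, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(profile.bin_edges[:-1], profile.bin_counts, width=0.05, align="edge")
    ax.set_xlabel("(ENCexp - ENCobs) / ENCexp")
    ax.set_ylabel("genes")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_pr2(pr2, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pr2.table["x"], pr2.table["y"], s=6, alpha=0.5)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.plot([pr2.mean_x], [pr2.mean_y], "ro", mfc="none", label="mean")
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_ca(ca, labels, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    coords = ca.gene_coords
    if "axis2" in coords.columns:
        colors = [_CLASS_COLORS.get(labels.get(g, "other"), "steelblue") for g in coords.index]
        axes[0].scatter(coords["axis1"], coords["axis2"], s=6, alpha=0.6, c=colors)
        axes[0].set_title("genes")
        axes[1].scatter(ca.codon_coords["axis1"], ca.codon_coords["axis2"], s=10)
        for codon, row in ca.codon_coords.iterrows():
            axes[1].annotate(codon, (row["axis1"], row["axis2"]), fontsize=5)
        axes[1].set_title("codons")
        for ax in axes:
            ax.set_xlabel("axis 1")
            ax.set_ylabel("axis 2")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_all(indices, neutrality, profile, pr2, ca, labels, out_dir) -> None:
    out_dir = Path(out_dir)
    plot_neutrality(neutrality, out_dir / "neutrality.png")
    plot_enc_gc3(profile, out_dir / "enc_gc3s.png")
    plot_enc_ratio_hist(profile, out_dir / "enc_ratio_hist.png")
    plot_pr2(pr2, out_dir / "pr2.png")
    plot_ca(ca, labels, out_dir / "ca.png")
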