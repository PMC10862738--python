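"""Optional figure-style outputs (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import VariantRecord


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_arm_summary(per_arm: pd.DataFrame, sample_id: str,
                     path: str | Path) -> Path:
    """Bar panel of per-arm PAM maintenance, mean VAF and mean CN for one
    sample — arms under LOH stand out as CN 1 / VAF 1 with possible loss."""
    plt = _pyplot()
    sub = per_arm[per_arm.sample_id == sample_id].copy()
    sub["label"] = sub.chrom + sub.arm
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    for ax, col, title in zip(
            axes, ("maintenance", "mean_vaf", "mean_cn"),
            ("PAM maintenance", "mean truncal-PAM VAF", "mean copy number")):
        ax.bar(sub.label, sub[col], color="#4477aa")
        ax.set_ylabel(title)
    axes[-1].set_xlabel("chromosome arm")
    fig.suptitle(f"{sample_id}: per-arm PAM maintenance / VAF / CN")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_vaf_histogram(records: Sequence[VariantRecord], path: str | Path,
                       bins: int = 50) -> Path:
    """VAF histogram of one sample's variants; peaks near 0.5 indicate
    heterozygosity, near 1.0 LOH, and intermediate peaks polyploidy."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist([r.vaf for r in records], bins=bins, range=(0, 1),
            color="#cc6677")
    ax.set_xlabel("variant allele fraction")
    ax.set_ylabel("variants")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
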