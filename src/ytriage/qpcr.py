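"""Relative copy-number estimation from qPCR Ct tables (2^-ddCt).

With a single animal and no calibrator sample, the classic two-sample
ddCt collapses to a single dCt against the single-copy reference gene:
per assay, dCt = mean Ct(target) - mean Ct(reference) and the fold
change is (1 + E)^(-dCt), with amplification efficiency E fixed at 1
(a factor of 2 per cycle) unless stated otherwise.  Fold changes are
multiplicative, so duplicate assays are combined by geometric mean;
dispersion is propagated from per-replicate fold values within each
assay and pooled across assays.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import validate_ct_table


@dataclass(frozen=True)
class CopyNumberEstimate:
    gene: str
    fold_change: float
    sd: float | None
    n_assays: int
    n_replicates: int


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    efficiency: float = 1.0,
) -> CopyNumberEstimate:
    """Fold change of a target gene relative to the single-copy reference.

    Raises if the reference is missing from any assay in which the target
    was measured.  The reference gene's own estimate is exactly 1.  With a
    single replicate the dispersion is reported as None.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    validate_ct_table(ct_table)
    base = 1.0 + efficiency
    target = ct_table[ct_table["gene"] == target_gene]
    if target.empty:
        raise ValueError(f"gene {target_gene!r} absent from Ct table")
    folds = []
    variances = []
    n_replicates = 0
    for assay, target_rows in target.groupby("assay"):
        ref_rows = ct_table[(ct_table["gene"] == reference_gene) & (ct_table["assay"] == assay)]
        if ref_rows.empty:
            raise ValueError(f"reference gene {reference_gene!r} missing from assay {assay}")
        ref_mean = ref_rows["ct"].mean()
        dct = target_rows["ct"].mean() - ref_mean
        folds.append(base ** (-dct))
        rep_folds = base ** (-(target_rows["ct"] - ref_mean))
        n_replicates += len(rep_folds)
        if len(rep_folds) > 1:
            variances.append(float(rep_folds.var(ddof=1)))
    fold = float(np.exp(np.mean(np.log(folds))))
    sd = float(math.sqrt(np.mean(variances))) if variances else None
    return CopyNumberEstimate(
        gene=target_gene,
        fold_change=fold,
        sd=sd,
        n_assays=len(folds),
        n_replicates=n_replicates,
    )


def estimate_all(ct_table: pd.DataFrame, reference_gene: str, efficiency: float = 1.0) -> pd.DataFrame:
    """Fold-change table for every gene in the Ct table (reference included)."""
    rows = []
    for gene in sorted(ct_table["gene"].unique()):
        est = ddct_fold_change(ct_table, gene, reference_gene, efficiency)
        rows.append(
            {
                "gene": est.gene,
                "fold_change": est.fold_change,
                "sd": np.nan if est.sd is None else est.sd,
                "n_assays": est.n_assays,
                "n_replicates": est.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def plot_fold_changes(estimates: pd.DataFrame, path: str, reference_gene: str | None = None) -> None:
    """Bar plot of fold changes with sd whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = estimates
    if reference_gene is not None:
        data = estimates[estimates["gene"] != reference_gene]
    fig, ax = plt.subplots(figsize=(1.2 * len(data) + 1, 4))
    ax.bar(
        data["gene"],
        data["fold_change"],
        yerr=data["sd"].fillna(0.0),
        capsize=4,
        color="#4878a8",
    )
    ax.set_ylabel("fold change vs single-copy reference")
    ax.axhline(1.0, color="grey", linewidth=0.8, linestyle="--")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
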