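"""Translation-efficiency classification of hetADAT-nnC-rich genes.

Genes whose coding sequences are unusually rich in the eight inosine-
dependent nnC codons (above a percentile threshold of the genome-wide nnC
fraction, top 1% by default) are asked whether their ribosome occupancy
changes between conditions independently of mRNA level: the difference of
Ribo-seq and RNA-seq log2 fold changes classifies each gene as higher, lower
or similar occupancy at a fold cutoff (2-fold by default), and the class
distribution of the nnC-high set is tested against the remaining genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import CodonVector

TE_CLASSES = ("higher", "lower", "similar")


def nnc_percentile_threshold(nnc_fractions: Mapping[str, float], percentile: float = 99.0) -> float:
    """Percentile threshold of the per-gene hetADAT-nnC codon fraction.

    Uses the linear-interpolation percentile definition. Fewer than 100 genes
    makes a 99th percentile unstable; a warning is emitted but the threshold
    is still computed.
    """
    vals = np.asarray(list(nnc_fractions.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no nnC fractions supplied")
    if vals.size < 100:
        warnings.warn(f"only {vals.size} genes: percentile threshold is unstable")
    return float(np.percentile(vals, percentile, method="linear"))


@dataclass
class TeClassTable:
    """Per-gene occupancy classes plus the nnC-high enrichment test.

    ``per_gene`` columns: gene_id, rna_log2fc, ribo_log2fc, delta, te_class,
    nnc_fraction, is_nnc_high. ``proportions`` holds the class distribution
    for the nnC-high set and the comparison set; ``test`` the chi-square (or
    exact) result on the 2x3 contingency table with BH-adjusted per-class
    two-proportion follow-ups.
    """

    per_gene: pd.DataFrame
    proportions: pd.DataFrame
    test: Dict[str, object]


def classify_te(
    de_ribo: pd.DataFrame,
    de_rna: pd.DataFrame,
    nnc_fractions: Mapping[str, float],
    threshold: float,
    fold: float = 2.0,
    include_high_in_background: bool = False,
    exact: bool = False,
) -> TeClassTable:
    """Classify genes by mRNA-independent ribosome-occupancy change.

    delta = ribo log2FC - rna log2FC; delta > log2(fold) is "higher",
    delta < -log2(fold) "lower", otherwise "similar". Genes with
    nnc_fraction strictly above ``threshold`` form the nnC-high set, whose
    class distribution is compared against the other genes (or against all
    genes when ``include_high_in_background``) with a chi-square test on the
    2x3 table (``exact=True`` switches to a Fisher-style exact test via
    Monte-Carlo-free enumeration through scipy where the table is 2x2-able,
    else falls back to chi-square).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    ribo = de_ribo.set_index("gene_id")["log2fc"]
    rna = de_rna.set_index("gene_id")["log2fc"]
    nnc = pd.Series(dict(nnc_fractions))
    genes = ribo.index.intersection(rna.index).intersection(nnc.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between ribo, rna and nnC inputs")
    delta = ribo[genes] - rna[genes]
    lim = np.log2(fold)
    te_class = np.where(delta > lim, "higher", np.where(delta < -lim, "lower", "similar"))
    is_high = nnc[genes] > threshold
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "rna_log2fc": rna[genes].to_numpy(),
            "ribo_log2fc": ribo[genes].to_numpy(),
            "delta": delta.to_numpy(),
            "te_class": te_class,
            "nnc_fraction": nnc[genes].to_numpy(),
            "is_nnc_high": is_high.to_numpy(),
        }
    )
    high = per_gene[per_gene["is_nnc_high"]]
    rest = per_gene if include_high_in_background else per_gene[~per_gene["is_nnc_high"]]
    counts = pd.DataFrame(
        {
            "nnc_high": high["te_class"].value_counts().reindex(TE_CLASSES, fill_value=0),
            "comparison": rest["te_class"].value_counts().reindex(TE_CLASSES, fill_value=0),
        }
    ).T
    proportions = counts.div(counts.sum(axis=1), axis=0)
    # drop class columns absent from both sets; a degenerate table (an empty
    # group or a single surviving class) yields no evidence: p = 1
    table = counts.loc[:, counts.sum(axis=0) > 0].to_numpy()
    degenerate = table.shape[1] < 2 or (table.sum(axis=1) == 0).any()
    if degenerate:
        chi2, p = np.nan, 1.0
    elif exact and table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        chi2 = np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(table)
    followups = []
    n_high, n_rest = counts.sum(axis=1)
    for cls in TE_CLASSES:
        k = np.array([counts.at["nnc_high", cls], counts.at["comparison", cls]])
        n = np.array([n_high, n_rest])
        tab = np.array([k, n - k]).T
        if tab.min() < 5:
            _, pc = stats.fisher_exact(tab)
        else:
            _, pc, _, _ = stats.chi2_contingency(tab)
        followups.append({"te_class": cls, "p": float(pc)})
    fu = pd.DataFrame(followups)
    fu["q"] = multipletests(fu["p"], method="fdr_bh")[1]
    test = {
        "chi2": float(chi2) if np.isfinite(np.asarray(chi2, dtype=float)) else None,
        "p": float(p),
        "counts": counts,
        "followups": fu,
    }
    return TeClassTable(per_gene=per_gene, proportions=proportions, test=test)


def nnc_fractions_from_vectors(vectors: Sequence[CodonVector]) -> Dict[str, float]:
    """Per-gene hetADAT-nnC fraction computed from codon vectors."""
    from .genetic_code import HETADAT_CODONS

    nnc = HETADAT_CODONS["nnC"]
    return {v.gene_id: sum(v.freq.get(c, 0.0) for c in nnc) for v in vectors}
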