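"""Codon, amino-acid, stability-class and GC enrichment of gene sets, and
GO-term codon-frequency PCA.

Enrichment of a gene set is the log2 fold change of its mean codon (or amino
acid, or stability-class) frequency relative to the background universe,
where both summaries are unweighted means of per-gene relative-frequency
vectors. Grouping genes by Gene Ontology term, averaging codon frequencies
per term and running a correlation-matrix PCA reveals the dominant axes of
codon-usage variation — typically GC content at the third codon position on
the first component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import ALL_CODONS, GENETIC_CODE, CodonVector


@dataclass
class GeneSet:
    """A labelled set of gene ids drawn from the background universe."""

    label: str
    gene_ids: Set[str]


def gene_sets_from_de(
    de_table: pd.DataFrame, padj_threshold: float = 0.05
) -> Tuple[GeneSet, GeneSet]:
    """Significantly up/down gene sets from a (gene_id, log2fc, padj) table."""
    sig = de_table[de_table["padj"] < padj_threshold]
    up = GeneSet("up", set(sig.loc[sig["log2fc"] > 0, "gene_id"]))
    down = GeneSet("down", set(sig.loc[sig["log2fc"] < 0, "gene_id"]))
    return up, down


def _freq_frame(vectors: Sequence[CodonVector]) -> pd.DataFrame:
    rows = {v.gene_id: [v.freq.get(c, 0.0) for c in ALL_CODONS] for v in vectors}
    return pd.DataFrame.from_dict(rows, orient="index", columns=ALL_CODONS)


def _to_amino_acid(freq: pd.DataFrame) -> pd.DataFrame:
    groups: Dict[str, List[str]] = {}
    for c in ALL_CODONS:
        groups.setdefault(GENETIC_CODE.codon_to_aa[c], []).append(c)
    return pd.DataFrame({aa: freq[cols].sum(axis=1) for aa, cols in sorted(groups.items())})


def group_codon_enrichment(
    group: GeneSet,
    background: Sequence[CodonVector],
    level: str = "codon",
    pooled: bool = False,
) -> pd.DataFrame:
    """log2 enrichment of codon (or amino-acid) frequencies in a gene set.

    Group and background summaries are unweighted means of per-gene frequency
    vectors (``pooled=True`` weights genes by codon count instead, i.e. pools
    counts). At amino-acid level, synonymous codon frequencies are summed per
    gene before averaging. A codon absent from the background but present in
    the group yields +inf with a warning.
    """
    if not group.gene_ids:
        raise ValueError("empty gene set")
    freq = _freq_frame(background)
    missing = group.gene_ids - set(freq.index)
    if missing:
        raise ValueError(f"group genes missing from background: {sorted(missing)[:5]}")
    if level == "amino_acid":
        freq = _to_amino_acid(freq)
    elif level != "codon":
        raise ValueError(f"unknown level {level!r}")
    if pooled:
        w = pd.Series({v.gene_id: v.n_codons for v in background}, dtype=float)
        bg_mean = freq.mul(w, axis=0).sum(axis=0) / w.sum()
        ids = sorted(group.gene_ids)
        wg = w[ids]
        grp_mean = freq.loc[ids].mul(wg, axis=0).sum(axis=0) / wg.sum()
    else:
        bg_mean = freq.mean(axis=0)
        grp_mean = freq.loc[sorted(group.gene_ids)].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(grp_mean / bg_mean)
    if ((bg_mean == 0) & (grp_mean > 0)).any():
        warnings.warn("codon present in group but absent from background: log2_fc is +inf")
    table = pd.DataFrame(
        {
            "group_mean_freq": grp_mean,
            "background_mean_freq": bg_mean,
            "log2_fc": lfc,
        }
    )
    table.index.name = level
    if level == "codon":
        table["third_base_class"] = [GENETIC_CODE.third_base_class[c] for c in table.index]
        table["degeneracy"] = [GENETIC_CODE.degeneracy[c] for c in table.index]
        table["hetadat"] = [GENETIC_CODE.is_hetadat(c) for c in table.index]
    return table


def load_stability_classes(path) -> Dict[str, str]:
    """Codon -> stability class map from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def stability_enrichment(
    group_a: GeneSet,
    group_b: GeneSet,
    background: Sequence[CodonVector],
    class_map: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stability-class enrichment per group plus a between-group test.

    ``class_map`` assigns each of the 61 sense codons a stability class
    (e.g. zebrafish-derived stabilizing/destabilizing tiers). Per-gene class
    frequencies (sums of member-codon frequencies) are compared between the
    two groups with a two-sided rank-sum test, BH-adjusted across classes.
    """
    sense = [c for c in ALL_CODONS if not GENETIC_CODE.is_stop(c)]
    unknown = set(class_map) - set(ALL_CODONS)
    if unknown:
        raise ValueError(f"unknown codons in class map: {sorted(unknown)}")
    uncovered = set(sense) - set(class_map)
    if uncovered:
        raise ValueError(f"class map does not cover sense codons: {sorted(uncovered)[:5]}")
    freq = _freq_frame(background)
    classes = sorted(set(class_map.values()))
    per_gene = pd.DataFrame(
        {
            cls: freq[[c for c in sense if class_map[c] == cls]].sum(axis=1)
            for cls in classes
        }
    )
    bg_mean = per_gene.mean(axis=0)
    rows = []
    for gs in (group_a, group_b):
        gm = per_gene.loc[sorted(gs.gene_ids)].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(gm / bg_mean)
        for cls in classes:
            rows.append(
                {
                    "group": gs.label,
                    "stability_class": cls,
                    "group_mean_freq": gm[cls],
                    "background_mean_freq": bg_mean[cls],
                    "log2_fc": lfc[cls],
                }
            )
    enrich = pd.DataFrame(rows)
    tests = []
    for cls in classes:
        a = per_gene.loc[sorted(group_a.gene_ids), cls]
        b = per_gene.loc[sorted(group_b.gene_ids), cls]
        stat, p = stats.ranksums(a, b)
        tests.append({"stability_class": cls, "statistic": float(stat), "p": float(p)})
    tests = pd.DataFrame(tests)
    tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    return enrich, tests


def gc_expression_association(
    vectors: Sequence[CodonVector], de_table: pd.DataFrame, padj_threshold: float = 0.05
) -> Dict[str, object]:
    """Spearman association of per-gene GC3 with expression log2 fold change.

    Also summarizes GC3 by significance class (up / down / not significant).
    """
    gc3 = pd.Series({v.gene_id: v.gc3 for v in vectors})
    merged = de_table.set_index("gene_id").join(gc3.rename("gc3"), how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 genes matched between vectors and DE table")
    rho, p = stats.spearmanr(merged["gc3"], merged["log2fc"])
    sig = merged["padj"] < padj_threshold
    cls = np.where(~sig, "ns", np.where(merged["log2fc"] > 0, "up", "down"))
    strat = merged.groupby(cls)["gc3"].agg(["mean", "count"])
    return {"rho": float(rho), "p": float(p), "n": len(merged), "by_class": strat}


# ---------------------------------------------------------------------------
# GO-term codon PCA


@dataclass
class GoProfile:
    """Mean codon-frequency vector of the genes annotated to one GO term."""

    term_id: str
    n_genes: int
    mean_freq: pd.Series  # indexed by the 64 codons
    gc1: float
    gc2: float
    gc3: float


@dataclass
class PcaResult:
    """Correlation-matrix PCA over GO-term codon profiles.

    Loadings are orthonormal; component signs are oriented so PC1 scores
    correlate positively with term-mean AT3 (= 1 - GC3), putting AT-ending
    codon usage on the positive side.
    """

    scores: pd.DataFrame  # terms x components
    loadings: pd.DataFrame  # codons x components
    explained_variance_ratio: np.ndarray
    dropped_codons: List[str]


def go_profiles(
    gene2go: pd.DataFrame,
    vectors: Sequence[CodonVector],
    min_genes: int = 40,
) -> List[GoProfile]:
    """Average codon frequencies per GO term; keep terms with >= min_genes.

    ``gene2go`` maps gene_id -> term_id (many-to-many). Genes lacking codon
    vectors are dropped from a term before the size filter applies.
    """
    by_id = {v.gene_id: v for v in vectors}
    usable = gene2go[gene2go["gene_id"].isin(by_id)]
    if usable.empty:
        raise ValueError("no overlap between gene2go and codon vectors")
    profiles = []
    for term_id, sub in usable.groupby("term_id"):
        genes = sorted(set(sub["gene_id"]))
        if len(genes) < min_genes:
            continue
        vs = [by_id[g] for g in genes]
        mean_freq = pd.Series(
            np.mean([[v.freq.get(c, 0.0) for c in ALL_CODONS] for v in vs], axis=0),
            index=ALL_CODONS,
        )
        profiles.append(
            GoProfile(
                term_id=term_id,
                n_genes=len(genes),
                mean_freq=mean_freq,
                gc1=float(np.mean([v.gc1 for v in vs])),
                gc2=float(np.mean([v.gc2 for v in vs])),
                gc3=float(np.mean([v.gc3 for v in vs])),
            )
        )
    return profiles


def go_pca(profiles: Sequence[GoProfile], n_components: Optional[int] = None) -> PcaResult:
    """PCA of GO-term codon profiles on the correlation matrix.

    Codon columns are standardized (zero mean, unit variance) before the
    decomposition, equivalent to eigen-decomposing the correlation matrix;
    zero-variance codon columns are dropped. PC1's sign is oriented so its
    scores correlate positively with term-mean AT3.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 GO profiles for PCA")
    X = pd.DataFrame(
        {p.term_id: p.mean_freq for p in profiles}
    ).T  # terms x codons
    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[sd == 0])
    X = X.loc[:, sd > 0]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    k = n_components or min(Z.shape)
    k = min(k, len(S))
    var = S**2
    evr = var / var.sum()
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # orient PC1 toward AT3; remaining PCs get a deterministic sign
    at3 = np.array([1.0 - p.gc3 for p in profiles])
    if np.corrcoef(scores[:, 0], at3)[0, 1] < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
    for j in range(1, k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            scores[:, j] *= -1
            loadings[:, j] *= -1
    cols = [f"PC{j+1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=cols),
        explained_variance_ratio=evr[:k],
        dropped_codons=dropped,
    )
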