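"""End-to-end orchestration: configuration, stage dispatch, run manifest.

``run_all`` executes the stages in dependency order — simulate (optional) →
codon vectors → enrichment / GO-PCA → ribosome-site occupancy → tRNA
inosine → nnC translation-efficiency classification — writing TSV outputs
and a JSON manifest with per-stage output checksums and discard tallies.
Every stage is also callable as a library function with the same contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from . import enrichment as enr
from . import inosine as ino
from . import ribosite as rs
from . import simulate as sim
from . import te
from .genetic_code import codon_vector, hetadat_nnc_fraction, load_cds, write_vectors_tsv


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    out_dir: str = "ribocodon_out"
    seed: int = 0
    simulate: bool = True
    mode: str = "human"  # human: fixed lengths 27-29 frame 0; mouse: auto-detect
    # input paths (required when simulate is false)
    cds_fasta: Optional[str] = None
    transcripts_fasta: Optional[str] = None
    cds_bed: Optional[str] = None
    ribo_sams_a: List[str] = field(default_factory=list)
    ribo_sams_b: List[str] = field(default_factory=list)
    trna_fasta: Optional[str] = None
    trna_annotation: Optional[str] = None
    trna_sams_a: List[str] = field(default_factory=list)
    trna_sams_b: List[str] = field(default_factory=list)
    de_rna: Optional[str] = None
    de_ribo: Optional[str] = None
    gene2go: Optional[str] = None
    # thresholds
    alpha: float = 0.05
    min_overlap: float = 0.5
    mapq: int = 20
    min_depth: int = 10
    percentile: float = 99.0
    fold: float = 2.0
    min_go_genes: int = 40
    # synthetic-run scale
    sim_n_genes: int = 300
    sim_n_footprints: int = 30000
    sim_n_replicates: int = 4

    def validate(self) -> None:
        if self.mode not in ("human", "mouse"):
            raise ValueError(f"mode must be human or mouse, got {self.mode!r}")
        if not self.simulate:
            required = ["transcripts_fasta", "cds_bed"]
            for key in required:
                if getattr(self, key) is None:
                    raise ValueError(f"missing required input path: {key}")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    version: str
    parameters: Dict
    stages: List[Dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: Dict[str, str], info: Optional[Dict] = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
                "info": info or {},
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "parameters": self.parameters, "stages": self.stages},
                fh,
                indent=1,
                default=str,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order; stop downstream on failure."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, parameters=dataclasses.asdict(config))
    manifest_path = out / "manifest.json"
    try:
        _run_stages(config, out, manifest)
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    seed = config.seed
    if config.simulate:
        scfg = sim.SimulationConfig(
            seed=seed,
            n_genes=config.sim_n_genes,
            n_footprints=config.sim_n_footprints,
            n_replicates=config.sim_n_replicates,
        )
        tx, tx_truth = sim.simulate_transcriptome(scfg)
        tx.write_fasta(out / "transcripts.fa")
        tx.write_cds_fasta(out / "cds.fa")
        tx.write_bed(out / "cds.bed")
        expr = sim.simulate_expression(tx, scfg)
        de_rna, _ = sim.simulate_de_tables(tx, scfg, seed=seed, gc3_coupling=0.5)
        de_ribo, _ = sim.simulate_de_tables(tx, scfg, seed=seed + 101, gc3_coupling=0.5)
        de_rna.to_csv(out / "de_rna.tsv", sep="\t", index=False)
        de_ribo.to_csv(out / "de_ribo.tsv", sep="\t", index=False)
        gene2go = sim.simulate_gene2go(tx, n_terms=6, genes_per_term=45, seed=seed)
        gene2go.to_csv(out / "gene2go.tsv", sep="\t", index=False)
        # condition A dwells longer on hetADAT-nnC codons at the P-site
        from .genetic_code import HETADAT_CODONS

        cfg_a = dataclasses.replace(
            scfg, p_dwell_weights={c: 1.5 for c in HETADAT_CODONS["nnC"]}
        )
        cfg_b = scfg
        ribo_sams_a, ribo_sams_b = [], []
        for r in range(config.sim_n_replicates):
            for cond, cfg_c, col, sams in (
                ("a", cfg_a, "expr_a", ribo_sams_a),
                ("b", cfg_b, "expr_b", ribo_sams_b),
            ):
                reads, _ = sim.simulate_footprints(
                    tx, dict(zip(expr["gene_id"], expr[col])), cfg_c, seed=seed + 10 * r + (0 if cond == "a" else 5)
                )
                p = out / f"ribo_{cond}_rep{r}.sam"
                sim.write_sam(reads, tx, p)
                sams.append(str(p))
        records, _, trna_truth = sim.simulate_trna_reads(scfg, seed=seed)
        trna_sams_a, trna_sams_b = [], []
        theta_a = trna_truth["inosine_rates"]
        theta_b = {k: max(0.0, v - 0.15) for k, v in theta_a.items()}
        genes_raw = sim.default_trna_set(seed)
        sim.write_trna_reference(genes_raw, out / "trna.fa", out / "trna_annotation.tsv")
        for r in range(2):
            for cond, rates, sams in (("a", theta_a, trna_sams_a), ("b", theta_b, trna_sams_b)):
                cfg_t = dataclasses.replace(scfg, inosine_rates=rates, trna_set=genes_raw)
                recs, reads_t, _ = sim.simulate_trna_reads(cfg_t, seed=seed + 50 + 10 * r + (0 if cond == "a" else 5))
                p = out / f"trna_{cond}_rep{r}.sam"
                sim.write_trna_sam(reads_t, recs, p)
                sams.append(str(p))
        config = dataclasses.replace(
            config,
            cds_fasta=str(out / "cds.fa"),
            transcripts_fasta=str(out / "transcripts.fa"),
            cds_bed=str(out / "cds.bed"),
            ribo_sams_a=ribo_sams_a,
            ribo_sams_b=ribo_sams_b,
            trna_fasta=str(out / "trna.fa"),
            trna_annotation=str(out / "trna_annotation.tsv"),
            trna_sams_a=trna_sams_a,
            trna_sams_b=trna_sams_b,
            de_rna=str(out / "de_rna.tsv"),
            de_ribo=str(out / "de_ribo.tsv"),
            gene2go=str(out / "gene2go.tsv"),
        )
        manifest.add_stage(
            "simulate",
            {"transcripts": out / "transcripts.fa", "cds_bed": out / "cds.bed"},
            {"n_genes": len(tx)},
        )

    # --- codon vectors
    cds = load_cds(config.cds_fasta)
    vectors = [codon_vector(c) for c in cds]
    write_vectors_tsv(vectors, out / "codon_vectors.tsv")
    nnc = {c.gene_id: hetadat_nnc_fraction(c) for c in cds}
    manifest.add_stage("codon_vectors", {"vectors": out / "codon_vectors.tsv"}, {"n_genes": len(vectors)})

    # --- enrichment + GO PCA
    if config.de_ribo:
        de_ribo_t = pd.read_csv(config.de_ribo, sep="\t")
        up, down = enr.gene_sets_from_de(de_ribo_t)
        for gs in (up, down):
            if gs.gene_ids:
                tab = enr.group_codon_enrichment(gs, vectors)
                tab.to_csv(out / f"enrichment_{gs.label}.tsv", sep="\t")
        assoc = enr.gc_expression_association(vectors, de_ribo_t)
        manifest.add_stage(
            "enrichment",
            {"up": out / "enrichment_up.tsv"},
            {"gc3_log2fc_rho": assoc["rho"], "n_up": len(up.gene_ids), "n_down": len(down.gene_ids)},
        )
    if config.gene2go:
        g2g = pd.read_csv(config.gene2go, sep="\t")
        profiles = enr.go_profiles(g2g, vectors, min_genes=config.min_go_genes)
        if len(profiles) >= 3:
            pca = enr.go_pca(profiles)
            pca.scores.to_csv(out / "go_pca_scores.tsv", sep="\t")
            pca.loadings.to_csv(out / "go_pca_loadings.tsv", sep="\t")
            manifest.add_stage(
                "go_pca",
                {"scores": out / "go_pca_scores.tsv", "loadings": out / "go_pca_loadings.tsv"},
                {"n_terms": len(profiles), "evr1": float(pca.explained_variance_ratio[0])},
            )

    # --- ribosome site occupancy
    if config.ribo_sams_a and config.ribo_sams_b:
        cds_iv = rs.load_bed(config.cds_bed)
        norm = {"a": [], "b": []}
        discards: Dict[str, int] = {}
        for cond, paths in (("a", config.ribo_sams_a), ("b", config.ribo_sams_b)):
            for p in paths:
                reads = rs.read_sam(p)
                if config.mode == "human":
                    profiles = rs.forced_profiles([27, 28, 29], frame=0)
                else:
                    profiles = rs.profile_frames(reads, cds_iv)
                m = rs.extract_site_codons(
                    reads, cds_iv, profiles,
                    min_overlap=config.min_overlap, mapq_min=config.mapq,
                    sample_id=f"{cond}:{Path(p).name}",
                )
                for k, v in m.discards.items():
                    discards[k] = discards.get(k, 0) + v
                norm[cond].append(rs.normalize_site_counts(m))
        diff = rs.differential_codon_usage(norm["a"], norm["b"], alpha=config.alpha)
        diff.to_csv(out / "differential_codon_usage.tsv", sep="\t", index=False)
        manifest.add_stage(
            "ribosite",
            {"differential": out / "differential_codon_usage.tsv"},
            {"discards": discards, "n_significant": int(diff["significant"].sum())},
        )

    # --- tRNA inosine
    if config.trna_fasta and config.trna_sams_a and config.trna_sams_b:
        records = ino.load_trna_reference(config.trna_fasta, config.trna_annotation)
        tabs = {"a": [], "b": []}
        for cond, paths in (("a", config.trna_sams_a), ("b", config.trna_sams_b)):
            for p in paths:
                pile = ino.pileup_from_sam(p, records)
                tabs[cond].append(
                    ino.estimate_inosine(pile, records, min_depth=config.min_depth,
                                         sample_id=f"{cond}:{Path(p).name}")
                )
        ino.inosine_table_tsv(tabs["a"][0], out / "inosine_a.tsv")
        ino.inosine_table_tsv(tabs["b"][0], out / "inosine_b.tsv")
        comp = ino.compare_conditions(tabs["a"], tabs["b"])
        comp["per_isotype_delta"].to_csv(out / "inosine_isotype_delta.tsv", sep="\t")
        manifest.add_stage(
            "inosine",
            {"per_trna_a": out / "inosine_a.tsv", "isotype_delta": out / "inosine_isotype_delta.tsv"},
            {
                "aggregate_a": comp["aggregate_a"],
                "aggregate_b": comp["aggregate_b"],
                "test_p": comp["aggregate_test"]["p"] if comp["aggregate_test"] else None,
            },
        )

    # --- nnC translation-efficiency classes
    if config.de_rna and config.de_ribo:
        de_rna_t = pd.read_csv(config.de_rna, sep="\t")
        de_ribo_t = pd.read_csv(config.de_ribo, sep="\t")
        thr = te.nnc_percentile_threshold(nnc, percentile=config.percentile)
        table = te.classify_te(de_ribo_t, de_rna_t, nnc, thr, fold=config.fold)
        table.per_gene.to_csv(out / "te_classes.tsv", sep="\t", index=False)
        manifest.add_stage(
            "te_nnc",
            {"classes": out / "te_classes.tsv"},
            {"threshold": thr, "chi2_p": table.test["p"]},
        )
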