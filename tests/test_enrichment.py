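"""Gene-set codon/amino-acid/stability enrichment and GO-term PCA."""

import numpy as np
import pandas as pd
import pytest

from ribocodon import enrichment as enr
from ribocodon import simulate as sim
from ribocodon.genetic_code import (
    ALL_CODONS,
    GENETIC_CODE,
    HETADAT_CODONS,
    CdsRecord,
    codon_vector,
)

SENSE = [c for c in ALL_CODONS if not GENETIC_CODE.is_stop(c)]


def _vectors(seqs):
    return [codon_vector(CdsRecord(g, s)) for g, s in seqs.items()]


class TestGroupEnrichment:
    def test_group_equals_background_is_zero(self, rng):
        seqs = {
            f"g{i}": "".join(SENSE[j] for j in rng.integers(0, 61, size=30))
            for i in range(8)
        }
        vs = _vectors(seqs)
        table = enr.group_codon_enrichment(enr.GeneSet("all", set(seqs)), vs)
        present = table["background_mean_freq"] > 0
        assert (table.loc[present, "log2_fc"] == 0.0).all()

    def test_hand_computed_two_gene_fixture(self):
        vs = _vectors({"g1": "GCCGCC", "g2": "GCAGCA"})
        t = enr.group_codon_enrichment(enr.GeneSet("grp", {"g1"}), vs)
        assert t.at["GCC", "group_mean_freq"] == pytest.approx(1.0)
        assert t.at["GCC", "background_mean_freq"] == pytest.approx(0.5)
        assert t.at["GCC", "log2_fc"] == pytest.approx(1.0)
        assert t.at["GCC", "hetadat"] and t.at["GCC", "third_base_class"] == "nnC"

    def test_amino_acid_level_collapses_synonyms(self):
        vs = _vectors({"g1": "GCCGCC", "g2": "GCAGCA"})
        t = enr.group_codon_enrichment(enr.GeneSet("grp", {"g1"}), vs, level="amino_acid")
        assert t.at["Ala", "log2_fc"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_fixture(self, rng):
        seqs = {
            f"g{i}": "".join(SENSE[j] for j in rng.integers(0, 61, size=40))
            for i in range(20)
        }
        vs = _vectors(seqs)
        group = {f"g{i}" for i in range(7)}
        t = enr.group_codon_enrichment(enr.GeneSet("grp", group), vs)
        for codon in rng.choice(ALL_CODONS, size=12, replace=False):
            gm = np.mean([vs[i].freq.get(codon, 0.0) for i in range(20) if f"g{i}" in group])
            bm = np.mean([v.freq.get(codon, 0.0) for v in vs])
            assert t.at[codon, "group_mean_freq"] == pytest.approx(gm, abs=1e-12)
            assert t.at[codon, "background_mean_freq"] == pytest.approx(bm, abs=1e-12)
            if bm > 0 and gm > 0:
                assert t.at[codon, "log2_fc"] == pytest.approx(np.log2(gm / bm), abs=1e-12)

    def test_codon_absent_everywhere_is_nan(self):
        vs = _vectors({"g1": "GCCGCC", "g2": "GCCGCC"})
        t = enr.group_codon_enrichment(enr.GeneSet("grp", {"g1"}), vs)
        assert np.isnan(t.at["AAA", "log2_fc"])  # 0/0: undefined, not inf

    def test_group_gene_missing_from_background_rejected(self):
        vs = _vectors({"g1": "GCCGCC"})
        with pytest.raises(ValueError, match="missing"):
            enr.group_codon_enrichment(enr.GeneSet("grp", {"zz"}), vs)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enr.group_codon_enrichment(enr.GeneSet("grp", set()), _vectors({"g": "GCC"}))


class TestStability:
    def _class_map(self, classes):
        return {c: classes[i % len(classes)] for i, c in enumerate(SENSE)}

    def test_single_class_everywhere(self, rng):
        class_map = {c: "neutral" for c in SENSE}
        seqs = {f"g{i}": "".join(SENSE[j] for j in rng.integers(0, 61, size=20))
                for i in range(10)}
        vs = _vectors(seqs)
        a = enr.GeneSet("a", {f"g{i}" for i in range(5)})
        b = enr.GeneSet("b", {f"g{i}" for i in range(5, 10)})
        enrich, tests = enr.stability_enrichment(a, b, vs, class_map)
        assert np.allclose(enrich["group_mean_freq"], 1.0)
        assert np.allclose(enrich["log2_fc"], 0.0)

    def test_maximal_separation_significant(self):
        destab = SENSE[:30]
        stab = SENSE[30:]
        class_map = {c: "destabilizing" for c in destab}
        class_map.update({c: "stabilizing" for c in stab})
        seqs = {}
        for i in range(8):
            seqs[f"a{i}"] = "".join(destab[:10]) * 2
            seqs[f"b{i}"] = "".join(stab[:10]) * 2
        vs = _vectors(seqs)
        a = enr.GeneSet("a", {f"a{i}" for i in range(8)})
        b = enr.GeneSet("b", {f"b{i}" for i in range(8)})
        _, tests = enr.stability_enrichment(a, b, vs, class_map)
        assert (tests["p"] < 0.01).all()

    def test_null_rarely_significant(self, rng):
        class_map = self._class_map(["s1", "s2", "s3"])
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            r = np.random.default_rng(s)
            seqs = {f"g{i}": "".join(SENSE[j] for j in r.integers(0, 61, size=30))
                    for i in range(16)}
            vs = _vectors(seqs)
            a = enr.GeneSet("a", {f"g{i}" for i in range(8)})
            b = enr.GeneSet("b", {f"g{i}" for i in range(8, 16)})
            _, tests = enr.stability_enrichment(a, b, vs, class_map)
            hits += (tests["q"] < 0.05).any()
        assert hits <= 1  # >= 95% of null simulations stay non-significant

    def test_incomplete_class_map_rejected(self):
        vs = _vectors({"g1": "GCCGCC"})
        with pytest.raises(ValueError, match="cover"):
            enr.stability_enrichment(
                enr.GeneSet("a", {"g1"}), enr.GeneSet("b", {"g1"}), vs, {"GCC": "s"})
        with pytest.raises(ValueError, match="unknown"):
            enr.stability_enrichment(
                enr.GeneSet("a", {"g1"}), enr.GeneSet("b", {"g1"}), vs,
                {**{c: "s" for c in SENSE}, "XXX": "s"})


class TestGcAssociation:
    def _vectors_with_gc3(self, n, rng):
        vs = []
        for i in range(n):
            # vary GC3 by mixing GCC (GC3=1) and GCA (GC3=0)
            k = i % 11
            seq = "GCC" * k + "GCA" * (10 - k)
            vs.append(codon_vector(CdsRecord(f"g{i}", seq)))
        return vs

    def test_monotone_gives_rho_one(self, rng):
        vs = self._vectors_with_gc3(44, rng)
        de = pd.DataFrame({
            "gene_id": [v.gene_id for v in vs],
            "log2fc": [v.gc3 * 2 + 0.1 for v in vs],
            "padj": 0.01,
        })
        res = enr.gc_expression_association(vs, de)
        assert res["rho"] == pytest.approx(1.0)
        anti = de.assign(log2fc=-de["log2fc"])
        assert enr.gc_expression_association(vs, anti)["rho"] == pytest.approx(-1.0)

    def test_null_association_small(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(100 + s)
            vs = self._vectors_with_gc3(1000, r)
            de = pd.DataFrame({
                "gene_id": [v.gene_id for v in vs],
                "log2fc": r.standard_normal(1000),
                "padj": r.uniform(0, 1, 1000),
            })
            if abs(enr.gc_expression_association(vs, de)["rho"]) < 0.1:
                hits += 1
        assert hits >= 9

    def test_too_few_genes_rejected(self):
        vs = _vectors({"g1": "GCC", "g2": "GCA"})
        de = pd.DataFrame({"gene_id": ["g1"], "log2fc": [1.0], "padj": [0.1]})
        with pytest.raises(ValueError, match="fewer than 3"):
            enr.gc_expression_association(vs, de)


class TestGoProfiles:
    def test_min_genes_filter(self, rng):
        seqs = {f"g{i}": "GCCGCAATTTAA" for i in range(80)}
        vs = _vectors(seqs)
        rows = [{"gene_id": f"g{i}", "term_id": "GO:small"} for i in range(39)]
        rows += [{"gene_id": f"g{i}", "term_id": "GO:big"} for i in range(40)]
        profiles = enr.go_profiles(pd.DataFrame(rows), vs, min_genes=40)
        assert [p.term_id for p in profiles] == ["GO:big"]
        assert profiles[0].n_genes == 40

    def test_identical_genes_profile_equals_vector(self):
        vs = _vectors({f"g{i}": "GCCGCAATTTAA" for i in range(40)})
        g2g = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)], "term_id": "GO:x"})
        p = enr.go_profiles(g2g, vs, min_genes=40)[0]
        for c in ("GCC", "GCA", "ATT", "TAA"):
            assert p.mean_freq[c] == pytest.approx(0.25)
        assert p.gc3 == pytest.approx(vs[0].gc3)

    def test_means_match_brute_force(self, rng):
        seqs = {f"g{i}": "".join(SENSE[j] for j in rng.integers(0, 61, size=25))
                for i in range(30)}
        vs = _vectors(seqs)
        rows = []
        for t in range(3):
            for i in range(30):
                if rng.random() < 0.6:
                    rows.append({"gene_id": f"g{i}", "term_id": f"GO:{t}"})
        profiles = enr.go_profiles(pd.DataFrame(rows), vs, min_genes=5)
        g2g = pd.DataFrame(rows)
        by_id = {v.gene_id: v for v in vs}
        for p in profiles:
            genes = sorted(set(g2g[g2g["term_id"] == p.term_id]["gene_id"]))
            manual = np.mean(
                [[by_id[g].freq.get(c, 0.0) for c in ALL_CODONS] for g in genes], axis=0)
            assert np.allclose(p.mean_freq.to_numpy(), manual, atol=1e-12)

    def test_no_overlap_rejected(self):
        vs = _vectors({"g1": "GCC"})
        with pytest.raises(ValueError, match="overlap"):
            enr.go_profiles(pd.DataFrame({"gene_id": ["zz"], "term_id": ["GO:1"]}), vs)


class TestGoPca:
    def _gradient_profiles(self, n_terms=15, seed=0):
        cfg = sim.SimulationConfig(seed=seed, n_genes=600, gene_length_range=(100, 150))
        tx, _ = sim.simulate_transcriptome(cfg)
        vs = [codon_vector(t.cds_record()) for t in tx]
        g2g = sim.simulate_gene2go(tx, n_terms=n_terms, genes_per_term=40, seed=seed)
        return enr.go_profiles(g2g, vs, min_genes=40)

    def test_pc1_recovers_gc3_gradient(self):
        profiles = self._gradient_profiles()
        res = enr.go_pca(profiles)
        gc3 = np.array([p.gc3 for p in profiles])
        r = np.corrcoef(res.scores["PC1"], gc3)[0, 1]
        assert abs(r) > 0.95
        assert r < 0  # PC1 oriented toward AT3

    def test_nnc_and_fourfold_nng_load_together(self):
        profiles = self._gradient_profiles()
        res = enr.go_pca(profiles)
        nnc = [c for c in HETADAT_CODONS["nnC"] if c in res.loadings.index]
        nng4 = [c for c in ALL_CODONS
                if c.endswith("G") and GENETIC_CODE.degeneracy[c] == 4
                and c in res.loadings.index]
        signs = np.sign(res.loadings.loc[nnc + nng4, "PC1"])
        assert len(set(signs)) == 1

    def test_duplicate_profiles_identical_scores(self):
        profiles = self._gradient_profiles(n_terms=6)
        dup = profiles + [
            enr.GoProfile(p.term_id + "_copy", p.n_genes, p.mean_freq.copy(), p.gc1, p.gc2, p.gc3)
            for p in profiles
        ]
        res = enr.go_pca(dup)
        for p in profiles:
            a = res.scores.loc[p.term_id]
            b = res.scores.loc[p.term_id + "_copy"]
            assert np.allclose(a, b, atol=1e-9)

    def test_loadings_orthonormal_variance_monotone(self):
        profiles = self._gradient_profiles()
        res = enr.go_pca(profiles)
        L = res.loadings.to_numpy()
        k = min(L.shape)
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-6)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-9

    def test_too_few_profiles_rejected(self):
        profiles = self._gradient_profiles(n_terms=6)[:2]
        with pytest.raises(ValueError, match="at least 3"):
            enr.go_pca(profiles)
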