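"""Frame detection, site extraction, normalization, differential testing."""

import numpy as np
import pandas as pd
import pytest

from ribocodon import ribosite as rs
from ribocodon import simulate as sim
from ribocodon.genetic_code import ALL_CODONS


def _reads_at(tid, positions, length=28, seq="A" * 28):
    return [rs.AlignedFootprint(tid, p, length, 50, seq) for p in positions]


def _frame_fixture(frame_counts, cds_start=30):
    """Reads of one length whose 5' ends realize the given per-frame totals,
    spread across codon positions 0..9 relative to the TIS."""
    reads = []
    for frame, n in enumerate(frame_counts):
        for i in range(n):
            cp = i % 10
            reads.append(rs.AlignedFootprint("t1", cds_start + 3 * cp + frame, 28, 50, ""))
    return reads, {"t1": (cds_start, cds_start + 300)}


class TestProfileFrames:
    def test_clean_dominant_frame_selected(self):
        reads, cds = _frame_fixture((500, 50, 40))
        prof = rs.profile_frames(reads, cds)[28]
        assert prof.selected and prof.dominant_frame == 0 and prof.trim == 0
        assert prof.counts_by_frame_total.tolist() == [500, 50, 40]

    def test_five_fold_rule_rejects(self):
        reads, cds = _frame_fixture((500, 150, 10))
        prof = rs.profile_frames(reads, cds)[28]
        assert not prof.selected and "not 5-fold" in prof.reason

    def test_majority_disagreement_rejects(self):
        # frame 1 wins in total but frame 0 wins most codon positions
        reads, cds = _frame_fixture((0, 0, 0))
        reads += _reads_at("t1", [30 + 3 * cp for cp in range(9)])  # frame 0 in 9 codons
        reads += _reads_at("t1", [30 + 1] * 100)  # frame 1 massed in one codon
        prof = rs.profile_frames(reads, cds)[28]
        assert not prof.selected

    def test_nonzero_frames_get_trim(self):
        for frame, trim in ((1, 2), (2, 1)):
            reads, cds = _frame_fixture(
                tuple(500 if f == frame else 0 for f in range(3)))
            prof = rs.profile_frames(reads, cds)[28]
            assert prof.selected and prof.dominant_frame == frame and prof.trim == trim

    def test_no_data_length(self):
        # reads exist but all 5' ends fall outside the TIS window
        reads = _reads_at("t1", [500, 510, 520])
        prof = rs.profile_frames(reads, {"t1": (30, 600)})[28]
        assert not prof.selected and prof.reason == "no data"

    def test_planted_frames_recovered(self):
        cfg = sim.SimulationConfig(
            seed=21, n_genes=40, n_footprints=20000,
            read_length_table={27: (0.4, 0), 28: (0.3, 1), 29: (0.3, {0: 0.40, 1: 0.35, 2: 0.25})},
        )
        tx, _ = sim.simulate_transcriptome(cfg)
        reads = sim.as_footprints(
            sim.simulate_footprints(tx, {t.gene_id: 1.0 for t in tx}, cfg)[0], tx)
        cds = {t.gene_id: (t.cds_start, t.cds_end) for t in tx}
        profs = rs.profile_frames(reads, cds)
        assert profs[27].selected and profs[27].dominant_frame == 0
        assert profs[28].selected and profs[28].dominant_frame == 1
        assert not profs[29].selected  # 40/35/25 mixture fails the 5-fold rule


class TestExtractSiteCodons:
    def test_single_read_p_and_a_sites(self):
        seq = "".join(ALL_CODONS[i] for i in (0, 1, 2, 3, 4, 5, 6, 7, 8)) + "A"  # 28 nt
        seq = "AAACCCGGGTTTACGTGCATCAGCTAGG"[:28]
        read = rs.AlignedFootprint("t1", 100, 28, 50, seq)
        profs = rs.forced_profiles([28], frame=0)
        cds = {"t1": (85, 400)}  # read start in frame: (100-85) % 3 == 0
        m = rs.extract_site_codons([read], cds, profs)
        assert m.n_reads_used == 1
        assert m.counts.at[seq[12:15], -1] == 1  # P-site = read nt 12-14
        assert m.counts.at[seq[15:18], 0] == 1  # A-site = read nt 15-17
        assert m.counts.at[seq[0:3], -5] == 1
        assert (m.counts.sum(axis=0) == 1).all()

    def test_low_overlap_discarded(self):
        # 11 of 28 nt in CDS (~39% overlap)
        read = rs.AlignedFootprint("t1", 100, 28, 50, "A" * 28)
        m = rs.extract_site_codons([read], {"t1": (117, 141)}, rs.forced_profiles([28]))
        assert m.n_reads_used == 0 and m.discards["low_overlap"] == 1

    def test_mapq_and_frame_filters(self):
        cds = {"t1": (99, 400)}
        low = rs.AlignedFootprint("t1", 102, 28, 5, "A" * 28)
        off = rs.AlignedFootprint("t1", 103, 28, 50, "A" * 28)
        m = rs.extract_site_codons([low, off], cds, rs.forced_profiles([28]))
        assert m.discards["low_mapq"] == 1 and m.discards["off_frame"] == 1

    def test_trimmed_read_too_short(self):
        read = rs.AlignedFootprint("t1", 101, 27, 50, "A" * 27)  # frame 2 -> trim 1 -> 26 nt
        m = rs.extract_site_codons([read], {"t1": (99, 400)}, rs.forced_profiles([27], frame=2))
        assert m.discards["too_short"] == 1

    def test_matches_naive_enumeration(self, small_dataset):
        fps = small_dataset["footprints"][:1000]
        cds = small_dataset["cds"]
        profs = rs.profile_frames(fps, cds)
        m = rs.extract_site_codons(fps, cds, profs)
        expected = np.zeros((64, 9), dtype=int)
        idx = {c: i for i, c in enumerate(ALL_CODONS)}
        selected = {l: p.dominant_frame for l, p in profs.items() if p.selected}
        for r in fps:
            s, e = cds[r.transcript_id]
            if r.length not in selected or r.mapq < 20:
                continue
            if (min(r.start + r.length, e) - max(r.start, s)) / r.length < 0.5:
                continue
            if (r.start - s) % 3 != selected[r.length]:
                continue
            t = (3 - selected[r.length]) % 3
            if r.length - t < 27:
                continue
            w = r.sequence[t : t + 27]
            for k in range(9):
                expected[idx[w[3 * k : 3 * k + 3]], k] += 1
        assert (m.counts.values == expected).all()


class TestNormalization:
    def test_identity_for_flat_codon(self):
        counts = pd.DataFrame(0, index=ALL_CODONS, columns=rs.SITE_POSITIONS)
        counts.loc["AAA"] = 10
        counts.loc["CCC"] = 90
        m = rs.SiteCountMatrix("s", counts, 100)
        nm = rs.normalize_site_counts(m)
        assert np.allclose(nm.values.loc["AAA"], 1.0)
        assert np.allclose(nm.values.loc["CCC"], 1.0)

    def test_enriched_position_value(self):
        # codon at fraction 0.02 in 8 positions and 0.04 at the A-site -> 1.8
        counts = pd.DataFrame(0, index=ALL_CODONS, columns=rs.SITE_POSITIONS)
        counts.loc["AAA"] = 2
        counts.loc["AAA", 0] = 4
        counts.loc["CCC"] = 98
        counts.loc["CCC", 0] = 96
        nm = rs.normalize_site_counts(rs.SiteCountMatrix("s", counts, 100))
        assert nm.values.at["AAA", 0] == pytest.approx(0.04 / (0.20 / 9))

    def test_row_means_one_and_missing_codons(self, small_dataset):
        m = rs.extract_site_codons(
            small_dataset["footprints"], small_dataset["cds"],
            rs.profile_frames(small_dataset["footprints"], small_dataset["cds"]))
        nm = rs.normalize_site_counts(m)
        means = nm.values.mean(axis=1)
        seen = m.counts.sum(axis=1) > 0
        assert np.allclose(means[seen], 1.0, atol=1e-9)
        assert nm.values.loc[~seen].isna().all().all()
        assert np.allclose(nm.fractions.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_matrix_rejected(self):
        counts = pd.DataFrame(0, index=ALL_CODONS, columns=rs.SITE_POSITIONS)
        with pytest.raises(ValueError):
            rs.normalize_site_counts(rs.SiteCountMatrix("s", counts, 0))


def _norm_from_values(values):
    df = pd.DataFrame(values, index=ALL_CODONS, columns=rs.SITE_POSITIONS)
    return rs.NormalizedSiteMatrix("s", df, df / 9)


class TestDifferential:
    def test_identical_replicates_null(self, rng):
        base = rng.uniform(0.5, 1.5, size=(64, 9))
        reps = [_norm_from_values(base) for _ in range(4)]
        table = rs.differential_codon_usage(reps, reps)
        assert (table["p"] == 1.0).all()
        assert (table["log2_fc"] == 0).all()

    def test_zero_variance_unequal_means_flagged(self, rng):
        a = rng.uniform(0.5, 1.5, size=(64, 9))
        b = a.copy()
        b[0, 0] *= 2
        table = rs.differential_codon_usage(
            [_norm_from_values(a)] * 2, [_norm_from_values(b)] * 2)
        hit = table[(table["codon"] == ALL_CODONS[0]) & (table["position"] == -5)]
        assert hit["flag"].iloc[0] == "zero-variance unequal means"
        assert hit["p"].iloc[0] > 0

    def test_bh_closed_form(self):
        assert rs.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        q = rs.bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert (q >= [0.01, 0.04, 0.03, 0.005]).all()
        assert (np.diff(np.sort(q)) >= -1e-15).all()

    def test_requires_two_replicates(self, rng):
        m = _norm_from_values(rng.uniform(0.5, 1.5, size=(64, 9)))
        with pytest.raises(ValueError, match="replicates"):
            rs.differential_codon_usage([m], [m, m])

    def test_welch_vs_student_switch(self, rng):
        mats_a = [_norm_from_values(1 + 0.01 * rng.standard_normal((64, 9))) for _ in range(4)]
        mats_b = [_norm_from_values(1 + 0.05 * rng.standard_normal((64, 9))) for _ in range(4)]
        welch = rs.differential_codon_usage(mats_a, mats_b)
        student = rs.differential_codon_usage(mats_a, mats_b, equal_var=True)
        assert not np.allclose(welch["p"], student["p"])


class TestShiftCorrelation:
    def _table(self, lfc):
        return pd.DataFrame({
            "codon": ALL_CODONS, "position": 0, "log2_fc": lfc})

    def test_self_and_anti_correlation(self, rng):
        lfc = rng.standard_normal(64)
        t = self._table(lfc)
        assert rs.correlate_codon_shifts(t, t, 0)["all"][0] == pytest.approx(1.0)
        assert rs.correlate_codon_shifts(t, self._table(-lfc), 0)["all"][0] == pytest.approx(-1.0)
        assert "hetadat" in rs.correlate_codon_shifts(t, t, 0)

    def test_too_few_codons(self):
        t = self._table(np.r_[np.ones(2), [np.nan] * 62])
        with pytest.raises(ValueError, match="shared"):
            rs.correlate_codon_shifts(t, t, 0)


class TestMonotonicity:
    def test_asite_value_monotone_in_dwell_weight(self):
        """Raising a codon's planted A-site dwell weight never lowers its
        recovered A-site normalized value (w in {1, 2, 4}, fixed seed)."""
        values = []
        for w in (1.0, 2.0, 4.0):
            cfg = sim.SimulationConfig(
                seed=31, n_genes=60, n_footprints=30000,
                gene_length_range=(80, 160), dwell_weights={"AAA": w},
            )
            tx, _ = sim.simulate_transcriptome(cfg)
            reads = sim.as_footprints(
                sim.simulate_footprints(tx, {t.gene_id: 1.0 for t in tx}, cfg, seed=31)[0], tx)
            cds = {t.gene_id: (t.cds_start, t.cds_end) for t in tx}
            m = rs.extract_site_codons(reads, cds, rs.forced_profiles([27, 28, 29]))
            values.append(rs.normalize_site_counts(m).values.at["AAA", 0])
        assert values[0] <= values[1] <= values[2]


class TestFlankConcordance:
    def test_stop_stall_lowers_asite_concordance(self, small_dataset):
        from ribocodon.genetic_code import codon_vector

        m = rs.extract_site_codons(
            small_dataset["footprints"], small_dataset["cds"],
            rs.forced_profiles([27, 28, 29]))
        vectors = [t.cds_record() for t in small_dataset["tx"]]
        genomic = rs.genomic_codon_distribution(
            [codon_vector(v) for v in vectors], small_dataset["expr"])
        r = rs.flank_concordance(m, genomic)
        # small fixture: flanks concordant up to sampling noise, A-site worst
        flanks = [r[p] for p in (-5, -4, -3, 1, 2, 3)]
        assert min(flanks) > 0.8
        assert r[0] < min(flanks)  # stop stalling perturbs the A-site most

    def test_empty_matrix_rejected(self):
        counts = pd.DataFrame(0, index=ALL_CODONS, columns=rs.SITE_POSITIONS)
        with pytest.raises(ValueError):
            rs.flank_concordance(rs.SiteCountMatrix("s", counts, 0),
                                 pd.Series(1 / 64, index=ALL_CODONS))
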