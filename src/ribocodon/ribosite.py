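"""Ribosome E/P/A-site codon occupancy from transcript-space footprints.

The central statistic: each sufficiently long, in-frame footprint read is
split into nine codons at positions -5..+3 (0 = A-site, -1 = P-site,
-2 = E-site; on an untrimmed in-frame read the P-site codon occupies read nt
12-14 and the A-site nt 15-17, 0-based). Counting codons per position and
normalizing each codon's positional fraction by its mean fraction across the
nine positions cancels transcript-abundance and decay effects, leaving the
relative dwell of the ribosome on that codon at that site. Flanking
positions (-5..-3, +1..+3) are not tRNA-bound and should track the
expression-weighted genomic codon distribution, serving as a negative
control.

Reading frames differ between read lengths within an experiment, so each
read length is calibrated independently from the 5'-end positions of its
reads around the translation initiation site (TIS), and lengths without a
clean dominant frame are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import ALL_CODONS, GENETIC_CODE, CodonVector

SITE_POSITIONS = list(range(-5, 4))
P_SITE_READ_OFFSET = 12  # P-site codon at read nt [12, 15) after trimming
A_SITE_READ_OFFSET = 15
READ_SPAN = 27  # nine codons
_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

#: TIS-relative codon window used for frame calibration.
TIS_WINDOW = (-7, 32)
FIVEFOLD = 5.0


@dataclass
class AlignedFootprint:
    """One ungapped single-end footprint alignment in transcript space."""

    transcript_id: str
    start: int
    length: int
    mapq: int
    sequence: str


def read_sam(path) -> List[AlignedFootprint]:
    """Load mapped, ungapped primary alignments from a SAM/BAM file."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            reads.append(
                AlignedFootprint(
                    transcript_id=a.reference_name,
                    start=a.reference_start,
                    length=a.query_length,
                    mapq=a.mapping_quality,
                    sequence=a.query_sequence or "",
                )
            )
    return reads


def load_bed(path) -> Dict[str, Tuple[int, int]]:
    """CDS intervals per transcript from a BED file (0-based half-open)."""
    out: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out[f[0]] = (int(f[1]), int(f[2]))
    return out


# ---------------------------------------------------------------------------
# Frame / offset detection


@dataclass
class FrameProfile:
    """Frame calibration verdict for one read length.

    ``counts_by_frame_total`` counts 5' ends per frame inside the TIS window;
    ``codon_wins`` counts, per frame, the codon positions where that frame
    holds the per-codon majority. A length is selected when one frame wins
    both tallies and is at least five-fold above the runner-up in each.
    ``trim`` is the number of nt to drop from the 5' end to bring reads of
    this length in frame (P-site back at read nt 12-14).
    """

    read_length: int
    counts_by_frame_total: np.ndarray
    per_codon_majority: Dict[int, int]
    codon_wins: np.ndarray
    selected: bool
    dominant_frame: Optional[int]
    trim: Optional[int]
    reason: str = ""


def _frame_trim(frame: int) -> int:
    return (3 - frame) % 3


def profile_frames(
    reads: Iterable[AlignedFootprint],
    cds: Mapping[str, Tuple[int, int]],
    tis_window: Tuple[int, int] = TIS_WINDOW,
    fold: float = FIVEFOLD,
) -> Dict[int, FrameProfile]:
    """Detect the dominant 5'-end reading frame per read length around the TIS.

    For each read length, 5' ends falling in codon positions
    ``tis_window`` relative to the TIS are tallied by frame, both in total
    and as per-codon majorities; the selection rule requires a single frame
    to win both tallies with at least ``fold``-fold margin.
    """
    lo, hi = tis_window
    by_len: Dict[int, np.ndarray] = {}
    for r in reads:
        iv = cds.get(r.transcript_id)
        if iv is None:
            continue
        grid = by_len.setdefault(r.length, np.zeros((hi - lo + 1, 3), dtype=np.int64))
        d = r.start - iv[0]
        cp = d // 3 if d >= 0 else -((-d + 2) // 3)
        if cp < lo or cp > hi:
            continue
        frame = d % 3
        grid[cp - lo, frame] += 1

    profiles: Dict[int, FrameProfile] = {}
    for length, grid in sorted(by_len.items()):
        totals = grid.sum(axis=0)
        majority: Dict[int, int] = {}
        wins = np.zeros(3, dtype=np.int64)
        for i in range(grid.shape[0]):
            if grid[i].sum() == 0:
                continue
            f = int(np.argmax(grid[i]))  # ties break to the lowest frame
            majority[lo + i] = f
            wins[f] += 1
        if totals.sum() == 0:
            profiles[length] = FrameProfile(length, totals, {}, wins, False, None, None, "no data")
            continue
        gw = int(np.argmax(totals))
        mw = int(np.argmax(wins))
        ts = np.sort(totals)[::-1]
        ws = np.sort(wins)[::-1]
        ok = True
        reason = ""
        if mw != gw:
            ok, reason = False, "per-codon majority frame disagrees with total"
        elif ts[1] > 0 and ts[0] < fold * ts[1]:
            ok, reason = False, f"total frame counts not {fold:g}-fold separated"
        elif ws[1] > 0 and ws[0] < fold * ws[1]:
            ok, reason = False, f"per-codon wins not {fold:g}-fold separated"
        profiles[length] = FrameProfile(
            read_length=length,
            counts_by_frame_total=totals,
            per_codon_majority=majority,
            codon_wins=wins,
            selected=ok,
            dominant_frame=gw if ok else None,
            trim=_frame_trim(gw) if ok else None,
            reason=reason,
        )
    return profiles


def forced_profiles(lengths: Sequence[int], frame: int = 0) -> Dict[int, FrameProfile]:
    """Fixed-length profiles (e.g. human mode: lengths 27-29, frame 0)."""
    return {
        l: FrameProfile(
            read_length=l,
            counts_by_frame_total=np.zeros(3, dtype=np.int64),
            per_codon_majority={},
            codon_wins=np.zeros(3, dtype=np.int64),
            selected=True,
            dominant_frame=frame,
            trim=_frame_trim(frame),
            reason="forced",
        )
        for l in lengths
    }


# ---------------------------------------------------------------------------
# Site extraction


@dataclass
class SiteCountMatrix:
    """Codon x position (-5..+3) footprint counts for one sample.

    Every used read contributes exactly one codon at each of the nine
    positions, so column sums are equal. ``discards`` tallies filter reasons.
    """

    sample_id: str
    counts: pd.DataFrame  # 64 codons x 9 positions
    n_reads_used: int
    discards: Dict[str, int] = field(default_factory=dict)

    def fractions(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=0)
        return self.counts / tot


@dataclass
class NormalizedSiteMatrix:
    """Per-position codon fractions scaled by each codon's nine-position mean.

    A value of 1 means the codon is no more frequent at that position than
    across the protected window; for each codon the mean across the nine
    positions is exactly 1. Codons never observed are missing (NaN).
    """

    sample_id: str
    values: pd.DataFrame
    fractions: pd.DataFrame


def extract_site_codons(
    reads: Iterable[AlignedFootprint],
    cds: Mapping[str, Tuple[int, int]],
    profiles: Mapping[int, FrameProfile],
    min_overlap: float = 0.5,
    mapq_min: int = 20,
    sample_id: str = "sample",
) -> SiteCountMatrix:
    """Count codons at the nine ribosome-protected positions.

    A read is used when its length was frame-selected, its mapping quality is
    at least ``mapq_min``, it overlaps the CDS by at least ``min_overlap`` of
    its length, and its 5'-end frame matches the expected frame for its
    length. After trimming the length-specific offset, read nt [0, 27) are
    split into the nine codons at positions -5..+3.
    """
    counts = np.zeros((64, 9), dtype=np.int64)
    discards = {
        "unknown_transcript": 0,
        "length_not_selected": 0,
        "low_mapq": 0,
        "low_overlap": 0,
        "off_frame": 0,
        "too_short": 0,
        "ambiguous_base": 0,
    }
    selected = {l: p for l, p in profiles.items() if p.selected}
    n_used = 0
    for r in reads:
        iv = cds.get(r.transcript_id)
        if iv is None:
            discards["unknown_transcript"] += 1
            continue
        prof = selected.get(r.length)
        if prof is None:
            discards["length_not_selected"] += 1
            continue
        if r.mapq < mapq_min:
            discards["low_mapq"] += 1
            continue
        ov = min(r.start + r.length, iv[1]) - max(r.start, iv[0])
        if ov / r.length < min_overlap:
            discards["low_overlap"] += 1
            continue
        if (r.start - iv[0]) % 3 != prof.dominant_frame:
            discards["off_frame"] += 1
            continue
        trim = prof.trim
        if r.length - trim < READ_SPAN:
            discards["too_short"] += 1
            continue
        window = r.sequence[trim : trim + READ_SPAN]
        idx = []
        ok = True
        for k in range(0, READ_SPAN, 3):
            ci = _CODON_INDEX.get(window[k : k + 3])
            if ci is None:
                ok = False
                break
            idx.append(ci)
        if not ok:
            discards["ambiguous_base"] += 1
            continue
        for pi, ci in enumerate(idx):
            counts[ci, pi] += 1
        n_used += 1
    return SiteCountMatrix(
        sample_id=sample_id,
        counts=pd.DataFrame(counts, index=ALL_CODONS, columns=SITE_POSITIONS),
        n_reads_used=n_used,
        discards=discards,
    )


def pool_counts(matrices: Sequence[SiteCountMatrix], sample_id: str = "pooled") -> SiteCountMatrix:
    """Sum replicate count matrices (for display; tests use per-replicate)."""
    counts = sum(m.counts for m in matrices)
    disc: Dict[str, int] = {}
    for m in matrices:
        for k, v in m.discards.items():
            disc[k] = disc.get(k, 0) + v
    return SiteCountMatrix(sample_id, counts, sum(m.n_reads_used for m in matrices), disc)


def normalize_site_counts(m: SiteCountMatrix) -> NormalizedSiteMatrix:
    """Scale each codon's per-position fraction by its nine-position mean."""
    tot = m.counts.sum(axis=0)
    if (tot == 0).any() or m.counts.values.sum() == 0:
        raise ValueError("empty position in site count matrix")
    frac = m.counts / tot
    rowmean = frac.mean(axis=1)
    values = frac.div(rowmean, axis=0)
    values[rowmean == 0] = np.nan
    return NormalizedSiteMatrix(sample_id=m.sample_id, values=values, fractions=frac)


# ---------------------------------------------------------------------------
# Differential codon usage


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def differential_codon_usage(
    cond_a: Sequence[NormalizedSiteMatrix],
    cond_b: Sequence[NormalizedSiteMatrix],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per (codon, position) test of normalized occupancy between conditions.

    Welch's unequal-variance two-sided t-test on replicate normalized values
    by default (``equal_var=True`` restores the pooled-variance Student
    test); Benjamini-Hochberg step-up across all tested (codon, position)
    pairs. ``log2_fc`` is condition B over condition A.
    """
    if len(cond_a) < 2 or len(cond_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    tiny = float(np.nextafter(0, 1))
    rows = []
    for codon in ALL_CODONS:
        for pos in SITE_POSITIONS:
            a = np.array([m.values.at[codon, pos] for m in cond_a], dtype=float)
            b = np.array([m.values.at[codon, pos] for m in cond_b], dtype=float)
            if np.isnan(a).any() or np.isnan(b).any():
                continue
            ma, mb = a.mean(), b.mean()
            degenerate = ""
            if a.var() == 0 and b.var() == 0:
                if ma == mb:
                    p, t = 1.0, 0.0
                else:
                    p, t = tiny, math.copysign(math.inf, mb - ma)
                    degenerate = "zero-variance unequal means"
            else:
                t, p = stats.ttest_ind(b, a, equal_var=equal_var)
            lfc = np.log2(mb / ma) if ma > 0 and mb > 0 else np.nan
            rows.append(
                {
                    "codon": codon,
                    "position": pos,
                    "mean_norm_a": ma,
                    "mean_norm_b": mb,
                    "log2_fc": lfc,
                    "t_statistic": float(t),
                    "p": float(p),
                    "flag": degenerate,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no (codon, position) pairs with complete replicate data")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["q"] < alpha
    return table


def correlate_codon_shifts(
    table_a: pd.DataFrame, table_b: pd.DataFrame, position: int
) -> Dict[str, Tuple[float, float]]:
    """Pearson correlation of per-codon log2 fold changes at one site.

    Used to compare codon-usage shifts across datasets or species. Returns
    correlations for all shared codons and for the hetADAT-dependent subset.
    """
    a = table_a[table_a["position"] == position].set_index("codon")["log2_fc"].dropna()
    b = table_b[table_b["position"] == position].set_index("codon")["log2_fc"].dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared codons")
    out: Dict[str, Tuple[float, float]] = {}
    r, p = stats.pearsonr(a[shared], b[shared])
    out["all"] = (float(r), float(p))
    het = [c for c in shared if GENETIC_CODE.is_hetadat(c)]
    if len(het) >= 3:
        r, p = stats.pearsonr(a[het], b[het])
        out["hetadat"] = (float(r), float(p))
    return out


def genomic_codon_distribution(
    vectors: Sequence[CodonVector], expression: Mapping[str, float]
) -> pd.Series:
    """Expression-weighted codon distribution of the transcriptome.

    Approximates the codon composition of the footprint pool: the mean of
    per-gene codon frequency vectors weighted by expression (footprints per
    gene scale with expression, and each footprint samples codons from its
    own gene, so gene length does not enter).
    """
    acc = np.zeros(64)
    for v in vectors:
        w = float(expression.get(v.gene_id, 0.0))
        if w <= 0:
            continue
        for c, f in v.freq.items():
            acc[_CODON_INDEX[c]] += w * f
    if acc.sum() == 0:
        raise ValueError("zero total expression weight")
    return pd.Series(acc / acc.sum(), index=ALL_CODONS)


def flank_concordance(m: SiteCountMatrix, genomic: pd.Series) -> pd.Series:
    """Pearson r per position between positional codon fractions and the
    genomic distribution — a QC gate: flanks should correlate highly while
    the A- and P-sites may deviate (they carry the dwell signal)."""
    if m.counts.values.sum() == 0:
        raise ValueError("empty site count matrix")
    frac = m.fractions()
    g = genomic.reindex(ALL_CODONS).fillna(0.0)
    out = {}
    for pos in SITE_POSITIONS:
        r, _ = stats.pearsonr(frac[pos].to_numpy(), g.to_numpy())
        out[pos] = float(r)
    return pd.Series(out)
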