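"""Seeded generators for every input the pipeline consumes, with ground truth.

The simulators emulate the statistical structure the downstream analyses
assume, so that planted truth can be recovered and asserted:

* a transcriptome whose per-gene synonymous codon choice is controlled by a
  planted GC3 parameter (third-base G/C fraction);
* two-condition expression with a known set of differentially expressed
  genes, exported as DESeq2-style tables (gene, log2FC, adjusted p);
* ribosome footprints placed with per-codon A-site (and optionally P-site)
  dwell weights and per-read-length 5'-end frame offsets, so that occupancy
  at a ribosome site is proportional to the planted dwell weight — exactly
  the assumption the nine-position occupancy statistic tests;
* tRNA-seq reads over a mature tRNA reference with planted wobble-position
  A-to-G (inosine) rates plus uniform sequencing error.

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .genetic_code import ALL_CODONS, GENETIC_CODE, CdsRecord

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_SENSE_CODONS = [c for c in ALL_CODONS if not GENETIC_CODE.is_stop(c)]
_STOP_CODONS = sorted(GENETIC_CODE.stop_codons)

FrameSpec = Union[int, Mapping[int, float]]


def _salted_rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, salt])


@dataclass
class TrnaGene:
    """A simulated tRNA gene: raw (pre-splicing) sequence plus annotation."""

    trna_id: str
    isotype: str
    anticodon: str
    raw_sequence: str
    anticodon_start: int  # 0-based, raw coordinates
    intron: Optional[Tuple[int, int]] = None  # 0-based half-open, raw coords


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study design the analyses were built for: four
    biological replicates per cell state, footprints dominated by read
    lengths 27–29 nt with in-frame 5' ends, stop codons dwelling ~4x longer
    at the A-site (termination pausing), and wobble-inosine levels in the
    0.6–0.9 range.
    """

    seed: int = 0
    n_genes: int = 1000
    gene_length_range: Tuple[int, int] = (100, 400)  # codons, incl. ATG+stop
    gc3_range: Tuple[float, float] = (0.2, 0.8)
    n_replicates: int = 4
    de_fraction: float = 0.1
    de_log2fc_range: Tuple[float, float] = (0.5, 3.0)
    dwell_weights: Dict[str, float] = field(
        default_factory=lambda: {c: 4.0 for c in _STOP_CODONS}
    )
    p_dwell_weights: Dict[str, float] = field(default_factory=dict)
    read_length_table: Dict[int, Tuple[float, FrameSpec]] = field(
        default_factory=lambda: {27: (0.3, 0), 28: (0.5, 0), 29: (0.2, 0)}
    )
    n_footprints: int = 100_000
    trna_set: Optional[List[TrnaGene]] = None
    inosine_rates: Optional[Dict[str, float]] = None
    n_reads_per_trna: int = 500
    seq_error_rate: float = 0.001
    utr5_range: Tuple[int, int] = (20, 50)
    utr3_range: Tuple[int, int] = (15, 40)

    def validate(self) -> None:
        if self.gene_length_range[0] < 3 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError(f"degenerate gene_length_range {self.gene_length_range}")
        fr = sum(f for f, _ in self.read_length_table.values())
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"read length fractions sum to {fr}, expected 1")
        for c, w in {**self.dwell_weights, **self.p_dwell_weights}.items():
            if w <= 0:
                raise ValueError(f"dwell weight for {c} must be > 0")
        for r in (self.de_fraction, self.seq_error_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.inosine_rates:
            for t, th in self.inosine_rates.items():
                if not 0 <= th <= 1:
                    raise ValueError(f"inosine rate for {t} outside [0, 1]")
        if self.utr5_range[0] < 17:
            raise ValueError("5' UTR must be >= 17 nt so upstream-shifted footprints fit")
        max_len = max(self.read_length_table)
        if max_len - 18 + 2 > self.utr3_range[0]:
            raise ValueError("3' UTR too short for the longest read length")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["read_length_table"] = {
            int(k): [v[0], v[1] if isinstance(v[1], int) else dict(v[1])]
            for k, v in self.read_length_table.items()
        }
        if d["trna_set"] is not None:
            d["trna_set"] = [dataclasses.asdict(t) for t in self.trna_set]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "read_length_table" in d:
            d["read_length_table"] = {
                int(k): (v[0], v[1] if isinstance(v[1], int) else {int(a): b for a, b in v[1].items()})
                for k, v in d["read_length_table"].items()
            }
        for key in ("gene_length_range", "gc3_range", "de_log2fc_range", "utr5_range", "utr3_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("trna_set"):
            d["trna_set"] = [
                TrnaGene(**{**t, "intron": tuple(t["intron"]) if t.get("intron") else None})
                for t in d["trna_set"]
            ]
        return cls(**d)


# ---------------------------------------------------------------------------
# Transcriptome


@dataclass
class Transcript:
    gene_id: str
    sequence: str  # full transcript: 5'UTR + CDS + 3'UTR
    cds_start: int  # 0-based half-open CDS interval on the transcript
    cds_end: int
    planted_gc3: float

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def cds_record(self) -> CdsRecord:
        return CdsRecord(gene_id=self.gene_id, sequence=self.cds)


@dataclass
class Transcriptome:
    transcripts: List[Transcript]

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def by_id(self) -> Dict[str, Transcript]:
        return {t.gene_id: t for t in self.transcripts}

    def cds_records(self) -> List[CdsRecord]:
        return [t.cds_record() for t in self.transcripts]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.gene_id}\n{t.sequence}\n")

    def write_cds_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.gene_id}\n{t.cds}\n")

    def write_bed(self, path) -> None:
        """CDS intervals in transcript coordinates, 0-based half-open BED."""
        with open(path, "w") as fh:
            for t in self.transcripts:
                fh.write(f"{t.gene_id}\t{t.cds_start}\t{t.cds_end}\t{t.gene_id}\t0\t+\n")


def _sample_codons(rng: np.random.Generator, n: int, gc3: float) -> List[str]:
    """Sample sense codons with third-base weight gc3 for G/C vs 1-gc3 for A/T."""
    w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in _SENSE_CODONS])
    w /= w.sum()
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=w)
    return [_SENSE_CODONS[i] for i in idx]


def simulate_transcriptome(config: SimulationConfig, seed: Optional[int] = None) -> Tuple[Transcriptome, Dict]:
    """Generate CDS-bearing transcripts with a planted per-gene GC3 gradient.

    Every CDS starts with ATG, ends with a single stop, and contains no
    internal stop. The planted GC3 controls the synonymous third-base choice;
    realized GC3 tracks it closely (r > 0.9 for n >= 500 genes).

    Returns the transcriptome and a truth record with the planted GC3 and
    UTR/CDS coordinates per gene.
    """
    config.validate()
    rng = _salted_rng(seed if seed is not None else config.seed, 1)
    lo, hi = config.gene_length_range
    g3lo, g3hi = config.gc3_range
    transcripts = []
    truth_rows = []
    for i in range(config.n_genes):
        gene_id = f"g{i:05d}"
        n_codons = int(rng.integers(lo, hi + 1))
        gc3 = float(rng.uniform(g3lo, g3hi))
        body = _sample_codons(rng, n_codons - 2, gc3)
        stop_w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in _STOP_CODONS])
        stop = _STOP_CODONS[int(rng.choice(3, p=stop_w / stop_w.sum()))]
        cds = "ATG" + "".join(body) + stop
        utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(*config.utr5_range))))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))))
        seq = utr5 + cds + utr3
        transcripts.append(
            Transcript(gene_id, seq, len(utr5), len(utr5) + len(cds), gc3)
        )
        truth_rows.append({"gene_id": gene_id, "planted_gc3": gc3, "n_codons": n_codons})
    truth = {"genes": pd.DataFrame(truth_rows)}
    return Transcriptome(transcripts), truth


# ---------------------------------------------------------------------------
# Expression and differential-expression tables


def simulate_expression(
    transcriptome: Transcriptome, config: SimulationConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Two-condition expression with a planted DE gene set.

    Columns: gene_id, expr_a, expr_b, true_log2fc, is_de. Expression is
    log-normal; condition B scales DE genes by 2**log2FC with random sign.
    """
    rng = _salted_rng(seed if seed is not None else config.seed, 2)
    n = len(transcriptome)
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    is_de = rng.random(n) < config.de_fraction
    lfc = np.zeros(n)
    lo, hi = config.de_log2fc_range
    lfc[is_de] = rng.uniform(lo, hi, size=is_de.sum()) * rng.choice([-1.0, 1.0], size=is_de.sum())
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcriptome],
            "expr_a": base,
            "expr_b": base * np.exp2(lfc),
            "true_log2fc": lfc,
            "is_de": is_de,
        }
    )


def simulate_de_tables(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    seed: Optional[int] = None,
    gc3_coupling: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """DESeq2-style (gene_id, log2fc, padj) tables plus planted truth.

    DE genes get their true log2FC perturbed by measurement noise and small
    adjusted p-values; null genes get noise around zero and adjusted
    p-values that rarely pass 0.05. ``gc3_coupling`` adds a GC3-proportional
    shift to every gene's log2FC, planting an association between codon
    usage and expression change.
    """
    rng = _salted_rng(seed if seed is not None else config.seed, 3)
    expr = simulate_expression(transcriptome, config, seed=seed)
    lfc = expr["true_log2fc"].to_numpy().copy()
    if gc3_coupling:
        gc3 = np.array([t.planted_gc3 for t in transcriptome])
        lfc = lfc + gc3_coupling * (gc3 - gc3.mean()) / max(gc3.std(), 1e-12)
    n = len(expr)
    obs = lfc + rng.normal(0, 0.15, size=n)
    de = expr["is_de"].to_numpy() | (np.abs(lfc) > 1.0)
    padj = np.where(de, 10.0 ** (-rng.uniform(2, 8, size=n)), rng.uniform(0.05, 1.0, size=n))
    table = pd.DataFrame({"gene_id": expr["gene_id"], "log2fc": obs, "padj": padj})
    truth = expr.assign(planted_log2fc=lfc)
    return table, truth


# ---------------------------------------------------------------------------
# Ribosome footprints

#: A-site codon sits at read nt [15, 18) on an untrimmed, frame-0 read.
A_SITE_OFFSET = 15
#: The nine ribosome-protected codon positions; 0 = A-site, -1 = P, -2 = E.
SITE_POSITIONS = list(range(-5, 4))


@dataclass
class SimRead:
    transcript_id: str
    start: int  # 0-based transcript coordinate of the 5' end
    length: int
    mapq: int = 50


def _frame_to_shift(frame: int) -> int:
    """nt the 5' end sits upstream of the in-frame position (== trim needed)."""
    return (3 - frame) % 3


def _dwell_array(weights: Mapping[str, float], codons: Sequence[str]) -> np.ndarray:
    return np.array([weights.get(c, 1.0) for c in codons])


def simulate_footprints(
    transcriptome: Transcriptome,
    expression: Mapping[str, float],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Tuple[List[SimRead], Dict]:
    """Place ribosome footprints with planted dwell weights and frame offsets.

    A read's gene is drawn proportional to expression; its A-site codon
    within the gene proportional to the planted A-site dwell weight of that
    codon (times the P-site weight of the preceding codon, when P-site
    weights are configured). Read length and the 5'-end frame offset follow
    ``config.read_length_table``; on an untrimmed frame-0 read the A-site
    occupies nt 15–17 and the P-site nt 12–14 (0-based).
    """
    config.validate()
    rng = _salted_rng(seed if seed is not None else config.seed, 4)
    tx = transcriptome.transcripts
    expr = np.array([max(float(expression.get(t.gene_id, 0.0)), 0.0) for t in tx])
    if expr.sum() <= 0:
        raise ValueError("all expression weights are zero")

    # Flat distribution over (gene, A-site codon) pairs.
    flat_p = []
    flat_gene = []
    flat_a = []
    for gi, t in enumerate(tx):
        if expr[gi] == 0:
            continue
        cods = [t.cds[i : i + 3] for i in range(0, t.cds_end - t.cds_start, 3)]
        w = _dwell_array(config.dwell_weights, cods)
        if config.p_dwell_weights:
            wp = np.ones(len(cods))
            wp[1:] = _dwell_array(config.p_dwell_weights, cods[:-1])
            w = w * wp
        p = expr[gi] * w / w.sum()
        flat_p.append(p)
        flat_gene.append(np.full(len(cods), gi, dtype=np.int32))
        flat_a.append(np.arange(len(cods), dtype=np.int32))
    p = np.concatenate(flat_p)
    p /= p.sum()
    gene_idx = np.concatenate(flat_gene)
    a_idx = np.concatenate(flat_a)

    pick = rng.choice(len(p), size=config.n_footprints, p=p)
    lengths_avail = sorted(config.read_length_table)
    len_frac = np.array([config.read_length_table[l][0] for l in lengths_avail])
    len_pick = rng.choice(len(lengths_avail), size=config.n_footprints, p=len_frac / len_frac.sum())
    lengths = np.array(lengths_avail)[len_pick]

    frames = np.empty(config.n_footprints, dtype=np.int32)
    for li, l in enumerate(lengths_avail):
        spec = config.read_length_table[l][1]
        mask = len_pick == li
        if isinstance(spec, int):
            frames[mask] = spec
        else:
            fr = np.array(sorted(spec))
            fw = np.array([spec[f] for f in fr], dtype=float)
            frames[mask] = fr[rng.choice(len(fr), size=int(mask.sum()), p=fw / fw.sum())]

    reads: List[SimRead] = []
    n_dropped = 0
    cds_starts = np.array([t.cds_start for t in tx])
    tx_lens = np.array([len(t.sequence) for t in tx])
    shifts = (3 - frames) % 3
    starts = cds_starts[gene_idx[pick]] + 3 * a_idx[pick] - A_SITE_OFFSET - shifts
    ends = starts + lengths
    ok = (starts >= 0) & (ends <= tx_lens[gene_idx[pick]])
    n_dropped = int((~ok).sum())
    for s, l, gi in zip(starts[ok], lengths[ok], gene_idx[pick][ok]):
        reads.append(SimRead(tx[gi].gene_id, int(s), int(l)))

    truth = {
        "dwell_weights": dict(config.dwell_weights),
        "p_dwell_weights": dict(config.p_dwell_weights),
        "read_length_frames": {
            l: config.read_length_table[l][1] for l in lengths_avail
        },
        "n_reads": len(reads),
        "n_dropped_out_of_bounds": n_dropped,
    }
    return reads, truth


def as_footprints(reads: Sequence[SimRead], transcriptome: Transcriptome):
    """Materialize simulated reads as aligned footprints (with sequences),
    bypassing SAM round-tripping for in-memory analysis."""
    from .ribosite import AlignedFootprint

    by_id = transcriptome.by_id()
    return [
        AlignedFootprint(
            transcript_id=r.transcript_id,
            start=r.start,
            length=r.length,
            mapq=r.mapq,
            sequence=by_id[r.transcript_id].sequence[r.start : r.start + r.length],
        )
        for r in reads
    ]


def write_sam(reads: Sequence[SimRead], transcriptome: Transcriptome, path) -> None:
    """Write transcript-space single-end ungapped alignments as text SAM."""
    by_id = transcriptome.by_id()
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": t.gene_id, "LN": len(t.sequence)} for t in transcriptome.transcripts
        ],
    }
    tid = {t.gene_id: i for i, t in enumerate(transcriptome.transcripts)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.reference_id = tid[r.transcript_id]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = 0
            seq = by_id[r.transcript_id].sequence[r.start : r.start + r.length]
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            out.write(a)


def expected_site_fractions(
    transcriptome: Transcriptome,
    expression: Mapping[str, float],
    config: SimulationConfig,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Closed-form expected per-position codon fractions under the planted model.

    Computes, exactly, the codon fraction at each of the nine ribosome-
    protected positions that the extraction step converges to: footprint
    placement weight (expression x dwell) times the probability mass of
    (read length, frame) combinations passing the CDS-overlap filter.
    Requires pure planted frames per read length (no frame mixtures).

    Returns a 64 x 9 DataFrame (rows = codons, columns = positions -5..+3).
    """
    for l, (_, spec) in config.read_length_table.items():
        if not isinstance(spec, int):
            raise ValueError("oracle requires a single planted frame per read length")
    lengths = sorted(config.read_length_table)
    lfrac = np.array([config.read_length_table[l][0] for l in lengths])
    lfrac = lfrac / lfrac.sum()
    lshift = np.array([_frame_to_shift(config.read_length_table[l][1]) for l in lengths])

    expr = {t.gene_id: max(float(expression.get(t.gene_id, 0.0)), 0.0) for t in transcriptome}
    total_expr = sum(expr.values())
    codon_index = {c: i for i, c in enumerate(ALL_CODONS)}
    counts = np.zeros((64, 9))
    for t in transcriptome:
        if expr[t.gene_id] == 0:
            continue
        L = (t.cds_end - t.cds_start) // 3
        cods = [t.cds[3 * i : 3 * i + 3] for i in range(L)]
        w = _dwell_array(config.dwell_weights, cods)
        if config.p_dwell_weights:
            wp = np.ones(L)
            wp[1:] = _dwell_array(config.p_dwell_weights, cods[:-1])
            w = w * wp
        w = expr[t.gene_id] / total_expr * w / w.sum()
        a = np.arange(L)
        # probability mass of (length, frame-shift) combos passing the filter
        pass_mass = np.zeros(L)
        for frac, l, sh in zip(lfrac, np.array(lengths), lshift):
            starts = t.cds_start + 3 * a - A_SITE_OFFSET - sh
            in_tx = (starts >= 0) & (starts + l <= len(t.sequence))
            ov = np.minimum(starts + l, t.cds_end) - np.maximum(starts, t.cds_start)
            pass_mass += frac * ((ov / l >= min_overlap) & in_tx)
        eff = w * pass_mass
        # in-frame codon sequence extended 5 codons into the 5'UTR and 3 into the 3'UTR
        ext = [
            codon_index[t.sequence[t.cds_start + 3 * i : t.cds_start + 3 * i + 3]]
            for i in range(-5, L + 3)
        ]
        ext = np.array(ext)
        for pi, pos in enumerate(SITE_POSITIONS):
            counts[:, pi] += np.bincount(ext[a + pos + 5], weights=eff, minlength=64)
    frac = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(frac, index=ALL_CODONS, columns=SITE_POSITIONS)


# ---------------------------------------------------------------------------
# tRNA reference and reads

# anticodon read by nnT codons (wobble A pairs with the codon's third base T);
# reverse complement of the nnT codon of each hetADAT isotype
_HETADAT_ANTICODONS = {
    "Ala": "AGC", "Arg": "ACG", "Ile": "AAT", "Leu": "AAG",
    "Pro": "AGG", "Ser": "AGA", "Thr": "AGT", "Val": "AAC",
}


def default_trna_set(seed: int = 0, isodecoders_per_isotype: int = 2) -> List[TrnaGene]:
    """A compact tRNA gene set: hetADAT substrates plus two controls.

    Each of the eight hetADAT isotypes contributes ``isodecoders_per_isotype``
    genes with adenosine at the anticodon wobble position (anticodon start,
    placed at the canonical offset 33 of the body). Two non-substrate tRNAs
    (Phe-GAA, Gly-GCC) carry G34. Two of the substrate genes carry a short
    intron downstream of the anticodon, exercising mature-reference splicing.
    """
    rng = _salted_rng(seed, 5)
    genes: List[TrnaGene] = []
    anticodon_start = 33

    def body(anticodon: str) -> str:
        up = "".join(rng.choice(list("ACGT"), size=anticodon_start))
        down = "".join(rng.choice(list("ACGT"), size=36))
        return up + anticodon + down

    k = 0
    for iso in sorted(_HETADAT_ANTICODONS):
        ac = _HETADAT_ANTICODONS[iso]
        for j in range(isodecoders_per_isotype):
            seq = body(ac)
            intron = None
            if k < 2:  # plant an intron in the first two genes
                ilen = int(rng.integers(10, 21))
                ipos = anticodon_start + 4
                iseq = "".join(rng.choice(list("ACGT"), size=ilen))
                seq = seq[:ipos] + iseq + seq[ipos:]
                intron = (ipos, ipos + ilen)
            genes.append(TrnaGene(f"tRNA-{iso}-{ac}-{j+1}", iso, ac, seq, anticodon_start, intron))
            k += 1
    for iso, ac in (("Phe", "GAA"), ("Gly", "GCC")):
        genes.append(TrnaGene(f"tRNA-{iso}-{ac}-1", iso, ac, body(ac), anticodon_start, None))
    return genes


def write_trna_reference(genes: Sequence[TrnaGene], fasta_path, annotation_path) -> None:
    """Write the raw (pre-splicing) tRNA FASTA and its annotation TSV."""
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.trna_id}\n{g.raw_sequence}\n")
    rows = []
    for g in genes:
        rows.append(
            {
                "trna_id": g.trna_id,
                "isotype": g.isotype,
                "anticodon": g.anticodon,
                "anticodon_start": g.anticodon_start,
                "intron_start": g.intron[0] if g.intron else "",
                "intron_end": g.intron[1] if g.intron else "",
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def simulate_trna_reads(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[List, List[Tuple[str, int, str]], Dict]:
    """Simulate tRNA-seq reads with planted wobble inosine rates.

    Returns (mature TrnaRecord list, reads, truth). Each read is a
    full-length copy of its mature tRNA; hetADAT substrates carry G instead
    of A at the anticodon wobble position with probability theta_t, and every
    base is independently flipped to a uniformly chosen other base with the
    per-base sequencing error rate. Reads are (trna_id, start=0, sequence).
    """
    from .inosine import build_mature_reference

    config.validate()
    rng = _salted_rng(seed if seed is not None else config.seed, 6)
    genes = config.trna_set if config.trna_set is not None else default_trna_set(
        seed if seed is not None else config.seed
    )
    records = build_mature_reference(genes)
    rec_by_id = {r.trna_id: r for r in records}

    rates = config.inosine_rates
    if rates is None:
        rates = {
            r.trna_id: float(rng.uniform(0.6, 0.9))
            for r in records
            if r.mature_sequence[r.anticodon_start] == "A"
        }
    for t, th in rates.items():
        rec = rec_by_id[t]
        if rec.mature_sequence[rec.anticodon_start] != "A":
            raise ValueError(f"{t}: inosine rate given but wobble base is not A")

    reads: List[Tuple[str, int, str]] = []
    eps = config.seq_error_rate
    for rec in records:
        seq = np.frombuffer(rec.mature_sequence.encode(), dtype="S1").copy()
        n = config.n_reads_per_trna
        mat = np.tile(seq, (n, 1))
        theta = rates.get(rec.trna_id)
        if theta is not None:
            sub = rng.random(n) < theta
            mat[sub, rec.anticodon_start] = b"G"
        if eps > 0:
            err = rng.random(mat.shape) < eps
            if err.any():
                alt = rng.integers(1, 4, size=int(err.sum()))
                base_idx = np.array([_BASE_IDX[b] for b in mat[err].astype(str)])
                bases = np.frombuffer(b"ACGT", dtype="S1")
                mat[err] = bases[(base_idx + alt) % 4]
        for row in mat:
            reads.append((rec.trna_id, 0, row.tobytes().decode()))
    truth = {"inosine_rates": dict(rates), "n_reads_per_trna": config.n_reads_per_trna}
    return records, reads, truth


def write_trna_sam(reads: Sequence[Tuple[str, int, str]], records, path) -> None:
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": r.trna_id, "LN": len(r.mature_sequence)} for r in records],
    }
    tid = {r.trna_id: i for i, r in enumerate(records)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (t, start, seq) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"trnaread{i}"
            a.reference_id = tid[t]
            a.reference_start = start
            a.mapping_quality = 50
            a.flag = 0
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            out.write(a)


# ---------------------------------------------------------------------------
# GO assignments and TE tables


def simulate_gene2go(
    transcriptome: Transcriptome,
    n_terms: int = 20,
    genes_per_term: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign genes to synthetic GO terms along the planted GC3 gradient.

    Genes are ranked by planted GC3 and cut into contiguous windows, one per
    term, so term-mean GC3 varies smoothly across terms — the structure a
    codon-frequency PCA should recover on its first component.
    """
    rng = _salted_rng(seed, 7)
    order = sorted(transcriptome.transcripts, key=lambda t: t.planted_gc3)
    n = len(order)
    rows = []
    for ti in range(n_terms):
        center = (ti + 0.5) / n_terms
        lo = max(0, int(center * n) - genes_per_term)
        hi = min(n, int(center * n) + genes_per_term)
        pool = order[lo:hi]
        take = rng.choice(len(pool), size=min(genes_per_term, len(pool)), replace=False)
        for gi in take:
            rows.append({"gene_id": pool[gi].gene_id, "term_id": f"GO:{ti:07d}"})
    return pd.DataFrame(rows)


def simulate_te_tables(
    n_genes: int = 5000,
    nnc_high_fraction: float = 0.01,
    odds_higher: float = 3.0,
    base_p_higher: float = 0.14,
    base_p_lower: float = 0.14,
    fold: float = 2.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ribo/RNA DE-table pair with planted TE classes and an nnC-high subset.

    A fraction of genes is flagged nnC-high; among those the odds of the
    "higher ribosome occupancy" class are multiplied by ``odds_higher``.
    Returns (de_ribo, de_rna, nnc_table, truth); nnc_table carries a
    synthetic nnC fraction exceeding the 99th percentile exactly for the
    flagged genes.
    """
    rng = _salted_rng(seed, 8)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    # exactly the stated fraction of nnC-high genes, at random positions
    n_high = int(round(nnc_high_fraction * n_genes))
    is_high = np.zeros(n_genes, dtype=bool)
    is_high[rng.choice(n_genes, size=n_high, replace=False)] = True
    p_hi = np.where(is_high, _odds_scale(base_p_higher, odds_higher), base_p_higher)
    p_lo = np.full(n_genes, base_p_lower)
    u = rng.random(n_genes)
    cls = np.where(u < p_hi, "higher", np.where(u < p_hi + p_lo, "lower", "similar"))
    lim = np.log2(fold)
    delta = np.where(
        cls == "higher",
        lim + rng.uniform(0.2, 2.0, n_genes),
        np.where(cls == "lower", -lim - rng.uniform(0.2, 2.0, n_genes),
                 rng.uniform(-0.9 * lim, 0.9 * lim, n_genes)),
    )
    rna = rng.normal(0, 1.0, n_genes)
    ribo = rna + delta
    padj = rng.uniform(0, 1, n_genes)
    de_rna = pd.DataFrame({"gene_id": gene_ids, "log2fc": rna, "padj": padj})
    de_ribo = pd.DataFrame({"gene_id": gene_ids, "log2fc": ribo, "padj": padj})
    # synthetic nnC fractions: nnC-high genes sit above the rest
    frac = rng.uniform(0.05, 0.20, n_genes)
    frac[is_high] = rng.uniform(0.30, 0.45, int(is_high.sum()))
    nnc = pd.DataFrame({"gene_id": gene_ids, "nnc_fraction": frac})
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_class": cls, "is_nnc_high": is_high, "true_delta": delta}
    )
    return de_ribo, de_rna, nnc, truth


def _odds_scale(p: float, k: float) -> float:
    o = k * p / (1 - p)
    return o / (1 + o)


def write_truth(truth: Dict, path) -> None:
    """Serialize a truth record to JSON (DataFrames as records)."""
    def enc(v):
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="list")
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    with open(path, "w") as fh:
        json.dump({k: enc(v) for k, v in truth.items()}, fh, indent=1, default=enc)
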