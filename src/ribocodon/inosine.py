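"""Wobble-inosine (A34I) quantification from tRNA-seq alignments.

Inosine at the anticodon wobble position (tRNA position 34, the first
anticodon base) is installed by hetADAT (ADAT2/ADAT3) on eight tRNA isotypes
and is read as guanosine by reverse transcriptases, so the modification level
per tRNA is the A-to-G substitution fraction at that position in aligned
reads. The wobble position is located through the annotated anticodon rather
than a fixed absolute coordinate — tRNA lengths vary — and the reference base
is verified to be A before a tRNA enters the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genetic_code import HETADAT_ISOTYPES

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class TrnaRecord:
    """A mature tRNA: introns spliced, CCA tail present, anticodon verified."""

    trna_id: str
    isotype: str
    anticodon: str
    anticodon_start: int  # 0-based offset of the anticodon in mature_sequence
    mature_sequence: str

    @property
    def wobble_base(self) -> str:
        return self.mature_sequence[self.anticodon_start]

    @property
    def is_hetadat_substrate(self) -> bool:
        return self.isotype in HETADAT_ISOTYPES and self.wobble_base == "A"


def build_mature_reference(genes) -> List[TrnaRecord]:
    """Splice introns, append the CCA tail, and verify the anticodon.

    ``genes`` is a sequence of objects with trna_id, isotype, anticodon,
    raw_sequence, anticodon_start (raw coordinates) and an optional intron
    interval (0-based half-open, raw coordinates). The anticodon offset is
    recomputed after splicing and checked against the annotated anticodon.
    """
    records = []
    for g in genes:
        seq = g.raw_sequence.upper()
        acs = g.anticodon_start
        if g.intron is not None:
            i0, i1 = g.intron
            if not (0 <= i0 < i1 <= len(seq)):
                raise ValueError(f"{g.trna_id}: intron {g.intron} outside sequence")
            if i0 < acs + 3 and i1 > acs:
                raise ValueError(f"{g.trna_id}: intron overlaps the anticodon")
            seq = seq[:i0] + seq[i1:]
            if i1 <= acs:
                acs -= i1 - i0
        if not seq.endswith("CCA"):
            seq = seq + "CCA"
        if seq[acs : acs + 3] != g.anticodon:
            raise ValueError(
                f"{g.trna_id}: anticodon {g.anticodon} not found at offset {acs} after splicing"
            )
        records.append(
            TrnaRecord(
                trna_id=g.trna_id,
                isotype=g.isotype,
                anticodon=g.anticodon,
                anticodon_start=acs,
                mature_sequence=seq,
            )
        )
    return records


def load_trna_reference(fasta_path, annotation_path) -> List[TrnaRecord]:
    """Read a raw tRNA FASTA plus annotation TSV and build mature records.

    The TSV columns are trna_id, isotype, anticodon, anticodon_start and
    optional intron_start/intron_end (0-based half-open, raw coordinates).
    """
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t")

    class _Gene:
        pass

    genes = []
    for _, row in ann.iterrows():
        g = _Gene()
        g.trna_id = row["trna_id"]
        g.isotype = row["isotype"]
        g.anticodon = row["anticodon"]
        g.anticodon_start = int(row["anticodon_start"])
        g.raw_sequence = seqs[row["trna_id"]]
        i0, i1 = row.get("intron_start"), row.get("intron_end")
        g.intron = (
            (int(i0), int(i1))
            if pd.notna(i0) and str(i0) != "" and pd.notna(i1) and str(i1) != ""
            else None
        )
        genes.append(g)
    return build_mature_reference(genes)


@dataclass
class TrnaPileup:
    """Per-tRNA, per-position A/C/G/T counts from ungapped alignments."""

    counts: Dict[str, np.ndarray]  # trna_id -> (length, 4) int array

    def base_counts(self, trna_id: str, position: int) -> Dict[str, int]:
        arr = self.counts[trna_id][position]
        return {b: int(arr[i]) for b, i in _BASE_IDX.items()}


def pileup_from_reads(
    reads: Sequence[Tuple[str, int, str]], records: Sequence[TrnaRecord]
) -> TrnaPileup:
    """Build a base pileup from in-memory (trna_id, start, sequence) reads."""
    counts = {r.trna_id: np.zeros((len(r.mature_sequence), 4), dtype=np.int64) for r in records}
    for tid, start, seq in reads:
        arr = counts.get(tid)
        if arr is None:
            continue
        for i, b in enumerate(seq):
            pos = start + i
            if pos >= arr.shape[0]:
                break
            j = _BASE_IDX.get(b)
            if j is not None:
                arr[pos, j] += 1
    return TrnaPileup(counts=counts)


def pileup_from_sam(path, records: Sequence[TrnaRecord]) -> TrnaPileup:
    """Build a base pileup from a SAM/BAM of ungapped tRNA alignments."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            reads.append((a.reference_name, a.reference_start, a.query_sequence or ""))
    return pileup_from_reads(reads, records)


@dataclass
class InosineTable:
    """Per-tRNA wobble A-to-G fractions with the sample-level aggregate.

    ``per_trna`` has columns trna_id, isotype, depth, g_count, fraction,
    included (depth above the reporting cutoff). ``aggregate`` is the
    read-weighted modification level: total G reads over total depth across
    hetADAT-substrate tRNAs — identically the depth-weighted mean of the
    per-tRNA fractions.
    """

    sample_id: str
    per_trna: pd.DataFrame
    aggregate: float
    isotype_means: pd.Series


def estimate_inosine(
    pileup: TrnaPileup,
    records: Sequence[TrnaRecord],
    min_depth: int = 10,
    sample_id: str = "sample",
) -> InosineTable:
    """Estimate per-tRNA and aggregate wobble-inosine levels.

    The per-tRNA fraction is G/(A+C+G+T) at the wobble position. tRNAs at or
    below ``min_depth`` reads are excluded from the reported per-tRNA
    distribution (``included=False``) but still contribute to the
    read-weighted aggregate. Isotype means average included tRNAs. tRNAs
    whose reference wobble base is not A are reported but never aggregated.
    """
    rows = []
    g_total = 0
    depth_total = 0
    for rec in records:
        bc = pileup.base_counts(rec.trna_id, rec.anticodon_start)
        depth = sum(bc.values())
        g = bc["G"]
        substrate = rec.isotype in HETADAT_ISOTYPES
        if substrate and rec.wobble_base != "A":
            raise ValueError(f"{rec.trna_id}: hetADAT substrate with wobble base {rec.wobble_base}")
        frac = g / depth if depth > 0 else np.nan
        if substrate and rec.wobble_base == "A":
            g_total += g
            depth_total += depth
        rows.append(
            {
                "trna_id": rec.trna_id,
                "isotype": rec.isotype,
                "wobble_base": rec.wobble_base,
                "depth": depth,
                "g_count": g,
                "fraction": frac,
                "is_substrate": substrate,
                "included": substrate and depth > min_depth,
            }
        )
    per_trna = pd.DataFrame(rows)
    aggregate = g_total / depth_total if depth_total else np.nan
    inc = per_trna[per_trna["included"]]
    isotype_means = inc.groupby("isotype")["fraction"].mean()
    return InosineTable(sample_id, per_trna, aggregate, isotype_means)


def compare_conditions(
    tables_a: Sequence[InosineTable],
    tables_b: Sequence[InosineTable],
) -> Dict[str, object]:
    """Compare wobble-inosine levels between two conditions.

    Per-tRNA and per-isotype deltas (B minus A) use the replicate-mean
    fractions; when both conditions supply >= 2 replicates, the per-sample
    aggregates are compared with a two-sided t-test, otherwise the test is
    omitted with a warning entry.
    """
    if not tables_a or not tables_b:
        raise ValueError("need at least one table per condition")

    def mean_frac(tables: Sequence[InosineTable]) -> pd.Series:
        per = pd.concat(
            [t.per_trna[t.per_trna["included"]][["trna_id", "fraction"]] for t in tables]
        )
        return per.groupby("trna_id")["fraction"].mean()

    fa, fb = mean_frac(tables_a), mean_frac(tables_b)
    shared = fa.index.intersection(fb.index)
    if len(shared) == 0:
        raise ValueError("no shared tRNA ids between conditions")
    delta = (fb[shared] - fa[shared]).rename("delta")
    iso = tables_a[0].per_trna.set_index("trna_id")["isotype"]
    per_isotype = delta.groupby(iso[shared]).mean()

    out: Dict[str, object] = {
        "per_trna_delta": delta,
        "per_isotype_delta": per_isotype,
        "aggregate_a": float(np.mean([t.aggregate for t in tables_a])),
        "aggregate_b": float(np.mean([t.aggregate for t in tables_b])),
    }
    if len(tables_a) >= 2 and len(tables_b) >= 2:
        t, p = stats.ttest_ind(
            [tb.aggregate for tb in tables_b], [ta.aggregate for ta in tables_a]
        )
        out["aggregate_test"] = {"t": float(t), "p": float(p)}
    else:
        out["aggregate_test"] = None
        out["warning"] = "test omitted: fewer than 2 replicates per condition"
    return out


def inosine_table_tsv(table: InosineTable, path) -> None:
    table.per_trna.to_csv(path, sep="\t", index=False)
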