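"""Genetic-code tables, CDS records, and per-gene codon frequency vectors.

Everything downstream (enrichment, ribosome-site occupancy, translation-
efficiency classification) consumes the :class:`CodonVector` produced here:
each coding sequence is represented as a vector of 64 relative codon
frequencies together with the GC fraction at each of the three codon
positions (GC1/GC2/GC3).

The module also defines the hetADAT codon sets: the heterodimeric adenosine
deaminase (ADAT2/ADAT3) deaminates adenosine 34 — the anticodon wobble base —
to inosine in eight tRNA isotypes (Ala, Arg, Ile, Leu, Pro, Ser, Thr, Val).
Inosine pairs with C, U and A, so those eight tRNAs read the corresponding
nnC, nnT and nnA codon sets; the eight nnC codons in particular depend on the
modification because they have few or no dedicated tRNA genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Set

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable as _CodonTable

BASES = "ACGT"

#: All 64 DNA codons in alphabetical order (fixed column order for outputs).
ALL_CODONS: List[str] = [a + b + c for a in BASES for b in BASES for c in BASES]

HETADAT_ISOTYPES: Set[str] = {"Ala", "Arg", "Ile", "Leu", "Pro", "Ser", "Thr", "Val"}

# Codons read by inosine-modified tRNAs, keyed by wobble base class. The
# first two bases identify the eight hetADAT isotypes.
HETADAT_CODONS: Dict[str, Set[str]] = {
    "nnC": {"GCC", "CGC", "ATC", "CTC", "CCC", "TCC", "ACC", "GTC"},
    "nnT": {"GCT", "CGT", "ATT", "CTT", "CCT", "TCT", "ACT", "GTT"},
    "nnA": {"GCA", "CGA", "ATA", "CTA", "CCA", "TCA", "ACA", "GTA"},
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCodeTable:
    """The standard genetic code plus wobble/degeneracy annotation.

    Attributes
    ----------
    codon_to_aa
        Maps each of the 64 codons to a three-letter amino acid or ``"STOP"``.
    stop_codons
        ``{"TAA", "TAG", "TGA"}``.
    degeneracy
        For each codon, the number of synonymous codons sharing its first two
        bases (its codon-box family size), e.g. 4 for GCN (Ala), 1 for ATG.
    third_base_class
        ``"nnA" | "nnC" | "nnG" | "nnT"`` by the wobble (third) base.
    hetadat_isotypes, hetadat_codons
        The eight inosine-dependent tRNA isotypes and their nnC/nnT/nnA codon
        boxes.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset
    degeneracy: Mapping[str, int]
    third_base_class: Mapping[str, str]
    hetadat_isotypes: frozenset = frozenset(HETADAT_ISOTYPES)
    hetadat_codons: Mapping[str, frozenset] = field(
        default_factory=lambda: {k: frozenset(v) for k, v in HETADAT_CODONS.items()}
    )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def is_hetadat(self, codon: str) -> bool:
        return any(codon in s for s in self.hetadat_codons.values())


def _build_standard_table() -> GeneticCodeTable:
    ncbi = _CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa: Dict[str, str] = {}
    for codon in ALL_CODONS:
        if codon in ncbi.stop_codons:
            codon_to_aa[codon] = "STOP"
        else:
            codon_to_aa[codon] = _AA3[ncbi.forward_table[codon]]
    degeneracy = {
        c: sum(
            1 for b in BASES if codon_to_aa[c[:2] + b] == codon_to_aa[c]
        )
        for c in ALL_CODONS
    }
    third_base_class = {c: "nn" + c[2] for c in ALL_CODONS}
    return GeneticCodeTable(
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(ncbi.stop_codons),
        degeneracy=degeneracy,
        third_base_class=third_base_class,
    )


#: Module-level singleton; all analyses use the standard code.
GENETIC_CODE: GeneticCodeTable = _build_standard_table()


class CdsError(ValueError):
    """Raised for coding sequences violating the CDS contract."""


@dataclass
class CdsRecord:
    """One representative coding sequence for one gene.

    The sequence is DNA over {A,C,G,T,N}, its length a multiple of three,
    with at most one stop codon and only at the terminal position. Isoform
    collapsing to one CDS per gene is the caller's responsibility.
    """

    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codons(self) -> List[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def validate(self, permissive: bool = False) -> None:
        if len(self.sequence) == 0:
            raise CdsError(f"{self.gene_id}: empty sequence")
        if len(self.sequence) % 3 != 0:
            raise CdsError(f"{self.gene_id}: length {len(self.sequence)} not multiple of 3")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise CdsError(f"{self.gene_id}: invalid characters {sorted(bad)}")
        if not permissive:
            cods = self.codons()
            for i, c in enumerate(cods[:-1]):
                if GENETIC_CODE.is_stop(c):
                    raise CdsError(f"{self.gene_id}: internal stop at codon {i}")


@dataclass
class CodonVector:
    """Relative codon frequencies and positional GC content of one CDS.

    ``freq`` sums to 1 over counted codons; codons containing N are excluded
    from ``n_codons`` and from the GC denominators.
    """

    gene_id: str
    freq: Dict[str, float]
    n_codons: int
    gc1: float
    gc2: float
    gc3: float
    gc_total: float


def load_cds(path, permissive: bool = False) -> List[CdsRecord]:
    """Read coding sequences from a FASTA file.

    Each record is validated (length a multiple of 3; stops only terminal
    unless ``permissive``); duplicate gene ids are rejected. Record order is
    preserved.
    """
    records: List[CdsRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise CdsError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        cds = CdsRecord(gene_id=gene_id, sequence=str(rec.seq).upper())
        cds.validate(permissive=permissive)
        records.append(cds)
    if not records:
        raise CdsError(f"no FASTA records found in {path}")
    return records


def codon_vector(cds: CdsRecord, include_stops: bool = True) -> CodonVector:
    """Compute the 64-entry relative codon frequency vector of one CDS.

    Stop codons are counted by default (the ribosome-site analysis uses
    them); pass ``include_stops=False`` for amino-acid-level summaries.
    Codons containing N are skipped. GCk is the fraction of counted codons
    whose k-th base is G or C.
    """
    counts: Dict[str, int] = {}
    gc = [0, 0, 0]
    n = 0
    for c in cds.codons():
        if "N" in c:
            continue
        if not include_stops and GENETIC_CODE.is_stop(c):
            continue
        counts[c] = counts.get(c, 0) + 1
        n += 1
        for k in range(3):
            if c[k] in "GC":
                gc[k] += 1
    if n == 0:
        raise CdsError(f"{cds.gene_id}: no countable codons")
    freq = {c: k / n for c, k in counts.items()}
    gc1, gc2, gc3 = (g / n for g in gc)
    return CodonVector(
        gene_id=cds.gene_id,
        freq=freq,
        n_codons=n,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc_total=(gc1 + gc2 + gc3) / 3.0,
    )


def hetadat_nnc_fraction(cds: CdsRecord) -> float:
    """Fraction of a gene's codons in the eight hetADAT-dependent nnC codons.

    These are the codons whose translation relies on wobble inosine; the
    gene-level fraction feeds the nnC-high translation-efficiency analysis.
    """
    nnc = HETADAT_CODONS["nnC"]
    n = 0
    hits = 0
    for c in cds.codons():
        if "N" in c:
            continue
        n += 1
        if c in nnc:
            hits += 1
    if n == 0:
        raise CdsError(f"{cds.gene_id}: no countable codons")
    return hits / n


def vectors_to_frame(vectors: Iterable[CodonVector]) -> pd.DataFrame:
    """Tabulate codon vectors: gene_id, 64 codon columns, n_codons, GC1-3."""
    rows = []
    for v in vectors:
        row = {"gene_id": v.gene_id}
        row.update({c: v.freq.get(c, 0.0) for c in ALL_CODONS})
        row.update(n_codons=v.n_codons, gc1=v.gc1, gc2=v.gc2, gc3=v.gc3)
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", *ALL_CODONS, "n_codons", "gc1", "gc2", "gc3"])


def write_vectors_tsv(vectors: Iterable[CodonVector], path) -> None:
    vectors_to_frame(vectors).to_csv(path, sep="\t", index=False)
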