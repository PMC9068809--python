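"""Core domain objects for clonal-lineage substitution analysis.

A :class:`ReferenceGenome` holds contig sequences and gene models whose CDS
segments define coding versus non-coding space and codon frames.  Diploid
variant calls against that reference live in :class:`GenotypeCallSet`; each
call records whether one (``het``) or both (``hom_alt``) alleles differ from
the reference, which is the unit every downstream count is built from.

Coordinates are 0-based half-open throughout; the standard GFF3/VCF 1-based
dialects are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

from Bio.Data.CodonTable import standard_dna_table

VALID_BASES = frozenset("ACGTN")
SNV_BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: codon -> amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS; codons containing N become 'X'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(
        CODON_TO_AA.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
    )


@dataclass
class GeneModel:
    """A single gene's CDS as ordered genomic intervals.

    ``cds_segments`` are 0-based half-open intervals listed in *translation
    order*: ascending genomic start for plus-strand genes, descending for
    minus-strand genes (whose sequence is read reverse-complemented).
    """

    gene_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.cds_segments:
            if not 0 <= start < end:
                raise ValueError(f"bad CDS segment ({start}, {end})")

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_segments)

    def spliced_cds(self, contigs: dict[str, str]) -> str:
        """The gene's coding sequence in translation order."""
        seq = contigs[self.contig]
        if self.strand == "+":
            return "".join(seq[s:e] for s, e in self.cds_segments)
        return "".join(revcomp(seq[s:e]) for s, e in self.cds_segments)

    def genomic_positions(self) -> Iterator[int]:
        """Genomic positions of each CDS base, in translation order."""
        for start, end in self.cds_segments:
            if self.strand == "+":
                yield from range(start, end)
            else:
                yield from range(end - 1, start - 1, -1)

    def cds_index_of(self, pos: int) -> int:
        """Translation-order index (0-based) of genomic position ``pos``."""
        acc = 0
        for start, end in self.cds_segments:
            if start <= pos < end:
                if self.strand == "+":
                    return acc + (pos - start)
                return acc + (end - 1 - pos)
            acc += end - start
        raise ValueError(f"position {pos} not in CDS of gene {self.gene_id}")

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_segments)


@dataclass
class ReferenceGenome:
    """Contig sequences plus gene models.

    Invariants (checked by :meth:`validate`): CDS segments lie within their
    contig, segments of one gene do not overlap each other, the alphabet is
    restricted to A/C/G/T/N, and every CDS length is a positive multiple of 3.
    """

    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    _coding_index: dict | None = field(
        default=None, repr=False, compare=False
    )
    _effect_index: object | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.contigs.values())

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name}: invalid characters {bad}")
        for gene in self.genes:
            if gene.contig not in self.contigs:
                raise ValueError(f"gene {gene.gene_id}: unknown contig {gene.contig}")
            clen = len(self.contigs[gene.contig])
            segs = sorted(gene.cds_segments)
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"gene {gene.gene_id}: overlapping CDS segments")
            for s, e in segs:
                if e > clen:
                    raise ValueError(
                        f"gene {gene.gene_id}: segment ({s}, {e}) beyond contig end"
                    )
            if gene.cds_length % 3 or gene.cds_length == 0:
                raise ValueError(
                    f"gene {gene.gene_id}: CDS length {gene.cds_length} "
                    "is not a positive multiple of 3"
                )
            protein = translate(gene.spliced_cds(self.contigs))
            if "*" in protein[:-1]:
                warnings.warn(
                    f"gene {gene.gene_id}: internal stop codon in translation",
                    stacklevel=2,
                )

    def coding_index(self) -> dict[tuple[str, int], list[GeneModel]]:
        """Lazy map (contig, pos) -> genes whose CDS covers the site."""
        if self._coding_index is None:
            index: dict[tuple[str, int], list[GeneModel]] = {}
            for gene in self.genes:
                for s, e in gene.cds_segments:
                    for pos in range(s, e):
                        index.setdefault((gene.contig, pos), []).append(gene)
            self._coding_index = index
        return self._coding_index

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos]


def site_region(genome: ReferenceGenome, contig: str, pos: int) -> str:
    """Classify a site as ``"coding"`` or ``"non_coding"``."""
    if contig not in genome.contigs:
        raise KeyError(f"unknown contig {contig!r}")
    if not 0 <= pos < len(genome.contigs[contig]):
        raise IndexError(f"position {pos} outside contig {contig}")
    return "coding" if (contig, pos) in genome.coding_index() else "non_coding"


def codon_context(
    genome: ReferenceGenome, gene: GeneModel, pos: int
) -> tuple[str, int]:
    """Reference codon covering ``pos`` and the within-codon offset.

    The codon is read in translation order (reverse-complemented for
    minus-strand genes) and may span two CDS segments split by an intron.
    The offset (0..2) counts in the translation direction.
    """
    i = gene.cds_index_of(pos)
    spliced = gene.spliced_cds(genome.contigs)
    codon_idx = i // 3
    return spliced[3 * codon_idx : 3 * codon_idx + 3], i % 3


@dataclass(frozen=True)
class VariantCall:
    """One filtered biallelic SNV call in a diploid genotype."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # "hom_alt" or "het"
    depth: int
    qual: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.zygosity not in {"hom_alt", "het"}:
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def alleles(self) -> tuple[str, str]:
        """The unordered diploid allele pair at this site."""
        if self.zygosity == "hom_alt":
            return (self.alt_allele, self.alt_allele)
        return tuple(sorted((self.ref_allele, self.alt_allele)))


@dataclass
class GenotypeCallSet:
    """One clonal genotype's filtered diploid calls against the reference.

    ``callable_sites`` is the number of nucleotides examined — the denominator
    of the per-genotype substitution rate.  It is an explicit input (from the
    lineage table or simulation), not inferred from the calls.
    """

    genotype_id: str
    lineage_id: str
    calls: dict[tuple[str, int], VariantCall]
    callable_sites: int

    def __post_init__(self) -> None:
        if self.callable_sites < len(self.calls):
            raise ValueError(
                f"{self.genotype_id}: callable_sites ({self.callable_sites}) "
                f"< number of calls ({len(self.calls)})"
            )

    @property
    def n_hom(self) -> int:
        return sum(1 for c in self.calls.values() if c.zygosity == "hom_alt")

    @property
    def n_het(self) -> int:
        return sum(1 for c in self.calls.values() if c.zygosity == "het")
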