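"""Readers and writers for FASTA, GFF3, VCF and the lineage-assignment table.

Standard libraries do the format work (Biopython for FASTA, gffutils for
GFF3, pysam for VCF, pandas for tables); this module applies the project's
conventions on top: coordinates become 0-based half-open, sequences are
case-folded to upper, and VCF records pass the depth/quality call filters
(depth >= 5 inclusive, quality > 20 strict, by default) before entering a
:class:`~clonediv.genome.GenotypeCallSet`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    GeneModel,
    GenotypeCallSet,
    ReferenceGenome,
    VariantCall,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_QUAL = 20.0

LINEAGE_TABLE_COLUMNS = ["genotype_id", "lineage_id", "vcf_path", "callable_sites"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a contig-id -> uppercase-sequence mapping."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path, contigs: dict[str, str]) -> list[GeneModel]:
    """Read CDS features grouped by Parent into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Minus-strand genes get their segments ordered by descending genomic
    start (translation order).  Genes whose summed CDS length is not a
    positive multiple of 3 are skipped with a warning, as are genes whose
    translation contains an internal stop.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list[gffutils.Feature]] = {}
    strands: dict[str, str] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(f"CDS feature without Parent/ID at {feat.seqid}:{feat.start}")
        gene_id = parents[0]
        grouped.setdefault(gene_id, []).append(feat)
        strands[gene_id] = feat.strand

    genes: list[GeneModel] = []
    for gene_id, feats in grouped.items():
        strand = strands[gene_id]
        segments = [(f.start - 1, f.end) for f in feats]
        segments.sort(key=lambda seg: seg[0], reverse=(strand == "-"))
        total = sum(e - s for s, e in segments)
        if total % 3 or total == 0:
            warnings.warn(
                f"gene {gene_id}: CDS length {total} not a positive multiple "
                "of 3; gene skipped",
                stacklevel=2,
            )
            continue
        gene = GeneModel(gene_id, feats[0].seqid, strand, segments)
        if gene.contig in contigs:
            protein = translate(gene.spliced_cds(contigs))
            if "*" in protein[:-1]:
                warnings.warn(
                    f"gene {gene_id}: internal stop codon in translation",
                    stacklevel=2,
                )
        genes.append(gene)
    return genes


def write_gff3(genome: ReferenceGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gene in genome.genes:
            start = min(s for s, _ in gene.cds_segments)
            end = max(e for _, e in gene.cds_segments)
            fh.write(
                f"{gene.contig}\tclonediv\tgene\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            acc = 0
            for s, e in gene.cds_segments:
                phase = (3 - acc % 3) % 3
                fh.write(
                    f"{gene.contig}\tclonediv\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t{phase}\tID={gene.gene_id}.cds;"
                    f"Parent={gene.gene_id}\n"
                )
                acc += e - s


def read_reference(fasta_path: str | Path, gff3_path: str | Path) -> ReferenceGenome:
    """Convenience loader combining FASTA and GFF3 into a ReferenceGenome."""
    contigs = read_fasta(fasta_path)
    genes = read_gff3(gff3_path, contigs)
    return ReferenceGenome(contigs, genes)


# ---------------------------------------------------------------- VCF

@dataclass
class VcfReadStats:
    """Record-level accounting from one VCF read."""

    n_records: int = 0
    n_retained: int = 0
    n_depth_dropped: int = 0
    n_qual_dropped: int = 0
    n_non_snv: int = 0
    n_ref_or_missing: int = 0


def read_vcf(
    path: str | Path,
    *,
    genotype_id: str | None = None,
    lineage_id: str = "",
    callable_sites: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_qual: float = DEFAULT_MIN_QUAL,
    stats: VcfReadStats | None = None,
) -> GenotypeCallSet:
    """Read a single-sample VCF into a filtered :class:`GenotypeCallSet`.

    Only biallelic SNVs with depth >= ``min_depth`` and QUAL strictly >
    ``min_qual`` are retained.  GT 1/1 maps to ``hom_alt``, 0/1 or 1/0 to
    ``het``; 0/0 and missing genotypes are dropped.  Indels and multiallelic
    records are dropped with a logged count.  ``callable_sites`` (the number
    of nucleotides examined) must be supplied by the caller.
    """
    stats = stats if stats is not None else VcfReadStats()
    calls: dict[tuple[str, int], VariantCall] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"{path}: expected a single-sample VCF, found {len(samples)} samples"
            )
        sample_name = samples[0]
        for rec in vcf:
            stats.n_records += 1
            alts = rec.alts or ()
            if (
                len(rec.ref) != 1
                or len(alts) != 1
                or alts[0] is None
                or len(alts[0]) != 1
                or alts[0] not in "ACGT"
            ):
                stats.n_non_snv += 1
                continue
            sample = rec.samples[sample_name]
            gt = sample.get("GT")
            if gt is None:
                raise ValueError(f"{path}: record without GT at {rec.chrom}:{rec.pos}")
            if any(a is None for a in gt):
                stats.n_ref_or_missing += 1
                continue
            if len(gt) != 2:
                raise ValueError(
                    f"{path}: ploidy {len(gt)} at {rec.chrom}:{rec.pos}; "
                    "genotypes must be diploid"
                )
            if set(gt) == {0}:
                stats.n_ref_or_missing += 1
                continue
            depth = sample.get("DP")
            if depth is None or depth < min_depth:
                stats.n_depth_dropped += 1
                continue
            if rec.qual is None or not rec.qual > min_qual:
                stats.n_qual_dropped += 1
                continue
            zygosity = "hom_alt" if set(gt) == {1} else "het"
            call = VariantCall(
                contig=rec.chrom,
                pos=rec.start,
                ref_allele=rec.ref.upper(),
                alt_allele=alts[0].upper(),
                zygosity=zygosity,
                depth=int(depth),
                qual=float(rec.qual),
            )
            calls[(call.contig, call.pos)] = call
            stats.n_retained += 1
    dropped = stats.n_records - stats.n_retained
    if dropped:
        logger.info("%s: retained %d of %d records (%d dropped by filters)",
                    path, stats.n_retained, stats.n_records, dropped)
    return GenotypeCallSet(
        genotype_id=genotype_id or sample_name,
        lineage_id=lineage_id,
        calls=calls,
        callable_sites=callable_sites,
    )


def write_vcf(
    callset: GenotypeCallSet, path: str | Path, contigs: dict[str, str]
) -> None:
    """Write a GenotypeCallSet as an uncompressed single-sample VCF v4.2."""
    header = pysam.VariantHeader()
    for name, seq in contigs.items():
        header.contigs.add(name, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(callset.genotype_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (contig, pos), call in sorted(callset.calls.items()):
            rec = out.new_record(
                contig=contig,
                start=pos,
                stop=pos + 1,
                alleles=(call.ref_allele, call.alt_allele),
                qual=call.qual,
            )
            sample = rec.samples[callset.genotype_id]
            sample["GT"] = (1, 1) if call.zygosity == "hom_alt" else (0, 1)
            sample["DP"] = call.depth
            out.write(rec)


# ---------------------------------------------------------------- lineage table

def read_lineage_table(path: str | Path) -> pd.DataFrame:
    """Read the lineage-assignment TSV (genotype_id, lineage_id, vcf_path,
    callable_sites); genotype ids must be unique."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in LINEAGE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: lineage table missing columns {missing}")
    dup = table["genotype_id"][table["genotype_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated genotype_id {sorted(set(dup))}")
    return table


def write_lineage_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_cohort(
    table_path: str | Path,
    *,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_qual: float = DEFAULT_MIN_QUAL,
    stats: dict[str, VcfReadStats] | None = None,
) -> dict[str, GenotypeCallSet]:
    """Load every genotype listed in a lineage table.

    Relative ``vcf_path`` entries are resolved against the table's directory.
    """
    table_path = Path(table_path)
    table = read_lineage_table(table_path)
    cohort: dict[str, GenotypeCallSet] = {}
    for row in table.itertuples(index=False):
        vcf_path = Path(row.vcf_path)
        if not vcf_path.is_absolute():
            vcf_path = table_path.parent / vcf_path
        read_stats = VcfReadStats()
        cohort[row.genotype_id] = read_vcf(
            vcf_path,
            genotype_id=row.genotype_id,
            lineage_id=row.lineage_id,
            callable_sites=int(row.callable_sites),
            min_depth=min_depth,
            min_qual=min_qual,
            stats=read_stats,
        )
        if stats is not None:
            stats[row.genotype_id] = read_stats
    return cohort
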