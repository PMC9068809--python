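"""Shared fixtures: hand-built genomes and call-set constructors."""

from __future__ import annotations

import pytest

from clonediv.genome import GeneModel, GenotypeCallSet, ReferenceGenome, VariantCall


def make_call(contig, pos, ref, alt, zygosity="het", depth=30, qual=60.0):
    return VariantCall(
        contig=contig, pos=pos, ref_allele=ref, alt_allele=alt,
        zygosity=zygosity, depth=depth, qual=qual,
    )


def make_callset(genotype_id, calls, callable_sites, lineage_id="L1"):
    return GenotypeCallSet(
        genotype_id=genotype_id,
        lineage_id=lineage_id,
        calls={(c.contig, c.pos): c for c in calls},
        callable_sites=callable_sites,
    )


@pytest.fixture
def tiny_genome():
    """60-bp contig with one plus-strand and one minus-strand gene.

    plus gene  [10, 22): ATG AAA CCC TAA
    minus gene [30, 42): genomic TCACCCAAACAT = revcomp(ATG TTT GGG TGA)
    """
    background = ("ACGT" * 15)[:60]
    seq = list(background)
    seq[10:22] = "ATGAAACCCTAA"
    seq[30:42] = "TCACCCAAACAT"
    genome = ReferenceGenome(
        contigs={"c1": "".join(seq)},
        genes=[
            GeneModel("gplus", "c1", "+", [(10, 22)]),
            GeneModel("gminus", "c1", "-", [(30, 42)]),
        ],
    )
    genome.validate()
    return genome


@pytest.fixture
def split_codon_genome():
    """Gene whose second codon spans an intron: CDS [0,4) + [8,16).

    Spliced CDS = seq[0:4] + seq[8:16] = ATGA + AATTTGGG = ATG AAA TTT GGG.
    """
    seq = "ATGA" + "CCCC" + "AATTTGGG" + "ACGT" * 4
    genome = ReferenceGenome(
        contigs={"c2": seq},
        genes=[GeneModel("gsplit", "c2", "+", [(0, 4), (8, 16)])],
    )
    genome.validate()
    return genome
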