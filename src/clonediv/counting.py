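"""Substitution counting for clonal diploid genotypes.

Implements the per-genotype substitution rate

    N_sub = (2*hom + het) / (number of nucleotides examined),

where *hom* and *het* count sites at which both or one of a diploid
genotype's nucleotides differ from the reference; synonymous/nonsynonymous
classification of coding changes; per-genotype S and N counts versus the
reference; within-lineage pairwise counts (dS, dN and the non-coding count
dn-C) with each coding pairwise difference sorted into a homozygous or
heterozygous bucket; and per-genotype tallies of genes carrying unique
(genotype-private) nonsynonymous substitutions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import (
    CODON_TO_AA,
    GenotypeCallSet,
    ReferenceGenome,
    SNV_BASES,
    _COMPLEMENT,
)

logger = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NON_CODING = "non_coding"


class EffectIndex:
    """Precomputed per-site, per-alternate-base coding effects.

    For every CDS position the index stores, for each of the three possible
    alternate bases, whether substituting it changes the encoded amino acid
    (stop gain/loss counts as nonsynonymous).  Sites covered by more than one
    gene take the nonsynonymous call if any overlapping gene yields one.
    Building the index costs one pass over all CDS bases and makes repeated
    classification O(1), which the simulator and pairwise counting rely on.
    """

    def __init__(self, genome: ReferenceGenome) -> None:
        self.effects: dict[tuple[str, int], dict[str, str]] = {}
        self.genes_at: dict[tuple[str, int], tuple[str, ...]] = {}
        for gene in genome.genes:
            seq = genome.contigs[gene.contig]
            spliced = gene.spliced_cds(genome.contigs)
            for i, pos in enumerate(gene.genomic_positions()):
                codon_idx, off = divmod(i, 3)
                codon = spliced[3 * codon_idx : 3 * codon_idx + 3]
                aa_ref = CODON_TO_AA.get(codon, "X")
                ref_base = seq[pos]
                key = (gene.contig, pos)
                site = self.effects.setdefault(key, {})
                prev_genes = self.genes_at.get(key, ())
                if gene.gene_id not in prev_genes:
                    self.genes_at[key] = prev_genes + (gene.gene_id,)
                for alt in SNV_BASES:
                    if alt == ref_base:
                        continue
                    cds_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
                    mutant = codon[:off] + cds_alt + codon[off + 1 :]
                    aa_alt = CODON_TO_AA.get(mutant, "X")
                    effect = SYNONYMOUS if aa_alt == aa_ref else NONSYNONYMOUS
                    if site.get(alt) == NONSYNONYMOUS:
                        continue  # nonsynonymous wins on overlapping genes
                    site[alt] = effect

    def effect(self, contig: str, pos: int, alt: str) -> str:
        """Effect of substituting ``alt`` at a site; non_coding outside CDS."""
        site = self.effects.get((contig, pos))
        if site is None:
            return NON_CODING
        return site[alt]


def get_effect_index(genome: ReferenceGenome) -> EffectIndex:
    """Return the genome's cached effect index, building it on first use."""
    if genome._effect_index is None:
        genome._effect_index = EffectIndex(genome)
    return genome._effect_index  # type: ignore[return-value]


def classify_change(
    genome: ReferenceGenome, contig: str, pos: int, alt_allele: str
) -> str:
    """Classify a single-base change as synonymous, nonsynonymous or
    non_coding (strand-aware, standard genetic code)."""
    ref = genome.base_at(contig, pos)
    if alt_allele == ref:
        raise ValueError(
            f"alt allele equals reference base {ref!r} at {contig}:{pos}"
        )
    return get_effect_index(genome).effect(contig, pos, alt_allele)


def substitution_rate(callset: GenotypeCallSet) -> float:
    """Per-genotype substitution rate (2*hom + het) / callable_sites."""
    if callset.callable_sites <= 0:
        raise ValueError(f"{callset.genotype_id}: callable_sites must be positive")
    return (2 * callset.n_hom + callset.n_het) / callset.callable_sites


@dataclass
class GenotypeCodingCounts:
    """Synonymous (S) and nonsynonymous (N) counts versus the reference."""

    genotype_id: str
    S: int
    N: int

    @property
    def ratio(self) -> float | None:
        """N/S, or None when S = 0 (undefined)."""
        return self.N / self.S if self.S > 0 else None


def count_S_N(
    genome: ReferenceGenome,
    callset: GenotypeCallSet,
    *,
    allele_weighted: bool = False,
) -> GenotypeCodingCounts:
    """Count synonymous and nonsynonymous substitutions versus the reference.

    By default each variant site counts once regardless of zygosity; with
    ``allele_weighted`` a homozygous site counts twice (sensitivity mode).
    """
    index = get_effect_index(genome)
    S = N = 0
    for call in callset.calls.values():
        effect = index.effect(call.contig, call.pos, call.alt_allele)
        if effect == NON_CODING:
            continue
        weight = 2 if allele_weighted and call.zygosity == "hom_alt" else 1
        if effect == SYNONYMOUS:
            S += weight
        else:
            N += weight
    return GenotypeCodingCounts(callset.genotype_id, S, N)


@dataclass
class PairwiseCounts:
    """Pairwise substitution counts for one within-lineage genotype pair.

    ``dnC`` counts differing non-coding sites; ``dS``/``dN`` differing coding
    sites by synonymous/nonsynonymous effect, each decomposed into a
    homozygous bucket (both genotypes homozygous at the site) and a
    heterozygous bucket (either genotype heterozygous), without regard to
    the direction of change between zygosity states.
    """

    genotype_a: str
    genotype_b: str
    lineage_id: str
    dnC: int = 0
    dS: int = 0
    dN: int = 0
    dS_hom: int = 0
    dS_het: int = 0
    dN_hom: int = 0
    dN_het: int = 0
    sites_compared: int = 0
    n_effect_ties: int = 0

    @property
    def total(self) -> int:
        return self.dnC + self.dS + self.dN


def _allele_counts(call, ref: str) -> Counter:
    if call is None:
        return Counter({ref: 2})
    return Counter(call.alleles)


def pairwise_counts(
    genome: ReferenceGenome,
    callset_a: GenotypeCallSet,
    callset_b: GenotypeCallSet,
    *,
    mask_a: set[tuple[str, int]] | None = None,
    mask_b: set[tuple[str, int]] | None = None,
    allele_level: bool = False,
) -> PairwiseCounts:
    """Count substitutions between two genotypes called against one reference.

    A site contributes when the unordered diploid allele pairs differ
    (an absent call is homozygous reference).  Contributing non-coding sites
    increment ``dnC``; coding sites increment ``dS`` or ``dN`` according to
    the classification of the non-shared alternate allele(s).  When the two
    non-shared alternates classify differently the site counts as
    nonsynonymous and the tie is logged.  By default a site counts once
    (site level); with ``allele_level`` it counts the number of differing
    alleles (1 or 2).

    ``sites_compared`` is the intersection of the two callability masks when
    both are given, else the full reference length.
    """
    index = get_effect_index(genome)
    result = PairwiseCounts(
        genotype_a=callset_a.genotype_id,
        genotype_b=callset_b.genotype_id,
        lineage_id=callset_a.lineage_id or callset_b.lineage_id,
    )
    if mask_a is not None and mask_b is not None:
        result.sites_compared = len(mask_a & mask_b)
    else:
        result.sites_compared = genome.total_length

    sites = set(callset_a.calls) | set(callset_b.calls)
    for site in sites:
        contig, pos = site
        call_a = callset_a.calls.get(site)
        call_b = callset_b.calls.get(site)
        refs = {c.ref_allele for c in (call_a, call_b) if c is not None}
        if len(refs) > 1:
            raise ValueError(
                f"conflicting reference alleles {sorted(refs)} at {contig}:{pos}"
            )
        ref = refs.pop()
        alleles_a = _allele_counts(call_a, ref)
        alleles_b = _allele_counts(call_b, ref)
        if alleles_a == alleles_b:
            continue
        n_diff = sum((alleles_a - alleles_b).values())
        weight = n_diff if allele_level else 1

        is_het = any(
            c is not None and c.zygosity == "het" for c in (call_a, call_b)
        )

        if index.effects.get(site) is None:
            result.dnC += weight
            continue

        relevant_alts = [
            base
            for base in set(alleles_a) | set(alleles_b)
            if base != ref and alleles_a[base] != alleles_b[base]
        ]
        effects = {index.effect(contig, pos, alt) for alt in relevant_alts}
        if len(effects) == 1:
            effect = effects.pop()
        else:
            effect = NONSYNONYMOUS  # conservative on disagreement
            result.n_effect_ties += 1
            logger.debug("effect tie at %s:%d (alts %s)", contig, pos, relevant_alts)

        if effect == SYNONYMOUS:
            result.dS += weight
            if is_het:
                result.dS_het += weight
            else:
                result.dS_hom += weight
        else:
            result.dN += weight
            if is_het:
                result.dN_het += weight
            else:
                result.dN_hom += weight
    return result


def pairwise_matrix(
    genome: ReferenceGenome,
    callsets: Mapping[str, GenotypeCallSet] | Sequence[GenotypeCallSet],
    **kwargs,
) -> list[PairwiseCounts]:
    """All n(n-1)/2 pairwise counts among one lineage's genotypes."""
    if isinstance(callsets, Mapping):
        ordered = [callsets[k] for k in sorted(callsets)]
    else:
        ordered = sorted(callsets, key=lambda c: c.genotype_id)
    if len(ordered) < 2:
        raise ValueError("pairwise_matrix needs at least 2 genotypes")
    return [
        pairwise_counts(genome, a, b, **kwargs) for a, b in combinations(ordered, 2)
    ]


@dataclass
class UniqueGeneCount:
    """Number of genes with genotype-private nonsynonymous substitutions."""

    genotype_id: str
    n_genes: int


def unique_nonsynonymous_genes(
    genome: ReferenceGenome,
    callsets: Mapping[str, GenotypeCallSet] | Sequence[GenotypeCallSet],
) -> list[UniqueGeneCount]:
    """Per genotype, count genes carrying >= 1 nonsynonymous variant
    (site + alternate allele) found in that genotype and in no other
    genotype of the same group."""
    if isinstance(callsets, Mapping):
        ordered = [callsets[k] for k in sorted(callsets)]
    else:
        ordered = sorted(callsets, key=lambda c: c.genotype_id)
    if len(ordered) < 2:
        raise ValueError("unique gene counting needs at least 2 genotypes")
    index = get_effect_index(genome)

    nonsyn_variants: dict[str, set[tuple[str, int, str]]] = {}
    for cs in ordered:
        variants = set()
        for call in cs.calls.values():
            if (
                index.effect(call.contig, call.pos, call.alt_allele)
                == NONSYNONYMOUS
            ):
                variants.add((call.contig, call.pos, call.alt_allele))
        nonsyn_variants[cs.genotype_id] = variants

    results = []
    for cs in ordered:
        others: set[tuple[str, int, str]] = set()
        for other in ordered:
            if other.genotype_id != cs.genotype_id:
                others |= nonsyn_variants[other.genotype_id]
        private = nonsyn_variants[cs.genotype_id] - others
        genes = set()
        for contig, pos, _alt in private:
            genes.update(index.genes_at.get((contig, pos), ()))
        results.append(UniqueGeneCount(cs.genotype_id, len(genes)))
    return results


def lineage_mean_unique(counts: Iterable[UniqueGeneCount | int | float]) -> float:
    """Arithmetic mean of per-genotype unique-gene counts (report to one
    decimal place)."""
    values = [c.n_genes if isinstance(c, UniqueGeneCount) else float(c) for c in counts]
    if not values:
        raise ValueError("empty unique-gene count list")
    return sum(values) / len(values)


# ---------------------------------------------------------------- tidy tables

def genotype_counts_frame(
    genome: ReferenceGenome, cohort: Mapping[str, GenotypeCallSet]
) -> pd.DataFrame:
    """Per-genotype S, N, N/S and N_sub as a tidy table."""
    rows = []
    for gid in sorted(cohort):
        cs = cohort[gid]
        counts = count_S_N(genome, cs)
        rows.append(
            {
                "genotype_id": gid,
                "lineage_id": cs.lineage_id,
                "S": counts.S,
                "N": counts.N,
                "N_over_S": counts.ratio,
                "n_hom": cs.n_hom,
                "n_het": cs.n_het,
                "callable_sites": cs.callable_sites,
                "N_sub": substitution_rate(cs),
            }
        )
    return pd.DataFrame(rows)


def pairwise_frame(pairs: Sequence[PairwiseCounts]) -> pd.DataFrame:
    """Pairwise counts as a tidy table (one row per genotype pair)."""
    return pd.DataFrame(
        [
            {
                "genotype_a": p.genotype_a,
                "genotype_b": p.genotype_b,
                "lineage_id": p.lineage_id,
                "dnC": p.dnC,
                "dS": p.dS,
                "dN": p.dN,
                "dS_hom": p.dS_hom,
                "dS_het": p.dS_het,
                "dN_hom": p.dN_hom,
                "dN_het": p.dN_het,
                "sites_compared": p.sites_compared,
            }
            for p in pairs
        ]
    )
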