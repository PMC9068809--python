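"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fast paths: classification is done
by re-translating the entire mutant CDS with Biopython, and pairwise
comparison by reconstructing both genotypes' diploid allele pairs at every
reference site and comparing site by site.
"""

from __future__ import annotations

from collections import Counter

from Bio.Seq import Seq


def translate_seq(cds: str) -> str:
    return str(Seq(cds).translate())


def brute_classify(genome, contig, pos, alt):
    """Classify a change by splicing and translating every covering gene's
    full mutant CDS; nonsynonymous wins when genes disagree."""
    effects = set()
    for gene in genome.genes:
        if gene.contig != contig or not gene.contains(pos):
            continue
        mutated = list(genome.contigs[contig])
        mutated[pos] = alt
        mutated_contigs = {contig: "".join(mutated)}
        ref_prot = translate_seq(gene.spliced_cds(genome.contigs))
        alt_prot = translate_seq(gene.spliced_cds(mutated_contigs))
        effects.add("synonymous" if ref_prot == alt_prot else "nonsynonymous")
    if not effects:
        return "non_coding"
    return "nonsynonymous" if "nonsynonymous" in effects else "synonymous"


def diploid_alleles(callset, contig, pos, ref):
    call = callset.calls.get((contig, pos))
    if call is None:
        return Counter({ref: 2})
    if call.zygosity == "hom_alt":
        return Counter({call.alt_allele: 2})
    return Counter({ref: 1, call.alt_allele: 1})


def brute_pairwise(genome, cs_a, cs_b):
    """Full-genome site-by-site diploid comparison.

    Returns a dict with the same count fields as PairwiseCounts.
    """
    out = dict(dnC=0, dS=0, dN=0, dS_hom=0, dS_het=0, dN_hom=0, dN_het=0)
    for contig, seq in genome.contigs.items():
        for pos in range(len(seq)):
            ref = seq[pos]
            aa = diploid_alleles(cs_a, contig, pos, ref)
            bb = diploid_alleles(cs_b, contig, pos, ref)
            if aa == bb:
                continue
            het = any(
                cs.calls.get((contig, pos)) is not None
                and cs.calls[(contig, pos)].zygosity == "het"
                for cs in (cs_a, cs_b)
            )
            alts = [
                base for base in set(aa) | set(bb)
                if base != ref and aa[base] != bb[base]
            ]
            effects = {brute_classify(genome, contig, pos, alt) for alt in alts}
            if effects == {"non_coding"}:
                out["dnC"] += 1
                continue
            effect = "synonymous" if effects == {"synonymous"} else "nonsynonymous"
            if effect == "synonymous":
                out["dS"] += 1
                out["dS_het" if het else "dS_hom"] += 1
            else:
                out["dN"] += 1
                out["dN_het" if het else "dN_hom"] += 1
    return out


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)
    idx = range(len(pooled))

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in idx if i not in set(group_a_idx)]
        return sum(1 for x in ga for y in gb if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    us = [u_stat(c) for c in combinations(idx, n_a)]
    n = len(us)
    p_low = sum(1 for u in us if u <= u_obs) / n
    p_high = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2 * min(p_low, p_high))
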