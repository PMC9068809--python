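"""Substitution counting: N_sub, S/N classification, pairwise counts with
hom/het sorting, and unique-gene tallies — each checked against independent
brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clonediv as cd
from clonediv.counting import (
    classify_change,
    count_S_N,
    lineage_mean_unique,
    pairwise_counts,
    pairwise_matrix,
    substitution_rate,
    unique_nonsynonymous_genes,
)

from conftest import make_call, make_callset
from oracles import brute_classify, brute_pairwise


# ---------------------------------------------------------------- N_sub

def test_substitution_rate_direct_arithmetic(tiny_genome):
    calls = [
        make_call("c1", 0, "A", "G", "hom_alt"),
        make_call("c1", 1, "C", "T", "hom_alt"),
        make_call("c1", 2, "G", "A", "het"),
        make_call("c1", 3, "T", "C", "het"),
        make_call("c1", 4, "A", "C", "het"),
    ]
    cs = make_callset("g1", calls, callable_sites=1000)
    assert substitution_rate(cs) == pytest.approx(0.007)


def test_substitution_rate_edge_cases():
    assert substitution_rate(make_callset("g", [], callable_sites=10)) == 0
    all_hom = [make_call("c1", i, "A", "G", "hom_alt") for i in range(4)]
    assert substitution_rate(make_callset("g", all_hom, callable_sites=100)) == (
        pytest.approx(8 / 100)
    )
    with pytest.raises(ValueError):
        substitution_rate(
            cd.GenotypeCallSet("g", "L", {}, callable_sites=0)
        )


@given(
    zygosities=st.lists(st.sampled_from(["hom_alt", "het"]), min_size=0, max_size=30),
    sites=st.integers(40, 10_000),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_substitution_rate_matches_hand_formula(zygosities, sites):
    calls = [
        make_call("c1", i, "A", "G", z) for i, z in enumerate(zygosities)
    ]
    cs = make_callset("g", calls, callable_sites=sites)
    hom = sum(z == "hom_alt" for z in zygosities)
    het = sum(z == "het" for z in zygosities)
    assert substitution_rate(cs) == (2 * hom + het) / sites


# ---------------------------------------------------------------- classification

def test_classify_change_genetic_code_facts(tiny_genome):
    # plus gene codon 2 is AAA at [13,16): third-position A->G is Lys->Lys
    assert classify_change(tiny_genome, "c1", 15, "G") == "synonymous"
    # first-position A->G makes GAA (Glu): nonsynonymous
    assert classify_change(tiny_genome, "c1", 13, "G") == "nonsynonymous"
    assert classify_change(tiny_genome, "c1", 0, "G") == "non_coding"
    with pytest.raises(ValueError):
        classify_change(tiny_genome, "c1", 13, tiny_genome.base_at("c1", 13))


def test_classify_change_minus_strand(tiny_genome):
    """Minus-strand classification is reverse-complement aware: the gene's
    codons are read off the opposite strand."""
    gminus = tiny_genome.genes[1]
    for pos in gminus.genomic_positions():
        ref = tiny_genome.base_at("c1", pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            assert classify_change(tiny_genome, "c1", pos, alt) == brute_classify(
                tiny_genome, "c1", pos, alt
            )


def test_classify_change_matches_retranslation_oracle():
    """Every possible coding change in a 10-gene synthetic genome matches a
    brute-force whole-CDS re-translation oracle."""
    config = cd.SimulationConfig(
        n_contigs=1, contig_length=6000, n_genes=10, gene_length=300,
        n_genotypes_per_lineage={"L1": 2}, generations={"L1": 0},
        omega={"L1": 1.0}, seed=21,
    )
    genome = cd.generate_reference(config)
    for gene in genome.genes:
        for pos in gene.genomic_positions():
            ref = genome.base_at(gene.contig, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                assert classify_change(genome, gene.contig, pos, alt) == (
                    brute_classify(genome, gene.contig, pos, alt)
                )


def test_count_S_N_basics(tiny_genome):
    cs = make_callset("g1", [
        make_call("c1", 15, "A", "G"),             # synonymous
        make_call("c1", 13, "A", "G", "hom_alt"),  # nonsynonymous
        make_call("c1", 2, "G", "A"),              # non-coding, ignored
    ], callable_sites=60)
    counts = count_S_N(tiny_genome, cs)
    assert (counts.S, counts.N) == (1, 1)
    assert counts.ratio == 1.0
    weighted = count_S_N(tiny_genome, cs, allele_weighted=True)
    assert (weighted.S, weighted.N) == (1, 2)


def test_count_S_N_undefined_ratio(tiny_genome):
    cs = make_callset("g1", [make_call("c1", 2, "G", "A")], callable_sites=60)
    counts = count_S_N(tiny_genome, cs)
    assert (counts.S, counts.N) == (0, 0)
    assert counts.ratio is None


# ---------------------------------------------------------------- pairwise

def test_pairwise_non_coding_hom_vs_absent(tiny_genome):
    a = make_callset("a", [make_call("c1", 2, "G", "A", "hom_alt")], 60)
    b = make_callset("b", [], 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert (p.dnC, p.dS, p.dN) == (1, 0, 0)
    assert p.sites_compared == 60


def test_pairwise_het_vs_hom_same_alt_is_het_difference(tiny_genome):
    """{ref,X} vs {X,X} differ by one allele; the site is heterozygous-
    sorted and classified on X (synonymous at this site)."""
    a = make_callset("a", [make_call("c1", 15, "A", "G", "het")], 60)
    b = make_callset("b", [make_call("c1", 15, "A", "G", "hom_alt")], 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert (p.dS, p.dS_het, p.dS_hom) == (1, 1, 0)
    assert p.dN == 0


def test_pairwise_identical_callsets_count_nothing(tiny_genome):
    calls = [make_call("c1", 15, "A", "G", "het"),
             make_call("c1", 2, "G", "A", "hom_alt")]
    a = make_callset("a", calls, 60)
    b = make_callset("b", calls, 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert p.total == 0


def test_pairwise_hom_ref_vs_hom_alt_is_hom_difference(tiny_genome):
    a = make_callset("a", [make_call("c1", 13, "A", "G", "hom_alt")], 60)
    b = make_callset("b", [], 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert (p.dN, p.dN_hom, p.dN_het) == (1, 1, 0)


def test_pairwise_two_distinct_alts(tiny_genome):
    """het X vs het Y at one site: one differing site, classified on both
    non-shared alleles; disagreement resolves nonsynonymous with a tie log."""
    # at pos 15 (codon AAA offset 2): G is synonymous, C and T are not
    a = make_callset("a", [make_call("c1", 15, "A", "G", "het")], 60)
    b = make_callset("b", [make_call("c1", 15, "A", "C", "het")], 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert (p.dS, p.dN) == (0, 1)
    assert p.n_effect_ties == 1


def test_pairwise_conflicting_reference_alleles_error(tiny_genome):
    a = make_callset("a", [make_call("c1", 15, "A", "G")], 60)
    b = make_callset("b", [make_call("c1", 15, "C", "G")], 60)
    with pytest.raises(ValueError, match="reference alleles"):
        pairwise_counts(tiny_genome, a, b)


def test_pairwise_enumerated_states_match_brute_force(tiny_genome):
    """Every combination of per-site diploid states for the two genotypes
    agrees with the whole-sequence reconstruction oracle."""
    pos, ref = 15, "A"  # coding; G synonymous, C/T nonsynonymous
    states = [None] + [
        make_call("c1", pos, ref, alt, zyg)
        for alt in "GCT" for zyg in ("het", "hom_alt")
    ]
    for ca in states:
        for cb in states:
            a = make_callset("a", [c for c in (ca,) if c], 60)
            b = make_callset("b", [c for c in (cb,) if c], 60)
            p = pairwise_counts(tiny_genome, a, b)
            o = brute_pairwise(tiny_genome, a, b)
            got = dict(dnC=p.dnC, dS=p.dS, dN=p.dN, dS_hom=p.dS_hom,
                       dS_het=p.dS_het, dN_hom=p.dN_hom, dN_het=p.dN_het)
            assert got == o, f"{ca} vs {cb}"


def test_pairwise_decomposition_invariant_on_simulated_pairs():
    cfg = cd.SimulationConfig(
        n_contigs=1, contig_length=20000, n_genes=20, gene_length=300,
        n_genotypes_per_lineage={"L1": 5}, mu=2e-6,
        generations={"L1": 2000}, omega={"L1": 0.6}, p_hom=0.3, seed=8,
    )
    genome = cd.generate_reference(cfg)
    pairs = pairwise_matrix(genome, cd.simulate_lineages(cfg, genome))
    assert len(pairs) == 10
    for p in pairs:
        assert p.dS == p.dS_hom + p.dS_het
        assert p.dN == p.dN_hom + p.dN_het
        assert min(p.dnC, p.dS, p.dN) >= 0


def test_pairwise_disjoint_private_mutations_add(tiny_genome):
    """For genotypes with disjoint mutation sets, the pairwise total equals
    the sum of their private call counts."""
    a = make_callset("a", [make_call("c1", 2, "G", "A"),
                           make_call("c1", 25, "C", "T", "hom_alt")], 60)
    b = make_callset("b", [make_call("c1", 50, "G", "C")], 60)
    p = pairwise_counts(tiny_genome, a, b)
    assert p.total == len(a.calls) + len(b.calls)


def test_pairwise_matrix_combinatorics_and_symmetry(tiny_genome):
    def sets(n):
        return {
            f"g{i}": make_callset(
                f"g{i}", [make_call("c1", i, tiny_genome.base_at("c1", i),
                                    "A" if tiny_genome.base_at("c1", i) != "A" else "C")],
                60,
            )
            for i in range(n)
        }

    assert len(pairwise_matrix(tiny_genome, sets(7))) == 21
    assert len(pairwise_matrix(tiny_genome, sets(5))) == 10
    with pytest.raises(ValueError):
        pairwise_matrix(tiny_genome, sets(1))
    seven = sets(7)
    fwd = pairwise_matrix(tiny_genome, seven)
    rev = pairwise_matrix(
        tiny_genome, dict(reversed(list(seven.items())))
    )
    key = lambda p: (p.genotype_a, p.genotype_b)
    assert {key(p): p.total for p in fwd} == {key(p): p.total for p in rev}


# ---------------------------------------------------------------- unique genes

def test_unique_genes_shared_and_private(tiny_genome):
    shared = make_call("c1", 13, "A", "G")  # nonsynonymous in gplus
    a = make_callset("a", [shared], 60)
    b = make_callset("b", [shared], 60)
    counts = {c.genotype_id: c.n_genes for c in
              unique_nonsynonymous_genes(tiny_genome, {"a": a, "b": b})}
    assert counts == {"a": 0, "b": 0}

    b_private = make_callset(
        "b", [shared, make_call("c1", 35, tiny_genome.base_at("c1", 35), "G")], 60
    )
    # pos 35 lies in the minus-strand gene; check it is nonsynonymous there
    if classify_change(tiny_genome, "c1", 35, "G") == "nonsynonymous":
        counts = {c.genotype_id: c.n_genes for c in
                  unique_nonsynonymous_genes(tiny_genome, {"a": a, "b": b_private})}
        assert counts == {"a": 0, "b": 1}


def test_unique_genes_match_set_algebra_oracle():
    cfg = cd.SimulationConfig(
        n_contigs=1, contig_length=15000, n_genes=15, gene_length=300,
        n_genotypes_per_lineage={"L1": 3}, mu=4e-6,
        generations={"L1": 2000}, omega={"L1": 1.0}, seed=13,
    )
    genome = cd.generate_reference(cfg)
    callsets = cd.simulate_lineages(cfg, genome)
    result = {c.genotype_id: c.n_genes
              for c in unique_nonsynonymous_genes(genome, callsets)}

    # oracle: per-gene set algebra with brute-force classification
    variants = {
        gid: {
            (c.contig, c.pos, c.alt_allele)
            for c in cs.calls.values()
            if brute_classify(genome, c.contig, c.pos, c.alt_allele)
            == "nonsynonymous"
        }
        for gid, cs in callsets.items()
    }
    expected = {}
    for gid in callsets:
        others = set().union(*(v for g, v in variants.items() if g != gid))
        private = variants[gid] - others
        genes = {
            gene.gene_id
            for (contig, pos, _alt) in private
            for gene in genome.genes
            if gene.contig == contig and gene.contains(pos)
        }
        expected[gid] = len(genes)
    assert result == expected


def test_lineage_mean_unique():
    assert lineage_mean_unique([cd.UniqueGeneCount("g", 7)]) == 7
    assert lineage_mean_unique([3, 4]) == pytest.approx(3.5)
    with pytest.raises(ValueError):
        lineage_mean_unique([])
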