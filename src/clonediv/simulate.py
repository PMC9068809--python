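"""Synthetic clonal-lineage generator.

Emulates the structure of the study system: two (or more) genetically
isolated lineages of diploid clonal genotypes, each descending independently
from a single founder (star topology), accumulating point substitutions in
an annotated genome.  Mutations arise as a Poisson process at rate ``mu``
per site per generation, uniformly over sites with a uniform choice among
the three alternate bases; a candidate whose amino-acid effect is
nonsynonymous is retained with lineage-specific probability ``omega`` (the
simulator's stand-in for purifying-selection strength — smaller omega,
stronger purging), every other candidate with probability 1.  Retained
mutations are homozygous with probability ``p_hom``, else heterozygous.

All randomness flows from a single seed; identical configs give identical
genomes, call sets and output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .counting import NONSYNONYMOUS, SYNONYMOUS, get_effect_index
from .genome import (
    CODON_TO_AA,
    GeneModel,
    GenotypeCallSet,
    ReferenceGenome,
    STOP_CODONS,
    SNV_BASES,
    VariantCall,
    revcomp,
)

logger = logging.getLogger(__name__)

#: per-site per-generation nuclear base-substitution rate measured for
#: Daphnia pulex in mutation-accumulation experiments
DEFAULT_MU = 7.17e-9

_SIM_DEPTH = 30
_SIM_QUAL = 60.0


@dataclass
class SimulationConfig:
    """All generator knobs.

    Defaults describe a desk-scale stand-in for the study system: a 1-Mb
    diploid genome with 200 single-CDS genes, two lineages of 7 and 5
    genotypes whose founders diverged ~2540 and ~1860 generations ago
    (the nuclear-rate lineage ages at five generations per year), with
    stronger purifying selection (lower omega) in the older lineage and a
    small homozygous fraction among retained mutations.

    ``generations_rel_sd`` spreads each genotype's elapsed generations
    around the lineage value by a mean-preserving lognormal multiplier.
    Clonal populations in different lakes realize different numbers of
    generations per year (populations can crash before the season ends),
    so genotypes accumulate mutational exposure at genuinely different
    rates; this shared exposure heterogeneity is what makes dn-C, dS and
    dN co-vary across genotype pairs and hence what the slope analyses
    regress on.  Set it to 0 for a strictly homogeneous-exposure star.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 500_000
    n_genes: int = 200
    gene_length: int = 900
    n_genotypes_per_lineage: dict[str, int] = field(
        default_factory=lambda: {"L1": 7, "L2": 5}
    )
    mu: float = DEFAULT_MU
    generations: dict[str, int] = field(
        default_factory=lambda: {"L1": 2540, "L2": 1860}
    )
    generations_rel_sd: float = 0.4
    omega: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.2, "L2": 0.5}
    )
    p_hom: float = 0.1
    gc_content: float = 0.4
    transition_bias: float | None = None  # kappa-style weight; None = uniform

    def validate(self) -> None:
        if not 0 < self.mu < 1e-2:
            raise ValueError("mu must be positive and small")
        if not 0 <= self.p_hom <= 1:
            raise ValueError("p_hom must lie in [0, 1]")
        if self.generations_rel_sd < 0:
            raise ValueError("generations_rel_sd must be non-negative")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.gene_length % 3 or self.gene_length < 9:
            raise ValueError("gene_length must be a multiple of 3 and >= 9")
        for lid in self.n_genotypes_per_lineage:
            if lid not in self.generations or lid not in self.omega:
                raise ValueError(f"lineage {lid!r} missing generations or omega")
            if not 0 <= self.omega[lid] <= 1:
                raise ValueError(f"omega[{lid!r}] must lie in [0, 1]")
            if self.generations[lid] < 0:
                raise ValueError("generations must be non-negative")
        per_contig = -(-self.n_genes // self.n_contigs) if self.n_genes else 0
        if per_contig and per_contig * (self.gene_length + 2) > self.contig_length:
            raise ValueError("genes cannot be placed: contigs too short")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _random_sense_codon(rng: np.random.Generator, base_p: np.ndarray) -> str:
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3, p=base_p))
        if codon not in STOP_CODONS:
            return codon


def generate_reference(config: SimulationConfig) -> ReferenceGenome:
    """Generate a random reference genome with non-overlapping genes.

    Each gene is a single-CDS ORF (ATG start, stop end, no internal stop)
    on a random strand; minus-strand genes carry the reverse complement of
    their CDS in the genomic sequence.  Deterministic under the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    contigs: dict[str, str] = {}
    seqs: dict[str, np.ndarray] = {}
    for i in range(config.n_contigs):
        name = f"chr{i + 1}"
        seqs[name] = rng.choice(bases, size=config.contig_length, p=base_p)

    # distribute genes round-robin over contigs; tile each contig into slots
    genes: list[GeneModel] = []
    per_contig: dict[str, int] = {name: 0 for name in seqs}
    names = list(seqs)
    for g in range(config.n_genes):
        per_contig[names[g % len(names)]] += 1

    stop_codons = sorted(STOP_CODONS)
    gene_no = 0
    for name, k in per_contig.items():
        if k == 0:
            continue
        slot = config.contig_length // k
        if slot < config.gene_length + 2:
            raise ValueError(f"genes cannot be placed on contig {name}")
        for j in range(k):
            gene_no += 1
            lo = j * slot
            start = lo + int(rng.integers(0, slot - config.gene_length - 1))
            n_mid = config.gene_length // 3 - 2
            codons = (
                ["ATG"]
                + [_random_sense_codon(rng, base_p) for _ in range(n_mid)]
                + [stop_codons[int(rng.integers(0, 3))]]
            )
            cds = "".join(codons)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = cds if strand == "+" else revcomp(cds)
            seqs[name][start : start + config.gene_length] = list(insert)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_no:04d}",
                    contig=name,
                    strand=strand,
                    cds_segments=[(start, start + config.gene_length)],
                )
            )

    contigs = {name: "".join(arr) for name, arr in seqs.items()}
    genome = ReferenceGenome(contigs, genes)
    genome.validate()
    return genome


def simulate_lineages(
    config: SimulationConfig, genome: ReferenceGenome
) -> dict[str, GenotypeCallSet]:
    """Simulate per-genotype call sets under the star-topology clone model.

    Each genotype draws Poisson(mu * L * t_i) candidate mutations
    independently of its lineage mates, where t_i is the lineage's
    generation count scaled by the genotype's exposure multiplier (see
    ``generations_rel_sd``); nonsynonymous candidates survive the selection
    filter with probability omega[lineage].  A later mutation at an
    already-mutated site overwrites the earlier one (logged).
    ``callable_sites`` is the full genome length.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from genome
    index = get_effect_index(genome)
    L = genome.total_length
    contig_names = list(genome.contigs)
    offsets = np.cumsum([0] + [len(genome.contigs[c]) for c in contig_names])

    callsets: dict[str, GenotypeCallSet] = {}
    n_overwrites = 0
    for lineage in sorted(config.n_genotypes_per_lineage):
        t = config.generations[lineage]
        omega = config.omega[lineage]
        for g in range(config.n_genotypes_per_lineage[lineage]):
            gid = f"{lineage}_g{g + 1:02d}"
            sigma = config.generations_rel_sd
            exposure = (
                float(np.exp(rng.normal(-sigma * sigma / 2, sigma)))
                if sigma > 0
                else 1.0
            )
            n_cand = rng.poisson(config.mu * L * t * exposure)
            calls: dict[tuple[str, int], VariantCall] = {}
            flat = rng.integers(0, L, size=n_cand)
            for fpos in flat:
                ci = int(np.searchsorted(offsets, fpos, side="right")) - 1
                contig = contig_names[ci]
                pos = int(fpos - offsets[ci])
                ref = genome.contigs[contig][pos]
                alts = [b for b in SNV_BASES if b != ref]
                if config.transition_bias is not None:
                    w = np.array(
                        [
                            config.transition_bias if _TRANSITION[ref] == b else 1.0
                            for b in alts
                        ]
                    )
                    alt = alts[int(rng.choice(3, p=w / w.sum()))]
                else:
                    alt = alts[int(rng.integers(0, 3))]
                effect = index.effect(contig, pos, alt)
                if effect == NONSYNONYMOUS and rng.random() >= omega:
                    continue
                zygosity = "hom_alt" if rng.random() < config.p_hom else "het"
                if (contig, pos) in calls:
                    n_overwrites += 1
                calls[(contig, pos)] = VariantCall(
                    contig=contig,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    zygosity=zygosity,
                    depth=_SIM_DEPTH,
                    qual=_SIM_QUAL,
                )
            callsets[gid] = GenotypeCallSet(
                genotype_id=gid,
                lineage_id=lineage,
                calls=calls,
                callable_sites=L,
            )
    if n_overwrites:
        logger.info("%d mutations overwrote an earlier one at the same site",
                    n_overwrites)
    return callsets


def site_opportunities(genome: ReferenceGenome) -> tuple[int, int, int]:
    """Enumerate all single-base changes in the genome.

    Returns (synonymous site-changes, nonsynonymous site-changes,
    non-coding sites).  The two coding counts sum to 3x the CDS footprint;
    they give the analytic mutational-opportunity ratio against which the
    simulator's realized dN/dS can be calibrated.
    """
    index = get_effect_index(genome)
    syn = nonsyn = 0
    for site_effects in index.effects.values():
        for effect in site_effects.values():
            if effect == SYNONYMOUS:
                syn += 1
            else:
                nonsyn += 1
    non_coding = genome.total_length - len(index.effects)
    return syn, nonsyn, non_coding


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic data bundle on disk.

    Writes reference FASTA + GFF3, one single-sample VCF per genotype, the
    lineage-assignment TSV and a YAML snapshot of the config.  Returns the
    paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_reference(config)
    callsets = simulate_lineages(config, genome)

    paths: dict[str, Path] = {
        "fasta": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "lineages": outdir / "lineages.tsv",
        "config": outdir / "config.yaml",
    }
    cio.write_fasta(genome.contigs, paths["fasta"])
    cio.write_gff3(genome, paths["gff3"])
    rows = []
    for gid in sorted(callsets):
        cs = callsets[gid]
        vcf_path = outdir / f"{gid}.vcf"
        cio.write_vcf(cs, vcf_path, genome.contigs)
        paths[f"vcf:{gid}"] = vcf_path
        rows.append(
            {
                "genotype_id": gid,
                "lineage_id": cs.lineage_id,
                "vcf_path": vcf_path.name,
                "callable_sites": cs.callable_sites,
            }
        )
    import pandas as pd

    cio.write_lineage_table(pd.DataFrame(rows), paths["lineages"])
    config.to_yaml(paths["config"])
    logger.info("synthetic bundle written to %s (seed %d)", outdir, config.seed)
    return paths
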