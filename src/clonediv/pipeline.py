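"""End-to-end orchestration: simulate -> count -> pairwise -> infer -> date.

``run_all`` produces the full analysis bundle from a simulation config:
genotype-level counts, within-lineage pairwise counts, the contrast-panel
inference table, unique-nonsynonymous-gene tallies, lineage ages, a text
summary and a JSON run manifest.  Re-running with the same config yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as cio
from .counting import (
    genotype_counts_frame,
    lineage_mean_unique,
    pairwise_frame,
    pairwise_matrix,
    unique_nonsynonymous_genes,
)
from .dating import AgeModel, GENS_PER_YEAR, lineage_age_years, mean_pairwise_rate
from .inference import LineageContrastModel
from .simulate import SimulationConfig, write_bundle

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class ValidationReport:
    """Cross-file consistency findings; non-fatal in report mode."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    fasta_path: str | Path,
    gff3_path: str | Path,
    lineage_table_path: str | Path,
) -> ValidationReport:
    """Cross-check FASTA/GFF3/VCF contig names and lineage-table integrity."""
    report = ValidationReport()
    for p in (fasta_path, gff3_path, lineage_table_path):
        if not Path(p).exists():
            report.errors.append(f"missing file: {p}")
    if report.errors:
        return report

    try:
        contigs = cio.read_fasta(fasta_path)
    except ValueError as exc:
        report.errors.append(f"FASTA: {exc}")
        return report

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        genes = cio.read_gff3(gff3_path, contigs)
    for gene in genes:
        if gene.contig not in contigs:
            report.errors.append(
                f"GFF3 gene {gene.gene_id} references unknown contig {gene.contig}"
            )

    table_path = Path(lineage_table_path)
    try:
        table = cio.read_lineage_table(table_path)
    except ValueError as exc:
        report.errors.append(str(exc))
        return report
    import pysam

    for row in table.itertuples(index=False):
        vcf_path = Path(row.vcf_path)
        if not vcf_path.is_absolute():
            vcf_path = table_path.parent / vcf_path
        if not vcf_path.exists():
            report.errors.append(f"missing VCF: {vcf_path}")
            continue
        with pysam.VariantFile(str(vcf_path)) as vcf:
            for contig in vcf.header.contigs:
                if contig not in contigs:
                    report.errors.append(
                        f"{vcf_path.name}: contig {contig} absent from FASTA"
                    )
    return report


@dataclass
class RunManifest:
    """Everything needed to reproduce and audit one pipeline run."""

    version: str
    seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    filter_drops: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_all(
    config: SimulationConfig,
    outdir: str | Path,
    *,
    n_rand: int = 1999,
    gens_per_year: float = GENS_PER_YEAR,
) -> RunManifest:
    """Run the full synthetic analysis and write every output table.

    Outputs (all TSV unless noted): genotype_counts, pairwise, inference,
    unique_genes, ages, summary.txt, manifest.json.  With a single lineage
    the inference stage is skipped with a logged reason.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, seed=config.seed, config=dataclasses.asdict(config)
    )

    # --- simulate stage: write bundle then read it back through the parsers
    stage = "simulate"
    try:
        paths = write_bundle(config, outdir / "data")
        genome = cio.read_reference(paths["fasta"], paths["gff3"])
        stats: dict[str, cio.VcfReadStats] = {}
        cohort = cio.load_cohort(paths["lineages"], stats=stats)
        for gid, st in sorted(stats.items()):
            manifest.filter_drops[gid] = st.n_records - st.n_retained

        stage = "count"
        counts = genotype_counts_frame(genome, cohort)
        counts_path = outdir / "genotype_counts.tsv"
        _write_tsv(counts, counts_path,
                   "per-genotype counts: S/N (sites), N_sub (subs per site)")

        stage = "pairwise"
        lineages = sorted({cs.lineage_id for cs in cohort.values()})
        by_lineage = {
            lid: {g: cs for g, cs in cohort.items() if cs.lineage_id == lid}
            for lid in lineages
        }
        all_pairs = []
        for lid in lineages:
            if len(by_lineage[lid]) >= 2:
                all_pairs.extend(pairwise_matrix(genome, by_lineage[lid]))
        pairwise_path = outdir / "pairwise.tsv"
        _write_tsv(pairwise_frame(all_pairs), pairwise_path,
                   "within-lineage pairwise substitution counts (sites)")

        stage = "unique_genes"
        unique_rows = []
        for lid in lineages:
            if len(by_lineage[lid]) < 2:
                continue
            for uc in unique_nonsynonymous_genes(genome, by_lineage[lid]):
                unique_rows.append(
                    {"genotype_id": uc.genotype_id, "lineage_id": lid,
                     "n_genes_unique_nonsyn": uc.n_genes}
                )
        unique_path = outdir / "unique_genes.tsv"
        _write_tsv(pd.DataFrame(unique_rows), unique_path,
                   "genes with genotype-private nonsynonymous substitutions")

        stage = "infer"
        inference_path = outdir / "inference.tsv"
        summary_lines = [f"clonediv {__version__} run (seed {config.seed})", ""]
        results = None
        if len(lineages) == 2:
            model = LineageContrastModel(pairwise_frame(all_pairs))
            results = model.fit(n_rand=n_rand, seed=config.seed)
            _write_tsv(results.to_frame(), inference_path,
                       "lineage contrast panel: slopes, diffs, randomization p")
            summary_lines.append(results.summary())
        else:
            logger.info(
                "inference skipped: %d lineage(s) present, need exactly 2",
                len(lineages),
            )
            summary_lines.append(
                f"inference skipped: {len(lineages)} lineage(s) present, need 2"
            )
            inference_path = None

        stage = "age"
        age_rows = []
        model_nuc = AgeModel(mu=config.mu, gens_per_year=gens_per_year)
        for lid in lineages:
            pairs = [p for p in all_pairs if p.lineage_id == lid]
            if not pairs:
                continue
            mean_rate, sd_rate = mean_pairwise_rate(pairs)
            est = lineage_age_years(mean_rate, model_nuc)
            age_rows.append(
                {
                    "lineage_id": lid,
                    "mean_pairwise_rate": mean_rate,
                    "sd_pairwise_rate": sd_rate,
                    "mu": config.mu,
                    "gens_per_year": gens_per_year,
                    "age_years_raw": est.years_raw,
                    "age_years": est.years,
                }
            )
            mean_uniq = lineage_mean_unique(
                [r["n_genes_unique_nonsyn"] for r in unique_rows
                 if r["lineage_id"] == lid] or [0]
            )
            summary_lines.append(
                f"{lid}: mean pairwise rate {mean_rate:.3e} (SD {sd_rate:.3e}), "
                f"age {est.years} yr at {gens_per_year:g} gen/yr; "
                f"mean unique-nonsyn genes {mean_uniq:.1f}"
            )
        ages_path = outdir / "ages.tsv"
        _write_tsv(pd.DataFrame(age_rows), ages_path,
                   "lineage ages: rate (subs/site), mu (subs/site/gen), age (yr)")

        summary_path = outdir / "summary.txt"
        summary_path.write_text("\n".join(summary_lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    outputs = {
        "genotype_counts": counts_path,
        "pairwise": pairwise_path,
        "unique_genes": unique_path,
        "ages": ages_path,
        "summary": summary_path,
    }
    if inference_path is not None:
        outputs["inference"] = inference_path
    for role, path in outputs.items():
        manifest.outputs[role] = str(path.relative_to(outdir))
        manifest.digests[role] = _sha256(path)
        if path.suffix == ".tsv":
            with open(path) as fh:
                manifest.row_counts[role] = sum(
                    1 for line in fh if not line.startswith("#")
                ) - 1  # header
    manifest.write(outdir / "manifest.json")
    return manifest
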