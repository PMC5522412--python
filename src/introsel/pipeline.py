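"""Stage orchestration over a workspace directory.

Each stage reads the exchange files earlier stages wrote, applies one
analysis step, writes its outputs atomically (temp file + rename) and
returns a :class:`StageReport`. Missing upstream files raise
:class:`DependencyError` naming the stage that produces them.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplonet, introgression, io, matching, modern, selection, simulate
from .types import SiteEvidence

_THRESHOLD_RANGES = {
    "alpha": (0.0, 1.0),
    "beb_cutoff": (0.0, 1.0),
    "meme_cutoff": (0.0, 1.0),
    "fubar_cutoff": (0.0, 1.0),
    "rel_cutoff": (0.0, float("inf")),
    "gamma_cutoff": (0.0, 1.0),
    "match_tolerance": (0.0, 1.0),
    "outlier_percentile": (0.0, 100.0),
    "s_percentile": (0.0, 100.0),
    "min_span": (0, float("inf")),
    "freq_threshold": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """All paths, thresholds and the seed for one pipeline run."""

    seed: int = 0
    outdir: str = "introsel_out"
    alpha: float = 0.05
    beb_cutoff: float = 0.90
    meme_cutoff: float = 0.10
    fubar_cutoff: float = 0.90
    rel_cutoff: float = 50.0
    gamma_cutoff: float = 0.75
    match_tolerance: float = 0.10
    match_features: str = "gc_length"
    outlier_percentile: float = 95.0
    s_percentile: float = 5.0
    min_span: int = 25_000
    freq_threshold: float = 0.90
    family_policy: str = "per_test"
    # simulate-stage knobs
    n_genes: int = 40
    n_background_genes: int = 400
    snps_per_gene: int = 40
    sweep_span_bp: int = 30_000
    lrt_n_genes: int = 500
    lrt_fraction_alt: float = 0.1
    lrt_ncp: float = 25.0
    lrt_df: int = 1
    site_n_codons: int = 300
    site_planted: tuple[int, ...] = (42, 137)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside documented range [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "site_planted" in data:
            data["site_planted"] = tuple(data["site_planted"])
        return cls(**data)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            seed=self.seed,
            n_genes=self.n_genes,
            n_background_genes=self.n_background_genes,
            snps_per_gene=self.snps_per_gene,
            sweep_span_bp=self.sweep_span_bp,
        )


@dataclass
class StageReport:
    stage: str
    n_inputs: int
    n_outputs: int
    warnings: list[str] = field(default_factory=list)
    elapsed: float = 0.0


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


def _require(workdir: Path, filename: str, producer: str) -> Path:
    path = workdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing {filename}; run the '{producer}' stage first"
        )
    return path


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _frame_atomic(df: pd.DataFrame, path: Path) -> None:
    _write_atomic(path, df.to_csv(sep="\t", index=False))


STAGES = ("simulate", "lrt", "sites", "constraint", "introgression", "network", "modern")


def run_stage(name: str, config: PipelineConfig) -> StageReport:
    """Run one named stage (or 'all') against the configured workspace."""
    if name == "all":
        reports = [run_stage(stage, config) for stage in STAGES]
        return StageReport(
            stage="all",
            n_inputs=sum(r.n_inputs for r in reports),
            n_outputs=sum(r.n_outputs for r in reports),
            warnings=[w for r in reports for w in r.warnings],
            elapsed=sum(r.elapsed for r in reports),
        )
    runner = _RUNNERS.get(name)
    if runner is None:
        raise ValueError(f"unknown stage {name!r}; stages: {', '.join(STAGES)}")
    workdir = Path(config.outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report = runner(workdir, config)
    report.elapsed = time.perf_counter() - t0
    _write_atomic(
        workdir / f"report_{name}.json", json.dumps(asdict(report), indent=2)
    )
    return report


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(workdir: Path, config: PipelineConfig) -> StageReport:
    cohort = simulate.generate_cohort(config.sim_config())
    io.write_cohort(cohort, workdir)
    lrt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lrt = simulate.generate_lrt_inputs(
        config.lrt_n_genes, config.lrt_fraction_alt, config.lrt_ncp, config.lrt_df, lrt_rng
    )
    lrt["test_id"] = "M8a_vs_M8"
    lrt["codon_freq"] = "F3X4"
    _frame_atomic(lrt, workdir / "lrt_inputs.tsv")
    site_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    evidence = simulate.generate_site_evidence(
        "G0000", list(config.site_planted), site_rng, n_codons=config.site_n_codons
    )
    _frame_atomic(
        pd.DataFrame([asdict(e) for e in evidence]), workdir / "site_evidence.tsv"
    )
    return StageReport(
        stage="simulate",
        n_inputs=0,
        n_outputs=len(cohort.genes) + len(cohort.snps) + len(lrt) + len(evidence),
    )


def _stage_lrt(workdir: Path, config: PipelineConfig) -> StageReport:
    path = _require(workdir, "lrt_inputs.tsv", "simulate")
    table = pd.read_csv(path, sep="\t")
    results = selection.build_lrt_results(table, families=config.family_policy)
    out = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "test_id": r.test_id,
                "codon_freq": r.codon_freq,
                "stat": r.stat,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.p_adj < config.alpha,
            }
            for r in results
        ]
    )
    _frame_atomic(out, workdir / "lrt_results.tsv")
    return StageReport(stage="lrt", n_inputs=len(table), n_outputs=len(out))


def _stage_sites(workdir: Path, config: PipelineConfig) -> StageReport:
    path = _require(workdir, "site_evidence.tsv", "simulate")
    df = pd.read_csv(path, sep="\t")
    evidence = [
        SiteEvidence(
            gene_id=str(r.gene_id),
            codon_index=int(r.codon_index),
            method=str(r.method),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]
    cutoffs = {
        "BEB_M8": ("ge", config.beb_cutoff),
        "FUBAR": ("ge", config.fubar_cutoff),
        "REL": ("ge", config.rel_cutoff),
    }
    sites = selection.consensus_phylogeny_sites(evidence, cutoffs)
    out = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "codon_index": s.codon_index,
                "supporting_methods": ",".join(sorted(s.supporting_methods)),
            }
            for s in sites
        ],
        columns=["gene_id", "codon_index", "supporting_methods"],
    )
    _frame_atomic(out, workdir / "consensus_sites.tsv")
    return StageReport(stage="sites", n_inputs=len(evidence), n_outputs=len(sites))


def _stage_constraint(workdir: Path, config: PipelineConfig) -> StageReport:
    genes = io.read_genes(_require(workdir, "genes.tsv", "simulate"))
    fvals = pd.read_csv(_require(workdir, "constraints.tsv", "simulate"), sep="\t")
    f_by_gene = dict(zip(fvals.gene_id, fvals.f))
    report: dict[str, object] = {}
    warnings: list[str] = []
    background = [g for g in genes if g.module_label == "background"]
    for module in ("M1", "M2"):
        focal = [g for g in genes if g.module_label == module]
        if not focal:
            warnings.append(f"no {module} genes in cohort")
            continue
        ref = matching.build_reference_set(
            focal, background, config.match_features, config.match_tolerance
        )
        warnings += [f"{module} focal gene {g} had no match" for g in ref.unmatched_focal]
        f_focal = [f_by_gene[g.gene_id] for g in focal]
        f_ref = [f_by_gene[g] for g in ref.matched_ids]
        comparison = matching.compare_focal_vs_matched(f_focal, f_ref, "t_test")
        report[module] = {
            "n_focal": len(focal),
            "n_matched": len(ref.matched_ids),
            "t_stat": comparison.statistic,
            "p": comparison.p_value,
        }
    groups = {
        "M1": [f_by_gene[g.gene_id] for g in genes if g.module_label == "M1"],
        "M2": [f_by_gene[g.gene_id] for g in genes if g.module_label == "M2"],
        "background": [f_by_gene[g.gene_id] for g in background],
    }
    three = matching.three_group_compare(groups, "anova_tukey")
    report["three_group"] = {
        "omnibus_F": three.omnibus_statistic,
        "omnibus_p": three.omnibus_p,
        "pairwise_p": {f"{a}|{b}": p for (a, b), p in three.pairwise_p.items()},
    }
    _write_atomic(workdir / "constraint_report.json", json.dumps(report, indent=2))
    return StageReport(
        stage="constraint", n_inputs=len(genes), n_outputs=len(report), warnings=warnings
    )


def _stage_introgression(workdir: Path, config: PipelineConfig) -> StageReport:
    genes = io.read_genes(_require(workdir, "genes.tsv", "simulate"))
    snps, warnings = io.read_variants(_require(workdir, "variants.vcf", "simulate"))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    score_rows = []
    outliers: dict[str, list[str]] = {}
    for population in ("EUR", "ASN"):
        scores = {}
        for gene in genes:
            result = introgression.gene_introgression_score(gene, snps, population)
            if result is None:
                warnings.append(f"{gene.gene_id}: no scored SNPs in {population}")
                continue
            scores[gene.gene_id] = result
            score_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "population": population,
                    "score": result.score,
                    "n_snps": result.n_snps,
                }
            )
        module_ids = {g.gene_id for g in genes if g.module_label != "background"}
        background = [
            s.score for g, s in scores.items() if g not in module_ids
        ]
        outliers[population] = introgression.call_outlier_genes(
            {g: s.score for g, s in scores.items() if g in module_ids},
            background,
            config.outlier_percentile,
        )
    _frame_atomic(pd.DataFrame(score_rows), workdir / "introgression_scores.tsv")
    _write_atomic(workdir / "outlier_genes.json", json.dumps(outliers, indent=2))

    calls = introgression.identify_archaic_snps(snps)
    flags = {c.snp_id: c.is_archaic for c in calls}
    snp_scores = {
        s.snp_id: max(s.neand_prob.values()) if s.neand_prob else None for s in snps
    }
    all_probs = [p for s in snps for p in s.neand_prob.values()]
    threshold = introgression.percentile_threshold(all_probs, config.outlier_percentile)
    regions = introgression.define_introgressed_regions(
        snps, flags, snp_scores, threshold
    )
    io.write_regions_bed(regions, workdir / "introgressed_regions.bed")
    return StageReport(
        stage="introgression",
        n_inputs=len(snps),
        n_outputs=len(score_rows) + len(regions),
        warnings=warnings[:20],
    )


def _stage_network(workdir: Path, config: PipelineConfig) -> StageReport:
    matrix = io.read_haplotype_matrix(_require(workdir, "haplotypes.tsv", "simulate"))
    haplotypes, excluded = haplonet.collapse_haplotypes(matrix.data, matrix.labels)
    network = haplonet.build_mj_network(haplotypes)
    network.excluded_rows = excluded
    haplonet.export_network(network, workdir / "hap_network.json", "json")
    haplonet.export_network(network, workdir / "hap_network.tsv", "tsv")
    return StageReport(
        stage="network",
        n_inputs=len(matrix.labels),
        n_outputs=len(network.nodes),
        warnings=[f"excluded row {r}" for r in excluded],
    )


def _stage_modern(workdir: Path, config: PipelineConfig) -> StageReport:
    snps, warnings = io.read_variants(_require(workdir, "variants.vcf", "simulate"))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    s_scores = [s.s_score for s in snps if s.s_score is not None]
    threshold = modern.genome_s_threshold(s_scores, config.s_percentile)
    regions = modern.sweep_scan(snps, threshold, config.min_span)
    io.write_regions_bed(regions, workdir / "sweep_regions.bed")
    calls = modern.filter_modern_specific(snps, config.freq_threshold)
    calls = modern.annotate_in_sweep(calls, regions)
    out = pd.DataFrame(
        [
            {
                "snp_id": c.snp_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "archaic_ancestral_ok": int(c.archaic_ancestral_ok),
                "frequency_ok": int(c.frequency_ok),
                "regulatory_ok": int(c.regulatory_ok),
                "passes": int(c.passes),
                "in_sweep_region": int(c.in_sweep_region),
            }
            for c in calls
        ]
    )
    _frame_atomic(out, workdir / "modern_allele_calls.tsv")
    return StageReport(
        stage="modern",
        n_inputs=len(snps),
        n_outputs=len(regions) + int(out["passes"].sum()) if len(out) else len(regions),
        warnings=warnings[:20],
    )


_RUNNERS = {
    "simulate": _stage_simulate,
    "lrt": _stage_lrt,
    "sites": _stage_sites,
    "constraint": _stage_constraint,
    "introgression": _stage_introgression,
    "network": _stage_network,
    "modern": _stage_modern,
}
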