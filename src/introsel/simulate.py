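"""Seeded synthetic cohorts with planted, recoverable signals.

The generator emulates the statistical structure of the inputs the
downstream stages consume: per-SNP Neanderthal-ancestry probabilities
(a background component concentrated near zero plus rare
high-probability haplotypes), selective-sweep-scan S scores with
plantable low-S runs, per-population derived-allele frequencies,
archaic (Altai Neanderthal / Denisova) genotypes, phased haplotypes
carrying a full-LD archaic haplotype, paired null/alternative
log-likelihoods for LRTs, per-site selection evidence, and per-gene
constraint (f) values.

Every planted feature is recorded in a :class:`TruthRecord` so that
parameter-recovery tests can check the downstream stages against known
truth. One root seed drives the whole cohort; each stage draws from its
own child stream, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import GeneModel, SNPRecord, SiteEvidence, ConstraintRecord

# Fixed stage order: child seed streams are assigned positionally, so new
# stages must be appended, never inserted.
_STAGES = (
    "genes",
    "snps",
    "haplotype",
    "sweep",
    "lrt",
    "sites",
    "constraint",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    ``ancestry_high_prob`` / ``ancestry_background_prob`` set the two
    components of the Neanderthal-ancestry mixture; ``sweep_span_bp``
    is the span of the planted low-S run (the scan only emits runs of
    at least 25 kb, so shorter plants are rejected by default);
    ``introgressed_hap_freq`` is the carrier frequency of the planted
    archaic haplotype on non-African chromosomes.
    """

    seed: int = 0
    n_genes: int = 40
    n_background_genes: int = 400
    snps_per_gene: int = 40
    ancestry_high_prob: float = 0.9
    ancestry_background_prob: float = 0.02
    sweep_span_bp: int = 30_000
    n_haplotype_snps: int = 20
    pop_labels: tuple[str, ...] = ("AFR", "EUR", "ASN")
    effect_sizes: dict = field(default_factory=lambda: {"f_shift": 0.2})
    introgressed_hap_freq: float = 0.06
    n_chrom_per_pop: int = 50
    min_sweep_span_bp: int = 25_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.snps_per_gene < 2:
            raise ValueError("snps_per_gene must be >= 2")
        for name in ("ancestry_high_prob", "ancestry_background_prob", "introgressed_hap_freq"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.sweep_span_bp < self.min_sweep_span_bp:
            raise ValueError(
                f"sweep_span_bp {self.sweep_span_bp} below the minimum "
                f"reportable span {self.min_sweep_span_bp}"
            )

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic child stream for a named stage."""
        index = _STAGES.index(stage)
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[index])


@dataclass
class TruthRecord:
    """Ground truth of every planted signal, for recovery testing."""

    introgressed_genes: list[str] = field(default_factory=list)
    introgressed_snp_ids: list[str] = field(default_factory=list)
    sweep_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    sweep_snp_ids: list[str] = field(default_factory=list)
    selected_sites: dict[str, list[int]] = field(default_factory=dict)
    f_shift: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 matrix: rows are chromosomes (modern, population-tagged,
    plus ALTAI and DENISOVA), columns are SNP ids."""

    labels: list[str]
    snp_ids: list[str]
    data: np.ndarray  # shape (n_chromosomes, n_snps), entries 0/1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.snp_ids)


@dataclass
class Cohort:
    """A fully generated synthetic cohort plus its ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    snps: list[SNPRecord]
    haplotypes: HaplotypeMatrix | None
    constraints: list[ConstraintRecord]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# genes


def generate_genes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], TruthRecord]:
    """Draw non-overlapping gene intervals with GC/length/GERP features.

    Module genes are split between M1-like and M2-like labels in roughly
    the 47:21 proportion of the study modules; background genes form the
    matching/score-distribution pool.
    """
    rng = rng if rng is not None else config.rng("genes")
    n_total = config.n_genes + config.n_background_genes
    n_m1 = max(1, round(config.n_genes * 47 / 68)) if config.n_genes > 1 else 1
    labels = ["M1"] * n_m1 + ["M2"] * (config.n_genes - n_m1)
    labels += ["background"] * config.n_background_genes

    n_chroms = max(2, n_total // 40)
    genes: list[GeneModel] = []
    cursors = {f"chr{c + 1}": 10_000 for c in range(n_chroms)}
    chrom_names = list(cursors)
    for i in range(n_total):
        chrom = chrom_names[i % n_chroms]
        span = int(rng.integers(20_000, 120_000))
        # module genes get a guaranteed-long footprint so that sweep and
        # haplotype planting always has room
        if labels[i] != "background" and span < config.sweep_span_bp + 20_000:
            span = config.sweep_span_bp + 20_000 + int(rng.integers(0, 40_000))
        start = cursors[chrom] + int(rng.integers(5_000, 50_000))
        end = start + span
        cursors[chrom] = end
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                module_label=labels[i],
                gc_fraction=float(rng.uniform(0.35, 0.65)),
                cds_length=int(rng.lognormal(7.3, 0.5)) + 150,
                gerp_score=float(rng.normal(2.0, 1.0)),
            )
        )
    return genes, TruthRecord()


# ---------------------------------------------------------------------------
# SNPs


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    anc, der = rng.choice(4, size=2, replace=False)
    return str(_BASES[anc]), str(_BASES[der])


def _background_ancestry(rng: np.random.Generator, mean: float) -> float:
    """Beta draw concentrated near zero with the configured mean."""
    if mean <= 0.0:
        return 0.0
    a = 0.5
    b = a * (1.0 - mean) / mean
    return float(rng.beta(a, b))


def generate_snps(
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SNPRecord]:
    """Populate every gene with SNPs carrying all downstream annotations."""
    if not genes:
        raise ValueError("generate_snps requires a non-empty gene list")
    rng = rng if rng is not None else config.rng("snps")
    snps: list[SNPRecord] = []
    counter = 0
    for gene in genes:
        n = max(2, int(rng.poisson(config.snps_per_gene)))
        positions = np.sort(
            rng.choice(np.arange(gene.start, gene.end), size=min(n, gene.span), replace=False)
        )
        for pos in positions:
            anc, der = _draw_alleles(rng)
            freqs = {pop: float(rng.beta(0.5, 2.0)) for pop in config.pop_labels}
            nprob = {
                pop: _background_ancestry(rng, config.ancestry_background_prob)
                for pop in config.pop_labels
                if pop != "AFR"
            }
            gt_draw = rng.random(2)
            altai = _archaic_gt(gt_draw[0], anc, der)
            denisova = _archaic_gt(gt_draw[1], anc, der)
            snps.append(
                SNPRecord(
                    snp_id=f"rs{counter:06d}",
                    chrom=gene.chrom,
                    pos=int(pos),
                    ancestral_allele=anc,
                    derived_allele=der,
                    pop_derived_freq=freqs,
                    neand_prob=nprob,
                    s_score=float(rng.normal(0.0, 1.0)),
                    altai_gt=altai,
                    denisova_gt=denisova,
                    brain_eqtl=bool(rng.random() < 0.05),
                    open_chromatin=bool(rng.random() < 0.10),
                    histone_enhancer=bool(rng.random() < 0.10),
                    dnase=bool(rng.random() < 0.10),
                )
            )
            counter += 1
    return snps


def _archaic_gt(u: float, anc: str, der: str) -> tuple[str, str] | None:
    """Mostly homozygous ancestral, with rare derived carriage and rare
    missing calls (missing is explicit, never encoded as frequency 0)."""
    if u < 0.02:
        return None
    if u < 0.05:
        return (anc, der)
    if u < 0.08:
        return (der, der)
    return (anc, anc)


# ---------------------------------------------------------------------------
# planted archaic haplotype


def plant_introgressed_haplotype(
    snps: list[SNPRecord],
    gene: GeneModel,
    config: SimConfig,
    truth: TruthRecord,
    rng: np.random.Generator | None = None,
    hap_freq: float | None = None,
) -> HaplotypeMatrix:
    """Plant a full-LD archaic haplotype across one gene.

    ``n_haplotype_snps`` SNPs in the gene are made archaic-specific:
    Altai (and Denisova) homozygous for the derived allele, derived
    frequency 0 in AFR and equal to the carrier frequency in EUR/ASN,
    and ancestry probability set to the high mixture component. A
    phased matrix is returned in which a minority of non-African
    chromosomes, plus the ALTAI and DENISOVA rows, carry the full
    derived haplotype; every other chromosome is fully ancestral, so
    all planted SNP pairs are in complete LD (r^2 = 1) among moderns.
    """
    rng = rng if rng is not None else config.rng("haplotype")
    hap_freq = config.introgressed_hap_freq if hap_freq is None else hap_freq
    gene_snps = sorted((s for s in snps if s.chrom == gene.chrom and gene.contains(s.pos)),
                       key=lambda s: s.pos)
    if len(gene_snps) < config.n_haplotype_snps:
        raise ValueError(
            f"gene {gene.gene_id} has {len(gene_snps)} SNPs; "
            f"{config.n_haplotype_snps} needed for the planted haplotype"
        )
    # spread the haplotype across the gene body
    idx = np.unique(np.linspace(0, len(gene_snps) - 1, config.n_haplotype_snps).round().astype(int))
    take = list(idx)
    j = 0
    while len(take) < config.n_haplotype_snps:  # fill collisions deterministically
        if j not in take:
            take.append(j)
        j += 1
    chosen = [gene_snps[i] for i in sorted(take)[: config.n_haplotype_snps]]

    for snp in chosen:
        snp.altai_gt = (snp.derived_allele, snp.derived_allele)
        snp.denisova_gt = (snp.derived_allele, snp.derived_allele)
        for pop in config.pop_labels:
            snp.pop_derived_freq[pop] = 0.0 if pop == "AFR" else hap_freq
        for pop in snp.neand_prob:
            snp.neand_prob[pop] = config.ancestry_high_prob

    labels = [
        f"{pop}_{i:03d}"
        for pop in config.pop_labels
        for i in range(config.n_chrom_per_pop)
    ]
    non_afr = [i for i, lab in enumerate(labels) if not lab.startswith("AFR")]
    n_carriers = int(round(hap_freq * len(non_afr)))
    if hap_freq > 0:
        n_carriers = max(1, n_carriers)
    carriers = rng.choice(non_afr, size=n_carriers, replace=False) if n_carriers else []

    snp_ids = [s.snp_id for s in chosen]
    data = np.zeros((len(labels) + 2, len(snp_ids)), dtype=int)
    for row in carriers:
        data[row, :] = 1
    data[len(labels), :] = 1  # ALTAI
    data[len(labels) + 1, :] = 1  # DENISOVA
    labels = labels + ["ALTAI", "DENISOVA"]

    truth.introgressed_genes.append(gene.gene_id)
    truth.introgressed_snp_ids.extend(snp_ids)
    return HaplotypeMatrix(labels=labels, snp_ids=snp_ids, data=data)


# ---------------------------------------------------------------------------
# planted sweep region


def plant_sweep_region(
    snps: list[SNPRecord],
    config: SimConfig,
    truth: TruthRecord,
    gene: GeneModel,
    rng: np.random.Generator | None = None,
) -> tuple[str, int, int]:
    """Assign below-5th-percentile S scores to a >= sweep_span_bp run of
    consecutive SNPs inside ``gene``.

    The immediate flanking SNPs are pushed safely above the threshold so
    the planted run has exact, recoverable membership. Returns the
    planted half-open interval (chrom, first_pos, last_pos + 1).
    """
    rng = rng if rng is not None else config.rng("sweep")
    gene_snps = sorted(
        (s for s in snps if s.chrom == gene.chrom and gene.contains(s.pos)),
        key=lambda s: s.pos,
    )
    if len(gene_snps) < 2:
        raise ValueError("target gene must contain at least 2 SNPs")
    positions = np.array([s.pos for s in gene_snps])
    # shortest run of consecutive SNPs spanning >= sweep_span_bp
    run = None
    for i in range(len(positions)):
        j = int(np.searchsorted(positions, positions[i] + config.sweep_span_bp, side="left"))
        if j < len(positions):
            run = (i, j)
            break
    if run is None:
        raise ValueError(
            f"gene {gene.gene_id} cannot host a {config.sweep_span_bp} bp sweep run"
        )
    i, j = run
    member = gene_snps[i : j + 1]
    member_ids = {s.snp_id for s in member}

    others = np.array(
        [s.s_score for s in snps if s.s_score is not None and s.snp_id not in member_ids]
    )
    q5 = float(np.percentile(others, 5))
    for s in member:
        s.s_score = float(rng.uniform(q5 - 3.0, q5 - 1.0))
    # flanks (chromosome-wide neighbours of the run) safely above any
    # plausible 5th percentile, so the planted run has exact membership
    median = float(np.percentile(others, 50))
    chrom_snps = sorted(
        (s for s in snps if s.chrom == gene.chrom), key=lambda s: s.pos
    )
    first_idx = next(k for k, s in enumerate(chrom_snps) if s.snp_id == member[0].snp_id)
    last_idx = next(k for k, s in enumerate(chrom_snps) if s.snp_id == member[-1].snp_id)
    for flank in (first_idx - 1, last_idx + 1):
        if 0 <= flank < len(chrom_snps):
            s = chrom_snps[flank]
            if s.s_score is None or s.s_score < median:
                s.s_score = median

    interval = (gene.chrom, int(positions[i]), int(positions[j]) + 1)
    truth.sweep_intervals.append(interval)
    truth.sweep_snp_ids.extend(s.snp_id for s in member)
    return interval


# ---------------------------------------------------------------------------
# LRT inputs


def generate_lrt_inputs(
    n_genes: int,
    fraction_alt: float,
    ncp: float,
    df: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Paired null/alternative log-likelihoods with a known truth column.

    Null genes get 2(lnL_alt - lnL_null) drawn from a central chi^2(df);
    alternative genes from a noncentral chi^2(df, ncp). With ncp=0 the
    two are indistinguishable.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    if not 0.0 <= fraction_alt <= 1.0:
        raise ValueError("fraction_alt must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_alt = int(round(fraction_alt * n_genes))
    is_alt = np.zeros(n_genes, dtype=bool)
    is_alt[:n_alt] = True
    stats = np.where(
        is_alt,
        rng.noncentral_chisquare(df, ncp, size=n_genes) if ncp > 0 else rng.chisquare(df, size=n_genes),
        rng.chisquare(df, size=n_genes),
    )
    lnl_null = rng.uniform(-9000.0, -1000.0, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n_genes)],
            "lnl_null": lnl_null,
            "lnl_alt": lnl_null + stats / 2.0,
            "df": df,
            "is_alt": is_alt,
        }
    )


# ---------------------------------------------------------------------------
# per-site selection evidence


_PHYLO_METHODS = ("BEB_M8", "FUBAR", "REL")
_BRANCH_METHODS = ("BEB_branch", "MEME")


def generate_site_evidence(
    gene_id: str,
    planted_sites: list[int],
    seed: int | np.random.Generator,
    n_codons: int = 300,
    family: str = "phylogeny",
) -> list[SiteEvidence]:
    """Per-codon method scores with planted consensus-passing sites.

    Planted sites pass their cutoffs in at least two methods (BEB 0.97
    and FUBAR 0.95 for the phylogeny family; BEB 0.97 and MEME p=0.01
    for the branch family); background sites pass at most one method.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted = set(planted_sites)
    for site in planted:
        if not 1 <= site <= n_codons:
            raise ValueError(f"planted site {site} outside codon range 1..{n_codons}")
    evidence: list[SiteEvidence] = []
    for codon in range(1, n_codons + 1):
        if codon in planted:
            if family == "phylogeny":
                scores = {"BEB_M8": 0.97, "FUBAR": 0.95, "REL": float(rng.uniform(0, 40))}
            elif family == "branch":
                scores = {"BEB_branch": 0.97, "MEME": 0.01}
            else:
                raise ValueError(f"unknown evidence family {family!r}")
        else:
            # background: at most one passing method (rare single passes
            # exercise the >= 2-method consensus rule)
            if family == "phylogeny":
                scores = {
                    "BEB_M8": float(rng.uniform(0.0, 0.85)),
                    "FUBAR": float(rng.uniform(0.0, 0.85)),
                    "REL": float(rng.uniform(0.0, 40.0)),
                }
                if rng.random() < 0.05:
                    lone = str(rng.choice(_PHYLO_METHODS))
                    scores[lone] = 0.95 if lone != "REL" else 80.0
            elif family == "branch":
                scores = {
                    "BEB_branch": float(rng.uniform(0.0, 0.85)),
                    "MEME": float(rng.uniform(0.15, 1.0)),
                }
                if rng.random() < 0.05:
                    lone = str(rng.choice(_BRANCH_METHODS))
                    scores[lone] = 0.95 if lone == "BEB_branch" else 0.02
            else:
                raise ValueError(f"unknown evidence family {family!r}")
        for method, score in scores.items():
            evidence.append(
                SiteEvidence(gene_id=gene_id, codon_index=codon, method=method, score=score)
            )
    return evidence


# ---------------------------------------------------------------------------
# constraint (f) values


def generate_constraint_values(
    genes: list[GeneModel],
    shift: float,
    seed: int | np.random.Generator,
    base_mean: float = 0.60,
    concentration: float = 40.0,
) -> list[ConstraintRecord]:
    """Per-gene f values: module genes drawn with mean lower by ``shift``
    than background genes (Beta draws at fixed concentration)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    module_mean = base_mean - shift
    if not 0.0 < module_mean <= 1.0:
        raise ValueError(f"shift {shift} pushes module mean f outside (0, 1]")
    records = []
    for gene in genes:
        mean = base_mean if gene.module_label == "background" else module_mean
        f = float(rng.beta(mean * concentration, (1.0 - mean) * concentration))
        records.append(ConstraintRecord(gene_id=gene.gene_id, f=f))
    return records


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate genes, SNPs, planted signals and constraint values from
    one root seed.

    The planted archaic haplotype goes into the first module gene with
    enough SNPs; the planted sweep run into a different module gene
    long enough to host it.
    """
    genes, truth = generate_genes(config)
    snps = generate_snps(genes, config)

    module_genes = [g for g in genes if g.module_label != "background"]
    by_gene = {
        g.gene_id: [s for s in snps if s.chrom == g.chrom and g.contains(s.pos)]
        for g in module_genes
    }
    hap_gene = next(
        (g for g in module_genes if len(by_gene[g.gene_id]) >= config.n_haplotype_snps),
        None,
    )
    haplotypes = None
    if hap_gene is not None:
        haplotypes = plant_introgressed_haplotype(snps, hap_gene, config, truth)

    sweep_gene = next(
        (
            g
            for g in module_genes
            if g.gene_id != (hap_gene.gene_id if hap_gene else None)
            and g.span >= config.sweep_span_bp + 5_000
            and len(by_gene[g.gene_id]) >= 5
        ),
        None,
    )
    if sweep_gene is not None:
        plant_sweep_region(snps, config, truth, sweep_gene)

    shift = float(config.effect_sizes.get("f_shift", 0.0))
    constraints = generate_constraint_values(genes, shift, config.rng("constraint"))
    truth.f_shift = shift
    return Cohort(
        config=config,
        genes=genes,
        snps=snps,
        haplotypes=haplotypes,
        constraints=constraints,
        truth=truth,
    )
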