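"""Core record types shared across pipeline stages.

All genomic intervals are 0-based half-open ([start, end)); 1-based
coordinates appear only at VCF boundaries and for codon indices, which
live in protein space. Probabilities and allele frequencies are floats
in [0, 1]; missing values are ``None``, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_ALLELES = frozenset("ACGT")
POPULATIONS = ("AFR", "EUR", "ASN")
NON_AFRICAN = ("EUR", "ASN")


@dataclass
class GeneModel:
    """A gene interval with the features used for scoring and matching.

    ``module_label`` distinguishes focal disease-module genes (M1, M2)
    from the genome-wide background pool; ``gc_fraction``, ``cds_length``
    and ``gerp_score`` are the matching features, ``chimp_mappable`` is an
    optional inclusion flag for divergence-based analyses.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    module_label: str = "background"
    gc_fraction: float | None = None
    cds_length: int | None = None
    gerp_score: float | None = None
    chimp_mappable: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gene {self.gene_id}: GC fraction outside [0, 1]")

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SNPRecord:
    """One biallelic variant with the annotations every stage consumes.

    ``pop_derived_freq`` maps population labels to derived-allele
    frequencies; ``neand_prob`` holds the per-population marginal
    probability that the surrounding haplotype is of Neanderthal origin;
    ``s_score`` is the selective-sweep scan statistic (negative in
    candidate sweep regions). Archaic genotypes are unordered allele
    pairs; ``None`` means the archaic genome is not called at the site,
    which is distinct from carrying the ancestral allele.
    """

    snp_id: str
    chrom: str
    pos: int  # 0-based
    ancestral_allele: str
    derived_allele: str
    pop_derived_freq: dict[str, float] = field(default_factory=dict)
    neand_prob: dict[str, float] = field(default_factory=dict)
    s_score: float | None = None
    altai_gt: tuple[str, str] | None = None
    denisova_gt: tuple[str, str] | None = None
    brain_eqtl: bool = False
    open_chromatin: bool = False
    histone_enhancer: bool = False
    dnase: bool = False

    def __post_init__(self) -> None:
        self.ancestral_allele = self.ancestral_allele.upper()
        self.derived_allele = self.derived_allele.upper()
        for allele in (self.ancestral_allele, self.derived_allele):
            if allele not in VALID_ALLELES:
                raise ValueError(f"SNP {self.snp_id}: invalid allele {allele!r}")
        for label, freq in self.pop_derived_freq.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"SNP {self.snp_id}: {label} frequency {freq} outside [0, 1]"
                )
        for label, prob in self.neand_prob.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(
                    f"SNP {self.snp_id}: {label} ancestry probability outside [0, 1]"
                )

    @property
    def any_regulatory(self) -> bool:
        return self.brain_eqtl or self.open_chromatin or self.histone_enhancer or self.dnase


@dataclass
class LRTResult:
    """A single likelihood-ratio test arm (gene x test family x codon model)."""

    gene_id: str
    test_id: str  # branch_mammalia | branch_sauropsida | M7_vs_M8 | M8a_vs_M8
    codon_freq: str  # F3X4 | F61
    lnl_null: float
    lnl_alt: float
    stat: float
    df: int
    p_raw: float
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if self.stat < 0:
            raise ValueError("LRT statistic must be clamped at 0")
        if self.p_adj is not None and self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


@dataclass(frozen=True)
class SiteEvidence:
    """Per-codon evidence from one site-level selection method.

    ``score`` is a posterior probability for BEB/FUBAR, a p-value for
    MEME, and a Bayes factor (>= 0, unbounded above) for REL.
    """

    gene_id: str
    codon_index: int  # 1-based, human protein coordinates
    method: str  # BEB_branch | MEME | BEB_M8 | FUBAR | REL
    score: float

    PROBABILITY_METHODS = ("BEB_branch", "BEB_M8", "FUBAR")

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise ValueError("codon indices are 1-based")
        if self.method in self.PROBABILITY_METHODS or self.method == "MEME":
            if not 0.0 <= self.score <= 1.0:
                raise ValueError(f"{self.method} score {self.score} outside [0, 1]")
        elif self.method == "REL":
            if self.score < 0:
                raise ValueError("REL Bayes factor must be >= 0")
        else:
            raise ValueError(f"unknown site method {self.method!r}")


@dataclass(frozen=True)
class ConsensusSite:
    """A codon called positively selected by at least two methods."""

    gene_id: str
    codon_index: int
    supporting_methods: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.supporting_methods) < 2:
            raise ValueError("consensus requires >= 2 supporting methods")


@dataclass(frozen=True)
class LineageSiteRecord:
    """A candidate lineage-specific selected site with Pr(gamma >= 1)."""

    gene_id: str
    lineage: str  # human | chimpanzee | gorilla
    codon_index: int
    ancestral_aa: str
    derived_aa: str
    pr_gamma_ge_1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr_gamma_ge_1 <= 1.0:
            raise ValueError("Pr(gamma >= 1) must be in [0, 1]")


@dataclass(frozen=True)
class ConstraintRecord:
    """Per-gene constraint parameter f: the proportion of non-synonymous
    mutations that are not deleterious (lower f = stronger purifying
    selection)."""

    gene_id: str
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f value {self.f} outside [0, 1]")


@dataclass(frozen=True)
class IntrogressionScore:
    """Per-gene, per-population mean Neanderthal-ancestry probability."""

    gene_id: str
    population: str
    score: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("a score requires at least one SNP")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("introgression score outside [0, 1]")


@dataclass
class IntrogressedRegion:
    """A run of archaic SNPs delimiting an introgressed haplotype block."""

    chrom: str
    start: int
    end: int  # half-open
    snp_ids: list[str]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ModernAlleleCall:
    """Audit record for the modern-human-specific allele filter."""

    snp_id: str
    chrom: str
    pos: int
    archaic_ancestral_ok: bool
    frequency_ok: bool
    regulatory_ok: bool
    in_sweep_region: bool = False

    @property
    def passes(self) -> bool:
        return self.archaic_ancestral_ok and self.frequency_ok and self.regulatory_ok


@dataclass
class SweepRegion:
    """A candidate early-modern-human selection region: a >= min_span run
    of consecutive SNPs all below the genome-wide S-score threshold."""

    chrom: str
    start: int
    end: int  # half-open
    n_snps: int
    max_s_inside: float

    @property
    def span(self) -> int:
        return self.end - self.start
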