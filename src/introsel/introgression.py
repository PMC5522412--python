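"""Neanderthal-introgression scoring and archaic-haplotype regions.

A gene's introgression score is the arithmetic mean of the per-SNP
marginal probabilities of Neanderthal ancestry over all SNPs in the
gene body (per population, never pooled). Genes scoring strictly above
the 95th percentile of the background distribution are outliers; within
them, archaic-specific SNPs (Altai-homozygous allele absent from Africa
but segregating in non-Africans) with high ancestry probability are
chained into introgressed regions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .types import GeneModel, IntrogressedRegion, IntrogressionScore, SNPRecord


def gene_introgression_score(
    gene: GeneModel, snps: Iterable[SNPRecord], population: str
) -> IntrogressionScore | None:
    """Mean Neanderthal-ancestry probability over the gene's SNPs.

    Returns ``None`` when no SNP in the gene has a non-missing
    probability for the population — a missing score is excluded
    downstream, never imputed as zero.
    """
    probs = [
        s.neand_prob[population]
        for s in snps
        if s.chrom == gene.chrom and gene.contains(s.pos) and population in s.neand_prob
    ]
    if not probs:
        return None
    return IntrogressionScore(
        gene_id=gene.gene_id,
        population=population,
        score=float(np.mean(probs)),
        n_snps=len(probs),
    )


def percentile_threshold(scores: Sequence[float], q: float) -> float:
    """Linear-interpolation empirical quantile (q in percent)."""
    if len(scores) == 0:
        raise ValueError("cannot take a percentile of an empty list")
    if not 0.0 < q < 100.0:
        raise ValueError("q must be strictly between 0 and 100")
    return float(np.percentile(np.asarray(scores, dtype=float), q))


def call_outlier_genes(
    module_scores: Mapping[str, float],
    background_scores: Sequence[float],
    q: float = 95.0,
) -> list[str]:
    """Module genes scoring strictly above the background q-th percentile."""
    if len(background_scores) == 0:
        raise ValueError("background score distribution is empty")
    threshold = percentile_threshold(background_scores, q)
    return [gene for gene, score in module_scores.items() if score > threshold]


@dataclass
class ArchaicCall:
    """Result of the archaic-SNP rule for one variant.

    ``is_archaic`` is None when the Altai genotype is missing (not
    callable, distinct from a negative call).
    """

    snp_id: str
    is_archaic: bool | None
    archaic_allele: str | None


def identify_archaic_snps(
    snps: Iterable[SNPRecord],
    afr_label: str = "AFR",
    non_african: tuple[str, ...] = ("EUR", "ASN"),
) -> list[ArchaicCall]:
    """Apply the archaic-SNP rule to each variant.

    A SNP is archaic iff the Altai Neanderthal is homozygous for an
    allele whose frequency is exactly 0 in the African population and
    strictly positive in at least one non-African population. The
    Denisova genotype is reported alongside in exports but does not
    gate the call.
    """
    calls = []
    for s in snps:
        if s.altai_gt is None:
            calls.append(ArchaicCall(snp_id=s.snp_id, is_archaic=None, archaic_allele=None))
            continue
        a1, a2 = s.altai_gt
        if a1 != a2:
            calls.append(ArchaicCall(snp_id=s.snp_id, is_archaic=False, archaic_allele=None))
            continue
        allele = a1
        if allele == s.derived_allele:
            freq = dict(s.pop_derived_freq)
        elif allele == s.ancestral_allele:
            freq = {pop: 1.0 - f for pop, f in s.pop_derived_freq.items()}
        else:
            # Altai carries a third allele never observed in moderns
            calls.append(ArchaicCall(snp_id=s.snp_id, is_archaic=False, archaic_allele=None))
            continue
        if afr_label not in freq:
            raise ValueError(f"SNP {s.snp_id} lacks the {afr_label} frequency")
        is_archaic = freq[afr_label] == 0.0 and any(
            freq.get(pop, 0.0) > 0.0 for pop in non_african
        )
        calls.append(
            ArchaicCall(
                snp_id=s.snp_id,
                is_archaic=is_archaic,
                archaic_allele=allele if is_archaic else None,
            )
        )
    return calls


def define_introgressed_regions(
    snps: Sequence[SNPRecord],
    archaic_flags: Mapping[str, bool | None],
    scores: Mapping[str, float],
    score_threshold: float,
    max_gap_bp: int | None = None,
) -> list[IntrogressedRegion]:
    """Chain qualifying archaic SNPs into maximal introgressed regions.

    A SNP qualifies when it is archaic and its ancestry probability
    exceeds ``score_threshold`` (strictly). Qualifying SNPs sorted by
    position form maximal runs, split where consecutive qualifying
    SNPs are farther apart than ``max_gap_bp`` (default: never split,
    reproducing one contiguous haplotype block per chromosome run).
    Region span is last - first member position (half-open end at
    last + 1).
    """
    last_pos: dict[str, int] = {}
    for s in snps:
        if s.chrom in last_pos and s.pos < last_pos[s.chrom]:
            raise ValueError("SNPs must be sorted by position within chromosomes")
        last_pos[s.chrom] = s.pos
    qualifying = [
        s
        for s in snps
        if archaic_flags.get(s.snp_id) is True
        and scores.get(s.snp_id) is not None
        and scores[s.snp_id] > score_threshold
    ]
    regions: list[IntrogressedRegion] = []
    current: list[SNPRecord] = []
    for s in qualifying:
        if current and (
            s.chrom != current[-1].chrom
            or (max_gap_bp is not None and s.pos - current[-1].pos > max_gap_bp)
        ):
            regions.append(_to_region(current))
            current = []
        current.append(s)
    if current:
        regions.append(_to_region(current))
    return regions


def _to_region(run: list[SNPRecord]) -> IntrogressedRegion:
    return IntrogressedRegion(
        chrom=run[0].chrom,
        start=run[0].pos,
        end=run[-1].pos + 1,
        snp_ids=[s.snp_id for s in run],
    )
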