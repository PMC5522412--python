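"""Modern-human-specific allele filtering and sweep-region scanning.

Modern-specific candidates are variants where both archaic genomes
(Altai Neanderthal and Denisova) are homozygous for the ancestral
allele while the derived allele is at high frequency in every modern
population, retained only when they carry brain-regulatory evidence
(brain eQTL, open chromatin, enhancer histone marks, or DNase
hypersensitivity). Candidate early-modern-human selection regions are
runs of consecutive SNPs, spanning at least 25 kb, whose S scores all
fall below the genome-wide 5th percentile.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

from .types import ModernAlleleCall, SNPRecord, SweepRegion


def filter_modern_specific(
    snps: Iterable[SNPRecord],
    freq_threshold: float = 0.90,
    populations: tuple[str, ...] = ("AFR", "EUR", "ASN"),
) -> list[ModernAlleleCall]:
    """Evaluate the three modern-specific criteria per SNP.

    A SNP passes iff (i) Altai AND Denisova are homozygous ancestral,
    (ii) the derived frequency is >= ``freq_threshold`` in every modern
    population, and (iii) it carries at least one regulatory/eQTL flag.
    SNPs with a missing archaic genotype are not callable and are
    skipped (a missing genome is not evidence of ancestral state).
    """
    calls = []
    for s in snps:
        if s.altai_gt is None or s.denisova_gt is None:
            continue
        anc = s.ancestral_allele
        archaic_ok = s.altai_gt == (anc, anc) and s.denisova_gt == (anc, anc)
        freq_ok = all(
            s.pop_derived_freq.get(pop, 0.0) >= freq_threshold for pop in populations
        )
        calls.append(
            ModernAlleleCall(
                snp_id=s.snp_id,
                chrom=s.chrom,
                pos=s.pos,
                archaic_ancestral_ok=archaic_ok,
                frequency_ok=freq_ok,
                regulatory_ok=s.any_regulatory,
            )
        )
    return calls


def genome_s_threshold(s_scores: Sequence[float], q: float = 5.0) -> float:
    """q-th percentile (linear interpolation) of the genome-wide S scores."""
    if len(s_scores) == 0:
        raise ValueError("cannot take a percentile of an empty list")
    return float(np.percentile(np.asarray(s_scores, dtype=float), q))


def sweep_scan(
    snps: Sequence[SNPRecord],
    threshold: float,
    min_span: int = 25_000,
) -> list[SweepRegion]:
    """Maximal runs of consecutive below-threshold SNPs spanning >= min_span.

    SNPs must be position-sorted within each chromosome. A run breaks at
    any SNP with S >= threshold (or missing S) and at chromosome
    boundaries; it is emitted iff last_pos - first_pos >= ``min_span``,
    with half-open coordinates [first_pos, last_pos + 1).
    """
    by_chrom_pos = [(s.chrom, s.pos) for s in snps]
    if by_chrom_pos != sorted(by_chrom_pos, key=lambda t: (t[0], t[1])):
        # allow chromosome blocks in any order as long as each is sorted
        last: dict[str, int] = {}
        for chrom, pos in by_chrom_pos:
            if chrom in last and pos < last[chrom]:
                raise ValueError("SNPs must be sorted by position within chromosomes")
            last[chrom] = pos
    regions: list[SweepRegion] = []
    run: list[SNPRecord] = []

    def flush() -> None:
        if run and run[-1].pos - run[0].pos >= min_span:
            regions.append(
                SweepRegion(
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos + 1,
                    n_snps=len(run),
                    max_s_inside=max(s.s_score for s in run),
                )
            )

    for s in snps:
        below = s.s_score is not None and s.s_score < threshold
        if run and (s.chrom != run[0].chrom or not below):
            flush()
            run = []
        if below:
            run.append(s)
    flush()
    return regions


def annotate_in_sweep(
    calls: Iterable[ModernAlleleCall], regions: Sequence[SweepRegion]
) -> list[ModernAlleleCall]:
    """Set ``in_sweep_region`` on each call (half-open containment)."""
    out = []
    for call in calls:
        call.in_sweep_region = any(
            r.chrom == call.chrom and r.start <= call.pos < r.end for r in regions
        )
        out.append(call)
    return out
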