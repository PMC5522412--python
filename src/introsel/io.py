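"""Readers and writers for the standard formats at the pipeline boundary.

Internal coordinates are 0-based half-open everywhere; conversion to
1-based happens only here (VCF POS). Variants travel as VCF 4.2 with
INFO keys AA (ancestral allele), NPEUR/NPASN (Neanderthal-ancestry
probabilities), SSC (S score), per-population derived-allele
frequencies (AFR_AF/EUR_AF/ASN_AF) and regulatory flags, plus archaic
genotypes as samples ALTAI and DENISOVA; genes as BED + TSV feature
tables; truth and reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import Cohort, HaplotypeMatrix
from .types import GeneModel, IntrogressedRegion, SNPRecord, SweepRegion

_FLAG_FIELDS = {
    "BRAIN_EQTL": "brain_eqtl",
    "OPEN_CHROM": "open_chromatin",
    "HISTONE": "histone_enhancer",
    "DNASE": "dnase",
}
_POP_AF = {"AFR": "AFR_AF", "EUR": "EUR_AF", "ASN": "ASN_AF"}
_POP_NP = {"EUR": "NPEUR", "ASN": "NPASN"}


# ---------------------------------------------------------------------------
# VCF


def write_variants_vcf(snps: list[SNPRecord], path: str | Path) -> Path:
    """Write SNPs as VCF 4.2 (REF = ancestral, ALT = derived allele)."""
    path = Path(path)
    chroms = sorted({s.chrom for s in snps})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##INFO=<ID=NPEUR,Number=1,Type=Float,Description="Neanderthal ancestry probability, Europeans">',
        '##INFO=<ID=NPASN,Number=1,Type=Float,Description="Neanderthal ancestry probability, Asians">',
        '##INFO=<ID=SSC,Number=1,Type=Float,Description="Selective sweep scan S score">',
        '##INFO=<ID=AFR_AF,Number=1,Type=Float,Description="Derived allele frequency, Africans">',
        '##INFO=<ID=EUR_AF,Number=1,Type=Float,Description="Derived allele frequency, Europeans">',
        '##INFO=<ID=ASN_AF,Number=1,Type=Float,Description="Derived allele frequency, Asians">',
    ]
    lines += [
        f'##INFO=<ID={key},Number=0,Type=Flag,Description="Regulatory annotation">'
        for key in _FLAG_FIELDS
    ]
    lines += ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tALTAI\tDENISOVA"
    )
    for s in sorted(snps, key=lambda x: (x.chrom, x.pos)):
        info = [f"AA={s.ancestral_allele}"]
        for pop, key in _POP_NP.items():
            if pop in s.neand_prob:
                info.append(f"{key}={s.neand_prob[pop]:.6g}")
        if s.s_score is not None:
            info.append(f"SSC={s.s_score:.6g}")
        for pop, key in _POP_AF.items():
            if pop in s.pop_derived_freq:
                info.append(f"{key}={s.pop_derived_freq[pop]:.6g}")
        for key, attr in _FLAG_FIELDS.items():
            if getattr(s, attr):
                info.append(key)
        gts = [_format_gt(gt, s) for gt in (s.altai_gt, s.denisova_gt)]
        lines.append(
            f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ancestral_allele}\t"
            f"{s.derived_allele}\t.\tPASS\t{';'.join(info)}\tGT\t{gts[0]}\t{gts[1]}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _format_gt(gt: tuple[str, str] | None, s: SNPRecord) -> str:
    if gt is None:
        return "./."
    index = {s.ancestral_allele: 0, s.derived_allele: 1}
    try:
        return f"{index[gt[0]]}/{index[gt[1]]}"
    except KeyError:
        return "./."


def read_variants(path: str | Path, dialect: str = "vcf") -> tuple[list[SNPRecord], list[str]]:
    """Read variants; returns (records, warnings).

    SNPs without an AA (ancestral allele) INFO entry cannot be
    polarized and are excluded, with a warning naming them.
    """
    if dialect == "vcf":
        return _read_vcf(Path(path))
    if dialect == "tsv":
        return _read_variants_tsv(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> tuple[list[SNPRecord], list[str]]:
    vcf = VCF(str(path))
    samples = {name: i for i, name in enumerate(vcf.samples)}
    records: list[SNPRecord] = []
    warnings: list[str] = []
    for v in vcf:
        aa = v.INFO.get("AA")
        if aa is None:
            warnings.append(f"{v.ID or v.POS}: missing AA; excluded from polarity-dependent analyses")
            continue
        alleles = [v.REF] + list(v.ALT)
        derived = next((a for a in alleles if a.upper() != aa.upper()), None)
        if derived is None:
            warnings.append(f"{v.ID}: no derived allele distinct from AA")
            continue
        freqs = {
            pop: float(v.INFO.get(key))
            for pop, key in _POP_AF.items()
            if v.INFO.get(key) is not None
        }
        nprob = {
            pop: float(v.INFO.get(key))
            for pop, key in _POP_NP.items()
            if v.INFO.get(key) is not None
        }
        ssc = v.INFO.get("SSC")
        gts = v.genotypes

        def archaic(name: str) -> tuple[str, str] | None:
            if name not in samples:
                return None
            a, b = gts[samples[name]][:2]
            if a < 0 or b < 0:
                return None
            return (alleles[a].upper(), alleles[b].upper())

        records.append(
            SNPRecord(
                snp_id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=v.CHROM,
                pos=v.POS - 1,
                ancestral_allele=aa,
                derived_allele=derived,
                pop_derived_freq=freqs,
                neand_prob=nprob,
                s_score=float(ssc) if ssc is not None else None,
                altai_gt=archaic("ALTAI"),
                denisova_gt=archaic("DENISOVA"),
                **{attr: bool(v.INFO.get(key)) for key, attr in _FLAG_FIELDS.items()},
            )
        )
    return records, warnings


_TSV_COLUMNS = [
    "snp_id", "chrom", "pos", "ancestral_allele", "derived_allele",
    "afr_freq", "eur_freq", "asn_freq", "npeur", "npasn", "s_score",
    "altai_gt", "denisova_gt", "brain_eqtl", "open_chromatin",
    "histone_enhancer", "dnase",
]


def write_variants_tsv(snps: list[SNPRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in snps:
        rows.append(
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "ancestral_allele": s.ancestral_allele,
                "derived_allele": s.derived_allele,
                "afr_freq": s.pop_derived_freq.get("AFR"),
                "eur_freq": s.pop_derived_freq.get("EUR"),
                "asn_freq": s.pop_derived_freq.get("ASN"),
                "npeur": s.neand_prob.get("EUR"),
                "npasn": s.neand_prob.get("ASN"),
                "s_score": s.s_score,
                "altai_gt": "".join(s.altai_gt) if s.altai_gt else ".",
                "denisova_gt": "".join(s.denisova_gt) if s.denisova_gt else ".",
                "brain_eqtl": int(s.brain_eqtl),
                "open_chromatin": int(s.open_chromatin),
                "histone_enhancer": int(s.histone_enhancer),
                "dnase": int(s.dnase),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def _read_variants_tsv(path: Path) -> tuple[list[SNPRecord], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    records, warnings = [], []
    for i, row in df.iterrows():
        if pd.isna(row["ancestral_allele"]):
            warnings.append(f"line {i + 2}: missing ancestral allele; excluded")
            continue

        def gt(text: object) -> tuple[str, str] | None:
            if not isinstance(text, str) or text in (".", ""):
                return None
            return (text[0].upper(), text[1].upper())

        freqs = {
            pop: float(row[col])
            for pop, col in (("AFR", "afr_freq"), ("EUR", "eur_freq"), ("ASN", "asn_freq"))
            if pd.notna(row[col])
        }
        nprob = {
            pop: float(row[col])
            for pop, col in (("EUR", "npeur"), ("ASN", "npasn"))
            if pd.notna(row[col])
        }
        try:
            records.append(
                SNPRecord(
                    snp_id=str(row["snp_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ancestral_allele=str(row["ancestral_allele"]),
                    derived_allele=str(row["derived_allele"]),
                    pop_derived_freq=freqs,
                    neand_prob=nprob,
                    s_score=float(row["s_score"]) if pd.notna(row["s_score"]) else None,
                    altai_gt=gt(row["altai_gt"]),
                    denisova_gt=gt(row["denisova_gt"]),
                    brain_eqtl=bool(row["brain_eqtl"]),
                    open_chromatin=bool(row["open_chromatin"]),
                    histone_enhancer=bool(row["histone_enhancer"]),
                    dnase=bool(row["dnase"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed variant record at line {i + 2}: {exc}") from exc
    return records, warnings


# ---------------------------------------------------------------------------
# genes


def write_genes(genes: list[GeneModel], bed_path: str | Path, tsv_path: str | Path) -> None:
    bed_path, tsv_path = Path(bed_path), Path(tsv_path)
    with bed_path.open("w") as fh:
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "module_label": g.module_label,
                "gc_fraction": g.gc_fraction,
                "cds_length": g.cds_length,
                "gerp_score": g.gerp_score,
                "chimp_mappable": int(g.chimp_mappable),
            }
            for g in genes
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def read_genes(tsv_path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            module_label=str(r.module_label),
            gc_fraction=float(r.gc_fraction),
            cds_length=int(r.cds_length),
            gerp_score=float(r.gerp_score),
            chimp_mappable=bool(r.chimp_mappable),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# intervals, matrices, misc tables


def write_regions_bed(
    regions: list[IntrogressedRegion] | list[SweepRegion], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\n")
    return path


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line {i + 1}")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_haplotype_matrix(matrix: HaplotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", index_label="chromosome")
    return path


def read_haplotype_matrix(path: str | Path) -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="chromosome")
    return HaplotypeMatrix(
        labels=[str(x) for x in df.index],
        snp_ids=[str(c) for c in df.columns],
        data=df.to_numpy(dtype=int),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Serialize a synthetic cohort to its on-disk exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_bed": outdir / "genes.bed",
        "genes_tsv": outdir / "genes.tsv",
        "variants_vcf": outdir / "variants.vcf",
        "variants_tsv": outdir / "variants.tsv",
        "constraints_tsv": outdir / "constraints.tsv",
        "truth_json": outdir / "truth.json",
    }
    write_genes(cohort.genes, paths["genes_bed"], paths["genes_tsv"])
    write_variants_vcf(cohort.snps, paths["variants_vcf"])
    write_variants_tsv(cohort.snps, paths["variants_tsv"])
    pd.DataFrame([{"gene_id": c.gene_id, "f": c.f} for c in cohort.constraints]).to_csv(
        paths["constraints_tsv"], sep="\t", index=False
    )
    paths["truth_json"].write_text(cohort.truth.to_json())
    if cohort.haplotypes is not None:
        paths["haplotypes_tsv"] = outdir / "haplotypes.tsv"
        write_haplotype_matrix(cohort.haplotypes, paths["haplotypes_tsv"])
    return paths


def cohort_digest(cohort: Cohort) -> str:
    """Stable content hash of a cohort, for determinism checks."""
    payload = {
        "genes": [asdict(g) for g in cohort.genes],
        "snps": [asdict(s) for s in cohort.snps],
        "constraints": [asdict(c) for c in cohort.constraints],
        "truth": asdict(cohort.truth),
        "haplotypes": None
        if cohort.haplotypes is None
        else {
            "labels": cohort.haplotypes.labels,
            "snp_ids": cohort.haplotypes.snp_ids,
            "data": np.asarray(cohort.haplotypes.data).tolist(),
        },
    }
    text = json.dumps(payload, sort_keys=True, default=repr)
    return hashlib.sha256(text.encode()).hexdigest()
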