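"""Worked-example data for the M1/M2 neurodevelopmental-disorder modules.

These small tables hold published branch-site and site-model LRT
outcomes and lineage-specific site posteriors for the two disease
modules (M1: 47 transcriptional-regulation genes; M2: 21 synaptic
genes), as consumed by the declaration and filtering rules. They are
inputs to worked examples and acceptance checks, not synthetic data.

``BRANCH_LRT``: one row per gene x branch with the F3X4 LRT statistic,
the published FDR-adjusted p, and whether the result was confirmed
under the F61 codon-frequency model (the second arm of the dual
codon-model declaration rule). Genes absent from the table had no
significant branch result in either module.
"""

from __future__ import annotations

from .types import LineageSiteRecord

M1_SIZE = 47
M2_SIZE = 21

#: (module, gene, branch, stat_f3x4, p_published, f61_confirmed)
BRANCH_LRT: list[tuple[str, str, str, float, float, bool]] = [
    ("M1", "CHD8", "mammalia", 58.044, 2.56e-14, True),
    ("M1", "CHD8", "sauropsida", 76.290, 4.90e-18, True),
    ("M1", "HSPA4", "mammalia", 0.0, 1.0, True),
    ("M1", "HSPA4", "sauropsida", 11.0829, 1.74e-3, True),
    ("M1", "MDM2", "mammalia", 12.255, 9.28e-4, True),
    ("M1", "MDM2", "sauropsida", 0.0, 1.0, True),
    ("M1", "MECP2", "mammalia", 4.950, 2.61e-2, True),
    ("M1", "MECP2", "sauropsida", 21.963, 5.56e-6, True),
    ("M1", "MYC", "mammalia", 10.527, 2.35e-3, True),
    ("M1", "MYC", "sauropsida", 8.519, 3.51e-3, False),
    ("M1", "RB1", "mammalia", 0.0, 1.0, True),
    ("M1", "RB1", "sauropsida", 15.493, 1.66e-4, True),
    ("M1", "SMARCC2", "mammalia", 15.721, 1.47e-4, True),
    ("M1", "SMARCC2", "sauropsida", 0.0, 1.0, True),
    ("M1", "UIMC1", "mammalia", 7.634, 7.85e-3, True),
    ("M1", "UIMC1", "sauropsida", 7.068, 7.85e-3, True),
    ("M2", "DLG4", "mammalia", 5.320, 4.22e-2, True),
    ("M2", "DLG4", "sauropsida", 0.0, 1.0, True),
    ("M2", "GRIN2A", "mammalia", 5.974, 1.73e-2, True),
    ("M2", "GRIN2A", "sauropsida", 5.667, 1.73e-2, False),
    ("M2", "GRIN2B", "mammalia", 0.0, 1.0, True),
    ("M2", "GRIN2B", "sauropsida", 8.337, 7.77e-3, True),
    ("M2", "KCNMA1", "mammalia", 18.850, 1.44e-5, True),
    ("M2", "KCNMA1", "sauropsida", 18.811, 1.44e-5, True),
    ("M2", "MAP1A", "mammalia", 61.374, 9.44e-15, True),
    ("M2", "MAP1A", "sauropsida", 32.349, 1.29e-8, True),
    ("M2", "SYNGAP1", "mammalia", 64.996, 1.50e-15, True),
    ("M2", "SYNGAP1", "sauropsida", 26.360, 2.83e-7, True),
]

#: (module, gene, test_id, stat, p_published); M7 vs M8 has df=2,
#: M8a vs M8 df=1, and each published p equals the plain central
#: chi-square upper tail of the statistic.
SITE_MODEL_LRT: list[tuple[str, str, str, float, float]] = [
    ("M1", "MDM2", "M7_vs_M8", 33.357, 1.142e-7),
    ("M1", "MDM2", "M8a_vs_M8", 4.683, 3.047e-2),
    ("M1", "MECP2", "M7_vs_M8", 11.692, 5.782e-3),
    ("M1", "MECP2", "M8a_vs_M8", 7.593, 5.860e-3),
    ("M1", "MYC", "M7_vs_M8", 18.374, 1.023e-4),
    ("M1", "MYC", "M8a_vs_M8", 16.927, 7.768e-5),
    ("M1", "SMARCC2", "M7_vs_M8", 55.960, 1.411e-12),
    ("M1", "SMARCC2", "M8a_vs_M8", 18.189, 2.000e-5),
    ("M1", "UIMC1", "M7_vs_M8", 147.783, 1.623e-32),
    ("M1", "UIMC1", "M8a_vs_M8", 87.994, 6.566e-21),
    ("M2", "GRIN2A", "M7_vs_M8", 82.719, 2.181e-18),
    ("M2", "GRIN2A", "M8a_vs_M8", 58.105, 2.485e-14),
    ("M2", "MAP1A", "M7_vs_M8", 189.749, 1.252e-41),
    ("M2", "MAP1A", "M8a_vs_M8", 147.643, 5.678e-34),
    ("M2", "SYNGAP1", "M7_vs_M8", 33.228, 1.218e-7),
    ("M2", "SYNGAP1", "M8a_vs_M8", 17.161, 3.433e-5),
]

TEST_DF = {"M7_vs_M8": 2, "M8a_vs_M8": 1}

#: Published lineage-specific candidate sites with Pr(gamma >= 1).
LINEAGE_SITES: list[LineageSiteRecord] = [
    LineageSiteRecord("GORASP2", "human", 257, "Ala", "Thr", 0.901),
    LineageSiteRecord("GORASP2", "gorilla", 247, "Pro", "Ser", 0.988),
    LineageSiteRecord("HSPA4", "human", 778, "Ile", "Thr", 0.982),
    LineageSiteRecord("MDM2", "human", 283, "Arg", "Gln", 0.960),
    LineageSiteRecord("MDM2", "human", 432, "Met", "Val", 0.961),
    LineageSiteRecord("MDM2", "gorilla", 413, "Ser", "Cys", 0.948),
    LineageSiteRecord("MYC", "human", 369, "Asp", "Val", 0.874),
    LineageSiteRecord("MYC", "chimpanzee", 224, "Ala", "Pro", 0.872),
    LineageSiteRecord("PSMA7", "human", 216, "Pro", "Ser", 0.911),
    LineageSiteRecord("RAB2A", "gorilla", 197, "Thr", "Ser", 0.752),
    LineageSiteRecord("RB1", "human", 233, "Val", "Met", 0.947),
    LineageSiteRecord("SETD5", "chimpanzee", 421, "Thr", "Ala", 0.759),
    LineageSiteRecord("SETD5", "chimpanzee", 563, "Pro", "Ala", 0.760),
    LineageSiteRecord("SMARCC1", "human", 117, "Thr", "Ala", 0.850),
    LineageSiteRecord("SMARCC1", "human", 437, "Pro", "Leu", 0.851),
    LineageSiteRecord("SYT1", "gorilla", 420, "Val", "Ile", 0.902),
    LineageSiteRecord("TRAF2", "human", 237, "Ala", "Val", 0.963),
    LineageSiteRecord("TRAF2", "human", 258, "Ser", "Leu", 0.963),
    LineageSiteRecord("TRAF2", "human", 373, "Thr", "Ile", 0.935),
    LineageSiteRecord("TRAF2", "gorilla", 221, "Ile", "Val", 0.781),
    LineageSiteRecord("UIMC1", "chimpanzee", 429, "Arg", "Gly", 0.958),
    LineageSiteRecord("UIMC1", "chimpanzee", 439, "Ala", "Thr", 0.960),
    LineageSiteRecord("UIMC1", "chimpanzee", 511, "Arg", "His", 0.911),
    LineageSiteRecord("UIMC1", "chimpanzee", 597, "Ser", "Gly", 0.974),
    LineageSiteRecord("UIMC1", "chimpanzee", 601, "Cys", "Phe", 0.974),
    LineageSiteRecord("UIMC1", "gorilla", 16, "Asn", "Ile", 0.913),
    LineageSiteRecord("UIMC1", "gorilla", 62, "Thr", "Ala", 0.894),
    LineageSiteRecord("UIMC1", "gorilla", 502, "Gln", "His", 0.764),
    LineageSiteRecord("UIMC1", "gorilla", 581, "Ser", "Cys", 0.775),
]


def branch_declarations(alpha: float = 0.05) -> dict[str, dict[str, bool]]:
    """Per-module gene declarations from the branch LRT table.

    A gene is declared on a branch iff the published adjusted p is
    below alpha AND the result was confirmed under the F61 model; a
    gene counts for its module if declared on at least one branch.
    """
    declared: dict[str, dict[str, bool]] = {"M1": {}, "M2": {}}
    for module, gene, _branch, _stat, p, f61 in BRANCH_LRT:
        hit = p < alpha and f61
        declared[module][gene] = declared[module].get(gene, False) or hit
    return declared
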