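"""Matched background gene sets and constraint (f) comparisons.

For each focal module gene, background genes within a relative
tolerance (default +/-10%) on every feature of the chosen matching
mode (GC content AND length jointly, or GERP score) form its matched
set; the union over focal genes is the module's reference set. The
constraint parameter f of the module is then compared against the
reference set with a two-sample test, and the three-group module
comparison runs an omnibus test plus the matching post-hoc family
(ANOVA + Tukey HSD, or Kruskal-Wallis + Nemenyi).
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import GeneModel

FEATURE_MODES: dict[str, tuple[str, ...]] = {
    "gc_length": ("gc_fraction", "cds_length"),
    "gerp": ("gerp_score",),
}


def _feature_values(gene: GeneModel, features: tuple[str, ...]) -> list[float]:
    values = []
    for name in features:
        value = getattr(gene, name)
        if value is None:
            raise ValueError(f"gene {gene.gene_id} lacks feature {name}")
        values.append(float(value))
    return values


def match_genes(
    focal: GeneModel,
    candidates: Iterable[GeneModel],
    features: str = "gc_length",
    tolerance: float = 0.10,
) -> list[str]:
    """Gene ids of candidates within relative ``tolerance`` of the focal
    gene on EVERY feature of the chosen mode.

    Relative deviation is |candidate - focal| / |focal|; a focal
    feature of exactly zero cannot anchor a relative tolerance and is
    signalled, not skipped.
    """
    if features not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {features!r}; use one of {sorted(FEATURE_MODES)}")
    names = FEATURE_MODES[features]
    focal_values = _feature_values(focal, names)
    if any(v == 0.0 for v in focal_values):
        raise ValueError(
            f"focal gene {focal.gene_id} has a zero-valued feature; "
            "relative tolerance is undefined"
        )
    matched = []
    for cand in candidates:
        cand_values = _feature_values(cand, names)
        if all(
            abs(c - f) / abs(f) <= tolerance for c, f in zip(cand_values, focal_values)
        ):
            matched.append(cand.gene_id)
    return matched


@dataclass
class ReferenceSet:
    """Union of per-focal matched sets with provenance."""

    matched_ids: list[str]
    provenance: dict[str, list[str]]  # focal_id -> matched ids
    unmatched_focal: list[str] = field(default_factory=list)


def build_reference_set(
    module_genes: Sequence[GeneModel],
    candidates: Sequence[GeneModel],
    features: str = "gc_length",
    tolerance: float = 0.10,
) -> ReferenceSet:
    """Deduplicated union of matches over all focal module genes.

    Candidates must exclude the module genes themselves; focal genes
    with zero matches are reported, not silently dropped.
    """
    if not candidates:
        raise ValueError("candidate pool is empty")
    module_ids = {g.gene_id for g in module_genes}
    pool = [c for c in candidates if c.gene_id not in module_ids]
    provenance: dict[str, list[str]] = {}
    union: dict[str, None] = {}
    unmatched = []
    for focal in module_genes:
        ids = match_genes(focal, pool, features, tolerance)
        provenance[focal.gene_id] = ids
        if not ids:
            unmatched.append(focal.gene_id)
        for gid in ids:
            union.setdefault(gid)
    return ReferenceSet(
        matched_ids=list(union), provenance=provenance, unmatched_focal=unmatched
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float


def compare_focal_vs_matched(
    f_focal: Sequence[float],
    f_matched: Sequence[float],
    method: str = "t_test",
) -> ComparisonResult:
    """Two-sided two-sample location test of module vs matched f values."""
    if len(f_focal) < 2 or len(f_matched) < 2:
        raise ValueError("each group needs at least 2 values")
    if method == "t_test":
        stat, p = stats.ttest_ind(f_focal, f_matched)
    elif method == "rank_sum":
        stat, p = stats.ranksums(f_focal, f_matched)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(method=method, statistic=float(stat), p_value=float(p))


@dataclass
class ThreeGroupResult:
    method: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]


def _nemenyi_pairwise(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Rank-based Nemenyi post-hoc p-values.

    Mean ranks over the pooled sample are compared with the
    studentized-range distribution (k groups, infinite df), the
    classical reference for all-pairs rank comparisons after a
    Kruskal-Wallis omnibus.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    sizes = {}
    offset = 0
    for k in labels:
        n_k = len(groups[k])
        mean_ranks[k] = float(np.mean(ranks[offset : offset + n_k]))
        sizes[k] = n_k
        offset += n_k
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    k_groups = len(labels)
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0) * (1.0 / sizes[a] + 1.0 / sizes[b]) * tie_term
        )
        q = abs(mean_ranks[a] - mean_ranks[b]) / se * math.sqrt(2.0)
        out[(a, b)] = float(stats.studentized_range.sf(q, k_groups, np.inf))
    return out


def three_group_compare(
    groups: Mapping[str, Sequence[float]],
    method: str = "anova_tukey",
) -> ThreeGroupResult:
    """Omnibus three-group comparison plus matching post-hoc family.

    ``anova_tukey``: one-way ANOVA with Tukey's HSD pairwise p-values.
    ``kruskal_nemenyi``: Kruskal-Wallis with the Nemenyi post-hoc test.
    """
    if len(groups) < 3:
        raise ValueError("three_group_compare requires at least three groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size == 0 for a in arrays):
        empty = [k for k, a in zip(labels, arrays) if a.size == 0]
        raise ValueError(f"empty group(s): {empty}")
    if method == "anova_tukey":
        stat, p = stats.f_oneway(*arrays)
        if np.isnan(p):  # degenerate: no between-group variance at all
            stat, p = 0.0, 1.0
        hsd = stats.tukey_hsd(*arrays)
        pairwise = {
            (labels[i], labels[j]): float(hsd.pvalue[i, j])
            for i, j in itertools.combinations(range(len(labels)), 2)
        }
    elif method == "kruskal_nemenyi":
        stat, p = stats.kruskal(*arrays)
        pairwise = _nemenyi_pairwise(groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ThreeGroupResult(
        method=method,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        pairwise_p=pairwise,
    )
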