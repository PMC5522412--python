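"""Positive-selection declarations and consensus site calling.

Likelihood pairs from nested codon models are turned into chi-square
LRT p-values, FDR-adjusted within configurable families, and combined
into per-gene declarations: a branch is declared under selection only
if the test is significant under BOTH codon-frequency models (F3X4 and
F61); the site-model declaration requires all four arms
({M7 vs M8, M8a vs M8} x {F3X4, F61}) significant. Per-site method
evidence (BEB/MEME posterior or p scores, FUBAR posteriors, REL Bayes
factors) is intersected into conservative consensus site calls.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .types import ConsensusSite, LineageSiteRecord, LRTResult, SiteEvidence

#: detection rule per site-level method: (direction, cutoff).
#: BEB/FUBAR report posterior probabilities (pass when >= cutoff),
#: MEME reports a p-value (pass when <= cutoff), REL a Bayes factor.
METHOD_CUTOFFS: dict[str, tuple[str, float]] = {
    "BEB_branch": ("ge", 0.90),
    "BEB_M8": ("ge", 0.90),
    "FUBAR": ("ge", 0.90),
    "MEME": ("le", 0.10),
    "REL": ("ge", 50.0),
}


def method_passes(method: str, score: float, cutoffs: Mapping[str, tuple[str, float]] | None = None) -> bool:
    """Whether one method's score passes its detection cutoff."""
    table = METHOD_CUTOFFS if cutoffs is None else cutoffs
    if method not in table:
        raise ValueError(f"unknown site method {method!r}")
    direction, cutoff = table[method]
    return score >= cutoff if direction == "ge" else score <= cutoff


# ---------------------------------------------------------------------------
# LRT machinery


def lrt_pvalue(lnl_null: float, lnl_alt: float, df: int) -> tuple[float, float]:
    """2*Delta(lnL) statistic and its central chi-square upper tail.

    The statistic is clamped at zero (the alternative can only fit at
    least as well up to numerical noise); a zero statistic gives p = 1.
    """
    if df not in (1, 2):
        raise ValueError(f"df must be 1 or 2, got {df}")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = 1.0 if stat == 0.0 else float(chi2.sf(stat, df))
    return stat, p


def chi2_upper_tail(stat: float, df: int) -> float:
    """Upper-tail p for an already-computed LRT statistic."""
    if df not in (1, 2):
        raise ValueError(f"df must be 1 or 2, got {df}")
    if stat < 0:
        raise ValueError("LRT statistic must be >= 0")
    return 1.0 if stat == 0.0 else float(chi2.sf(stat, df))


def bh_adjust(
    p_values: Sequence[float],
    families: Sequence[object] | None = None,
) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    ``families`` optionally assigns each p-value to an adjustment
    family; the correction is computed independently within each
    family (the appropriate family grouping is analysis configuration,
    not a property of the statistic).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.empty_like(p)
    if families is None:
        groups: dict[object, list[int]] = {None: list(range(p.size))}
    else:
        if len(families) != p.size:
            raise ValueError("families must align with p_values")
        groups = defaultdict(list)
        for i, key in enumerate(families):
            groups[key].append(i)
    for idx in groups.values():
        adjusted[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adjusted.tolist()


def build_lrt_results(
    table,
    families: str | None = "per_test",
) -> list[LRTResult]:
    """Compute stats, raw and BH-adjusted p for a table of likelihood pairs.

    ``table`` is a DataFrame-like with columns gene_id, test_id,
    codon_freq, lnl_null, lnl_alt, df. With ``families="per_test"``
    (default) adjustment runs within each test_id x codon_freq family;
    ``families=None`` adjusts across everything at once.
    """
    rows = table.to_dict("records")
    stats_p = [lrt_pvalue(r["lnl_null"], r["lnl_alt"], int(r["df"])) for r in rows]
    raw = [p for _, p in stats_p]
    if families == "per_test":
        keys = [(r.get("test_id"), r.get("codon_freq")) for r in rows]
    elif families is None:
        keys = None
    else:
        keys = [r.get(families) for r in rows]
    adj = bh_adjust(raw, keys)
    return [
        LRTResult(
            gene_id=r["gene_id"],
            test_id=r.get("test_id", "branch_mammalia"),
            codon_freq=r.get("codon_freq", "F3X4"),
            lnl_null=float(r["lnl_null"]),
            lnl_alt=float(r["lnl_alt"]),
            stat=s,
            df=int(r["df"]),
            p_raw=p,
            p_adj=a,
        )
        for r, (s, p), a in zip(rows, stats_p, adj)
    ]


# ---------------------------------------------------------------------------
# declarations


def declare_branch_selection(results: Iterable[LRTResult], alpha: float = 0.05) -> bool:
    """Branch-level declaration: significant under both codon models.

    Expects exactly one F3X4 and one F61 result for one gene x branch.
    """
    by_freq = {}
    for r in results:
        if r.codon_freq in by_freq:
            raise ValueError(f"duplicate codon-frequency arm {r.codon_freq}")
        by_freq[r.codon_freq] = r
    missing = {"F3X4", "F61"} - set(by_freq)
    if missing:
        raise ValueError(f"missing codon-frequency arm(s): {sorted(missing)}")
    return all(_adj(r) < alpha for r in by_freq.values())


def declare_site_model_selection(results: Iterable[LRTResult], alpha: float = 0.05) -> bool:
    """Site-model declaration: both neutral models (M7 and M8a) rejected
    in favour of M8 under both codon-frequency models (four arms)."""
    seen = {}
    for r in results:
        key = (r.test_id, r.codon_freq)
        if key in seen:
            raise ValueError(f"duplicate arm {key}")
        seen[key] = r
    required = {(t, c) for t in ("M7_vs_M8", "M8a_vs_M8") for c in ("F3X4", "F61")}
    missing = required - set(seen)
    if missing:
        raise ValueError(f"missing arm(s): {sorted(missing)}")
    return all(_adj(seen[k]) < alpha for k in required)


def _adj(result: LRTResult) -> float:
    if result.p_adj is None:
        raise ValueError(f"result for {result.gene_id} has no adjusted p")
    return result.p_adj


def module_selection_fraction(declared: Mapping[str, bool] | Iterable[bool], module_size: int) -> float:
    """Percentage of module genes declared selected on >= 1 branch,
    reported to one decimal."""
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    values = list(declared.values()) if isinstance(declared, Mapping) else list(declared)
    n_declared = sum(bool(v) for v in values)
    return round(100.0 * n_declared / module_size, 1)


# ---------------------------------------------------------------------------
# consensus site calling


def _score_map(evidence: Iterable[SiteEvidence], allowed: set[str]) -> tuple[str | None, dict[tuple[int, str], float]]:
    gene_ids = set()
    table: dict[tuple[int, str], float] = {}
    for e in evidence:
        if e.method not in allowed:
            raise ValueError(f"unexpected method {e.method!r} in evidence")
        gene_ids.add(e.gene_id)
        table[(e.codon_index, e.method)] = e.score
    if len(gene_ids) > 1:
        raise ValueError(f"evidence mixes gene ids: {sorted(gene_ids)}")
    return (gene_ids.pop() if gene_ids else None), table


def consensus_branch_sites(
    beb: Iterable[SiteEvidence],
    meme: Iterable[SiteEvidence],
    beb_cutoff: float = 0.90,
    meme_cutoff: float = 0.10,
) -> list[ConsensusSite]:
    """Branch consensus: BEB posterior >= cutoff AND MEME p <= cutoff at
    the same codon."""
    gene_b, beb_scores = _score_map(beb, {"BEB_branch"})
    gene_m, meme_scores = _score_map(meme, {"MEME"})
    if gene_b and gene_m and gene_b != gene_m:
        raise ValueError(f"mixed gene ids: {gene_b} vs {gene_m}")
    gene_id = gene_b or gene_m
    sites = []
    for (codon, _), score in sorted(beb_scores.items()):
        if score >= beb_cutoff and meme_scores.get((codon, "MEME"), np.inf) <= meme_cutoff:
            sites.append(
                ConsensusSite(
                    gene_id=gene_id,
                    codon_index=codon,
                    supporting_methods=frozenset({"BEB_branch", "MEME"}),
                )
            )
    return sites


def consensus_phylogeny_sites(
    evidence: Iterable[SiteEvidence],
    cutoffs: Mapping[str, tuple[str, float]] | None = None,
) -> list[ConsensusSite]:
    """Phylogeny-wide consensus: >= 2 of {BEB_M8, FUBAR, REL} pass their
    cutoffs at the same codon; supporters are recorded."""
    allowed = {"BEB_M8", "FUBAR", "REL"}
    gene_id, table = _score_map(evidence, allowed)
    by_codon: dict[int, set[str]] = defaultdict(set)
    for (codon, method), score in table.items():
        if method_passes(method, score, cutoffs):
            by_codon[codon].add(method)
    return [
        ConsensusSite(gene_id=gene_id, codon_index=codon, supporting_methods=frozenset(methods))
        for codon, methods in sorted(by_codon.items())
        if len(methods) >= 2
    ]


def lineage_selected_sites(
    records: Iterable[LineageSiteRecord], cutoff: float = 0.75
) -> list[LineageSiteRecord]:
    """Keep sites with posterior Pr(gamma >= 1) strictly above ``cutoff``."""
    return [r for r in records if r.pr_gamma_ge_1 > cutoff]
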