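import numpy as np
import pytest

from introsel.simulate import Cohort, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_genes=12, n_background_genes=120, snps_per_gene=30)


@pytest.fixture(scope="session")
def cohort(small_config) -> Cohort:
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# brute-force oracles shared between unit and acceptance tests


def bh_oracle(p_values):
    """Definitional BH step-up: adj(rank k) = min over j >= k of p(j)*n/j."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    for rank, idx in enumerate(order, start=1):
        adjusted[idx] = min(
            min(p_values[order[j - 1]] * n / j for j in range(rank, n + 1)), 1.0
        )
    return adjusted


def sweep_oracle(snps, threshold, min_span):
    """All maximal sub-runs of below-threshold SNPs with span >= min_span."""
    regions = []
    n = len(snps)

    def below(k):
        return snps[k].s_score is not None and snps[k].s_score < threshold

    for i in range(n):
        for j in range(i, n):
            run = snps[i : j + 1]
            if any(s.chrom != snps[i].chrom for s in run):
                continue
            if not all(below(k) for k in range(i, j + 1)):
                continue
            left_max = i == 0 or snps[i - 1].chrom != snps[i].chrom or not below(i - 1)
            right_max = j == n - 1 or snps[j + 1].chrom != snps[j].chrom or not below(j + 1)
            if left_max and right_max and run[-1].pos - run[0].pos >= min_span:
                regions.append((run[0].chrom, run[0].pos, run[-1].pos + 1, len(run)))
    return regions


def steiner_oracle(sequences, max_extra=2):
    """Exhaustive Steiner-minimal connection cost over the binary hypercube."""
    import itertools

    import networkx as nx

    sequences = [tuple(s) for s in sequences]
    length = len(sequences[0])

    def mst_cost(nodes):
        if len(nodes) <= 1:
            return 0
        g = nx.Graph()
        for a, b in itertools.combinations(range(len(nodes)), 2):
            w = sum(x != y for x, y in zip(nodes[a], nodes[b]))
            g.add_edge(a, b, weight=w)
        return int(sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g)))

    candidates = [
        c for c in itertools.product((0, 1), repeat=length) if c not in sequences
    ]
    best = mst_cost(sequences)
    for k in range(1, min(max_extra, max(0, len(sequences) - 2)) + 1):
        for extra in itertools.combinations(candidates, k):
            best = min(best, mst_cost(sequences + list(extra)))
    return best


def matched_oracle(focal, candidates, feature_names, tolerance):
    """All-pairs relative-tolerance filter."""
    out = []
    for cand in candidates:
        ok = True
        for name in feature_names:
            f, c = getattr(focal, name), getattr(cand, name)
            if abs(c - f) / abs(f) > tolerance:
                ok = False
                break
        if ok:
            out.append(cand.gene_id)
    return out
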