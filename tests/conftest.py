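import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_scenario(tmp_path_factory):
    """A small written synthetic scenario shared across tests."""
    from drs3p.synthetic import SyntheticConfig, write_scenario

    outdir = tmp_path_factory.mktemp("tiny_scenario")
    cfg = SyntheticConfig(n_genes=30, reads_per_gene=40, seed=7)
    paths = write_scenario(cfg, outdir)
    return cfg, paths


@pytest.fixture(scope="session")
def tiny_bundle(tiny_scenario, tmp_path_factory):
    """Pipeline output on the tiny scenario."""
    from drs3p.pipeline import PipelineConfig, run_pipeline

    cfg, paths = tiny_scenario
    outdir = tmp_path_factory.mktemp("tiny_run")
    pcfg = PipelineConfig(
        sample_sheet=str(paths.sample_sheet), annotation=str(paths.gff3), outdir=str(outdir)
    )
    return run_pipeline(pcfg)


# ---------------------------------------------------------------- oracles


def oracle_cluster_transitive_closure(positions, max_gap=24):
    """O(n^2) union-find over the 'within max_gap of each other' relation.

    Independent of the chaining implementation: builds the transitive
    closure of pairwise proximity and returns the partition in coordinate
    order, each cluster as a sorted multiset.
    """
    pos = sorted(positions)
    n = len(pos)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pos[i] - pos[j]) <= max_gap:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pos[i])
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def oracle_assign_largest_overlap(read, genes):
    """Exhaustive largest-overlap assignment over all genes for one read."""
    best_bp, best = 0, []
    for g in genes:
        if g.strand != read.read_strand or g.chrom != read.interval.chrom:
            continue
        bp = max(0, min(g.interval.end, read.interval.end) - max(g.interval.start, read.interval.start))
        if bp > best_bp:
            best_bp, best = bp, [g.gene_id]
        elif bp == best_bp and bp > 0:
            best.append(g.gene_id)
    if len(best) == 1:
        return best[0], best_bp
    return None, 0


def oracle_exact_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of C(n+m, n)
    group labelings (tie-free inputs only)."""
    from itertools import combinations

    import numpy as np

    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = pooled.argsort().argsort() + 1  # tie-free
    idx = range(n + m)
    u_obs = float(np.sum(ranks[:n])) - n * (n + 1) / 2
    us = []
    for comb in combinations(idx, n):
        us.append(float(np.sum(ranks[list(comb)])) - n * (n + 1) / 2)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))
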