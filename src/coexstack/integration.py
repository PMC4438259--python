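"""Stacking of two module partitions into a bipartite regulatory network.

The two layers' module sets are compared by gene membership: every
(module A, module B) pair is scored with an upper-tail hypergeometric
test on the shared gene count, pairs with p below alpha become edges of
the bipartite network, and each retained edge carries the Pearson
correlation across samples between the two layers' eigengenes recomputed
on the pair's shared genes. The same hypergeometric kernel drives
enrichment of modules for differentially expressed genes and for
user-supplied gene sets; a "coordinated" disease pair is a bipartite edge
whose two endpoint modules are both enriched for the same contrast's
differentially expressed genes.

Unassigned features (module label 0) belong to no module but do count in
the universe N, which enters every hypergeometric margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .io_formats import ConsistencyError, ExpressionMatrix, GeneSetCollection
from .network import CoexpressionNetwork, ModulePartition, module_eigengene


# ---------------------------------------------------------------------------
# Hypergeometric kernel
# ---------------------------------------------------------------------------

def hypergeometric_upper(n_universe: int, n_a: int, n_b: int,
                         n_shared: int) -> float:
    """P[X >= n_shared] for X ~ Hypergeometric(N, K=n_a, n=n_b).

    Summed in log space for stability in deep tails.
    """
    if not (0 <= n_shared <= min(n_a, n_b) <= n_universe):
        raise ConsistencyError(
            f"inconsistent counts N={n_universe} K={n_a} n={n_b} k={n_shared}"
        )
    if max(n_a, n_b) > n_universe:
        raise ConsistencyError("margin exceeds universe")
    if n_shared == 0:
        return 1.0
    lo = max(n_shared, n_a + n_b - n_universe)
    hi = min(n_a, n_b)
    ks = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(ks, n_universe, n_a, n_b)
    return float(min(1.0, math.exp(logsumexp(logp))))


def bh_adjust(p_values: list[float]) -> list[float]:
    if not p_values:
        return []
    return list(stats.false_discovery_control(np.asarray(p_values), method="bh"))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ModuleOverlap:
    module_a: int
    module_b: int
    n_universe: int
    n_a: int
    n_b: int
    n_shared: int
    p_value: float
    q_value: float = float("nan")
    #: Pearson r across samples between the two layers' shared-gene
    #: eigengenes; None when n_shared < 3 or no matrices were supplied
    eigengene_correlation: float | None = None


@dataclass
class BipartiteNetwork:
    """Modules of both layers as nodes, significant overlaps as edges."""

    #: (layer tag, module label, module size)
    nodes: list[tuple[str, int, int]]
    edges: list[ModuleOverlap]
    alpha: float
    #: fraction of retained edges with positive eigengene correlation
    #: (over edges where the correlation is defined); None if no such edge
    fraction_positive_correlation: float | None

    def edge_pairs(self) -> set[tuple[int, int]]:
        return {(e.module_a, e.module_b) for e in self.edges}


@dataclass
class EnrichmentResult:
    module: int
    set_name: str
    n_universe: int
    n_module: int
    n_set: int
    n_overlap: int
    p_value: float
    q_value: float = float("nan")
    tested: bool = True


# ---------------------------------------------------------------------------
# Module overlap / bipartite stacking
# ---------------------------------------------------------------------------

def _check_universe(partition: ModulePartition, universe: list[str]) -> None:
    missing = set(partition.assignment) - set(universe)
    extra = set(universe) - set(partition.assignment)
    if missing or extra:
        raise ConsistencyError(
            f"partition/universe mismatch ({len(missing)} unknown, "
            f"{len(extra)} unassigned-in-partition)"
        )


def _shared_gene_eigengene_r(shared: list[str], matrix_a: ExpressionMatrix,
                             matrix_b: ExpressionMatrix) -> float:
    """Correlate the two layers' eigengenes computed on the shared genes."""
    sub_a = matrix_a.subset_features(shared)
    sub_b = matrix_b.subset_features(shared).subset_samples(matrix_a.sample_ids)
    part = ModulePartition({g: 1 for g in shared})
    e_a = module_eigengene(sub_a, part).loc[1].to_numpy()
    part_b = ModulePartition({g: 1 for g in shared})
    e_b = module_eigengene(sub_b, part_b).loc[1].to_numpy()
    return float(np.corrcoef(e_a, e_b)[0, 1])


def module_overlap_table(partition_a: ModulePartition,
                         partition_b: ModulePartition,
                         universe: list[str], alpha: float = 0.05,
                         matrix_a: ExpressionMatrix | None = None,
                         matrix_b: ExpressionMatrix | None = None,
                         layer_tags: tuple[str, str] = ("A", "B"),
                         ) -> tuple[list[ModuleOverlap], BipartiteNetwork]:
    """Score every cross-layer module pair and build the bipartite network.

    One row per (module_a, module_b) pair with the hypergeometric
    upper-tail p for the shared-gene count; pairs with p < alpha become
    edges. Eigengene correlation is computed on the shared genes when
    n_shared >= 3 and both layer matrices are supplied. BH q-values over
    the full pair grid are reported informationally and never drive edge
    retention.
    """
    _check_universe(partition_a, universe)
    _check_universe(partition_b, universe)
    n_univ = len(universe)
    members_a = {m: set(partition_a.members(m)) for m in partition_a.labels}
    members_b = {m: set(partition_b.members(m)) for m in partition_b.labels}
    table: list[ModuleOverlap] = []
    for la in sorted(members_a):
        for lb in sorted(members_b):
            shared = sorted(members_a[la] & members_b[lb])
            p = hypergeometric_upper(n_univ, len(members_a[la]),
                                     len(members_b[lb]), len(shared))
            r = None
            if len(shared) >= 3 and matrix_a is not None and matrix_b is not None:
                r = _shared_gene_eigengene_r(shared, matrix_a, matrix_b)
            table.append(ModuleOverlap(la, lb, n_univ, len(members_a[la]),
                                       len(members_b[lb]), len(shared), p,
                                       eigengene_correlation=r))
    qs = bh_adjust([row.p_value for row in table])
    for row, q in zip(table, qs):
        row.q_value = float(q)
    edges = [row for row in table if row.p_value < alpha]
    defined = [e for e in edges if e.eigengene_correlation is not None]
    frac_pos = (sum(e.eigengene_correlation > 0 for e in defined) / len(defined)
                if defined else None)
    nodes = [(layer_tags[0], m, len(members_a[m])) for m in sorted(members_a)]
    nodes += [(layer_tags[1], m, len(members_b[m])) for m in sorted(members_b)]
    return table, BipartiteNetwork(nodes, edges, alpha, frac_pos)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def module_de_enrichment(partition: ModulePartition,
                         significant_features: list[str],
                         universe: list[str], alpha: float = 0.05,
                         set_name: str = "DE") -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each module for a significant-gene list."""
    _check_universe(partition, universe)
    sig = set(significant_features)
    if not sig <= set(universe):
        raise ConsistencyError("significant features not a subset of universe")
    out = []
    for label in partition.labels:
        members = set(partition.members(label))
        overlap = len(members & sig)
        p = hypergeometric_upper(len(universe), len(members), len(sig), overlap)
        out.append(EnrichmentResult(label, set_name, len(universe),
                                    len(members), len(sig), overlap, p))
    qs = bh_adjust([r.p_value for r in out])
    for r, q in zip(out, qs):
        r.q_value = float(q)
    return out


def gene_set_enrichment(partition: ModulePartition, sets: GeneSetCollection,
                        universe: list[str]) -> list[EnrichmentResult]:
    """Module x gene-set over-representation against user-supplied sets.

    Set members are intersected with the universe before testing; a set
    with no member in the universe is recorded as untested. BH q-values
    are computed across all tested (module, set) pairs.
    """
    _check_universe(partition, universe)
    univ = set(universe)
    out: list[EnrichmentResult] = []
    for set_name in sorted(sets.sets):
        in_universe = sorted(set(sets.sets[set_name]) & univ)
        for label in partition.labels:
            members = set(partition.members(label))
            if not in_universe:
                out.append(EnrichmentResult(label, set_name, len(universe),
                                            len(members), 0, 0,
                                            float("nan"), tested=False))
                continue
            overlap = len(members & set(in_universe))
            p = hypergeometric_upper(len(universe), len(members),
                                     len(in_universe), overlap)
            out.append(EnrichmentResult(label, set_name, len(universe),
                                        len(members), len(in_universe),
                                        overlap, p))
    tested = [r for r in out if r.tested]
    qs = bh_adjust([r.p_value for r in tested])
    for r, q in zip(tested, qs):
        r.q_value = float(q)
    return out


# ---------------------------------------------------------------------------
# Coordinated disease pairs
# ---------------------------------------------------------------------------

def coordinated_pairs(bipartite: BipartiteNetwork,
                      enrich_a: list[EnrichmentResult],
                      enrich_b: list[EnrichmentResult],
                      alpha: float = 0.05,
                      ) -> list[tuple[int, int, float]]:
    """Bipartite edges whose two endpoint modules are both enriched
    (p < alpha) for the same contrast's differentially expressed genes,
    ranked by decreasing mean -log10 enrichment p."""
    p_a = {r.module: r.p_value for r in enrich_a}
    p_b = {r.module: r.p_value for r in enrich_b}
    missing = ({e.module_a for e in bipartite.edges} - set(p_a)) | \
              ({e.module_b for e in bipartite.edges} - set(p_b))
    if missing:
        raise ConsistencyError(f"enrichment tables missing modules {sorted(missing)}")
    out = []
    for e in bipartite.edges:
        pa, pb = p_a[e.module_a], p_b[e.module_b]
        if pa < alpha and pb < alpha:
            score = float(-(math.log10(pa) + math.log10(pb)) / 2.0)
            out.append((e.module_a, e.module_b, score))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# Connectivity comparison and cross-study validation
# ---------------------------------------------------------------------------

def connectivity_comparison(net_a: CoexpressionNetwork,
                            net_b: CoexpressionNetwork,
                            ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test comparing the two layers' total
    connectivity distributions {k_i}. Returns (statistic, p)."""
    if set(net_a.feature_ids) != set(net_b.feature_ids):
        raise ConsistencyError("networks cover different feature universes")
    res = stats.ranksums(net_a.connectivity, net_b.connectivity)
    return float(res.statistic), float(res.pvalue)


def cross_study_module_comparison(partition_a: ModulePartition,
                                  external: dict[str, int],
                                  alpha: float = 0.05,
                                  min_shared: int = 10,
                                  ) -> tuple[list[ModuleOverlap], dict[int, bool]]:
    """Compare this study's modules against an externally published
    partition, restricted to the genes present in both.

    External genes absent from this study's universe are silently dropped
    (with the count reflected in the restricted universe size). Returns
    the overlap table over the shared universe and, per internal module,
    whether at least one external module overlaps at p < alpha.
    """
    shared = sorted(set(partition_a.assignment) & set(external))
    if len(shared) < min_shared:
        raise ConsistencyError(
            f"only {len(shared)} genes shared with external study (need "
            f">= {min_shared})"
        )
    sub_a = ModulePartition({g: partition_a.assignment[g] for g in shared})
    sub_b = ModulePartition({g: external[g] for g in shared})
    table, _ = module_overlap_table(sub_a, sub_b, shared, alpha=alpha)
    validated = {m: False for m in sub_a.labels}
    for row in table:
        if row.p_value < alpha:
            validated[row.module_a] = True
    return table, validated
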