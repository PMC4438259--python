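"""Single-layer signed weighted co-expression network.

The construction follows the standard signed weighted-network recipe:
Pearson correlation r across samples is mapped to adjacency
a_ij = ((1 + r_ij)/2)^beta, so perfectly anti-correlated features get
adjacency 0 and the soft-thresholding power beta sharpens the contrast.
beta is chosen as the smallest power whose scale-free topology fit — the
signed R^2 of the log-log regression of binned connectivity frequency on
mean connectivity — reaches a target (default 0.90). Pairwise similarity
for clustering is the topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,

which credits shared neighborhoods as well as direct adjacency. Modules
are subtrees of the average-linkage dendrogram of 1 - TOM cut at a fixed
height (the deterministic static variant of tree cutting), labelled
1..M in decreasing size order with 0 for unassigned features; each
module is summarized by its eigengene, the first principal component of
the standardized member profiles across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .io_formats import ConsistencyError, ExpressionMatrix

logger = logging.getLogger("coexstack")

DEFAULT_CANDIDATE_BETAS = tuple(range(1, 21))
DEFAULT_TARGET_R2 = 0.90
DEFAULT_MIN_MODULE_SIZE = 100
DEFAULT_CUT_HEIGHT = 0.99


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    feature_ids: list[str]
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    connectivity: np.ndarray
    scale_free_r2: float


@dataclass
class ModulePartition:
    """Feature -> module assignment (label 0 means unassigned) plus the
    module x sample eigengene matrix once computed."""

    assignment: dict[str, int]
    eigengenes: pd.DataFrame | None = None
    module_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.module_sizes:
            sizes: dict[int, int] = {}
            for label in self.assignment.values():
                if label != 0:
                    sizes[label] = sizes.get(label, 0) + 1
            self.module_sizes = sizes

    @property
    def labels(self) -> list[int]:
        return sorted(self.module_sizes)

    def members(self, label: int) -> list[str]:
        return [f for f, m in self.assignment.items() if m == label]

    @property
    def n_assigned(self) -> int:
        return sum(self.module_sizes.values())


@dataclass
class SoftThresholdResult:
    beta: int
    reached_target: bool
    #: columns beta, r2, mean_k — one row per candidate power
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Adjacency and scale-free fit
# ---------------------------------------------------------------------------

def _signed_similarity(matrix: ExpressionMatrix) -> np.ndarray:
    if matrix.n_samples < 3:
        raise ConsistencyError("need >=3 samples to build a network")
    if np.any(matrix.values.var(axis=1) == 0):
        bad = [matrix.feature_ids[i]
               for i in np.flatnonzero(matrix.values.var(axis=1) == 0)[:5]]
        raise ConsistencyError(
            f"zero-variance feature(s) {bad}; run intersect_features first"
        )
    r = np.corrcoef(matrix.values)
    return np.clip((1.0 + r) / 2.0, 0.0, 1.0)


def signed_adjacency(matrix: ExpressionMatrix, beta: int) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + r_ij)/2)^beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = _signed_similarity(matrix) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Per-feature total connectivity k_i = sum_{j != i} a_ij."""
    return adjacency.sum(axis=1)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    Features are binned into ``n_bins`` equal-width connectivity bins;
    log10 of the per-bin frequency is regressed on log10 of the per-bin
    mean connectivity over non-empty bins. The R^2 is multiplied by
    -sign(slope) so that positive values indicate the decreasing degree
    distribution a scale-free network requires.
    """
    k = connectivity(adjacency)
    if np.unique(k).size < 2:
        raise ConsistencyError("all connectivities identical; fit undefined")
    if np.unique(k).size < n_bins:
        logger.warning("scale_free_fit: only %d distinct connectivity values "
                       "for %d bins", np.unique(k).size, n_bins)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        mean_k = k[idx == b].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(counts[b]))
    if len(xs) < 2:
        raise ConsistencyError("fewer than 2 usable connectivity bins")
    fit = linregress(xs, ys)
    r2 = fit.rvalue ** 2
    return float(r2 * (-np.sign(fit.slope))) if fit.slope != 0 else 0.0


def pick_soft_threshold(matrix: ExpressionMatrix,
                        candidate_betas=DEFAULT_CANDIDATE_BETAS,
                        target_r2: float = DEFAULT_TARGET_R2,
                        n_bins: int = 10) -> SoftThresholdResult:
    """Choose the smallest soft-thresholding power reaching the target
    scale-free fit.

    If no candidate reaches the target, the power with the maximal signed
    R^2 is returned with a warning. The full (beta, R^2, mean k) scan
    table is logged and returned.
    """
    candidates = sorted(int(b) for b in candidate_betas)
    if not candidates:
        raise ValueError("empty candidate beta list")
    base = _signed_similarity(matrix)
    rows = []
    for beta in candidates:
        a = base ** beta
        np.fill_diagonal(a, 0.0)
        try:
            r2 = scale_free_fit(a, n_bins=n_bins)
        except ConsistencyError:
            r2 = float("nan")
        rows.append((beta, r2, float(connectivity(a).mean())))
    table = pd.DataFrame(rows, columns=["beta", "r2", "mean_k"])
    logger.info("soft-threshold scan:\n%s", table.to_string(index=False))
    reaching = table[table["r2"] >= target_r2]
    if len(reaching):
        beta = int(reaching["beta"].iloc[0])
        return SoftThresholdResult(beta, True, table)
    best = int(table.loc[table["r2"].idxmax(), "beta"])
    logger.warning("no candidate beta reached target R2=%.2f; using beta=%d "
                   "(max R2=%.3f)", target_r2, best, table["r2"].max())
    return SoftThresholdResult(best, False, table)


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def _validate_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConsistencyError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ConsistencyError("adjacency must be symmetric")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ConsistencyError("adjacency entries must lie in [0, 1]")
    if np.any(np.abs(np.diag(a)) > 1e-12):
        raise ConsistencyError("adjacency diagonal must be zero")
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a valid signed adjacency."""
    a = _validate_adjacency(adjacency)
    # zero diagonal makes A @ A exactly sum_{u != i,j} a_iu a_uj off-diagonal
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def cluster_and_cut(tom: np.ndarray, feature_ids: list[str],
                    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
                    cut_height: float = DEFAULT_CUT_HEIGHT) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM, cut at a fixed height.

    Subtrees with at least ``min_module_size`` leaves become modules
    labelled 1..M in decreasing size order (size ties broken by the
    lexicographically smallest member id, so labels are invariant to
    feature order); everything else is labelled 0.
    """
    if not 0.0 < cut_height < 1.0:
        raise ValueError("cut_height must be in (0, 1)")
    n = len(feature_ids)
    if tom.shape != (n, n):
        raise ConsistencyError("TOM shape does not match feature ids")
    if min_module_size > n:
        logger.warning("min_module_size %d exceeds feature count %d; "
                       "all features unassigned", min_module_size, n)
        return ModulePartition({f: 0 for f in feature_ids})
    d = 1.0 - tom
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for f, c in zip(feature_ids, raw):
        clusters.setdefault(int(c), []).append(f)
    keepers = [members for members in clusters.values()
               if len(members) >= min_module_size]
    keepers.sort(key=lambda m: (-len(m), min(m)))
    assignment = {f: 0 for f in feature_ids}
    for label, members in enumerate(keepers, start=1):
        for f in members:
            assignment[f] = label
    return ModulePartition(assignment)


def module_eigengene(matrix: ExpressionMatrix,
                     partition: ModulePartition) -> pd.DataFrame:
    """First principal component of each module's standardized member rows.

    Rows are z-scored across samples; the leading right singular vector
    (across samples, unit norm) is the eigengene, sign-oriented so its
    average correlation with the member profiles is positive. Returns a
    module x sample DataFrame and stores it on the partition.
    """
    index = {f: i for i, f in enumerate(matrix.feature_ids)}
    rows = {}
    for label in partition.labels:
        members = partition.members(label)
        if len(members) < 2:
            raise ConsistencyError(f"module {label} has <2 members")
        sub = matrix.values[[index[f] for f in members], :]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ConsistencyError(f"module {label} contains a constant feature")
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        member_corr = z @ eig / (np.linalg.norm(z, axis=1) * np.linalg.norm(eig))
        if member_corr.mean() < 0:
            eig = -eig
        rows[label] = eig
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=matrix.sample_ids)
    frame.index.name = "module"
    partition.eigengenes = frame
    return frame


def intramodular_connectivity(partition: ModulePartition,
                              adjacency: np.ndarray,
                              feature_ids: list[str]) -> dict[str, float]:
    """k_in(i) = sum of adjacency to same-module members (0 for unassigned)."""
    index = {f: i for i, f in enumerate(feature_ids)}
    out = {f: 0.0 for f in feature_ids}
    for label in partition.labels:
        members = partition.members(label)
        idx = [index[f] for f in members]
        block = adjacency[np.ix_(idx, idx)]
        k_in = block.sum(axis=1)
        for f, k in zip(members, k_in):
            out[f] = float(k)
    return out


def hub_genes(partition: ModulePartition, adjacency: np.ndarray,
              feature_ids: list[str], top_n: int = 10) -> dict[int, list[str]]:
    """Top-n members per module by intramodular connectivity, ties
    broken lexicographically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    k_in = intramodular_connectivity(partition, adjacency, feature_ids)
    out: dict[int, list[str]] = {}
    for label in partition.labels:
        ranked = sorted(partition.members(label), key=lambda f: (-k_in[f], f))
        out[label] = ranked[:top_n]
    return out


# ---------------------------------------------------------------------------
# One-call layer construction
# ---------------------------------------------------------------------------

def build_network(matrix: ExpressionMatrix, beta: int | None = None,
                  candidate_betas=DEFAULT_CANDIDATE_BETAS,
                  target_r2: float = DEFAULT_TARGET_R2) -> CoexpressionNetwork:
    """Build adjacency, TOM and connectivity for one layer, picking the
    soft threshold when ``beta`` is not fixed by the caller."""
    if beta is None:
        beta = pick_soft_threshold(matrix, candidate_betas, target_r2).beta
    a = signed_adjacency(matrix, beta)
    return CoexpressionNetwork(
        feature_ids=list(matrix.feature_ids),
        beta=int(beta),
        adjacency=a,
        tom=topological_overlap(a),
        connectivity=connectivity(a),
        scale_free_r2=scale_free_fit(a),
    )
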