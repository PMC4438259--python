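"""Coupled two-layer synthetic data with planted ground truth.

The generator emulates the statistical structure the stacked-network
analysis assumes: two feature x sample layers (think promoter-mark signal
and expression) over one shared gene universe, each layer carrying latent
modules whose members load on a module eigengene, a subset of module
pairs coupled across layers, and group mean-shifts planted on selected
module eigengenes.

Per module m the eigengene is drawn e_m ~ N(0, 1) across samples, with a
shift of delta (in sd units) added to the samples of a targeted group
when m is an effect module. Member gene g gets

    x_gs = lambda_g * e_ms + sqrt(1 - lambda_g^2) * eps_gs,

with loading lambda_g uniform in ``loading_range`` and noise
eps ~ N(0, noise_sd^2), so at noise_sd = 1 every member has unit marginal
variance and the expected within-module correlation of members g, h is
lambda_g * lambda_h. A coupled layer-B module shares its gene block with
its layer-A partner and uses the eigengene

    e'_m = rho * e_m + sqrt(1 - rho^2) * z,   z fresh N(0, 1),

so a group shift planted on the layer-A eigengene propagates into the
coupled layer attenuated by rho — the way a promoter-mark change would
drive a correlated expression change. A pair declared with rho = 0 is
fully uncoupled: independent eigengenes over disjoint gene blocks, the
null regime for coupling recovery. Genes modular in only one layer are
pure noise in the other; ``n_background`` genes are noise in both.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .io_formats import ConsistencyError, ExpressionMatrix
from .network import ModulePartition

#: study-sized sample design: 8 controls, 8 alcohol, 7 cocaine
DEFAULT_GROUPS = {"control": 8, "alcohol": 8, "cocaine": 7}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic two-layer dataset.

    coupled_pairs entries are (module_a, module_b, rho); effect_modules
    entries are (layer "A"/"B", module label, group, delta in sd units).
    """

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    n_modules_a: int = 8
    n_modules_b: int = 8
    module_sizes: int | list[int] = 150
    n_background: int = 350
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 1.0
    #: residualize latent eigengenes against the group design and make them
    #: mutually orthogonal within each layer, so planted deltas and rhos are
    #: the only group structure / inter-module dependence (see generate)
    orthogonal_eigengenes: bool = True
    coupled_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 1, 0.9), (2, 2, 0.9), (3, 3, 0.9)])
    effect_modules: list[tuple[str, int, str, float]] = field(
        default_factory=lambda: [("A", 1, "alcohol", 1.5),
                                 ("A", 2, "cocaine", 1.5)])
    seed: int = 0

    def sizes(self, layer: str) -> list[int]:
        n = self.n_modules_a if layer == "A" else self.n_modules_b
        if isinstance(self.module_sizes, int):
            return [self.module_sizes] * n
        if len(self.module_sizes) < n:
            raise ValueError("module_sizes list shorter than module count")
        return [int(s) for s in self.module_sizes[:n]]

    def validate(self) -> None:
        if any(c <= 0 for c in self.n_samples_per_group.values()):
            raise ValueError("sample counts must be positive")
        if not (0 < self.loading_range[0] <= self.loading_range[1] <= 1):
            raise ValueError("loading_range must satisfy 0 < lo <= hi <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        sizes_a, sizes_b = self.sizes("A"), self.sizes("B")
        for ma, mb, rho in self.coupled_pairs:
            if not (1 <= ma <= self.n_modules_a and 1 <= mb <= self.n_modules_b):
                raise ValueError(f"coupled pair ({ma},{mb}) out of range")
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
            if rho != 0 and sizes_a[ma - 1] != sizes_b[mb - 1]:
                raise ValueError(
                    f"coupled modules A{ma}/B{mb} must have equal sizes"
                )
        for layer, m, group, _ in self.effect_modules:
            if layer not in ("A", "B"):
                raise ValueError("effect layer must be 'A' or 'B'")
            n = self.n_modules_a if layer == "A" else self.n_modules_b
            if not 1 <= m <= n:
                raise ValueError(f"effect module {layer}{m} out of range")
            if group not in self.n_samples_per_group:
                raise ValueError(f"unknown effect group {group!r}")


@dataclass
class SyntheticDataset:
    layer_a: ExpressionMatrix
    layer_b: ExpressionMatrix
    truth_partition_a: dict[str, int]
    truth_partition_b: dict[str, int]
    truth_coupled_pairs: list[tuple[int, int, float]]
    truth_effect_modules: list[tuple[str, int, str, float]]
    config: SyntheticConfig


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; bit-for-bit reproducible given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for group, count in config.n_samples_per_group.items():
        for i in range(1, count + 1):
            sid = f"{group}_{i}"
            sample_ids.append(sid)
            groups[sid] = group
    n_s = len(sample_ids)
    group_mask = {g: np.array([groups[s] == g for s in sample_ids])
                  for g in config.n_samples_per_group}

    sizes_a, sizes_b = config.sizes("A"), config.sizes("B")
    coupled = [(ma, mb, rho) for ma, mb, rho in config.coupled_pairs if rho != 0]
    coupled_a = {ma for ma, _, _ in coupled}
    coupled_b = {mb for _, mb, _ in coupled}

    # --- gene allocation: shared coupled blocks, layer-exclusive blocks,
    # --- then genes that are background in both layers
    truth_a: dict[str, int] = {}
    truth_b: dict[str, int] = {}
    next_gene = 0

    def new_genes(count: int) -> list[str]:
        nonlocal next_gene
        out = [f"g{next_gene + i:05d}" for i in range(count)]
        next_gene += count
        return out

    members_a: dict[int, list[str]] = {}
    members_b: dict[int, list[str]] = {}
    for ma, mb, _ in coupled:
        block = new_genes(sizes_a[ma - 1])
        members_a[ma] = block
        members_b[mb] = block
    for m in range(1, config.n_modules_a + 1):
        if m not in coupled_a:
            members_a[m] = new_genes(sizes_a[m - 1])
    for m in range(1, config.n_modules_b + 1):
        if m not in coupled_b:
            members_b[m] = new_genes(sizes_b[m - 1])
    background = new_genes(config.n_background)
    gene_ids = [f"g{i:05d}" for i in range(next_gene)]
    for m, genes in members_a.items():
        for g in genes:
            truth_a[g] = m
    for m, genes in members_b.items():
        for g in genes:
            truth_b[g] = m
    truth_a.update({g: 0 for g in gene_ids if g not in truth_a})
    truth_b.update({g: 0 for g in gene_ids if g not in truth_b})

    # --- eigengenes: layer A first, then layer B (coupled ones reuse A's)
    def apply_effects(e: np.ndarray, layer: str, m: int) -> np.ndarray:
        for lay, mod, group, delta in config.effect_modules:
            if lay == layer and mod == m:
                e = e + delta * group_mask[group]
        return e

    def draw_factors(count: int) -> list[np.ndarray]:
        """Latent unit-variance factors, one per module of a layer.

        With orthogonal_eigengenes the raw Gaussian draws are residualized
        against the group-indicator design and made mutually orthonormal
        (QR), so effect-free modules carry exactly zero group structure and
        distinct modules within a layer are uncorrelated by construction;
        otherwise the raw draws are returned as-is.
        """
        if count == 0:
            return []
        raw = rng.standard_normal((n_s, count))
        if not config.orthogonal_eigengenes:
            return [raw[:, i] for i in range(count)]
        design = np.stack([group_mask[g].astype(float)
                           for g in config.n_samples_per_group], axis=1)
        if count > n_s - design.shape[1]:
            raise ValueError(
                f"{count} modules need more than the {n_s} samples minus "
                f"{design.shape[1]} group constraints allow"
            )
        coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
        resid = raw - design @ coef
        q, _ = np.linalg.qr(resid)
        # align each factor with its raw draw so signs are reproducible
        signs = np.sign(np.sum(q * raw, axis=0))
        signs[signs == 0] = 1.0
        q = q * signs
        return [q[:, i] * np.sqrt(n_s) for i in range(count)]

    factors_a = draw_factors(config.n_modules_a)
    eig_a = {}
    for m in range(1, config.n_modules_a + 1):
        eig_a[m] = apply_effects(factors_a[m - 1], "A", m)
    factors_b = draw_factors(config.n_modules_b)
    pair_of_b = {mb: (ma, rho) for ma, mb, rho in coupled}
    eig_b = {}
    for m in range(1, config.n_modules_b + 1):
        z = factors_b[m - 1]
        if m in pair_of_b:
            ma, rho = pair_of_b[m]
            e = rho * eig_a[ma] + np.sqrt(1 - rho ** 2) * z
        else:
            e = z
        eig_b[m] = apply_effects(e, "B", m)

    # --- member rows, in gene order, layer A then layer B
    lo, hi = config.loading_range

    def make_layer(truth: dict[str, int], eig: dict[int, np.ndarray]) -> np.ndarray:
        values = np.empty((len(gene_ids), n_s))
        for i, g in enumerate(gene_ids):
            m = truth[g]
            if m == 0:
                values[i] = config.noise_sd * rng.standard_normal(n_s)
            else:
                lam = rng.uniform(lo, hi)
                eps = config.noise_sd * rng.standard_normal(n_s)
                values[i] = lam * eig[m] + np.sqrt(1 - lam ** 2) * eps
        return values

    layer_a = ExpressionMatrix(list(gene_ids), list(sample_ids),
                               make_layer(truth_a, eig_a), dict(groups))
    layer_b = ExpressionMatrix(list(gene_ids), list(sample_ids),
                               make_layer(truth_b, eig_b), dict(groups))
    return SyntheticDataset(layer_a, layer_b, truth_a, truth_b,
                            list(coupled), list(config.effect_modules), config)


def strong_regime_config(seed: int = 0) -> SyntheticConfig:
    """The strong-recovery regime: 5 modules of 120 genes per layer over
    23 study-sized samples, loadings in [0.7, 0.9], three module pairs
    coupled at rho = 0.9, and a 1.5-sd group shift planted on one coupled
    pair per drug (on the layer-A eigengene, propagating through the
    coupling). The universe is exactly the genes of the two layers'
    modules: genes modular in only one layer are the other layer's noise
    features."""
    return SyntheticConfig(
        n_modules_a=5, n_modules_b=5, module_sizes=120, n_background=0,
        loading_range=(0.7, 0.9),
        coupled_pairs=[(1, 1, 0.9), (2, 2, 0.9), (3, 3, 0.9)],
        effect_modules=[("A", 1, "alcohol", 1.5), ("A", 2, "cocaine", 1.5)],
        seed=seed,
    )


def null_config(seed: int = 0, n_features: int = 2000,
                n_samples_per_group: dict[str, int] | None = None,
                ) -> SyntheticConfig:
    """Pure-noise regime: no modules, no coupling, no effects."""
    return SyntheticConfig(
        n_samples_per_group=n_samples_per_group or dict(DEFAULT_GROUPS),
        n_modules_a=0, n_modules_b=0, module_sizes=0,
        n_background=n_features, coupled_pairs=[], effect_modules=[],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground-truth evaluators
# ---------------------------------------------------------------------------

@dataclass
class ModuleRecovery:
    ari: float
    #: truth module -> best-match Jaccard index against inferred modules
    jaccard: dict[int, float]
    #: truth module -> inferred label achieving the best Jaccard (0 if none)
    best_match: dict[int, int]


def evaluate_module_recovery(truth: dict[str, int],
                             inferred: ModulePartition) -> ModuleRecovery:
    """Score an inferred partition against planted truth.

    The ARI is computed over the features the inferred partition assigns
    (label != 0), with truth background kept as its own class; per truth
    module the best-match Jaccard against any inferred module is reported.
    """
    if set(truth) != set(inferred.assignment):
        raise ConsistencyError("truth and inferred partitions cover "
                               "different universes")
    assigned = [f for f, m in inferred.assignment.items() if m != 0]
    if assigned:
        ari = float(adjusted_rand_score([truth[f] for f in assigned],
                                        [inferred.assignment[f] for f in assigned]))
    else:
        ari = 0.0
    truth_modules: dict[int, set[str]] = {}
    for f, m in truth.items():
        if m != 0:
            truth_modules.setdefault(m, set()).add(f)
    jaccard: dict[int, float] = {}
    best: dict[int, int] = {}
    for m, mem in truth_modules.items():
        scores = {
            lab: len(mem & set(inferred.members(lab))) /
            len(mem | set(inferred.members(lab)))
            for lab in inferred.labels
        }
        if scores:
            lab = max(sorted(scores), key=lambda k: scores[k])
            jaccard[m], best[m] = scores[lab], lab
        else:
            jaccard[m], best[m] = 0.0, 0
    return ModuleRecovery(ari, jaccard, best)


@dataclass
class IntegrationRecovery:
    #: fraction of truth coupled pairs present as bipartite edges
    coupled_sensitivity: float
    #: fraction of truth effect-carrying coupled pairs returned as
    #: coordinated pairs in the matching contrast
    coordinated_sensitivity: float
    #: returned coordinated pairs not matching any truth effect pair
    false_coordinated: int


def evaluate_integration_recovery(
        dataset: SyntheticDataset,
        inferred_a: ModulePartition, inferred_b: ModulePartition,
        bipartite_edges: set[tuple[int, int]],
        coordinated: dict[str, list[tuple[int, int, float]]],
) -> IntegrationRecovery:
    """Map truth modules to their best-match inferred modules and score
    coupled-pair and coordinated-pair recovery.

    ``coordinated`` maps each contrast (drug group) to the coordinated
    pairs called for it, as (module_a, module_b, score) tuples of
    inferred labels.
    """
    rec_a = evaluate_module_recovery(dataset.truth_partition_a, inferred_a)
    rec_b = evaluate_module_recovery(dataset.truth_partition_b, inferred_b)

    mapped_pairs = {}
    for ma, mb, _ in dataset.truth_coupled_pairs:
        mapped_pairs[(ma, mb)] = (rec_a.best_match.get(ma, 0),
                                  rec_b.best_match.get(mb, 0))
    hits = sum(1 for pair in mapped_pairs.values()
               if 0 not in pair and pair in bipartite_edges)
    coupled_sens = hits / len(mapped_pairs) if mapped_pairs else float("nan")

    # truth coordinated pairs per contrast: coupled pairs with a planted
    # effect on either endpoint for that drug group
    effect_by_group: dict[str, set[tuple[int, int]]] = {}
    for layer, m, group, delta in dataset.truth_effect_modules:
        if delta == 0:
            continue
        for ma, mb, _ in dataset.truth_coupled_pairs:
            if (layer == "A" and m == ma) or (layer == "B" and m == mb):
                effect_by_group.setdefault(group, set()).add((ma, mb))

    n_truth = sum(len(v) for v in effect_by_group.values())
    n_found = 0
    n_false = 0
    for group, called in coordinated.items():
        called_pairs = {(a, b) for a, b, _ in called}
        truth_pairs = {mapped_pairs[p] for p in effect_by_group.get(group, set())
                       if 0 not in mapped_pairs[p]}
        n_found += len(called_pairs & truth_pairs)
        n_false += len(called_pairs - truth_pairs)
    coord_sens = n_found / n_truth if n_truth else float("nan")
    return IntegrationRecovery(coupled_sens, coord_sens, n_false)
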