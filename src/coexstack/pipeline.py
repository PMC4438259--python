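"""Config-driven orchestration of the full stacked-network analysis.

Stages, in order: peak annotation (optional, when the second layer comes
as peak-level signal), common-feature intersection, per-drug differential
expression in both layers, per-layer signed network + module detection,
cross-layer module overlap and bipartite stacking, DE and gene-set
enrichment, coordinated-pair calling, and the layer connectivity
comparison. All outputs land in one run directory; the JSON results
bundle echoes the effective configuration so every parameter of a run is
auditable, and a rerun with the same config and seed is byte-identical
apart from the timestamp field.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import integration, io_formats, network, peak_annotation
from .diffexpr import DEResult, fit_two_group, overlap_summary
from .io_formats import CoexstackError, ConsistencyError

logger = logging.getLogger("coexstack")


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run.

    The expression layer is always a gene x sample TSV. The ChIP layer is
    either a gene-level TSV (``chip_matrix``) or a peak-level TSV plus BED
    peaks and a TSS table, in which case annotation and per-gene collapse
    run first.
    """

    expression_matrix: str = ""
    metadata: str = ""
    chip_matrix: str | None = None
    chip_peak_matrix: str | None = None
    chip_peaks_bed: str | None = None
    tss_table: str | None = None
    gmt: str | None = None
    external_partition: str | None = None
    output_dir: str = "run"

    control_group: str = "control"
    drug_groups: list[str] = field(default_factory=lambda: ["alcohol", "cocaine"])
    alpha: float = 0.05
    candidate_betas: list[int] = field(
        default_factory=lambda: list(network.DEFAULT_CANDIDATE_BETAS))
    target_r2: float = network.DEFAULT_TARGET_R2
    min_module_size: int = network.DEFAULT_MIN_MODULE_SIZE
    cut_height: float = network.DEFAULT_CUT_HEIGHT
    moderation: bool = True
    collapse: str = "nearest"
    beta_expression: int | None = None
    beta_chip: int | None = None
    edge_weight_threshold: float = 0.1
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CoexstackError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate_paths(self) -> None:
        required = [self.expression_matrix, self.metadata]
        if self.chip_matrix:
            required.append(self.chip_matrix)
        elif self.chip_peak_matrix:
            required += [self.chip_peak_matrix, self.chip_peaks_bed or "",
                         self.tss_table or ""]
            if not (self.chip_peaks_bed and self.tss_table):
                raise CoexstackError(
                    "peak-level ChIP input needs chip_peaks_bed and tss_table"
                )
        else:
            raise CoexstackError("no ChIP layer input configured")
        for opt in (self.gmt, self.external_partition):
            if opt:
                required.append(opt)
        missing = [p for p in required if p and not Path(p).exists()]
        if missing:
            raise CoexstackError(f"input path(s) not found: {missing}")

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _overlap_rows(table: list[integration.ModuleOverlap]) -> list[dict]:
    return [
        {
            "module_a": r.module_a, "module_b": r.module_b,
            "n_universe": r.n_universe, "n_a": r.n_a, "n_b": r.n_b,
            "n_shared": r.n_shared, "p": r.p_value, "q": r.q_value,
            "eigengene_r": r.eigengene_correlation,
        }
        for r in table
    ]


def _enrichment_rows(results: list[integration.EnrichmentResult]) -> list[dict]:
    return [
        {
            "module": r.module, "set": r.set_name, "n_universe": r.n_universe,
            "n_module": r.n_module, "n_set": r.n_set, "n_overlap": r.n_overlap,
            "p": r.p_value if r.tested else None,
            "q": r.q_value if r.tested else None, "tested": r.tested,
        }
        for r in results
    ]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{c:.9g}" if isinstance(c, float) else str(c) for c in row
            ) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the results bundle."""
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    stage = "read inputs"
    try:
        expr = io_formats.read_expression_matrix(config.expression_matrix,
                                                 config.metadata)
        if config.chip_matrix:
            chip = io_formats.read_expression_matrix(config.chip_matrix,
                                                     config.metadata)
        else:
            stage = "peak annotation"
            peak_signal = io_formats.read_expression_matrix(
                config.chip_peak_matrix, config.metadata)
            peaks = peak_annotation.read_bed(config.chip_peaks_bed)
            tss = peak_annotation.read_tss_table(config.tss_table)
            assignments = peak_annotation.nearest_tss(peaks, tss)
            chip = peak_annotation.collapse_per_gene(assignments, peak_signal,
                                                     rule=config.collapse)
        expr.require_groups()

        stage = "feature intersection"
        expr, chip = peak_annotation.intersect_features(expr, chip)
        universe = list(expr.feature_ids)
        logger.info("common universe: %d genes, %d samples", len(universe),
                    expr.n_samples)

        stage = "differential expression"
        layers = {"expression": expr, "chip": chip}
        de: dict[str, dict[str, DEResult]] = {lay: {} for lay in layers}
        for lay, mat in layers.items():
            for drug in config.drug_groups:
                res = fit_two_group(mat, drug, config.control_group,
                                    moderation=config.moderation,
                                    alpha=config.alpha)
                res.write_tsv(outdir / f"de_{drug}_{lay}.tsv")
                de[lay][drug] = res
        drug_overlap = {}
        if len(config.drug_groups) == 2:
            d1, d2 = config.drug_groups
            for lay in layers:
                n_a, n_b, shared, p = overlap_summary(de[lay][d1], de[lay][d2])
                drug_overlap[lay] = {d1: n_a, d2: n_b, "shared": shared, "p": p}

        stage = "network construction"
        nets: dict[str, network.CoexpressionNetwork] = {}
        parts: dict[str, network.ModulePartition] = {}
        soft: dict[str, dict] = {}
        fixed = {"expression": config.beta_expression, "chip": config.beta_chip}
        for lay, mat in layers.items():
            if fixed[lay] is not None:
                beta, reached, scan = int(fixed[lay]), True, None
            else:
                pick = network.pick_soft_threshold(mat, config.candidate_betas,
                                                   config.target_r2)
                beta, reached = pick.beta, pick.reached_target
                scan = pick.table.to_dict(orient="records")
            net = network.build_network(mat, beta=beta)
            part = network.cluster_and_cut(net.tom, net.feature_ids,
                                           config.min_module_size,
                                           config.cut_height)
            if part.labels:
                network.module_eigengene(mat, part)
            k_in = network.intramodular_connectivity(part, net.adjacency,
                                                     net.feature_ids)
            hubs = network.hub_genes(part, net.adjacency, net.feature_ids,
                                     top_n=10) if part.labels else {}
            hub_set = {f for ranked in hubs.values() for f in ranked}
            io_formats.write_module_assignment(
                outdir / f"modules_{lay}.tsv", net.feature_ids,
                [part.assignment[f] for f in net.feature_ids],
                [k_in[f] for f in net.feature_ids], hub_set)
            nets[lay], parts[lay] = net, part
            soft[lay] = {"beta": beta, "scale_free_r2": net.scale_free_r2,
                         "reached_target": reached, "scan": scan}
            logger.info("%s layer: beta=%d R2=%.3f, %d modules", lay, beta,
                        net.scale_free_r2, len(part.labels))

        stage = "module overlap / bipartite stacking"
        table, bipartite = integration.module_overlap_table(
            parts["chip"], parts["expression"], universe, alpha=config.alpha,
            matrix_a=chip, matrix_b=expr, layer_tags=("CSM", "RSM"))
        _write_tsv(outdir / "overlaps.tsv",
                   ["module_chip", "module_expression", "n_a", "n_b",
                    "n_shared", "p", "q", "eigengene_r"],
                   [[r.module_a, r.module_b, r.n_a, r.n_b, r.n_shared,
                     r.p_value, r.q_value,
                     "" if r.eigengene_correlation is None
                     else r.eigengene_correlation] for r in table])
        _write_tsv(outdir / "bipartite_edges.tsv",
                   ["source", "target", "n_shared", "p"],
                   [[f"CSM{e.module_a}", f"RSM{e.module_b}", e.n_shared,
                     e.p_value] for e in bipartite.edges])

        stage = "enrichment"
        enrich: dict[str, list[integration.EnrichmentResult]] = {}
        for lay in layers:
            for drug in config.drug_groups:
                key = f"{drug}_{lay}"
                enrich[key] = integration.module_de_enrichment(
                    parts[lay], de[lay][drug].significant_features, universe,
                    alpha=config.alpha, set_name=f"DE_{drug}")
                _write_tsv(outdir / f"enrichment_{key}.tsv",
                           ["module", "set", "n_module", "n_set", "n_overlap",
                            "p", "q"],
                           [[r.module, r.set_name, r.n_module, r.n_set,
                             r.n_overlap, r.p_value, r.q_value]
                            for r in enrich[key]])
        gene_sets = {}
        if config.gmt:
            sets = io_formats.read_gmt(config.gmt)
            for lay in layers:
                res = integration.gene_set_enrichment(parts[lay], sets, universe)
                gene_sets[lay] = _enrichment_rows(res)

        stage = "coordinated pairs"
        coordinated = {}
        for drug in config.drug_groups:
            coordinated[drug] = integration.coordinated_pairs(
                bipartite, enrich[f"{drug}_chip"], enrich[f"{drug}_expression"],
                alpha=config.alpha)
        _write_tsv(outdir / "coordinated_pairs.tsv",
                   ["drug", "module_chip", "module_expression",
                    "mean_neglog10_p"],
                   [[drug, a, b, s] for drug, pairs in coordinated.items()
                    for a, b, s in pairs])

        stage = "connectivity comparison"
        conn_stat, conn_p = integration.connectivity_comparison(
            nets["chip"], nets["expression"])

        cross_study = None
        if config.external_partition:
            stage = "cross-study comparison"
            external = io_formats.read_module_assignment(config.external_partition)
            known = {g: m for g, m in external.items()
                     if g in parts["expression"].assignment}
            logger.info("cross-study: %d/%d external genes in universe",
                        len(known), len(external))
            xs_table, validated = integration.cross_study_module_comparison(
                parts["expression"], known, alpha=config.alpha)
            cross_study = {
                "validated": {str(m): v for m, v in validated.items()},
                "validated_fraction": (sum(validated.values()) / len(validated)
                                       if validated else None),
                "table": _overlap_rows(xs_table),
            }
    except CoexstackError as exc:
        raise CoexstackError(f"stage '{stage}' failed: {exc}") from exc

    results = {
        "config": config.echo(),
        "seed": config.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "universe_size": len(universe),
        "modules": {lay: {f: parts[lay].assignment[f]
                          for f in nets[lay].feature_ids}
                    for lay in layers},
        "module_sizes": {lay: {str(k): v
                               for k, v in parts[lay].module_sizes.items()}
                         for lay in layers},
        "soft_threshold": soft,
        "de_summary": {
            lay: {drug: {"n_significant": len(de[lay][drug].significant_features)}
                  for drug in config.drug_groups} for lay in layers},
        "drug_overlap": drug_overlap,
        "overlap_table": _overlap_rows(table),
        "bipartite": {
            "n_edges": len(bipartite.edges),
            "edges": [[e.module_a, e.module_b] for e in bipartite.edges],
            "fraction_positive_correlation":
                bipartite.fraction_positive_correlation,
        },
        "enrichment": {key: _enrichment_rows(rows)
                       for key, rows in enrich.items()},
        "gene_set_enrichment": gene_sets,
        "coordinated_pairs": {drug: [[a, b, s] for a, b, s in pairs]
                              for drug, pairs in coordinated.items()},
        "connectivity_comparison": {"statistic": conn_stat, "p": conn_p},
        "cross_study": cross_study,
    }
    io_formats.write_results_bundle(results, outdir / "results.json")
    return results


def simulate_to_dir(config, outdir) -> None:
    """Materialize a synthetic dataset as the pipeline's input files."""
    from .synthetic_data import generate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate(config)
    io_formats.write_expression_matrix(ds.layer_a, outdir / "layer_a.tsv")
    io_formats.write_expression_matrix(ds.layer_b, outdir / "layer_b.tsv")
    io_formats.write_sample_metadata(ds.layer_a.sample_groups,
                                     outdir / "metadata.tsv")
    for name, truth in (("truth_modules_a.tsv", ds.truth_partition_a),
                        ("truth_modules_b.tsv", ds.truth_partition_b)):
        _write_tsv(outdir / name, ["feature_id", "module_label"],
                   [[g, m] for g, m in sorted(truth.items())])
    _write_tsv(outdir / "truth_coupled_pairs.tsv",
               ["module_a", "module_b", "rho"],
               [[a, b, r] for a, b, r in ds.truth_coupled_pairs])
    _write_tsv(outdir / "truth_effect_modules.tsv",
               ["layer", "module", "group", "delta"],
               [list(t) for t in ds.truth_effect_modules])
    echo = dataclasses.asdict(config)
    echo["n_samples_per_group"] = dict(config.n_samples_per_group)
    with open(outdir / "config.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
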