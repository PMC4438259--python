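"""Assign ChIP peaks to the gene with the nearest transcription start site
and collapse the peak-level signal matrix to one row per gene.

Coordinate conventions are BED-style throughout: peaks are 0-based
half-open intervals [start, end), TSS positions are 0-based points. A TSS
falling inside a peak gives distance 0; outside, the distance is measured
from the nearer covered base, i.e. min(|tss - start|, |tss - (end-1)|).
Ties are broken lexicographically at every level so the annotation is a
deterministic function of its inputs, invariant to record order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ConsistencyError, ExpressionMatrix, FormatError

logger = logging.getLogger("coexstack")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    peak_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise FormatError(
                f"peak {self.peak_id}: start {self.start} must be < end {self.end}"
            )


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __post_init__(self):
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate peak ids")


@dataclass(frozen=True)
class TssRecord:
    gene_symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"TSS {self.gene_symbol}: strand must be + or -")
        if self.tss < 0:
            raise FormatError(f"TSS {self.gene_symbol}: position must be >= 0")


@dataclass
class TssTable:
    records: list[TssRecord]

    def __post_init__(self):
        keys = [(r.gene_symbol, r.tss) for r in self.records]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (gene, tss) records")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_symbol: str
    distance: int


# ---------------------------------------------------------------------------
# Readers (typed here, per the external-interface contract)
# ---------------------------------------------------------------------------

def read_bed(path) -> PeakSet:
    """Read BED3+ peaks. Column 4, when present, supplies the peak id;
    otherwise ids are chrom:start-end. Extra columns are ignored."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: BED needs >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-integer coordinates") from None
            peak_id = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            peaks.append(Peak(peak_id, chrom, start, end))
    return PeakSet(peaks)


def read_tss_table(path) -> TssTable:
    """Read a TSS table as TSV: gene, chrom, strand, tss (header optional)."""
    records: list[TssRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{line_no}: TSS table needs 4 columns")
            if line_no == 1 and parts[0].lower() in {"gene", "gene_symbol"}:
                continue
            try:
                pos = int(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{line_no}: non-integer TSS") from None
            records.append(TssRecord(parts[0], parts[1], parts[2], pos))
    return TssTable(records)


def tss_from_gff3(path, feature_type: str = "gene",
                  symbol_attr: str = "Name") -> TssTable:
    """Derive a TSS table from GFF3 gene records: the TSS is the 5' end of
    the feature per strand (start for +, end for -), converted from GFF's
    1-based closed coordinates to 0-based points."""
    records: list[TssRecord] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{line_no}: GFF3 needs 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature_type:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            symbol = attr_map.get(symbol_attr) or attr_map.get("ID")
            if symbol is None:
                raise FormatError(f"{path}:{line_no}: no {symbol_attr}/ID attribute")
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            if (symbol, tss) in seen:
                continue
            seen.add((symbol, tss))
            records.append(TssRecord(symbol, chrom, strand, tss))
    return TssTable(records)


# ---------------------------------------------------------------------------
# Nearest-TSS annotation
# ---------------------------------------------------------------------------

def _peak_tss_distance(peak: Peak, tss: int) -> int:
    if peak.start <= tss < peak.end:
        return 0
    return min(abs(tss - peak.start), abs(tss - (peak.end - 1)))


def nearest_tss(peaks: PeakSet, tss: TssTable) -> list[PeakGeneAssignment]:
    """Assign every peak to the gene with the nearest TSS on its chromosome.

    Peaks on chromosomes with no TSS record are dropped with a logged
    count. Ties on distance are broken by lexicographic gene symbol.
    """
    if not tss.records:
        raise ConsistencyError("empty TSS table")
    if not peaks.peaks:
        raise ConsistencyError("empty peak set")
    by_chrom: dict[str, list[TssRecord]] = {}
    for rec in tss.records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    peak_chroms = {p.chrom for p in peaks.peaks}
    if not peak_chroms & set(by_chrom):
        raise ConsistencyError(
            "no chromosome shared between peaks and TSS table "
            f"(peaks: {sorted(peak_chroms)}, tss: {sorted(by_chrom)})"
        )
    assignments: list[PeakGeneAssignment] = []
    dropped = 0
    for peak in peaks.peaks:
        candidates = by_chrom.get(peak.chrom)
        if not candidates:
            dropped += 1
            continue
        best = min(
            candidates,
            key=lambda r: (_peak_tss_distance(peak, r.tss), r.gene_symbol),
        )
        assignments.append(
            PeakGeneAssignment(peak.peak_id, best.gene_symbol,
                               _peak_tss_distance(peak, best.tss))
        )
    if dropped:
        logger.info("nearest_tss: dropped %d peak(s) on chromosomes with no TSS",
                    dropped)
    return assignments


def collapse_per_gene(assignments: list[PeakGeneAssignment],
                      peak_signal: ExpressionMatrix,
                      rule: str = "nearest") -> ExpressionMatrix:
    """Collapse the peak x sample signal matrix to one row per gene.

    With the default ``nearest`` rule, a gene annotated by several peaks
    keeps the row of the peak with the smallest TSS distance, ties broken
    by larger mean signal, then lexicographic peak id. ``rule='sum'`` sums
    the rows of all peaks assigned to the gene instead.
    """
    if rule not in ("nearest", "sum"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    index = {p: i for i, p in enumerate(peak_signal.feature_ids)}
    missing = [a.peak_id for a in assignments if a.peak_id not in index]
    if missing:
        raise ConsistencyError(f"peaks absent from signal matrix: {missing[:5]}")
    per_gene: dict[str, list[PeakGeneAssignment]] = {}
    for a in assignments:
        per_gene.setdefault(a.gene_symbol, []).append(a)
    genes = sorted(per_gene)
    rows = np.empty((len(genes), peak_signal.n_samples))
    for gi, gene in enumerate(genes):
        cands = per_gene[gene]
        if rule == "sum":
            rows[gi] = sum(peak_signal.values[index[a.peak_id]] for a in cands)
        else:
            winner = min(
                cands,
                key=lambda a: (a.distance,
                               -float(peak_signal.values[index[a.peak_id]].mean()),
                               a.peak_id),
            )
            rows[gi] = peak_signal.values[index[winner.peak_id]]
    logger.info("collapse_per_gene: %d peaks -> %d genes", len(assignments),
                len(genes))
    return ExpressionMatrix(genes, list(peak_signal.sample_ids), rows,
                            dict(peak_signal.sample_groups))


def intersect_features(layer_a: ExpressionMatrix,
                       layer_b: ExpressionMatrix,
                       ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both layers to their common features and drop features with
    zero variance across samples in either layer.

    Outputs share an identical (sorted) feature order. Each zero-variance
    removal is logged per feature; empty intersection or mismatched sample
    sets are errors.
    """
    if set(layer_a.sample_ids) != set(layer_b.sample_ids):
        raise ConsistencyError("sample sets differ between layers")
    common = sorted(set(layer_a.feature_ids) & set(layer_b.feature_ids))
    if not common:
        raise ConsistencyError("no common features between layers")
    a = layer_a.subset_features(common)
    b = layer_b.subset_features(common)
    var_a = a.values.var(axis=1)
    var_b = b.values.var(axis=1)
    keep = []
    for i, gene in enumerate(common):
        if var_a[i] == 0.0 or var_b[i] == 0.0:
            layer = "A" if var_a[i] == 0.0 else "B"
            logger.info("intersect_features: dropping %s (zero variance in layer %s)",
                        gene, layer)
        else:
            keep.append(gene)
    if not keep:
        raise ConsistencyError("all common features have zero variance")
    return a.subset_features(keep), b.subset_features(keep)
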