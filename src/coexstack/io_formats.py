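"""Readers and writers for the pipeline's external representations.

Canonical on-disk formats are plain text: tab-separated matrices (first
column feature ids, header row sample ids), GMT gene-set files, TSV edge
lists importable into Cytoscape, and a versioned JSON results bundle.
Missing values are not supported — the expected inputs are complete,
log-transformed, normalized signal matrices — so any NA token is a hard
error rather than a silent coercion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("coexstack")

RESULTS_SCHEMA_VERSION = 1

#: tokens that spreadsheets and R commonly emit for missing values; all rejected
_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null", "None"}


class CoexstackError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CoexstackError):
    """Malformed external input (bad dialect, duplicate ids, non-numeric cells)."""


class ConsistencyError(CoexstackError):
    """Inputs that are individually well-formed but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2-scale signal with group labels.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (gene symbols or peak ids).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_features, n_samples)
        Finite log2-scale signal.
    sample_groups : dict, optional
        Maps sample id to a group label (e.g. control/alcohol/cocaine).
        Required only by group-dependent operations.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("matrix contains non-finite values")
        unknown = set(self.sample_groups) - set(self.sample_ids)
        if unknown:
            raise ConsistencyError(
                f"metadata samples missing from matrix: {sorted(unknown)}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered list of member sample ids."""
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            g = self.sample_groups.get(s)
            if g is not None:
                out.setdefault(g, []).append(s)
        return out

    def require_groups(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise ConsistencyError(f"samples without group label: {missing}")

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Restrict to the given features, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in keep]
        return ExpressionMatrix(
            list(keep), list(self.sample_ids), self.values[rows, :],
            dict(self.sample_groups),
        )

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in keep]
        return ExpressionMatrix(
            list(self.feature_ids), list(keep), self.values[:, cols],
            {s: g for s, g in self.sample_groups.items() if s in set(keep)},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets, the carrier for GMT-style enrichment inputs."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

def _parse_cell(token: str, path, line_no: int) -> float:
    if token in _NA_TOKENS:
        raise FormatError(f"{path}:{line_no}: missing value {token!r} not supported")
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{line_no}: non-numeric cell {token!r}") from None


def read_matrix(path) -> ExpressionMatrix:
    """Read a TSV matrix (no metadata): header row of sample ids, first
    column feature ids. Comma dialects are rejected."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        if "\t" not in header and "," in header:
            raise FormatError(f"{path}: expected tab-separated values")
        cols = header.split("\t")
        sample_ids = cols[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}:{line_no}: expected {len(cols)} fields, got {len(parts)}"
                )
            feature_ids.append(parts[0])
            rows.append([_parse_cell(t, path, line_no) for t in parts[1:]])
    if len(set(feature_ids)) != len(feature_ids):
        seen: set[str] = set()
        dups = sorted({f for f in feature_ids if f in seen or seen.add(f)})
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(feature_ids, sample_ids, values)


def read_sample_metadata(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group); a header line with the
    literal fields 'sample'/'sample_id' is tolerated and skipped."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{line_no}: expected 2 tab-separated fields")
            sid, grp = parts[0], parts[1]
            if line_no == 1 and sid.lower() in {"sample", "sample_id"}:
                continue
            if sid in groups:
                raise FormatError(f"{path}:{line_no}: duplicate sample id {sid!r}")
            groups[sid] = grp
    return groups


def read_expression_matrix(path, metadata_path=None) -> ExpressionMatrix:
    """Read a TSV matrix and, optionally, attach sample group labels.

    Every metadata sample must be a column of the matrix; the converse is
    not required (unlabelled samples are simply unusable in group-dependent
    operations).
    """
    mat = read_matrix(path)
    if metadata_path is not None:
        mat = ExpressionMatrix(mat.feature_ids, mat.sample_ids, mat.values,
                               read_sample_metadata(metadata_path))
    return mat


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV with 9 significant digits (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, f in enumerate(matrix.feature_ids):
            cells = "\t".join(f"{v:.9g}" for v in matrix.values[i])
            fh.write(f"{f}\t{cells}\n")


def write_sample_metadata(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in groups.items():
            fh.write(f"{sid}\t{grp}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read the standard GMT dialect: name TAB description TAB member...

    Duplicate members within a line are deduplicated (first occurrence
    kept) with a logged warning; a line with fewer than three fields is a
    format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: GMT line needs >=3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: set %r has %d duplicate member(s), deduplicated",
                               path, line_no, name, len(members) - len(deduped))
            if name in sets:
                raise FormatError(f"{path}:{line_no}: duplicate set name {name!r}")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def write_edge_list(feature_ids: list[str], weights: np.ndarray, path,
                    weight_threshold: float = 0.0) -> int:
    """Write a symmetric weighted graph as a Cytoscape-importable TSV.

    Each undirected edge is written once with lexicographic source < target;
    edges with weight below ``weight_threshold`` are omitted. Returns the
    number of edges written.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(feature_ids)
    if weights.shape != (n, n):
        raise ConsistencyError("weight matrix shape does not match feature ids")
    written = 0
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                w = weights[i, j]
                if w < weight_threshold:
                    continue
                a, b = sorted((feature_ids[i], feature_ids[j]))
                fh.write(f"{a}\t{b}\t{w:.9g}\n")
                written += 1
    return written


def read_edge_list(path) -> list[tuple[str, str, float]]:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "weight"]:
            raise FormatError(f"{path}: expected source/target/weight header")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{line_no}: expected 3 fields")
            edges.append((parts[0], parts[1], _parse_cell(parts[2], path, line_no)))
    return edges


# ---------------------------------------------------------------------------
# Module assignment tables
# ---------------------------------------------------------------------------

def write_module_assignment(path, feature_ids, labels, connectivity=None,
                            hubs: set[str] | None = None) -> None:
    """TSV of feature_id, module_label, intramodular_connectivity, is_hub."""
    hubs = hubs or set()
    with open(path, "w") as fh:
        fh.write("feature_id\tmodule_label\tintramodular_connectivity\tis_hub\n")
        for i, f in enumerate(feature_ids):
            k = "" if connectivity is None else f"{connectivity[i]:.9g}"
            fh.write(f"{f}\t{labels[i]}\t{k}\t{int(f in hubs)}\n")


def read_module_assignment(path) -> dict[str, int]:
    """Read a two-or-more-column TSV of (feature_id, module_label)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{line_no}: expected >=2 fields")
            if line_no == 1 and parts[0].lower() in {"feature_id", "gene"}:
                continue
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{line_no}: non-integer module label {parts[1]!r}"
                ) from None
    return out


# ---------------------------------------------------------------------------
# JSON results bundle
# ---------------------------------------------------------------------------

MANDATORY_BUNDLE_SECTIONS = (
    "modules", "soft_threshold", "overlap_table", "enrichment",
    "coordinated_pairs",
)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def validate_results_bundle(results: dict) -> None:
    missing = [s for s in MANDATORY_BUNDLE_SECTIONS if s not in results]
    if missing:
        raise ConsistencyError(f"results bundle missing sections: {missing}")


def write_results_bundle(results: dict, path) -> None:
    """Serialize completed pipeline outputs as one versioned JSON document."""
    validate_results_bundle(results)
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **_jsonable(results)}
    try:
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise CoexstackError(f"unserializable results payload: {exc}") from exc
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_results_bundle(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != RESULTS_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {payload.get('schema_version')!r}"
        )
    return payload
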