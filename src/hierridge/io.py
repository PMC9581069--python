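"""Readers and writers for feature, outcome, and meta-feature files.

Dense matrices travel as TSV/CSV with a header row of column IDs and an
index column of row IDs; sparse matrices as MatrixMarket ``.mtx`` with
plain-text ``.rows``/``.cols`` ID sidecars.  Meta-features may instead be
given as group annotations — either a two-column (feature, group) table or
a GMT-style file — which are expanded to binary indicator columns.

Alignment between X columns and Z rows is always by feature ID when IDs are
available; positional interpretation is used only when neither side carries
IDs.  Silent row misalignment is the gravest failure mode for meta-feature
models, so mismatches raise with the offending IDs listed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_outcome",
    "write_outcome",
    "read_annotation_pairs",
    "read_gmt",
    "expand_groups",
    "align_meta",
    "filter_top_variable",
    "RunManifest",
]


def _check_ids(ids, what, path):
    ids = [str(i) for i in ids]
    seen = {}
    dups = []
    for ln, i in enumerate(ids):
        if i in seen:
            dups.append((i, seen[i], ln))
        seen.setdefault(i, ln)
    if dups:
        detail = "; ".join(f"{i!r} at rows {a} and {b}" for i, a, b in dups[:5])
        raise ValueError(f"duplicate {what} IDs in {path}: {detail}")
    return ids


def read_matrix(path):
    """Read a matrix with row/column identifiers.

    Returns ``(M, row_ids, col_ids)`` where M is a dense ndarray for
    .tsv/.csv and a CSR sparse matrix for .mtx (IDs from the .rows/.cols
    sidecar files, or positional labels when sidecars are absent).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".csv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        _check_ids(header[1:], "column", path)  # pandas silently renames duplicates
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            for c in bad:
                row = df[c].map(lambda v: isinstance(v, str)).idxmax()
                line = list(df.index).index(row) + 2  # header + 1-based
                raise ValueError(
                    f"non-numeric cell in {path}, column {c!r} near line {line}"
                )
        M = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(M)):
            i, j = np.argwhere(~np.isfinite(M))[0]
            raise ValueError(
                f"missing/non-finite value in {path} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}; imputation is not supported"
            )
        rows = _check_ids(df.index, "row", path)
        cols = _check_ids(df.columns, "column", path)
        return M, rows, cols
    if suffix == ".mtx":
        M = sp.csr_matrix(scipy.io.mmread(path))
        rows_file = path.with_suffix(".mtx.rows")
        cols_file = path.with_suffix(".mtx.cols")
        rows = (
            _check_ids(rows_file.read_text().split(), "row", rows_file)
            if rows_file.exists()
            else [f"r{i}" for i in range(M.shape[0])]
        )
        cols = (
            _check_ids(cols_file.read_text().split(), "column", cols_file)
            if cols_file.exists()
            else [f"c{i}" for i in range(M.shape[1])]
        )
        if len(rows) != M.shape[0] or len(cols) != M.shape[1]:
            raise ValueError(
                f"sidecar ID counts ({len(rows)}, {len(cols)}) do not match "
                f"matrix shape {M.shape} for {path}"
            )
        return M, rows, cols
    raise ValueError(f"unsupported matrix format {suffix!r} for {path}")


def write_matrix(path, M, row_ids=None, col_ids=None):
    """Write a matrix in the format implied by the extension (see read_matrix)."""
    path = Path(path)
    suffix = path.suffix.lower()
    n, m = M.shape
    row_ids = [str(r) for r in (row_ids if row_ids is not None else range(n))]
    col_ids = [str(c) for c in (col_ids if col_ids is not None else range(m))]
    if suffix in (".tsv", ".csv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        dense = M.toarray() if sp.issparse(M) else np.asarray(M)
        pd.DataFrame(dense, index=row_ids, columns=col_ids).to_csv(path, sep=sep)
    elif suffix == ".mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(M))
        path.with_suffix(".mtx.rows").write_text("\n".join(row_ids) + "\n")
        path.with_suffix(".mtx.cols").write_text("\n".join(col_ids) + "\n")
    else:
        raise ValueError(f"unsupported matrix format {suffix!r} for {path}")


def read_outcome(path) -> np.ndarray:
    """Read a single-column outcome file (one value per line, optional header)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty outcome file {path}")
    try:
        float(lines[0])
    except ValueError:
        lines = lines[1:]  # header
    try:
        return np.array([float(v) for v in lines])
    except ValueError as e:
        raise ValueError(f"non-numeric outcome value in {path}: {e}") from None


def write_outcome(path, y):
    Path(path).write_text("\n".join(f"{v:.17g}" for v in np.asarray(y).ravel()) + "\n")


# ---------------------------------------------------------------------------
# group annotations -> indicator meta-features
# ---------------------------------------------------------------------------


def read_annotation_pairs(path) -> list[tuple[str, str]]:
    """Two-column long-format annotation: feature<TAB>group per line."""
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_gmt(path) -> list[tuple[str, str]]:
    """GMT group file (group, description, member IDs...) -> (feature, group) pairs."""
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT lines need group, description, members")
        group = parts[0]
        for feat in parts[2:]:
            if feat:
                pairs.append((feat, group))
    return pairs


def expand_groups(
    pairs,
    feature_ids,
    *,
    normalize: bool = False,
    min_group_size: int = 1,
) -> tuple[np.ndarray, list[str]]:
    """Expand (feature, group) annotations to a binary indicator matrix Z.

    One column per group, ordered by first appearance; features absent from
    the annotation get all-zero rows, and a feature may belong to several
    (overlapping) groups.  ``normalize`` divides each column by its sum so
    the group coefficient reads as the average effect of the group's
    features.  Groups mapping fewer than ``min_group_size`` present features
    are dropped with a warning.
    """
    feature_ids = [str(f) for f in feature_ids]
    pos = {f: i for i, f in enumerate(feature_ids)}
    groups: dict[str, list[int]] = {}
    unknown = []
    for feat, grp in pairs:
        feat, grp = str(feat), str(grp)
        if feat in pos:
            groups.setdefault(grp, []).append(pos[feat])
        else:
            unknown.append(feat)
    if unknown:
        raise ValueError(
            f"{len(unknown)} annotated feature(s) not present in the feature matrix: "
            f"{sorted(set(unknown))[:10]}"
        )
    kept, names = [], []
    for grp, members in groups.items():
        members = sorted(set(members))
        if len(members) < min_group_size:
            log.warning("dropping group %r: only %d mapped feature(s)", grp, len(members))
            continue
        kept.append(members)
        names.append(grp)
    if not kept:
        raise ValueError("no groups survive the minimum-size filter")
    Z = np.zeros((len(feature_ids), len(kept)))
    for j, members in enumerate(kept):
        Z[members, j] = 1.0
    if normalize:
        Z = Z / Z.sum(axis=0)
    return Z, names


def align_meta(feature_ids, Z, z_row_ids) -> np.ndarray:
    """Reorder Z rows to match the feature-matrix column order by ID."""
    feature_ids = [str(f) for f in feature_ids]
    z_row_ids = [str(r) for r in z_row_ids]
    pos = {r: i for i, r in enumerate(z_row_ids)}
    missing = [f for f in feature_ids if f not in pos]
    if missing:
        raise ValueError(
            f"meta-feature rows missing for {len(missing)} feature(s): {missing[:10]}"
        )
    order = [pos[f] for f in feature_ids]
    if order != list(range(len(feature_ids))):
        log.info("meta-feature rows reordered to match feature matrix columns")
    Z = Z.tocsr()[order] if sp.issparse(Z) else np.asarray(Z)[order]
    return Z


def filter_top_variable(X, k: int):
    """Keep the k columns of X with largest sample variance.

    Ties break deterministically toward the earlier column; the kept columns
    retain their original relative order.  Returns (reduced X, kept indices).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    p = X.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds the number of columns {p}")
    if sp.issparse(X):
        mu = np.asarray(X.mean(axis=0)).ravel()
        var = np.asarray(X.multiply(X).mean(axis=0)).ravel() - mu**2
    else:
        var = np.asarray(X).var(axis=0)
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.sort(order)
    return (X.tocsc()[:, keep].tocsr() if sp.issparse(X) else np.asarray(X)[:, keep]), keep


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit given the inputs."""

    command: str
    version: str
    seed: int | None
    family: str
    config: dict
    selected_penalties: dict | None = None
    convergence: dict | None = None
    timing_seconds: float | None = None

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_json_default) + "\n")

    @staticmethod
    def read(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
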