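"""Readers and writers for every on-disk artifact.

Dialects (all plain TSV, ``#`` starts a comment line):

* **spatial BED** — one row per UMI-collapsed molecule:
  ``chrom  start  end  name  score  strand  gene_tag  x  y``
  with 0-based half-open coordinates, strand ``+``/``-``, ``.`` for an empty
  gene tag, and 1-based integer array coordinates ``x``, ``y``.
* **matrix TSV** — header ``spot`` + tag-cluster ids ``chrom:start-end:strand``;
  one row per spot, first column the spot id ``<x>x<y>``.
* **labels TSV** — header ``dataset  x  y  label``.
* **predictions TSV** — header ``dataset  x  y  p_<class>...  predicted_label``.
* **cluster BED** — ``chrom start end id total_count strand n_sites
  min_density max_density gene_id gene_name``.

Parsers are total: every input either parses fully or raises a
:class:`ParseError` naming the offending line; rows are never silently
dropped.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    CLASSES,
    READ_COLUMNS,
    RAW,
    GeneModel,
    SpotLabel,
    SpotMatrix,
    TagCluster,
    canonical_label,
    parse_spot_id,
    spot_id,
)

__all__ = [
    "ParseError",
    "read_spatial_bed",
    "write_spatial_bed",
    "read_gene_annotation",
    "read_labels",
    "write_labels",
    "read_matrix",
    "write_matrix",
    "read_predictions",
    "write_predictions",
    "read_clusters_bed",
    "write_clusters_bed",
]


class ParseError(ValueError):
    """A located parse failure: file, 1-based line number, reason."""

    def __init__(self, path, lineno: int, reason: str):
        self.path = str(path)
        self.lineno = lineno
        self.reason = reason
        super().__init__(f"{path}:{lineno}: {reason}")


def _data_lines(path) -> tuple[list[str], list[int]]:
    """Non-comment, non-blank lines of a file with their 1-based numbers."""
    lines, numbers = [], []
    with open(path, "rt") as fh:
        for n, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            lines.append(stripped)
            numbers.append(n)
    return lines, numbers


# ---------------------------------------------------------------------------
# spatial BED
# ---------------------------------------------------------------------------

def read_spatial_bed(path, array_bounds: tuple[int, int] | None = None,
                     dataset_id: str | None = None) -> pd.DataFrame:
    """Read a spatial BED file into a read table.

    Parameters
    ----------
    path
        Path to a 9-column spatial BED file (see module docstring).
    array_bounds
        Optional ``(width, height)``; spot coordinates must satisfy
        ``1 <= x <= width`` and ``1 <= y <= height``.
    dataset_id
        If given, added as a ``dataset`` column (defaults to the file stem).

    Returns
    -------
    pandas.DataFrame
        Columns ``READ_COLUMNS`` (+ ``dataset``), one row per molecule, in
        file order. The number of rows equals the number of non-comment
        lines of the file.
    """
    lines, numbers = _data_lines(path)
    if not lines:
        df = pd.DataFrame({c: [] for c in READ_COLUMNS})
    else:
        try:
            df = pd.read_csv(
                _io.StringIO("\n".join(lines)), sep="\t", header=None, dtype=str
            )
        except Exception as exc:  # pragma: no cover - pandas edge failures
            raise ParseError(path, numbers[0], f"unreadable TSV: {exc}")
        if df.shape[1] < len(READ_COLUMNS):
            bad = int((df.notna().sum(axis=1) < len(READ_COLUMNS)).idxmax())
            raise ParseError(
                path, numbers[bad],
                f"expected {len(READ_COLUMNS)} tab-separated fields, "
                f"found {df.shape[1]}",
            )
        df = df.iloc[:, : len(READ_COLUMNS)].set_axis(list(READ_COLUMNS), axis=1)

    def _fail_at(mask: np.ndarray, reason: str):
        row = int(np.flatnonzero(mask)[0])
        raise ParseError(path, numbers[row], reason)

    if len(df):
        short = df[list(READ_COLUMNS)].isna().any(axis=1).to_numpy()
        if short.any():
            _fail_at(short, f"expected {len(READ_COLUMNS)} tab-separated fields")

    for col in ("start", "end", "x", "y"):
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = nums.isna().to_numpy() | (nums % 1 != 0).to_numpy()
        if bad.any():
            _fail_at(bad, f"non-integer value in column {col!r}")
        df[col] = nums.astype(np.int64)

    incomplete = df[["chrom", "strand", "gene_tag"]].isna().any(axis=1).to_numpy()
    if incomplete.any():
        _fail_at(incomplete, "missing required field")
    bad_strand = ~df["strand"].isin(["+", "-"]).to_numpy()
    if bad_strand.any():
        _fail_at(bad_strand, f"unknown strand {df['strand'].to_numpy()[bad_strand][0]!r} "
                             "(must be '+' or '-')")
    bad_iv = (df["start"].to_numpy() < 0) | (df["end"].to_numpy() <= df["start"].to_numpy())
    if bad_iv.any():
        _fail_at(bad_iv, "interval must satisfy 0 <= start < end")
    bad_xy = (df["x"].to_numpy() < 1) | (df["y"].to_numpy() < 1)
    if array_bounds is not None:
        w, h = array_bounds
        bad_xy |= (df["x"].to_numpy() > w) | (df["y"].to_numpy() > h)
    if bad_xy.any():
        _fail_at(bad_xy, "spot coordinates outside the array bounds")

    score = pd.to_numeric(df["score"], errors="coerce")
    if not score.isna().any():
        df["score"] = score
    df["gene_tag"] = df["gene_tag"].replace(".", "")
    df["dataset"] = dataset_id if dataset_id is not None else Path(path).stem
    return df.reset_index(drop=True)


def write_spatial_bed(reads: pd.DataFrame, path) -> None:
    """Write a read table as a 9-column spatial BED file."""
    out = reads.loc[:, list(READ_COLUMNS)].copy()
    out["gene_tag"] = out["gene_tag"].replace("", ".")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation (GTF)
# ---------------------------------------------------------------------------

def _gtf_attr(attrs: str, key: str) -> str:
    # GTF attribute field: key "value"; ... — a light regex-free scan.
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "\t"):
            val = part[len(key):].strip()
            return val.strip('"')
    return ""


def read_gene_annotation(path) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Uses ``gene`` feature rows when present; otherwise derives one model per
    ``gene_id`` as the union span of its transcript/exon rows. GTF 1-based
    closed coordinates are converted to 0-based half-open on read.
    """
    lines, numbers = _data_lines(path)
    records: dict[str, dict] = {}
    have_gene_rows = False
    for line, n in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(path, n, "GTF rows need 9 tab-separated fields")
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
        if feature not in ("gene", "transcript", "exon"):
            continue
        try:
            start0, end0 = int(start) - 1, int(end)
        except ValueError:
            raise ParseError(path, n, "non-integer GTF coordinates")
        if strand not in ("+", "-"):
            raise ParseError(path, n, f"unknown strand {strand!r}")
        gene_id = _gtf_attr(attrs, "gene_id")
        if not gene_id:
            raise ParseError(path, n, "missing gene_id attribute")
        gene_name = _gtf_attr(attrs, "gene_name") or gene_id
        is_gene = feature == "gene"
        have_gene_rows = have_gene_rows or is_gene
        rec = records.get(gene_id)
        if rec is None:
            records[gene_id] = dict(
                gene_name=gene_name, chrom=chrom, strand=strand,
                start=start0, end=end0, from_gene_row=is_gene,
            )
        else:
            if is_gene and not rec["from_gene_row"]:
                rec.update(start=start0, end=end0, from_gene_row=True,
                           gene_name=gene_name)
            elif is_gene == rec["from_gene_row"]:
                rec["start"] = min(rec["start"], start0)
                rec["end"] = max(rec["end"], end0)
    if not records:
        raise ParseError(path, numbers[-1] if numbers else 0,
                         "no gene-like features in annotation")
    return [
        GeneModel(gene_id=gid, gene_name=rec["gene_name"], chrom=rec["chrom"],
                  strand=rec["strand"], start=rec["start"], end=rec["end"])
        for gid, rec in records.items()
    ]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def read_labels(path) -> list[SpotLabel]:
    """Read a spot-label TSV (``dataset  x  y  label``, header required).

    Labels are canonicalized case-insensitively; an unknown class or a
    duplicate ``(dataset, x, y)`` key raises.
    """
    lines, numbers = _data_lines(path)
    if not lines:
        raise ParseError(path, 1, "empty labels file")
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:4]] != ["dataset", "x", "y", "label"]:
        raise ParseError(path, numbers[0],
                         "labels header must be: dataset, x, y, label")
    labels: list[SpotLabel] = []
    seen: set[tuple[str, int, int]] = set()
    for line, n in zip(lines[1:], numbers[1:]):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, n, "expected 4 tab-separated fields")
        dataset, xs, ys, raw_label = (f.strip() for f in fields[:4])
        try:
            x, y = int(xs), int(ys)
        except ValueError:
            raise ParseError(path, n, "non-integer spot coordinates")
        try:
            label = canonical_label(raw_label)
        except ValueError as exc:
            raise ParseError(path, n, str(exc))
        key = (dataset, x, y)
        if key in seen:
            raise ParseError(path, n, f"duplicate spot label for {key}")
        seen.add(key)
        labels.append(SpotLabel(dataset, x, y, label))
    return labels


def write_labels(labels: Iterable[SpotLabel], path) -> None:
    with open(path, "wt") as fh:
        fh.write("dataset\tx\ty\tlabel\n")
        for lab in labels:
            fh.write(f"{lab.dataset_id}\t{lab.x}\t{lab.y}\t{lab.label}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: SpotMatrix, path) -> None:
    """Write a single-dataset matrix as a spot x tag-cluster TSV."""
    datasets = matrix.datasets
    if len(datasets) != 1:
        raise ValueError(
            "write_matrix expects a single-dataset matrix; "
            "use write_matrix_dir for multi-dataset matrices"
        )
    df = matrix.df.copy()
    df.index = [spot_id(x, y) for (_d, x, y) in df.index]
    df.index.name = "spot"
    if matrix.space == RAW:
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.17g")


def write_matrix_dir(matrix: SpotMatrix, out_dir) -> list[Path]:
    """Write one ``<dataset>.matrix.tsv`` per dataset; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in matrix.datasets:
        p = out_dir / f"{ds}.matrix.tsv"
        write_matrix(matrix.for_dataset(ds), p)
        paths.append(p)
    return paths


def read_matrix(path, dataset_id: str | None = None, space: str = RAW) -> SpotMatrix:
    """Read a matrix TSV back into a :class:`SpotMatrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    ds = dataset_id if dataset_id is not None else Path(path).stem.removesuffix(".matrix")
    try:
        xy = [parse_spot_id(s) for s in df.index]
    except ValueError as exc:
        raise ParseError(path, 2, str(exc))
    df.index = pd.MultiIndex.from_tuples(
        [(ds, x, y) for x, y in xy], names=["dataset", "x", "y"]
    )
    return SpotMatrix(df, space)


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(result, path) -> None:
    """Write per-spot class probabilities and the predicted label.

    ``result`` is a :class:`stsig.classify.PredictionResult`.
    """
    probs = result.probabilities
    out = pd.DataFrame(
        {
            "dataset": [k[0] for k in probs.index],
            "x": [k[1] for k in probs.index],
            "y": [k[2] for k in probs.index],
        }
    )
    for cls in CLASSES:
        out[f"p_{cls}"] = probs[cls].to_numpy()
    out["predicted_label"] = result.predicted.to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    expected = ["dataset", "x", "y"] + [f"p_{c}" for c in CLASSES] + ["predicted_label"]
    if list(df.columns) != expected:
        raise ParseError(path, 1, f"prediction header must be: {expected}")
    return df


# ---------------------------------------------------------------------------
# cluster BED
# ---------------------------------------------------------------------------

def _fmt_density(val: float) -> str:
    return "inf" if math.isinf(val) else repr(float(val))


def write_clusters_bed(clusters: Sequence[TagCluster], path) -> None:
    """Write tag clusters as an 11-column BED (0-based half-open)."""
    with open(path, "wt") as fh:
        for tc in clusters:
            fh.write(
                "\t".join(
                    [
                        tc.chrom, str(tc.start), str(tc.end), tc.id,
                        str(tc.total_count), tc.strand, str(tc.n_sites),
                        _fmt_density(tc.min_density), _fmt_density(tc.max_density),
                        tc.gene_id or ".", tc.gene_name or ".",
                    ]
                )
                + "\n"
            )


def read_clusters_bed(path) -> list[TagCluster]:
    lines, numbers = _data_lines(path)
    clusters = []
    for line, n in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) < 11:
            raise ParseError(path, n, "cluster BED rows need 11 fields")
        chrom, start, end, _cid, total, strand, n_sites, dmin, dmax, gid, gname = fields[:11]
        try:
            tc = TagCluster(
                chrom=chrom, strand=strand, start=int(start), end=int(end),
                n_sites=int(n_sites), total_count=int(total),
                min_density=float(dmin), max_density=float(dmax),
                gene_id="" if gid == "." else gid,
                gene_name="" if gname == "." else gname,
            )
        except ValueError as exc:
            raise ParseError(path, n, str(exc))
        clusters.append(tc)
    return clusters
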