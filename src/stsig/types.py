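"""Core domain types shared across the pipeline.

Conventions fixed here once and used everywhere:

* Genomic intervals are 0-based half-open ``[start, end)``; GTF input is
  converted on read.
* Strand is ``'+'`` or ``'-'`` (ASCII hyphen-minus).
* A spot is keyed by ``(dataset_id, x, y)``; its string id is ``"<x>x<y>"``
  (the dataset is carried by the file or section name, not the spot id).
* Region classes are ordered ``non-malignant, DCIS, IDC``; this order is the
  tie-break order everywhere (argmax ties, majority-vote ties, report rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical region classes, in canonical (tie-break) order.
CLASSES: tuple[str, str, str] = ("non-malignant", "DCIS", "IDC")

#: Label used for spots with unclear identity; excluded from training and
#: from F1 denominators.
UNASSIGNED: str = "unassigned"

STRANDS = ("+", "-")

#: Read-table column layout used for in-memory collections of spatial reads.
READ_COLUMNS = ("chrom", "start", "end", "name", "score", "strand",
                "gene_tag", "x", "y")

_LABEL_ALIASES = {
    "non-malignant": CLASSES[0],
    "nonmalignant": CLASSES[0],
    "non_malignant": CLASSES[0],
    "non-mal": CLASSES[0],
    "dcis": CLASSES[1],
    "idc": CLASSES[2],
    "unassigned": UNASSIGNED,
}


def canonical_label(raw: str) -> str:
    """Map a class label to its canonical spelling (case-insensitive).

    Raises ``ValueError`` listing the allowed classes for anything else.
    """
    key = raw.strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        allowed = ", ".join(CLASSES + (UNASSIGNED,))
        raise ValueError(
            f"unknown class label {raw!r}; allowed classes: {allowed}"
        ) from None


def spot_id(x: int, y: int) -> str:
    """String id of an array position, e.g. ``'17x21'``."""
    return f"{x}x{y}"


def parse_spot_id(sid: str) -> tuple[int, int]:
    try:
        xs, ys = sid.split("x")
        return int(xs), int(ys)
    except ValueError:
        raise ValueError(f"malformed spot id {sid!r}; expected '<x>x<y>'") from None


@dataclass(frozen=True)
class SpatialRead:
    """One captured molecule: genomic interval, strand and spot coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_tag: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.x < 1 or self.y < 1:
            raise ValueError("spot coordinates must be positive integers")

    @property
    def three_prime(self) -> int:
        """0-based position of the molecule's 3' end."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware genomic interval (0-based half-open)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tts(self) -> int:
        """0-based position of the transcription termination site."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SpotLabel:
    dataset_id: str
    x: int
    y: int
    label: str


@dataclass
class ClusterNode:
    """A node of the parametric density decomposition of one chrom+strand.

    A node is the maximal-scoring segment for densities in
    ``(min_density, max_density)``; its two children take over above
    ``max_density``. Leaves (single sites) have ``max_density = +inf``.
    """

    chrom: str
    strand: str
    start: int            # first member site position
    end: int              # last member site position + 1
    n_sites: int
    total_count: int
    min_density: float
    max_density: float
    reportable: bool = True
    children: list["ClusterNode"] = field(default_factory=list)
    # index range [i, j] into the per-(chrom, strand) site arrays
    i: int = 0
    j: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start

    def walk(self) -> Iterable["ClusterNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass
class TagCluster:
    """A surviving tag cluster (ST-TC): a disjoint 3'-end expression feature."""

    chrom: str
    strand: str
    start: int
    end: int
    n_sites: int
    total_count: int
    min_density: float
    max_density: float
    summit: int = -1
    gene_id: str = ""
    gene_name: str = ""

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def span(self) -> int:
        return self.end - self.start


RAW = "raw-counts"
LOGNORM = "log-normalized"


class SpotMatrix:
    """Spots x tag-clusters expression table.

    Thin wrapper around a :class:`pandas.DataFrame` whose index is a
    ``(dataset, x, y)`` MultiIndex and whose columns are tag-cluster id
    strings, plus a ``space`` flag distinguishing raw integer counts from
    log2 median-of-ratios-normalized values.
    """

    def __init__(self, df: pd.DataFrame, space: str = RAW):
        if space not in (RAW, LOGNORM):
            raise ValueError(f"unknown matrix space {space!r}")
        if df.index.nlevels != 3:
            raise ValueError("SpotMatrix index must be (dataset, x, y)")
        if df.index.has_duplicates:
            raise ValueError("duplicate spot keys")
        if df.columns.has_duplicates:
            raise ValueError("duplicate tag-cluster ids")
        if space == RAW:
            vals = df.to_numpy()
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValueError("raw-count matrix must hold integers")
            df = df.astype(np.int64)
        else:
            df = df.astype(np.float64)
        df.index = df.index.set_names(["dataset", "x", "y"])
        self.df = df
        self.space = space

    # -- basic accessors -------------------------------------------------
    @property
    def spot_keys(self) -> list[tuple[str, int, int]]:
        return list(self.df.index)

    @property
    def tc_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.df.index.get_level_values(0)))

    def total(self) -> int:
        return int(self.df.to_numpy().sum())

    # -- subsetting ------------------------------------------------------
    def for_dataset(self, dataset_id: str) -> "SpotMatrix":
        mask = self.df.index.get_level_values(0) == dataset_id
        if not mask.any():
            raise KeyError(f"dataset {dataset_id!r} not in matrix")
        return SpotMatrix(self.df.loc[mask], self.space)

    def subset_spots(self, keys: Sequence[tuple[str, int, int]]) -> "SpotMatrix":
        return SpotMatrix(self.df.loc[list(keys)], self.space)

    def subset_tcs(self, tc_ids: Sequence[str]) -> "SpotMatrix":
        return SpotMatrix(self.df.loc[:, list(tc_ids)], self.space)

    def reindex_tcs(self, tc_ids: Sequence[str]) -> "SpotMatrix":
        """Align to a feature universe; absent features become 0."""
        fill = 0 if self.space == RAW else 0.0
        return SpotMatrix(
            self.df.reindex(columns=list(tc_ids), fill_value=fill), self.space
        )

    @staticmethod
    def concat(matrices: Sequence["SpotMatrix"]) -> "SpotMatrix":
        spaces = {m.space for m in matrices}
        if len(spaces) != 1:
            raise ValueError("cannot concatenate matrices of mixed spaces")
        cols = list(dict.fromkeys(c for m in matrices for c in m.tc_ids))
        fill = 0 if matrices[0].space == RAW else 0.0
        frames = [m.df.reindex(columns=cols, fill_value=fill) for m in matrices]
        return SpotMatrix(pd.concat(frames, axis=0), matrices[0].space)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpotMatrix):
            return NotImplemented
        return self.space == other.space and self.df.equals(other.df)

    def __repr__(self) -> str:
        n_s, n_t = self.shape
        return f"<SpotMatrix {n_s} spots x {n_t} tag clusters [{self.space}]>"


def labels_to_series(labels: Iterable[SpotLabel]) -> pd.Series:
    """Index labels by (dataset, x, y); raises on duplicate keys."""
    keys, vals = [], []
    for lab in labels:
        keys.append((lab.dataset_id, lab.x, lab.y))
        vals.append(lab.label)
    idx = pd.MultiIndex.from_tuples(keys, names=["dataset", "x", "y"]) if keys else \
        pd.MultiIndex.from_arrays([[], [], []], names=["dataset", "x", "y"])
    ser = pd.Series(vals, index=idx, dtype=object, name="label")
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise ValueError(f"duplicate spot label for {dup}")
    return ser
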