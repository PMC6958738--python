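"""Label-free grouping of spots: PCA to two components, Ward clustering.

The log-normalized matrix is centered (not scaled) and projected on its top
two right singular directions. Spots are then agglomerated with Ward's
minimum-variance criterion (the Ward.2 convention: Euclidean coordinates,
squared distances in the Lance-Williams update) and the tree is cut at k
groups. When expert labels exist for some spots, each group is mapped to
its majority class and the agreement fraction is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .types import CLASSES, UNASSIGNED, SpotMatrix, LOGNORM

logger = logging.getLogger(__name__)

__all__ = ["Embedding", "ClusterAssignment", "pca_embed", "ward_cluster",
           "map_groups_to_classes"]


@dataclass
class Embedding:
    coordinates: pd.DataFrame            # spots x components
    explained_variance: np.ndarray       # per-component variance of scores

    @property
    def spot_keys(self) -> list:
        return list(self.coordinates.index)


@dataclass
class ClusterAssignment:
    groups: pd.Series                    # spot -> group in 1..k
    class_map: dict[int, str] = field(default_factory=dict)
    agreement: float | None = None

    @property
    def spot_keys(self) -> list:
        return list(self.groups.index)

    def predicted_classes(self) -> pd.Series:
        if not self.class_map:
            raise ValueError("no class map; call map_groups_to_classes first")
        return self.groups.map(self.class_map).rename("predicted")


def pca_embed(matrix: SpotMatrix, n_components: int = 2) -> Embedding:
    """Project spots on the top principal components of the log matrix.

    Columns are centered but not scaled. Sign convention: each component's
    loading vector has its largest-magnitude entry positive, which makes the
    embedding reproducible across platforms.
    """
    if matrix.space != LOGNORM:
        raise ValueError("pca_embed expects a log-normalized matrix")
    X = matrix.df.to_numpy(dtype=float)
    n = X.shape[0]
    if n < max(3, n_components + 1):
        raise ValueError("too few spots for the requested components")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    scores = U[:, :k] * S[:k]
    for c in range(k):
        v = Vt[c]
        if v[int(np.argmax(np.abs(v)))] < 0:
            Vt[c] = -v
            scores[:, c] = -scores[:, c]
    coords = pd.DataFrame(
        scores, index=matrix.df.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    explained = (S[:k] ** 2) / (n - 1)
    return Embedding(coordinates=coords, explained_variance=explained)


def ward_cluster(embedding: Embedding, k: int = 3) -> ClusterAssignment:
    """Cut the Ward merge tree at k groups.

    Groups are renumbered 1..k by first appearance in input order so the
    numbering is deterministic under a fixed input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = embedding.coordinates.to_numpy(dtype=float)
    n = coords.shape[0]
    if k > n:
        raise ValueError("more groups requested than spots")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(coords, method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    for g in raw:
        if g not in remap:
            remap[g] = len(remap) + 1
    groups = pd.Series([remap[g] for g in raw], index=embedding.coordinates.index,
                       name="group")
    return ClusterAssignment(groups=groups)


def map_groups_to_classes(assignment: ClusterAssignment, labels: pd.Series
                          ) -> ClusterAssignment:
    """Majority-vote mapping of groups to classes, plus agreement.

    ``labels`` is a Series over (dataset, x, y) spot keys with canonical
    class values; unassigned labels are ignored. Ties go to the canonical
    class order. A group without labeled members maps to ``unassigned``
    with a warning. Agreement is the fraction of labeled spots whose
    group's class equals their own label.
    """
    labels = labels[labels.isin(CLASSES)]
    common = assignment.groups.index.intersection(labels.index)
    lab = labels.loc[common]
    grp = assignment.groups.loc[common]
    class_map: dict[int, str] = {}
    for g in sorted(assignment.groups.unique()):
        members = lab[grp == g]
        if members.empty:
            logger.warning("group %d has no labeled member; mapped to %r",
                           g, UNASSIGNED)
            class_map[g] = UNASSIGNED
            continue
        votes = members.value_counts()
        best = max(CLASSES, key=lambda c: (votes.get(c, 0), -CLASSES.index(c)))
        class_map[g] = best
    agree = float((grp.map(class_map) == lab).mean()) if len(lab) else float("nan")
    return ClusterAssignment(groups=assignment.groups.copy(),
                             class_map=class_map, agreement=agree)
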