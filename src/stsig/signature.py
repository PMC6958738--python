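"""Region-class expression signatures by negative-binomial testing.

Counts per tag cluster are modeled as negative binomial with mean mu and
variance ``mu + alpha * mu^2``. For each of the three pairwise contrasts
between region classes (non-malignant vs DCIS, DCIS vs IDC, non-malignant
vs IDC) every tag cluster gets a Wald test:

* normalized counts ``y = k / sf``; group means ``m_a``, ``m_b``;
* ``log2fc = log2((m_b + 1) / (m_a + 1))`` (pseudocount keeps it finite);
* dispersion by the method of moments on pooled within-group residuals,
  ``alpha = max((s2 - mbar) / mbar^2, 1e-8)``;
* delta-method standard error of the fold change from the NB variance of
  each group mean; two-sided p from the normal reference.

P-values are Benjamini-Hochberg adjusted within each contrast, and the
signature is the union over contrasts of tag clusters with
``|log2fc| > lfc_threshold`` and ``q < fdr_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import CLASSES, SpotMatrix, RAW

__all__ = ["nb_test", "nb_test_matrix", "bh_adjust", "derive_signature",
           "SignatureSet", "CONTRASTS"]

#: The three pairwise contrasts, in canonical order (a, b); fold changes are
#: b over a.
CONTRASTS: tuple[tuple[str, str], ...] = (
    (CLASSES[0], CLASSES[1]),
    (CLASSES[1], CLASSES[2]),
    (CLASSES[0], CLASSES[2]),
)

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


def nb_test_matrix(counts_a: np.ndarray, counts_b: np.ndarray,
                   sf_a: np.ndarray, sf_b: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NB Wald test over the rows of two count blocks.

    ``counts_a`` and ``counts_b`` are (features x spots) raw-count arrays of
    the two groups; ``sf_a``/``sf_b`` the per-spot size factors. Returns
    ``(log2fc, dispersion, p_value)`` arrays over features.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 spots")
    y_a = counts_a / np.asarray(sf_a, dtype=float)
    y_b = counts_b / np.asarray(sf_b, dtype=float)

    m_a = y_a.mean(axis=1)
    m_b = y_b.mean(axis=1)
    log2fc = np.log2((m_b + 1.0) / (m_a + 1.0))

    # method-of-moments dispersion from pooled within-group residuals
    ss = ((y_a - m_a[:, None]) ** 2).sum(axis=1) + \
         ((y_b - m_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n_a + n_b - 2)
    mbar = (y_a.sum(axis=1) + y_b.sum(axis=1)) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mbar > 0, (s2 - mbar) / np.square(mbar), 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    var_ma = (m_a + alpha * m_a**2) / n_a
    var_mb = (m_b + alpha * m_b**2) / n_b
    se = np.sqrt(var_ma / np.square(m_a + 1.0)
                 + var_mb / np.square(m_b + 1.0)) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return log2fc, alpha, p


def nb_test(counts: np.ndarray, groups: np.ndarray, size_factors: np.ndarray
            ) -> tuple[float, float, float]:
    """NB Wald test for one tag cluster.

    ``counts`` are raw counts over spots, ``groups`` a boolean/0-1 array
    (False/0 = group a, True/1 = group b), ``size_factors`` per-spot
    factors. Returns ``(log2fc, dispersion, p_value)`` with the fold change
    of group b over group a.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups).astype(bool)
    size_factors = np.asarray(size_factors, dtype=float)
    lfc, alpha, p = nb_test_matrix(
        counts[~groups][None, :], counts[groups][None, :],
        size_factors[~groups], size_factors[groups],
    )
    return float(lfc[0]), float(alpha[0]), float(p[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass
class SignatureSet:
    """Per-contrast differential-expression tables plus the selected set."""

    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)
    selected_tc_ids: list[str] = field(default_factory=list)
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.01

    def __len__(self) -> int:
        return len(self.selected_tc_ids)

    def to_frame(self) -> pd.DataFrame:
        """One row per contrast x tag cluster, with a selected flag."""
        frames = []
        selected = set(self.selected_tc_ids)
        for name, tab in self.contrasts.items():
            t = tab.copy()
            t.insert(0, "contrast", name)
            t["selected"] = [tc in selected for tc in t["tc_id"]]
            frames.append(t)
        return pd.concat(frames, axis=0, ignore_index=True)


def derive_signature(matrix: SpotMatrix, labels: pd.Series,
                     lfc_threshold: float = 2.0, fdr_threshold: float = 0.01,
                     size_factors_: pd.Series | None = None) -> SignatureSet:
    """Select the class-specific tag-cluster signature.

    Runs the NB Wald test per tag cluster for each pairwise class contrast
    on the labeled spots, adjusts p-values per contrast, selects
    ``|log2fc| > lfc_threshold`` and ``q < fdr_threshold``, and unions the
    three selections (ordered by matrix column order).

    ``labels`` is a Series over (dataset, x, y); unlabeled or unassigned
    spots are ignored. ``size_factors_`` defaults to factors computed on
    the labeled submatrix.
    """
    if matrix.space != RAW:
        raise ValueError("derive_signature operates on raw counts")
    labels = labels[labels.isin(CLASSES)]
    common = matrix.df.index.intersection(labels.index)
    present = set(labels.loc[common])
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise ValueError(f"labeled spots missing for class(es): {missing}")
    sub = matrix.df.loc[common]
    lab = labels.loc[common]
    if size_factors_ is None:
        from .preprocess import size_factors as _sf
        size_factors_ = _sf(SpotMatrix(sub, RAW))
    sf = size_factors_.loc[common].to_numpy()

    counts = sub.to_numpy(dtype=float).T          # features x spots
    tc_ids = list(sub.columns)
    sig = SignatureSet(lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold)
    selected: list[str] = []
    seen: set[str] = set()
    for cls_a, cls_b in CONTRASTS:
        in_a = (lab == cls_a).to_numpy()
        in_b = (lab == cls_b).to_numpy()
        lfc, alpha, p = nb_test_matrix(
            counts[:, in_a], counts[:, in_b], sf[in_a], sf[in_b]
        )
        q = bh_adjust(p)
        y = counts / sf
        tab = pd.DataFrame(
            {
                "tc_id": tc_ids,
                "group_a": cls_a,
                "group_b": cls_b,
                "base_mean_a": y[:, in_a].mean(axis=1),
                "base_mean_b": y[:, in_b].mean(axis=1),
                "log2fc": lfc,
                "dispersion": alpha,
                "p_value": p,
                "q_value": q,
            }
        )
        sig.contrasts[f"{cls_a} vs {cls_b}"] = tab
        hits = (np.abs(lfc) > lfc_threshold) & (q < fdr_threshold)
        for tc in np.asarray(tc_ids, dtype=object)[hits]:
            if tc not in seen:
                seen.add(tc)
                selected.append(tc)
    # order by matrix column order for determinism
    sig.selected_tc_ids = [tc for tc in tc_ids if tc in seen]
    return sig
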