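"""Low-expression filtering and log2 median-of-ratios normalization.

Library depth varies strongly between spots, so raw counts are scaled by a
per-spot size factor before any comparison. The size factor is the
median-of-ratios estimator: each tag cluster's geometric mean across spots
serves as a pseudo-reference sample, and a spot's factor is the median of
its count-to-reference ratios. The textbook estimator restricts the
reference to features with nonzero counts in *every* spot, which is
untenable on sparse spot-level data; when that reference set is too small
we fall back to geometric means over positive counts only (see
:func:`size_factors`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import SpotMatrix, RAW, LOGNORM

logger = logging.getLogger(__name__)

__all__ = ["filter_matrix", "size_factors", "normalize_log"]

DEFAULT_MIN_TC_SPOTS = 2
DEFAULT_MIN_SPOT_COUNTS = 100
DEFAULT_MIN_SPOT_FEATURES = 100

#: Minimum size of the all-nonzero reference set before falling back to
#: positive-count geometric means.
MIN_REFERENCE_TCS = 50


def filter_matrix(matrix: SpotMatrix,
                  min_spot_counts: int = DEFAULT_MIN_SPOT_COUNTS,
                  min_spot_features: int = DEFAULT_MIN_SPOT_FEATURES,
                  min_tc_spots: int = DEFAULT_MIN_TC_SPOTS) -> SpotMatrix:
    """Drop sparse tag clusters, then underpowered spots.

    Tag clusters detected (count >= 1) in fewer than ``min_tc_spots`` spots
    are removed first; then spots with total counts below
    ``min_spot_counts`` or fewer than ``min_spot_features`` detected
    features are removed. Raises if nothing survives.
    """
    if matrix.space != RAW:
        raise ValueError("filter_matrix operates on raw counts")
    df = matrix.df
    detected_in = (df > 0).sum(axis=0)
    keep_tcs = detected_in >= min_tc_spots
    df = df.loc[:, keep_tcs]
    dropped_tcs = list(detected_in.index[~keep_tcs])

    totals = df.sum(axis=1)
    features = (df > 0).sum(axis=1)
    keep_spots = (totals >= min_spot_counts) & (features >= min_spot_features)
    dropped_spots = list(df.index[~keep_spots])
    df = df.loc[keep_spots]

    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("filtering removed every spot or every tag cluster")
    if dropped_tcs or dropped_spots:
        logger.info("filtered out %d tag clusters and %d spots",
                    len(dropped_tcs), len(dropped_spots))
    return SpotMatrix(df, RAW)


def size_factors(matrix: SpotMatrix) -> pd.Series:
    """Median-of-ratios size factor per spot.

    The reference profile is the per-tag-cluster geometric mean over spots,
    computed on the set R of tag clusters with nonzero counts in every spot;
    ``factor(spot) = median over R of count(spot, tc) / reference(tc)``.
    If ``|R| < 50`` the reference falls back to geometric means over
    positive counts only (tag clusters detected in >= 2 spots), and each
    spot's median runs over its positive ratios. Factors are not rescaled.
    """
    if matrix.space != RAW:
        raise ValueError("size factors are computed on raw counts")
    df = matrix.df
    if df.shape[0] < 2:
        raise ValueError("size factors need at least 2 spots")
    counts = df.to_numpy(dtype=float)

    all_positive = (counts > 0).all(axis=0)
    if int(all_positive.sum()) >= MIN_REFERENCE_TCS:
        sub = counts[:, all_positive]
        ref = np.exp(np.mean(np.log(sub), axis=0))
        factors = np.median(sub / ref, axis=1)
    else:
        positive = counts > 0
        usable = positive.sum(axis=0) >= 2
        if not usable.any():
            raise ValueError("no usable reference tag clusters for size factors")
        sub = counts[:, usable]
        pos = sub > 0
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, sub, 1.0)), 0.0)
        ref = np.exp(logs.sum(axis=0) / pos.sum(axis=0))
        ratios = sub / ref
        factors = np.empty(sub.shape[0])
        for s in range(sub.shape[0]):
            r = ratios[s][pos[s]]
            if r.size == 0:
                raise ValueError(
                    "a spot has no positive counts among reference tag clusters"
                )
            factors[s] = np.median(r)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factors must be positive and finite")
    return pd.Series(factors, index=df.index, name="size_factor")


def normalize_log(matrix: SpotMatrix, factors: pd.Series) -> SpotMatrix:
    """log2(count / size_factor + 1), flagged as log-normalized."""
    if matrix.space != RAW:
        raise ValueError("normalize_log expects raw counts")
    if not matrix.df.index.equals(factors.index):
        raise ValueError("size factors are not aligned to the matrix spots")
    vals = np.log2(matrix.df.to_numpy(dtype=float)
                   / factors.to_numpy()[:, None] + 1.0)
    return SpotMatrix(
        pd.DataFrame(vals, index=matrix.df.index, columns=matrix.df.columns),
        LOGNORM,
    )
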