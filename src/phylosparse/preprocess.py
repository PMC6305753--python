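"""Real-data preparation pipeline for OTU count tables.

The fixed stage order is: sample-outlier flagging (Bray-Curtis outlier
index) -> prevalence filtering -> GMPR size-factor normalization ->
winsorization at a high quantile -> square-root transform, with a rank-based
inverse-normal transform available for a continuous outcome.  All matrices
here are oriented samples x OTUs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "flag_outlier_samples",
    "prevalence_filter",
    "gmpr_size_factors",
    "winsorize",
    "sqrt_transform",
    "quantile_normal_transform",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


def _as_array(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts
    return np.asarray(counts, dtype=float), None


def flag_outlier_samples(counts, threshold_sd: float = 2.5) -> np.ndarray:
    """Flag samples whose Bray-Curtis outlier index is extreme.

    The outlier index of a sample is its *median* Bray-Curtis distance (on
    relative abundances) to all other samples; a sample is flagged when its
    index exceeds mean + ``threshold_sd`` standard deviations of the indices.
    Returns a boolean mask (True = outlier).
    """
    X, _ = _as_array(counts)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to define an outlier index")
    rel = X / X.sum(axis=1, keepdims=True)
    Dist = squareform(pdist(rel, metric="braycurtis"))
    idx = np.array([np.median(np.delete(Dist[i], i)) for i in range(n)])
    sd = idx.std(ddof=1)
    if sd == 0:
        return np.zeros(n, dtype=bool)
    return idx > idx.mean() + threshold_sd * sd


def prevalence_filter(counts, min_prevalence: float = 0.10):
    """Keep OTUs present (count > 0) in at least ``min_prevalence`` of samples."""
    X, df = _as_array(counts)
    prev = (X > 0).mean(axis=0)
    keep = prev >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every OTU")
    if df is not None:
        return df.loc[:, keep]
    return X[:, keep]


def gmpr_size_factors(counts) -> np.ndarray:
    """Geometric mean of pairwise ratios (GMPR) size factors, one per sample.

    For each ordered sample pair (i, j), the pairwise ratio r_ij is the
    median of count ratios c_ik / c_jk over the OTUs k nonzero in both; the
    size factor of sample i is the geometric mean of r_ij over the samples j
    it shares at least one nonzero OTU with.  Zero-robust: zeros never enter
    any ratio.  Errors if some sample shares no OTU with any other.
    """
    X, df = _as_array(counts)
    n = X.shape[0]
    logr = np.full((n, n), np.nan)
    nz = X > 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = nz[i] & nz[j]
            if shared.any():
                logr[i, j] = np.median(np.log(X[i, shared]) - np.log(X[j, shared]))
    sf = np.empty(n)
    for i in range(n):
        vals = logr[i, ~np.isnan(logr[i])]
        if vals.size == 0:
            name = df.index[i] if df is not None else i
            raise ValueError(
                f"sample {name!r} shares no nonzero OTU with any other sample"
            )
        sf[i] = np.exp(vals.mean())
    return sf


def winsorize(abundances, quantile: float = 0.97, per_otu: bool = True):
    """Cap values above a high quantile (linear-interpolation quantile).

    ``per_otu=True`` caps each OTU at its own quantile across samples;
    otherwise a single global cap is used.
    """
    if not (0.5 < quantile < 1):
        raise ValueError("quantile must lie in (0.5, 1)")
    X, df = _as_array(abundances)
    X = X.copy()
    if per_otu:
        caps = np.quantile(X, quantile, axis=0)
        X = np.minimum(X, caps[None, :])
    else:
        X = np.minimum(X, np.quantile(X, quantile))
    if df is not None:
        return pd.DataFrame(X, index=df.index, columns=df.columns)
    return X


def sqrt_transform(abundances):
    """Entrywise square root (tames the influence of abundant OTUs)."""
    X, df = _as_array(abundances)
    if np.any(X < 0):
        raise ValueError("negative abundances cannot be square-root transformed")
    out = np.sqrt(X)
    if df is not None:
        return pd.DataFrame(out, index=df.index, columns=df.columns)
    return out


def quantile_normal_transform(y) -> np.ndarray:
    """Rank-based inverse-normal transform Phi^{-1}((rank - 0.5) / n).

    Ties receive average ranks.  Errors on a constant vector.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(y == y[0]):
        raise ValueError("constant outcome cannot be quantile-transformed")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


def preprocess_pipeline(
    counts: pd.DataFrame,
    y=None,
    outlier_sd: float = 2.5,
    min_prevalence: float = 0.10,
    winsor_quantile: float = 0.97,
    transform_outcome: bool = False,
):
    """Run the full pipeline in its fixed order; returns (X, y, log).

    ``counts`` is samples x OTUs.  The log records input/output dimensions
    of every stage, removed sample/OTU names, and the thresholds used.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(np.asarray(counts))
    log: dict = {"stages": [], "thresholds": {
        "outlier_sd": outlier_sd, "min_prevalence": min_prevalence,
        "winsor_quantile": winsor_quantile,
    }}

    def _stage(name, before, after, **extra):
        entry = {"stage": name, "in_shape": list(before.shape),
                 "out_shape": list(after.shape), **extra}
        log["stages"].append(entry)
        logger.info("%s: %s -> %s", name, before.shape, after.shape)

    flagged = flag_outlier_samples(counts, outlier_sd)
    kept = counts.loc[~flagged]
    _stage("outlier_removal", counts, kept,
           removed_samples=[str(s) for s in counts.index[flagged]])
    if y is not None:
        y = np.asarray(y)[~flagged]

    filtered = prevalence_filter(kept, min_prevalence)
    _stage("prevalence_filter", kept, filtered,
           removed_otus=[str(o) for o in kept.columns
                         if o not in set(filtered.columns)])

    sf = gmpr_size_factors(filtered)
    normalized = filtered.div(sf, axis=0)
    _stage("gmpr_normalization", filtered, normalized)

    winsorized = winsorize(normalized, winsor_quantile)
    _stage("winsorization", normalized, winsorized)

    transformed = sqrt_transform(winsorized)
    _stage("sqrt_transform", winsorized, transformed)

    if y is not None and transform_outcome:
        y = quantile_normal_transform(y)
        log["stages"].append({"stage": "outcome_quantile_transform",
                              "in_shape": [int(len(y))],
                              "out_shape": [int(len(y))]})
    return transformed, y, log
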