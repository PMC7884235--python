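"""Vectorized association-metric kernels.

Each kernel scores row pairs of relative-abundance vectors across
samples.  The batch forms take ``X, Y`` of shape ``(B, n)`` (B resampled
replicates of one SV pair) and return ``B`` scores; this is what makes
permutation nulls and bootstraps over hundreds of candidate edges cheap.
Correlation kernels return NaN for zero-variance vectors; callers decide
how to treat those replicates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

METRICS = (
    "pearson",
    "spearman",
    "mutual_information",
    "bray_curtis",
    "kullback_leibler",
)

#: Whether a large score indicates co-presence (similarity) or a large
#: score indicates divergence (dissimilarity).
METRIC_KIND = {
    "pearson": "similarity",
    "spearman": "similarity",
    "mutual_information": "similarity",
    "bray_curtis": "dissimilarity",
    "kullback_leibler": "dissimilarity",
}

#: Metrics that detect association strength but cannot orient it:
#: mutual information is equally high for co-presence and exclusion, so
#: it supports an edge under whichever sign the signed metrics agree on.
UNSIGNED_METRICS = frozenset({"mutual_information"})


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc**2).sum(axis=1) * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def batch_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return _rowwise_pearson(np.asarray(X, float), np.asarray(Y, float))


def batch_spearman(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    rx = rankdata(X, axis=1, method="average")
    ry = rankdata(Y, axis=1, method="average")
    return _rowwise_pearson(rx, ry)


def batch_bray_curtis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    num = np.abs(X - Y).sum(axis=1)
    den = (X + Y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    d[den == 0] = np.nan
    return d


def batch_kl(X: np.ndarray, Y: np.ndarray, pseudocount: float) -> np.ndarray:
    """Symmetrized (Jeffreys) KL divergence of the two sample-profiles.

    Each vector is shifted by the pseudocount and closed to sum 1, then
    ``sum((p - q) * (ln p - ln q))`` -- zero iff the profiles coincide.
    """
    P = np.asarray(X, float) + pseudocount
    Q = np.asarray(Y, float) + pseudocount
    P = P / P.sum(axis=1, keepdims=True)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return ((P - Q) * (np.log(P) - np.log(Q))).sum(axis=1)


def equal_frequency_bins(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Row-wise equal-frequency bin labels in ``0 .. n_bins - 1``.

    Rank-based: ties are broken by (stable) sample order, which keeps
    the discretization deterministic.
    """
    X = np.atleast_2d(X)
    n = X.shape[1]
    order = np.argsort(X, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return (ranks * n_bins) // n


def batch_mutual_information(X: np.ndarray, Y: np.ndarray, n_bins: int) -> np.ndarray:
    """Mutual information (nats) of equal-frequency-binned row pairs."""
    bx = equal_frequency_bins(X, n_bins)
    by = equal_frequency_bins(Y, n_bins)
    B, n = bx.shape
    code = bx * n_bins + by
    joint = np.zeros((B, n_bins * n_bins), dtype=np.int64)
    np.add.at(joint, (np.repeat(np.arange(B), n), code.ravel()), 1)
    pxy = joint.reshape(B, n_bins, n_bins) / n
    px = pxy.sum(axis=2)
    py = pxy.sum(axis=1)
    outer = px[:, :, None] * py[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = pxy * np.log(pxy / outer)
    return np.nansum(terms, axis=(1, 2))


def batch_score(
    metric: str,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    n_bins: int = 0,
    pseudocount: float = 1e-8,
) -> np.ndarray:
    """Dispatch one metric over row pairs of ``X`` and ``Y``."""
    if metric == "pearson":
        return batch_pearson(X, Y)
    if metric == "spearman":
        return batch_spearman(X, Y)
    if metric == "mutual_information":
        return batch_mutual_information(X, Y, n_bins)
    if metric == "bray_curtis":
        return batch_bray_curtis(X, Y)
    if metric == "kullback_leibler":
        return batch_kl(X, Y, pseudocount)
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_scores(
    R: np.ndarray,
    metric: str,
    *,
    n_bins: int = 0,
    pseudocount: float = 1e-8,
) -> np.ndarray:
    """Symmetric score matrix over all row pairs of ``R`` (SVs x samples)."""
    R = np.asarray(R, float)
    m = R.shape[0]
    if metric == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.corrcoef(R)
    elif metric == "spearman":
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.corrcoef(rankdata(R, axis=1, method="average"))
    elif metric == "bray_curtis":
        S = squareform(pdist(R, metric="braycurtis"))
    elif metric == "kullback_leibler":
        P = R + pseudocount
        P = P / P.sum(axis=1, keepdims=True)
        L = np.log(P)
        M = P @ L.T
        d = np.diag(M)
        S = d[:, None] + d[None, :] - M - M.T
        np.fill_diagonal(S, 0.0)
    elif metric == "mutual_information":
        iu, ju = np.triu_indices(m, k=1)
        S = np.zeros((m, m))
        chunk = 20_000
        for start in range(0, len(iu), chunk):
            sl = slice(start, start + chunk)
            vals = batch_mutual_information(R[iu[sl]], R[ju[sl]], n_bins)
            S[iu[sl], ju[sl]] = vals
            S[ju[sl], iu[sl]] = vals
    else:
        raise ValueError(f"unknown metric {metric!r}")
    S = np.asarray(S, float)
    np.fill_diagonal(S, 0.0 if METRIC_KIND[metric] == "dissimilarity" else 1.0)
    return S
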