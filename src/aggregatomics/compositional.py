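"""Compositional data analysis: CZM zero replacement, CLR, Aitchison geometry.

Amplicon counts are compositional -- only relative information survives
sequencing -- so community structure is compared in the Aitchison
geometry: counts are closed to proportions, zeros are imputed with the
count-zero-multiplicative (CZM) scheme, the centred log-ratio (CLR)
transform maps each sample into unconstrained Euclidean space, and
Aitchison distance is ordinary Euclidean distance there.  The fixed
pipeline order is abundance filter -> CZM -> CLR -> distance/PCA.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .feature_table import SVTable, abundance_filter

__all__ = [
    "czm_replace",
    "clr",
    "aitchison_distance",
    "aitchison_pipeline",
    "within_group_distances",
    "pca_scores",
]

#: CZM multiplicative replacement fraction; the published default of the
#: count-zero-multiplicative scheme.  A zero in a sample of total N is
#: imputed as CZM_F / (N + 1), and nonzero parts are rescaled to keep the
#: composition closed.
CZM_F = 0.65


def czm_replace(table: SVTable, f: float = CZM_F) -> pd.DataFrame:
    """Replace zero counts multiplicatively; return closed proportions.

    Per sample with total ``N`` and ``z`` zeros, each zero becomes
    ``delta = f / (N + 1)`` and each nonzero proportion ``p`` is rescaled
    to ``p * (1 - z * delta)``, so columns still sum to 1 and every entry
    is strictly positive.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [table.sample_ids[j] for j in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    props = counts / totals
    zeros = counts == 0
    n_zero = zeros.sum(axis=0)
    delta = f / (totals + 1.0)
    out = props * (1.0 - n_zero * delta)
    out[zeros] = np.broadcast_to(delta, counts.shape)[zeros]
    return pd.DataFrame(out, index=table.sv_ids, columns=table.sample_ids)


def clr(composition: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform, per sample (column).

    ``clr(p)_j = ln(p_j / g(p))`` with ``g`` the geometric mean of the
    sample's parts; each transformed column sums to zero.  Requires
    strictly positive input, i.e. CZM must run first on sparse counts.
    """
    values = composition.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("CLR requires strictly positive compositions; run CZM first")
    logs = np.log(values)
    out = logs - logs.mean(axis=0)
    return pd.DataFrame(out, index=composition.index, columns=composition.columns)


def aitchison_distance(composition: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Aitchison distances: Euclidean distance of CLR columns."""
    transformed = clr(composition)
    dist = squareform(pdist(transformed.to_numpy().T, metric="euclidean"))
    ids = composition.columns
    return pd.DataFrame(dist, index=ids, columns=ids)


def aitchison_pipeline(
    table: SVTable, abundance_threshold: Optional[float] = 0.001
) -> pd.DataFrame:
    """Distance matrix from raw counts via the fixed pipeline order.

    Removes SVs below ``abundance_threshold`` relative abundance in all
    compared samples, CZM-replaces zeros, CLR-transforms, and returns the
    Euclidean (Aitchison) distance matrix over samples.
    """
    if abundance_threshold is not None:
        table = abundance_filter(table, abundance_threshold)
    return aitchison_distance(czm_replace(table))


def within_group_distances(
    distances: pd.DataFrame, groups: pd.Series
) -> Dict[str, np.ndarray]:
    """Pairwise distances among samples of the same group.

    ``groups`` maps sample id to group label; singleton groups are
    omitted with a warning (no within-group pair exists).  Returns, per
    group, the ``n (n - 1) / 2`` condensed distances.
    """
    groups = groups.loc[distances.index]
    out: Dict[str, np.ndarray] = {}
    for label, members in groups.groupby(groups).groups.items():
        members = list(members)
        if len(members) < 2:
            warnings.warn(f"group {label!r} has a single sample; omitted", stacklevel=2)
            continue
        sub = distances.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        out[str(label)] = sub[iu]
    return out


def summarize_group_distances(distance_lists: Dict[str, np.ndarray]) -> pd.DataFrame:
    """Median and quartiles of the within-group distances, for plotting."""
    rows = []
    for label, values in distance_lists.items():
        rows.append(
            {
                "group": label,
                "n_pairs": len(values),
                "q25": float(np.percentile(values, 25)),
                "median": float(np.median(values)),
                "q75": float(np.percentile(values, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def pca_scores(
    clr_matrix: pd.DataFrame, n_components: Optional[int] = None
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of CLR-transformed samples.

    Columns of ``clr_matrix`` are samples.  Samples are the observations;
    each SV (row) is centred across samples, with no unit-variance
    scaling -- the standard choice in Aitchison geometry.  Returns sample
    coordinates and the explained-variance fractions (summing to <= 1
    over the returned axes).
    """
    n_samples = clr_matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    X = clr_matrix.to_numpy(dtype=float).T  # samples x SVs
    X = X - X.mean(axis=0)
    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=clr_matrix.columns, columns=cols), explained
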