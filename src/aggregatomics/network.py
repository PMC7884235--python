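"""Ensemble co-occurrence network inference with ReBoot significance.

The engine scores every SV pair with five association metrics (Pearson,
Spearman, mutual information, Bray-Curtis, symmetrized Kullback-Leibler),
keeps the k highest- and k lowest-scoring edges per metric, and then
assesses each candidate edge with the ReBoot scheme:

* **permutation null with renormalization** -- the two focal SVs'
  relative abundances are shuffled independently across samples and every
  sample's composition is re-closed to sum 1 before rescoring.  The
  re-closure preserves the compositional coupling that makes relative
  abundances spuriously correlate, so the null distribution absorbs that
  artifact instead of the edge;
* **bootstrap stability** -- samples are resampled with replacement and
  an edge whose observed score falls outside the central interval of its
  bootstrap distribution is unstable;
* **evidence combination** -- per-metric empirical p-values are merged
  with Brown's method (Fisher's method corrected for the dependence
  between metrics, estimated from the shared permutation null), followed
  by Benjamini-Hochberg correction across candidate edges.

Strict mode applies the stability filter, requires sign-consistent
support from at least ``min_support`` metrics, and keeps edges with
q <= ``q_threshold``.  Lenient mode skips the stability/support filters
and the multiple-testing correction, keeping edges with merged p below
the threshold -- appropriate only when the strict network is empty and
false discoveries are tolerable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._metrics import METRIC_KIND, METRICS, UNSIGNED_METRICS, batch_score, pairwise_scores
from .feature_table import SVTable, abundance_filter, relative_abundance

__all__ = [
    "NetworkConfig",
    "MetricEvidence",
    "EdgeStats",
    "NetworkResult",
    "compute_scores",
    "preselect_edges",
    "reboot_null",
    "bootstrap_scores",
    "stability_filter",
    "edge_pvalue",
    "brown_merge",
    "bh_adjust",
    "build_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Every tuning constant of the ensemble procedure."""

    metrics: Tuple[str, ...] = METRICS
    k_preselect: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    ci_percentiles: Tuple[float, float] = (2.5, 97.5)
    min_support: int = 3
    q_threshold: float = 0.05
    kl_pseudocount: float = 1e-8
    mi_bins: Optional[int] = None  # None -> floor(sqrt(n_samples))
    abundance_threshold: float = 0.002
    p_method: str = "empirical"  # or "gaussian" (classical normal fit)
    strict_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in METRIC_KIND]
        if unknown:
            raise ValueError(f"unknown metric(s): {unknown}")
        if self.k_preselect < 1 or self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("k_preselect, n_perm and n_boot must be >= 1")
        lo, hi = self.ci_percentiles
        if not 0 < lo < hi < 100:
            raise ValueError("ci_percentiles must be ordered within (0, 100)")
        if self.p_method not in ("empirical", "gaussian"):
            raise ValueError("p_method must be empirical or gaussian")
        if self.min_support > len(self.metrics):
            raise ValueError("min_support cannot exceed the number of metrics")

    def bins_for(self, n_samples: int) -> int:
        return self.mi_bins if self.mi_bins else max(2, int(math.floor(math.sqrt(n_samples))))


@dataclass
class MetricEvidence:
    """Per-metric evidence for one candidate edge."""

    observed: float
    null_mean: float
    p: float
    sign: int
    ci_low: float
    ci_high: float
    stable: bool
    tails: Tuple[str, ...]


@dataclass
class EdgeStats:
    """Aggregated evidence for one candidate SV pair."""

    sv_a: str
    sv_b: str
    per_metric: Dict[str, MetricEvidence]
    sign: int = 0
    support_count: int = 0
    stable: bool = False
    merged_p: float = float("nan")
    q: float = float("nan")


@dataclass
class NetworkResult:
    """Final node/edge sets of one network build."""

    nodes: pd.DataFrame
    edges: List[EdgeStats]
    mode: str
    config: NetworkConfig
    seed: int
    n_candidates: int = 0
    tested: List[EdgeStats] = field(default_factory=list)  # full audit trail

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_table(self) -> pd.DataFrame:
        """Tab-friendly edge summary with per-metric score columns."""
        rows = []
        for e in self.edges:
            row = {
                "sv_a": e.sv_a,
                "sv_b": e.sv_b,
                "sign": e.sign,
                "support_count": e.support_count,
                "stable": e.stable,
                "merged_p": e.merged_p,
                "q": e.q,
            }
            for m in self.config.metrics:
                ev = e.per_metric.get(m)
                row[f"score_{m}"] = ev.observed if ev is not None else np.nan
            rows.append(row)
        cols = ["sv_a", "sv_b", "sign", "support_count", "stable", "merged_p", "q"] + [
            f"score_{m}" for m in self.config.metrics
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph(mode=self.mode, seed=self.seed)
        for sv, row in self.nodes.iterrows():
            G.add_node(sv, **{k: row[k] for k in self.nodes.columns})
        for e in self.edges:
            attrs = {
                "sign": int(e.sign),
                "support_count": int(e.support_count),
                "stable": bool(e.stable),
                "merged_p": float(e.merged_p),
            }
            if np.isfinite(e.q):
                attrs["q"] = float(e.q)
            G.add_edge(e.sv_a, e.sv_b, **attrs)
        return G


# ---------------------------------------------------------------------------
# scoring and preselection


def compute_scores(rel: pd.DataFrame, metric: str, config: NetworkConfig) -> pd.DataFrame:
    """Symmetric SV-by-SV association scores on relative abundances."""
    if rel.shape[1] < 3:
        raise ValueError("need at least 3 samples to score associations")
    S = pairwise_scores(
        rel.to_numpy(float),
        metric,
        n_bins=config.bins_for(rel.shape[1]),
        pseudocount=config.kl_pseudocount,
    )
    return pd.DataFrame(S, index=rel.index, columns=rel.index)


def preselect_edges(
    scores: Dict[str, pd.DataFrame], config: NetworkConfig
) -> Dict[Tuple[int, int], Dict[str, Tuple[str, ...]]]:
    """Union of each metric's k highest and k lowest scoring pairs.

    Ties are broken by lexicographic pair position for determinism.
    Pairs with an undefined score under a metric (constant SV under a
    correlation) are excluded from that metric's ranking with a warning.
    Returns a map from index pair (i < j, in the score-matrix row order)
    to the metrics that selected it and from which tail.
    """
    first = next(iter(scores.values()))
    m = first.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    candidates: Dict[Tuple[int, int], Dict[str, Tuple[str, ...]]] = {}
    for metric, S in scores.items():
        v = S.to_numpy(float)[iu, ju]
        valid = np.isfinite(v)
        if not valid.all():
            warnings.warn(
                f"{metric}: {np.count_nonzero(~valid)} pair(s) with undefined "
                "score excluded from preselection",
                stacklevel=2,
            )
        vi, vj, vv = iu[valid], ju[valid], v[valid]
        k = min(config.k_preselect, len(vv))
        for tail, order in (
            ("high", np.lexsort((vj, vi, -vv))),
            ("low", np.lexsort((vj, vi, vv))),
        ):
            for idx in order[:k]:
                pair = (int(vi[idx]), int(vj[idx]))
                tails = candidates.setdefault(pair, {}).setdefault(metric, ())
                if tail not in tails:
                    candidates[pair][metric] = tails + (tail,)
    return candidates


# ---------------------------------------------------------------------------
# resampling cores


def _reboot_core(
    x: np.ndarray,
    y: np.ndarray,
    rest: np.ndarray,
    metrics: Sequence[str],
    config: NetworkConfig,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Shared permutation-renormalization null for several metrics.

    One set of permutations is drawn and every metric is evaluated on the
    same permuted data, so the inter-metric dependence of the null scores
    (needed for Brown's covariance) is preserved.
    """
    n = x.size
    B = config.n_perm
    px = np.argsort(rng.random((B, n)), axis=1)
    py = np.argsort(rng.random((B, n)), axis=1)
    Xp = x[px]
    Yp = y[py]
    s = np.maximum(rest[None, :] + Xp + Yp, 1e-300)
    Xn = Xp / s
    Yn = Yp / s
    n_bins = config.bins_for(n)
    return {
        m: batch_score(m, Xn, Yn, n_bins=n_bins, pseudocount=config.kl_pseudocount)
        for m in metrics
    }


def _bootstrap_core(
    x: np.ndarray,
    y: np.ndarray,
    metrics: Sequence[str],
    config: NetworkConfig,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Shared sample-bootstrap score distributions for several metrics."""
    n = x.size
    idx = rng.integers(0, n, size=(config.n_boot, n))
    Xb = x[idx]
    Yb = y[idx]
    n_bins = config.bins_for(n)
    return {
        m: batch_score(m, Xb, Yb, n_bins=n_bins, pseudocount=config.kl_pseudocount)
        for m in metrics
    }


def _edge_vectors(rel: pd.DataFrame, edge) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = rel.loc[edge[0]].to_numpy(float)
    y = rel.loc[edge[1]].to_numpy(float)
    rest = rel.to_numpy(float).sum(axis=0) - x - y
    return x, y, rest


def reboot_null(
    rel: pd.DataFrame,
    edge: Tuple[str, str],
    metric: str,
    config: NetworkConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation-renormalization null scores for one edge and metric."""
    x, y, rest = _edge_vectors(rel, edge)
    return _reboot_core(x, y, rest, [metric], config, rng)[metric]


def bootstrap_scores(
    rel: pd.DataFrame,
    edge: Tuple[str, str],
    metric: str,
    config: NetworkConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap score distribution for one edge and metric."""
    x, y, _ = _edge_vectors(rel, edge)
    return _bootstrap_core(x, y, [metric], config, rng)[metric]


# ---------------------------------------------------------------------------
# per-edge statistics


def edge_pvalue(observed: float, null_sample: np.ndarray, kind: str = "similarity") -> Tuple[float, int]:
    """Empirical two-sided p-value about the null mean, plus the edge sign.

    ``p = (1 + #{null at least as far from the null mean}) / (B + 1)``;
    the add-one keeps p in (0, 1].  Sign is +1 (co-presence) when the
    observed score exceeds the null mean for a similarity metric or falls
    below it for a dissimilarity metric, else -1 (exclusion).
    """
    null = np.asarray(null_sample, float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null sample")
    mu = null.mean()
    dev_obs = abs(observed - mu)
    count = int(np.count_nonzero(np.abs(null - mu) >= dev_obs - 1e-12))
    p = (1.0 + count) / (null.size + 1.0)
    above = observed >= mu
    sign = 1 if (above == (kind == "similarity")) else -1
    return min(p, 1.0), sign


def edge_pvalue_gaussian(
    observed: float, null_sample: np.ndarray, kind: str = "similarity"
) -> Tuple[float, int]:
    """Two-sided p-value from a normal fit to the permutation null.

    The permutation distribution is summarized by its mean and standard
    deviation and the observed score referred to that normal -- the
    classical ReBoot construction.  Unlike empirical counting this is not
    floored at ``1 / (n_perm + 1)``, so overwhelming evidence stays
    distinguishable from merely extreme evidence when p-values are merged
    across metrics.
    """
    null = np.asarray(null_sample, float)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("empty null sample")
    mu = null.mean()
    sd = null.std(ddof=1) if null.size > 1 else 0.0
    above = observed >= mu
    sign = 1 if (above == (kind == "similarity")) else -1
    if sd == 0:
        return 1.0, sign
    z = abs(observed - mu) / sd
    p = 2.0 * stats.norm.sf(z)
    return float(min(max(p, 1e-300), 1.0)), sign


def stability_filter(
    observed: float, bootstrap_sample: np.ndarray, config: NetworkConfig
) -> bool:
    """Edge stability: observed score inside the central bootstrap interval.

    Bounds are the configured percentiles (linear interpolation),
    inclusive.  If more than half of the bootstrap replicates are
    undefined (degenerate resamples), the edge is unstable.
    """
    boot = np.asarray(bootstrap_sample, float)
    finite = boot[np.isfinite(boot)]
    if finite.size == 0 or finite.size < 0.5 * boot.size:
        return False
    lo, hi = np.percentile(finite, config.ci_percentiles)
    return bool(lo - 1e-12 <= observed <= hi + 1e-12)


def _null_pvalues(null: np.ndarray, method: str = "empirical") -> np.ndarray:
    """Two-sided p-value of each null score within its own null sample.

    These per-permutation p-values carry the inter-metric dependence into
    Brown's covariance estimate, so they are computed exactly like the
    observed edge's p-value.
    """
    if method == "gaussian":
        mu = null.mean()
        sd = null.std(ddof=1)
        if sd == 0:
            return np.ones_like(null)
        p = 2.0 * stats.norm.sf(np.abs(null - mu) / sd)
        return np.clip(p, 1e-300, 1.0)
    dev = np.abs(null - null.mean())
    sorted_dev = np.sort(dev)
    count_ge = dev.size - np.searchsorted(sorted_dev, dev, side="left")
    return np.maximum(count_ge, 1) / (dev.size + 1.0)


def brown_merge(
    pvals: Sequence[float], null_pval_matrix: Optional[np.ndarray] = None
) -> float:
    """Combine dependent p-values with Brown's scaled chi-square method.

    Fisher's statistic ``X = -2 sum(ln p)`` has mean ``2 m`` and, under
    dependence, variance ``4 m + 2 sum_{i<j} cov(-2 ln p_i, -2 ln p_j)``.
    The covariances are estimated empirically from ``null_pval_matrix``
    (per-permutation p-values of the same metrics, columns aligned with
    ``pvals``).  ``X / c`` is referred to a chi-square with ``2 E^2/Var``
    degrees of freedom, ``c = Var / (2 E)``.  With independent metrics
    this reduces to Fisher's method; with perfectly dependent ones it
    returns the single shared p-value.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return float(p[0])
    m = p.size
    X = -2.0 * np.log(p).sum()
    E = 2.0 * m
    var = 4.0 * m
    if null_pval_matrix is not None:
        L = -2.0 * np.log(np.asarray(null_pval_matrix, float))
        if L.shape[1] != m:
            raise ValueError("null p-value matrix must have one column per p-value")
        C = np.cov(L, rowvar=False)
        iu, ju = np.triu_indices(m, k=1)
        var += 2.0 * C[iu, ju].sum()
    var = max(var, 1e-9)
    c = var / (2.0 * E)
    df = 2.0 * E**2 / var
    return float(stats.chi2.sf(X / c, df))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full build


def _consensus_sign(evidence: Dict[str, MetricEvidence], eligible: List[str]) -> int:
    """Majority sign among eligible metrics; ties go to the smallest p."""
    signs = [evidence[m].sign for m in eligible]
    total = sum(signs)
    if total != 0:
        return 1 if total > 0 else -1
    best = min(eligible, key=lambda m: (evidence[m].p, m))
    return evidence[best].sign


def _empty_result(config: NetworkConfig, mode: str) -> NetworkResult:
    nodes = pd.DataFrame(columns=["mean_rel_abundance"])
    nodes.index.name = "sv_id"
    return NetworkResult(nodes=nodes, edges=[], mode=mode, config=config, seed=config.seed)


def build_network(
    table: SVTable,
    metadata: Optional[pd.DataFrame] = None,
    config: Optional[NetworkConfig] = None,
    group: Optional[str] = None,
) -> NetworkResult:
    """Run the full ensemble inference on a (contaminant-filtered) table.

    Pipeline: relativize -> abundance preselection of SVs -> five score
    matrices -> per-metric edge preselection -> per-candidate ReBoot
    null, bootstrap, p-value and sign -> strict or lenient assembly.
    ``group`` restricts the samples via the metadata ``label`` (or
    ``group``) column.  Fewer than three samples or an empty candidate
    set yields an explicit empty network.
    """
    if config is None:
        config = NetworkConfig()
    mode = "strict" if config.strict_mode else "lenient"
    if group is not None:
        if metadata is None:
            raise ValueError("group selection requires metadata")
        meta = metadata.loc[table.sample_ids]
        key = "label" if "label" in meta.columns else "group"
        keep = meta.index[(meta[key] == group) & ~meta["is_control"]]
        table = table.subset_samples(list(keep))
    if table.shape[1] < 3:
        return _empty_result(config, mode)

    rel_full = relative_abundance(table)
    filtered = abundance_filter(table, config.abundance_threshold)
    rel = rel_full.loc[filtered.sv_ids]
    if rel.shape[0] < 2:
        return _empty_result(config, mode)

    scores = {m: compute_scores(rel, m, config) for m in config.metrics}
    candidates = preselect_edges(scores, config)
    if not candidates:
        return _empty_result(config, mode)

    sv_ids = list(rel.index)
    ordered = sorted(candidates.items())
    children = np.random.SeedSequence(config.seed).spawn(len(ordered))

    surviving: List[EdgeStats] = []
    pending: List[tuple] = []
    for ((i, j), metric_tails), child in zip(ordered, children):
        rng = np.random.default_rng(child)
        sv_a, sv_b = sv_ids[i], sv_ids[j]
        x, y, rest = _edge_vectors(rel, (sv_a, sv_b))
        metrics_here = [m for m in config.metrics if m in metric_tails]
        nulls = _reboot_core(x, y, rest, metrics_here, config, rng)
        boots = _bootstrap_core(x, y, metrics_here, config, rng)

        evidence: Dict[str, MetricEvidence] = {}
        null_z: Dict[str, np.ndarray] = {}
        for m in metrics_here:
            obs = float(scores[m].iat[i, j])
            null = nulls[m]
            finite_null = null[np.isfinite(null)]
            if finite_null.size == 0:
                continue
            pfun = edge_pvalue_gaussian if config.p_method == "gaussian" else edge_pvalue
            p, sign = pfun(obs, finite_null, METRIC_KIND[m])
            boot = boots[m]
            fb = boot[np.isfinite(boot)]
            lo, hi = (
                np.percentile(fb, config.ci_percentiles) if fb.size else (np.nan, np.nan)
            )
            evidence[m] = MetricEvidence(
                observed=obs,
                null_mean=float(finite_null.mean()),
                p=p,
                sign=sign,
                ci_low=float(lo),
                ci_high=float(hi),
                stable=stability_filter(obs, boot, config),
                tails=metric_tails[m],
            )
            mu = finite_null.mean()
            sd = finite_null.std(ddof=1) if finite_null.size > 1 else 0.0
            null_z[m] = (finite_null - mu) / sd if sd > 0 else np.zeros(finite_null.size)

        if not evidence:
            continue
        # The (biased-under-bootstrap) stability veto does not apply to
        # unsigned metrics: equal-frequency-binned mutual information is
        # systematically inflated by the duplicated samples of a
        # bootstrap draw, so its observed score sits below any central
        # bootstrap interval even for the strongest edges.
        if config.strict_mode:
            eligible = [
                m for m in evidence if evidence[m].stable or m in UNSIGNED_METRICS
            ]
        else:
            eligible = list(evidence)
        if not eligible:
            continue
        signed = [m for m in eligible if m not in UNSIGNED_METRICS]
        consensus = _consensus_sign(evidence, signed if signed else eligible)
        supporting = [
            m
            for m in eligible
            if m in UNSIGNED_METRICS or evidence[m].sign == consensus
        ]
        if not supporting:
            continue
        edge = EdgeStats(
            sv_a=sv_a,
            sv_b=sv_b,
            per_metric=evidence,
            sign=consensus,
            support_count=len(supporting),
            stable=all(evidence[m].stable for m in evidence),
        )
        pending.append(
            (edge, supporting, {m: z.astype(np.float32) for m, z in null_z.items()})
        )

    # Brown's covariance needs, per edge, the per-permutation p-values of
    # the supporting metrics over the *shared* permutations; the
    # standardized null scores preserve exactly that dependence.
    for edge, supporting, nz in pending:
        min_len = min(nz[m].size for m in supporting)
        null_matrix = np.column_stack(
            [
                _null_pvalues(nz[m][:min_len].astype(float), config.p_method)
                for m in supporting
            ]
        )
        edge.merged_p = brown_merge([edge.per_metric[m].p for m in supporting], null_matrix)
        surviving.append(edge)

    if config.strict_mode:
        # BH spans every candidate edge that was actually tested; the
        # stability and support filters then prune memberships of the
        # final edge set without shrinking the multiple-testing family.
        if surviving:
            qvals = bh_adjust([e.merged_p for e in surviving])
            for e, q in zip(surviving, qvals):
                e.q = float(q)
        final = [
            e
            for e in surviving
            if e.q <= config.q_threshold and e.support_count >= config.min_support
        ]
    else:
        final = [e for e in surviving if e.merged_p <= config.q_threshold]

    node_ids = sorted({e.sv_a for e in final} | {e.sv_b for e in final})
    nodes = pd.DataFrame(
        {"mean_rel_abundance": rel_full.loc[node_ids].mean(axis=1)}, index=node_ids
    )
    nodes.index.name = "sv_id"
    return NetworkResult(
        nodes=nodes,
        edges=final,
        mode=mode,
        config=config,
        seed=config.seed,
        n_candidates=len(ordered),
        tested=surviving,
    )
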