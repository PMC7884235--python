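"""Sequence-variant count tables: I/O, filtering rules and summaries.

The universal currency of the pipeline is a nonnegative integer matrix of
sequence variants (SVs, i.e. exact 16S amplicon variants) by samples,
accompanied by per-sample metadata (soil mass, sample group, control
flag).  This module implements the contaminant rule -- an SV reaching the
threshold relative abundance in *any* no-soil control of an experiment is
a potential reagent contaminant -- together with abundance-prevalence
filters, Good's coverage, and the copies-per-gram scaling used to compare
qPCR readouts across soil masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SVTable",
    "FilterConfig",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "relative_abundance",
    "flag_contaminants",
    "remove_svs",
    "abundance_filter",
    "goods_coverage",
    "prevalence_by_group",
    "overlap_percentage",
    "count_shared_svs",
    "scale_copies_per_gram",
]


class SVTable:
    """An SV-by-sample integer count matrix with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame with SV identifiers as index and sample identifiers as
        columns; values must be nonnegative integers.
    taxonomy
        Optional per-SV rank strings, aligned to the count index.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: Optional[pd.Series] = None):
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate SV id(s): {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if values.size and (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = counts.astype(np.int64) if values.size else counts
        if taxonomy is not None:
            taxonomy = taxonomy.reindex(counts.index)
        self.taxonomy = taxonomy

    @property
    def sv_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "SVTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return SVTable(self.counts[sample_ids], self.taxonomy)

    def __eq__(self, other) -> bool:
        return isinstance(other, SVTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"SVTable({self.shape[0]} SVs x {self.shape[1]} samples)"


@dataclass(frozen=True)
class FilterConfig:
    """Relative-abundance thresholds of the filtering rules.

    ``contaminant_threshold``: an SV at or above this fraction in any
    control sample is flagged (default 0.1%).  ``abundance_threshold_pca``
    (0.1%) and ``abundance_threshold_network`` (0.2%) gate which SVs enter
    the ordination/distance and network stages respectively; both are
    inclusive and evaluated over the current comparison sample set.
    """

    contaminant_threshold: float = 0.001
    abundance_threshold_pca: float = 0.001
    abundance_threshold_network: float = 0.002

    def __post_init__(self) -> None:
        for v in (
            self.contaminant_threshold,
            self.abundance_threshold_pca,
            self.abundance_threshold_network,
        ):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


def read_table(path) -> SVTable:
    """Read a tab-delimited SV matrix (first column = SV id)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
                )
            index.append(parts[0])
            try:
                row = [int(x) for x in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer count ({exc})") from None
            if any(v < 0 for v in row):
                raise ValueError(f"{path}: line {lineno}: negative count")
            rows.append(row)
    counts = pd.DataFrame(rows, index=index, columns=header[1:], dtype=np.int64)
    counts.index.name = header[0] or "sv_id"
    return SVTable(counts)


def write_table(table: SVTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "sv_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta["is_control"] = meta["is_control"].astype(bool)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def relative_abundance(table: SVTable) -> pd.DataFrame:
    """Relativize each sample to its total sequence count (columns sum to 1)."""
    totals = table.sample_totals()
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValueError(f"sample(s) with zero total reads: {empty}")
    return table.counts / totals


def flag_contaminants(
    table: SVTable,
    metadata: pd.DataFrame,
    config: Optional[FilterConfig] = None,
) -> Set[str]:
    """SVs reaching the threshold relative abundance in any control sample.

    Reagent contaminants dominate no-soil controls, so any SV at >=
    ``contaminant_threshold`` (inclusive) relative abundance in at least
    one control extract of the experiment is a potential contaminant.
    The rule is undefined without controls.
    """
    if config is None:
        config = FilterConfig()
    meta = metadata.loc[table.sample_ids]
    controls = meta.index[meta["is_control"]].tolist()
    if not controls:
        raise ValueError("contaminant rule requires at least one control sample")
    rel = relative_abundance(table.subset_samples(controls))
    flagged = rel.index[(rel >= config.contaminant_threshold).any(axis=1)]
    return set(flagged)


def remove_svs(table: SVTable, sv_ids: Iterable[str]) -> Tuple[SVTable, pd.Series]:
    """Drop SV rows; report the per-sample fraction of reads removed.

    Samples are retained even if emptied.  The fraction-removed report
    mirrors the usual contamination diagnostic (share of each extract's
    reads attributable to the dropped SVs).
    """
    drop = [s for s in sv_ids if s in table.counts.index]
    totals = table.sample_totals().astype(float)
    removed_reads = table.counts.loc[drop].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (removed_reads / totals).fillna(0.0)
    kept = table.counts.drop(index=drop)
    if kept.shape[0] == 0:
        warnings.warn("all SVs removed; table has zero rows", stacklevel=2)
    taxonomy = table.taxonomy.drop(index=drop) if table.taxonomy is not None else None
    return SVTable(kept, taxonomy), frac.rename("fraction_removed")


def abundance_filter(table: SVTable, threshold: float) -> SVTable:
    """Keep SVs reaching ``threshold`` relative abundance in >= 1 sample.

    Relative abundances are recomputed on the table as given, i.e. over
    the current comparison sample set after any prior subsetting.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rel = relative_abundance(table)
    keep = rel.index[(rel >= threshold).any(axis=1)]
    taxonomy = table.taxonomy.loc[keep] if table.taxonomy is not None else None
    return SVTable(table.counts.loc[keep], taxonomy)


def goods_coverage(sample_counts) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton SVs, N = total reads)."""
    counts = np.asarray(sample_counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero reads")
    singletons = int((counts == 1).sum())
    return 1.0 - singletons / total


def prevalence_by_group(
    table: SVTable, metadata: pd.DataFrame, detection_threshold: int = 1
) -> pd.DataFrame:
    """SV-by-group matrix of detection counts (samples with count >= 1).

    Groups are taken from the metadata ``label`` column when present
    (soil mass classes), else from ``group``.
    """
    meta = metadata.loc[table.sample_ids]
    key = "label" if "label" in meta.columns else "group"
    detected = table.counts >= detection_threshold
    return detected.T.groupby(meta[key]).sum().T


def overlap_percentage(n_shared: int, n_total: int) -> int:
    """Shared-SV percentage rounded to the nearest integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_shared > n_total or n_shared < 0:
        raise ValueError("n_shared must lie in [0, n_total]")
    return int(round(100.0 * n_shared / n_total))


def count_shared_svs(
    table: SVTable,
    metadata: pd.DataFrame,
    focal_label: str,
    reference_label: str,
    min_reference_fraction: float = 0.5,
) -> Tuple[int, int, int]:
    """How many SVs of one sample class recur in a reference class.

    Counts SVs detected anywhere in the focal group, how many of those
    are present in at least ``min_reference_fraction`` of the reference
    group's samples, and the rounded percentage.
    Returns ``(n_focal, n_shared, percent)``.
    """
    meta = metadata.loc[table.sample_ids]
    key = "label" if "label" in meta.columns else "group"
    focal = meta.index[meta[key] == focal_label]
    ref = meta.index[meta[key] == reference_label]
    if len(focal) == 0 or len(ref) == 0:
        raise ValueError("focal or reference group has no samples")
    detected_focal = (table.counts[focal] >= 1).any(axis=1)
    ref_prev = (table.counts[ref] >= 1).sum(axis=1)
    in_ref = ref_prev >= np.ceil(min_reference_fraction * len(ref))
    n_focal = int(detected_focal.sum())
    n_shared = int((detected_focal & in_ref).sum())
    return n_focal, n_shared, overlap_percentage(n_shared, n_focal)


def scale_copies_per_gram(
    copies_per_ul: float,
    elution_ul: float,
    dilution_factor: float,
    soil_mass_mg: float,
) -> float:
    """Convert a qPCR readout to gene copies per gram of soil wet weight.

    The extract of ``soil_mass_mg`` mg soil is eluted in ``elution_ul``
    microlitres and measured at ``dilution_factor``-fold dilution.
    """
    if min(copies_per_ul, elution_ul, dilution_factor, soil_mass_mg) <= 0:
        raise ValueError("all inputs must be positive")
    return copies_per_ul * dilution_factor * elution_ul / (soil_mass_mg / 1000.0)
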