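"""Normalization of ASV counts and host parameters, plus phylum summaries.

The microbial normalization chain is fixed:

    drop singletons -> 99.5% cumulative-abundance filter -> counts per
    million -> quantile normalization (per experiment) -> log2(x + 1)

Host parameters are normalized in two stages: first each value is divided by
its birth-cohort mean (removing litter/cohort effects), then parameters
measured in both experiments are z-scored per experiment so the two studies
are on a comparable scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "AsvCountTable",
    "FeatureTable",
    "drop_singletons",
    "filter_cumulative_abundance",
    "relativize_per_million",
    "quantile_normalize",
    "log2_transform",
    "normalize_host_by_cohort",
    "aggregate_phylum",
    "bacteroidetes_firmicutes_ratio",
    "preprocess_microbes",
    "validate_metadata",
]

METADATA_COLUMNS = ("experiment", "group", "cohort")


@dataclass
class AsvCountTable:
    """Integer abundance matrix (samples x ASVs) with a taxonomy map."""

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids in count table")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate ASV ids in count table")
        if (self.counts.values < 0).any():
            raise ValueError("negative entries in count table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_asvs(self, asv_ids) -> "AsvCountTable":
        tax = self.taxonomy.loc[asv_ids] if self.taxonomy is not None else None
        return AsvCountTable(self.counts.loc[:, asv_ids], tax)


@dataclass
class FeatureTable:
    """Real-valued samples x features matrix with per-column kind labels.

    ``kinds`` maps each feature to 'microbe' or 'host'; ``provenance``
    records which normalization stages have been applied.
    """

    values: pd.DataFrame
    kinds: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kinds = self.kinds.reindex(self.values.columns)
        unknown = set(self.kinds.dropna().unique()) - {"microbe", "host"}
        if unknown:
            raise ValueError(f"unknown feature kinds: {unknown}")

    def microbe_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == "microbe"]

    def host_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == "host"]

    @staticmethod
    def concat(microbes: "FeatureTable", hosts: "FeatureTable") -> "FeatureTable":
        values = pd.concat([microbes.values, hosts.values], axis=1)
        kinds = pd.concat([microbes.kinds, hosts.kinds])
        prov = {"microbe": microbes.provenance, "host": hosts.provenance}
        return FeatureTable(values, kinds, prov)


def validate_metadata(metadata: pd.DataFrame, sample_ids=None) -> None:
    """Check required columns and that every sample appears exactly once."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {', '.join(missing)}")
    if metadata.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if sample_ids is not None:
        orphans = set(sample_ids) - set(metadata.index)
        if orphans:
            raise ValueError(f"samples missing from metadata: {sorted(orphans)}")


def drop_singletons(table: AsvCountTable) -> AsvCountTable:
    """Remove ASVs whose total count across all samples equals exactly 1.

    An all-zero ASV is not a singleton and survives this filter (it is
    dropped later by the cumulative-abundance filter).
    """
    if table.counts.size == 0:
        raise ValueError("empty count table")
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals != 1]
    return table.subset_asvs(keep)


def filter_cumulative_abundance(table: AsvCountTable, threshold: float = 0.995) -> AsvCountTable:
    """Keep the most abundant ASVs up to a cumulative-abundance threshold.

    ASVs are ranked by grand total over all samples (both experiments
    pooled); the minimal descending prefix whose cumulative share of the
    grand total reaches ``threshold`` is retained, including the ASV that
    crosses the boundary.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    totals = table.counts.sum(axis=0).sort_values(ascending=False, kind="mergesort")
    grand = totals.sum()
    if grand == 0:
        raise ValueError("count table has zero total abundance")
    cum = totals.cumsum() / grand
    # index of the first position reaching the threshold
    n_keep = int(np.searchsorted(cum.values, threshold - 1e-12) + 1)
    n_keep = min(n_keep, int((totals > 0).sum()))
    keep = totals.index[:n_keep]
    # preserve original column order
    keep = [a for a in table.asv_ids if a in set(keep)]
    return table.subset_asvs(keep)


def relativize_per_million(table: AsvCountTable) -> pd.DataFrame:
    """Convert counts to counts-per-million within each sample."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total count: {bad}")
    return table.counts.div(totals, axis=0) * 1e6


def _quantile_normalize_block(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows of a (samples x features) block.

    The k-th smallest value of every sample is replaced by the mean of the
    k-th smallest values across samples; tied values receive the average of
    the reference values at the tied ranks (via average ranks).
    """
    n, p = values.shape
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, p + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(values[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return out


def quantile_normalize(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples within each experiment separately.

    After normalization the sorted value vector of every sample in an
    experiment is identical (the mean order-statistic profile of that
    experiment).  An experiment with a single sample is returned unchanged
    with a warning.
    """
    validate_metadata(metadata, values.index)
    out = values.copy().astype(float)
    for exp, sub in metadata.loc[values.index].groupby("experiment", sort=False):
        ids = sub.index
        if len(ids) < 2:
            warnings.warn(
                f"experiment {exp!r} has a single sample; quantile normalization is the identity"
            )
            continue
        out.loc[ids] = _quantile_normalize_block(values.loc[ids].to_numpy(dtype=float))
    return out


def log2_transform(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); requires non-negative input."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2 transform requires non-negative values")
    return pd.DataFrame(np.log2(arr + pseudocount), index=values.index,
                        columns=values.columns)


def normalize_host_by_cohort(
    host: pd.DataFrame,
    metadata: pd.DataFrame,
    stat: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two-stage host-parameter normalization.

    Stage 1 divides each value by its birth cohort's ``stat`` ('mean' or
    'median') of that parameter.  Stage 2 z-scores, per experiment, every
    parameter measured in both (all) experiments; single-experiment
    parameters skip stage 2 and are flagged.

    Returns (stage-2 table, stage-1 table, flags) — the stage-1 table is the
    positive ratio scale on which host fold changes are computed, and
    ``flags`` marks parameters that skipped cross-study normalization.
    """
    validate_metadata(metadata, host.index)
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    meta = metadata.loc[host.index]

    stage1 = host.copy().astype(float)
    for cohort, sub in meta.groupby("cohort", sort=False):
        ids = sub.index
        if len(ids) < 2:
            warnings.warn(f"cohort {cohort!r} has < 2 samples; normalizing by overall {stat}")
            center = getattr(host, stat)(axis=0)
        else:
            center = getattr(host.loc[ids], stat)(axis=0)
        if (center == 0).any():
            bad = list(center.index[center == 0])
            raise ValueError(f"cohort {cohort!r} has zero {stat} for parameter(s) {bad}")
        stage1.loc[ids] = host.loc[ids] / center

    # Parameters present in every experiment (non-NaN somewhere) get
    # cross-study z-scoring; others are flagged and passed through.
    experiments = meta["experiment"].unique()
    measured = pd.DataFrame(
        {e: host.loc[meta.index[meta["experiment"] == e]].notna().any(axis=0)
         for e in experiments}
    )
    shared = measured.all(axis=1)

    stage2 = stage1.copy()
    for exp in experiments:
        ids = meta.index[meta["experiment"] == exp]
        block = stage1.loc[ids, shared.index[shared]]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1).replace(0.0, 1.0)
        stage2.loc[ids, shared.index[shared]] = (block - mu) / sd
    flags = ~shared
    flags.name = "single_experiment"
    return stage2, stage1, flags


def preprocess_microbes(
    table: AsvCountTable,
    metadata: pd.DataFrame,
    threshold: float = 0.995,
    pseudocount: float = 1.0,
) -> FeatureTable:
    """Full microbial normalization chain; provenance flags record the stages."""
    validate_metadata(metadata, table.sample_ids)
    filtered = filter_cumulative_abundance(drop_singletons(table), threshold)
    cpm = relativize_per_million(filtered)
    qn = quantile_normalize(cpm, metadata)
    logged = log2_transform(qn, pseudocount)
    kinds = pd.Series("microbe", index=logged.columns)
    prov = {
        "singletons_removed": True,
        "cumulative_threshold": threshold,
        "relativized": True,
        "quantile_normalized": True,
        "log_transformed": True,
        "pseudocount": pseudocount,
    }
    return FeatureTable(logged, kinds, prov)


def _phylum_of(lineage) -> str:
    if not isinstance(lineage, str) or not lineage.strip():
        return "Unclassified"
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith("p__"):
            name = part[3:].strip()
            return name if name else "Unclassified"
    return "Unclassified"


def aggregate_phylum(table: AsvCountTable) -> pd.DataFrame:
    """Sum counts per phylum within each sample (samples x phyla)."""
    if table.taxonomy is None:
        raise ValueError("count table has no taxonomy map")
    phyla = table.taxonomy.reindex(table.counts.columns).map(_phylum_of)
    return table.counts.T.groupby(phyla.values).sum().T


# the paper's figures misspell the phylum; both spellings are accepted
_BACTEROIDETES = ("Bacteroidetes", "Bacteriodetes", "Bacteroidota")
_FIRMICUTES = ("Firmicutes", "Bacillota")


def _find_column(phyla: pd.DataFrame, names) -> str:
    for n in names:
        if n in phyla.columns:
            return n
    raise ValueError(f"phylum table lacks a column among {names}")


def bacteroidetes_firmicutes_ratio(phyla: pd.DataFrame) -> pd.Series:
    """Per-sample Bacteroidetes:Firmicutes ratio; NaN where Firmicutes is 0."""
    b = phyla[_find_column(phyla, _BACTEROIDETES)].astype(float)
    f = phyla[_find_column(phyla, _FIRMICUTES)].astype(float)
    ratio = b / f.where(f != 0)
    ratio.name = "bacteroidetes_firmicutes_ratio"
    return ratio
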