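"""Edge inference: per-group Spearman correlations, consistency filters,
Fisher-Z fixed-effect meta-analysis, and class-specific FDR gating.

Every candidate feature pair is correlated within each analysis group
(experiment x treatment arm; four groups in the default design).  An edge
survives only if

1. its correlation has the same strict sign in all groups,
2. it is coherent with the endpoints' treatment responses
   (sign(rho) = sign(delta_A) x sign(delta_B), the "causality" rule),
3. both endpoint features changed in the same direction in every experiment,
4. for microbe-host edges, every per-group p-value is < 0.6 (two named
   edges may be rescued past this prefilter), and
5. its fixed-effect meta-analysis p-value passes the Benjamini-Hochberg FDR
   threshold of its class (microbe-microbe 0.05, microbe-host 0.15,
   host-host 0.10).

All candidate edges — kept and removed — are retained in the output table
with per-group statistics, filter flags and the first failing filter, so a
run is fully auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureTable, validate_metadata

__all__ = [
    "GroupPartition",
    "FDR_THRESHOLDS",
    "make_group_partition",
    "spearman_by_group",
    "compute_fold_changes",
    "fisher_z_meta",
    "sign_consistency",
    "causality_ok",
    "fold_change_consistent",
    "benjamini_hochberg",
    "build_edge_table",
    "filter_stage_counts",
]

FDR_THRESHOLDS = {
    "microbe-microbe": 0.05,
    "microbe-host": 0.15,
    "host-host": 0.10,
}

DEFAULT_P_PREFILTER = 0.6
MIN_GROUP_SIZE = 4

FILTER_ORDER = ("undefined", "sign", "causality", "fold_change", "prefilter", "fdr")


@dataclass
class GroupPartition:
    """Disjoint analysis groups: one per (experiment, treatment arm)."""

    groups: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [f"{e}/{g}" for e, g, _ in self.groups]

    def __len__(self) -> int:
        return len(self.groups)


def make_group_partition(metadata: pd.DataFrame, sample_ids=None) -> GroupPartition:
    """Partition samples into (experiment, group) cells, each >= 4 samples."""
    validate_metadata(metadata, sample_ids)
    meta = metadata if sample_ids is None else metadata.loc[list(sample_ids)]
    groups = []
    for (exp, grp), sub in meta.groupby(["experiment", "group"], sort=True):
        if len(sub) < MIN_GROUP_SIZE:
            raise ValueError(
                f"group {exp}/{grp} has {len(sub)} samples; "
                f"at least {MIN_GROUP_SIZE} are required for Spearman p-values"
            )
        groups.append((str(exp), str(grp), list(sub.index)))
    return GroupPartition(groups)


def spearman_by_group(
    features: FeatureTable, partition: GroupPartition
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame, int]]:
    """All-pairs Spearman rho and two-sided p within each group.

    Ties get average ranks; p-values use the t approximation on n-2 df.
    A feature that is constant within a group yields NaN rho/p for its
    pairs (such edges are later flagged and excluded).
    """
    out = {}
    cols = features.values.columns
    for exp, grp, ids in partition.groups:
        X = features.values.loc[ids].to_numpy(dtype=float)
        n = X.shape[0]
        rho, p = _spearman_matrix(X)
        label = f"{exp}/{grp}"
        out[label] = (
            pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols),
            n,
        )
    return out


def _spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho (Pearson on average ranks) and two-sided p
    from the t approximation on n-2 df.  Constant columns yield NaN for
    their pairs only."""
    n = X.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        r = np.clip(rho, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    return rho, p


def compute_fold_changes(
    fc_scale: pd.DataFrame, metadata: pd.DataFrame,
    control: str = "Control", treatment: str = "Treatment",
) -> pd.DataFrame:
    """Per-feature median fold change (treatment/control) per experiment.

    ``fc_scale`` must be on a positive scale (back-transformed microbe
    abundances; stage-1 cohort-normalized host values).  A zero control
    median leaves that experiment's fold change undefined and the feature
    inconsistent.  Returns one row per feature with per-experiment fold
    changes, per-experiment directions, a consistency flag, and the average
    median fold change used as a node attribute.
    """
    validate_metadata(metadata, fc_scale.index)
    meta = metadata.loc[fc_scale.index]
    experiments = list(dict.fromkeys(meta["experiment"]))
    rows = {}
    for exp in experiments:
        t_ids = meta.index[(meta["experiment"] == exp) & (meta["group"] == treatment)]
        c_ids = meta.index[(meta["experiment"] == exp) & (meta["group"] == control)]
        med_t = fc_scale.loc[t_ids].median(axis=0)
        med_c = fc_scale.loc[c_ids].median(axis=0)
        fc = med_t / med_c.where(med_c != 0)
        rows[f"fc_{exp}"] = fc
    df = pd.DataFrame(rows)
    dirs = np.sign(df.to_numpy(dtype=float) - 1.0)
    dir_df = pd.DataFrame(dirs, index=df.index,
                          columns=[c.replace("fc_", "dir_") for c in df.columns])
    valid = np.isfinite(dirs).all(axis=1) & (dirs != 0).all(axis=1)
    consistent = valid & (np.abs(dirs.sum(axis=1)) == dirs.shape[1])
    out = pd.concat([df, dir_df], axis=1)
    out["consistent"] = consistent
    out["direction"] = np.where(consistent, dirs[:, 0], 0.0)
    out["average_median_fold_change"] = df.mean(axis=1)
    return out


def fisher_z_meta(rhos, ns) -> tuple[float, float]:
    """Fixed-effect meta-analysis of correlations via Fisher's Z transform.

    Each correlation is transformed z_i = atanh(rho_i) with weight
    w_i = n_i - 3 (inverse variance of the transform); the pooled mean
    z-bar = sum(w z)/sum(w) has standard error 1/sqrt(sum(w)).  Returns the
    standardized statistic z-bar/SE and its two-sided normal p-value.

    Correlations at exactly +/-1 are clamped to 1 - 1e-7 with a warning.
    """
    rhos = np.asarray(rhos, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if rhos.shape != ns.shape or rhos.ndim != 1 or rhos.size == 0:
        raise ValueError("rhos and ns must be equal-length non-empty 1-d sequences")
    if (ns <= 3).any():
        raise ValueError("every group needs n > 3 for Fisher-Z weighting")
    if (np.abs(rhos) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    if (np.abs(rhos) == 1).any():
        warnings.warn("correlation at +/-1 clamped to 1 - 1e-7 for Fisher-Z pooling")
        rhos = np.clip(rhos, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(rhos)
    w = ns - 3.0
    zbar = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / np.sqrt(np.sum(w))
    stat = zbar / se
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return stat, p


def _fisher_z_meta_matrix(rho_mat: np.ndarray, ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Fisher-Z pooling: rho_mat is (n_groups, n_edges)."""
    r = np.clip(rho_mat, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    w = (ns - 3.0)[:, None]
    zbar = (w * z).sum(axis=0) / w.sum()
    stat = zbar * np.sqrt(w.sum())
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return stat, p


def sign_consistency(rhos) -> bool:
    """True iff all correlations strictly share one sign (a zero fails)."""
    r = np.asarray(rhos, dtype=float)
    if np.isnan(r).any():
        return False
    return bool((r > 0).all() or (r < 0).all())


def causality_ok(avg_rho: float, dir_a: float, dir_b: float) -> bool:
    """Sign-coherence rule: sign(rho) must equal sign(dA) x sign(dB)."""
    if dir_a == 0 or dir_b == 0 or avg_rho == 0 or not np.isfinite(avg_rho):
        return False
    return bool(np.sign(avg_rho) == np.sign(dir_a) * np.sign(dir_b))


def fold_change_consistent(consistent_a: bool, consistent_b: bool) -> bool:
    """True iff both endpoints changed in the same direction in every experiment."""
    return bool(consistent_a and consistent_b)


def benjamini_hochberg(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """BH (or BY) adjusted p-values; empty input returns an empty array."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method=method)[1]


def _edge_class(kind_a: str, kind_b: str) -> str:
    kinds = sorted([kind_a, kind_b])
    if kinds == ["microbe", "microbe"]:
        return "microbe-microbe"
    if kinds == ["host", "microbe"]:
        return "microbe-host"
    return "host-host"


def edge_id(a: str, b: str) -> str:
    """Canonical (order-independent) edge identifier."""
    a, b = sorted([a, b])
    return f"{a}<==>{b}"


def build_edge_table(
    features: FeatureTable,
    partition: GroupPartition,
    fold_changes: pd.DataFrame,
    p_prefilter: float = DEFAULT_P_PREFILTER,
    rescue: list[str] | None = None,
    fdr_thresholds: dict[str, float] | None = None,
    fdr_method: str = "fdr_bh",
    use_causality_filter: bool = True,
) -> pd.DataFrame:
    """Score every feature pair and apply the full filter cascade.

    Returns one row per candidate edge with per-group statistics, filter
    flags, the meta-analysis p-value, the class-wise FDR, the kept flag and
    the first failing filter (``removal_reason``).  ``rescue`` lists edge
    ids (see :func:`edge_id`) exempt from the microbe-host p-value
    prefilter.
    """
    rescue_set = set(rescue or [])
    thresholds = dict(FDR_THRESHOLDS)
    if fdr_thresholds:
        thresholds.update(fdr_thresholds)

    stats_by_group = spearman_by_group(features, partition)
    labels = list(stats_by_group)
    cols = list(features.values.columns)
    kinds = features.kinds

    iu, ju = np.triu_indices(len(cols), k=1)
    n_edges = iu.size
    rho_mat = np.stack([stats_by_group[g][0].to_numpy()[iu, ju] for g in labels])
    p_mat = np.stack([stats_by_group[g][1].to_numpy()[iu, ju] for g in labels])
    ns = np.array([stats_by_group[g][2] for g in labels], dtype=float)

    node_a = np.array(cols, dtype=object)[iu]
    node_b = np.array(cols, dtype=object)[ju]
    classes = np.array([_edge_class(kinds[a], kinds[b]) for a, b in zip(node_a, node_b)])
    ids = np.array([edge_id(a, b) for a, b in zip(node_a, node_b)], dtype=object)

    defined = np.isfinite(rho_mat).all(axis=0)
    avg_rho = np.where(defined, rho_mat.mean(axis=0), np.nan)
    sign_ok = defined & ((rho_mat > 0).all(axis=0) | (rho_mat < 0).all(axis=0))

    fc = fold_changes.reindex(cols)
    dir_by_node = fc["direction"].to_numpy(dtype=float)
    cons_by_node = fc["consistent"].to_numpy(dtype=bool)
    dir_a, dir_b = dir_by_node[iu], dir_by_node[ju]
    fc_ok = cons_by_node[iu] & cons_by_node[ju]
    with np.errstate(invalid="ignore"):
        caus_ok = (np.sign(avg_rho) == dir_a * dir_b) & (dir_a != 0) & (dir_b != 0)
    caus_ok &= defined
    if not use_causality_filter:
        caus_ok = np.ones(n_edges, dtype=bool)

    is_mh = classes == "microbe-host"
    all_p_below = defined & (p_mat < p_prefilter).all(axis=0)
    rescued = np.isin(ids.astype(str), list(rescue_set))
    prefilter_ok = ~is_mh | all_p_below | rescued
    rescued = rescued & is_mh & ~all_p_below  # only meaningful where it changed the outcome

    meta_z = np.full(n_edges, np.nan)
    meta_p = np.full(n_edges, np.nan)
    if defined.any():
        mz, mp = _fisher_z_meta_matrix(rho_mat[:, defined], ns)
        meta_z[defined], meta_p[defined] = mz, mp

    candidate = sign_ok & caus_ok & fc_ok & prefilter_ok
    fdr = np.full(n_edges, np.nan)
    for cls in np.unique(classes):
        mask = candidate & (classes == cls)
        if mask.any():
            fdr[mask] = benjamini_hochberg(meta_p[mask], method=fdr_method)
    thr = np.array([thresholds[c] for c in classes])
    kept = candidate & ((fdr < thr) | rescued)

    reason = np.full(n_edges, "", dtype=object)
    reason[~defined] = "undefined_correlation"
    step_masks = [
        ("sign_inconsistent", ~sign_ok),
        ("causality", ~caus_ok),
        ("fold_change_inconsistent", ~fc_ok),
        ("prefilter", ~prefilter_ok),
        ("fdr", candidate & ~kept),
    ]
    for name, mask in step_masks:
        todo = mask & (reason == "") & ~kept
        reason[todo] = name

    table = pd.DataFrame({
        "edge_id": ids,
        "node_a": node_a,
        "node_b": node_b,
        "edge_class": classes,
    })
    for g, lab in enumerate(labels):
        safe = lab.replace("/", "_")
        table[f"rho_{safe}"] = rho_mat[g]
        table[f"p_{safe}"] = p_mat[g]
        table[f"n_{safe}"] = int(ns[g])
    table["average_rho"] = avg_rho
    table["sign_consistent"] = sign_ok
    table["causality_ok"] = caus_ok
    table["fc_consistent"] = fc_ok
    table["prefilter_ok"] = prefilter_ok
    table["rescued"] = rescued
    table["meta_z"] = meta_z
    table["meta_p"] = meta_p
    table["fdr"] = fdr
    table["kept"] = kept
    table["removal_reason"] = reason
    return table


def filter_stage_counts(edges: pd.DataFrame) -> dict[str, int]:
    """Surviving-edge counts after each filter stage (monotone non-increasing)."""
    defined = edges["removal_reason"] != "undefined_correlation"
    s = edges["sign_consistent"] & defined
    c = s & edges["causality_ok"]
    f = c & edges["fc_consistent"]
    p = f & (edges["prefilter_ok"] | edges["rescued"])
    return {
        "candidates": int(len(edges)),
        "defined": int(defined.sum()),
        "after_sign": int(s.sum()),
        "after_causality": int(c.sum()),
        "after_fold_change": int(f.sum()),
        "after_prefilter": int(p.sum()),
        "kept": int(edges["kept"].sum()),
    }
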