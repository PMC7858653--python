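import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tknet
from tknet.assoc import (
    FDR_THRESHOLDS,
    GroupPartition,
    _spearman_matrix,
    benjamini_hochberg,
    build_edge_table,
    causality_ok,
    compute_fold_changes,
    edge_id,
    fisher_z_meta,
    fold_change_consistent,
    make_group_partition,
    sign_consistency,
    spearman_by_group,
)
from tknet.preprocess import FeatureTable


# ---------------------------------------------------------------- spearman

class TestSpearman:
    @pytest.mark.parametrize("y, expected", [
        ([1, 2, 3, 4, 5], 1.0),
        ([5, 4, 3, 2, 1], -1.0),
    ])
    def test_perfect_monotone(self, y, expected):
        rho, _ = _spearman_matrix(np.array([[1, 2, 3, 4, 5], y], float).T)
        assert rho[0, 1] == pytest.approx(expected)

    def test_hand_ranked_sum_of_squared_differences(self):
        # ranks equal values; d = (-1, 1, -1, 1); rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = _spearman_matrix(np.array([[1, 2, 3, 4], [2, 1, 4, 3]], float).T)
        assert rho[0, 1] == pytest.approx(0.6)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 6))
        X[:, 2] = np.round(X[:, 2])  # introduce ties
        rho, p = _spearman_matrix(X)
        ref_rho, ref_p = stats.spearmanr(X, axis=0)
        assert np.allclose(rho, ref_rho, atol=1e-12)
        assert np.allclose(p, ref_p, atol=1e-12)

    def test_constant_feature_gives_nan_for_its_pairs_only(self):
        X = np.array([[1, 5, 2], [1, 4, 3], [1, 3, 1], [1, 1, 4]], float)
        rho, p = _spearman_matrix(X)
        assert np.isnan(rho[0, 1]) and np.isnan(rho[0, 2])
        assert np.isfinite(rho[1, 2]) and np.isfinite(p[1, 2])

    def test_group_partition_requires_four_samples(self):
        meta = pd.DataFrame({"experiment": ["E"] * 3, "group": ["g"] * 3,
                             "cohort": ["c"] * 3}, index=list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            make_group_partition(meta)

    def test_by_group_shapes(self, default_dataset, default_result):
        counts, host, meta, _ = default_dataset
        ft = default_result.features
        part = make_group_partition(meta, ft.values.index)
        out = spearman_by_group(ft, part)
        assert len(out) == 4
        for rho, p, n in out.values():
            assert n == 8
            assert rho.shape == (ft.values.shape[1],) * 2
            finite = rho.values[np.isfinite(rho.values)]
            assert ((finite >= -1) & (finite <= 1)).all()


# ------------------------------------------------------------------ filters

class TestSignConsistency:
    @pytest.mark.parametrize("rhos, expected", [
        ((0.5, 0.4, 0.7, 0.2), True),
        ((-0.5, -0.4, -0.7, -0.2), True),
        ((0.5, -0.1, 0.7, 0.2), False),
        ((0.5, 0.0, 0.7, 0.2), False),   # zero has no sign
    ])
    def test_cases(self, rhos, expected):
        assert sign_consistency(rhos) is expected


class TestFoldChangeFilter:
    @pytest.mark.parametrize("a, b, expected", [
        (True, True, True),
        (False, True, False),
        (True, False, False),
    ])
    def test_requires_both_endpoints(self, a, b, expected):
        assert fold_change_consistent(a, b) is expected

    def test_zero_change_has_no_direction(self):
        meta = pd.DataFrame({
            "experiment": ["E1"] * 4 + ["E2"] * 4,
            "group": ["Control", "Control", "Treatment", "Treatment"] * 2,
            "cohort": "c",
        }, index=[f"s{i}" for i in range(8)])
        vals = pd.DataFrame({
            "flat": [1.0, 3.0, 1.0, 3.0] * 2,          # fc exactly 1 -> no sign
            "up": [1.0, 1.0, 2.0, 2.0] * 2,
        }, index=meta.index)
        fc = compute_fold_changes(vals, meta)
        assert not fc.loc["flat", "consistent"]
        assert fc.loc["flat", "direction"] == 0
        assert fc.loc["up", "consistent"] and fc.loc["up", "direction"] == 1

    def test_zero_control_median_flags_node(self):
        meta = pd.DataFrame({
            "experiment": ["E1"] * 4 + ["E2"] * 4,
            "group": ["Control", "Control", "Treatment", "Treatment"] * 2,
            "cohort": "c",
        }, index=[f"s{i}" for i in range(8)])
        vals = pd.DataFrame({"z": [0.0, 0.0, 2.0, 2.0] * 2}, index=meta.index)
        fc = compute_fold_changes(vals, meta)
        assert not fc.loc["z", "consistent"]


class TestCausalityRule:
    def test_all_eight_sign_combinations(self):
        # coherent iff sign(rho) = dir_a * dir_b: exactly 4 of 8 combinations
        kept = [(r, a, b) for r, a, b in itertools.product([1, -1], repeat=3)
                if causality_ok(r, a, b)]
        assert len(kept) == 4
        for r, a, b in kept:
            assert np.sign(r) == a * b

    def test_undefined_direction_fails(self):
        assert not causality_ok(0.5, 0.0, 1.0)
        assert not causality_ok(0.0, 1.0, 1.0)
        assert not causality_ok(np.nan, 1.0, 1.0)


# ---------------------------------------------------------------- meta & FDR

class TestFisherZMeta:
    def test_all_zero_correlations_give_p_one(self):
        z, p = fisher_z_meta([0, 0, 0, 0], [10, 10, 10, 10])
        assert z == 0.0 and p == 1.0

    def test_single_group_closed_form(self):
        _, p = fisher_z_meta([0.5], [20])
        expected = 2 * stats.norm.sf(np.arctanh(0.5) * np.sqrt(17))
        assert p == pytest.approx(expected, abs=1e-15)

    def test_pooling_beats_any_single_group(self):
        _, pooled = fisher_z_meta([0.5] * 4, [10] * 4)
        _, single = fisher_z_meta([0.5], [10])
        assert pooled < single

    def test_permutation_invariance_and_sign_equivariance(self):
        rhos, ns = [0.2, 0.5, -0.1, 0.4], [8, 9, 7, 10]
        z1, p1 = fisher_z_meta(rhos, ns)
        z2, p2 = fisher_z_meta(rhos[::-1], ns[::-1])
        assert z1 == pytest.approx(z2) and p1 == pytest.approx(p2)
        z3, p3 = fisher_z_meta([-r for r in rhos], ns)
        assert z3 == pytest.approx(-z1) and p3 == pytest.approx(p1)

    def test_extreme_correlation_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, p = fisher_z_meta([1.0, 0.5], [10, 10])
        assert 0 < p < 1

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_meta([0.5], [3])


def _bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestFdr:
    def test_hand_example(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.123])[0] == pytest.approx(0.123)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), _bh_oracle(p), atol=1e-12)


# ------------------------------------------------------------- edge cascade

def _toy_features_and_meta():
    """Four groups of 5 samples; 2 microbes + 2 hosts with planted structure."""
    rng = np.random.default_rng(7)
    idx, meta_rows = [], []
    for e in ("E1", "E2"):
        for g in ("Control", "Treatment"):
            for i in range(5):
                sid = f"{e}{g[0]}{i}"
                idx.append(sid)
                meta_rows.append({"experiment": e, "group": g, "cohort": f"{e}c"})
    meta = pd.DataFrame(meta_rows, index=idx)
    base = rng.normal(size=20)
    up = (meta["group"] == "Treatment").to_numpy() * 3.0
    vals = pd.DataFrame({
        "M1": base + up,                      # microbe, up, drives H1
        "M2": rng.normal(size=20) + up,       # microbe, up, independent
        "H1": base + up + rng.normal(scale=0.1, size=20),
        "H2": rng.normal(size=20),            # host, no change
    }, index=idx)
    kinds = pd.Series({"M1": "microbe", "M2": "microbe", "H1": "host", "H2": "host"})
    return FeatureTable(vals, kinds), meta


def test_edge_cascade_flags_and_classes():
    ft, meta = _toy_features_and_meta()
    part = make_group_partition(meta)
    # fold changes on a positive scale
    fc = compute_fold_changes(np.exp(ft.values), meta)
    edges = build_edge_table(ft, part, fc)
    edges = edges.set_index("edge_id")
    assert set(edges["edge_class"]) <= {"microbe-microbe", "microbe-host", "host-host"}
    planted = edges.loc[edge_id("M1", "H1")]
    assert planted["sign_consistent"] and planted["causality_ok"]
    assert planted["kept"]
    # kept implies the invariant chain
    k = edges[edges["kept"]]
    assert (k["sign_consistent"] & k["causality_ok"] & k["fc_consistent"]).all()
    assert ((k["fdr"] < [FDR_THRESHOLDS[c] for c in k["edge_class"]])
            | k["rescued"]).all()
    # average rho sign matches the shared per-group sign where consistent
    rho_cols = [c for c in edges.columns if c.startswith("rho_")]
    sc = edges[edges["sign_consistent"]]
    assert (np.sign(sc["average_rho"]) == np.sign(sc[rho_cols[0]])).all()


def test_prefilter_applies_only_to_microbe_host_edges():
    ft, meta = _toy_features_and_meta()
    part = make_group_partition(meta)
    fc = compute_fold_changes(np.exp(ft.values), meta)
    strict = build_edge_table(ft, part, fc, p_prefilter=1e-9)
    p_cols = [c for c in strict.columns if c.startswith("p_")]
    mh = strict[strict["edge_class"] == "microbe-host"]
    expected = (mh[p_cols] < 1e-9).all(axis=1)
    assert (mh["prefilter_ok"] == expected).all()
    assert strict.loc[strict["edge_class"] != "microbe-host", "prefilter_ok"].all()


def _rescue_example():
    """One microbe-host pair with per-group rho = 0.8 (p ~ 0.104, n = 5),
    consistent signs, and a clean upward treatment response everywhere."""
    idx, meta_rows, m_vals, h_vals = [], [], [], []
    for e in ("E1", "E2"):
        for g, offset in (("Control", 0.0), ("Treatment", 10.0)):
            for i in range(5):
                idx.append(f"{e}{g[0]}{i}")
                meta_rows.append({"experiment": e, "group": g, "cohort": f"{e}c"})
            m_vals += [v + offset for v in (1, 2, 3, 4, 5)]
            h_vals += [v + offset for v in (2, 1, 4, 3, 5)]
    meta = pd.DataFrame(meta_rows, index=idx)
    vals = pd.DataFrame({"M1": m_vals, "H1": h_vals}, index=idx)
    kinds = pd.Series({"M1": "microbe", "H1": "host"})
    return FeatureTable(vals, kinds), meta


def test_rescue_bypasses_prefilter_only():
    ft, meta = _rescue_example()
    part = make_group_partition(meta)
    fc = compute_fold_changes(ft.values, meta)
    eid = edge_id("M1", "H1")
    plain = build_edge_table(ft, part, fc, p_prefilter=0.05).set_index("edge_id")
    row = plain.loc[eid]
    assert row["rho_E1_Control"] == pytest.approx(0.8)
    assert row["sign_consistent"] and row["causality_ok"] and row["fc_consistent"]
    assert not row["prefilter_ok"]
    assert not row["kept"] and row["removal_reason"] == "prefilter"
    rescued = build_edge_table(ft, part, fc, p_prefilter=0.05,
                               rescue=[eid]).set_index("edge_id")
    row = rescued.loc[eid]
    assert row["rescued"] and row["prefilter_ok"] and row["kept"]


def test_removal_reason_follows_documented_order(default_result):
    edges = default_result.edges
    reason_checks = {
        "sign_inconsistent": ~edges["sign_consistent"],
        "causality": edges["sign_consistent"] & ~edges["causality_ok"],
        "fold_change_inconsistent": (edges["sign_consistent"] & edges["causality_ok"]
                                     & ~edges["fc_consistent"]),
    }
    for reason, mask in reason_checks.items():
        mask = mask & (edges["removal_reason"] != "undefined_correlation")
        assert (edges.loc[mask, "removal_reason"] == reason).all()
    kept = edges[edges["kept"]]
    assert (kept["removal_reason"] == "").all()


def test_filter_stage_counts_monotone(default_result):
    counts = tknet.assoc.filter_stage_counts(default_result.edges)
    seq = [counts["candidates"], counts["defined"], counts["after_sign"],
           counts["after_causality"], counts["after_fold_change"],
           counts["after_prefilter"], counts["kept"]]
    assert all(a >= b for a, b in zip(seq, seq[1:]))
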