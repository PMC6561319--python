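"""Unit and property tests for the quantitative-proteomics statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stresstox.lfq_stats import (
    ImputeConfig,
    IntensityMatrix,
    TestConfig,
    assign_groups,
    cog_summary,
    compute_fold_changes,
    filter_min_valid,
    impute_downshifted_normal,
    log2_transform,
    normalize_median,
    read_protein_groups,
    s0_permutation_test,
    volcano_table,
    write_protein_groups,
)

# ---------------------------------------------------------------------------
# reading


def test_read_protein_groups_zero_becomes_missing(protein_groups_tsv):
    m = read_protein_groups(protein_groups_tsv)
    assert m.protein_ids == ["A", "B", "C"]
    assert m.sample_ids == ["s1", "s2"]
    assert m.values.isna().sum().sum() == 1
    assert np.isnan(m.values.loc["B", "s1"])


def test_read_protein_groups_requires_lfq_columns(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("Protein IDs\tIntensity s1\nA\t1\n")
    with pytest.raises(ValueError, match="prefix"):
        read_protein_groups(bad)


def test_read_rejects_duplicate_ids(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text(
        "Protein IDs\tLFQ intensity s1\tLFQ intensity s2\nA\t1\t2\nA\t3\t4\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_protein_groups(p)


def test_write_read_round_trip(tmp_path):
    from stresstox.synthetic_data import SimConfig, generate_lfq_experiment

    matrix, _ = generate_lfq_experiment(
        SimConfig(n_proteins=50, n_tfs=5, n_altered_tfs=2, seed=2)
    )
    path = tmp_path / "pg.tsv"
    write_protein_groups(matrix, path)
    back = read_protein_groups(path)
    pd.testing.assert_frame_equal(
        back.values, matrix.values, check_exact=False, rtol=1e-12
    )


# ---------------------------------------------------------------------------
# filtering


def _matrix_from_array(vals, n_ctrl=4, log2=True):
    n = vals.shape[1]
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n - n_ctrl)]
    df = pd.DataFrame(vals, index=[f"P{i:03d}" for i in range(len(vals))], columns=samples)
    groups = {s: ("ctrl" if s.startswith("c") else "trt") for s in samples}
    return IntensityMatrix(values=df, group_of=groups, log2_applied=log2)


def test_filter_min_valid_rule_literals():
    vals = np.full((2, 8), 25.0)
    vals[0, 3:] = np.nan        # 3 valid in ctrl, 0 in trt -> retained
    vals[1, [0, 1, 4, 5]] = np.nan  # 2 valid in each group -> removed
    m = _matrix_from_array(vals)
    kept = filter_min_valid(m, 3)
    assert kept.protein_ids == ["P000"]


def test_filter_min_valid_matches_bruteforce():
    rng = np.random.default_rng(0)
    vals = rng.normal(25, 2, (60, 8))
    vals[rng.random((60, 8)) < 0.4] = np.nan
    m = _matrix_from_array(vals)
    kept = set(filter_min_valid(m, 3).protein_ids)
    expected = {
        pid
        for pid, row in m.values.iterrows()
        if row.iloc[:4].notna().sum() >= 3 or row.iloc[4:].notna().sum() >= 3
    }
    assert kept == expected


def test_filter_min_valid_rejects_impossible_threshold():
    m = _matrix_from_array(np.full((3, 8), 25.0))
    with pytest.raises(ValueError, match="min_valid"):
        filter_min_valid(m, 5)


# ---------------------------------------------------------------------------
# transform / normalize


def test_log2_transform_and_round_trip():
    m = _matrix_from_array(np.full((2, 8), 1024.0), log2=False)
    t = log2_transform(m)
    assert np.allclose(t.values.to_numpy(), 10.0)
    with pytest.raises(ValueError, match="already"):
        log2_transform(t)
    back = 2.0 ** t.values.to_numpy()
    assert np.allclose(back, m.values.to_numpy(), rtol=1e-12)


def test_log2_transform_rejects_nonpositive():
    vals = np.full((2, 8), 10.0)
    vals[0, 0] = -1.0
    # bypass the raw-matrix negativity check to hit the transform guard
    m = _matrix_from_array(np.abs(vals), log2=False)
    m.values.iloc[0, 0] = 0.0
    with pytest.raises(ValueError, match="non-positive"):
        log2_transform(m)


def test_normalize_sample_mode_zeroes_column_medians(toy_matrix_4v4):
    out = normalize_median(toy_matrix_4v4, "sample")
    med = out.values.median(axis=0)
    assert np.allclose(med.to_numpy(), 0.0, atol=1e-12)


def test_normalize_constant_column_becomes_zero():
    vals = np.full((5, 8), 7.0)
    out = normalize_median(_matrix_from_array(vals), "sample")
    assert np.allclose(out.values.to_numpy(), 0.0)


def test_group_mode_equals_sample_mode_when_medians_shared():
    rng = np.random.default_rng(1)
    base = rng.normal(25, 2, (21, 1))
    vals = np.repeat(base, 8, axis=1)  # every column identical -> shared medians
    m = _matrix_from_array(vals)
    a = normalize_median(m, "sample").values.to_numpy()
    b = normalize_median(m, "group").values.to_numpy()
    assert np.allclose(a, b, atol=1e-12)


# ---------------------------------------------------------------------------
# imputation


def test_impute_noop_without_missing(toy_matrix_4v4):
    out = impute_downshifted_normal(toy_matrix_4v4, ImputeConfig(seed=1))
    pd.testing.assert_frame_equal(out.values, toy_matrix_4v4.values)
    assert not out.imputed_mask.to_numpy().any()


def test_impute_deterministic_under_seed():
    rng = np.random.default_rng(3)
    vals = rng.normal(25, 2, (50, 8))
    vals[rng.random((50, 8)) < 0.2] = np.nan
    m = _matrix_from_array(vals)
    a = impute_downshifted_normal(m, ImputeConfig(seed=7)).values
    b = impute_downshifted_normal(m, ImputeConfig(seed=7)).values
    pd.testing.assert_frame_equal(a, b)
    c = impute_downshifted_normal(m, ImputeConfig(seed=8)).values
    assert not a.equals(c)


def test_impute_requires_two_observed_values():
    vals = np.full((4, 8), np.nan)
    vals[0, :] = 25.0
    vals[1, 1:] = 25.0  # column 0 has 1 observed value only
    vals[2:, 1:] = 26.0
    m = _matrix_from_array(vals)
    with pytest.raises(ValueError, match="fewer than 2"):
        impute_downshifted_normal(m, ImputeConfig(seed=0))


# ---------------------------------------------------------------------------
# S0 permutation test


def _oracle_s0_test(matrix, s0, fdr):
    """Independent brute-force reimplementation (pure Python loops)."""
    samples = list(matrix.values.columns)
    treated = matrix.samples_in(matrix.groups[1])
    n_t = len(treated)

    def stats(cols_t):
        cols_c = [s for s in samples if s not in cols_t]
        out = {}
        for pid, row in matrix.values.iterrows():
            xt = [row[c] for c in cols_t]
            xc = [row[c] for c in cols_c]
            mt, mc = sum(xt) / len(xt), sum(xc) / len(xc)
            vt = sum((v - mt) ** 2 for v in xt) / (len(xt) - 1)
            vc = sum((v - mc) ** 2 for v in xc) / (len(xc) - 1)
            sp2 = ((len(xt) - 1) * vt + (len(xc) - 1) * vc) / (len(xt) + len(xc) - 2)
            se = math.sqrt(sp2 * (1 / len(xt) + 1 / len(xc)))
            out[pid] = (mt - mc) / (se + s0)
        return out

    d_obs = stats(treated)
    perms = list(itertools.combinations(samples, n_t))
    pooled = [abs(d) for p in perms for d in stats(list(p)).values()]
    n_perm = len(perms)
    ids = sorted(d_obs, key=lambda p: (-abs(d_obs[p]), p))
    rank = {pid: i + 1 for i, pid in enumerate(ids)}
    null_ge = {pid: sum(1 for v in pooled if v >= abs(d_obs[pid])) for pid in d_obs}
    p_perm = {pid: null_ge[pid] / len(pooled) for pid in d_obs}
    q = {pid: min(null_ge[pid] / n_perm / rank[pid], 1.0) for pid in d_obs}
    running = math.inf
    for pid in reversed(ids):  # least -> most significant
        running = min(running, q[pid])
        q[pid] = running
    return d_obs, p_perm, q


def test_s0_test_matches_bruteforce_oracle(toy_matrix_4v4):
    res = s0_permutation_test(toy_matrix_4v4, TestConfig(s0=1.0))
    assert res.exact and res.n_permutations == 70
    d, p, q = _oracle_s0_test(toy_matrix_4v4, s0=1.0, fdr=0.05)
    for pid in toy_matrix_4v4.protein_ids:
        assert res.table.loc[pid, "d_stat"] == pytest.approx(d[pid], abs=1e-12)
        assert res.table.loc[pid, "p_perm"] == pytest.approx(p[pid], abs=1e-12)
        assert res.table.loc[pid, "q_value"] == pytest.approx(q[pid], abs=1e-12)


def test_identical_groups_give_zero_statistic():
    rng = np.random.default_rng(5)
    half = rng.normal(25, 2, (10, 4))
    vals = np.hstack([half, half])  # treated replicates mirror control
    res = s0_permutation_test(_matrix_from_array(vals), TestConfig())
    assert np.allclose(res.table["d_stat"], 0.0)
    assert not res.table["significant"].any()


def test_huge_s0_limit_is_mean_difference_test(toy_matrix_4v4):
    """As s0 grows the statistic collapses to diff/s0: |d| vanishes while
    the q-values become those of a plain mean-difference permutation test
    (q is invariant to the overall scale of d)."""
    res = s0_permutation_test(toy_matrix_4v4, TestConfig(s0=1e6))
    assert np.all(np.abs(res.table["d_stat"]) < 1e-4)
    res2 = s0_permutation_test(toy_matrix_4v4, TestConfig(s0=1e9))
    assert np.allclose(res.table["q_value"], res2.table["q_value"], atol=1e-9)
    # ranking in the limit is by |mean difference|
    order_d = np.argsort(-np.abs(res.table["d_stat"].to_numpy()))
    order_diff = np.argsort(-np.abs(res.table["log2_diff"].to_numpy()))
    np.testing.assert_array_equal(order_d, order_diff)


def test_group_swap_antisymmetry(toy_matrix_4v4):
    a = s0_permutation_test(toy_matrix_4v4, TestConfig(), control="ctrl", treated="trt")
    b = s0_permutation_test(toy_matrix_4v4, TestConfig(), control="trt", treated="ctrl")
    assert np.allclose(a.table["d_stat"], -b.table["d_stat"], atol=1e-12)
    assert np.allclose(a.table["log2_diff"], -b.table["log2_diff"], atol=1e-12)
    assert np.allclose(a.table["q_value"], b.table["q_value"], atol=1e-12)


def test_constant_matrix_is_an_error():
    with pytest.raises(ValueError, match="constant"):
        s0_permutation_test(_matrix_from_array(np.full((5, 8), 3.0)), TestConfig())


def test_power_on_large_planted_effects():
    """|log2fc| = 2 effects at 0.25 noise in a 4v4 design are nearly all found."""
    from stresstox.config import PipelineConfig
    from stresstox.pipeline import differential_abundance
    from stresstox.synthetic_data import SimConfig, direct_ground_truth, generate_lfq_experiment

    truth = direct_ground_truth(500, de_fraction=0.2, effect_log2fc=2.0, seed=9)
    cfg = SimConfig(n_proteins=500, noise_sd=0.25, seed=9)
    matrix, truth = generate_lfq_experiment(cfg, ground_truth=truth)
    _, res = differential_abundance(matrix, PipelineConfig())
    tl = truth.true_log2fc.reindex(res.table.index)
    flagged = res.table.loc[tl.abs() == 2.0, "significant"]
    assert flagged.mean() >= 0.90


# ---------------------------------------------------------------------------
# fold changes / volcano / COG


def test_fold_change_values(toy_matrix_4v4):
    res = compute_fold_changes(s0_permutation_test(toy_matrix_4v4, TestConfig()))
    t = res.table
    assert np.allclose(t["fold_change"], 2.0 ** np.abs(t["log2_diff"]))
    # printed-table worked examples
    assert round(2.0 ** 5.361, 1) == 41.1
    assert round(2.0 ** 5.921, 1) == 60.6


def test_fold_change_unity_for_equal_means():
    half = np.random.default_rng(0).normal(25, 2, (5, 4))
    res = compute_fold_changes(
        s0_permutation_test(_matrix_from_array(np.hstack([half, half])), TestConfig())
    )
    assert np.allclose(res.table["fold_change"], 1.0)


def test_volcano_table_consistency(toy_matrix_4v4):
    res = s0_permutation_test(toy_matrix_4v4, TestConfig())
    v = volcano_table(res)
    assert len(v) == len(res.table)
    assert (v["significant"] == res.table["significant"]).all()
    res.table.loc[res.table["p_perm"] == 1.0, "p_perm"]  # p=1 -> 0 on -log10
    assert np.all(v.loc[res.table["p_perm"] == 1.0, "neg_log10_p"] == 0.0)


def test_cog_summary_buckets(toy_matrix_4v4):
    res = s0_permutation_test(toy_matrix_4v4, TestConfig())
    sig = res.table[res.table["significant"]]
    n_up = int((sig["log2_diff"] >= 0).sum())
    n_down = int((sig["log2_diff"] < 0).sum())
    assert len(sig) > 0  # the fixture plants real effects
    # no annotation at all -> everything lands in the unassigned bucket
    summary = cog_summary(res, annotation=None)
    assert summary.loc["unassigned", "n_up"] == n_up
    assert summary.loc["unassigned", "n_down"] == n_down
    # counts are conserved under any annotation
    ann = {pid: "C" for pid in list(sig.index)[:2]}
    s2 = cog_summary(res, ann)
    assert s2["n_up"].sum() == n_up and s2["n_down"].sum() == n_down


def test_cog_summary_empty_when_nothing_significant():
    half = np.random.default_rng(1).normal(25, 2, (5, 4))
    res = s0_permutation_test(_matrix_from_array(np.hstack([half, half])), TestConfig())
    assert cog_summary(res, {}).empty
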