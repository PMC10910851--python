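"""Tests of normalization, filtering, QC, and the NB Wald DEG caller."""

import numpy as np
import pandas as pd
import pytest

from mutexpr import expression as xp

from conftest import make_count_matrix


# -- size factors -----------------------------------------------------------


def test_size_factors_identical_samples_are_one():
    df = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2]}, index=["a", "b", "c"])
    f = xp.size_factors(df)
    assert np.allclose(f, [1.0, 1.0])


def test_size_factors_hand_calculation():
    # geomeans (sqrt(12), sqrt(48)); ratios (0.577.., 1.732..) in both genes
    df = pd.DataFrame({"s1": [2, 4], "s2": [6, 12]}, index=["g1", "g2"])
    f = xp.size_factors(df)
    assert f["s1"] == pytest.approx(1 / np.sqrt(3), rel=1e-12)
    assert f["s2"] == pytest.approx(np.sqrt(3), rel=1e-12)


def test_size_factors_exclude_genes_with_zeros():
    # g2 has a zero, so factors must come from g1 alone
    df = pd.DataFrame({"s1": [2, 0], "s2": [8, 10]}, index=["g1", "g2"])
    f = xp.size_factors(df)
    geo = np.sqrt(2 * 8)
    assert f["s1"] == pytest.approx(2 / geo)
    assert f["s2"] == pytest.approx(8 / geo)


def test_size_factors_error_without_reference_gene():
    df = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="reference gene"):
        xp.size_factors(df)


def test_size_factors_scale_equivariant():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(1, 200, (30, 4)), columns=list("abcd"))
    f = xp.size_factors(df)
    df2 = df.copy()
    df2["c"] = df2["c"] * 7
    f2 = xp.size_factors(df2)
    # scaling one sample by c rescales every per-gene geometric mean by
    # c^(1/n), so the equivariance holds for factor ratios, not single factors
    assert (f2["c"] / f2["a"]) / (f["c"] / f["a"]) == pytest.approx(7.0, rel=1e-9)


# -- FPKM -------------------------------------------------------------------


def test_fpkm_unit_case():
    df = pd.DataFrame({"s": [100, 999_900]}, index=["g", "rest"])
    lengths = pd.Series({"g": 1000, "rest": 1000})
    out = xp.fpkm(df, lengths)
    assert out.loc["g", "s"] == pytest.approx(100.0)


def test_fpkm_halves_when_library_doubles():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.integers(1, 100, (5, 2)), columns=["s1", "s2"])
    lengths = pd.Series(rng.integers(500, 3000, 5), index=df.index)
    base = xp.fpkm(df, lengths)
    doubled = xp.fpkm(df * 2, lengths)
    # counts double AND the library doubles, so FPKM is unchanged; instead
    # append a filler gene that doubles the library only
    filler = df.sum(axis=0)
    df2 = pd.concat([df, filler.to_frame().T.rename(index={0: "filler"})])
    lengths2 = pd.concat([lengths, pd.Series({"filler": 1000})])
    halved = xp.fpkm(df2, lengths2).loc[df.index]
    assert np.allclose(halved, base / 2)
    assert np.allclose(doubled, base)


def test_fpkm_matches_per_cell_brute_force():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.integers(0, 500, (5, 3)), columns=list("xyz"))
    lengths = pd.Series(rng.integers(200, 5000, 5), index=df.index)
    out = xp.fpkm(df, lengths)
    for g in df.index:
        for s in df.columns:
            expect = df.loc[g, s] * 1e9 / (lengths[g] * df[s].sum())
            assert out.loc[g, s] == pytest.approx(expect, rel=1e-12)


def test_fpkm_zero_library_errors():
    df = pd.DataFrame({"s": [0, 0]})
    with pytest.raises(ValueError, match="library"):
        xp.fpkm(df, pd.Series([100, 100], index=df.index))


# -- filtering --------------------------------------------------------------


def _random_cm(n_genes=100, seed=3):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 400, (n_genes, 6))
    return make_count_matrix(counts, n_anc=3, n_line=3)


def test_filter_target_one_is_identity():
    cm = _random_cm()
    out = xp.filter_low_counts(cm, target_retained=1.0)
    assert out is cm


def test_filter_drops_lowest_ranked_genes():
    cm = _random_cm(100)
    out = xp.filter_low_counts(cm, target_retained=0.95)
    assert len(out.counts) == 95
    # sort oracle: the dropped genes have the smallest filter statistic
    norm = xp.normalized_counts(cm)
    stat = norm.mean(axis=1)  # single strain: strain mean == overall mean
    dropped = set(cm.counts.index) - set(out.counts.index)
    kept_min = stat[out.counts.index].min()
    assert all(stat[g] <= kept_min for g in dropped)


def test_filter_always_drops_all_zero_gene():
    rng = np.random.default_rng(4)
    counts = rng.integers(1, 100, (20, 6))
    counts[7] = 0
    cm = make_count_matrix(counts, 3, 3)
    out = xp.filter_low_counts(cm, target_retained=0.9)
    assert "g7" not in out.counts.index


def test_filter_rejects_bad_fraction():
    with pytest.raises(ValueError):
        xp.filter_low_counts(_random_cm(), target_retained=0.0)


# -- replicate QC -----------------------------------------------------------


def test_replicate_qc_identical_replicates_pass():
    rng = np.random.default_rng(5)
    base = rng.lognormal(3, 1, 30)
    fpkm_table = pd.DataFrame({"a_r1": base, "a_r2": base})
    meta = pd.DataFrame({"sample_id": ["a_r1", "a_r2"], "line_id": ["a", "a"]})
    out = xp.replicate_qc(fpkm_table, meta)
    assert np.allclose(out["mean_r"], 1.0)
    assert not out["flagged"].any()


def test_replicate_qc_negated_replicate_flagged():
    rng = np.random.default_rng(6)
    base = rng.normal(10, 2, 30)
    mirrored = 2 * base.mean() - base  # r = -1 with the original
    fpkm_table = pd.DataFrame({"a_r1": base, "a_r2": mirrored})
    meta = pd.DataFrame({"sample_id": ["a_r1", "a_r2"], "line_id": ["a", "a"]})
    out = xp.replicate_qc(fpkm_table, meta)
    assert np.allclose(out["mean_r"], -1.0)
    assert out["flagged"].all()


def test_replicate_qc_mean_correlation_matches_direct_formula():
    rng = np.random.default_rng(7)
    cols = {f"a_r{i+1}": rng.lognormal(3, 1, 25) for i in range(3)}
    fpkm_table = pd.DataFrame(cols)
    meta = pd.DataFrame({"sample_id": list(cols), "line_id": "a"})
    out = xp.replicate_qc(fpkm_table, meta).set_index("sample_id")
    for i, sid in enumerate(cols):
        rs = [
            np.corrcoef(fpkm_table[sid], fpkm_table[other])[0, 1]
            for other in cols if other != sid
        ]
        assert out.loc[sid, "mean_r"] == pytest.approx(np.mean(rs), rel=1e-12)


def test_replicate_qc_constant_replicate_flagged_with_reason():
    fpkm_table = pd.DataFrame({"a_r1": [1.0, 1.0, 1.0], "a_r2": [1.0, 2.0, 3.0]})
    meta = pd.DataFrame({"sample_id": ["a_r1", "a_r2"], "line_id": ["a", "a"]})
    out = xp.replicate_qc(fpkm_table, meta).set_index("sample_id")
    assert out.loc["a_r1", "flagged"]
    assert "undefined" in out.loc["a_r1", "reason"]


# -- BH ---------------------------------------------------------------------


def test_bh_step_up_hand_case():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(xp.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(8)
    p = rng.random(40)
    out = xp.bh_adjust(p)
    # brute-force step-up oracle
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    assert np.allclose(out, adj)
    # monotone in rank order, never below the raw p
    assert np.all(out >= p - 1e-15)
    assert np.all(np.diff(out[order]) >= -1e-15)


# -- DEG caller -------------------------------------------------------------


def _effect_experiment(seed, n_genes=1000, n_true=50, effect_l2=2.0):
    """Counts with known DEGs: NB-style noise via a log-normal perturbation."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(4.5, 1.2, n_genes)
    sf = rng.uniform(0.7, 1.4, 6)
    delta = np.zeros(n_genes)
    true_idx = rng.choice(n_genes, n_true, replace=False)
    delta[true_idx] = rng.choice([-effect_l2, effect_l2], n_true) * np.log(2)
    lam = np.empty((n_genes, 6))
    for s in range(6):
        shift = delta if s >= 3 else 0.0
        lam[:, s] = sf[s] * mu * np.exp(shift + rng.normal(0, 0.2, n_genes))
    counts = rng.poisson(lam)
    return make_count_matrix(counts, 3, 3), {f"g{i}" for i in true_idx}


def test_call_degs_identical_counts_yield_no_degs():
    rng = np.random.default_rng(9)
    col = rng.integers(5, 500, 200)
    counts = np.tile(col[:, None], (1, 6))
    cm = make_count_matrix(counts, 3, 3)
    out = xp.call_degs(cm, "S1_L1", target_retained=1.0)
    assert np.allclose(out["log2fc"], 0.0)
    assert not out["significant"].any()


def test_call_degs_recall_and_fdr_on_planted_effects():
    recalls, fdrs = [], []
    for seed in range(20):
        cm, true_set = _effect_experiment(seed)
        out = xp.call_degs(cm, "S1_L1", target_retained=1.0)
        called = set(out.loc[out["significant"], "gene_id"])
        tp = len(called & true_set)
        recalls.append(tp / len(true_set))
        fdrs.append((len(called) - tp) / max(len(called), 1))
    assert np.mean(recalls) >= 0.8
    assert np.mean(fdrs) <= 0.1


def test_call_degs_global_null_fdr_consistent():
    from scipy import stats

    n_sig = 0
    n_tests = 0
    for seed in range(50):
        cm, _ = _effect_experiment(1000 + seed, n_genes=300, n_true=0)
        out = xp.call_degs(cm, "S1_L1", target_retained=1.0)
        n_sig += int(out["significant"].sum())
        n_tests += len(out)
    # the fraction of significant genes must be consistent with <= 5%
    assert stats.binomtest(n_sig, n_tests, 0.05, alternative="greater").pvalue > 0.01


def test_call_degs_requires_replicates():
    rng = np.random.default_rng(10)
    cm = make_count_matrix(rng.integers(1, 50, (10, 4)), 3, 1)
    with pytest.raises(ValueError, match="replicates"):
        xp.call_degs(cm, "S1_L1")


def test_deg_record_invariants(small_experiment):
    _, _, _, cm = small_experiment
    line = cm.ma_line_ids[0]
    out = xp.call_degs(cm, line)
    assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
    assert (out["p_adj"] >= out["p"] - 1e-15).all()
    assert (out["significant"] == (out["p_adj"] < 0.05)).all()
    assert set(out["direction"]) <= {"up", "down"}
    assert list(out.columns) == xp.DEG_COLUMNS


# -- directional sums -------------------------------------------------------


def _deg_table(rows):
    return pd.DataFrame(rows, columns=["line_id", "gene_id", "log2fc",
                                       "significant"])


def test_directional_sums_no_significant_degs():
    degs = _deg_table([("L1", "g1", 2.0, False)])
    out = xp.directional_change_sums(degs).iloc[0]
    assert out["sum_up"] == 0.0 and out["sum_down"] == 0.0
    assert out["n_degs"] == 0


def test_directional_sums_arithmetic():
    degs = _deg_table(
        [("L1", "g1", 1.0, True), ("L1", "g2", 2.0, True),
         ("L1", "g3", -0.5, True)]
    )
    out = xp.directional_change_sums(degs).iloc[0]
    assert out["sum_up"] == pytest.approx(3.0)
    assert out["sum_down"] == pytest.approx(-0.5)
    assert out["n_degs"] == 3
    assert out["sum_abs_log2fc"] == pytest.approx(3.5)


def test_directional_sums_match_filter_and_sum_oracle():
    rng = np.random.default_rng(11)
    rows = [
        (f"L{rng.integers(1, 4)}", f"g{i}", float(rng.normal()), bool(rng.random() < 0.5))
        for i in range(200)
    ]
    degs = _deg_table(rows)
    out = xp.directional_change_sums(degs).set_index("line_id")
    for line, grp in degs.groupby("line_id"):
        sig = grp[grp["significant"]]["log2fc"]
        assert out.loc[line, "sum_up"] == pytest.approx(sig[sig > 0].sum())
        assert out.loc[line, "sum_down"] == pytest.approx(sig[sig < 0].sum())
        assert out.loc[line, "n_degs"] == len(sig)


# -- CountMatrix invariants -------------------------------------------------


def test_count_matrix_rejects_mismatched_meta():
    counts = pd.DataFrame({"s1": [1], "s2": [2]})
    meta = pd.DataFrame(
        {"sample_id": ["s2", "s1"], "strain": "S", "line_id": "L",
         "replicate": [1, 2], "is_ancestor": [True, False],
         "generations": 0, "n_mutations": 0}
    )
    with pytest.raises(ValueError, match="match"):
        xp.CountMatrix(counts, meta)


def test_count_matrix_requires_ancestor_per_strain():
    counts = pd.DataFrame({"s1": [1], "s2": [2]})
    meta = pd.DataFrame(
        {"sample_id": ["s1", "s2"], "strain": "S", "line_id": "L",
         "replicate": [1, 2], "is_ancestor": [False, False],
         "generations": 100, "n_mutations": 5}
    )
    with pytest.raises(ValueError, match="ancestor"):
        xp.CountMatrix(counts, meta)
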