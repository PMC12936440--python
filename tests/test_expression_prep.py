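"""Normalisation, batch correction, DE testing and DEG-set filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from budnet import expression_prep as ep
from budnet.containers import ExpressionMatrix
from budnet.synthetic_data import SimulationConfig, simulate_expression


# ------------------------------------------------------------- TMM oracle
def tmm_oracle(counts: pd.DataFrame, trim_m=0.3, trim_a=0.05) -> pd.Series:
    """Independent trimmed-mean-of-M-values computation, written from the
    definition with explicit loops and list sorting."""
    lib = counts.sum(axis=0)
    f75 = {}
    for s in counts.columns:
        pos = counts[s][counts[s] > 0]
        f75[s] = np.quantile(pos / lib[s], 0.75)
    mean75 = np.mean(list(f75.values()))
    ref = min(counts.columns, key=lambda s: abs(f75[s] - mean75))
    logf = {}
    for s in counts.columns:
        if s == ref:
            logf[s] = 0.0
            continue
        entries = []
        for g in counts.index:
            o, r = counts.loc[g, s], counts.loc[g, ref]
            if o > 0 and r > 0:
                m = np.log2((o / lib[s]) / (r / lib[ref]))
                a = 0.5 * np.log2((o / lib[s]) * (r / lib[ref]))
                w = (lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r)
                entries.append((m, a, w))
        n = len(entries)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = stats.rankdata([e[0] for e in entries])
        rank_a = stats.rankdata([e[1] for e in entries])
        num = den = 0.0
        for (m, a, w), rm, ra in zip(entries, rank_m, rank_a):
            if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
                num += m / w
                den += 1.0 / w
        logf[s] = num / den if den > 0 else 0.0
    vals = pd.Series(logf)[counts.columns]
    vals -= vals.mean()
    return 2.0**vals


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        np.testing.assert_allclose(ep.tmm_factors(counts).to_numpy(), [1.0, 1.0])

    def test_pure_depth_difference_is_absorbed(self):
        a = pd.Series([100, 250, 30, 5000, 60])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(ep.tmm_factors(counts).to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_composition_bias_toy_matches_oracle(self):
        # one highly expressed gene unique to sample b distorts b's composition
        counts = pd.DataFrame(
            {"a": [100, 200, 300, 1], "b": [100, 200, 300, 5000]},
            index=["g1", "g2", "g3", "g4"],
        )
        ours = ep.tmm_factors(counts)
        oracle = tmm_oracle(counts)
        np.testing.assert_allclose(ours.to_numpy(), oracle.to_numpy(), atol=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_matrices_match_oracle_and_geomean_is_one(self, seed):
        g = np.random.default_rng(seed)
        counts = pd.DataFrame(
            g.negative_binomial(5, 0.05, size=(30, 4)) + 1,
            columns=list("abcd"),
        )
        ours = ep.tmm_factors(counts)
        np.testing.assert_allclose(ours.to_numpy(), tmm_oracle(counts).to_numpy(), atol=1e-10)
        assert np.exp(np.log(ours).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            ep.tmm_factors(counts)


class TestLogCPM:
    def test_zero_count_gives_log2_pseudocount(self):
        counts = pd.DataFrame({"a": [0, 1000], "b": [0, 1000]})
        logm = ep.normalize_log_cpm(counts, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert logm.values.iloc[0, 0] == pytest.approx(np.log2(1.0))

    def test_depth_invariance(self):
        g = np.random.default_rng(1)
        counts = pd.DataFrame(g.poisson(50, size=(20, 3)), columns=list("abc"))
        ones = pd.Series(1.0, index=counts.columns)
        a = ep.normalize_log_cpm(counts, ones).values
        b = ep.normalize_log_cpm(counts * 2, ones).values
        pd.testing.assert_frame_equal(a, b)

    def test_two_by_two_hand_computation(self):
        counts = pd.DataFrame({"a": [90, 10], "b": [50, 50]})
        ones = pd.Series(1.0, index=["a", "b"])
        logm = ep.normalize_log_cpm(counts, ones).values
        # sample a: lib 100 -> gene1 cpm = 90/100*1e6 = 9e5
        assert logm.loc[0, "a"] == pytest.approx(np.log2(9e5 + 1))
        assert logm.loc[1, "b"] == pytest.approx(np.log2(5e5 + 1))

    def test_layer_tag_enforced(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        m = ExpressionMatrix(values=counts, layer="counts")
        logm = ep.normalize_log_cpm(m, pd.Series(1.0, index=["a", "b"]))
        assert logm.layer == "log2"
        with pytest.raises(ValueError, match="counts layer"):
            ep.normalize_log_cpm(logm, pd.Series(1.0, index=["a", "b"]))


class TestBatchCorrection:
    @staticmethod
    def _design(n_genes=60, batch_sd=1.0, seed=0):
        cfg = SimulationConfig(
            n_genes=n_genes, n_replicates=4, batch_effect_sd=batch_sd,
            noise_dispersion=0.02, seed=seed,
        )
        m, _ = simulate_expression(cfg)
        return ep.normalize_log_cpm(m)

    @staticmethod
    def _batch_r2(frame, meta):
        """Share of within-group residual variance explained by batch."""
        group = meta["organ"].astype(str) + ":" + meta["timepoint"].astype(str)
        x = frame.to_numpy()
        resid = np.zeros_like(x)
        for g in group.unique():
            cols = (group == g).to_numpy()
            resid[:, cols] = x[:, cols] - x[:, cols].mean(axis=1, keepdims=True)
        b = (meta["batch"] == "B").to_numpy(dtype=float)
        b = b - b.mean()
        coef = resid @ b / (b @ b)
        explained = np.outer(coef, b)
        return float((explained**2).sum() / (resid**2).sum())

    def test_single_batch_is_identity(self):
        logm = self._design(batch_sd=0.0)
        meta = logm.sample_meta.copy()
        meta["batch"] = "A"
        single = ExpressionMatrix(values=logm.values, layer="log2", sample_meta=meta)
        out = ep.correct_batch(single)
        pd.testing.assert_frame_equal(out.values, logm.values)

    def test_planted_batch_structure_is_removed(self):
        logm = self._design(batch_sd=1.0)
        before = self._batch_r2(logm.values, logm.sample_meta)
        out = ep.correct_batch(logm, n_components=3)
        after = self._batch_r2(out.values, out.sample_meta)
        assert before > 0.5
        assert after < 0.05

    def test_group_means_preserved(self):
        logm = self._design(batch_sd=1.0)
        out = ep.correct_batch(logm, n_components=3)
        meta = logm.sample_meta
        group = meta["organ"].astype(str) + ":" + meta["timepoint"].astype(str)
        for g in group.unique():
            cols = meta.index[group == g]
            np.testing.assert_allclose(
                out.values[cols].mean(axis=1), logm.values[cols].mean(axis=1), atol=1e-8
            )

    def test_zero_variance_gene_untouched(self):
        logm = self._design(batch_sd=1.0)
        vals = logm.values.copy()
        vals.iloc[0, :] = 3.0
        flat = ExpressionMatrix(values=vals, layer="log2", sample_meta=logm.sample_meta)
        out = ep.correct_batch(flat, n_components=3)
        np.testing.assert_allclose(out.values.iloc[0, :], 3.0, atol=1e-10)


class TestDifferentialExpression:
    def test_constant_gene_has_p_one(self):
        frame = pd.DataFrame([[5.0] * 6], index=["flat"], columns=[f"s{i}" for i in range(6)])
        recs = ep.test_de(frame, timepoints=[0, 0, 0, 1, 1, 1])
        assert (recs["p_value"] == 1.0).all()

    def test_planted_twofold_step_recovers_log2fc_one(self):
        frame = pd.DataFrame(
            [[2.0, 2.0, 2.0, 3.0, 3.0, 3.0]], index=["g"], columns=[f"s{i}" for i in range(6)]
        )
        recs = ep.test_de(frame, timepoints=[0, 0, 0, 1, 1, 1])
        assert recs["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_f_statistic_matches_hand_anova(self):
        # 3 vs 3 one-way ANOVA computed from sums of squares by hand
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        grand = np.mean(a + b)
        ss_between = 3 * (np.mean(a) - grand) ** 2 + 3 * (np.mean(b) - grand) ** 2
        ss_within = sum((x - np.mean(a)) ** 2 for x in a) + sum((x - np.mean(b)) ** 2 for x in b)
        f_hand = (ss_between / 1) / (ss_within / 4)
        p_hand = float(stats.f.sf(f_hand, 1, 4))
        frame = pd.DataFrame([a + b], index=["g"], columns=[f"s{i}" for i in range(6)])
        recs = ep.test_de(frame, timepoints=[0, 0, 0, 1, 1, 1])
        assert recs["p_value"].iloc[0] == pytest.approx(p_hand, rel=1e-10)

    def test_single_replicate_timepoint_excluded_with_warning(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 9.0]], index=["g"], columns=[f"s{i}" for i in range(5)]
        )
        with pytest.warns(UserWarning, match="single replicate"):
            recs = ep.test_de(frame, timepoints=[0, 0, 1, 1, 2])
        assert set(recs["contrast"]) == {"1_vs_0"}


class TestBHAdjustment:
    def test_single_p_unchanged(self):
        assert ep.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        out = ep.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        out = ep.bh_adjust(np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(out, 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ep.bh_adjust(np.array([0.1, np.nan]))


def _records(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "p_value", "fdr"])


class TestDEGFilter:
    def test_boundary_fold_change_retained(self):
        recs = _records([("g", "1_vs_0", np.log2(1.4), 0.001, 0.001)])
        assert ep.filter_deg(recs, fc_min=1.4, fdr_max=0.05) == {"g"}

    def test_high_fdr_excluded(self):
        recs = _records([("g", "1_vs_0", 1.0, 0.1, 0.2)])
        assert ep.filter_deg(recs, fc_min=1.4, fdr_max=0.05) == set()

    def test_five_gene_toy_matches_brute_force(self):
        g = np.random.default_rng(2)
        rows = []
        for gene in "abcde":
            for c in ("1_vs_0", "2_vs_0"):
                rows.append((gene, c, g.normal(0, 1), 0.0, g.uniform(0, 0.1)))
        recs = _records(rows)
        expected = set()
        for gene in "abcde":
            sub = recs[recs["gene_id"] == gene]
            if sub["log2fc"].abs().max() >= np.log2(1.4) and sub["fdr"].min() <= 0.05:
                expected.add(gene)
        assert ep.filter_deg(recs, 1.4, 0.05) == expected

    def test_monotone_in_both_thresholds(self):
        g = np.random.default_rng(3)
        rows = [
            (f"g{i}", "1_vs_0", g.normal(0, 1.5), 0.0, g.uniform(0, 0.2)) for i in range(40)
        ]
        recs = _records(rows)
        prev = None
        for fc in (1.0, 1.4, 1.5, 2.0):
            cur = ep.filter_deg(recs, fc, 0.05)
            if prev is not None:
                assert cur <= prev
            prev = cur
        prev = None
        for fdr in (0.2, 0.05, 0.01):
            cur = ep.filter_deg(recs, 1.4, fdr)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_fc_below_one_rejected(self):
        with pytest.raises(ValueError):
            ep.filter_deg(_records([]), fc_min=0.5)


class TestVennPartition:
    def test_identical_sets(self):
        assert ep.venn_partition({1, 2}, {1, 2}) == {"shared": 2, "unique_a": 0, "unique_b": 0}

    def test_disjoint_sets(self):
        assert ep.venn_partition({1}, {2, 3}) == {"shared": 0, "unique_a": 1, "unique_b": 2}

    def test_published_deg_arithmetic(self):
        # sets sized like the reported DEG overlap: 5913 shared, 2969 and
        # 2726 unique; totals must come out 8882 and 8639
        shared = {f"s{i}" for i in range(5913)}
        a = shared | {f"a{i}" for i in range(2969)}
        b = shared | {f"b{i}" for i in range(2726)}
        part = ep.venn_partition(a, b)
        assert part == {"shared": 5913, "unique_a": 2969, "unique_b": 2726}
        assert part["shared"] + part["unique_a"] == 8882
        assert part["shared"] + part["unique_b"] == 8639
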