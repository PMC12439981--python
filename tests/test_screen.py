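"""Screen statistics: normalization, dispersion, NB testing, hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histkit import screen as scr
from histkit.screen import (
    DomainAnnotation,
    H4_DOMAINS,
    ScreenCountTable,
    bh_adjust,
    call_hits,
    call_role_switchers,
    control_size_factors,
    count_exact_matches,
    estimate_dispersion,
    positional_enrichment,
    replicate_concordance,
)
from histkit.variants import SubstitutionVariant

from conftest import make_table


def nb_counts(rng, mean, phi, size):
    if phi <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestCountExactMatches:
    barcode_map = {"AAAA": "s1", "CCCC": "s2"}
    library = {"c7": "GGGGTTTT", "c8": "GGGGTTTA"}

    def test_exact_read_counts_once(self):
        table, discards = count_exact_matches(
            ["AAAA" + "GGGGTTTT"], self.barcode_map, self.library
        )
        assert table.counts.loc["c7", "s1"] == 1
        assert table.counts.to_numpy().sum() == 1
        assert sum(discards.values()) == 0

    def test_single_substitution_discarded(self):
        table, discards = count_exact_matches(
            ["AAAA" + "GGGGTTTC"], self.barcode_map, self.library
        )
        assert table.counts.to_numpy().sum() == 0
        assert discards["unmatched_insert"] == 1

    def test_unknown_barcode_discarded(self):
        _, discards = count_exact_matches(
            ["TTTT" + "GGGGTTTT"], self.barcode_map, self.library
        )
        assert discards["undemultiplexed"] == 1

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            count_exact_matches([], {"AAAA": "s1", "AAAT": "s1"}, self.library)


class TestSizeFactors:
    def test_identical_controls_give_equal_factors(self):
        counts = pd.DataFrame(
            {"a": [50, 80, 10], "b": [50, 80, 12]}, index=["g1", "g2", "x"]
        )
        t = make_table(counts, ["high_bin", "low_bin"], controls=["g1", "g2"])
        f = control_size_factors(t)
        assert f["a"] == pytest.approx(f["b"])

    def test_hand_computed_twofold_ratio(self):
        # controls (100, 200) and (400, 800): sample b is exactly 2x sample a
        counts = pd.DataFrame({"a": [100, 400, 7], "b": [200, 800, 9]},
                              index=["g1", "g2", "x"])
        t = make_table(counts, ["high_bin", "low_bin"], controls=["g1", "g2"])
        f = control_size_factors(t)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_single_control_row_degenerate_median(self):
        counts = pd.DataFrame({"a": [100, 5], "b": [300, 5]}, index=["g1", "x"])
        t = make_table(counts, ["high_bin", "low_bin"], controls=["g1"])
        f = control_size_factors(t)
        assert f["b"] / f["a"] == pytest.approx(3.0)

    def test_all_zero_controls_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 5]}, index=["g1", "x"])
        t = make_table(counts, ["high_bin", "low_bin"], controls=["g1"])
        with pytest.raises(ValueError):
            control_size_factors(t)


class TestDispersion:
    def _table(self, counts):
        df = pd.DataFrame(
            counts, columns=["r1_h", "r2_h", "r1_l", "r2_l"],
            index=[f"g{i}" for i in range(counts.shape[0])],
        )
        return make_table(df, ["high_bin", "high_bin", "low_bin", "low_bin"],
                          replicates=[1, 2, 1, 2])

    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(0)
        mean = rng.uniform(120, 2000, size=500)
        counts = rng.poisson(mean[:, None], size=(500, 4))
        t = self._table(counts)
        alpha = estimate_dispersion(t, pd.Series(1.0, index=t.counts.columns))
        assert np.median(alpha) < 0.01

    def test_planted_dispersion_recovered_within_twofold(self):
        rng = np.random.default_rng(1)
        mean = rng.uniform(200, 2000, size=500)
        counts = nb_counts(rng, mean[:, None], 0.1, (500, 4))
        t = self._table(counts)
        alpha = estimate_dispersion(t, pd.Series(1.0, index=t.counts.columns))
        assert 0.05 <= np.median(alpha) <= 0.2

    def test_constant_counts_hit_lower_clip(self):
        counts = np.full((20, 4), 500)
        t = self._table(counts)
        alpha = estimate_dispersion(t, pd.Series(1.0, index=t.counts.columns))
        assert np.allclose(alpha, 1e-8, atol=1e-9)

    def test_single_replicate_condition_rejected(self):
        counts = pd.DataFrame({"a": [5], "b": [5], "c": [5]}, index=["g"])
        t = make_table(counts, ["high_bin", "low_bin", "low_bin"])
        with pytest.raises(ValueError):
            estimate_dispersion(t, pd.Series(1.0, index=t.counts.columns))


class TestBHAdjust:
    def test_spec_examples(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        # independent brute-force BH: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        m = len(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            brute[i] = running
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)


class TestEnrichmentTest:
    def test_identical_normalized_counts_are_null(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(500, size=30)
        counts = pd.DataFrame(
            {"a": base, "b": base, "c": base, "d": base},
            index=[f"g{i}" for i in range(30)],
        )
        t = make_table(counts, ["high_bin", "high_bin", "low_bin", "low_bin"],
                       replicates=[1, 2, 1, 2], controls=["g0", "g1"])
        res = scr.test_enrichment(t)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.999).all()

    def test_antisymmetry_under_label_swap(self, small_nb_table):
        t, _ = small_nb_table
        res = scr.test_enrichment(t, contrast=("high_bin", "low_bin"))
        rev = scr.test_enrichment(t, contrast=("low_bin", "high_bin"))
        np.testing.assert_allclose(res["log2fc"], -rev["log2fc"], atol=1e-9)
        np.testing.assert_allclose(res["pvalue"], rev["pvalue"], atol=1e-12)

    def test_scale_equivariance(self, small_nb_table):
        t, _ = small_nb_table
        res = scr.test_enrichment(t)
        f = control_size_factors(t)
        scaled_counts = t.counts.copy()
        scaled_counts["r1_high"] = scaled_counts["r1_high"] * 3
        t2 = ScreenCountTable(scaled_counts, t.sample_meta, t.control_ids)
        f2 = control_size_factors(t2)
        # the scaled sample's factor grows; normalized counts change uniformly
        assert (f2 / f)["r1_high"] > (f2 / f)["r2_high"]
        res2 = scr.test_enrichment(t2)
        np.testing.assert_allclose(res["log2fc"], res2["log2fc"], atol=1e-9)
        # p-values are asymptotically, not exactly, invariant to depth rescaling
        np.testing.assert_allclose(res["pvalue"], res2["pvalue"], rtol=0.2, atol=1e-3)

    def test_planted_effects_recovered_with_direction(self, small_nb_table):
        t, lfc = small_nb_table
        res = scr.test_enrichment(t)
        hits = call_hits(res, alpha=0.05)
        planted_up = {f"c{i:02d}" for i in range(6) if lfc[i] > 0}
        planted_down = {f"c{i:02d}" for i in range(6) if lfc[i] < 0}
        assert planted_up <= hits["enriched"]
        assert planted_down <= hits["depleted"]

    def test_agrees_with_deseq2_reference(self):
        """Independent cross-check against the DESeq2 implementation."""
        import contextlib, io

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(21)
        n = 60
        mu = rng.lognormal(5.5, 0.7, n)
        lfc = np.zeros(n)
        lfc[:8] = rng.normal(0, 2.5, 8)
        cols, conds = {}, []
        for name, cond in [("r1_h", "high_bin"), ("r2_h", "high_bin"),
                           ("r1_l", "low_bin"), ("r2_l", "low_bin")]:
            m = mu * np.where(cond == "high_bin", 2.0**lfc, 1.0)
            cols[name] = nb_counts(rng, m, 0.05, n)
            conds.append(cond)
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        t = make_table(counts, conds, replicates=[1, 2, 1, 2])
        with pytest.warns(UserWarning):
            ours = scr.test_enrichment(t)  # no controls: all-row size factors

        meta = pd.DataFrame({"condition": conds}, index=counts.columns)
        with contextlib.redirect_stdout(io.StringIO()):
            dds = DeseqDataSet(counts=counts.T, metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "high_bin", "low_bin"],
                            quiet=True)
            ds.summary()
        ref = ds.results_df
        r = np.corrcoef(ours["log2fc"], ref["log2FoldChange"])[0, 1]
        assert r > 0.95
        strong = np.abs(lfc) > 1
        assert np.all(np.sign(ours["log2fc"][strong]) == np.sign(ref["log2FoldChange"][strong]))


class TestHitCalling:
    def _result(self, padj, lfc):
        return pd.DataFrame(
            {"padj": padj, "log2fc": lfc, "is_control": False},
            index=[f"g{i}" for i in range(len(padj))],
        )

    def test_empty_result(self):
        hits = call_hits(self._result([], []))
        assert hits == {"enriched": set(), "depleted": set()}

    def test_threshold_is_strict(self):
        hits = call_hits(self._result([0.05], [1.0]), alpha=0.05)
        assert hits["enriched"] == set()

    def test_direction_partition(self):
        hits = call_hits(self._result([0.01, 0.2], [-1.0, 2.0]))
        assert hits == {"enriched": set(), "depleted": {"g0"}}


class TestConcordance:
    def _res(self, lfc):
        return pd.DataFrame({"log2fc": lfc}, index=[f"g{i}" for i in range(len(lfc))])

    def test_identical_replicates(self):
        a = self._res(np.arange(10, dtype=float))
        c = replicate_concordance(a, a)
        assert c.r2 == pytest.approx(1.0) and c.r == pytest.approx(1.0)

    def test_sign_blindness_reports_signed_r(self):
        a = self._res(np.arange(10, dtype=float))
        b = self._res(-np.arange(10, dtype=float))
        c = replicate_concordance(a, b)
        assert c.r2 == pytest.approx(1.0) and c.r == pytest.approx(-1.0)

    def test_independent_replicates_near_zero(self):
        rng = np.random.default_rng(0)
        c = replicate_concordance(
            self._res(rng.standard_normal(1000)), self._res(rng.standard_normal(1000))
        )
        assert c.r2 < 0.02

    def test_too_few_shared_constructs(self):
        with pytest.raises(ValueError):
            replicate_concordance(self._res([1.0, 2.0]), self._res([1.0, 2.0]))


class TestRoleSwitchers:
    def _res(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2fc": lfc}, index=["g0"])

    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [
            (((0.01,), (0.01,)), ((-1.0,), (1.0,)), "switcher"),
            (((0.5,), (0.5,)), ((-1.0,), (1.0,)), "not_significant"),
            (((0.01,), (0.3,)), ((1.0,), (2.0,)), "stable_hit"),
        ],
    )
    def test_caption_rule(self, padj, lfc, expected):
        calls = call_role_switchers(
            self._res(padj[0], lfc[0]), self._res(padj[1], lfc[1])
        )
        assert calls.loc["g0", "status"] == expected

    def test_ranked_by_fc_change(self):
        a = pd.DataFrame({"padj": [0.01, 0.01], "log2fc": [0.0, 0.0]}, index=["g0", "g1"])
        b = pd.DataFrame({"padj": [0.01, 0.01], "log2fc": [1.0, 3.0]}, index=["g0", "g1"])
        calls = call_role_switchers(a, b)
        assert list(calls.index) == ["g1", "g0"]


class TestPositionalEnrichment:
    def test_hand_computed_ratio(self):
        hits = [SubstitutionVariant(p, "G", "D") for p in [2, 5, 9, 12, 20]]
        hits += [SubstitutionVariant(p, "G", "D") for p in [30, 40, 50, 60, 70]]
        df = positional_enrichment(hits, H4_DOMAINS)
        assert df.loc["tail", "density"] == pytest.approx(5 / 25)
        assert df.loc["globular", "density"] == pytest.approx(5 / 77)
        assert df.attrs["ratio"] == pytest.approx((5 / 25) / (5 / 77))
        assert df.attrs["ratio"] == pytest.approx(3.08, abs=0.01)

    def test_no_hits_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            df = positional_enrichment([], H4_DOMAINS)
        assert np.isnan(df.attrs["ratio"])

    def test_all_hits_in_tail_gives_inf(self):
        hits = [SubstitutionVariant(p, "G", "D") for p in [2, 5]]
        df = positional_enrichment(hits, H4_DOMAINS)
        assert np.isinf(df.attrs["ratio"])

    def test_uncovered_position_rejected(self):
        ann = DomainAnnotation({"tail": (1, 5)})
        with pytest.raises(KeyError):
            positional_enrichment([SubstitutionVariant(9, "G", "D")], ann)
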