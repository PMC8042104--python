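"""Zygotic-early identification, intron signal, rank-sum comparisons."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from embryoquant import (
    SampleMeta,
    architecture_compare,
    identify_zygotic_early,
    intron_read_fraction,
    rank_sum_compare,
)
from embryoquant.io import GeneModel, GeneModelSet, ValidationError
from embryoquant.zygotic import _exact_tail_p, _normal_tail_p

SAMPLES = [SampleMeta(f"t{t}h", float(t)) for t in range(1, 7)]


def _detected(rows, genes=None):
    arr = np.asarray(rows, dtype=bool)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[s.sample_id for s in SAMPLES])


class TestIdentifyZygoticEarly:
    @pytest.mark.parametrize(
        "pattern, included",
        [
            ([0, 0, 0, 1, 1, 1], True),
            ([0, 0, 1, 0, 0, 0], True),  # detected at 3 h only (> 2 h)
            ([1, 0, 0, 1, 1, 1], False),  # detected at 1 h
            ([0, 1, 0, 1, 1, 1], False),  # detected at 2 h
            ([0, 0, 0, 0, 0, 0], False),  # never detected
        ],
    )
    def test_detectability_rule(self, pattern, included):
        out = identify_zygotic_early(_detected([pattern]), SAMPLES)
        assert (out == ["g0"]) == included

    def test_requires_early_and_late_samples(self):
        late_only = [SampleMeta("t4h", 4.0), SampleMeta("t5h", 5.0)]
        det = pd.DataFrame([[True, True]], index=["g0"],
                           columns=["t4h", "t5h"])
        with pytest.raises(ValidationError, match="no samples at <= 2"):
            identify_zygotic_early(det, late_only)
        early_only = [SampleMeta("t1h", 1.0), SampleMeta("t2h", 2.0)]
        det2 = pd.DataFrame([[False, False]], index=["g0"], columns=["t1h", "t2h"])
        with pytest.raises(ValidationError, match="after"):
            identify_zygotic_early(det2, early_only)

    def test_invariant_to_subthreshold_magnitude_changes(self, fitted, default_sim):
        """The call depends only on detection, so scaling all counts by a
        constant (which leaves RPG10K untouched) preserves the gene set."""
        from embryoquant import AbsoluteQuantModel, CountMatrix

        base = identify_zygotic_early(fitted.detected, default_sim.counts.samples)
        scaled_counts = CountMatrix(
            default_sim.counts.counts * 3, samples=default_sim.counts.samples
        )
        res2 = AbsoluteQuantModel(scaled_counts, default_sim.spikes).fit()
        again = identify_zygotic_early(res2.detected, scaled_counts.samples)
        assert base == again

    def test_recovers_simulated_zygotic_genes(self, fitted, default_sim):
        zset = set(identify_zygotic_early(fitted.detected, default_sim.counts.samples))
        truth = default_sim.truth.genes
        zyg4 = truth.index[(truth.group == "zygotic") & (truth.onset == 4.0)]
        recall = np.mean([g in zset for g in zyg4])
        assert recall >= 0.9


class TestIntronReadFraction:
    def test_arithmetic_and_degenerate(self):
        ex = pd.DataFrame({"s1": [6, 0]}, index=["a", "b"])
        intr = pd.DataFrame({"s1": [4, 0]}, index=["a", "b"])
        out = intron_read_fraction(ex, intr)
        assert out.loc["a", "intron_fraction"] == pytest.approx(0.4)
        assert np.isnan(out.loc["b", "intron_fraction"])

    def test_pooling_respects_detection(self):
        ex = pd.DataFrame([[10, 100]], index=["a"], columns=["s1", "s2"])
        intr = pd.DataFrame([[0, 100]], index=["a"], columns=["s1", "s2"])
        det = pd.DataFrame([[True, False]], index=["a"], columns=["s1", "s2"])
        out = intron_read_fraction(ex, intr, detected=det)
        assert out.loc["a", "intron_fraction"] == 0.0  # s2 not pooled

    def test_intron_free_gene_flagged_not_applicable(self):
        model = GeneModel("a", "chr1", "+", 1, "a.t1", 100, 1, ((1, 100),), ())
        models = GeneModelSet([model])
        ex = pd.DataFrame({"s1": [5]}, index=["a"])
        intr = pd.DataFrame({"s1": [0]}, index=["a"])
        out = intron_read_fraction(ex, intr, models=models)
        assert not out.loc["a", "applicable"]

    def test_negative_counts_rejected(self):
        ex = pd.DataFrame({"s1": [-1]}, index=["a"])
        with pytest.raises(ValidationError, match="negative"):
            intron_read_fraction(ex, ex.abs())

    def test_zygotic_genes_show_elevated_intron_signal(self, fitted, default_sim):
        truth = default_sim.truth.genes
        total = default_sim.counts.gene_counts()
        intr = default_sim.intron_counts
        out = intron_read_fraction(
            total - intr, intr, detected=fitted.detected, models=default_sim.models
        )
        ok = out["applicable"] & out["intron_fraction"].notna()
        zyg = out.loc[ok & (truth.group == "zygotic"), "intron_fraction"]
        mat = out.loc[ok & (truth.group == "maternal_down"), "intron_fraction"]
        assert zyg.median() > mat.median()


class TestRankSum:
    def test_exact_enumeration_on_separated_groups(self):
        res = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_less == pytest.approx(1 / 20)  # 1 / C(6,3)
        assert res.p_one == pytest.approx(0.05)

    def test_tied_singletons_are_symmetric(self):
        res = rank_sum_compare([5], [5])
        assert res.u == 0.5
        assert res.p_two == pytest.approx(1.0)

    def test_swapping_groups_maps_u_and_preserves_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 6)
        r1 = rank_sum_compare(a, b)
        r2 = rank_sum_compare(b, a)
        assert r2.u == pytest.approx(len(a) * len(b) - r1.u)
        assert r2.p_two == pytest.approx(r1.p_two)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a, b = rng.normal(0, 1, 8), rng.normal(0.3, 1, 9)
            res = rank_sum_compare(a, b)
            sp_less = mannwhitneyu(a, b, alternative="less", method="exact")
            assert res.u == pytest.approx(
                mannwhitneyu(a, b, alternative="two-sided").statistic
            )
            assert res.p_less == pytest.approx(sp_less.pvalue, rel=1e-12)

    def test_exact_and_normal_branches_agree_at_n10(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
            res = rank_sum_compare(a, b)
            assert res.method == "exact"
            pl, pg = _normal_tail_p(res.u, 10, 10, np.concatenate([a, b]))
            approx_two = min(1.0, 2 * min(pl, pg))
            assert approx_two == pytest.approx(res.p_two, rel=0.10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_compare([], [1.0])


class TestArchitectureCompare:
    @staticmethod
    def _models(lengths, exon_counts):
        models = []
        pos = 1
        for gid, (L, E) in enumerate(zip(lengths, exon_counts)):
            exons = tuple((pos + i * (L // E + 10), pos + i * (L // E + 10) + L // E - 1)
                          for i in range(E))
            models.append(
                GeneModel(f"g{gid}", "chr1", "+", exons[0][0], f"g{gid}.t1",
                          sum(e - s + 1 for s, e in exons), E, exons, ())
            )
            pos += L + 1000
        return GeneModelSet(models)

    def test_exact_enumeration_on_two_vs_two(self):
        models = self._models([500, 600, 2000, 3000], [1, 1, 1, 1])
        report = architecture_compare(models, ["g0", "g1"], ["g2", "g3"])
        row = report.loc["length"]
        assert row["median_zygotic"] < row["median_background"]
        assert row["p_less"] == pytest.approx(1 / 6)  # 1 / C(4,2)
        assert row["method"] == "exact"

    def test_identical_sets_give_p_one(self):
        models = self._models([100, 100], [2, 2])
        report = architecture_compare(models, ["g0"], ["g1"])
        assert report.loc["length", "p_two"] == pytest.approx(1.0)

    def test_missing_gene_is_an_error(self):
        models = self._models([100], [1])
        with pytest.raises(ValidationError, match="ghost"):
            architecture_compare(models, ["ghost"], ["g0"])

    def test_fixture_zygotic_genes_are_shorter(self, fitted, default_sim):
        zset = identify_zygotic_early(fitted.detected, default_sim.counts.samples)
        background = [g for g in fitted.detected.index if g not in set(zset)]
        report = architecture_compare(default_sim.models, zset, background)
        assert (
            report.loc["length", "median_zygotic"]
            < report.loc["length", "median_background"]
        )
        assert report.loc["length", "p_less"] < 1e-6
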