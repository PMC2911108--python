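"""Robust cutoffs, G-test, and the multi-experiment hit-calling rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from barseq.hitcall import (
    Experiment,
    HitCallParams,
    call_sensitive,
    g_test,
    gi_cutoffs,
    rank_resistant,
    robust_stats,
)
from barseq.scoring import ExperimentDesign, GIRecord, GITable


class TestRobustStats:
    def test_constant_vector(self):
        rs = robust_stats([0.3, 0.3, 0.3, 0.3])
        assert rs.median == 0.3 and rs.niqr == 0.0

    def test_normal_quartiles_give_unit_niqr(self):
        """On exact standard-normal quantiles NIQR estimates sigma = 1."""
        n = 10001
        values = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert robust_stats(values).niqr == pytest.approx(1.0, abs=1e-3)

    def test_one_to_five_hand_case(self):
        rs = robust_stats([1, 2, 3, 4, 5])
        assert rs.iqr == pytest.approx(2.0)
        assert rs.niqr == pytest.approx(1.4826)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            robust_stats([1.0])


def binomial_lr_oracle(a, b, ta, tb):
    """Independent likelihood-ratio statistic 2 ln(L1/L0) for two binomial
    proportions, via scipy's binomial log-pmf."""
    p1, p2 = a / ta, b / tb
    p0 = (a + b) / (ta + tb)
    l1 = stats.binom.logpmf(a, ta, p1) + stats.binom.logpmf(b, tb, p2)
    l0 = stats.binom.logpmf(a, ta, p0) + stats.binom.logpmf(b, tb, p0)
    return 2.0 * (l1 - l0)


class TestGTest:
    def test_equal_proportions_null(self):
        res = g_test(10, 20, 100, 200)
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_worked_example_50_vs_25_per_million(self):
        res = g_test(50, 25, 10**6, 10**6)
        assert res.g == pytest.approx(8.50, abs=0.01)
        assert res.p == pytest.approx(0.0036, abs=0.0001)

    def test_double_zero_is_null(self):
        res = g_test(0, 0, 1000, 1000)
        assert res.g == 0.0 and res.p == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            g_test(0, 0, 0, 0)

    def test_williams_correction_shrinks_g(self):
        plain = g_test(50, 25, 1000, 1000)
        corrected = g_test(50, 25, 1000, 1000, williams=True)
        assert corrected.g < plain.g

    @given(
        a=st.integers(0, 500),
        b=st.integers(0, 500),
        extra_a=st.integers(1, 500),
        extra_b=st.integers(1, 500),
    )
    def test_matches_binomial_likelihood_ratio(self, a, b, extra_a, extra_b):
        """G equals the binomial LR statistic on the same table to 1e-9."""
        ta, tb = a + extra_a, b + extra_b
        res = g_test(a, b, ta, tb)
        assert abs(res.g - binomial_lr_oracle(a, b, ta, tb)) < 1e-9

    def test_null_false_positive_rate_near_nominal(self, rng):
        """Identical multinomial proportions in control and treatment: the
        p < 0.005 rate stays within binomial 99% bounds of 0.005."""
        n_barcodes, depth = 10_000, 10**6
        p = rng.dirichlet(np.full(n_barcodes, 5.0))
        a = rng.multinomial(depth, p)
        b = rng.multinomial(depth, p)
        hits = sum(
            g_test(int(x), int(y), depth, depth).p < 0.005
            for x, y in zip(a, b)
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], n_barcodes, 0.005)
        assert lo <= hits <= hi


class TestCutoffs:
    def test_translation_equivariance(self, rng):
        values = rng.normal(size=200)
        base = gi_cutoffs(values)
        shifted = gi_cutoffs(values + 0.7)
        assert np.allclose(np.array(shifted), np.array(base) + 0.7)

    def test_toy_set_hand_computed(self):
        values = [-0.1, 0, 0, 0.1, 0.2]
        rs = robust_stats(values)
        cuts = gi_cutoffs(values)
        assert cuts == (
            pytest.approx(rs.median + 3 * rs.niqr),
            pytest.approx(rs.median + 2.5 * rs.niqr),
            pytest.approx(rs.median + 2 * rs.niqr),
        )
        # hand values: median 0, quartiles 0 and 0.1 -> NIQR 0.07413
        assert rs.median == pytest.approx(0.0)
        assert rs.niqr == pytest.approx(0.07413)


def make_experiment(gi_by_gene: dict, label: str, significant=None,
                    g: float = 5.0) -> Experiment:
    """Hand-built experiment: gi_by_gene maps gene -> (gi_up, gi_dn); the
    ``significant`` set gets clearly unequal counts, the rest equal ones."""
    significant = significant if significant is not None else set(gi_by_gene)
    design = ExperimentDesign.single_timepoint("c", "t", g, "C", "T", replicate=label)
    records, tag_counts = [], {}
    for gene, (up, dn) in gi_by_gene.items():
        defined = [v for v in (up, dn) if v is not None]
        combined = sum(defined) / len(defined) if defined else None
        records.append(GIRecord(gene_id=gene, gi_up=up, gi_dn=dn, gi=combined))
        counts = (400, 50) if gene in significant else (400, 400)
        for cls in ("up", "dn"):
            tag_counts[(gene, cls)] = (*counts, 10**6, 10**6)
    return Experiment(GITable(records, design), tag_counts, label=label)


class TestCallSensitive:
    CUTS = (0.5, 0.4, 0.3)  # frozen (single, averaged, per-tag) thresholds

    def test_all_zero_gi_no_hits(self):
        # a fully null experiment: flat GI and flat counts everywhere
        exps = [
            make_experiment(
                {f"g{i}": (0.0, 0.0) for i in range(10)}, l, significant=set()
            )
            for l in "ABC"
        ]
        table = call_sensitive(exps)
        assert table.hits() == []

    def test_two_of_three_rule(self):
        """Passing in exactly 1 of 3 experiments is not a hit; 2 of 3 is."""
        high, low = (0.9, 0.9), (0.0, 0.0)
        base = {"once": low, "twice": low, "ref": low}
        exps = [
            make_experiment({**base, "once": high, "twice": high}, "A"),
            make_experiment({**base, "twice": high}, "B"),
            make_experiment(base, "C"),
        ]
        table = call_sensitive(exps, frozen_cutoffs=[self.CUTS] * 3)
        assert table.status["twice"] == "sensitive"
        assert table.status["once"] == "none"
        assert table.n_passing["once"] == 1 and table.n_passing["twice"] == 2

    def test_single_tag_branch_uses_3niqr_cutoff(self):
        genes = {"hi": (0.55, None), "mid": (0.45, None), "ref": (0.0, 0.0)}
        exps = [make_experiment(genes, l) for l in "AB"]
        table = call_sensitive(exps, frozen_cutoffs=[self.CUTS] * 2)
        assert table.status["hi"] == "sensitive"     # 0.55 >= 0.5
        assert table.status["mid"] == "none"         # 0.45 < single-tag cutoff

    def test_dual_tag_branch_needs_both_tags_above_2niqr(self):
        genes = {
            "ok": (0.45, 0.45),        # avg 0.45 >= 0.4, both >= 0.3
            "weak_tag": (0.85, 0.25),  # avg 0.55 but dntag below per-tag cutoff
            "weak_avg": (0.35, 0.35),  # both tags pass but avg < 0.4
            "ref": (0.0, 0.0),
        }
        exps = [make_experiment(genes, l) for l in "AB"]
        table = call_sensitive(exps, frozen_cutoffs=[self.CUTS] * 2)
        assert table.status["ok"] == "sensitive"
        assert table.status["weak_tag"] == "none"
        assert table.status["weak_avg"] == "none"

    def test_p_value_filter_blocks_flat_counts(self):
        genes = {"hit": (0.9, 0.9), "flat": (0.9, 0.9), "ref": (0.0, 0.0)}
        exps = [
            make_experiment(genes, l, significant={"hit"}) for l in "AB"
        ]
        table = call_sensitive(exps, frozen_cutoffs=[self.CUTS] * 2)
        assert table.status["hit"] == "sensitive"
        assert table.status["flat"] == "none"  # GI passes, G-test does not

    def test_monotone_under_frozen_cutoffs(self):
        genes = {"x": (0.45, 0.45), "ref": (0.0, 0.0)}
        exps = [make_experiment(genes, l) for l in "AB"]
        before = call_sensitive(exps, frozen_cutoffs=[self.CUTS] * 2)
        raised = {"x": (0.65, 0.65), "ref": (0.0, 0.0)}
        exps2 = [make_experiment(raised, l) for l in "AB"]
        after = call_sensitive(exps2, frozen_cutoffs=[self.CUTS] * 2)
        assert before.status["x"] == "sensitive"
        assert after.status["x"] == "sensitive"

    def test_deterministic_output(self, tmp_path):
        genes = {"a": (0.9, 0.9), "b": (0.0, 0.0), "ref": (0.1, 0.1)}
        exps = [make_experiment(genes, l) for l in "ABC"]
        p1, p2 = tmp_path / "h1.tsv", tmp_path / "h2.tsv"
        call_sensitive(exps).write_tsv(p1)
        call_sensitive(exps).write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestRankResistant:
    @staticmethod
    def table(gis: dict):
        design = ExperimentDesign.single_timepoint("c", "t", 5, "C", "T")
        records = [
            GIRecord(gene_id=g, gi_up=v, gi_dn=v, gi=v) for g, v in gis.items()
        ]
        return GITable(records, design)

    def test_ascending_order_and_flag(self):
        ranking = rank_resistant(self.table({"a": 0.2, "b": -0.9, "c": 0.0}))
        assert [r[1] for r in ranking] == ["b", "c", "a"]
        assert ranking[0][3] is True and ranking[1][3] is False

    def test_boundary_minus_half_inclusive(self):
        ranking = rank_resistant(self.table({"edge": -0.5, "in": -0.51, "out": -0.49}))
        flags = {gene: f for _, gene, _, f in ranking}
        assert flags == {"in": True, "edge": True, "out": False}

    def test_ties_break_by_gene_id(self):
        ranking = rank_resistant(self.table({"zz": 0.1, "aa": 0.1}))
        assert [r[1] for r in ranking] == ["aa", "zz"]
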