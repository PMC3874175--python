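"""PDI network similarity, enrichment, projection and family statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intronreg.pdi import (
    PDINetwork,
    coexpression_enrichment,
    family_enrichment,
    freeman_halton_2x3,
    genome_projection,
    jaccard_similarity,
    screen_bookkeeping,
    similarity_table,
)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), set(), None),
            (set(), {"x"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = set(rng.choice(12, size=rng.integers(0, 8), replace=False))
            b = set(rng.choice(12, size=rng.integers(0, 8), replace=False))
            j = jaccard_similarity(a, b)
            assert j == jaccard_similarity(b, a)
            if j is not None:
                assert 0.0 <= j <= 1.0


class TestSimilarityTable:
    def _network(self, sets_p, sets_i):
        edges = set()
        for g, tfs in sets_p.items():
            edges |= {(tf, g, "promoter") for tf in tfs}
        for g, tfs in sets_i.items():
            edges |= {(tf, g, "first_intron") for tf in tfs}
        return PDINetwork(edges=edges)

    def test_pair_count(self):
        net = self._network({f"g{i}": {"t"} for i in range(3)}, {})
        assert len(similarity_table(net, [f"g{i}" for i in range(3)])) == 3
        net24 = self._network({f"g{i}": {"t"} for i in range(24)}, {})
        tab = similarity_table(net24, [f"g{i}" for i in range(24)])
        assert len(tab) == 276
        assert tab["j_combined"].between(0, 1).all()

    def test_combined_pools_before_jaccard(self):
        net = self._network({"g1": {"a"}, "g2": set()},
                            {"g1": set(), "g2": {"a"}})
        tab = similarity_table(net, ["g1", "g2"])
        row = tab.iloc[0]
        assert row["j_combined"] == 1.0
        assert row["j_promoter"] == 0.0  # promoter sets {a} vs empty

    def test_combined_not_determined_by_marginals(self):
        """Two pairs with identical promoter-only and intron-only Jaccard
        can differ in combined Jaccard (pooling is not separable)."""
        # pair 1: shared promoter TF, disjoint intron TFs
        net1 = self._network({"a": {"p"}, "b": {"p"}},
                             {"a": {"x"}, "b": {"y"}})
        # pair 2: same marginals, larger disjoint intron sets
        net2 = self._network({"a": {"p"}, "b": {"p"}},
                             {"a": {"x", "u"}, "b": {"y", "v"}})
        r1 = similarity_table(net1, ["a", "b"]).iloc[0]
        r2 = similarity_table(net2, ["a", "b"]).iloc[0]
        assert r1["j_promoter"] == r2["j_promoter"] == 1.0
        assert r1["j_first_intron"] == r2["j_first_intron"] == 0.0
        assert r1["j_combined"] != r2["j_combined"]

    def test_tsv_round_trip(self, tmp_path):
        net = self._network({"g1": {"a", "b"}}, {"g2": {"c"}})
        path = tmp_path / "pdi.tsv"
        path.write_text(net.to_tsv())
        back = PDINetwork.from_tsv(str(path))
        assert back.edges == net.edges


def _records(j_values, coexp_values, mode="combined"):
    col = {"promoter": "j_promoter", "first_intron": "j_first_intron",
           "combined": "j_combined"}[mode]
    df = pd.DataFrame({
        "gene_a": "a", "gene_b": "b",
        "j_promoter": np.nan, "j_first_intron": np.nan, "j_combined": np.nan,
        "coexpression": coexp_values,
    })
    df[col] = j_values
    return df


class TestEnrichment:
    def test_proportional_table_not_significant(self):
        j = [0.1] * 30 + [0.5] * 30
        co = ([0.1] * 10 + [0.3] * 10 + [0.6] * 10) * 2
        out = coexpression_enrichment(_records(j, co))
        assert out.fisher_p == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        j = [0.1] * 10 + [0.5] * 10
        co = [0.0] * 10 + [0.9] * 10
        out = coexpression_enrichment(_records(j, co))
        assert out.table.tolist() == [[10, 0, 0], [0, 0, 10]]
        # exhaustive two-sided Fisher oracle on the 2x2 collapse
        expected = sum(
            stats.hypergeom.pmf(k, 20, 10, 10)
            for k in range(11)
            if stats.hypergeom.pmf(k, 20, 10, 10)
            <= stats.hypergeom.pmf(0, 20, 10, 10) * (1 + 1e-9)
        )
        assert out.fisher_p == pytest.approx(expected)
        assert out.fisher_p == pytest.approx(2 / math.comb(20, 10))

    def test_empty_margin_reported_undefined(self):
        out = coexpression_enrichment(_records([0.1] * 5, [0.1] * 5))
        assert out.fisher_p is None

    def test_undefined_j_pairs_excluded(self):
        j = [np.nan, 0.1, 0.5, 0.5]
        co = [0.9, 0.1, 0.6, 0.6]
        out = coexpression_enrichment(_records(j, co))
        assert out.n_undefined_j == 1
        assert out.table.sum() == 3

    def test_freeman_halton_reduces_to_fisher_when_column_empty(self):
        table = [[8, 2, 0], [1, 9, 0]]
        fh = freeman_halton_2x3(table)
        fisher = stats.fisher_exact([[8, 2], [1, 9]])[1]
        assert fh == pytest.approx(fisher)

    def test_planted_combined_signal_detected(self):
        """Co-expression generated from combined-region similarity is
        detected as enrichment at 276 pairs."""
        from intronreg.simulate import SimConfig, simulate_pdi_network

        net, coexp = simulate_pdi_network(SimConfig(seed=2))
        genes = sorted({g for _, g, _ in net.edges})
        tab = similarity_table(net, genes, coexp)
        out = coexpression_enrichment(tab, mode="combined")
        assert out.fisher_p < 0.01


class TestProjection:
    def test_all_bound_projects_to_one(self):
        out = genome_projection([10, 100, 600], [1, 2, 3], [20, 90, 700, 800])
        assert out.fraction_bound == 1.0

    def test_single_bin_equals_screen_statistics(self):
        out = genome_projection([30, 40], [0, 2], [20, 25, 30])
        assert out.fraction_bound == 0.5
        assert out.mean_interactions == 1.0
        assert not out.partial

    def test_matches_weighted_average_oracle(self):
        rng = np.random.default_rng(8)
        screen_len = rng.integers(10, 2000, size=150)
        screen_cnt = rng.poisson(screen_len / 400)
        genome_len = rng.integers(10, 2000, size=2000)
        out = genome_projection(screen_len, screen_cnt, genome_len)
        edges = [65, 129, 257, 513]
        sbin = np.digitize(screen_len, edges)
        gbin = np.digitize(genome_len, edges)
        frac = mean = wsum = 0.0
        for b in range(5):
            w = (gbin == b).mean()
            sel = screen_cnt[sbin == b]
            if len(sel):
                frac += w * (sel >= 1).mean()
                mean += w * sel.mean()
                wsum += w
        assert out.fraction_bound == pytest.approx(frac / wsum, abs=1e-12)
        assert out.mean_interactions == pytest.approx(mean / wsum, abs=1e-12)

    def test_uncovered_bin_flags_partial(self):
        out = genome_projection([30], [1], [30, 1000])
        assert out.partial


class TestFamilyEnrichment:
    def test_whole_genome_family_is_null(self):
        universe = [f"g{i}" for i in range(100)]
        out = family_enrichment(universe[:10], {"fam": universe}, universe)
        assert out[0].p_value == pytest.approx(1.0)

    def test_fully_contained_family_matches_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        selection = universe[:10]
        fam = universe[:5]
        out = family_enrichment(selection, {"fam": fam}, universe)
        # P(X >= 5) for X ~ Hypergeom(N=100, K=5, n=10), by enumeration
        expected = (
            math.comb(5, 5) * math.comb(95, 5) / math.comb(100, 10)
        )
        assert out[0].overlap == 5
        assert out[0].p_value == pytest.approx(expected)
        assert out[0].q_value == out[0].p_value  # single family: BH identity

    def test_bh_q_values_monotone_in_sorted_p(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(200)]
        selection = list(rng.choice(universe, size=40, replace=False))
        families = {
            f"fam{k}": list(rng.choice(universe, size=rng.integers(5, 30),
                                       replace=False))
            for k in range(12)
        }
        out = family_enrichment(selection, families, universe)
        ordered = sorted(out, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in out)


def test_screen_bookkeeping_totals():
    s = screen_bookkeeping(n_baits=164, n_removed=10, n_zero_interaction=56,
                           n_positive=585, n_tested=133_210)
    assert s.n_screened == 154
    assert s.n_bound == 98
    assert s.positive_rate == pytest.approx(585 / 133_210)
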