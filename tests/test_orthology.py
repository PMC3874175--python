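"""Orthologous exon mapping and intron length conservation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intronreg.genome import extract_fragments
from intronreg.orthology import (
    ExonCorrespondence,
    align_exons_translated,
    conservation_comparison,
    intron_length_ratio,
    length_ratio_records,
    random_pair_ratios,
)
from intronreg.simulate import SimConfig, simulate_genome_pair


def _random_cds(rng, n_codons):
    return "".join(rng.choice(list("ACGT"), size=3 * n_codons).tolist())


class TestExonAlignment:
    def test_identical_exons_give_identity_mapping(self):
        rng = np.random.default_rng(1)
        exons = [_random_cds(rng, 40) for _ in range(4)]
        corr = align_exons_translated(exons, list(exons))
        assert corr.is_one_to_one and corr.is_identical_structure
        assert [(i, j) for i, j, _ in sorted(corr.pairs)] == \
            [(k, k) for k in range(4)]

    def test_missing_exon_breaks_identical_structure(self):
        rng = np.random.default_rng(2)
        exons = [_random_cds(rng, 40) for _ in range(5)]
        partner = exons[:2] + exons[3:]  # exon 3 of 5 missing
        corr = align_exons_translated(exons, partner)
        assert not corr.is_identical_structure

    def test_short_exon_scores_zero_without_error(self):
        rng = np.random.default_rng(3)
        corr = align_exons_translated(["AC"], [_random_cds(rng, 30)])
        assert corr.pairs == []

    def test_identity_recovered_under_wobble_divergence(self):
        """Orthologs with ~10% substitutions at wobble positions keep a
        detectable one-to-one exon correspondence."""
        pair = simulate_genome_pair(
            SimConfig(seed=11, n_genes=40, structure_violation_rate=0.0)
        )
        genes_b = {g.gene_id: g for g in pair.species_b.genes}
        hits = 0
        for ga, gb in pair.orthologs:
            ex_a = [f.sequence for f in extract_fragments(
                pair.species_a.gene(ga), pair.species_a.genome) if f.kind == "exon"]
            ex_b = [f.sequence for f in extract_fragments(
                genes_b[gb], pair.species_b.genome) if f.kind == "exon"]
            hits += align_exons_translated(ex_a, ex_b).is_identical_structure
        assert hits >= 0.95 * len(pair.orthologs)

    def test_structure_violations_are_detected(self):
        pair = simulate_genome_pair(
            SimConfig(seed=12, n_genes=30, structure_violation_rate=0.4)
        )
        genes_b = {g.gene_id: g for g in pair.species_b.genes}
        for ga, gb in pair.orthologs:
            if ga not in pair.truth.structure_violated:
                continue
            ex_a = [f.sequence for f in extract_fragments(
                pair.species_a.gene(ga), pair.species_a.genome) if f.kind == "exon"]
            ex_b = [f.sequence for f in extract_fragments(
                genes_b[gb], pair.species_b.genome) if f.kind == "exon"]
            assert not align_exons_translated(ex_a, ex_b).is_identical_structure


def _brute_force_one_to_one(pairs, na, nb):
    """Oracle: kept pairs equal some strictly monotone bijection of all exons."""
    if na != nb or len(pairs) != na:
        return False
    kept = {(i, j) for i, j, _ in pairs}
    for perm in itertools.permutations(range(nb)):
        if all(perm[i] < perm[i + 1] for i in range(nb - 1)):
            if {(i, perm[i]) for i in range(na)} == kept:
                return True
    return False


@given(st.data())
@settings(max_examples=200, deadline=None)
def test_one_to_one_agrees_with_exhaustive_enumeration(data):
    na = data.draw(st.integers(1, 5))
    nb = data.draw(st.integers(1, 5))
    n_pairs = data.draw(st.integers(0, min(na, nb)))
    i_idx = sorted(data.draw(st.permutations(range(na)))[:n_pairs])
    j_idx = data.draw(st.permutations(range(nb)))[:n_pairs]
    pairs = [(i, j, 100.0) for i, j in zip(i_idx, j_idx)]
    corr = ExonCorrespondence(pairs=pairs, n_exons_a=na, n_exons_b=nb)
    assert corr.is_one_to_one == _brute_force_one_to_one(pairs, na, nb)


class TestLengthRatio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(600, 600, 1.0), (1000, 500, 2.0), (742, 519, 742 / 519)],
    )
    def test_ratio_values(self, a, b, expected):
        assert intron_length_ratio(a, b) == pytest.approx(expected)

    @given(st.integers(1, 10**6), st.integers(1, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_ratio_symmetric_and_at_least_one(self, a, b):
        assert intron_length_ratio(a, b) == intron_length_ratio(b, a)
        assert intron_length_ratio(a, b) >= 1.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            intron_length_ratio(0, 100)


class TestConservationComparison:
    def _records(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        recs = []
        for g in range(n):
            lens_a = [int(rng.lognormal(np.log(300), 1.0)) + 10 for _ in range(4)]
            recs.extend(length_ratio_records(
                f"a{g}", f"b{g}", lens_a,
                [max(10, int(round(l * np.exp(rng.normal(
                    0, 0.15 if k == 0 else 0.6)))))
                 for k, l in enumerate(lens_a)],
            ))
        return recs

    def test_filter_monotone_in_cutoff(self):
        recs = self._records()
        counts = [
            sum(r.passes_filter(c) for r in recs) for c in (100, 300, 500, 900)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_mismatched_intron_counts_rejected(self):
        with pytest.raises(ValueError):
            length_ratio_records("a", "b", [100, 200], [100])

    def test_tight_first_intron_jitter_detected(self):
        """sigma_first < sigma_other shows up as a lower first-intron
        median ratio with a strong two-sided U-test."""
        report = conservation_comparison(self._records(seed=5, n=300))
        assert report.median_first < report.median_other
        assert report.p_value < 0.01

    def test_undefined_p_for_tiny_groups(self):
        recs = length_ratio_records("a", "b", [600], [700])
        report = conservation_comparison(recs)
        assert report.p_value is None

    def test_random_pair_null_less_conserved(self):
        """Permuting species-B partners breaks length conservation: the
        null median ratio exceeds the orthologous-pair median."""
        rng = np.random.default_rng(7)
        recs = self._records(seed=6, n=300)
        firsts = [r for r in recs if r.is_first]
        null = random_pair_ratios(
            [r.length_a for r in firsts], [r.length_b for r in firsts], rng
        )
        orth = conservation_comparison(recs)
        assert np.median(null) > orth.median_first

    def test_sigma_ordering_recovered_across_replicates(self):
        """The generator's sigma_first < sigma_other ordering is recovered
        as a median-ratio ordering in >= 95% of replicates."""
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            ratios = {"first": [], "other": []}
            for _ in range(60):
                for k in range(4):
                    sigma = 0.15 if k == 0 else 0.6
                    la = int(rng.lognormal(np.log(300), 1.0)) + 10
                    lb = max(10, int(round(la * np.exp(rng.normal(0, sigma)))))
                    if max(la, lb) > 500:
                        ratios["first" if k == 0 else "other"].append(
                            intron_length_ratio(la, lb)
                        )
            if ratios["first"] and ratios["other"]:
                wins += np.median(ratios["first"]) < np.median(ratios["other"])
        assert wins >= 0.95 * n_rep

    def test_generator_truth_lengths_reproduce_signal(self):
        """End to end on generator ground truth: identical-structure genes'
        intron ratios show the planted first-intron conservation."""
        pair = simulate_genome_pair(
            SimConfig.conservation_preset(
                seed=21, n_genes=150, structure_violation_rate=0.0
            )
        )
        recs = []
        for ga, gb in pair.orthologs:
            recs.extend(length_ratio_records(
                ga, gb,
                pair.truth.intron_lengths_a[ga],
                pair.truth.intron_lengths_b[ga],
            ))
        report = conservation_comparison(recs)
        assert report.median_first < report.median_other
        assert report.p_value < 0.01
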