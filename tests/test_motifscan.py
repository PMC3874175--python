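"""Energy-matrix construction, occupancy scanning and conserved predictions."""

import math

import numpy as np
import pytest

from intronreg.motifscan import (
    NO_DATA,
    PWM,
    EnergyMatrix,
    conserved_predicted_tfs,
    mean_conserved_by_region,
    predicted_tfs,
    pwm_to_energy,
    read_pwms_meme,
    read_pwms_tsv,
    scan_fragment,
)


def sharp_pwm(consensus: str, p: float = 0.9, tf_id: str = "tf") -> PWM:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = p
    return PWM(tf_id=tf_id, matrix=mat)


def brute_force_scan(seq: str, em: EnergyMatrix):
    """Independent per-window enumeration of both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = em.width
    cutoff = em.energy_cutoff
    hits = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        if any(b not in idx for b in window):
            continue
        e_fwd = sum(em.epsilon[i, idx[b]] for i, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        e_rev = sum(em.epsilon[i, idx[b]] for i, b in enumerate(rc))
        if e_fwd <= cutoff:
            hits.append((off, "+", e_fwd))
        if e_rev <= cutoff and not (e_fwd <= cutoff and e_fwd == e_rev):
            hits.append((off, "-", e_rev))
    return hits


class TestEnergyMatrix:
    def test_uniform_row_has_zero_energies(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        em = pwm_to_energy(pwm)
        assert np.allclose(em.epsilon, 0.0)

    def test_log_ratio_to_consensus(self):
        mat = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        em = pwm_to_energy(PWM("t", mat), pseudocount=1e-3)
        f = (mat[0] + 1e-3) / (mat[0] + 1e-3).sum()
        assert em.epsilon[0, 0] == 0.0
        assert em.epsilon[0, 1] == pytest.approx(math.log(f[0] / f[1]))

    def test_deterministic_row_stays_finite_and_symmetric(self):
        mat = np.array([[1.0, 0.0, 0.0, 0.0]] * 5)
        em = pwm_to_energy(PWM("t", mat))
        assert np.all(np.isfinite(em.epsilon))
        assert em.epsilon[0, 1] == em.epsilon[0, 2] == em.epsilon[0, 3]

    def test_energy_cutoff_matches_threshold(self):
        em = pwm_to_energy(sharp_pwm("ACGTA"))
        assert em.energy_cutoff == pytest.approx(math.log(1 / 0.09 - 1))
        assert em.energy_cutoff == pytest.approx(2.3136, abs=1e-4)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            EnergyMatrix("t", np.zeros((4, 4)), threshold=1.5)

    def test_occupancy_decreases_with_each_mutation(self):
        em = pwm_to_energy(sharp_pwm("AAAAAA"))
        seqs = ["AAAAAA", "CAAAAA", "CCAAAA", "CCCAAA"]
        occs = []
        for s in seqs:
            e = sum(em.epsilon[i, {"A": 0, "C": 1}[b]] for i, b in enumerate(s))
            occs.append(float(em.occupancy(e)))
        assert all(a > b for a, b in zip(occs, occs[1:]))


class TestScan:
    def test_consensus_site_called_with_half_occupancy(self):
        em = pwm_to_energy(sharp_pwm("ACGTAC", p=0.97))
        seq = "TTTTTT" + "ACGTAC" + "TTTTTT"
        sites = [s for s in scan_fragment(seq, em) if s.strand == "+"]
        assert [s.offset for s in sites] == [6]
        assert sites[0].energy == pytest.approx(0.0)
        assert sites[0].occupancy == pytest.approx(0.5)

    def test_uniform_matrix_calls_every_window(self):
        em = pwm_to_energy(PWM("u", np.full((4, 4), 0.25)))
        seq = "ACGTACGTAC"
        sites = scan_fragment(seq, em)
        # every window passes; palindromic double-calls collapse to +
        assert [s.offset for s in sites] == list(range(len(seq) - 4 + 1))
        assert {s.strand for s in sites} == {"+"}

    def test_fragment_shorter_than_width_is_empty(self):
        em = pwm_to_energy(sharp_pwm("ACGTAC"))
        assert scan_fragment("ACG", em) == []

    def test_windows_with_n_are_skipped(self):
        em = pwm_to_energy(PWM("u", np.full((4, 4), 0.25)))
        sites = scan_fragment("ACNTACGT", em)
        assert [s.offset for s in sites] == [3, 4]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(33)
        ems = [
            pwm_to_energy(sharp_pwm("ACGTAG", p=0.6, tf_id="loose")),
            pwm_to_energy(sharp_pwm("TTGACA", p=0.95, tf_id="sharp")),
        ]
        for _ in range(25):
            n = int(rng.integers(10, 100))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04],
                                     size=n).tolist())
            for em in ems:
                got = [(s.offset, s.strand, s.energy)
                       for s in scan_fragment(seq, em)]
                expected = brute_force_scan(seq, em)
                assert [(o, st) for o, st, _ in got] == \
                    [(o, st) for o, st, _ in expected]
                assert np.allclose([e for *_, e in got],
                                   [e for *_, e in expected])

    def test_strand_symmetry(self):
        """Scanning the reverse complement yields the mirrored site list."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(44)
        seq = "".join(rng.choice(list("ACGT"), size=80).tolist())
        rc = "".join(comp[b] for b in reversed(seq))
        em = pwm_to_energy(sharp_pwm("ACGTA", p=0.55))
        fwd = scan_fragment(seq, em)
        rev = scan_fragment(rc, em)
        w = em.width
        mirrored = sorted(
            (len(seq) - s.offset - w, {"+": "-", "-": "+"}[s.strand],
             round(s.energy, 9))
            for s in rev
        )
        assert sorted((s.offset, s.strand, round(s.energy, 9)) for s in fwd) == \
            mirrored


class TestPredictedSets:
    def test_no_match_gives_empty_set(self):
        ems = [pwm_to_energy(sharp_pwm("GGGGGG", p=0.97))]
        assert predicted_tfs("ACACACACAC", ems) == set()

    def test_two_matrices_of_same_tf_count_once(self):
        ems = [
            pwm_to_energy(sharp_pwm("ACGTA", p=0.97, tf_id="tfX")),
            pwm_to_energy(sharp_pwm("ACGTAC", p=0.97, tf_id="tfX")),
        ]
        assert predicted_tfs("TTACGTACTT", ems) == {"tfX"}

    def test_conserved_is_intersection(self):
        ems = [
            pwm_to_energy(sharp_pwm("AAAAAA", p=0.97, tf_id="a")),
            pwm_to_energy(sharp_pwm("CCCCCC", p=0.97, tf_id="c")),
        ]
        both = "GGAAAAAAGG"
        only_c = "GGCCCCCCGG"
        assert conserved_predicted_tfs(both, both, ems) == {"a"}
        assert conserved_predicted_tfs(both, only_c, ems) == set()

    def test_no_sites_anywhere_marks_no_data(self):
        ems = [pwm_to_energy(sharp_pwm("GGGGGG", p=0.97, tf_id="g"))]
        assert conserved_predicted_tfs("ACACACAC", "TGTGTGTG", ems) is NO_DATA

    def test_region_means_exclude_no_data(self):
        entries = [
            ("first_intron", {"a", "b"}),
            ("first_intron", NO_DATA),
            ("other_intron", set()),
        ]
        summary = mean_conserved_by_region(entries)
        assert summary.per_class["first_intron"] == {
            "mean": 2.0, "sem": 0.0, "n": 1
        }
        assert summary.per_class["other_intron"]["mean"] == 0.0

    def test_planted_conserved_ratio_recovered(self, pair_scan_entries):
        summary = mean_conserved_by_region(pair_scan_entries)
        first = summary.per_class["first_intron"]["mean"]
        other = summary.per_class["other_intron"]["mean"]
        assert first / other == pytest.approx(1.5, abs=0.2)


@pytest.fixture(scope="module")
def pair_scan_entries():
    """Conserved-TF entries from a planted-motif genome pair (first introns
    planted at 1.5x the rate of other introns)."""
    from intronreg.genome import extract_fragments
    from intronreg.simulate import SimConfig, simulate_genome_pair

    pair = simulate_genome_pair(
        SimConfig.conservation_preset(
            seed=55, n_genes=220, structure_violation_rate=0.0
        )
    )
    ems = [pwm_to_energy(p) for p in pair.pwms]
    genes_b = {g.gene_id: g for g in pair.species_b.genes}
    entries = []
    for ga, gb in pair.orthologs:
        fa = {f.index: f.sequence for f in extract_fragments(
            pair.species_a.gene(ga), pair.species_a.genome) if f.kind == "intron"}
        fb = {f.index: f.sequence for f in extract_fragments(
            genes_b[gb], pair.species_b.genome) if f.kind == "intron"}
        for idx in fa:
            if idx in fb:
                entries.append((
                    "first_intron" if idx == 1 else "other_intron",
                    conserved_predicted_tfs(fa[idx], fb[idx], ems),
                ))
    return entries


class TestReaders:
    def test_meme_minimal_round_trip(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "strands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF tfZ\n"
            "letter-probability matrix: alphabet= 4 w= 4 nsites= 20 E= 0\n"
            " 0.700 0.100 0.100 0.100\n"
            " 0.100 0.700 0.100 0.100\n"
            " 0.100 0.100 0.700 0.100\n"
            " 0.100 0.100 0.100 0.700\n"
        )
        path = tmp_path / "m.meme"
        path.write_text(text)
        pwms = read_pwms_meme(str(path))
        assert len(pwms) == 1 and pwms[0].tf_id == "tfZ"
        assert pwms[0].consensus == "ACGT"

    def test_tsv_round_trip(self, tmp_path):
        from intronreg.simulate import SimConfig, _make_pwms, _child_rng, write_pwms_tsv

        cfg = SimConfig(seed=9)
        pwms = _make_pwms(cfg, _child_rng(cfg.seed, "motifs"))
        path = tmp_path / "pwms.tsv"
        write_pwms_tsv(pwms, str(path))
        back = read_pwms_tsv(str(path))
        assert [p.tf_id for p in back] == [p.tf_id for p in pwms]
        for a, b in zip(back, pwms):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)
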