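import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spanfold import (Fold, RnaSequence, gamma_centroid, splice_delta,
                      stem_probability, window_average)
from spanfold.features import (BasePairProbabilities, CoordinateError,
                               SecondaryStructure, StructureError)
from spanfold.oracle import (designed_hairpin, enumerate_ensemble, make_gene_fixture,
                             random_sequence)


class TestBasePairProbabilities:
    def test_homopolymer_has_empty_map(self, zero_model):
        f = Fold(RnaSequence("a", "AAAAAAAA"), w=8, model=zero_model)
        assert f.bpp.to_dict() == {}

    def test_gaaac_pair_probability_is_half(self, gaaac, zero_model):
        f = Fold(gaaac, w=5, model=zero_model)
        assert f.bpp.get(1, 5) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_oracle_on_random_sequences(self, seed, default_model):
        n = 10 + seed
        seq = random_sequence(n, 0.6, seed=seed + 200)
        full = enumerate_ensemble(seq, n, default_model)
        for w in range(4, n + 1, 3):
            f = Fold(seq, w=w, model=default_model)
            oracle_p = full.restrict(w).pair_probabilities()
            for (a, b), p in oracle_p.items():
                assert f.bpp.get(a, b) == pytest.approx(p, abs=1e-9)
            for (a, b), p in f.bpp.items():
                if (a, b) not in oracle_p:
                    assert p == pytest.approx(0.0, abs=1e-9)

    def test_probability_bounds_and_row_sums(self, default_model):
        seq = random_sequence(300, 0.6, seed=42)
        f = Fold(seq, w=40, model=default_model)
        band = f.bpp.band
        assert band.min() >= -1e-9 and band.max() <= 1 + 1e-9
        assert np.all(f.p_stem <= 1 + 1e-9)


class TestStemProbability:
    def test_homopolymer_all_accessible(self, zero_model):
        f = Fold(RnaSequence("a", "A" * 20), w=10, model=zero_model)
        assert np.all(f.p_stem == 0.0)
        assert np.all(f.accessibility == 1.0)

    def test_gaaac_profile_values(self, gaaac, zero_model):
        f = Fold(gaaac, w=5, model=zero_model)
        assert f.p_stem == pytest.approx([0.5, 0, 0, 0, 0.5])

    def test_accessibility_complements_stem(self, default_model):
        f = Fold(random_sequence(100, 0.5, seed=1), w=30, model=default_model)
        assert np.allclose(f.accessibility + f.p_stem, 1.0)

    def test_designed_hairpin_is_strongly_paired(self, default_model):
        hp = designed_hairpin(20, 4, seed=3)
        f = Fold(hp, w=hp.n, model=default_model)
        stem_positions = list(range(20)) + list(range(hp.n - 20, hp.n))
        stems = f.p_stem[stem_positions]
        # terminal and loop-adjacent pairs breathe; the helix core is locked
        assert stems.min() > 0.7
        assert stems.mean() > 0.9
        assert np.median(stems) > 0.95


class TestStructuralProfile:
    def test_homopolymer_is_all_exterior(self, zero_model):
        f = Fold(RnaSequence("a", "A" * 15), w=8, model=zero_model)
        assert np.all(f.profile["exterior"] == 1.0)

    def test_gaaac_loop_split(self, gaaac, zero_model):
        f = Fold(gaaac, w=5, model=zero_model)
        for t in (1, 2, 3):  # positions 2-4 (0-based 1..3)
            assert f.profile["hairpin"][t] == pytest.approx(0.5)
            assert f.profile["exterior"][t] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_loop_classification(self, seed, default_model):
        seq = random_sequence(14 + seed, 0.65, seed=seed + 300)
        w = min(seq.n, 12)
        f = Fold(seq, w=w, model=default_model)
        ens = enumerate_ensemble(seq, w, default_model)
        assert np.abs(f.profile.values - ens.profile()).max() < 1e-9

    def test_rows_sum_to_one_on_random_sequences(self, default_model):
        for seed in range(10):
            f = Fold(random_sequence(60, 0.55, seed=seed + 400), w=25, model=default_model)
            assert np.abs(f.profile.values.sum(axis=1) - 1.0).max() < 1e-9

    def test_w_saturation_equals_unconstrained_fold(self, default_model):
        """For W >= N the span constraint is vacuous: equals the global fold."""
        seq = random_sequence(16, 0.6, seed=500)
        ens = enumerate_ensemble(seq, seq.n, default_model)
        f = Fold(seq, w=seq.n, model=default_model)
        assert np.abs(f.profile.values - ens.profile()).max() < 1e-9
        assert f.log_z == pytest.approx(ens.log_z, abs=1e-9)


class TestGammaCentroid:
    def test_low_probabilities_and_exact_ties_give_empty_structure(self, zero_model):
        # the only candidate pair has p = 1/2 exactly: the strict threshold
        # p > 1/(gamma+1) excludes it, guaranteeing nestedness
        f = Fold(RnaSequence("x", "GAAACAAA"), w=8, model=zero_model)
        assert max(p for _, p in f.bpp.items()) == pytest.approx(0.5)
        assert f.centroid(1.0).pairs == ()

    def test_designed_hairpin_recovered(self, default_model):
        hp = designed_hairpin(20, 4, seed=7)
        f = Fold(hp, w=hp.n, model=default_model)
        cen = f.centroid(1.0)
        designed = {(t + 1, hp.n - t) for t in range(20)}
        assert len(designed & set(cen.pairs)) >= 18
        db = cen.dot_bracket()
        assert len(db) == hp.n and db.count("(") == len(cen.pairs)

    def test_gamma_one_equals_half_threshold(self, default_model):
        f = Fold(random_sequence(80, 0.6, seed=8), w=30, model=default_model)
        cen = f.centroid(1.0)
        manual = {(a, b) for (a, b), p in f.bpp.items() if p > 0.5}
        assert set(cen.pairs) == manual

    def test_gamma_above_one_unsupported(self, default_model):
        f = Fold(random_sequence(30, 0.5, seed=9), w=10, model=default_model)
        with pytest.raises(ValueError):
            f.centroid(1.5)

    def test_structure_invariants_enforced(self):
        with pytest.raises(StructureError):
            SecondaryStructure(n=10, pairs=((1, 6), (3, 8)))  # crossing
        with pytest.raises(StructureError):
            SecondaryStructure(n=10, pairs=((1, 4),))  # hairpin too short
        with pytest.raises(StructureError):
            SecondaryStructure(n=10, pairs=((1, 6), (6, 10)))  # reused position


class TestWindowAverage:
    def test_constant_series(self):
        assert np.all(window_average(np.full(64, 0.3), 32) == pytest.approx(0.3))

    def test_non_overlapping_counts(self):
        assert window_average(np.arange(64), 32).size == 2
        assert window_average(np.arange(65), 32).size == 2  # partial window dropped

    def test_sliding_means(self):
        out = window_average(np.arange(1.0, 11.0), 5, "sliding")
        assert out == pytest.approx([3, 4, 5, 6, 7, 8])  # N - L + 1 windows

    def test_window_longer_than_series_is_empty(self):
        assert window_average(np.arange(10), 11).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=40),
           st.integers(min_value=1, max_value=40))
    def test_sliding_matches_naive(self, values, length):
        values = np.asarray(values)
        got = window_average(values, length, "sliding")
        naive = [values[i:i + length].mean() for i in range(values.size - length + 1)]
        assert np.allclose(got, naive, atol=1e-12)


class TestSpliceDelta:
    def test_identity_splicing_gives_zero_delta(self):
        p = np.linspace(0, 1, 30)
        sd = splice_delta(p, p, [(1, 30)])
        assert np.all(sd.delta == 0.0)
        assert sd.junctions == ()

    def test_intron_pairing_reduces_junction_stems(self, default_model):
        """An intron complementary to the exon end pairs with it in the
        pre-mRNA; splicing removes the partner, so delta is negative near
        the junction."""
        pre, mrna, exons = make_gene_fixture(seed=1)
        f_pre = Fold(pre, w=60, model=default_model)
        f_mrna = Fold(mrna, w=60, model=default_model)
        sd = splice_delta(f_pre.p_stem, f_mrna.p_stem, exons)
        j = sd.junctions[0]
        near = sd.delta[j - 8 : j]
        assert near.mean() < -0.2
        assert sd.junction_stats[0][0] < 0  # median

    def test_median_mad_match_direct_computation(self):
        delta_src = np.array([0.1, -0.2, 0.3, -0.4, 0.0, 0.2, -0.1, 0.05] * 10)
        pre = np.zeros(delta_src.size)
        sd = splice_delta(pre + 0, delta_src, [(1, 40), (41, delta_src.size)],
                          window=20)
        j = sd.junctions[0]
        win = sd.delta[j - 10 : j + 10]
        med = np.median(win)
        assert sd.junction_stats[0] == pytest.approx((med, np.median(np.abs(win - med))))

    def test_inconsistent_coordinates_rejected(self):
        with pytest.raises(CoordinateError):
            splice_delta(np.zeros(30), np.zeros(10), [(1, 5), (4, 8)])
        with pytest.raises(CoordinateError):
            splice_delta(np.zeros(30), np.zeros(10), [(1, 5)])

    def test_delta_bounds(self, default_model):
        pre, mrna, exons = make_gene_fixture(seed=2)
        sd = splice_delta(Fold(pre, w=50, model=default_model).p_stem,
                          Fold(mrna, w=50, model=default_model).p_stem, exons)
        assert np.all(sd.delta >= -1) and np.all(sd.delta <= 1)
        up, down = sd.smoothed_around(0)
        assert up.size > 0 and down.size > 0


class TestLocality:
    def test_mid_sequence_motif_matches_padded_subsequence(self, default_model):
        """p_stem of an embedded motif agrees with the 5W-padded computation."""
        w = 20
        motif = random_sequence(60, 0.5, seed=600).residues
        left = random_sequence(400, 0.5, seed=601).residues
        right = random_sequence(400, 0.5, seed=602).residues
        big = Fold(RnaSequence("big", left + motif + right), w=w, model=default_model)
        pad = 5 * w
        small = Fold(RnaSequence("small", left[-pad:] + motif + right[:pad]),
                     w=w, model=default_model)
        diff = np.abs(big.p_stem[400:460] - small.p_stem[pad:pad + 60]).max()
        assert diff < 1e-3
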