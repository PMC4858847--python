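import numpy as np
import pytest

from spanfold import (Fold, RnaSequence, build_ratios, global_reference_fold,
                      inside_banded, outside_local, outside_over_z,
                      potential_outermost_pairs, ratio_r, transition_prob)
from spanfold.oracle import enumerate_ensemble, random_sequence
from spanfold.ratios import DatabaseError, RatioDatabase, attach_ratios


class TestBuildRatios:
    def test_homopolymer_fold_changes_are_unity(self, zero_model):
        db = build_ratios(RnaSequence("a", "A" * 50), 10, zero_model)
        assert np.all(db.log_dalpha == 0.0)
        assert np.all(db.log_dbeta == 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_raw_accumulation(self, seed, default_model):
        seq = random_sequence(30, 0.5, seed=seed)
        w = 12
        db = build_ratios(seq, w, default_model)
        _, la, lb = global_reference_fold(seq, w, default_model)
        assert np.abs(db.log_dalpha - np.diff(la)).max() < 1e-10
        assert np.abs(db.log_dbeta - (-np.diff(lb))).max() < 1e-10

    def test_telescoping_to_log_z(self, default_model):
        seq = random_sequence(40, 0.6, seed=3)
        db = build_ratios(seq, 15, default_model)
        logz, _, _ = global_reference_fold(seq, 15, default_model)
        assert db.log_z == pytest.approx(logz, abs=1e-9)

    def test_entries_finite_and_at_least_unpaired_weight(self, default_model):
        db = build_ratios(random_sequence(200, 0.6, seed=4), 30, default_model)
        assert np.all(np.isfinite(db.log_dalpha)) and np.all(np.isfinite(db.log_dbeta))
        assert np.all(db.log_dalpha >= 0.0)  # dalpha >= t(Outer->Outer) = 1

    def test_recomputation_is_bit_stable(self, default_model):
        seq = random_sequence(100, 0.5, seed=5)
        a = build_ratios(seq, 20, default_model)
        b = build_ratios(seq, 20, default_model)
        assert np.array_equal(a.log_dalpha, b.log_dalpha)
        assert np.array_equal(a.log_dbeta, b.log_dbeta)


class TestRatioR:
    def test_no_pair_sequence_gives_unity(self, zero_model):
        seq = RnaSequence("a", "AAAAAAAAAA")
        db = build_ratios(seq, 6, zero_model)
        tables = inside_banded(seq, 6, zero_model)
        for i in range(0, seq.n):
            for j in range(i, min(seq.n, i + 6) + 1):
                if j - i <= 6:
                    assert ratio_r(i, j, db, tables) == pytest.approx(0.0, abs=1e-12)

    def test_gaaac_r_equals_two(self, gaaac, zero_model):
        db = build_ratios(gaaac, 5, zero_model)
        tables = inside_banded(gaaac, 5, zero_model)
        assert np.exp(ratio_r(0, 5, db, tables)) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_reference_fold(self, seed, default_model):
        seq = random_sequence(25, 0.5, seed=seed)
        w = 10
        db = build_ratios(seq, w, default_model)
        tables = inside_banded(seq, w, default_model)
        logz, la, lb = global_reference_fold(seq, w, default_model)
        for i in range(0, seq.n + 1, 3):
            for j in range(i, min(seq.n, i + w) + 1, 2):
                expected = logz - la[i] - lb[j]
                assert ratio_r(i, j, db, tables) == pytest.approx(expected, abs=1e-9)

    def test_span_violation_rejected(self, gaaac, zero_model):
        db = build_ratios(gaaac, 5, zero_model)
        tables = inside_banded(gaaac, 5, zero_model)
        with pytest.raises(ValueError):
            ratio_r(3, 1, db, tables)


class TestOutsideOverZ:
    def test_unreachable_state_is_zero(self, gaaac, zero_model):
        db = build_ratios(gaaac, 5, zero_model)
        tables = inside_banded(gaaac, 5, zero_model)
        assert outside_over_z("Multi", 1, 4, db, tables) == 0.0

    def test_gaaac_stem_outside_is_half(self, gaaac, zero_model):
        db = build_ratios(gaaac, 5, zero_model)
        tables = inside_banded(gaaac, 5, zero_model)
        assert outside_over_z("Stem", 0, 5, db, tables) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_reference_fold_window_sum(self, seed, default_model):
        """beta_state(k,l)/Z equals the sum over windows of local outside / r."""
        seq = random_sequence(18, 0.6, seed=seed + 30)
        w = 10
        f = Fold(seq, w=w, model=default_model)
        pairs = potential_outermost_pairs(seq, w)
        locals_ = {p: outside_local(f.tables, p) for p in pairs}
        for state in ("Stem", "StemEnd", "Multi2"):
            for k in range(seq.n + 1):
                for l in range(k, min(seq.n, k + w) + 1):
                    acc = 0.0
                    for (i, j) in pairs:
                        if i <= k and l <= j:
                            loc = locals_[(i, j)][state][k, l - k]
                            if loc != -np.inf:
                                acc += np.exp(loc - ratio_r(i, j, f.db, f.tables))
                    direct = outside_over_z(state, k, l, f.db, f.tables)
                    assert direct == pytest.approx(acc, abs=1e-9)


class TestTransitionProb:
    def test_zero_weight_transition_is_zero(self, zero_model):
        seq = RnaSequence("a", "AAAAAAAA")
        f = Fold(seq, w=6, model=zero_model)
        assert transition_prob(("Outer", "OuterStem", 0, 6), f.db, f.tables) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_anchor_decomposition_sums_to_one(self, seed, default_model):
        seq = random_sequence(16, 0.6, seed=seed + 50)
        w = 9
        f = Fold(seq, w=w, model=default_model)
        pairs = potential_outermost_pairs(seq, w)
        for anchor in range(seq.n):
            total = transition_prob(("Outer", "Outer", anchor), f.db, f.tables)
            for (p, q) in pairs:
                if p <= anchor < q:
                    total += transition_prob(("Outer", "OuterStem", p, q), f.db, f.tables)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_oracle_ensemble_frequencies(self, default_model):
        seq = random_sequence(18, 0.6, seed=77)
        w = 10
        f = Fold(seq, w=w, model=default_model)
        ens = enumerate_ensemble(seq, w, default_model)
        for t in range(1, seq.n + 1):
            p = transition_prob(("Outer", "Outer", t - 1), f.db, f.tables)
            assert p == pytest.approx(ens.exterior_unpaired_frequency(t), abs=1e-9)
        for (p, q) in potential_outermost_pairs(seq, w):
            tp = transition_prob(("Outer", "OuterStem", p, q), f.db, f.tables)
            assert tp == pytest.approx(ens.outermost_frequency(p, q), abs=1e-9)


class TestScaleFreeness:
    def test_fold_changes_bounded_on_long_sequence(self, default_model):
        """No overflow at large N: |log dalpha| stays model-bounded."""
        seq = random_sequence(100_000, 0.5, seed=99)
        db = build_ratios(seq, 25, default_model)
        bound = 25 * 3.5 / default_model.rt  # crude C*W bound
        assert np.abs(db.log_dalpha).max() < bound
        assert np.abs(db.log_dbeta).max() < bound
        assert np.all(np.isfinite(db.log_dalpha))


class TestDatabaseFile:
    def test_round_trip_is_bit_exact(self, default_model, tmp_path):
        seq = random_sequence(60, 0.5, seed=6)
        db = build_ratios(seq, 15, default_model)
        path = tmp_path / "db.tsv"
        db.to_file(path)
        back = RatioDatabase.from_file(path)
        assert np.array_equal(back.log_dalpha, db.log_dalpha)
        assert np.array_equal(back.log_dbeta, db.log_dbeta)
        assert back.dumps() == db.dumps()

    def test_digest_mismatch_detected(self, default_model):
        seq = random_sequence(30, 0.5, seed=7)
        other = random_sequence(30, 0.5, seed=8)
        db = build_ratios(seq, 10, default_model)
        tables = inside_banded(other, 10, default_model)
        with pytest.raises(DatabaseError):
            attach_ratios(tables, db)
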