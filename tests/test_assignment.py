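import itertools
import math

import numpy as np
import pytest

import registercheck as rc
from registercheck.alphabet import AA_ORDER, N_TYPES, seq_to_indices
from registercheck.assignment import (all_placement_scores, best_placement,
                                      identify_reference, placement_pvalue,
                                      placement_score)
from registercheck.scoring import ResidueTypeProfile, uniform_profile
from registercheck.synthetic import profile_from_sequence, random_sequence


def one_hot(sequence):
    rows = np.zeros((len(sequence), N_TYPES))
    rows[np.arange(len(sequence)), seq_to_indices(sequence)] = 1.0
    return ResidueTypeProfile(rows)


def brute_force_score(profile, reference, offset):
    logp = profile.log_probabilities()
    ref = seq_to_indices(reference)
    return sum(logp[i, ref[offset + i]] for i in range(profile.length))


class TestPlacementScore:
    def test_one_hot_exact_match_scores_zero(self):
        ref = "ACDEFGHIKLMNP"
        profile = one_hot(ref[3:8])
        assert placement_score(profile, ref, 3) == pytest.approx(0.0)

    def test_uniform_profile_closed_form(self):
        profile = uniform_profile(12)
        ref = random_sequence(np.random.default_rng(0), 30)
        for offset in (0, 7, 18):
            assert placement_score(profile, ref, offset) == pytest.approx(
                12 * math.log(1 / 20))

    def test_matches_brute_force_at_every_offset(self):
        rng = np.random.default_rng(2)
        profile = ResidueTypeProfile(rng.dirichlet(np.ones(20), size=5))
        ref = random_sequence(rng, 12)
        for offset in range(12 - 5 + 1):
            assert placement_score(profile, ref, offset) == pytest.approx(
                brute_force_score(profile, ref, offset))

    def test_offset_out_of_range(self):
        profile = uniform_profile(10)
        with pytest.raises(ValueError):
            placement_score(profile, "A" * 15, 6)
        with pytest.raises(ValueError):
            placement_score(profile, "A" * 15, -1)


class TestBestPlacement:
    def test_unique_subsequence_found(self):
        ref = "MKVLAWDERTYGHCISPQNF"
        profile = one_hot(ref[6:12])
        offset, score = best_placement(profile, ref)
        assert offset == 6
        assert score == pytest.approx(0.0)

    def test_uniform_ties_break_to_smallest_offset(self):
        offset, _ = best_placement(uniform_profile(10), "A" * 30)
        assert offset == 0

    def test_oracle_equivalence_100_instances(self):
        """Vectorized search equals exhaustive enumeration everywhere."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            L = int(rng.integers(3, 11))
            N = int(rng.integers(L, 51))
            profile = ResidueTypeProfile(rng.dirichlet(np.ones(20), size=L))
            ref = random_sequence(rng, N)
            scores = [brute_force_score(profile, ref, o) for o in range(N - L + 1)]
            expected_offset = int(np.argmax(scores))
            offset, score = best_placement(profile, ref)
            assert offset == expected_offset
            assert score == pytest.approx(scores[expected_offset])

    def test_reference_shorter_than_profile(self):
        with pytest.raises(ValueError):
            best_placement(uniform_profile(10), "ACDEF")


class TestPlacementPvalue:
    def test_uniform_profile_degenerate_null(self):
        profile = uniform_profile(10)
        ref = random_sequence(np.random.default_rng(1), 60)
        _, score = best_placement(profile, ref)
        assert placement_pvalue(profile, ref, score) == 1.0

    def test_unique_one_hot_10mer_is_significant(self):
        rng = np.random.default_rng(3)
        ref = random_sequence(rng, 200)
        profile = one_hot(ref[90:100])
        offset, score = best_placement(profile, ref)
        assert offset == 90
        p = placement_pvalue(profile, ref, score, n_null=200, seed=7)
        assert p <= 0.01

    def test_two_letter_alphabet_matches_exact_enumeration(self):
        """Reference AAACCC, fragment favouring ACC: the Gumbel-calibrated
        p-value approximates the exact tail over all 20 distinguishable
        shuffles of the reference."""
        ref = "AAACCC"
        rows = np.full((3, N_TYPES), 1e-6)
        ia, ic = AA_ORDER.index("A"), AA_ORDER.index("C")
        for i, aa in enumerate([ia, ic, ic]):
            rows[i, aa] = 0.7
            rows[i, ia if aa == ic else ic] = 0.3 - 1e-6 * (N_TYPES - 2)
        profile = ResidueTypeProfile(rows / rows.sum(axis=1, keepdims=True))
        _, observed = best_placement(profile, ref)
        # exact null: every distinct arrangement of AAACCC is equally likely
        best_scores = []
        for perm in set(itertools.permutations(ref)):
            _, s = best_placement(profile, "".join(perm))
            best_scores.append(s)
        exact = np.mean([s >= observed - 1e-9 for s in best_scores])
        p = placement_pvalue(profile, ref, observed, n_null=400, seed=5)
        assert p == pytest.approx(exact, abs=0.15)

    def test_n_null_floor(self):
        with pytest.raises(ValueError):
            placement_pvalue(uniform_profile(10), "A" * 40, 0.0, n_null=10)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        ref = random_sequence(rng, 100)
        profile = profile_from_sequence(ref[20:40], 0.6, rng)
        _, score = best_placement(profile, ref)
        a = placement_pvalue(profile, ref, score, seed=11)
        b = placement_pvalue(profile, ref, score, seed=11)
        assert a == b


class TestIdentifyReference:
    def test_true_sequence_ranked_first(self):
        rng = np.random.default_rng(0)
        true_seq = random_sequence(rng, 150)
        database = [("true", true_seq)] + [
            (f"decoy_{i}", "".join(rng.permutation(list(true_seq))))
            for i in range(19)]
        profile = profile_from_sequence(true_seq, 0.6, rng)
        matches = identify_reference(profile, database, n_null=100, seed=rng)
        assert matches and matches[0].sequence_id == "true"

    def test_uniform_profile_returns_no_match(self):
        rng = np.random.default_rng(1)
        database = [(f"s{i}", random_sequence(rng, 80)) for i in range(5)]
        assert identify_reference(uniform_profile(40), database, seed=2) == []

    def test_single_sequence_perfect_profile(self):
        rng = np.random.default_rng(2)
        seq = random_sequence(rng, 120)
        profile = one_hot(seq)
        matches = identify_reference(profile, [("only", seq)], n_null=999, seed=3)
        assert len(matches) == 1
        assert matches[0].e_value <= 1e-6

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            identify_reference(uniform_profile(10), [])


class TestStatisticalProperties:
    def test_monotone_in_signal(self):
        """Raising profile accuracy never raises the median p-value of
        correct placements (checked over an accuracy grid)."""
        rng = np.random.default_rng(8)
        medians = []
        for accuracy in (0.2, 0.4, 0.6, 0.8):
            ps = []
            for _ in range(25):
                ref = random_sequence(rng, 150)
                profile = profile_from_sequence(ref[40:60], accuracy, rng)
                _, score = best_placement(profile, ref)
                ps.append(placement_pvalue(profile, ref, score,
                                           n_null=100, seed=rng))
            medians.append(np.median(ps))
        assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))

    def test_longer_fragments_more_conclusive(self):
        """Median -log(p) of correct assignments grows with fragment length."""
        rng = np.random.default_rng(9)
        med = {}
        for L in (20, 40):
            ps = []
            for _ in range(40):
                ref = random_sequence(rng, 150)
                profile = profile_from_sequence(ref[30:30 + L], 0.35, rng)
                _, score = best_placement(profile, ref)
                ps.append(placement_pvalue(profile, ref, score,
                                           n_null=100, seed=rng))
            med[L] = np.median(-np.log(np.array(ps)))
        assert med[40] >= med[20]
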