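"""PWM construction, PWMS scoring, consensus, information, paired test."""

import itertools
import math

import numpy as np
import pytest

from cassex.errors import InvalidBackgroundError, ShapeError, ValidationError
from cassex.pwm import (
    SCORE_FLOOR,
    build_pwm,
    column_information,
    consensus,
    max_score,
    paired_pwms_test,
    score_sequence,
)
from cassex.simulate import sample_donors


def test_build_pwm_closed_form_pseudocount_zero():
    pwm = build_pwm(["GT"] * 4, position_labels=["+1", "+2"], pseudocount=0.0)
    assert score_sequence(pwm, "GT").per_position_contributions[0] == pytest.approx(2.0)
    # unseen base at pseudocount 0 is floored, not -inf
    assert pwm.scores[0, 0] == SCORE_FLOOR


def test_background_matching_counts_scores_zero():
    pwm = build_pwm(["A", "C", "G", "T"], position_labels=["+1"], pseudocount=0.0)
    assert np.allclose(pwm.scores, 0.0)


def test_build_pwm_input_validation():
    with pytest.raises(ShapeError):
        build_pwm(["AC", "ACG"])
    with pytest.raises(InvalidBackgroundError):
        build_pwm(["AC", "AC"], background=[0.5, 0.5, 0.0, 0.0])
    with pytest.raises(ValidationError):
        build_pwm(["AC"])


def test_pseudocounted_frequencies_normalised():
    pwm = build_pwm(["ACGT", "AAAA", "ACGG", "NNNN"], pseudocount=1.0)
    assert np.allclose(pwm.frequencies().sum(axis=0), 1.0)


def test_probability_recovery_improves_with_n():
    """Sampling from a known probability matrix recovers it within +/- 0.02
    at n = 5000, improving on the n = 50 error."""
    rng = np.random.default_rng(7)
    truth = rng.dirichlet([2, 2, 2, 2], size=9).T  # (4, 9)
    errors = {}
    for n in (50, 500, 5000):
        donors = sample_donors(truth, n, seed=123)
        pwm = build_pwm(donors, pseudocount=0.0)
        freq = pwm.counts / n
        errors[n] = np.abs(freq - truth).max()
    assert errors[5000] < 0.02
    assert errors[5000] <= errors[50]


def test_pwms_additivity_against_naive_loop(chr22_pwm):
    rng = np.random.default_rng(1)
    bases = "ACGT"
    for _ in range(50):
        seq = "".join(rng.choice(list(bases), size=13))
        res = score_sequence(chr22_pwm, seq)
        naive = sum(chr22_pwm.scores["ACGT".index(b), j] for j, b in enumerate(seq))
        assert res.score == pytest.approx(naive, abs=1e-12)
        assert res.score == pytest.approx(sum(res.per_position_contributions))


def test_printed_matrix_scores_human_donor(chr22_pwm):
    """Summing the printed columns for the human 5'SS_6 window gives 9.0273."""
    assert score_sequence(chr22_pwm, "TCAAAGTAAGTGA").score == pytest.approx(9.0273, abs=1e-4)


def test_ambiguity_symbol_contributes_zero(chr22_pwm):
    a = score_sequence(chr22_pwm, "TCAAAGTAAGTGA").score
    b = score_sequence(chr22_pwm, "NCAAAGTAAGTGA").score
    assert b == pytest.approx(a - chr22_pwm.scores[3, 0])


def test_length_mismatch_rejected(chr22_pwm):
    with pytest.raises(ShapeError):
        score_sequence(chr22_pwm, "GTAAGT")


def test_argmax_sequence_attains_max_score(chr22_pwm):
    best = consensus(chr22_pwm).sequence
    assert score_sequence(chr22_pwm, best).score == pytest.approx(max_score(chr22_pwm))


def test_printed_matrix_max_score(chr22_pwm):
    assert max_score(chr22_pwm) == pytest.approx(14.3656, abs=1e-4)


def test_any_downward_substitution_strictly_decreases(chr22_pwm):
    seq = consensus(chr22_pwm).sequence
    base_score = score_sequence(chr22_pwm, seq).score
    for j in range(13):
        for b in "ACGT":
            if b == seq[j]:
                continue
            mutated = seq[:j] + b + seq[j + 1:]
            assert score_sequence(chr22_pwm, mutated).score < base_score


def test_consensus_of_printed_matrix(chr22_pwm):
    """Positions -3..+6 of the printed matrix spell the canonical donor
    consensus CAG|GTAAGT."""
    assert consensus(chr22_pwm, columns=slice(2, 11)).sequence == "CAGGTAAGT"
    assert consensus(chr22_pwm).tie_positions == []


def test_uniform_pwm_flags_all_ties():
    pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
    assert consensus(pwm).tie_positions == [0]


def test_planted_consensus_recovered():
    truth = np.full((4, 6), 0.1)
    planted = "GTAAGT"
    for j, b in enumerate(planted):
        truth["ACGT".index(b), j] = 0.7
    pwm = build_pwm(sample_donors(truth, 2000, seed=5))
    assert consensus(pwm).sequence == planted


def test_max_score_bounds_random_sequences():
    rng = np.random.default_rng(3)
    pwm = build_pwm(sample_donors(rng.dirichlet([1] * 4, size=8).T, 200, seed=9))
    top = max_score(pwm)
    for _ in range(1000):
        seq = "".join(rng.choice(list("ACGT"), size=8))
        assert score_sequence(pwm, seq).score <= top + 1e-12


def test_consensus_optimality_exhaustive_small_width():
    pwm = build_pwm(["ACAC", "ACAA", "ACCA", "CCAA", "ACAT"], pseudocount=1.0)
    best = consensus(pwm).sequence
    best_score = score_sequence(pwm, best).score
    for combo in itertools.product("ACGT", repeat=4):
        assert score_sequence(pwm, "".join(combo)).score <= best_score + 1e-12


def test_column_information_closed_forms():
    fixed = build_pwm(["G", "G", "G", "G"], pseudocount=0.0)
    assert column_information(fixed)[0] == pytest.approx(2.0)
    uniform = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
    assert column_information(uniform)[0] == pytest.approx(0.0)


def test_column_information_matches_direct_formula():
    pwm = build_pwm(["GTAAGT", "GTAAGC", "GTGAGT", "GTAATT"], pseudocount=1.0)
    freq = pwm.frequencies()
    for j in range(6):
        H = -sum(p * math.log2(p) for p in freq[:, j] if p > 0)
        assert column_information(pwm)[j] == pytest.approx(2.0 - H)


def test_paired_test_identical_pairs_degenerate_zero():
    res = paired_pwms_test([(1.0, 1.0)] * 5)
    assert res.t_statistic == 0.0 and res.p_value == 1.0 and res.degenerate


def test_paired_test_constant_nonzero_difference_is_infinite():
    res = paired_pwms_test([(1.0, 0.0)] * 4)
    assert res.mean_diff == 1.0
    assert math.isinf(res.t_statistic) and res.degenerate


def test_paired_test_matches_textbook_formula():
    rng = np.random.default_rng(8)
    diffs = rng.normal(2.0, 0.5, size=12)
    pairs = [(d, 0.0) for d in diffs]
    res = paired_pwms_test(pairs)
    t_manual = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(12))
    assert res.t_statistic == pytest.approx(t_manual, abs=1e-9)
    assert res.degrees_of_freedom == 11
    assert res.n_pairs - 1 == res.degrees_of_freedom


def test_column_monotonicity(chr22_pwm):
    """Replacing a base with a higher-scoring one never lowers the PWMS."""
    seq = "TCAAAGTAAGTGA"
    s0 = score_sequence(chr22_pwm, seq).score
    for j in range(13):
        col = chr22_pwm.scores[:, j]
        current = col["ACGT".index(seq[j])]
        for i, b in enumerate("ACGT"):
            if col[i] >= current:
                better = seq[:j] + b + seq[j + 1:]
                assert score_sequence(chr22_pwm, better).score >= s0 - 1e-12
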