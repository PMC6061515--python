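"""The dual-path backtracking search and its independent oracles."""

import numpy as np
import pytest

from altchip import (
    SearchConfig,
    brute_force_oracle,
    ideal_spectrum,
    inject_negative,
    inject_positive,
    interleave,
    max_steps,
    repetition_stats,
    solve,
    verification_element,
    verify_candidate,
)
from altchip.errors import InvalidInstanceError, InvalidParameterError

from conftest import TOY_K, TOY_PREFIX, TOY_TARGET, random_dna


@pytest.mark.parametrize(
    "n, k, expected",
    [(8, 3, (1, 1)), (6, 3, (0, 0)), (100, 8, (42, 42)), (101, 8, (43, 42))],
)
def test_max_steps_split_by_parity(n, k, expected):
    assert max_steps(n, k) == expected


def test_max_steps_rejects_too_short_instances():
    with pytest.raises(InvalidInstanceError):
        max_steps(5, 3)


@pytest.mark.parametrize(
    "odd, even, n, expected",
    [("AGAG", "CTCG", 8, "ACGTACGG"), ("A", "", 1, "A"), ("AG", "C", 3, "ACG")],
)
def test_interleave(odd, even, n, expected):
    assert interleave(odd, even, n) == expected


def test_interleave_rejects_mismatched_lengths():
    with pytest.raises(InvalidInstanceError):
        interleave("AG", "CTG", 5)


def test_verification_element_combines_opposite_postfix_and_new_letter():
    # odd-path postfix ...T, A, G plus a new even nucleotide C (k = 4)
    assert verification_element(["A", "T", "A", "G"], 8, "C", 4) == "TXAXGC"
    # toy instance: even letters at positions 4 and 6 license odd G at 7
    assert verification_element(["C", "T", "C"], 7, "G", 3) == "TXCG"


def test_verification_element_unconstructible_when_opposite_lags():
    assert verification_element(["C", "T"], 7, "G", 3) is None  # needs position 6
    assert verification_element(["C"], 3, "G", 3) is None  # would start before 1


def test_verify_candidate_modes(toy_spectrum):
    odd, even = list("AGA"), list("CTC")  # toy prefix letters
    s2 = toy_spectrum.s2
    # ideal mode: the true continuation G at position 7 verifies via TXCG
    assert verify_candidate(odd, even, "odd", "GXAXG", 1, s2, "ideal", 3)
    # a wrong letter fails: element TXCA is absent
    assert not verify_candidate(odd, even, "odd", "GXAXA", 1, s2, "ideal", 3)
    # weight > 1 is inadmissible without negative errors
    assert not verify_candidate(odd, even, "odd", "AXGXG", 2, s2, "ideal", 3)
    # relaxed negative-mode rule: longer overlap accepted without verification
    assert verify_candidate(odd, even, "odd", "AXGXG", 2, s2, "negative_only", 3)
    assert not verify_candidate(odd, even, "odd", "GXAXA", 1, s2, "negative_only", 3)


def test_toy_instance_unique_solution(toy_spectrum):
    report = solve(toy_spectrum, TOY_PREFIX, 8, SearchConfig(mode="ideal"))
    assert report.sequences == [TOY_TARGET]
    assert not report.timed_out
    sol = report.solutions[0]
    # paths are vertex-disjoint and steps accounting is conserved
    odd_vertices = {v for v, _ in sol.odd_path}
    even_vertices = {v for v, _ in sol.even_path}
    assert not odd_vertices & even_vertices
    assert sum(w for _, w in sol.odd_path) == max_steps(8, 3)[0]
    assert sum(w for _, w in sol.even_path) == max_steps(8, 3)[1]


def test_minimal_instance_returns_prefix(rng):
    target = random_dna(rng, 8)
    spec = ideal_spectrum(target, 4)
    for mode in ("ideal", "positive_only", "negative_only", "both"):
        report = solve(spec, target, 8, SearchConfig(mode=mode))
        assert report.sequences == [target]


def test_inconsistent_declared_length_rejected(toy_spectrum):
    with pytest.raises(InvalidInstanceError):
        solve(toy_spectrum, TOY_PREFIX, 9, SearchConfig())


def test_invalid_mode_rejected():
    with pytest.raises(InvalidParameterError):
        SearchConfig(mode="exhaustive")


def _repeat_free_target(rng, k, extra):
    while True:
        t = random_dna(rng, 2 * k + extra)
        if repetition_stats(t, k).total == 0:
            return t


def test_solve_matches_oracle_ideal_and_positive(rng):
    for trial in range(25):
        k = 3 + trial % 2
        target = _repeat_free_target(rng, k, int(rng.integers(0, 7)))
        n = len(target)
        spec = ideal_spectrum(target, k)
        got = set(solve(spec, target[: 2 * k], n, SearchConfig(mode="ideal")).sequences)
        assert got == brute_force_oracle(spec, target[: 2 * k], n, "ideal")
        assert target in got
        noisy = inject_positive(spec, 10, np.random.default_rng(trial))
        got = set(
            solve(noisy, target[: 2 * k], n, SearchConfig(mode="positive_only")).sequences
        )
        assert got == brute_force_oracle(noisy, target[: 2 * k], n, "positive_only")
        assert target in got


def test_solve_matches_replay_oracle_negative_modes(rng):
    for trial in range(15):
        k = 3 + trial % 2
        target = random_dna(rng, 2 * k + int(rng.integers(1, 6)))
        n = len(target)
        spec = inject_negative(
            ideal_spectrum(target, k), 5, np.random.default_rng(trial)
        )
        cfg = SearchConfig(mode="negative_only", declared_negative_pct=5)
        got = set(solve(spec, target[: 2 * k], n, cfg).sequences)
        exp = brute_force_oracle(
            spec, target[: 2 * k], n, "negative_only", declared_negative_pct=5
        )
        assert got == exp
        # repetition-only flavour: untouched spectrum, shortfalls only
        spec2 = ideal_spectrum(target, k)
        cfg2 = SearchConfig(mode="negative_only", declared_negative_pct=0)
        got2 = set(solve(spec2, target[: 2 * k], n, cfg2).sequences)
        exp2 = brute_force_oracle(
            spec2, target[: 2 * k], n, "negative_only", declared_negative_pct=0
        )
        assert got2 == exp2
        assert target in got2


def test_emitted_solutions_explain_the_spectrum_exactly_in_ideal_mode(rng):
    for _ in range(10):
        target = _repeat_free_target(rng, 4, 6)
        spec = ideal_spectrum(target, 4)
        report = solve(spec, target[:8], len(target), SearchConfig(mode="ideal"))
        assert report.sequences  # the target is always reconstructible
        for seq in report.sequences:
            assert ideal_spectrum(seq, 4).s1 == spec.s1
            assert ideal_spectrum(seq, 4).s2 == spec.s2


def test_solver_reports_are_deterministic(rng):
    target = random_dna(rng, 60)
    spec = inject_negative(ideal_spectrum(target, 6), 3, np.random.default_rng(9))
    cfg = SearchConfig(mode="negative_only", declared_negative_pct=3, time_limit=30)
    r1 = solve(spec, target[:12], 60, cfg)
    r2 = solve(spec, target[:12], 60, cfg)
    assert not r1.timed_out and not r2.timed_out  # the search space is exhausted
    assert r1.sequences == r2.sequences
    assert (r1.nodes_expanded, r1.backtracks) == (r2.nodes_expanded, r2.backtracks)
    # solutions are pairwise distinct sequences
    assert len(set(r1.sequences)) == len(r1.sequences)


def test_time_limit_monotonicity(rng):
    target = random_dna(rng, 30)
    spec = inject_negative(ideal_spectrum(target, 4), 5, np.random.default_rng(2))
    cfg_short = SearchConfig(mode="negative_only", declared_negative_pct=5, time_limit=0.05)
    cfg_long = SearchConfig(mode="negative_only", declared_negative_pct=5, time_limit=10)
    short = set(solve(spec, target[:8], 30, cfg_short).sequences)
    long = set(solve(spec, target[:8], 30, cfg_long).sequences)
    assert short <= long


def test_vertex_disjointness_and_prefix_on_all_solutions(rng):
    target = random_dna(rng, 30)
    k = 3
    spec = inject_negative(ideal_spectrum(target, k), 4, np.random.default_rng(4))
    cfg = SearchConfig(mode="negative_only", declared_negative_pct=4, time_limit=3)
    report = solve(spec, target[: 2 * k], 30, cfg)
    for sol in report.solutions:
        assert sol.sequence.startswith(target[: 2 * k])
        odd_vertices = [v for v, _ in sol.odd_path]
        even_vertices = [v for v, _ in sol.even_path]
        assert len(set(odd_vertices + even_vertices)) == len(odd_vertices) + len(
            even_vertices
        )
        odd_letters = sol.sequence[0::2]
        even_letters = sol.sequence[1::2]
        assert interleave(odd_letters, even_letters, 30) == sol.sequence
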