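"""Instance generation, the study pipeline and metric accounting."""

import math

import numpy as np
import pytest

from altchip import (
    ErrorProfile,
    ExperimentConfig,
    InstanceResult,
    generate_target,
    run_grid,
    run_instance,
    summarize,
)
from altchip.errors import InvalidParameterError
from altchip.experiments import instance_seed
from altchip.spectrum_sim import RepetitionStats

from conftest import random_dna


def _fake_result(n_solutions: int, target_found: bool = True) -> InstanceResult:
    seqs = tuple(f"SEQ{i}" for i in range(n_solutions))
    return InstanceResult(
        target="SEQ0",
        n=8,
        k=3,
        profile=ErrorProfile(),
        mode="ideal",
        sequences=seqs,
        target_found=target_found and n_solutions > 0,
        ambiguous=n_solutions > 1,
        repetitions=RepetitionStats(0, 0),
        elapsed=0.0,
        timed_out=False,
    )


def test_generate_target_modes(rng):
    assert generate_target(0, rng) == ""
    a = generate_target(25, np.random.default_rng(3))
    b = generate_target(25, np.random.default_rng(3))
    assert a == b and set(a) <= set("ACGT")
    pool = "ACGT" * 1000
    sub = generate_target(100, np.random.default_rng(1), pool)
    assert len(sub) == 100 and sub in pool
    with pytest.raises(InvalidParameterError):
        generate_target(10, rng, pool="ACGT")


def test_run_instance_error_free_pipeline(rng):
    from altchip import repetition_stats

    while True:  # repeat-free target: the spectrum is genuinely ideal
        target = random_dna(rng, 50)
        if repetition_stats(target, 6).total == 0:
            break
    result = run_instance(target, 6, ErrorProfile(), time_limit=30, seed=1)
    assert result.mode == "ideal"
    assert result.target_found
    assert target in result.sequences


def test_run_instance_repetition_shortfall_switches_mode(rng):
    from altchip import repetition_stats

    while True:  # force at least one repeated window
        target = random_dna(rng, 60)
        if repetition_stats(target, 4).total > 0:
            break
    result = run_instance(
        target, 4, ErrorProfile(), time_limit=10, max_solutions=1, seed=1
    )
    assert result.mode == "negative_only"


def test_run_instance_minimal_length(rng):
    target = random_dna(rng, 8)
    result = run_instance(target, 4, ErrorProfile(), time_limit=5, seed=0)
    assert result.sequences == (target,)
    assert not result.ambiguous


def test_run_instance_mode_selection(rng):
    target = random_dna(rng, 60)
    neg = run_instance(
        target, 6, ErrorProfile(negative_pct=3), time_limit=20, max_solutions=1, seed=2
    )
    assert neg.mode == "negative_only"
    both = run_instance(
        target,
        6,
        ErrorProfile(negative_pct=3, positive_pct=3),
        time_limit=20,
        max_solutions=1,
        seed=2,
    )
    assert both.mode == "both"


def test_summarize_counts_and_averages():
    results = [_fake_result(1) for _ in range(100)] + [_fake_result(2)]
    m = summarize(results)
    assert m.instances == 101
    assert m.found_count == 101
    assert m.unambiguous_count == 100
    assert m.ambiguous_count == 1
    assert math.isclose(m.avg_solutions, 102 / 101)
    # zero-solution instances count in denominators but not in avg_solutions
    mixed = summarize([_fake_result(1), _fake_result(0, target_found=False)])
    assert mixed.found_count == 1 and mixed.instances == 2
    assert mixed.avg_solutions == 1.0
    assert mixed.cell == "1(1)[1]"
    with pytest.raises(InvalidParameterError):
        summarize([])


def test_instance_seed_is_stable_and_distinct():
    p = ErrorProfile(negative_pct=1)
    s = instance_seed(7, 8, 100, p, 3)
    assert s == instance_seed(7, 8, 100, p, 3)
    assert s != instance_seed(7, 8, 100, p, 4)
    assert s != instance_seed(8, 8, 100, p, 3)
    assert 0 <= s < 2**31


def test_run_grid_reproducible_and_sound():
    config = ExperimentConfig(
        k_values=(6,),
        lengths=(40,),
        cells=(ErrorProfile(), ErrorProfile(negative_pct=3)),
        instances=3,
        time_limit=20.0,
        master_seed=5,
    )
    t1 = run_grid(config)
    t2 = run_grid(config)
    assert t1.equals(t2)
    assert list(t1["instances"]) == [3, 3]
    assert (t1["found"] <= t1["instances"]).all()
    # error-free row: every solved instance contains the target
    row = t1[t1["negative_pct"] == 0].iloc[0]
    assert row["target_found"] == row["found"]
    assert row["cell"] == f"{row['found']}({row['unambiguous']})[{row['target_found']}]"


def test_experiment_config_validation():
    with pytest.raises(InvalidParameterError):
        ExperimentConfig(k_values=(4,), lengths=(6,), cells=(ErrorProfile(),))
    with pytest.raises(InvalidParameterError):
        ExperimentConfig(
            k_values=(4,), lengths=(40,), cells=(ErrorProfile(),), instances=0
        )
    with pytest.raises(InvalidParameterError):
        ErrorProfile(negative_pct=150)
    with pytest.raises(InvalidParameterError):
        ErrorProfile(negative_pct=2, repetition_only=True)
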