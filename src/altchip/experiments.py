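"""Synthetic-instance generation and the simulation-study harness.

The study protocol: draw a target sequence (uniform i.i.d. letters by
default, or a random substring of a user-supplied FASTA pool emulating merged
coding sequences), build its ideal spectrum, inject the requested errors,
then solve with the first ``2k`` nucleotides given and a wall-clock limit.
Per-cell metrics follow the three-value convention
``found(unambiguous)[target_found]`` plus the average number of solutions
over the solved instances.

The solver mode for an instance is selected from the declared error profile
plus the one negative-error signal a real experiment would have: a spectrum
set smaller than its theoretical ideal cardinality proves negative errors
(typically repetition losses) even when none were declared.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .reconstructor import SearchConfig, solve
from .spectrum_sim import (
    ErrorProfile,
    RepetitionStats,
    ideal_cardinality,
    ideal_spectrum,
    inject_negative,
    inject_positive,
    repetition_stats,
)

_LETTERS = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark grid: chip sizes x target lengths x error cells."""

    k_values: Tuple[int, ...]
    lengths: Tuple[int, ...]
    cells: Tuple[ErrorProfile, ...]
    instances: int = 100
    time_limit: float = 60.0
    max_solutions: int = 0
    master_seed: int = 0
    source: str = "uniform"  # or "fasta-pool"
    pool: Optional[str] = None  # concatenated pool sequence for "fasta-pool"

    def __post_init__(self) -> None:
        if self.instances < 1:
            raise InvalidParameterError("instances must be >= 1")
        if self.source not in ("uniform", "fasta-pool"):
            raise InvalidParameterError(f"unknown target source {self.source!r}")
        for k in self.k_values:
            for n in self.lengths:
                if n < 2 * k:
                    raise InvalidParameterError(
                        f"length {n} below minimum 2k = {2 * k} for k={k}"
                    )


@dataclass
class InstanceResult:
    """Outcome of one simulated instance."""

    target: str
    n: int
    k: int
    profile: ErrorProfile
    mode: str
    sequences: Tuple[str, ...]
    target_found: bool
    ambiguous: bool
    repetitions: RepetitionStats
    elapsed: float
    timed_out: bool


@dataclass
class Metrics:
    """Per-cell summary in the study's accounting."""

    instances: int
    found_count: int
    target_found_count: int
    unambiguous_count: int
    ambiguous_count: int
    avg_solutions: float
    avg_repetitions: float

    @property
    def cell(self) -> str:
        """The three-value cell string ``found(unambiguous)[target_found]``."""
        return f"{self.found_count}({self.unambiguous_count})[{self.target_found_count}]"


def generate_target(length: int, rng: np.random.Generator, pool: Optional[str] = None) -> str:
    """Draw a target sequence: i.i.d. uniform letters, or a uniformly placed
    substring of ``pool`` when one is given."""
    if length == 0:
        return ""
    if pool is None:
        idx = rng.integers(0, 4, size=length)
        return _LETTERS[idx].tobytes().decode("ascii")
    if len(pool) < length:
        raise InvalidParameterError(
            f"pool of length {len(pool)} shorter than requested target ({length})"
        )
    off = int(rng.integers(0, len(pool) - length + 1))
    return pool[off : off + length]


def instance_seed(master_seed: int, k: int, n: int, profile: ErrorProfile, index: int) -> int:
    """Stable per-instance seed so any cell can be recomputed independently."""
    key = (
        f"{master_seed}|{k}|{n}|{profile.negative_pct}|{profile.positive_pct}|"
        f"{int(profile.repetition_only)}|{index}"
    )
    return zlib.crc32(key.encode("ascii")) & 0x7FFFFFFF


def _select_mode(profile: ErrorProfile, shortfall: bool) -> str:
    negative = profile.negative_pct > 0 or profile.repetition_only or shortfall
    positive = profile.positive_pct > 0
    if negative and positive:
        return "both"
    if negative:
        return "negative_only"
    if positive:
        return "positive_only"
    return "ideal"


def run_instance(
    target: str,
    k: int,
    profile: ErrorProfile,
    time_limit: float = 60.0,
    max_solutions: int = 0,
    seed: int = 0,
) -> InstanceResult:
    """Full pipeline for one instance: spectrum, errors, solve, flags."""
    n = len(target)
    spectrum = ideal_spectrum(target, k)
    reps = repetition_stats(target, k)
    rng = np.random.default_rng(seed)
    if profile.negative_pct:
        spectrum = inject_negative(spectrum, profile.negative_pct, rng)
    if profile.positive_pct:
        spectrum = inject_positive(spectrum, profile.positive_pct, rng)
    win1, win2 = ideal_cardinality(n, k)
    shortfall = len(spectrum.s1) < win1 or len(spectrum.s2) < win2
    mode = _select_mode(profile, shortfall)
    config = SearchConfig(
        mode=mode,
        time_limit=time_limit,
        max_solutions=max_solutions,
        declared_negative_pct=profile.negative_pct,
    )
    report = solve(spectrum, target[: 2 * k], n, config)
    seqs = tuple(report.sequences)
    return InstanceResult(
        target=target,
        n=n,
        k=k,
        profile=profile,
        mode=mode,
        sequences=seqs,
        target_found=target in seqs,
        ambiguous=len(seqs) > 1,
        repetitions=reps,
        elapsed=report.elapsed,
        timed_out=report.timed_out,
    )


def summarize(results: Sequence[InstanceResult]) -> Metrics:
    """Aggregate instance outcomes into the study's cell metrics.

    ``avg_solutions`` averages over instances with at least one solution
    (NaN when none solved); zero-solution instances still count in the
    denominators of the other fields.
    """
    if not results:
        raise InvalidParameterError("cannot summarize an empty result list")
    solved = [r for r in results if r.sequences]
    found = len(solved)
    return Metrics(
        instances=len(results),
        found_count=found,
        target_found_count=sum(r.target_found for r in results),
        unambiguous_count=sum(len(r.sequences) == 1 for r in results),
        ambiguous_count=sum(r.ambiguous for r in results),
        avg_solutions=(
            float(np.mean([len(r.sequences) for r in solved])) if solved else float("nan")
        ),
        avg_repetitions=float(np.mean([r.repetitions.total for r in results])),
    )


def _spawn_rngs(seed: int) -> Tuple[np.random.Generator, int]:
    """Independent target-rng and error-injection seed from one instance seed."""
    ss = np.random.SeedSequence(seed)
    child_target, child_err = ss.spawn(2)
    err_seed = int(child_err.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
    return np.random.default_rng(child_target), err_seed


def run_cell(
    k: int,
    n: int,
    profile: ErrorProfile,
    instances: int,
    time_limit: float = 60.0,
    max_solutions: int = 0,
    master_seed: int = 0,
    pool: Optional[str] = None,
) -> List[InstanceResult]:
    """Run the seeded instances of one grid cell."""
    out = []
    for i in range(instances):
        seed = instance_seed(master_seed, k, n, profile, i)
        rng_target, err_seed = _spawn_rngs(seed)
        target = generate_target(n, rng_target, pool)
        out.append(
            run_instance(target, k, profile, time_limit, max_solutions, seed=err_seed)
        )
    return out


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Metrics table over the whole grid, one row per (k, n, error cell)."""
    rows = []
    for k in config.k_values:
        for n in config.lengths:
            for profile in config.cells:
                results = run_cell(
                    k,
                    n,
                    profile,
                    config.instances,
                    config.time_limit,
                    config.max_solutions,
                    config.master_seed,
                    config.pool,
                )
                m = summarize(results)
                rows.append(
                    {
                        "k": k,
                        "n": n,
                        "negative_pct": profile.negative_pct,
                        "positive_pct": profile.positive_pct,
                        "repetition_only": profile.repetition_only,
                        "instances": m.instances,
                        "found": m.found_count,
                        "unambiguous": m.unambiguous_count,
                        "ambiguous": m.ambiguous_count,
                        "target_found": m.target_found_count,
                        "avg_solutions": m.avg_solutions,
                        "avg_repetitions": m.avg_repetitions,
                        "cell": m.cell,
                    }
                )
    return pd.DataFrame(rows)
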