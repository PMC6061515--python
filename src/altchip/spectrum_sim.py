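"""Hybridization-spectrum simulation: ideal spectra and error injection.

An ideal spectrum of a target sequence is the pair of sets obtained by masking
every sliding window of length ``l1`` (S1 pattern) and ``l2`` (S2 pattern).
Spectra are sets, not multisets: identical fragments of the target collapse to
one element, which is the repetition-induced flavour of negative errors.

General negative errors are simulated by removing elements, positive errors by
adding near-duplicates (one natural letter substituted) of existing elements.
Error counts are percentages of the per-set window count ``n - l + 1`` (the
only base determined by ``n`` alone), rounded half-up.  Removal happens before
addition so that an injected false element can never be removed again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .chip_model import (
    DNA_ALPHABET,
    is_s1_element,
    is_s2_element,
    s1_mask,
    s2_mask,
)
from .errors import InvalidInstanceError, InvalidParameterError, InvalidSpectrumError


@dataclass(frozen=True)
class Spectrum:
    """The sequence evidence available to the solver.

    Attributes
    ----------
    s1, s2 : frozenset of str
        S1-type and S2-type elements that hybridized (set semantics;
        multiplicities are unknown by assumption).
    k : int
        Chip parameter.
    n : int
        Declared length of the target sequence.
    """

    s1: frozenset
    s2: frozenset
    k: int
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "s1", frozenset(self.s1))
        object.__setattr__(self, "s2", frozenset(self.s2))
        for e in self.s1:
            if not is_s1_element(e, self.k):
                raise InvalidSpectrumError(f"not an S1 element for k={self.k}: {e!r}")
        for e in self.s2:
            if not is_s2_element(e, self.k):
                raise InvalidSpectrumError(f"not an S2 element for k={self.k}: {e!r}")


@dataclass(frozen=True)
class ErrorProfile:
    """Error levels applied to an ideal spectrum.

    ``repetition_only`` declares that no general (detection-loss) negative
    errors are present beyond the inherent set-deduplication; it requires
    ``negative_pct == 0``.
    """

    negative_pct: float = 0.0
    positive_pct: float = 0.0
    repetition_only: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for pct in (self.negative_pct, self.positive_pct):
            if not 0 <= pct <= 100:
                raise InvalidParameterError(f"error percentage out of [0, 100]: {pct}")
        if self.repetition_only and self.negative_pct:
            raise InvalidParameterError(
                "repetition_only profiles cannot also declare general negative errors"
            )


@dataclass(frozen=True)
class RepetitionStats:
    """Repetition-induced element losses (windows minus distinct elements)."""

    s1_losses: int
    s2_losses: int

    @property
    def total(self) -> int:
        return self.s1_losses + self.s2_losses


def round_half_up(x: float) -> int:
    """Round a non-negative float with .5 going up (error-count convention)."""
    return int(math.floor(x + 0.5))


def ideal_cardinality(n: int, k: int) -> Tuple[int, int]:
    """Window counts ``(n - l1 + 1, n - l2 + 1)`` — the error-free set sizes
    of a repetition-free target, and the percentage base for error injection."""
    if n < 2 * k:
        raise InvalidInstanceError(f"target length {n} below minimum 2k = {2 * k}")
    return n - (2 * k - 1) + 1, n - (2 * k - 2) + 1


def _check_target(target: str, k: int) -> None:
    if len(target) < 2 * k:
        raise InvalidInstanceError(
            f"target of length {len(target)} too short for k={k} (need >= {2 * k})"
        )
    for ch in target:
        if ch not in DNA_ALPHABET:
            raise InvalidInstanceError(f"target must be over {{A,C,G,T}}, got {ch!r}")


def ideal_spectrum(target: str, k: int) -> Spectrum:
    """Error-free spectrum of ``target``: masks of all sliding windows.

    Repetition losses are implicit in the set semantics.
    """
    target = target.upper()
    _check_target(target, k)
    n = len(target)
    l1, l2 = 2 * k - 1, 2 * k - 2
    s1 = frozenset(s1_mask(target[i : i + l1]) for i in range(n - l1 + 1))
    s2 = frozenset(s2_mask(target[i : i + l2]) for i in range(n - l2 + 1))
    return Spectrum(s1=s1, s2=s2, k=k, n=n)


def repetition_stats(target: str, k: int) -> RepetitionStats:
    """Count elements lost to repeated (identically masked) windows."""
    target = target.upper()
    _check_target(target, k)
    spec = ideal_spectrum(target, k)
    win1, win2 = ideal_cardinality(len(target), k)
    return RepetitionStats(win1 - len(spec.s1), win2 - len(spec.s2))


def inject_negative(spectrum: Spectrum, pct: float, rng: np.random.Generator) -> Spectrum:
    """Remove ``round(pct% of window count)`` elements from each set, uniformly.

    Never removes more than a set holds.  ``pct = 0`` is the identity.
    """
    if not 0 <= pct <= 100:
        raise InvalidParameterError(f"pct out of [0, 100]: {pct}")
    if pct == 0:
        return spectrum
    win1, win2 = ideal_cardinality(spectrum.n, spectrum.k)
    new_sets = []
    for members, win in ((spectrum.s1, win1), (spectrum.s2, win2)):
        pool = sorted(members)
        r = min(round_half_up(pct / 100.0 * win), len(pool))
        drop = set()
        if r:
            idx = rng.choice(len(pool), size=r, replace=False)
            drop = {pool[i] for i in idx}
        new_sets.append(frozenset(m for m in members if m not in drop))
    return Spectrum(s1=new_sets[0], s2=new_sets[1], k=spectrum.k, n=spectrum.n)


_NATURAL_POSITIONS = {}


def _natural_positions(length: int) -> list:
    """String indices of the natural letters of an element of ``length``."""
    try:
        return _NATURAL_POSITIONS[length]
    except KeyError:
        if length % 2 == 1:  # S1
            pos = list(range(0, length, 2))
        else:  # S2
            pos = list(range(0, length - 1, 2)) + [length - 1]
        _NATURAL_POSITIONS[length] = pos
        return pos


def inject_positive(
    spectrum: Spectrum,
    pct: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> Spectrum:
    """Add ``round(pct% of window count)`` false elements to each set.

    Each false element is a copy of a uniformly chosen existing element with
    one uniformly chosen natural letter substituted by a different letter;
    candidates already present are re-drawn (``max_retries`` attempts each).
    """
    if not 0 <= pct <= 100:
        raise InvalidParameterError(f"pct out of [0, 100]: {pct}")
    if pct == 0:
        return spectrum
    win1, win2 = ideal_cardinality(spectrum.n, spectrum.k)
    new_sets = []
    for members, win in ((spectrum.s1, win1), (spectrum.s2, win2)):
        r = round_half_up(pct / 100.0 * win)
        if r and not members:
            raise InvalidSpectrumError(
                "cannot inject positive errors into an empty spectrum set"
            )
        pool = sorted(members)
        current = set(members)
        for _ in range(r):
            for _attempt in range(max_retries):
                base = pool[int(rng.integers(len(pool)))]
                positions = _natural_positions(len(base))
                j = positions[int(rng.integers(len(positions)))]
                others = [c for c in DNA_ALPHABET if c != base[j]]
                repl = others[int(rng.integers(3))]
                cand = base[:j] + repl + base[j + 1 :]
                if cand not in current:
                    current.add(cand)
                    break
            else:
                raise RuntimeError(
                    "could not place a fresh positive error; pattern space exhausted"
                )
        new_sets.append(frozenset(current))
    return Spectrum(s1=new_sets[0], s2=new_sets[1], k=spectrum.k, n=spectrum.n)
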