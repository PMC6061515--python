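"""Alternating-chip probe patterns, derived sizes and masking maps.

The alternating chip is a non-classical SBH microarray whose probes contain a
universal base (written ``X`` here) that pairs with every natural nucleotide.
Probes come in two families, each carrying ``k`` natural letters:

* S1 pattern ``N1 x N2 x ... x Nk`` — length ``l1 = 2k - 1``, natural letters
  at the odd (1-based) positions, ``X`` at the even ones;
* S2 pattern ``N1 x N2 x ... x N(k-1) Nk`` — length ``l2 = 2k - 2``, the last
  two natural letters adjacent, ``X`` at the remaining even positions.

Each family therefore holds ``4**k`` distinct probes and the chip ``2 * 4**k``
in total.  The probe universes are defined implicitly by pattern validation;
they are never enumerated.  Elements are plain strings over ``{A,C,G,T,X}``;
the pattern family is implied by the string length (odd = S1, even = S2).

Positions are 1-based in the documentation (matching the odd/even nucleotide
language of the sequencing model) and 0-based in the code.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError, LengthMismatchError, PatternError

DNA_ALPHABET = "ACGT"
UNIVERSAL = "X"
ALT_ALPHABET = DNA_ALPHABET + UNIVERSAL

_DNA_SET = frozenset(DNA_ALPHABET)


@dataclass(frozen=True)
class ChipSpec:
    """Derived lengths and capacities of an alternating chip.

    Parameters
    ----------
    k : int
        Number of natural letters per probe pattern; must be at least 2
        (smaller values degenerate both patterns).
    """

    k: int

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or isinstance(self.k, bool) or self.k < 2:
            raise InvalidParameterError(
                f"chip parameter k must be an integer >= 2, got {self.k!r}"
            )

    @property
    def l1(self) -> int:
        """Length of an S1-type element (``2k - 1``)."""
        return 2 * self.k - 1

    @property
    def l2(self) -> int:
        """Length of an S2-type element (``2k - 2``)."""
        return 2 * self.k - 2

    @property
    def l_sigma(self) -> int:
        """Natural letters per S1 element, ``(l1 + 1) / 2 = k``."""
        return self.k

    @property
    def per_set_capacity(self) -> int:
        """Distinct probes per pattern family, ``4**k``."""
        return 4**self.k

    @property
    def total_capacity(self) -> int:
        """Probes on the whole chip, ``2 * 4**k``."""
        return 2 * 4**self.k


def chip_spec(k: int) -> ChipSpec:
    """Return the :class:`ChipSpec` for chip parameter ``k``."""
    return ChipSpec(k)


def canonicalize(element: str) -> str:
    """Uppercase ``element`` and check it is over the alternating alphabet."""
    up = element.upper()
    for ch in up:
        if ch not in ALT_ALPHABET:
            raise PatternError(f"illegal character {ch!r} in element {element!r}")
    return up


def _check_natural(fragment: str, what: str = "fragment") -> None:
    for ch in fragment:
        if ch not in _DNA_SET:
            raise PatternError(f"{what} must be over {{A,C,G,T}}, got {ch!r}")


def s1_mask(fragment: str) -> str:
    """Mask a natural fragment of length ``2k - 1`` into its S1-type element.

    Letters at odd 1-based positions are kept, the rest are replaced by the
    universal base, e.g. ``ACGCGAA -> AXGXGXA``.
    """
    if len(fragment) < 3 or len(fragment) % 2 == 0:
        raise LengthMismatchError(
            f"S1 fragment must have odd length 2k-1 >= 3, got {len(fragment)}"
        )
    _check_natural(fragment)
    return "".join(
        ch if i % 2 == 0 else UNIVERSAL for i, ch in enumerate(fragment)
    )


def s2_mask(fragment: str) -> str:
    """Mask a natural fragment of length ``2k - 2`` into its S2-type element.

    Letters at 1-based positions ``1, 3, ..., 2k-3`` and ``2k-2`` are kept
    (the last two natural letters end up adjacent), e.g. ``TACG -> TXCG``.
    """
    last = len(fragment) - 1
    if len(fragment) < 2 or len(fragment) % 2 == 1:
        raise LengthMismatchError(
            f"S2 fragment must have even length 2k-2 >= 2, got {len(fragment)}"
        )
    _check_natural(fragment)
    return "".join(
        ch if (i % 2 == 0 or i == last) else UNIVERSAL
        for i, ch in enumerate(fragment)
    )


def is_s1_element(element: str, k: int | None = None) -> bool:
    """True iff ``element`` follows the S1 pattern (for chip ``k`` if given)."""
    m = len(element)
    if m < 3 or m % 2 == 0:
        return False
    if k is not None and m != 2 * k - 1:
        return False
    return all(
        (ch in _DNA_SET) if i % 2 == 0 else (ch == UNIVERSAL)
        for i, ch in enumerate(element)
    )


def is_s2_element(element: str, k: int | None = None) -> bool:
    """True iff ``element`` follows the S2 pattern (for chip ``k`` if given)."""
    m = len(element)
    if m < 2 or m % 2 == 1:
        return False
    if k is not None and m != 2 * k - 2:
        return False
    last = m - 1
    return all(
        (ch in _DNA_SET) if (i % 2 == 0 or i == last) else (ch == UNIVERSAL)
        for i, ch in enumerate(element)
    )


def element_type(element: str) -> str:
    """Classify a well-formed element as ``"S1"`` or ``"S2"``.

    Raises :class:`PatternError` for strings violating both patterns.
    """
    if is_s1_element(element):
        return "S1"
    if is_s2_element(element):
        return "S2"
    raise PatternError(f"{element!r} matches neither alternating-chip pattern")


def natural_letters(element: str) -> str:
    """Return the natural letters of a well-formed element, in order.

    Both pattern families carry exactly ``k`` natural letters.
    """
    element_type(element)  # validates
    return "".join(ch for ch in element if ch != UNIVERSAL)


def probe_oligo_count(spec: ChipSpec, pattern_type: str) -> int:
    """Number of natural oligonucleotides matching one probe of a family.

    A probe's universal positions each accept any of the four bases, so a
    single S1 probe matches ``4**(k-1)`` oligonucleotides and a single S2
    probe ``4**(k-2)``.
    """
    pt = pattern_type.upper()
    if pt == "S1":
        return 4 ** (spec.k - 1)
    if pt == "S2":
        return 4 ** (spec.k - 2)
    raise InvalidParameterError(f"pattern_type must be 'S1' or 'S2', got {pattern_type!r}")
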