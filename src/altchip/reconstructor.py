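"""Dual-path, verification-driven backtracking reconstruction.

The target sequence is rebuilt as two vertex-disjoint paths through the S1
overlap graph: the odd path supplies the nucleotides at odd target positions,
the even path those at even positions.  Each path starts from a trusted start
vertex (mask of a prefix window) that already contributes ``k`` letters; the
paths then accumulate arc weights until the odd path has gathered
``ceil(n/2) - k`` steps and the even path ``floor(n/2) - k``.

Every candidate extension is screened against the verification set S2: the
S2-like element spanning target positions ``q-2k+3 .. q`` combines the
opposite path's most recent ``k - 1`` letters with the newly added nucleotide
at ``q`` and must be present in S2.  Only nucleotides whose element is already
constructible (the opposite path covers position ``q - 1``) can be checked.

Verification and move admissibility depend on the declared error scenario
(``SearchConfig.mode``):

``ideal`` / ``positive_only``
    No negative errors: consecutive windows all hybridized, so only weight-1
    arcs are admissible and every extension is verified.  An emitted sequence
    must additionally use exactly the ideal number of elements from both sets
    (equality with the spectrum in ``ideal`` mode, full-cardinality subset in
    ``positive_only``).
``negative_only`` / ``both``
    Arcs of weight ``w > 1`` are admissible; they skip ``w - 1`` windows of
    the reconstruction, and every skipped window must be justified: it is
    either an already-visited vertex (a repeat occurrence, free), or absent
    from S1 (charged against the missing-S1 budget), or present in S1 but
    blocked by a lost verification element (charged against the missing-S2
    budget; only available when general negative errors are declared).  Each
    budget is the larger of the declared negative-error count and the
    observed cardinality shortfall of its set.  When general negative errors
    are declared, S2 itself may have lost elements, so per the relaxed rule
    only maximal-overlap (weight-1) candidates are verified; with only
    repetition losses declared, repetitions never remove S2 evidence and
    candidates of every weight are verified on their constructible
    nucleotides.  In ``negative_only`` mode an emitted sequence must use
    every spectrum element (each one occurs among its windows); in ``both``
    mode no set-level count is known.

Backtracking is strictly chronological, and candidate order (weight-ascending,
then lexicographic) is fixed, so the whole search is deterministic; a time
limit and an optional solution cap bound the enumeration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, List, Optional, Set, Tuple

from .alt_graph import AltGraph, StartVertices, start_vertices
from .chip_model import DNA_ALPHABET, UNIVERSAL, natural_letters, s1_mask, s2_mask
from .errors import InvalidInstanceError, InvalidParameterError
from .spectrum_sim import Spectrum, ideal_cardinality, round_half_up

logger = logging.getLogger("altchip.reconstructor")

MODES = ("ideal", "positive_only", "negative_only", "both")


@dataclass
class SearchConfig:
    """Knobs of the backtracking search.

    Parameters
    ----------
    mode : str
        Error scenario, one of :data:`MODES`.
    time_limit : float
        Wall-clock budget in seconds (default 60, the study setting).
    max_solutions : int
        Stop after this many distinct sequences; 0 enumerates until the time
        limit or exhaustion.
    declared_negative_pct : float or None
        Estimated general negative error rate; must be at least the real one.
        In the negative-error modes it sizes the skip budgets and selects
        relaxed (non-zero) versus full (zero/None) verification.
    seed : int or None
        Reserved for randomized tie-breaking; the default search is
        deterministic and ignores it.
    """

    mode: str = "ideal"
    time_limit: float = 60.0
    max_solutions: int = 0
    declared_negative_pct: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.time_limit <= 0:
            raise InvalidParameterError("time_limit must be positive")
        if self.max_solutions < 0:
            raise InvalidParameterError("max_solutions must be >= 0")


@dataclass(frozen=True)
class Solution:
    """One reconstructed sequence with the vertex paths that produced it."""

    sequence: str
    odd_path: Tuple[Tuple[str, int], ...]
    even_path: Tuple[Tuple[str, int], ...]


@dataclass
class SolverReport:
    """Outcome of one :func:`solve` run."""

    solutions: List[Solution] = field(default_factory=list)
    timed_out: bool = False
    nodes_expanded: int = 0
    backtracks: int = 0
    elapsed: float = 0.0

    @property
    def sequences(self) -> List[str]:
        return [s.sequence for s in self.solutions]


def max_steps(n: int, k: int) -> Tuple[int, int]:
    """Step targets ``(maxsteps_o, maxsteps_e)`` for the two paths.

    The odd path must supply ``ceil(n/2)`` nucleotides and the even path
    ``floor(n/2)``; each start vertex already provides ``k`` of them.
    """
    if n < 2 * k:
        raise InvalidInstanceError(f"target length {n} below minimum 2k = {2 * k}")
    return (n + 1) // 2 - k, n // 2 - k


def interleave(odd_letters: str, even_letters: str, n: int) -> str:
    """Merge the parity classes back into the length-``n`` sequence."""
    if len(odd_letters) != (n + 1) // 2 or len(even_letters) != n // 2:
        raise InvalidInstanceError(
            f"cannot interleave {len(odd_letters)} odd and {len(even_letters)} even "
            f"letters into a length-{n} sequence"
        )
    out = []
    for o, e in zip(odd_letters, even_letters):
        out.append(o)
        out.append(e)
    if n % 2 == 1:
        out.append(odd_letters[-1])
    return "".join(out)


def _opposite_index(p: int) -> int:
    # 0-based index of 1-based target position p in its parity letter list
    return p // 2 - 1 if p % 2 == 0 else (p - 1) // 2


def verification_element(opposite_letters, q: int, new_letter: str, k: int) -> Optional[str]:
    """S2-like element licensing a new nucleotide at target position ``q``.

    ``opposite_letters`` are the natural letters reconstructed so far on the
    path of the opposite parity (their positions interleave with ``q``'s
    parity class).  Returns ``None`` when the element is not constructible,
    i.e. the opposite path does not yet cover position ``q - 1``.
    """
    lo = q - 2 * k + 3
    if lo < 1 or len(opposite_letters) < q // 2:
        return None
    chars: List[str] = []
    for p in range(lo, q, 2):
        chars.append(opposite_letters[_opposite_index(p)])
        chars.append(UNIVERSAL)
    chars[-1] = new_letter
    return "".join(chars)


def verify_candidate(
    odd_letters,
    even_letters,
    parity: str,
    candidate: str,
    weight: int,
    s2: Iterable[str],
    mode: str,
    k: int,
    relaxed: Optional[bool] = None,
) -> bool:
    """Reference verification predicate for one candidate extension.

    ``parity`` names the path being extended (``"odd"`` or ``"even"``).
    With ``relaxed`` verification (the default in the negative-error modes)
    weight-1 candidates must pass verification and longer jumps are accepted
    blindly; otherwise every constructible new nucleotide is checked.  Skip
    budgets (see the module docstring) are a separate admissibility layer on
    top of this predicate.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if relaxed is None:
        relaxed = mode in ("negative_only", "both")
    if mode in ("ideal", "positive_only") and weight != 1:
        return False
    if relaxed and weight > 1:
        return True
    s2 = set(s2) if not isinstance(s2, (set, frozenset)) else s2
    if parity == "odd":
        mine, opposite = odd_letters, even_letters
        q0 = 2 * (len(mine) + 1) - 1
    else:
        mine, opposite = even_letters, odd_letters
        q0 = 2 * (len(mine) + 1)
    letters = natural_letters(candidate)[k - weight :]
    for t in range(weight):
        elem = verification_element(opposite, q0 + 2 * t, letters[t], k)
        if elem is not None and elem not in s2:
            return False
    return True


def _negative_budgets(
    spectrum: Spectrum,
    start: StartVertices,
    declared_pct: Optional[float],
) -> Tuple[int, int]:
    """Skip budgets ``(missing_s1, missing_s2)`` for the negative-error modes.

    Each is the larger of the declared negative-error count for its set and
    the observed cardinality shortfall; the start vertices count as present
    since they are restored from the trusted prefix.  The S2 budget is zero
    when no general negative errors are declared: repetition losses never
    remove verification evidence.
    """
    win1, win2 = ideal_cardinality(spectrum.n, spectrum.k)
    have1 = len(spectrum.s1 | {start.odd_start, start.even_start})
    b1 = max(0, win1 - have1)
    b2 = 0
    if declared_pct:
        b1 = max(b1, round_half_up(declared_pct / 100.0 * win1))
        b2 = max(
            round_half_up(declared_pct / 100.0 * win2), win2 - len(spectrum.s2), 0
        )
    return b1, b2


def _emission_ok(seq: str, spectrum: Spectrum, mode: str) -> bool:
    """Mode-dependent acceptance of a completed sequence.

    ideal: the sequence explains the spectrum exactly; positive_only: its
    ideal spectrum has full cardinality and is contained in the given sets
    ("exactly that number of elements from both sets"); negative_only: every
    given element must be used, i.e. occur among the sequence windows; both:
    no set-level constraint can be imposed.
    """
    if mode == "both":
        return True
    k, n = spectrum.k, spectrum.n
    l1, l2 = 2 * k - 1, 2 * k - 2
    win1, win2 = n - l1 + 1, n - l2 + 1
    ws1 = {s1_mask(seq[i : i + l1]) for i in range(win1)}
    ws2 = {s2_mask(seq[i : i + l2]) for i in range(win2)}
    if mode == "ideal":
        return ws1 == spectrum.s1 and ws2 == spectrum.s2
    if mode == "positive_only":
        return (
            len(ws1) == win1
            and len(ws2) == win2
            and ws1 <= spectrum.s1
            and ws2 <= spectrum.s2
        )
    return spectrum.s1 <= ws1 and spectrum.s2 <= ws2  # negative_only


def candidate_extensions(
    graph: AltGraph,
    parity: str,
    last_vertex: str,
    visited: Set[str],
    remaining_steps: int,
) -> List[Tuple[str, int]]:
    """Unverified admissible moves for one path, in deterministic order.

    Successors of the path's last vertex minus already-visited vertices and
    weights that would overshoot the step target.  Verification and the skip
    budgets are applied on top of this list by the search.
    """
    out = []
    for v, w in graph.successors(last_vertex):
        if w > remaining_steps or v in visited:
            continue
        out.append((v, w))
    return out


def solve(spectrum: Spectrum, prefix: str, n: int, config: Optional[SearchConfig] = None) -> SolverReport:
    """Enumerate sequences of length ``n`` consistent with ``spectrum``.

    ``prefix`` is the known first ``2k`` nucleotides of the target.  The
    report lists distinct sequences in discovery order; for a fixed input and
    configuration it is fully deterministic (up to the wall-clock cutoff).
    """
    if config is None:
        config = SearchConfig()
    k = spectrum.k
    if spectrum.n != n:
        raise InvalidInstanceError(
            f"declared spectrum length {spectrum.n} != requested n {n}"
        )
    if n < 2 * k:
        raise InvalidInstanceError(f"target length {n} below minimum 2k = {2 * k}")
    prefix = prefix.upper()
    sv = start_vertices(prefix, k)
    mode = config.mode
    weight1_only = mode in ("ideal", "positive_only")
    relaxed = (
        mode in ("negative_only", "both")
        and (config.declared_negative_pct or 0) > 0
    )
    if weight1_only:
        b1 = b2 = 0
    else:
        b1, b2 = _negative_budgets(spectrum, sv, config.declared_negative_pct)

    t0 = time.monotonic()
    graph = AltGraph(spectrum.s1, sv, k)
    maxo, maxe = max_steps(n, k)
    s2 = spectrum.s2
    nat = graph.naturals
    vertices = graph.vertices
    succ_w = graph._succ_by_weight
    succ_wl = graph._succ_by_weight_letter

    odd: List[str] = list(prefix[0::2])
    even: List[str] = list(prefix[1::2])
    path_o: List[Tuple[str, int]] = [(sv.odd_start, 0)]
    path_e: List[Tuple[str, int]] = [(sv.even_start, 0)]
    visited: Set[str] = {sv.odd_start, sv.even_start}
    # so/se: accumulated steps; used1/used2: consumed skip-budget units
    state = {"so": 0, "se": 0, "used1": 0, "used2": 0}

    solutions: List[Solution] = []
    seen: Set[str] = set()
    nodes = 0
    backtracks = 0
    timed_out = False
    deadline = t0 + config.time_limit

    def pick_parity() -> int:
        so, se = state["so"], state["se"]
        if so < maxo and (se >= maxe or so <= se):
            return 0
        return 1

    def allowed_first_letters(opp: List[str], q: int):
        lo = q - 2 * k + 3
        if lo < 1 or len(opp) < q // 2:
            return None
        chars = []
        for p in range(lo, q, 2):
            chars.append(opp[_opposite_index(p)])
            chars.append(UNIVERSAL)
        stem = "".join(chars[:-1])
        return tuple(c for c in DNA_ALPHABET if stem + c in s2)

    def later_letters_ok(v: str, w: int, q0: int, opp: List[str]) -> bool:
        letters = nat[v][k - w :]
        for t in range(1, w):
            elem = verification_element(opp, q0 + 2 * t, letters[t], k)
            if elem is None:
                break  # not constructible yet; later ones are not either
            if elem not in s2:
                return False
        return True

    def skip_needs(mine: List[str], v: str, w: int, rem1: int, rem2: int):
        """Budget units needed by the w-1 windows a weight-w move skips,
        or None when they exceed the remaining budgets."""
        i = len(mine)
        joined = mine + list(nat[v][k - w :])
        n1 = n2 = 0
        for s in range(1, w):
            m = UNIVERSAL.join(joined[i - k + s : i + s])
            if m in visited:
                continue
            if m in vertices:
                n2 += 1
                if n2 > rem2:
                    return None
            else:
                n1 += 1
                if n1 > rem1:
                    return None
        return n1, n2

    def candidates(par: int) -> List[Tuple[str, int, int, int]]:
        if par == 0:
            last = path_o[-1][0]
            rem = maxo - state["so"]
            mine, opp = odd, even
            q0 = 2 * (len(odd) + 1) - 1
        else:
            last = path_e[-1][0]
            rem = maxe - state["se"]
            mine, opp = even, odd
            q0 = 2 * (len(even) + 1)
        by_w = succ_w.get(last)
        if not by_w:
            return []
        rem1 = b1 - state["used1"]
        rem2 = b2 - state["used2"]
        out: List[Tuple[str, int, int, int]] = []
        allowed = None
        allowed_known = False
        for w in sorted(by_w):
            if w > rem:
                break
            if weight1_only and w > 1:
                break
            if relaxed and w > 1:
                group = [v for v in by_w[w] if v not in visited]
            else:
                if not allowed_known:
                    allowed = allowed_first_letters(opp, q0)
                    allowed_known = True
                if allowed is None:
                    group = [v for v in by_w[w] if v not in visited]
                else:
                    wl = succ_wl[last]
                    picked: List[str] = []
                    for c in allowed:
                        picked.extend(wl.get((w, c), ()))
                    group = sorted(v for v in picked if v not in visited)
                if w > 1:
                    group = [v for v in group if later_letters_ok(v, w, q0, opp)]
            if w == 1:
                out.extend((v, 1, 0, 0) for v in group)
            else:
                for v in group:
                    needs = skip_needs(mine, v, w, rem1, rem2)
                    if needs is not None:
                        out.append((v, w, needs[0], needs[1]))
        return out

    def apply(par: int, v: str, w: int, n1: int, n2: int) -> None:
        letters = nat[v][k - w :]
        if par == 0:
            odd.extend(letters)
            path_o.append((v, w))
            state["so"] += w
        else:
            even.extend(letters)
            path_e.append((v, w))
            state["se"] += w
        visited.add(v)
        state["used1"] += n1
        state["used2"] += n2

    def undo(par: int, v: str, w: int, n1: int, n2: int) -> None:
        if par == 0:
            del odd[len(odd) - w :]
            path_o.pop()
            state["so"] -= w
        else:
            del even[len(even) - w :]
            path_e.pop()
            state["se"] -= w
        visited.remove(v)
        state["used1"] -= n1
        state["used2"] -= n2

    def emit() -> None:
        seq = interleave("".join(odd), "".join(even), n)
        if seq in seen:
            return
        if _emission_ok(seq, spectrum, mode):
            seen.add(seq)
            solutions.append(Solution(seq, tuple(path_o), tuple(path_e)))
            logger.debug("solution found: #%d after %d nodes", len(solutions), nodes)

    if maxo == 0 and maxe == 0:
        emit()
        return SolverReport(solutions, False, 0, 0, time.monotonic() - t0)

    # frames: [candidates, next index, applied move or None, parity]
    par0 = pick_parity()
    frames: List[list] = [[candidates(par0), 0, None, par0]]
    capped = False
    while frames:
        if time.monotonic() > deadline:
            timed_out = True
            logger.debug("timeout after %d nodes, %d backtracks", nodes, backtracks)
            break
        fr = frames[-1]
        i = fr[1]
        cands = fr[0]
        if i >= len(cands):
            frames.pop()
            backtracks += 1
            if fr[2] is not None:
                undo(*fr[2])
            continue
        fr[1] = i + 1
        move = cands[i]
        par = fr[3]
        apply(par, *move)
        nodes += 1
        if state["so"] == maxo and state["se"] == maxe:
            emit()
            undo(par, *move)
            if config.max_solutions and len(solutions) >= config.max_solutions:
                capped = True
                break
        else:
            np_ = pick_parity()
            frames.append([candidates(np_), 0, (par, *move), np_])
    if not frames and not capped:
        logger.debug("search space exhausted: %d nodes, %d backtracks", nodes, backtracks)
    return SolverReport(solutions, timed_out, nodes, backtracks, time.monotonic() - t0)


def _replay_accepts(
    seq: str,
    spectrum: Spectrum,
    mode: str,
    declared_negative_pct: Optional[float],
) -> bool:
    """Declarative restatement of the negative-mode acceptance of ``seq``.

    Searches over weight decompositions of the fixed candidate sequence only
    (no graph), mirroring the alternation policy, vertex disjointness, the
    verification rules and the skip budgets.  Verification elements are
    rebuilt from the candidate's own windows via :func:`s2_mask`.
    """
    k, n = spectrum.k, len(seq)
    maxo, maxe = max_steps(n, k)
    sv = start_vertices(seq[: 2 * k], k)
    s1 = set(spectrum.s1) | {sv.odd_start, sv.even_start}
    s2 = spectrum.s2
    relaxed = (declared_negative_pct or 0) > 0
    b1, b2 = _negative_budgets(spectrum, sv, declared_negative_pct)
    if not _emission_ok(seq, spectrum, mode):
        return False
    if maxo == 0 and maxe == 0:
        return True
    odd_seq = seq[0::2]
    even_seq = seq[1::2]
    used = {sv.odd_start, sv.even_start}

    def verified(q: int, covered_opposite: int) -> bool:
        # covered_opposite: letters so far on the opposite-parity path
        if q - 2 * k + 3 < 1 or covered_opposite < q // 2:
            return True  # not constructible: cannot be checked
        return s2_mask(seq[q - 2 * k + 2 : q]) in s2

    def rec(so: int, se: int, u1: int, u2: int) -> bool:
        if so == maxo and se == maxe:
            return True
        extend_odd = so < maxo and (se >= maxe or so <= se)
        if extend_odd:
            mine, i, rem, opp_cov = odd_seq, k + so, maxo - so, k + se
            q0 = 2 * (i + 1) - 1
        else:
            mine, i, rem, opp_cov = even_seq, k + se, maxe - se, k + so
            q0 = 2 * (i + 1)
        for w in range(1, min(k, rem + 1)):
            vertex = UNIVERSAL.join(mine[i + w - k : i + w])
            if vertex not in s1 or vertex in used:
                continue
            if relaxed:
                ok = w > 1 or verified(q0, opp_cov)
            else:
                ok = all(verified(q0 + 2 * t, opp_cov) for t in range(w))
            if not ok:
                continue
            n1 = n2 = 0
            for s in range(1, w):
                m = UNIVERSAL.join(mine[i - k + s : i + s])
                if m in used:
                    continue
                if m in s1:
                    n2 += 1
                else:
                    n1 += 1
            if u1 + n1 > b1 or u2 + n2 > b2:
                continue
            used.add(vertex)
            hit = (
                rec(so + w, se, u1 + n1, u2 + n2)
                if extend_odd
                else rec(so, se + w, u1 + n1, u2 + n2)
            )
            used.remove(vertex)
            if hit:
                return True
        return False

    return rec(0, 0, 0, 0)


def brute_force_oracle(
    spectrum: Spectrum,
    prefix: str,
    n: int,
    mode: str,
    declared_negative_pct: Optional[float] = None,
    max_candidates: int = 4**10,
) -> Set[str]:
    """Exhaustively enumerate the sequences the search should accept.

    Every completion of ``prefix`` to length ``n`` is tested against a
    declarative restatement of the mode: exact spectrum equality (``ideal``),
    full-cardinality containment (``positive_only``), or the existence of an
    accepting extension trajectory (negative-error modes).  Intended as an
    independent test oracle; refuses instances with more than
    ``max_candidates`` completions.
    """
    if mode not in MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    k = spectrum.k
    free = n - 2 * k
    if free < 0:
        raise InvalidInstanceError(f"target length {n} below minimum 2k = {2 * k}")
    if 4**free > max_candidates:
        raise InvalidParameterError(
            f"instance too large for exhaustive enumeration: 4^{free} completions"
        )
    prefix = prefix.upper()
    if len(prefix) != 2 * k:
        raise InvalidInstanceError(f"prefix must have length 2k = {2 * k}")
    l1, l2 = 2 * k - 1, 2 * k - 2
    win1, win2 = n - l1 + 1, n - l2 + 1
    # compare natural-letter projections: within one pattern family the map
    # element <-> natural letters is a bijection, and slicing is much cheaper
    # than building masked strings for every candidate
    given1 = {e[0::2] for e in spectrum.s1}
    given2 = {e[0:-1:2] + e[-1] for e in spectrum.s2}
    accepted: Set[str] = set()
    for tail in product(DNA_ALPHABET, repeat=free):
        seq = prefix + "".join(tail)
        if mode in ("ideal", "positive_only"):
            ws1 = {seq[i : i + l1 : 2] for i in range(win1)}
            ws2 = {seq[i : i + l2 - 1 : 2] + seq[i + l2 - 1] for i in range(win2)}
            if mode == "ideal":
                ok = ws1 == given1 and ws2 == given2
            else:
                ok = (
                    len(ws1) == win1
                    and len(ws2) == win2
                    and ws1 <= given1
                    and ws2 <= given2
                )
        else:
            ok = _replay_accepts(seq, spectrum, mode, declared_negative_pct)
        if ok:
            accepted.add(seq)
    return accepted
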