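"""The search graph built from S1-type spectrum elements.

Every S1 element is a vertex; an arc ``(u, v, w)`` with weight ``w`` in
``1..k-1`` exists iff the last ``k - w`` natural letters of ``u`` equal the
first ``k - w`` natural letters of ``v``.  Maximal overlap (``k - 1`` natural
letters) has weight 1: following such an arc extends the reconstructed
nucleotide sequence of one parity class by a single letter, weight ``w`` adds
``w`` letters.  Parallel arcs with different weights between the same ordered
pair are distinct moves.

Two trusted start vertices are derived from the known ``2k``-letter prefix of
the target (masks of its first and second length-``l1`` windows, for the odd
and even nucleotide paths) and injected into the graph even when negative
errors removed them from the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .chip_model import s1_mask
from .errors import InvalidSpectrumError, LengthMismatchError, UnknownVertexError


@dataclass(frozen=True)
class StartVertices:
    """S1-like start vertices for the odd and even nucleotide paths."""

    odd_start: str
    even_start: str
    prefix: str


def start_vertices(prefix: str, k: int) -> StartVertices:
    """Derive the two start vertices from the first ``2k`` target letters.

    ``odd_start`` masks prefix positions ``1..2k-1`` and ``even_start``
    positions ``2..2k`` (1-based), e.g. ``ACGCGAAT`` (k=4) gives
    ``AXGXGXA`` and ``CXCXAXT``.
    """
    prefix = prefix.upper()
    if len(prefix) != 2 * k:
        raise LengthMismatchError(
            f"prefix must have length 2k = {2 * k}, got {len(prefix)}"
        )
    return StartVertices(
        odd_start=s1_mask(prefix[: 2 * k - 1]),
        even_start=s1_mask(prefix[1 : 2 * k]),
        prefix=prefix,
    )


def _naturals(element: str) -> str:
    return element[0::2]


class AltGraph:
    """Overlap graph over S1 elements plus the two start vertices.

    Successor lists are ordered ascending by weight with lexicographic
    tie-breaks, so exploration order (and hence every downstream report) is
    deterministic.
    """

    def __init__(self, s1_elements: Iterable[str], start: StartVertices, k: int):
        self.k = k
        l1 = 2 * k - 1
        vertices = set(s1_elements)
        for v in vertices:
            if len(v) != l1:
                raise InvalidSpectrumError(
                    f"S1 element {v!r} has length {len(v)}, expected l1={l1}"
                )
        vertices.add(start.odd_start)
        vertices.add(start.even_start)
        self.start = start
        self.vertices = vertices
        self.naturals: Dict[str, str] = {v: _naturals(v) for v in vertices}

        ordered = sorted(vertices)
        # prefix_index[d][p] = vertices whose first d natural letters are p
        prefix_index: Dict[int, Dict[str, List[str]]] = {}
        for d in range(1, k):
            idx: Dict[str, List[str]] = {}
            for v in ordered:
                idx.setdefault(self.naturals[v][:d], []).append(v)
            prefix_index[d] = idx

        # succ_by_weight[u][w] = lexicographically sorted successors via weight w
        # succ_by_weight_letter[u][(w, c)] = those whose first new natural letter
        # (index k - w of their naturals) is c — the letter the verification
        # step constrains.
        succ_w: Dict[str, Dict[int, List[str]]] = {}
        succ_wl: Dict[str, Dict[Tuple[int, str], List[str]]] = {}
        for u in ordered:
            nu = self.naturals[u]
            by_w: Dict[int, List[str]] = {}
            by_wl: Dict[Tuple[int, str], List[str]] = {}
            for w in range(1, k):
                hits = prefix_index[k - w].get(nu[w:])
                if not hits:
                    continue
                by_w[w] = hits
                for v in hits:
                    c = self.naturals[v][k - w]
                    by_wl.setdefault((w, c), []).append(v)
            if by_w:
                succ_w[u] = by_w
                succ_wl[u] = by_wl
        self._succ_by_weight = succ_w
        self._succ_by_weight_letter = succ_wl

    def successors(self, v: str) -> List[Tuple[str, int]]:
        """Outgoing arcs of ``v`` as ``(successor, weight)`` pairs,
        weight-ascending with lexicographic ties; empty if none."""
        if v not in self.vertices:
            raise UnknownVertexError(f"vertex not in graph: {v!r}")
        out: List[Tuple[str, int]] = []
        for w, group in sorted(self._succ_by_weight.get(v, {}).items()):
            out.extend((s, w) for s in group)
        return out

    def arcs(self) -> List[Tuple[str, str, int]]:
        """All arcs as ``(from, to, weight)``, in deterministic order."""
        out = []
        for u in sorted(self.vertices):
            for v, w in self.successors(u):
                out.append((u, v, w))
        return out

    def dump(self, path) -> None:
        """Write a tab-separated ``from<TAB>to<TAB>weight`` debug listing."""
        with open(path, "w", encoding="ascii") as fh:
            for u, v, w in self.arcs():
                fh.write(f"{u}\t{v}\t{w}\n")


def build_graph(s1_elements: Iterable[str], start: StartVertices, k: int) -> AltGraph:
    """Construct the :class:`AltGraph` for a spectrum's S1 set."""
    return AltGraph(s1_elements, start, k)


def successors(graph: AltGraph, v: str) -> List[Tuple[str, int]]:
    """Functional alias for :meth:`AltGraph.successors`."""
    return graph.successors(v)
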