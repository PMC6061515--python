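# Methods

## The sequencing model

Sequencing by hybridization (SBH) reads a DNA string of known length `n` by
detecting which probes of a chip bind it, then reconstructing the string from
the detected probe set (the *spectrum*).  `altchip` implements the
*alternating chip*, a non-classical design whose probes contain a universal
base `x` that pairs with all four natural nucleotides.  The chip holds all
probes of two patterns with `k` natural letters each:

    N1 x N2 x ... x Nk          (set A1, length l1 = 2k - 1)
    N1 x N2 x ... x N(k-1) Nk   (set A2, length l2 = 2k - 2)

so each pattern family contributes `4^k` probes and the chip `2 * 4^k` in
total.  A single probe matches `4^(k-1)` (S1) or `4^(k-2)` (S2) natural
oligonucleotides through its universal positions.  A hybridization experiment
against a target of length `n` ideally reports, for every sliding window of
length `l1` (resp. `l2`), the masked window with natural letters at the
pattern positions — the spectrum sets `S1` and `S2`.  Spectra are *sets*:
nothing is known about multiplicities, so identical masked windows collapse
(`repetition` negative errors).  General negative errors remove further
elements; positive errors add spurious ones.

## Spectrum simulation

`ideal_spectrum` masks all `n - l + 1` windows per set.  Error injection uses
the window count (the only base determined by `n` alone) as the percentage
base with half-up rounding:

* `inject_negative` removes `round(pct% * (n - l + 1))` uniformly chosen
  elements from each set independently;
* `inject_positive` adds the same count of fresh elements per set, each a
  copy of a uniformly chosen existing element with exactly one natural letter
  substituted ("slightly modified" fixed to Hamming distance 1 on the natural
  letters); duplicates are re-drawn.

Removal precedes addition so injected elements can never be removed again.
All randomness flows through a caller-supplied `numpy` generator; fixed seeds
give bit-identical spectra.

## Reconstruction

Only `S1` builds the search graph (using the shorter `S2` elements would
halve the maximal overlap and densify the graph): every `S1` element is a
vertex and an arc `(u, v, w)`, `w` in `1..k-1`, exists when the last `k - w`
natural letters of `u` equal the first `k - w` of `v`.  Weight-1 arcs are
maximal overlaps and extend the reconstruction by one nucleotide; weight `w`
adds `w`.  The first `2k` nucleotides of the target are part of the input;
their two window masks become trusted start vertices (re-inserted even if
negative errors removed them), one for the path reconstructing the odd
target positions (`P_o`) and one for the even positions (`P_e`).

The depth-first search alternately extends the path with fewer accumulated
steps (odd first on ties), which keeps the two paths within one position of
each other, until `P_o` has gathered `ceil(n/2) - k` steps and `P_e`
`floor(n/2) - k`.  The two paths may not share a vertex (sets carry no
multiplicities).  A new nucleotide at position `q` is *verified* by building
the S2-like element spanning positions `q-2k+3 .. q` — the opposite path's
latest `k - 1` letters plus the new letter — and requiring it in `S2`; the
element is constructible only when the opposite path already covers
`q - 1`, so of a multi-nucleotide extension typically only the first letter
can be checked.  Backtracking is strictly chronological, candidate order is
weight-ascending with lexicographic ties, and solutions (deduplicated by
sequence) are enumerated until exhaustion, a time limit (default 60 s), or
an optional cap.  The search is deterministic for a fixed input.

### Error modes

* **ideal / positive_only** — with no negative errors every consecutive
  window is present, so only weight-1 arcs are admissible and every extension
  is verified.  An emitted sequence must use exactly the theoretical number
  of elements: its ideal spectrum must equal the input (`ideal`) or be a
  full-cardinality subset of it (`positive_only`).
* **negative_only / both** — longer arcs become admissible.  Every window a
  weight-`w` arc skips must be justified: it is an already-visited vertex
  (the second occurrence of a repeat; free), or absent from `S1` (charged to
  a missing-`S1` budget), or present but blocked by a lost verification
  element (charged to a missing-`S2` budget; only available when general
  negative errors are declared).  Each budget is the larger of the declared
  negative-error count for its set and the observed cardinality shortfall
  (`n - l + 1` minus the set size, with the start vertices counted present).
  This is the package's reading of two constraints of the model: in the
  negative-only scenario *all* spectrum elements must be used — enforced
  exactly at emission (every given element must occur among the sequence
  windows) and near-locally during the search — and the declared error
  estimates, which the input contract requires to exceed the real rates,
  bound how much evidence may be missing.  Without this accounting the
  search revisits combinatorially many weight decompositions of the same
  sequence and cannot finish enumerating within any realistic limit.
* **Verification strength.**  When general negative errors are declared,
  `S2` itself may have lost elements and verification would wrongly reject
  correct moves; following the relaxed rule, only maximal-overlap (weight-1)
  candidates are verified and longer jumps pass unverified.  When only
  repetition losses are declared (rate 0), repetitions cannot remove
  verification evidence — a repeated S2 window is still present once — so
  candidates of *every* weight are verified on their constructible letters,
  and the missing-`S2` budget is zero.

The experiment harness selects the mode from the declared profile plus the
one negative-error signal a real experiment has: set cardinalities below the
theoretical `n - l + 1` prove (typically repetition-induced) negative errors
even when none were declared.

## Parameters

| parameter | meaning | default / study setting |
| --- | --- | --- |
| `k` | natural letters per probe; chip capacity `2 * 4^k` | 8 or 10 |
| `n` | target length (bp) | 100–700; 1000–5000 repetition-only |
| `negative_pct`, `positive_pct` | injected error rates, % of window count | 0–5 |
| `declared_negative_pct` | declared upper estimate of the general negative rate | equals the injected rate |
| `time_limit` | wall-clock seconds per reconstruction | 60 |
| `max_solutions` | stop after this many sequences (0 = enumerate) | 0 |

## Synthetic targets

`generate_target` draws i.i.d. uniform letters by default, or a uniformly
placed substring of a user-supplied FASTA pool (mirroring the protocol of
cutting random fragments out of one long merged coding sequence).  Uniform
targets reproduce the qualitative error response of the method but not the
repeat structure of genomic DNA: repetition counts of real coding sequences
are source-dependent, so the harness reports average repetitions without
treating them as a reference value, and results on repeat-rich genomic
regions may be worse than the uniform-target numbers suggest.

Per-instance seeds are a CRC-32 hash of the master seed, the cell parameters
and the instance index, so any cell of a grid can be recomputed
independently of the rest.

## Problem sizes used by the shipped checks

The test suite runs the simulation cells at 20 instances per cell (the study
convention is 100) with the 60-second limit: error-free cells at
`n ∈ {100, 300, 700}, k = 8`; 5 % positive errors at `n = 100, k = 8`; 1 %
negative at `n = 100, k = 8`; 1 % + 1 % at `n = 100, k = 10`; and
repetition-only losses at `n = 1000, k = 10`.  `scripts/acceptance.py` runs
the two reference cells at the full 100 instances.  Search-versus-oracle
equivalence is checked on 200 random instances with `k ∈ {3, 4}` and at most
8 unknown positions, where exhaustive enumeration over all completions is
feasible.

## Numerical and representation choices

* Elements are uppercase strings over `{A,C,G,T,X}`; parsers accept
  lowercase and `x`.  Genomic and element positions are 1-based in prose,
  0-based in code.
* The probe universes `A1`/`A2` are never materialized; membership is
  pattern validation.
* Error counts round half-up; removals never exceed the set size.
* Successor lists, spectrum files and result tables use fixed lexicographic
  orders, so every artefact is byte-stable under a fixed seed.
* `avg_solutions` averages over solved instances only; zero-solution
  instances count in the other denominators.

## Known limitations

* With general negative errors at small `k` (dense graphs) or high error
  rates on long targets, the relaxed, budget-bounded search still explodes;
  runs then end at the time limit with whatever was found, which matches the
  degraded long-target cells of the study.
* A target whose final window of either parity was removed (or is a repeat)
  cannot be completed — there is no later window to jump to — so a small
  fraction of instances is unreconstructible by construction.
* Multiplicity-aware spectra, similarity-maximizing (metaheuristic)
  reconstruction and the gapped/binary chip designs are out of scope.
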