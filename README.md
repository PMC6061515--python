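# altchip

Sequencing by hybridization (SBH) with an **alternating DNA chip** — a
non-classical microarray whose probes contain a universal base `x` that binds
every natural nucleotide.  `altchip` simulates the hybridization experiment
(spectrum generation with controllable negative and positive errors) and
reconstructs the target sequence exactly with a dual-path, verification-driven
backtracking search.  It is aimed at people studying SBH chip designs and
reconstruction algorithms who need a reproducible, scriptable simulation
pipeline rather than wet-lab tooling.

## The model

The chip holds all probes of the two patterns

```
N1 x N2 x ... x Nk            set A1, oligonucleotide length l1 = 2k - 1
N1 x N2 x ... x N(k-1) Nk     set A2, oligonucleotide length l2 = 2k - 2
```

with `k` natural letters each, i.e. `4^k` probes per set and a total capacity
`||C_alt(k)|| = 2 * 4^k` (k = 8 gives 65,536 probes per set, k = 10 gives
1,048,576).  Hybridizing a target of length `n` ideally yields the spectrum
sets `S1` and `S2`: the masks of all sliding windows of lengths `l1` and
`l2`.  Reconstruction searches the overlap graph built from `S1` for two
vertex-disjoint paths — one recovering the odd-position nucleotides, one the
even ones, both anchored in the known first `l1 + 1` nucleotides — while
elements of `S2` *verify* every extension by linking the two parity classes.
Negative errors (lost elements, including losses from repeated fragments) and
positive errors (spurious elements) are handled by mode-specific verification
and accounting rules; see `docs/methods.md` for the full algorithm.

## Worked example

Simulate a spectrum of a 16-mer on a k = 4 chip with 10 % general negative
errors, then reconstruct it from the spectrum file, the declared length and
the first 8 nucleotides:

```
$ altchip simulate --target ACGTACGGATCGTTAC --k 4 --negative 10 --seed 5 \
      --out demo.spectrum
$ altchip solve --spectrum demo.spectrum --mode neg --declared-negative 10
{
  "mode": "negative_only",
  "n": 16,
  "k": 4,
  "solutions": 1,
  "sequences": [
    "ACGTACGGATCGTTAC"
  ],
  "timed_out": false,
  "nodes_expanded": 14,
  "backtracks": 13,
  "elapsed": 0.0
}
```

One negative error was injected into each spectrum set (10 % of the window
counts 10 and 11, rounded), yet the search recovers the original sequence as
the *unique* reconstruction after expanding 14 graph vertices: `solutions`
counts the distinct sequences consistent with the spectrum under the
negative-error rules, and the reported sequence equals the simulated target.
Exit status is 0 when at least one sequence is found, 1 otherwise, 2 on bad
input.

The same pipeline is available as a library:

```python
from altchip import ErrorProfile, run_instance

result = run_instance(target, k=8, profile=ErrorProfile(negative_pct=1), seed=7)
result.target_found, len(result.sequences)
```

and `altchip bench --config grid.yaml --out results.tsv` runs whole
simulation grids (chip sizes x target lengths x error levels) with per-cell
metrics in the `found(unambiguous)[target_found]` convention.

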