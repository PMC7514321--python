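# Methods

This note documents the model class, the measures, the numerical conventions,
and the design choices behind `causalcomp`, in enough detail to reproduce or
audit any quantity the package computes.

## System model

A system is a set of `n` binary nodes updating synchronously in discrete
time. Each node carries a mechanism: its probability of being ON at `t`
given the full system state at `t−1`. Node updates are conditionally
independent given the prior state (no instantaneous causation), so the
system is fully described either by a `2^n × 2^n` row-stochastic
state-by-state TPM or, equivalently, by a `2^n × n` state-by-node table of
per-node ON-probabilities. Deterministic TPMs always satisfy conditional
independence; generic probabilistic state-by-state matrices may not, in
which case the state-by-node conversion refuses in strict mode (default)
and returns the non-faithful per-node marginals in lenient mode.

State indexing is little-endian over node positions everywhere: node 0 is
the least significant bit, so row `r` encodes the state with bit
`(r >> i) & 1` for node `i`, and a printed tuple `(0,1,1)` maps
positionally onto the node labels. TPMs serialize to JSON (with an explicit
`state_ordering` tag) and CSV (bit-string row labels; `repr` of floats, so
deterministic systems round-trip bit-exactly).

Only binary nodes are supported. The theory extends to finite-valued
elements, but every data structure here hard-codes base-2 state indexing.

## Information measures

All logarithms are base 2; all quantities are in bits; `0·log2(0) := 0`.
KL divergence requires the support of the first argument to be contained in
the second and raises rather than returning infinity — inside this framework
a repertoire comparison should never leave the reference support, so an
infinite divergence always indicates a bug or invalid input.

Predictive information is `I(V_{t−1}; V_t)` under a caller-supplied prior,
computed as the prior-weighted mean KL divergence of each TPM row from the
prior mixture of rows. Effective information (EI) imposes the uniform
perturbational prior, making it a property of the mechanisms alone; for a
deterministic TPM it equals the mean over rows of
`−log2(preimage_count / 2^n)`, and it attains `n` bits exactly for
permutation TPMs (reversible dynamics).

## Cause and effect repertoires

A mechanism is a node subset `X` in a fixed current state `x_t`. Excluded
variables are *causally marginalized*: averaged uniformly over all their
states, equivalent to feeding them independent maximum-entropy noise.

- Effect repertoire over purview `Z` at `t+1`: the product over purview
  nodes of their interventional ON-marginals given `do(x_t)` with
  `W = S∖X` marginalized. The product (rather than the joint conditional)
  deliberately discounts correlations induced by common inputs from `W`.
- Cause repertoire over `Z` at `t−1`: for each mechanism element
  separately, Bayes inversion of its marginal likelihood under a uniform
  prior over all `2^n` prior states, marginalizing prior nodes outside the
  purview; the per-element distributions are multiplied and renormalized.
  The uniform prior is hard-coded: repertoires quantify the constraints the
  mechanism itself imposes, and any observed state statistics would smuggle
  in extrinsic information.
- The empty mechanism yields the unconstrained repertoires (uniform on the
  cause side; product of perturbational node marginals on the effect side).

If a mechanism state has zero probability under every perturbation (common
for multi-node mechanisms of convergent deterministic maps: the per-element
inversions can have disjoint support), the cause repertoire is undefined.
The corresponding `φ_C` is set to 0 and flagged `undefined`; this is a
convention, logged at debug level because it is a routine occurrence in
random ensembles, not an anomaly.

`brute_force_repertoire` recomputes both definitions by literal summation
over all state completions with plain Python loops, reading only the
state-by-state matrix. It is deliberately slow and structurally independent
of the production path; the tests use it (together with an independently
written partition enumerator) as the oracle.

## Irreducible information (small phi)

A partition of a mechanism splits it into `m ≥ 2` non-empty parts and
assigns each purview node to exactly one part or to a leftover set rendered
completely unconstrained. Purview parts may be empty; mechanism parts may
not (an empty mechanism part would add vacuous partitions whose repertoire
is already generated by assigning those purview nodes to the leftover).
The partitioned repertoire is the product of the part repertoires times the
unconstrained repertoire of the leftover. `φ` is the minimal KL divergence
from the intact repertoire over all partitions (the MIP); single-node
mechanisms are compared to the unconstrained repertoire directly.

The purview is fixed to the full node set. With KL divergence as the
difference measure this loses nothing: both intact and partitioned
repertoires factor over any node the mechanism does not constrain, KLD is
additive over independent factors, and those factors contribute exactly
zero. The *effective purview* — the nodes actually constrained — is
reported separately. A node counts as constrained when the repertoire does
not factorize into (marginal over the rest) × (that node's unconstrained
repertoire); a plain marginal comparison would miss joint cause-side
constraints such as an XOR mechanism, which constrains the parity of two
nodes while leaving both single-node marginals uniform.

Two search implementations exist and are cross-checked: an exhaustive path
that materializes every partitioned repertoire, and the default fast path,
which exploits (a) on the effect side, per-node additivity of KLD between
product distributions, so the best purview assignment can be chosen node by
node within each mechanism set-partition; (b) on the cause side, the
identity `D_KL(p ‖ ∏_j q_j × U) = −H(p) − Σ_j ⟨p_j, log2 q_j⟩ + |leftover|`
with cached block marginals and log-repertoires. MIP ties are broken by
deterministic enumeration order (set partitions with parts ordered by
smallest element; purview assignments lexicographic); `record_ties=True`
retrieves all co-minimal partitions within 1e−9.

Numerical conventions: probabilities clipped to `[0,1]` only within 1e−12;
row-stochasticity and round-trip tolerance 1e−9; φ comparisons at absolute
tolerance 1e−9; φ floored at 0 against rounding error.

## System integration (big phi)

A unidirectional cut `Ψ = X ↛ S∖X` severs every connection from a source
subset into the rest: each target node's mechanism is replaced by its
average over all states of its severed inputs. Source nodes keep their
mechanisms, and the cut TPM is conditionally independent by construction.
One cut TPM serves both the cause- and effect-side re-evaluation — the cut
defines a single partitioned system within which both repertoire directions
are computed (the alternative of direction-specific cuts was considered and
dropped: the single-cut semantics reproduces all reference values).

For every mechanism with positive intact `φ` (separately per direction),
`φ` is re-evaluated in the cut system with a fresh MIP search, and the
losses are summed per direction. `Φ⊆` is the minimum over the `2^n − 2`
cuts of the smaller of the two sums, floored at 0; the minimizing cut and
side are reported. Mechanisms with intact `φ = 0` are not re-evaluated and
contribute nothing.

Two Δφ accounting strategies are provided; this was the one genuinely open
design choice in the framework:

- `"distinction"` (default): a mechanism's contribution is tied to the
  purview it constrains. If the cut leaves the effective purview unchanged,
  the contribution is the signed difference `φ − φ^Ψ`; if the cut drives
  `φ^Ψ` to zero, the full `φ` is lost; if the mechanism survives but now
  constrains a *different* effective purview, the intact distinction has
  been destroyed and an unrelated one created, and both count
  (`φ + φ^Ψ`). This is a distance between the intact and cut cause–effect
  structures in which displaced information is charged to the cut. Under
  this accounting, the MCX example at state (0,1,1) yields `Φ⊆ = 1.019`
  bits at the cut severing X → MC on the effect side: exactly the three
  eliminated contributions 0.189 (X) + 0.415 (CX) + 0.415 (MCX). The
  competing cut {M,X} ↛ C moves M's effect distinction from purview
  {M,C} (1.189 bits) onto purview {M} (0.189 bits) and is charged
  1.378 bits for it.
- `"mechanism"`: the literal per-mechanism signed difference `φ − φ^Ψ`
  regardless of purview. Negative differences (the MIP re-minimization in
  the cut system can raise φ) are kept unclipped and logged. Under this
  accounting the same example gives `Φ⊆ = 1.0` via the cut {M,X} ↛ C,
  because the purview displacement of M is free.

`mean_big_phi` averages `Φ⊆` over all `2^n` states, unweighted.

## Ensembles and their defaults

The samplers implement the two standard random ensembles: deterministic
TPMs (each prior state assigned a uniformly random successor) and
probabilistic TPMs (every state-by-node entry i.i.d. `U(0,1)`). Both take a
single integer seed (or a shared `numpy` Generator) and are reproducible
run-to-run. These generators emulate the *structureless* extremes of the
model class; they do not emulate biologically structured networks (sparse
connectivity, canalizing functions, degree heterogeneity), so conclusions
drawn from them characterize the measure, not any particular organism's
network.

Reversibility is decided on the matrix (permutation check), ergodicity on
the cycle decomposition (a single `2^n`-cycle). Exhaustive enumeration
yields one TPM per permutation of the state space in lexicographic order —
`(2^n)!` systems, guarded to `n ≤ 3` (8! = 40,320; at `n = 4`, 16! ≈ 2·10¹³
is out of reach by design, not implementation). Systems are counted as
distinct TPMs without quotienting by node relabelling, which is what makes
the counts 40,320 and 5,040 (= 7!). Time reversal is the inverse
permutation and is an involution preserving both properties.

`sweep` evaluates selected metrics (EI, state-averaged `Σφ` sums,
state-averaged `Φ⊆`, reversibility) over any system stream and returns a
DataFrame; the composition-sum metrics share one per-state evaluation.

## Problem sizes used in the shipped checks

All reference quantities are desk-scale: the 3-node example system
(14 mechanism–direction pairs, 6 cuts), the exhaustive 40,320-system
enumeration with per-system EI, and qualitative ensemble comparisons on 200
deterministic plus 200 probabilistic sampled systems (probabilistic systems
carry visibly less total φ; total φ and `Φ⊆` rank-correlate positively).
These sizes reproduce every published figure the package asserts while
keeping the full test suite at a few minutes on one CPU.

## Known limitations

- KL divergence is the only difference measure; alternative intrinsic
  distances change φ values and possibly MIP identities.
- `Σφ_C` and `Σφ_E` are summed independently; no per-mechanism
  `min(φ_C, φ_E)` distinction existence requirement, and no search over
  candidate subsystems for maxima of `Φ⊆` (expressible via the API, not
  packaged).
- The `"distinction"` strategy identifies a distinction by its mechanism
  and effective purview; a purview-preserving but qualitatively repertoire-
  changing cut is still scored by the φ difference alone.
- Exhaustive partition search scales as set-partitions × `(m+1)^n` per
  mechanism and `2^n − 2` cuts per state; practical up to roughly `n = 5`
  for composition and `n = 4` for state-averaged `Φ⊆` sweeps.
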