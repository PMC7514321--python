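# causalcomp

Compositional integrated-information analysis of small discrete dynamical
systems (Boolean networks, logic-gate circuits, elementary cellular-automaton
style models).

## The problem

Two systems can have *identical global dynamics* — the same state-transition
diagram, the same predictive and effective information — and still be built
from entirely different mechanisms. Holistic measures (entropy, mutual
information between consecutive states) and reductionist descriptions (the
individual node update rules) both miss what the *subsets* of a system
specify about each other. `causalcomp` quantifies exactly that: the
state-dependent, causal, compositional information structure of a system,
for researchers studying information integration, autonomy, and causal
emergence in small networks.

## The measures

For a system of `n` binary nodes with transition probabilities
`p(v_t | v_{t-1}) = ∏_i p(v_{i,t} | v_{t-1})` (a conditionally independent
TPM), the package computes:

- **Effective information** `EI(S) = ⟨D_KL(p(V_t | v_{t-1}) ‖ p(V_t))⟩` with
  a uniform (perturbational) prior over the `2^n` prior states — a holistic
  baseline.
- **Cause/effect repertoires** `π(Z_{t∓1} | x_t)`: the distribution over a
  purview `Z` implied by a mechanism subset `X` in state `x_t`, with all
  other variables causally marginalized (fed independent uniform noise) and
  common-input correlations discounted by per-element factorization.
- **Irreducible information** `φ_C/φ_E`: the KL divergence between a
  mechanism's repertoire and the closest repertoire obtainable after
  partitioning the mechanism (the minimum-information partition, MIP).
  Single-node mechanisms are compared to the unconstrained repertoire.
- **Composition**: `φ_C` and `φ_E` for all `2^n − 1` mechanism subsets, and
  the totals `Σφ_C`, `Σφ_E`, `Σφ_C + Σφ_E` (the system's intrinsic
  information).
- **Compositional big phi**
  `Φ⊆ = min_Ψ min(ΣΔφ_C, ΣΔφ_E)`: the minimal compositional information
  lost under any unidirectional system cut `Ψ = X ↛ S∖X` (connections from
  `X` into the rest severed and noised).
- **Ensembles**: random deterministic/probabilistic TPM samplers, exhaustive
  enumeration of the `(2^n)!` reversible (permutation) systems and the
  `(2^n − 1)!` ergodic-reversible ones, time reversal, attractor profiles,
  and metric sweeps.

## Worked example

The canonical example is the 3-node system **MCX**: `M` = majority(M, C, X),
`C` = copy(M), `X` = xor(M, C), analyzed in its current state
`(M, C, X) = (0, 1, 1)`:

```python
>>> from causalcomp import mcx, effective_information, composition, big_phi
>>> tpm = mcx()
>>> effective_information(tpm)
2.5
>>> table = composition(tpm, (0, 1, 1))
>>> print(table.to_dataframe().round(3))
                M      C      X   MC     MX     CX    MCX    sum
phi_cause   1.000  1.000  1.000  1.0  0.415  1.000  0.000  5.415
phi_effect  1.189  0.189  0.189  1.0  0.000  0.415  0.415  3.396
>>> result = big_phi(tpm, (0, 1, 1), intact=table)
>>> round(result.big_phi, 2), result.minimizing_cut.source, result.side
(1.02, (2,), 'effect')
```

Reading the output: although the system is deterministic, most subsets only
constrain the past and future *probabilistically* (e.g. `C=1` alone implies
`p(M_{t+1}=1) = 0.75`). Every single node is an irreducible mechanism; the
pair `MX` is almost reducible (`φ_C = 0.415`, `φ_E = 0`), and the whole
system adds nothing beyond its parts on the cause side (`φ_C(MCX) = 0`).
The system carries 8.81 bits of compositional intrinsic information in this
state, of which at least 1.02 bits are *integrated*: the least-destructive
cut (severing the connections from `X` into `M` and `C`, node index 2)
eliminates the effect information specified by `X`, `CX`, and `MCX`
(0.189 + 0.415 + 0.415 bits).

The same analysis from the shell:

```sh
causalcomp fixture mcx --out mcx.json
causalcomp analyze --tpm mcx.json --state 011
causalcomp sweep --sample deterministic:100:42 --metrics ei,mean_sum_phi,mean_big_phi
```

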