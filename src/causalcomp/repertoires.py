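"""Cause and effect repertoires of mechanism subsets.

A *mechanism* is a subset of nodes ``X`` in a fixed current state ``x_t``.
Its *effect repertoire* over a purview ``Z`` at ``t+1`` is the product over
purview nodes of their interventional marginals given ``do(x_t)``, with the
remaining nodes ``W = S \\ X`` causally marginalized (fed independent uniform
noise).  Its *cause repertoire* over a purview at ``t-1`` is the per-element
Bayesian inversion under a uniform perturbational prior, multiplied across
mechanism elements and renormalized.  Both constructions deliberately discount
correlations induced by common inputs from outside the mechanism (the
"virtual node" factorization), so a repertoire is generally *not* the plain
conditional distribution ``p(Z | x_t)``.

The uniform prior over full system states is fixed by the causal semantics:
repertoires quantify what the mechanism itself constrains, not what an
observer's state statistics would add.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tpm_core import Tpm, _substate_index

__all__ = [
    "MechanismInState",
    "Repertoire",
    "UndefinedCauseRepertoireError",
    "effect_repertoire",
    "cause_repertoire",
    "unconstrained_repertoire",
    "brute_force_repertoire",
]


class UndefinedCauseRepertoireError(ValueError):
    """The mechanism state is unreachable under every perturbation, so the
    Bayesian inversion has a zero normalizer and no cause repertoire exists."""


@dataclass(frozen=True)
class MechanismInState:
    """A node subset together with its values within the current system state."""

    nodes: tuple[int, ...]
    state: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.state):
            raise ValueError("one state value per mechanism node required")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("mechanism nodes must be distinct")
        if any(b not in (0, 1) for b in self.state):
            raise ValueError("mechanism state must be binary")
        order = np.argsort(self.nodes, kind="stable")
        object.__setattr__(self, "nodes", tuple(int(self.nodes[i]) for i in order))
        object.__setattr__(self, "state", tuple(int(self.state[i]) for i in order))

    @classmethod
    def from_system_state(
        cls, nodes: Sequence[int], system_state: Sequence[int]
    ) -> "MechanismInState":
        return cls(tuple(nodes), tuple(system_state[i] for i in nodes))

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Repertoire:
    """A normalized distribution over purview states.

    ``dist[z]`` is the probability of the purview sub-state whose bit for the
    ``k``-th purview node (ascending node order) is ``(z >> k) & 1``.
    """

    direction: str  # "cause" | "effect"
    purview: tuple[int, ...]
    dist: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in ("cause", "effect"):
            raise ValueError("direction must be 'cause' or 'effect'")
        d = np.asarray(self.dist, dtype=float)
        if d.shape != (2 ** len(self.purview),):
            raise ValueError("distribution length must be 2^|purview|")
        object.__setattr__(self, "dist", d)

    def marginal(self, node: int) -> float:
        """Probability that a purview node is ON."""
        k = self.purview.index(node)
        z = np.arange(len(self.dist))
        return float(self.dist[(z >> k) & 1 == 1].sum())

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "purview": list(self.purview),
            "dist": self.dist.tolist(),
        }


def _check_purview(tpm: Tpm, purview: Sequence[int]) -> tuple[int, ...]:
    purview = tuple(sorted(int(z) for z in purview))
    if not purview:
        raise ValueError("purview must be non-empty")
    if len(set(purview)) != len(purview) or not all(
        0 <= z < tpm.n_nodes for z in purview
    ):
        raise ValueError("purview must be a set of valid node indices")
    return purview


def _mechanism_rows(tpm: Tpm, mech: MechanismInState) -> np.ndarray:
    """Prior/current full-state rows consistent with the mechanism state."""
    return tpm._completions(dict(zip(mech.nodes, mech.state)))


def effect_node_marginal(tpm: Tpm, mech: MechanismInState, node: int) -> float:
    """``pi(Z_i,t+1 = 1 | x_t)``: the node's ON-marginal with the mechanism
    clamped and all other current nodes causally marginalized."""
    rows = _mechanism_rows(tpm, mech)
    return float(tpm.node_marginals[rows, node].mean())


def effect_repertoire(
    tpm: Tpm, mech: MechanismInState, purview: Sequence[int]
) -> Repertoire:
    """Effect repertoire of ``mech`` over ``purview`` at ``t+1``.

    Factorizes over purview nodes by construction; reduces to the TPM row when
    the mechanism and purview are both the full system.
    """
    purview = _check_purview(tpm, purview)
    rows = _mechanism_rows(tpm, mech)
    p_on = tpm.node_marginals[rows][:, list(purview)].mean(axis=0)
    z = np.arange(2 ** len(purview))
    dist = np.ones(len(z))
    for k in range(len(purview)):
        bit = (z >> k) & 1
        dist *= np.where(bit, p_on[k], 1.0 - p_on[k])
    return Repertoire("effect", purview, dist)


def _cause_element_dist(
    tpm: Tpm, node: int, value: int, purview: tuple[int, ...]
) -> np.ndarray:
    """Eq-style single-element inversion ``pi(Z_{t-1} | x_{i,t})``: uniform
    perturbational prior over all full prior states, Bayes inversion of the
    node's marginal, then causal marginalization of prior nodes outside the
    purview."""
    marg = tpm.node_marginals[:, node]
    weight = marg if value == 1 else 1.0 - marg
    total = weight.sum()
    if total <= 0:
        raise UndefinedCauseRepertoireError(
            f"node {node} can never be {value}; cause repertoire undefined"
        )
    sub = _purview_subindex(tpm.n_states, purview)
    dist = np.zeros(2 ** len(purview))
    np.add.at(dist, sub, weight)
    return dist / total


def cause_repertoire(
    tpm: Tpm, mech: MechanismInState, purview: Sequence[int]
) -> Repertoire:
    """Cause repertoire of ``mech`` over ``purview`` at ``t-1``.

    Product over mechanism elements of their single-element inversions,
    renormalized.  Raises :class:`UndefinedCauseRepertoireError` if the
    normalizer vanishes (mechanism state unreachable by every perturbation).
    """
    purview = _check_purview(tpm, purview)
    dist = np.ones(2 ** len(purview))
    for node, value in zip(mech.nodes, mech.state):
        dist *= _cause_element_dist(tpm, node, value, purview)
    total = dist.sum()
    if total <= 0:
        raise UndefinedCauseRepertoireError(
            f"mechanism {mech.nodes}={mech.state} has an empty cause repertoire "
            f"over purview {purview}"
        )
    return Repertoire("cause", purview, dist / total)


def unconstrained_repertoire(
    tpm: Tpm, direction: str, purview: Sequence[int]
) -> Repertoire:
    """Repertoire of the empty mechanism (convention ``pi(emptyset) = 1``):
    uniform on the cause side, product of perturbational per-node marginals on
    the effect side."""
    empty = MechanismInState((), ())
    if direction == "cause":
        purview = _check_purview(tpm, purview)
        k = 2 ** len(purview)
        return Repertoire("cause", purview, np.full(k, 1.0 / k))
    if direction == "effect":
        return effect_repertoire(tpm, empty, purview)
    raise ValueError("direction must be 'cause' or 'effect'")


# ---------------------------------------------------------------------------
# internal indexing cache
# ---------------------------------------------------------------------------

_SUBINDEX_CACHE: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}


def _purview_subindex(n_states: int, purview: tuple[int, ...]) -> np.ndarray:
    """Map every full-state index to its purview sub-state index."""
    key = (n_states, purview)
    out = _SUBINDEX_CACHE.get(key)
    if out is None:
        out = np.array(
            [_substate_index(r, purview) for r in range(n_states)], dtype=np.intp
        )
        _SUBINDEX_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# independent brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def brute_force_repertoire(
    tpm: Tpm, mech: MechanismInState, purview: Sequence[int], direction: str
) -> Repertoire:
    """Literal summation over all completions, without algebraic shortcuts.

    Enumerates full prior/next states with plain Python loops and reads
    probabilities off the state-by-state matrix only.  Intended as an
    independent cross-check at small ``n``; refuses systems with more than
    five nodes.
    """
    if tpm.n_nodes > 5:
        raise ValueError("brute-force oracle limited to n <= 5")
    purview = tuple(sorted(purview))
    if not purview:
        raise ValueError("purview must be non-empty")
    n = tpm.n_nodes
    sbs = tpm.state_by_state
    states = list(itertools.product((0, 1), repeat=n))  # index = little-endian

    def full_index(state: Sequence[int]) -> int:
        return sum(b << i for i, b in enumerate(state))

    def node_prob(prior: Sequence[int], node: int, value: int) -> float:
        # marginal p(v_{node,t} = value | do(prior)) from the state-by-state row
        row = sbs[full_index(prior)]
        total = 0.0
        for nxt in states:
            if nxt[node] == value:
                total += row[full_index(nxt)]
        return total

    mech_map = dict(zip(mech.nodes, mech.state))
    free = [i for i in range(n) if i not in mech_map]

    if direction == "effect":
        marginals = []
        for z in purview:
            acc = 0.0
            count = 0
            for fill in itertools.product((0, 1), repeat=len(free)):
                prior = [0] * n
                for i, b in mech_map.items():
                    prior[i] = b
                for i, b in zip(free, fill):
                    prior[i] = b
                acc += node_prob(prior, z, 1)
                count += 1
            marginals.append(acc / count)
        dist = np.zeros(2 ** len(purview))
        for zi, zstate in enumerate(itertools.product((0, 1), repeat=len(purview))):
            p = 1.0
            for k, b in enumerate(zstate):
                p *= marginals[k] if b else 1.0 - marginals[k]
            dist[sum(b << k for k, b in enumerate(zstate))] = p
        return Repertoire("effect", purview, dist)

    if direction == "cause":
        outside = [i for i in range(n) if i not in purview]
        dist = np.ones(2 ** len(purview))
        for node, value in zip(mech.nodes, mech.state):
            elem = np.zeros(2 ** len(purview))
            for zstate in itertools.product((0, 1), repeat=len(purview)):
                acc = 0.0
                for fill in itertools.product((0, 1), repeat=len(outside)):
                    prior = [0] * n
                    for k, z in enumerate(purview):
                        prior[z] = zstate[k]
                    for k, y in enumerate(outside):
                        prior[y] = fill[k]
                    acc += node_prob(prior, node, value)
                elem[sum(b << k for k, b in enumerate(zstate))] = acc
            if elem.sum() <= 0:
                raise UndefinedCauseRepertoireError(
                    f"node {node} can never be {value}"
                )
            dist *= elem / elem.sum()
        total = dist.sum()
        if total <= 0:
            raise UndefinedCauseRepertoireError("zero normalizer")
        return Repertoire("cause", purview, dist / total)

    raise ValueError("direction must be 'cause' or 'effect'")
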