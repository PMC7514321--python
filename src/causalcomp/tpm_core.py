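"""Transition probability matrices (TPMs) of discrete dynamical causal networks.

A system of ``n`` binary nodes updating in discrete time under conditionally
independent node mechanisms, ``p(v_t | v_{t-1}) = prod_i p(v_{i,t} | v_{t-1})``,
is fully described by its one-step TPM.  Two dialects are supported:

* **state-by-state** -- a ``2^n x 2^n`` row-stochastic matrix, rows indexed by
  the prior state, columns by the next state;
* **state-by-node** -- a ``2^n x n`` matrix of per-node probabilities of being
  ON given each prior state (valid only under conditional independence, which
  every deterministic TPM satisfies automatically).

State ordering is little-endian over node positions throughout the package:
node index 0 varies fastest, so row ``r`` encodes the prior state whose bit for
node ``i`` is ``(r >> i) & 1``.  Printed state tuples such as ``(0, 1, 1)`` map
positionally onto node labels (node 0 = first label).
"""

from __future__ import annotations

import csv
import io
import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NodeMechanism",
    "Tpm",
    "build_tpm",
    "sbs_to_sbn",
    "sbn_to_sbs",
    "connectivity",
    "condition_and_marginalize",
    "all_states",
    "state_to_index",
    "index_to_state",
]

#: default numerical tolerance for stochasticity / round-trip checks
TOL = 1e-9


# ---------------------------------------------------------------------------
# state indexing helpers (little-endian: node 0 is the least significant bit)
# ---------------------------------------------------------------------------

def state_to_index(state: Sequence[int]) -> int:
    """Index of a binary state tuple under little-endian ordering."""
    r = 0
    for i, bit in enumerate(state):
        if bit not in (0, 1):
            raise ValueError(f"state entries must be 0 or 1, got {bit!r}")
        r |= int(bit) << i
    return r


def index_to_state(index: int, n: int) -> tuple[int, ...]:
    """Binary state tuple of a row/column index for an ``n``-node system."""
    return tuple((index >> i) & 1 for i in range(n))


def all_states(n: int) -> list[tuple[int, ...]]:
    """All ``2^n`` states in index order."""
    return [index_to_state(r, n) for r in range(2**n)]


def _substate_index(state_index: int, nodes: Sequence[int]) -> int:
    """Index of the restriction of a full-state index to ``nodes``.

    The sub-state is ordered little-endian over the *positions in ``nodes``*
    (first listed node varies fastest).
    """
    z = 0
    for k, node in enumerate(nodes):
        z |= ((state_index >> node) & 1) << k
    return z


# ---------------------------------------------------------------------------
# node mechanisms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeMechanism:
    """One node's conditional output distribution given a full prior state.

    ``on_probability[r]`` is the probability that the node is ON at ``t``
    given that the full system was in the state with index ``r`` at ``t-1``.
    """

    node_index: int
    on_probability: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.on_probability, dtype=float)
        if p.ndim != 1 or len(p) & (len(p) - 1):
            raise ValueError("on_probability must be a 1-D array of length 2^n")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "on_probability", np.clip(p, 0.0, 1.0))

    @property
    def n_nodes(self) -> int:
        return int(np.log2(len(self.on_probability)))

    @property
    def is_deterministic(self) -> bool:
        p = self.on_probability
        return bool(np.all((p == 0.0) | (p == 1.0)))

    @classmethod
    def from_function(
        cls, node_index: int, n: int, fn: Callable[[tuple[int, ...]], float]
    ) -> "NodeMechanism":
        """Build from a truth table / update function over full prior states."""
        table = np.array([fn(index_to_state(r, n)) for r in range(2**n)], dtype=float)
        return cls(node_index, table)


# ---------------------------------------------------------------------------
# the TPM container
# ---------------------------------------------------------------------------

class Tpm:
    """A one-time-step transition probability matrix over binary nodes.

    Parameters
    ----------
    state_by_state:
        ``2^n x 2^n`` row-stochastic matrix; rows are prior states, columns
        next states, both in little-endian index order.
    node_labels:
        Optional node names; defaults to ``n0, n1, ...``.
    validate:
        Check shape and row-stochasticity (tolerance ``1e-9``).
    """

    def __init__(
        self,
        state_by_state: np.ndarray,
        node_labels: Sequence[str] | None = None,
        validate: bool = True,
    ) -> None:
        sbs = np.asarray(state_by_state, dtype=float)
        n_states = sbs.shape[0]
        n = int(round(np.log2(n_states)))
        if validate:
            if sbs.ndim != 2 or sbs.shape[0] != sbs.shape[1] or 2**n != n_states:
                raise ValueError("state-by-state matrix must be 2^n x 2^n")
            if np.any(sbs < -1e-12):
                raise ValueError("transition probabilities must be nonnegative")
            rowsums = sbs.sum(axis=1)
            if np.any(np.abs(rowsums - 1.0) > TOL):
                raise ValueError("state-by-state rows must sum to 1")
        self._sbs = np.clip(sbs, 0.0, None)
        self.n_nodes = n
        self.node_labels: tuple[str, ...] = tuple(
            node_labels if node_labels is not None else (f"n{i}" for i in range(n))
        )
        if len(self.node_labels) != n:
            raise ValueError("number of labels must equal number of nodes")
        self._node_marginals: np.ndarray | None = None

    # -- basic properties ---------------------------------------------------

    @property
    def state_by_state(self) -> np.ndarray:
        """The ``2^n x 2^n`` row-stochastic matrix (read-only view)."""
        v = self._sbs.view()
        v.flags.writeable = False
        return v

    @property
    def n_states(self) -> int:
        return 2**self.n_nodes

    @property
    def is_deterministic(self) -> bool:
        return bool(np.all(np.isin(self._sbs, (0.0, 1.0))))

    @property
    def node_marginals(self) -> np.ndarray:
        """``2^n x n`` matrix of per-node ON-marginals ``p(v_{i,t}=1 | v_{t-1})``.

        These marginals exist for any TPM; they determine the TPM only under
        conditional independence of the node updates.
        """
        if self._node_marginals is None:
            cols = np.arange(self.n_states)
            bits = np.stack(
                [(cols >> i) & 1 for i in range(self.n_nodes)], axis=1
            ).astype(float)
            self._node_marginals = self._sbs @ bits
        return self._node_marginals

    def state_by_node(self, strict: bool = True) -> np.ndarray:
        """Convert to the state-by-node dialect.

        Raises ``ValueError`` in strict mode if the product of per-node
        marginals fails to reproduce the matrix (conditional independence
        violated); in lenient mode the marginals are returned regardless.
        """
        sbn = self.node_marginals
        if strict and not self.is_conditionally_independent():
            raise ValueError(
                "TPM is not conditionally independent across nodes; "
                "it has no faithful state-by-node representation"
            )
        return sbn.copy()

    def is_conditionally_independent(self, tol: float = TOL) -> bool:
        """Whether the matrix factorizes as a product of per-node marginals."""
        recon = sbn_to_sbs(self.node_marginals)
        return bool(np.max(np.abs(recon - self._sbs)) <= tol)

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_state_by_node(
        cls, sbn: np.ndarray, node_labels: Sequence[str] | None = None
    ) -> "Tpm":
        sbn = np.asarray(sbn, dtype=float)
        if sbn.ndim != 2 or sbn.shape[0] != 2 ** sbn.shape[1]:
            raise ValueError("state-by-node matrix must be 2^n x n")
        if np.any(sbn < -1e-12) or np.any(sbn > 1 + 1e-12):
            raise ValueError("on-probabilities must lie in [0, 1]")
        return cls(sbn_to_sbs(np.clip(sbn, 0.0, 1.0)), node_labels)

    @classmethod
    def from_mechanisms(
        cls,
        mechanisms: Sequence[NodeMechanism],
        node_labels: Sequence[str] | None = None,
    ) -> "Tpm":
        """Assemble the TPM of conditionally independent node mechanisms."""
        if not mechanisms:
            raise ValueError("need at least one mechanism")
        n = len(mechanisms)
        indices = sorted(m.node_index for m in mechanisms)
        if indices != list(range(n)):
            raise ValueError("exactly one mechanism per node index 0..n-1 required")
        by_index = {m.node_index: m for m in mechanisms}
        sbn = np.empty((2**n, n))
        for i in range(n):
            mech = by_index[i]
            if mech.n_nodes != n:
                raise ValueError(
                    f"mechanism for node {i} is defined over {mech.n_nodes} nodes, "
                    f"expected {n}"
                )
            sbn[:, i] = mech.on_probability
        return cls.from_state_by_node(sbn, node_labels)

    @classmethod
    def from_node_functions(
        cls,
        functions: Sequence[Callable[[tuple[int, ...]], float]],
        node_labels: Sequence[str] | None = None,
    ) -> "Tpm":
        """Convenience constructor from per-node update functions."""
        n = len(functions)
        mechs = [NodeMechanism.from_function(i, n, fn) for i, fn in enumerate(functions)]
        return cls.from_mechanisms(mechs, node_labels)

    def mechanisms(self) -> list[NodeMechanism]:
        """Per-node mechanisms recovered from the node marginals."""
        return [
            NodeMechanism(i, self.node_marginals[:, i].copy())
            for i in range(self.n_nodes)
        ]

    # -- derived structure ----------------------------------------------------

    def connectivity(self) -> np.ndarray:
        """``n x n`` binary adjacency: entry ``(i, j) = 1`` iff node ``j``'s
        mechanism depends on node ``i`` (two prior states differing only at
        ``i`` give different ON-probabilities for ``j``)."""
        n = self.n_nodes
        marg = self.node_marginals
        adj = np.zeros((n, n), dtype=int)
        rows = np.arange(self.n_states)
        for i in range(n):
            low = rows[(rows >> i) & 1 == 0]
            high = low | (1 << i)
            diff = np.abs(marg[low] - marg[high]).max(axis=0)
            adj[i] = (diff > TOL).astype(int)
        return adj

    def condition_and_marginalize(
        self,
        fixed: Mapping[int, int],
        out_nodes: Sequence[int],
    ) -> np.ndarray:
        """Distribution over the ``out_nodes`` next-state given a partial prior.

        The unfixed prior nodes are causally marginalized: the conditional
        ``p(out state | full prior)`` is averaged uniformly over all their
        completions.  Sub-states of ``out_nodes`` are indexed little-endian in
        the order the nodes are listed.
        """
        out_nodes = list(out_nodes)
        if not out_nodes:
            raise ValueError("out_nodes must be non-empty")
        rows = self._completions(fixed)
        cols = np.arange(self.n_states)
        sub = np.array([_substate_index(c, out_nodes) for c in cols])
        dist = np.zeros(2 ** len(out_nodes))
        avg_row = self._sbs[rows].mean(axis=0)
        np.add.at(dist, sub, avg_row)
        return dist / dist.sum()

    def _completions(self, fixed: Mapping[int, int]) -> np.ndarray:
        """Row indices of all prior states consistent with a partial state."""
        for node, bit in fixed.items():
            if not 0 <= node < self.n_nodes:
                raise ValueError(f"node index {node} out of range")
            if bit not in (0, 1):
                raise ValueError("fixed values must be 0 or 1")
        rows = np.arange(self.n_states)
        mask = np.ones(self.n_states, dtype=bool)
        for node, bit in fixed.items():
            mask &= ((rows >> node) & 1) == bit
        return rows[mask]

    # -- serialization ----------------------------------------------------------

    def to_json(self, dialect: str = "state_by_state") -> str:
        if dialect == "state_by_state":
            matrix = self._sbs.tolist()
        elif dialect == "state_by_node":
            matrix = self.state_by_node().tolist()
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "node_labels": list(self.node_labels),
                "dialect": dialect,
                "state_ordering": "little_endian",
                "matrix": matrix,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Tpm":
        obj = json.loads(text)
        if obj.get("state_ordering", "little_endian") != "little_endian":
            raise ValueError("only little-endian state ordering is supported")
        matrix = np.asarray(obj["matrix"], dtype=float)
        labels = obj.get("node_labels")
        if obj["dialect"] == "state_by_node":
            return cls.from_state_by_node(matrix, labels)
        return cls(matrix, labels)

    def to_csv(self) -> str:
        """State-by-state CSV: header of next-state bit strings, one row per
        prior state labelled by its bit string (node 0 first)."""
        buf = io.StringIO()
        writer = csv.writer(buf)
        labels = ["".join(map(str, index_to_state(c, self.n_nodes)))
                  for c in range(self.n_states)]
        writer.writerow(["state"] + labels)
        for r in range(self.n_states):
            writer.writerow([labels[r]] + [repr(float(x)) for x in self._sbs[r]])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, node_labels: Sequence[str] | None = None) -> "Tpm":
        reader = csv.reader(io.StringIO(text))
        next(reader)  # header of next-state labels
        rows = sorted(reader, key=lambda row: state_to_index([int(b) for b in row[0]]))
        sbs = np.array([[float(x) for x in row[1:]] for row in rows])
        return cls(sbs, node_labels)

    # -- misc -------------------------------------------------------------------

    def next_state(self, state: Sequence[int]) -> tuple[int, ...]:
        """Deterministic successor of a state (errors on stochastic rows)."""
        row = self._sbs[state_to_index(state)]
        hot = np.flatnonzero(row == 1.0)
        if len(hot) != 1:
            raise ValueError("next_state requires a deterministic row")
        return index_to_state(int(hot[0]), self.n_nodes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Tpm) and np.array_equal(self._sbs, other._sbs)

    def __repr__(self) -> str:
        kind = "deterministic" if self.is_deterministic else "probabilistic"
        return f"<Tpm n={self.n_nodes} ({kind}) labels={self.node_labels}>"


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------

def sbn_to_sbs(sbn: np.ndarray) -> np.ndarray:
    """Expand a state-by-node matrix into the state-by-state product form."""
    sbn = np.asarray(sbn, dtype=float)
    n = sbn.shape[1]
    cols = np.arange(2**n)
    sbs = np.ones((2**n, 2**n))
    for i in range(n):
        bit = (cols >> i) & 1
        sbs *= np.where(bit, sbn[:, i : i + 1], 1.0 - sbn[:, i : i + 1])
    return sbs


def build_tpm(
    mechanisms: Sequence[NodeMechanism], node_labels: Sequence[str] | None = None
) -> Tpm:
    """Build a TPM from one mechanism per node (see :meth:`Tpm.from_mechanisms`)."""
    return Tpm.from_mechanisms(mechanisms, node_labels)


def sbs_to_sbn(tpm: Tpm, strict: bool = True) -> np.ndarray:
    """State-by-node form of a TPM (see :meth:`Tpm.state_by_node`)."""
    return tpm.state_by_node(strict=strict)


def connectivity(tpm: Tpm) -> np.ndarray:
    """Causal adjacency matrix of a TPM (see :meth:`Tpm.connectivity`)."""
    return tpm.connectivity()


def condition_and_marginalize(
    tpm: Tpm, fixed: Mapping[int, int], out_nodes: Sequence[int]
) -> np.ndarray:
    """See :meth:`Tpm.condition_and_marginalize`."""
    return tpm.condition_and_marginalize(fixed, out_nodes)
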