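"""Irreducible cause/effect information of mechanisms (small phi).

A mechanism's repertoire is *integrated* only to the extent that no partition
of the mechanism (and of the purview it constrains) reproduces it.  A
permissible partition splits the mechanism into ``m >= 2`` non-empty parts and
assigns each purview node to exactly one part or to a leftover set that is
rendered completely unconstrained.  The partitioned repertoire is the product
of the part repertoires times the unconstrained repertoire of the leftover.
The minimum-information partition (MIP) is the one whose partitioned
repertoire is closest (in KL divergence) to the intact repertoire, and

    phi = D_KL( intact || MIP-partitioned )

Single-node mechanisms cannot be partitioned; their phi is the KL divergence
from the unconstrained repertoire (their total intrinsic information).

Purviews are fixed to the full node set: with KL divergence as the difference
measure, purview nodes that the mechanism does not constrain contribute
exactly zero (KLD is additive over the product structure), so evaluating over
the full purview already yields the maximal phi.  The *effective purview* --
the nodes actually constrained -- is reported for display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .info_measures import entropy, kld
from .repertoires import (
    MechanismInState,
    Repertoire,
    UndefinedCauseRepertoireError,
    cause_repertoire,
    effect_repertoire,
    unconstrained_repertoire,
)
from .tpm_core import Tpm

__all__ = [
    "SubsetPartition",
    "PhiResult",
    "CompositionTable",
    "enumerate_partitions",
    "partitioned_repertoire",
    "phi",
    "composition",
]

logger = logging.getLogger(__name__)

#: absolute tolerance for comparing phi values
PHI_TOL = 1e-9


@dataclass(frozen=True)
class SubsetPartition:
    """A partition of a mechanism and its purview.

    ``parts`` pairs each mechanism part (non-empty) with a purview part
    (possibly empty); purview parts are pairwise disjoint and any purview
    nodes in no part form ``leftover_purview``, which the partition leaves
    completely unconstrained.
    """

    parts: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    leftover_purview: tuple[int, ...] = ()

    def __str__(self) -> str:
        blocks = " x ".join(
            f"({','.join(map(str, z)) or 'o'}|{','.join(map(str, x))})"
            for x, z in self.parts
        )
        if self.leftover_purview:
            blocks += f" x ({','.join(map(str, self.leftover_purview))}|o)"
        return blocks


@dataclass
class PhiResult:
    """Outcome of the irreducibility analysis of one mechanism."""

    mechanism: MechanismInState
    direction: str
    phi: float
    mip: SubsetPartition | None
    repertoire: Repertoire | None
    effective_purview: tuple[int, ...] = ()
    undefined: bool = False
    co_minimal: tuple[SubsetPartition, ...] | None = None


# ---------------------------------------------------------------------------
# partition enumeration
# ---------------------------------------------------------------------------

def _set_partitions(elements: tuple[int, ...]) -> Iterator[tuple[tuple[int, ...], ...]]:
    """All set partitions of ``elements`` into >= 2 non-empty parts.

    Parts appear ordered by their smallest contained element; the enumeration
    is deterministic (element 0 is always in the first part).
    """

    def rec(idx: int, parts: list[list[int]]) -> Iterator[tuple[tuple[int, ...], ...]]:
        if idx == len(elements):
            if len(parts) >= 2:
                yield tuple(tuple(p) for p in parts)
            return
        for p in parts:
            p.append(elements[idx])
            yield from rec(idx + 1, parts)
            p.pop()
        parts.append([elements[idx]])
        yield from rec(idx + 1, parts)
        parts.pop()

    yield from rec(0, [])


def enumerate_partitions(
    mechanism: Sequence[int], purview: Sequence[int]
) -> Iterator[SubsetPartition]:
    """Yield every permissible partition of ``mechanism`` over ``purview``.

    For each set partition of the mechanism into ``m`` parts, every assignment
    of each purview node to one of the ``m`` parts or to the leftover set is
    produced, in deterministic (lexicographic) order.
    """
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    if len(mechanism) < 2:
        raise ValueError("partitions require a mechanism of at least two nodes")
    for mech_parts in _set_partitions(mechanism):
        m = len(mech_parts)
        for assignment in itertools.product(range(m + 1), repeat=len(purview)):
            zparts: list[list[int]] = [[] for _ in range(m)]
            leftover: list[int] = []
            for node, j in zip(purview, assignment):
                (leftover if j == m else zparts[j]).append(node)
            yield SubsetPartition(
                parts=tuple(
                    (mech_parts[j], tuple(zparts[j])) for j in range(m)
                ),
                leftover_purview=tuple(leftover),
            )


_PARTITION_LIST_CACHE: dict[tuple, list[SubsetPartition]] = {}


def _partitions_for(mechanism: tuple[int, ...], purview: tuple[int, ...]):
    key = (mechanism, purview)
    out = _PARTITION_LIST_CACHE.get(key)
    if out is None:
        out = list(enumerate_partitions(mechanism, purview))
        _PARTITION_LIST_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# per-TPM repertoire caches
# ---------------------------------------------------------------------------

def _tpm_cache(tpm: Tpm) -> dict:
    return tpm.__dict__.setdefault("_causalcomp_cache", {})


def _cached_rep(
    tpm: Tpm, direction: str, nodes: tuple[int, ...], state: tuple[int, ...],
    purview: tuple[int, ...],
) -> np.ndarray:
    """Repertoire distribution of a (sub-)mechanism, cached per TPM."""
    cache = _tpm_cache(tpm)
    key = ("rep", direction, nodes, state, purview)
    dist = cache.get(key)
    if dist is None:
        mech = MechanismInState(nodes, state)
        if direction == "cause":
            dist = cause_repertoire(tpm, mech, purview).dist
        else:
            dist = effect_repertoire(tpm, mech, purview).dist
        cache[key] = dist
    return dist


def _cached_effect_marginal(
    tpm: Tpm, nodes: tuple[int, ...], state: tuple[int, ...], node: int
) -> float:
    cache = _tpm_cache(tpm)
    key = ("emarg", nodes, state, node)
    p = cache.get(key)
    if p is None:
        p = float(_cached_rep(tpm, "effect", nodes, state, (node,))[1])
        cache[key] = p
    return p


_GATHER_CACHE: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}


def _gather(purview_size: int, positions: tuple[int, ...]) -> np.ndarray:
    """Map each full-purview state index to the sub-state index over the
    purview positions in ``positions``."""
    key = (purview_size, positions)
    out = _GATHER_CACHE.get(key)
    if out is None:
        z = np.arange(2**purview_size)
        out = np.zeros_like(z)
        for k, pos in enumerate(positions):
            out |= ((z >> pos) & 1) << k
        _GATHER_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# partitioned repertoires
# ---------------------------------------------------------------------------

def partitioned_repertoire(
    tpm: Tpm,
    mech: MechanismInState,
    purview: Sequence[int],
    psi: SubsetPartition,
    direction: str,
) -> Repertoire:
    """Repertoire of ``mech`` over ``purview`` under partition ``psi``.

    Product of the part repertoires times the unconstrained repertoire of the
    leftover purview nodes.
    """
    purview = tuple(sorted(purview))
    p = len(purview)
    state_of = dict(zip(mech.nodes, mech.state))
    dist = np.ones(2**p)
    for mech_part, z_part in psi.parts:
        if not z_part:
            continue
        part_state = tuple(state_of[i] for i in mech_part)
        rep = _cached_rep(tpm, direction, tuple(mech_part), part_state, tuple(z_part))
        positions = tuple(purview.index(z) for z in z_part)
        dist = dist * rep[_gather(p, positions)]
    if psi.leftover_purview:
        lo = tuple(psi.leftover_purview)
        if direction == "cause":
            dist = dist / 2 ** len(lo)
        else:
            rep = _cached_rep(tpm, "effect", (), (), lo)
            positions = tuple(purview.index(z) for z in lo)
            dist = dist * rep[_gather(p, positions)]
    total = dist.sum()
    if total <= 0:
        raise UndefinedCauseRepertoireError("partitioned repertoire is empty")
    return Repertoire(direction, purview, dist / total)


# ---------------------------------------------------------------------------
# phi searches
# ---------------------------------------------------------------------------

def _kl_bernoulli(p: float, q: float) -> float:
    acc = 0.0
    if p > 0:
        if q <= 0:
            raise RuntimeError("partitioned repertoire lost intact support")
        acc += p * np.log2(p / q)
    if p < 1:
        if q >= 1:
            raise RuntimeError("partitioned repertoire lost intact support")
        acc += (1 - p) * np.log2((1 - p) / (1 - q))
    return float(acc)


def _effective_purview(
    tpm: Tpm, intact: Repertoire, direction: str
) -> tuple[int, ...]:
    """Purview nodes the mechanism actually constrains.

    A node is *unconstrained* if the repertoire factorizes into the marginal
    over the remaining nodes times that node's unconstrained repertoire (a
    per-node marginal check alone would miss joint cause-side constraints such
    as an XOR, whose single-node marginals are uniform).
    """
    purview = intact.purview
    p = len(purview)
    dist = intact.dist
    z = np.arange(2**p)
    out = []
    for k, node in enumerate(purview):
        rest_positions = tuple(i for i in range(p) if i != k)
        if rest_positions:
            g = _gather(p, rest_positions)
            rest = np.bincount(g, weights=dist, minlength=2 ** (p - 1))
            base = rest[g]
        else:
            base = np.ones(2**p)
        if direction == "cause":
            q1 = 0.5
        else:
            q1 = _cached_effect_marginal(tpm, (), (), node)
        recon = base * np.where((z >> k) & 1, q1, 1.0 - q1)
        if np.max(np.abs(recon - dist)) > PHI_TOL:
            out.append(node)
    return tuple(out)


def _search_effect(
    tpm: Tpm, mech: MechanismInState, purview: tuple[int, ...]
) -> tuple[float, SubsetPartition]:
    """MIP search on the effect side.

    Both the intact and every partitioned effect repertoire factorize over
    purview nodes, and KL divergence is additive over independent factors, so
    the best purview assignment can be chosen per node within each mechanism
    set partition.
    """
    intact_marg = [
        _cached_effect_marginal(tpm, mech.nodes, mech.state, z) for z in purview
    ]
    best: tuple[float, SubsetPartition] | None = None
    state_of = dict(zip(mech.nodes, mech.state))
    for mech_parts in _set_partitions(mech.nodes):
        m = len(mech_parts)
        part_states = [tuple(state_of[i] for i in part) for part in mech_parts]
        total = 0.0
        choice: list[int] = []
        for k, z in enumerate(purview):
            candidates = [
                _kl_bernoulli(
                    intact_marg[k],
                    _cached_effect_marginal(tpm, mech_parts[j], part_states[j], z),
                )
                for j in range(m)
            ]
            candidates.append(
                _kl_bernoulli(intact_marg[k], _cached_effect_marginal(tpm, (), (), z))
            )
            j_best = int(np.argmin(candidates))  # first minimum: lexicographic MIP
            total += candidates[j_best]
            choice.append(j_best)
        if best is None or total < best[0]:
            zparts: list[list[int]] = [[] for _ in range(m)]
            leftover: list[int] = []
            for z, j in zip(purview, choice):
                (leftover if j == m else zparts[j]).append(z)
            psi = SubsetPartition(
                parts=tuple((mech_parts[j], tuple(zparts[j])) for j in range(m)),
                leftover_purview=tuple(leftover),
            )
            best = (total, psi)
    assert best is not None
    return best


def _search_cause(
    tpm: Tpm, mech: MechanismInState, purview: tuple[int, ...], intact: np.ndarray
) -> tuple[float, SubsetPartition]:
    """MIP search on the cause side.

    For a partitioned repertoire ``q = prod_j q_j x uniform(leftover)``,
    ``D_KL(p || q) = -H(p) - sum_j <p_j, log2 q_j> + |leftover|`` where
    ``p_j`` is the marginal of the intact repertoire on block ``j``.
    """
    p = len(purview)
    neg_h = -entropy(intact)
    state_of = dict(zip(mech.nodes, mech.state))
    cache = _tpm_cache(tpm)

    def block_marginal(positions: tuple[int, ...]) -> np.ndarray:
        key = ("imarg", mech.nodes, mech.state, positions)
        out = cache.get(key)
        if out is None:
            out = np.bincount(
                _gather(p, positions), weights=intact, minlength=2 ** len(positions)
            )
            cache[key] = out
        return out

    def block_logq(
        part: tuple[int, ...], z_part: tuple[int, ...]
    ) -> np.ndarray:
        key = ("logq", part, tuple(state_of[i] for i in part), z_part)
        out = cache.get(key)
        if out is None:
            q = _cached_rep(
                tpm, "cause", part, tuple(state_of[i] for i in part), z_part
            )
            with np.errstate(divide="ignore"):
                out = np.log2(q)
            cache[key] = out
        return out

    best: tuple[float, SubsetPartition] | None = None
    for psi in _partitions_for(mech.nodes, purview):
        total = neg_h + len(psi.leftover_purview)
        for part, z_part in psi.parts:
            if not z_part:
                continue
            positions = tuple(purview.index(z) for z in z_part)
            pj = block_marginal(positions)
            logq = block_logq(part, z_part)
            mask = pj > 0
            if np.any(np.isneginf(logq[mask])):
                raise RuntimeError("partitioned repertoire lost intact support")
            total += -float(pj[mask] @ logq[mask])
        if best is None or total < best[0]:
            best = (max(total, 0.0), psi)
    assert best is not None
    return best


def phi(
    tpm: Tpm,
    mech: MechanismInState,
    direction: str,
    method: str = "fast",
    record_ties: bool = False,
) -> PhiResult:
    """Irreducible cause or effect information of a mechanism (Eq-level MIP
    search over the full purview).

    ``method="exhaustive"`` evaluates every partition through the generic
    :func:`partitioned_repertoire` path (slower, used for cross-checks);
    ``"fast"`` exploits KLD additivity on the effect side and a block
    decomposition on the cause side.  ``record_ties`` collects all co-minimal
    partitions (within ``1e-9``); it implies the exhaustive path.
    """
    if direction not in ("cause", "effect"):
        raise ValueError("direction must be 'cause' or 'effect'")
    if len(mech) == 0:
        raise ValueError("mechanism must be non-empty")
    purview = tuple(range(tpm.n_nodes))
    try:
        if direction == "cause":
            intact = cause_repertoire(tpm, mech, purview)
        else:
            intact = effect_repertoire(tpm, mech, purview)
    except UndefinedCauseRepertoireError:
        # common for multi-node mechanisms of convergent deterministic maps;
        # the result carries undefined=True, so log quietly
        logger.debug(
            "mechanism %s=%s: state unreachable under every perturbation; "
            "phi set to 0", mech.nodes, mech.state,
        )
        return PhiResult(mech, direction, 0.0, None, None, undefined=True)

    eff_purview = _effective_purview(tpm, intact, direction)

    if len(mech) == 1:
        unconstrained = unconstrained_repertoire(tpm, direction, purview)
        value = kld(intact.dist, unconstrained.dist)
        return PhiResult(mech, direction, value, None, intact, eff_purview)

    if record_ties or method == "exhaustive":
        best_val: float | None = None
        best_psi: SubsetPartition | None = None
        ties: list[SubsetPartition] = []
        for psi in _partitions_for(mech.nodes, purview):
            part = partitioned_repertoire(tpm, mech, purview, psi, direction)
            value = kld(intact.dist, part.dist)
            if best_val is None or value < best_val - 1e-15:
                best_val, best_psi = value, psi
            if record_ties:
                ties.append((value, psi))  # filtered below
        assert best_val is not None
        co = None
        if record_ties:
            co = tuple(psi for v, psi in ties if v <= best_val + PHI_TOL)
        return PhiResult(
            mech, direction, max(best_val, 0.0), best_psi, intact, eff_purview,
            co_minimal=co,
        )

    if direction == "effect":
        value, psi = _search_effect(tpm, mech, purview)
    else:
        value, psi = _search_cause(tpm, mech, purview, intact.dist)
    return PhiResult(mech, direction, max(value, 0.0), psi, intact, eff_purview)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """phi of every non-empty mechanism subset in both directions, plus sums."""

    state: tuple[int, ...]
    node_labels: tuple[str, ...]
    results: dict[tuple[tuple[int, ...], str], PhiResult] = field(default_factory=dict)

    @property
    def subsets(self) -> list[tuple[int, ...]]:
        seen = []
        for nodes, _ in self.results:
            if nodes not in seen:
                seen.append(nodes)
        return seen

    def phi_value(self, nodes: Sequence[int], direction: str) -> float:
        return self.results[(tuple(sorted(nodes)), direction)].phi

    @property
    def sum_cause(self) -> float:
        return sum(r.phi for (_, d), r in self.results.items() if d == "cause")

    @property
    def sum_effect(self) -> float:
        return sum(r.phi for (_, d), r in self.results.items() if d == "effect")

    @property
    def total(self) -> float:
        return self.sum_cause + self.sum_effect

    def subset_label(self, nodes: tuple[int, ...]) -> str:
        return "".join(self.node_labels[i] for i in nodes)

    def to_dataframe(self):
        import pandas as pd

        cols = {}
        for nodes in self.subsets:
            label = self.subset_label(nodes)
            cols[label] = [
                self.phi_value(nodes, "cause"),
                self.phi_value(nodes, "effect"),
            ]
        cols["sum"] = [self.sum_cause, self.sum_effect]
        return pd.DataFrame(cols, index=["phi_cause", "phi_effect"])

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index_label="direction")

    def to_dict(self) -> dict:
        out = {
            "state": list(self.state),
            "node_labels": list(self.node_labels),
            "subsets": [],
            "sum_phi_cause": self.sum_cause,
            "sum_phi_effect": self.sum_effect,
            "total": self.total,
        }
        for nodes in self.subsets:
            entry = {"nodes": list(nodes), "label": self.subset_label(nodes)}
            for d in ("cause", "effect"):
                r = self.results[(nodes, d)]
                entry[f"phi_{d}"] = r.phi
                entry[f"mip_{d}"] = str(r.mip) if r.mip is not None else None
                entry[f"effective_purview_{d}"] = list(r.effective_purview)
            out["subsets"].append(entry)
        return out


def composition(tpm: Tpm, state: Sequence[int], method: str = "fast") -> CompositionTable:
    """Evaluate phi for all ``2^n - 1`` non-empty subsets in both directions."""
    state = tuple(int(b) for b in state)
    if len(state) != tpm.n_nodes or any(b not in (0, 1) for b in state):
        raise ValueError("state must be a binary tuple of length n")
    table = CompositionTable(state, tpm.node_labels)
    nodes = range(tpm.n_nodes)
    for size in range(1, tpm.n_nodes + 1):
        for subset in itertools.combinations(nodes, size):
            mech = MechanismInState.from_system_state(subset, state)
            for direction in ("cause", "effect"):
                table.results[(subset, direction)] = phi(
                    tpm, mech, direction, method=method
                )
    return table
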