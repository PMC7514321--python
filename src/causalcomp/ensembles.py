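"""Ensembles of small Boolean systems: random samplers, exhaustive
enumeration of reversible dynamics, time reversal, and metric sweeps.

A deterministic system is *reversible* when its global transition map is a
bijection on the state space -- the state-by-state TPM is a permutation
matrix (a single 1 in every column as well as every row).  Every state then
completely specifies both its predecessor and successor, which forces the
effective information to its maximum of ``n`` bits.  A reversible system is
*ergodic-reversible* (ER) when the permutation is one cycle through all
``2^n`` states, so the observed stationary distribution is exactly uniform
and predictive information coincides with effective information.

Systems are counted as distinct TPMs (no quotienting by node relabelling):
there are ``(2^n)!`` reversible and ``(2^n - 1)!`` ergodic-reversible
``n``-node systems, i.e. 40,320 and 5,040 for ``n = 3``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .tpm_core import Tpm

__all__ = [
    "AttractorProfile",
    "sample_deterministic",
    "sample_probabilistic",
    "is_reversible",
    "is_ergodic_reversible",
    "enumerate_reversible",
    "permutation_tpm",
    "time_reverse",
    "attractor_profile",
    "sweep",
]


# ---------------------------------------------------------------------------
# random samplers
# ---------------------------------------------------------------------------

def sample_deterministic(
    n: int, seed: int | np.random.Generator | None = None
) -> Tpm:
    """Random deterministic TPM: each prior state is assigned a uniformly
    random successor state."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    targets = rng.integers(0, 2**n, size=2**n)
    sbs = np.zeros((2**n, 2**n))
    sbs[np.arange(2**n), targets] = 1.0
    return Tpm(sbs)


def sample_probabilistic(
    n: int, seed: int | np.random.Generator | None = None
) -> Tpm:
    """Random probabilistic TPM: every state-by-node entry drawn from
    ``U(0, 1)``; conditionally independent by construction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return Tpm.from_state_by_node(rng.random((2**n, n)))


# ---------------------------------------------------------------------------
# reversibility
# ---------------------------------------------------------------------------

def is_reversible(tpm: Tpm) -> bool:
    """Deterministic with a permutation-matrix TPM (single 1 per column)."""
    if not tpm.is_deterministic:
        return False
    sbs = tpm.state_by_state
    return bool(np.all(sbs.sum(axis=0) == 1.0))


def _permutation_of(tpm: Tpm) -> np.ndarray:
    if not is_reversible(tpm):
        raise ValueError("TPM is not reversible")
    return np.argmax(tpm.state_by_state, axis=1)


def _cycles(successor: np.ndarray) -> list[list[int]]:
    """Cycle decomposition of a permutation, cycles ordered by smallest state."""
    seen = np.zeros(len(successor), dtype=bool)
    cycles = []
    for start in range(len(successor)):
        if seen[start]:
            continue
        cycle = [start]
        seen[start] = True
        nxt = int(successor[start])
        while nxt != start:
            cycle.append(nxt)
            seen[nxt] = True
            nxt = int(successor[nxt])
        cycles.append(cycle)
    return cycles


def is_ergodic_reversible(tpm: Tpm) -> bool:
    """Whether the permutation is a single cycle through all ``2^n`` states.

    Raises ``ValueError`` for non-reversible input.
    """
    perm = _permutation_of(tpm)
    return len(_cycles(perm)) == 1


def permutation_tpm(perm: Sequence[int], node_labels=None) -> Tpm:
    """TPM whose deterministic map sends state index ``r`` to ``perm[r]``."""
    perm = np.asarray(perm, dtype=int)
    sbs = np.zeros((len(perm), len(perm)))
    sbs[np.arange(len(perm)), perm] = 1.0
    return Tpm(sbs, node_labels)


def enumerate_reversible(n: int) -> Iterator[Tpm]:
    """All ``(2^n)!`` reversible systems, one per permutation of the state
    space, in lexicographic permutation order.  Guarded to ``n <= 3``."""
    if n > 3:
        raise ValueError(
            "exhaustive enumeration of (2^n)! reversible systems is limited "
            "to n <= 3"
        )
    for perm in itertools.permutations(range(2**n)):
        yield permutation_tpm(perm)


def time_reverse(tpm: Tpm) -> Tpm:
    """The time-reversed dynamical equivalent of a reversible system: the
    inverse permutation (transpose of the permutation matrix)."""
    if not is_reversible(tpm):
        raise ValueError("time reversal is defined for reversible systems")
    return Tpm(tpm.state_by_state.T.copy(), tpm.node_labels)


# ---------------------------------------------------------------------------
# attractor structure
# ---------------------------------------------------------------------------

@dataclass
class AttractorProfile:
    """Cycle decomposition and basins of a deterministic system's state map."""

    cycles: list[list[int]]
    basin_sizes: list[int]  # states per attractor, including the cycle itself

    @property
    def fixed_points(self) -> int:
        return sum(1 for c in self.cycles if len(c) == 1)

    @property
    def n_attractors(self) -> int:
        return len(self.cycles)

    @property
    def cycle_lengths(self) -> list[int]:
        return [len(c) for c in self.cycles]


def attractor_profile(tpm: Tpm) -> AttractorProfile:
    """Attractors and basin sizes of a deterministic TPM, by traversal of the
    functional digraph of the state map."""
    if not tpm.is_deterministic:
        raise ValueError("attractor analysis requires a deterministic TPM")
    successor = np.argmax(tpm.state_by_state, axis=1)
    n_states = len(successor)

    # find states on cycles: iterate n_states steps to land inside a cycle
    on_cycle = np.zeros(n_states, dtype=bool)
    for start in range(n_states):
        s = start
        for _ in range(n_states):
            s = int(successor[s])
        # s is now on a cycle; mark the whole cycle
        if not on_cycle[s]:
            c = s
            while True:
                on_cycle[c] = True
                c = int(successor[c])
                if c == s:
                    break

    cycle_states = np.flatnonzero(on_cycle)
    cycles = []
    seen = set()
    for s in cycle_states:
        if s in seen:
            continue
        cycle = [int(s)]
        seen.add(int(s))
        c = int(successor[s])
        while c != s:
            cycle.append(c)
            seen.add(c)
            c = int(successor[c])
        cycles.append(cycle)

    # basin: attractor index reached from each state
    attractor_of_cycle_state = {}
    for idx, cycle in enumerate(cycles):
        for s in cycle:
            attractor_of_cycle_state[s] = idx
    basin_sizes = [0] * len(cycles)
    for start in range(n_states):
        s = start
        while s not in attractor_of_cycle_state:
            s = int(successor[s])
        basin_sizes[attractor_of_cycle_state[s]] += 1
    return AttractorProfile(cycles, basin_sizes)


# ---------------------------------------------------------------------------
# metric sweeps
# ---------------------------------------------------------------------------

#: metric name -> callable(tpm) used by :func:`sweep`
def _metric_functions():
    from .info_measures import effective_information
    from .mechanism_phi import composition
    from .system_phi import mean_big_phi
    from .tpm_core import index_to_state

    def mean_sums(tpm: Tpm) -> tuple[float, float]:
        sc = se = 0.0
        for r in range(tpm.n_states):
            table = composition(tpm, index_to_state(r, tpm.n_nodes))
            sc += table.sum_cause
            se += table.sum_effect
        return sc / tpm.n_states, se / tpm.n_states

    return {
        "ei": effective_information,
        "_mean_sums": mean_sums,
        "mean_big_phi": mean_big_phi,
        "reversible": is_reversible,
    }


def sweep(
    systems: Iterable[Tpm],
    metrics: Sequence[str] = ("ei", "mean_sum_phi", "mean_big_phi"),
    progress: bool = False,
):
    """Evaluate metrics over a stream of systems; returns a DataFrame with one
    row per system.

    ``mean_*`` metrics are state averages over all ``2^n`` states.  The two
    composition sums share their per-state evaluation, so requesting both
    costs no more than one.
    """
    import pandas as pd

    available = _metric_functions()
    sum_metrics = {"mean_sum_phi_cause", "mean_sum_phi_effect", "mean_sum_phi"}
    valid = (set(available) - {"_mean_sums"}) | sum_metrics
    unknown = [m for m in metrics if m not in valid]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {sorted(valid)}")

    rows = []
    for idx, tpm in enumerate(systems):
        row: dict = {"system": idx}
        sums: tuple[float, float] | None = None
        for m in metrics:
            if m in sum_metrics:
                if sums is None:
                    sums = available["_mean_sums"](tpm)
                sc, se = sums
                row[m] = {"mean_sum_phi_cause": sc,
                          "mean_sum_phi_effect": se,
                          "mean_sum_phi": sc + se}[m]
            else:
                row[m] = available[m](tpm)
        rows.append(row)
        if progress and (idx + 1) % 100 == 0:
            print(f"sweep: {idx + 1} systems done", flush=True)
    return pd.DataFrame(rows)
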