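"""System-level integration: unidirectional cuts and compositional big phi.

A system is an integrated whole only if every part constrains, and is
constrained by, the rest.  This is probed with unidirectional cuts
``X -/-> S\\X``: all connections from a source subset into the rest are
severed by causally marginalizing those inputs (the targets receive
independent uniform noise in place of the severed edges).  Within the cut
system, phi is re-evaluated for every subset that was irreducible in the
intact system, and the losses ``delta_phi = phi - phi_cut`` are summed
separately over the cause and effect sides.  The compositional integrated
information is

    big_phi = min over cuts of min( sum delta_phi_C, sum delta_phi_E )

A single cut TPM serves both the cause- and effect-side re-evaluation: the
cut defines one partitioned system inside which both repertoire directions
are computed.

Two accounting strategies for ``delta_phi`` are provided:

* ``"distinction"`` (default) -- a mechanism's contribution is tied to the
  purview it actually constrains.  If the cut leaves the effective purview
  unchanged, the contribution is the signed difference ``phi - phi_cut``; if
  the cut moves the mechanism onto a different effective purview, the intact
  distinction is destroyed and a new one created, and both count
  (``phi + phi_cut``).  This is the cause-effect-structure distance under
  which a cut is charged for all compositional information it displaces.
* ``"mechanism"`` -- the literal per-mechanism difference ``phi - phi_cut``
  regardless of purview, without clipping; the MIP re-minimization inside the
  cut system can in principle raise phi, and a negative delta is logged
  rather than silently truncated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .mechanism_phi import PHI_TOL, CompositionTable, PhiResult, composition, phi
from .repertoires import MechanismInState
from .tpm_core import Tpm

__all__ = [
    "SystemCut",
    "BigPhiResult",
    "enumerate_cuts",
    "apply_cut",
    "phi_under_cut",
    "big_phi",
    "mean_big_phi",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SystemCut:
    """Unidirectional cut severing all connections ``source -> rest``."""

    source: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", tuple(sorted(self.source)))

    def label(self, node_labels: Sequence[str]) -> str:
        src = "".join(node_labels[i] for i in self.source)
        rest = "".join(
            node_labels[i] for i in range(len(node_labels)) if i not in self.source
        )
        return f"{src} -/-> {rest}"


@dataclass
class BigPhiResult:
    """Big-phi analysis of one system state."""

    state: tuple[int, ...]
    big_phi: float
    minimizing_cut: SystemCut | None
    side: str | None
    composition: CompositionTable
    cut_sums: dict[SystemCut, tuple[float, float]] = field(default_factory=dict)
    delta_table: dict[tuple[tuple[int, ...], str], float] = field(default_factory=dict)


def enumerate_cuts(n: int) -> Iterator[SystemCut]:
    """The ``2^n - 2`` unidirectional cuts, sources ordered by size then
    lexicographically."""
    for size in range(1, n):
        for source in itertools.combinations(range(n), size):
            yield SystemCut(source)


def apply_cut(tpm: Tpm, cut: SystemCut) -> Tpm:
    """TPM of the system with all connections ``source -> rest`` severed.

    Every node outside the source gets a new mechanism equal to its original
    ON-probability averaged uniformly over all states of its inputs inside the
    source (causal marginalization of the severed edges); source nodes keep
    their mechanisms.  The result is conditionally independent by
    construction.
    """
    if not cut.source or len(cut.source) >= tpm.n_nodes:
        raise ValueError("cut source must be a non-empty proper subset")
    sbn = tpm.node_marginals.copy()
    rows = np.arange(tpm.n_states)
    targets = [j for j in range(tpm.n_nodes) if j not in cut.source]
    for i in cut.source:
        partner = rows ^ (1 << i)
        sbn[:, targets] = 0.5 * (sbn[:, targets] + sbn[partner][:, targets])
    return Tpm.from_state_by_node(sbn, tpm.node_labels)


def phi_under_cut(
    tpm: Tpm, cut: SystemCut, mech: MechanismInState, direction: str
) -> PhiResult:
    """phi of a mechanism re-evaluated inside the cut system: the full MIP
    search is re-run on the cut TPM."""
    return phi(apply_cut(tpm, cut), mech, direction)


def _delta_phi(
    intact_result: PhiResult, cut_result: PhiResult, strategy: str
) -> float:
    if strategy == "mechanism":
        return intact_result.phi - cut_result.phi
    if strategy != "distinction":
        raise ValueError("strategy must be 'distinction' or 'mechanism'")
    if cut_result.phi <= PHI_TOL:
        return intact_result.phi  # distinction destroyed outright
    if cut_result.effective_purview == intact_result.effective_purview:
        return intact_result.phi - cut_result.phi
    # the cut displaced the distinction onto a different purview: the intact
    # distinction is lost and an unrelated one appears; both count
    return intact_result.phi + cut_result.phi


def big_phi(
    tpm: Tpm,
    state: Sequence[int],
    intact: CompositionTable | None = None,
    strategy: str = "distinction",
) -> BigPhiResult:
    """Compositional integrated information of the system in ``state``.

    For each unidirectional cut, ``delta_phi`` is summed over all subsets
    whose intact phi is positive (separately per direction); subsets with
    intact phi = 0 are not re-evaluated and contribute zero.  ``big_phi`` is
    the minimum over cuts of the smaller of the two sums.  See the module
    docstring for the ``strategy`` choices.
    """
    state = tuple(int(b) for b in state)
    if intact is None:
        intact = composition(tpm, state)
    result = BigPhiResult(state, 0.0, None, None, intact)

    positive = {
        key: r
        for key, r in intact.results.items()
        if r.phi > PHI_TOL and not r.undefined
    }
    if not positive:
        return result

    best: tuple[float, SystemCut, str, dict] | None = None
    for cut in enumerate_cuts(tpm.n_nodes):
        cut_tpm = apply_cut(tpm, cut)
        sums = {"cause": 0.0, "effect": 0.0}
        deltas: dict[tuple[tuple[int, ...], str], float] = {}
        negatives: list[float] = []
        for (nodes, direction), intact_result in positive.items():
            mech = MechanismInState.from_system_state(nodes, state)
            cut_result = phi(cut_tpm, mech, direction)
            delta = _delta_phi(intact_result, cut_result, strategy)
            if delta < -PHI_TOL:
                negatives.append(delta)
                logger.debug(
                    "negative delta phi (%.4g) for mechanism %s (%s) under cut %s",
                    delta, nodes, direction, cut.source,
                )
            deltas[(nodes, direction)] = delta
            sums[direction] += delta
        if negatives:
            # kept unclipped by design; the MIP re-minimization inside the cut
            # system can raise phi for individual mechanisms
            logger.info(
                "cut %s: %d negative delta-phi term(s), most negative %.4g",
                cut.source, len(negatives), min(negatives),
            )
        result.cut_sums[cut] = (sums["cause"], sums["effect"])
        for side in ("cause", "effect"):
            if best is None or sums[side] < best[0]:
                best = (sums[side], cut, side, deltas)
    assert best is not None
    value, cut, side, deltas = best
    result.big_phi = max(value, 0.0)
    result.minimizing_cut = cut
    result.side = side
    result.delta_table = deltas
    return result


def mean_big_phi(tpm: Tpm, strategy: str = "distinction") -> float:
    """Unweighted mean of big phi over all ``2^n`` system states."""
    values = [
        big_phi(tpm, s, strategy=strategy).big_phi
        for s in _all_states(tpm.n_nodes)
    ]
    return float(np.mean(values))


def _all_states(n: int) -> Iterator[tuple[int, ...]]:
    from .tpm_core import index_to_state

    return (index_to_state(r, n) for r in range(2**n))
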