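"""Ready-made example systems and logic-gate building blocks.

``mcx()`` is the canonical worked example used throughout the package and its
tests: three binary nodes where M computes the majority of (M, C, X), C
copies M, and X is the exclusive-or of M and C.  The system is deterministic
but convergent (two states map onto 000), so it is not reversible.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .ensembles import permutation_tpm
from .tpm_core import Tpm

__all__ = [
    "mcx",
    "identity_tpm",
    "cyclic_shift",
    "majority",
    "copy_of",
    "xor_of",
    "not_of",
    "FIXTURES",
    "get_fixture",
]


def majority(inputs: Sequence[int]) -> Callable[[tuple[int, ...]], int]:
    """ON iff at least half of the listed input nodes (strictly more than
    half when even) were ON; here: >= 2 of 3 in the 3-input case."""
    inputs = list(inputs)
    threshold = len(inputs) / 2

    def fn(state: tuple[int, ...]) -> int:
        return int(sum(state[i] for i in inputs) > threshold)

    return fn


def copy_of(source: int) -> Callable[[tuple[int, ...]], int]:
    return lambda state: state[source]


def not_of(source: int) -> Callable[[tuple[int, ...]], int]:
    return lambda state: 1 - state[source]


def xor_of(a: int, b: int) -> Callable[[tuple[int, ...]], int]:
    return lambda state: state[a] ^ state[b]


def mcx() -> Tpm:
    """The 3-node majority/copy/xor example system."""
    return Tpm.from_node_functions(
        [majority([0, 1, 2]), copy_of(0), xor_of(0, 1)], node_labels="MCX"
    )


def identity_tpm(n: int = 3) -> Tpm:
    """Identity permutation: every state is a fixed point (reversible, not
    ergodic)."""
    return permutation_tpm(np.arange(2**n))


def cyclic_shift(n: int = 3) -> Tpm:
    """Single ``2^n``-cycle sending state index ``r`` to ``r + 1 (mod 2^n)``:
    the simplest ergodic-reversible system."""
    k = 2**n
    return permutation_tpm((np.arange(k) + 1) % k)


FIXTURES: dict[str, Callable[[], Tpm]] = {
    "mcx": mcx,
    "identity3": lambda: identity_tpm(3),
    "shift3": lambda: cyclic_shift(3),
}


def get_fixture(name: str) -> Tpm:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
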