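import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from causalcomp.fixtures import mcx
from causalcomp.repertoires import MechanismInState, brute_force_repertoire
from causalcomp.tpm_core import Tpm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def mcx_tpm() -> Tpm:
    return mcx()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190989)


# ---------------------------------------------------------------------------
# independent phi oracle: brute-force repertoires + an independently written
# partition enumerator, combined by explicit state loops
# ---------------------------------------------------------------------------

def oracle_kld(p, q):
    from scipy.special import rel_entr

    return float(np.sum(rel_entr(p, q)) / np.log(2))


def oracle_set_partitions(elements):
    """Set partitions into >= 2 parts via label vectors + canonicalization
    (deliberately different from the production recursive generator)."""
    elements = tuple(elements)
    seen = set()
    out = []
    for labels in itertools.product(range(len(elements)), repeat=len(elements)):
        parts = {}
        for el, lab in zip(elements, labels):
            parts.setdefault(lab, []).append(el)
        if len(parts) < 2:
            continue
        canon = frozenset(frozenset(p) for p in parts.values())
        if canon not in seen:
            seen.add(canon)
            out.append([tuple(sorted(p)) for p in parts.values()])
    return out


def oracle_partitioned_dist(tpm, mech, purview, mech_parts, assignment, direction):
    """Partitioned repertoire by explicit per-state multiplication of
    brute-force part repertoires."""
    m = len(mech_parts)
    state_of = dict(zip(mech.nodes, mech.state))
    p = len(purview)
    dist = np.ones(2**p)
    blocks = []
    for j, part in enumerate(mech_parts):
        z_part = tuple(z for z, a in zip(purview, assignment) if a == j)
        blocks.append((MechanismInState(part, tuple(state_of[i] for i in part)), z_part))
    leftover = tuple(z for z, a in zip(purview, assignment) if a == m)
    if leftover:
        blocks.append((MechanismInState((), ()), leftover))
    for block_mech, z_part in blocks:
        if not z_part:
            continue
        rep = brute_force_repertoire(tpm, block_mech, z_part, direction).dist
        for z in range(2**p):
            sub = 0
            for k, node in enumerate(z_part):
                pos = purview.index(node)
                sub |= ((z >> pos) & 1) << k
            dist[z] *= rep[sub]
    total = dist.sum()
    return dist / total


def oracle_phi(tpm, mech, direction, purview=None):
    """phi via brute-force repertoires and exhaustive partition search."""
    if purview is None:
        purview = tuple(range(tpm.n_nodes))
    purview = tuple(sorted(purview))
    intact = brute_force_repertoire(tpm, mech, purview, direction).dist
    if len(mech) == 1:
        unconstrained = brute_force_repertoire(
            tpm, MechanismInState((), ()), purview, direction
        ).dist
        return oracle_kld(intact, unconstrained)
    best = np.inf
    for mech_parts in oracle_set_partitions(mech.nodes):
        m = len(mech_parts)
        for assignment in itertools.product(range(m + 1), repeat=len(purview)):
            q = oracle_partitioned_dist(
                tpm, mech, purview, mech_parts, assignment, direction
            )
            best = min(best, oracle_kld(intact, q))
    return max(best, 0.0)


def relabel_tpm(tpm: Tpm, perm) -> Tpm:
    """Apply a node relabelling: node i of the original becomes perm[i]."""
    n = tpm.n_nodes
    idx = np.empty(2**n, dtype=int)
    for r in range(2**n):
        new = 0
        for i in range(n):
            new |= ((r >> i) & 1) << perm[i]
        idx[r] = new
    sbs = np.zeros_like(tpm.state_by_state)
    old = tpm.state_by_state
    for r in range(2**n):
        for c in range(2**n):
            sbs[idx[r], idx[c]] = old[r, c]
    labels = [""] * n
    for i in range(n):
        labels[perm[i]] = tpm.node_labels[i]
    return Tpm(sbs, labels)
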