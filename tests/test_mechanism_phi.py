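import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import oracle_phi
from causalcomp.info_measures import kld
from causalcomp.mechanism_phi import (
    SubsetPartition,
    composition,
    enumerate_partitions,
    partitioned_repertoire,
    phi,
)
from causalcomp.repertoires import (
    MechanismInState,
    cause_repertoire,
    effect_repertoire,
    unconstrained_repertoire,
)
from causalcomp.tpm_core import Tpm

MCX_STATE = (0, 1, 1)

# the published composition table of the majority/copy/xor system at (0,1,1)
TABLE = {
    ((0,), "cause"): 1.0,
    ((1,), "cause"): 1.0,
    ((2,), "cause"): 1.0,
    ((0, 1), "cause"): 1.0,
    ((0, 2), "cause"): 0.415,
    ((1, 2), "cause"): 1.0,
    ((0, 1, 2), "cause"): 0.0,
    ((0,), "effect"): 1.189,
    ((1,), "effect"): 0.189,
    ((2,), "effect"): 0.189,
    ((0, 1), "effect"): 1.0,
    ((0, 2), "effect"): 0.0,
    ((1, 2), "effect"): 0.415,
    ((0, 1, 2), "effect"): 0.415,
}


def mech_at(nodes, state=MCX_STATE):
    return MechanismInState.from_system_state(nodes, state)


class TestEnumeratePartitions:
    def test_two_node_mechanism_three_node_purview_count(self):
        parts = list(enumerate_partitions((0, 1), (0, 1, 2)))
        assert len(parts) == 27  # one bipartition x 3^3 purview assignments

    def test_minimal_purview_assignments(self):
        parts = list(enumerate_partitions((0, 1), (2,)))
        # node 2 -> part 1, part 2, or leftover
        assert len(parts) == 3
        destinations = set()
        for p in parts:
            if p.leftover_purview:
                destinations.add("leftover")
            else:
                destinations.add(tuple(z for _, z in p.parts))
        assert len(destinations) == 3

    def test_three_node_mechanism_part_structures(self):
        structures = {
            tuple(x for x, _ in p.parts)
            for p in enumerate_partitions((0, 1, 2), (0,))
        }
        # 3 bipartitions + 1 tripartition of the mechanism
        assert len(structures) == 4
        assert {len(s) for s in structures} == {2, 3}

    def test_singleton_mechanism_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_partitions((0,), (0, 1)))

    def test_mechanism_parts_are_exhaustive_and_disjoint(self):
        for p in enumerate_partitions((0, 1, 2), (0, 1)):
            mech_nodes = [i for part, _ in p.parts for i in part]
            assert sorted(mech_nodes) == [0, 1, 2]
            purview_nodes = [z for _, zs in p.parts for z in zs] + list(
                p.leftover_purview
            )
            assert len(purview_nodes) == len(set(purview_nodes))


class TestPartitionedRepertoire:
    def test_published_cause_partition_value(self, mcx_tpm):
        # {M,X}=(0,1) cut as (X_prev | M) x (MC_prev | X): costs 0.415 bits
        psi = SubsetPartition(parts=(((0,), (2,)), ((2,), (0, 1))))
        intact = cause_repertoire(mcx_tpm, mech_at((0, 2)), (0, 1, 2))
        part = partitioned_repertoire(mcx_tpm, mech_at((0, 2)), (0, 1, 2), psi, "cause")
        assert kld(intact.dist, part.dist) == pytest.approx(0.415, abs=0.0005)

    def test_published_effect_partition_value(self, mcx_tpm):
        # MCX=(0,1,1) cut as (CX_next | MC) x (M_next | X): costs 0.415 bits
        psi = SubsetPartition(parts=(((0, 1), (1, 2)), ((2,), (0,))))
        m = mech_at((0, 1, 2))
        intact = effect_repertoire(mcx_tpm, m, (0, 1, 2))
        part = partitioned_repertoire(mcx_tpm, m, (0, 1, 2), psi, "effect")
        assert part.marginal(0) == pytest.approx(0.75)
        assert kld(intact.dist, part.dist) == pytest.approx(0.415, abs=0.0005)

    def test_vacuous_cut_reproduces_intact_repertoire(self):
        # node 1 constrains nothing about node 0's next state
        tpm = Tpm.from_node_functions([lambda s: s[0], lambda s: s[0]])
        m = MechanismInState((0, 1), (1, 1))
        psi = SubsetPartition(parts=(((0,), (0, 1)), ((1,), ())))
        intact = effect_repertoire(tpm, m, (0, 1))
        part = partitioned_repertoire(tpm, m, (0, 1), psi, "effect")
        assert np.allclose(part.dist, intact.dist, atol=1e-9)


class TestPhi:
    @pytest.mark.parametrize("key, expected", sorted(TABLE.items()))
    def test_published_composition_table(self, mcx_tpm, key, expected):
        nodes, direction = key
        result = phi(mcx_tpm, mech_at(nodes), direction)
        assert result.phi == pytest.approx(expected, abs=0.0005)

    def test_single_node_phi_equals_kld_to_unconstrained(self, mcx_tpm):
        for node in range(3):
            for direction in ("cause", "effect"):
                m = mech_at((node,))
                result = phi(mcx_tpm, m, direction)
                intact = (
                    cause_repertoire(mcx_tpm, m, (0, 1, 2))
                    if direction == "cause"
                    else effect_repertoire(mcx_tpm, m, (0, 1, 2))
                )
                expected = kld(
                    intact.dist,
                    unconstrained_repertoire(mcx_tpm, direction, (0, 1, 2)).dist,
                )
                assert result.phi == pytest.approx(expected, abs=1e-12)

    def test_disconnected_nodes_are_reducible(self):
        tpm = Tpm.from_node_functions([lambda s: s[0], lambda s: 1 - s[1]])
        m = MechanismInState((0, 1), (1, 0))
        for direction in ("cause", "effect"):
            assert phi(tpm, m, direction).phi == pytest.approx(0.0, abs=1e-9)

    def test_fast_and_exhaustive_searches_agree_on_mcx(self, mcx_tpm):
        for nodes in [(0, 1), (0, 2), (1, 2), (0, 1, 2)]:
            for direction in ("cause", "effect"):
                fast = phi(mcx_tpm, mech_at(nodes), direction, method="fast")
                slow = phi(mcx_tpm, mech_at(nodes), direction, method="exhaustive")
                assert fast.phi == pytest.approx(slow.phi, abs=1e-9)

    def test_matches_independent_oracle_on_mcx(self, mcx_tpm):
        for nodes in [(0,), (0, 1), (0, 2), (0, 1, 2)]:
            for direction in ("cause", "effect"):
                expected = oracle_phi(mcx_tpm, mech_at(nodes), direction)
                assert phi(mcx_tpm, mech_at(nodes), direction).phi == pytest.approx(
                    expected, abs=1e-9
                )

    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_two_node_systems(self, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            sbs = np.zeros((4, 4))
            sbs[np.arange(4), rng.integers(0, 4, 4)] = 1.0
            tpm = Tpm(sbs)
        else:
            tpm = Tpm.from_state_by_node(rng.random((4, 2)))
        state = tuple(rng.integers(0, 2, 2).tolist())
        m = MechanismInState.from_system_state((0, 1), state)
        for direction in ("cause", "effect"):
            result = phi(tpm, m, direction)
            if result.undefined:
                continue
            assert result.phi == pytest.approx(
                oracle_phi(tpm, m, direction), abs=1e-9
            )

    @given(st.integers(0, 2**31 - 1))
    def test_phi_is_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        tpm = Tpm.from_state_by_node(rng.random((8, 3)))
        state = tuple(rng.integers(0, 2, 3).tolist())
        nodes = tuple(sorted(rng.choice(3, rng.integers(1, 4), replace=False)))
        m = MechanismInState.from_system_state(nodes, state)
        for direction in ("cause", "effect"):
            assert phi(tpm, m, direction).phi >= 0.0

    def test_unconstrained_purview_nodes_add_nothing(self, mcx_tpm):
        """phi over the effective purview equals phi over the full purview
        (KLD additivity: unconstrained nodes contribute zero)."""
        for nodes in [(0,), (1,), (0, 1), (1, 2), (0, 1, 2)]:
            for direction in ("cause", "effect"):
                result = phi(mcx_tpm, mech_at(nodes), direction)
                if not result.effective_purview or result.phi < 1e-9:
                    continue
                restricted = oracle_phi(
                    mcx_tpm, mech_at(nodes), direction,
                    purview=result.effective_purview,
                )
                assert result.phi == pytest.approx(restricted, abs=1e-9)

    def test_unreachable_mechanism_state_yields_flagged_zero(self):
        tpm = Tpm.from_node_functions([lambda s: 1, lambda s: s[0]])
        result = phi(tpm, MechanismInState((0,), (0,)), "cause")
        assert result.undefined and result.phi == 0.0

    def test_mip_ties_recorded(self, mcx_tpm):
        result = phi(mcx_tpm, mech_at((0, 1, 2)), "cause", record_ties=True)
        assert result.co_minimal is not None
        assert result.mip in result.co_minimal
        # the fully reducible mechanism admits several zero-cost partitions
        assert result.phi == pytest.approx(0.0, abs=1e-9)
        assert len(result.co_minimal) >= 1


class TestComposition:
    def test_mcx_sums(self, mcx_tpm):
        table = composition(mcx_tpm, MCX_STATE)
        assert len(table.subsets) == 7
        assert table.sum_cause == pytest.approx(5.415, abs=0.005)
        assert table.sum_effect == pytest.approx(3.396, abs=0.005)
        assert table.total == pytest.approx(8.811, abs=0.005)

    def test_disconnected_system_has_no_multinode_phi(self):
        tpm = Tpm.from_node_functions([lambda s: s[0], lambda s: s[1], lambda s: s[2]])
        table = composition(tpm, (1, 0, 1))
        for nodes in table.subsets:
            if len(nodes) > 1:
                assert table.phi_value(nodes, "cause") == pytest.approx(0.0, abs=1e-9)
                assert table.phi_value(nodes, "effect") == pytest.approx(0.0, abs=1e-9)

    def test_export_round_trip(self, mcx_tpm):
        table = composition(mcx_tpm, MCX_STATE)
        frame = table.to_dataframe()
        assert list(frame.columns)[:-1] == ["M", "C", "X", "MC", "MX", "CX", "MCX"]
        assert frame.loc["phi_cause", "sum"] == pytest.approx(table.sum_cause)
        d = table.to_dict()
        assert d["total"] == pytest.approx(8.811, abs=0.005)
        assert "MX" in [s["label"] for s in d["subsets"]]
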