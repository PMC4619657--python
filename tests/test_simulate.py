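"""Lattice simulator: placement, diffusion, SSA kinetics, complex extraction."""

import math

import numpy as np
import pytest

from sicompre.simulate import (
    LatticeConfig,
    diffusion_step,
    extract_complexes,
    initialize_state,
    react_subvolume,
    run_simulation,
    read_scs,
    write_scs,
)
from tests.conftest import make_model


def _dimer_model(n_a=1, n_b=1):
    return make_model({"A": (n_a ** 2, ["d1"]), "B": (n_b ** 2, ["d2"])},
                      [("A", "d1", "B", "d2")])


class TestInitialize:
    def test_placement_counts_and_free_slots(self):
        model = make_model({"A": (16, ["d1"])}, [])
        cfg = LatticeConfig(grid_side=2, seed=3)
        state = initialize_state(model, cfg, run_seed=3)
        assert len(state.instances) == 4
        for inst in state.instances:
            sv = state.groups[inst.gid].sv
            assert sv[0] in (0, 1) and sv[1] in (0, 1)
            assert inst.slot_state == [None]

    def test_same_seed_identical_placement(self, default_model):
        cfg = LatticeConfig(seed=5)
        s1 = initialize_state(default_model, cfg, run_seed=42)
        s2 = initialize_state(default_model, cfg, run_seed=42)
        assert [g.sv for g in s1.groups.values()] == [g.sv for g in s2.groups.values()]

    def test_degenerate_single_subvolume(self):
        model = _dimer_model(3, 3)
        state = initialize_state(model, LatticeConfig(grid_side=1), run_seed=0)
        assert {g.sv for g in state.groups.values()} == {(0, 0)}

    def test_zero_instances_rejected(self):
        model = make_model({"A": (0, ["d1"])}, [])
        with pytest.raises(ValueError):
            initialize_state(model, LatticeConfig(grid_side=2), run_seed=0)


class TestDiffusion:
    def test_single_subvolume_never_moves(self):
        model = _dimer_model(2, 2)
        state = initialize_state(model, LatticeConfig(grid_side=1), run_seed=0)
        for _ in range(10):
            diffusion_step(state)
        assert {g.sv for g in state.groups.values()} == {(0, 0)}

    def test_corner_moves_stay_on_grid(self):
        model = make_model({"A": (1, ["d1"])}, [])
        cfg = LatticeConfig(grid_side=3, seed=0)
        seen = set()
        for seed in range(200):
            state = initialize_state(model, cfg, run_seed=seed)
            group = next(iter(state.groups.values()))
            group_sv_before = group.sv
            state.sv_groups[group_sv_before].discard(next(iter(state.groups)))
            group.sv = (0, 0)  # force the corner
            state.sv_groups.setdefault((0, 0), set()).add(next(iter(state.groups)))
            diffusion_step(state)
            seen.add(next(iter(state.groups.values())).sv)
        assert seen == {(0, 0), (0, 1), (1, 0)}

    def test_bound_group_moves_as_unit(self):
        model = make_model(
            {"A": (1, ["d1"]), "B": (1, ["d2", "d3"]), "C": (1, ["d4"])},
            [("A", "d1", "B", "d2"), ("B", "d3", "C", "d4")])
        state = initialize_state(model, LatticeConfig(grid_side=1, k_off=0.0),
                                 run_seed=1)
        react_subvolume(state, (0, 0), duration=200.0)
        assert len(state.groups) == 1  # the trimer assembled
        state.grid_side = 4  # widen the lattice, then walk the complex around
        for _ in range(100):
            diffusion_step(state)
            group = next(iter(state.groups.values()))
            assert len(group.members) == 3


class TestReactSubvolume:
    def test_absorbing_limit_forms_bond(self):
        model = _dimer_model(1, 1)
        state = initialize_state(model, LatticeConfig(grid_side=1, k_off=0.0),
                                 run_seed=0)
        react_subvolume(state, (0, 0), duration=100.0)
        assert len(state.bonds) == 1
        assert len(state.groups) == 1

    def test_site_exclusivity_one_slot_one_partner(self):
        # one A with a single slot, two Bs able to bind it
        model = _dimer_model(1, 2)
        cfg = LatticeConfig(grid_side=1, k_on=5.0, k_off=1.0, seed=0)
        state = initialize_state(model, cfg, run_seed=0)
        for _ in range(200):
            react_subvolume(state, (0, 0), duration=0.5)
            assert len(state.bonds) <= 1
            state.check_invariants()

    def test_two_state_occupancy_closed_form(self):
        # single A-B pair, symmetric rates: stationary bound probability 1/2
        model = _dimer_model(1, 1)
        cfg = LatticeConfig(grid_side=1, k_on=1.0, k_off=1.0, seed=0)
        state = initialize_state(model, cfg, run_seed=12)
        trace = []
        horizon = 20000.0
        react_subvolume(state, (0, 0), duration=horizon, trace=trace)
        assert len(trace) >= 10_000
        bound_time = 0.0
        prev_t, prev_bonds = 0.0, 0
        for t, n_bonds in trace:
            bound_time += (t - prev_t) * prev_bonds
            prev_t, prev_bonds = t, n_bonds
        frac = bound_time / prev_t
        n_cycles = len(trace) / 2
        se = 1.0 / (2.0 * math.sqrt(2.0 * n_cycles))
        assert abs(frac - 0.5) <= 3 * se

    def test_no_rules_no_events(self):
        model = make_model({"A": (9, ["d1"]), "B": (9, ["d2"])}, [])
        state = initialize_state(model, LatticeConfig(grid_side=1), run_seed=0)
        react_subvolume(state, (0, 0), duration=50.0)
        assert not state.bonds and state.n_events == 0


class TestExtractComplexes:
    def test_chain_is_one_complex(self):
        model = make_model(
            {"A": (1, ["d1"]), "B": (1, ["d2", "d3"]), "C": (1, ["d4"]),
             "D": (1, ["d9"])},
            [("A", "d1", "B", "d2"), ("B", "d3", "C", "d4")])
        state = initialize_state(model, LatticeConfig(grid_side=1, k_off=0.0),
                                 run_seed=0)
        react_subvolume(state, (0, 0), duration=500.0)
        scs = extract_complexes(state, run_id=0, sample_time=1.0)
        assert len(scs) == 1
        assert scs[0].members == ("A", "B", "C")  # D stays free

    def test_no_bonds_empty(self):
        model = make_model({"A": (4, ["d1"])}, [])
        state = initialize_state(model, LatticeConfig(grid_side=2), run_seed=0)
        assert extract_complexes(state, 0, 1.0) == []


class TestIncrementalGrouping:
    def test_matches_union_find_oracle_under_random_churn(self):
        """Random bond add/remove sequences: groups == union-find components."""
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(5, 50))
            model = make_model(
                {f"P{i}": (1, ["x", "x", "x"]) for i in range(n)},
                [(f"P{i}", "x", f"P{j}", "x")
                 for i in range(n) for j in range(i, n)])
            state = initialize_state(model, LatticeConfig(grid_side=1), run_seed=0)
            bonds = {}
            for _step in range(120):
                if bonds and rng.random() < 0.4:
                    bid = list(bonds)[int(rng.integers(len(bonds)))]
                    state.break_bond(bid)
                    del bonds[bid]
                else:
                    free = [(inst.uid, si) for inst in state.instances
                            for si in range(3) if inst.slot_state[si] is None]
                    if len(free) < 2:
                        continue
                    i, j = rng.choice(len(free), size=2, replace=False)
                    (ua, sa), (ub, sb) = free[i], free[j]
                    rule = state.rules_by_typepair.get(frozenset((
                        (state.instances[ua].protein, "x"),
                        (state.instances[ub].protein, "x"))))
                    if rule is None:
                        continue
                    bid = state.form_bond((ua, sa), (ub, sb), rule)
                    bonds[bid] = ((ua, sa), (ub, sb))
            # union-find oracle over the surviving bond list
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for (ua, _), (ub, _) in bonds.values():
                parent[find(ua)] = find(ub)
            oracle = {}
            for uid in range(n):
                oracle.setdefault(find(uid), set()).add(uid)
            got = {frozenset(g.members) for g in state.groups.values()}
            assert got == {frozenset(c) for c in oracle.values()}
            state.check_invariants()


class TestRunSimulation:
    def test_four_collection_points(self, default_model):
        cfg = LatticeConfig(seed=0, t_end=10.0)
        scs = run_simulation(default_model, cfg)
        tags = {(sc.run_id, sc.sample_time) for sc in scs}
        assert tags <= {(0, 5.0), (0, 10.0), (1, 5.0), (1, 10.0)}
        assert {t for _r, t in tags} == {5.0, 10.0}
        assert {r for r, _t in tags} == {0, 1}

    def test_no_rules_no_complexes(self):
        model = make_model({"A": (25, ["d1"]), "B": (25, ["d2"])}, [])
        assert run_simulation(model, LatticeConfig(seed=1, t_end=5.0)) == []

    def test_dimer_conservation_bound(self):
        model = _dimer_model(10, 10)
        cfg = LatticeConfig(grid_side=2, k_off=0.0, t_end=50.0, n_runs=1, seed=2)
        scs = run_simulation(model, cfg)
        assert scs, "dimers should have formed"
        for time in (25.0, 50.0):
            snapshot = [sc for sc in scs if sc.sample_time == time]
            assert all(sc.members == ("A", "B") for sc in snapshot)
            assert len(snapshot) <= 10

    def test_deterministic_given_seed(self, default_model):
        cfg = LatticeConfig(seed=17, t_end=20.0)
        assert run_simulation(default_model, cfg) == run_simulation(default_model, cfg)

    def test_invariants_at_every_snapshot(self, default_model):
        cfg = LatticeConfig(seed=4, t_end=20.0, sample_times=(5.0, 10.0, 20.0))
        checked = []
        run_simulation(default_model, cfg,
                       snapshot_callback=lambda s, r, t: (s.check_invariants(),
                                                          checked.append((r, t))))
        assert len(checked) == 6


def test_sc_roundtrip(tmp_path, default_scs):
    path = tmp_path / "scs.tsv"
    write_scs(path, default_scs)
    again = read_scs(path)
    assert again == list(default_scs)


def test_config_validation():
    with pytest.raises(ValueError):
        LatticeConfig(k_on=0.0).validate()
    with pytest.raises(ValueError):
        LatticeConfig(sample_times=(0.0,)).validate()
    with pytest.raises(ValueError):
        LatticeConfig(sample_times=(300.0,), t_end=200.0).validate()
    LatticeConfig(k_off=0.0).validate()  # absorbing limit is allowed
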