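"""Spatial stochastic simulation of domain-mediated protein binding.

The cytoplasm is discretized into a 2D square lattice of sub-volumes (SVs).
Protein instances carry one exclusive binding slot per annotated domain
occurrence.  The dynamics follow a Gillespie-multiparticle operator split:

* every ``diffusion_interval`` time units each bound group (and each free
  instance) performs one lattice move — stay or step to one of its four
  neighbours, uniformly, with off-grid moves resampled among valid
  neighbours (reflecting boundary) or wrapped (periodic);
* between moves, an exact stochastic simulation (Gillespie SSA) runs
  independently inside every occupied SV: each co-located pair of free,
  rule-complementary slots is an association channel with propensity
  ``k_on``; each existing bond is a dissociation channel with propensity
  ``k_off``.

Bound instances move as a rigid unit, so all members of a complex always
share one SV.  A slot engaged in a bond contributes to no association
channel, which makes competing proteins mutually exclusive on that slot —
the mechanism by which relative abundances shape the complexome.

Connected bound groups of two or more instances are recorded as simulated
complexes (SCs) at the configured sampling times of each run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .model import FICTITIOUS, IntegratedModel, InteractionRule

_DIRS = ((-1, 0), (1, 0), (0, -1), (0, 1))

TypeKey = tuple[str, str]  # (protein id, domain id)
SlotRef = tuple[int, int]  # (instance uid, slot index)


@dataclass
class LatticeConfig:
    """Simulation parameters.

    grid_side: sub-volumes per axis; ``None`` sizes the lattice to hold
        roughly 50 instances per SV.
    diffusion_interval: time between diffusion sweeps (time units).
    k_on: association propensity per complementary co-located free slot pair.
    k_off: dissociation propensity per bond.
    t_end: simulated duration per run.
    sample_times: snapshot times; ``None`` means {t_end/2, t_end}.
    n_runs: independent runs with fresh random initial placements.
    seed: master RNG seed; run seeds are derived deterministically from it.
    periodic: toroidal instead of reflecting boundaries.
    """

    grid_side: int | None = None
    diffusion_interval: float = 1.0
    k_on: float = 1.0
    k_off: float = 0.1
    t_end: float = 200.0
    sample_times: tuple[float, ...] | None = None
    n_runs: int = 2
    seed: int = 0
    periodic: bool = False

    def resolved_sample_times(self) -> list[float]:
        times = self.sample_times
        if times is None:
            times = (self.t_end / 2.0, self.t_end)
        return sorted(set(float(t) for t in times))

    def validate(self) -> None:
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError("k_on must be positive and k_off non-negative")
        if self.t_end <= 0 or self.diffusion_interval <= 0:
            raise ValueError("t_end and diffusion_interval must be positive")
        if self.grid_side is not None and self.grid_side < 1:
            raise ValueError("grid_side must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for t in self.resolved_sample_times():
            if not (0.0 < t <= self.t_end + 1e-9):
                raise ValueError(f"sample time {t} outside (0, t_end]")


@dataclass(frozen=True)
class SimulatedComplex:
    """One connected bound group observed at a sampling point of one run.

    ``members`` is a sorted multiset (the same protein may appear several
    times when instances from more than one copy of a complex chain up).
    """

    members: tuple[str, ...]
    bonds: tuple[tuple[str, str, str, str], ...]
    run_id: int
    sample_time: float
    fictitious_fraction: float

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


class ProteinInstance:
    __slots__ = ("uid", "protein", "slot_domains", "slot_state", "gid")

    def __init__(self, uid: int, protein: str, slot_domains: tuple[str, ...], gid: int):
        self.uid = uid
        self.protein = protein
        self.slot_domains = slot_domains
        self.slot_state: list[int | None] = [None] * len(slot_domains)
        self.gid = gid


class Group:
    """A maximal set of instances connected by bonds, co-located in one SV."""

    __slots__ = ("members", "sv", "bonds")

    def __init__(self, members: set[int], sv: tuple[int, int]):
        self.members = members
        self.sv = sv
        self.bonds: set[int] = set()


class _Pool:
    """List with O(1) swap-pop removal and uniform sampling."""

    __slots__ = ("items", "pos")

    def __init__(self):
        self.items: list = []
        self.pos: dict = {}

    def __len__(self):
        return len(self.items)

    def add(self, x) -> None:
        self.pos[x] = len(self.items)
        self.items.append(x)

    def remove(self, x) -> None:
        i = self.pos.pop(x)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i


class SimulationState:
    """Mutable lattice state: instances, bonds and connected groups."""

    def __init__(self, model: IntegratedModel, config: LatticeConfig,
                 grid_side: int, rng: np.random.Generator):
        self.model = model
        self.config = config
        self.grid_side = grid_side
        self.rng = rng
        self.instances: list[ProteinInstance] = []
        self.groups: dict[int, Group] = {}
        self.bonds: dict[int, tuple[SlotRef, SlotRef, InteractionRule]] = {}
        self.sv_groups: dict[tuple[int, int], set[int]] = {}
        self._next_gid = 0
        self._next_bid = 0
        self.n_events = 0
        # rule lookup tables keyed by (protein, domain) slot type
        self.rules_by_typepair: dict[frozenset, InteractionRule] = {}
        self.rules_by_type: dict[TypeKey, list[tuple[TypeKey, InteractionRule]]] = {}
        for rule in model.rules:
            ka = (rule.protein_a, rule.domain_a)
            kb = (rule.protein_b, rule.domain_b)
            self.rules_by_typepair[frozenset((ka, kb))] = rule
            self.rules_by_type.setdefault(ka, []).append((kb, rule))
            if kb != ka:
                self.rules_by_type.setdefault(kb, []).append((ka, rule))

    # -- bookkeeping ------------------------------------------------------

    def _new_group(self, members: set[int], sv: tuple[int, int]) -> int:
        gid = self._next_gid
        self._next_gid += 1
        self.groups[gid] = Group(members, sv)
        self.sv_groups.setdefault(sv, set()).add(gid)
        return gid

    def form_bond(self, end_a: SlotRef, end_b: SlotRef, rule: InteractionRule) -> int:
        """Create a bond between two free slots and merge their groups."""
        (ua, sa), (ub, sb) = end_a, end_b
        inst_a, inst_b = self.instances[ua], self.instances[ub]
        if inst_a.slot_state[sa] is not None or inst_b.slot_state[sb] is not None:
            raise RuntimeError("slot already engaged in a bond")
        bid = self._next_bid
        self._next_bid += 1
        self.bonds[bid] = (end_a, end_b, rule)
        inst_a.slot_state[sa] = bid
        inst_b.slot_state[sb] = bid
        ga, gb = inst_a.gid, inst_b.gid
        if ga != gb:
            big, small = (ga, gb) if len(self.groups[ga].members) >= len(self.groups[gb].members) else (gb, ga)
            g_big, g_small = self.groups[big], self.groups[small]
            for uid in g_small.members:
                self.instances[uid].gid = big
            g_big.members |= g_small.members
            g_big.bonds |= g_small.bonds
            self.sv_groups[g_small.sv].discard(small)
            del self.groups[small]
            ga = big
        self.groups[ga].bonds.add(bid)
        return bid

    def break_bond(self, bid: int) -> tuple[int, int | None]:
        """Delete a bond; split the group if its bond graph disconnects.

        Returns (gid of the surviving group, gid of the split-off fragment or
        None).  Fragments stay in the same SV.
        """
        end_a, end_b, _rule = self.bonds.pop(bid)
        (ua, sa), (ub, sb) = end_a, end_b
        self.instances[ua].slot_state[sa] = None
        self.instances[ub].slot_state[sb] = None
        gid = self.instances[ua].gid
        group = self.groups[gid]
        group.bonds.discard(bid)
        # connectivity check within the group
        adj: dict[int, list[int]] = {}
        for other in group.bonds:
            (xa, _), (xb, _), _ = self.bonds[other]
            adj.setdefault(xa, []).append(xb)
            adj.setdefault(xb, []).append(xa)
        reached = {ua}
        stack = [ua]
        while stack:
            node = stack.pop()
            for nxt in adj.get(node, ()):
                if nxt not in reached:
                    reached.add(nxt)
                    stack.append(nxt)
        if ub in reached and len(reached) == len(group.members):
            return gid, None
        # split: 'reached' keeps gid, the remainder becomes a new group
        remainder = group.members - reached
        group.members = reached
        new_gid = self._new_group(remainder, group.sv)
        new_group = self.groups[new_gid]
        for uid in remainder:
            self.instances[uid].gid = new_gid
        moved = {b for b in group.bonds
                 if self.bonds[b][0][0] in remainder}
        group.bonds -= moved
        new_group.bonds |= moved
        return gid, new_gid

    # -- invariants (used by the test-suite and debug runs) ----------------

    def check_invariants(self) -> None:
        counts: Counter[str] = Counter()
        seen_slots: set[SlotRef] = set()
        for gid, group in self.groups.items():
            for uid in group.members:
                inst = self.instances[uid]
                assert inst.gid == gid, "instance/group id mismatch"
                counts[inst.protein] += 1
            for bid in group.bonds:
                end_a, end_b, rule = self.bonds[bid]
                for (uid, si) in (end_a, end_b):
                    assert (uid, si) not in seen_slots, "slot in two bonds"
                    seen_slots.add((uid, si))
                    inst = self.instances[uid]
                    assert inst.slot_state[si] == bid, "slot state out of sync"
                    assert self.groups[inst.gid].sv == group.sv, "bond across sub-volumes"
                (ua, sa), (ub, sb) = end_a, end_b
                key = frozenset(((self.instances[ua].protein, self.instances[ua].slot_domains[sa]),
                                 (self.instances[ub].protein, self.instances[ub].slot_domains[sb])))
                assert key in self.rules_by_typepair, "unlicensed bond"
        for pid, spec in self.model.proteins.items():
            assert counts.get(pid, 0) == spec.instance_count, (
                f"conservation violated for {pid}")


def default_grid_side(model: IntegratedModel, target_per_sv: int = 50) -> int:
    total = sum(p.instance_count for p in model.proteins.values())
    return max(1, math.ceil(math.sqrt(total / target_per_sv)))


def initialize_state(model: IntegratedModel, config: LatticeConfig,
                     run_seed) -> SimulationState:
    """Place every instance uniformly at random; all slots free.

    Proteins are placed in sorted-identifier order so that an identical seed
    reproduces an identical layout.
    """
    config.validate()
    side = config.grid_side if config.grid_side is not None else default_grid_side(model)
    if side < 1:
        raise ValueError("lattice has no sub-volumes")
    total = sum(p.instance_count for p in model.proteins.values())
    if total == 0:
        raise ValueError("model contains zero instances")
    rng = np.random.default_rng(run_seed)
    state = SimulationState(model, config, side, rng)
    uid = 0
    for pid in sorted(model.proteins):
        spec = model.proteins[pid]
        n = spec.instance_count
        if n == 0:
            continue
        coords = rng.integers(0, side, size=(n, 2))
        slots = tuple(spec.domain_slots)
        for k in range(n):
            sv = (int(coords[k, 0]), int(coords[k, 1]))
            gid = state._new_group({uid}, sv)
            state.instances.append(ProteinInstance(uid, pid, slots, gid))
            uid += 1
    return state


def diffusion_step(state: SimulationState) -> None:
    """One lattice sweep: every group stays or moves to a random neighbour."""
    side = state.grid_side
    if side == 1:
        return
    gids = sorted(state.groups)
    moves = state.rng.integers(0, 5, size=len(gids))
    periodic = state.config.periodic
    for gid, mv in zip(gids, moves):
        if mv == 0:
            continue
        group = state.groups[gid]
        r, c = group.sv
        dr, dc = _DIRS[mv - 1]
        nr, nc = r + dr, c + dc
        if periodic:
            nr, nc = nr % side, nc % side
        elif not (0 <= nr < side and 0 <= nc < side):
            valid = [(r + dr2, c + dc2) for dr2, dc2 in _DIRS
                     if 0 <= r + dr2 < side and 0 <= c + dc2 < side]
            nr, nc = valid[int(state.rng.integers(len(valid)))]
        state.sv_groups[group.sv].discard(gid)
        group.sv = (nr, nc)
        state.sv_groups.setdefault((nr, nc), set()).add(gid)


def react_subvolume(state: SimulationState, sv: tuple[int, int], duration: float,
                    trace: list | None = None) -> None:
    """Exact SSA restricted to one sub-volume for the given duration.

    Channels: association (propensity ``k_on`` per complementary free slot
    pair present in the SV) and dissociation (``k_off`` per bond in the SV).
    If ``trace`` is a list, ``(event_time, n_bonds_after)`` tuples are
    appended for every event, which lets callers reconstruct time-weighted
    occupancies.
    """
    rng = state.rng
    k_on = state.config.k_on
    k_off = state.config.k_off
    gids = state.sv_groups.get(sv)
    if not gids:
        return

    pools: dict[TypeKey, _Pool] = {}
    sv_bonds = _Pool()
    for gid in sorted(gids):
        group = state.groups[gid]
        for uid in sorted(group.members):
            inst = state.instances[uid]
            for si, dom in enumerate(inst.slot_domains):
                if inst.slot_state[si] is None:
                    key = (inst.protein, dom)
                    pool = pools.get(key)
                    if pool is None:
                        pool = pools[key] = _Pool()
                    pool.add((uid, si))
        for bid in sorted(group.bonds):
            sv_bonds.add(bid)

    # candidate association rules: both slot types seen in this SV
    cand: dict[frozenset, tuple[TypeKey, TypeKey, InteractionRule]] = {}

    def _register_type(key: TypeKey) -> None:
        for other, rule in state.rules_by_type.get(key, ()):
            if other == key or other in pools:
                pair = frozenset((key, other))
                if pair not in cand:
                    cand[pair] = (key, other, rule)

    for key in list(pools):
        _register_type(key)

    t = 0.0
    while True:
        weights: list[tuple[float, object]] = []
        total = 0.0
        for pair, (ka, kb, rule) in cand.items():
            pa = pools.get(ka)
            na = len(pa) if pa is not None else 0
            if ka == kb:
                n_chan = na * (na - 1) // 2
            else:
                pb = pools.get(kb)
                nb = len(pb) if pb is not None else 0
                n_chan = na * nb
            if n_chan:
                w = k_on * n_chan
                total += w
                weights.append((w, (ka, kb, rule)))
        a_diss = k_off * len(sv_bonds)
        total += a_diss
        if total <= 0.0:
            return
        t += rng.exponential() / total
        if t >= duration:
            return
        state.n_events += 1
        u = rng.random() * total
        if u < a_diss:
            # dissociation: uniform over bonds in this SV
            bid = sv_bonds.items[int(rng.integers(len(sv_bonds)))]
            end_a, end_b, _rule = state.bonds[bid]
            sv_bonds.remove(bid)
            state.break_bond(bid)
            for (uid, si) in (end_a, end_b):
                inst = state.instances[uid]
                key = (inst.protein, inst.slot_domains[si])
                pool = pools.get(key)
                if pool is None:
                    pool = pools[key] = _Pool()
                pool.add((uid, si))
                _register_type(key)
        else:
            u -= a_diss
            chosen = None
            for w, payload in weights:
                if u < w:
                    chosen = payload
                    break
                u -= w
            if chosen is None:  # numerical edge: take the last channel
                chosen = weights[-1][1]
            ka, kb, rule = chosen
            pa = pools[ka]
            if ka == kb:
                n = len(pa)
                i = int(rng.integers(n))
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                end_a, end_b = pa.items[i], pa.items[j]
                pa.remove(end_a)
                pa.remove(end_b)
            else:
                pb = pools[kb]
                end_a = pa.items[int(rng.integers(len(pa)))]
                end_b = pb.items[int(rng.integers(len(pb)))]
                pa.remove(end_a)
                pb.remove(end_b)
            bid = state.form_bond(end_a, end_b, rule)
            sv_bonds.add(bid)
        if trace is not None:
            trace.append((t, len(sv_bonds)))


def extract_complexes(state: SimulationState, run_id: int,
                      sample_time: float) -> list[SimulatedComplex]:
    """Report every connected bound group of size >= 2 as a simulated complex."""
    out = []
    for gid in sorted(state.groups):
        group = state.groups[gid]
        if len(group.members) < 2:
            continue
        members = tuple(sorted(state.instances[uid].protein for uid in group.members))
        bond_rows = []
        n_fict = 0
        for bid in sorted(group.bonds):
            (ua, sa), (ub, sb), rule = state.bonds[bid]
            ia, ib = state.instances[ua], state.instances[ub]
            pa, da = ia.protein, ia.slot_domains[sa]
            pb, db = ib.protein, ib.slot_domains[sb]
            if (pb, db) < (pa, da):
                pa, da, pb, db = pb, db, pa, da
            bond_rows.append((pa, da, pb, db))
            if rule.provenance == FICTITIOUS:
                n_fict += 1
        fict_frac = n_fict / len(group.bonds) if group.bonds else 0.0
        out.append(SimulatedComplex(
            members=members,
            bonds=tuple(sorted(bond_rows)),
            run_id=run_id,
            sample_time=sample_time,
            fictitious_fraction=fict_frac,
        ))
    return out


def run_simulation(
    model: IntegratedModel,
    config: LatticeConfig,
    snapshot_callback: Callable[[SimulationState, int, float], None] | None = None,
) -> list[SimulatedComplex]:
    """Run ``n_runs`` independent simulations and pool all sampled complexes.

    Each run alternates one diffusion sweep with an SSA interval in every
    occupied SV, snapshotting whenever a sampling time is crossed.  The
    optional ``snapshot_callback(state, run_id, t)`` is invoked at every
    snapshot (used for state-level diagnostics).
    """
    config.validate()
    samples = config.resolved_sample_times()
    eps = 1e-9
    scs: list[SimulatedComplex] = []
    run_seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    for run_id, run_seed in enumerate(run_seeds):
        state = initialize_state(model, config, run_seed)
        t = 0.0
        si = 0
        while t < config.t_end - eps:
            dt = min(config.diffusion_interval, config.t_end - t)
            diffusion_step(state)
            for sv in sorted(state.sv_groups):
                if state.sv_groups[sv]:
                    react_subvolume(state, sv, dt)
            t += dt
            while si < len(samples) and samples[si] <= t + eps:
                if snapshot_callback is not None:
                    snapshot_callback(state, run_id, samples[si])
                scs.extend(extract_complexes(state, run_id, samples[si]))
                si += 1
    return scs


def write_scs(path, scs: Iterable[SimulatedComplex]) -> None:
    """SC list as TSV: run, time, members, bonds, fictitious fraction."""
    from .io import write_tsv

    rows = []
    for sc in scs:
        bonds = ";".join(f"{pa}:{da}-{pb}:{db}" for pa, da, pb, db in sc.bonds)
        rows.append((sc.run_id, sc.sample_time, ";".join(sc.members), bonds,
                     repr(sc.fictitious_fraction)))
    write_tsv(path, rows, header=["run_id", "sample_time", "members", "bonds",
                                  "fictitious_fraction"])


def read_scs(path) -> list[SimulatedComplex]:
    from .io import _rows

    scs = []
    for _ln, fields in _rows(path, 5):
        fixed = []
        for part in fields[3].split(";"):
            if not part:
                continue
            left, right = part.split("-", 1)
            pa, da = left.split(":", 1)
            pb, db = right.split(":", 1)
            fixed.append((pa, da, pb, db))
        scs.append(SimulatedComplex(
            members=tuple(fields[2].split(";")),
            bonds=tuple(fixed),
            run_id=int(fields[0]),
            sample_time=float(fields[1]),
            fictitious_fraction=float(fields[4]),
        ))
    return scs
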