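"""Refinement of simulated complexes into a consensus complexome.

Simulated complexes (SCs) pooled over runs and sampling times are noisy:
many are partial or chained copies of the same underlying complex.  The
refinement counts, for every protein pair, how many SCs contain both
proteins (the frequency matrix), converts the counts to a max-normalized
affinity, and clusters the affinity matrix by average-linkage agglomeration.
Each resulting cluster of two or more proteins is a refined complex (RC).

Every SC is then assigned to the RC it overlaps best; the number of SCs
assigned to an RC is its simulated abundance, and the reported abundance is
that count squared — undoing the square-root compression applied to protein
copy numbers on the way into the simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import IntegratedModel
from .scoring import overlap_score
from .simulate import SimulatedComplex

log = logging.getLogger(__name__)


@dataclass
class FrequencyMatrix:
    """Symmetric pair co-occurrence counts over SCs.

    ``entries`` maps a sorted protein pair to the number of SCs containing
    both proteins; ``occurrence`` counts SCs containing each protein at all.
    """

    entries: dict[tuple[str, str], int] = field(default_factory=dict)
    occurrence: dict[str, int] = field(default_factory=dict)

    def count(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.entries.get(key, 0)

    def affinity(self, a: str, b: str) -> float:
        denom = max(self.occurrence.get(a, 0), self.occurrence.get(b, 0))
        return self.count(a, b) / denom if denom else 0.0


@dataclass
class RefinedComplex:
    rc_id: str
    members: frozenset[str]
    sim_abundance: int = 0
    per_run_abundance: dict[int, int] = field(default_factory=dict)
    per_snapshot_abundance: dict[tuple[int, float], int] = field(default_factory=dict)
    cv: float | None = None
    fictitious_fraction: float | None = None

    @property
    def reported_abundance(self) -> int:
        return self.sim_abundance ** 2


@dataclass
class FilterPolicy:
    """Abundance/size filter: LG drops low-abundance large RCs, SM small ones."""

    mode: str = "none"  # none | LG | SM
    abundance_threshold: int = 2
    size_threshold: int = 10

    def __post_init__(self):
        if self.mode not in ("none", "LG", "SM"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.abundance_threshold < 0 or self.size_threshold < 0:
            raise ValueError("thresholds must be non-negative")


class AssignmentResult(NamedTuple):
    rcs: list[RefinedComplex]
    n_unassigned: int


def build_frequency_matrix(scs: Iterable[SimulatedComplex]) -> FrequencyMatrix:
    """Count pair co-occurrences: +1 per SC containing both proteins."""
    freq = FrequencyMatrix()
    for sc in scs:
        distinct = sorted(set(sc.members))
        for p in distinct:
            freq.occurrence[p] = freq.occurrence.get(p, 0) + 1
        for i, a in enumerate(distinct):
            for b in distinct[i + 1:]:
                key = (a, b)
                freq.entries[key] = freq.entries.get(key, 0) + 1
    return freq


def cluster_matrix(freq: FrequencyMatrix, tau: float = 0.5) -> list[frozenset[str]]:
    """Average-linkage clustering of the affinity matrix, cut at 1 - tau.

    affinity(a, b) = count(a, b) / max(occurrence(a), occurrence(b)); the
    dendrogram over distance 1 - affinity is cut at distance 1 - tau.
    Clusters of at least two proteins become RC member sets.  Proteins that
    never co-occur with anything form no RC.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    proteins = sorted({p for pair in freq.entries for p in pair})
    if len(proteins) < 2:
        return []
    idx = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for (a, b), _count in freq.entries.items():
        d = 1.0 - freq.affinity(a, b)
        dist[idx[a], idx[b]] = d
        dist[idx[b], idx[a]] = d
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=1.0 - tau, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for p, lab in zip(proteins, labels):
        clusters.setdefault(int(lab), []).append(p)
    member_sets = [frozenset(c) for c in clusters.values() if len(c) >= 2]
    return sorted(member_sets, key=lambda s: (-len(s), tuple(sorted(s))))


def assign_abundance(
    rc_members: list[frozenset[str]],
    scs: list[SimulatedComplex],
    assoc_threshold: float = 0.25,
) -> AssignmentResult:
    """Assign each SC to its best-overlapping RC and count assignments.

    An SC is assigned to the RC maximizing the overlap score of its member
    set, provided the score reaches ``assoc_threshold``; ties go to the
    larger RC, then to the lexicographically smallest rc_id.  The RC's
    simulated abundance is its assignment count (also tallied per run and
    per snapshot); the coefficient of variation is computed over per-run
    counts (sample standard deviation / mean).
    """
    ordered = sorted(rc_members, key=lambda s: (-len(s), tuple(sorted(s))))
    rcs = [RefinedComplex(rc_id=f"RC{k:04d}", members=m) for k, m in enumerate(ordered)]
    runs = sorted({sc.run_id for sc in scs})
    for rc in rcs:
        rc.per_run_abundance = {r: 0 for r in runs}
    fict_sums = [0.0] * len(rcs)
    n_unassigned = 0
    for sc in scs:
        sset = sc.member_set
        best_idx, best_score = None, 0.0
        for i, rc in enumerate(rcs):
            score = overlap_score(sset, rc.members)
            if score > best_score:  # ties keep the earlier RC: larger, then smaller id
                best_idx, best_score = i, score
        if best_idx is None or best_score < assoc_threshold:
            n_unassigned += 1
            continue
        rc = rcs[best_idx]
        rc.sim_abundance += 1
        rc.per_run_abundance[sc.run_id] = rc.per_run_abundance.get(sc.run_id, 0) + 1
        key = (sc.run_id, sc.sample_time)
        rc.per_snapshot_abundance[key] = rc.per_snapshot_abundance.get(key, 0) + 1
        fict_sums[best_idx] += sc.fictitious_fraction
    for i, rc in enumerate(rcs):
        values = [rc.per_run_abundance.get(r, 0) for r in runs]
        mean = float(np.mean(values)) if values else 0.0
        if mean > 0 and len(values) >= 2:
            rc.cv = float(np.std(values, ddof=1)) / mean
        if rc.sim_abundance > 0:
            rc.fictitious_fraction = fict_sums[i] / rc.sim_abundance
        else:
            log.info("RC %s received no simulated complex above the association "
                     "threshold", rc.rc_id)
    if n_unassigned:
        log.info("%d simulated complexes not assigned to any refined complex",
                 n_unassigned)
    return AssignmentResult(rcs=rcs, n_unassigned=n_unassigned)


def filter_complexes(rcs: list[RefinedComplex], policy: FilterPolicy) -> list[RefinedComplex]:
    """Apply the LG/SM low-abundance filter; mode 'none' is the identity."""
    if policy.mode == "none":
        return list(rcs)
    out = []
    for rc in rcs:
        low = rc.sim_abundance < policy.abundance_threshold
        large = len(rc.members) > policy.size_threshold
        if policy.mode == "LG" and large and low:
            continue
        if policy.mode == "SM" and not large and low:
            continue
        out.append(rc)
    return out


def rc_overlap_graph(rcs: list[RefinedComplex], threshold: float = 0.1):
    """Graph of RCs sharing components: edge iff overlap score >= threshold.

    Returns a ``networkx.Graph`` whose nodes are rc_ids annotated with size
    and reported abundance.
    """
    import networkx as nx

    if not rcs:
        raise ValueError("need at least one refined complex")
    graph = nx.Graph()
    for rc in rcs:
        graph.add_node(rc.rc_id, size=len(rc.members),
                       reported_abundance=rc.reported_abundance)
    for i, a in enumerate(rcs):
        for b in rcs[i + 1:]:
            omega = overlap_score(a.members, b.members)
            if omega >= threshold:
                graph.add_edge(a.rc_id, b.rc_id, overlap=omega)
    return graph


class UnboundStats(NamedTuple):
    free_mean: float
    fraction: float
    degree: int


def unbound_fractions(
    model: IntegratedModel,
    scs: list[SimulatedComplex],
    snapshots: list[tuple[int, float]] | None = None,
) -> dict[str, UnboundStats]:
    """Per protein: mean free copies over snapshots, free fraction, PPI degree.

    A protein's bound count in a snapshot is its multiplicity summed over all
    recorded complexes of that snapshot; free = instance_count - bound.
    Proteins absent from every snapshot are fully free (fraction 1).
    """
    if snapshots is None:
        snapshots = sorted({(sc.run_id, sc.sample_time) for sc in scs})
    if not snapshots:
        raise ValueError("no snapshots available")
    bound: dict[tuple[int, float], dict[str, int]] = {snap: {} for snap in snapshots}
    for sc in scs:
        snap = (sc.run_id, sc.sample_time)
        if snap not in bound:
            continue
        tally = bound[snap]
        for p in sc.members:
            tally[p] = tally.get(p, 0) + 1
    out = {}
    for pid, spec in model.proteins.items():
        if spec.instance_count == 0:
            continue
        frees = []
        for snap in snapshots:
            b = bound[snap].get(pid, 0)
            frees.append(spec.instance_count - b)
        free_mean = float(np.mean(frees))
        out[pid] = UnboundStats(
            free_mean=free_mean,
            fraction=free_mean / spec.instance_count,
            degree=model.ppi_degree(pid),
        )
    return out


def refine_pipeline(
    scs: list[SimulatedComplex],
    tau: float = 0.5,
    assoc_threshold: float = 0.25,
    policy: FilterPolicy | None = None,
) -> AssignmentResult:
    """frequency matrix → clustering → abundance assignment → optional filter."""
    freq = build_frequency_matrix(scs)
    members = cluster_matrix(freq, tau=tau)
    result = assign_abundance(members, scs, assoc_threshold=assoc_threshold)
    if policy is not None and policy.mode != "none":
        return AssignmentResult(filter_complexes(result.rcs, policy), result.n_unassigned)
    return result


def write_rcs(path, rcs: list[RefinedComplex]) -> None:
    from .io import write_tsv

    rows = []
    for rc in rcs:
        rows.append((
            rc.rc_id,
            ";".join(sorted(rc.members)),
            rc.sim_abundance,
            rc.reported_abundance,
            "NA" if rc.cv is None else f"{rc.cv:.4f}",
            "NA" if rc.fictitious_fraction is None else f"{rc.fictitious_fraction:.4f}",
        ))
    write_tsv(path, rows, header=["rc_id", "members", "sim_abundance",
                                  "reported_abundance", "cv", "fictitious_fraction"])


def write_overlap_graph(path, graph) -> None:
    from .io import write_tsv

    rows = [(a, b, f"{data['overlap']:.4f}")
            for a, b, data in sorted(graph.edges(data=True))]
    write_tsv(path, rows, header=["rc_i", "rc_j", "overlap"])
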