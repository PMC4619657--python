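"""Synthetic input bundles with planted ground-truth complexes.

The generator emulates the shape of a real model-building corpus — a PPI
edge list, per-protein domain slots, a DDI list covering only part of the
edges, log-normally spread copy numbers, and functional annotation — while
planting a known set of disjoint complexes so that recovery can be scored
exactly.  Each planted complex is wired as a random spanning tree plus extra
edges, every edge carrying its own private domain pair, so the complex can
assemble in the simulator if and only if its members meet in space.  Members
of one planted complex share a complex-specific annotation term, mirroring
the fact that subunits of a real complex act in the same biological process;
uncovered planted edges are therefore always eligible for fictitious-domain
rescue, while noise edges share a term only at the configured rate.

Decoy proteins receive abundances, background domains and annotations but
(mostly) no interactions, exercising the model builder's retention rules.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio

_N_BACKGROUND_DOMAINS = 40
_N_GENERIC_TERMS = 20
_EXTRA_EDGE_PROB = 0.3


@dataclass
class FixtureConfig:
    n_planted: int = 10
    size_range: tuple[int, int] = (3, 8)
    n_decoys: int = 100
    noise_ppi_rate: float = 0.05
    ddi_coverage: float = 0.34
    abundance_lognormal: tuple[float, float] = (4.0, 1.0)
    shared_function_rate: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError(f"infeasible size_range {self.size_range}; "
                             "minimum planted complex size is 3")
        for name in ("noise_ppi_rate", "ddi_coverage", "shared_function_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted < 1:
            raise ValueError("need at least one planted complex")


@dataclass
class PlantedEdge:
    a: str
    b: str
    dom_a: str
    dom_b: str
    covered: bool


@dataclass
class FixtureBundle:
    """All input tables plus the planted ground truth."""

    ppi: list[tuple[str, str]]
    domains: dict[str, list[str]]
    ddi: list[tuple[str, str]]
    abundance: dict[str, float]
    annotations: dict[str, set[str]]
    reference: list[frozenset[str]]
    planted: list[list[str]]
    planted_edges: list[list[PlantedEdge]]
    config: FixtureConfig
    drug_targets: dict[str, set[str]] = field(default_factory=dict)
    drug_abundance: float | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_tsv(outdir / "ppi.tsv", sorted(self.ppi))
        sio.write_tsv(outdir / "domains.tsv",
                      [(p, d) for p in sorted(self.domains) for d in self.domains[p]])
        sio.write_tsv(outdir / "ddi.tsv", sorted(self.ddi))
        sio.write_tsv(outdir / "abundance.tsv",
                      [(p, self.abundance[p]) for p in sorted(self.abundance)])
        sio.write_tsv(outdir / "annotations.tsv",
                      [(p, t) for p in sorted(self.annotations)
                       for t in sorted(self.annotations[p])])
        sio.write_tsv(outdir / "reference_complexes.tsv",
                      [tuple(sorted(c)) for c in self.reference])
        if self.drug_targets:
            sio.write_tsv(outdir / "drug_targets.tsv",
                          [(d, p) for d in sorted(self.drug_targets)
                           for p in sorted(self.drug_targets[d])])


def generate_fixture(config: FixtureConfig | None = None) -> FixtureBundle:
    """Deterministically generate a complete input bundle under config.seed."""
    config = config or FixtureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.size_range

    planted: list[list[str]] = []
    for c in range(config.n_planted):
        size = int(rng.integers(lo, hi + 1))
        planted.append([f"C{c:02d}P{i:02d}" for i in range(size)])
    decoys = [f"DEC{j:03d}" for j in range(config.n_decoys)]
    all_proteins = [p for members in planted for p in members] + decoys

    domains: dict[str, list[str]] = {p: [] for p in all_proteins}
    annotations: dict[str, set[str]] = {p: set() for p in all_proteins}
    ddi: list[tuple[str, str]] = []
    ppi: list[tuple[str, str]] = []
    planted_edges: list[list[PlantedEdge]] = []
    edge_counter = 0

    def _wire_edge(a: str, b: str) -> PlantedEdge:
        nonlocal edge_counter
        dom_a = f"D{edge_counter:04d}A"
        dom_b = f"D{edge_counter:04d}B"
        edge_counter += 1
        domains[a].append(dom_a)
        domains[b].append(dom_b)
        covered = bool(rng.random() < config.ddi_coverage)
        if covered:
            ddi.append((dom_a, dom_b))
        ppi.append((a, b) if a <= b else (b, a))
        return PlantedEdge(a, b, dom_a, dom_b, covered)

    for c, members in enumerate(planted):
        edges = []
        # random spanning tree keeps the complex connected
        for i in range(1, len(members)):
            j = int(rng.integers(0, i))
            edges.append(_wire_edge(members[j], members[i]))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if any({e.a, e.b} == {members[i], members[j]} for e in edges):
                    continue
                if rng.random() < _EXTRA_EDGE_PROB:
                    edges.append(_wire_edge(members[i], members[j]))
        planted_edges.append(edges)
        term = f"FUNC_C{c:02d}"
        for p in members:
            annotations[p].add(term)

    # background domains and generic annotation for every protein
    for p in all_proteins:
        for _ in range(int(rng.integers(1, 4))):
            domains[p].append(f"BG{int(rng.integers(_N_BACKGROUND_DOMAINS)):02d}")
        annotations[p].add(f"FUNC_G{int(rng.integers(_N_GENERIC_TERMS)):02d}")

    # spurious edges: noise_ppi_rate of the final PPI list
    n_planted_edges = len(ppi)
    rate = config.noise_ppi_rate
    n_noise = int(round(rate / (1.0 - rate) * n_planted_edges)) if rate < 1.0 else 0
    complex_of = {p: c for c, members in enumerate(planted) for p in members}
    existing = {frozenset(e) for e in ppi}
    attempts = 0
    added = 0
    while added < n_noise and attempts < 100 * n_noise + 100:
        attempts += 1
        a, b = (all_proteins[int(k)] for k in rng.integers(0, len(all_proteins), 2))
        if a == b or frozenset((a, b)) in existing:
            continue
        if complex_of.get(a) is not None and complex_of.get(a) == complex_of.get(b):
            continue  # keep the planted ground truth clean
        edge = _wire_edge(a, b)
        existing.add(frozenset((a, b)))
        if rng.random() < config.shared_function_rate:
            term = f"FUNC_N{added:03d}"
            annotations[a].add(term)
            annotations[b].add(term)
        added += 1

    mu, sigma = config.abundance_lognormal
    draws = rng.lognormal(mean=mu, sigma=sigma, size=len(all_proteins))
    abundance = {p: float(max(1, round(v))) for p, v in zip(all_proteins, draws)}

    reference = [frozenset(members) for members in planted]
    return FixtureBundle(
        ppi=ppi,
        domains=domains,
        ddi=ddi,
        abundance=abundance,
        annotations=annotations,
        reference=reference,
        planted=planted,
        planted_edges=planted_edges,
        config=config,
    )


def generate_drug_fixture(
    base: FixtureBundle,
    victim: int,
    drug_id: str = "DRUG01",
    drug_abundance: float = 250_000.0,
) -> FixtureBundle:
    """Derive a drug-perturbation bundle: one planted complex becomes the victim.

    The victim complex is rewired so that every internal bond runs through a
    single bridging domain carried by all of its members and (by
    construction) by no other protein — the enrichable signal that domain
    enrichment on the drug's target list must recover.  All rewired edges are
    DDI-covered so the victim does not depend on fictitious rescue.  The drug
    target list is exactly the victim's member set.
    """
    if not (0 <= victim < len(base.planted)):
        raise ValueError(f"victim index {victim} out of range")
    bundle = copy.deepcopy(base)
    members = bundle.planted[victim]
    bridge = f"BRIDGE_C{victim:02d}"
    ddi_set = {frozenset(p) for p in bundle.ddi}
    for edge in bundle.planted_edges[victim]:
        bundle.domains[edge.a].remove(edge.dom_a)
        bundle.domains[edge.b].remove(edge.dom_b)
        if edge.covered:
            bundle.ddi = [p for p in bundle.ddi
                          if frozenset(p) != frozenset((edge.dom_a, edge.dom_b))]
        bundle.domains[edge.a].append(bridge)
        bundle.domains[edge.b].append(bridge)
        edge.dom_a = bridge
        edge.dom_b = bridge
        edge.covered = True
    if frozenset((bridge,)) not in ddi_set:
        bundle.ddi.append((bridge, bridge))
    bundle.drug_targets = {drug_id: set(members)}
    bundle.drug_abundance = drug_abundance
    return bundle
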