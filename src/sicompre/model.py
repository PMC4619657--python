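"""Integrated protein–domain interaction model.

Builds the simulator's substrate from five flat tables: a protein–protein
interaction (PPI) edge list, per-protein domain slots, a domain–domain
interaction (DDI) list, protein abundances and functional annotation.

A PPI edge is *covered* when at least one domain pair across the two partners
is a known DDI; covered edges yield binding rules directly.  Uncovered edges
are rescued with a fresh pair of fictitious domains, but only when the two
proteins share at least one functional annotation term; otherwise the edge is
dropped.  Protein copy numbers are down-scaled to the square root of the
measured abundance, which keeps relative abundance ordering while making
proteome-scale lattices tractable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

Edge = tuple[str, str]

KNOWN_DDI = "known_ddi"
FICTITIOUS = "fictitious"
DRUG = "drug"


class EmptyModelError(ValueError):
    """No protein survives the intersection of PPI, domain and abundance data."""


@dataclass
class ProteinSpec:
    """One protein species: identity, copy number and binding slots.

    ``domain_slots`` is an ordered list; a repeated domain identifier denotes
    multiple independent binding sites of the same type.
    """

    id: str
    abundance_raw: float
    instance_count: int
    domain_slots: list[str]
    functions: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class InteractionRule:
    """A licensed binding: two proteins may bond via the stated domain pair."""

    protein_a: str
    protein_b: str
    domain_a: str
    domain_b: str
    provenance: str  # known_ddi | fictitious | drug

    def canonical(self) -> "InteractionRule":
        if (self.protein_a, self.domain_a) <= (self.protein_b, self.domain_b):
            return self
        return InteractionRule(self.protein_b, self.protein_a, self.domain_b,
                               self.domain_a, self.provenance)


@dataclass
class CoverageStats:
    n_ppi_input: int
    n_proteins_input: int
    n_proteins_model: int
    n_interactions_model: int
    ddi_coverage_before: float
    ddi_coverage_after: float


@dataclass
class IntegratedModel:
    proteins: dict[str, ProteinSpec]
    rules: list[InteractionRule]
    coverage: CoverageStats

    def ppi_degree(self, protein: str) -> int:
        partners = set()
        for r in self.rules:
            if r.protein_a == protein:
                partners.add(r.protein_b)
            if r.protein_b == protein:
                partners.add(r.protein_a)
        return len(partners)

    def to_json(self) -> dict:
        return {
            "proteins": {
                p.id: {
                    "abundance_raw": p.abundance_raw,
                    "instance_count": p.instance_count,
                    "domain_slots": list(p.domain_slots),
                    "functions": sorted(p.functions),
                }
                for p in self.proteins.values()
            },
            "rules": [
                {
                    "protein_a": r.protein_a,
                    "protein_b": r.protein_b,
                    "domain_a": r.domain_a,
                    "domain_b": r.domain_b,
                    "provenance": r.provenance,
                }
                for r in self.rules
            ],
            "coverage": dict(self.coverage.__dict__),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_json(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, payload: dict) -> "IntegratedModel":
        proteins = {
            pid: ProteinSpec(pid, spec["abundance_raw"], spec["instance_count"],
                             list(spec["domain_slots"]), set(spec["functions"]))
            for pid, spec in payload["proteins"].items()
        }
        rules = [InteractionRule(r["protein_a"], r["protein_b"], r["domain_a"],
                                 r["domain_b"], r["provenance"])
                 for r in payload["rules"]]
        return cls(proteins, rules, CoverageStats(**payload["coverage"]))

    @classmethod
    def load(cls, path: str | Path) -> "IntegratedModel":
        with open(path, encoding="utf-8") as handle:
            return cls.from_json(json.load(handle))


def transform_abundance(abundance_raw: float) -> int:
    """Copies-per-cell → simulated instance count: round(sqrt(x)), half up.

    Any protein detected at one copy or more keeps at least one instance so
    that low-abundance proteins are not silently erased by the rescaling.
    """
    if abundance_raw < 0:
        raise ValueError(f"abundance must be non-negative, got {abundance_raw}")
    if abundance_raw == 0:
        return 0
    n = int(math.floor(math.sqrt(abundance_raw) + 0.5))
    return max(1, n)


def _canonical_edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def dedup_edges(ppi: list[Edge]) -> list[Edge]:
    """Collapse an undirected edge list (both orders, repeats) to unique edges."""
    seen: dict[Edge, None] = {}
    for a, b in ppi:
        seen.setdefault(_canonical_edge(a, b), None)
    return sorted(seen)


def derive_known_rules(
    ppi: list[Edge],
    domains: dict[str, list[str]],
    ddi: list[tuple[str, str]],
) -> tuple[list[InteractionRule], list[Edge]]:
    """Emit one rule per DDI-supported domain pair on each PPI edge.

    Edges with no supporting domain pair (including edges whose proteins have
    no domain annotation at all) are returned as ``uncovered``.
    """
    ddi_set = {frozenset(pair) if pair[0] != pair[1] else frozenset((pair[0],))
               for pair in ddi}
    rules: list[InteractionRule] = []
    uncovered: list[Edge] = []
    for a, b in dedup_edges(ppi):
        slots_a = domains.get(a)
        slots_b = domains.get(b)
        edge_rules: set[InteractionRule] = set()
        if slots_a and slots_b:
            for da in sorted(set(slots_a)):
                for db in sorted(set(slots_b)):
                    key = frozenset((da,)) if da == db else frozenset((da, db))
                    if key not in ddi_set:
                        continue
                    if a == b and da == db and slots_a.count(da) < 2:
                        # a homodimer bond on one domain type needs two slots
                        continue
                    edge_rules.add(InteractionRule(a, b, da, db, KNOWN_DDI).canonical())
        if edge_rules:
            rules.extend(sorted(edge_rules, key=lambda r: (r.protein_a, r.protein_b,
                                                           r.domain_a, r.domain_b)))
        else:
            uncovered.append((a, b))
    return rules, uncovered


def add_fictitious_rules(
    uncovered: list[Edge],
    domains: dict[str, list[str]],
    functions: dict[str, set[str]],
) -> tuple[list[InteractionRule], list[Edge]]:
    """Rescue uncovered PPI edges whose partners share a functional term.

    Each rescued edge receives its own fresh fictitious domain pair, appended
    as new slots on both proteins (``domains`` is modified in place).  A
    private pair per edge guarantees fictitious slots can never license
    binding on any other edge.  Edges without a shared term are dropped.
    """
    rules: list[InteractionRule] = []
    dropped: list[Edge] = []
    for k, (a, b) in enumerate(sorted(_canonical_edge(x, y) for x, y in uncovered)):
        shared = functions.get(a, set()) & functions.get(b, set())
        if not shared:
            dropped.append((a, b))
            continue
        dom_a = f"FICT_{a}_{b}_{k}a"
        dom_b = f"FICT_{a}_{b}_{k}b"
        domains.setdefault(a, []).append(dom_a)
        domains.setdefault(b, []).append(dom_b)
        rules.append(InteractionRule(a, b, dom_a, dom_b, FICTITIOUS).canonical())
    return rules, dropped


def build_model(
    ppi: list[Edge],
    ddi: list[tuple[str, str]],
    domains: dict[str, list[str]],
    abundance: dict[str, float],
    functions: dict[str, set[str]],
) -> IntegratedModel:
    """Assemble the integrated model from the five input tables.

    Retention rule: a protein enters the model iff it has abundance data and
    participates in at least one surviving rule.  Rules touching a protein
    without abundance are discarded (and may orphan the partner in turn).
    Coverage statistics are computed over the de-duplicated PPI edge list,
    before abundance filtering, so they describe the DDI/annotation data
    alone.
    """
    edges = dedup_edges(ppi)
    working_domains = {p: list(slots) for p, slots in domains.items()}
    known, uncovered = derive_known_rules(edges, working_domains, ddi)
    fictitious, _dropped = add_fictitious_rules(uncovered, working_domains, functions)

    n_edges = len(edges)
    n_covered = n_edges - len(uncovered)
    rescued_edges = {_canonical_edge(r.protein_a, r.protein_b) for r in fictitious}
    coverage_before = n_covered / n_edges if n_edges else 0.0
    coverage_after = (n_covered + len(rescued_edges)) / n_edges if n_edges else 0.0

    have_abundance = set(abundance)
    rules = [r for r in known + fictitious
             if r.protein_a in have_abundance and r.protein_b in have_abundance]
    retained = sorted({p for r in rules for p in (r.protein_a, r.protein_b)})
    if not retained:
        raise EmptyModelError(
            "empty model: no protein has both abundance data and a usable interaction rule")

    proteins = {
        p: ProteinSpec(
            id=p,
            abundance_raw=abundance[p],
            instance_count=transform_abundance(abundance[p]),
            domain_slots=list(working_domains.get(p, [])),
            functions=set(functions.get(p, set())),
        )
        for p in retained
    }
    n_interactions = len({_canonical_edge(r.protein_a, r.protein_b) for r in rules})
    coverage = CoverageStats(
        n_ppi_input=n_edges,
        n_proteins_input=len({p for e in edges for p in e}),
        n_proteins_model=len(proteins),
        n_interactions_model=n_interactions,
        ddi_coverage_before=coverage_before,
        ddi_coverage_after=coverage_after,
    )
    return IntegratedModel(proteins=proteins, rules=rules, coverage=coverage)
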