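"""Drug perturbation of a simulated complexome.

A drug is modelled as an extra diffusing species whose binding slots occupy
protein domains, occluding the protein–protein bonds that would otherwise
form through them.  The bound domain types are inferred from the drug's
target list by hypergeometric enrichment against the model proteome.  The
pipeline simulates a control and a treated condition, matches the two
complexomes by best overlap, and calls each complex:

* ``qualitative_change`` — no counterpart above the match threshold in the
  other condition;
* ``quantitative_change`` — matched, with a Welch t-test on per-snapshot
  abundances significant at ``alpha``;
* ``unchanged`` — matched, test not significant;
* ``untestable`` — matched but fewer than two replicates per arm.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import DRUG, IntegratedModel, InteractionRule, ProteinSpec, transform_abundance
from .refine import RefinedComplex
from .scoring import overlap_score

log = logging.getLogger(__name__)

QUANTITATIVE = "quantitative_change"
QUALITATIVE = "qualitative_change"
UNCHANGED = "unchanged"
UNTESTABLE = "untestable"


@dataclass
class DrugSpec:
    id: str
    target_proteins: set[str]
    bound_domains: set[str] = field(default_factory=set)
    abundance_raw: float = 0.0

    @property
    def instance_count(self) -> int:
        return transform_abundance(self.abundance_raw)

    def slot_domain(self, domain: str) -> str:
        # the drug-side identifier of the slot that binds a protein domain
        return f"DRUGSITE:{domain}"


@dataclass
class PerturbationCall:
    control_rc: RefinedComplex | None
    treated_rc: RefinedComplex | None
    overlap: float | None
    p_value: float | None
    call: str


def infer_drug_domains(
    targets: set[str],
    model: IntegratedModel,
    alpha: float = 0.05,
) -> set[str]:
    """Domain types enriched among target proteins (hypergeometric + BH).

    One-sided enrichment of each domain type's presence among the targets
    against the model proteome; Benjamini–Hochberg-adjusted p < alpha.  When
    nothing passes, falls back to domain types carried by a majority (> 50%)
    of the targets, which is logged.
    """
    universe = set(model.proteins)
    targets_in_model = targets & universe
    if not targets_in_model:
        raise ValueError("no drug target is present in the model")
    carriers: dict[str, set[str]] = {}
    for pid in universe:
        for dom in set(model.proteins[pid].domain_slots):
            carriers.setdefault(dom, set()).add(pid)
    domains = sorted(d for d, c in carriers.items() if c & targets_in_model)
    if not domains:
        return set()
    big_n = len(universe)
    n_draw = len(targets_in_model)
    pvals = []
    for dom in domains:
        k = len(carriers[dom] & targets_in_model)
        big_k = len(carriers[dom])
        pvals.append(float(stats.hypergeom.sf(k - 1, big_n, big_k, n_draw)))
    rejected, _adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    enriched = {dom for dom, rej in zip(domains, rejected) if rej}
    if not enriched:
        enriched = {dom for dom in domains
                    if len(carriers[dom] & targets_in_model) > 0.5 * n_draw}
        log.info("no domain enriched at alpha=%s; majority-rule fallback chose %s",
                 alpha, sorted(enriched))
    return enriched


def add_drug(model: IntegratedModel, drug: DrugSpec) -> IntegratedModel:
    """Return a copy of the model with the drug as a competing species.

    The drug gets one slot per bound domain type and a binding rule against
    every protein that carries the domain and either is a target or shares a
    PPI edge with one.  Drug occupancy of a protein slot excludes any
    protein–protein bond through it (site exclusivity).
    """
    if not drug.bound_domains:
        log.warning("drug %s has no bound domains; model unchanged", drug.id)
        return model
    if drug.id in model.proteins:
        raise ValueError(f"species {drug.id!r} already in the model")
    new = copy.deepcopy(model)
    partners_of_targets: set[str] = set(drug.target_proteins)
    for rule in model.rules:
        if rule.protein_a in drug.target_proteins:
            partners_of_targets.add(rule.protein_b)
        if rule.protein_b in drug.target_proteins:
            partners_of_targets.add(rule.protein_a)
    slots = [drug.slot_domain(d) for d in sorted(drug.bound_domains)]
    new.proteins[drug.id] = ProteinSpec(
        id=drug.id,
        abundance_raw=drug.abundance_raw,
        instance_count=drug.instance_count,
        domain_slots=slots,
        functions=set(),
    )
    added = 0
    for dom in sorted(drug.bound_domains):
        for pid in sorted(partners_of_targets & set(model.proteins)):
            if dom in model.proteins[pid].domain_slots:
                new.rules.append(InteractionRule(
                    drug.id, pid, drug.slot_domain(dom), dom, DRUG).canonical())
                added += 1
    log.info("drug %s: %d binding rules over domains %s", drug.id, added,
             sorted(drug.bound_domains))
    return new


def match_complexomes(
    control_rcs: list[RefinedComplex],
    treated_rcs: list[RefinedComplex],
    match_threshold: float = 0.25,
) -> tuple[list[tuple[RefinedComplex, RefinedComplex, float]],
           list[RefinedComplex], list[RefinedComplex]]:
    """Greedy one-to-one matching of the two complexomes by descending overlap.

    Returns (matched pairs with their overlap, unmatched control RCs,
    unmatched treated RCs).
    """
    candidates = []
    for i, c in enumerate(control_rcs):
        for j, t in enumerate(treated_rcs):
            omega = overlap_score(c.members, t.members)
            if omega >= match_threshold:
                candidates.append((omega, i, j))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for omega, i, j in candidates:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        pairs.append((control_rcs[i], treated_rcs[j], omega))
    lone_control = [rc for i, rc in enumerate(control_rcs) if i not in used_c]
    lone_treated = [rc for j, rc in enumerate(treated_rcs) if j not in used_t]
    return pairs, lone_control, lone_treated


def abundance_test(control_rc: RefinedComplex, treated_rc: RefinedComplex,
                   overlap: float, alpha: float = 0.05) -> PerturbationCall:
    """Welch two-sample t-test on per-snapshot abundances of a matched pair."""
    a = [v for _k, v in sorted(control_rc.per_snapshot_abundance.items())]
    b = [v for _k, v in sorted(treated_rc.per_snapshot_abundance.items())]
    if len(a) < 2 or len(b) < 2:
        return PerturbationCall(control_rc, treated_rc, overlap, None, UNTESTABLE)
    if len(set(a)) == 1 and set(a) == set(b):
        p = 1.0  # identical replicate vectors carry no evidence of change
    else:
        with warnings.catch_warnings():
            # near-constant replicate vectors trip a precision warning; the
            # resulting p is still conservative for our accept/reject use
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0  # degenerate variance; no evidence either way
    call = QUANTITATIVE if p < alpha else UNCHANGED
    return PerturbationCall(control_rc, treated_rc, overlap, p, call)


def call_perturbations(
    control_rcs: list[RefinedComplex],
    treated_rcs: list[RefinedComplex],
    match_threshold: float = 0.25,
    alpha: float = 0.05,
) -> list[PerturbationCall]:
    """Match the two complexomes and call every RC exactly once."""
    pairs, lone_control, lone_treated = match_complexomes(
        control_rcs, treated_rcs, match_threshold)
    calls = [abundance_test(c, t, omega, alpha) for c, t, omega in pairs]
    calls.extend(PerturbationCall(rc, None, None, None, QUALITATIVE)
                 for rc in lone_control)
    calls.extend(PerturbationCall(None, rc, None, None, QUALITATIVE)
                 for rc in lone_treated)
    return calls


def write_calls(path, calls: list[PerturbationCall]) -> None:
    from .io import write_tsv

    def _fmt(x, spec="{:.4g}"):
        return "NA" if x is None else spec.format(x)

    rows = []
    for call in calls:
        rows.append((
            call.control_rc.rc_id if call.control_rc else "NA",
            call.treated_rc.rc_id if call.treated_rc else "NA",
            _fmt(call.overlap),
            _fmt(call.p_value),
            call.call,
        ))
    write_tsv(path, rows, header=["control_rc", "treated_rc", "overlap",
                                  "p_value", "call"])
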