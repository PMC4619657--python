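"""Evaluation of a predicted complexome against a reference complex set.

All metrics operate on plain member sets.  The matching statistic is the
overlap score omega(A, B) = |A ∩ B|^2 / (|A| * |B|), the standard criterion
in complex-prediction benchmarking: it is 1 only for identical sets and 0
only for disjoint ones, and penalizes both missing and spurious members.

Metrics:

* recall — fraction of reference complexes matched (omega above threshold)
  by at least one prediction;
* MMR — maximal matching ratio: total weight of a maximum one-to-one
  omega-weighted matching between reference and predicted complexes,
  divided by the number of reference complexes;
* geometric accuracy — sqrt(Sn * PPV) over the reference x prediction
  intersection-count matrix (clustering-wise sensitivity and positive
  predictive value);
* composite — recall + MMR + accuracy, in [0, 3];
* f-score — harmonic mean of complex-level precision and recall.

Predictions whose best overlap with every reference complex stays at or
below the novelty threshold are labelled as new complexes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

MemberSet = frozenset[str]


@dataclass
class ReferenceComplexSet:
    complexes: list[MemberSet]
    source: str = "reference"


@dataclass
class ScoreReport:
    recall: float | None
    mmr: float | None
    accuracy: float
    composite: float | None
    fscore: float
    precision: float
    n_matched: int
    n_new: int


def overlap_score(a: Iterable[str], b: Iterable[str]) -> float:
    """omega(A, B) = |A ∩ B|^2 / (|A| |B|); symmetric, 1 iff A == B."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


@dataclass
class MatchLabel:
    prediction: MemberSet
    best_reference: MemberSet | None
    best_omega: float
    is_new: bool


def match_and_label(
    pred: Sequence[MemberSet],
    ref: ReferenceComplexSet,
    new_threshold: float = 0.25,
) -> list[MatchLabel]:
    """Best reference match per prediction; omega <= new_threshold means new."""
    if not (0.0 <= new_threshold <= 1.0):
        raise ValueError("new_threshold must be in [0, 1]")
    labels = []
    for p in pred:
        best_ref, best_omega = None, 0.0
        for r in ref.complexes:
            omega = overlap_score(p, r)
            if omega > best_omega:
                best_ref, best_omega = r, omega
        labels.append(MatchLabel(prediction=p, best_reference=best_ref,
                                 best_omega=best_omega,
                                 is_new=best_omega <= new_threshold))
    return labels


def recall_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet,
                 match_threshold: float = 0.25) -> float | None:
    """Fraction of reference complexes hit by a prediction with omega > threshold."""
    if not ref.complexes:
        return None
    hit = 0
    for r in ref.complexes:
        if any(overlap_score(p, r) > match_threshold for p in pred):
            hit += 1
    return hit / len(ref.complexes)


def mmr_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet) -> float | None:
    """Maximum-weight one-to-one matching weight divided by |reference|."""
    if not ref.complexes:
        return None
    if not pred:
        return 0.0
    weights = np.array([[overlap_score(r, p) for p in pred] for r in ref.complexes])
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(weights[rows, cols].sum()) / len(ref.complexes)


def accuracy_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet) -> float:
    """Geometric accuracy sqrt(Sn * PPV) over intersection counts t_ij."""
    if not ref.complexes or not pred:
        return 0.0
    t = np.array([[len(r & p) for p in pred] for r in ref.complexes], dtype=float)
    if not t.any():
        return 0.0
    sn = t.max(axis=1).sum() / sum(len(r) for r in ref.complexes)
    ppv = t.max(axis=0).sum() / t.sum()
    return math.sqrt(sn * ppv)


def composite_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet,
                    match_threshold: float = 0.25) -> float | None:
    recall = recall_score(pred, ref, match_threshold)
    mmr = mmr_score(pred, ref)
    if recall is None or mmr is None:
        return None
    return recall + mmr + accuracy_score(pred, ref)


def precision_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet,
                    match_threshold: float = 0.25) -> float:
    if not pred:
        return 0.0
    hit = sum(1 for p in pred
              if any(overlap_score(p, r) > match_threshold for r in ref.complexes))
    return hit / len(pred)


def f_score(pred: Sequence[MemberSet], ref: ReferenceComplexSet,
            match_threshold: float = 0.25) -> float:
    """Harmonic mean of complex-level precision and recall; 0 when P + R = 0."""
    precision = precision_score(pred, ref, match_threshold)
    recall = recall_score(pred, ref, match_threshold) or 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def score_report(pred: Sequence[MemberSet], ref: ReferenceComplexSet,
                 match_threshold: float = 0.25,
                 new_threshold: float = 0.25) -> ScoreReport:
    labels = match_and_label(pred, ref, new_threshold)
    n_new = sum(1 for lab in labels if lab.is_new)
    recall = recall_score(pred, ref, match_threshold)
    mmr = mmr_score(pred, ref)
    accuracy = accuracy_score(pred, ref)
    composite = None if recall is None or mmr is None else recall + mmr + accuracy
    return ScoreReport(
        recall=recall,
        mmr=mmr,
        accuracy=accuracy,
        composite=composite,
        fscore=f_score(pred, ref, match_threshold),
        precision=precision_score(pred, ref, match_threshold),
        n_matched=len(labels) - n_new,
        n_new=n_new,
    )


def dedup_reference(
    raw: Sequence[Iterable[str]],
    min_size: int = 3,
    redundancy_threshold: float = 0.8,
    source: str = "reference",
) -> ReferenceComplexSet:
    """Drop undersized complexes, then redundant ones by a greedy size-descending scan.

    A complex is redundant when its overlap score against an already-kept
    complex reaches ``redundancy_threshold``.  Scanning large-to-small with a
    lexicographic tie-break makes the result independent of input order.
    """
    sized = [frozenset(c) for c in raw if len(frozenset(c)) >= min_size]
    sized.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    kept: list[MemberSet] = []
    for candidate in sized:
        if candidate in kept:
            continue
        if any(overlap_score(candidate, k) >= redundancy_threshold for k in kept):
            continue
        kept.append(candidate)
    return ReferenceComplexSet(complexes=kept, source=source)


def baseline_subunit_average(members: Iterable[str],
                             abundance: dict[str, float]) -> float:
    """Naive complex-abundance baseline: mean raw abundance of the subunits."""
    values = []
    for m in members:
        if m in abundance:
            values.append(abundance[m])
        else:
            log.warning("no abundance for %s; skipped in subunit average", m)
    if not values:
        raise ValueError("no member has abundance data")
    return float(np.mean(values))
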