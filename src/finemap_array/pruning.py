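"""Final pruning: designability filter, priority partition, INFO-score
threshold search under a bead budget, assembly and bead-type accounting.

The pruning logic is deliberately inverted relative to a quality filter:
variants that impute *well* from the base array (INFO above the threshold)
are excluded from custom content, because the array can recover them for
free; hard-to-impute variants are the ones worth physical probes.  The
threshold is searched on the grid of observed INFO values so that the
retained set exactly exhausts the remaining bead budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import (
    ARM_CODING,
    GenotypeProbabilityRecord,
    SelectionRecord,
    ValidationError,
    VariantKey,
)
from .replication import ReplicationStatus, StatusClass

logger = logging.getLogger(__name__)

DEFAULT_DESIGNABILITY_MIN = 0.5

_AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


class BudgetError(RuntimeError):
    """The bead budget cannot accommodate the non-prunable content."""


@dataclass(frozen=True)
class InfoScore:
    """Imputation information quality in [0, 1]; 1 = perfectly imputed."""

    key: VariantKey
    info: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.info <= 1.0):
            raise ValidationError(f"INFO score outside [0,1]: {self.info}")


@dataclass(frozen=True)
class BeadBudget:
    """Maximum number of bead types available for custom content."""

    max_bead_types: int

    def __post_init__(self) -> None:
        if self.max_bead_types <= 0:
            raise ValidationError("bead budget must be positive")


def count_bead_types(key: VariantKey) -> int:
    """Bead types an assay needs: 2 for strand-ambiguous SNPs (A/T, C/G) and
    indels (Infinium I chemistry), 1 otherwise (Infinium II)."""
    if key.is_indel or key.allele_set in _AMBIGUOUS_PAIRS:
        return 2
    return 1


def with_bead_counts(
    records: Iterable[SelectionRecord],
    rule: Callable[[VariantKey], int] = count_bead_types,
) -> list[SelectionRecord]:
    """Set ``bead_count`` on every record (in place) and return the list."""
    records = list(records)
    for r in records:
        r.bead_count = rule(r.key)
    return records


def total_beads(records: Iterable[SelectionRecord]) -> int:
    total = 0
    for r in records:
        if r.bead_count is None:
            raise ValidationError(f"bead count not set for {r.key}")
        total += r.bead_count
    return total


def filter_designable(
    records: Sequence[SelectionRecord],
    scores: Mapping[VariantKey, float],
    min_score: float = DEFAULT_DESIGNABILITY_MIN,
) -> list[SelectionRecord]:
    """Keep records whose assay-designability score is >= ``min_score``.

    Records without a score cannot be designed and are dropped (warned).
    """
    kept = []
    n_missing = 0
    for r in records:
        score = scores.get(r.key)
        if score is None:
            n_missing += 1
            continue
        if score >= min_score:
            kept.append(r)
    if n_missing:
        logger.warning("%d records had no designability score and were dropped", n_missing)
    return kept


def partition_priority(
    records: Sequence[SelectionRecord],
    statuses: Mapping[VariantKey, ReplicationStatus],
) -> tuple[list[SelectionRecord], list[SelectionRecord]]:
    """Split records into a must-keep priority set and an INFO-prunable set.

    Priority: every coding/regulatory record, plus fine-mapping records whose
    signal replicated (status BOTH or ONE) in at least one contributing
    signal.  Fine-mapping records of OPPOSITE/NONE signals are prunable.
    The partition is exhaustive and disjoint; the flag is set on each record.
    """
    priority: list[SelectionRecord] = []
    prunable: list[SelectionRecord] = []
    for r in records:
        if r.arm == ARM_CODING:
            keep = True
        else:
            classes = set()
            for sig in r.signal_keys:
                status = statuses.get(sig)
                if status is None:
                    raise ValidationError(f"no replication status for signal {sig}")
                classes.add(status.cls)
            keep = bool(classes & {StatusClass.BOTH, StatusClass.ONE})
        r.priority = keep
        (priority if keep else prunable).append(r)
    return priority, prunable


def compute_info_score(rec: GenotypeProbabilityRecord) -> InfoScore:
    """Ratio-of-variances imputation INFO from genotype probability triples.

    With per-sample expected dose e_i = p_i1 + 2 p_i2, second moment
    f_i = p_i1 + 4 p_i2, and estimated allele frequency theta = sum(e)/2N:

        info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta))

    Hard calls give info = 1 exactly; a monomorphic estimate (theta 0 or 1)
    is defined as 1 by convention.  The result is clamped to [0, 1].
    """
    probs = rec.probs
    n = probs.shape[0]
    e = probs[:, 1] + 2.0 * probs[:, 2]
    f = probs[:, 1] + 4.0 * probs[:, 2]
    theta = float(e.sum()) / (2.0 * n)
    if theta <= 0.0 or theta >= 1.0:
        return InfoScore(rec.key, 1.0)
    info = 1.0 - float((f - e * e).sum()) / (2.0 * n * theta * (1.0 - theta))
    return InfoScore(rec.key, min(max(info, 0.0), 1.0))


def find_info_threshold(
    prunable: Sequence[SelectionRecord],
    infos: Mapping[VariantKey, float],
    priority_beads: int,
    budget: BeadBudget,
) -> tuple[float, list[SelectionRecord]]:
    """Largest INFO threshold t whose retained set fits the bead budget.

    Retention keeps the hard-to-impute tail: retained(t) = {info <= t}.
    Candidate thresholds are the observed INFO values plus the sentinel 0.0
    ("retain nothing excludable" — records with missing INFO are treated as
    info 0 and are therefore never excludable).  Returns (t, retained).

    Raises :class:`BudgetError` when no threshold fits, distinguishing
    priority content alone overflowing from never-excludable records doing so.
    """
    prunable = list(prunable)
    if priority_beads > budget.max_bead_types:
        raise BudgetError(
            f"priority content alone needs {priority_beads} bead types, "
            f"budget is {budget.max_bead_types}"
        )

    info_of: dict[VariantKey, float] = {}
    n_missing = 0
    for r in prunable:
        value = infos.get(r.key)
        if value is None:
            n_missing += 1
            value = 0.0
        info_of[r.key] = value
    if n_missing:
        logger.warning("%d prunable records lack INFO scores; treated as 0 (never excluded)", n_missing)

    beads = {}
    for r in prunable:
        beads[r.key] = r.bead_count if r.bead_count is not None else count_bead_types(r.key)

    grid = sorted({0.0} | set(info_of.values()))
    best_t: Optional[float] = None
    best_retained: list[SelectionRecord] = []
    for t in grid:
        retained = [r for r in prunable if info_of[r.key] <= t]
        used = priority_beads + sum(beads[r.key] for r in retained)
        if used <= budget.max_bead_types:
            best_t, best_retained = t, retained
        else:
            break  # retained set (hence bead use) is monotone in t
    if best_t is None:
        raise BudgetError(
            "no feasible INFO threshold: records with INFO 0 (never excludable) "
            "plus priority content exceed the bead budget"
        )
    return best_t, best_retained


def assemble_final(
    priority: Sequence[SelectionRecord],
    retained: Sequence[SelectionRecord],
    rule: Callable[[VariantKey], int] = count_bead_types,
) -> tuple[list[SelectionRecord], dict]:
    """Union the priority and retained sets and account bead types.

    The two sets must be disjoint; counts and bead totals are additive and
    reported in the returned summary.
    """
    priority = list(priority)
    retained = list(retained)
    overlap = {r.key for r in priority} & {r.key for r in retained}
    if overlap:
        raise ValidationError(f"priority and retained sets overlap: {sorted(overlap)[:5]}")
    final = with_bead_counts(priority + retained, rule)
    summary = {
        "n_priority": len(priority),
        "n_retained": len(retained),
        "n_final": len(final),
        "beads_priority": total_beads(priority),
        "beads_retained": total_beads(retained),
        "beads_final": total_beads(final),
    }
    return final, summary
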