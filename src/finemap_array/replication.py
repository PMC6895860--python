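"""Replication-status classification and the status-specific LD criterion.

Each index signal is classed from its Hispanic (AMR) and African American
(AA) replication summary statistics:

* ``BOTH``     — one-sided p <= 0.05 (direction-consistent) in both samples;
* ``ONE``      — one-sided p <= 0.05 in exactly one sample;
* ``OPPOSITE`` — significant (two-sided p <= 0.10) with the opposite effect
  direction in a sample;
* ``NONE``     — neither test satisfied.

The class determines which reference-panel pools a candidate must be in LD
with (r² >= 0.1) to be carried as fine-mapping content:

* BOTH         → r² >= 0.1 in ALL of NFE, AMR and AA;
* ONE(pop)     → ALL of NFE and the replicating pool;
* OPPOSITE(pop)→ ANY of NFE or the relevant pool (LD structures diverge);
* NONE         → NFE only.

Missing replication data never satisfies a test.  Default precedence is
BOTH > OPPOSITE > ONE > NONE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Collection, Mapping, Optional, Sequence

from .ld import ld_neighbors, pairwise_r2
from .panels import GenotypePanel
from .records import (
    ARM_FINE_MAPPING,
    IndexSignal,
    Manifest,
    ReplicationRecord,
    SelectionRecord,
    ValidationError,
    VariantKey,
)
from .regions import Region

logger = logging.getLogger(__name__)

DEFAULT_P_ONE_SIDED = 0.05
DEFAULT_P_TWO_OPPOSITE = 0.10
DEFAULT_R2_THRESHOLD = 0.1


class StatusClass(str, Enum):
    BOTH = "BOTH"
    ONE = "ONE"
    OPPOSITE = "OPPOSITE"
    NONE = "NONE"


DEFAULT_PRECEDENCE = (StatusClass.BOTH, StatusClass.OPPOSITE, StatusClass.ONE)


@dataclass(frozen=True)
class ReplicationStatus:
    """Outcome of replication classification for one index signal."""

    cls: StatusClass
    population: Optional[str] = None

    def __post_init__(self) -> None:
        needs_pop = self.cls in (StatusClass.ONE, StatusClass.OPPOSITE)
        if needs_pop != (self.population is not None):
            raise ValidationError(
                f"population must be set iff class is ONE or OPPOSITE (got {self.cls}, {self.population})"
            )


@dataclass(frozen=True)
class LDRequirement:
    """A combinator (ALL/ANY) over population pools with an r² threshold."""

    combinator: str  # "ALL" | "ANY"
    populations: frozenset
    threshold: float = DEFAULT_R2_THRESHOLD

    def __post_init__(self) -> None:
        if self.combinator not in ("ALL", "ANY"):
            raise ValidationError(f"combinator must be ALL or ANY, got {self.combinator}")
        if not self.populations:
            raise ValidationError("LD requirement needs at least one population pool")
        if "NFE" not in self.populations:
            raise ValidationError("NFE is always part of the LD requirement")


def one_sided_p(rec: ReplicationRecord) -> Optional[float]:
    """Direction-aware one-sided p from a two-sided p and an effect sign.

    p/2 when the replication effect has the discovery direction, 1 - p/2
    otherwise; None when either field is missing.
    """
    if rec.p_two_sided is None or rec.effect_sign is None:
        return None
    half = rec.p_two_sided / 2.0
    return half if rec.effect_sign == 1 else 1.0 - half


def classify_replication_status(
    signal: IndexSignal,
    p_one_max: float = DEFAULT_P_ONE_SIDED,
    p_two_opposite: float = DEFAULT_P_TWO_OPPOSITE,
    precedence: Sequence[StatusClass] = DEFAULT_PRECEDENCE,
) -> ReplicationStatus:
    """Classify one signal; total over every (sign, p) configuration."""
    pops = ("AMR", "AA")
    replicated = {}
    opposite = {}
    for pop in pops:
        rec = signal.replication[pop]
        p1 = one_sided_p(rec)
        replicated[pop] = p1 is not None and p1 <= p_one_max
        opposite[pop] = (
            rec.p_two_sided is not None
            and rec.effect_sign == -1
            and rec.p_two_sided <= p_two_opposite
        )

    def opposite_pop() -> Optional[str]:
        hits = [p for p in pops if opposite[p]]
        if len(hits) == 2:
            # Both samples significant-opposite: take the smaller p and flag.
            hits.sort(key=lambda p: signal.replication[p].p_two_sided)
            logger.warning(
                "signal %s opposite-significant in both samples; using %s", signal.key, hits[0]
            )
        return hits[0] if hits else None

    for status_class in precedence:
        if status_class is StatusClass.BOTH and all(replicated.values()):
            return ReplicationStatus(StatusClass.BOTH)
        if status_class is StatusClass.OPPOSITE:
            pop = opposite_pop()
            if pop is not None:
                return ReplicationStatus(StatusClass.OPPOSITE, pop)
        if status_class is StatusClass.ONE:
            hits = [p for p in pops if replicated[p]]
            if len(hits) >= 1:
                return ReplicationStatus(StatusClass.ONE, hits[0])
    return ReplicationStatus(StatusClass.NONE)


def ld_requirement(
    status: ReplicationStatus, threshold: float = DEFAULT_R2_THRESHOLD
) -> LDRequirement:
    """Map a replication status to its population-pool LD requirement."""
    if status.cls is StatusClass.BOTH:
        return LDRequirement("ALL", frozenset({"NFE", "AMR", "AA"}), threshold)
    if status.cls is StatusClass.ONE:
        return LDRequirement("ALL", frozenset({"NFE", status.population}), threshold)
    if status.cls is StatusClass.OPPOSITE:
        return LDRequirement("ANY", frozenset({"NFE", status.population}), threshold)
    return LDRequirement("ALL", frozenset({"NFE"}), threshold)


def select_fine_mapping_variants(
    signal: IndexSignal,
    panels: Mapping[str, GenotypePanel],
    region: Region,
    manifest: Manifest,
    tri_allelic: Collection[VariantKey] = (),
    threshold: float = DEFAULT_R2_THRESHOLD,
    status: Optional[ReplicationStatus] = None,
    p_one_max: float = DEFAULT_P_ONE_SIDED,
    p_two_opposite: float = DEFAULT_P_TWO_OPPOSITE,
) -> list[SelectionRecord]:
    """Candidates in LD with one index signal under its status-specific rule.

    Under an ALL combinator a pool in which the index variant is absent (or
    monomorphic) makes the requirement unsatisfiable for that signal; under
    ANY the remaining pools still contribute.  Base-array overlap and
    tri-allelic keys are removed after the LD criterion, and provenance
    records the status class and the pools in which the criterion held.
    """
    if status is None:
        status = classify_replication_status(signal, p_one_max, p_two_opposite)
    requirement = ld_requirement(status, threshold)

    per_pool: dict[str, set[VariantKey]] = {}
    for pop in sorted(requirement.populations):
        panel = panels.get(pop)
        if panel is None or not panel.has(signal.key):
            logger.warning(
                "index %s absent from %s panel; %s-pool criterion unsatisfiable there",
                signal.key, pop, pop,
            )
            per_pool[pop] = set()
            continue
        per_pool[pop] = ld_neighbors(panel, signal.key, region, threshold)

    if requirement.combinator == "ALL":
        chosen = set.intersection(*per_pool.values()) if per_pool else set()
    else:
        chosen = set.union(*per_pool.values()) if per_pool else set()

    tri_flagged = set(tri_allelic)
    for panel in panels.values():
        tri_flagged |= panel.tri_allelic

    records = []
    for key in sorted(chosen):
        if key in manifest or key in tri_flagged:
            continue
        held = tuple(f"pool:{pop}" for pop in sorted(per_pool) if key in per_pool[pop])
        status_tag = f"status:{status.cls.value}" + (
            f":{status.population}" if status.population else ""
        )
        records.append(
            SelectionRecord(
                key=key,
                arm=ARM_FINE_MAPPING,
                criteria=(status_tag,) + held,
                region_id=region.region_id,
                signal_keys=(signal.key,),
            )
        )
    return records
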