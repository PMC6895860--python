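"""Funnel report: per-stage in/out counts for an end-to-end design run.

Stages are emitted in pipeline order so a reader can follow the cascade
from region extraction to final bead accounting.
"""

from __future__ import annotations

from typing import Mapping

STAGE_ORDER = (
    "regions",
    "coding_regulatory_arm",
    "fine_mapping_arm",
    "union_dedup",
    "designability",
    "priority_partition",
    "info_pruning",
    "assembly",
    "bead_accounting",
)


class FunnelReport:
    """Ordered per-stage counters, renderable as text or a key-value table."""

    def __init__(self) -> None:
        self._stages: list[tuple[str, dict]] = []

    def add(self, stage: str, **counts) -> None:
        self._stages.append((stage, dict(counts)))

    @property
    def stages(self) -> list[tuple[str, dict]]:
        return list(self._stages)

    def stage(self, name: str) -> Mapping:
        for stage, counts in self._stages:
            if stage == name:
                return counts
        raise KeyError(f"no stage named {name!r}")

    def __len__(self) -> int:
        return len(self._stages)

    def to_text(self) -> str:
        lines = ["# selection funnel"]
        for stage, counts in self._stages:
            lines.append(f"[{stage}]")
            for key, value in counts.items():
                lines.append(f"  {key}\t{value}")
        return "\n".join(lines) + "\n"

    def to_rows(self) -> list[tuple[str, str, object]]:
        """Machine-readable (stage, key, value) rows."""
        return [(stage, k, v) for stage, counts in self._stages for k, v in counts.items()]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())
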