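"""End-to-end orchestration: config, validation, and the full design run.

Stage order follows the selection workflow: region building → the two
selection arms (coding/regulatory, replication-conditional LD) → union and
dedup → designability filter → priority partition → INFO pruning under the
bead budget → assembly → bead accounting.  Every stage's in/out counts are
recorded in a funnel report, and a run is deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import io as fio
from .coding import (
    DEFAULT_CADD_MIN,
    DEFAULT_REGULOME_CATEGORIES,
    FrequencyThresholds,
    passes_frequency_filter,
    select_coding_regulatory,
)
from .panels import GenotypePanel
from .pruning import (
    BeadBudget,
    DEFAULT_DESIGNABILITY_MIN,
    assemble_final,
    filter_designable,
    find_info_threshold,
    partition_priority,
    total_beads,
    with_bead_counts,
)
from .records import (
    AnnotationRecord,
    IndexSignal,
    Manifest,
    SelectionRecord,
    ValidationError,
    VariantKey,
)
from .regions import Region, build_regions, mhc_region, signals_outside_mhc
from .replication import (
    DEFAULT_P_ONE_SIDED,
    DEFAULT_P_TWO_OPPOSITE,
    DEFAULT_R2_THRESHOLD,
    ReplicationStatus,
    StatusClass,
    classify_replication_status,
    select_fine_mapping_variants,
)
from .report import FunnelReport

logger = logging.getLogger(__name__)

_PRECEDENCE_NAMES = {"BOTH", "OPPOSITE", "ONE"}


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one design run.

    All thresholds default to the published selection rules; every one is
    overridable (the INFO/bead threshold in particular is an explicit budget
    choice rather than a scientific constant).
    """

    signals: str = ""
    panels: Mapping[str, str] = field(default_factory=dict)
    annotations: str = ""
    manifest: str = ""
    designability: str = ""
    info_scores: Optional[str] = None
    genotype_probabilities: Optional[str] = None
    out_dir: Optional[str] = None

    afr_maf: float = 0.01
    amr_maf: float = 0.01
    nfe_maf: float = 0.05
    eas_maf: float = 0.05
    cadd_min: float = DEFAULT_CADD_MIN
    regulome_categories: tuple = tuple(sorted(DEFAULT_REGULOME_CATEGORIES))
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    p_one_sided: float = DEFAULT_P_ONE_SIDED
    p_two_opposite: float = DEFAULT_P_TWO_OPPOSITE
    designability_min: float = DEFAULT_DESIGNABILITY_MIN
    bead_budget: int = 20_000

    apply_frequency_filter_fine_mapping: bool = False
    status_precedence: tuple = ("BOTH", "OPPOSITE", "ONE")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = raw.pop("thresholds", {}) or {}
        flags = raw.pop("flags", {}) or {}
        kwargs = {}
        for name in ("signals", "annotations", "manifest", "designability",
                     "info_scores", "genotype_probabilities", "out_dir", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        kwargs["panels"] = dict(raw.get("panels", {}))
        mapping = {
            "afr_maf": "afr_maf", "amr_maf": "amr_maf", "nfe_maf": "nfe_maf",
            "eas_maf": "eas_maf", "cadd_min": "cadd_min",
            "r2": "r2_threshold", "p_one_sided": "p_one_sided",
            "p_two_opposite": "p_two_opposite",
            "designability_min": "designability_min", "bead_budget": "bead_budget",
        }
        for src, dst in mapping.items():
            if src in thresholds:
                kwargs[dst] = thresholds[src]
        if "regulome_categories" in thresholds:
            kwargs["regulome_categories"] = tuple(thresholds["regulome_categories"])
        if "apply_frequency_filter_fine_mapping" in flags:
            kwargs["apply_frequency_filter_fine_mapping"] = bool(
                flags["apply_frequency_filter_fine_mapping"]
            )
        if "status_precedence" in flags:
            kwargs["status_precedence"] = tuple(flags["status_precedence"])
        return cls(**kwargs)

    def frequency_thresholds(self) -> FrequencyThresholds:
        return FrequencyThresholds(self.afr_maf, self.amr_maf, self.nfe_maf, self.eas_maf)

    def precedence(self) -> tuple:
        return tuple(StatusClass(name) for name in self.status_precedence)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations; empty iff the config is usable."""
    violations: list[str] = []

    def check_range(name, value, lo, hi, lo_open=False, hi_open=False):
        ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
        if not ok:
            violations.append(f"{name}={value} outside allowed range")

    for name in ("afr_maf", "amr_maf", "nfe_maf", "eas_maf"):
        check_range(name, getattr(config, name), 0.0, 0.5, lo_open=True, hi_open=True)
    check_range("cadd_min", config.cadd_min, 0.0, 99.0)
    check_range("r2_threshold", config.r2_threshold, 0.0, 1.0)
    check_range("p_one_sided", config.p_one_sided, 0.0, 1.0, lo_open=True)
    check_range("p_two_opposite", config.p_two_opposite, 0.0, 1.0, lo_open=True)
    check_range("designability_min", config.designability_min, 0.0, 1.0)
    if config.bead_budget <= 0:
        violations.append(f"bead_budget={config.bead_budget} must be positive")
    if not config.regulome_categories:
        violations.append("regulome_categories must be non-empty")
    if not _PRECEDENCE_NAMES.issuperset(config.status_precedence):
        violations.append(f"status_precedence contains unknown classes: {config.status_precedence}")

    for name in ("signals", "annotations", "manifest", "designability"):
        path = getattr(config, name)
        if not path:
            violations.append(f"missing required path: {name}")
        elif not Path(path).exists():
            violations.append(f"{name} path does not exist: {path}")
    if not config.panels:
        violations.append("missing required path: panels")
    for pop, path in config.panels.items():
        if not Path(path).exists():
            violations.append(f"panel path for {pop} does not exist: {path}")
    if config.info_scores is None and config.genotype_probabilities is None:
        violations.append("either info_scores or genotype_probabilities must be provided")
    for name in ("info_scores", "genotype_probabilities"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            violations.append(f"{name} path does not exist: {path}")
    return violations


@dataclass
class PipelineResult:
    """Everything a design run produces, for inspection or writing."""

    final: list
    report: FunnelReport
    regions: list
    statuses: dict
    info_threshold: float
    coding_records: list
    fine_records: list
    priority: list
    retained: list


def _dedup_merge(records: Sequence[SelectionRecord]) -> list[SelectionRecord]:
    merged: dict[VariantKey, SelectionRecord] = {}
    for r in records:
        merged[r.key] = merged[r.key].merged_with(r) if r.key in merged else r
    return [merged[k] for k in sorted(merged)]


def run_design(
    config: PipelineConfig,
    signals: Optional[Sequence[IndexSignal]] = None,
    panels: Optional[Mapping[str, GenotypePanel]] = None,
    annotations: Optional[Sequence[AnnotationRecord]] = None,
    manifest: Optional[Manifest] = None,
) -> PipelineResult:
    """Execute the full selection workflow and return the final content.

    Inputs are read from the config's paths unless pre-loaded objects are
    passed in (useful for tests and notebooks).
    """
    errors = validate_config(config) if signals is None else []
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))

    report = FunnelReport()

    signals = list(signals) if signals is not None else fio.read_index_signals(config.signals)
    panels = dict(panels) if panels is not None else {
        pop: fio.read_panel_vcf(path, pop) for pop, path in config.panels.items()
    }
    annotations = (
        list(annotations) if annotations is not None
        else fio.read_annotation_table(config.annotations)
    )
    manifest = manifest if manifest is not None else fio.read_manifest(config.manifest)
    designability = fio.read_designability(config.designability) if config.designability else {}
    if config.info_scores is not None:
        infos = fio.read_info_scores(config.info_scores)
    elif config.genotype_probabilities is not None:
        from .pruning import compute_info_score

        probs = fio.read_genotype_probabilities(config.genotype_probabilities)
        infos = {rec.key: compute_info_score(rec).info for rec in probs}
    else:
        infos = {}

    tri_allelic: set[VariantKey] = set()
    for panel in panels.values():
        tri_allelic |= panel.tri_allelic

    # 1. regions -----------------------------------------------------------
    fm_signals = signals_outside_mhc(signals)
    regions = build_regions(fm_signals)
    mhc = mhc_region(region_id=len(regions))
    report.add(
        "regions",
        n_signals=len(signals),
        n_fine_mapping_signals=len(fm_signals),
        n_merged_regions=len(regions),
        mhc_included=1,
    )

    # 2. coding/regulatory arm --------------------------------------------
    thresholds = config.frequency_thresholds()
    coding = select_coding_regulatory(
        annotations,
        list(regions) + [mhc],
        manifest,
        thresholds=thresholds,
        tri_allelic=tri_allelic,
        min_cadd=config.cadd_min,
        regulome_categories=set(config.regulome_categories),
    )
    tag_counts = {
        "n_effect": sum(1 for r in coding if any(t.startswith("effect:") for t in r.criteria)),
        "n_cadd": sum(1 for r in coding if "cadd" in r.criteria),
        "n_regulome": sum(1 for r in coding if "regulome" in r.criteria),
    }
    report.add("coding_regulatory_arm", n_annotations=len(annotations),
               n_selected=len(coding), **tag_counts)

    # 3. fine-mapping arm --------------------------------------------------
    statuses = {
        s.key: classify_replication_status(
            s, config.p_one_sided, config.p_two_opposite, config.precedence()
        )
        for s in signals
    }
    freq_pass: Optional[set[VariantKey]] = None
    if config.apply_frequency_filter_fine_mapping:
        freq_pass = {a.key for a in annotations if passes_frequency_filter(a, thresholds)}

    region_of_signal: dict[VariantKey, Region] = {}
    for region in regions:
        for key in region.index_keys:
            region_of_signal[key] = region

    n_candidates = len(
        {k for p in panels.values() for k in p.keys if any(
            r.contains(k.chrom, k.pos) for r in regions
        )}
    )
    fine_raw: list[SelectionRecord] = []
    status_counts: dict[str, int] = {}
    for signal in fm_signals:
        status = statuses[signal.key]
        status_counts[status.cls.value] = status_counts.get(status.cls.value, 0) + 1
        recs = select_fine_mapping_variants(
            signal,
            panels,
            region_of_signal[signal.key],
            manifest,
            tri_allelic=tri_allelic,
            threshold=config.r2_threshold,
            status=status,
        )
        if freq_pass is not None:
            recs = [r for r in recs if r.key in freq_pass]
        fine_raw.extend(recs)
    fine = _dedup_merge(fine_raw)
    report.add(
        "fine_mapping_arm",
        n_candidates_in_regions=n_candidates,
        n_selected=len(fine),
        **{f"n_signals_{k}": v for k, v in sorted(status_counts.items())},
    )

    # 4. union / dedup -----------------------------------------------------
    coding_keys = {r.key for r in coding}
    fine_keys = {r.key for r in fine}
    union = _dedup_merge(list(coding) + list(fine))
    report.add(
        "union_dedup",
        n_coding=len(coding),
        n_fine_mapping=len(fine),
        n_overlap=len(coding_keys & fine_keys),
        n_union=len(union),
    )

    # 5. designability -----------------------------------------------------
    designable = filter_designable(union, designability, config.designability_min)
    report.add("designability", n_in=len(union), n_out=len(designable),
               n_removed=len(union) - len(designable))

    # 6. priority partition ------------------------------------------------
    priority, prunable = partition_priority(designable, statuses)
    report.add("priority_partition", n_priority=len(priority), n_prunable=len(prunable))

    # 7. INFO pruning ------------------------------------------------------
    with_bead_counts(priority)
    with_bead_counts(prunable)
    threshold, retained = find_info_threshold(
        prunable, infos, total_beads(priority), BeadBudget(config.bead_budget)
    )
    report.add(
        "info_pruning",
        info_threshold=threshold,
        n_retained=len(retained),
        n_excluded=len(prunable) - len(retained),
    )

    # 8. assembly ----------------------------------------------------------
    final, summary = assemble_final(priority, retained)
    report.add("assembly", n_final=summary["n_final"],
               n_priority=summary["n_priority"], n_retained=summary["n_retained"])

    # 9. bead accounting ---------------------------------------------------
    report.add(
        "bead_accounting",
        beads_priority=summary["beads_priority"],
        beads_retained=summary["beads_retained"],
        beads_final=summary["beads_final"],
        bead_budget=config.bead_budget,
    )

    result = PipelineResult(
        final=final, report=report, regions=list(regions) + [mhc], statuses=statuses,
        info_threshold=threshold, coding_records=coding, fine_records=fine,
        priority=priority, retained=retained,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the selection TSV/BED, regions BED, funnel and status audit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fio.write_selection(result.final, out_dir / "selection.tsv", funnel=result.report,
                        funnel_path=out_dir / "funnel.txt")
    fio.write_selection_bed(result.final, out_dir / "selection.bed")
    fio.write_regions_bed(result.regions, out_dir / "regions.bed")
    audit = pd.DataFrame(
        [
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "status": status.cls.value, "population": status.population or ".",
            }
            for key, status in sorted(result.statuses.items())
        ]
    )
    audit.to_csv(out_dir / "status_audit.tsv", sep="\t", index=False)
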