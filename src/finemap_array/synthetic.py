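"""Synthetic study generator: panels, signals, annotations with known truth.

Every pipeline input can be generated with controlled statistical structure:
haplotype panels with *planted* pairwise r² between each candidate and its
index variant (drawn from the exact four-gamete distribution), replication
tables whose signals classify to intended statuses by construction, and
annotation/manifest tables with exact criterion fractions.  Ground-truth
sidecar files are always written so tests never re-derive expectations from
the generator's internals.

Haplotypes are drawn independently per individual from exact gamete
frequencies — no recombination map, no admixture LD.  That is sufficient to
exercise every selection rule; population-genetic realism is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import ValidationError, VariantKey, chrom_sort_key

DEFAULT_SAMPLE_SIZES = {"NFE": 403, "AMR": 338, "AA": 149}

#: Per-candidate planted r² targets (NFE, AMR, AA), cycled across the
#: candidates of each signal.  The cycle covers every selection regime:
#: LD in all pools, in NFE plus one minority pool, in NFE only, in a
#: minority pool only, at the 0.1 boundary's two sides, and in none.
DEFAULT_R2_PROFILES: tuple[dict, ...] = (
    {"NFE": 0.50, "AMR": 0.50, "AA": 0.50},
    {"NFE": 0.40, "AMR": 0.40, "AA": 0.40},
    {"NFE": 0.40, "AMR": 0.40, "AA": 0.02},
    {"NFE": 0.40, "AMR": 0.02, "AA": 0.40},
    {"NFE": 0.40, "AMR": 0.02, "AA": 0.02},
    {"NFE": 0.25, "AMR": 0.03, "AA": 0.03},
    {"NFE": 0.18, "AMR": 0.18, "AA": 0.18},
    {"NFE": 0.02, "AMR": 0.02, "AA": 0.02},
    {"NFE": 0.02, "AMR": 0.40, "AA": 0.02},
    {"NFE": 0.02, "AMR": 0.02, "AA": 0.40},
    {"NFE": 0.30, "AMR": 0.30, "AA": 0.30},
    {"NFE": 0.05, "AMR": 0.30, "AA": 0.30},
)

#: Allele pairs cycled across generated variants; includes strand-ambiguous
#: SNPs and an indel so bead-type accounting is exercised.
DEFAULT_ALLELE_CYCLE = (
    ("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"),
    ("A", "T"), ("C", "G"), ("AT", "A"), ("T", "C"),
)

#: Default replication-status mix for 20 signals: the 16/85/5/94 split of a
#: 200-signal study at one-tenth scale (ONE split between the two samples).
DEFAULT_STATUS_MIX = {
    "BOTH": 2,
    "ONE:AMR": 4,
    "ONE:AA": 4,
    "OPPOSITE:AA": 1,
    "NONE": 9,
}


class FeasibilityError(ValidationError):
    """The requested (pA, pB, r²) combination is not attainable."""


@dataclass
class FixtureSpec:
    """Study conditions for a full synthetic design run.

    Defaults emulate the reference study at one-tenth the signal count:
    20 index signals in a 2/8/1/9 replication-status mix, reference pools of
    403 NFE / 338 AMR / 149 AA individuals, 12 LD candidates per signal.
    """

    n_signals: int = 20
    status_mix: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_STATUS_MIX))
    sample_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    candidates_per_signal: int = 12
    r2_profiles: Sequence[Mapping[str, float]] = DEFAULT_R2_PROFILES
    index_maf_range: tuple[float, float] = (0.2, 0.45)
    effect_fraction: float = 0.08
    cadd_fraction: float = 0.04
    regulome_fraction: float = 0.04
    freq_pass_fraction: float = 0.85
    manifest_fraction: float = 0.10
    designability_low_fraction: float = 0.10
    designability_missing_fraction: float = 0.02
    designability_min: float = 0.5
    r2_threshold: float = 0.1
    bead_budget: int = 120
    exact_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.status_mix.values()) != self.n_signals:
            raise ValidationError(
                f"status mix totals {sum(self.status_mix.values())}, expected {self.n_signals} signals"
            )
        for profile in self.r2_profiles:
            for pop, r2 in profile.items():
                if not (0.0 <= r2 <= 1.0):
                    raise ValidationError(f"target r² for {pop} outside [0,1]: {r2}")
        for name in (
            "effect_fraction", "cadd_fraction", "regulome_fraction", "freq_pass_fraction",
            "manifest_fraction", "designability_low_fraction", "designability_missing_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} outside [0,1]: {value}")


@dataclass(frozen=True)
class StudyPaths:
    """Locations of every generated input plus ground-truth sidecars."""

    root: Path
    signals: Path
    panels: Mapping[str, Path]
    annotations: Path
    manifest: Path
    designability: Path
    info_scores: Path
    config: Path
    truth_replication: Path
    truth_planted_r2: Path
    truth_annotation: Path


# ---------------------------------------------------------------------------
# planted two-locus LD
# ---------------------------------------------------------------------------

def gamete_frequencies(
    p_a: float, p_b: float, target_r2: float, sign: int = 1
) -> np.ndarray:
    """Four-gamete frequencies (AB, Ab, aB, ab) realizing a target r².

    D is set to sign * sqrt(target_r2 * pA qA pB qB); infeasible targets
    (|D| beyond the allele-frequency bounds) raise with the attainable max.
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise FeasibilityError(f"allele frequencies must be in (0,1): pA={p_a}, pB={p_b}")
    if not (0.0 <= target_r2 <= 1.0):
        raise FeasibilityError(f"target r² outside [0,1]: {target_r2}")
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d = sign * np.sqrt(target_r2 * denom)
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b) if sign >= 0 else min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if abs(d) > d_max + 1e-12:
        attainable = d_max * d_max / denom
        raise FeasibilityError(
            f"target r²={target_r2} infeasible for pA={p_a}, pB={p_b}, sign={sign:+d}; "
            f"attainable maximum is {attainable:.4f}"
        )
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    return np.clip(freqs, 0.0, None) / np.clip(freqs, 0.0, None).sum()


def _exact_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of n * freqs to integers summing to n."""
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def plant_ld_pair(
    p_a: float,
    p_b: float,
    target_r2: float,
    n_haplotypes: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sign: int = 1,
    exact: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a pair of haplotype vectors with planted r².

    ``exact=True`` uses largest-remainder rounded gamete counts instead of a
    multinomial draw, so the realized sample r² matches the target to O(1/n);
    the default multinomial draw matches it in expectation.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    freqs = gamete_frequencies(p_a, p_b, target_r2, sign)
    counts = _exact_counts(freqs, n_haplotypes) if exact else rng.multinomial(n_haplotypes, freqs)
    gametes = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    haps = np.repeat(gametes, counts, axis=0)
    perm = rng.permutation(n_haplotypes)
    haps = haps[perm]
    return haps[:, 0].copy(), haps[:, 1].copy()


def _conditional_candidate(
    index_hap: np.ndarray,
    p_a: float,
    p_b: float,
    target_r2: float,
    rng: np.random.Generator,
    exact: bool = False,
) -> np.ndarray:
    """Candidate haplotypes conditional on realized index alleles.

    Uses P(B|A) = pAB/pA and P(B|a) = paB/qA from the planted gamete
    distribution, so several candidates can share one index vector while
    each carries its own target r².
    """
    freqs = gamete_frequencies(p_a, p_b, target_r2)
    p_b_given_a = freqs[0] / (freqs[0] + freqs[1])
    p_b_given_not_a = freqs[2] / (freqs[2] + freqs[3])
    out = np.zeros_like(index_hap)
    for value, prob in ((1, p_b_given_a), (0, p_b_given_not_a)):
        idx = np.flatnonzero(index_hap == value)
        if idx.size == 0:
            continue
        if exact:
            k = int(round(prob * idx.size))
            chosen = rng.permutation(idx)[:k]
            out[chosen] = 1
        else:
            out[idx] = rng.random(idx.size) < prob
    return out.astype(np.int8)


# ---------------------------------------------------------------------------
# study layout
# ---------------------------------------------------------------------------

def _parse_status_label(label: str) -> tuple[str, Optional[str]]:
    parts = label.split(":")
    cls = parts[0]
    pop = parts[1] if len(parts) > 1 else None
    if cls not in ("BOTH", "ONE", "OPPOSITE", "NONE"):
        raise ValidationError(f"unknown status label {label!r}")
    if cls in ("ONE", "OPPOSITE") and pop not in ("AMR", "AA"):
        raise ValidationError(f"status {cls} needs a population (AMR/AA): {label!r}")
    return cls, pop


def _signal_positions(n_signals: int) -> list[tuple[str, int]]:
    """Deterministic signal placement: non-overlapping 2-Mb windows."""
    out = []
    for i in range(n_signals):
        chrom = str((i % 22) + 1)
        pos = 20_000_000 + (i // 22) * 6_000_000
        out.append((chrom, pos))
    return out


def _allele_pair(i: int) -> tuple[str, str]:
    return DEFAULT_ALLELE_CYCLE[i % len(DEFAULT_ALLELE_CYCLE)]


def _candidate_offsets(k: int) -> list[int]:
    """k distinct non-zero offsets within +/- 480 kb of the index."""
    grid = np.linspace(-480_000, 480_000, k)
    return [int(o) if int(o) != 0 else 1000 for o in grid]


@dataclass(frozen=True)
class _StudyLayout:
    signal_keys: list
    statuses: list            # (cls, pop) per signal
    candidate_keys: list      # list of lists, per signal
    targets: list             # list of lists of {pop: r2}, per signal


def _build_layout(spec: FixtureSpec, rng: np.random.Generator) -> _StudyLayout:
    labels: list[tuple[str, Optional[str]]] = []
    for label, count in spec.status_mix.items():
        labels.extend([_parse_status_label(label)] * count)
    rng.shuffle(labels)

    signal_keys, candidate_keys, targets = [], [], []
    allele_i = 0
    for i, (chrom, pos) in enumerate(_signal_positions(spec.n_signals)):
        ref, alt = ("A", "G")  # index variants: plain SNPs (always designable)
        signal_keys.append(VariantKey(chrom, pos, ref, alt))
        keys, tg = [], []
        for j, offset in enumerate(_candidate_offsets(spec.candidates_per_signal)):
            ref, alt = _allele_pair(allele_i)
            allele_i += 1
            keys.append(VariantKey(chrom, pos + offset, ref, alt))
            tg.append(dict(spec.r2_profiles[j % len(spec.r2_profiles)]))
        candidate_keys.append(keys)
        targets.append(tg)
    return _StudyLayout(signal_keys, labels, candidate_keys, targets)


# ---------------------------------------------------------------------------
# generators (one per input kind)
# ---------------------------------------------------------------------------

def generate_replication_table(
    spec: FixtureSpec,
    signal_keys: Sequence[VariantKey],
    statuses: Sequence[tuple[str, Optional[str]]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index-signal table whose rows classify to the intended statuses.

    Returns (signal table, truth table).  p-values are drawn inside ranges
    that guarantee the intended class under the 0.05 one-sided / 0.10
    opposite-two-sided thresholds with strict margins.
    """

    def replicated_p() -> float:
        return float(rng.uniform(0.002, 0.098))  # one-sided 0.001-0.049

    def null_p() -> float:
        return float(rng.uniform(0.2, 0.9))      # one-sided >= 0.1 when same-sign

    rows, truth = [], []
    for key, (cls, pop) in zip(signal_keys, statuses):
        stats = {"AMR": (1, null_p()), "AA": (1, null_p())}
        if cls == "BOTH":
            stats["AMR"] = (1, replicated_p())
            stats["AA"] = (1, replicated_p())
        elif cls == "ONE":
            stats[pop] = (1, replicated_p())
        elif cls == "OPPOSITE":
            stats[pop] = (-1, replicated_p())  # two-sided <= 0.098 < 0.10
        rows.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "discovery_direction": 1,
                "amr_beta_sign": stats["AMR"][0], "amr_p2": round(stats["AMR"][1], 6),
                "aa_beta_sign": stats["AA"][0], "aa_p2": round(stats["AA"][1], 6),
            }
        )
        truth.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "status": cls, "population": pop or ".",
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def generate_panel_vcf(
    spec: FixtureSpec,
    layout: _StudyLayout,
    out_dir: Path,
    rng: np.random.Generator,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one phased VCF per population pool with planted per-pop r².

    Returns ({population: path}, planted-r² truth table).  Deterministic
    given the generator state: same seed, byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_rows = []

    # Haplotype columns are generated per (signal, pop) so the truth table is
    # population-resolved; all variants of a pool share one VCF.
    pop_columns: dict[str, dict[VariantKey, np.ndarray]] = {p: {} for p in spec.sample_sizes}
    for sig_i, sig_key in enumerate(layout.signal_keys):
        for pop in spec.sample_sizes:
            n_hap = 2 * spec.sample_sizes[pop]
            p_index = float(rng.uniform(*spec.index_maf_range))
            index_hap = np.zeros(n_hap, dtype=np.int8)
            if spec.exact_counts:
                k = int(round(p_index * n_hap))
                index_hap[rng.permutation(n_hap)[:k]] = 1
            else:
                index_hap[:] = rng.random(n_hap) < p_index
            pop_columns[pop][sig_key] = index_hap
            for cand_key, target in zip(layout.candidate_keys[sig_i], layout.targets[sig_i]):
                r2_target = target[pop]
                p_cand = p_index if r2_target >= 0.1 else float(rng.uniform(0.15, 0.45))
                cand_hap = _conditional_candidate(
                    index_hap, p_index, p_cand, r2_target, rng, exact=spec.exact_counts
                )
                pop_columns[pop][cand_key] = cand_hap
                truth_rows.append(
                    {
                        "signal": str(sig_key), "candidate": str(cand_key),
                        "population": pop, "target_r2": r2_target,
                    }
                )

    for pop, columns in pop_columns.items():
        n = spec.sample_sizes[pop]
        samples = [f"{pop}{i:04d}" for i in range(n)]
        keys = sorted(columns, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))
        path = out_dir / f"panel_{pop}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=finemap_array synthetic study generator\n")
            for chrom in sorted({k.chrom for k in keys}, key=chrom_sort_key):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for key in keys:
                hap = columns[key]
                gts = "\t".join(f"{hap[2 * i]}|{hap[2 * i + 1]}" for i in range(n))
                fh.write(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gts}\n")
        paths[pop] = path
    return paths, pd.DataFrame(truth_rows)


def generate_annotation_and_manifest(
    spec: FixtureSpec,
    signal_keys: Sequence[VariantKey],
    candidate_keys: Sequence[VariantKey],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Annotation + manifest tables with exact criterion fractions.

    Criterion memberships (effect / CADD / RegulomeDB / frequency-pass) are
    allocated by independent permutations with exactly round(fraction * n)
    members each, so a variant can satisfy several criteria.  The manifest
    holds every index variant plus an exact fraction of candidates.
    Returns (annotations, manifest, truth).
    """
    keys = list(signal_keys) + list(candidate_keys)
    n = len(keys)

    def pick(fraction: float) -> set[VariantKey]:
        k = int(round(fraction * n))
        return set(np.array(keys, dtype=object)[rng.permutation(n)[:k]])

    effect_set = pick(spec.effect_fraction)
    cadd_set = pick(spec.cadd_fraction)
    regulome_set = pick(spec.regulome_fraction)
    freq_set = pick(spec.freq_pass_fraction)

    effect_cycle = ("nonsynonymous", "stopgain", "stoploss", "splicing")
    regulome_pass = ("1a", "1b", "1c", "1d", "1e")
    regulome_fail = ("1f", "2a", "3a", "4", "5", "6", "7")

    ann_rows, truth_rows = [], []
    effect_i = 0
    for key in keys:
        in_effect = key in effect_set
        if in_effect:
            effect = effect_cycle[effect_i % len(effect_cycle)]
            effect_i += 1
        else:
            effect = "synonymous" if rng.random() < 0.5 else "other"
        cadd = round(float(rng.uniform(30.0, 50.0)), 2) if key in cadd_set else round(float(rng.uniform(0.0, 25.0)), 2)
        regulome = (
            regulome_pass[int(rng.integers(len(regulome_pass)))]
            if key in regulome_set
            else regulome_fail[int(rng.integers(len(regulome_fail)))]
        )
        if key in freq_set:
            freqs = {p: round(float(rng.uniform(0.06, 0.45)), 4) for p in ("afr", "amr", "nfe", "eas")}
        else:
            freqs = {p: 0.005 for p in ("afr", "amr", "nfe", "eas")}
        ann_rows.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "effect": effect, "cadd": cadd, "regulome": regulome,
                "afr_maf": freqs["afr"], "amr_maf": freqs["amr"],
                "nfe_maf": freqs["nfe"], "eas_maf": freqs["eas"],
            }
        )
        truth_rows.append(
            {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                "effect_pass": int(in_effect), "cadd_pass": int(key in cadd_set),
                "regulome_pass": int(key in regulome_set), "freq_pass": int(key in freq_set),
            }
        )

    n_cand = len(candidate_keys)
    k_manifest = int(round(spec.manifest_fraction * n_cand))
    manifest_candidates = set(
        np.array(list(candidate_keys), dtype=object)[rng.permutation(n_cand)[:k_manifest]]
    )
    manifest_keys = list(signal_keys) + sorted(
        manifest_candidates, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt)
    )
    manifest_df = pd.DataFrame(
        [
            {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "source": "base_array"}
            for k in manifest_keys
        ]
    )
    truth = pd.DataFrame(truth_rows)
    truth["in_manifest"] = [int(k in set(manifest_keys)) for k in keys]
    return pd.DataFrame(ann_rows), manifest_df, truth


def generate_score_tables(
    spec: FixtureSpec,
    keys: Sequence[VariantKey],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Designability and INFO score tables over all variants.

    An exact low-score fraction falls below the designability cutoff and a
    small fraction is missing entirely; INFO scores are uniform on [0, 1].
    """
    n = len(keys)
    perm = rng.permutation(n)
    n_low = int(round(spec.designability_low_fraction * n))
    n_missing = int(round(spec.designability_missing_fraction * n))
    low = set(perm[:n_low])
    missing = set(perm[n_low:n_low + n_missing])

    design_rows, info_rows = [], []
    for i, key in enumerate(keys):
        if i not in missing:
            score = float(rng.uniform(0.05, 0.45)) if i in low else float(rng.uniform(0.55, 0.99))
            design_rows.append(
                {"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                 "score": round(score, 4)}
            )
        info_rows.append(
            {"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
             "info": round(float(rng.uniform(0.0, 1.0)), 4)}
        )
    return pd.DataFrame(design_rows), pd.DataFrame(info_rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(spec: FixtureSpec, out_dir) -> StudyPaths:
    """Write a complete, self-consistent input set for a design run.

    Emits per-pool phased VCFs, the index-signal table, annotation and
    manifest tables, designability and INFO scores, ground-truth sidecars,
    and a ready-to-run pipeline config.  Identical specs (including seed)
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_layout, rng_repl, rng_panel, rng_ann, rng_score = (
        np.random.default_rng(s) for s in streams
    )

    layout = _build_layout(spec, rng_layout)
    all_candidates = [k for keys in layout.candidate_keys for k in keys]
    all_keys = layout.signal_keys + all_candidates

    signals_df, repl_truth = generate_replication_table(
        spec, layout.signal_keys, layout.statuses, rng_repl
    )
    panel_paths, planted_truth = generate_panel_vcf(spec, layout, out_dir / "panels", rng_panel)
    ann_df, manifest_df, ann_truth = generate_annotation_and_manifest(
        spec, layout.signal_keys, all_candidates, rng_ann
    )
    design_df, info_df = generate_score_tables(spec, all_keys, rng_score)

    paths = StudyPaths(
        root=out_dir,
        signals=out_dir / "index_signals.tsv",
        panels=panel_paths,
        annotations=out_dir / "annotations.tsv",
        manifest=out_dir / "manifest.tsv",
        designability=out_dir / "designability.tsv",
        info_scores=out_dir / "info_scores.tsv",
        config=out_dir / "config.yaml",
        truth_replication=out_dir / "truth_replication.tsv",
        truth_planted_r2=out_dir / "truth_planted_r2.tsv",
        truth_annotation=out_dir / "truth_annotation.tsv",
    )
    signals_df.to_csv(paths.signals, sep="\t", index=False)
    ann_df.to_csv(paths.annotations, sep="\t", index=False)
    manifest_df.to_csv(paths.manifest, sep="\t", index=False)
    design_df.to_csv(paths.designability, sep="\t", index=False)
    info_df.to_csv(paths.info_scores, sep="\t", index=False)
    repl_truth.to_csv(paths.truth_replication, sep="\t", index=False)
    planted_truth.to_csv(paths.truth_planted_r2, sep="\t", index=False)
    ann_truth.to_csv(paths.truth_annotation, sep="\t", index=False)

    config = {
        "signals": str(paths.signals),
        "panels": {pop: str(p) for pop, p in panel_paths.items()},
        "annotations": str(paths.annotations),
        "manifest": str(paths.manifest),
        "designability": str(paths.designability),
        "info_scores": str(paths.info_scores),
        "thresholds": {
            "afr_maf": 0.01, "amr_maf": 0.01, "nfe_maf": 0.05, "eas_maf": 0.05,
            "cadd_min": 30.0,
            "regulome_categories": ["1a", "1b", "1c", "1d", "1e"],
            "r2": spec.r2_threshold,
            "p_one_sided": 0.05,
            "p_two_opposite": 0.10,
            "designability_min": spec.designability_min,
            "bead_budget": spec.bead_budget,
        },
        "flags": {
            "apply_frequency_filter_fine_mapping": False,
            "status_precedence": ["BOTH", "OPPOSITE", "ONE"],
        },
        "seed": spec.seed,
    }
    with open(paths.config, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
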