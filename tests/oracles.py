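"""Independent reference implementations used to check the package.

Each oracle is a deliberately naive computation (grid search, brute-force
scan, direct formula evaluation) kept separate from the library code paths
it validates.
"""

from __future__ import annotations

import numpy as np


def grid_max_loglik(counts: np.ndarray, resolution: float = 1e-4) -> float:
    """Max multinomial log-likelihood of a 3x3 genotype table over pAB.

    Allele frequencies are fixed at their (phase-independent) sample values;
    pAB is scanned over its Fréchet bounds at the given resolution.
    """
    counts = np.asarray(counts, dtype=float)
    n2 = 2.0 * counts.sum()
    row, col = counts.sum(axis=1), counts.sum(axis=0)
    p_a = (2 * row[2] + row[1]) / n2
    p_b = (2 * col[2] + col[1]) / n2
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    pab_grid = np.arange(lo, hi + resolution, resolution)
    pab_grid = np.clip(pab_grid, lo, hi)

    pAB = pab_grid
    pAb = p_a - pAB
    paB = p_b - pAB
    pab = 1.0 - p_a - p_b + pAB
    probs = np.empty((9, pAB.size))
    probs[0] = pab * pab                      # (0,0)
    probs[1] = 2 * paB * pab                  # (0,1)
    probs[2] = paB * paB                      # (0,2)
    probs[3] = 2 * pAb * pab                  # (1,0)
    probs[4] = 2 * (pAB * pab + pAb * paB)    # (1,1)
    probs[5] = 2 * pAB * paB                  # (1,2)
    probs[6] = pAb * pAb                      # (2,0)
    probs[7] = 2 * pAB * pAb                  # (2,1)
    probs[8] = pAB * pAB                      # (2,2)
    flat = counts.reshape(-1)  # row-major: (0,0),(0,1),(0,2),(1,0),...
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
    logp[np.isnan(logp)] = -np.inf
    loglik = np.where(flat[:, None] > 0, flat[:, None] * logp, 0.0).sum(axis=0)
    return float(np.nanmax(loglik))


def brute_merge(windows: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """O(n^2) merge of 1-based inclusive intervals; abutting intervals merge."""
    merged = [list(w) for w in windows]
    changed = True
    while changed:
        changed = False
        out = []
        while merged:
            cur = merged.pop()
            for other in merged:
                if cur[0] == other[0] and cur[1] <= other[2] + 1 and other[1] <= cur[2] + 1:
                    other[1] = min(other[1], cur[1])
                    other[2] = max(other[2], cur[2])
                    changed = True
                    break
            else:
                out.append(cur)
        merged = out
    return sorted((c, s, e) for c, s, e in merged)


def brute_assign(chrom: str, pos: int, regions) -> object:
    """Linear scan region assignment (inclusive bounds)."""
    for region in regions:
        if region.chrom == chrom and region.start <= pos <= region.end:
            return region
    return None


def info_formula(probs: np.ndarray) -> float:
    """Direct, loop-based evaluation of the ratio-of-variances INFO measure."""
    probs = np.asarray(probs, dtype=float)
    n = probs.shape[0]
    e = [p[1] + 2 * p[2] for p in probs]
    f = [p[1] + 4 * p[2] for p in probs]
    theta = sum(e) / (2 * n)
    if theta in (0.0, 1.0):
        return 1.0
    num = sum(fi - ei * ei for ei, fi in zip(e, f))
    return 1.0 - num / (2 * n * theta * (1 - theta))


def exhaustive_info_threshold(infos: list[float], beads: list[int], priority_beads: int, budget: int):
    """Try every candidate threshold (observed values plus 0) exhaustively."""
    grid = sorted(set([0.0] + list(infos)))
    best = None
    for t in grid:
        used = priority_beads + sum(b for i, b in zip(infos, beads) if i <= t)
        if used <= budget:
            best = t
    return best


def brute_coding_select(annotations, regions, manifest_keys, tri_allelic, thresholds,
                        min_cadd=30.0, regulome_ok=("1a", "1b", "1c", "1d", "1e")):
    """Predicate-by-predicate set evaluation of the coding/regulatory arm.

    ``manifest_keys`` is a set of (chrom, pos, frozenset(alleles)) triples.
    Returns the set of selected VariantKeys.
    """
    included_effects = {"nonsynonymous", "stopgain", "stoploss", "splicing"}
    selected = set()
    for ann in annotations:
        key = ann.key
        if brute_assign(key.chrom, key.pos, regions) is None:
            continue
        freq_ok = any(
            ann.freqs.get(pop) is not None and ann.freqs[pop] > th
            for pop, th in thresholds.items()
        )
        if not freq_ok:
            continue
        crit = (
            ann.effect_class.value in included_effects
            or (ann.cadd_phred is not None and ann.cadd_phred >= min_cadd)
            or (ann.regulome_category in regulome_ok)
        )
        if not crit:
            continue
        if (key.chrom, key.pos, frozenset({key.ref, key.alt})) in manifest_keys:
            continue
        if key in tri_allelic:
            continue
        selected.add(key)
    return selected


def sample_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r² as the literal squared Pearson correlation of two 0/1 vectors."""
    return float(np.corrcoef(hap_a, hap_b)[0, 1] ** 2)
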