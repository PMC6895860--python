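"""INFO scores from genotype probabilities and budget-driven pruning.

Computes imputation INFO (ratio-of-variances) for three variants from
per-sample genotype probability triples, then searches the threshold that
keeps the hard-to-impute tail within a two-bead budget.  Variants that
impute well (high INFO) are *excluded* from custom content — the base array
already recovers them for free.
"""

import numpy as np

from finemap_array import (
    BeadBudget,
    GenotypeProbabilityRecord,
    SelectionRecord,
    VariantKey,
    compute_info_score,
    find_info_threshold,
)
from finemap_array.pruning import with_bead_counts
from finemap_array.records import ARM_FINE_MAPPING

rng = np.random.default_rng(3)
records, infos = [], {}
for i, certainty in enumerate((1.0, 0.7, 0.55)):  # hard calls .. very fuzzy
    key = VariantKey("1", 1000 + i, "A", "G")
    probs = np.full((40, 3), (1 - certainty) / 2)
    probs[np.arange(40), rng.integers(0, 3, 40)] = certainty
    info = compute_info_score(GenotypeProbabilityRecord(key, probs / probs.sum(1, keepdims=True)))
    infos[key] = info.info
    records.append(SelectionRecord(key, ARM_FINE_MAPPING, ("status:NONE",)))
    print(f"variant {key}: INFO = {info.info:.3f}")

with_bead_counts(records)
threshold, retained = find_info_threshold(records, infos, priority_beads=0, budget=BeadBudget(2))
print(f"chosen INFO threshold  : {threshold:.3f}")
print(f"retained (info <= t)   : {[str(r.key) for r in retained]}")
# The two lowest-INFO variants fill the budget; the well-imputed variant is
# pruned because the base array can impute it.
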