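"""Classify replication outcomes and show the LD rule each one triggers.

Each index signal's Hispanic (AMR) and African American (AA) replication
summary statistics (effect sign relative to discovery, two-sided p) map to a
status class, which in turn decides which reference-panel pools a candidate
must be in LD with (r² >= 0.1) to be carried as fine-mapping content.
"""

from finemap_array import (
    IndexSignal,
    ReplicationRecord,
    VariantKey,
    classify_replication_status,
    ld_requirement,
)

cases = {
    "replicates in both samples": {"AMR": (1, 0.06), "AA": (1, 0.08)},
    "replicates in AMR only":     {"AMR": (1, 0.04), "AA": (1, 0.40)},
    "opposite direction in AA":   {"AMR": (1, 0.60), "AA": (-1, 0.09)},
    "replicates nowhere":         {"AMR": (1, 0.50), "AA": (1, 0.90)},
}

for label, stats in cases.items():
    signal = IndexSignal(
        VariantKey("1", 5_000_000, "A", "G"),
        replication={
            pop: ReplicationRecord(pop, sign, p) for pop, (sign, p) in stats.items()
        },
    )
    status = classify_replication_status(signal)
    rule = ld_requirement(status)
    pools = "+".join(sorted(rule.populations))
    print(f"{label:28s} -> status {status.cls.value:8s} "
          f"LD rule: r2 >= {rule.threshold} in {rule.combinator}({pools})")
# BOTH demands LD in every pool (the shared signal must tag the causal
# variant everywhere); OPPOSITE relaxes to ANY because diverging LD
# structure is the working explanation for the sign flip.
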