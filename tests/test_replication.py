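import numpy as np
import pytest

from finemap_array.ld import pairwise_r2
from finemap_array.records import (
    IndexSignal,
    Manifest,
    ManifestEntry,
    ReplicationRecord,
    VariantKey,
)
from finemap_array.regions import build_regions
from finemap_array.replication import (
    LDRequirement,
    ReplicationStatus,
    StatusClass,
    classify_replication_status,
    ld_requirement,
    one_sided_p,
    select_fine_mapping_variants,
)
from finemap_array.synthetic import gamete_frequencies
from conftest import make_panel

INDEX = VariantKey("1", 5_000_000, "A", "G")


def signal(amr=(None, None), aa=(None, None)):
    return IndexSignal(
        INDEX,
        discovery_direction=1,
        replication={
            "AMR": ReplicationRecord("AMR", amr[0], amr[1]),
            "AA": ReplicationRecord("AA", aa[0], aa[1]),
        },
    )


class TestOneSidedP:
    def test_same_direction_halves(self):
        assert one_sided_p(ReplicationRecord("AMR", 1, 0.04)) == pytest.approx(0.02)

    def test_opposite_direction_complements(self):
        assert one_sided_p(ReplicationRecord("AMR", -1, 0.04)) == pytest.approx(0.98)

    def test_null_boundary(self):
        assert one_sided_p(ReplicationRecord("AA", 1, 1.0)) == pytest.approx(0.5)
        assert one_sided_p(ReplicationRecord("AA", -1, 1.0)) == pytest.approx(0.5)

    def test_missing_fields_give_missing(self):
        assert one_sided_p(ReplicationRecord("AA", None, 0.04)) is None
        assert one_sided_p(ReplicationRecord("AA", 1, None)) is None


class TestClassification:
    def test_both(self):
        status = classify_replication_status(signal(amr=(1, 0.06), aa=(1, 0.08)))
        assert status == ReplicationStatus(StatusClass.BOTH)

    def test_one(self):
        status = classify_replication_status(signal(amr=(1, 0.04), aa=(1, 0.80)))
        assert status == ReplicationStatus(StatusClass.ONE, "AMR")

    def test_opposite(self):
        status = classify_replication_status(signal(amr=(1, 0.60), aa=(-1, 0.09)))
        assert status == ReplicationStatus(StatusClass.OPPOSITE, "AA")

    def test_none_and_missing_never_satisfies(self):
        assert classify_replication_status(signal()).cls is StatusClass.NONE
        assert classify_replication_status(signal(amr=(1, 0.5), aa=(1, 0.9))).cls is StatusClass.NONE
        # significant but opposite-direction never counts as replication
        assert classify_replication_status(signal(amr=(-1, 0.04), aa=(None, None))).cls is StatusClass.OPPOSITE

    def test_sign_alone_never_triggers_opposite(self):
        status = classify_replication_status(signal(amr=(-1, 0.5), aa=(1, 0.9)))
        assert status.cls is StatusClass.NONE

    def test_precedence_opposite_over_one(self):
        # AMR replicates; AA is significant-opposite: default order says OPPOSITE
        status = classify_replication_status(signal(amr=(1, 0.02), aa=(-1, 0.05)))
        assert status == ReplicationStatus(StatusClass.OPPOSITE, "AA")
        flipped = classify_replication_status(
            signal(amr=(1, 0.02), aa=(-1, 0.05)),
            precedence=(StatusClass.BOTH, StatusClass.ONE, StatusClass.OPPOSITE),
        )
        assert flipped == ReplicationStatus(StatusClass.ONE, "AMR")

    def test_truth_table_is_total(self):
        """Every (sign, p) configuration maps to exactly one status."""
        values = [(None, None), (1, 0.04), (1, 0.5), (-1, 0.04), (-1, 0.5), (1, 1.0)]
        for amr in values:
            for aa in values:
                status = classify_replication_status(signal(amr=amr, aa=aa))
                assert status.cls in StatusClass
                if status.cls in (StatusClass.ONE, StatusClass.OPPOSITE):
                    assert status.population in ("AMR", "AA")


class TestLdRequirement:
    def test_mapping(self):
        assert ld_requirement(ReplicationStatus(StatusClass.BOTH)) == LDRequirement(
            "ALL", frozenset({"NFE", "AMR", "AA"})
        )
        assert ld_requirement(ReplicationStatus(StatusClass.ONE, "AMR")) == LDRequirement(
            "ALL", frozenset({"NFE", "AMR"})
        )
        assert ld_requirement(ReplicationStatus(StatusClass.OPPOSITE, "AA")) == LDRequirement(
            "ANY", frozenset({"NFE", "AA"})
        )
        assert ld_requirement(ReplicationStatus(StatusClass.NONE)) == LDRequirement(
            "ALL", frozenset({"NFE"})
        )

    def test_nfe_always_required(self):
        with pytest.raises(Exception):
            LDRequirement("ALL", frozenset({"AMR"}))


def planted_panels(r2_by_pop, n_hap=2000, candidate=VariantKey("1", 5_100_000, "C", "T")):
    """Three pools where the candidate has an exact planted r² to the index."""
    panels = {}
    for pop, r2 in r2_by_pop.items():
        freqs = gamete_frequencies(0.5, 0.5, r2)
        a = np.zeros(n_hap, dtype=np.int8)
        a[: n_hap // 2] = 1
        b = np.zeros(n_hap, dtype=np.int8)
        ones, zeros = np.flatnonzero(a == 1), np.flatnonzero(a == 0)
        b[ones[: int(np.ceil(freqs[0] / 0.5 * ones.size))]] = 1
        b[zeros[: int(np.floor(freqs[2] / 0.5 * zeros.size))]] = 1
        panels[pop] = make_panel(pop, {INDEX: a, candidate: b})
    return panels


CANDIDATE = VariantKey("1", 5_100_000, "C", "T")


class TestSelectFineMapping:
    region = build_regions([IndexSignal(INDEX)])[0]

    def test_none_status_needs_only_nfe(self):
        panels = planted_panels({"NFE": 0.2, "AMR": 0.02, "AA": 0.02})
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.NONE),
        )
        assert CANDIDATE in {r.key for r in recs}

    def test_both_status_requires_every_pool(self):
        panels = planted_panels({"NFE": 0.5, "AMR": 0.5, "AA": 0.05})
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.BOTH),
        )
        assert CANDIDATE not in {r.key for r in recs}

    def test_opposite_status_any_pool_suffices(self):
        panels = planted_panels({"NFE": 0.5, "AMR": 0.5, "AA": 0.05})
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.OPPOSITE, "AA"),
        )
        assert CANDIDATE in {r.key for r in recs}

    def test_manifest_and_tri_allelic_removed(self):
        panels = planted_panels({"NFE": 0.5, "AMR": 0.5, "AA": 0.5})
        manifest = Manifest([ManifestEntry(CANDIDATE)])
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, manifest,
            status=ReplicationStatus(StatusClass.NONE),
        )
        assert CANDIDATE not in {r.key for r in recs}
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(), tri_allelic={CANDIDATE},
            status=ReplicationStatus(StatusClass.NONE),
        )
        assert CANDIDATE not in {r.key for r in recs}

    def test_index_absent_from_required_panel(self):
        panels = planted_panels({"NFE": 0.5, "AA": 0.5})
        panels["AMR"] = make_panel("AMR", {CANDIDATE: np.array([0, 1] * 100, dtype=np.int8)})
        under_all = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.ONE, "AMR"),
        )
        assert under_all == []  # ALL{NFE, AMR} unsatisfiable without the index in AMR
        under_any = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.OPPOSITE, "AMR"),
        )
        assert CANDIDATE in {r.key for r in under_any}  # NFE alone suffices

    def test_nesting_of_combinators(self):
        """ALL{NFE,AMR,AA} ⊆ ALL{NFE,pop} ⊆ ALL{NFE} ⊆ ANY{NFE,pop}."""
        rng = np.random.default_rng(12)
        candidates = {
            VariantKey("1", 5_000_000 + 10_000 * (i + 1), "C", "T"): {
                pop: float(rng.uniform(0, 0.4)) for pop in ("NFE", "AMR", "AA")
            }
            for i in range(8)
        }
        panels = {}
        n_hap = 1000
        for pop in ("NFE", "AMR", "AA"):
            a = np.zeros(n_hap, dtype=np.int8)
            a[: n_hap // 2] = 1
            cols = {INDEX: a}
            for key, targets in candidates.items():
                freqs = gamete_frequencies(0.5, 0.5, targets[pop])
                b = np.zeros(n_hap, dtype=np.int8)
                ones, zeros = np.flatnonzero(a == 1), np.flatnonzero(a == 0)
                b[ones[: int(round(freqs[0] / 0.5 * ones.size))]] = 1
                b[zeros[: int(round(freqs[2] / 0.5 * zeros.size))]] = 1
                cols[key] = b
            panels[pop] = make_panel(pop, cols)

        def select(status):
            return {
                r.key
                for r in select_fine_mapping_variants(
                    signal(), panels, self.region, Manifest(), status=status
                )
            }

        all_three = select(ReplicationStatus(StatusClass.BOTH))
        for pop in ("AMR", "AA"):
            all_two = select(ReplicationStatus(StatusClass.ONE, pop))
            nfe_only = select(ReplicationStatus(StatusClass.NONE))
            any_two = select(ReplicationStatus(StatusClass.OPPOSITE, pop))
            assert all_three <= all_two <= nfe_only <= any_two

    def test_provenance_records_status_and_pools(self):
        panels = planted_panels({"NFE": 0.5, "AMR": 0.5, "AA": 0.5})
        recs = select_fine_mapping_variants(
            signal(), panels, self.region, Manifest(),
            status=ReplicationStatus(StatusClass.BOTH),
        )
        rec = next(r for r in recs if r.key == CANDIDATE)
        assert "status:BOTH" in rec.criteria
        assert {"pool:NFE", "pool:AMR", "pool:AA"} <= set(rec.criteria)
        assert rec.signal_keys == (INDEX,)
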