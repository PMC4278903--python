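"""Germline subtraction, tumor/node partition, depth filter, catalogs."""

import random

import numpy as np
import pytest
from scipy.stats import poisson

from clonetriage.casestudy import cosmic_six_catalog, cosmic_six_trio
from clonetriage.io import CatalogSnapshot
from clonetriage.triage import (
    annotate_cosmic,
    annotate_known,
    compare_tumor_node,
    cosmic_report,
    count_known_novel,
    filter_min_depth,
    subtract_normal,
)
from clonetriage.variants import (
    CallStatus,
    ContractViolationError,
    SampleVariantSet,
)

from conftest import make_call, random_sample


@pytest.fixture
def case_partition():
    normal, tumor, node = cosmic_six_trio()
    return compare_tumor_node(
        subtract_normal(tumor, normal), subtract_normal(node, normal)
    )


class TestSubtractNormal:
    def test_set_difference(self):
        a, b, c = make_call(start=1), make_call(start=2), make_call(start=3)
        tumor = SampleVariantSet("t", "tumor", [a, b, c])
        normal = SampleVariantSet("n", "normal", [make_call(start=2)])
        out = subtract_normal(tumor, normal)
        assert out.keys() == {a.key, c.key}

    def test_empty_normal_is_identity(self, rng):
        tumor = random_sample(rng, "tumor", 25)
        out = subtract_normal(tumor, SampleVariantSet("n", "normal"))
        assert out.keys() == tumor.keys()

    def test_case_study_all_six_survive(self):
        normal, tumor, node = cosmic_six_trio()
        assert len(subtract_normal(tumor, normal)) == len(tumor)
        assert len(subtract_normal(node, normal)) == len(node)

    def test_role_contract(self, rng):
        tumor = random_sample(rng, "tumor", 3)
        with pytest.raises(ContractViolationError):
            subtract_normal(tumor, random_sample(rng, "node", 3))

    def test_normal_no_call_tagged_low_confidence(self):
        shared = make_call(start=7)
        normal_nc = make_call(start=7)
        normal_nc.call_status = CallStatus.NO_CALL
        tumor = SampleVariantSet("t", "tumor", [shared])
        normal = SampleVariantSet("n", "normal", [normal_nc])
        out = subtract_normal(tumor, normal)
        assert shared.key in out.keys()
        assert "low_confidence_somatic" in out.get(shared.key).catalog_ids

    def test_output_never_contains_normal_called_keys(self, rng):
        for _ in range(20):
            tumor = random_sample(rng, "tumor", rng.randint(0, 30))
            normal = random_sample(rng, "normal", rng.randint(0, 30))
            out = subtract_normal(tumor, normal)
            assert not (out.keys() & normal.called_keys())


class TestCompareTumorNode:
    def test_case_study_three_one_two(self, case_partition):
        p = case_partition
        assert p.counts() == {"shared": 2, "tumor_private": 3, "node_private": 1}
        genes = lambda bucket: {c.gene_hint for c in bucket.values()}
        assert genes(p.tumor_private) == {"MUC12", "FHOD1", "ZNF99"}
        assert genes(p.node_private) == {"PDS5B"}
        assert {t.gene_hint for t, _ in p.shared.values()} == {"ARAP3", "TP53"}

    def test_identical_inputs_all_shared(self, rng):
        t = random_sample(rng, "tumor", 15)
        n = SampleVariantSet("n", "node", list(t))
        p = compare_tumor_node(t, n)
        assert len(p.shared) == 15
        assert not p.tumor_private and not p.node_private

    def test_disjoint_inputs(self, rng):
        t = random_sample(rng, "tumor", 8)
        n = SampleVariantSet(
            "n", "node", [make_call("2", 50 + i) for i in range(5)]
        )
        p = compare_tumor_node(t, n)
        assert (len(p.tumor_private), len(p.node_private), len(p.shared)) == (8, 5, 0)

    def test_partition_property_fuzzed(self, rng):
        """|shared| + |tumor_private| + |node_private| == |union| always."""
        for _ in range(200):
            t = random_sample(rng, "tumor", rng.randint(0, 40))
            n = random_sample(rng, "node", rng.randint(0, 40))
            p = compare_tumor_node(t, n)
            assert sum(p.counts().values()) == len(t.keys() | n.keys())
            assert not (set(p.shared) & set(p.tumor_private))
            assert not (set(p.shared) & set(p.node_private))
            assert not (set(p.tumor_private) & set(p.node_private))

    def test_symmetry_up_to_private_swap(self, rng):
        t = random_sample(rng, "tumor", 20)
        n = random_sample(rng, "node", 20)
        p = compare_tumor_node(t, n)
        t2 = SampleVariantSet("t2", "tumor", list(n))
        n2 = SampleVariantSet("n2", "node", list(t))
        q = compare_tumor_node(t2, n2)
        assert set(p.shared) == set(q.shared)
        assert set(p.tumor_private) == set(q.node_private)
        assert set(p.node_private) == set(q.tumor_private)


class TestDepthFilter:
    def test_identity_at_zero(self, rng):
        s = random_sample(rng, "tumor", 20)
        assert filter_min_depth(s, 0).keys() == s.keys()

    def test_boundary_inclusive(self):
        calls = [
            make_call(start=i, depth=d, alt_reads=0)
            for i, d in enumerate([99, 100, 101])
        ]
        s = SampleVariantSet("t", "tumor", calls)
        kept = filter_min_depth(s, 100)
        assert len(kept) == 2
        assert {c.position_read_depth for c in kept} == {100, 101}

    def test_negative_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            filter_min_depth(random_sample(rng, "tumor", 2), -1)

    def test_partition_disjointness_preserved(self, rng):
        t = random_sample(rng, "tumor", 30)
        n = random_sample(rng, "node", 30)
        p = filter_min_depth(compare_tumor_node(t, n), 150)
        assert not (set(p.shared) & set(p.tumor_private))
        assert all(
            c.position_read_depth >= 150 for c in p.tumor_private.values()
        )

    def test_poisson_tail_retention(self):
        """With depth ~ Poisson(120), the ≥100 filter keeps the Poisson
        upper-tail fraction P(D ≥ 100), within binomial sampling error."""
        rng = np.random.default_rng(5)
        n = 4000
        depths = rng.poisson(120, size=n)
        calls = [
            make_call(start=10 + 2 * i, depth=int(d), alt_reads=0)
            for i, d in enumerate(depths)
        ]
        s = SampleVariantSet("t", "tumor", calls)
        frac = len(filter_min_depth(s, 100)) / n
        expected = poisson.sf(99, 120)
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < tol


class TestCatalogAnnotation:
    def test_empty_catalog_all_novel(self, case_partition):
        annotate_known(case_partition, CatalogSnapshot("dbSNP", {}))
        grid = count_known_novel(case_partition)
        assert (grid.xs("known", level="count") == 0).all().all()

    def test_catalog_of_shared_keys_marks_only_shared(self, case_partition):
        snap = CatalogSnapshot("dbSNP", {k: "rs1" for k in case_partition.shared})
        annotate_known(case_partition, snap)
        known = [k for k, v in case_partition.known_in_dbsnp.items() if v]
        assert set(known) == set(case_partition.shared)

    def test_grid_total_equals_known_plus_novel_fuzzed(self, rng):
        for _ in range(30):
            t = random_sample(rng, "tumor", rng.randint(1, 40))
            n = random_sample(rng, "node", rng.randint(1, 40))
            p = compare_tumor_node(t, n)
            some = random.Random(0).sample(
                sorted(p.all_keys), k=len(p.all_keys) // 2
            )
            annotate_known(p, CatalogSnapshot("dbSNP", {k: "rs" for k in some}))
            grid = count_known_novel(p)
            total = grid.xs("total", level="count").reset_index(drop=True)
            known = grid.xs("known", level="count").reset_index(drop=True)
            novel = grid.xs("novel", level="count").reset_index(drop=True)
            assert (total == known + novel).all().all()

    def test_cosmic_report_matches_case_study(self, case_partition):
        annotate_cosmic(case_partition, cosmic_six_catalog())
        df = cosmic_report(case_partition)
        assert len(df) == 6
        assert set(df.cosmic_id) == {
            "COSM32578", "COSM147730", "COSM85618",
            "COSM50200", "COSM10704", "COSM140394",
        }
        tp53 = df[df.cosmic_id == "COSM10704"].iloc[0]
        assert (tp53.tumor, tp53.node) == ("Yes", "Yes")
        pds5b = df[df.cosmic_id == "COSM85618"].iloc[0]
        assert (pds5b.tumor, pds5b.node) == ("No", "Yes")

    def test_no_overlap_empty_report(self, case_partition):
        annotate_cosmic(case_partition, CatalogSnapshot("COSMIC", {}))
        assert cosmic_report(case_partition).empty

    def test_report_rows_equal_cosmic_hits(self, case_partition, rng):
        keys = sorted(case_partition.all_keys)[:3]
        annotate_cosmic(
            case_partition, CatalogSnapshot("COSMIC", {k: "C" for k in keys})
        )
        assert len(cosmic_report(case_partition)) == 3
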