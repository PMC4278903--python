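"""Region assignment, functional impact, panel restriction, enrichment."""

import itertools
import math
import random
from math import comb

import pytest

from clonetriage.annotate import (
    DictReference,
    Impact,
    Region,
    assign_region,
    functional_impact,
    gene_set_enrichment,
    restrict_to_panel,
)
from clonetriage.casestudy import (
    case_gene_models,
    cosmic_six_trio,
    tgif2_discordant_pair,
)
from clonetriage.io import GeneModel, GenePanel
from clonetriage.triage import compare_tumor_node, subtract_normal
from clonetriage.variants import GenomicInterval

from conftest import make_call

# independent genetic-code oracle (sampled entries, not Bio.Seq)
CODON_ORACLE = {
    "ATG": "M", "ATA": "I", "TGG": "W", "TAG": "*", "TAA": "*",
    "AAA": "K", "AAG": "K", "GCT": "A", "GCC": "A", "CGA": "R",
    "TCA": "S", "TGA": "*", "GGG": "G", "TTT": "F",
}


def _gene(strand="+", chrom="1"):
    """span [1000,3000): UTR/CDS/intron/CDS/UTR, two 300 bp CDS exons."""
    cds = [GenomicInterval(chrom, 1200, 1500), GenomicInterval(chrom, 2200, 2500)]
    low = GenomicInterval(chrom, 1000, 1200)
    high = GenomicInterval(chrom, 2500, 3000)
    return GeneModel(
        gene_symbol="G",
        chrom=chrom,
        strand=strand,
        gene_span=GenomicInterval(chrom, 1000, 3000),
        cds_intervals=cds,
        utr5_intervals=[low if strand == "+" else high],
        utr3_intervals=[high if strand == "+" else low],
    )


class TestAssignRegion:
    def test_upstream_plus_strand(self):
        ra = assign_region(make_call(start=500), _gene("+"), upstream_window=2000)
        assert ra.region is Region.UPSTREAM_TSS
        assert ra.distance_to_tss == -500

    def test_upstream_minus_strand_mirrored(self):
        # upstream of a minus-strand gene lies at larger coordinates
        ra = assign_region(make_call(start=3499), _gene("-"), upstream_window=2000)
        assert ra.region is Region.UPSTREAM_TSS
        assert ra.distance_to_tss == -500

    def test_beyond_window_no_upstream(self):
        ra = assign_region(make_call(start=500), _gene("+"), upstream_window=100,
                           flank_window=100)
        assert ra is None

    def test_cds_beats_intron(self):
        assert assign_region(make_call(start=1300), _gene("+")).region is Region.CDS

    def test_intron_interior(self):
        assert assign_region(make_call(start=1800), _gene("+")).region is Region.INTRON

    def test_utr3_insertion(self):
        # a single-base insertion strictly inside the 3'UTR is a UTR3 call
        # (the TGIF2 pattern)
        ra = assign_region(make_call(start=2700, ref="", alt="A"), _gene("+"))
        assert ra.region is Region.UTR3

    def test_splice_donor_acceptor_plus(self):
        g = _gene("+")  # intron [1500, 2200)
        assert assign_region(make_call(start=1500), g).region is Region.SPLICE_DONOR
        assert assign_region(make_call(start=1501), g).region is Region.SPLICE_DONOR
        assert assign_region(make_call(start=2199), g).region is Region.SPLICE_ACCEPTOR
        assert assign_region(make_call(start=2198), g).region is Region.SPLICE_ACCEPTOR
        assert assign_region(make_call(start=1502), g).region is Region.INTRON

    def test_splice_sites_flip_with_strand(self):
        g = _gene("-")
        assert assign_region(make_call(start=1500), g).region is Region.SPLICE_ACCEPTOR
        assert assign_region(make_call(start=2199), g).region is Region.SPLICE_DONOR

    def test_other_chromosome_no_assignment(self):
        assert assign_region(make_call(chrom="9", start=1300), _gene("+")) is None

    def test_downstream_and_flank(self):
        assert assign_region(make_call(start=3200), _gene("+")).region is Region.DOWNSTREAM
        assert assign_region(make_call(start=3200), _gene("-")).region is Region.UPSTREAM_TSS

    def test_strand_mirror_property(self):
        """Reflecting all coordinates and flipping strand leaves the region
        label unchanged."""
        L = 10_000  # reflection pivot
        g_plus = _gene("+")

        def reflect_iv(iv):
            return GenomicInterval(iv.chrom, L - iv.end, L - iv.start)

        g_minus = GeneModel(
            gene_symbol="G",
            chrom="1",
            strand="-",
            gene_span=reflect_iv(g_plus.gene_span),
            cds_intervals=[reflect_iv(iv) for iv in g_plus.cds_intervals],
            utr5_intervals=[reflect_iv(iv) for iv in g_plus.utr5_intervals],
            utr3_intervals=[reflect_iv(iv) for iv in g_plus.utr3_intervals],
        )
        rng = random.Random(2)
        for _ in range(300):
            pos = rng.randrange(0, 6000)
            ra1 = assign_region(make_call(start=pos), g_plus)
            # reflect the SNV: position p maps to L-1-p
            ra2 = assign_region(make_call(start=L - 1 - pos), g_minus)
            r1 = ra1.region if ra1 else None
            r2 = ra2.region if ra2 else None
            assert r1 == r2, f"pos {pos}: {r1} vs {r2}"


def _reference_for(gene, seq_override=None):
    rng = random.Random(7)
    seq = list("".join(rng.choice("ACGT") for _ in range(4000)))
    if seq_override:
        for pos, b in seq_override.items():
            seq[pos] = b
    return DictReference({"1": "".join(seq)})


class TestFunctionalImpact:
    def test_one_base_coding_insertion_is_frameshift(self):
        # the PDS5B pattern: a 1-bp insertion in a CDS shifts the frame
        g = _gene("+")
        ref = _reference_for(g)
        call = make_call(start=1300, ref="", alt="A")
        assert functional_impact(call, g, ref).impact is Impact.FRAMESHIFT

    def test_three_base_insertion_inframe(self):
        g = _gene("+")
        ref = _reference_for(g)
        call = make_call(start=1300, ref="", alt="ACT")
        assert functional_impact(call, g, ref).impact is Impact.INFRAME_INDEL

    def test_frameshift_iff_net_length_not_multiple_of_three(self):
        g = _gene("+")
        ref = _reference_for(g)
        rng = random.Random(3)
        for _ in range(200):
            pos = rng.randrange(1210, 1480)
            k = rng.randint(1, 6)
            if rng.random() < 0.5:
                call_ref, call_alt = "", "".join(rng.choice("ACGT") for _ in range(k))
            else:
                call_ref, call_alt = ref.fetch("1", pos, pos + k), ""
            if not call_ref and not call_alt:
                continue
            try:
                call = make_call(start=pos, ref=call_ref, alt=call_alt)
            except ValueError:
                continue
            impact = functional_impact(call, g, ref).impact
            net = len(call_alt) - len(call_ref)
            region = assign_region(call, g).region
            if region in (Region.SPLICE_DONOR, Region.SPLICE_ACCEPTOR):
                assert impact is Impact.SPLICE_SITE
            elif region is Region.CDS:
                assert (impact is Impact.FRAMESHIFT) == (net % 3 != 0)
            else:
                assert impact is Impact.NONCODING

    @pytest.mark.parametrize(
        "codon,pos_in_codon,alt,expected",
        [
            ("ATG", 2, "A", Impact.MISSENSE),    # ATG→ATA  M→I
            ("AAA", 2, "G", Impact.SYNONYMOUS),  # AAA→AAG  K→K
            ("TGG", 1, "A", Impact.NONSENSE),    # TGG→TAG  W→*
            ("TCA", 1, "G", Impact.NONSENSE),    # TCA→TGA  S→*
        ],
    )
    def test_snv_consequences_against_codon_oracle(
        self, codon, pos_in_codon, alt, expected
    ):
        g = _gene("+")
        # place the codon at the start of the first CDS exon
        override = {1200 + i: b for i, b in enumerate(codon)}
        ref = _reference_for(g, override)
        call = make_call(
            start=1200 + pos_in_codon, ref=codon[pos_in_codon], alt=alt
        )
        got = functional_impact(call, g, ref)
        assert got.impact is expected
        mutated = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
        aa_b, aa_a = CODON_ORACLE[codon], CODON_ORACLE[mutated]
        assert (aa_a == aa_b) == (expected is Impact.SYNONYMOUS)
        assert (aa_a == "*") == (expected is Impact.NONSENSE)

    def test_minus_strand_codon_read_on_reverse_complement(self):
        g = _gene("-")
        # minus strand: last codon of the transcript CDS is the revcomp of
        # the first genomic bases.  Put CAT at 1200..1203 → transcript ...ATG
        override = {1200: "C", 1201: "A", 1202: "T"}
        ref = _reference_for(g, override)
        # genomic T>C at 1202 reads A>G on the transcript: ATG codon's A
        call = make_call(start=1202, ref="T", alt="C")
        got = functional_impact(call, g, ref)
        assert got.impact in (Impact.MISSENSE, Impact.NONSENSE, Impact.SYNONYMOUS)
        # independent check: codon ATG (M) mutated at first position to GTG (V)
        assert got.impact is Impact.MISSENSE

    def test_reference_mismatch_raises(self):
        from clonetriage.variants import ReferenceInconsistencyError

        g = _gene("+")
        ref = _reference_for(g, {1300: "A"})
        call = make_call(start=1300, ref="C", alt="T")
        with pytest.raises(ReferenceInconsistencyError):
            functional_impact(call, g, ref)


class TestPanelRestriction:
    def _case_partition(self):
        normal, tumor, node = cosmic_six_trio()
        return compare_tumor_node(
            subtract_normal(tumor, normal), subtract_normal(node, normal)
        )

    def test_tp53_only_panel_keeps_tp53_shared_key(self):
        p = self._case_partition()
        restricted, assignments = restrict_to_panel(
            p, GenePanel("one", {"TP53"}), case_gene_models()
        )
        assert len(restricted.shared) == 1
        (key,) = restricted.shared
        assert key.chrom == "17"
        assert not restricted.tumor_private and not restricted.node_private
        assert assignments[key][0].gene_symbol == "TP53"

    def test_panel_without_fixture_genes_empty(self):
        p = self._case_partition()
        restricted, _ = restrict_to_panel(
            p, GenePanel("none", {"BRCA1"}), case_gene_models()
        )
        assert not restricted.all_keys

    def test_empty_panel_rejected(self):
        p = self._case_partition()
        with pytest.warns(UserWarning):
            empty = GenePanel("empty", set())
        with pytest.raises(ValueError):
            restrict_to_panel(p, empty, case_gene_models())

    def test_upstream_window_monotonicity(self):
        """Enlarging the upstream window can only grow the retained set."""
        node, gene, panel = tgif2_discordant_pair()
        from clonetriage.variants import SampleVariantSet

        p = compare_tumor_node(
            SampleVariantSet("t", "tumor"), node
        )
        sizes = []
        for w in (0, 50, 100, 200, 500, 1000):
            restricted, _ = restrict_to_panel(
                p, panel, [gene], upstream_window=w, flank_window=0
            )
            sizes.append(len(restricted.all_keys))
        assert sizes == sorted(sizes)
        assert sizes[0] == 1  # the 3'UTR insertion needs no window
        assert sizes[-1] == 2  # the upstream insertion needs the promoter window


def brute_force_hypergeom(M, n, N, k):
    """P(overlap ≥ k) by exhaustive enumeration over all C(M, N) draws."""
    total = comb(M, N)
    favorable = sum(
        comb(n, j) * comb(M - n, N - j)
        for j in range(k, min(n, N) + 1)
    )
    return favorable / total


class TestEnrichment:
    def test_term_equal_to_query_near_minimal_p(self):
        bg = {f"g{i}" for i in range(200)}
        query = {f"g{i}" for i in range(5)}
        df = gene_set_enrichment(query, bg, {"T": set(query)})
        assert df.overlap.iloc[0] == 5
        assert df.p_raw.iloc[0] < 1e-9

    def test_disjoint_term_p_one(self):
        bg = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(5)}
        df = gene_set_enrichment(query, bg, {"T": {f"g{i}" for i in range(20, 28)}})
        assert df.p_raw.iloc[0] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"x"}, {"a", "b"}, {"T": {"a"}})

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric tail equals brute-force draw enumeration for every
        configuration with background ≤ 20."""
        bg = [f"g{i}" for i in range(20)]
        rng = random.Random(4)
        for M in (5, 10, 20):
            background = set(bg[:M])
            for N in (1, 3, 5):
                if N > M:
                    continue
                for n in (1, M // 2, M):
                    query = set(rng.sample(sorted(background), N))
                    term = set(rng.sample(sorted(background), n))
                    df = gene_set_enrichment(query, background, {"T": term})
                    k = len(term & query)
                    expected = brute_force_hypergeom(M, n, N, k)
                    assert df.p_raw.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_ordering(self):
        bg = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        terms = {
            "hit": {f"g{i}" for i in range(10)},
            "partial": {f"g{i}" for i in range(5, 25)},
            "miss": {f"g{i}" for i in range(50, 70)},
        }
        df = gene_set_enrichment(query, bg, terms)
        assert (df.p_bh >= df.p_raw - 1e-15).all()
        assert list(df.term) == list(df.sort_values("p_raw", kind="stable").term)
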