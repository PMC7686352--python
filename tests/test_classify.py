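import numpy as np
import pandas as pd
import pytest

from lncforge.annotation import Catalogue, Gene, GenomicInterval, Transcript
from lncforge.classify import (
    classification_frame,
    classify_genes,
    classify_transcript_pair,
    distance_bin,
    find_closest_pcg,
    find_hosts,
    gene_level_classification,
    pair_distance,
)
from lncforge.simulate import (
    SimulationConfig,
    make_hosted_small_rnas,
    make_pairs,
)

from conftest import make_gene


def tx(gid, chrom, start, end, strand, exons=None):
    if exons is None:
        exons = [(start, end)]
    return Transcript(f"{gid}.t1", gid,
                      [GenomicInterval(chrom, s, e, strand) for s, e in exons])


class TestPairDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((5_000, 8_000), (10_000, 12_000), 1_999),  # strictly-between count
            ((100, 200), (201, 300), 0),  # bookended
            ((100, 300), (200, 400), 0),  # overlapping
        ],
    )
    def test_examples(self, a, b, expected):
        ia = GenomicInterval("chr1", *a, "+")
        ib = GenomicInterval("chr1", *b, "+")
        assert pair_distance(ia, ib) == expected
        assert pair_distance(ib, ia) == expected

    def test_different_chromosomes_raise(self):
        with pytest.raises(ValueError):
            pair_distance(GenomicInterval("chr1", 1, 10), GenomicInterval("chr2", 1, 10))


class TestDistanceBin:
    @pytest.mark.parametrize(
        "d, expected",
        [(0, "<=1kb"), (1_000, "<=1kb"), (1_001, "<=5kb"),
         (5_000, "<=5kb"), (5_001, ">5kb")],
    )
    def test_boundaries_inclusive_on_small_side(self, d, expected):
        assert distance_bin(d) == expected


class TestTranscriptPair:
    @pytest.mark.parametrize(
        "lnc_strand, pcg_strand, expected_direction",
        [
            # LNC left at 5000-8000, PCG right at 10000-12000
            ("-", "+", "divergent"),   # 5'-to-5' across the gap
            ("+", "-", "convergent"),  # 3'-to-3'
            ("+", "+", "same_strand"),
            ("-", "-", "same_strand"),
        ],
    )
    def test_intergenic_orientation(self, lnc_strand, pcg_strand, expected_direction):
        c = classify_transcript_pair(
            tx("L", "chr1", 5_000, 8_000, lnc_strand),
            tx("P", "chr1", 10_000, 12_000, pcg_strand),
        )
        assert c.ptype == "intergenic"
        assert c.direction == expected_direction
        assert c.distance_bp == 1_999 and c.distance_class == "<=5kb"

    def test_orientation_truth_table_both_sides(self):
        # full enumeration: LNC on either side of the PCG, every strand combo
        for lnc_left in (True, False):
            lspan = (5_000, 8_000) if lnc_left else (15_000, 18_000)
            for ls in "+-":
                for ps in "+-":
                    c = classify_transcript_pair(
                        tx("L", "chr1", *lspan, ls),
                        tx("P", "chr1", 10_000, 12_000, ps),
                    )
                    if ls == ps:
                        expected = "same_strand"
                    else:
                        left_strand = ls if lnc_left else ps
                        expected = "divergent" if left_strand == "-" else "convergent"
                    assert c.direction == expected
                    expected_loc = ("upstream" if lnc_left == (ps == "+")
                                    else "downstream")
                    assert c.location == expected_loc

    def test_genic_nested_intronic_antisense(self):
        pcg = Transcript("P.t1", "P", [
            GenomicInterval("chr1", 10_000, 10_200, "+"),
            GenomicInterval("chr1", 11_500, 12_000, "+"),
        ])
        lnc = tx("L", "chr1", 10_500, 10_800, "-")
        c = classify_transcript_pair(lnc, pcg)
        assert (c.ptype, c.direction, c.subtype, c.location) == (
            "genic", "antisense", "nested", "intronic")
        assert c.distance_bp == 0

    def test_genic_containing_and_overlapping(self):
        pcg = tx("P", "chr1", 10_000, 12_000, "+")
        containing = classify_transcript_pair(tx("L", "chr1", 9_000, 13_000, "+"), pcg)
        assert (containing.subtype, containing.direction) == ("containing", "sense")
        partial = classify_transcript_pair(tx("L", "chr1", 9_000, 10_500, "+"), pcg)
        assert partial.subtype == "overlapping"
        assert partial.location == "exonic"

    def test_unstranded_transcript_rejected(self):
        with pytest.raises(ValueError, match="unstranded"):
            classify_transcript_pair(tx("L", "chr1", 1, 10, "."),
                                     tx("P", "chr1", 100, 200, "+"))

    def test_reflection_with_strand_flip_is_invariant(self):
        # reflecting every coordinate and flipping every strand views the
        # locus from the other DNA strand: the classification cannot change
        rng = np.random.default_rng(42)
        L = 1_000_000
        flip = {"+": "-", "-": "+"}
        for _ in range(200):
            s1 = int(rng.integers(1, L - 20_000))
            e1 = s1 + int(rng.integers(100, 5_000))
            s2 = int(rng.integers(1, L - 20_000))
            e2 = s2 + int(rng.integers(100, 5_000))
            st1, st2 = rng.choice(["+", "-"], size=2)
            a = tx("L", "chr1", s1, e1, st1)
            b = tx("P", "chr1", s2, e2, st2)
            ra = tx("L", "chr1", L + 1 - e1, L + 1 - s1, flip[st1])
            rb = tx("P", "chr1", L + 1 - e2, L + 1 - s2, flip[st2])
            c, rc = classify_transcript_pair(a, b), classify_transcript_pair(ra, rb)
            assert (c.ptype, c.direction, c.subtype, c.location, c.distance_bp) == \
                   (rc.ptype, rc.direction, rc.subtype, rc.location, rc.distance_bp)


class TestClosestPcg:
    def test_no_pcg_in_window_is_unclassified(self):
        lnc = make_gene("L1", "contig7", 1_000, 2_000, "+")
        pcgs = Catalogue([make_gene("P1", "chr1", 1_000, 2_000, "+",
                                    biotype="protein_coding")])
        assert find_closest_pcg(lnc, pcgs) == []
        (rec,) = classify_genes(Catalogue([lnc]), pcgs)
        assert rec.ptype == "unclassified" and rec.pcg_gene_id is None

    def test_beyond_window_is_unclassified(self):
        lnc = make_gene("L1", "chr1", 1_000, 2_000, "+")
        pcgs = Catalogue([make_gene("P1", "chr1", 300_000, 302_000, "+",
                                    biotype="protein_coding")])
        assert find_closest_pcg(lnc, pcgs, window_bp=100_000) == []

    def test_closest_candidate_selected(self):
        lnc = make_gene("L1", "chr1", 10_000, 12_000, "+")
        pcgs = Catalogue([
            make_gene("P_far", "chr1", 14_001, 15_000, "+", biotype="protein_coding"),
            make_gene("P_near", "chr1", 12_501, 13_000, "+", biotype="protein_coding"),
        ])
        (call,) = find_closest_pcg(lnc, pcgs)
        assert call.pcg_gene_id == "P_near" and call.distance_bp == 500

    def test_tie_prefers_upstream_candidate(self):
        # equal 500 bp gaps on both sides of a "+" LNC: upstream (left) wins
        lnc = make_gene("L1", "chr1", 10_000, 12_000, "+")
        pcgs = Catalogue([
            make_gene("P_down", "chr1", 12_501, 13_500, "+", biotype="protein_coding"),
            make_gene("P_up", "chr1", 8_500, 9_499, "+", biotype="protein_coding"),
        ])
        (call,) = find_closest_pcg(lnc, pcgs)
        assert call.pcg_gene_id == "P_up"

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(99)
        pcg_genes = []
        for i in range(40):
            s = int(rng.integers(1, 2_000_000))
            pcg_genes.append(make_gene(f"P{i:02d}", "chr1", s, s + int(rng.integers(200, 3_000)),
                                       str(rng.choice(["+", "-"])), biotype="protein_coding"))
        pcgs = Catalogue(pcg_genes)
        for j in range(20):
            s = int(rng.integers(1, 2_000_000))
            lnc = make_gene(f"L{j}", "chr1", s, s + 1_000, str(rng.choice(["+", "-"])))
            calls = find_closest_pcg(lnc, pcgs, window_bp=100_000)
            gaps = []
            for p in pcg_genes:
                lo = max(lnc.span.start, p.span.start)
                hi = min(lnc.span.end, p.span.end)
                gaps.append(0 if lo <= hi else (max(lnc.span.start, p.span.start)
                                                - min(lnc.span.end, p.span.end) - 1))
            best = min(gaps)
            if best > 100_000:
                assert calls == []
            else:
                assert calls[0].distance_bp == best


class TestGeneLevel:
    def base_call(self, **kw):
        from lncforge.classify import PairClassification
        defaults = dict(lnc_gene_id="L", pcg_gene_id="P", ptype="intergenic",
                        direction="divergent", subtype=None, location="upstream",
                        distance_bp=100, distance_class="<=1kb")
        defaults.update(kw)
        return PairClassification(**defaults)

    def test_agreeing_transcripts_no_conflict(self):
        calls = [self.base_call(distance_bp=200), self.base_call(distance_bp=100)]
        g = gene_level_classification(calls)
        assert g.conflict is False and g.distance_bp == 100

    def test_genic_beats_intergenic_with_conflict(self):
        calls = [
            self.base_call(),
            self.base_call(ptype="genic", direction="antisense",
                           subtype="nested", location="intronic", distance_bp=0),
        ]
        g = gene_level_classification(calls)
        assert g.ptype == "genic" and g.conflict is True

    def test_different_partners_choose_closer(self):
        calls = [self.base_call(pcg_gene_id="P1", distance_bp=500),
                 self.base_call(pcg_gene_id="P2", distance_bp=200)]
        g = gene_level_classification(calls)
        assert g.pcg_gene_id == "P2" and g.conflict is True

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            gene_level_classification([])


class TestPlantedConfigurations:
    def test_all_planted_labels_recovered(self, sim_config):
        lncs, pcgs, truth = make_pairs(sim_config)
        df = classification_frame(classify_genes(lncs, pcgs)).set_index("lnc_gene_id")
        assert len(df) == len(truth.pairs)  # one record per LNC gene
        for rec in truth.pairs:
            row = df.loc[rec["lnc_gene_id"]]
            for key in ("pcg_gene_id", "ptype", "direction", "subtype",
                        "location", "distance_bp", "distance_class"):
                got = row[key]
                want = rec[key]
                assert (want is None and pd.isna(got)) or got == want, (
                    rec["lnc_gene_id"], key, got, want)
            assert not row["conflict"]


class TestHosts:
    def host_lnc(self):
        return Gene("L1", "lncRNA", "t", [Transcript("L1.t1", "L1", [
            GenomicInterval("chr1", 5_000, 5_500, "+"),
            GenomicInterval("chr1", 7_500, 8_000, "+"),
        ])])

    @pytest.mark.parametrize("strand, relation", [("+", "sense"), ("-", "antisense")])
    def test_intronic_host(self, strand, relation):
        mir = make_gene("M1", "chr1", 6_000, 6_080, strand, biotype="miRNA")
        (rel,) = find_hosts(Catalogue([mir]), Catalogue([self.host_lnc()]))
        assert (rel.strand_relation, rel.location) == (relation, "intronic")

    def test_exonic_host(self):
        mir = make_gene("M1", "chr1", 5_100, 5_180, "+", biotype="miRNA")
        (rel,) = find_hosts(Catalogue([mir]), Catalogue([self.host_lnc()]))
        assert rel.location == "exonic"

    def test_straddling_small_rna_is_not_hosted(self):
        mir = make_gene("M1", "chr1", 7_900, 8_100, "+", biotype="miRNA")
        assert find_hosts(Catalogue([mir]), Catalogue([self.host_lnc()])) == []

    def test_non_small_rna_biotypes_ignored(self):
        pcg = make_gene("P1", "chr1", 6_000, 6_080, "+", biotype="protein_coding")
        assert find_hosts(Catalogue([pcg]), Catalogue([self.host_lnc()])) == []

    def test_planted_hosts_recovered(self, sim_config):
        lncs, smalls, truth = make_hosted_small_rnas(sim_config)
        rels = find_hosts(smalls, lncs)
        got = {(r.host_lnc_id, r.small_rna_id, r.strand_relation, r.location)
               for r in rels}
        want = {(h["host_lnc_id"], h["small_rna_id"], h["strand_relation"],
                 h["location"]) for h in truth.hosts}
        assert got == want  # and the straddling decoy is absent
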