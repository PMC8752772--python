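"""Overlap counting, dosage filtering, schema-driven annotation and tiling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvimpact.annotation import (
    AnnotationSchema,
    CNVRecord,
    CnvType,
    ConfigurationError,
    ElementCatalog,
    GenomicInterval,
    LOSS_ATTRIBUTES,
    GAIN_ATTRIBUTES,
    ValidationError,
    annotate_cnv,
    count_overlapping_elements,
    filter_dosage_sensitive,
    tile_genome,
)


def brute_force_count(query, track):
    """O(n*m) oracle: literal definition of any-overlap counting."""
    return sum(
        1
        for el in track
        if el.chrom == query.chrom and el.start < query.end and query.start < el.end
    )


class TestCountOverlaps:
    def test_empty_track(self):
        assert count_overlapping_elements(GenomicInterval("chr1", 100, 200), []) == 0

    def test_containment_and_wrong_chromosome(self):
        q = GenomicInterval("chr1", 100, 200)
        assert count_overlapping_elements(q, [GenomicInterval("chr1", 150, 160)]) == 1
        assert count_overlapping_elements(q, [GenomicInterval("chr2", 150, 160)]) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_intervals(self, seed):
        """Indexed counting equals all-pairs checking on a 10-Mbp chromosome."""
        rng = np.random.default_rng(seed)

        def random_intervals(n, max_len):
            starts = rng.integers(0, 10_000_000, size=n)
            lengths = rng.integers(1, max_len, size=n)
            chroms = rng.choice(["chr1", "chr2"], size=n)
            return [
                GenomicInterval(c, int(s), int(s + l))
                for c, s, l in zip(chroms, starts, lengths)
            ]

        queries = random_intervals(200, 100_000)
        track = random_intervals(500, 20_000)
        for q in queries:
            assert count_overlapping_elements(q, track) == brute_force_count(q, track)

    def test_one_base_overlap_and_adjacency(self):
        q = GenomicInterval("chr1", 100, 200)
        assert count_overlapping_elements(q, [GenomicInterval("chr1", 199, 300)]) == 1
        # half-open: element starting exactly at query end does not overlap
        assert count_overlapping_elements(q, [GenomicInterval("chr1", 200, 300)]) == 0
        assert count_overlapping_elements(q, [GenomicInterval("chr1", 50, 100)]) == 0

    @given(
        shift=st.integers(min_value=0, max_value=10_000),
        qs=st.integers(min_value=0, max_value=1000),
        ql=st.integers(min_value=1, max_value=500),
        es=st.integers(min_value=0, max_value=1000),
        el=st.integers(min_value=1, max_value=500),
    )
    def test_symmetry_and_shift_invariance(self, shift, qs, ql, es, el):
        q = GenomicInterval("chr1", qs, qs + ql)
        e = GenomicInterval("chr1", es, es + el)
        n = count_overlapping_elements(q, [e])
        assert n == count_overlapping_elements(e, [q])
        q2 = GenomicInterval("chr1", qs + shift, qs + ql + shift)
        e2 = GenomicInterval("chr1", es + shift, es + el + shift)
        assert count_overlapping_elements(q2, [e2]) == n

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError, match="chr1:200-100"):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -5, 10)


class TestDosageFilter:
    def test_equality_filter(self):
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(5)]
        kept = filter_dosage_sensitive(ivs, [3, 2, 3, 1, 40], required_score=3)
        assert kept == [ivs[0], ivs[2]]

    def test_all_matching_is_identity(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        assert filter_dosage_sensitive(ivs, [3, 3]) == ivs

    def test_missing_score_is_an_error(self):
        ivs = [GenomicInterval("chr1", 0, 10)]
        with pytest.raises(ValidationError):
            filter_dosage_sensitive(ivs, [None])
        with pytest.raises(ValidationError):
            filter_dosage_sensitive(ivs, None)

    def test_matches_predicate_filter(self):
        rng = np.random.default_rng(0)
        ivs = [GenomicInterval("chr1", i, i + 1) for i in range(50)]
        scores = rng.integers(0, 5, size=50).tolist()
        expected = [iv for iv, s in zip(ivs, scores) if s == 3]
        assert filter_dosage_sensitive(ivs, scores) == expected


def _full_catalog(fill=()):
    """Catalog covering the whole vocabulary; `fill` maps category -> intervals."""
    catalog = ElementCatalog()
    fill = dict(fill)
    for name in set(LOSS_ATTRIBUTES) | set(GAIN_ATTRIBUTES):
        catalog.add_track(name, fill.get(name, []))
    return catalog


class TestAnnotateCnv:
    def test_schema_attribute_lists(self):
        assert len(LOSS_ATTRIBUTES) == 19
        assert len(GAIN_ATTRIBUTES) == 18
        assert "haploinsufficient_genes" in LOSS_ATTRIBUTES
        assert "haploinsufficient_genes" not in GAIN_ATTRIBUTES
        assert "triplosensitive_regions" in GAIN_ATTRIBUTES
        assert "triplosensitive_regions" not in LOSS_ATTRIBUTES

    def test_cnv_overlapping_nothing_gives_zero_vector(self):
        cnv = CNVRecord(GenomicInterval("chr9", 0, 1000), CnvType.LOSS)
        fv = annotate_cnv(cnv, _full_catalog())
        assert len(fv.counts) == 19
        assert (fv.counts == 0).all()

    def test_hand_built_toy_catalog(self):
        """2 protein-coding genes, 1 morbid gene, 3 enhancers under the CNV."""
        catalog = _full_catalog(
            {
                "protein_coding_genes": [
                    GenomicInterval("chr1", 1_000, 5_000),
                    GenomicInterval("chr1", 8_000, 12_000),
                    GenomicInterval("chr1", 50_000, 60_000),  # outside
                ],
                "morbid_genes": [GenomicInterval("chr1", 9_000, 9_500)],
                "enhancers": [
                    GenomicInterval("chr1", 2_000, 2_100),
                    GenomicInterval("chr1", 3_000, 3_100),
                    GenomicInterval("chr1", 9_999, 20_000),
                ],
            }
        )
        cnv = CNVRecord(GenomicInterval("chr1", 0, 10_000), CnvType.LOSS)
        fv = annotate_cnv(cnv, catalog).as_dict()
        assert fv["protein_coding_genes"] == 2
        assert fv["morbid_genes"] == 1
        assert fv["enhancers"] == 3
        assert sum(fv.values()) == 6

    def test_gain_and_loss_schema_lengths_on_same_coordinates(self):
        catalog = _full_catalog()
        iv = GenomicInterval("chr1", 0, 10_000)
        loss = annotate_cnv(CNVRecord(iv, CnvType.LOSS), catalog)
        gain = annotate_cnv(CNVRecord(iv, CnvType.GAIN), catalog)
        assert len(loss.counts) == 19
        assert len(gain.counts) == 18

    def test_missing_category_lists_names(self):
        catalog = ElementCatalog()
        catalog.add_track("enhancers", [])
        cnv = CNVRecord(GenomicInterval("chr1", 0, 1000), CnvType.LOSS)
        with pytest.raises(ConfigurationError, match="protein_coding_genes"):
            annotate_cnv(cnv, catalog)

    def test_whole_chromosome_cnv_counts_everything(self, toy_genome):
        chrom = "chr1"
        cnv = CNVRecord(
            GenomicInterval(chrom, 0, 10_000_000), CnvType.LOSS
        )
        fv = annotate_cnv(cnv, toy_genome.catalog).as_dict()
        schema = AnnotationSchema.for_type(CnvType.LOSS)
        for name in schema.attribute_names:
            on_chrom = sum(
                1 for el in toy_genome.catalog.tracks[name] if el.chrom == chrom
            )
            assert fv[name] == on_chrom

    def test_unknown_category_ignored_with_warning(self, caplog):
        catalog = ElementCatalog()
        with caplog.at_level("WARNING"):
            catalog.add_track("exotic_track", [GenomicInterval("chr1", 0, 10)])
        assert "exotic_track" not in catalog.tracks
        assert "exotic_track" in caplog.text


class TestTileGenome:
    def test_partial_trailing_tile(self):
        pairs = tile_genome({"chr1": 2_500_000}, 1_000_000)
        intervals = [p[0].interval for p in pairs]
        assert [(iv.start, iv.end) for iv in intervals] == [
            (0, 1_000_000),
            (1_000_000, 2_000_000),
            (2_000_000, 2_500_000),
        ]

    def test_chromosome_shorter_than_tile(self):
        pairs = tile_genome({"chrM": 16_569}, 1_000_000)
        assert len(pairs) == 1
        assert pairs[0][0].interval == GenomicInterval("chrM", 0, 16_569)

    def test_pairs_carry_both_types(self):
        pairs = tile_genome({"chr1": 3_000_000})
        for loss, gain in pairs:
            assert loss.cnv_type is CnvType.LOSS
            assert gain.cnv_type is CnvType.GAIN
            assert loss.interval == gain.interval

    def test_tiles_partition_every_base(self):
        sizes = {"chr1": 3_456_789, "chr2": 999_999}
        pairs = tile_genome(sizes, 1_000_000)
        for chrom, size in sizes.items():
            tiles = sorted(
                (p[0].interval for p in pairs if p[0].interval.chrom == chrom),
                key=lambda iv: iv.start,
            )
            # position sweep: consecutive, disjoint, exact cover
            assert tiles[0].start == 0
            assert tiles[-1].end == size
            for a, b in zip(tiles, tiles[1:]):
                assert a.end == b.start

    def test_non_positive_tile_length_rejected(self):
        with pytest.raises(ValidationError):
            tile_genome({"chr1": 100}, 0)
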