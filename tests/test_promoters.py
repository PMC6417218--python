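"""Operon-aware promoter extraction: interval arithmetic, strand handling,
sequence fetch, and global invariants on random annotations."""

import numpy as np
import pandas as pd
import pytest

from promquant import synthetic
from promquant.errors import (DegenerateRegionError, InvalidArgumentError,
                              NotFoundError)
from promquant.promoters import (Annotation, OperonTable, PromoterRegion,
                                 extract_promoter, fetch_sequence,
                                 read_genome_fasta, read_gff3, resolve_anchor,
                                 write_genome_fasta, write_gff3)


class TestResolveAnchor:
    def test_non_operon_gene_anchors_itself(self, toy_operons):
        assert resolve_anchor("gC", toy_operons) == "gC"

    def test_operon_member_resolves_to_lead(self, toy_operons):
        assert resolve_anchor("gB", toy_operons) == "gA"
        assert resolve_anchor("gA", toy_operons) == "gA"

    def test_all_members_share_one_anchor_and_promoter(self):
        ann, ops, _ = synthetic.gen_annotation(40, operon_fraction=1.0,
                                               min_gap=50, seed=5)
        for oid in ops.table["operon_id"].unique():
            members = ops.members(oid)
            anchors = {resolve_anchor(m, ops) for m in members}
            assert anchors == {members[0]}
            regions = {extract_promoter(a, ann) for a in anchors}
            assert len(regions) == 1

    def test_unknown_gene_raises(self, toy_operons, toy_annotation):
        with pytest.raises(NotFoundError):
            resolve_anchor("nope", toy_operons, toy_annotation)


class TestExtractPromoter:
    def test_plus_strand_intergenic_interval(self, toy_annotation):
        r = extract_promoter("gB", toy_annotation)
        assert (r.start, r.end, r.length, r.strand) == (401, 500, 100, "+")
        assert not r.truncated

    def test_minus_strand_mirrors_plus_strand_rule(self):
        """Extraction on the reverse-complemented genome reproduces the
        - strand result through the + strand rule."""
        genes = pd.DataFrame([
            {"gene_id": "gM", "contig": "c1", "strand": "-", "start": 100, "end": 400},
            {"gene_id": "gN", "contig": "c1", "strand": "+", "start": 501, "end": 700},
        ])
        L = 800
        r = extract_promoter("gM", Annotation(genes))
        assert (r.start, r.end) == (401, 500)
        # mirror: flip coordinates around the contig and strands
        flipped = genes.assign(
            start=L - genes["end"] + 1, end=L - genes["start"] + 1,
            strand=genes["strand"].map({"+": "-", "-": "+"}))
        r2 = extract_promoter("gM", Annotation(flipped))
        assert (L - r2.end + 1, L - r2.start + 1) == (r.start, r.end)

    def test_adjacent_orfs_raise_degenerate_region(self):
        genes = pd.DataFrame([
            {"gene_id": "g1", "contig": "c1", "strand": "+", "start": 1, "end": 400},
            {"gene_id": "g2", "contig": "c1", "strand": "+", "start": 401, "end": 800},
        ])
        with pytest.raises(DegenerateRegionError):
            extract_promoter("g2", Annotation(genes))

    def test_first_gene_on_contig_is_truncated_at_position_one(self, toy_annotation):
        r = extract_promoter("gA", toy_annotation)
        assert r.truncated and r.start == 1 and r.end == 100

    def test_last_minus_strand_gene_truncates_at_contig_end(self, toy_annotation):
        r = extract_promoter("gC", toy_annotation, contig_lengths={"c1": 2000})
        assert r.truncated and (r.start, r.end) == (1501, 2000)


class TestFetchSequence:
    def test_plus_strand_slice_is_one_based_inclusive(self):
        region = PromoterRegion("g", "c1", "+", 2, 4)
        out = fetch_sequence(region, {"c1": "AACGT"})
        assert out.sequence == "ACG"

    def test_minus_strand_returns_reverse_complement(self):
        region = PromoterRegion("g", "c1", "-", 2, 4)
        out = fetch_sequence(region, {"c1": "AACGT"})
        assert out.sequence == "CGT"

    def test_out_of_bounds_raises(self):
        with pytest.raises(InvalidArgumentError):
            fetch_sequence(PromoterRegion("g", "c1", "+", 2, 9), {"c1": "AACGT"})

    def test_round_trip_relocates_by_string_search(self):
        ann, ops, genome = synthetic.gen_annotation(30, min_gap=200, seed=9)
        lengths = {c: len(s) for c, s in genome.items()}
        for gid in ann.genes["gene_id"]:
            anchor = resolve_anchor(gid, ops)
            region = fetch_sequence(
                extract_promoter(anchor, ann, lengths), genome)
            if region.length < 30:
                continue  # short sequences may recur by chance
            contig = genome[region.contig]
            query = region.sequence
            if region.strand == "-":
                from Bio.Seq import Seq
                query = str(Seq(query).reverse_complement())
            assert contig.find(query) == region.start - 1


class TestGlobalInvariants:
    def test_extracted_regions_never_overlap_any_orf(self):
        for seed in range(20):
            ann, ops, genome = synthetic.gen_annotation(
                40, n_contigs=2, operon_fraction=0.4, min_gap=30, seed=seed)
            lengths = {c: len(s) for c, s in genome.items()}
            for gid in ann.genes["gene_id"]:
                region = extract_promoter(resolve_anchor(gid, ops), ann, lengths)
                on_contig = ann.on_contig(region.contig)
                overlap = ((on_contig["start"] <= region.end)
                           & (on_contig["end"] >= region.start))
                assert not overlap.any(), f"seed {seed}, gene {gid}"

    def test_strand_symmetry_preserves_sequences(self):
        """Reverse-complementing the genome with flipped annotation yields
        mirrored coordinates and identical promoter sequences."""
        from Bio.Seq import Seq
        for seed in range(5):
            ann, ops, genome = synthetic.gen_annotation(
                25, operon_fraction=0.0, min_gap=40, seed=seed)
            lengths = {c: len(s) for c, s in genome.items()}
            flipped_genes = ann.genes.assign(
                start=[lengths[c] - e + 1 for c, e in
                       zip(ann.genes["contig"], ann.genes["end"])],
                end=[lengths[c] - s + 1 for c, s in
                     zip(ann.genes["contig"], ann.genes["start"])],
                strand=ann.genes["strand"].map({"+": "-", "-": "+"}))
            flipped_ann = Annotation(flipped_genes)
            flipped_genome = {c: str(Seq(s).reverse_complement())
                              for c, s in genome.items()}
            for gid in ann.genes["gene_id"]:
                r1 = fetch_sequence(extract_promoter(gid, ann, lengths), genome)
                r2 = fetch_sequence(extract_promoter(gid, flipped_ann, lengths),
                                    flipped_genome)
                L = lengths[r1.contig]
                assert (r2.start, r2.end) == (L - r1.end + 1, L - r1.start + 1)
                assert r2.sequence == r1.sequence


class TestFileRoundTrips:
    def test_gff3_and_fasta_round_trip(self, tmp_path):
        ann, _, genome = synthetic.gen_annotation(20, seed=2)
        write_gff3(ann, tmp_path / "a.gff3")
        write_genome_fasta(genome, tmp_path / "g.fasta")
        ann2 = read_gff3(tmp_path / "a.gff3")
        pd.testing.assert_frame_equal(
            ann.genes.sort_values("gene_id").reset_index(drop=True),
            ann2.genes.sort_values("gene_id").reset_index(drop=True),
            check_like=True)
        assert read_genome_fasta(tmp_path / "g.fasta") == genome
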