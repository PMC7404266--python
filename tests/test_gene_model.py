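import io

import numpy as np
import pytest

from tsmeth.gene_model import (
    GtfParseError,
    PromoterRegion,
    derive_promoter,
    derive_promoters,
    read_bed,
    read_gene_model,
    representative_transcript,
    write_bed,
)


def gtf(lines):
    return io.StringIO("\n".join(lines) + "\n")


def exon_line(chrom, start, end, strand, gene, tx):
    return (
        f"{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";'
    )


TWO_EXON_PLUS = [
    exon_line("chr1", 1001, 1200, "+", "gA", "gA.t1"),
    exon_line("chr1", 1501, 1800, "+", "gA", "gA.t1"),
]
TWO_EXON_MINUS = [
    exon_line("chr1", 1001, 1200, "-", "gB", "gB.t1"),
    exon_line("chr1", 1501, 1800, "-", "gB", "gB.t1"),
]


class TestReadGeneModel:
    def test_tss_is_five_prime_most_in_transcription_direction(self):
        model = read_gene_model(gtf(TWO_EXON_PLUS + TWO_EXON_MINUS))
        assert model.get("gA").transcripts[0].tss == 1001
        assert model.get("gB").transcripts[0].tss == 1800

    def test_empty_stream_gives_empty_model(self):
        assert len(read_gene_model(io.StringIO(""))) == 0

    def test_genes_ordered_by_chrom_then_start(self):
        lines = [
            exon_line("chr2", 500, 600, "+", "g3", "g3.t"),
            exon_line("chr1", 900, 950, "+", "g2", "g2.t"),
            exon_line("chr1", 100, 200, "+", "g1", "g1.t"),
        ]
        model = read_gene_model(gtf(lines))
        assert [g.gene_id for g in model] == ["g1", "g2", "g3"]

    def test_malformed_line_names_line_number(self):
        bad = gtf([exon_line("chr1", 1, 10, "+", "g", "t"), "only\tthree\tfields"])
        with pytest.raises(GtfParseError, match="line 2"):
            read_gene_model(bad)

    def test_overlapping_exons_rejected(self):
        lines = [
            exon_line("chr1", 100, 300, "+", "g", "g.t"),
            exon_line("chr1", 250, 400, "+", "g", "g.t"),
        ]
        with pytest.raises(GtfParseError, match="overlap"):
            read_gene_model(gtf(lines))

    def test_non_exon_features_ignored(self):
        lines = [
            "chr1\tsrc\tCDS\t1\t9\t.\t+\t.\t" + 'gene_id "g"; transcript_id "t";',
            exon_line("chr1", 1001, 1200, "+", "g", "t"),
        ]
        model = read_gene_model(gtf(lines))
        assert model.get("g").transcripts[0].exons == ((1001, 1200),)


class TestRepresentativeTranscript:
    def test_five_prime_most_tss_wins(self):
        lines = TWO_EXON_PLUS + [exon_line("chr1", 900, 1000, "+", "gA", "gA.t0")]
        model = read_gene_model(gtf(lines))
        assert representative_transcript(model.get("gA")).transcript_id == "gA.t0"

    def test_tie_broken_by_transcript_id(self):
        lines = [
            exon_line("chr1", 1001, 1100, "+", "g", "g.tB"),
            exon_line("chr1", 1001, 1200, "+", "g", "g.tA"),
        ]
        model = read_gene_model(gtf(lines))
        assert representative_transcript(model.get("g")).transcript_id == "g.tA"


class TestDerivePromoters:
    @pytest.mark.parametrize(
        "lines,gene,kind,expected",
        [
            (TWO_EXON_PLUS, "gA", "proximal", (800, 1050)),
            (TWO_EXON_MINUS, "gB", "proximal", (1750, 2000)),
            (TWO_EXON_PLUS, "gA", "expanded", (0, 1500)),  # clipped at origin
            (TWO_EXON_MINUS, "gB", "typical", (1800, 3800)),
        ],
    )
    def test_window_coordinates(self, lines, gene, kind, expected):
        model = read_gene_model(gtf(lines))
        r = derive_promoter(model.get(gene), kind)
        assert (r.start, r.end) == expected

    def test_minus_strand_proximal_mirrors_plus(self):
        # TSS at 1-based 2000 on '-' covers [1950, 2200) 0-based half-open
        lines = [exon_line("chr1", 1500, 2000, "-", "g", "g.t")]
        model = read_gene_model(gtf(lines))
        r = derive_promoter(model.get("g"), "proximal")
        assert (r.start, r.end) == (1950, 2200)

    def test_span_invariants(self):
        model = read_gene_model(gtf(
            [exon_line("chr1", 50_000, 50_200, "+", "g", "g.t"),
             exon_line("chr1", 51_000, 51_500, "+", "g", "g.t")]
        ))
        g = model.get("g")
        assert derive_promoter(g, "proximal").span == 250
        assert derive_promoter(g, "typical").span == 2000
        assert derive_promoter(g, "expanded").span >= 2000

    def test_single_exon_expanded_flagged_runs_to_transcript_end(self):
        model = read_gene_model(gtf([exon_line("chr1", 50_000, 50_800, "+", "g", "g.t")]))
        r = derive_promoter(model.get("g"), "expanded")
        assert "no_first_intron" in r.flags
        assert r.end == 50_800

    def test_minus_strand_expanded_covers_tss_through_first_intron(self):
        model = read_gene_model(gtf(TWO_EXON_MINUS))
        r = derive_promoter(model.get("gB"), "expanded")
        # first intron in transcription direction: 1-based 1201..1500
        assert (r.start, r.end) == (1200, 1800 + 2000)

    def test_proximal_contained_in_expanded_for_multi_exon(self):
        model = read_gene_model(gtf(
            [exon_line("chr1", 50_000, 50_200, "+", "g", "g.t"),
             exon_line("chr1", 51_000, 51_500, "+", "g", "g.t")]
        ))
        g = model.get("g")
        prox = derive_promoter(g, "proximal")
        exp = derive_promoter(g, "expanded")
        assert exp.start <= prox.start and prox.end <= exp.end

    def test_strand_mirror_property(self):
        """Reflecting all coordinates and flipping strand reflects promoters."""
        rng = np.random.default_rng(0)
        L = 1_000_000
        for _ in range(20):
            tss = int(rng.integers(10_000, 900_000))
            e1 = (tss, tss + int(rng.integers(50, 500)))
            gap = int(rng.integers(100, 2000))
            e2 = (e1[1] + gap, e1[1] + gap + int(rng.integers(50, 500)))
            fwd = read_gene_model(gtf([
                exon_line("c", e1[0], e1[1], "+", "g", "g.t"),
                exon_line("c", e2[0], e2[1], "+", "g", "g.t"),
            ]))
            # reflection: 1-based pos p -> L + 1 - p, interval endpoints swap
            r1 = (L + 1 - e1[1], L + 1 - e1[0])
            r2 = (L + 1 - e2[1], L + 1 - e2[0])
            rev = read_gene_model(gtf([
                exon_line("c", r2[0], r2[1], "-", "g", "g.t"),
                exon_line("c", r1[0], r1[1], "-", "g", "g.t"),
            ]))
            for kind in ("proximal", "typical", "expanded"):
                f = derive_promoter(fwd.get("g"), kind)
                b = derive_promoter(rev.get("g"), kind)
                # 0-based half-open [s, e) reflects to [L - e, L - s)
                assert (b.start, b.end) == (L - f.end, L - f.start), kind


class TestBedRoundTrip:
    def test_write_then_read_preserves_regions(self):
        regions = [
            PromoterRegion("g1", "proximal", "chr1", 800, 1050, "+"),
            PromoterRegion("g2", "expanded", "chr2", 0, 2500, "-"),
        ]
        buf = io.StringIO()
        write_bed(regions, buf)
        buf.seek(0)
        back = read_bed(buf)
        assert [(r.gene_id, r.kind, r.chrom, r.start, r.end, r.strand) for r in back] == [
            ("g1", "proximal", "chr1", 800, 1050, "+"),
            ("g2", "expanded", "chr2", 0, 2500, "-"),
        ]

    def test_derive_promoters_covers_all_genes(self, sim_model):
        regions = derive_promoters(sim_model, "proximal")
        assert len(regions) == len(sim_model)
        assert all(r.span == 250 for r in regions)
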