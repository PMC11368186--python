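"""Format readers/writers: coordinate conventions and round trips."""

import pytest

from multiguide.errors import ConfigurationError, FormatError
from multiguide.genome_io import (
    build_allowed_regions,
    derive_introns,
    export_results,
    read_fasta,
    read_genes,
    read_repeatmasker,
    write_fasta,
)
from multiguide.guide_search import (
    GuideCandidate,
    GuideReport,
    HitRecord,
)
from multiguide.model import Interval, RegionSet


# -- FASTA -------------------------------------------------------------------


def test_read_fasta_lengths_and_uppercasing(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1 extra description\n" + "ACGT" * 15 + "\n>chr2\n" + "A" * 40 + "\n")
    asm = read_fasta(fa)
    assert asm.lengths == {"chr1": 60, "chr2": 40}
    assert set(asm.chromosomes["chr1"]) <= set("ACGT")


def test_read_fasta_records_softmask_intervals(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c\nAACGTacgtAACGT\n")
    asm = read_fasta(fa)
    assert asm.chromosomes["c"] == "AACGTACGTAACGT"
    assert asm.softmask["c"] == [(5, 9)]


def test_fasta_round_trip_preserves_sequences(tmp_path, small_synthetic):
    path = tmp_path / "rt.fa"
    write_fasta(path, small_synthetic.assembly.chromosomes)
    back = read_fasta(path)
    assert back.chromosomes == small_synthetic.assembly.chromosomes


@pytest.mark.parametrize(
    "content",
    [
        ">a\nACGT\n>a\nACGT\n",  # duplicate header
        ">a\nACXT\n",  # non-IUPAC character
        "",  # empty file
        "no header line\n",  # not FASTA
    ],
)
def test_read_fasta_format_errors(tmp_path, content):
    fa = tmp_path / "bad.fa"
    fa.write_text(content)
    with pytest.raises(FormatError):
        read_fasta(fa)


# -- GTF introns -------------------------------------------------------------


def _gtf_line(chrom, feature, start, end, strand, gene, tx):
    attrs = f'gene_id "{gene}";'
    if tx:
        attrs += f' transcript_id "{tx}";'
    return f"{chrom}\tsrc\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def test_intron_coordinates_shift_start_by_one(tmp_path):
    """Exons at 101-200 and 301-400 (1-based inclusive) leave one intron
    [200, 300) in half-open coordinates."""
    gtf = tmp_path / "a.gtf"
    gtf.write_text(
        _gtf_line("chr1", "exon", 101, 200, "+", "g1", "t1")
        + "\n"
        + _gtf_line("chr1", "exon", 301, 400, "+", "g1", "t1")
        + "\n"
    )
    introns = derive_introns(gtf)
    assert [(iv.chromosome, iv.start, iv.end) for iv in introns.intervals] == [
        ("chr1", 200, 300)
    ]


def test_single_exon_transcript_yields_no_introns(tmp_path):
    gtf = tmp_path / "b.gtf"
    gtf.write_text(_gtf_line("chr1", "exon", 1, 500, "+", "g1", "t1") + "\n")
    assert len(derive_introns(gtf)) == 0


def test_overlapping_transcripts_merge_to_interval_union(tmp_path):
    """Two transcripts with staggered exon gaps: the merged intron set
    equals a per-base union oracle."""
    gtf = tmp_path / "c.gtf"
    lines = [
        _gtf_line("chr1", "exon", 1, 100, "+", "g1", "t1"),
        _gtf_line("chr1", "exon", 201, 300, "+", "g1", "t1"),
        _gtf_line("chr1", "exon", 1, 150, "+", "g1", "t2"),
        _gtf_line("chr1", "exon", 251, 300, "+", "g1", "t2"),
    ]
    gtf.write_text("\n".join(lines) + "\n")
    introns = derive_introns(gtf).merged()
    # t1 gap [100,200); t2 gap [150,250): union is [100,250)
    covered = set()
    for lo, hi in [(100, 200), (150, 250)]:
        covered.update(range(lo, hi))
    got = set()
    for iv in introns.intervals:
        got.update(range(iv.start, iv.end))
    assert got == covered


def test_exon_without_transcript_id_is_skipped_and_counted(tmp_path):
    gtf = tmp_path / "d.gtf"
    lines = [
        _gtf_line("chr1", "exon", 1, 100, "+", "g1", "t1"),
        _gtf_line("chr1", "exon", 201, 300, "+", "g1", "t1"),
        _gtf_line("chr1", "exon", 401, 500, "+", "g2", None),
    ]
    gtf.write_text("\n".join(lines) + "\n")
    introns = derive_introns(gtf)
    assert introns.n_skipped == 1
    assert len(introns) == 1


def test_inverted_exon_coordinates_raise_format_error(tmp_path):
    gtf = tmp_path / "e.gtf"
    gtf.write_text(_gtf_line("chr1", "exon", 400, 300, "+", "g1", "t1") + "\n")
    with pytest.raises(FormatError):
        derive_introns(gtf)


def test_read_genes_reports_span_and_strand(tmp_path):
    gtf = tmp_path / "f.gtf"
    lines = [
        _gtf_line("chr1", "exon", 101, 200, "-", "gX", "tX"),
        _gtf_line("chr1", "exon", 401, 500, "-", "gX", "tX"),
    ]
    gtf.write_text("\n".join(lines) + "\n")
    genes = read_genes(gtf)
    (g,) = genes.intervals
    assert (g.start, g.end, g.strand, g.label) == (100, 500, "-", "gX")


# -- RepeatMasker / BED ------------------------------------------------------

RM_HEADER = "h1\nh2\n\n"


def test_repeatmasker_out_is_one_based_inclusive(tmp_path):
    out = tmp_path / "r.out"
    out.write_text(
        RM_HEADER
        + "  500 10.0 0.0 0.0 chr2L 1001 1500 (0) + roo Unknown 1 500 (0) 1\n"
    )
    rs = read_repeatmasker(out)
    (iv,) = rs.intervals
    assert (iv.chromosome, iv.start, iv.end, iv.label) == ("chr2L", 1000, 1500, "roo")


def test_bed_repeats_are_half_open_with_label(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr2\t500\t800\troo\n")
    (iv,) = read_repeatmasker(bed).intervals
    assert (iv.chromosome, iv.start, iv.end, iv.label) == ("chr2", 500, 800, "roo")


def test_malformed_out_row_names_line_number(tmp_path):
    out = tmp_path / "r.out"
    out.write_text(RM_HEADER + "too few columns\n")
    with pytest.raises(FormatError, match=":4"):
        read_repeatmasker(out)


def test_fixture_annotation_round_trip(tmp_path, small_synthetic):
    """.out written by the generator re-parses to the TE truth intervals."""
    syn = small_synthetic
    from multiguide.synthesis import make_genome

    syn = make_genome({"chrZ": 20_000}, 0.5, seed=4, out_dir=tmp_path)
    parsed = read_repeatmasker(syn.paths["rmout"])
    truth = sorted((iv.chromosome, iv.start, iv.end) for iv in syn.tes.intervals)
    got = sorted((iv.chromosome, iv.start, iv.end) for iv in parsed.intervals)
    assert got == truth


# -- allowed regions ---------------------------------------------------------


def test_allowed_regions_restrict_to_listed_chromosomes():
    introns = RegionSet([Interval("chr2L", 100, 200)], "intron")
    tes = RegionSet([], "TE")
    assert len(build_allowed_regions(introns, tes, ["chr3L"])) == 0


def test_allowed_regions_merge_intron_and_te():
    introns = RegionSet([Interval("chr2L", 100, 200)], "intron")
    tes = RegionSet([Interval("chr2L", 150, 300)], "TE")
    merged = build_allowed_regions(introns, tes, ["chr2L"])
    assert [(iv.start, iv.end) for iv in merged.intervals] == [(100, 300)]


def test_allowed_regions_empty_chromosome_list_is_config_error():
    with pytest.raises(ConfigurationError):
        build_allowed_regions(RegionSet([], "intron"), RegionSet([], "TE"), [])


# -- export ------------------------------------------------------------------


def _toy_report(status="selected"):
    cand = GuideCandidate("g000001", "G" + "ACGT" * 4 + "CAT")
    hits = [
        HitRecord("chr2L", 1000, "+", 0, 0, True, True),
        HitRecord("chr2L", 25_000, "-", 0, 0, True, True),
    ]
    return GuideReport(
        candidate=cand,
        hits=hits,
        per_chromosome_counts={"chr2L": 2},
        multiplicity=2,
        status=status,
        rejection_reasons=[] if status == "selected" else ["mismatched_hit"],
    )


def test_export_propagates_counts_and_bed_records(tmp_path):
    paths = export_results([_toy_report()], tmp_path / "out", ["chr2L", "chr3L"])
    lines = paths["tsv"].read_text().splitlines()
    header = lines[0].split("\t")
    row = dict(zip(header, lines[1].split("\t")))
    assert row["total_hits"] == "2"
    assert row["hits_chr2L"] == "2"
    assert row["hits_chr3L"] == "0"
    assert len(paths["bed"].read_text().splitlines()) == 2
    assert ">g000001" in paths["fasta"].read_text()


def test_export_zero_reports_writes_header_only(tmp_path):
    paths = export_results([], tmp_path / "empty", ["chr2L"])
    assert len(paths["tsv"].read_text().splitlines()) == 1
    assert paths["bed"].read_text() == ""


def test_bed_round_trip_recovers_hit_coordinates(tmp_path):
    rep = _toy_report()
    paths = export_results([rep], tmp_path / "rt", ["chr2L"])
    back = read_repeatmasker(paths["bed"].rename(tmp_path / "rt.bed"))
    got = sorted((iv.chromosome, iv.start, iv.end, iv.strand) for iv in back.intervals)
    glen = len(rep.candidate.sequence)
    want = sorted(
        (h.chromosome, h.start, h.start + glen, h.strand) for h in rep.hits
    )
    assert got == want
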