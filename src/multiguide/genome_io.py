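"""Readers and writers for genomes, annotations and result tables.

GTF and RepeatMasker coordinates are 1-based inclusive on disk and are
converted to the package-wide 0-based half-open convention here, at the
format boundary, by shifting the start coordinate by exactly one.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import ConfigurationError, FormatError
from .model import GenomeAssembly, Interval, RegionSet

if TYPE_CHECKING:  # pragma: no cover
    from .guide_search import GuideReport

logger = logging.getLogger(__name__)

_LOWERCASE_RUN = re.compile(r"[a-z]+")


def read_fasta(path: str | Path, name: str = "") -> GenomeAssembly:
    """Read a genome FASTA into a :class:`GenomeAssembly`.

    Sequences are uppercased; lowercase (soft-masked) runs are recorded
    as 0-based half-open intervals in ``assembly.softmask``. Headers are
    truncated at the first whitespace and must be unique.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    softmask: dict[str, list[tuple[int, int]]] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython's parse error
        raise FormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or not FASTA-formatted")
    for rec in records:
        if rec.id in chromosomes:
            raise FormatError(f"{path}: duplicate header {rec.id!r}")
        raw = str(rec.seq)
        chromosomes[rec.id] = raw
        softmask[rec.id] = [
            (m.start(), m.end()) for m in _LOWERCASE_RUN.finditer(raw)
        ]
    try:
        return GenomeAssembly(chromosomes, softmask, name=name or path.stem)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(
    path: str | Path, sequences: dict[str, str], width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def derive_introns(gtf_path: str | Path) -> RegionSet:
    """Derive introns as gaps between consecutive exons of each transcript.

    GTF "intron" features, if present, are ignored; introns are always
    recomputed from exon features, the reproducible reading of an
    annotation. Single-exon transcripts contribute nothing. Exons missing
    a transcript_id attribute are skipped; the skip count is returned on
    the result as ``n_skipped``.
    """
    gtf_path = Path(gtf_path)
    exons_by_tx: dict[str, list[tuple[str, int, int]]] = {}
    n_skipped = 0
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{gtf_path}:{lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise FormatError(
                    f"{gtf_path}:{lineno}: exon end {feat.end} < start {feat.start}"
                )
            tx = feat.attributes.get("transcript_id")
            if not tx:
                n_skipped += 1
                logger.warning(
                    "%s:%d: exon without transcript_id skipped", gtf_path, lineno
                )
                continue
            # GTF is 1-based inclusive: [start-1, end) in half-open coords.
            exons_by_tx.setdefault(tx[0], []).append(
                (feat.seqid, feat.start - 1, feat.end)
            )
    introns: list[Interval] = []
    for tx, exons in exons_by_tx.items():
        exons.sort(key=lambda e: (e[0], e[1]))
        for (chrom_a, _, end_a), (chrom_b, start_b, _) in zip(exons, exons[1:]):
            if chrom_a == chrom_b and start_b > end_a:
                introns.append(Interval(chrom_a, end_a, start_b, label=tx))
    out = RegionSet(introns, class_tag="intron")
    out.n_skipped = n_skipped
    return out


def read_genes(gtf_path: str | Path) -> RegionSet:
    """Gene spans (union of each gene's exons) with strand, for TSS use.

    The TSS of a + strand gene is its span start; of a - strand gene its
    last spanned base.
    """
    gtf_path = Path(gtf_path)
    spans: dict[str, list] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{gtf_path}:{lineno}: {exc}") from exc
            if feat.featuretype not in ("exon", "gene", "transcript"):
                continue
            gene = feat.attributes.get("gene_id")
            if not gene:
                continue
            key = gene[0]
            rec = spans.setdefault(
                key, [feat.seqid, feat.start - 1, feat.end, feat.strand]
            )
            rec[1] = min(rec[1], feat.start - 1)
            rec[2] = max(rec[2], feat.end)
    genes = [
        Interval(chrom, start, end, strand if strand in "+-" else ".", gid)
        for gid, (chrom, start, end, strand) in spans.items()
    ]
    return RegionSet(genes, class_tag="custom")


def read_repeatmasker(path: str | Path) -> RegionSet:
    """Read repeat annotation from RepeatMasker .out or BED.

    The dialect is chosen by extension: ``.bed`` is parsed as BED
    (already 0-based half-open), anything else as the RepeatMasker .out
    table (3 header lines, whitespace-delimited, 1-based inclusive query
    coordinates). Intervals are labeled with the repeat family name.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed_repeats(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 10 columns, got {len(fields)}"
                )
            chrom, begin, end = fields[4], fields[5], fields[6]
            strand = "+" if fields[8] == "+" else "-"
            family = fields[9]
            try:
                start0, end0 = int(begin) - 1, int(end)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            intervals.append(Interval(chrom, start0, end0, strand, family))
    return RegionSet(intervals, class_tag="TE")


def _read_bed_repeats(path: Path) -> RegionSet:
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(
                Interval(fields[0], int(fields[1]), int(fields[2]), strand, label)
            )
    return RegionSet(intervals, class_tag="TE")


def build_allowed_regions(
    introns: RegionSet, tes: RegionSet, chromosomes: Sequence[str]
) -> RegionSet:
    """Union of intron and TE intervals on the listed chromosomes, merged."""
    if not chromosomes:
        raise ConfigurationError("chromosome list must not be empty")
    keep = set(chromosomes)
    pooled = [
        iv
        for iv in list(introns.intervals) + list(tes.intervals)
        if iv.chromosome in keep
    ]
    merged = RegionSet(pooled, class_tag="allowed").merged()
    merged.class_tag = "allowed"
    return merged


def export_results(
    reports: Iterable["GuideReport"],
    out_prefix: str | Path,
    chromosomes: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write the result tables for a set of guide reports.

    Produces ``<prefix>.tsv`` (one row per guide: sequence, status,
    rejection reasons, total and per-chromosome hit counts, hit
    coordinates as chrom:start:strand), ``<prefix>.hits.bed`` (BED6 of
    protospacer spans) and ``<prefix>.selected.fa`` (FASTA of selected
    guides). Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    reports = list(reports)
    if chromosomes is None:
        chromosomes = sorted(
            {h.chromosome for rep in reports for h in rep.hits}
        )
    tsv_path = out_prefix.with_suffix(".tsv")
    bed_path = out_prefix.with_suffix(".hits.bed")
    fa_path = out_prefix.with_suffix(".selected.fa")

    header = (
        ["guide_id", "sequence", "status", "rejection_reasons", "total_hits"]
        + [f"hits_{c}" for c in chromosomes]
        + ["hit_coordinates"]
    )
    try:
        with open(tsv_path, "w") as tsv:
            tsv.write("\t".join(header) + "\n")
            for rep in reports:
                counts = rep.per_chromosome_counts
                coords = ";".join(
                    f"{h.chromosome}:{h.start}:{h.strand}" for h in rep.hits
                )
                row = [
                    rep.candidate.guide_id,
                    rep.candidate.sequence,
                    rep.status,
                    ",".join(rep.rejection_reasons) or ".",
                    str(len(rep.hits)),
                    *[str(counts.get(c, 0)) for c in chromosomes],
                    coords or ".",
                ]
                tsv.write("\t".join(row) + "\n")
        with open(bed_path, "w") as bed:
            for rep in reports:
                glen = len(rep.candidate.sequence)
                for h in rep.hits:
                    bed.write(
                        f"{h.chromosome}\t{h.start}\t{h.start + glen}\t"
                        f"{rep.candidate.guide_id}\t0\t{h.strand}\n"
                    )
        selected = [r for r in reports if r.status == "selected"]
        with open(fa_path, "w") as fa:
            writer = SeqIO.FastaIO.FastaWriter(fa, wrap=70)
            writer.write_file(
                [
                    SeqRecord(
                        Seq(r.candidate.sequence),
                        id=r.candidate.guide_id,
                        description=f"multiplicity={r.multiplicity}",
                    )
                    for r in selected
                ]
            )
    except OSError as exc:
        raise OSError(f"cannot write results to {out_prefix}: {exc}") from exc
    return {"tsv": tsv_path, "bed": bed_path, "fasta": fa_path}
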