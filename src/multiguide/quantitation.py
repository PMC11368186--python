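"""Copy-number, coverage, insertion-call and TSS-proximity quantitation.

These are the companion estimators for sequencing-based validation of
edited genomes:

* read-depth coverage, whole-genome or per window;
* transposon-family copy number from consensus-mapped read counts,
  normalized by consensus length and genomic coverage depth;
* qPCR copy number under the per-cycle doubling model,
  copies = 2^(reference CT - target CT) with replicate averaging;
* insertion-call filtering (minimum read support) and zygosity
  labeling from coverage frequency;
* signed insertion-to-TSS distances with a within-1-kb flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Interval

#: paired-end read length in bases per pair (2 x 150 nt)
DEFAULT_READ_LENGTH_TOTAL = 300


@dataclass
class CtRecord:
    """Replicate threshold cycles for one sample's target and reference assays."""

    sample_id: str
    target: str
    ct_values: list[float]
    reference_cts: dict[str, list[float]]


@dataclass
class InsertionCall:
    chromosome: str
    position: int
    support_reads: int
    coverage_frequency: float
    zygosity_label: str = "unset"


@dataclass
class TEFamilyCount:
    family: str
    mapped_read_count: int
    consensus_length: int
    normalized_copies: float = 0.0


@dataclass
class TSSAnnotation:
    insertion: Interval
    nearest_gene: str
    distance: int  # negative = upstream of the gene, in gene orientation
    within_1kb: bool
    orientation: str  # sense | antisense | unknown


def coverage_depth(
    read_count: int,
    read_length_total: float = DEFAULT_READ_LENGTH_TOTAL,
    span: float = 1.0,
) -> float:
    """Depth = read_count x read_length_total / span.

    *span* is the genome size for overall coverage or the window size
    for per-window coverage.
    """
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    if read_length_total <= 0:
        raise ValueError("read_length_total must be positive")
    return read_count * read_length_total / span


def te_copy_number(
    mapped_read_count: int,
    read_length_total: float,
    consensus_length: float,
    genome_coverage: float,
) -> float:
    """Copies = reads x read_length_total / (consensus_length x coverage).

    Expresses read base pairs per TE consensus base pair, divided by the
    genomic coverage depth, so a single-copy family at uniform coverage
    yields 1.0.
    """
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    if genome_coverage <= 0:
        raise ValueError("genome_coverage must be positive")
    return mapped_read_count * read_length_total / (consensus_length * genome_coverage)


def qpcr_copy_number(record: CtRecord) -> float:
    """Copy number = 2^(mean reference CT - mean target CT).

    Replicates are averaged per assay; the per-gene reference means are
    then averaged into one reference CT. The direction of the exponent
    is fixed by the doubling model: more template halves the target CT
    per doubling, so lower target CT means more copies.
    """
    if not record.ct_values:
        raise ValueError(f"{record.sample_id}: no target CT replicates")
    if not record.reference_cts or not all(record.reference_cts.values()):
        raise ValueError(f"{record.sample_id}: no reference CT replicates")
    target_ct = float(np.mean(record.ct_values))
    reference_ct = float(
        np.mean([np.mean(v) for v in record.reference_cts.values()])
    )
    return float(2.0 ** (reference_ct - target_ct))


def qpcr_copy_numbers_from_table(
    table: pd.DataFrame,
    target_assay: str = "target",
) -> pd.DataFrame:
    """Apply :func:`qpcr_copy_number` to a long-format CT table.

    Expects columns sample_id, assay, replicate, ct; every assay other
    than *target_assay* is treated as an autosomal reference gene.
    """
    out = []
    for sample, grp in table.groupby("sample_id", sort=True):
        target = grp.loc[grp["assay"] == target_assay, "ct"].tolist()
        refs = {
            a: g["ct"].tolist()
            for a, g in grp[grp["assay"] != target_assay].groupby("assay")
        }
        rec = CtRecord(str(sample), target_assay, target, refs)
        out.append({"sample_id": sample, "copies": qpcr_copy_number(rec)})
    return pd.DataFrame(out)


def process_insertion_calls(
    calls: Iterable[InsertionCall],
    min_support: int = 2,
    hom_threshold: float = 0.7,
) -> list[InsertionCall]:
    """Filter by read support and label zygosity from coverage frequency.

    Calls supported by fewer than *min_support* reads are removed;
    survivors are labeled homozygous_like when coverage_frequency >=
    *hom_threshold* (boundary inclusive), else segregating. Input order
    is preserved; support and frequency values are never altered.
    """
    out: list[InsertionCall] = []
    for call in calls:
        if not 0.0 <= call.coverage_frequency <= 1.0:
            raise ValueError(
                f"{call.chromosome}:{call.position}: coverage_frequency "
                f"{call.coverage_frequency} outside [0, 1]"
            )
        if call.support_reads < min_support:
            continue
        label = (
            "homozygous_like"
            if call.coverage_frequency >= hom_threshold
            else "segregating"
        )
        out.append(replace(call, zygosity_label=label))
    return out


def insertion_calls_from_table(table: pd.DataFrame) -> list[InsertionCall]:
    return [
        InsertionCall(
            str(r.chromosome),
            int(r.position),
            int(r.support_reads),
            float(r.coverage_frequency),
        )
        for r in table.itertuples()
    ]


def te_copy_table(
    table: pd.DataFrame,
    genome_coverage: float,
    read_length_total: float = DEFAULT_READ_LENGTH_TOTAL,
) -> pd.DataFrame:
    """Append normalized_copies to a family read-count table."""
    out = table.copy()
    out["normalized_copies"] = [
        te_copy_number(
            int(r.mapped_read_count),
            read_length_total,
            float(r.consensus_length),
            genome_coverage,
        )
        for r in table.itertuples()
    ]
    return out


def gene_tss(gene: Interval) -> int:
    """TSS position: gene start on +, last base (end - 1) on -."""
    return gene.start if gene.strand != "-" else gene.end - 1


def annotate_tss_proximity(
    insertions: Sequence[Interval],
    genes: Sequence[Interval],
    within: int = 1000,
) -> list[TSSAnnotation]:
    """Annotate each insertion with its nearest-TSS distance and gene.

    The distance is signed in gene orientation: negative means the
    insertion lies upstream (5') of the TSS of its nearest gene,
    positive downstream, respecting the gene's strand. The nearest gene
    is chosen by absolute distance (ties: first gene in input order).
    Only genes on the insertion's chromosome are considered; an
    insertion on a chromosome with no genes gets no nearest gene and an
    undefined (sentinel) distance.
    """
    if not genes:
        raise ValueError("gene set must not be empty")
    tss_by_chrom: dict[str, list[tuple[int, Interval]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chromosome, []).append((gene_tss(g), g))
    out: list[TSSAnnotation] = []
    for ins in insertions:
        pos = ins.start
        candidates = tss_by_chrom.get(ins.chromosome, [])
        if not candidates:
            out.append(TSSAnnotation(ins, "", 0, False, "unknown"))
            continue
        tss, gene = min(candidates, key=lambda t: abs(pos - t[0]))
        genomic = pos - tss
        distance = genomic if gene.strand != "-" else -genomic
        orientation = "unknown"
        if ins.strand in "+-":
            orientation = "sense" if ins.strand == gene.strand else "antisense"
        out.append(
            TSSAnnotation(
                insertion=ins,
                nearest_gene=gene.label,
                distance=distance,
                within_1kb=abs(distance) <= within,
                orientation=orientation,
            )
        )
    return out
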