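"""Synthetic fixtures: genomes, annotations, planted guide sites, decoys,
mutated assembly panels and simulated quantitation inputs.

Every generator is deterministic per seed and returns explicit ground
truth, so downstream modules can be tested against exactly known
answers. :func:`brute_force_hits` is the independent position-by-
position matching oracle for :func:`multiguide.guide_search.find_hits`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import IUPAC, encode, iupac_masks, revcomp, revcomp_iupac
from .errors import ConfigurationError
from .genome_io import write_fasta
from .guide_search import (
    GuideCandidate,
    HitRecord,
    MatchPolicy,
    RepeatFilterPolicy,
    has_simple_repeat,
)
from .model import GenomeAssembly, Interval, RegionSet

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_hits(
    guide: GuideCandidate | str,
    genome: GenomeAssembly,
    match_policy: MatchPolicy | None = None,
) -> list[HitRecord]:
    """Position-by-position scan of both strands with direct per-block
    mismatch counting; no index, no shortcuts. Output contract identical
    to :func:`multiguide.guide_search.find_hits`.
    """
    policy = match_policy or MatchPolicy()
    seq = guide.sequence if isinstance(guide, GuideCandidate) else guide
    if len(seq) != policy.guide_len:
        raise ValueError("guide length does not match policy")
    if "N" in seq:
        raise ValueError("guide sequence must not contain N")
    glen, dlen, slen = policy.guide_len, policy.distal_len, policy.seed_len
    plen = len(policy.pam)
    g_fwd = encode(seq)
    g_rev = encode(revcomp(seq))
    pam_fwd = iupac_masks(policy.pam)
    pam_rev = iupac_masks(revcomp_iupac(policy.pam))

    hits: list[HitRecord] = []
    for chrom in genome.chromosomes:
        codes = genome.encoded(chrom)
        L = codes.size
        n = L - glen + 1
        if n <= 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, glen)
        has_n = (win == 4).any(axis=1)
        # + strand: distal block is guide[0:dlen], seed is guide[dlen:]
        mm_fwd = win != g_fwd
        seed_mm = mm_fwd[:, dlen:].sum(axis=1)
        distal_mm = mm_fwd[:, :dlen].sum(axis=1)
        padded = np.concatenate([codes, np.full(plen, 4, dtype=np.uint8)])
        pam_win = np.lib.stride_tricks.sliding_window_view(padded, plen)[glen:]
        pam_ok = pam_fwd[np.arange(plen), pam_win].all(axis=1)
        cand = (seed_mm == 0) & (distal_mm <= policy.max_distal_mm) & ~has_n
        if policy.require_pam_at_hits:
            cand &= pam_ok
        for s in np.flatnonzero(cand):
            hits.append(
                HitRecord(chrom, int(s), "+", 0, int(distal_mm[s]), bool(pam_ok[s]))
            )
        # - strand: window equals revcomp(guide); its first slen bases
        # are the reverse complement of the seed, the rest of the distal
        mm_rev = win != g_rev
        seed_mm_r = mm_rev[:, :slen].sum(axis=1)
        distal_mm_r = mm_rev[:, slen:].sum(axis=1)
        padded_l = np.concatenate([np.full(plen, 4, dtype=np.uint8), codes])
        pam_win_l = np.lib.stride_tricks.sliding_window_view(padded_l, plen)[:n]
        pam_ok_r = pam_rev[np.arange(plen), pam_win_l].all(axis=1)
        cand_r = (seed_mm_r == 0) & (distal_mm_r <= policy.max_distal_mm) & ~has_n
        if policy.require_pam_at_hits:
            cand_r &= pam_ok_r
        for s in np.flatnonzero(cand_r):
            hits.append(
                HitRecord(
                    chrom, int(s), "-", 0, int(distal_mm_r[s]), bool(pam_ok_r[s])
                )
            )
    hits.sort(key=HitRecord.sort_key)
    return hits


# ---------------------------------------------------------------------------
# genome and annotation generation


@dataclass
class SyntheticGenome:
    assembly: GenomeAssembly
    introns: RegionSet
    tes: RegionSet
    paths: dict[str, Path] = field(default_factory=dict)
    seed: int = 0


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return (
        rng.choice(_BASES, size=length, p=probs).tobytes().decode("ascii")
    )


def make_genome(
    chromosome_lengths: dict[str, int],
    gc_content: float = 0.5,
    seed: int = 0,
    out_dir: str | Path | None = None,
    genes_per_100kb: float = 4.0,
    tes_per_100kb: float = 4.0,
) -> SyntheticGenome:
    """Random i.i.d. genome with multi-exon gene models and TE intervals.

    Writes FASTA, GTF and a RepeatMasker-style .out file when *out_dir*
    is given. Deterministic per seed.
    """
    if any(L < 1000 for L in chromosome_lengths.values()):
        raise ConfigurationError("chromosome lengths must be >= 1000")
    if not 0.0 < gc_content < 1.0:
        raise ConfigurationError("gc_content must be in (0, 1) exclusive")
    rng = np.random.default_rng(seed)
    chroms = {
        name: _random_sequence(rng, L, gc_content)
        for name, L in chromosome_lengths.items()
    }
    assembly = GenomeAssembly(chroms, name=f"synthetic_seed{seed}")

    introns: list[Interval] = []
    gtf_lines: list[str] = []
    tes: list[Interval] = []
    gene_no = 0
    for name, L in chromosome_lengths.items():
        n_genes = int(round(genes_per_100kb * L / 100_000))
        n_tes = int(round(tes_per_100kb * L / 100_000))
        # a gene footprint is at most ~4 exons + 3 introns ~ 4.2 kb
        if n_genes * 4200 + n_tes * 3000 > L:
            raise ConfigurationError(
                f"{name}: annotation density infeasible for length {L}"
            )
        for _ in range(n_genes):
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(100, 301, size=n_exons)
            intron_lens = rng.integers(200, 1001, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            start = int(rng.integers(0, max(1, L - span)))
            strand = "+" if rng.integers(2) == 0 else "-"
            pos = start
            exons = []
            for i in range(n_exons):
                exons.append((pos, pos + int(exon_lens[i])))
                if i < n_exons - 1:
                    intron_start = pos + int(exon_lens[i])
                    pos = intron_start + int(intron_lens[i])
                    introns.append(Interval(name, intron_start, pos, strand, gid))
                else:
                    pos += int(exon_lens[i])
            for es, ee in exons:
                gtf_lines.append(
                    f"{name}\tsynthetic\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{gid}.t1";'
                )
        for t in range(n_tes):
            te_len = int(rng.integers(500, 3001))
            start = int(rng.integers(0, max(1, L - te_len)))
            strand = "+" if rng.integers(2) == 0 else "-"
            family = f"TEfam{int(rng.integers(1, 9))}"
            tes.append(Interval(name, start, start + te_len, strand, family))

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["fasta"] = out_dir / "genome.fa"
        write_fasta(paths["fasta"], chroms)
        paths["gtf"] = out_dir / "genes.gtf"
        paths["gtf"].write_text("\n".join(gtf_lines) + ("\n" if gtf_lines else ""))
        paths["rmout"] = out_dir / "repeats.out"
        _write_repeatmasker_out(paths["rmout"], tes)
    return SyntheticGenome(
        assembly=assembly,
        introns=RegionSet(introns, "intron"),
        tes=RegionSet(tes, "TE"),
        paths=paths,
        seed=seed,
    )


def _write_repeatmasker_out(path: Path, tes: list[Interval]) -> None:
    header = (
        "   SW  perc perc perc  query     position in query    matching"
        "  repeat         position in repeat\n"
        "score  div. del. ins.  sequence  begin   end  (left)  repeat"
        "         class/family   begin end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, iv in enumerate(sorted(tes, key=lambda x: (x.chromosome, x.start)), 1):
            strand = "+" if iv.strand != "-" else "C"
            fh.write(
                f"  500  10.0  0.0  0.0  {iv.chromosome}  {iv.start + 1}  "
                f"{iv.end}  (0)  {strand}  {iv.label or 'TEfam1'}  "
                f"Unknown  1  {len(iv)}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# site planting


@dataclass
class PlantTruth:
    """Ground truth for a genome with planted protospacer sites."""

    guide: str
    perfect_sites: list[tuple[str, int, str]]
    decoys: list[tuple[str, int, str, int, int]]  # (+seed_mm, distal_mm)
    site_spans: list[Interval]
    te_intervals: list[Interval] = field(default_factory=list)
    intron_intervals: list[Interval] = field(default_factory=list)
    seed: int = 0

    def site_region_set(self) -> RegionSet:
        """The planted protospacer spans as an allowed-region set."""
        return RegionSet(list(self.site_spans), "TE")


def random_guide(
    rng: np.random.Generator,
    match_policy: MatchPolicy | None = None,
    repeat_policy: RepeatFilterPolicy | None = None,
) -> str:
    """A random guide satisfying the 5' G and simple-repeat constraints."""
    policy = match_policy or MatchPolicy()
    rpolicy = repeat_policy or RepeatFilterPolicy()
    for _ in range(1000):
        body = rng.choice(_BASES, size=policy.guide_len - 1).tobytes().decode()
        seq = ("G" + body) if policy.require_5prime_g else (
            rng.choice(_BASES, size=1).tobytes().decode() + body
        )
        if not has_simple_repeat(seq, rpolicy):
            return seq
    raise ConfigurationError("could not draw a repeat-free guide")


def _concrete_pam(pam: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in pam)


def _mutate_block(
    guide: str, positions: list[int], rng: np.random.Generator
) -> str:
    seq = list(guide)
    for p in positions:
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        seq[p] = choices[int(rng.integers(3))]
    return "".join(seq)


def plant_sites(
    genome: GenomeAssembly,
    guide: str,
    k: int,
    regions: RegionSet,
    spacing: int = 10_000,
    decoy_spec: list[tuple] | None = None,
    seed: int = 0,
    match_policy: MatchPolicy | None = None,
) -> tuple[GenomeAssembly, PlantTruth]:
    """Write *k* perfect protospacer+PAM sites and the requested decoys
    into a copy of *genome*, inside *regions*, with pairwise spacing.

    Each decoy spec is ``(seed_mm, distal_mm)`` with mismatch positions
    drawn uniformly inside the respective block, or
    ``(seed_mm, distal_mm, positions)`` with explicit guide positions
    (0 = 5', PAM-distal end). After writing, the genome is rescanned
    with :func:`brute_force_hits` to verify the counted-hit set is
    exactly the planted truth; stray background matches are scrubbed and
    the scan repeated (bounded rounds).
    """
    policy = match_policy or MatchPolicy()
    decoy_spec = list(decoy_spec or [])
    if len(guide) != policy.guide_len:
        raise ConfigurationError("guide length does not match policy")
    rng = np.random.default_rng(seed)
    glen, dlen, plen = policy.guide_len, policy.distal_len, len(policy.pam)
    block_len = glen + plen

    # candidate block starts inside regions, per chromosome
    merged = regions.merged()
    usable: list[tuple[str, int, int]] = [
        (iv.chromosome, iv.start, iv.end - block_len)
        for iv in merged.intervals
        if len(iv) >= block_len and iv.chromosome in genome.chromosomes
    ]
    if not usable:
        raise ConfigurationError("regions cannot host a protospacer+PAM block")

    n_sites = k + len(decoy_spec)
    for attempt in range(50):
        # block starts are padded by the PAM length so protospacer starts
        # (which shift by plen on the - strand) still honor the spacing
        placements = _draw_placements(usable, n_sites, spacing + plen, block_len, rng)
        if placements is not None:
            break
    else:
        raise ConfigurationError(
            f"cannot place {n_sites} sites with spacing {spacing}"
        )

    seqs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    perfect: list[tuple[str, int, str]] = []
    decoys: list[tuple[str, int, str, int, int]] = []
    spans: list[Interval] = []
    for i, (chrom, b) in enumerate(placements):
        strand = "+" if rng.integers(2) == 0 else "-"
        if i < k:
            site_seq = guide
            seed_mm = distal_mm = 0
        else:
            spec = decoy_spec[i - k]
            seed_mm, distal_mm = int(spec[0]), int(spec[1])
            if len(spec) > 2 and spec[2] is not None:
                positions = sorted(int(p) for p in spec[2])
                got_d = sum(1 for p in positions if p < dlen)
                got_s = len(positions) - got_d
                if (got_s, got_d) != (seed_mm, distal_mm):
                    raise ConfigurationError(
                        "explicit decoy positions disagree with mismatch counts"
                    )
            else:
                positions = sorted(
                    [int(p) for p in rng.choice(dlen, size=distal_mm, replace=False)]
                    + [
                        dlen + int(p)
                        for p in rng.choice(
                            policy.seed_len, size=seed_mm, replace=False
                        )
                    ]
                )
            site_seq = _mutate_block(guide, positions, rng)
        pam = _concrete_pam(policy.pam, rng)
        if strand == "+":
            block = site_seq + pam
            proto_start = b
        else:
            block = revcomp(site_seq + pam)
            proto_start = b + plen
        seqs[chrom][b : b + block_len] = block.encode("ascii")
        if i < k:
            perfect.append((chrom, proto_start, strand))
        else:
            decoys.append((chrom, proto_start, strand, seed_mm, distal_mm))
        spans.append(Interval(chrom, proto_start, proto_start + glen, strand))

    planted = GenomeAssembly(
        {c: bytes(s).decode("ascii") for c, s in seqs.items()},
        name=genome.name + "+planted",
    )
    planted = _scrub_stray_hits(planted, guide, perfect, decoys, spans, policy, rng)
    truth = PlantTruth(
        guide=guide,
        perfect_sites=sorted(perfect),
        decoys=sorted(decoys),
        site_spans=spans,
        seed=seed,
    )
    _verify_truth(planted, truth, policy)
    return planted, truth


def _draw_placements(usable, n_sites, spacing, block_len, rng):
    """Random block starts with pairwise per-chromosome gaps >= spacing.

    Sites are apportioned to intervals by capacity, then placed within
    each interval by the order-statistics construction (sorted uniform
    draws plus fixed gaps), which packs up to the interval's capacity.
    """
    gap = max(spacing, block_len)
    caps = [
        (hi - lo) // gap + 1 if hi >= lo else 0 for _, lo, hi in usable
    ]
    if sum(caps) < n_sites:
        return None
    # weighted assignment of site counts, capped by interval capacity
    counts = [0] * len(usable)
    remaining = list(caps)
    for _ in range(n_sites):
        total = sum(remaining)
        r = int(rng.integers(total))
        acc = 0
        for i, c in enumerate(remaining):
            acc += c
            if r < acc:
                counts[i] += 1
                remaining[i] -= 1
                break
    placements: list[tuple[str, int]] = []
    for (chrom, lo, hi), m in zip(usable, counts):
        if m == 0:
            continue
        slack = (hi - lo) - (m - 1) * gap
        offsets = np.sort(rng.integers(0, slack + 1, size=m))
        for j, off in enumerate(offsets):
            placements.append((chrom, int(lo + off + j * gap)))
    # adjacent intervals on one chromosome could still violate the gap
    by_chrom: dict[str, list[int]] = {}
    for chrom, b in placements:
        by_chrom.setdefault(chrom, []).append(b)
    for starts in by_chrom.values():
        starts.sort()
        if any(b - a < gap for a, b in zip(starts, starts[1:])):
            return None
    return placements


def _scrub_stray_hits(
    planted, guide, perfect, decoys, spans, policy, rng
) -> GenomeAssembly:
    """Remove accidental background matches by substituting one seed base
    outside all planted spans; bounded rounds."""
    expected = {(c, s, st) for c, s, st in perfect}
    expected |= {
        (c, s, st)
        for c, s, st, smm, dmm in decoys
        if smm == 0 and dmm <= policy.max_distal_mm
    }
    span_set = [(iv.chromosome, iv.start, iv.end) for iv in spans]
    for _round in range(10):
        stray = [
            h
            for h in brute_force_hits(guide, planted, policy)
            if (h.chromosome, h.start, h.strand) not in expected
        ]
        if not stray:
            return planted
        seqs = {c: bytearray(s, "ascii") for c, s in planted.chromosomes.items()}
        for h in stray:
            glen = policy.guide_len
            if h.strand == "+":
                seed_lo = h.start + policy.distal_len
            else:
                seed_lo = h.start
            cand_pos = [
                p
                for p in range(seed_lo, seed_lo + policy.seed_len)
                if not any(
                    c == h.chromosome and a <= p < b for c, a, b in span_set
                )
            ]
            if not cand_pos:
                raise ConfigurationError(
                    "stray hit overlaps a planted site; replant with a new seed"
                )
            p = cand_pos[int(rng.integers(len(cand_pos)))]
            old = chr(seqs[h.chromosome][p])
            new = [b for b in "ACGT" if b != old][int(rng.integers(3))]
            seqs[h.chromosome][p] = ord(new)
        planted = GenomeAssembly(
            {c: bytes(s).decode("ascii") for c, s in seqs.items()},
            name=planted.name,
        )
    raise ConfigurationError("could not scrub stray matches")


def _verify_truth(planted: GenomeAssembly, truth: PlantTruth, policy: MatchPolicy):
    hits = brute_force_hits(truth.guide, planted, policy)
    got_perfect = sorted(
        (h.chromosome, h.start, h.strand)
        for h in hits
        if h.distal_mismatches == 0
    )
    if got_perfect != truth.perfect_sites:
        raise ConfigurationError(
            "post-write verification failed: perfect-site set mismatch"
        )
    expected_near = sorted(
        (c, s, st, dmm)
        for c, s, st, smm, dmm in truth.decoys
        if smm == 0 and 0 < dmm <= policy.max_distal_mm
    )
    got_near = sorted(
        (h.chromosome, h.start, h.strand, h.distal_mismatches)
        for h in hits
        if h.distal_mismatches > 0
    )
    if got_near != expected_near:
        raise ConfigurationError(
            "post-write verification failed: near-miss decoy set mismatch"
        )


# ---------------------------------------------------------------------------
# assembly panel derivation


def mutate_panel(
    ancestor: GenomeAssembly,
    n_assemblies: int,
    snp_rate: float,
    indel_rate: float,
    protect: PlantTruth | None = None,
    seed: int = 0,
    break_sites: float = 0.0,
    match_policy: MatchPolicy | None = None,
) -> tuple[list[GenomeAssembly], list[list[tuple[str, int, str]]]]:
    """Derive assemblies from an ancestor by random SNPs and small indels.

    Protected site spans (protospacer+PAM of *protect*) are never
    mutated, unless *break_sites* > 0: then ``round(break_sites * k)``
    of the k protected perfect sites, chosen at random across the whole
    panel, each receive one seed substitution in one assembly. Returns
    the assemblies and, per assembly, the list of sites broken in it.
    """
    for rate in (snp_rate, indel_rate):
        if not 0.0 <= rate <= 0.1:
            raise ConfigurationError("mutation rates must be within [0, 0.1]")
    policy = match_policy or MatchPolicy()
    rng = np.random.default_rng(seed)
    plen = len(policy.pam)
    protected: list[tuple[str, int, int]] = []
    sites = list(protect.perfect_sites) if protect else []
    if protect:
        for iv in protect.site_spans:
            protected.append((iv.chromosome, iv.start - plen, iv.end + plen))

    n_break = int(round(break_sites * len(sites))) if sites else 0
    break_assign: dict[int, list[tuple[str, int, str]]] = {}
    if n_break:
        picked = rng.choice(len(sites), size=n_break, replace=False)
        for si in picked:
            ai = int(rng.integers(n_assemblies))
            break_assign.setdefault(ai, []).append(sites[int(si)])

    assemblies: list[GenomeAssembly] = []
    broken_per_assembly: list[list[tuple[str, int, str]]] = []
    for ai in range(n_assemblies):
        seqs = {c: bytearray(s, "ascii") for c, s in ancestor.chromosomes.items()}
        for chrom, seq in seqs.items():
            L = len(seq)
            is_protected = np.zeros(L, dtype=bool)
            for c, a, b in protected:
                if c == chrom:
                    is_protected[max(0, a) : min(L, b)] = True
            n_snp = rng.binomial(L, snp_rate)
            for p in rng.integers(0, L, size=n_snp):
                p = int(p)
                if is_protected[p]:
                    continue
                old = chr(seq[p])
                if old == "N":
                    continue
                seq[p] = ord([b for b in "ACGT" if b != old][int(rng.integers(3))])
            n_indel = rng.binomial(L, indel_rate)
            # indels are applied right-to-left so positions stay valid
            for p in sorted((int(x) for x in rng.integers(0, L, size=n_indel)), reverse=True):
                if p >= len(seq) or is_protected[min(p, L - 1)]:
                    continue
                size = int(rng.integers(1, 6))
                if rng.integers(2) == 0:
                    ins = rng.choice(_BASES, size=size).tobytes()
                    seq[p:p] = ins
                else:
                    del seq[p : p + size]
        for chrom, start, strand in break_assign.get(ai, []):
            # one substitution in the seed block destroys the site
            if strand == "+":
                p = start + policy.distal_len + int(rng.integers(policy.seed_len))
            else:
                p = start + int(rng.integers(policy.seed_len))
            old = chr(seqs[chrom][p])
            seqs[chrom][p] = ord(
                [b for b in "ACGT" if b != old][int(rng.integers(3))]
            )
        assemblies.append(
            GenomeAssembly(
                {c: bytes(s).decode("ascii") for c, s in seqs.items()},
                name=f"{ancestor.name}.derived{ai}",
            )
        )
        broken_per_assembly.append(break_assign.get(ai, []))
    return assemblies, broken_per_assembly


# ---------------------------------------------------------------------------
# quantitation input simulation


@dataclass
class SimulatedQuantData:
    ct_table: pd.DataFrame
    insertion_table: pd.DataFrame
    te_table: pd.DataFrame
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_quant_inputs(
    copy_numbers: dict[str, float],
    reference_genes: tuple[str, ...] = ("Dmn", "Und", "nos"),
    reference_ct: float = 20.0,
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    te_families: dict[str, tuple[float, int]] | None = None,
    depth: float = 20.0,
    read_length_total: int = 300,
    insertions: list[tuple[int, float]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedQuantData:
    """Simulate qPCR CT tables, insertion-call tables and TE read counts.

    CT construction inverts the doubling model: a sample with true copy
    number c gets target CT = reference CT - log2(c), plus Gaussian
    replicate noise, so the noise-free estimator recovers c exactly.
    TE read counts are Poisson with mean copies x consensus_length x
    depth / read_length_total. Insertion calls carry the requested
    (support, coverage frequency) pairs.
    """
    if any(c <= 0 for c in copy_numbers.values()):
        raise ConfigurationError("copy-number truth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, c in copy_numbers.items():
        target_ct = reference_ct - float(np.log2(c))
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample_id": sample,
                    "assay": "target",
                    "replicate": rep + 1,
                    "ct": target_ct + rng.normal(0.0, noise_sd),
                }
            )
            for gene in reference_genes:
                rows.append(
                    {
                        "sample_id": sample,
                        "assay": gene,
                        "replicate": rep + 1,
                        "ct": reference_ct + rng.normal(0.0, noise_sd),
                    }
                )
    ct_table = pd.DataFrame(rows)

    if insertions is None:
        insertions = [(int(s), float(f)) for s, f in zip(
            rng.integers(1, 30, size=40), rng.uniform(0.05, 1.0, size=40)
        )]
    ins_rows = [
        {
            "chromosome": f"chr{1 + i % 3}",
            "position": 1000 * (i + 1),
            "support_reads": sup,
            "coverage_frequency": round(freq, 4),
        }
        for i, (sup, freq) in enumerate(insertions)
    ]
    insertion_table = pd.DataFrame(
        ins_rows,
        columns=["chromosome", "position", "support_reads", "coverage_frequency"],
    )

    te_families = te_families or {"TEfam1": (8.0, 3000)}
    te_rows = []
    for family, (copies, consensus_len) in te_families.items():
        mean_reads = copies * consensus_len * depth / read_length_total
        te_rows.append(
            {
                "family": family,
                "mapped_read_count": int(rng.poisson(mean_reads)),
                "consensus_length": consensus_len,
            }
        )
    te_table = pd.DataFrame(te_rows)

    truth = {
        "copy_numbers": dict(copy_numbers),
        "reference_ct": reference_ct,
        "te_families": {f: c for f, (c, _) in te_families.items()},
        "depth": depth,
        "read_length_total": read_length_total,
        "insertions": insertions,
        "seed": seed,
    }
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["ct"] = out_dir / "ct_table.tsv"
        ct_table.to_csv(paths["ct"], sep="\t", index=False)
        paths["insertions"] = out_dir / "insertion_calls.tsv"
        insertion_table.to_csv(paths["insertions"], sep="\t", index=False)
        paths["te"] = out_dir / "te_read_counts.tsv"
        te_table.to_csv(paths["te"], sep="\t", index=False)
        paths["truth"] = out_dir / "truth.tsv"
        pd.DataFrame(
            [{"key": k, "value": repr(v)} for k, v in truth.items()]
        ).to_csv(paths["truth"], sep="\t", index=False)
    return SimulatedQuantData(ct_table, insertion_table, te_table, truth, paths)
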