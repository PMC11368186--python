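"""Guide candidate generation, hit counting and multiplicity selection.

The hit model mirrors heuristic short-read mapping of 20-nt guide
sequences: a genomic site counts as a hit when the 12 bases adjacent to
the PAM (the seed, or proximal block) match perfectly and the 8 bases
furthest from the PAM (the distal block) carry at most two mismatches.
Sites whose distal block mismatches are tolerated during counting but
disqualify a guide from selection: a selected guide's hits are all
perfect, all inside the allowed (intron/TE) regions, all on the
configured chromosomes, and pairwise separated by a minimum spacing.

Scanning is seed-indexed: each chromosome is hashed once into a sorted
table of seed-length k-mer codes, and every guide lookup reduces to a
binary search plus per-site distal/PAM verification. The brute-force
position-by-position scan in :mod:`multiguide.synthesis` serves as the
independent oracle for this index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import (
    encode,
    is_valid_iupac,
    iupac_masks,
    matches_iupac,
    revcomp,
    revcomp_iupac,
)
from .errors import ConfigurationError
from .model import GenomeAssembly, Interval, RegionSet

logger = logging.getLogger(__name__)

REJECTION_REASONS = (
    "simple_repeat",
    "mismatched_hit",
    "off_region_hit",
    "off_chromosome_hit",
    "clustered_hits",
    "no_hits",
)


@dataclass(frozen=True)
class MatchPolicy:
    """Parameters of the seed/distal mismatch model.

    guide_len
        protospacer length in bases (20).
    seed_len
        PAM-adjacent block requiring a perfect match (12).
    distal_len
        PAM-distal block (8) tolerating up to ``max_distal_mm``
        mismatches (2) at counted sites.
    pam
        IUPAC motif required 3' of the protospacer (NGG).
    require_5prime_g
        candidate guides must start with G (U6-promoter convention).
    require_pam_at_hits
        when False, hit counting ignores the PAM flank and behaves like
        a plain short-read aligner mapping bare 20-mers.
    """

    guide_len: int = 20
    seed_len: int = 12
    distal_len: int = 8
    max_distal_mm: int = 2
    pam: str = "NGG"
    require_5prime_g: bool = True
    require_pam_at_hits: bool = True

    def __post_init__(self):
        if self.seed_len + self.distal_len != self.guide_len:
            raise ConfigurationError(
                f"seed_len {self.seed_len} + distal_len {self.distal_len} "
                f"must equal guide_len {self.guide_len}"
            )
        if not 0 <= self.max_distal_mm <= self.distal_len:
            raise ConfigurationError(
                f"max_distal_mm {self.max_distal_mm} exceeds distal_len"
            )
        if not is_valid_iupac(self.pam):
            raise ConfigurationError(f"invalid IUPAC PAM {self.pam!r}")


@dataclass(frozen=True)
class RepeatFilterPolicy:
    """Simple-repeat exclusion: >= min_units tandem copies of a unit of
    length <= max_unit_len (defaults exclude AAAA and ACACACAC)."""

    max_unit_len: int = 2
    min_units: int = 4

    def __post_init__(self):
        if self.min_units < 2:
            raise ConfigurationError("min_units must be >= 2")
        if self.max_unit_len < 1:
            raise ConfigurationError("max_unit_len must be >= 1")


@dataclass(frozen=True)
class ProximityPolicy:
    """Minimum distance between the starts of any two hits of one guide
    on the same chromosome; closer pairs reject the guide (clustered
    cuts risk rearrangements and large deletions)."""

    min_site_spacing: int = 10_000

    def __post_init__(self):
        if self.min_site_spacing < 0:
            raise ConfigurationError("min_site_spacing must be >= 0")


@dataclass(frozen=True)
class GuideCandidate:
    guide_id: str
    sequence: str
    source: Interval | None = None


@dataclass
class HitRecord:
    chromosome: str
    start: int  # 0-based protospacer start in + strand coordinates
    strand: str
    seed_mismatches: int = 0
    distal_mismatches: int = 0
    pam_present: bool = True
    inside_allowed: bool | None = None

    def sort_key(self):
        return (self.chromosome, self.start, 0 if self.strand == "+" else 1)


@dataclass
class GuideReport:
    candidate: GuideCandidate
    hits: list[HitRecord]
    per_chromosome_counts: dict[str, int]
    multiplicity: int
    status: str  # "selected" | "rejected"
    rejection_reasons: list[str] = field(default_factory=list)


def has_simple_repeat(sequence: str, repeat_policy: RepeatFilterPolicy | None = None) -> bool:
    """True iff the sequence contains >= min_units exact tandem copies of
    a primitive unit of length <= max_unit_len.

    Self-periodic units (e.g. "AA") are canonicalized to their shortest
    period before counting, so a run is always attributed to its
    primitive repeat unit.
    """
    policy = repeat_policy or RepeatFilterPolicy()
    if not sequence:
        raise ValueError("sequence must be nonempty")
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must contain only A/C/G/T")
    n = len(sequence)
    for unit_len in range(1, policy.max_unit_len + 1):
        for i in range(n - unit_len * policy.min_units + 1):
            unit = sequence[i : i + unit_len]
            # skip non-primitive units; their runs are counted at the
            # shorter period
            if unit_len > 1 and any(
                unit == unit[:p] * (unit_len // p)
                for p in range(1, unit_len)
                if unit_len % p == 0
            ):
                continue
            count = 1
            j = i + unit_len
            while sequence[j : j + unit_len] == unit:
                count += 1
                j += unit_len
            if count >= policy.min_units:
                return True
    return False


class SeedIndex:
    """Sorted k-mer code table per chromosome for seed lookups.

    Each seed-length window is encoded as a base-4 integer (windows
    containing N are dropped); positions are stored sorted by code so a
    lookup is a binary search.
    """

    def __init__(self, genome: GenomeAssembly, seed_len: int):
        self.genome = genome
        self.seed_len = seed_len
        self._powers = 4 ** np.arange(seed_len - 1, -1, -1, dtype=np.int64)
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in genome.chromosomes:
            codes = genome.encoded(chrom)
            n = codes.size - seed_len + 1
            if n <= 0:
                self._tables[chrom] = (
                    np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64),
                )
                continue
            h = np.zeros(n, dtype=np.int64)
            for j in range(seed_len):
                h += codes[j : j + n].astype(np.int64) * int(self._powers[j])
            has_n = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
            bad = (has_n[seed_len:] - has_n[:-seed_len]) > 0
            h[bad] = -1
            order = np.argsort(h, kind="stable").astype(np.int64)
            self._tables[chrom] = (h[order], order)

    def positions(self, chrom: str, kmer: str) -> np.ndarray:
        """Ascending start positions of exact occurrences of *kmer*."""
        codes = encode(kmer)
        if (codes == 4).any():
            return np.empty(0, dtype=np.int64)
        h = int(codes.astype(np.int64) @ self._powers)
        sorted_h, order = self._tables[chrom]
        lo = np.searchsorted(sorted_h, h, side="left")
        hi = np.searchsorted(sorted_h, h, side="right")
        return np.sort(order[lo:hi])


def _count_mismatches(codes: np.ndarray, start: int, pattern: np.ndarray) -> int:
    """Mismatch count of genome block vs pattern; genome N never matches."""
    block = codes[start : start + pattern.size]
    return int((block != pattern).sum())


def find_hits(
    guide: GuideCandidate | str,
    genome: GenomeAssembly,
    match_policy: MatchPolicy | None = None,
    index: SeedIndex | None = None,
) -> list[HitRecord]:
    """All genomic hits of a guide under the seed/distal model.

    Both strands are scanned. A site is a hit iff the seed block matches
    exactly, the distal block has at most ``max_distal_mm`` mismatches,
    the protospacer span is N-free, and (when required) the 3'-flanking
    PAM matches. Hits are sorted by (chromosome, start, strand).
    """
    policy = match_policy or MatchPolicy()
    seq = guide.sequence if isinstance(guide, GuideCandidate) else guide
    if len(seq) != policy.guide_len:
        raise ValueError(
            f"guide length {len(seq)} != policy guide_len {policy.guide_len}"
        )
    if "N" in seq:
        raise ValueError("guide sequence must not contain N")
    if index is None:
        index = SeedIndex(genome, policy.seed_len)
    elif index.seed_len != policy.seed_len:
        raise ValueError("index seed length does not match policy")

    glen, dlen, plen = policy.guide_len, policy.distal_len, len(policy.pam)
    seed = seq[dlen:]
    distal_fwd = encode(seq[:dlen])
    distal_rev = encode(revcomp(seq[:dlen]))
    pam_fwd = iupac_masks(policy.pam)
    pam_rev = iupac_masks(revcomp_iupac(policy.pam))

    hits: list[HitRecord] = []
    for chrom in genome.chromosomes:
        codes = genome.encoded(chrom)
        L = codes.size
        # + strand: seed occupies [s+dlen, s+glen), PAM at [s+glen, s+glen+plen)
        for p in index.positions(chrom, seed):
            s = int(p) - dlen
            if s < 0 or s + glen > L:
                continue
            if (codes[s : s + glen] == 4).any():
                continue
            mm = _count_mismatches(codes, s, distal_fwd)
            if mm > policy.max_distal_mm:
                continue
            pam_ok = _pam_matches(codes, s + glen, pam_fwd)
            if policy.require_pam_at_hits and not pam_ok:
                continue
            hits.append(HitRecord(chrom, s, "+", 0, mm, pam_ok))
        # - strand: protospacer at + coords [s, s+glen) with the seed as
        # its reverse complement at [s, s+slen); PAM at [s-plen, s)
        for p in index.positions(chrom, revcomp(seed)):
            s = int(p)
            if s + glen > L:
                continue
            if (codes[s : s + glen] == 4).any():
                continue
            mm = _count_mismatches(codes, s + policy.seed_len, distal_rev)
            if mm > policy.max_distal_mm:
                continue
            pam_ok = s - plen >= 0 and _pam_matches(codes, s - plen, pam_rev)
            if policy.require_pam_at_hits and not pam_ok:
                continue
            hits.append(HitRecord(chrom, s, "-", 0, mm, pam_ok))
    hits.sort(key=HitRecord.sort_key)
    return hits


def _pam_matches(codes: np.ndarray, start: int, masks: np.ndarray) -> bool:
    if start < 0 or start + masks.shape[0] > codes.size:
        return False
    block = codes[start : start + masks.shape[0]]
    return bool(masks[np.arange(masks.shape[0]), block].all())


def evaluate_guide(
    guide: GuideCandidate,
    hits: Sequence[HitRecord],
    allowed: RegionSet,
    chromosomes: Sequence[str],
    proximity: ProximityPolicy | None = None,
) -> GuideReport:
    """Apply the selection filters and assemble a report.

    All applicable rejection reasons are reported, not just the first.
    Multiplicity counts perfect (0-mismatch) hits only.
    """
    proximity = proximity or ProximityPolicy()
    glen = len(guide.sequence)
    listed = set(chromosomes)
    reasons: set[str] = set()
    annotated: list[HitRecord] = []
    per_chrom: dict[str, int] = {}
    for h in hits:
        inside = allowed.contains(h.chromosome, h.start, h.start + glen)
        annotated.append(replace(h, inside_allowed=inside))
        per_chrom[h.chromosome] = per_chrom.get(h.chromosome, 0) + 1
        if h.distal_mismatches > 0:
            reasons.add("mismatched_hit")
        if not inside:
            reasons.add("off_region_hit")
        if h.chromosome not in listed:
            reasons.add("off_chromosome_hit")
    starts_by_chrom: dict[str, list[int]] = {}
    for h in annotated:
        starts_by_chrom.setdefault(h.chromosome, []).append(h.start)
    for starts in starts_by_chrom.values():
        starts.sort()
        if any(
            b - a < proximity.min_site_spacing
            for a, b in zip(starts, starts[1:])
        ):
            reasons.add("clustered_hits")
    if not hits:
        reasons.add("no_hits")
    multiplicity = sum(1 for h in annotated if h.distal_mismatches == 0)
    ordered = [r for r in REJECTION_REASONS if r in reasons]
    return GuideReport(
        candidate=guide,
        hits=annotated,
        per_chromosome_counts=per_chrom,
        multiplicity=multiplicity,
        status="selected" if not ordered else "rejected",
        rejection_reasons=ordered,
    )


def draw_quotas(
    lengths: Mapping[str, int], n: int, rng: np.random.Generator
) -> dict[str, int]:
    """Multinomial per-chromosome draw counts, probabilities proportional
    to chromosome length. Chromosomes are taken in sorted name order."""
    chroms = sorted(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n, probs)
    return dict(zip(chroms, (int(c) for c in counts)))


DEFAULT_POOL_SIZE = 500_000  # initial candidate pool before deduplication
MAX_RETRY_FACTOR = 50  # attempts allowed per chromosome, x nominal quota


def sample_candidates(
    genome: GenomeAssembly,
    allowed: RegionSet,
    n: int,
    seed: int,
    match_policy: MatchPolicy | None = None,
    repeat_policy: RepeatFilterPolicy | None = None,
    exclude_softmask: bool = False,
) -> list[GuideCandidate]:
    """Draw guide candidates from random positions inside allowed regions.

    Exactly *n* draws are attempted, split across chromosomes by a
    seeded multinomial with probabilities proportional to chromosome
    length. A draw is accepted when the protospacer lies fully inside an
    allowed interval, starts with G (when required), is N-free, is
    followed by a PAM on its source strand, and passes the simple-repeat
    filter; rejected draws are retried up to ``MAX_RETRY_FACTOR`` times
    the chromosome quota. Duplicate sequences collapse to one candidate;
    identifiers are assigned in first-draw order.
    """
    policy = match_policy or MatchPolicy()
    rpolicy = repeat_policy or RepeatFilterPolicy()
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if n == 0:
        return []
    region_chroms = sorted(
        {iv.chromosome for iv in allowed.intervals} & set(genome.chromosomes)
    )
    if not region_chroms:
        raise ConfigurationError("allowed region set is empty on this genome")

    rng = np.random.default_rng(seed)
    quotas = draw_quotas(
        {c: genome.lengths[c] for c in region_chroms}, n, rng
    )
    merged = allowed.merged()
    glen, plen = policy.guide_len, len(policy.pam)

    seen: dict[str, GuideCandidate] = {}
    order: list[str] = []
    next_id = 1
    for chrom in region_chroms:
        quota = quotas[chrom]
        if quota == 0:
            continue
        ivs = [iv for iv in merged.intervals if iv.chromosome == chrom]
        starts = np.array(
            [iv.start for iv in ivs if len(iv) >= glen], dtype=np.int64
        )
        counts = np.array(
            [len(iv) - glen + 1 for iv in ivs if len(iv) >= glen],
            dtype=np.int64,
        )
        if counts.size == 0:
            logger.warning(
                "%s: allowed intervals too short for %d-base guides", chrom, glen
            )
            continue
        cum = np.concatenate(([0], np.cumsum(counts)))
        total = int(cum[-1])
        chrom_seq = genome.chromosomes[chrom]
        L = len(chrom_seq)
        mask_ivs = genome.softmask.get(chrom, []) if exclude_softmask else []
        accepted = 0
        attempts = 0
        budget = quota * MAX_RETRY_FACTOR
        while accepted < quota and attempts < budget:
            attempts += 1
            r = int(rng.integers(total))
            k = int(np.searchsorted(cum, r, side="right")) - 1
            s = int(starts[k] + (r - cum[k]))
            strand = "+" if rng.integers(2) == 0 else "-"
            if strand == "+":
                if s + glen + plen > L:
                    continue
                seq = chrom_seq[s : s + glen]
                pam = chrom_seq[s + glen : s + glen + plen]
            else:
                if s - plen < 0:
                    continue
                seq = revcomp(chrom_seq[s : s + glen])
                pam = revcomp(chrom_seq[s - plen : s])
            if "N" in seq or "N" in pam:
                continue
            if policy.require_5prime_g and not seq.startswith("G"):
                continue
            if not matches_iupac(pam, policy.pam):
                continue
            if has_simple_repeat(seq, rpolicy):
                continue
            if mask_ivs and any(a < s + glen and s < b for a, b in mask_ivs):
                continue
            accepted += 1
            if seq not in seen:
                cand = GuideCandidate(
                    guide_id=f"g{next_id:06d}",
                    sequence=seq,
                    source=Interval(chrom, s, s + glen, strand),
                )
                next_id += 1
                seen[seq] = cand
                order.append(seq)
        if accepted < quota:
            logger.warning(
                "%s: drew %d of %d requested candidates (shortfall %d)",
                chrom,
                accepted,
                quota,
                quota - accepted,
            )
    return [seen[s] for s in order]


@dataclass
class SearchResult:
    """All guide reports plus a by-multiplicity view of selected guides."""

    reports: list[GuideReport]

    def selection_view(
        self, requested: Iterable[int] | None = None
    ) -> dict[int, list[GuideReport]]:
        groups: dict[int, list[GuideReport]] = {}
        for rep in self.reports:
            if rep.status == "selected":
                groups.setdefault(rep.multiplicity, []).append(rep)
        if requested is None:
            return dict(sorted(groups.items()))
        view: dict[int, list[GuideReport]] = {}
        for k in sorted(set(requested)):
            view[k] = groups.get(k, [])
            if not view[k]:
                logger.warning("no selected guide with multiplicity %d", k)
        return view


def run_search(config) -> SearchResult:
    """End-to-end search: read inputs, sample, count hits, select.

    *config* is a :class:`multiguide.config.RunConfig`. Deterministic
    given identical inputs and seed.
    """
    from . import genome_io

    genome = genome_io.read_fasta(config.genome)
    unknown = [c for c in config.chromosomes if c not in genome]
    if unknown:
        raise ConfigurationError(
            f"chromosomes not in genome: {', '.join(unknown)}"
        )
    introns = (
        genome_io.derive_introns(config.gtf)
        if config.gtf
        else RegionSet([], "intron")
    )
    tes = (
        genome_io.read_repeatmasker(config.repeats)
        if config.repeats
        else RegionSet([], "TE")
    )
    allowed = genome_io.build_allowed_regions(introns, tes, config.chromosomes)
    candidates = sample_candidates(
        genome,
        allowed,
        config.n_candidates,
        config.seed,
        config.match_policy,
        config.repeat_policy,
        exclude_softmask=config.respect_softmask,
    )
    index = SeedIndex(genome, config.match_policy.seed_len)
    reports = []
    for cand in candidates:
        hits = find_hits(cand, genome, config.match_policy, index)
        reports.append(
            evaluate_guide(
                cand, hits, allowed, config.chromosomes, config.proximity_policy
            )
        )
    return SearchResult(reports)
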