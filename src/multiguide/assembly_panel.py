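"""Multi-assembly guide validation and amplicon edit classification.

A guide designed on a reference genome is re-counted on a panel of
strain assemblies; the diploid target number is twice the mean haploid
perfect-hit count across the panel, with a concordance flag when all
assemblies agree. Amplicons Sanger-sequenced across a cut site are
classified edited/unedited from an end-gap-free pairwise alignment to
the unedited reference region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .errors import ConfigurationError
from .guide_search import GuideCandidate, HitRecord, MatchPolicy, find_hits
from .model import GenomeAssembly

logger = logging.getLogger(__name__)

#: blunt cut position: 3 bases 5' of the PAM
CUT_OFFSET_FROM_PAM = 3
DEFAULT_EDIT_WINDOW = 20


@dataclass
class PanelCount:
    guide_id: str
    per_assembly: dict[str, int]
    per_assembly_hits: dict[str, list[HitRecord]]
    near_miss: dict[str, int] = field(default_factory=dict)


@dataclass
class DiploidTargetCount:
    guide_id: str
    mean_haploid: float
    diploid_exact: float
    diploid_reported: int
    concordant: bool


@dataclass
class Difference:
    position: int  # event start relative to the cut site
    type: str  # substitution | insertion | deletion
    length: int
    in_window: bool


@dataclass
class EditCall:
    amplicon_id: str
    classification: str  # edited | unedited
    evidence: list[Difference]


def count_on_panel(
    guide: GuideCandidate | str,
    assemblies: Sequence[GenomeAssembly],
    match_policy: MatchPolicy | None = None,
) -> PanelCount:
    """Perfect-hit counts of one guide on each assembly of a panel.

    Near-miss hits (distal mismatches within the counting tolerance) do
    not contribute to the haploid count; they are tallied separately and
    logged as warnings.
    """
    if not assemblies:
        raise ConfigurationError("assembly panel must not be empty")
    policy = match_policy or MatchPolicy()
    guide_id = guide.guide_id if isinstance(guide, GuideCandidate) else "guide"
    per_assembly: dict[str, int] = {}
    per_hits: dict[str, list[HitRecord]] = {}
    near: dict[str, int] = {}
    for i, asm in enumerate(assemblies):
        name = asm.name or f"assembly{i + 1}"
        if name in per_assembly:
            name = f"{name}#{i + 1}"
        hits = find_hits(guide, asm, policy)
        perfect = [h for h in hits if h.distal_mismatches == 0]
        n_near = len(hits) - len(perfect)
        if n_near:
            logger.warning(
                "%s on %s: %d near-miss hit(s) excluded from the haploid count",
                guide_id,
                name,
                n_near,
            )
        per_assembly[name] = len(perfect)
        per_hits[name] = hits
        near[name] = n_near
    return PanelCount(guide_id, per_assembly, per_hits, near)


def diploid_count(panel: PanelCount) -> DiploidTargetCount:
    """Diploid target number: twice the mean haploid count over the panel."""
    counts = list(panel.per_assembly.values())
    mean = sum(counts) / len(counts)
    exact = 2.0 * mean
    reported = int(math.floor(exact + 0.5))  # half away from zero (counts >= 0)
    return DiploidTargetCount(
        guide_id=panel.guide_id,
        mean_haploid=mean,
        diploid_exact=exact,
        diploid_reported=reported,
        concordant=len(set(counts)) == 1,
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # end gaps free: amplicons rarely cover the whole reference region
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def classify_edit(
    reference_region: str,
    amplicon: str,
    cut_offset: int,
    window: int = DEFAULT_EDIT_WINDOW,
    amplicon_id: str = "amplicon",
) -> EditCall:
    """Classify an amplicon as edited or unedited around a cut site.

    The amplicon is aligned to the reference region end-gap-free;
    substitutions and indels whose span intersects cut_offset +/- window
    flip the call to edited. Differences outside the window are reported
    as evidence but do not affect the classification.
    """
    if not 0 <= cut_offset <= len(reference_region):
        raise ValueError("cut_offset outside reference region")
    if len(amplicon) < 2 * window:
        logger.warning(
            "%s: amplicon (%d bp) shorter than the 2x%d bp inspection "
            "window; classifying on the available span",
            amplicon_id,
            len(amplicon),
            window,
        )
    alignment = _aligner().align(reference_region, amplicon)[0]
    t_blocks, q_blocks = alignment.aligned
    lo, hi = cut_offset - window, cut_offset + window

    def in_window(start: int, length: int) -> bool:
        # closed window; zero-length events (insertions) are points
        return start <= hi and (start + max(length, 1) - 1) >= lo

    evidence: list[Difference] = []
    for i, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        run_start = None
        for k in range(te - ts):
            if reference_region[ts + k] != amplicon[qs + k]:
                if run_start is None:
                    run_start = ts + k
            elif run_start is not None:
                length = ts + k - run_start
                evidence.append(
                    Difference(
                        run_start - cut_offset,
                        "substitution",
                        length,
                        in_window(run_start, length),
                    )
                )
                run_start = None
        if run_start is not None:
            length = te - run_start
            evidence.append(
                Difference(
                    run_start - cut_offset,
                    "substitution",
                    length,
                    in_window(run_start, length),
                )
            )
        if i + 1 < len(t_blocks):
            nts, nqs = t_blocks[i + 1][0], q_blocks[i + 1][0]
            if nts > te:  # reference bases absent from the amplicon
                evidence.append(
                    Difference(
                        te - cut_offset, "deletion", nts - te, in_window(te, nts - te)
                    )
                )
            if nqs > qe:  # amplicon bases absent from the reference
                evidence.append(
                    Difference(te - cut_offset, "insertion", nqs - qe, in_window(te, 0))
                )
    classification = (
        "edited" if any(d.in_window for d in evidence) else "unedited"
    )
    return EditCall(amplicon_id, classification, evidence)


def cut_offset_for_protospacer(
    protospacer_start: int, strand: str, guide_len: int = 20
) -> int:
    """Blunt cut coordinate for a protospacer given in + strand coordinates."""
    if strand == "+":
        return protospacer_start + guide_len - CUT_OFFSET_FROM_PAM
    return protospacer_start + CUT_OFFSET_FROM_PAM


def edit_rate(calls: Iterable[EditCall]) -> float:
    """Fraction of calls classified edited."""
    calls = list(calls)
    if not calls:
        raise ValueError("edit_rate of an empty call set is undefined")
    return sum(1 for c in calls if c.classification == "edited") / len(calls)
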