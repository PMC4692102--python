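"""Genomic context of repeat hits relative to ORF annotations.

Classifies each repeat as intragenic (coding / non-coding strand) or
intergenic, derives the orientation class of the flanking ORFs
(aligned / convergent / divergent), measures distances to the nearest
start and stop codons with the 0-50 / 50-100 / >100 bp binning used for
the distance distributions, and detects convergent inverted repeat
pairs (a plus-strand array followed by a nearby minus-strand array).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .genome_io import ContractError, OrfAnnotation
from .repeat_scanner import RepeatHit

__all__ = [
    "NeighborRelation",
    "ContextAnnotation",
    "InvertedPair",
    "classify_location",
    "orientation_class",
    "neighbor_relations",
    "distance_bin",
    "detect_inverted_pairs",
    "annotate_contexts",
]

LOCATION_CLASSES = ("intragenic_coding", "intragenic_noncoding", "intergenic")
ORIENTATION_CLASSES = (
    "aligned_coding",
    "aligned_noncoding",
    "convergent",
    "divergent",
    "undefined",
)


@dataclass(frozen=True)
class NeighborRelation:
    """Relation of an intergenic repeat to one flanking ORF."""

    orf_locus_tag: str
    relation: str  # repeat_upstream_of_orf | repeat_downstream_of_orf
    strand_relation: str  # coding | noncoding
    distance: int  # bases strictly between repeat and codon boundary; 0 on overlap
    bin: str  # d0_50 | d50_100 | d_gt100


@dataclass(frozen=True)
class ContextAnnotation:
    """Context of one repeat.  ``upstream_relation`` is the relation to the
    genomically preceding (left) flanking ORF, ``downstream_relation`` to
    the following (right) one; each relation records on its own whether
    the repeat lies upstream or downstream of that ORF's reading frame."""

    repeat_id: str
    location_class: str
    orientation_class: str  # "undefined" for intragenic repeats
    overlapped_orf: Optional[str] = None
    upstream_relation: Optional[NeighborRelation] = None
    downstream_relation: Optional[NeighborRelation] = None


@dataclass(frozen=True)
class InvertedPair:
    plus_repeat_id: str
    minus_repeat_id: str
    gap: int


def distance_bin(d: int) -> str:
    """Bin a repeat-to-codon distance: <=50, 50-100 (upper-inclusive), >100."""
    if d < 0:
        raise ContractError("distance must be >= 0")
    if d <= 50:
        return "d0_50"
    if d <= 100:
        return "d50_100"
    return "d_gt100"


def classify_location(
    hit: RepeatHit, orfs: Sequence[OrfAnnotation]
) -> tuple[str, Optional[OrfAnnotation]]:
    """Intragenic (any base overlap with an ORF) vs intergenic.

    Ties among several overlapped ORFs go to the largest overlap, then
    the smallest ORF start.  ``orfs`` must be sorted by start.
    """
    best: Optional[OrfAnnotation] = None
    best_ov = 0
    for orf in orfs:
        if orf.start >= hit.end:
            break
        ov = min(hit.end, orf.end) - max(hit.start, orf.start)
        if ov > 0 and (ov > best_ov or (ov == best_ov and best and orf.start < best.start)):
            best, best_ov = orf, ov
    if best is None:
        return "intergenic", None
    cls = "intragenic_coding" if hit.strand == best.strand else "intragenic_noncoding"
    return cls, best


def _flanking_orfs(
    hit: RepeatHit, orfs: Sequence[OrfAnnotation]
) -> tuple[Optional[OrfAnnotation], Optional[OrfAnnotation]]:
    """Nearest ORF fully left of the hit, and fully right of it.

    Nearest is by boundary distance; ties go to the ORF with the
    smaller start.  Assumes the hit overlaps no ORF (intergenic).
    """
    left = right = None
    for orf in orfs:
        if orf.end <= hit.start:
            if left is None or orf.end > left.end:
                left = orf
        elif orf.start >= hit.end:
            if right is None or orf.start < right.start:
                right = orf
    return left, right


def orientation_class(
    left_orf: Optional[OrfAnnotation],
    right_orf: Optional[OrfAnnotation],
    repeat_strand: str,
) -> str:
    """Orientation of the flanking ORFs around an intergenic repeat."""
    if left_orf is None or right_orf is None:
        return "undefined"
    if left_orf.strand == right_orf.strand:
        return (
            "aligned_coding"
            if repeat_strand == left_orf.strand
            else "aligned_noncoding"
        )
    if left_orf.strand == "+":  # and right is "-"
        return "convergent"
    return "divergent"


def _relation_for_neighbor(
    hit: RepeatHit, orf: OrfAnnotation, side: str
) -> NeighborRelation:
    """Relation and distance for one flanking ORF.

    ``side`` is "left" (ORF before the hit) or "right" (ORF after).
    The ORF's own orientation decides upstream vs downstream: a repeat
    before an ORF's start codon is upstream of it, after its stop codon
    downstream.
    """
    if side == "left":
        gap = hit.start - orf.end
        relation = (
            "repeat_downstream_of_orf" if orf.strand == "+" else "repeat_upstream_of_orf"
        )
    else:
        gap = orf.start - hit.end
        relation = (
            "repeat_upstream_of_orf" if orf.strand == "+" else "repeat_downstream_of_orf"
        )
    d = max(0, gap)
    return NeighborRelation(
        orf_locus_tag=orf.locus_tag,
        relation=relation,
        strand_relation="coding" if hit.strand == orf.strand else "noncoding",
        distance=d,
        bin=distance_bin(d),
    )


def neighbor_relations(
    hit: RepeatHit, orfs: Sequence[OrfAnnotation]
) -> list[NeighborRelation]:
    """Up to two relations (left and right flanking ORF) for an intergenic hit."""
    left, right = _flanking_orfs(hit, orfs)
    out = []
    if left is not None:
        out.append(_relation_for_neighbor(hit, left, "left"))
    if right is not None:
        out.append(_relation_for_neighbor(hit, right, "right"))
    return out


def annotate_contexts(
    hits: Sequence[RepeatHit], orfs: Sequence[OrfAnnotation]
) -> list[ContextAnnotation]:
    """Full context annotation for every hit; ORFs must be sorted by start."""
    out = []
    for hit in hits:
        loc, overlapped = classify_location(hit, orfs)
        if loc != "intergenic":
            out.append(
                ContextAnnotation(
                    repeat_id=hit.repeat_id,
                    location_class=loc,
                    orientation_class="undefined",
                    overlapped_orf=overlapped.locus_tag if overlapped else None,
                )
            )
            continue
        left, right = _flanking_orfs(hit, orfs)
        ori = orientation_class(left, right, hit.strand)
        upstream = (
            _relation_for_neighbor(hit, left, "left") if left is not None else None
        )
        downstream = (
            _relation_for_neighbor(hit, right, "right") if right is not None else None
        )
        out.append(
            ContextAnnotation(
                repeat_id=hit.repeat_id,
                location_class="intergenic",
                orientation_class=ori,
                upstream_relation=upstream,
                downstream_relation=downstream,
            )
        )
    return out


def detect_inverted_pairs(
    hits: Sequence[RepeatHit], max_gap: int = 100
) -> list[InvertedPair]:
    """Convergent inverted pairs: a "+" hit whose end precedes a "-" hit's
    start by at most ``max_gap`` bases.

    Each hit joins at most one pair; candidate pairs are matched by
    nearest gap first, ties to the leftmost partner.
    """
    plus = [h for h in hits if h.strand == "+"]
    minus = [h for h in hits if h.strand == "-"]
    cands = []
    for p in plus:
        for m in minus:
            gap = m.start - p.end
            if 0 <= gap <= max_gap:
                cands.append((gap, p.start, m.start, p, m))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[str] = set()
    pairs = []
    for gap, _, _, p, m in cands:
        if p.repeat_id in used or m.repeat_id in used:
            continue
        used.update((p.repeat_id, m.repeat_id))
        pairs.append(InvertedPair(p.repeat_id, m.repeat_id, gap))
    return sorted(pairs, key=lambda pr: pr.plus_repeat_id)
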