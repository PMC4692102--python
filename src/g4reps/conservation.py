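"""Cross-genome conservation of repeat-containing loci.

Each query locus is the repeat-containing intergenic region together
with its two flanking ORFs.  Pairwise local-alignment hits (standard
12-column tabular format) against a subject genome drive two calls:

* repeat presence — is a qualifying repeat array still found at the
  orthologous position (``conserved`` / ``absent_or_mutated`` /
  ``no_alignment``);
* region change — ``no_change``, ``insertion``, ``deletion``,
  ``flanking_change`` or ``no_homology``, from flanking-ORF homology
  and the change in inter-ORF distance.

Control sets of repeat-free intergenic regions (random, position
matched, orientation matched) and per-category one-sample t-tests
quantify whether repeat loci are more conserved than background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import betainc

from .genome_io import ContractError, FormatError, GenomeRecord, OrfAnnotation
from .repeat_scanner import RepeatHit, RepeatPreset, scan_repeats

__all__ = [
    "LocalAlignment",
    "QueryRegion",
    "ConservationCall",
    "CategoryTestResult",
    "parse_alignment_table",
    "write_alignment_table",
    "build_query_regions",
    "classify_repeat_presence",
    "classify_region",
    "classify_conservation",
    "category_fractions",
    "build_control_sets",
    "region_orientation",
    "one_sample_t",
    "run_category_tests",
]

REPEAT_STATUSES = ("conserved", "absent_or_mutated", "no_alignment")
REGION_CLASSES = ("no_change", "insertion", "deletion", "flanking_change", "no_homology")


@dataclass(frozen=True)
class LocalAlignment:
    """One row of a 12-column tabular local-alignment hit.

    Query/subject coordinates are 1-based inclusive; ``send < sstart``
    means a minus-strand alignment on the subject.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def is_minus(self) -> bool:
        return self.send < self.sstart

    @property
    def q_interval(self) -> tuple[int, int]:
        """0-based half-open query interval."""
        return self.qstart - 1, self.qend

    def map_query_interval(self, a: int, b: int) -> tuple[int, int]:
        """Map query interval [a, b) (clipped to this alignment) onto the
        subject, returned 0-based half-open on the subject forward strand.

        Assumes collinearity within the alignment (gaps ignored)."""
        qa, qb = self.q_interval
        a, b = max(a, qa), min(b, qb)
        if a >= b:
            raise ContractError("interval does not overlap alignment")
        if not self.is_minus:
            s0 = self.sstart - 1
            return s0 + (a - qa), s0 + (b - qa)
        s0 = self.sstart - 1  # highest subject offset, maps to qstart
        hi = s0 - (a - qa)
        lo = s0 - (b - 1 - qa)
        return lo, hi + 1


def parse_alignment_table(path: str | Path) -> list[LocalAlignment]:
    """Parse whitespace/tab-separated 12-column alignment rows."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                rec = LocalAlignment(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.qstart > rec.qend or rec.aln_length < 1:
                raise FormatError(f"{path}:{lineno}: invalid alignment coordinates")
            out.append(rec)
    return out


def write_alignment_table(alignments: Sequence[LocalAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.query_id}\t{a.subject_id}\t{a.percent_identity:.2f}\t"
                f"{a.aln_length}\t{a.mismatches}\t{a.gap_opens}\t{a.qstart}\t"
                f"{a.qend}\t{a.sstart}\t{a.send}\t{a.evalue:.2g}\t{a.bitscore:.1f}\n"
            )


@dataclass(frozen=True)
class QueryRegion:
    """An intergenic region with its two flanking ORFs."""

    region_id: str
    genome_id: str
    left_orf: Optional[OrfAnnotation]
    right_orf: Optional[OrfAnnotation]
    inter_start: int
    inter_end: int
    contains_repeat: bool
    repeat_id: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        """Full query span: left ORF start to right ORF end."""
        start = self.left_orf.start if self.left_orf else self.inter_start
        end = self.right_orf.end if self.right_orf else self.inter_end
        return start, end


def build_query_regions(
    orfs: Sequence[OrfAnnotation], hits: Sequence[RepeatHit]
) -> list[QueryRegion]:
    """Assemble intergenic regions flanked by two ORFs.

    Repeat-containing gaps produce one region per repeat located in the
    gap; repeat-free gaps produce one region each.  Gaps at genome ends
    (missing flank) are excluded.
    """
    regions: list[QueryRegion] = []
    ordered = sorted(orfs, key=lambda o: (o.start, o.end))
    idx = 0
    prev: Optional[OrfAnnotation] = None
    prev_end = -1
    for orf in ordered:
        if prev is not None and orf.start > prev_end:
            gs, ge = prev_end, orf.start
            inside = [h for h in hits if h.start >= gs and h.end <= ge]
            genome_id = orf.genome_id
            if inside:
                for h in sorted(inside, key=lambda h: h.start):
                    regions.append(
                        QueryRegion(
                            region_id=f"region_{idx:05d}",
                            genome_id=genome_id,
                            left_orf=prev,
                            right_orf=orf,
                            inter_start=gs,
                            inter_end=ge,
                            contains_repeat=True,
                            repeat_id=h.repeat_id,
                        )
                    )
                    idx += 1
            else:
                regions.append(
                    QueryRegion(
                        region_id=f"region_{idx:05d}",
                        genome_id=genome_id,
                        left_orf=prev,
                        right_orf=orf,
                        inter_start=gs,
                        inter_end=ge,
                        contains_repeat=False,
                    )
                )
                idx += 1
        if orf.end > prev_end:
            prev, prev_end = orf, orf.end
    return regions


@dataclass(frozen=True)
class ConservationCall:
    region_id: str
    repeat_status: str
    region_class: str


def _alignments_for_span(
    alignments: Sequence[LocalAlignment], start: int, end: int
) -> list[LocalAlignment]:
    return [
        a for a in alignments if a.q_interval[0] < end and a.q_interval[1] > start
    ]


def classify_repeat_presence(
    region: QueryRegion,
    repeat: RepeatHit,
    alignments: Sequence[LocalAlignment],
    subject_genome: GenomeRecord,
    preset: RepeatPreset,
    flank: int = 100,
) -> str:
    """Is the repeat conserved at the orthologous subject locus?

    The best alignment covering at least half of the repeat span maps it
    onto the subject; the mapped interval padded by ``flank`` is
    re-scanned with the same preset.
    """
    half = (repeat.end - repeat.start) / 2
    best = None
    best_key = (-1.0, -1.0)
    for a in alignments:
        qa, qb = a.q_interval
        ov = min(qb, repeat.end) - max(qa, repeat.start)
        if ov >= half and (ov, a.bitscore) > best_key:
            best, best_key = a, (ov, a.bitscore)
    if best is None:
        return "no_alignment"
    lo, hi = best.map_query_interval(repeat.start, repeat.end)
    lo = max(0, lo - flank)
    hi = min(subject_genome.length, hi + flank)
    if lo >= hi:
        raise ContractError("mapped subject interval outside subject genome")
    window = GenomeRecord(id="subject_window", sequence=subject_genome.sequence[lo:hi])
    return "conserved" if scan_repeats(window, preset) else "absent_or_mutated"


def _best_orf_alignment(
    orf: OrfAnnotation,
    alignments: Sequence[LocalAlignment],
    min_identity: float,
    min_coverage: float,
):
    """The best single alignment qualifying the ORF, or None."""
    best = None
    best_key = (-1.0, -1.0, -1.0)
    L = orf.end - orf.start
    for a in alignments:
        if a.percent_identity < min_identity:
            continue
        qa, qb = a.q_interval
        ov = min(qb, orf.end) - max(qa, orf.start)
        if ov <= 0 or ov / L < min_coverage:
            continue
        key = (ov, a.percent_identity, a.bitscore)
        if key > best_key:
            best, best_key = a, key
    return best


def classify_region(
    region: QueryRegion,
    alignments: Sequence[LocalAlignment],
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
    indel_threshold: int = 300,
) -> str:
    """Region-change category from flanking-ORF homology.

    Both ORFs homologous: the change in inter-ORF distance between query
    and subject decides insertion / deletion / no_change at
    ``indel_threshold``.  Exactly one homologous ORF is a flanking
    change; none is no homology.  ORFs mapping to different subject
    sequences are coerced to flanking_change.
    """
    if region.left_orf is None or region.right_orf is None:
        raise ContractError("classify_region requires both flanking ORFs")
    left = _best_orf_alignment(region.left_orf, alignments, min_identity, min_coverage)
    right = _best_orf_alignment(region.right_orf, alignments, min_identity, min_coverage)
    if left is None and right is None:
        return "no_homology"
    if left is None or right is None:
        return "flanking_change"
    if left.subject_id != right.subject_id:
        return "flanking_change"
    ls = left.map_query_interval(region.left_orf.start, region.left_orf.end)
    rs = right.map_query_interval(region.right_orf.start, region.right_orf.end)
    first, second = sorted((ls, rs))
    subject_gap = second[0] - first[1]
    query_gap = region.right_orf.start - region.left_orf.end
    delta = subject_gap - query_gap
    if delta >= indel_threshold:
        return "insertion"
    if delta <= -indel_threshold:
        return "deletion"
    return "no_change"


def classify_conservation(
    regions: Sequence[QueryRegion],
    repeats_by_id: Mapping[str, RepeatHit],
    alignments: Sequence[LocalAlignment],
    subject_genome: GenomeRecord,
    preset: RepeatPreset,
    min_identity: float = 80.0,
    min_coverage: float = 0.8,
    indel_threshold: int = 300,
    flank: int = 100,
) -> list[ConservationCall]:
    """Repeat-presence and region-change calls for repeat-containing regions."""
    calls = []
    for region in regions:
        if not region.contains_repeat:
            continue
        span = region.span
        local = _alignments_for_span(alignments, *span)
        region_class = classify_region(
            region, local, min_identity, min_coverage, indel_threshold
        )
        if region_class == "no_homology":
            status = "no_alignment"
        else:
            status = classify_repeat_presence(
                region,
                repeats_by_id[region.repeat_id],
                local,
                subject_genome,
                preset,
                flank,
            )
        calls.append(ConservationCall(region.region_id, status, region_class))
    return calls


def category_fractions(
    calls: Sequence[ConservationCall], field: str = "region_class"
) -> dict[str, float]:
    """Fractions over all calls; absent categories are 0 and omitted."""
    n = len(calls)
    counts: dict[str, int] = {}
    for c in calls:
        key = getattr(c, field)
        counts[key] = counts.get(key, 0) + 1
    return {k: v / n for k, v in sorted(counts.items())} if n else {}


def region_orientation(region: QueryRegion) -> str:
    """aligned / convergent / divergent layout of the flanking ORFs."""
    l, r = region.left_orf, region.right_orf
    if l is None or r is None:
        return "undefined"
    if l.strand == r.strand:
        return "aligned"
    return "convergent" if l.strand == "+" else "divergent"


def _largest_remainder(fracs: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fracs]
    base = [math.floor(x) for x in raw]
    rem = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i]), reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def build_control_sets(
    orfs: Sequence[OrfAnnotation],
    repeat_regions: Sequence[QueryRegion],
    genome: GenomeRecord | None = None,
    pool_size: int = 260,
    set_size: int = 117,
    designs: Sequence[str] = ("random", "random", "random", "position_matched",
                              "orientation_matched"),
    seed: int = 0,
) -> dict[str, list[list[QueryRegion]]]:
    """Assemble control sets of repeat-free intergenic regions.

    A pool of ``pool_size`` repeat-free regions (sampled once, seeded)
    feeds every design.  ``random`` samples ``set_size`` regions without
    replacement; ``position_matched`` greedily pairs each repeat region
    with the unused pool region of nearest midpoint; and
    ``orientation_matched`` samples so the aligned / convergent /
    divergent composition matches the repeat regions (largest-remainder
    rounding).
    """
    all_regions = build_query_regions(orfs, [])
    repeat_gaps = {(r.inter_start, r.inter_end) for r in repeat_regions}
    pool_all = [
        r
        for r in all_regions
        if (r.inter_start, r.inter_end) not in repeat_gaps
    ]
    if len(pool_all) < pool_size:
        raise ContractError(
            f"control pool too small: need {pool_size}, "
            f"have {len(pool_all)} (deficit {pool_size - len(pool_all)})"
        )
    rng = np.random.default_rng(seed)
    pool_idx = rng.choice(len(pool_all), size=pool_size, replace=False)
    pool = [pool_all[i] for i in sorted(pool_idx)]
    if set_size > pool_size:
        raise ContractError("set_size exceeds pool_size")

    out: dict[str, list[list[QueryRegion]]] = {}
    for design in designs:
        if design == "random":
            idx = rng.choice(pool_size, size=set_size, replace=False)
            chosen = [pool[i] for i in sorted(idx)]
        elif design == "position_matched":
            used: set[int] = set()
            chosen = []
            for rr in sorted(repeat_regions, key=lambda r: r.inter_start)[:set_size]:
                mid = (rr.inter_start + rr.inter_end) / 2
                best_i = min(
                    (i for i in range(pool_size) if i not in used),
                    key=lambda i: (
                        abs((pool[i].inter_start + pool[i].inter_end) / 2 - mid),
                        pool[i].inter_start,
                    ),
                )
                used.add(best_i)
                chosen.append(pool[best_i])
        elif design == "orientation_matched":
            cats = ("aligned", "convergent", "divergent")
            rep_counts = [
                sum(1 for r in repeat_regions if region_orientation(r) == c)
                for c in cats
            ]
            n_rep = sum(rep_counts) or 1
            targets = _largest_remainder([c / n_rep for c in rep_counts], set_size)
            chosen = []
            for cat, want in zip(cats, targets):
                members = [r for r in pool if region_orientation(r) == cat]
                if len(members) < want:
                    raise ContractError(
                        f"pool has {len(members)} {cat} regions, need {want}"
                    )
                idx = rng.choice(len(members), size=want, replace=False)
                chosen.extend(members[i] for i in sorted(idx))
        else:
            raise ContractError(f"unknown control design {design!r}")
        out.setdefault(design, []).append(chosen)
    return out


@dataclass(frozen=True)
class CategoryTestResult:
    category: str
    repeat_value: float
    control_values: tuple[float, ...]
    t_stat: float
    df: int
    p_two_sided: float


def one_sample_t(
    control_values: Sequence[float], reference_value: float, category: str = ""
) -> CategoryTestResult:
    """Two-sided one-sample t-test of the control fractions against the
    repeat-group fraction.

    t = (mean - reference) / (sd / sqrt(n)), df = n - 1; the p-value
    comes from the closed-form t CDF via the regularized incomplete
    beta function.
    """
    vals = [float(v) for v in control_values]
    n = len(vals)
    if n < 2:
        raise ContractError("one_sample_t requires at least 2 control values")
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    df = n - 1
    if sd == 0.0:
        if mean == reference_value:
            return CategoryTestResult(category, reference_value, tuple(vals), 0.0, df, 1.0)
        raise ContractError("degenerate sample: zero variance with mean != reference")
    t = (mean - reference_value) / (sd / math.sqrt(n))
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return CategoryTestResult(category, reference_value, tuple(vals), t, df, p)


def run_category_tests(
    repeat_fractions: Mapping[str, float],
    control_fractions: Sequence[Mapping[str, float]],
    categories: Sequence[str] = REGION_CLASSES,
) -> list[CategoryTestResult]:
    """One t-test per category, controls as the sample and the repeat-group
    fraction as the reference value."""
    out = []
    for cat in categories:
        controls = [c.get(cat, 0.0) for c in control_fractions]
        out.append(one_sample_t(controls, repeat_fractions.get(cat, 0.0), category=cat))
    return out
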