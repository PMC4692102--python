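"""Seeded generators of synthetic survey genomes with full ground truth.

The generator plants degenerate heptamer tandem arrays into a scrubbed
random background: unit counts follow a distribution peaked at four
units, interior unit positions that are free in the degenerate pattern
mutate at a configurable per-position rate, terminal units occasionally
acquire a G-tract point mutation (which detaches them from the array),
and a configurable fraction of repeats form convergent inverted pairs.
ORF annotations are laid out to realize a requested orientation mix.
Background sequence is rejection-scrubbed so that no seed heptamer (or
its reverse complement) occurs outside planted loci, and array flanks
are resampled so planted extents are exactly maximal — every scanner
hit is planted and every planted array is recovered verbatim.

Ortholog and transcript generators derive edited subject genomes with
exact truth alignment tables, and transcript intervals realizing
requested position classes, for closed-loop testing of the
conservation and transcript stages.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .context_annotator import InvertedPair
from .conservation import LocalAlignment, QueryRegion, build_query_regions
from .genome_io import ContractError, GenomeRecord, OrfAnnotation, revcomp
from .repeat_scanner import (
    UNIT_LENGTH,
    RepeatHit,
    RepeatPreset,
    call_g4_capability,
    matches_iupac,
)
from .transcript_mapper import TranscriptInterval

__all__ = [
    "SurveyParams",
    "SyntheticTruth",
    "simulate_survey",
    "simulate_ortholog",
    "simulate_transcripts",
    "write_truth_json",
]

INTERGENIC_CATEGORIES = ("aligned_coding", "aligned_noncoding", "convergent", "divergent")
INTRAGENIC_CATEGORIES = ("intragenic_coding", "intragenic_noncoding")


def _default_unit_distribution() -> dict[int, float]:
    # mode at 4 units, tail to 7
    return {2: 0.20, 3: 0.15, 4: 0.40, 5: 0.15, 6: 0.06, 7: 0.04}


def _default_orientation_mix() -> dict[str, float]:
    return {
        "aligned_coding": 0.30,
        "aligned_noncoding": 0.35,
        "convergent": 0.16,
        "divergent": 0.08,
        "intragenic_coding": 0.06,
        "intragenic_noncoding": 0.05,
    }


@dataclass
class SurveyParams:
    """Knobs of the synthetic survey; defaults emulate the xanthomonad
    chromosome surveys at desk scale (same repeat architecture, higher
    repeat density on a much shorter sequence)."""

    genome_length: int = 120_000
    gc_content: float = 0.65
    n_repeats: int = 40
    unit_count_distribution: dict[int, float] = field(
        default_factory=_default_unit_distribution
    )
    degenerate_position_mut_rate: float = 0.10
    g_tract_mut_rate: float = 0.05
    minus_strand_prob: float = 0.5
    inverted_pair_fraction: float = 0.30
    pair_gap_range: tuple[int, int] = (40, 90)
    orientation_mix: dict[str, float] = field(default_factory=_default_orientation_mix)
    orf_length_range: tuple[int, int] = (300, 900)
    flank_gap_range: tuple[int, int] = (20, 120)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "gc_content",
            "degenerate_position_mut_rate",
            "g_tract_mut_rate",
            "minus_strand_prob",
            "inverted_pair_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        for dist, label in (
            (self.unit_count_distribution, "unit_count_distribution"),
            (self.orientation_mix, "orientation_mix"),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ContractError(f"{label} must sum to 1, sums to {total}")
        if any(k < 2 for k in self.unit_count_distribution):
            raise ContractError("unit counts below 2 cannot be planted")
        for key in self.orientation_mix:
            if key not in INTERGENIC_CATEGORIES + INTRAGENIC_CATEGORIES:
                raise ContractError(f"unknown orientation category {key!r}")


@dataclass
class SyntheticTruth:
    """Ground truth tables for one synthetic survey."""

    planted_repeats: list[RepeatHit] = field(default_factory=list)
    planted_orfs: list[OrfAnnotation] = field(default_factory=list)
    planted_pairs: list[InvertedPair] = field(default_factory=list)
    # repeat_id -> (location_class, six-way category)
    planted_classes: dict[str, tuple[str, str]] = field(default_factory=dict)
    # (region_id, edit_kind, applied size)
    ortholog_edits: list[tuple[str, str, int]] = field(default_factory=list)
    # repeat_id -> (position_class, strand_content or None)
    planted_transcript_classes: dict[str, tuple[str, Optional[str]]] = field(
        default_factory=dict
    )


def _largest_remainder(fracs: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fracs]
    base = [int(np.floor(x)) for x in raw]
    rem = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def _random_background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=probs))


def _sample_range(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def _hit_id(genome_id: str, start: int, end: int, strand: str) -> str:
    return f"{genome_id}:{start}-{end}({strand})"


# ---------------------------------------------------------------------------
# Repeat locus construction
# ---------------------------------------------------------------------------


def _mutable_positions(pattern: str) -> list[int]:
    """Unit positions where the degenerate pattern allows any base (N)."""
    return [i for i, p in enumerate(pattern) if p == "N"]


def _build_units(
    rng: np.random.Generator, preset: RepeatPreset, params: SurveyParams
) -> list[str]:
    """Sample a unit list: seeds, then degenerate-position mutations with a
    guaranteed floor of exact seed units."""
    counts = sorted(params.unit_count_distribution)
    probs = [params.unit_count_distribution[k] for k in counts]
    n = int(rng.choice(counts, p=probs))
    seeds = sorted(preset.seed_units)
    base_seed = seeds[int(rng.integers(0, len(seeds)))]
    units = [base_seed] * n
    mut_pos = _mutable_positions(preset.degenerate_unit)
    for i in range(n):
        u = list(units[i])
        for pos in mut_pos:
            if rng.random() < params.degenerate_position_mut_rate:
                alternatives = [b for b in "ACGT" if b != u[pos]]
                u[pos] = alternatives[int(rng.integers(0, 3))]
        units[i] = "".join(u)
    # restore the seed floor by reverting mutated units (lowest index first)
    n_seed = sum(1 for u in units if u in preset.seed_units)
    i = 0
    while n_seed < preset.min_seed_units and i < n:
        if units[i] not in preset.seed_units:
            units[i] = base_seed
            n_seed += 1
        i += 1
    return units


def _break_g_tract(rng: np.random.Generator, unit: str, tpl: int) -> str:
    """Point-mutate one of the unit's leading G's, detaching it from the array."""
    pos = int(rng.integers(0, tpl))
    u = list(unit)
    u[pos] = ["A", "C", "T"][int(rng.integers(0, 3))]
    return "".join(u)


@dataclass
class _PlannedRepeat:
    units: list[str]
    strand: str
    category: str  # six-way
    broken_left: str = ""  # detached G-tract-mutated units flanking the array
    broken_right: str = ""

    @property
    def array_seq(self) -> str:
        return "".join(self.units)

    @property
    def locus_seq_plus(self) -> str:
        """Forward-strand text of the locus (array read G-rich on its strand)."""
        s = self.broken_left + self.array_seq + self.broken_right
        return s if self.strand == "+" else revcomp(s)


def _plan_repeat(
    rng: np.random.Generator,
    preset: RepeatPreset,
    params: SurveyParams,
    category: str,
    strand: Optional[str] = None,
) -> _PlannedRepeat:
    units = _build_units(rng, preset, params)
    if strand is None:
        strand = "-" if rng.random() < params.minus_strand_prob else "+"
    broken_left = broken_right = ""
    tpl = preset.tract_prefix_length
    for side in ("left", "right"):
        if len(units) - 1 < preset.min_units:
            break
        victim = units[0] if side == "left" else units[-1]
        remaining = units[1:] if side == "left" else units[:-1]
        n_seed_rem = sum(1 for u in remaining if u in preset.seed_units)
        if n_seed_rem < preset.min_seed_units:
            continue
        if rng.random() < params.g_tract_mut_rate:
            broken = _break_g_tract(rng, victim, tpl)
            units = remaining
            if side == "left":
                broken_left = broken
            else:
                broken_right = broken
    return _PlannedRepeat(
        units=units, strand=strand, category=category,
        broken_left=broken_left, broken_right=broken_right,
    )


# ---------------------------------------------------------------------------
# Background scrubbing and flank repair
# ---------------------------------------------------------------------------


def _find_all(seq: str, pattern: str) -> list[int]:
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def _scrub_pass(
    rng: np.random.Generator,
    seq: list[str],
    protected: np.ndarray,
    patterns: Sequence[str],
    gc: float,
) -> bool:
    """Resample free positions of any forbidden-pattern occurrence that is
    not fully inside a protected (planted) span.  Returns True if clean."""
    text = "".join(seq)
    clean = True
    for pat in patterns:
        for pos in _find_all(text, pat):
            window = slice(pos, pos + len(pat))
            if protected[window].all():
                continue
            clean = False
            for i in range(pos, pos + len(pat)):
                if not protected[i]:
                    seq[i] = _random_background(rng, 1, gc)[0]
    return clean


def _flank_ok(seq: list[str], protected: np.ndarray, hit_start: int, hit_end: int,
              strand: str, preset: RepeatPreset) -> list[int]:
    """Return free positions to resample so the planted array is maximal:
    the in-frame window preceding the array must not match the degenerate
    unit, and the tract-prefix window after it must not be all G (both in
    the array's reading direction)."""
    n = len(seq)
    tpl = preset.tract_prefix_length
    pat = preset.degenerate_unit
    bad: list[int] = []
    if strand == "+":
        before = slice(hit_start - UNIT_LENGTH, hit_start)
        after = slice(hit_end, hit_end + tpl)
        if before.start >= 0:
            w = "".join(seq[before])
            if matches_iupac(w, pat):
                bad.extend(i for i in range(before.start, before.stop) if not protected[i])
        if after.stop <= n:
            w = "".join(seq[after])
            if w == "G" * tpl:
                bad.extend(i for i in range(after.start, after.stop) if not protected[i])
    else:
        before = slice(hit_end, hit_end + UNIT_LENGTH)  # reading-direction upstream
        after = slice(hit_start - tpl, hit_start)
        if before.stop <= n:
            w = revcomp("".join(seq[before]))
            if matches_iupac(w, pat):
                bad.extend(i for i in range(before.start, before.stop) if not protected[i])
        if after.start >= 0:
            w = revcomp("".join(seq[after]))
            if w == "G" * tpl:
                bad.extend(i for i in range(after.start, after.stop) if not protected[i])
    return bad


# ---------------------------------------------------------------------------
# Survey assembly
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    seq_parts: list[str]
    orfs: list[tuple[int, int, str]]  # (offset, length, strand) within block
    repeats: list[tuple[int, _PlannedRepeat]]  # (offset of locus_seq_plus, plan)
    pair: bool = False

    @property
    def length(self) -> int:
        return sum(len(p) for p in self.seq_parts)


def _cassette_intergenic(
    rng: np.random.Generator, params: SurveyParams, plans: list[_PlannedRepeat]
) -> _Block:
    """[ORF_L][gap][locus (+ pair partner)][gap][ORF_R]"""
    first = plans[0]
    cat = first.category
    if cat == "aligned_coding":
        ls = rs = first.strand
    elif cat == "aligned_noncoding":
        ls = rs = "-" if first.strand == "+" else "+"
    elif cat == "convergent":
        ls, rs = "+", "-"
    else:  # divergent
        ls, rs = "-", "+"
    orf_l = _sample_range(rng, params.orf_length_range)
    orf_r = _sample_range(rng, params.orf_length_range)
    gap_l = _sample_range(rng, params.flank_gap_range)
    gap_r = _sample_range(rng, params.flank_gap_range)
    orfs = [(0, orf_l, ls)]
    parts = ["B" * orf_l]  # "B" marks placeholder background, backfilled later
    offset = orf_l + gap_l
    parts.append("B" * gap_l)
    repeats = []
    for i, plan in enumerate(plans):
        locus = plan.locus_seq_plus
        repeats.append((offset, plan))
        parts.append(locus)
        offset += len(locus)
        if i + 1 < len(plans):
            pg = _sample_range(rng, params.pair_gap_range)
            parts.append("B" * pg)
            offset += pg
    parts.append("B" * gap_r)
    offset += gap_r
    orfs.append((offset, orf_r, rs))
    parts.append("B" * orf_r)
    return _Block(parts, orfs, repeats, pair=len(plans) > 1)


def _cassette_intragenic(
    rng: np.random.Generator, params: SurveyParams, plan: _PlannedRepeat
) -> _Block:
    locus = plan.locus_seq_plus
    orf_strand = (
        plan.strand
        if plan.category == "intragenic_coding"
        else ("-" if plan.strand == "+" else "+")
    )
    pad = 60  # keep the repeat well inside the ORF
    orf_len = max(_sample_range(rng, params.orf_length_range), len(locus) + 2 * pad)
    inner = int(rng.integers(pad, orf_len - len(locus) - pad + 1))
    parts = ["B" * inner, locus, "B" * (orf_len - inner - len(locus))]
    return _Block(parts, [(0, orf_len, orf_strand)], [(inner, plan)])


def simulate_survey(
    params: SurveyParams, preset: RepeatPreset
) -> tuple[GenomeRecord, list[OrfAnnotation], SyntheticTruth]:
    """Generate a genome, ORF annotations and complete ground truth.

    Deterministic given ``params.seed``; raises if the requested repeats
    do not fit into ``genome_length``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genome_id = "synthetic_survey"

    n_pairs = int(round(params.inverted_pair_fraction * params.n_repeats / 2))
    n_singles = params.n_repeats - 2 * n_pairs

    cats = list(params.orientation_mix)
    single_counts = _largest_remainder(
        [params.orientation_mix[c] for c in cats], n_singles
    )
    single_cats: list[str] = []
    for c, k in zip(cats, single_counts):
        single_cats.extend([c] * k)
    single_cats = [single_cats[i] for i in rng.permutation(len(single_cats))]

    inter_mix = {
        "aligned": params.orientation_mix.get("aligned_coding", 0.0)
        + params.orientation_mix.get("aligned_noncoding", 0.0),
        "convergent": params.orientation_mix.get("convergent", 0.0),
        "divergent": params.orientation_mix.get("divergent", 0.0),
    }
    tot = sum(inter_mix.values()) or 1.0
    layouts = list(inter_mix)
    layout_probs = [inter_mix[k] / tot for k in layouts]

    blocks: list[_Block] = []
    for cat in single_cats:
        if cat in INTRAGENIC_CATEGORIES:
            plan = _plan_repeat(rng, preset, params, cat)
            blocks.append(_cassette_intragenic(rng, params, plan))
        else:
            strand = "-" if rng.random() < params.minus_strand_prob else "+"
            plan = _plan_repeat(rng, preset, params, cat, strand=strand)
            blocks.append(_cassette_intergenic(rng, params, [plan]))
    for _ in range(n_pairs):
        layout = layouts[int(rng.choice(len(layouts), p=layout_probs))]
        if layout == "aligned":
            orf_strand = "+" if rng.random() < 0.5 else "-"
            cat_plus = "aligned_coding" if orf_strand == "+" else "aligned_noncoding"
            cat_minus = "aligned_noncoding" if orf_strand == "+" else "aligned_coding"
        else:
            cat_plus = cat_minus = layout
        plan_p = _plan_repeat(rng, preset, params, cat_plus, strand="+")
        plan_m = _plan_repeat(rng, preset, params, cat_minus, strand="-")
        blocks.append(_cassette_intergenic(rng, params, [plan_p, plan_m]))
    blocks = [blocks[i] for i in rng.permutation(len(blocks))]

    min_spacer = 150
    need = sum(b.length for b in blocks) + min_spacer * (len(blocks) + 1)
    if need > params.genome_length:
        raise ContractError(
            f"cannot place {params.n_repeats} repeats in {params.genome_length} bp "
            f"(need >= {need}); increase genome_length"
        )
    extra = params.genome_length - need
    n_slots = len(blocks) + 1
    spacers = [min_spacer + extra // n_slots] * n_slots
    spacers[-1] += extra - (extra // n_slots) * n_slots

    # assemble with placeholders, tracking absolute coordinates
    seq_parts: list[str] = []
    pos = 0
    orfs: list[OrfAnnotation] = []
    planted: list[tuple[int, _PlannedRepeat]] = []
    pair_groups: list[list[int]] = []
    orf_idx = 0
    for block, spacer in zip(blocks, spacers):
        seq_parts.append("B" * spacer)
        pos += spacer
        for off, length, strand in block.orfs:
            orfs.append(
                OrfAnnotation(
                    genome_id=genome_id,
                    start=pos + off,
                    end=pos + off + length,
                    strand=strand,
                    locus_tag=f"orf_{orf_idx:04d}",
                )
            )
            orf_idx += 1
        group = []
        for off, plan in block.repeats:
            group.append(len(planted))
            planted.append((pos + off, plan))
        if block.pair:
            pair_groups.append(group)
        for part in block.seq_parts:
            seq_parts.append(part)
        pos += block.length
    seq_parts.append("B" * (params.genome_length - pos))
    text = "".join(seq_parts)
    assert len(text) == params.genome_length

    # backfill placeholders with background, mark protected (planted array) spans
    seq = list(text)
    protected = np.zeros(params.genome_length, dtype=bool)
    hit_spans: list[tuple[int, int, _PlannedRepeat]] = []
    for locus_start, plan in planted:
        bl, br = len(plan.broken_left), len(plan.broken_right)
        locus_len = bl + 7 * len(plan.units) + br
        if plan.strand == "+":
            s = locus_start + bl
            e = locus_start + locus_len - br
        else:
            s = locus_start + br
            e = locus_start + locus_len - bl
        protected[locus_start : locus_start + locus_len] = True
        hit_spans.append((s, e, plan))
    free = [i for i, b in enumerate(seq) if b == "B"]
    bg = _random_background(rng, len(free), params.gc_content)
    for i, b in zip(free, bg):
        seq[i] = b

    # scrub seeds from background and repair array flanks until stable
    patterns = sorted(preset.seed_units) + sorted(
        revcomp(s) for s in preset.seed_units
    )
    for _ in range(200):
        clean = _scrub_pass(rng, seq, protected, patterns, params.gc_content)
        bad: list[int] = []
        for s, e, plan in hit_spans:
            bad.extend(_flank_ok(seq, protected, s, e, plan.strand, preset))
        for i in bad:
            seq[i] = _random_background(rng, 1, params.gc_content)[0]
        if clean and not bad:
            break
    else:  # pragma: no cover - rejection sampling converges in a few passes
        raise ContractError("background scrubbing did not converge")

    genome = GenomeRecord(id=genome_id, sequence="".join(seq))

    truth = SyntheticTruth(planted_orfs=sorted(orfs, key=lambda o: (o.start, o.end)))
    hits_by_index: list[RepeatHit] = []
    for s, e, plan in hit_spans:
        units = tuple(plan.units)
        n_seed = sum(1 for u in units if u in preset.seed_units)
        run, capable = call_g4_capability(units, "", preset.tract_prefix_length)
        rid = _hit_id(genome_id, s, e, plan.strand)
        hit = RepeatHit(
            genome_id=genome_id,
            start=s,
            end=e,
            strand=plan.strand,
            units=units,
            n_seed_units=n_seed,
            trailing_partial="",
            intact_tracts_max_run=run,
            g4_capable=capable,
            preset_name=preset.name,
            repeat_id=rid,
        )
        hits_by_index.append(hit)
        truth.planted_repeats.append(hit)
        loc = (
            "intergenic"
            if plan.category in INTERGENIC_CATEGORIES
            else (
                "intragenic_coding"
                if plan.category == "intragenic_coding"
                else "intragenic_noncoding"
            )
        )
        truth.planted_classes[rid] = (loc, plan.category)
    for group in pair_groups:
        plus_hit = hits_by_index[group[0]]
        minus_hit = hits_by_index[group[1]]
        truth.planted_pairs.append(
            InvertedPair(
                plus_repeat_id=plus_hit.repeat_id,
                minus_repeat_id=minus_hit.repeat_id,
                gap=minus_hit.start - plus_hit.end,
            )
        )
    truth.planted_repeats.sort(key=lambda h: (h.start, h.end, h.strand))
    return genome, truth.planted_orfs, truth


# ---------------------------------------------------------------------------
# Ortholog generator
# ---------------------------------------------------------------------------

EDIT_KINDS = ("none", "insertion", "deletion", "flanking_loss", "locus_loss")

_DEFAULT_EDIT_SIZES = {
    "insertion": (400, 600),
    "deletion": (400, 600),
    "flanking_loss": (0, 0),
    "locus_loss": (0, 0),
}


def simulate_ortholog(
    genome: GenomeRecord,
    orfs: Sequence[OrfAnnotation],
    truth: SyntheticTruth,
    edit_rates: Optional[Mapping[str, float]] = None,
    sizes: Optional[Mapping[str, tuple[int, int]]] = None,
    seed: int = 0,
    preset: Optional[RepeatPreset] = None,
    background_edit_rates: Optional[Mapping[str, float]] = None,
) -> tuple[GenomeRecord, list[tuple[str, str, int]], list[LocalAlignment]]:
    """Derive an edited subject genome plus an exact truth alignment table.

    Per repeat-containing intergenic region one edit kind is sampled from
    ``edit_rates`` (remaining mass is "none"): an intergenic insertion, an
    intergenic deletion (clipped to the space before the first repeat), a
    scrambled right flanking ORF, or a scrambled whole locus.
    ``background_edit_rates``, when given, applies the same scheme to
    repeat-free intergenic regions (an edit whose span would collide
    with an already scheduled one is skipped), which lets repeat loci
    and background evolve at different rates.  Alignment rows cover
    every unedited block; scrambled blocks get none.
    """

    def _check_rates(r: Mapping[str, float]) -> None:
        for k in r:
            if k not in EDIT_KINDS[1:]:
                raise ContractError(f"unknown edit kind {k!r}")
        if sum(r.values()) > 1.0 + 1e-9:
            raise ContractError("edit rates must sum to <= 1")

    rates = dict(edit_rates or {})
    bg_rates = dict(background_edit_rates or {})
    _check_rates(rates)
    _check_rates(bg_rates)
    size_ranges = dict(_DEFAULT_EDIT_SIZES)
    size_ranges.update(sizes or {})
    rng = np.random.default_rng(seed)

    regions = build_query_regions(orfs, truth.planted_repeats)
    gaps: dict[tuple[int, int], list[QueryRegion]] = {}
    for r in regions:
        if r.contains_repeat:
            gaps.setdefault((r.inter_start, r.inter_end), []).append(r)
    free_gaps = [r for r in regions if not r.contains_repeat]

    edits: list[tuple[int, int, str, str]] = []  # (qstart, qend, replacement, kind)
    edit_truth: list[tuple[str, str, int]] = []
    repeats_by_id = {h.repeat_id: h for h in truth.planted_repeats}

    def _collides(a: int, b: int) -> bool:
        return any(a < qe and qs < b for qs, qe, _, _ in edits) if a < b else any(
            qs < a <= qe or qs <= a < qe for qs, qe, _, _ in edits
        )

    def _sample_kind(r: Mapping[str, float]) -> str:
        kinds = list(r) + ["none"]
        probs = [r[k] for k in r] + [1.0 - sum(r.values())]
        return kinds[int(rng.choice(len(kinds), p=probs))]

    def _apply_edit(kind: str, region: QueryRegion, first_rep: Optional[int]) -> int:
        """Schedule one edit; returns the applied size (0 if skipped)."""
        gs, ge = region.inter_start, region.inter_end
        if kind == "insertion":
            size = _sample_range(rng, size_ranges["insertion"])
            if _collides(gs, gs):
                return 0
            frag = "".join(_random_background(rng, size, 0.5))
            edits.append((gs, gs, frag, kind))
            return size
        if kind == "deletion":
            limit = (first_rep if first_rep is not None else ge) - gs - 1
            size = min(_sample_range(rng, size_ranges["deletion"]), max(limit, 0))
            if size <= 0 or _collides(gs, gs + size):
                return 0
            edits.append((gs, gs + size, "", kind))
            return size
        if kind == "flanking_loss":
            orf = region.right_orf
            if _collides(orf.start, orf.end):
                return 0
            scram = "".join(_random_background(rng, orf.end - orf.start, 0.5))
            edits.append((orf.start, orf.end, scram, kind))
            return orf.end - orf.start
        if kind == "locus_loss":
            a, b = region.span
            if _collides(a, b):
                return 0
            scram = "".join(_random_background(rng, b - a, 0.5))
            edits.append((a, b, scram, kind))
            return b - a
        return 0

    for (gs, ge), members in sorted(gaps.items()):
        kind = _sample_kind(rates)
        first_rep = min(repeats_by_id[m.repeat_id].start for m in members)
        applied = _apply_edit(kind, members[0], first_rep) if kind != "none" else 0
        if kind != "none" and applied == 0:
            kind = "none"
        for m in members:
            edit_truth.append((m.region_id, kind, applied))
    if bg_rates:
        for region in sorted(free_gaps, key=lambda r: r.inter_start):
            kind = _sample_kind(bg_rates)
            applied = _apply_edit(kind, region, None) if kind != "none" else 0
            if kind != "none" and applied == 0:
                kind = "none"
            edit_truth.append((region.region_id, kind, applied))

    # scrub any accidental seeds out of inserted/scrambled fragments
    preset_seeds: list[str] = []
    if preset is not None:
        preset_seeds = sorted(preset.seed_units) + sorted(
            revcomp(s) for s in preset.seed_units
        )

    def _clean_fragment(frag: str) -> str:
        chars = list(frag)
        prot = np.zeros(len(chars), dtype=bool)
        for _ in range(50):
            if _scrub_pass(rng, chars, prot, preset_seeds, 0.5):
                break
        return "".join(chars)

    edits = [
        (qs, qe, _clean_fragment(rep) if rep else rep, kind)
        for qs, qe, rep, kind in edits
    ]

    # build subject and truth alignments from the unedited blocks
    subject_id = genome.id + "_ortholog"
    subject_parts: list[str] = []
    alignments: list[LocalAlignment] = []
    qpos = 0
    spos = 0
    MIN_SEG = 30

    def _emit(q0: int, q1: int, s0: int) -> None:
        length = q1 - q0
        if length >= MIN_SEG:
            alignments.append(
                LocalAlignment(
                    query_id=genome.id,
                    subject_id=subject_id,
                    percent_identity=100.0,
                    aln_length=length,
                    mismatches=0,
                    gap_opens=0,
                    qstart=q0 + 1,
                    qend=q1,
                    sstart=s0 + 1,
                    send=s0 + length,
                    evalue=0.0,
                    bitscore=2.0 * length,
                )
            )

    for qs, qe, replacement, _kind in sorted(edits, key=lambda e: e[0]):
        if qs > qpos:
            copied = genome.sequence[qpos:qs]
            subject_parts.append(copied)
            _emit(qpos, qs, spos)
            spos += len(copied)
        subject_parts.append(replacement)
        spos += len(replacement)
        qpos = qe
    if qpos < genome.length:
        copied = genome.sequence[qpos:]
        subject_parts.append(copied)
        _emit(qpos, genome.length, spos)

    subject = GenomeRecord(id=subject_id, sequence="".join(subject_parts))
    truth.ortholog_edits = edit_truth
    return subject, edit_truth, alignments


# ---------------------------------------------------------------------------
# Transcript generator
# ---------------------------------------------------------------------------


def _default_class_mix() -> dict[str, float]:
    return {"start": 0.25, "stop": 0.35, "middle": 0.20, "no_transcript": 0.20}


def simulate_transcripts(
    genome: GenomeRecord,
    orfs: Sequence[OrfAnnotation],
    truth: SyntheticTruth,
    class_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    g_rich_fraction: float = 0.5,
    max_after: int = 30,
) -> list[TranscriptInterval]:
    """Emit transcript intervals realizing an exact position-class mix for
    every intergenic planted repeat; intragenic repeats get none.

    Transcript extents are clipped so no transcript reaches a
    neighboring planted repeat, which makes the planted labels the
    unique classification outcome.
    """
    mix = dict(class_mix or _default_class_mix())
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ContractError("class_mix must sum to 1")
    for k in mix:
        if k not in ("start", "stop", "middle", "no_transcript"):
            raise ContractError(f"unknown position class {k!r}")
    rng = np.random.default_rng(seed)

    eligible = [
        h
        for h in sorted(truth.planted_repeats, key=lambda h: h.start)
        if truth.planted_classes[h.repeat_id][0] == "intergenic"
    ]
    classes = list(mix)
    counts = _largest_remainder([mix[c] for c in classes], len(eligible))
    assigned: list[str] = []
    for c, k in zip(classes, counts):
        assigned.extend([c] * k)
    assigned = [assigned[i] for i in rng.permutation(len(assigned))]

    all_sorted = sorted(truth.planted_repeats, key=lambda h: h.start)
    bounds: dict[str, tuple[int, int]] = {}
    for i, h in enumerate(all_sorted):
        left = all_sorted[i - 1].end if i > 0 else 0
        right = all_sorted[i + 1].start if i + 1 < len(all_sorted) else genome.length
        bounds[h.repeat_id] = (left, right)

    transcripts: list[TranscriptInterval] = []
    tx_idx = 0
    for h, cls in zip(eligible, assigned):
        if cls == "no_transcript":
            truth.planted_transcript_classes[h.repeat_id] = (cls, None)
            continue
        g_rich = rng.random() < g_rich_fraction
        strand = h.strand if g_rich else ("-" if h.strand == "+" else "+")
        lb, rb = bounds[h.repeat_id]
        left_room = h.start - lb - 1 if lb > 0 else h.start
        right_room = rb - h.end - 1 if rb < genome.length else genome.length - h.end
        ext_l = max(1, min(200, left_room))
        ext_r = max(1, min(200, right_room))
        if cls == "middle" and strand == "+" and ext_r <= max_after:
            raise ContractError("not enough room past the repeat for a middle call")
        if cls == "middle" and strand == "-" and ext_l <= max_after:
            raise ContractError("not enough room before the repeat for a middle call")
        if strand == "+":
            if cls == "start":
                off = int(rng.integers(0, min(3, h.end - h.start - 1) + 1))
                t0, t1 = h.start + off, h.end + ext_r
            elif cls == "stop":
                d = int(rng.integers(0, min(max_after, right_room) + 1))
                t0, t1 = h.start - ext_l, h.end + d
            else:  # middle
                t0, t1 = h.start - ext_l, h.end + ext_r
        else:
            if cls == "start":
                off = int(rng.integers(0, min(3, h.end - h.start - 1) + 1))
                t0, t1 = h.start - ext_l, h.end - off
            elif cls == "stop":
                d = int(rng.integers(0, min(max_after, left_room) + 1))
                t0, t1 = h.start - d, h.end + ext_r
            else:
                t0, t1 = h.start - ext_l, h.end + ext_r
        t0 = max(0, t0)
        t1 = min(genome.length, t1)
        transcripts.append(
            TranscriptInterval(
                transcript_id=f"tx_{tx_idx:04d}",
                genome_id=genome.id,
                start=t0,
                end=t1,
                strand=strand,
                expression=float(np.round(rng.uniform(1.0, 100.0), 3)),
            )
        )
        tx_idx += 1
        truth.planted_transcript_classes[h.repeat_id] = (
            cls,
            "g_rich" if g_rich else "c_rich",
        )
    return transcripts


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_repeats": [dataclasses.asdict(h) for h in truth.planted_repeats],
        "planted_orfs": [dataclasses.asdict(o) for o in truth.planted_orfs],
        "planted_pairs": [dataclasses.asdict(p) for p in truth.planted_pairs],
        "planted_classes": truth.planted_classes,
        "ortholog_edits": truth.ortholog_edits,
        "planted_transcript_classes": truth.planted_transcript_classes,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
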