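"""Detection of tandem arrays of degenerate G-rich 7-mer units.

An array is seeded by an exact consensus heptamer (e.g. GGGAATC) and
extended in 7-base steps in both directions while each adjacent window
matches the degenerate unit pattern (e.g. GGGANTN).  A terminal partial
unit consisting of the unit's leading G-run may follow the last full
unit; it feeds G-quadruplex calling but is never counted as a unit.

G4 capability requires four consecutive intact G-tracts: a unit's tract
is intact when its first ``tract_prefix_length`` bases are all G.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome_io import ContractError, GenomeRecord, revcomp

__all__ = [
    "RepeatPreset",
    "RepeatHit",
    "builtin_presets",
    "scan_repeats",
    "call_g4_capability",
    "matches_iupac",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

UNIT_LENGTH = 7


def matches_iupac(window: str, pattern: str) -> bool:
    """True iff *window* matches the IUPAC *pattern* position by position.

    An ``N`` base in the genome never matches anything, not even pattern N.
    """
    if len(window) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(window, pattern))


@dataclass(frozen=True)
class RepeatPreset:
    """Parameters defining one repeat family."""

    name: str
    seed_units: frozenset[str]
    degenerate_unit: str
    min_units: int = 2
    min_seed_units: int = 1
    min_total_length: int = 14
    tract_prefix_length: int = 3

    def __post_init__(self) -> None:
        if len(self.degenerate_unit) != UNIT_LENGTH:
            raise ContractError("degenerate unit must be 7 characters")
        if self.min_units < 2:
            raise ContractError("min_units must be >= 2")
        if self.min_seed_units < 1:
            raise ContractError("min_seed_units must be >= 1")
        if self.min_total_length > UNIT_LENGTH * self.min_units + UNIT_LENGTH:
            raise ContractError("min_total_length inconsistent with min_units")
        for seed in self.seed_units:
            if not matches_iupac(seed, self.degenerate_unit):
                raise ContractError(
                    f"seed {seed!r} does not match degenerate unit "
                    f"{self.degenerate_unit!r}"
                )
        if not (1 <= self.tract_prefix_length <= UNIT_LENGTH):
            raise ContractError("tract_prefix_length out of range")


def builtin_presets() -> dict[str, RepeatPreset]:
    """The two built-in repeat families.

    ``xan``: the xanthomonad GGGAATC family — degenerate unit GGGANTN,
    at least 2 units, at least one exact seed, total length >= 14 bp.
    ``ana``: the cyanobacterial GGGGA(C/T)T family — degenerate unit
    GGGGANT with at least two exact seed units.
    """
    return {
        "xan": RepeatPreset(
            name="xan",
            seed_units=frozenset({"GGGAATC"}),
            degenerate_unit="GGGANTN",
            min_units=2,
            min_seed_units=1,
            min_total_length=14,
            tract_prefix_length=3,
        ),
        "ana": RepeatPreset(
            name="ana",
            seed_units=frozenset({"GGGGATT", "GGGGACT"}),
            degenerate_unit="GGGGANT",
            min_units=2,
            min_seed_units=2,
            min_total_length=14,
            tract_prefix_length=3,
        ),
    }


@dataclass(frozen=True)
class RepeatHit:
    """One maximal tandem heptamer array, in forward-strand coordinates.

    ``units`` are read 5'->3' on the repeat (G-rich) strand.  The span
    ``[start, end)`` includes the trailing partial unit when present.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    units: tuple[str, ...]
    n_seed_units: int
    trailing_partial: str
    intact_tracts_max_run: int
    g4_capable: bool
    preset_name: str
    repeat_id: str = ""

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def length(self) -> int:
        return self.end - self.start


def _hit_id(genome_id: str, start: int, end: int, strand: str) -> str:
    return f"{genome_id}:{start}-{end}({strand})"


def _drop_wrap_shadows(hits, L: int):
    """In circular mode an origin-spanning hit shadows its truncated copy
    found at the start of the linear sequence; drop the copies."""
    wraps = [h for h in hits if h.end > L]
    out = []
    for h in hits:
        shadowed = any(
            w is not h
            and w.strand == h.strand
            and w.end > L
            and h.end <= w.end - L
            for w in wraps
        )
        if not shadowed:
            out.append(h)
    return out


def call_g4_capability(
    units: tuple[str, ...] | list[str],
    trailing_partial: str,
    tract_prefix_length: int,
) -> tuple[int, bool]:
    """Longest run of consecutive intact G-tracts, and whether it reaches 4.

    A unit contributes an intact tract iff its first ``tract_prefix_length``
    characters are all G; a qualifying trailing partial contributes one
    additional tract after the last unit.
    """
    if not units:
        raise ContractError("call_g4_capability requires at least one unit")
    tract_ok = [u[:tract_prefix_length] == "G" * tract_prefix_length for u in units]
    if trailing_partial:
        tract_ok.append(True)
    best = run = 0
    for ok in tract_ok:
        run = run + 1 if ok else 0
        best = max(best, run)
    return best, best >= 4


def _candidates_one_strand(seq: str, preset: RepeatPreset):
    """Maximal seed-anchored arrays on one strand, as (start, units, partial)."""
    pat = preset.degenerate_unit
    tpl = preset.tract_prefix_length
    n = len(seq)
    seen: set[tuple[int, int]] = set()
    out = []
    for seed in sorted(preset.seed_units):
        for m in re.finditer(f"(?={re.escape(seed)})", seq):
            p = m.start()
            left = p
            while left - UNIT_LENGTH >= 0 and matches_iupac(
                seq[left - UNIT_LENGTH : left], pat
            ):
                left -= UNIT_LENGTH
            right = p + UNIT_LENGTH
            while right + UNIT_LENGTH <= n and matches_iupac(
                seq[right : right + UNIT_LENGTH], pat
            ):
                right += UNIT_LENGTH
            if (left, right) in seen:
                continue
            seen.add((left, right))
            units = tuple(
                seq[i : i + UNIT_LENGTH] for i in range(left, right, UNIT_LENGTH)
            )
            partial = ""
            tail = seq[right : right + tpl]
            if len(tail) == tpl and tail == "G" * tpl:
                partial = tail
            out.append((left, units, partial))
    return out


def _filter_candidates(cands, preset: RepeatPreset):
    kept = []
    for start, units, partial in cands:
        n_units = len(units)
        n_seed = sum(1 for u in units if u in preset.seed_units)
        total = UNIT_LENGTH * n_units + len(partial)
        if n_units < preset.min_units:
            continue
        if n_seed < preset.min_seed_units:
            continue
        if total < preset.min_total_length:
            continue
        kept.append((start, units, partial, n_seed))
    return kept


def resolve_overlaps(cands):
    """Greedy overlap resolution among same-strand candidates.

    Keeps, in priority order, the candidate with more seed units, then
    more units, then smaller start; a candidate overlapping an already
    accepted one is dropped.  Input/output items:
    (start, units, partial, n_seed).
    """
    ordered = sorted(
        cands, key=lambda c: (-c[3], -len(c[1]), c[0])
    )
    accepted = []
    spans: list[tuple[int, int]] = []
    for c in ordered:
        start = c[0]
        end = start + UNIT_LENGTH * len(c[1]) + len(c[2])
        if any(start < e and s < end for s, e in spans):
            continue
        accepted.append(c)
        spans.append((start, end))
    return sorted(accepted, key=lambda c: c[0])


def scan_repeats(
    genome: GenomeRecord, preset: RepeatPreset, circular: bool = False,
    origin_pad: int = 512,
) -> list[RepeatHit]:
    """Scan both strands of *genome* for tandem heptamer arrays.

    Minus-strand hits are found on the reverse complement and mapped back
    to forward coordinates; overlapping candidates are resolved per
    strand, while hits on opposite strands may overlap and are both kept.
    Result is sorted by (start, end, strand).

    With ``circular`` the first ``origin_pad`` bases are appended so
    arrays spanning the origin are found; such hits keep ``start < L``
    and report ``end > L`` (coordinates wrap).
    """
    if circular:
        ext = GenomeRecord(
            id=genome.id,
            sequence=genome.sequence + genome.sequence[: min(origin_pad, genome.length)],
        )
        kept = [h for h in scan_repeats(ext, preset) if h.start < genome.length]
        return _drop_wrap_shadows(kept, genome.length)
    hits: list[RepeatHit] = []
    L = genome.length
    for strand in ("+", "-"):
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        cands = _filter_candidates(_candidates_one_strand(seq, preset), preset)
        for start_s, units, partial, n_seed in resolve_overlaps(cands):
            span = UNIT_LENGTH * len(units) + len(partial)
            if strand == "+":
                start, end = start_s, start_s + span
            else:
                start, end = L - (start_s + span), L - start_s
            run, capable = call_g4_capability(
                units, partial, preset.tract_prefix_length
            )
            hits.append(
                RepeatHit(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    units=units,
                    n_seed_units=n_seed,
                    trailing_partial=partial,
                    intact_tracts_max_run=run,
                    g4_capable=capable,
                    preset_name=preset.name,
                    repeat_id=_hit_id(genome.id, start, end, strand),
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))
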