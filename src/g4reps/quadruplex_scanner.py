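"""Generic putative G-quadruplex (PQS) motif scan.

A tract is a maximal run of >= ``g_min`` guanines.  Consecutive tracts
chain when separated by a loop of ``loop_min``..``loop_max`` bases, and
a hit is a maximal chain of >= ``min_tracts`` tracts.  Hits are greedy,
maximal and non-overlapping per strand; minus-strand hits are found on
the reverse complement (equivalently C-tract patterns on the forward
strand) and reported in forward coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome_io import ContractError, GenomeRecord, revcomp

__all__ = ["QuadruplexHit", "scan_pqs"]


@dataclass(frozen=True)
class QuadruplexHit:
    genome_id: str
    start: int
    end: int
    strand: str
    tract_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    sequence: str  # as read on the hit strand

    @property
    def n_tracts(self) -> int:
        return len(self.tract_lengths)


def _chains_one_strand(seq: str, g_min: int, loop_min: int, loop_max: int,
                       min_tracts: int):
    """Maximal chains of G-tracts as (start, end, tract_lengths, loop_lengths)."""
    tracts = [
        (m.start(), m.end())
        for m in re.finditer("G+", seq)
        if m.end() - m.start() >= g_min
    ]
    chains = []
    i = 0
    while i < len(tracts):
        j = i
        while (
            j + 1 < len(tracts)
            and loop_min <= tracts[j + 1][0] - tracts[j][1] <= loop_max
        ):
            j += 1
        members = tracts[i : j + 1]
        if len(members) >= min_tracts:
            tl = tuple(e - s for s, e in members)
            ll = tuple(
                members[k + 1][0] - members[k][1] for k in range(len(members) - 1)
            )
            chains.append((members[0][0], members[-1][1], tl, ll))
        i = j + 1
    return chains


def scan_pqs(
    genome: GenomeRecord,
    g_min: int = 3,
    loop_min: int = 1,
    loop_max: int = 5,
    min_tracts: int = 4,
    g_max: int | None = None,
    circular: bool = False,
    origin_pad: int = 256,
) -> list[QuadruplexHit]:
    """Scan both strands for putative quadruplex motifs.

    ``g_max``, when given, drops hits containing a tract longer than
    ``g_max``; runs of G are never split.  Result sorted by
    (start, end, strand).  ``circular`` appends ``origin_pad`` leading
    bases so motifs spanning the origin are found (their ``end``
    exceeds the genome length).
    """
    if circular:
        ext = GenomeRecord(
            id=genome.id,
            sequence=genome.sequence + genome.sequence[: min(origin_pad, genome.length)],
        )
        kept = [
            h
            for h in scan_pqs(ext, g_min, loop_min, loop_max, min_tracts, g_max)
            if h.start < genome.length
        ]
        L = genome.length
        return [
            h
            for h in kept
            if not any(
                w is not h and w.strand == h.strand and w.end > L and h.end <= w.end - L
                for w in kept
            )
        ]
    if g_min < 2:
        raise ContractError("g_min must be >= 2")
    if loop_min < 1 or loop_max < loop_min:
        raise ContractError("need 1 <= loop_min <= loop_max")
    if min_tracts < 4:
        raise ContractError("min_tracts must be >= 4")
    if g_max is not None and g_max < g_min:
        raise ContractError("g_max must be >= g_min")
    hits: list[QuadruplexHit] = []
    L = genome.length
    for strand in ("+", "-"):
        seq = genome.sequence if strand == "+" else revcomp(genome.sequence)
        for s, e, tl, ll in _chains_one_strand(seq, g_min, loop_min, loop_max,
                                               min_tracts):
            if g_max is not None and any(t > g_max for t in tl):
                continue
            if strand == "+":
                start, end = s, e
            else:
                start, end = L - e, L - s
            hits.append(
                QuadruplexHit(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    tract_lengths=tl,
                    loop_lengths=ll,
                    sequence=seq[s:e],
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))
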