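"""Position of repeats on assembled transcripts.

Each intergenic repeat is either not covered by any transcript, or the
transcript's 5' end starts within the repeat (``start``), its 3' end
lies within the repeat or at most ``max_after`` bases past it in the
transcript's reading direction (``stop``), or the repeat sits in the
transcript interior (``middle``).  ``strand_content`` records whether
the transcript carries the G-rich or the C-rich strand of the repeat.
Repeats are split into a G4-capable set and a control set of short /
mutated arrays; repeats in coding regions are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .context_annotator import ContextAnnotation
from .genome_io import ContractError, FormatError
from .repeat_scanner import RepeatHit

__all__ = [
    "TranscriptInterval",
    "TranscriptRepeatCall",
    "read_transcripts",
    "assign_sets",
    "classify_transcript_position",
    "position_summary",
]

POSITION_CLASSES = ("no_transcript", "start", "stop", "middle")


@dataclass(frozen=True)
class TranscriptInterval:
    transcript_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    expression: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"transcript {self.transcript_id!r}: start >= end")

    @property
    def five_prime(self) -> int:
        """Offset of the transcript's first base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Offset of the transcript's last base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TranscriptRepeatCall:
    repeat_id: str
    set_label: str  # g4 | control
    position_class: str
    transcript_id: Optional[str] = None
    strand_content: Optional[str] = None  # g_rich | c_rich


def read_transcripts(path: str | Path, format: str = "bed") -> list[TranscriptInterval]:
    """Read transcript genome intervals from BED6 (score column doubles as
    an expression value when numeric) or GFF3."""
    path = Path(path)
    out = []
    if format == "bed":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                expr = float(cols[4])
            except ValueError:
                expr = 0.0
            out.append(
                TranscriptInterval(
                    transcript_id=cols[3],
                    genome_id=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=cols[5],
                    expression=expr,
                )
            )
    elif format == "gff3":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            attrs = dict(
                kv.partition("=")[::2] for kv in cols[8].split(";") if kv
            )
            out.append(
                TranscriptInterval(
                    transcript_id=attrs.get("ID", f"transcript_{lineno}"),
                    genome_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    expression=float(cols[5]) if cols[5] != "." else 0.0,
                )
            )
    else:
        raise ContractError(f"unknown transcript format {format!r}")
    return sorted(out, key=lambda t: (t.start, t.end))


def assign_sets(
    repeats: Sequence[RepeatHit], contexts: Sequence[ContextAnnotation]
) -> dict[str, str]:
    """repeat_id -> "g4" | "control"; intragenic repeats are excluded.

    Both members of an inverted pair are retained individually.
    """
    ctx = {c.repeat_id: c for c in contexts}
    out: dict[str, str] = {}
    for r in repeats:
        c = ctx.get(r.repeat_id)
        if c is None:
            raise ContractError(f"missing context for repeat {r.repeat_id}")
        if c.location_class != "intergenic":
            continue
        out[r.repeat_id] = "g4" if r.g4_capable else "control"
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return min(a1, b1) - max(a0, b0)


def classify_transcript_position(
    repeat: RepeatHit,
    transcripts: Sequence[TranscriptInterval],
    max_after: int = 30,
    set_label: str = "",
) -> TranscriptRepeatCall:
    """Classify one repeat against the transcript set.

    Candidates overlap the repeat by >= 1 base (or abut it exactly);
    the candidate with the greatest overlap wins, ties broken by higher
    expression, then greater length, then smaller start.
    """
    cands = []
    for t in transcripts:
        ov = _overlap(t.start, t.end, repeat.start, repeat.end)
        if ov > 0 or (ov == 0 and (t.end == repeat.start or t.start == repeat.end)):
            cands.append((ov, t))
    if not cands:
        return TranscriptRepeatCall(
            repeat.repeat_id, set_label, "no_transcript", None, None
        )
    cands.sort(
        key=lambda c: (-c[0], -c[1].expression, -(c[1].end - c[1].start), c[1].start)
    )
    t = cands[0][1]
    if repeat.start <= t.five_prime < repeat.end:
        cls = "start"
    elif repeat.start <= t.three_prime < repeat.end:
        cls = "stop"
    else:
        # distance past the repeat's 3'-most boundary in transcript direction
        past = (t.end - repeat.end) if t.strand == "+" else (repeat.start - t.start)
        cls = "stop" if 0 < past <= max_after else "middle"
    content = "g_rich" if t.strand == repeat.strand else "c_rich"
    return TranscriptRepeatCall(repeat.repeat_id, set_label, cls, t.transcript_id, content)


def classify_all(
    repeats: Sequence[RepeatHit],
    contexts: Sequence[ContextAnnotation],
    transcripts: Sequence[TranscriptInterval],
    max_after: int = 30,
) -> list[TranscriptRepeatCall]:
    """Set assignment plus position classification for every retained repeat."""
    sets = assign_sets(repeats, contexts)
    by_id = {r.repeat_id: r for r in repeats}
    return [
        classify_transcript_position(by_id[rid], transcripts, max_after, label)
        for rid, label in sets.items()
    ]


def position_summary(
    calls: Sequence[TranscriptRepeatCall],
) -> dict[str, dict[str, float]]:
    """Fractions per set_label x position_class, and per set_label x
    position_class x strand_content; fractions within each set sum to 1."""
    out: dict[str, dict[str, float]] = {}
    for label in sorted({c.set_label for c in calls}):
        members = [c for c in calls if c.set_label == label]
        n = len(members)
        table: dict[str, float] = {}
        for cls in POSITION_CLASSES:
            k = sum(1 for c in members if c.position_class == cls)
            if k:
                table[cls] = k / n
            for content in ("g_rich", "c_rich"):
                kk = sum(
                    1
                    for c in members
                    if c.position_class == cls and c.strand_content == content
                )
                if kk:
                    table[f"{cls}.{content}"] = kk / n
        out[label] = table
    return out
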