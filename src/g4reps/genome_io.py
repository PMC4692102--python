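"""Reading genomes and ORF annotations; writing interval tables.

All internal coordinates are 0-based half-open on the forward strand.
1-based inclusive coordinates appear only at the GFF3 boundary and in
report text.  Strands are ``"+"`` and ``"-"``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "ContractError",
    "GenomeRecord",
    "OrfAnnotation",
    "read_genome",
    "read_orfs",
    "read_intervals",
    "write_intervals",
    "write_fasta",
    "write_orfs_gff3",
]

VALID_BASES = frozenset("ACGTN")
STRANDS = ("+", "-")


class FormatError(ValueError):
    """Input file violates its declared format or the alphabet rules."""


class ContractError(ValueError):
    """A call violated an operation's input contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """One nucleotide sequence entry (chromosome or plasmid)."""

    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("genome record id must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ContractError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class OrfAnnotation:
    """An annotated coding region; the reference frame for context calls."""

    start: int
    end: int
    strand: str
    locus_tag: str
    genome_id: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"ORF {self.locus_tag!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"ORF {self.locus_tag!r}: bad strand {self.strand!r}")


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for offset, base in enumerate(seq):
        if base not in VALID_BASES:
            raise FormatError(
                f"record {record_id!r}: illegal character {base!r} at offset {offset}"
            )
    return seq


def read_genome(path: str | Path, format: str = "fasta") -> list[GenomeRecord]:
    """Read genome sequences from FASTA or GenBank.

    Lowercase is upcased and U mapped to T; characters outside
    ``{A,C,G,T,N}`` raise :class:`FormatError` naming the offset.
    """
    if format not in ("fasta", "genbank"):
        raise ContractError(f"unknown genome format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), format):
        topology = "linear"
        if format == "genbank":
            topology = rec.annotations.get("topology", "linear")
            if topology not in ("linear", "circular"):
                topology = "linear"
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=_normalize_sequence(str(rec.seq), rec.id),
                topology=topology,
            )
        )
    if not records:
        raise FormatError(f"{path}: no sequence records found")
    return records


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_orfs(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "CDS",
    genome_length: int | None = None,
) -> list[OrfAnnotation]:
    """Read ORF annotations from GFF3 or GenBank, sorted by (start, end).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    if format not in ("gff3", "genbank"):
        raise ContractError(f"unknown annotation format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    orfs: list[OrfAnnotation] = []
    if format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
                seqid, _, ftype, start1, end1, _, strand, _, attrs = cols
                if ftype != feature_type:
                    continue
                try:
                    start1i, end1i = int(start1), int(end1)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
                if start1i > end1i:
                    raise FormatError(f"{path}:{lineno}: start {start1i} > end {end1i}")
                if strand not in STRANDS:
                    raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
                att = _parse_gff3_attributes(attrs)
                orfs.append(
                    OrfAnnotation(
                        genome_id=seqid,
                        start=start1i - 1,
                        end=end1i,
                        strand=strand,
                        locus_tag=att.get("locus_tag", att.get("ID", f"feature_{lineno}")),
                        product=att.get("product", ""),
                    )
                )
    else:  # genbank
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type != feature_type:
                    continue
                start = int(feat.location.start)
                end = int(feat.location.end)
                if start > end:
                    raise FormatError(
                        f"{path}: feature with start {start} > end {end} in {rec.id}"
                    )
                strand = "-" if feat.location.strand == -1 else "+"
                quals = feat.qualifiers
                orfs.append(
                    OrfAnnotation(
                        genome_id=rec.id,
                        start=start,
                        end=end,
                        strand=strand,
                        locus_tag=quals.get("locus_tag", [f"{rec.id}_{start}"])[0],
                        product=quals.get("product", [""])[0],
                    )
                )
    if genome_length is not None:
        for orf in orfs:
            if orf.end > genome_length:
                raise FormatError(
                    f"ORF {orf.locus_tag!r} extends to {orf.end}, "
                    f"beyond genome length {genome_length}"
                )
    return sorted(orfs, key=lambda o: (o.start, o.end))


# ---------------------------------------------------------------------------
# Interval record output (BED6 / TSV / JSON), deterministic bytes.
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("genome_id", "start", "end", "strand")


def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        d = dataclasses.asdict(rec)
    elif isinstance(rec, dict):
        d = dict(rec)
    else:
        raise ContractError(f"cannot serialize record of type {type(rec).__name__}")
    for key in _REQUIRED_FIELDS:
        if key not in d:
            raise ContractError(f"interval record missing required field {key!r}")
    return d


def _format_value(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple)):
        return ",".join(str(x) for x in v)
    if isinstance(v, bool):
        return str(int(v))
    return str(v)


def write_intervals(records: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write located hits as BED6, TSV (with header) or JSON.

    Output is byte-identical across runs for identical input: field order
    follows the first record, floats use a fixed ``%.6g`` format.
    """
    if format not in ("bed", "tsv", "json"):
        raise ContractError(f"unknown interval format {format!r}")
    dicts = [_record_to_dict(r) for r in records]
    path = Path(path)
    if format == "bed":
        lines = []
        for d in dicts:
            name = d.get("repeat_id") or d.get("transcript_id") or d.get("name") or "."
            lines.append(f"{d['genome_id']}\t{d['start']}\t{d['end']}\t{name}\t0\t{d['strand']}")
        path.write_text("".join(line + "\n" for line in lines))
    elif format == "tsv":
        if dicts:
            cols = list(dicts[0].keys())
            body = [
                "\t".join(_format_value(d[c]) for c in cols) for d in dicts
            ]
            path.write_text("\t".join(cols) + "\n" + "".join(b + "\n" for b in body))
        else:
            path.write_text("\t".join(_REQUIRED_FIELDS) + "\n")
    else:
        path.write_text(json.dumps(dicts, indent=1, sort_keys=False) + "\n")


def read_intervals(path: str | Path, format: str = "tsv") -> list[dict]:
    """Read back interval tables written by :func:`write_intervals`.

    Returns dicts with ``start``/``end`` as ints; other fields as written
    (TSV values stay text except coordinates).
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            out = json.load(fh)
    elif format == "bed":
        out = []
        for line in path.read_text().splitlines():
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}: BED6 line with {len(cols)} columns")
            out.append(
                {
                    "genome_id": cols[0],
                    "start": int(cols[1]),
                    "end": int(cols[2]),
                    "name": cols[3],
                    "score": cols[4],
                    "strand": cols[5],
                }
            )
    elif format == "tsv":
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        out = []
        for line in lines[1:]:
            if not line:
                continue
            d = dict(zip(header, line.split("\t")))
            for key in ("start", "end"):
                if key in d:
                    d[key] = int(d[key])
            out.append(d)
    else:
        raise ContractError(f"unknown interval format {format!r}")
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_orfs_gff3(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    """Write ORFs as GFF3 CDS rows (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            attrs = f"ID={orf.locus_tag};locus_tag={orf.locus_tag}"
            if orf.product:
                attrs += f";product={orf.product}"
            fh.write(
                f"{orf.genome_id}\tg4reps\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\t{attrs}\n"
            )


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTN", "TGCAN")
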