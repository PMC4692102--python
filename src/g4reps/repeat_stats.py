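"""Summary statistics over repeat surveys.

Position-frequency matrix of the heptamer unit (the data behind a
sequence logo), unit-count histograms, and strand / location /
orientation composition tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context_annotator import ContextAnnotation
from .genome_io import ContractError
from .repeat_scanner import UNIT_LENGTH, RepeatHit

__all__ = [
    "PositionFrequencyMatrix",
    "build_pfm",
    "unit_histogram",
    "composition_summary",
]

BASES = "ACGT"


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts across all full repeat units.

    Rows A, C, G, T; columns are unit positions 1-7.  Information
    content per position is 2 + sum(f * log2 f) bits against a uniform
    background, with 0 * log 0 = 0.
    """

    counts: np.ndarray  # shape (4, 7), int
    n_units_total: int

    @property
    def frequencies(self) -> np.ndarray:
        col = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(col > 0, self.counts / col, 0.0)
        return f

    @property
    def info_bits(self) -> np.ndarray:
        f = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(BASES), columns=range(1, UNIT_LENGTH + 1)
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="base")


def build_pfm(hits: Sequence[RepeatHit]) -> PositionFrequencyMatrix:
    """PFM over every full 7-mer unit of every hit, read on the repeat strand.

    Trailing partial units are excluded.
    """
    counts = np.zeros((4, UNIT_LENGTH), dtype=int)
    n_units = 0
    idx = {b: i for i, b in enumerate(BASES)}
    for hit in hits:
        for unit in hit.units:
            n_units += 1
            for pos, base in enumerate(unit):
                if base in idx:
                    counts[idx[base], pos] += 1
    if n_units == 0:
        raise ContractError("build_pfm requires at least one full unit")
    return PositionFrequencyMatrix(counts=counts, n_units_total=n_units)


def unit_histogram(hits: Sequence[RepeatHit]) -> dict[int, int]:
    """Mapping unit count -> number of repeats; absent keys mean zero."""
    return dict(sorted(Counter(h.n_units for h in hits).items()))


def composition_summary(
    hits: Sequence[RepeatHit], contexts: Sequence[ContextAnnotation]
) -> dict[str, dict[str, float]]:
    """Fractions of hits by strand, by location, and by the six-way
    orientation/location category.

    Each partition's fractions sum to 1 over all hits.  Raises if a hit
    has no context annotation.
    """
    ctx_by_id: Mapping[str, ContextAnnotation] = {c.repeat_id: c for c in contexts}
    missing = [h.repeat_id for h in hits if h.repeat_id not in ctx_by_id]
    if missing:
        raise ContractError(f"missing context for hits: {missing[:3]}...")
    n = len(hits)
    strand = Counter(h.strand for h in hits)
    location = Counter(
        "intergenic"
        if ctx_by_id[h.repeat_id].location_class == "intergenic"
        else "intragenic"
        for h in hits
    )
    category: Counter[str] = Counter()
    for h in hits:
        ctx = ctx_by_id[h.repeat_id]
        if ctx.location_class == "intergenic":
            category[ctx.orientation_class] += 1
        else:
            category[ctx.location_class] += 1

    def fractions(counter: Counter) -> dict[str, float]:
        return {k: v / n for k, v in sorted(counter.items())} if n else {}

    return {
        "strand": fractions(strand),
        "location": fractions(location),
        "category": fractions(category),
    }
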