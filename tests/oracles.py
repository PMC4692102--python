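"""Independent brute-force oracles for the scanners.

These enumerate candidates by a different route than the library
(frame-wise window enumeration instead of seed-anchored extension;
explicit tract-adjacency chains instead of linked maximal runs) and are
deliberately slow and simple.
"""

from __future__ import annotations

from itertools import groupby

from g4reps.genome_io import revcomp
from g4reps.repeat_scanner import IUPAC, RepeatPreset


def _window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(window, pattern)
    )


def brute_force_repeats(sequence: str, preset: RepeatPreset):
    """Enumerate every maximal degenerate 7-mer array on both strands.

    For each strand and each of the 7 frames, chop the sequence into
    consecutive 7-windows, take maximal runs of pattern-matching
    windows that contain at least one exact seed, then apply the same
    trailing-partial rule, thresholds and same-strand overlap
    resolution as the scanner.  Returns a set of
    (start, end, strand, units, partial, n_seed) in forward coordinates.
    """
    L = len(sequence)
    pat = preset.degenerate_unit
    tpl = preset.tract_prefix_length
    results = set()
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        cands = {}
        for frame in range(7):
            starts = [s for s in range(frame, L - 6, 7)]
            matching = [(_window_matches(seq[s : s + 7], pat), s) for s in starts]
            for key, grp in groupby(matching, key=lambda t: t[0]):
                if not key:
                    continue
                run = [s for _, s in grp]
                units = tuple(seq[s : s + 7] for s in run)
                if not any(u in preset.seed_units for u in units):
                    continue
                cands[(run[0], run[-1] + 7)] = units
        filtered = []
        for (a, b), units in cands.items():
            tail = seq[b : b + tpl]
            partial = tail if len(tail) == tpl and tail == "G" * tpl else ""
            n_seed = sum(1 for u in units if u in preset.seed_units)
            if len(units) < preset.min_units:
                continue
            if n_seed < preset.min_seed_units:
                continue
            if 7 * len(units) + len(partial) < preset.min_total_length:
                continue
            filtered.append((a, b + len(partial), units, partial, n_seed))
        # overlap resolution: more seeds, then more units, then leftmost
        filtered.sort(key=lambda c: (-c[4], -len(c[2]), c[0]))
        accepted = []
        for c in filtered:
            if all(c[1] <= a or b <= c[0] for a, b, *_ in accepted):
                accepted.append(c)
        for a, b, units, partial, n_seed in accepted:
            if strand == "+":
                results.add((a, b, "+", units, partial, n_seed))
            else:
                results.add((L - b, L - a, "-", units, partial, n_seed))
    return results


def brute_force_pqs(
    sequence: str,
    g_min: int = 3,
    loop_min: int = 1,
    loop_max: int = 5,
    min_tracts: int = 4,
):
    """Enumerate maximal G-tract chains on both strands.

    Tracts come from character run-length encoding; every pair of
    consecutive tracts is tested for chainability and maximal chains of
    enough tracts are reported as (start, end, strand, tract_lengths,
    loop_lengths) in forward coordinates.
    """
    L = len(sequence)
    results = set()
    for strand in "+-":
        seq = sequence if strand == "+" else revcomp(sequence)
        tracts = []
        pos = 0
        for base, grp in groupby(seq):
            n = len(list(grp))
            if base == "G" and n >= g_min:
                tracts.append((pos, pos + n))
            pos += n
        linked = [
            loop_min <= tracts[i + 1][0] - tracts[i][1] <= loop_max
            for i in range(len(tracts) - 1)
        ]
        i = 0
        while i < len(tracts):
            j = i
            while j < len(tracts) - 1 and linked[j]:
                j += 1
            chain = tracts[i : j + 1]
            if len(chain) >= min_tracts:
                a, b = chain[0][0], chain[-1][1]
                tl = tuple(e - s for s, e in chain)
                ll = tuple(chain[k + 1][0] - chain[k][1] for k in range(len(chain) - 1))
                if strand == "+":
                    results.add((a, b, "+", tl, ll))
                else:
                    results.add((L - b, L - a, "-", tl, ll))
            i = j + 1
    return results
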