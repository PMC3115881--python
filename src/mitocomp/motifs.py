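"""AT-rich control-region analysis: homopolymer runs, motif counts, repeats.

Occurrence counting is overlap-aware (a sliding window), which matters on
AT-rich sequences where short motifs such as ATA overlap themselves.
Approximate repeats are found by a deterministic seed-and-extend scan:
exact k-mer seeds anchor candidate pairs, which are extended ungapped while
the running identity stays at or above the configured minimum (default
75%); consensus strings render mismatching columns as parenthesized
alternatives, e.g. ``ATAT(GT/AA)ATA``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # 1-based
    length: int


@dataclass(frozen=True)
class MotifCount:
    motif: str
    count: int
    positions: tuple[int, ...]  # 1-based, overlapping occurrences included


@dataclass(frozen=True)
class RepeatPair:
    start1: int  # 1-based inclusive
    end1: int
    start2: int
    end2: int
    length: int
    identity: float
    consensus: str


def homopolymer_runs(seq: str, min_len: int = 2) -> list[HomopolymerRun]:
    """Maximal single-base runs of length ≥ ``min_len``, with positions."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append(HomopolymerRun(seq[i], i + 1, j - i + 1))
        i = j + 1
    return runs


def run_length_ranges(runs) -> dict[str, tuple[int, int]]:
    """Per-base (min, max) run length observed, e.g. {"A": (3, 11)}."""
    out: dict[str, tuple[int, int]] = {}
    for r in runs:
        lo, hi = out.get(r.base, (r.length, r.length))
        out[r.base] = (min(lo, r.length), max(hi, r.length))
    return out


def count_motif(seq: str, motif: str) -> MotifCount:
    """Overlapping occurrence count of one motif by sliding window."""
    seq, motif = seq.upper(), motif.upper()
    if len(motif) > len(seq):
        raise ValueError("motif longer than sequence")
    positions = tuple(
        i + 1 for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    )
    return MotifCount(motif, len(positions), positions)


def count_motifs(seq: str, motifs=None, k_range=(2, 4), top: int | None = 10
                 ) -> list[MotifCount]:
    """Count explicit motifs, or rank all k-mers for k in ``k_range``.

    With ``motifs=None`` every k-mer of each length in the inclusive range
    is counted and the ``top`` most frequent per length are returned
    (ranked by count, ties by motif string).
    """
    seq = seq.upper()
    if motifs is not None:
        return [count_motif(seq, m) for m in motifs]
    out: list[MotifCount] = []
    for k in range(k_range[0], k_range[1] + 1):
        found: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            found[seq[i : i + k]].append(i + 1)
        ranked = sorted(found.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        if top is not None:
            ranked = ranked[:top]
        out.extend(MotifCount(m, len(p), tuple(p)) for m, p in ranked)
    return out


# ---------------------------------------------------------------------------
# Approximate repeats

def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _extend(seq: str, i: int, j: int, k: int, min_identity: float,
            max_gap_cols: int = 4) -> tuple[int, int, int] | None:
    """Greedy ungapped extension of a seed pair; returns (i, j, length).

    Extends right then left one column at a time, tolerating mismatches as
    long as the running identity of the whole window stays at or above
    ``min_identity``; gives up a direction after ``max_gap_cols``
    consecutive mismatches. The final window is trimmed to end on matches.
    """
    length = k
    # extend right
    misses = 0
    while j + length < len(seq) and (i + length) <= j:
        cand = length + 1
        ident = _identity(seq[i : i + cand], seq[j : j + cand])
        if ident >= min_identity:
            length = cand
            misses = 0 if seq[i + cand - 1] == seq[j + cand - 1] else misses + 1
        else:
            misses += 1
            if misses > max_gap_cols:
                break
            length = cand  # provisional; trimmed later
    # trim right end to last matching column with acceptable identity
    while length > k and (
        seq[i + length - 1] != seq[j + length - 1]
        or _identity(seq[i : i + length], seq[j : j + length]) < min_identity
    ):
        length -= 1
    # extend left
    misses = 0
    while i > 0 and j > i + length:
        ni, nj, cand = i - 1, j - 1, length + 1
        ident = _identity(seq[ni : ni + cand], seq[nj : nj + cand])
        if ident >= min_identity:
            i, j, length = ni, nj, cand
            misses = 0 if seq[ni] == seq[nj] else misses + 1
        else:
            misses += 1
            if misses > max_gap_cols:
                break
            i, j, length = ni, nj, cand
    while length > k and (
        seq[i] != seq[j]
        or _identity(seq[i : i + length], seq[j : j + length]) < min_identity
    ):
        i, j, length = i + 1, j + 1, length - 1
    if _identity(seq[i : i + length], seq[j : j + length]) < min_identity:
        return None
    return i, j, length


def consensus_string(a: str, b: str) -> str:
    """Two-sequence consensus with alternatives in parentheses.

    Runs of consecutive mismatching columns are grouped:
    ``ATATTA(C/T)ATAT``.
    """
    parts: list[str] = []
    alt_a: list[str] = []
    alt_b: list[str] = []
    for x, y in zip(a, b):
        if x == y:
            if alt_a:
                parts.append(f"({''.join(alt_a)}/{''.join(alt_b)})")
                alt_a, alt_b = [], []
            parts.append(x)
        else:
            alt_a.append(x)
            alt_b.append(y)
    if alt_a:
        parts.append(f"({''.join(alt_a)}/{''.join(alt_b)})")
    return "".join(parts)


def approximate_repeats(seq: str, min_len: int = 30, min_identity: float = 0.75,
                        seed_k: int = 8) -> list[RepeatPair]:
    """Pairs of similar regions found by exact-seed anchoring and extension.

    Overlapping/duplicate pairs are merged (≥50% reciprocal overlap on both
    sides), keeping the longest extension. Positions are 1-based.
    """
    if min_len < 8:
        raise ValueError("min_len must be at least 8")
    seq = seq.upper()
    seeds: dict[str, list[int]] = defaultdict(list)
    for idx in range(len(seq) - seed_k + 1):
        seeds[seq[idx : idx + seed_k]].append(idx)
    raw: list[tuple[int, int, int]] = []
    for positions in seeds.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                if j - i < seed_k:  # self-overlapping tandem seed
                    continue
                ext = _extend(seq, i, j, seed_k, min_identity)
                if ext and ext[2] >= min_len:
                    raw.append(ext)
    # merge pairs with >=50% reciprocal overlap on both intervals
    merged: list[tuple[int, int, int]] = []
    for cand in sorted(raw, key=lambda r: -r[2]):
        ci, cj, cl = cand
        keep = True
        for mi, mj, ml in merged:
            o1 = max(0, min(ci + cl, mi + ml) - max(ci, mi))
            o2 = max(0, min(cj + cl, mj + ml) - max(cj, mj))
            if o1 >= 0.5 * min(cl, ml) and o2 >= 0.5 * min(cl, ml):
                keep = False
                break
        if keep:
            merged.append(cand)
    out = []
    for i, j, length in sorted(merged):
        a = seq[i : i + length]
        b = seq[j : j + length]
        out.append(RepeatPair(
            start1=i + 1, end1=i + length, start2=j + 1, end2=j + length,
            length=length, identity=_identity(a, b),
            consensus=consensus_string(a, b),
        ))
    return out
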