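"""Bounded infix (semi-global) edit distance.

Finds the minimum Levenshtein distance between a short pattern and any
substring of a longer text, capped at ``k + 1``.  The hot path uses the
pigeonhole principle: any match with at most ``k`` edits must contain at
least one of ``k + 1`` contiguous pattern pieces verbatim, so exact piece
hits (C-speed ``str.find``) nominate candidate alignments which are then
verified with a banded dynamic program.  This keeps per-read cost near
O(text) for the overwhelming majority of error-free reads while remaining
exact for every input.
"""

from __future__ import annotations

from typing import List, Optional, Tuple


def _piece_spans(m: int, k: int) -> List[Tuple[int, int]]:
    """k+1 contiguous, near-equal pieces covering the pattern."""
    n_pieces = k + 1
    base, extra = divmod(m, n_pieces)
    spans = []
    pos = 0
    for i in range(n_pieces):
        size = base + (1 if i < extra else 0)
        spans.append((pos, pos + size))
        pos += size
    return spans


def _find_all(text: str, piece: str) -> List[int]:
    hits = []
    pos = text.find(piece)
    while pos != -1:
        hits.append(pos)
        pos = text.find(piece, pos + 1)
    return hits


def _banded_distance(pattern: str, text: str, start: int, k: int) -> int:
    """Edit distance of pattern vs text aligned near ``start``, capped at k+1.

    Diagonal-banded DP: after consuming ``i`` pattern characters the text
    cursor is constrained to ``start + i + delta`` with ``|delta| <= k``,
    which is exact for any alignment whose start lies within ``k`` of the
    nominated candidate position.
    """
    m = len(pattern)
    n = len(text)
    big = k + 1
    width = 2 * k + 1
    prev = [0 if 0 <= start + d - k <= n else big for d in range(width)]
    for i in range(1, m + 1):
        ch = pattern[i - 1]
        cur = [big] * width
        base = start + i - k
        for d in range(width):
            p = base + d  # text prefix length at this cell
            if p < 0 or p > n:
                continue
            best = big
            if p >= 1:
                v = prev[d] + (0 if text[p - 1] == ch else 1)
                if v < best:
                    best = v
            if d + 1 < width:
                v = prev[d + 1] + 1
                if v < best:
                    best = v
            if d >= 1 and p >= 1:
                v = cur[d - 1] + 1
                if v < best:
                    best = v
            cur[d] = best
        prev = cur
        if min(prev) > k:
            return big
    return min(prev)


def bounded_infix_distance(pattern: str, text: str, k: int,
                           ) -> Tuple[int, Optional[Tuple[int, int]]]:
    """(distance, approximate match span) with distance capped at ``k + 1``.

    Returns ``(0, (start, start + m))`` for exact substring hits.  For
    inexact hits the span is the candidate alignment region (accurate to
    within ``k`` positions).  A distance of ``k + 1`` means "more than k".
    """
    m = len(pattern)
    if m == 0:
        return 0, (0, 0)
    pos = text.find(pattern)
    if pos != -1:
        return 0, (pos, pos + m)
    if k == 0:
        return 1, None

    candidates = set()
    for (p_lo, p_hi) in _piece_spans(m, k):
        piece = pattern[p_lo:p_hi]
        if not piece:
            continue
        for hit in _find_all(text, piece):
            candidates.add(hit - p_lo)  # implied pattern start in text
    if not candidates:
        return k + 1, None

    best = k + 1
    best_span = None
    for start in sorted(candidates):
        d = _banded_distance(pattern, text, start, k)
        if d < best:
            best = d
            best_span = (max(0, start), min(len(text), start + m))
            if best == 1:
                break
    return best, best_span


def infix_distance_dp(pattern: str, text: str) -> int:
    """Uncapped semi-global edit distance by the full O(mn) dynamic program.

    Slow reference implementation; used as a cross-check and as the
    fallback when no pigeonhole candidate exists but an exact value is
    still wanted.
    """
    m = len(pattern)
    prev = list(range(m + 1))
    best = prev[m]
    for ch in text:
        cur = [0] * (m + 1)
        for i in range(1, m + 1):
            cost = 0 if pattern[i - 1] == ch else 1
            cur[i] = min(prev[i - 1] + cost, prev[i] + 1, cur[i - 1] + 1)
        best = min(best, cur[m])
        prev = cur
    return best
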