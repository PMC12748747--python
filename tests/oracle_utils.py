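"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: full dynamic-programming matrices,
nested loops, direct string assembly.  None of it shares code with the
package internals it checks.
"""

from typing import Dict, List, Tuple

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def dp_infix_edit_distance(pattern: str, text: str) -> int:
    """Full O(mn) semi-global edit-distance matrix, no shortcuts."""
    m, n = len(pattern), len(text)
    matrix = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        matrix[i][0] = i
    for j in range(1, n + 1):
        matrix[0][j] = 0  # a match may start at any text position
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            matrix[i][j] = min(
                matrix[i - 1][j - 1] + cost,
                matrix[i - 1][j] + 1,
                matrix[i][j - 1] + 1,
            )
    return min(matrix[m])


def oracle_junction_label(insert: str, windows: Dict[str, str], max_edit: int,
                          ) -> Tuple[str, int]:
    """Reference decision rule over a full DP scan of every window.

    Returns (label, distance); ties collapse to a joint label when all tied
    windows are string-identical, otherwise 'unclassified'.
    """
    distances = {
        label: dp_infix_edit_distance(window, insert)
        for label, window in windows.items()
    }
    best = min(distances.values())
    if best > max_edit:
        return "unclassified", best
    tied = sorted(label for label, d in distances.items() if d == best)
    if len(tied) == 1:
        return tied[0], best
    if len({windows[label] for label in tied}) == 1:
        return "|".join(tied), best
    return "unclassified", best


def assemble_joined_duplex(top_seq: str, bottom_variant_info, insertion: str,
                           ) -> Tuple[str, str]:
    """Brute-force model-2 duplex: top strand joined with an insertion, the
    bottom strand synthesised fully complementary except at the strand-ID.

    ``bottom_variant_info`` is ``(top_interval, bottom_variant)`` with the
    interval in top-strand coordinates.  Returns (top_full, bottom_full),
    bottom in its own 5'->3' orientation.
    """
    (lo, hi), bottom_variant = bottom_variant_info
    top_full = top_seq + insertion + top_seq
    bottom = list(naive_revcomp(top_full))
    total = len(top_full)
    for offset in (0, len(top_seq) + len(insertion)):
        # top-interval [offset+lo, offset+hi) maps to
        # [total-offset-hi, total-offset-lo) on the reversed strand
        start = total - offset - hi
        bottom[start:start + (hi - lo)] = bottom_variant
    return top_full, "".join(bottom)


def nested_loop_group(reads) -> Dict[str, Dict[str, List]]:
    """Hash-free quadratic grouping of annotated reads by UMI and strand."""
    seen_umis: List[str] = []
    for read in reads:
        if read.strand == "undetermined":
            continue
        already = False
        for umi in seen_umis:
            if umi == read.umi:
                already = True
                break
        if not already:
            seen_umis.append(read.umi)
    families: Dict[str, Dict[str, List]] = {}
    for umi in seen_umis:
        families[umi] = {"top": [], "bottom": []}
        for read in reads:
            if read.strand != "undetermined" and read.umi == umi:
                families[umi][read.strand].append(read)
    return families


def best_overlap_by_enumeration(seq1: str, seq2_rc: str, min_overlap: int,
                                max_rate: float):
    """Exhaustive suffix/prefix overlap scoring for the pair merger."""
    best = None
    for overlap in range(min_overlap, min(len(seq1), len(seq2_rc)) + 1):
        mism = sum(a != b for a, b in zip(seq1[-overlap:], seq2_rc[:overlap]))
        rate = mism / overlap
        if rate <= max_rate:
            if best is None or rate < best[0] or (rate == best[0] and overlap > best[1]):
                best = (rate, overlap)
    return best
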