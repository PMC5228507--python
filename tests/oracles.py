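"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written without reference to the package's
internal algorithms: edit distances come from edlib (or a tiny pure-Python
DP), occurrence enumeration scans every substring, chaining enumerates every
subset, and alignment scans every diagonal offset.
"""

from __future__ import annotations

import itertools

import edlib

_L = str.maketrans("N", "{")
_R = str.maketrans("N", "}")

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def lev_python(a: str, b: str) -> int:
    """Textbook O(nm) edit distance; N mismatches everything, including N."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cost = 0 if (ca == cb and ca != "N") else 1
            cur.append(min(prev[j - 1] + cost, prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def lev_edlib(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a.translate(_L), b.translate(_R), task="distance")[
        "editDistance"
    ]


def scan_occurrences(read: str, query: str, d_max: int) -> list[tuple[int, int, int]]:
    """All collapsed occurrences of one oriented query by exhaustive scan.

    For every end position, the minimum edit distance over all starts is
    found by enumerating substrings; sub-threshold ends get their best span
    (minimum edits, then shortest); overlapping spans collapse to the best
    (minimum edits, then shortest span, then leftmost). Returns
    (start, end, edits) triples sorted by position.
    """
    m = len(query)
    candidates = []
    for j in range(len(read) + 1):
        best_e, best_i = None, None
        for span in range(max(0, m - d_max), m + d_max + 1):
            i = j - span
            if i < 0:
                continue
            e = lev_edlib(read[i:j], query)
            if best_e is None or e < best_e:
                best_e, best_i = e, i
        if best_e is not None and best_e <= d_max and best_i < j:
            # shortest span among starts achieving best_e
            for span in range(max(0, m - d_max), m + d_max + 1):
                i = j - span
                if i < 0:
                    continue
                if lev_edlib(read[i:j], query) == best_e:
                    best_i = i
                    break
            candidates.append((best_i, j, best_e))
    # collapse chained-overlap groups
    out = []
    group: list[tuple[int, int, int]] = []
    group_end = None
    for cand in sorted(candidates):
        if group and cand[0] < group_end:
            group.append(cand)
            group_end = max(group_end, cand[1])
        else:
            if group:
                out.append(min(group, key=lambda c: (c[2], c[1] - c[0], c[0])))
            group = [cand]
            group_end = cand[1]
    if group:
        out.append(min(group, key=lambda c: (c[2], c[1] - c[0], c[0])))
    return out


def best_chain(matches):
    """Exhaustive best maximal non-overlapping subset of DRMatch objects.

    Subsets are ranked by their priority-sorted key sequences,
    lexicographically; priority = (edits, -span, start, end, query_id,
    strand). Only maximal subsets compete.
    """
    def key(m):
        return (m.edits, -(m.end - m.start), m.start, m.end, m.query_id, m.strand)

    def compatible(sub):
        return all(
            a.end <= b.start or b.end <= a.start
            for a, b in itertools.combinations(sub, 2)
        )

    matches = list(matches)
    best, best_rank = None, None
    for r in range(len(matches), 0, -1):
        for sub in itertools.combinations(matches, r):
            if not compatible(sub):
                continue
            rest = [m for m in matches if m not in sub]
            maximal = all(
                any(not (m.end <= s.start or s.end <= m.start) for s in sub)
                for m in rest
            )
            if not maximal:
                continue
            rank = tuple(sorted(key(m) for m in sub))
            if best_rank is None or rank < best_rank:
                best, best_rank = sub, rank
    return sorted(best, key=lambda m: (m.start, m.end)) if best else []


def nw_identities(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Global alignment by explicit DP: (best score, identities in the
    identity-maximal optimal alignment)."""
    n, m = len(a), len(b)
    prev = [(gap * j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(gap * i, 0)]
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            cands = [
                (prev[j - 1][0] + (match if eq else mismatch),
                 prev[j - 1][1] + (1 if eq else 0)),
                (prev[j][0] + gap, prev[j][1]),
                (cur[j - 1][0] + gap, cur[j - 1][1]),
            ]
            cur.append(max(cands))
        prev = cur
    return prev[m]


def best_ungapped_segment(spacer: str, subject: str, match=1, mismatch=-2):
    """Best-scoring ungapped segment over every diagonal offset, by
    exhaustive enumeration of all (offset, start, end). Returns the score."""
    best = None
    m, n = len(spacer), len(subject)
    for diag in range(-m + 1, n):
        lo = max(0, -diag)
        hi = min(m, n - diag)
        if hi <= lo:
            continue
        scores = [
            match
            if (spacer[i] == subject[i + diag] and spacer[i] != "N"
                and subject[i + diag] != "N")
            else mismatch
            for i in range(lo, hi)
        ]
        for a in range(len(scores)):
            total = 0
            for b in range(a, len(scores)):
                total += scores[b]
                if best is None or total > best:
                    best = total
    return best
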