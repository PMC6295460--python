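"""Independent brute-force oracles used to validate the implementation.

Deliberately naive: plain window loops, exhaustive alignment enumeration,
direct recomputation.  Nothing here shares code with the package paths it
checks.
"""

from __future__ import annotations

import math

from eetsurvey.heme_motifs import MotifGrammar
from eetsurvey.tm_topology import KYTE_DOOLITTLE


def brute_force_scan(seq: str, grammar: MotifGrammar) -> list[tuple[str, int, str]]:
    """Position-by-position window check; one hit per heme site (the C,H
    pair ending the pattern), earliest grammar class wins."""
    claimed: set[int] = set()
    hits: list[tuple[str, int, str]] = []
    for name, pat in grammar.classes:
        for s in range(len(seq) - len(pat) + 1):
            site = s + len(pat) - 2
            if site in claimed:
                continue
            if all(pc == "X" or seq[s + i] == pc for i, pc in enumerate(pat)):
                claimed.add(site)
                hits.append((name, s, seq[s:s + len(pat)]))
    order = {name: i for i, (name, _) in enumerate(grammar.classes)}
    hits.sort(key=lambda h: (h[1], order[h[0]]))
    return hits


def brute_force_profile(seq: str, window: int) -> list[float | None]:
    """Windowed hydropathy means by direct recomputation."""
    half = window // 2
    out: list[float | None] = []
    for i in range(len(seq)):
        if i < half or i >= len(seq) - half:
            out.append(None)
        else:
            vals = [KYTE_DOOLITTLE[c] for c in seq[i - half:i + half + 1]]
            out.append(sum(vals) / window)
    return out


def enumerate_global_score(a: str, b: str, matrix, gap_open: float,
                           gap_extend: float) -> float:
    """Exhaustive enumeration of every gapped global alignment.

    A gap run of length L costs gap_open + (L-1)*gap_extend; end gaps are
    penalized.  Exponential: only for tiny sequences.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "D")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "P" else gap_open), "P")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "Q" else gap_open), "Q")

    rec(0, 0, 0.0, None)
    return best
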