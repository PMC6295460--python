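"""Heme-binding motif grammar scanning.

c-type cytochromes attach heme covalently through the cysteines of a
CXXCH motif (the histidine is the proximal axial ligand).  The scanner
matches a small declarative grammar of fixed-length templates over
{specific residue, wildcard X}:

* ``TYPICAL_CX2CH``  — C x x C H, the canonical heme-binding motif;
* ``ATYPICAL_CX3CH`` — C x x x C H, a spacing variant seen next to the
  transmembrane domain of some homologs;
* ``ATYPICAL_AX2CH`` — A x x C H, the alanine-initial variant.

All matches of all classes are reported, and overlapping matches of
distinct heme sites are all kept; but each heme site — identified by the
position of its ligating C,H pair at the pattern's end — is reported once,
under the earliest grammar class that matches it.  The typical motif
therefore takes precedence over the atypical fallbacks describing the same
site.  The grammar is user-extensible (e.g. CX4CH) through
:meth:`MotifGrammar.from_patterns`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import ConsistencyError, ProteinRecord, UsageError

DEFAULT_PATTERNS = [
    ("TYPICAL_CX2CH", "CXXCH"),
    ("ATYPICAL_CX3CH", "CXXXCH"),
    ("ATYPICAL_AX2CH", "AXXCH"),
]


def _validate_pattern(name: str, pattern: str) -> None:
    if len(pattern) < 3:
        raise UsageError(f"motif class {name!r}: pattern must have length >= 3")
    if not (pattern[-1] == "H" and pattern[-2] == "C"):
        raise UsageError(
            f"motif class {name!r}: pattern must end in the heme-ligating pair C,H"
        )


@dataclass
class MotifGrammar:
    """Ordered list of (class name, fixed-length template) pairs."""

    classes: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_PATTERNS))

    def __post_init__(self) -> None:
        names = [n for n, _ in self.classes]
        if len(set(names)) != len(names):
            raise UsageError("motif class names must be unique")
        for name, pattern in self.classes:
            _validate_pattern(name, pattern)

    @classmethod
    def from_patterns(cls, patterns: dict[str, str]) -> "MotifGrammar":
        return cls(classes=list(patterns.items()))

    def compiled(self) -> list[tuple[str, "re.Pattern", int]]:
        out = []
        for name, pattern in self.classes:
            # wildcard X matches any residue, including the unknown residue X
            rx = re.compile("(?=(" + "".join("." if c == "X" else re.escape(c) for c in pattern) + "))")
            out.append((name, rx, len(pattern)))
        return out


@dataclass
class MotifHit:
    """A single motif match: class, 0-based start, and the literal substring."""

    class_name: str
    start: int
    matched: str


def scan_motifs(protein: ProteinRecord, grammar: MotifGrammar | None = None) -> list[MotifHit]:
    """Scan a protein for all grammar matches.

    Returns hits sorted by start then grammar class order.  Overlapping
    matches at distinct heme sites are all reported; a heme site (the
    ligating C,H pair at the pattern's end) already claimed by an earlier
    grammar class is not reported again under a later class.
    """
    if grammar is None:
        grammar = MotifGrammar()
    if not grammar.classes:
        raise UsageError("grammar must contain at least one motif class")
    seq = protein.sequence
    claimed_sites: set[int] = set()
    hits: list[MotifHit] = []
    for name, rx, plen in grammar.compiled():
        for m in rx.finditer(seq):
            start = m.start()
            site = start + plen - 2  # position of the ligating cysteine
            if site in claimed_sites:
                continue
            claimed_sites.add(site)
            hits.append(MotifHit(class_name=name, start=start, matched=m.group(1)))
    order = {name: i for i, (name, _) in enumerate(grammar.classes)}
    hits.sort(key=lambda h: (h.start, order[h.class_name]))
    return hits


@dataclass
class MotifSummary:
    counts: dict[str, int]
    n_typical: int
    n_atypical: int
    total: int
    n_terminal_fraction: float


def summarize_motifs(hits: list[MotifHit], length: int) -> MotifSummary:
    """Per-protein motif counts and the fraction of hits in the N-terminal half.

    ``total`` sums typical and atypical counts; the N-terminal fraction is the
    share of hits starting before ``length/2`` (0 when there are no hits).
    Class names beginning with ``TYPICAL`` count as typical.
    """
    counts: dict[str, int] = {}
    n_nterm = 0
    for hit in hits:
        if hit.start + len(hit.matched) > length or hit.start < 0:
            raise ConsistencyError(
                f"motif hit at {hit.start} ({hit.class_name}) outside sequence of length {length}"
            )
        counts[hit.class_name] = counts.get(hit.class_name, 0) + 1
        if hit.start < length / 2:
            n_nterm += 1
    n_typical = sum(v for k, v in counts.items() if k.startswith("TYPICAL"))
    total = sum(counts.values())
    return MotifSummary(
        counts=counts,
        n_typical=n_typical,
        n_atypical=total - n_typical,
        total=total,
        n_terminal_fraction=(n_nterm / total) if total else 0.0,
    )


def motif_table(protein_id: str, hits: list[MotifHit]) -> list[dict]:
    """Rows for the TSV output: protein_id, class, start (0-based), matched."""
    return [
        {"protein_id": protein_id, "class": h.class_name, "start": h.start, "matched": h.matched}
        for h in hits
    ]
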