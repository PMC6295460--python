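"""Iterative template-based homolog survey with architecture verification.

The survey's core procedure: candidate proteins are screened for similarity
to family templates (global alignment, Karlin-Altschul E <= threshold), the
survivors are inspected for the family's domain architecture (heme-binding
motif counts and transmembrane layout), and every verified homolog joins
the template set for the next search round, until a round discovers
nothing new.

Three multiheme cytochrome families are modelled, following the layouts
observed across their known members:

* ``CYMA`` — a short tetra/penta-heme cytochrome with a single N-terminal
  transmembrane anchor (NapC/NirT-like);
* ``CBCL_MTRH_MTOC`` — an N-terminal heme-rich region (3-23 CXXCH) ahead
  of a C-terminal block of 4-6 transmembrane helices;
* ``IMCH`` — 1-3 N-terminal transmembrane helices followed by an atypical
  CX3CH and 5-9 typical CXXCH motifs.

The rule bounds derive from those observed ranges (with modest slack on
length) and are config-overridable; the families' published reports never
state numeric acceptance criteria, so observed ranges are the proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

from .align import (
    AlignParams,
    alignment_score,
    estimate_evalue,
    global_align,
    make_aligner,
    percent_identity,
)
from .heme_motifs import MotifGrammar, MotifHit, scan_motifs, summarize_motifs
from .seqio import ProteinRecord, UsageError
from .tm_topology import (
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_LEN,
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW,
    TmSegment,
    predict_tm_segments,
)

logger = logging.getLogger("eetsurvey")

FAMILIES = ("CYMA", "CBCL_MTRH_MTOC", "IMCH")


@dataclass
class TmParams:
    window: int = DEFAULT_WINDOW
    threshold: float = DEFAULT_THRESHOLD
    merge_gap: int = DEFAULT_MERGE_GAP
    min_len: int = DEFAULT_MIN_LEN


@dataclass
class ArchitectureProfile:
    """Per-protein architecture summary feeding the family rules."""

    protein_id: str
    length: int
    motifs: list[MotifHit]
    tm: list[TmSegment]

    @property
    def n_typical(self) -> int:
        return sum(1 for m in self.motifs if m.class_name.startswith("TYPICAL"))

    @property
    def n_atypical(self) -> int:
        return len(self.motifs) - self.n_typical

    @property
    def total_hemes(self) -> int:
        return len(self.motifs)

    @property
    def n_tm(self) -> int:
        return len(self.tm)

    @property
    def first_tm_start(self) -> Optional[int]:
        return self.tm[0].start if self.tm else None

    @property
    def hemes_before_first_tm(self) -> int:
        if not self.tm:
            return 0
        first = self.tm[0].start
        return sum(1 for m in self.motifs if m.start + len(m.matched) <= first)

    @property
    def hemes_after_last_tm(self) -> int:
        if not self.tm:
            return 0
        last = self.tm[-1].end
        return sum(1 for m in self.motifs if m.start >= last)


def build_architecture(
    protein: ProteinRecord,
    grammar: MotifGrammar | None = None,
    tm_params: TmParams | None = None,
) -> ArchitectureProfile:
    """Compose motif scanning and TM prediction into one profile."""
    if tm_params is None:
        tm_params = TmParams()
    hits = scan_motifs(protein, grammar)
    summarize_motifs(hits, len(protein))  # consistency check on coordinates
    segments = predict_tm_segments(
        protein,
        window=tm_params.window,
        threshold=tm_params.threshold,
        merge_gap=tm_params.merge_gap,
        min_len=tm_params.min_len,
    )
    return ArchitectureProfile(
        protein_id=protein.id, length=len(protein), motifs=hits, tm=segments
    )


@dataclass
class FamilyRuleSet:
    """Closed-interval bounds a profile must satisfy for one family."""

    family: str
    n_tm: tuple[int, int]
    length: Optional[tuple[int, int]] = None
    total_hemes: Optional[tuple[int, int]] = None
    n_typical: Optional[tuple[int, int]] = None
    first_tm_start_max: Optional[int] = None
    heme_side: Optional[str] = None  # 'before_tm' | 'after_tm'

    def evaluate(self, profile: ArchitectureProfile) -> dict[str, bool]:
        checks: dict[str, bool] = {}
        checks["n_tm"] = self.n_tm[0] <= profile.n_tm <= self.n_tm[1]
        if self.length is not None:
            checks["length"] = self.length[0] <= profile.length <= self.length[1]
        if self.total_hemes is not None:
            checks["total_hemes"] = self.total_hemes[0] <= profile.total_hemes <= self.total_hemes[1]
        if self.n_typical is not None:
            checks["n_typical"] = self.n_typical[0] <= profile.n_typical <= self.n_typical[1]
        if self.first_tm_start_max is not None:
            checks["first_tm_start"] = (
                profile.first_tm_start is not None
                and profile.first_tm_start <= self.first_tm_start_max
            )
        if self.heme_side == "before_tm":
            checks["hemes_before_tm"] = (
                profile.total_hemes > 0
                and profile.hemes_before_first_tm == profile.total_hemes
            )
        elif self.heme_side == "after_tm":
            checks["hemes_after_tm"] = (
                profile.total_hemes > 0
                and profile.hemes_after_last_tm == profile.total_hemes
            )
        return checks


def default_family_rules() -> dict[str, FamilyRuleSet]:
    return {
        "CYMA": FamilyRuleSet(
            family="CYMA", n_tm=(1, 1), first_tm_start_max=40,
            total_hemes=(4, 5), length=(150, 400),
        ),
        "CBCL_MTRH_MTOC": FamilyRuleSet(
            family="CBCL_MTRH_MTOC", n_tm=(4, 6), n_typical=(3, 23),
            heme_side="before_tm", length=(400, 1100),
        ),
        "IMCH": FamilyRuleSet(
            family="IMCH", n_tm=(1, 3), first_tm_start_max=80,
            n_typical=(5, 9), heme_side="after_tm",
        ),
    }


@dataclass
class FamilyAssignment:
    protein_id: str
    family: str
    best_template_id: str
    score: float
    evalue: float
    pct_identity: float
    rules_satisfied: dict[str, bool]
    iteration: int = 0


def _template_db_size(templates: dict[str, list[ProteinRecord]]) -> int:
    return sum(len(t) for fam in templates.values() for t in fam)


def classify_family(
    profile: ArchitectureProfile,
    protein: ProteinRecord,
    templates: dict[str, list[ProteinRecord]],
    rules: dict[str, FamilyRuleSet] | None = None,
    params: AlignParams | None = None,
) -> Optional[FamilyAssignment]:
    """Assign a protein to the best-supported family, or None.

    Candidate families are those with a template alignment at
    E <= threshold whose rules the architecture profile satisfies; among
    candidates the highest alignment score wins (ties: lowest E, then
    template order).
    """
    if rules is None:
        rules = default_family_rules()
    if params is None:
        params = AlignParams()
    if not any(templates.get(f) for f in templates):
        raise UsageError("need a non-empty template set for at least one family")
    n = params.db_size or _template_db_size(templates)
    aligner = make_aligner(params)
    candidates: list[tuple[float, float, int, str, ProteinRecord]] = []
    for fam_idx, (family, fam_templates) in enumerate(templates.items()):
        if not fam_templates:
            continue
        best: tuple[float, int, ProteinRecord] | None = None
        for t_idx, template in enumerate(fam_templates):
            s = alignment_score(protein, template, params, aligner)
            if best is None or s > best[0]:
                best = (s, t_idx, template)
        score, t_idx, template = best
        evalue = estimate_evalue(score, len(protein), n, params)
        if evalue > params.evalue_threshold:
            continue
        checks = rules[family].evaluate(profile)
        if not all(checks.values()):
            continue
        candidates.append((score, evalue, fam_idx * 10000 + t_idx, family, template))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    score, evalue, _, family, template = candidates[0]
    res = global_align(protein, template, params)
    return FamilyAssignment(
        protein_id=protein.id,
        family=family,
        best_template_id=template.id,
        score=score,
        evalue=evalue,
        pct_identity=percent_identity(res, "shorter"),
        rules_satisfied=rules[family].evaluate(profile),
        iteration=0,
    )


@dataclass
class RoundLogEntry:
    round: int
    protein_id: str
    family: str
    template_id: str
    score: float
    evalue: float


def iterative_search(
    database: list[ProteinRecord],
    seed_templates: dict[str, list[ProteinRecord]],
    rules: dict[str, FamilyRuleSet] | None = None,
    params: AlignParams | None = None,
    max_rounds: int = 10,
    grammar: MotifGrammar | None = None,
    tm_params: TmParams | None = None,
) -> tuple[list[FamilyAssignment], list[RoundLogEntry]]:
    """Iterative homolog search with template expansion.

    Round r aligns every unassigned database protein against the current
    template set; verified hits (E <= threshold and family rules satisfied)
    are assigned with ``iteration = r`` and join the templates for round
    r + 1.  Stops when a round adds nothing or ``max_rounds`` is reached.
    The E-value database size is the total residue count of the database,
    held fixed across rounds for stable statistics.
    """
    if max_rounds < 1:
        raise UsageError("max_rounds must be >= 1")
    if not database:
        raise UsageError("database must be non-empty")
    if not any(seed_templates.get(f) for f in seed_templates):
        raise UsageError("need at least one seed template")
    if rules is None:
        rules = default_family_rules()
    if params is None:
        params = AlignParams()
    db_size = sum(len(p) for p in database)
    params = replace(params, db_size=db_size)
    aligner = make_aligner(params)

    profiles = {p.id: build_architecture(p, grammar, tm_params) for p in database}
    db_sorted = sorted(database, key=lambda p: p.id)
    templates: dict[str, list[ProteinRecord]] = {
        fam: list(seed_templates.get(fam, [])) for fam in seed_templates
    }
    # incremental best-hit cache: (protein_id, family) -> (score, t_idx, template)
    best_hit: dict[tuple[str, str], tuple[float, int, ProteinRecord]] = {}
    t_counter = {fam: 0 for fam in templates}
    new_templates = {fam: list(ts) for fam, ts in templates.items()}

    assigned: dict[str, FamilyAssignment] = {}
    log: list[RoundLogEntry] = []

    for rnd in range(1, max_rounds + 1):
        # fold the templates added last round into the cache
        for fam, ts in new_templates.items():
            for template in ts:
                t_idx = t_counter[fam]
                t_counter[fam] += 1
                for protein in db_sorted:
                    if protein.id in assigned:
                        continue
                    s = alignment_score(protein, template, params, aligner)
                    key = (protein.id, fam)
                    if key not in best_hit or s > best_hit[key][0]:
                        best_hit[key] = (s, t_idx, template)
        added: list[ProteinRecord] = []
        for protein in db_sorted:
            if protein.id in assigned:
                continue
            profile = profiles[protein.id]
            candidates = []
            for fam_idx, fam in enumerate(templates):
                key = (protein.id, fam)
                if key not in best_hit:
                    continue
                score, t_idx, template = best_hit[key]
                evalue = estimate_evalue(score, len(protein), db_size, params)
                if evalue > params.evalue_threshold:
                    continue
                checks = rules[fam].evaluate(profile)
                if not all(checks.values()):
                    continue
                candidates.append((score, evalue, fam_idx * 100000 + t_idx, fam, template))
            if not candidates:
                continue
            candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
            score, evalue, _, fam, template = candidates[0]
            res = global_align(protein, template, params)
            assignment = FamilyAssignment(
                protein_id=protein.id,
                family=fam,
                best_template_id=template.id,
                score=score,
                evalue=evalue,
                pct_identity=percent_identity(res, "shorter"),
                rules_satisfied=rules[fam].evaluate(profile),
                iteration=rnd,
            )
            assigned[protein.id] = assignment
            added.append(protein)
            log.append(RoundLogEntry(rnd, protein.id, fam, template.id, score, evalue))
        if not added:
            logger.info("round %d added nothing: search converged", rnd)
            break
        logger.info("round %d: %d new assignments", rnd, len(added))
        new_templates = {fam: [] for fam in templates}
        for protein in added:
            fam = assigned[protein.id].family
            templates[fam].append(protein)
            new_templates[fam].append(protein)

    assignments = sorted(assigned.values(), key=lambda a: a.protein_id)
    return assignments, log


def assignment_table(assignments: list[FamilyAssignment],
                     profiles: dict[str, ArchitectureProfile]) -> list[dict]:
    """TSV rows: protein_id, family, best_template, score, evalue,
    pct_identity, n_typical, n_atypical, n_tm, iteration."""
    rows = []
    for a in assignments:
        prof = profiles[a.protein_id]
        rows.append({
            "protein_id": a.protein_id,
            "family": a.family,
            "best_template": a.best_template_id,
            "score": round(a.score, 1),
            "evalue": f"{a.evalue:.3g}",
            "pct_identity": round(a.pct_identity, 1),
            "n_typical": prof.n_typical,
            "n_atypical": prof.n_atypical,
            "n_tm": prof.n_tm,
            "iteration": a.iteration,
        })
    return rows
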