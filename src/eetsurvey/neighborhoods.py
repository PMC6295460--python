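"""Gene-neighborhood (cluster) analysis around verified homolog loci.

Quinol-oxidase/quinone-reductase genes tend to sit in clusters with other
c-type cytochrome genes and, for the CymA and CbcL/MtrH/MtoC families,
with MtrB/MtoB-like outer-membrane porin genes.  "Adjacent" is defined by
gene-rank distance along a contig (default window: 5 genes each side,
never crossing a contig boundary) — the published clusters span a handful
of consecutive locus tags, and rank distance is robust to intergenic-gap
variation.

A neighbor is called a putative c-Cyt when its protein carries >= 1
heme-binding motif (multiheme: >= 2) and porin-like when it aligns to an
MtrB/MtoB template at E below the search threshold; no beta-barrel
structure prediction is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .align import AlignParams, alignment_score, estimate_evalue, make_aligner
from .heme_motifs import MotifGrammar, scan_motifs
from .seqio import GeneRecord, ProteinRecord, SurveyError

logger = logging.getLogger("eetsurvey")

DEFAULT_WINDOW = 5
MULTIHEME_MIN = 2


class LookupError_(SurveyError):
    """Focal protein id missing or ambiguous in the gene set."""


@dataclass
class Neighbor:
    gene: GeneRecord
    offset: int  # signed gene-rank distance from the focal gene
    heme_motif_count: Optional[int] = None
    porin_hit: Optional[tuple[str, float]] = None  # (template id, E-value)


@dataclass
class NeighborhoodReport:
    focal_gene: GeneRecord
    neighbors: list[Neighbor] = field(default_factory=list)
    window_used: int = DEFAULT_WINDOW


def find_neighborhood(genes: list[GeneRecord], focal_protein_id: str,
                      window: int = DEFAULT_WINDOW) -> NeighborhoodReport:
    """Genes within ``window`` rank positions of the focal gene's locus.

    Neighbors are taken on either strand, ordered by rank along the contig;
    a focal gene alone on its contig yields an empty neighbor list.
    """
    matches = [g for g in genes if g.protein_id == focal_protein_id or g.id == focal_protein_id]
    if len(matches) != 1:
        raise LookupError_(
            f"focal id {focal_protein_id!r} matches {len(matches)} genes (need exactly 1)"
        )
    focal = matches[0]
    contig_genes = sorted(
        (g for g in genes if g.contig == focal.contig), key=lambda g: (g.start, g.id)
    )
    rank = contig_genes.index(focal)
    neighbors = [
        Neighbor(gene=contig_genes[r], offset=r - rank)
        for r in range(max(0, rank - window), min(len(contig_genes), rank + window + 1))
        if r != rank
    ]
    return NeighborhoodReport(focal_gene=focal, neighbors=neighbors, window_used=window)


def annotate_cluster(
    report: NeighborhoodReport,
    proteins: dict[str, ProteinRecord],
    porin_templates: list[ProteinRecord],
    grammar: MotifGrammar | None = None,
    params: AlignParams | None = None,
) -> NeighborhoodReport:
    """Fill heme-motif counts and porin-likeness for each neighbor.

    Heme counts include typical and atypical motifs.  A porin hit records
    the best MtrB/MtoB-like template with E <= threshold.  Neighbors
    without a resolvable protein product get count 0 and no porin flag
    (logged, not fatal).
    """
    if params is None:
        params = AlignParams()
    n = params.db_size or sum(len(p) for p in proteins.values()) or 1
    aligner = make_aligner(params) if porin_templates else None
    for nb in report.neighbors:
        prot = proteins.get(nb.gene.protein_id) if nb.gene.protein_id else None
        if prot is None:
            if nb.gene.protein_id:
                logger.warning("neighbor %s: protein %s not found", nb.gene.id, nb.gene.protein_id)
            nb.heme_motif_count = 0
            nb.porin_hit = None
            continue
        nb.heme_motif_count = len(scan_motifs(prot, grammar))
        nb.porin_hit = None
        best: Optional[tuple[float, ProteinRecord]] = None
        for template in porin_templates:
            s = alignment_score(prot, template, params, aligner)
            if best is None or s > best[0]:
                best = (s, template)
        if best is not None:
            evalue = estimate_evalue(best[0], len(prot), n, params)
            if evalue <= params.evalue_threshold:
                nb.porin_hit = (best[1].id, evalue)
    return report


def neighborhood_table(report: NeighborhoodReport) -> list[dict]:
    """TSV rows: focal_id, neighbor_id, offset, strand, heme_count,
    porin_template, evalue."""
    rows = []
    for nb in report.neighbors:
        rows.append({
            "focal_id": report.focal_gene.id,
            "neighbor_id": nb.gene.id,
            "offset": nb.offset,
            "strand": nb.gene.strand,
            "heme_count": nb.heme_motif_count if nb.heme_motif_count is not None else "",
            "porin_template": nb.porin_hit[0] if nb.porin_hit else "",
            "evalue": f"{nb.porin_hit[1]:.3g}" if nb.porin_hit else "",
        })
    return rows


def render_cluster_svg(report: NeighborhoodReport, scale: float = 0.02,
                       height: int = 90) -> str:
    """Cluster diagram: one arrow per gene, length proportional to gene
    length, orientation showing strand, heme count in parentheses.

    Deterministic: identical reports produce identical SVG bytes.
    """
    genes = sorted([report.focal_gene] + [nb.gene for nb in report.neighbors],
                   key=lambda g: g.start)
    counts = {nb.gene.id: nb.heme_motif_count for nb in report.neighbors}
    porins = {nb.gene.id for nb in report.neighbors if nb.porin_hit}
    if not genes:
        return '<svg xmlns="http://www.w3.org/2000/svg" width="10" height="10"></svg>'
    origin = genes[0].start
    width = int((genes[-1].end - origin) * scale) + 60
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
    ]
    y, arrow_h = height // 2, 18
    for g in genes:
        x0 = (g.start - origin) * scale + 20
        x1 = (g.end - origin) * scale + 20
        head = min(8.0, (x1 - x0) / 3)
        if g.strand == "+":
            pts = (f"{x0:.1f},{y - arrow_h / 2:.1f} {x1 - head:.1f},{y - arrow_h / 2:.1f} "
                   f"{x1:.1f},{y:.1f} {x1 - head:.1f},{y + arrow_h / 2:.1f} {x0:.1f},{y + arrow_h / 2:.1f}")
        else:
            pts = (f"{x1:.1f},{y - arrow_h / 2:.1f} {x0 + head:.1f},{y - arrow_h / 2:.1f} "
                   f"{x0:.1f},{y:.1f} {x0 + head:.1f},{y + arrow_h / 2:.1f} {x1:.1f},{y + arrow_h / 2:.1f}")
        if g.id == report.focal_gene.id:
            fill = "#c0392b"
        elif g.id in porins:
            fill = "#2471a3"
        elif (counts.get(g.id) or 0) >= MULTIHEME_MIN:
            fill = "#b7950b"
        else:
            fill = "#aab7b8"
        parts.append(f'<polygon points="{pts}" fill="{fill}" stroke="black"/>')
        label = g.id
        if counts.get(g.id) is not None:
            label += f" ({counts[g.id]})"
        parts.append(
            f'<text x="{x0:.1f}" y="{y + arrow_h + 12}" font-size="9">{label}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)
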