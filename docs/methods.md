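# Methods

This note documents the models and procedures implemented in `eetsurvey`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Heme-binding motif grammar

c-type cytochromes bind heme covalently through the two cysteines of a
CXXCH motif; the histidine provides the proximal axial ligand.  The
scanner matches an ordered grammar of fixed-length templates over
{specific residue, wildcard X}:

| class | pattern | role |
|---|---|---|
| `TYPICAL_CX2CH` | C x x C H | canonical heme-binding motif |
| `ATYPICAL_CX3CH` | C x x x C H | spacing variant near TM domains |
| `ATYPICAL_AX2CH` | A x x C H | alanine-initial variant |

Every window is tested against every class and overlapping matches of
distinct heme sites are all reported.  A *heme site* is identified by the
position of the ligating C,H pair at the pattern's end; each site is
reported once, under the earliest matching grammar class.  This gives the
typical motif precedence over the atypical fallbacks that describe the
same site (e.g. in `CAAACH` the CX₃CH match at 0 and the AX₂CH match at 1
end in the same C,H pair; only the CX₃CH hit is reported).  The grammar is
extensible through configuration (e.g. a CX₄CH class) without code change.

Counts of typical and atypical motifs are reported separately throughout,
since published tallies are not consistent about whether atypical motifs
count as "heme-binding motifs".

## Transmembrane topology

TM segments are called from Kyte–Doolittle hydropathy with a sliding
window (default 19, the span of a membrane-crossing helix) and cutoff 1.6
(the classic strongly-hydrophobic criterion).  Positions whose windowed
mean reaches the cutoff are candidates; each maximal candidate run is
widened to the union of the windows that voted for it (half a window on
each side), runs separated by ≤ 3 residues are merged, and runs shorter
than 15 residues are discarded.  The unknown residue X scores 0 so that
low-quality metagenome ORFs do not produce phantom segments.  No
inside/outside orientation is predicted; downstream rules use only helix
count and position.

Because of the union-of-windows boundary rule, a predicted segment for a
21-residue hydrophobic block extends roughly half a window beyond the
block on each side; segment *midpoints*, not start coordinates, are the
stable quantity, and all planted-versus-predicted comparisons use
midpoints with a ±5-residue tolerance.  A consequence of the 19-residue
window is that two helices separated by a loop shorter than ~24 residues
merge into one predicted segment; the synthetic generator therefore
spaces planted helices by at least 24 residues (real TM predictors based
on trained HMMs resolve tighter packings; this caller trades that
resolution for determinism and zero dependencies).

## Alignment and search statistics

Pairwise alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62; gap open 10, extend 0.2 — the ClustalW protein defaults; a gap
of length L costs `open + (L−1)·extend`; end gaps are penalized).  The X
row/column of the matrix is overridden to −1, a conservative treatment of
unknown residues.  Percent identity supports three denominators —
`shorter` (the default, the ClustalW pairwise convention), `columns`, and
`ungapped_columns` — because published identity figures rarely state
their convention.

Significance uses the Karlin–Altschul form on a background-corrected
score:

```
E = K · m · n · exp(−λ · (S − c·m))
```

with the standard gapped-BLOSUM62 constants (λ = 0.267, K = 0.041), m the
query length, n the total residue count of the database searched, and
c = 0.30 the measured background gain of this scoring system per query
residue.  The correction exists because the classical constants describe
*local* alignment with expensive gaps; under global alignment with a
near-free gap extension (0.2), the optimal score of two unrelated random
proteins grows roughly linearly at ~0.3 per residue of the shorter
sequence (cheap long gaps chain together coincidentally similar
segments).  Without the correction, essentially every desk-scale
comparison would be "significant".  With it, unrelated pairs sit at
E ≫ 1 while genuine homologs at ≥ 30% identity score E ≪ 0.01.  All
constants are configuration-overridable.  Even corrected, the E-gate is a
coarse filter; the architecture rules below do the decisive gating, which
mirrors how the survey procedure is meant to work.

The progressive multiple aligner builds a neighbor-joining guide tree
from pairwise identity distances and merges profiles bottom-up with
profile–profile Needleman–Wunsch under mean-of-pairs column scores (gap
characters score 0; the same affine penalties apply).  It is deterministic
given input order, and de-gapping any output row reproduces the input.

## Family architecture rules

The survey never had numeric acceptance criteria in its published form;
the observed ranges across known family members are used as testable
closed-interval bounds (all configuration-overridable):

| family | TM count | first TM start | hemes | length | heme layout |
|---|---|---|---|---|---|
| CYMA | 1 | ≤ 40 | 4–5 total | 150–400 | — |
| CBCL_MTRH_MTOC | 4–6 | — | 3–23 typical | 400–1100 | all N-terminal of the TM block |
| IMCH | 1–3 | ≤ 80 | 5–9 typical | — | all C-terminal of the TM block; CX₃CH permitted |

Published heme ranges for the ImcH family disagree between sources (5–9
vs 6–10); the rules use 5–9 typical motifs with the atypical CX₃CH
counted separately.

## Iterative survey

Round r aligns every unassigned database protein against the current
template set (screening on score only, traceback only for accepted hits).
A protein is assigned to a family when its best template alignment for
that family reaches E ≤ 0.01 *and* its architecture profile satisfies all
of the family's rules; among qualifying families the highest alignment
score wins (ties: lowest E, then template order).  Verified homologs join
the template set for round r+1; the search stops when a round adds
nothing (or after `max_rounds`, default 10).  The E-value database size n
is the total residue count of the input database, held fixed across
rounds for stable statistics.  A protein is assigned at most one family;
the assignment set is non-decreasing over rounds and the procedure is
deterministic and idempotent (re-seeding with its own output reproduces
the same assignments).

## Gene neighborhoods

"Adjacent" means gene-rank distance ≤ 5 (configurable) along the same
contig, either strand — published clusters span a handful of consecutive
locus tags, and rank distance is robust to intergenic-gap variation.
Neighbors are annotated with their protein's total heme-motif count
(putative c-Cyt: ≥ 1; multiheme: ≥ 2) and with porin-likeness, defined
purely as alignment to an MtrB/MtoB-like template at E ≤ 0.01 (no
β-barrel structure prediction).  Cluster diagrams are emitted as SVG with
arrow length proportional to gene length and heme counts in parentheses.

## Phylogeny

Distance trees stand in for likelihood inference: the survey uses trees
only for clustering statements, which neighbor joining reproduces.
Distances come from the multiple alignment with pairwise deletion (each
pair uses only columns where neither row is gapped — family members vary
several-fold in length, and complete deletion would discard most columns)
as p-distance or Poisson-corrected −ln(1−p).  Neighbor joining follows
Saitou–Nei with ties in the Q-matrix broken on the lowest index pair and
negative branch lengths clamped to zero (deficit logged).  NJ is exact on
additive matrices, which the test suite exploits.

Bootstrap support resamples alignment columns with replacement; replicate
r draws from the independent seed stream (seed, r), so supports do not
depend on taxon input order and replicates are parallel-safe.  An
internal edge's support is the fraction of replicate trees containing the
same leaf bipartition.  Supports are written as internal-node labels in
Newick output.

## Synthetic data

The generator emulates the three family architectures with exact ground
truth:

* Three deterministic synthetic seed templates per family (lengths
  187/250/364 for CymA — the long template carrying the fifth heme motif
  of the long natural variants; 460/700/1000 with 5/9/23 heme motifs for
  CbcL/MtrH/MtoC; 480/520/560 for ImcH), plus a 650-residue MtrB/MtoB-like
  porin template.  These are synthetic stand-ins generated from a fixed
  internal seed, not database sequences.
* Members inherit their template's planted layout, optionally dropping
  heme motifs (CbcL members span the 3–23 range), stretch or truncate the
  C-terminal tail, and are mutated at background positions to the target
  identity (default 0.65; planted elements are never touched, so the
  truth manifest is exact and the realized identity — recorded per
  member — stays above 0.55).
* Decoys come in three classes: random motif-free proteins; motif-bearing
  but template-unrelated proteins; and template-derived proteins with all
  heme motifs deleted (similar enough to pass the E-gate, guaranteed to
  fail verification).
* Every generated protein is *self-verified*: after "scrubbing" (a
  background cysteine that completes a spurious motif becomes serine; a
  spurious hydrophobic run receives aspartates; hydrophobic residues
  flanking a planted block are made hydrophilic), scanning reproduces the
  planted motif coordinates exactly and the TM caller finds exactly the
  planted blocks.
* Annotated genomes place homolog–c-Cyt–porin clusters among filler genes
  on multi-contig layouts; CDS length is 3·aa+3 and the nucleotide
  contigs are uniform-random placeholders (no stage reads codons).
* Taxonomy labels are drawn per family with weights following the
  published per-phylum tallies (CymA confined to Proteobacteria).
* All randomness flows from one seed; identical seeds give byte-identical
  FASTA/GFF3/manifest output.

What passing the benchmark shows — and does not.  The benchmark
demonstrates that the pipeline's logic is correct: planted architectures
are recovered exactly, the iterative search separates members from
decoys, neighborhoods match the planted clusters.  It does not
demonstrate performance on real proteomes: background composition is
uniform rather than biological, mutation is i.i.d. substitution with no
indels or rate variation, TM helices are idealized hydrophobic blocks,
and member-to-template identity (≥ 55%) is higher than the most remote
real homologs (~22–33%).  Real surveys additionally face database-scale
multiple testing that the desk-scale E-statistics here only approximate.

## Problem sizes

Default sizes keep every stage exact rather than heuristic: benchmark
corpora of 200 proteins (50 members + 150 decoys, ~10⁵ residues),
alignment oracle checks on sequences up to length 8 (where exhaustive
enumeration of all gapped alignments is feasible), NJ exactness on 4–8
taxa, bootstrap clade checks with 8 taxa × 200 replicates.  The full
survey benchmark runs in well under a minute on one core.

## Known limitations

* The TM caller is a hydropathy heuristic, not a trained HMM; published
  per-accession helix counts from HMM-based predictors are not guaranteed
  to be reproduced (tracked as calibration, not correctness).
* Global alignment E-values with the background-gain correction are a
  pragmatic desk-scale statistic, not BLAST statistics; the architecture
  rules are the decisive filter.
* Trees are NJ on distance corrections without rate heterogeneity or
  model selection; use them for clustering statements, not for branch
  length interpretation.
* Partial/truncated ORFs are accepted as-is; filtering is left to
  callers.
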