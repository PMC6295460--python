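"""Transmembrane-segment prediction from Kyte-Doolittle hydropathy.

A deterministic sliding-window caller: positions whose windowed mean
hydropathy reaches a cutoff are candidate membrane-spanning residues;
maximal candidate runs are widened to the union of their contributing
windows, nearby runs merged, and short remnants discarded.  The defaults
(window 19, cutoff 1.6) are the classic criterion for a strongly
hydrophobic membrane-spanning stretch.  The unknown residue X scores 0
(neutral) so low-quality metagenome ORFs do not produce phantom segments.

No inside/outside orientation is predicted; downstream family rules use
only helix count and position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqio import ProteinRecord, UsageError

logger = logging.getLogger("eetsurvey")

#: Kyte-Doolittle hydropathy scale; X is neutral.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MERGE_GAP = 3
DEFAULT_MIN_LEN = 15


@dataclass
class TmSegment:
    """A predicted membrane-spanning segment, 0-based half-open coordinates."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def hydropathy_values(sequence: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE[c] for c in sequence], dtype=float)


def hydropathy_profile(protein: ProteinRecord, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed mean hydropathy per position.

    Position ``i`` holds the mean Kyte-Doolittle value of the window centered
    at ``i``; positions whose window would overhang either end are NaN.
    """
    seq = protein.sequence
    if window % 2 == 0 or window < 5:
        raise UsageError(f"window must be odd and >= 5, got {window}")
    if window > len(seq):
        raise UsageError(f"window {window} longer than sequence ({len(seq)} aa)")
    vals = hydropathy_values(seq)
    half = window // 2
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    profile = np.full(len(seq), np.nan)
    profile[half:len(seq) - half] = means
    return profile


def predict_tm_segments(
    protein: ProteinRecord,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[TmSegment]:
    """Predict non-overlapping, sorted membrane-spanning segments.

    Candidate positions have windowed mean >= ``threshold``; each maximal run
    of candidates is widened by half a window on each side (the union of the
    windows that voted for it, clipped to the sequence), runs separated by
    <= ``merge_gap`` residues are merged and runs shorter than ``min_len``
    discarded.
    """
    seq = protein.sequence
    if len(seq) < window:
        logger.warning(
            "protein %s shorter (%d aa) than window %d: no TM prediction",
            protein.id, len(seq), window,
        )
        return []
    profile = hydropathy_profile(protein, window)
    half = window // 2
    candidates = np.where(np.nan_to_num(profile, nan=-np.inf) >= threshold)[0]
    if candidates.size == 0:
        return []
    # maximal runs of consecutive candidate centers
    runs: list[list[int]] = []
    run_start = prev = int(candidates[0])
    for c in candidates[1:]:
        c = int(c)
        if c == prev + 1:
            prev = c
        else:
            runs.append([run_start, prev])
            run_start = prev = c
    runs.append([run_start, prev])
    # widen to the union of contributing windows, then merge close runs
    spans = [[max(0, s - half), min(len(seq), e + half + 1)] for s, e in runs]
    merged: list[list[int]] = [spans[0]]
    for s, e in spans[1:]:
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    vals = hydropathy_values(seq)
    return [
        TmSegment(start=s, end=e, mean_hydropathy=float(vals[s:e].mean()))
        for s, e in merged
        if e - s >= min_len
    ]


def tm_table(protein_id: str, segments: list[TmSegment]) -> list[dict]:
    """Rows for the TSV output: protein_id, start, end, mean_hydropathy."""
    return [
        {
            "protein_id": protein_id,
            "start": seg.start,
            "end": seg.end,
            "mean_hydropathy": round(seg.mean_hydropathy, 4),
        }
        for seg in segments
    ]
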