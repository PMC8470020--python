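"""Multiheme c-type cytochrome (MHC) detection in protein sequences.

c-type cytochromes bind heme covalently at CxxCH motifs (Cys-any-any-Cys-His).
Proteins carrying several such motifs are multiheme cytochromes, the workhorses
of extracellular electron transfer in metal-reducing prokaryotes and in ANME
archaea, where they are thought to wire methane oxidation to external electron
acceptors. This module counts CxxCH motifs per protein, predicts C-terminal
transmembrane anchoring with a Kyte-Doolittle hydropathy window, applies a
minimum-motif call threshold, and rolls results up per genome bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "KYTE_DOOLITTLE",
    "MotifScan",
    "TMPrediction",
    "MHCRecord",
    "MHCSummary",
    "find_heme_motifs",
    "predict_c_terminal_tm",
    "classify_protein",
    "summarize_mag",
    "scan_proteins",
    "summaries_to_frame",
]

# Kyte & Doolittle hydropathy scale. Ambiguity codes score 0 (neutral) and
# never match the motif letters C/H.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class MotifScan:
    """All CxxCH motif start positions (0-based) in one protein."""

    protein_id: str
    positions: Tuple[int, ...]

    @property
    def motif_count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TMPrediction:
    """C-terminal transmembrane helix prediction for one protein."""

    has_c_terminal_tm: bool
    tm_span: Optional[Tuple[int, int]] = None  # [start, end) residue interval
    reason: Optional[str] = None


@dataclass(frozen=True)
class MHCRecord:
    protein_id: str
    motif_count: int
    has_c_terminal_tm: bool
    tm_span: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class MHCSummary:
    """Per-MAG multiheme cytochrome statistics.

    ``n_mhc_gt10`` counts MHCs with strictly more than 10 CxxCH motifs;
    ``max_motifs`` is 0 when the MAG encodes no MHC.
    """

    mag_id: str
    n_mhc: int
    n_mhc_gt10: int
    max_motifs: int
    n_with_tm: int


def find_heme_motifs(sequence: str, protein_id: str = "") -> MotifScan:
    """Locate every CxxCH heme-binding motif, overlapping matches included.

    Position ``p`` matches when ``seq[p] == 'C'``, ``seq[p+3] == 'C'`` and
    ``seq[p+4] == 'H'``; the two middle residues are unrestricted. Ambiguity
    codes ('X' etc.) never stand in for C or H. An empty sequence yields an
    empty scan.
    """
    seq = sequence.upper()
    positions = tuple(
        p for p in range(len(seq) - 4)
        if seq[p] == "C" and seq[p + 3] == "C" and seq[p + 4] == "H"
    )
    return MotifScan(protein_id=protein_id, positions=positions)


def predict_c_terminal_tm(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    c_term_window: int = 40,
) -> TMPrediction:
    """Sliding-window hydropathy prediction of a C-terminal membrane anchor.

    A helix is called when some length-``window`` segment whose start lies
    within the last ``c_term_window`` residues has mean Kyte-Doolittle
    hydropathy >= ``threshold``. The reported span is the maximal-scoring
    qualifying window. Sequences shorter than the window are never called
    (the reason is recorded).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return TMPrediction(False, None, reason="sequence shorter than window")

    scores = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq]
    first_start = max(0, n - c_term_window)
    best: Optional[Tuple[float, int]] = None
    for start in range(first_start, n - window + 1):
        mean = sum(scores[start:start + window]) / window
        # tolerance keeps the threshold comparison inclusive under float error
        if mean >= threshold - 1e-9 and (best is None or mean > best[0]):
            best = (mean, start)
    if best is None:
        return TMPrediction(False, None)
    return TMPrediction(True, (best[1], best[1] + window))


def classify_protein(
    scan: MotifScan, tm: TMPrediction, min_motifs: int = 2
) -> Optional[MHCRecord]:
    """Call a protein an MHC when it carries at least ``min_motifs`` motifs."""
    if min_motifs < 1:
        raise ValueError(f"min_motifs must be >= 1, got {min_motifs}")
    if scan.motif_count < min_motifs:
        return None
    return MHCRecord(
        protein_id=scan.protein_id,
        motif_count=scan.motif_count,
        has_c_terminal_tm=tm.has_c_terminal_tm,
        tm_span=tm.tm_span,
    )


def summarize_mag(mag_id: str, records: Sequence[MHCRecord]) -> MHCSummary:
    counts = [r.motif_count for r in records]
    return MHCSummary(
        mag_id=mag_id,
        n_mhc=len(records),
        n_mhc_gt10=sum(c > 10 for c in counts),
        max_motifs=max(counts, default=0),
        n_with_tm=sum(r.has_c_terminal_tm for r in records),
    )


def scan_proteins(
    proteins: Iterable[Tuple[str, str]],
    min_motifs: int = 2,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    c_term_window: int = 40,
) -> Tuple[list[MHCRecord], pd.DataFrame]:
    """Scan ``(protein_id, sequence)`` pairs; return MHC calls and a full table.

    The table has one row per input protein (called or not) with columns
    protein_id, motif_count, positions, tm_flag, tm_span.
    """
    records: list[MHCRecord] = []
    rows = []
    for protein_id, seq in proteins:
        scan = find_heme_motifs(seq, protein_id)
        tm = predict_c_terminal_tm(seq, tm_window, tm_threshold, c_term_window)
        rec = classify_protein(scan, tm, min_motifs=min_motifs)
        if rec is not None:
            records.append(rec)
        rows.append({
            "protein_id": protein_id,
            "motif_count": scan.motif_count,
            "positions": ",".join(map(str, scan.positions)),
            "tm_flag": tm.has_c_terminal_tm,
            "tm_span": "" if tm.tm_span is None else f"{tm.tm_span[0]}-{tm.tm_span[1]}",
            "is_mhc": rec is not None,
        })
    return records, pd.DataFrame(rows)


def summaries_to_frame(summaries: Sequence[MHCSummary]) -> pd.DataFrame:
    """Tabulate per-MAG summaries in the layout of a cytochrome inventory."""
    return pd.DataFrame(
        [{
            "mag_id": s.mag_id,
            "n_mhc": s.n_mhc,
            "n_mhc_gt10": s.n_mhc_gt10,
            "max_motifs": s.max_motifs,
            "n_with_tm": s.n_with_tm,
        } for s in summaries]
    )
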