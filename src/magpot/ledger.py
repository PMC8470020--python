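"""MAG summary-ledger operations and report rendering.

The ledger is the study's genome-bin overview table: one row per MAG with
domain, taxon, CheckM completeness/contamination, contig count, genome size,
16S rRNA gene length (absent when no 16S was recovered in the bin) and
relative abundance from read mapping. A transcription of the Karabetova Gora
mud-volcano reference ledger (33 bins >50% complete, <5% contamination) ships
with the package, together with the bin-to-phylum mapping used for the
phylum abundance sums.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "MAGRecord",
    "load_reference_ledger",
    "load_reference_phyla",
    "load_ledger",
    "band_count",
    "count_complete_16s",
    "phylum_abundance_sum",
    "coding_fraction",
    "render_reports",
]

LEDGER_COLUMNS = (
    "bin_id", "domain", "taxon", "completeness_pct", "contamination_pct",
    "n_contigs", "genome_size_mbp", "s16_length_bp", "abundance_pct",
)


@dataclass(frozen=True)
class MAGRecord:
    bin_id: str
    domain: str                     # "A" (Archaea) or "B" (Bacteria)
    taxon: str
    completeness_pct: float
    contamination_pct: float
    n_contigs: int
    genome_size_mbp: float
    s16_length_bp: Optional[int]    # None when no 16S gene was recovered
    abundance_pct: float


def _frame_to_records(df: pd.DataFrame) -> list[MAGRecord]:
    records = []
    for row in df.itertuples(index=False):
        s16 = row.s16_length_bp
        records.append(MAGRecord(
            bin_id=row.bin_id,
            domain=row.domain,
            taxon=row.taxon,
            completeness_pct=float(row.completeness_pct),
            contamination_pct=float(row.contamination_pct),
            n_contigs=int(row.n_contigs),
            genome_size_mbp=float(row.genome_size_mbp),
            s16_length_bp=None if pd.isna(s16) else int(s16),
            abundance_pct=float(row.abundance_pct),
        ))
    return records


def load_ledger(path) -> pd.DataFrame:
    """Read a ledger TSV; '-' in the 16S column denotes an absent gene."""
    df = pd.read_csv(path, sep="\t", na_values=["-"], dtype={"bin_id": str})
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ledger is missing columns: {sorted(missing)}")
    return df


def load_reference_ledger(as_records: bool = False):
    """Packaged Karabetova Gora reference ledger (33 MAGs)."""
    path = importlib.resources.files("magpot.data") / "karabetova_mag_ledger.tsv"
    df = load_ledger(str(path))
    if len(df) != 33:
        raise ValueError(f"reference ledger corrupt: expected 33 records, got {len(df)}")
    return _frame_to_records(df) if as_records else df


def load_reference_phyla() -> Mapping[str, str]:
    """Packaged bin-to-phylum mapping for the reference ledger."""
    path = importlib.resources.files("magpot.data") / "karabetova_mag_phyla.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["bin_id"], df["phylum"]))


def band_count(
    ledger: pd.DataFrame,
    lo: float,
    hi: float,
    lo_closed: bool = True,
    hi_closed: bool = False,
) -> int:
    """Count MAGs whose completeness lies in the given band.

    Interval closure is explicit so the exact-100 band can be expressed as
    [100, 100] with both ends closed.
    """
    if lo > hi or (lo == hi and not (lo_closed and hi_closed)):
        raise ValueError(f"empty band [{lo}, {hi}] with given closure")
    c = ledger["completeness_pct"].astype(float)
    lower = c >= lo if lo_closed else c > lo
    upper = c <= hi if hi_closed else c < hi
    return int((lower & upper).sum())


def count_complete_16s(ledger: pd.DataFrame, min_len_bp: int = 1400,
                       strict: bool = True) -> int:
    """MAGs with a recovered 16S gene longer than ``min_len_bp`` (strict >
    by default; absent entries never count)."""
    length = ledger["s16_length_bp"]
    present = length.notna()
    if strict:
        return int((present & (length > min_len_bp)).sum())
    return int((present & (length >= min_len_bp)).sum())


def phylum_abundance_sum(
    ledger: pd.DataFrame,
    phylum_map: Optional[Mapping[str, str]] = None,
) -> pd.Series:
    """Sum relative abundance per phylum.

    ``phylum_map`` maps bin_id -> phylum; when omitted the packaged reference
    mapping is used. Bins missing from the map are collected under
    "unresolved" rather than silently dropped. Full precision is retained;
    round at display time.
    """
    if phylum_map is None:
        phylum_map = load_reference_phyla()
    phyla = ledger["bin_id"].map(lambda b: phylum_map.get(b, "unresolved"))
    sums = ledger["abundance_pct"].astype(float).groupby(phyla).sum()
    return sums.sort_values(ascending=False)


def coding_fraction(protein_length_aa: int, genome_size_bp: float) -> float:
    """Percent of a genome occupied by one protein's coding sequence
    (3 bp per residue)."""
    if protein_length_aa <= 0 or genome_size_bp <= 0:
        raise ValueError("lengths must be positive")
    return 100.0 * 3.0 * protein_length_aa / genome_size_bp


def _format_ledger(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["s16_length_bp"] = out["s16_length_bp"].map(
        lambda v: "-" if pd.isna(v) else str(int(v)))
    return out


def render_reports(
    out_dir,
    ledger: pd.DataFrame,
    mhc_summaries: Optional[pd.DataFrame] = None,
    completeness: Optional[pd.DataFrame] = None,
    metabolism_calls: Optional[pd.DataFrame] = None,
) -> dict:
    """Write the report bundle as deterministic TSVs; returns a manifest.

    Cross-table bin ids are checked against the ledger; mismatches are
    reported in the manifest rather than silently accepted.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "id_mismatches": {}}
    known = set(ledger["bin_id"])

    def _write(name: str, df: pd.DataFrame, index: bool = False):
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.2f")
        manifest["files"][name] = str(path)

    _write("mag_ledger.tsv", _format_ledger(ledger))
    for name, df, id_col, index in (
        ("mhc_summary.tsv", mhc_summaries, "mag_id", False),
        ("carbon_fixation_completeness.tsv", completeness, None, True),
        ("metabolism_calls.tsv", metabolism_calls, "mag_id", False),
    ):
        if df is None:
            continue
        ids = set(df.index if id_col is None else df[id_col])
        extra = sorted(ids - known)
        if extra:
            manifest["id_mismatches"][name] = extra
        _write(name, df, index=index)
    return manifest
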