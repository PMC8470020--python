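"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its spec and seed: the same call gives
byte-identical output. The generators emulate the study conditions of a
methane-venting mud-volcano metagenome:

* protein sets with a controlled number of planted CxxCH heme-binding motifs
  and hydrophobic C-terminal tails, against a guaranteed motif-free
  background (accidental motifs are rewritten, not filtered out, so the
  background keeps a realistic residue composition);
* annotation tables with carbon-fixation gene complements at chosen
  completeness fractions and chosen marker-gene sets;
* ASV count tables with specified true richness and a log-series or
  log-normal abundance shape (sigma = 0 degenerates to uniform);
* qPCR runs whose standards follow Cq = intercept + slope*log10(copies) with
  slope = -1/log10(1 + E) for amplification efficiency E, plus Cq noise;
* radiotracer incubations with a specified true oxidation rate and a killed
  control.

The packaged marker table of the 33-bin Karabetova Gora community (gene
complements, autotrophic pathways and reference metabolism labels) is loaded
here too, so the full community can be regenerated as an annotation table.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerCatalog, load_marker_catalog
from .pathways import PathwayDefinition, load_pathway_definitions

__all__ = [
    "SyntheticMagSpec",
    "QPCRRun",
    "generate_protein_set",
    "write_fasta",
    "generate_annotation_table",
    "generate_asv_counts",
    "generate_qpcr_run",
    "generate_tracer_samples",
    "load_reference_marker_table",
    "build_community_annotations",
    "REFERENCE_MHC_PROFILE",
    "mhc_community_specs",
]

# 20-residue alphabet with rough natural frequencies (Swiss-Prot-like).
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    8.3, 1.4, 5.5, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
    2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

# spacer alphabet for planted proteins: no C, no H, so planted motif counts
# are exact by construction; strongly hydrophobic residues excluded so that
# only deliberately planted tails can satisfy the TM hydropathy window
_SAFE = np.array(list("ADEGKMNPQRSTWY"))
_TM_RESIDUES = np.array(list("LIVFA"))
_TM_LENGTH = 21
_POLAR_CAP = "DKE"


@dataclass(frozen=True)
class SyntheticMagSpec:
    """Recipe for one synthetic MAG.

    ``planted_mhcs`` lists (motif_count, has_c_terminal_tm) per planted
    multiheme cytochrome; ``pathway_fractions`` maps pathway name to the
    fraction of its essential genes to include; ``marker_genes`` are marker
    symbols planted verbatim via the catalog.
    """

    mag_id: str
    n_background_proteins: int = 20
    background_length_range: Tuple[int, int] = (80, 300)
    planted_mhcs: Tuple[Tuple[int, bool], ...] = ()
    pathway_fractions: Mapping[str, float] = field(default_factory=dict)
    marker_genes: Tuple[str, ...] = ()
    seed: int = 0


def _count_motifs(seq: str) -> int:
    # independent, deliberately naive counter used to enforce invariants
    return sum(
        1 for p in range(len(seq) - 4)
        if seq[p] == "C" and seq[p + 3] == "C" and seq[p + 4] == "H"
    )


def _motif_free_background(rng: np.random.Generator, length: int) -> str:
    seq = list(rng.choice(_AA, size=length, p=_AA_FREQ))
    # local rewrite: break any accidental CxxCH by mutating its His
    changed = True
    while changed:
        changed = False
        for p in range(len(seq) - 4):
            if seq[p] == "C" and seq[p + 3] == "C" and seq[p + 4] == "H":
                seq[p + 4] = "K"
                changed = True
    return "".join(seq)


def _planted_protein(
    rng: np.random.Generator,
    motif_count: int,
    has_tm: bool,
    target_length: int,
) -> str:
    tail_len = (_TM_LENGTH + len(_POLAR_CAP)) if has_tm else 0
    core_budget = max(target_length - tail_len, 5 * motif_count + 2 * (motif_count + 1))
    spare = core_budget - 5 * motif_count
    # split spare residues into motif_count + 1 spacers, each >= 2
    cuts = np.sort(rng.integers(0, spare - 2 * (motif_count + 1) + 1,
                                size=motif_count)) if spare > 2 * (motif_count + 1) else \
        np.zeros(motif_count, dtype=int)
    spacer_extra = np.diff(np.concatenate(([0], cuts, [max(spare - 2 * (motif_count + 1), 0)])))
    parts = []
    for i in range(motif_count):
        spacer_len = 2 + int(spacer_extra[i])
        parts.append("".join(rng.choice(_SAFE, size=spacer_len)))
        middle = "".join(rng.choice(_SAFE, size=2))
        parts.append(f"C{middle}CH")
    parts.append("".join(rng.choice(_SAFE, size=2 + int(spacer_extra[-1]))))
    if has_tm:
        parts.append("".join(rng.choice(_TM_RESIDUES, size=_TM_LENGTH)))
        parts.append(_POLAR_CAP)
    return "".join(parts)


def generate_protein_set(
    spec: SyntheticMagSpec,
) -> Tuple[list[Tuple[str, str]], pd.DataFrame]:
    """Generate the MAG's protein set and its per-protein truth table.

    Returns ``(records, truth)`` where records are (protein_id, sequence)
    pairs and truth has one row per protein (is_mhc, motif_count, has_tm).
    """
    lo, hi = spec.background_length_range
    if lo < 5 or lo > hi:
        raise ValueError(f"invalid background_length_range {spec.background_length_range}")
    for count, has_tm in spec.planted_mhcs:
        if count < 1:
            raise ValueError("planted motif counts must be >= 1")
        required = 5 * count + 2 * (count + 1) + ((_TM_LENGTH + len(_POLAR_CAP)) if has_tm else 0)
        if required > hi:
            raise ValueError(
                f"background_length_range too short to host {count} motifs "
                f"(needs >= {required} residues, range max is {hi})")

    rng = np.random.default_rng(spec.seed)
    records: list[Tuple[str, str]] = []
    rows = []
    for i, (count, has_tm) in enumerate(spec.planted_mhcs):
        target = int(rng.integers(lo, hi + 1))
        seq = _planted_protein(rng, count, has_tm, target)
        got = _count_motifs(seq)
        if got != count:  # pragma: no cover - construction guarantees this
            raise AssertionError(f"planted {count} motifs, built {got}")
        pid = f"{spec.mag_id}_mhc{i + 1:03d}"
        records.append((pid, seq))
        rows.append({"mag_id": spec.mag_id, "protein_id": pid, "is_mhc": True,
                     "motif_count": count, "has_tm": has_tm})
    for i in range(spec.n_background_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _motif_free_background(rng, length)
        pid = f"{spec.mag_id}_bg{i + 1:04d}"
        records.append((pid, seq))
        rows.append({"mag_id": spec.mag_id, "protein_id": pid, "is_mhc": False,
                     "motif_count": 0, "has_tm": False})
    return records, pd.DataFrame(rows)


def write_fasta(records: Sequence[Tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA via Biopython, deterministically."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqs = [SeqRecord(Seq(s), id=pid, description="") for pid, s in records]
    with open(path, "w") as fh:
        seqio_write(seqs, fh, "fasta")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_annotation_table(
    spec: SyntheticMagSpec,
    definitions: Optional[Sequence[PathwayDefinition]] = None,
    catalog: Optional[MarkerCatalog] = None,
) -> pd.DataFrame:
    """Annotation table (mag_id, gene_id, annotation_id) for one MAG.

    Each pathway contributes exactly round(fraction * |essential set|)
    distinct essential genes, chosen by seeded shuffle-then-prefix; marker
    symbols are planted via their catalog aliases.
    """
    definitions = load_pathway_definitions() if definitions is None else definitions
    catalog = load_marker_catalog() if catalog is None else catalog
    by_name = {d.name: d for d in definitions}
    unknown = set(spec.pathway_fractions) - set(by_name)
    if unknown:
        raise ValueError(f"unknown pathway names: {sorted(unknown)}")
    unknown_markers = [m for m in spec.marker_genes if m not in catalog]
    if unknown_markers:
        raise ValueError(f"unknown marker symbols: {unknown_markers}")

    rng = np.random.default_rng(spec.seed)
    annotation_ids: list[str] = []
    for name in sorted(spec.pathway_fractions):
        frac = spec.pathway_fractions[name]
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"pathway fraction for {name!r} outside [0, 1]: {frac}")
        genes = sorted(by_name[name].essential_genes)
        n = _round_half_up(frac * len(genes))
        order = rng.permutation(len(genes))
        annotation_ids.extend(genes[j] for j in order[:n])
    for symbol in spec.marker_genes:
        annotation_ids.extend(catalog.primary_aliases(symbol))

    rows = [
        {"mag_id": spec.mag_id, "gene_id": f"{spec.mag_id}_gene{i + 1:05d}",
         "annotation_id": aid}
        for i, aid in enumerate(annotation_ids)
    ]
    return pd.DataFrame(rows, columns=["mag_id", "gene_id", "annotation_id"])


def generate_asv_counts(
    true_richness: int,
    depth: int,
    abundance_model: str = "lognormal",
    sigma: float = 1.5,
    logseries_p: float = 0.99,
    group_weights: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """ASV count table with known true richness and total count = depth.

    ``abundance_model`` is "lognormal" (sigma = 0 gives uniform abundances)
    or "logseries". ``group_weights`` optionally partitions the community
    into taxonomy groups whose expected relative abundances equal the given
    weights (used to plant a dominant group).
    """
    if true_richness < 1:
        raise ValueError("true_richness must be >= 1")
    if depth < true_richness:
        raise ValueError("depth must be >= true_richness")
    rng = np.random.default_rng(seed)
    if abundance_model == "lognormal":
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        weights = rng.lognormal(0.0, sigma, size=true_richness) if sigma > 0 \
            else np.ones(true_richness)
    elif abundance_model == "logseries":
        if not 0.0 < logseries_p < 1.0:
            raise ValueError("logseries_p must be in (0, 1)")
        weights = stats.logser.rvs(logseries_p, size=true_richness,
                                   random_state=rng).astype(float)
    else:
        raise ValueError(f"unknown abundance model {abundance_model!r}")
    weights = weights / weights.sum()

    if group_weights:
        names = list(group_weights)
        target = np.array([group_weights[g] for g in names], dtype=float)
        if (target <= 0).any():
            raise ValueError("group weights must be positive")
        target = target / target.sum()
        # allocate species to groups proportionally (>= 1 each), then rescale
        # each group's abundance mass to its target share
        alloc = np.maximum(1, np.floor(target * true_richness).astype(int))
        while alloc.sum() > true_richness:
            alloc[int(np.argmax(alloc))] -= 1
        alloc[int(np.argmax(alloc))] += true_richness - alloc.sum()
        taxonomy = np.repeat(names, alloc)
        for g in names:
            mask = taxonomy == g
            weights[mask] *= target[names.index(g)] / weights[mask].sum()
    else:
        taxonomy = np.array(["Bacteria;unclassified"] * true_richness)

    counts = rng.multinomial(depth, weights)
    return pd.DataFrame({
        "asv_id": [f"ASV{i + 1:05d}" for i in range(true_richness)],
        "count": counts,
        "taxonomy": taxonomy,
    })


@dataclass(frozen=True)
class QPCRRun:
    standards: pd.DataFrame      # columns: copies, cq
    samples: pd.DataFrame        # columns: label, replicate, cq
    true_slope: float
    true_intercept: float
    true_copies: Mapping[str, float]


def generate_qpcr_run(
    true_copies: Mapping[str, float],
    efficiency_pct: float = 90.0,
    cq_noise_sd: float = 0.1,
    seed: int = 0,
    standard_copies: Sequence[float] = (1e3, 1e4, 1e5, 1e6, 1e7, 1e8),
    intercept: float = 38.0,
    replicates: int = 3,
) -> QPCRRun:
    """Simulate a qPCR run: a standard dilution series plus replicated
    unknowns, all on the line Cq = intercept + slope*log10(copies) with
    slope = -1/log10(1 + E/100), plus Gaussian Cq noise."""
    if not 0.0 < efficiency_pct <= 120.0:
        raise ValueError(f"efficiency_pct must be in (0, 120], got {efficiency_pct}")
    std = np.asarray(standard_copies, dtype=float)
    if (std <= 0).any() or any(v <= 0 for v in true_copies.values()):
        raise ValueError("copy numbers must be positive")
    if np.log10(std.max() / std.min()) < 3.0:
        raise ValueError("standards must span >= 3 decades")
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + efficiency_pct / 100.0)

    def cq_of(copies: np.ndarray, n: int) -> np.ndarray:
        base = intercept + slope * np.log10(copies)
        noise = rng.normal(0.0, cq_noise_sd, size=n) if cq_noise_sd > 0 else 0.0
        return base + noise

    std_rows = []
    for c in std:
        for _ in range(replicates):
            std_rows.append({"copies": c, "cq": float(cq_of(np.array([c]), 1)[0])})
    sample_rows = []
    for label, c in true_copies.items():
        for r in range(replicates):
            sample_rows.append({
                "label": label, "replicate": r + 1,
                "cq": float(cq_of(np.array([c]), 1)[0]),
            })
    return QPCRRun(
        standards=pd.DataFrame(std_rows),
        samples=pd.DataFrame(sample_rows),
        true_slope=slope,
        true_intercept=intercept,
        true_copies=dict(true_copies),
    )


def generate_tracer_samples(
    true_rate: float = 0.47,
    ch4_pool: float = 1400.0,
    incubation_days: float = 5.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    a_total: float = 1.0e4,
    control_rate: float = 0.02,
) -> pd.DataFrame:
    """Radiotracer incubation records (live replicates plus killed controls).

    The label fraction transferred to oxidation products is
    rate * days / ch4_pool per replicate, perturbed multiplicatively by
    ``noise_cv``. ``control_rate`` models the abiotic blank: killed controls
    transfer label at that rate alone, live samples at true_rate plus the
    blank, so control subtraction recovers true_rate without bias. Units:
    rate nmol cm^-3 day^-1, pool nmol cm^-3, activities arbitrary (only the
    ratio matters).
    """
    if true_rate < 0 or control_rate < 0:
        raise ValueError("rates must be non-negative")
    if ch4_pool <= 0 or incubation_days <= 0:
        raise ValueError("ch4_pool and incubation_days must be positive")
    fraction = (true_rate + control_rate) * incubation_days / ch4_pool
    control_fraction = control_rate * incubation_days / ch4_pool
    if fraction > 1.0 or control_fraction > 1.0:
        raise ValueError("label fraction would exceed 1: methane pool too small")
    rng = np.random.default_rng(seed)
    rows = []
    for is_control, frac in ((False, fraction), (True, control_fraction)):
        for r in range(n_replicates):
            noisy = frac * max(0.0, 1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else frac
            rows.append({
                "replicate": r + 1,
                "a_product": min(noisy, 1.0) * a_total,
                "a_total": a_total,
                "is_control": is_control,
            })
    return pd.DataFrame(rows)


def load_reference_marker_table() -> pd.DataFrame:
    """Marker-gene complements, autotrophic pathways and reference metabolism
    labels for the 33 Karabetova Gora MAGs."""
    path = importlib.resources.files("magpot.data") / "karabetova_marker_table.tsv"
    df = pd.read_csv(str(path), sep="\t", keep_default_na=False)
    if len(df) != 33:
        raise ValueError(f"marker table corrupt: expected 33 rows, got {len(df)}")
    df["markers"] = df["markers"].map(
        lambda s: tuple(m for m in s.split(",") if m))
    df["reverse_methanogenesis"] = df["reverse_methanogenesis"].astype(bool)
    df["expected_labels"] = df["expected_labels"].map(
        lambda s: tuple(l for l in s.split(";") if l))
    return df


def build_community_annotations(
    seed: int = 0,
    marker_table: Optional[pd.DataFrame] = None,
    definitions: Optional[Sequence[PathwayDefinition]] = None,
    catalog: Optional[MarkerCatalog] = None,
) -> pd.DataFrame:
    """Regenerate the 33-MAG community as a single annotation table.

    Each MAG gets its marker complement, the full essential-gene set of its
    autotrophic pathway (if any), and — for the anaerobic methanotrophs — the
    complete seven-step methanogenesis core plus membrane electron-transfer
    complexes, with hydrogenase and methyltransferase genes absent.
    """
    marker_table = load_reference_marker_table() if marker_table is None else marker_table
    definitions = load_pathway_definitions() if definitions is None else definitions
    catalog = load_marker_catalog() if catalog is None else catalog

    frames = []
    for i, row in enumerate(marker_table.itertuples(index=False)):
        fractions = {row.autotrophic_pathway: 1.0} if row.autotrophic_pathway else {}
        spec = SyntheticMagSpec(
            mag_id=row.bin_id,
            pathway_fractions=fractions,
            marker_genes=tuple(row.markers),
            seed=seed + i,
        )
        table = generate_annotation_table(spec, definitions, catalog)
        if row.reverse_methanogenesis:
            extra_ids = [genes[0] for genes in catalog.methanogenesis["core_steps"].values()]
            extra_ids += [genes[0] for genes in catalog.methanogenesis["electron_transfer"].values()]
            n0 = len(table)
            extra = pd.DataFrame({
                "mag_id": row.bin_id,
                "gene_id": [f"{row.bin_id}_gene{n0 + j + 1:05d}" for j in range(len(extra_ids))],
                "annotation_id": extra_ids,
            })
            table = pd.concat([table, extra], ignore_index=True)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


#: Planted multiheme-cytochrome profiles shaped like the study's cytochrome
#: inventory: (motif counts, number with a C-terminal TM helix) per bin.
REFERENCE_MHC_PROFILE: Mapping[str, Tuple[Tuple[int, ...], int]] = {
    "KA19": ((2, 2, 3, 3, 4, 5, 6, 7, 8, 11, 12, 14, 15), 10),
    "KA2": ((2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 8, 9, 10,
             11, 12, 13, 14, 15, 16, 18, 20, 22, 25, 30, 40, 50, 67), 23),
    "KA5": ((2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 9, 10, 10,
             11, 11, 12, 12, 13, 14, 15, 15, 16, 16), 10),
}


def mhc_community_specs(
    seed: int = 0,
    n_background_proteins: int = 30,
    profile: Optional[Mapping[str, Tuple[Tuple[int, ...], int]]] = None,
) -> list[SyntheticMagSpec]:
    """Per-MAG specs planting the reference-shaped cytochrome inventories."""
    profile = REFERENCE_MHC_PROFILE if profile is None else profile
    specs = []
    for i, (mag, (counts, n_tm)) in enumerate(profile.items()):
        planted = tuple(
            (c, j < n_tm) for j, c in enumerate(counts)
        )
        specs.append(SyntheticMagSpec(
            mag_id=mag,
            n_background_proteins=n_background_proteins,
            background_length_range=(80, 600),
            planted_mhcs=planted,
            seed=seed + i,
        ))
    return specs
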