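"""Carbon-fixation pathway completeness scoring and autotrophy calls.

Seven recognised CO2-fixation pathways (CBB, WL, rTCA, 3-HP, 3-HP/4-HB,
DC/4-HB, roTCA) are each described by an essential-gene set in an orthology
namespace. A MAG's completeness for a pathway is the percentage of essential
genes with at least one annotation row; a MAG is called a putative autotroph
for a pathway when completeness reaches the threshold (default 100%) and the
pathway's diagnostic key genes are all present. The roTCA cycle carries an
extra guard: citrate synthase alone is widespread in heterotrophs, so a call
additionally requires the full TCA-cycle gene complement.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

PATHWAY_ORDER: Tuple[str, ...] = (
    "CBB", "WL", "rTCA", "3-HP", "3-HP/4-HB", "DC/4-HB", "roTCA",
)

__all__ = [
    "PATHWAY_ORDER",
    "PathwayDefinition",
    "load_pathway_definitions",
    "score_pathway",
    "completeness_matrix",
    "call_autotrophs",
]


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    essential_genes: frozenset
    key_genes: frozenset = frozenset()
    guard_genes: frozenset = frozenset()
    description: str = ""

    def __post_init__(self):
        if not self.essential_genes:
            raise ValueError(f"pathway {self.name!r}: empty essential gene set")
        if not self.key_genes <= self.essential_genes:
            raise ValueError(f"pathway {self.name!r}: key genes not a subset of essential genes")
        if not self.guard_genes <= self.essential_genes:
            raise ValueError(f"pathway {self.name!r}: guard genes not a subset of essential genes")


def _default_config_path():
    return importlib.resources.files("magpot.data") / "pathways.yaml"


def load_pathway_definitions(
    config_path=None,
    overrides: Optional[Mapping[str, Mapping]] = None,
) -> list[PathwayDefinition]:
    """Load pathway definitions from YAML; ``overrides`` replaces per-pathway
    blocks (gene lists) while leaving the others untouched."""
    path = _default_config_path() if config_path is None else config_path
    with open(str(path)) as fh:
        raw = yaml.safe_load(fh)
    blocks = dict(raw["pathways"])
    if overrides:
        for name, block in overrides.items():
            merged = dict(blocks.get(name, {}))
            merged.update(block)
            blocks[name] = merged

    defs = []
    seen = set()
    for name, block in blocks.items():
        if name in seen:
            raise ValueError(f"duplicate pathway name {name!r}")
        seen.add(name)
        defs.append(PathwayDefinition(
            name=name,
            essential_genes=frozenset(block["essential"]),
            key_genes=frozenset(block.get("key", [])),
            guard_genes=frozenset(block.get("guard", [])),
            description=block.get("description", ""),
        ))
    # stable presentation order: the canonical seven first, extras after
    defs.sort(key=lambda d: (PATHWAY_ORDER.index(d.name)
                             if d.name in PATHWAY_ORDER else len(PATHWAY_ORDER), d.name))
    return defs


def _mag_sort_key(mag_id: str):
    # natural sort so KA2 precedes KA10
    head = mag_id.rstrip("0123456789")
    tail = mag_id[len(head):]
    return (head, int(tail) if tail else -1)


def _annotated_sets(annotations: pd.DataFrame) -> dict[str, Set[str]]:
    required = {"mag_id", "annotation_id"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    return {
        mag: set(group["annotation_id"])
        for mag, group in annotations.groupby("mag_id", sort=False)
    }


def score_pathway(annotated: Iterable[str], definition: PathwayDefinition) -> float:
    """Percent of the pathway's essential genes with >=1 annotation."""
    present = definition.essential_genes & set(annotated)
    return 100.0 * len(present) / len(definition.essential_genes)


def completeness_matrix(
    annotations: pd.DataFrame,
    definitions: Sequence[PathwayDefinition],
    mag_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """MAG x pathway percent-present matrix (rows natural-sorted, columns in
    the canonical pathway order). ``mag_ids`` forces rows for MAGs with no
    annotations at all."""
    by_mag = _annotated_sets(annotations)
    rows = set(by_mag)
    if mag_ids is not None:
        rows |= set(mag_ids)
    if not rows:
        raise ValueError("no MAGs to score")
    index = sorted(rows, key=_mag_sort_key)
    data = {
        d.name: [score_pathway(by_mag.get(mag, ()), d) for mag in index]
        for d in definitions
    }
    matrix = pd.DataFrame(data, index=pd.Index(index, name="mag_id"))
    return matrix[[d.name for d in definitions]]


def call_autotrophs(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    definitions: Sequence[PathwayDefinition],
    threshold: float = 100.0,
    key_gene_guard: bool = True,
) -> Set[Tuple[str, str]]:
    """Return (mag_id, pathway) pairs with full genomic potential for
    CO2 fixation: completeness >= threshold, all key genes present (when the
    guard is on), and — for pathways defining guard genes — the complete
    guard complement present."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    by_mag = _annotated_sets(annotations)
    defs = {d.name: d for d in definitions}
    calls: Set[Tuple[str, str]] = set()
    for mag in matrix.index:
        annotated = by_mag.get(mag, set())
        for name in matrix.columns:
            if matrix.at[mag, name] < threshold:
                continue
            d = defs[name]
            if key_gene_guard and not d.key_genes <= annotated:
                continue
            if d.guard_genes and not d.guard_genes <= annotated:
                continue
            calls.add((mag, name))
    return calls
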