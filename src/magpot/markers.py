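"""Marker-gene detection and rule-based putative-metabolism labelling.

Energy metabolism of a genome bin is profiled in three steps:

1. ``detect_markers`` turns an annotation table into a MAG x marker boolean
   presence matrix using a catalog of marker symbols and their annotation
   aliases (union semantics; multi-subunit complexes flagged ``require_all``
   need the complete complement).
2. ``check_reverse_methanogenesis`` interrogates the seven central steps of
   the methanogenic pathway (fmd, ftr, mch, mtd, mer, mtr, mcr), the canonical
   methanogen hydrogenases (Ech, Vho, Mvh, Frh), methylotrophy
   methyltransferases, nitrate/sulfate respiration genes and the
   membrane electron-transfer complexes (Fpo, HdrABC, HdrDE, Rnf). A MAG is a
   reverse-methanogenesis candidate — an anaerobic methanotroph running the
   methanogenic pathway backwards — when all seven core steps are present
   while hydrogenases and methyltransferases are absent.
3. ``assign_metabolism`` applies a fixed, documented rule order to produce the
   putative-metabolism labels. The order and its suppression clauses encode
   how such tables are curated in practice (see docs/methods.md): cbb3-type
   oxidase alone does not imply an aerobic lifestyle, lifestyle labels are
   omitted for organisms already labelled by a more specific energy
   metabolism, and uptake hydrogenases of fermenters or sulfur-oxidizing
   autotrophs are treated as accessory.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

__all__ = [
    "LABEL_ORDER",
    "MarkerDef",
    "MarkerCatalog",
    "MethanogenesisCheck",
    "MetabolismCall",
    "load_marker_catalog",
    "detect_markers",
    "check_reverse_methanogenesis",
    "assign_metabolism",
]

#: Fixed label vocabulary, in canonical output order.
LABEL_ORDER: Tuple[str, ...] = (
    "anaerobic methane oxidation",
    "aerobic methane oxidation",
    "autotrophic",
    "denitrification",
    "nitrate reduction",
    "sulfite/sulfate reduction",
    "sulfur compound oxidation",
    "aerobic",
    "facultatively anaerobic",
    "fermentation",
    "H2 utilization",
    "carbohydrate utilization",
    "aromatic compound utilization",
    "acetogenic",
)

UNIDENTIFIED = "Unidentified"

# markers treated as respiratory electron acceptors (suppress the
# fermentation label) and as anaerobic-respiration evidence (drive the
# facultative split for coxA-carrying MAGs)
_RESPIRATORY_ACCEPTORS = ("coxA", "ccoN", "napA", "narG", "nosZ", "dsrAB")
_ANAEROBIC_EVIDENCE = ("Fe-hyd", "dsrAB")


@dataclass(frozen=True)
class MarkerDef:
    symbol: str
    aliases: frozenset
    require_all: bool = False

    def __post_init__(self):
        if not self.aliases:
            raise ValueError(f"marker {self.symbol!r}: empty alias set")

    def present_in(self, annotated: Set[str]) -> bool:
        if self.require_all:
            return self.aliases <= annotated
        return bool(self.aliases & annotated)


@dataclass(frozen=True)
class MarkerCatalog:
    markers: Mapping[str, MarkerDef]
    methanogenesis: Mapping[str, Mapping[str, Tuple[str, ...]]]

    def __getitem__(self, symbol: str) -> MarkerDef:
        return self.markers[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.markers

    @property
    def symbols(self) -> Tuple[str, ...]:
        return tuple(self.markers)

    def primary_aliases(self, symbol: str) -> Tuple[str, ...]:
        """Annotation identifiers to emit when planting this marker: the full
        complement for require_all markers, the first alias otherwise."""
        d = self.markers[symbol]
        if d.require_all:
            return tuple(sorted(d.aliases))
        # preserve YAML order: first alias is the canonical gene symbol
        return (self._alias_order[symbol][0],)

    _alias_order: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)


def load_marker_catalog(config_path=None) -> MarkerCatalog:
    path = (importlib.resources.files("magpot.data") / "markers.yaml"
            if config_path is None else config_path)
    with open(str(path)) as fh:
        raw = yaml.safe_load(fh)
    markers: Dict[str, MarkerDef] = {}
    alias_order: Dict[str, Tuple[str, ...]] = {}
    for symbol, block in raw["markers"].items():
        if symbol in markers:
            raise ValueError(f"duplicate marker symbol {symbol!r}")
        markers[symbol] = MarkerDef(
            symbol=symbol,
            aliases=frozenset(block["aliases"]),
            require_all=bool(block.get("require_all", False)),
        )
        alias_order[symbol] = tuple(block["aliases"])
    methanogenesis = {
        group: {name: tuple(genes) for name, genes in block.items()}
        for group, block in raw["methanogenesis"].items()
    }
    return MarkerCatalog(markers=markers, methanogenesis=methanogenesis,
                         _alias_order=alias_order)


def detect_markers(
    annotations: pd.DataFrame,
    catalog: MarkerCatalog,
    mag_ids=None,
) -> pd.DataFrame:
    """Boolean MAG x marker presence matrix from an annotation table with
    columns (mag_id, gene_id, annotation_id). ``mag_ids`` forces all-false
    rows for MAGs absent from the table."""
    by_mag = {
        mag: set(group["annotation_id"])
        for mag, group in annotations.groupby("mag_id", sort=False)
    }
    rows = set(by_mag)
    if mag_ids is not None:
        rows |= set(mag_ids)
    index = sorted(rows, key=_mag_sort_key)
    data = {
        symbol: [catalog[symbol].present_in(by_mag.get(mag, set())) for mag in index]
        for symbol in catalog.symbols
    }
    return pd.DataFrame(data, index=pd.Index(index, name="mag_id"))


def _mag_sort_key(mag_id: str):
    head = mag_id.rstrip("0123456789")
    tail = mag_id[len(head):]
    return (head, int(tail) if tail else -1)


@dataclass(frozen=True)
class MethanogenesisCheck:
    """Presence/absence audit of the reverse-methanogenesis gene complement."""

    mag_id: str
    core_steps_present: Mapping[str, bool]
    hydrogenases_absent: Mapping[str, bool]
    methyltransferases_absent: Mapping[str, bool]
    nitrate_genes_absent: Mapping[str, bool]
    sulfate_genes_absent: Mapping[str, bool]
    electron_transfer_present: Mapping[str, bool]

    @property
    def is_candidate(self) -> bool:
        return (all(self.core_steps_present.values())
                and all(self.hydrogenases_absent.values())
                and all(self.methyltransferases_absent.values()))

    @property
    def missing_steps(self) -> Tuple[str, ...]:
        return tuple(s for s, ok in self.core_steps_present.items() if not ok)


def check_reverse_methanogenesis(
    annotated: Iterable[str], catalog: MarkerCatalog, mag_id: str = ""
) -> MethanogenesisCheck:
    """Audit one MAG's annotations against the methanogenesis gene groups."""
    ids = set(annotated)
    groups = catalog.methanogenesis

    def present(genes: Tuple[str, ...]) -> bool:
        return bool(ids & set(genes))

    return MethanogenesisCheck(
        mag_id=mag_id,
        core_steps_present={k: present(v) for k, v in groups["core_steps"].items()},
        hydrogenases_absent={k: not present(v) for k, v in groups["hydrogenases"].items()},
        methyltransferases_absent={k: not present(v) for k, v in groups["methyltransferases"].items()},
        nitrate_genes_absent={k: not present(v) for k, v in groups["nitrate_reduction"].items()},
        sulfate_genes_absent={k: not present(v) for k, v in groups["sulfate_reduction"].items()},
        electron_transfer_present={k: present(v) for k, v in groups["electron_transfer"].items()},
    )


@dataclass(frozen=True)
class MetabolismCall:
    mag_id: str
    labels: Tuple[str, ...]
    evidence: Mapping[str, Tuple[str, ...]]

    def __post_init__(self):
        if not self.labels:
            raise ValueError("labels may not be empty; use the Unidentified placeholder")
        if UNIDENTIFIED in self.labels and len(self.labels) > 1:
            raise ValueError("Unidentified may not co-occur with other labels")


def assign_metabolism(
    presence: Mapping[str, bool],
    autotrophy_pathways: Set[str],
    check: Optional[MethanogenesisCheck] = None,
    mag_id: str = "",
) -> MetabolismCall:
    """Derive putative-metabolism labels for one MAG.

    ``presence`` is the MAG's row of the marker matrix, ``autotrophy_pathways``
    the pathway names for which the MAG was called a putative autotroph
    (e.g. from :func:`magpot.pathways.call_autotrophs`), and ``check`` the
    reverse-methanogenesis audit (may be None for bacteria).

    Rule order (each adds a label and its marker evidence):

    1.  reverse-methanogenesis candidate -> "anaerobic methane oxidation"
    2.  pMMO -> "aerobic methane oxidation"
    3.  any autotrophy call -> "autotrophic"
    4.  narG & nosZ -> "denitrification"; else napA | narG -> "nitrate reduction"
    5.  dsrAB -> "sulfite/sulfate reduction"
    6.  soxB | soxYZ | sqr | soeA -> "sulfur compound oxidation"
    7.  coxA (aa3-type oxidase), unless the MAG is a methane oxidizer or an
        autotroph: with Fe-hyd or dsrAB -> "facultatively anaerobic",
        otherwise -> "aerobic". ccoN (cbb3-type) alone fires nothing.
    8.  Fe-hyd with no respiratory acceptor -> "fermentation"
    9.  hybC | hyaB -> "H2 utilization", unless fermentative or a
        sulfur-oxidizing autotroph
    10. GH1 -> "carbohydrate utilization"
    11. bzd (complete) -> "aromatic compound utilization"
    12. WL autotrophy & cooS & cooF -> "acetogenic"
    13. no rule fired -> "Unidentified"
    """
    def on(symbol: str) -> bool:
        return bool(presence.get(symbol, False))

    labels: Dict[str, Tuple[str, ...]] = {}

    methane_oxidizer = False
    if check is not None and check.is_candidate:
        labels["anaerobic methane oxidation"] = ("mcrA",) if on("mcrA") else ()
        methane_oxidizer = True
    if on("pMMO"):
        labels["aerobic methane oxidation"] = ("pMMO",)
        methane_oxidizer = True

    autotroph = bool(autotrophy_pathways)
    if autotroph:
        labels["autotrophic"] = tuple(sorted(autotrophy_pathways))

    if on("narG") and on("nosZ"):
        labels["denitrification"] = ("narG", "nosZ")
    elif on("napA") or on("narG"):
        labels["nitrate reduction"] = tuple(s for s in ("napA", "narG") if on(s))

    if on("dsrAB"):
        labels["sulfite/sulfate reduction"] = ("dsrAB",)

    sulfur_ox = tuple(s for s in ("soxB", "soxYZ", "sqr", "soeA") if on(s))
    if sulfur_ox:
        labels["sulfur compound oxidation"] = sulfur_ox

    if on("coxA") and not methane_oxidizer and not autotroph:
        anaerobic = tuple(s for s in _ANAEROBIC_EVIDENCE if on(s))
        if anaerobic:
            labels["facultatively anaerobic"] = ("coxA",) + anaerobic
        else:
            labels["aerobic"] = ("coxA",)

    fermentative = on("Fe-hyd") and not any(on(s) for s in _RESPIRATORY_ACCEPTORS)
    if fermentative:
        labels["fermentation"] = ("Fe-hyd",)

    h2_markers = tuple(s for s in ("hybC", "hyaB") if on(s))
    if h2_markers and not fermentative and not (autotroph and sulfur_ox):
        labels["H2 utilization"] = h2_markers

    if on("GH1"):
        labels["carbohydrate utilization"] = ("GH1",)
    if on("bzd"):
        labels["aromatic compound utilization"] = ("bzd",)
    if "WL" in autotrophy_pathways and on("cooS") and on("cooF"):
        labels["acetogenic"] = ("cooS", "cooF")

    if not labels:
        return MetabolismCall(mag_id=mag_id, labels=(UNIDENTIFIED,), evidence={})
    ordered = tuple(l for l in LABEL_ORDER if l in labels)
    return MetabolismCall(mag_id=mag_id, labels=ordered,
                          evidence={l: labels[l] for l in ordered})
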