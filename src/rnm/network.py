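"""Signed regulatory networks: parsing, validation, summaries and export.

The central container is :class:`RegulatoryNetwork`: named protein nodes with
functional categories, plus signed directed interactions (activation +1,
inhibition −1) each carrying literature-evidence annotations.  The canonical
on-disk format is an edge-list CSV with columns

    source, target, effect [, reference_id, cell_type, species, culture,
    pathology, source_category, target_category, ...]

Unknown columns are preserved as free-form annotations.  GraphML
(Cytoscape-compatible) and SIF are supported for export and re-import.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "NodeRecord",
    "EvidenceRecord",
    "InteractionRecord",
    "RegulatoryNetwork",
    "CorpusSummary",
    "NetworkError",
    "NetworkFormatError",
    "NetworkValidationError",
    "SignConflictError",
    "UnknownNodeError",
    "parse_interaction_table",
    "degree_of_connectivity",
    "merge_nodes",
    "remove_nodes",
    "corpus_summary",
    "export_network",
    "load_graphml",
    "load_sif",
    "canonical_name",
]

NODE_CATEGORIES = frozenset(
    {
        "structural",
        "degrading-enzyme",
        "protease-inhibitor",
        "pro-inflammatory-cytokine",
        "anti-inflammatory-cytokine",
        "growth-factor",
        "chemokine",
        "angiogenic",
        "other",
    }
)

CELL_TYPES = frozenset({"IVD-NPC", "chondrocyte", "other", "database", "n/a"})
SPECIES = frozenset({"human", "animal", "n/a"})
CULTURES = frozenset({"2D", "3D", "n/a"})
PATHOLOGIES = frozenset({"normal", "degenerate", "n/a"})

# ASCII aliases for node labels that mix Greek/Latin notation in the corpus.
GREEK_ALIASES = {
    "IL-1a": "IL-1α",
    "IL-1alpha": "IL-1α",
    "IL-1b": "IL-1β",
    "IL-1beta": "IL-1β",
    "TGF-b": "TGF-β",
    "TGF-beta": "TGF-β",
    "TGFb": "TGF-β",
    "IFN-g": "IFN-γ",
    "IFN-gamma": "IFN-γ",
    "IFNg": "IFN-γ",
}

_EFFECT_TOKENS = {
    "1": 1,
    "+1": 1,
    "+": 1,
    "activation": 1,
    "activates": 1,
    "activator": 1,
    "-1": -1,
    "−1": -1,
    "-": -1,
    "−": -1,
    "inhibition": -1,
    "inhibits": -1,
    "inhibitor": -1,
}

_EVIDENCE_FIELDS = ("reference_id", "cell_type", "species", "culture", "pathology")


class NetworkError(Exception):
    """Base class for all regulatory-network errors."""


class NetworkFormatError(NetworkError):
    """Malformed input file (missing columns, unparsable effect, ...)."""


class NetworkValidationError(NetworkError):
    """Structurally invalid network."""


class SignConflictError(NetworkValidationError):
    """Duplicate (source, target) pair with opposite signs."""


class UnknownNodeError(NetworkError, KeyError):
    """A referenced node does not exist in the network."""


def canonical_name(name: str) -> str:
    """Whitespace-trim a node label and resolve ASCII aliases to Greek forms."""
    name = str(name).strip()
    return GREEK_ALIASES.get(name, name)


def _parse_effect(raw) -> int:
    token = str(raw).strip().lower()
    if token in _EFFECT_TOKENS:
        return _EFFECT_TOKENS[token]
    try:
        value = int(float(token))
    except ValueError:
        raise NetworkFormatError(f"unparsable effect value: {raw!r}") from None
    if value in (1, -1):
        return value
    raise NetworkFormatError(f"effect must be +1 or -1, got {raw!r}")


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature/database source backing an interaction."""

    reference_id: str
    cell_type: str = "n/a"
    species: str = "n/a"
    culture: str = "n/a"
    pathology: str = "n/a"

    def __post_init__(self):
        for attr, allowed in (
            ("cell_type", CELL_TYPES),
            ("species", SPECIES),
            ("culture", CULTURES),
            ("pathology", PATHOLOGIES),
        ):
            if getattr(self, attr) not in allowed:
                raise NetworkValidationError(
                    f"EvidenceRecord.{attr}={getattr(self, attr)!r} "
                    f"not in {sorted(allowed)}"
                )


@dataclass(frozen=True)
class NodeRecord:
    """A named protein node with a functional category.

    ``merged_from`` records the original labels when nodes were collapsed
    (e.g. ADAMTS4 and ADAMTS5 merged into "ADAMTS4/5").
    """

    name: str
    category: str = "other"
    merged_from: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise NetworkValidationError("node name must be non-empty")
        if self.category not in NODE_CATEGORIES:
            raise NetworkValidationError(
                f"unknown node category {self.category!r} for {self.name!r}"
            )
        object.__setattr__(self, "merged_from", tuple(self.merged_from))


@dataclass(frozen=True)
class InteractionRecord:
    """A signed directed interaction: effect +1 activation, −1 inhibition."""

    source: str
    target: str
    effect: int
    evidence: tuple[EvidenceRecord, ...] = ()
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.effect not in (1, -1):
            raise NetworkValidationError(
                f"effect must be +1 or -1, got {self.effect!r} "
                f"for ({self.source}, {self.target})"
            )
        object.__setattr__(self, "evidence", tuple(self.evidence))
        object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass
class RegulatoryNetwork:
    """A validated signed directed protein-interaction network."""

    nodes: list[NodeRecord] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise NetworkValidationError(f"duplicate node names: {dup}")
        name_set = set(names)
        for node in self.nodes:
            bad = [m for m in node.merged_from if m in name_set]
            if bad:
                raise NetworkValidationError(
                    f"merged_from labels of {node.name!r} are live nodes: {bad}"
                )
        dangling = [
            (i.source, i.target)
            for i in self.interactions
            if i.source not in name_set or i.target not in name_set
        ]
        if dangling:
            raise NetworkValidationError(
                f"interactions with endpoints not in the node list: {dangling}"
            )
        seen: dict[tuple[str, str], int] = {}
        for i in self.interactions:
            key = (i.source, i.target)
            if key in seen:
                if seen[key] != i.effect:
                    raise SignConflictError(
                        f"conflicting signs for interaction {key}"
                    )
                raise NetworkValidationError(f"duplicate interaction {key}")
            seen[key] = i.effect

    # -- convenience accessors ---------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeRecord:
        for n in self.nodes:
            if n.name == name:
                return n
        raise UnknownNodeError(name)

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def activators_of(self, name: str) -> list[str]:
        """Regulators with activating (+1) edges into ``name``."""
        if not self.has_node(name):
            raise UnknownNodeError(name)
        return [i.source for i in self.interactions if i.target == name and i.effect == 1]

    def inhibitors_of(self, name: str) -> list[str]:
        if not self.has_node(name):
            raise UnknownNodeError(name)
        return [i.source for i in self.interactions if i.target == name and i.effect == -1]

    def categories(self) -> dict[str, str]:
        return {n.name: n.category for n in self.nodes}

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        mine = {(n.name, n.category) for n in self.nodes}
        theirs = {(n.name, n.category) for n in other.nodes}
        if mine != theirs:
            return False
        return {(i.source, i.target, i.effect) for i in self.interactions} == {
            (i.source, i.target, i.effect) for i in other.interactions
        }


# ---------------------------------------------------------------------------
# parsing


def parse_interaction_table(path, dialect: str | None = None) -> RegulatoryNetwork:
    """Read an edge-list CSV/TSV into a validated :class:`RegulatoryNetwork`.

    ``dialect`` is ``"edge-list-csv"`` or ``"edge-list-tsv"``; when omitted it
    is inferred from the file extension (``.tsv`` → tab, otherwise comma).
    Required columns: ``source``, ``target``, ``effect``.  Recognised optional
    columns: the evidence fields and per-endpoint ``*_category``; anything
    else is kept as a string annotation on the interaction.
    """
    path = Path(path)
    if not path.exists():
        raise NetworkFormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "edge-list-tsv" if path.suffix.lower() == ".tsv" else "edge-list-csv"
    if dialect not in ("edge-list-csv", "edge-list-tsv"):
        raise NetworkFormatError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "edge-list-tsv" else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return network_from_frame(frame)


def network_from_frame(frame: pd.DataFrame) -> RegulatoryNetwork:
    """Build a network from a pandas edge table (columns as in the CSV)."""
    required = {"source", "target", "effect"}
    missing = required - set(frame.columns)
    if missing:
        raise NetworkFormatError(f"missing required columns: {sorted(missing)}")
    known = required | set(_EVIDENCE_FIELDS) | {"source_category", "target_category"}
    extra_cols = [c for c in frame.columns if c not in known]

    categories: dict[str, str] = {}
    interactions: list[InteractionRecord] = []
    pair_rows: dict[tuple[str, str], int] = {}
    pair_evidence: dict[tuple[str, str], list[EvidenceRecord]] = {}
    pair_annotations: dict[tuple[str, str], list[tuple[str, str]]] = {}
    order: list[tuple[str, str]] = []

    for idx, row in enumerate(frame.itertuples(index=False)):
        rec = row._asdict()
        src = canonical_name(rec["source"])
        tgt = canonical_name(rec["target"])
        if not src or not tgt:
            raise NetworkValidationError(f"row {idx}: empty endpoint")
        effect = _parse_effect(rec["effect"])
        for endpoint, col in ((src, "source_category"), (tgt, "target_category")):
            cat = str(rec.get(col, "") or "").strip()
            if cat:
                prev = categories.get(endpoint)
                if prev is not None and prev != cat:
                    raise NetworkValidationError(
                        f"row {idx}: conflicting categories for {endpoint!r}: "
                        f"{prev!r} vs {cat!r}"
                    )
                categories[endpoint] = cat
        key = (src, tgt)
        if key in pair_rows:
            if pair_rows[key] != effect:
                raise SignConflictError(
                    f"conflicting signs for interaction {key} "
                    f"(duplicate rows with opposite effects)"
                )
        else:
            pair_rows[key] = effect
            pair_evidence[key] = []
            pair_annotations[key] = []
            order.append(key)
        ref = str(rec.get("reference_id", "") or "").strip()
        if ref:
            pair_evidence[key].append(
                EvidenceRecord(
                    reference_id=ref,
                    cell_type=str(rec.get("cell_type", "") or "n/a").strip() or "n/a",
                    species=str(rec.get("species", "") or "n/a").strip() or "n/a",
                    culture=str(rec.get("culture", "") or "n/a").strip() or "n/a",
                    pathology=str(rec.get("pathology", "") or "n/a").strip() or "n/a",
                )
            )
        for col in extra_cols:
            val = str(rec.get(col, "") or "").strip()
            if val:
                pair_annotations[key].append((col, val))

    node_names: list[str] = []
    seen = set()
    for src, tgt in order:
        for name in (src, tgt):
            if name not in seen:
                seen.add(name)
                node_names.append(name)
    nodes = [
        NodeRecord(name=n, category=categories.get(n, "other")) for n in node_names
    ]
    for key in order:
        interactions.append(
            InteractionRecord(
                source=key[0],
                target=key[1],
                effect=pair_rows[key],
                evidence=tuple(pair_evidence[key]),
                annotations=tuple(dict(pair_annotations[key]).items()),
            )
        )
    return RegulatoryNetwork(nodes=nodes, interactions=interactions)


# ---------------------------------------------------------------------------
# operations


def degree_of_connectivity(net: RegulatoryNetwork) -> dict[str, int]:
    """Degree of connectivity per node: incident edges, counted once per
    endpoint regardless of direction; a self-loop counts once."""
    doc = {n.name: 0 for n in net.nodes}
    for i in net.interactions:
        if i.source == i.target:
            doc[i.source] += 1
        else:
            doc[i.source] += 1
            doc[i.target] += 1
    return doc


def merge_nodes(
    net: RegulatoryNetwork, group: list[str], new_name: str
) -> RegulatoryNetwork:
    """Collapse ``group`` into a single node named ``new_name``.

    Edges are re-targeted to the merged node; duplicates with the same sign
    collapse; opposite signs on the same re-targeted (source, target) pair
    raise :class:`SignConflictError` — conflicts are a curation decision, not
    something resolved silently.
    """
    group = [canonical_name(g) for g in group]
    for g in group:
        if not net.has_node(g):
            raise UnknownNodeError(g)
    new_name = canonical_name(new_name)
    group_set = set(group)
    merged_from: list[str] = []
    for g in group:
        merged_from.append(g)
        merged_from.extend(net.node(g).merged_from)
    category = net.node(group[0]).category

    def _map(name: str) -> str:
        return new_name if name in group_set else name

    kept: dict[tuple[str, str], InteractionRecord] = {}
    order: list[tuple[str, str]] = []
    for i in net.interactions:
        src, tgt = _map(i.source), _map(i.target)
        key = (src, tgt)
        if key in kept:
            if kept[key].effect != i.effect:
                raise SignConflictError(
                    f"merging {group} into {new_name!r} creates conflicting "
                    f"signs on {key}"
                )
            kept[key] = replace(
                kept[key], evidence=kept[key].evidence + i.evidence
            )
        else:
            kept[key] = replace(i, source=src, target=tgt)
            order.append(key)

    nodes = [n for n in net.nodes if n.name not in group_set]
    nodes.append(
        NodeRecord(name=new_name, category=category, merged_from=tuple(merged_from))
    )
    return RegulatoryNetwork(nodes=nodes, interactions=[kept[k] for k in order])


def remove_nodes(net: RegulatoryNetwork, names: list[str]) -> RegulatoryNetwork:
    """Drop nodes and every incident edge; the result is re-validated."""
    names = [canonical_name(n) for n in names]
    for n in names:
        if not net.has_node(n):
            raise UnknownNodeError(n)
    drop = set(names)
    return RegulatoryNetwork(
        nodes=[n for n in net.nodes if n.name not in drop],
        interactions=[
            i
            for i in net.interactions
            if i.source not in drop and i.target not in drop
        ],
    )


@dataclass
class CorpusSummary:
    """Link/paper counts cross-tabulated over the evidence annotations."""

    by_source: pd.DataFrame  # index: cell_type, species, culture
    by_pathology: pd.DataFrame  # index: pathology
    total_links: int
    total_papers: int

    def links(self, cell_type: str) -> int:
        sub = self.by_source.reset_index()
        return int(sub.loc[sub["cell_type"] == cell_type, "n_links"].sum())


def corpus_summary(net: RegulatoryNetwork) -> CorpusSummary:
    """Tabulate the evidence corpus: number of links and distinct references
    per (cell_type, species, culture) cell and per pathology.

    A link is counted once per evidence record attached to it (one edge with
    two sources contributes to two cells); edges without evidence count under
    "n/a".  Papers are distinct ``reference_id`` values.
    """
    rows = []
    for i in net.interactions:
        records = i.evidence or (EvidenceRecord(reference_id="n/a"),)
        for ev in records:
            rows.append(
                {
                    "cell_type": ev.cell_type,
                    "species": ev.species,
                    "culture": ev.culture,
                    "pathology": ev.pathology,
                    "reference_id": ev.reference_id,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        empty = pd.DataFrame(columns=["n_links", "n_papers"])
        return CorpusSummary(empty, empty, 0, 0)
    by_source = (
        frame.groupby(["cell_type", "species", "culture"])
        .agg(n_links=("reference_id", "size"), n_papers=("reference_id", "nunique"))
        .sort_index()
    )
    by_pathology = (
        frame.groupby("pathology")
        .agg(n_links=("reference_id", "size"), n_papers=("reference_id", "nunique"))
        .sort_index()
    )
    papers = frame.loc[frame["reference_id"] != "n/a", "reference_id"].nunique()
    return CorpusSummary(
        by_source=by_source,
        by_pathology=by_pathology,
        total_links=len(frame),
        total_papers=int(papers),
    )


# ---------------------------------------------------------------------------
# export


def network_to_frame(net: RegulatoryNetwork) -> pd.DataFrame:
    """Flatten a network to the canonical edge-list table (one row per
    evidence record, or a single bare row for un-evidenced edges)."""
    cats = net.categories()
    rows = []
    for i in net.interactions:
        base = {
            "source": i.source,
            "target": i.target,
            "effect": i.effect,
            "source_category": cats[i.source],
            "target_category": cats[i.target],
        }
        base.update(dict(i.annotations))
        if i.evidence:
            for ev in i.evidence:
                row = dict(base)
                row.update(
                    reference_id=ev.reference_id,
                    cell_type=ev.cell_type,
                    species=ev.species,
                    culture=ev.culture,
                    pathology=ev.pathology,
                )
                rows.append(row)
        else:
            rows.append(base)
    return pd.DataFrame(rows)


def export_network(net: RegulatoryNetwork, path, format: str | None = None) -> Path:
    """Write a network to disk as ``edge-list-csv``, ``edge-list-tsv``,
    ``graphml`` or ``sif``; round-trips through the matching loader."""
    path = Path(path)
    if format is None:
        format = {
            ".csv": "edge-list-csv",
            ".tsv": "edge-list-tsv",
            ".graphml": "graphml",
            ".sif": "sif",
        }.get(path.suffix.lower())
        if format is None:
            raise NetworkFormatError(f"cannot infer format from {path.name!r}")
    if format in ("edge-list-csv", "edge-list-tsv", "csv", "tsv"):
        sep = "\t" if "tsv" in format else ","
        frame = network_to_frame(net)
        if frame.empty:
            frame = pd.DataFrame(columns=["source", "target", "effect"])
        frame.to_csv(path, sep=sep, index=False)
    elif format == "graphml":
        graph = nx.DiGraph()
        for n in net.nodes:
            graph.add_node(n.name, category=n.category)
        for i in net.interactions:
            graph.add_edge(i.source, i.target, effect=int(i.effect))
        nx.write_graphml(graph, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for i in net.interactions:
                relation = "activates" if i.effect == 1 else "inhibits"
                fh.write(f"{i.source}\t{relation}\t{i.target}\n")
    else:
        raise NetworkFormatError(f"unsupported export format {format!r}")
    return path


def load_graphml(path) -> RegulatoryNetwork:
    graph = nx.read_graphml(path)
    nodes = [
        NodeRecord(name=str(n), category=str(data.get("category", "other")))
        for n, data in graph.nodes(data=True)
    ]
    interactions = [
        InteractionRecord(source=str(u), target=str(v), effect=int(data["effect"]))
        for u, v, data in graph.edges(data=True)
    ]
    return RegulatoryNetwork(nodes=nodes, interactions=interactions)


def load_sif(path) -> RegulatoryNetwork:
    interactions = []
    names: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkFormatError(f"bad SIF line: {line!r}")
            src, relation, tgt = parts
            if relation not in ("activates", "inhibits"):
                raise NetworkFormatError(f"unknown SIF relation {relation!r}")
            interactions.append(
                InteractionRecord(
                    source=src,
                    target=tgt,
                    effect=1 if relation == "activates" else -1,
                )
            )
            for name in (src, tgt):
                if name not in seen:
                    seen.add(name)
                    names.append(name)
    return RegulatoryNetwork(
        nodes=[NodeRecord(name=n) for n in names], interactions=interactions
    )
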