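"""Synthetic signed-network generators and toy test motifs.

The random generator produces hub-dominated signed directed networks with an
exact node/edge budget, an inhibitory-edge fraction, optional exact
degree-of-connectivity constraints for named nodes, and preferential
attachment for the remaining edges.  ``generate_paper_like_fixture`` builds a
33-node / 153-edge disc-cell network carrying the published protein names,
categories and the published degree-of-connectivity values of eight hub
nodes; its *edge placement is synthetic* — the true curated topology lives
in an external corpus file this package accepts as input, and nothing here
claims to reproduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SimulationConfig, find_fixed_points
from .network import (
    EvidenceRecord,
    InteractionRecord,
    NodeRecord,
    RegulatoryNetwork,
)

__all__ = [
    "GeneratorSpec",
    "Motif",
    "FeasibilityError",
    "generate_random_network",
    "generate_paper_like_fixture",
    "generate_toy_motifs",
    "PAPER_NODES",
    "PAPER_DOC_CONSTRAINTS",
]


class FeasibilityError(ValueError):
    """The requested constraints cannot be satisfied."""


@dataclass
class GeneratorSpec:
    """Parameters of the random signed-network generator.

    hub_bias is the preferential-attachment exponent (0 = uniform);
    named_degree_constraints pins the degree of connectivity (incident-edge
    count) of specific nodes exactly.
    """

    n_nodes: int
    n_edges: int
    inhibitory_fraction: float = 0.35
    hub_bias: float = 1.0
    named_degree_constraints: dict[str, int] = field(default_factory=dict)
    node_names: list[str] | None = None
    categories: dict[str, str] | None = None
    min_in_degree: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise FeasibilityError("need at least one node")
        if not 0 <= self.inhibitory_fraction <= 1:
            raise FeasibilityError("inhibitory_fraction must lie in [0, 1]")
        if self.hub_bias < 0:
            raise FeasibilityError("hub_bias must be >= 0")
        cap = self.n_nodes * (self.n_nodes - 1)  # ordered pairs, no self-loops
        if self.n_edges > cap:
            raise FeasibilityError(
                f"{self.n_edges} edges exceed the {cap} ordered node pairs"
            )
        for name, doc in self.named_degree_constraints.items():
            if doc < 0 or doc > 2 * (self.n_nodes - 1):
                raise FeasibilityError(
                    f"DoC constraint {name}={doc} impossible with "
                    f"{self.n_nodes} nodes"
                )
        if sum(self.named_degree_constraints.values()) > 2 * self.n_edges:
            raise FeasibilityError("sum of DoC constraints exceeds 2·n_edges")
        if self.node_names is not None and len(self.node_names) != self.n_nodes:
            raise FeasibilityError("node_names length must equal n_nodes")
        unknown = set(self.named_degree_constraints) - set(self._names())
        if unknown:
            raise FeasibilityError(f"constrained nodes not in node list: {unknown}")

    def _names(self) -> list[str]:
        if self.node_names is not None:
            return list(self.node_names)
        width = len(str(self.n_nodes - 1))
        return [f"N{str(i).zfill(width)}" for i in range(self.n_nodes)]


def _doc_counts(edges: list[tuple[str, str]], names: list[str]) -> dict[str, int]:
    doc = {n: 0 for n in names}
    for u, v in edges:
        doc[u] += 1
        if v != u:
            doc[v] += 1
    return doc


def _place_edges(spec: GeneratorSpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    names = spec._names()
    constrained = dict(spec.named_degree_constraints)
    edges: list[tuple[str, str]] = []
    used: set[tuple[str, str]] = set()
    deg = {n: 0 for n in names}
    remaining = dict(constrained)

    def pair_free(u: str, v: str) -> bool:
        return (u, v) not in used or (v, u) not in used

    def add_edge(u: str, v: str):
        dirs = [d for d in ((u, v), (v, u)) if d not in used]
        choice = dirs[int(rng.integers(len(dirs)))]
        used.add(choice)
        edges.append(choice)
        deg[u] += 1
        deg[v] += 1
        for node in (u, v):
            if node in remaining:
                remaining[node] -= 1

    # phase 1: satisfy exact DoC constraints, preferring fresh partners
    while any(r > 0 for r in remaining.values()):
        u = max(remaining, key=lambda k: (remaining[k], k))
        if remaining[u] <= 0:
            break
        fresh, reuse = [], []
        for v in names:
            if v == u or not pair_free(u, v):
                continue
            if v in remaining and remaining[v] <= 0:
                continue  # saturated constrained node
            if (u, v) in used or (v, u) in used:
                reuse.append(v)
            else:
                fresh.append(v)
        candidates = fresh or reuse
        if not candidates:
            raise FeasibilityError(
                f"cannot satisfy DoC constraint for {u!r}: no partners left"
            )
        weights = np.array(
            [
                remaining.get(v, 0) * 2.0 + (deg[v] + 1.0) ** spec.hub_bias
                for v in candidates
            ]
        )
        v = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
        add_edge(u, v)
        if len(edges) > spec.n_edges:
            raise FeasibilityError(
                "DoC constraints require more edges than the edge budget"
            )

    # phase 1.5: seed an in-edge for unconstrained nodes that must end up
    # regulated (constrained nodes are handled by flips afterwards)
    free_nodes = [n for n in names if n not in constrained]
    if spec.min_in_degree > 0:
        indeg = {n: 0 for n in names}
        for _, v in edges:
            indeg[v] += 1
        for n in free_nodes:
            while indeg[n] < spec.min_in_degree:
                sources = [
                    u for u in free_nodes if u != n and (u, n) not in used
                ]
                if not sources or len(edges) >= spec.n_edges:
                    raise FeasibilityError(
                        "cannot reach requested minimum in-degree"
                    )
                w = np.array([(deg[u] + 1.0) ** spec.hub_bias for u in sources])
                u = sources[int(rng.choice(len(sources), p=w / w.sum()))]
                used.add((u, n))
                edges.append((u, n))
                deg[u] += 1
                deg[n] += 1
                indeg[n] += 1

    # phase 2: preferential attachment among unconstrained nodes
    guard = 0
    while len(edges) < spec.n_edges:
        if len(free_nodes) < 2:
            raise FeasibilityError("not enough unconstrained nodes for edge budget")
        w = np.array([(deg[n] + 1.0) ** spec.hub_bias for n in free_nodes])
        u = free_nodes[int(rng.choice(len(free_nodes), p=w / w.sum()))]
        partners = [v for v in free_nodes if v != u and (u, v) not in used]
        if not partners:
            guard += 1
            if guard > 10 * spec.n_edges + 100:
                raise FeasibilityError("edge budget infeasible under constraints")
            continue
        wp = np.array([(deg[v] + 1.0) ** spec.hub_bias for v in partners])
        v = partners[int(rng.choice(len(partners), p=wp / wp.sum()))]
        used.add((u, v))
        edges.append((u, v))
        deg[u] += 1
        deg[v] += 1

    # repair pass for constrained nodes: give each an in-edge by flipping one
    # of its out-edges (a flip changes direction only, never DoC)
    if spec.min_in_degree > 0:
        for _ in range(spec.n_nodes):
            indeg = {n: 0 for n in names}
            for _, v in edges:
                indeg[v] += 1
            starved = [n for n in names if indeg[n] < spec.min_in_degree]
            if not starved:
                break
            progress = False
            for n in starved:
                for k, (u, v) in enumerate(edges):
                    if u == n and indeg[v] > spec.min_in_degree and (v, u) not in used:
                        used.discard((u, v))
                        used.add((v, u))
                        edges[k] = (v, u)
                        indeg[u] += 1
                        indeg[v] -= 1
                        progress = True
                        break
            if not progress:
                raise FeasibilityError("cannot reach requested minimum in-degree")
    return edges


def generate_random_network(spec: GeneratorSpec) -> RegulatoryNetwork:
    """Sample a network matching ``spec`` exactly; deterministic per seed.

    Node and edge counts are exact; named DoC constraints are satisfied
    exactly (verified before returning); the realised inhibitory fraction is
    the nearest achievable to the target (within 1/n_edges).
    """
    rng = np.random.default_rng(spec.seed)
    names = spec._names()
    edges = _place_edges(spec, rng)
    n_inh = int(round(spec.inhibitory_fraction * len(edges)))
    signs = {e: 1 for e in edges}
    for k in rng.choice(len(edges), size=n_inh, replace=False):
        signs[edges[int(k)]] = -1
    cats = spec.categories or {}
    net = RegulatoryNetwork(
        nodes=[NodeRecord(name=n, category=cats.get(n, "other")) for n in names],
        interactions=[
            InteractionRecord(source=u, target=v, effect=signs[(u, v)])
            for u, v in edges
        ],
    )
    from .network import degree_of_connectivity

    doc = degree_of_connectivity(net)
    for name, want in spec.named_degree_constraints.items():
        if doc[name] != want:
            raise FeasibilityError(
                f"internal error: DoC({name})={doc[name]} != required {want}"
            )
    return net


# ---------------------------------------------------------------------------
# disc-cell fixture

PAPER_NODES: dict[str, str] = {
    "ACAN": "structural",
    "COL1A": "structural",
    "COL2A": "structural",
    "COL10A1": "structural",
    "ADAMTS4/5": "degrading-enzyme",
    "MMP1": "degrading-enzyme",
    "MMP2": "degrading-enzyme",
    "MMP3": "degrading-enzyme",
    "MMP9": "degrading-enzyme",
    "MMP13": "degrading-enzyme",
    "TIMP1/2": "protease-inhibitor",
    "TIMP3": "protease-inhibitor",
    "IL-1α": "pro-inflammatory-cytokine",
    "IL-1β": "pro-inflammatory-cytokine",
    "IL-6": "pro-inflammatory-cytokine",
    "IL-12A": "pro-inflammatory-cytokine",
    "IL-17A": "pro-inflammatory-cytokine",
    "IL-18": "pro-inflammatory-cytokine",
    "TNF": "pro-inflammatory-cytokine",
    "IFN-γ": "pro-inflammatory-cytokine",
    "CSF2": "pro-inflammatory-cytokine",
    "IL-1Ra": "anti-inflammatory-cytokine",
    "IL-4": "anti-inflammatory-cytokine",
    "IL-10": "anti-inflammatory-cytokine",
    "IL-8": "chemokine",
    "CCL": "chemokine",
    "CCL22": "chemokine",
    "TGF-β": "growth-factor",
    "IGF1": "growth-factor",
    "GDF5": "growth-factor",
    "CCN2": "growth-factor",
    "VEGF": "angiogenic",
    "PGRN": "other",
}

# published degree-of-connectivity values for the enriched network's
# anti-inflammatory / growth-factor / protease-inhibitor hubs
PAPER_DOC_CONSTRAINTS: dict[str, int] = {
    "IL-10": 18,
    "IL-4": 19,
    "TGF-β": 15,
    "IGF1": 8,
    "CCN2": 3,
    "GDF5": 6,
    "TIMP1/2": 9,
    "TIMP3": 3,
}

# sign rules by (source category, target category); unruled pairs are filled
# randomly to reach the target inhibitory fraction
_SIGN_RULES: dict[tuple[str, str], int] = {
    ("pro-inflammatory-cytokine", "structural"): -1,
    ("pro-inflammatory-cytokine", "degrading-enzyme"): 1,
    ("pro-inflammatory-cytokine", "pro-inflammatory-cytokine"): 1,
    ("pro-inflammatory-cytokine", "growth-factor"): -1,
    ("pro-inflammatory-cytokine", "angiogenic"): 1,
    ("pro-inflammatory-cytokine", "chemokine"): 1,
    ("anti-inflammatory-cytokine", "pro-inflammatory-cytokine"): -1,
    ("anti-inflammatory-cytokine", "degrading-enzyme"): -1,
    ("anti-inflammatory-cytokine", "structural"): 1,
    ("anti-inflammatory-cytokine", "growth-factor"): 1,
    ("anti-inflammatory-cytokine", "chemokine"): -1,
    ("growth-factor", "structural"): 1,
    ("growth-factor", "degrading-enzyme"): -1,
    ("growth-factor", "pro-inflammatory-cytokine"): -1,
    ("growth-factor", "growth-factor"): 1,
    ("growth-factor", "protease-inhibitor"): 1,
    ("protease-inhibitor", "degrading-enzyme"): -1,
    ("degrading-enzyme", "structural"): -1,
    ("degrading-enzyme", "pro-inflammatory-cytokine"): 1,
    ("chemokine", "pro-inflammatory-cytokine"): 1,
}

_CELL_TYPE_POOL = ("IVD-NPC", "IVD-NPC", "IVD-NPC", "chondrocyte", "database", "other")
_SPECIES_POOL = ("human", "human", "animal", "n/a")
_CULTURE_POOL = ("2D", "2D", "3D", "n/a")
_PATHOLOGY_POOL = ("normal", "degenerate", "n/a")


def generate_paper_like_fixture(
    seed: int = 0, inhibitory_fraction: float = 0.35
) -> RegulatoryNetwork:
    """A 33-protein / 153-interaction disc-cell network for testing.

    Node names, categories and the eight published hub degree-of-connectivity
    values are fixed; edge placement, the remaining degrees and the evidence
    annotations are SYNTHETIC (seeded, reproducible) and do not reproduce the
    published curated topology.  Every node is guaranteed at least one
    regulator so the fixture has a well-defined global attractor structure.
    """
    names = list(PAPER_NODES)
    spec = GeneratorSpec(
        n_nodes=33,
        n_edges=153,
        inhibitory_fraction=inhibitory_fraction,
        hub_bias=1.0,
        named_degree_constraints=dict(PAPER_DOC_CONSTRAINTS),
        node_names=names,
        categories=dict(PAPER_NODES),
        min_in_degree=1,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    edges = _place_edges(spec, np.random.default_rng(seed))

    cats = PAPER_NODES
    signs: dict[tuple[str, str], int | None] = {}
    for u, v in edges:
        signs[(u, v)] = _SIGN_RULES.get((cats[u], cats[v]))
    target_inh = int(round(inhibitory_fraction * len(edges)))
    ruled_inh = sum(1 for s in signs.values() if s == -1)
    unruled = [e for e, s in signs.items() if s is None]
    need = int(np.clip(target_inh - ruled_inh, 0, len(unruled)))
    flip = set(
        tuple(unruled[int(k)])
        for k in rng.choice(len(unruled), size=need, replace=False)
    )
    for e in unruled:
        signs[e] = -1 if e in flip else 1

    interactions = []
    for k, (u, v) in enumerate(edges):
        ev = EvidenceRecord(
            reference_id=f"SYN-{1 + int(rng.integers(60)):04d}",
            cell_type=_CELL_TYPE_POOL[int(rng.integers(len(_CELL_TYPE_POOL)))],
            species=_SPECIES_POOL[int(rng.integers(len(_SPECIES_POOL)))],
            culture=_CULTURE_POOL[int(rng.integers(len(_CULTURE_POOL)))],
            pathology=_PATHOLOGY_POOL[int(rng.integers(len(_PATHOLOGY_POOL)))],
        )
        interactions.append(
            InteractionRecord(source=u, target=v, effect=signs[(u, v)], evidence=(ev,))
        )
    net = RegulatoryNetwork(
        nodes=[NodeRecord(name=n, category=cats[n]) for n in names],
        interactions=interactions,
    )
    from .network import degree_of_connectivity

    doc = degree_of_connectivity(net)
    for name, want in PAPER_DOC_CONSTRAINTS.items():
        assert doc[name] == want, (name, doc[name], want)
    return net


# ---------------------------------------------------------------------------
# toy motifs


@dataclass
class Motif:
    """A small named network with its verified stable-fixed-point inventory.

    ``fixed_points`` maps a condition label (clamp set on input nodes, or
    "free" for closed motifs) to the list of stable states found by Newton
    search from a grid of starting points at h=10, γ=1.
    """

    name: str
    network: RegulatoryNetwork
    description: str
    fixed_points: dict[str, list[np.ndarray]] = field(default_factory=dict)
    input_nodes: tuple[str, ...] = ()


def _motif(name, cats, edges, description) -> Motif:
    net = RegulatoryNetwork(
        nodes=[NodeRecord(name=n) for n in cats],
        interactions=[
            InteractionRecord(source=u, target=v, effect=s) for u, v, s in edges
        ],
    )
    targets = {v for _, v, _ in edges}
    inputs = tuple(n for n in cats if n not in targets)
    return Motif(name=name, network=net, description=description, input_nodes=inputs)


def generate_toy_motifs(cfg: SimulationConfig | None = None) -> dict[str, Motif]:
    """The standard motif test suite, each with a brute-force-verified stable
    fixed-point inventory at the default gain/decay (h=10, γ=1).

    Motifs: 2-node cascades (activating, inhibiting), the mutual-inhibition
    toggle switch, a 3-node incoherent feed-forward loop and a 3-node
    negative-feedback ring.
    """
    cfg = cfg or SimulationConfig()
    motifs = {
        "cascade-activation": _motif(
            "cascade-activation",
            ["A", "B"],
            [("A", "B", 1)],
            "A activates B; B tracks A through the sigmoid.",
        ),
        "cascade-inhibition": _motif(
            "cascade-inhibition",
            ["A", "B"],
            [("A", "B", -1)],
            "A inhibits B; B is extinguished when A is high.",
        ),
        "toggle-switch": _motif(
            "toggle-switch",
            ["A", "B"],
            [("A", "B", -1), ("B", "A", -1)],
            "Mutual inhibition; bistable — the node that starts high wins.",
        ),
        "incoherent-ffl": _motif(
            "incoherent-ffl",
            ["A", "B", "C"],
            [("A", "B", 1), ("A", "C", 1), ("B", "C", -1)],
            "A drives C directly and represses it via B; inhibition "
            "dominates at steady state.",
        ),
        "negative-feedback": _motif(
            "negative-feedback",
            ["A", "B", "C"],
            [("A", "B", 1), ("B", "C", 1), ("C", "A", -1)],
            "Three-node ring with one repression; at h=10 the interior fixed "
            "point is unstable and trajectories settle on a bounded "
            "oscillation (flagged unconverged).",
        ),
    }
    for motif in motifs.values():
        conditions: list[tuple[str, dict[str, float]]] = []
        if motif.input_nodes:
            for level in (0.0, 1.0):
                label = ",".join(f"{n}={level:g}" for n in motif.input_nodes)
                conditions.append((label, {n: level for n in motif.input_nodes}))
        else:
            conditions.append(("free", {}))
        for label, clamps in conditions:
            fps = find_fixed_points(motif.network, cfg, clamps=clamps, grid=5)
            motif.fixed_points[label] = [
                fp["state"] for fp in fps if fp["stable"]
            ]
    return motifs
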