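"""Glycan biosynthesis pathways as reaction networks.

A pathway is a directed graph whose nodes are glycan structures and whose
edges are enzymatic reactions.  Every reaction carries a boolean
*gene-requirement* expression describing which genes must be expressed for
the reaction to proceed: alternatives (isoenzymes) are combined with OR,
obligate complex subunits with AND, arbitrarily nested.  Reactions whose
catalyzing gene has not been identified carry no requirement at all
(``requirement is None``); downstream code treats such reactions as a
distinct "unknown" class rather than as inactive.

The module provides the JSON on-disk format, a small recursive-descent
parser for requirement expressions (``'|'`` = OR, ``'&'`` = AND, ``'&'``
binds tighter, parentheses allowed), structural validation, a deterministic
layered layout for pathways that ship without coordinates, a seeded random
pathway generator for testing, and loaders for the packaged pathway
fixtures.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional, Union

import networkx as nx

__all__ = [
    "Gene",
    "Or",
    "And",
    "Requirement",
    "make_or",
    "make_and",
    "parse_requirement",
    "requirement_to_string",
    "requirement_genes",
    "GlycanStructure",
    "Reaction",
    "Pathway",
    "Diagnostic",
    "parse_pathway",
    "serialize_pathway",
    "validate_pathway",
    "default_layout",
    "generate_synthetic_pathway",
    "list_fixtures",
    "load_fixture",
    "PathwayError",
    "RequirementSyntaxError",
    "PathwaySchemaError",
    "DuplicateIdError",
    "DanglingReferenceError",
    "STRUCTURE_CATEGORIES",
    "SNFG_CODES",
]

#: Monosaccharide codes with a dedicated SNFG glyph.  Compositions may use
#: additional codes (e.g. the queuosine base "Que"); renderers fall back to a
#: generic glyph for those.
SNFG_CODES = frozenset(
    {
        "Glc", "Gal", "Man", "GlcNAc", "GalNAc", "Fuc",
        "Neu5Ac", "Neu5Gc", "Xyl", "GlcA", "IdoA", "Rib",
    }
)

STRUCTURE_CATEGORIES = ("core", "terminal_modification", "degradation_intermediate")


class PathwayError(ValueError):
    """Base class for pathway definition errors."""


class RequirementSyntaxError(PathwayError):
    """Malformed gene-requirement expression."""


class PathwaySchemaError(PathwayError):
    """Pathway document violates the schema or an invariant."""


class DuplicateIdError(PathwaySchemaError):
    """A structure or reaction id occurs more than once."""


class DanglingReferenceError(PathwaySchemaError):
    """A reaction references a structure id that does not exist."""


# ---------------------------------------------------------------------------
# Gene-requirement expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """Leaf of a requirement tree: a single gene symbol (uppercase)."""

    symbol: str


@dataclass(frozen=True)
class Or:
    """Isoenzyme alternatives: any child suffices."""

    children: tuple["Requirement", ...]


@dataclass(frozen=True)
class And:
    """Enzyme-complex subunits: all children are required."""

    children: tuple["Requirement", ...]


Requirement = Union[Gene, Or, And]


def make_or(children: Iterable[Requirement]) -> Requirement:
    """Build an OR node in canonical (flattened) form.

    Nested ORs are absorbed and a single child is returned as-is, so every
    tree built through this factory serializes/reparses to itself.
    """
    flat: list[Requirement] = []
    for child in children:
        if isinstance(child, Or):
            flat.extend(child.children)
        else:
            flat.append(child)
    if not flat:
        raise RequirementSyntaxError("OR node needs at least one child")
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


def make_and(children: Iterable[Requirement]) -> Requirement:
    """Build an AND node in canonical (flattened) form."""
    flat: list[Requirement] = []
    for child in children:
        if isinstance(child, And):
            flat.extend(child.children)
        else:
            flat.append(child)
    if not flat:
        raise RequirementSyntaxError("AND node needs at least one child")
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


_TOKEN_RE = re.compile(r"[A-Za-z0-9_.\-]+|[|&()]")


def _tokenize(expr: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    n = len(expr)
    while pos < n:
        if expr[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise RequirementSyntaxError(
                f"unexpected character {expr[pos]!r} at position {pos} in {expr!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def parse_requirement(expr: str) -> Requirement:
    """Parse a requirement expression into its canonical tree.

    Grammar: ``expr := term ('|' term)*``, ``term := factor ('&' factor)*``,
    ``factor := SYMBOL | '(' expr ')'``.  ``'&'`` binds tighter than
    ``'|'``; whitespace is ignored; symbols are uppercased.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise RequirementSyntaxError("empty requirement expression")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> Requirement:
        nonlocal pos
        terms = [parse_and()]
        while peek() == "|":
            pos += 1
            terms.append(parse_and())
        return make_or(terms)

    def parse_and() -> Requirement:
        nonlocal pos
        factors = [parse_factor()]
        while peek() == "&":
            pos += 1
            factors.append(parse_factor())
        return make_and(factors)

    def parse_factor() -> Requirement:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise RequirementSyntaxError(f"dangling operator in {expr!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise RequirementSyntaxError(f"unbalanced parentheses in {expr!r}")
            pos += 1
            return node
        if tok in "|&)":
            raise RequirementSyntaxError(
                f"dangling operator near {tok!r} in {expr!r}"
            )
        pos += 1
        return Gene(tok.upper())

    tree = parse_or()
    if pos != len(tokens):
        raise RequirementSyntaxError(
            f"unexpected trailing token {tokens[pos]!r} in {expr!r}"
        )
    return tree


def requirement_to_string(req: Requirement) -> str:
    """Serialize a requirement tree with minimal parentheses.

    ``parse_requirement(requirement_to_string(t)) == t`` for every tree in
    canonical form (the form the parser and factories produce).
    """
    if isinstance(req, Gene):
        return req.symbol
    if isinstance(req, And):
        parts = [
            f"({requirement_to_string(c)})" if isinstance(c, Or)
            else requirement_to_string(c)
            for c in req.children
        ]
        return "&".join(parts)
    if isinstance(req, Or):
        return "|".join(requirement_to_string(c) for c in req.children)
    raise TypeError(f"not a requirement node: {req!r}")


def requirement_genes(req: Requirement) -> frozenset[str]:
    """All gene symbols appearing as leaves of the tree."""
    if isinstance(req, Gene):
        return frozenset({req.symbol})
    out: set[str] = set()
    for child in req.children:
        out |= requirement_genes(child)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Pathway containers
# ---------------------------------------------------------------------------

@dataclass
class GlycanStructure:
    """A glycan node: id, display name, monosaccharide composition, flags.

    ``composition`` is a multiset (code -> positive count); linkage topology
    is deliberately not modelled, the engine computes on pathway topology.
    """

    id: str
    name: str
    composition: dict[str, int]
    is_root: bool = False
    is_terminal: bool = False
    category: str = "core"


@dataclass
class Reaction:
    """A directed substrate -> product edge with a gene requirement.

    ``requirement is None`` marks a reaction whose catalyzing gene is not
    known (rendered with a question mark / gray dashed arrow).
    """

    id: str
    substrate_id: str
    product_id: str
    requirement: Optional[Requirement]
    step_label: Optional[str] = None

    @property
    def is_unknown(self) -> bool:
        return self.requirement is None


@dataclass
class Pathway:
    name: str
    structures: dict[str, GlycanStructure]
    reactions: dict[str, Reaction]
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)
    description: str = ""

    def graph(self) -> nx.MultiDiGraph:
        """Structure graph; parallel reactions become parallel edges."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.structures)
        for r in self.reactions.values():
            g.add_edge(r.substrate_id, r.product_id, key=r.id, reaction=r)
        return g

    @property
    def roots(self) -> list[str]:
        return sorted(s.id for s in self.structures.values() if s.is_root)

    @property
    def terminals(self) -> list[str]:
        return sorted(s.id for s in self.structures.values() if s.is_terminal)

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            if r.requirement is not None:
                out |= requirement_genes(r.requirement)
        return sorted(out)

    def outgoing(self, structure_id: str) -> list[Reaction]:
        return sorted(
            (r for r in self.reactions.values() if r.substrate_id == structure_id),
            key=lambda r: r.id,
        )


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _require(cond: bool, exc_type: type, msg: str) -> None:
    if not cond:
        raise exc_type(msg)


def parse_pathway(text: str) -> Pathway:
    """Parse a pathway JSON document and validate all hard invariants.

    A missing or partial ``layout`` is completed with :func:`default_layout`
    (deterministic longest-path layering).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PathwaySchemaError(f"not valid JSON: {exc}") from exc
    _require(isinstance(doc, dict), PathwaySchemaError, "top level must be an object")
    name = doc.get("name")
    _require(isinstance(name, str) and name != "", PathwaySchemaError,
             "pathway 'name' must be a non-empty string")

    structures: dict[str, GlycanStructure] = {}
    for entry in doc.get("structures", []):
        _require(isinstance(entry, dict), PathwaySchemaError,
                 f"structure entries must be objects, got {entry!r}")
        sid = entry.get("id")
        _require(isinstance(sid, str) and sid != "", PathwaySchemaError,
                 f"structure id must be a non-empty string, got {sid!r}")
        if sid in structures:
            raise DuplicateIdError(f"duplicate structure id {sid!r}")
        comp = entry.get("composition", {})
        _require(isinstance(comp, dict), PathwaySchemaError,
                 f"composition of {sid!r} must be an object")
        for code, count in comp.items():
            _require(
                isinstance(count, int) and not isinstance(count, bool) and count > 0,
                PathwaySchemaError,
                f"composition count for {code!r} in structure {sid!r} "
                f"must be a positive integer, got {count!r}",
            )
        category = entry.get("category", "core")
        _require(category in STRUCTURE_CATEGORIES, PathwaySchemaError,
                 f"structure {sid!r} has unknown category {category!r}")
        structures[sid] = GlycanStructure(
            id=sid,
            name=entry.get("name", sid),
            composition={str(k): int(v) for k, v in comp.items()},
            is_root=bool(entry.get("is_root", False)),
            is_terminal=bool(entry.get("is_terminal", False)),
            category=category,
        )
    _require(len(structures) > 0, PathwaySchemaError, "pathway has no structures")
    _require(any(s.is_root for s in structures.values()), PathwaySchemaError,
             "pathway has no root structure")

    reactions: dict[str, Reaction] = {}
    for entry in doc.get("reactions", []):
        _require(isinstance(entry, dict), PathwaySchemaError,
                 f"reaction entries must be objects, got {entry!r}")
        rid = entry.get("id")
        _require(isinstance(rid, str) and rid != "", PathwaySchemaError,
                 f"reaction id must be a non-empty string, got {rid!r}")
        if rid in reactions:
            raise DuplicateIdError(f"duplicate reaction id {rid!r}")
        sub = entry.get("substrate")
        prod = entry.get("product")
        for endpoint in (sub, prod):
            if endpoint not in structures:
                raise DanglingReferenceError(
                    f"reaction {rid!r} references unknown structure {endpoint!r}"
                )
        _require(sub != prod, PathwaySchemaError,
                 f"reaction {rid!r} has identical substrate and product {sub!r}")
        req_text = entry.get("requirement")
        requirement = None if req_text is None else parse_requirement(req_text)
        reactions[rid] = Reaction(
            id=rid,
            substrate_id=sub,
            product_id=prod,
            requirement=requirement,
            step_label=entry.get("step_label"),
        )

    layout_doc = doc.get("layout") or {}
    layout = {
        sid: (float(xy[0]), float(xy[1]))
        for sid, xy in layout_doc.items()
        if sid in structures
    }
    pathway = Pathway(
        name=name,
        structures=structures,
        reactions=reactions,
        layout=layout,
        description=doc.get("description", ""),
    )
    if set(layout) != set(structures):
        pathway.layout = default_layout(pathway)
    return pathway


def serialize_pathway(pathway: Pathway) -> str:
    """Serialize a pathway back to its JSON document form."""
    doc: dict = {"name": pathway.name}
    if pathway.description:
        doc["description"] = pathway.description
    doc["structures"] = [
        {
            "id": s.id,
            "name": s.name,
            "composition": dict(sorted(s.composition.items())),
            "is_root": s.is_root,
            "is_terminal": s.is_terminal,
            "category": s.category,
        }
        for s in sorted(pathway.structures.values(), key=lambda s: s.id)
    ]
    doc["reactions"] = [
        {
            "id": r.id,
            "substrate": r.substrate_id,
            "product": r.product_id,
            "requirement": (
                None if r.requirement is None
                else requirement_to_string(r.requirement)
            ),
            "step_label": r.step_label,
        }
        for r in sorted(pathway.reactions.values(), key=lambda r: r.id)
    ]
    doc["layout"] = {
        sid: [float(x), float(y)]
        for sid, (x, y) in sorted(pathway.layout.items())
    }
    return json.dumps(doc, indent=1, sort_keys=False)


# ---------------------------------------------------------------------------
# Validation and layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """A validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    code: str
    subject: str
    message: str


def validate_pathway(pathway: Pathway) -> list[Diagnostic]:
    """Check soft invariants; returns diagnostics instead of raising.

    Errors: unresolved reaction endpoints, substrate == product, non-positive
    composition counts, missing root, structures unreachable from every root
    (reachability ignores gene expression).  Warnings: cycles and reactions
    with unknown gene requirements.
    """
    out: list[Diagnostic] = []
    if not any(s.is_root for s in pathway.structures.values()):
        out.append(Diagnostic("error", "no-root", pathway.name,
                              "pathway has no root structure"))
    for s in sorted(pathway.structures.values(), key=lambda s: s.id):
        for code, count in s.composition.items():
            if not isinstance(count, int) or count <= 0:
                out.append(Diagnostic(
                    "error", "bad-composition", s.id,
                    f"composition count {code}={count!r} is not a positive integer",
                ))
    for r in sorted(pathway.reactions.values(), key=lambda r: r.id):
        for endpoint in (r.substrate_id, r.product_id):
            if endpoint not in pathway.structures:
                out.append(Diagnostic(
                    "error", "dangling-reference", r.id,
                    f"reaction {r.id} references unknown structure {endpoint!r}",
                ))
        if r.substrate_id == r.product_id:
            out.append(Diagnostic(
                "error", "self-loop", r.id,
                f"reaction {r.id} has identical substrate and product",
            ))
        if r.requirement is None:
            out.append(Diagnostic(
                "warning", "unknown-requirement", r.id,
                f"reaction {r.id} has no known catalyzing gene",
            ))

    g = pathway.graph()
    roots = [s.id for s in pathway.structures.values() if s.is_root]
    reachable: set[str] = set(roots)
    for root in roots:
        if root in g:
            reachable |= nx.descendants(g, root)
    for sid in sorted(pathway.structures):
        if sid not in reachable:
            out.append(Diagnostic(
                "error", "unreachable-structure", sid,
                f"structure {sid} is not reachable from any root",
            ))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        nodes = "->".join(str(edge[0]) for edge in cycle)
        out.append(Diagnostic(
            "warning", "cycle", nodes,
            f"pathway contains a cycle through {nodes}",
        ))
    return out


def default_layout(pathway: Pathway) -> dict[str, tuple[float, float]]:
    """Deterministic layered coordinates in abstract canvas units.

    Layers are longest-path ranks from the roots on acyclic pathways (BFS
    depth when cycles are present); within a layer structures are stacked
    alphabetically.  Output: ``id -> (layer, index)``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(pathway.structures)
    for r in pathway.reactions.values():
        g.add_edge(r.substrate_id, r.product_id)
    roots = [s.id for s in pathway.structures.values() if s.is_root]

    layer: dict[str, int] = {}
    if nx.is_directed_acyclic_graph(g):
        for node in nx.topological_sort(g):
            preds = [layer[p] for p in g.predecessors(node) if p in layer]
            if node in roots:
                layer[node] = 0
            elif preds:
                layer[node] = max(preds) + 1
            else:
                layer[node] = 0  # unreachable: park in the first layer
    else:
        # cycles break longest-path ranks; fall back to BFS depth
        depth = {r: 0 for r in roots}
        frontier = list(roots)
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.successors(u):
                    if v not in depth:
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            frontier = nxt
        layer = {sid: depth.get(sid, 0) for sid in pathway.structures}

    by_layer: dict[int, list[str]] = {}
    for sid in sorted(pathway.structures):
        by_layer.setdefault(layer.get(sid, 0), []).append(sid)
    coords: dict[str, tuple[float, float]] = {}
    for lv in sorted(by_layer):
        for idx, sid in enumerate(by_layer[lv]):
            coords[sid] = (float(lv), float(idx))
    return coords


# ---------------------------------------------------------------------------
# Synthetic pathway generator
# ---------------------------------------------------------------------------

_SYNTH_CODES = ("Gal", "GalNAc", "Glc", "GlcNAc", "Fuc", "Man", "Neu5Ac", "Xyl")


def _random_requirement(rng: random.Random, pool: list[str]) -> Requirement:
    if rng.random() < 0.5:
        return Gene(rng.choice(pool))
    top_is_or = rng.random() < 0.6
    children: list[Requirement] = []
    for _ in range(rng.randint(2, 3)):
        if rng.random() < 0.8:
            children.append(Gene(rng.choice(pool)))
        else:
            inner = tuple(Gene(rng.choice(pool)) for _ in range(2))
            children.append(And(inner) if top_is_or else Or(inner))
    return Or(tuple(children)) if top_is_or else And(tuple(children))


def generate_synthetic_pathway(
    n_structures: int, branching: float = 1.0, seed: int = 0
) -> Pathway:
    """Random acyclic single-root pathway for testing.

    Every structure beyond the root gets one incoming reaction from an
    earlier structure (guaranteeing reachability and acyclicity); an extra
    ``round((branching - 1) * (n_structures - 1))`` edges are added between
    random earlier/later pairs, so ``branching`` is the expected number of
    incoming reactions per non-root structure.  Requirements are random
    OR/AND trees over a synthetic gene universe ``G000, G001, ...``.
    Deterministic for a fixed seed.
    """
    if n_structures < 2:
        raise ValueError("n_structures must be >= 2")
    if branching <= 0:
        raise ValueError("branching must be > 0")
    rng = random.Random(seed)
    ids = [f"S{i:02d}" for i in range(n_structures)]

    edges: list[tuple[int, int]] = [
        (rng.randrange(i), i) for i in range(1, n_structures)
    ]
    present = set(edges)
    extra_n = int(round((branching - 1.0) * (n_structures - 1)))
    candidates = sorted(
        (u, v)
        for u in range(n_structures)
        for v in range(u + 1, n_structures)
        if (u, v) not in present
    )
    if extra_n > 0 and candidates:
        edges.extend(rng.sample(candidates, min(extra_n, len(candidates))))
    edges.sort()

    pool = [f"G{k:03d}" for k in range(max(8, n_structures))]
    sinks = set(range(n_structures)) - {u for u, _ in edges}

    structures = {}
    for i, sid in enumerate(ids):
        codes = rng.sample(_SYNTH_CODES, rng.randint(1, 3))
        composition = {code: rng.randint(1, 4) for code in sorted(codes)}
        structures[sid] = GlycanStructure(
            id=sid,
            name=f"synthetic glycan {i}",
            composition=composition,
            is_root=(i == 0),
            is_terminal=(i in sinks),
            category="core",
        )
    reactions = {}
    for k, (u, v) in enumerate(edges):
        rid = f"R{k:03d}"
        reactions[rid] = Reaction(
            id=rid,
            substrate_id=ids[u],
            product_id=ids[v],
            requirement=_random_requirement(rng, pool),
        )
    pathway = Pathway(
        name=f"synthetic-{seed}",
        structures=structures,
        reactions=reactions,
        description="randomly generated test pathway",
    )
    pathway.layout = default_layout(pathway)
    return pathway


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_dir():
    return resources.files("glycopath").joinpath("data")


def list_fixtures() -> list[str]:
    """Names of the pathway definitions shipped with the package."""
    return sorted(
        entry.name[: -len(".json")]
        for entry in _data_dir().iterdir()
        if entry.name.endswith(".json")
    )


def load_fixture(name: str) -> Pathway:
    """Load a packaged pathway by name (see :func:`list_fixtures`)."""
    candidate = _data_dir().joinpath(f"{name}.json")
    if not candidate.is_file():
        raise KeyError(
            f"no packaged pathway named {name!r}; available: {list_fixtures()}"
        )
    return parse_pathway(candidate.read_text(encoding="utf-8"))
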