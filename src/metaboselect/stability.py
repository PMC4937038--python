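"""Stability-consensus selection via formal concept analysis.

The top-feature sets of the ten ranking routes are combined into a formal
context: objects are features, attributes are techniques, and the incidence
records which technique selected which feature.  A feature's *stability
degree* is its row sum — the number of techniques that selected it — and the
consensus rule keeps features selected by at least ``k`` techniques
(``k=6`` of 10 in the reference workflow).  The full concept lattice of the
context is derived with the NextClosure algorithm (lectic-order closure
enumeration over attribute sets), giving a complete, duplicate-free list of
(extent, intent) concepts together with their cover relation for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FormalContext",
    "Concept",
    "ConceptLattice",
    "build_context",
    "stability_degrees",
    "consensus_select",
    "derive_concepts",
    "lattice_stats",
    "lattice_to_graphml",
]


@dataclass
class FormalContext:
    """Binary incidence between objects (features) and attributes (techniques)."""

    objects: list[str]
    attributes: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.objects = [str(o) for o in self.objects]
        self.attributes = [str(a) for a in self.attributes]
        self.incidence = np.asarray(self.incidence, dtype=int)
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("duplicate objects in context")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("duplicate attributes in context")
        if self.incidence.shape != (len(self.objects), len(self.attributes)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.objects)} objects × {len(self.attributes)} attributes"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def row_masks(self) -> list[int]:
        """Each object's attribute set as a bitmask (attribute j ↦ bit j)."""
        masks = []
        for row in self.incidence:
            m = 0
            for j, v in enumerate(row):
                if v:
                    m |= 1 << j
            masks.append(m)
        return masks


@dataclass(frozen=True)
class Concept:
    """A formal concept: mutually closed (extent, intent) pair."""

    extent: frozenset
    intent: frozenset


@dataclass
class ConceptLattice:
    """All concepts of a context with their cover relation.

    ``covers`` lists index pairs ``(lower, upper)`` of the cover relation of
    the sub-concept order (extent containment): ``lower`` is an immediate
    sub-concept of ``upper``.
    """

    concepts: list[Concept]
    covers: list[tuple[int, int]]

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def top(self) -> Concept:
        return max(self.concepts, key=lambda c: len(c.extent))

    @property
    def bottom(self) -> Concept:
        return min(self.concepts, key=lambda c: len(c.extent))

    def height(self) -> int:
        """Length (in edges) of the longest chain bottom → top."""
        order = sorted(range(len(self.concepts)), key=lambda i: len(self.concepts[i].extent))
        longest = {i: 0 for i in range(len(self.concepts))}
        up: dict[int, list[int]] = {i: [] for i in range(len(self.concepts))}
        for lo, hi in self.covers:
            up[lo].append(hi)
        for i in order:
            for j in up[i]:
                longest[j] = max(longest[j], longest[i] + 1)
        return max(longest.values(), default=0)


def build_context(top_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]]) -> FormalContext:
    """Presence/absence context of features × selection techniques.

    Objects are the union of all top sets in lexicographic order; attributes
    keep the given method order.  Features selected by no technique cannot
    occur (objects come from the sets themselves).
    """
    pairs = list(top_sets.items()) if isinstance(top_sets, Mapping) else list(top_sets)
    if not pairs:
        raise ValueError("at least one method required")
    methods = [m for m, _ in pairs]
    if len(set(methods)) != len(methods):
        raise ValueError(f"duplicate method ids: {methods}")
    sets = {m: set(map(str, fs)) for m, fs in pairs}
    for m, fs in sets.items():
        if not fs:
            raise ValueError(f"method {m!r} has an empty top set")
    objects = sorted(set().union(*sets.values()))
    incidence = np.zeros((len(objects), len(methods)), dtype=int)
    for j, m in enumerate(methods):
        for i, obj in enumerate(objects):
            if obj in sets[m]:
                incidence[i, j] = 1
    return FormalContext(objects=objects, attributes=methods, incidence=incidence)


def stability_degrees(context: FormalContext) -> dict[str, int]:
    """Stability degree per feature: number of techniques that selected it."""
    sums = context.incidence.sum(axis=1)
    return {obj: int(s) for obj, s in zip(context.objects, sums)}


def consensus_select(context: FormalContext, k: int = 6) -> list[str]:
    """Features selected by at least ``k`` techniques.

    Ordered by stability degree (descending) then lexicographically.
    """
    if not 1 <= k <= len(context.attributes):
        raise ValueError(
            f"k={k} out of range [1, {len(context.attributes)}]"
        )
    degrees = stability_degrees(context)
    chosen = [f for f, d in degrees.items() if d >= k]
    return sorted(chosen, key=lambda f: (-degrees[f], f))


# ----------------------------------------------------------------------
# Concept enumeration (NextClosure)
# ----------------------------------------------------------------------

def _closure_fn(context: FormalContext):
    """Return ``closure(attr_mask) -> (attr_mask, extent_mask)``."""
    rows = context.row_masks()
    m = len(context.attributes)
    full = (1 << m) - 1

    def closure(b: int) -> tuple[int, int]:
        extent = 0
        intent = full
        for i, row in enumerate(rows):
            if row & b == b:
                extent |= 1 << i
                intent &= row
        if extent == 0:
            intent = full
        return intent, extent

    return closure, m, full


def derive_concepts(context: FormalContext) -> ConceptLattice:
    """Enumerate all formal concepts of a context and their cover relation.

    Closed attribute sets are produced in lectic order by NextClosure; each
    closed intent pairs with its extent to form a concept.  The cover
    relation is computed afterwards by transitive reduction of extent
    containment.
    """
    closure, m, full = _closure_fn(context)
    closed: list[tuple[int, int]] = []  # (intent_mask, extent_mask)
    a, ext = closure(0)
    closed.append((a, ext))
    while a != full:
        nxt = _next_closure(a, m, closure)
        if nxt is None:
            break
        a, ext = nxt
        closed.append((a, ext))
    concepts = [
        Concept(
            extent=frozenset(context.objects[i] for i in _bits(ext)),
            intent=frozenset(context.attributes[j] for j in _bits(intent)),
        )
        for intent, ext in closed
    ]
    extents = [ext for _, ext in closed]
    covers = _cover_relation(extents)
    return ConceptLattice(concepts=concepts, covers=covers)


def _next_closure(a: int, m: int, closure) -> tuple[int, int] | None:
    for i in range(m - 1, -1, -1):
        bit = 1 << i
        if a & bit:
            a &= ~bit
        else:
            b, ext = closure(a | bit)
            if not (b & ~a & (bit - 1)):
                return b, ext
    return None


def _bits(mask: int):
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


def _cover_relation(extents: list[int]) -> list[tuple[int, int]]:
    """Transitive reduction of the extent-containment order (bitmask extents)."""
    n = len(extents)
    sizes = [bin(e).count("1") for e in extents]
    order = sorted(range(n), key=lambda i: sizes[i])
    covers: list[tuple[int, int]] = []
    for ai in range(n):
        e = extents[ai]
        # candidate supersets, smallest first
        supers = [bi for bi in order if sizes[bi] > sizes[ai] or (sizes[bi] == sizes[ai] and bi != ai)]
        supers = [bi for bi in supers if extents[bi] != e and extents[bi] & e == e]
        chosen: list[int] = []
        for bi in supers:
            if not any(extents[bi] & extents[c] == extents[c] for c in chosen):
                chosen.append(bi)
                covers.append((ai, bi))
    return covers


def lattice_stats(lattice: ConceptLattice) -> tuple[int, int, list[tuple[int, int]]]:
    """(number of concepts, lattice height, per-concept (|extent|, |intent|))."""
    sizes = [(len(c.extent), len(c.intent)) for c in lattice.concepts]
    return lattice.n_concepts, lattice.height(), sizes


def lattice_to_graphml(lattice: ConceptLattice, path) -> None:
    """Write the cover relation as a GraphML digraph (edges point upward)."""
    import networkx as nx

    g = nx.DiGraph()
    for i, c in enumerate(lattice.concepts):
        g.add_node(
            i,
            extent_size=len(c.extent),
            intent_size=len(c.intent),
            intent=",".join(sorted(c.intent)),
        )
    for lo, hi in lattice.covers:
        g.add_edge(lo, hi)
    nx.write_graphml(g, path)
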