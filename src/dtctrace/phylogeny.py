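"""Clone-tree reconstruction via the pigeonhole principle, refined by
single-cell co-occurrence, with placement of DTCs onto the tree.

Bulk subclonal reconstruction yields, per sample, a set of CNA events
each with a cancer cell fraction (CCF). Two events whose CCFs sum above
1 cannot live in disjoint cell populations (pigeonhole principle), so
the lower-CCF event must be nested under the higher one. Pairs the
pigeonhole leaves unordered can still be resolved when a sequenced
single cell carries both events: the events are then collinear on one
lineage, with nesting direction taken from the CCFs. Contradictory
evidence (suggesting convergent evolution) is reported, never silently
resolved.

The root of the tree is the most recent common ancestor (MRCA),
carrying the clonal events (CCF 1). DTCs are placed at the deepest node
whose path events they fully support; remaining events are private.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations

import dendropy
import pandas as pd

__all__ = [
    "Subclone",
    "CloneNode",
    "CloneTree",
    "pigeonhole_nest",
    "cooccurrence_refine",
    "place_cell",
    "render_tree",
    "read_tree",
]

ROOT_ID = "MRCA"

#: CCFs closer than this are treated as tied (measurement noise).
CCF_TIE_TOL = 0.02


@dataclass(frozen=True)
class Subclone:
    """One bulk subclonal unit: an event (or event set) with its CCF."""

    label: str
    ccf: float
    sample: str = "primary"
    events: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.ccf <= 1:
            raise ValueError("subclone CCF must be in (0, 1]")
        if not self.events:
            object.__setattr__(self, "events", (self.label,))


@dataclass
class CloneNode:
    id: str
    ccf: float
    sample: str = "primary"
    events: tuple[str, ...] = ()
    parent: str | None = None
    children: list[str] = field(default_factory=list)


@dataclass
class CloneTree:
    nodes: dict[str, CloneNode]
    root: str = ROOT_ID
    placements: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    unresolved: list[frozenset[str]] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)

    def path_events(self, node_id: str) -> frozenset[str]:
        out: set[str] = set()
        cur: str | None = node_id
        while cur is not None:
            out.update(self.nodes[cur].events)
            cur = self.nodes[cur].parent
        return frozenset(out)

    def depth(self, node_id: str) -> int:
        d, cur = 0, self.nodes[node_id].parent
        while cur is not None:
            d += 1
            cur = self.nodes[cur].parent
        return d


def pigeonhole_nest(
    subclones: list[Subclone],
    generalized: bool = True,
    tie_tol: float = CCF_TIE_TOL,
) -> set[tuple[str, str]]:
    """Partial order on subclones forced by the pigeonhole principle.

    For every same-sample pair whose CCFs sum above 1 (generalized
    form; the strict form requires both CCFs > 0.5), some cells must
    carry both events, so the lower-CCF subclone nests under the
    higher. Pairs with tied CCFs (within ``tie_tol``) are left
    unresolved, as are cross-sample pairs (CCFs from different samples
    share no denominator). Returns (ancestor, descendant) pairs.
    """
    order: set[tuple[str, str]] = set()
    for a, b in combinations(subclones, 2):
        if a.sample != b.sample:
            continue
        forced = (a.ccf > 0.5 and b.ccf > 0.5) if not generalized else a.ccf + b.ccf > 1.0
        if not forced:
            continue
        if abs(a.ccf - b.ccf) <= tie_tol:
            continue
        hi, lo = (a, b) if a.ccf > b.ccf else (b, a)
        order.add((hi.label, lo.label))
    return order


def _transitive_closure(order: set[tuple[str, str]]) -> set[tuple[str, str]]:
    closure = set(order)
    changed = True
    while changed:
        changed = False
        for x, y in list(closure):
            for y2, z in list(closure):
                if y == y2 and (x, z) not in closure and x != z:
                    closure.add((x, z))
                    changed = True
    return closure


def cooccurrence_refine(
    partial_order: set[tuple[str, str]],
    subclones: list[Subclone],
    cells: dict[str, frozenset[str] | set[str]],
    clonal_events: tuple[str, ...] = (),
    tie_tol: float = CCF_TIE_TOL,
) -> CloneTree:
    """Resolve pigeonhole-ambiguous pairs using single-cell co-occurrence.

    A cell carrying two subclones' events proves they are collinear;
    the nesting direction comes from the CCFs (lower under higher), or,
    when CCFs tie, from subset evidence (a cell carrying A without B
    puts A above B). Contradictions — a cell carrying the nested event
    without its supposed ancestor, or subset evidence in both
    directions — are recorded as conflicts and the pair left unordered.
    The result is a tree rooted at the MRCA (CCF 1, the clonal events)
    with unordered siblings attached to their lowest resolved ancestor.
    """
    by_label = {s.label: s for s in subclones}
    ccf = {s.label: s.ccf for s in subclones}
    conflicts: list[dict] = []
    order = set(partial_order)

    def carries(cell_labels, s: Subclone) -> bool:
        return set(s.events) <= set(cell_labels)

    # check pigeonhole orders against cells (convergence detection)
    for anc, desc in sorted(partial_order):
        violators = [
            cid
            for cid, labs in cells.items()
            if carries(labs, by_label[desc]) and not carries(labs, by_label[anc])
        ]
        if violators:
            conflicts.append(
                {"pair": (anc, desc), "type": "cell_contradicts_pigeonhole", "cells": violators}
            )

    ordered_pairs = {frozenset(p) for p in order}
    for a, b in combinations(sorted(by_label), 2):
        if frozenset((a, b)) in ordered_pairs:
            continue
        sa, sb = by_label[a], by_label[b]
        both = [cid for cid, labs in cells.items() if carries(labs, sa) and carries(labs, sb)]
        if not both:
            continue
        only_a = [cid for cid, labs in cells.items() if carries(labs, sa) and not carries(labs, sb)]
        only_b = [cid for cid, labs in cells.items() if carries(labs, sb) and not carries(labs, sa)]
        if abs(ccf[a] - ccf[b]) > tie_tol:
            hi, lo = (a, b) if ccf[a] > ccf[b] else (b, a)
            lo_without_hi = only_a if lo == a else only_b
            if lo_without_hi:
                conflicts.append(
                    {"pair": (hi, lo), "type": "conflicting_orders", "cells": sorted(both + lo_without_hi)}
                )
                continue
            order.add((hi, lo))
        else:
            if only_a and only_b:
                conflicts.append(
                    {"pair": (a, b), "type": "conflicting_orders", "cells": sorted(only_a + only_b)}
                )
            elif only_a:
                order.add((a, b))
            elif only_b:
                order.add((b, a))
            # no direction evidence: stays unresolved

    closure = _transitive_closure(order)
    # drop cyclic pairs (mutual orders) as conflicts
    for x, y in sorted(closure):
        if (y, x) in closure and x < y:
            conflicts.append({"pair": (x, y), "type": "cyclic_order", "cells": []})
    closure = {(x, y) for x, y in closure if (y, x) not in closure}

    nodes: dict[str, CloneNode] = {
        ROOT_ID: CloneNode(id=ROOT_ID, ccf=1.0, events=tuple(clonal_events))
    }
    for s in subclones:
        nodes[s.label] = CloneNode(id=s.label, ccf=s.ccf, sample=s.sample, events=s.events)

    ancestors: dict[str, list[str]] = {s.label: [] for s in subclones}
    for anc, desc in closure:
        ancestors[desc].append(anc)
    for label in sorted(ancestors):
        anc = ancestors[label]
        if anc:
            parent = min(anc, key=lambda x: (ccf[x], x))
        else:
            parent = ROOT_ID
        nodes[label].parent = parent
    for label in sorted(nodes):
        if label != ROOT_ID:
            nodes[nodes[label].parent].children.append(label)
    for node in nodes.values():
        node.children.sort(key=lambda x: (-nodes[x].ccf, x))

    unresolved = []
    for node in nodes.values():
        sibs = node.children
        for a, b in combinations(sibs, 2):
            if frozenset((a, b)) not in {frozenset(p) for p in closure}:
                unresolved.append(frozenset((a, b)))

    return CloneTree(nodes=nodes, conflicts=conflicts, unresolved=unresolved)


def place_cell(
    cell_events: set[str] | frozenset[str], tree: CloneTree, cell_id: str | None = None
) -> tuple[str, frozenset[str]]:
    """Place one DTC at the deepest fully supported tree node.

    A node is supported when the cell carries every event the node
    itself introduces and its parent is supported; the root only
    requires sharing at least one clonal event (single-cell dropout may
    hide the rest). Events not on the chosen node's path are private.
    Deterministic: ties in depth resolve by node id.

    Raises
    ------
    ValueError
        If the cell shares no clonal event at all (such a cell should
        have been classified AU, not placed).
    """
    cell_events = set(cell_events)
    root = tree.nodes[tree.root]
    if root.events and not cell_events & set(root.events):
        raise ValueError("cell shares no clonal events with the tree; refusing placement")

    supported: dict[str, bool] = {tree.root: True}

    def visit(node_id: str) -> None:
        for ch in tree.nodes[node_id].children:
            ok = supported[node_id] and set(tree.nodes[ch].events) <= cell_events
            supported[ch] = ok
            if ok:
                visit(ch)

    visit(tree.root)
    candidates = [nid for nid, ok in supported.items() if ok]
    best = max(candidates, key=lambda nid: (tree.depth(nid), nid))
    private = frozenset(cell_events - tree.path_events(best))
    if cell_id is not None:
        tree.placements[cell_id] = (best, private)
    return best, private


def _to_dendropy(tree: CloneTree) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=tns)
    mapping = {tree.root: dt.seed_node}
    dt.seed_node.label = tree.root
    stack = [tree.root]
    while stack:
        nid = stack.pop(0)
        for ch in tree.nodes[nid].children:
            child = mapping[nid].new_child()
            child.label = ch
            mapping[ch] = child
            stack.append(ch)
    # dendropy renders leaves through taxa, internal nodes through labels
    for nid, node in mapping.items():
        if node.is_leaf():
            node.taxon = tns.new_taxon(nid)
    return dt


def render_tree(tree: CloneTree) -> tuple[str, pd.DataFrame]:
    """Serialize a clone tree as annotated Newick plus a node table.

    The Newick string carries node labels only; CCFs, samples, events
    and cell placements live in the side table. ``render_tree`` after
    :func:`read_tree` reproduces the exact same strings (lossless round
    trip).
    """
    dt = _to_dendropy(tree)
    newick = dt.as_string(schema="newick", suppress_rooting=True)
    placed: dict[str, list[str]] = {}
    for cid, (nid, _) in sorted(tree.placements.items()):
        placed.setdefault(nid, []).append(cid)
    rows = []
    order = [tree.root]
    i = 0
    while i < len(order):
        order.extend(tree.nodes[order[i]].children)
        i += 1
    for nid in order:
        node = tree.nodes[nid]
        rows.append(
            {
                "node": nid,
                "parent": node.parent or "",
                "ccf": node.ccf,
                "sample": node.sample,
                "events": ";".join(node.events),
                "placed_cells": ";".join(placed.get(nid, [])),
            }
        )
    return newick, pd.DataFrame(rows)


def read_tree(newick: str, node_table: pd.DataFrame) -> CloneTree:
    """Rebuild a :class:`CloneTree` from Newick + node table."""
    dt = dendropy.Tree.get(file=StringIO(newick), schema="newick")
    meta = node_table.set_index("node")
    nodes: dict[str, CloneNode] = {}
    root_label = dt.seed_node.label or str(dt.seed_node.taxon.label)

    def build(dnode, parent_label) -> None:
        label = dnode.label if dnode.label else (dnode.taxon.label if dnode.taxon else None)
        row = meta.loc[label]
        events = tuple(str(row["events"]).split(";")) if str(row["events"]) else ()
        nodes[label] = CloneNode(
            id=label,
            ccf=float(row["ccf"]),
            sample=str(row["sample"]),
            events=events,
            parent=parent_label,
        )
        if parent_label is not None:
            nodes[parent_label].children.append(label)
        for ch in dnode.child_nodes():
            build(ch, label)

    build(dt.seed_node, None)
    placements: dict[str, tuple[str, frozenset[str]]] = {}
    for _, row in node_table.iterrows():
        cells = str(row["placed_cells"])
        if cells and cells != "nan":
            for cid in cells.split(";"):
                if cid:
                    placements[cid] = (row["node"], frozenset())
    return CloneTree(nodes=nodes, root=root_label, placements=placements)
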