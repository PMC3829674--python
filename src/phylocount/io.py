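"""Parsers and writers for constraint-tree encodings.

Three encodings are supported for ranked constraint trees:

* compact tuple text, e.g. ``(0,2,3,2,{(2,1),(3,1),(4,2)})`` — leaf counts in
  rank order followed by the parent pairs ``(child, parent)``;
* JSON: ``{"leaf_counts": [...], "parents": {"2": 1, ...}}``;
* an annotated Newick dialect, e.g. ``((a,b,(c,d)4)2,(e,f,g)3)1;`` — no
  branch lengths, interior node labels are their integer ranks, leaf names
  are arbitrary and discarded (resolution counts depend only on shape and
  ranks).

Fully ranked constraint trees are supported as JSON
(``{"k":…, "l":…, "ranks":[…], "leaf_matrix":[[…]], "parents":{…}}``, where
``leaf_matrix`` holds leaf children only) and as Newick with ``#level``
suffixes on leaf names, e.g. ``((A#3,B#3)2,C#4)1;``.

Enumerated oracle trees can be written in the same Newick dialect (sampled
ancestors appear as unary nodes).  All parsers round-trip exactly with the
corresponding writers.
"""

from __future__ import annotations

import json
import re

import dendropy

from .constraints import ConstraintTree
from .fr_constraints import FRConstraintTree

__all__ = [
    "parse_constraint_tuple",
    "write_constraint_tuple",
    "parse_constraint_json",
    "write_constraint_json",
    "parse_newick_constraint",
    "write_newick_constraint",
    "parse_fr_constraint",
    "parse_fr_constraint_json",
    "write_fr_constraint_json",
    "parse_fr_constraint_newick",
    "write_fr_constraint_newick",
    "parse_constraint",
    "write_tree_newick",
]


class ParseError(ValueError):
    """Malformed input text; ``position`` is a character offset when known."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# Compact tuple format
# ---------------------------------------------------------------------------

_PAIR_RE = re.compile(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)")


def parse_constraint_tuple(text: str) -> ConstraintTree:
    """Parse the compact ``(n1,...,nk,{(i,f(i)),...})`` encoding."""
    s = text.strip()
    if not s.startswith("(") or not s.endswith(")"):
        raise ParseError("expected outer parentheses", 0)
    body = s[1:-1].strip()
    brace = body.find("{")
    if brace == -1:
        counts_part, pairs_part = body, ""
    else:
        if not body.rstrip().endswith("}"):
            raise ParseError("unterminated parent set", len(s) - 1)
        counts_part = body[:brace].rstrip().rstrip(",")
        pairs_part = body[brace + 1: body.rfind("}")]
    counts_part = counts_part.strip().rstrip(",")
    if not counts_part:
        raise ParseError("no leaf counts given", 1)
    try:
        counts = tuple(int(tok) for tok in counts_part.split(","))
    except ValueError as exc:
        raise ParseError(f"bad leaf count: {exc}", 1) from None
    parents: dict[int, int] = {}
    consumed = _PAIR_RE.sub("", pairs_part).replace(",", "").strip()
    if consumed:
        raise ParseError(f"unexpected text in parent set: {consumed!r}")
    for child, parent in _PAIR_RE.findall(pairs_part):
        child, parent = int(child), int(parent)
        if child in parents:
            raise ParseError(f"duplicate parent entry for node {child}")
        parents[child] = parent
    return ConstraintTree(counts, parents)


def write_constraint_tuple(ctree: ConstraintTree) -> str:
    counts = ",".join(str(c) for c in ctree.leaf_counts)
    pairs = ",".join(f"({i},{p})" for i, p in sorted(ctree.parents.items()))
    return f"({counts},{{{pairs}}})"


# ---------------------------------------------------------------------------
# JSON formats
# ---------------------------------------------------------------------------

def parse_constraint_json(text: str) -> ConstraintTree:
    data = json.loads(text)
    try:
        counts = tuple(data["leaf_counts"])
        parents = {int(k): int(v) for k, v in data.get("parents", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"bad constraint-tree JSON: {exc}") from None
    return ConstraintTree(counts, parents)


def write_constraint_json(ctree: ConstraintTree) -> str:
    return json.dumps(
        {
            "leaf_counts": list(ctree.leaf_counts),
            "parents": {str(i): p for i, p in sorted(ctree.parents.items())},
        }
    )


def parse_fr_constraint_json(text: str) -> FRConstraintTree:
    data = json.loads(text)
    try:
        ranks = tuple(data["ranks"])
        matrix = tuple(tuple(row) for row in data["leaf_matrix"])
        parents = {int(k): int(v) for k, v in data.get("parents", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"bad fully-ranked-constraint JSON: {exc}") from None
    tree = FRConstraintTree(ranks, matrix, parents)
    if "k" in data and data["k"] != tree.k:
        raise ParseError(f"declared k = {data['k']} but matrix has {tree.k} rows")
    if "l" in data and data["l"] != tree.l:
        raise ParseError(f"declared l = {data['l']} but matrix has {tree.l} columns")
    return tree


def write_fr_constraint_json(tree: FRConstraintTree) -> str:
    return json.dumps(
        {
            "k": tree.k,
            "l": tree.l,
            "ranks": list(tree.ranks),
            "leaf_matrix": [list(row) for row in tree.leaf_matrix],
            "parents": {str(i): p for i, p in sorted(tree.parents.items())},
        }
    )


# ---------------------------------------------------------------------------
# Annotated Newick
# ---------------------------------------------------------------------------

def _load_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"Newick parse failure: {exc}") from None


def _interior_rank(node: dendropy.Node) -> int:
    label = node.label
    if label is None or not re.fullmatch(r"\d+", str(label)):
        raise ParseError(
            f"interior node needs a bare integer rank label, got {label!r}"
        )
    return int(label)


def parse_newick_constraint(text: str) -> ConstraintTree:
    """Parse the ranked-constraint Newick dialect (interior labels = ranks)."""
    tree = _load_newick(text)
    interior = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    ranks = [_interior_rank(nd) for nd in interior]
    if sorted(ranks) != list(range(1, len(interior) + 1)):
        raise ParseError(
            f"interior ranks must be exactly 1..{len(interior)}, got {sorted(ranks)}"
        )
    by_rank = {r: nd for r, nd in zip(ranks, interior)}
    counts = []
    parents: dict[int, int] = {}
    node_rank = {id(nd): r for r, nd in by_rank.items()}
    for r in range(1, len(interior) + 1):
        nd = by_rank[r]
        counts.append(sum(1 for ch in nd.child_nodes() if ch.is_leaf()))
        if nd.parent_node is not None:
            parents[r] = node_rank[id(nd.parent_node)]
    return ConstraintTree(tuple(counts), parents)


def write_newick_constraint(ctree: ConstraintTree) -> str:
    """Write a constraint tree with generated leaf names ``l1, l2, ...``."""
    children: dict[int, list[int]] = {i: [] for i in range(1, ctree.k + 1)}
    for child, parent in ctree.parents.items():
        children[parent].append(child)
    counter = [0]

    def emit(i: int) -> str:
        parts = []
        for _ in range(ctree.leaf_counts[i - 1]):
            counter[0] += 1
            parts.append(f"l{counter[0]}")
        for ch in sorted(children[i]):
            parts.append(emit(ch))
        return f"({','.join(parts)}){i}"

    return emit(1) + ";"


def parse_fr_constraint_newick(text: str) -> FRConstraintTree:
    """Parse the fully-ranked dialect: leaf names carry ``#level`` suffixes,
    interior labels are level numbers."""
    tree = _load_newick(text)
    interior = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    levels = [_interior_rank(nd) for nd in interior]
    if len(set(levels)) != len(levels):
        raise ParseError(f"duplicate interior level among {sorted(levels)}")
    order = sorted(range(len(interior)), key=lambda idx: levels[idx])
    index_of = {id(interior[idx]): pos + 1 for pos, idx in enumerate(order)}
    ranks = tuple(levels[idx] for idx in order)
    leaf_levels = []
    leaf_info = []  # (owner index, level)
    for nd in tree.leaf_node_iter():
        name = nd.taxon.label if nd.taxon is not None else (nd.label or "")
        mm = re.fullmatch(r"(.*)#(\d+)", name)
        if not mm:
            raise ParseError(f"leaf name {name!r} lacks a '#level' suffix")
        lev = int(mm.group(2))
        if nd.parent_node is None:
            raise ParseError("leaf without parent")
        leaf_info.append((index_of[id(nd.parent_node)], lev))
        leaf_levels.append(lev)
    l = max(leaf_levels + [r + 1 for r in ranks])
    k = len(ranks)
    matrix = [[0] * l for _ in range(k)]
    for owner, lev in leaf_info:
        if lev > l:
            raise ParseError(f"leaf level {lev} beyond deepest level {l}")
        matrix[owner - 1][lev - 1] += 1
    parents = {}
    for nd in interior:
        if nd.parent_node is not None:
            parents[index_of[id(nd)]] = index_of[id(nd.parent_node)]
    return FRConstraintTree(ranks, tuple(tuple(row) for row in matrix), parents)


def write_fr_constraint_newick(tree: FRConstraintTree) -> str:
    children: dict[int, list[int]] = {i: [] for i in range(1, tree.k + 1)}
    for child, parent in tree.parents.items():
        children[parent].append(child)
    counter = [0]

    def emit(i: int) -> str:
        parts = []
        for j in range(1, tree.l + 1):
            for _ in range(tree.leaf_matrix[i - 1][j - 1]):
                counter[0] += 1
                parts.append(f"l{counter[0]}#{j}")
        for ch in sorted(children[i]):
            parts.append(emit(ch))
        return f"({','.join(parts)}){tree.ranks[i - 1]}"

    return emit(1) + ";"


# ---------------------------------------------------------------------------
# Dispatchers
# ---------------------------------------------------------------------------

def parse_constraint(text: str, fmt: str = "auto") -> ConstraintTree:
    """Parse a ranked constraint tree in ``tuple``, ``json`` or ``newick``
    format (``auto`` guesses from the first character)."""
    if fmt == "auto":
        stripped = text.strip()
        if stripped.startswith("{"):
            fmt = "json"
        elif stripped.endswith(";"):
            fmt = "newick"
        else:
            fmt = "tuple"
    if fmt == "tuple":
        return parse_constraint_tuple(text)
    if fmt == "json":
        return parse_constraint_json(text)
    if fmt == "newick":
        return parse_newick_constraint(text)
    raise ValueError(f"unknown format {fmt!r}")


def parse_fr_constraint(text: str, fmt: str = "auto") -> FRConstraintTree:
    """Parse a fully ranked constraint tree in ``json`` or ``newick`` format."""
    if fmt == "auto":
        fmt = "json" if text.lstrip().startswith("{") else "newick"
    if fmt == "json":
        return parse_fr_constraint_json(text)
    if fmt == "newick":
        return parse_fr_constraint_newick(text)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Writing enumerated trees
# ---------------------------------------------------------------------------

def write_tree_newick(node) -> str:
    """Write an oracle tree (ranked / fully ranked / FRS tuple form) as Newick.

    Interior labels are ranks; leaf and sampled-ancestor names carry
    ``#level`` suffixes when ranked; sampled ancestors appear as unary nodes.
    """

    def emit(nd) -> str:
        kind = nd[0]
        if kind == "L":
            return f"{nd[1]}#{nd[2]}" if len(nd) > 2 else str(nd[1])
        if kind == "A":
            return f"({emit(nd[3])}){nd[1]}#{nd[2]}"
        return f"({emit(nd[2])},{emit(nd[3])}){nd[1]}"

    return emit(node) + ";"
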