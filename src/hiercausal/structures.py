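"""Enumeration of grouping trees and causal structures.

A *grouping tree* organises the n moving elements of a scene into nested
reference frames: leaves are the elements, internal nodes are groups and
supergroups, and every root hangs off the stationary WORLD frame.  A
*causal structure* augments a tree with one binary flag per node saying
whether that node's velocity relative to its parent frame is exactly zero
(flag 0, the delta component of the prior) or nonzero (flag 1, the slow
Gaussian component).

Grammar
-------
Trees are generated as chains of partitions: level 1 partitions the
elements, level 2 partitions the level-1 blocks, and so on.  Every block at
every level is a node with its own relative velocity.  Two rules make the
enumeration finite and non-redundant:

* each level must be non-trivial (contain at least one merge), and
* singleton chains hanging directly off WORLD are pruned — a group that
  contains a single child and answers to nothing above it is
  indistinguishable from that child moving in the world frame.

Label-respecting canonical deduplication then removes partition chains that
build the same tree.  Under this grammar a scene of two elements admits 12
causal structures and a scene of three admits 264, and the largest tree
over n elements has n(n+1)/2 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterator

WORLD = -1
#: Sentinel returned by :func:`percept_node` when no node on the element's
#: path to WORLD carries a nonzero relative velocity.
STATIONARY = -1

ELEMENT = "element"
GROUP = "group"

MAX_ELEMENTS = 4


@dataclass(frozen=True)
class GroupingTree:
    """A grouping tree over ``n_elements`` leaves.

    Nodes ``0 .. n_elements-1`` are the element leaves in element order;
    group nodes follow in canonical order.  ``parents[i]`` is the parent
    node index, or ``WORLD`` (-1) for roots.
    """

    n_elements: int
    parents: tuple[int, ...]
    kinds: tuple[str, ...]

    def __post_init__(self):
        if len(self.parents) != len(self.kinds):
            raise ValueError("parents and kinds length mismatch")
        for i in range(self.n_elements):
            if self.kinds[i] != ELEMENT:
                raise ValueError("first n_elements nodes must be element leaves")

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    @property
    def leaves(self) -> range:
        return range(self.n_elements)

    def children(self, node: int) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.parents) if p == node)

    def path_to_world(self, element: int) -> tuple[int, ...]:
        """Nodes on the path from an element leaf up to (excluding) WORLD."""
        if not 0 <= element < self.n_elements:
            raise ValueError(f"unknown element id {element}")
        path = []
        node = element
        while node != WORLD:
            path.append(node)
            node = self.parents[node]
        return tuple(path)

    def group_nodes(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == GROUP)

    def n_roots(self) -> int:
        return sum(1 for p in self.parents if p == WORLD)

    def descendant_elements(self, node: int) -> frozenset[int]:
        if self.kinds[node] == ELEMENT:
            return frozenset((node,))
        out: set[int] = set()
        for c in self.children(node):
            out |= self.descendant_elements(c)
        return frozenset(out)


@dataclass(frozen=True)
class CausalStructure:
    """A grouping tree plus a stationarity flag per node.

    ``moving_flags[i]`` is 1 when node i has a nonzero relative velocity
    and 0 when it is exactly stationary in its parent frame.  The S
    (same-structure) variables of the generative model are implied by the
    tree's edges and are not stored separately.
    """

    tree: GroupingTree
    moving_flags: tuple[int, ...]

    def __post_init__(self):
        if len(self.moving_flags) != self.tree.n_nodes:
            raise ValueError("one flag per tree node required")
        if any(f not in (0, 1) for f in self.moving_flags):
            raise ValueError("flags must be 0 or 1")

    @property
    def n_elements(self) -> int:
        return self.tree.n_elements

    def to_json(self) -> dict:
        return {
            "n_elements": self.tree.n_elements,
            "parents": list(self.tree.parents),
            "kinds": list(self.tree.kinds),
            "flags": list(self.moving_flags),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CausalStructure":
        tree = GroupingTree(
            n_elements=int(obj["n_elements"]),
            parents=tuple(int(p) for p in obj["parents"]),
            kinds=tuple(obj["kinds"]),
        )
        return cls(tree=tree, moving_flags=tuple(int(f) for f in obj["flags"]))


# ---------------------------------------------------------------------------
# enumeration


def _partitions(items: list[int]) -> Iterator[list[list[int]]]:
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _partition_chains(n_units: int) -> Iterator[list[list[list[int]]]]:
    """All chains of non-trivial partitions, coarsening level by level."""

    def rec(n: int, prefix: list) -> Iterator[list]:
        yield list(prefix)
        if n <= 1:
            return
        for part in _partitions(list(range(n))):
            if all(len(b) == 1 for b in part):
                continue
            prefix.append([sorted(b) for b in part])
            yield from rec(len(part), prefix)
            prefix.pop()

    yield from rec(n_units, [])


def _build_pruned_tree(n: int, chain: list) -> tuple[tuple[int, ...], tuple[str, ...]]:
    parents: list = [WORLD] * n
    kinds: list = [ELEMENT] * n
    roots = list(range(n))
    for level in chain:
        new_roots = []
        for block in level:
            gid = len(parents)
            parents.append(WORLD)
            kinds.append(GROUP)
            for u in block:
                parents[roots[u]] = gid
            new_roots.append(gid)
        roots = new_roots
    # prune top-level singleton chains
    changed = True
    while changed:
        changed = False
        for nid, p in enumerate(parents):
            if p == WORLD and kinds[nid] == GROUP:
                ch = [i for i, q in enumerate(parents) if q == nid]
                if len(ch) == 1:
                    parents[ch[0]] = WORLD
                    parents[nid] = None  # mark deleted
                    changed = True
    keep = [i for i in range(len(parents)) if parents[i] is not None]
    remap = {old: new for new, old in enumerate(keep)}
    P = tuple(WORLD if parents[i] == WORLD else remap[parents[i]] for i in keep)
    K = tuple(kinds[i] for i in keep)
    return P, K


def _signature(parents, kinds, node, children):
    if kinds[node] == ELEMENT:
        return ("e", node)
    return ("g", tuple(sorted(_signature(parents, kinds, c, children) for c in children[node])))


def _canonicalize(parents, kinds, n):
    """Reorder nodes: elements first (element order), then groups sorted by
    (descendant element set, height).  Returns a canonical GroupingTree."""
    nn = len(parents)
    children: dict = {i: [] for i in range(nn)}
    for i, p in enumerate(parents):
        if p != WORLD:
            children[p].append(i)

    def desc(i):
        if kinds[i] == ELEMENT:
            return (i,)
        out: set = set()
        for c in children[i]:
            out.update(desc(c))
        return tuple(sorted(out))

    def height(i):
        if kinds[i] == ELEMENT:
            return 0
        return 1 + max(height(c) for c in children[i])

    groups = [i for i in range(nn) if kinds[i] == GROUP]
    groups.sort(key=lambda i: (desc(i), height(i)))
    order = list(range(n)) + groups
    remap = {old: new for new, old in enumerate(order)}
    P = tuple(WORLD if parents[old] == WORLD else remap[parents[old]] for old in order)
    K = tuple(kinds[old] for old in order)
    return GroupingTree(n_elements=n, parents=P, kinds=K)


@lru_cache(maxsize=None)
def enumerate_grouping_trees(n_elements: int) -> tuple[GroupingTree, ...]:
    """All distinct grouping trees over ``n_elements`` labeled elements.

    Deterministic canonical order: by node count, then by the tree's
    parent/kind encoding.
    """
    if not isinstance(n_elements, int) or n_elements < 1:
        raise ValueError("n_elements must be a positive integer")
    if n_elements > MAX_ELEMENTS:
        raise ValueError(f"enumeration supported for n <= {MAX_ELEMENTS}")
    seen: dict = {}
    for chain in _partition_chains(n_elements):
        P, K = _build_pruned_tree(n_elements, chain)
        children: dict = {i: [] for i in range(len(P))}
        for i, p in enumerate(P):
            if p != WORLD:
                children[p].append(i)
        roots = [i for i, p in enumerate(P) if p == WORLD]
        sig = tuple(sorted(_signature(P, K, r, children) for r in roots))
        if sig not in seen:
            seen[sig] = _canonicalize(P, K, n_elements)
    trees = sorted(seen.values(), key=lambda t: (t.n_nodes, t.parents, t.kinds))
    return tuple(trees)


@lru_cache(maxsize=None)
def enumerate_causal_structures(n_elements: int) -> tuple[CausalStructure, ...]:
    """Every grouping tree crossed with all stationarity-flag assignments.

    Flags iterate lexicographically (node 0 slowest) within each tree;
    trees follow their canonical order.
    """
    out = []
    seen = set()
    for tree in enumerate_grouping_trees(n_elements):
        for flags in product((0, 1), repeat=tree.n_nodes):
            s = CausalStructure(tree=tree, moving_flags=flags)
            key = (tree.parents, tree.kinds, flags)
            if key not in seen:
                seen.add(key)
                out.append(s)
    return tuple(out)


def count_causal_structures(n_elements: int) -> int:
    """Number of distinct causal structures for a scene of n elements."""
    return len(enumerate_causal_structures(n_elements))


def structure_count_bound(n_elements: int) -> int:
    """The loose bound T(n) * 2^(n(n+1)/2) on the number of structures."""
    t = len(enumerate_grouping_trees(n_elements))
    return t * 2 ** (n_elements * (n_elements + 1) // 2)


# ---------------------------------------------------------------------------
# structure queries


def percept_node(structure: CausalStructure, element: int) -> int:
    """The node whose relative velocity defines the element's percept.

    Walks the path element -> WORLD and returns the first node with a
    nonzero relative velocity (flag 1); returns :data:`STATIONARY` when
    every node on the path is stationary.
    """
    for node in structure.tree.path_to_world(element):
        if structure.moving_flags[node] == 1:
            return node
    return STATIONARY


def is_pure(structure: CausalStructure) -> bool:
    """True when every group has at least one exactly-stationary child."""
    tree = structure.tree
    for g in tree.group_nodes():
        if all(structure.moving_flags[c] == 1 for c in tree.children(g)):
            return False
    return True
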