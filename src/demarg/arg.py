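"""Local trees with population-path-labelled branches, and the ARG container.

A :class:`LocalTree` is a binary coalescent tree over the model's haploid
lineages at one genomic segment.  Node ids are *slot-stable*: leaf ``i`` is
always the i-th haploid lineage of the model (absent leaves are marked), and
internal nodes are renumbered canonically after every edit — sorted by
(coalescence time, smallest descendant leaf) — so that serialized ARGs are
reproducible byte-for-byte for a given seed.

Every branch carries a ``path`` id referencing the model's global population
path table; a coalescence is only valid when the two joining branches occupy
the same population at the coalescence time.

An :class:`ARG` is an ordered list of local trees whose half-open column
spans tile the window, with at most one subtree-prune-regraft (SPR) event
between adjacent trees.  All genomic coordinates here are 0-based half-open
in *compressed-column* units; a separate column map converts to base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .demography import DemographicModel

__all__ = [
    "LocalTree",
    "SPREvent",
    "ARG",
    "ThreadRecord",
    "validate_tree",
    "unthread",
    "thread",
    "migrant_tracts",
]

ABSENT = -2
NULL = -1


def _match_label(path_pops: np.ndarray, cur: int, lo: int, hi: int) -> int:
    """Lowest path id whose populations match ``cur``'s over [lo, hi]."""
    seg = path_pops[cur, lo:hi + 1]
    cand = np.nonzero((path_pops[:, lo:hi + 1] == seg).all(axis=1))[0]
    return int(cand[0]) if cand.size else cur


class LocalTree:
    """Binary coalescent tree over up to ``n_slots`` haploid lineages.

    ``parent[v]`` is the parent node id (-1 for the root, -2 for an absent
    leaf slot), ``time[v]`` the grid time index of node ``v``, and ``path[v]``
    the global population-path id of the branch *above* ``v`` (for the root,
    the path of its upward extension to the top of the grid).
    """

    __slots__ = ("n_slots", "parent", "time", "path", "_keys", "_children")

    def __init__(self, n_slots: int, parent, time, path):
        self.n_slots = int(n_slots)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.time = np.asarray(time, dtype=np.int32)
        self.path = np.asarray(path, dtype=np.int32)
        self._keys = None      # caches: trees are not mutated once built
        self._children = None

    # -- constructors -------------------------------------------------- #

    @classmethod
    def single_lineage(cls, n_slots: int, leaf: int, age: int, path_id: int) -> "LocalTree":
        parent = np.full(n_slots, ABSENT, dtype=np.int32)
        time = np.full(n_slots, NULL, dtype=np.int32)
        path = np.full(n_slots, NULL, dtype=np.int32)
        parent[leaf] = NULL
        time[leaf] = age
        path[leaf] = path_id
        return cls(n_slots, parent, time, path)

    def copy(self) -> "LocalTree":
        return LocalTree(self.n_slots, self.parent.copy(), self.time.copy(), self.path.copy())

    # -- basic queries -------------------------------------------------- #

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_slots) if self.parent[i] != ABSENT]

    @property
    def root(self) -> int:
        for v in range(self.n_nodes):
            if self.parent[v] == NULL:
                return v
        raise ValueError("tree has no root")

    def children(self) -> dict[int, list[int]]:
        if self._children is not None:
            return self._children
        ch: dict[int, list[int]] = {}
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                ch.setdefault(int(p), []).append(v)
        self._children = ch
        return ch

    def keys(self) -> np.ndarray:
        """Bitmask of descendant leaves per node (leaf i contributes bit i)."""
        if self._keys is not None:
            return self._keys
        k = np.zeros(self.n_nodes, dtype=np.int64)
        ch = self.children()
        stack = [self.root]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(ch.get(v, []))
        for v in reversed(order):  # children before parents
            if v < self.n_slots:
                k[v] = 1 << v
            else:
                for c in ch[v]:
                    k[v] |= k[c]
        self._keys = k
        return k

    def node_by_key(self, key: int) -> int:
        k = self.keys()
        for v in range(self.n_nodes):
            if k[v] == key and (v < self.n_slots and self.parent[v] != ABSENT or v >= self.n_slots):
                return v
        raise KeyError(f"no node with leaf set {key:b}")

    def parent_time(self, v: int, K: int) -> int:
        """Grid index of the top of v's branch (top of grid for the root)."""
        p = self.parent[v]
        return int(self.time[p]) if p >= 0 else K - 1

    # -- canonical renumbering ------------------------------------------ #

    def canonical(self) -> "LocalTree":
        """Renumber internal nodes by (time, smallest descendant leaf)."""
        # deterministic total order: (time, leaf-set key); a node and its
        # parent can share a time (the grid ties node times) but never a key
        keys = self.keys()
        internal = [v for v in range(self.n_nodes) if v >= self.n_slots]
        internal.sort(key=lambda v: (int(self.time[v]), int(keys[v])))
        remap = {v: v for v in range(self.n_slots)}
        for i, v in enumerate(internal):
            remap[v] = self.n_slots + i
        n = self.n_slots + len(internal)
        parent = np.full(n, ABSENT, dtype=np.int32)
        time = np.full(n, NULL, dtype=np.int32)
        path = np.full(n, NULL, dtype=np.int32)
        for v in range(self.n_nodes):
            if v < self.n_slots and self.parent[v] == ABSENT:
                continue
            nv = remap[v]
            p = self.parent[v]
            parent[nv] = remap[int(p)] if p >= 0 else NULL
            time[nv] = self.time[v]
            path[nv] = self.path[v]
        return LocalTree(self.n_slots, parent, time, path)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocalTree):
            return NotImplemented
        return (
            self.n_slots == other.n_slots
            and self.parent.shape == other.parent.shape
            and np.array_equal(self.parent, other.parent)
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.path, other.path)
        )

    def __hash__(self):
        return hash((self.n_slots, self.parent.tobytes(), self.time.tobytes(), self.path.tobytes()))

    # -- edits ----------------------------------------------------------- #

    def attach(self, leaf: int, target: int, t: int, path_id: int,
               parent_path: Optional[int] = None,
               model: Optional[DemographicModel] = None) -> "LocalTree":
        """Thread ``leaf`` onto the branch above ``target`` at time index ``t``.

        The new coalescence node continues along the target branch's path
        (``parent_path`` overrides this only when rebuilding a recorded ARG).
        With a ``model``, the split segments are re-labelled canonically: the
        lowest path id whose populations match each segment's span (so a
        band that moved above a segment's top no longer labels it).
        """
        if self.parent[leaf] != ABSENT:
            raise ValueError(f"leaf {leaf} already present")
        if self.time[leaf] < 0:
            raise ValueError(f"leaf {leaf} has no sampling age set")
        n = self.n_nodes
        parent = np.append(self.parent, NULL).astype(np.int32)
        time = np.append(self.time, t).astype(np.int32)
        up = self.path[target] if parent_path is None else parent_path
        path = np.append(self.path, up).astype(np.int32)
        m = n  # the new coalescence node
        parent[m] = self.parent[target]
        parent[target] = m
        parent[leaf] = m
        path[leaf] = path_id
        if model is not None:
            pp = model.path_pops_matrix
            K = pp.shape[1]
            # lower target segment [time(target), t]
            path[target] = _match_label(pp, int(path[target]),
                                        int(time[target]), t)
            if parent_path is None:
                top = int(time[parent[m]]) if parent[m] >= 0 else K - 1
                path[m] = _match_label(pp, int(path[m]), t, top)
        tree = LocalTree(self.n_slots, parent, time, path)
        return tree.canonical()

    def attach_leaf(self, leaf: int, age: int, target: int, t: int, path_id: int,
                    parent_path: Optional[int] = None,
                    model: Optional[DemographicModel] = None) -> "LocalTree":
        tmp = self.copy()
        tmp.time[leaf] = age
        return tmp.attach(leaf, target, t, path_id, parent_path, model)

    def detach(self, leaf: int, model: Optional[DemographicModel] = None
               ) -> tuple["LocalTree", tuple[int, int, int, int]]:
        """Remove ``leaf``; returns (new tree, (sibling key, coalescence time,
        leaf path, parent-branch path)).

        With a ``model``, the merged branch (sibling's segment plus the
        removed parent's upper segment) is labelled with the lowest path id
        matching the composite populations over the merged span; this keeps
        a migration event carried by the upper segment attached to the
        surviving lineage.
        """
        if self.parent[leaf] == ABSENT:
            raise ValueError(f"leaf {leaf} not present")
        p = int(self.parent[leaf])
        if p == NULL:
            raise ValueError("cannot detach the last remaining lineage")
        sib = [v for v in range(self.n_nodes) if self.parent[v] == p and v != leaf][0]
        keys = self.keys()
        record = (int(keys[sib]), int(self.time[p]), int(self.path[leaf]),
                  int(self.path[p]))
        merged_label = int(self.path[sib])
        if model is not None and self.path[p] != self.path[sib]:
            pp = model.path_pops_matrix
            K = pp.shape[1]
            gp = int(self.parent[p])
            top = int(self.time[gp]) if gp >= 0 else K - 1
            t_lo, t_mid = int(self.time[sib]), int(self.time[p])
            comp = np.concatenate([
                pp[int(self.path[sib]), t_lo:t_mid],
                pp[int(self.path[p]), t_mid:top + 1],
            ])
            cand = np.nonzero((pp[:, t_lo:top + 1] == comp).all(axis=1))[0]
            if cand.size:
                merged_label = int(cand[0])
        keep = [v for v in range(self.n_nodes) if v != p and not (v == leaf)]
        remap = {}
        n_internal = 0
        for v in keep:
            if v < self.n_slots:
                remap[v] = v
            else:
                remap[v] = self.n_slots + n_internal
                n_internal += 1
        n = self.n_slots + n_internal
        parent = np.full(n, ABSENT, dtype=np.int32)
        time = np.full(n, NULL, dtype=np.int32)
        path = np.full(n, NULL, dtype=np.int32)
        for v in keep:
            if v < self.n_slots and self.parent[v] == ABSENT:
                continue
            nv = remap[v]
            pv = int(self.parent[v])
            if v == sib:
                pv = int(self.parent[p])
            parent[nv] = remap[pv] if pv >= 0 else NULL
            time[nv] = self.time[v]
            path[nv] = merged_label if v == sib else self.path[v]
        out = LocalTree(self.n_slots, parent, time, path).canonical()
        return out, record

    # -- population-path queries ---------------------------------------- #

    def crossing_nodes(self, model: DemographicModel, band: Optional[int] = None) -> list[int]:
        """Nodes whose branch crosses a migration band within its time span."""
        out = []
        K = model.K
        for v in range(self.n_nodes):
            if v < self.n_slots and self.parent[v] == ABSENT:
                continue
            pth = model.paths[int(self.path[v])]
            if pth.band is None or (band is not None and pth.band != band):
                continue
            top = self.parent_time(v, K)
            if self.time[v] <= pth.band_j and top >= pth.band_j + 1:
                out.append(v)
        return out

    def lineage_is_migrant(self, model: DemographicModel, band: int, leaf: int) -> bool:
        """Does ``leaf``'s ancestral line cross ``band``?

        Walk up from the leaf to the branch that spans the band's half time;
        that branch's path decides whether the ancestor migrated.
        """
        j = model._band_j[band]
        K = model.K
        v = leaf
        if self.parent[v] == ABSENT:
            return False
        while True:
            top = self.parent_time(v, K)
            if self.time[v] <= j and top >= j + 1:
                pth = model.paths[int(self.path[v])]
                return pth.band == band and pth.band_j == j
            if self.parent[v] < 0:
                return False
            v = int(self.parent[v])


@dataclass(frozen=True)
class SPREvent:
    """Recombination relating two adjacent local trees.

    The recombination occurs immediately before ``position`` on the branch
    above the node with leaf-set ``recomb_key``, at grid time
    ``recomb_time``; the broken branch re-coalesces onto the branch above
    ``recoal_key`` at ``recoal_time`` following path ``recoal_path``.
    """

    position: int
    recomb_key: int
    recomb_time: int
    recoal_key: int
    recoal_time: int
    recoal_path: int


class ARG:
    """Ordered local trees tiling ``[0, L)`` columns, with SPRs between them."""

    def __init__(self, L: int, starts: list[int], trees: list[LocalTree],
                 sprs: Optional[list[Optional[SPREvent]]] = None):
        if not starts or starts[0] != 0 or len(starts) != len(trees):
            raise ValueError("segment starts must begin at 0 and match trees")
        if any(b <= a for a, b in zip(starts, starts[1:])) or (len(starts) and starts[-1] >= L):
            raise ValueError("segment starts must be strictly increasing within [0, L)")
        self.L = int(L)
        self.starts = list(starts)
        self.trees = list(trees)
        self.sprs = list(sprs) if sprs is not None else [None] * (len(trees) - 1)
        if len(self.sprs) != len(trees) - 1:
            raise ValueError("need exactly one SPR slot between adjacent trees")

    def segments(self) -> Iterator[tuple[int, int, LocalTree]]:
        for i, tree in enumerate(self.trees):
            end = self.starts[i + 1] if i + 1 < len(self.trees) else self.L
            yield self.starts[i], end, tree

    def tree_at(self, col: int) -> LocalTree:
        i = int(np.searchsorted(self.starts, col, side="right")) - 1
        return self.trees[i]

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def __eq__(self, other):
        if not isinstance(other, ARG):
            return NotImplemented
        return (
            self.L == other.L
            and self.starts == other.starts
            and all(a == b for a, b in zip(self.trees, other.trees))
        )


@dataclass
class ThreadRecord:
    """Per-segment original coalescence of a removed lineage.

    ``pieces`` is a list of ``(start, end, (target_key, time, path_id))``
    over the original segmentation, enough to rebuild the original ARG by
    re-threading.
    """

    lineage: int
    age: int
    pieces: list[tuple[int, int, tuple[int, int, int]]]


def validate_tree(tree: LocalTree, model: DemographicModel,
                  max_one_migration: bool = True) -> list[str]:
    """Structural and population-path checks; returns a list of violations."""
    v_list: list[str] = []
    K = model.K
    ch = tree.children()
    roots = [v for v in range(tree.n_nodes) if tree.parent[v] == NULL]
    if len(roots) != 1:
        v_list.append(f"expected one root, found {len(roots)}")
        return v_list
    leaves = tree.leaves
    ages = model.lineage_ages
    for v in leaves:
        if tree.time[v] != ages[v]:
            v_list.append(f"leaf {v}: time {tree.time[v]} != sampling age {ages[v]}")
    for v in range(tree.n_slots, tree.n_nodes):
        kids = ch.get(v, [])
        if len(kids) != 2:
            v_list.append(f"internal node {v} has {len(kids)} children")
            continue
        t = int(tree.time[v])
        pops = []
        for c in kids:
            # leaf branches have positive length; internal node times may tie
            # (coalescence at the same discrete grid time)
            strict = c < tree.n_slots
            if (tree.time[c] > t) or (strict and tree.time[c] == t):
                v_list.append(f"branch {c}->{v}: child time {tree.time[c]} !< parent {t}")
            pth = model.paths[int(tree.path[c])]
            pops.append(pth.pops[t])
            if pth.band is not None and not (tree.time[c] <= pth.band_j < t):
                v_list.append(f"branch {c}->{v}: migrant path's band outside branch span")
        if len(set(pops)) > 1:
            v_list.append(f"coalescence at node {v}: branches in different populations {pops}")
        own = model.paths[int(tree.path[v])]
        if pops and own.pops[t] != pops[0]:
            v_list.append(f"node {v}: parent branch path does not continue in population {pops[0]}")
    # leaf branches must start in the sampled population
    lpops = model.lineage_pops
    for v in leaves:
        pth = model.paths[int(tree.path[v])]
        if pth.pops[tree.time[v]] != lpops[v]:
            v_list.append(f"leaf {v}: path does not start in its sampled population")
    if max_one_migration:
        crossing = tree.crossing_nodes(model)
        if len(crossing) > 1:
            v_list.append(
                f"{len(crossing)} migrant branches at one position under the "
                f"max-one-migration constraint"
            )
    return v_list


def unthread(arg: ARG, lineage: int,
             model: Optional[DemographicModel] = None) -> tuple[ARG, ThreadRecord]:
    """Remove one haploid lineage from every local tree.

    Adjacent segments whose trees become identical are merged (their SPR —
    which necessarily involved the removed branch — is dropped).  The
    returned :class:`ThreadRecord` reconstructs the original ARG exactly via
    :func:`thread`.
    """
    first = arg.trees[0]
    if lineage < 0 or lineage >= first.n_slots or first.parent[lineage] == ABSENT:
        raise ValueError(f"lineage {lineage} not present in ARG")
    age = int(first.time[lineage])
    pieces = []
    new_trees: list[LocalTree] = []
    new_starts: list[int] = []
    new_sprs: list[Optional[SPREvent]] = []
    for i, (start, end, tree) in enumerate(arg.segments()):
        stripped, rec = tree.detach(lineage, model)
        pieces.append((start, end, rec))
        if new_trees and stripped == new_trees[-1]:
            continue
        if new_trees:
            new_sprs.append(arg.sprs[i - 1])
        new_trees.append(stripped)
        new_starts.append(start)
    partial = ARG(arg.L, new_starts, new_trees, new_sprs)
    return partial, ThreadRecord(lineage=lineage, age=age, pieces=pieces)


def thread(partial: ARG, record_or_pieces, lineage: Optional[int] = None,
           age: Optional[int] = None,
           model: Optional[DemographicModel] = None) -> ARG:
    """Re-insert a lineage given per-segment coalescence states.

    ``record_or_pieces`` is a :class:`ThreadRecord` or a list of
    ``(start, end, (target_key, time, path_id))`` pieces whose boundaries,
    together with the partial ARG's own boundaries, define the new
    segmentation.  A new SPR (on the re-threaded branch) is recorded at every
    piece boundary where the state changes across an unchanged partial tree.
    """
    if isinstance(record_or_pieces, ThreadRecord):
        rec = record_or_pieces
        pieces, lineage, age = rec.pieces, rec.lineage, rec.age
    else:
        pieces = record_or_pieces
        if lineage is None or age is None:
            raise ValueError("lineage and age required with raw pieces")
    # merge boundaries
    bounds = sorted({0, partial.L} | {s for s, _, _ in pieces} | set(partial.starts))
    if pieces[0][0] != 0 or max(e for _, e, _ in pieces) != partial.L:
        raise ValueError("pieces must tile the window")
    states: dict[int, tuple[int, int, int]] = {}
    for s, e, st in pieces:
        states[s] = st
    trees: list[LocalTree] = []
    starts: list[int] = []
    sprs: list[Optional[SPREvent]] = []
    cur_state = None
    piece_iter = sorted(states.items())
    state_at = {}
    k = 0
    for b in bounds[:-1]:
        while k + 1 < len(piece_iter) and piece_iter[k + 1][0] <= b:
            k += 1
        state_at[b] = piece_iter[k][1]
    prev_partial_tree = None
    for b, b_next in zip(bounds[:-1], bounds[1:]):
        ptree = partial.tree_at(b)
        key, t, path_id, *rest = state_at[b]
        target = ptree.node_by_key(key)
        full = ptree.attach_leaf(lineage, age, target, t, path_id,
                                 parent_path=rest[0] if rest else None,
                                 model=model)
        if trees and full == trees[-1]:
            prev_partial_tree = ptree
            cur_state = (key, t, path_id)
            continue
        if trees:
            if ptree is prev_partial_tree or ptree == prev_partial_tree:
                old_key, old_t, old_p = cur_state[:3]
                sprs.append(SPREvent(
                    position=b, recomb_key=1 << lineage,
                    recomb_time=min(int(old_t), int(t)),
                    recoal_key=key, recoal_time=t, recoal_path=path_id,
                ))
            else:
                i = partial.starts.index(b) if b in partial.starts else None
                sprs.append(partial.sprs[i - 1] if i else None)
        trees.append(full)
        starts.append(b)
        prev_partial_tree = ptree
        cur_state = (key, t, path_id)
    return ARG(partial.L, starts, trees, sprs)


def migrant_tracts(arg: ARG, model: DemographicModel, band, lineage: int
                   ) -> list[tuple[int, int]]:
    """Maximal half-open column intervals where ``lineage``'s ancestral line
    crosses ``band``."""
    bi = model.band_index(band)
    out: list[tuple[int, int]] = []
    for start, end, tree in arg.segments():
        if tree.lineage_is_migrant(model, bi, lineage):
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
    return out
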