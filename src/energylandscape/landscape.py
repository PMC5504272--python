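"""Exhaustive energy landscapes over the 2**K binary activity patterns.

The landscape is the hypercube graph of all patterns (two patterns are
adjacent iff they differ in exactly one network's activity) decorated with
the pairwise-MEM energies.  From it we derive:

* local minima -- patterns strictly below all K neighbours;
* the disconnectivity tree -- at what energy threshold pairs of minima
  become disconnected (merge heights are minimax path barriers);
* attraction basins -- steepest-descent assignment of every pattern to a
  minimum, with basin sizes as fractions of 2**K;
* the labelled brain-state partition (major #1/#2, minor #1/#2), either
  from an explicit grouping of the minima or automatically from the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mem import ENUMERATION_CAP, MEMParams, all_patterns, all_state_energies

__all__ = [
    "STATE_LABELS",
    "EnergyLandscape",
    "DisconnectivityTree",
    "TreeNode",
    "BasinMap",
    "BrainStatePartition",
    "build_landscape",
    "find_local_minima",
    "build_disconnectivity_graph",
    "assign_basins",
    "define_brain_states",
]

#: canonical state labels, ordered by convention (majors first)
STATE_LABELS = ("major1", "major2", "minor1", "minor2")


@dataclass
class EnergyLandscape:
    """Energies of all 2**K patterns indexed by pattern code."""

    k: int
    energies: np.ndarray
    params: MEMParams | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.k > ENUMERATION_CAP:
            raise ValueError(f"K={self.k} exceeds the enumeration cap")
        if self.energies.shape != (2**self.k,):
            raise ValueError(
                f"need exactly 2**K={2**self.k} energies, got {self.energies.shape}"
            )

    @property
    def n_patterns(self) -> int:
        return self.energies.shape[0]

    def neighbours(self, code: int) -> np.ndarray:
        """Codes of the K patterns at Hamming distance 1."""
        return np.array([code ^ (1 << i) for i in range(self.k)])

    def neighbour_table(self) -> np.ndarray:
        """(2**K, K) table: row c, column i = c with bit i flipped."""
        codes = np.arange(self.n_patterns)
        return codes[:, None] ^ (1 << np.arange(self.k))[None, :]


@dataclass
class TreeNode:
    """Node of a disconnectivity tree.

    Leaves carry a local-minimum ``code`` and its own energy; internal
    nodes carry the ``merge_energy`` (the minimax barrier at which their
    children's minima groups first connect) and two or more children.
    """

    energy: float
    code: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.code is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.code]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class DisconnectivityTree:
    """Hierarchy of local minima with minimax merge barriers."""

    root: TreeNode
    k: int

    def leaves(self) -> list[int]:
        return self.root.leaves()

    def merge_energy(self, a: int, b: int) -> float:
        """Barrier at which minima ``a`` and ``b`` first connect."""
        node = self._lca(self.root, a, b)
        if node is None:
            raise KeyError(f"minima {a}, {b} not both in tree")
        return node.energy

    def _lca(self, node: TreeNode, a: int, b: int) -> TreeNode | None:
        if node.is_leaf:
            return node if a == b == node.code else None
        containing = [c for c in node.children if {a, b} & set(c.leaves())]
        for c in node.children:
            sub = set(c.leaves())
            if a in sub and b in sub:
                return self._lca(c, a, b)
        if len(containing) >= 2 or (a == b and containing):
            return node
        return None

    def to_newick(self) -> str:
        """Newick string; merge energies annotate internal nodes, leaf
        branch lengths are (merge energy - leaf energy)."""

        def fmt(node: TreeNode, parent_energy: float | None) -> str:
            if node.is_leaf:
                s = f"m{node.code}"
            else:
                inner = ",".join(fmt(c, node.energy) for c in node.children)
                s = f"({inner})E={node.energy:.6g}"
            if parent_energy is not None:
                s += f":{parent_energy - node.energy:.6g}"
            return s

        return fmt(self.root, None) + ";"


@dataclass
class BasinMap:
    """Steepest-descent basin of every pattern and basin-size fractions."""

    basin_of: np.ndarray  # pattern code -> local-minimum code
    basin_sizes: dict[int, float]  # minimum code -> fraction of 2**K

    def __post_init__(self) -> None:
        total = sum(self.basin_sizes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"basin sizes must sum to 1, got {total}")


@dataclass
class BrainStatePartition:
    """Labelled grouping of local minima (hence all patterns) into states.

    ``state_of_minimum`` maps each local-minimum code to one of
    :data:`STATE_LABELS` (a truncated prefix of it when the landscape has
    fewer than four minima groups).  ``pattern_state`` maps every pattern
    code to the index of its basin's state in ``labels``.  The coarse
    'intermediate' state is the union of the minor states.
    """

    state_of_minimum: dict[int, str]
    labels: tuple[str, ...]
    pattern_state: np.ndarray
    state_sizes: dict[str, float]

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def state_index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def major_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.labels) if s.startswith("major"))

    @property
    def minor_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.labels) if s.startswith("minor"))


def build_landscape(params: MEMParams) -> EnergyLandscape:
    """Enumerate all 2**K pattern energies (128 for the 7-network case)."""
    return EnergyLandscape(k=params.k, energies=all_state_energies(params), params=params)


def find_local_minima(ls: EnergyLandscape) -> list[int]:
    """Codes whose energy is strictly below all K Hamming-1 neighbours."""
    nbr = ls.neighbour_table()
    is_min = np.all(ls.energies[:, None] < ls.energies[nbr], axis=1)
    return [int(c) for c in np.flatnonzero(is_min)]


def _descent_step(ls: EnergyLandscape, code: int) -> int:
    """One steepest-descent step; ties broken toward the lowest code."""
    nbr = ls.neighbours(code)
    e_n = ls.energies[nbr]
    best = e_n.min()
    if best >= ls.energies[code]:
        return code
    cands = nbr[e_n == best]
    return int(cands.min())


def assign_basins(ls: EnergyLandscape, minima: Sequence[int]) -> BasinMap:
    """Steepest-descent basin assignment for every pattern.

    From each pattern, repeatedly move to the lowest-energy neighbour while
    one is strictly lower; the terminal pattern must be a local minimum
    (an exact energy tie can strand the descent on a non-minimum plateau,
    which raises an error naming the pattern).
    """
    if len(minima) == 0:
        raise ValueError("no local minima")
    minima_set = set(int(m) for m in minima)
    n = ls.n_patterns
    basin = np.full(n, -1, dtype=np.int64)
    for start in range(n):
        if basin[start] >= 0:
            continue
        path = []
        code = start
        while basin[code] < 0:
            path.append(code)
            nxt = _descent_step(ls, code)
            if nxt == code:
                break
            code = nxt
        if basin[code] >= 0:
            terminal = basin[code]
        else:
            if code not in minima_set:
                raise ValueError(
                    f"steepest descent from pattern {start} terminated at "
                    f"pattern {code}, which is not a strict local minimum "
                    "(exact energy tie with a neighbour)"
                )
            terminal = code
        basin[path] = terminal
        basin[code] = terminal
    sizes = {m: float(np.sum(basin == m)) / n for m in sorted(minima_set)}
    return BasinMap(basin_of=basin, basin_sizes=sizes)


def build_disconnectivity_graph(
    ls: EnergyLandscape, minima: Sequence[int]
) -> DisconnectivityTree:
    """Disconnectivity tree of the local minima.

    Implements the descending-threshold procedure: remove patterns with
    energy >= E_th and test which minima remain connected on the hypercube,
    sweeping E_th down through the sorted distinct energy values until all
    minima are isolated.  The merge energy of two minima is the lowest
    level at which they remain connected -- equivalently the minimax
    barrier over connecting paths, which is what the implementation
    computes directly: patterns are inserted in increasing energy order and
    merged with already-inserted neighbours (a Kruskal-style union-find),
    so two minima's groups meet exactly at the saddle pattern of their
    best path.
    """
    if len(minima) == 0:
        raise ValueError("no local minima")
    minima_set = set(int(m) for m in minima)
    n = ls.n_patterns
    order = np.lexsort((np.arange(n), ls.energies))  # energy asc, code tiebreak

    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = int(parent[x])
        return x

    inserted = np.zeros(n, dtype=bool)
    tree_of_root: dict[int, TreeNode] = {}

    for code in order:
        code = int(code)
        inserted[code] = True
        my_root = find(code)
        if code in minima_set:
            tree_of_root[my_root] = TreeNode(energy=float(ls.energies[code]), code=code)
        # union with every inserted neighbour; collect distinct groups
        roots = {my_root}
        for i in range(ls.k):
            nb = code ^ (1 << i)
            if inserted[nb]:
                roots.add(find(nb))
        if len(roots) > 1:
            trees = [tree_of_root.pop(r) for r in roots if r in tree_of_root]
            new_root = my_root
            for r in roots:
                parent[r] = new_root
            parent[new_root] = new_root
            if len(trees) >= 2:
                merged = TreeNode(energy=float(ls.energies[code]), children=trees)
                tree_of_root[find(new_root)] = merged
            elif len(trees) == 1:
                tree_of_root[find(new_root)] = trees[0]

    roots_left = {find(int(m)) for m in minima_set}
    assert len(roots_left) == 1, "hypercube is connected; all minima must merge"
    return DisconnectivityTree(root=tree_of_root[roots_left.pop()], k=ls.k)


def _cut_tree(root: TreeNode, n_groups: int) -> list[list[int]]:
    """Cut the dendrogram below its ``n_groups - 1`` highest merges."""
    frontier = [root]
    while len(frontier) < n_groups:
        internal = [nd for nd in frontier if not nd.is_leaf]
        if not internal:
            break
        top = max(internal, key=lambda nd: nd.energy)
        frontier.remove(top)
        frontier.extend(top.children)
    return [nd.leaves() for nd in frontier]


def define_brain_states(
    tree: DisconnectivityTree,
    basin_map: BasinMap,
    grouping: Mapping[int, str] | None = None,
    n_states: int = 4,
    barrier_gap: float | None = None,
    absorb_unlisted: bool = False,
) -> BrainStatePartition:
    """Label the local minima as major/minor brain states.

    With an explicit ``grouping`` (minimum code -> label) the labels are
    taken as given; grouping keys that are not minima of this landscape
    are ignored, and minima missing from the grouping raise an error
    unless ``absorb_unlisted=True``, in which case each unlisted minimum
    inherits the label of the labelled minimum it merges with at the
    lowest barrier (useful when a fitted landscape adds shallow spurious
    minima to a reference set of labelled ones).

    Without a grouping the disconnectivity tree is cut automatically:
    either below its highest ``n_states - 1`` merges (default, yielding up
    to four groups), or -- when ``barrier_gap`` is given -- by
    single-linkage merging of minima whose barrier above the deeper member
    is below the gap.  Groups are then ranked by summed basin fraction:
    the two largest become the major states, the remainder the minor
    states.  State sizes are the summed basin fractions of the member
    minima.
    """
    minima = sorted(basin_map.basin_sizes)
    if grouping is not None:
        listed = [m for m in minima if m in grouping]
        missing = [m for m in minima if m not in grouping]
        if missing and not absorb_unlisted:
            raise ValueError(f"grouping omits local minima: {missing}")
        if not listed:
            raise ValueError("grouping covers none of the landscape's minima")
        bad = {grouping[m] for m in listed} - set(STATE_LABELS)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        state_of = {int(m): grouping[m] for m in listed}
        for m in missing:
            host = min(listed, key=lambda l: tree.merge_energy(m, l))
            state_of[int(m)] = grouping[host]
        labels = tuple(s for s in STATE_LABELS if s in set(state_of.values()))
    else:
        if barrier_gap is not None:
            groups = _gap_groups(tree, basin_map, barrier_gap)
        else:
            groups = _cut_tree(tree.root, n_states)
        if len(groups) > len(STATE_LABELS):
            raise ValueError(
                f"automatic grouping produced {len(groups)} groups; at most "
                f"{len(STATE_LABELS)} states are supported"
            )
        groups = sorted(
            groups,
            key=lambda g: (-sum(basin_map.basin_sizes[m] for m in g), min(g)),
        )
        state_of = {}
        for label, group in zip(STATE_LABELS, groups):
            for m in group:
                state_of[int(m)] = label
        labels = tuple(STATE_LABELS[: len(groups)])

    sizes = {lab: 0.0 for lab in labels}
    for m in minima:
        sizes[state_of[m]] += basin_map.basin_sizes[m]

    idx_of_label = {lab: i for i, lab in enumerate(labels)}
    min_state_idx = {m: idx_of_label[state_of[m]] for m in minima}
    pattern_state = np.array(
        [min_state_idx[int(b)] for b in basin_map.basin_of], dtype=np.int8
    )
    return BrainStatePartition(
        state_of_minimum=state_of,
        labels=labels,
        pattern_state=pattern_state,
        state_sizes=sizes,
    )


def _gap_groups(
    tree: DisconnectivityTree, basin_map: BasinMap, barrier_gap: float
) -> list[list[int]]:
    """Single-linkage groups of minima with relative barriers < gap."""
    minima = sorted(basin_map.basin_sizes)
    groups = [[m] for m in minima]
    # leaf energies
    leaf_e: dict[int, float] = {}

    def collect(node: TreeNode) -> None:
        if node.is_leaf:
            leaf_e[node.code] = node.energy
        for c in node.children:
            collect(c)

    collect(tree.root)
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                barrier = min(
                    tree.merge_energy(a, b) for a in groups[i] for b in groups[j]
                )
                base = max(
                    min(leaf_e[m] for m in groups[i]),
                    min(leaf_e[m] for m in groups[j]),
                )
                if barrier - base < barrier_gap:
                    groups[i] = groups[i] + groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return groups
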