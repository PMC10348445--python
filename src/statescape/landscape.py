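"""Energy landscape: local minima, attractor basins, disconnectivity tree.

The landscape is the hypercube graph over all ``2**N`` activity patterns
(two patterns adjacent iff they differ at exactly one node) with the MEM
energy attached to each pattern.  Local minima — patterns whose energy is
strictly below all N single-flip neighbours — define the brain states;
every pattern is assigned to the basin of the minimum reached by steepest
descent; the disconnectivity tree records the minimal threshold energies
at which pairs of minima become mutually reachable.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field

import numpy as np

from .mem import MEMParameters, _all_energies
from .patterns import code_to_pattern, neighbor_codes

__all__ = [
    "EnergyLandscape",
    "LocalMinimum",
    "BasinMap",
    "DisconnectivityTree",
    "enumerate_energies",
    "find_local_minima",
    "assign_basins",
    "build_disconnectivity_tree",
]


def _letter_label(rank: int) -> str:
    """a, b, ..., z, aa, ab, ... for minima ranked by ascending energy."""
    letters = string.ascii_lowercase
    label = ""
    rank += 1
    while rank > 0:
        rank, rem = divmod(rank - 1, 26)
        label = letters[rem] + label
    return label


@dataclass
class LocalMinimum:
    """A pattern strictly below all N single-flip neighbours in energy."""

    pattern_code: int
    pattern: np.ndarray
    energy: float
    label: str

    @property
    def state_label(self) -> str:
        """Brain-state label: uppercase of the minimum label (a → A)."""
        return self.label.upper()


@dataclass
class EnergyLandscape:
    """Energies of all ``2**N`` patterns plus cached derived structure."""

    n_nodes: int
    energies: np.ndarray
    params: MEMParameters | None = None
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape[0] != 2**self.n_nodes:
            raise ValueError("energy vector length must be 2**n_nodes")
        if not np.isfinite(self.energies).all():
            raise ValueError("energies must be finite")
        if not self.node_names:
            self.node_names = [f"node{i}" for i in range(self.n_nodes)]
        self._minima: list[LocalMinimum] | None = None
        self._basins: "BasinMap | None" = None
        self._tree: "DisconnectivityTree | None" = None

    def local_minima(self) -> list[LocalMinimum]:
        if self._minima is None:
            self._minima = find_local_minima(self)
        return self._minima

    def basins(self) -> "BasinMap":
        if self._basins is None:
            self._basins = assign_basins(self, self.local_minima())
        return self._basins

    def disconnectivity_tree(self) -> "DisconnectivityTree":
        if self._tree is None:
            self._tree = build_disconnectivity_tree(self, self.local_minima())
        return self._tree

    def to_dict(self, include_energies: bool = False) -> dict:
        basins = self.basins()
        payload = {
            "n_nodes": self.n_nodes,
            "node_names": self.node_names,
            "minima": [
                {
                    "code": m.pattern_code,
                    "pattern": m.pattern.tolist(),
                    "energy": m.energy,
                    "label": m.label,
                }
                for m in self.local_minima()
            ],
            "basin_labels": basins.labels().tolist(),
            "n_ambiguous": int(basins.ambiguous.sum()),
            "tree": self.disconnectivity_tree().to_dict(),
        }
        if include_energies:
            payload["energies"] = self.energies.tolist()
        return payload

    def save(self, path, include_energies: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_energies=include_energies), fh, indent=2)


def enumerate_energies(
    params: MEMParameters, node_names: list[str] | None = None
) -> EnergyLandscape:
    """Energies of every pattern code under the model parameters."""
    energies = _all_energies(params)
    return EnergyLandscape(
        n_nodes=params.n_nodes,
        energies=energies,
        params=params,
        node_names=list(node_names) if node_names else [],
    )


def find_local_minima(landscape: EnergyLandscape) -> list[LocalMinimum]:
    """Exhaustive scan for strict local minima.

    Labels ``a, b, …`` are assigned in ascending-energy order, ties
    broken by pattern code.
    """
    n = landscape.n_nodes
    E = landscape.energies
    nbr = neighbor_codes(n)
    is_min = (E[:, None] < E[nbr]).all(axis=1)
    codes = np.flatnonzero(is_min)
    order = sorted(codes, key=lambda c: (E[c], c))
    return [
        LocalMinimum(
            pattern_code=int(c),
            pattern=code_to_pattern(int(c), n),
            energy=float(E[c]),
            label=_letter_label(rank),
        )
        for rank, c in enumerate(order)
    ]


@dataclass
class BasinMap:
    """Assignment of every pattern to a local minimum's basin.

    ``assignment[k]`` is the index (into ``minima``) of the basin of
    pattern ``k``, or −1 for the rare patterns that have no strictly
    descending neighbour yet are not strict minima (energy plateaus).
    ``ambiguous[k]`` flags saddle-like patterns where two or more
    neighbours tie for the steepest descent; the deterministic
    lowest-code tie-break still assigns them, and callers may choose to
    drop them.
    """

    minima: list[LocalMinimum]
    assignment: np.ndarray  # minimum index per code, -1 = unassigned
    ambiguous: np.ndarray  # bool per code
    descent_rule: str = "steepest-descent, ties to lowest neighbour code"

    def labels(self) -> np.ndarray:
        """Per-code state labels (uppercase); '-' for unassigned."""
        lookup = np.array(
            [m.state_label for m in self.minima] + ["-"], dtype=object
        )
        return lookup[self.assignment]

    @property
    def state_labels(self) -> list[str]:
        return [m.state_label for m in self.minima]

    def basin_sizes(self) -> dict[str, int]:
        sizes = {}
        for i, m in enumerate(self.minima):
            sizes[m.state_label] = int((self.assignment == i).sum())
        return sizes


def assign_basins(
    landscape: EnergyLandscape, minima: list[LocalMinimum] | None = None
) -> BasinMap:
    """Steepest-descent basin assignment of every pattern.

    From each pattern, repeatedly move to the neighbour with the largest
    energy drop (ties broken by lowest neighbour code; equal-energy
    neighbours are non-descending) until a local minimum is reached.
    Processing patterns in ascending-energy order lets each pattern
    inherit the already-computed assignment of its descent target.
    """
    if minima is None:
        minima = landscape.local_minima()
    if not minima:
        raise ValueError("landscape has no local minima")
    n = landscape.n_nodes
    E = landscape.energies
    P = E.shape[0]
    nbr = neighbor_codes(n)
    min_index = {m.pattern_code: i for i, m in enumerate(minima)}

    assignment = np.full(P, -1, dtype=np.int64)
    ambiguous = np.zeros(P, dtype=bool)

    order = np.lexsort((np.arange(P), E))  # ascending energy, then code
    for code in order:
        if code in min_index:
            assignment[code] = min_index[code]
            continue
        neighbors = nbr[code]
        nbrE = E[neighbors]
        best = nbrE.min()
        if best >= E[code]:
            # plateau: not a strict minimum but no strictly lower neighbour
            ambiguous[code] = True
            continue
        ties = neighbors[nbrE == best]
        if ties.shape[0] > 1:
            ambiguous[code] = True  # saddle-like: steepest descent not unique
        target = int(ties.min())
        assignment[code] = assignment[target]
    return BasinMap(minima=minima, assignment=assignment, ambiguous=ambiguous)


@dataclass
class _TreeNode:
    merge_energy: float | None  # None for leaves
    label: str | None  # leaf label
    code: int | None
    energy: float | None
    children: list["_TreeNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        if self.label is not None:
            return {"leaf": self.label, "code": self.code, "energy": self.energy}
        return {
            "merge_energy": self.merge_energy,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class DisconnectivityTree:
    """Hierarchy of local minima by minimal connecting threshold energy.

    Leaves are the local minima; an internal node at height
    ``merge_energy`` joins subtrees whose minima first become mutually
    reachable when patterns with energy up to that value are allowed.
    """

    leaves: list[LocalMinimum]
    root: _TreeNode
    _pair_energy: dict[frozenset, float] = field(default_factory=dict)

    def merge_energy(self, label_a: str, label_b: str) -> float:
        """Threshold energy at which minima a and b first connect."""
        if label_a == label_b:
            raise ValueError("merge energy needs two distinct minima")
        key = frozenset((label_a.lower(), label_b.lower()))
        return self._pair_energy[key]

    def to_dict(self) -> dict:
        return self.root.to_dict()

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-energy heights."""

        def height(node: _TreeNode) -> float:
            return node.energy if node.label is not None else node.merge_energy

        def render(node: _TreeNode, parent_height: float | None) -> str:
            if node.label is not None:
                body = node.label
            else:
                body = "(" + ",".join(
                    render(c, height(node)) for c in node.children
                ) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - height(node):.6g}"

        return render(self.root, None) + ";"


def build_disconnectivity_tree(
    landscape: EnergyLandscape, minima: list[LocalMinimum] | None = None
) -> DisconnectivityTree:
    """Build the disconnectivity tree by ascending-energy percolation.

    Equivalent to the descending-threshold procedure (remove patterns
    above a threshold, check which minima remain connected, lower the
    threshold): inserting patterns in ascending energy into a union–find
    structure and uniting each with its already-inserted neighbours
    discovers, for every pair of minima, the lowest threshold at which a
    connecting path exists.  The merge energy recorded when two
    minima-bearing components unite is the energy of the pattern whose
    insertion merged them.
    """
    if minima is None:
        minima = landscape.local_minima()
    if not minima:
        raise ValueError("landscape has no local minima")
    n = landscape.n_nodes
    E = landscape.energies
    P = E.shape[0]
    nbr = neighbor_codes(n)

    parent = np.arange(P, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    # component root -> subtree over minima (None when no minimum inside)
    subtree: dict[int, _TreeNode] = {}
    leaf_nodes = {
        m.pattern_code: _TreeNode(
            merge_energy=None, label=m.label, code=m.pattern_code, energy=m.energy
        )
        for m in minima
    }
    leaf_sets: dict[int, frozenset] = {}
    pair_energy: dict[frozenset, float] = {}

    inserted = np.zeros(P, dtype=bool)
    order = np.lexsort((np.arange(P), E))
    for code in order:
        code = int(code)
        inserted[code] = True
        if code in leaf_nodes:
            subtree[code] = leaf_nodes[code]
            leaf_sets[code] = frozenset([leaf_nodes[code].label])
        for nb in nbr[code]:
            nb = int(nb)
            if not inserted[nb]:
                continue
            ra, rb = find(code), find(nb)
            if ra == rb:
                continue
            ta, tb = subtree.pop(ra, None), subtree.pop(rb, None)
            sa, sb = leaf_sets.pop(ra, frozenset()), leaf_sets.pop(rb, frozenset())
            parent[ra] = rb
            root = find(rb)
            if ta is not None and tb is not None:
                merged = _TreeNode(
                    merge_energy=float(E[code]),
                    label=None,
                    code=None,
                    energy=None,
                    children=[ta, tb],
                )
                for la in sa:
                    for lb in sb:
                        pair_energy[frozenset((la, lb))] = float(E[code])
                subtree[root] = merged
                leaf_sets[root] = sa | sb
            elif ta is not None or tb is not None:
                subtree[root] = ta if ta is not None else tb
                leaf_sets[root] = sa | sb
        if len(pair_energy) == len(minima) * (len(minima) - 1) // 2:
            if len(subtree) == 1:
                break

    roots = list(subtree.values())
    if len(roots) != 1:  # pragma: no cover - hypercube is connected
        raise RuntimeError("disconnectivity construction did not converge to one tree")
    return DisconnectivityTree(leaves=minima, root=roots[0], _pair_energy=pair_energy)
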