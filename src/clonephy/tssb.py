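"""Tree-structured stick-breaking (TSSB) state: clone-tree topology,
per-sample auxiliary masses eta, and derived population frequencies phi.

Each node represents a subclonal population; ``eta_v`` is the fraction of
cells belonging *exactly* to node v (summing to 1 over the tree per sample),
and the population frequency of v is the mass of its whole subtree::

    phi_v = eta_v + sum_{w in children(v)} phi_w

so phi at the root is always 1 and phi never increases down a root path —
the clonal evolutionary constraint.  Depth sticks ``nu ~ Beta(1, alpha *
lam**depth)`` and branch sticks ``psi ~ Beta(1, gamma)`` define the prior
mass landing on each node; the tree is materialized lazily up to a depth
cap.
"""

from __future__ import annotations

import copy
import json
from typing import Optional

import numpy as np

__all__ = ["TreeNode", "TreeState", "phi_from_eta", "add_node", "prune_empty_nodes"]

MAX_DEPTH = 15


class TreeNode:
    """A subclonal lineage node.

    Attributes
    ----------
    eta : ndarray
        Per-sample mass of cells belonging exactly to this node.
    nu, psi : float
        Depth stick and branch stick of the stick-breaking construction.
    mutations : list of str
        Ids of SSMs and pseudo-SSMs assigned to this node.
    """

    __slots__ = ("id", "parent", "children", "eta", "nu", "psi", "mutations")

    def __init__(self, node_id: int, n_samples: int, parent: Optional["TreeNode"] = None,
                 nu: float = 0.5, psi: float = 0.5):
        self.id = node_id
        self.parent = parent
        self.children: list[TreeNode] = []
        self.eta = np.zeros(n_samples, dtype=float)
        self.nu = nu
        self.psi = psi
        self.mutations: list[str] = []

    @property
    def depth(self) -> int:
        d, u = 0, self
        while u.parent is not None:
            d, u = d + 1, u.parent
        return d

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode(id={self.id}, n_mut={len(self.mutations)})"


class TreeState:
    """Clone tree with TSSB hyperparameters alpha (depth), gamma (width) and
    depth-decay lam; holds per-sample eta on every node."""

    def __init__(self, n_samples: int = 1, alpha: float = 25.0, gamma: float = 1.0,
                 lam: float = 0.25):
        self.n_samples = n_samples
        self.alpha = alpha
        self.gamma = gamma
        self.lam = lam
        self._next_id = 0
        self.root = self._new_node(parent=None)
        self.root.eta[:] = 1.0

    def _new_node(self, parent: Optional[TreeNode]) -> TreeNode:
        node = TreeNode(self._next_id, self.n_samples, parent=parent)
        self._next_id += 1
        return node

    # -- traversal ----------------------------------------------------------

    def nodes(self) -> list[TreeNode]:
        """Depth-first preorder list of all nodes."""
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(u.children))
        return out

    def __len__(self) -> int:
        return len(self.nodes())

    @staticmethod
    def is_ancestor_or_self(anc: TreeNode, node: TreeNode) -> bool:
        u = node
        while u is not None:
            if u is anc:
                return True
            u = u.parent
        return False

    def find(self, node_id: int) -> TreeNode:
        for u in self.nodes():
            if u.id == node_id:
                return u
        raise KeyError(node_id)

    # -- mass bookkeeping ---------------------------------------------------

    def eta_map(self, sample: int) -> dict[TreeNode, float]:
        return {u: float(u.eta[sample]) for u in self.nodes()}

    def check_normalized(self, atol: float = 1e-9) -> None:
        for s in range(self.n_samples):
            total = sum(float(u.eta[s]) for u in self.nodes())
            if abs(total - 1.0) > atol:
                raise RuntimeError(f"eta not normalized in sample {s}: {total}")

    def set_eta_vector(self, sample: int, values: np.ndarray) -> None:
        """Assign eta for all nodes (preorder order) in one sample."""
        nodes = self.nodes()
        if len(values) != len(nodes):
            raise ValueError("eta vector length mismatch")
        for u, v in zip(nodes, values):
            u.eta[sample] = v

    # -- stick weights ------------------------------------------------------

    def node_weights(self) -> tuple[dict[TreeNode, float], dict[TreeNode, float]]:
        """Prior probability mass on each materialized node, plus the
        unallocated mass below each node (candidate region for new children).

        mass(v) = subtree_mass(v) * nu_v; the remainder of a subtree is split
        among children by their psi sticks, with the leftover after all
        children forming the unallocated region of v.
        """
        weights: dict[TreeNode, float] = {}
        rest: dict[TreeNode, float] = {}

        def descend(u: TreeNode, subtree_mass: float) -> None:
            weights[u] = subtree_mass * u.nu
            remaining = subtree_mass * (1.0 - u.nu)
            for child in u.children:
                take = remaining * child.psi
                remaining -= take
                descend(child, take)
            rest[u] = remaining

        descend(self.root, 1.0)
        return weights, rest

    def node_path(self, node: TreeNode) -> tuple[int, ...]:
        """Path of child indices from the root (root = empty tuple)."""
        path: list[int] = []
        u = node
        while u.parent is not None:
            path.append(u.parent.children.index(u))
            u = u.parent
        return tuple(reversed(path))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        phi = {s: phi_from_eta(self, s) for s in range(self.n_samples)}
        return {
            "n_samples": self.n_samples,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "lam": self.lam,
            "nodes": [
                {
                    "id": u.id,
                    "parent": u.parent.id if u.parent else None,
                    "eta": [float(x) for x in u.eta],
                    "phi": [float(phi[s][u]) for s in range(self.n_samples)],
                    "nu": u.nu,
                    "psi": u.psi,
                    "mutations": list(u.mutations),
                }
                for u in self.nodes()
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeState":
        tree = cls(n_samples=payload["n_samples"], alpha=payload["alpha"],
                   gamma=payload["gamma"], lam=payload["lam"])
        specs = payload["nodes"]
        by_id: dict[int, TreeNode] = {}
        root_spec = specs[0]
        tree.root.id = root_spec["id"]
        tree.root.eta = np.array(root_spec["eta"], dtype=float)
        tree.root.nu, tree.root.psi = root_spec["nu"], root_spec["psi"]
        tree.root.mutations = list(root_spec["mutations"])
        by_id[tree.root.id] = tree.root
        for spec in specs[1:]:
            parent = by_id[spec["parent"]]
            node = TreeNode(spec["id"], tree.n_samples, parent=parent,
                            nu=spec["nu"], psi=spec["psi"])
            node.eta = np.array(spec["eta"], dtype=float)
            node.mutations = list(spec["mutations"])
            parent.children.append(node)
            by_id[node.id] = node
        tree._next_id = max(by_id) + 1
        return tree

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_newick(self, sample: int = 0) -> str:
        """Topology with phi as branch annotations, Newick format."""
        phi = phi_from_eta(self, sample)

        def fmt(u: TreeNode) -> str:
            label = f"n{u.id}:{phi[u]:.6g}"
            if not u.children:
                return label
            return "(" + ",".join(fmt(c) for c in u.children) + ")" + label

        return fmt(self.root) + ";"

    def copy(self) -> "TreeState":
        return copy.deepcopy(self)


def phi_from_eta(tree: TreeState, sample: int) -> dict[TreeNode, float]:
    """Population frequency of every node: bottom-up subtree sums of eta."""
    phi: dict[TreeNode, float] = {}

    def descend(u: TreeNode) -> float:
        total = float(u.eta[sample])
        for child in u.children:
            total += descend(child)
        phi[u] = total
        return total

    root_phi = descend(tree.root)
    if abs(root_phi - 1.0) > 1e-6:
        raise RuntimeError(f"eta not normalized (phi_root={root_phi})")
    return phi


def add_node(tree: TreeState, parent: TreeNode, rng: np.random.Generator) -> TreeNode:
    """Create a new child of ``parent``.

    Per sample the child's eta is drawn Uniform(0, eta_parent) and subtracted
    from the parent, preserving the global normalization exactly; the child's
    sticks are drawn from the TSSB priors at its depth.
    """
    node = tree._new_node(parent)
    depth = parent.depth + 1
    if depth > MAX_DEPTH:
        raise RuntimeError(f"maximum tree depth {MAX_DEPTH} exceeded")
    node.nu = float(rng.beta(1.0, max(tree.alpha * tree.lam ** depth, 1e-6)))
    node.psi = float(rng.beta(1.0, tree.gamma))
    for s in range(tree.n_samples):
        draw = float(rng.uniform(0.0, parent.eta[s])) if parent.eta[s] > 0 else 0.0
        node.eta[s] = draw
        parent.eta[s] -= draw
    parent.children.append(node)
    return node


def remove_node(tree: TreeState, node: TreeNode) -> None:
    """Remove a mutation-free leaf, returning its eta to the parent."""
    if node.children or node.parent is None:
        raise ValueError("only non-root leaves can be removed")
    if node.mutations:
        raise ValueError("node still holds mutations")
    node.parent.eta += node.eta
    node.parent.children.remove(node)
    node.parent = None


def prune_empty_nodes(tree: TreeState) -> TreeState:
    """Reporting view: repeatedly strip mutation-free leaves (never the
    root), folding their eta back into the parent.  Empty internal nodes
    with non-empty descendants are retained."""
    pruned = tree.copy()
    changed = True
    while changed:
        changed = False
        for u in pruned.nodes():
            if u.parent is not None and not u.children and not u.mutations:
                remove_node(pruned, u)
                changed = True
    return pruned
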