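"""Structure trees and ordered tree edit distance.

Secondary structures are compared as rooted ordered trees, the convention of
the classic RNA structure-distance tools. In the *full* representation every
base pair is an internal node (label ``P``) whose children are the elements
it encloses in 5'->3' order, every unpaired position is a leaf (``U``), and a
virtual root (``R``) holds the exterior elements. The optional *coarse*
representation collapses helices to stem nodes (``S``) and labels loops by
type (hairpin ``H``, bulge ``B``, internal ``I``, multiloop ``M``, exterior
``E``).

Distances are exact ordered-tree edit distances (Zhang-Shasha dynamic
program) with unit insert/delete/relabel costs: the score is 0 iff the trees
are identical, symmetric, and satisfies the triangle inequality. Lower score
means more similar structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SecondaryStructure

__all__ = ["TreeNode", "StructureTree", "to_tree", "tree_edit_distance"]


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def __repr__(self) -> str:  # compact bracket form, e.g. R(P(U U U))
        if not self.children:
            return self.label
        return f"{self.label}({' '.join(repr(c) for c in self.children)})"


@dataclass(frozen=True)
class StructureTree:
    root: TreeNode
    representation: str  # "full" | "coarse"

    def size(self) -> int:
        return self.root.size()


def _full_tree(structure: SecondaryStructure) -> TreeNode:
    table = structure.pair_table

    def build(lo: int, hi: int) -> list[TreeNode]:
        nodes, p = [], lo
        while p <= hi:
            q = table.get(p)
            if q is not None and q > p:
                node = TreeNode("P", build(p + 1, q - 1))
                nodes.append(node)
                p = q + 1
            else:
                nodes.append(TreeNode("U"))
                p += 1
        return nodes

    return TreeNode("R", build(1, structure.length))


def _coarse_tree(structure: SecondaryStructure) -> TreeNode:
    """Loop-level tree: stems become S nodes, loops typed H/B/I/M, root E."""
    table = structure.pair_table

    def children_pairs(lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, p = [], 0, lo
        while p <= hi:
            q = table.get(p)
            if q is not None and q > p:
                kids.append((p, q))
                p = q + 1
            else:
                unpaired += 1
                p += 1
        return kids, unpaired

    def build_stem(i: int, j: int) -> TreeNode:
        length = 1
        while table.get(i + 1) == j - 1:  # strictly stacked run
            i, j = i + 1, j - 1
            length += 1
        kids, unpaired = children_pairs(i + 1, j - 1)
        if not kids:
            loop = TreeNode("H")
        elif len(kids) == 1:
            (k, l) = kids[0]
            one_sided = (k == i + 1) or (l == j - 1)
            loop = TreeNode("B" if one_sided else "I", [build_stem(k, l)])
        else:
            loop = TreeNode("M", [build_stem(k, l) for k, l in kids])
        stem = TreeNode(f"S{length}", [loop])
        return stem

    kids, _ = children_pairs(1, structure.length)
    return TreeNode("E", [build_stem(i, j) for i, j in kids])


def to_tree(structure: SecondaryStructure, representation: str = "full") -> StructureTree:
    """Deterministic tree encoding of a structure."""
    if representation == "full":
        return StructureTree(_full_tree(structure), "full")
    if representation == "coarse":
        return StructureTree(_coarse_tree(structure), "coarse")
    raise ValueError(f"unknown representation {representation!r}")


# ---------------------------------------------------------------------------
# Zhang-Shasha ordered tree edit distance, unit costs

def _postorder(root: TreeNode):
    """Post-order labels and leftmost-leaf indices (1-based), plus keyroots."""
    labels: list[str] = []
    lml: list[int] = []  # leftmost leaf descendant, 1-based postorder index

    def walk(node: TreeNode) -> int:
        if not node.children:
            labels.append(node.label)
            lml.append(len(labels))
            return len(labels)
        first = None
        for c in node.children:
            idx = walk(c)
            if first is None:
                first = lml[idx - 1]
        labels.append(node.label)
        lml.append(first)
        return len(labels)

    walk(root)
    n = len(labels)
    keyroots = [i for i in range(1, n + 1) if not any(lml[k - 1] == lml[i - 1] for k in range(i + 1, n + 1))]
    return labels, lml, keyroots


def tree_edit_distance(t1: StructureTree, t2: StructureTree) -> int:
    """Exact edit distance (insert/delete/relabel, unit costs) between ordered
    trees. Raises ``ValueError`` if the representations differ."""
    if t1.representation != t2.representation:
        raise ValueError(
            f"representation mismatch: {t1.representation} vs {t2.representation}"
        )
    l1, lml1, kr1 = _postorder(t1.root)
    l2, lml2, kr2 = _postorder(t2.root)
    n1, n2 = len(l1), len(l2)
    td = [[0] * (n2 + 1) for _ in range(n1 + 1)]

    for i in kr1:
        for j in kr2:
            li, lj = lml1[i - 1], lml2[j - 1]
            m, n = i - li + 2, j - lj + 2
            fd = [[0] * n for _ in range(m)]
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + 1
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + 1
            for x in range(1, m):
                for y in range(1, n):
                    a, b = li + x - 1, lj + y - 1
                    if lml1[a - 1] == li and lml2[b - 1] == lj:
                        cost = 0 if l1[a - 1] == l2[b - 1] else 1
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[x - 1][y - 1] + cost,
                        )
                        td[a][b] = fd[x][y]
                    else:
                        p, q = lml1[a - 1] - li, lml2[b - 1] - lj
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[p][q] + td[a][b],
                        )
    return td[n1][n2]
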