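"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the folding
oracle enumerates every nested structure and scores each by loop-decomposition
energy evaluation; the tree-edit oracle is the textbook exponential forest
recursion; structure sampling is direct recursive generation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from reifold.fold_engine import evaluate_energy, pair_code
from reifold.seqio import RnaSequence, SecondaryStructure
from reifold.structure_compare import StructureTree, TreeNode

BASES = "ACGU"


def all_structures(seq, constraints=None, min_hairpin=3):
    """Every pseudoknot-free structure of ``seq`` (as frozensets of pairs)."""
    n = len(seq)
    ok = set()
    for i in range(1, n + 1):
        for j in range(i + min_hairpin + 1, n + 1):
            if pair_code(seq.base(i), seq.base(j)) >= 0 and (
                constraints is None or constraints.allows(i, j)
            ):
                ok.add((i, j))

    @lru_cache(maxsize=None)
    def gen(i, j):
        if i > j:
            return [frozenset()]
        out = list(gen(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if (i, k) in ok:
                for a in gen(i + 1, k - 1):
                    for b in gen(k + 1, j):
                        out.append(a | b | {(i, k)})
        return out

    return gen(1, n)


def oracle_mfe(seq, model, constraints=None):
    """Minimum energy over exhaustive enumeration (includes the open chain).

    When constraints carry forced pairs / forced-unpaired positions, the
    enumeration is filtered to structures satisfying them.
    """
    best_e, best_s = 0.0, frozenset()
    forced = constraints.forced_pairs if constraints is not None else frozenset()
    must_have = set(forced)
    if must_have:
        best_e = None
    for pairs in all_structures(seq, constraints, model.min_hairpin):
        if must_have and not must_have <= pairs:
            continue
        e = evaluate_energy(seq, SecondaryStructure(len(seq), pairs), model)
        if best_e is None or e < best_e:
            best_e, best_s = e, pairs
    return best_e, best_s


def random_sequence(rng: np.random.Generator, n: int, p=None) -> RnaSequence:
    return RnaSequence("rnd", "".join(rng.choice(list(BASES), size=n, p=p)))


def random_structure(rng: np.random.Generator, n: int, density=0.6) -> SecondaryStructure:
    """Sample a random valid nested structure by recursive construction."""

    def build(i, j):
        pairs = set()
        while i <= j:
            if j - i >= 4 and rng.random() < density:
                k = int(rng.integers(i + 4, j + 1))
                pairs.add((i, k))
                pairs |= build(i + 1, k - 1)
                i = k + 1
            else:
                i += 1
        return pairs

    return SecondaryStructure(n, frozenset(build(1, n)))


def random_tree(rng: np.random.Generator, n_nodes: int, labels=("P", "U", "X")) -> StructureTree:
    """A random rooted ordered tree with exactly ``n_nodes`` nodes."""
    nodes = [TreeNode(str(rng.choice(list(labels))))]
    for _ in range(n_nodes - 1):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        child = TreeNode(str(rng.choice(list(labels))))
        parent.children.append(child)
        nodes.append(child)
    return StructureTree(nodes[0], "full")


def _freeze(node: TreeNode):
    return (node.label, tuple(_freeze(c) for c in node.children))


def brute_force_tree_distance(t1: StructureTree, t2: StructureTree) -> int:
    """Exponential forest edit recursion (delete / insert / match roots)."""

    @lru_cache(maxsize=None)
    def ed(f1, f2):
        if not f1 and not f2:
            return 0
        best = None
        if f1:
            label, kids = f1[0]
            cand = 1 + ed(kids + f1[1:], f2)
            best = cand if best is None else min(best, cand)
        if f2:
            label, kids = f2[0]
            cand = 1 + ed(f1, kids + f2[1:])
            best = cand if best is None else min(best, cand)
        if f1 and f2:
            (l1, k1), (l2, k2) = f1[0], f2[0]
            cand = (l1 != l2) + ed(k1, k2) + ed(f1[1:], f2[1:])
            best = cand if best is None else min(best, cand)
        return best

    return ed((_freeze(t1.root),), (_freeze(t2.root),))
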