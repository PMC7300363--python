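"""Independent oracles shared across tests.

Everything here is deliberately implemented by a different route from the
package code it checks: exhaustive enumeration for likelihoods and
posteriors, hand-rolled union-find for graph components, and Hamming
identity for equal-length sequences.
"""

from __future__ import annotations

import itertools

import numpy as np

from magevo.io_core import AnnotatedTree, TreeNode
from magevo.gene_content_asr import transition_matrix


def random_tree(rng: np.random.Generator, n_tips: int,
                min_len: float = 0.05, max_len: float = 1.5) -> AnnotatedTree:
    """Random rooted binary topology by repeated random tip splitting."""
    root = TreeNode("")
    tips = [root.add_child(TreeNode("")), root.add_child(TreeNode(""))]
    while len(tips) < n_tips:
        node = tips.pop(rng.integers(len(tips)))
        tips.append(node.add_child(TreeNode("")))
        tips.append(node.add_child(TreeNode("")))
    counter = 0

    def label(node: TreeNode) -> None:
        nonlocal counter
        if not node.children:
            counter += 1
            node.label = f"t{counter}"
        for child in node.children:
            label(child)

    label(root)
    tree = AnnotatedTree(root)
    for node in tree.preorder():
        if node.parent is not None:
            node.length = float(rng.uniform(min_len, max_len))
    return tree


def enumeration_loglik(tree, matrix, model) -> np.ndarray:
    """Per-OG log-likelihood by brute-force summation over every internal
    state assignment."""
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_tip]
    prior = model.root_prior
    mats = {id(n): transition_matrix(model.rates, n.length)
            for n in nodes if n.parent is not None}
    out = []
    for og in matrix.og_ids:
        obs = {lab: int(matrix.frame.loc[lab, og]) for lab in matrix.taxon_ids}
        total = 0.0
        for assign in itertools.product([0, 1], repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            for t in tree.tips():
                states[id(t)] = obs[t.label]
            p = prior[states[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                p *= mats[id(n)][states[id(n.parent)], states[id(n)]]
            total += p
        out.append(np.log(total) if total > 0 else -np.inf)
    return np.array(out)


def enumeration_marginal(tree, matrix, model, node_label: str) -> np.ndarray:
    """Per-OG posterior P(state=1 at node) by brute-force summation."""
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_tip]
    prior = model.root_prior
    mats = {id(n): transition_matrix(model.rates, n.length)
            for n in nodes if n.parent is not None}
    target = tree.node(node_label)
    out = []
    for og in matrix.og_ids:
        obs = {lab: int(matrix.frame.loc[lab, og]) for lab in matrix.taxon_ids}
        num = den = 0.0
        for assign in itertools.product([0, 1], repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            for t in tree.tips():
                states[id(t)] = obs[t.label]
            p = prior[states[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                p *= mats[id(n)][states[id(n.parent)], states[id(n)]]
            den += p
            if states[id(target)] == 1:
                num += p
        out.append(num / den)
    return np.array(out)


class UnionFind:
    """Independent component oracle for the RBH graph."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def hamming_identity(a: str, b: str) -> float:
    """Identity over the shorter sequence for equal-length, gap-free pairs."""
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / min(len(a), len(b))


def greedy_cluster_oracle(records, threshold, identity_fn):
    """Brute-force re-statement of the greedy incremental clustering rule."""
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps = []
    membership = {}
    for rec in ordered:
        for rep in reps:
            if identity_fn(rec.residues, rep.residues) >= threshold:
                membership[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            membership[rec.id] = rec.id
    return membership
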