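"""Ancestral state reconstruction and implicit-parsimony indel counting.

For every column the most likely state (A, C, G, T or gap) is assigned to
each node from its marginal posterior (an up-down pass; a joint max-product
reconstruction is available behind a flag).  Along every branch, a
parent-gap/child-residue pair counts one insertion site and the opposite
pair one deletion site; a deletion spanning n columns therefore contributes
n deletion sites.  The deletion/insertion length ratio (D/I) aggregated over
all families is the weighting used by the per-site indel scaling test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GAP, AlignmentSet, PhyloTree
from .likelihood import (LEAF_PARTIAL_TABLE, ModelContext, branch_matrices,
                         leaf_code_matrix, model_context, upward_pass)

logger = logging.getLogger("indelphase")


@dataclass
class EventCounts:
    insertions: int = 0
    deletions: int = 0
    per_branch: dict = field(default_factory=dict)  # (family, branch) -> [ins, del]

    @property
    def di_ratio(self) -> float | None:
        """Deletion/insertion length ratio; None when no insertions."""
        if self.insertions == 0:
            return None
        return self.deletions / self.insertions

    def add(self, family_id: str, branch: str, ins: int, dels: int) -> None:
        key = (family_id, branch)
        rec = self.per_branch.setdefault(key, [0, 0])
        rec[0] += ins
        rec[1] += dels
        self.insertions += ins
        self.deletions += dels

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tbranch\tinsertion_sites\tdeletion_sites\n")
            for (fam, br), (i, d) in sorted(self.per_branch.items()):
                fh.write(f"{fam}\t{br}\t{i}\t{d}\n")


def marginal_posteriors(tree: PhyloTree, codes: np.ndarray, ctx: ModelContext,
                        p_branch: np.ndarray | None = None) -> np.ndarray:
    """(n_nodes, n_cols, 5) marginal posterior state probabilities given the
    whole column, via the up-down algorithm with the model's root prior."""
    if p_branch is None:
        p_branch = branch_matrices(tree, ctx.q)
    root, _, partials, messages = upward_pass(tree, codes, p_branch,
                                              keep_all=True)
    n_cols = codes.shape[1]
    out: list = [None] * tree.n_nodes
    out[0] = np.broadcast_to(ctx.root_weights, (n_cols, 5))
    post = np.empty((tree.n_nodes, n_cols, 5))
    for node in tree.preorder:
        for child in tree.children[node]:
            above = out[node]
            for sib in tree.children[node]:
                if sib != child:
                    above = above * messages[sib]
            o = above @ p_branch[child]
            scale = np.maximum(o.max(axis=1), 1e-300)
            out[child] = o / scale[:, None]
        joint = partials[node] * out[node]
        total = np.maximum(joint.sum(axis=1), 1e-300)
        post[node] = joint / total[:, None]
    return post


def marginal_reconstruction(tree: PhyloTree, codes: np.ndarray,
                            model_or_ctx,
                            p_branch: np.ndarray | None = None) -> np.ndarray:
    """(n_nodes, n_cols) most-likely states; ties resolve toward residues in
    alphabetical order (argmax over the fixed A,C,G,T,- state order)."""
    ctx = (model_or_ctx if isinstance(model_or_ctx, ModelContext)
           else model_context(model_or_ctx))
    post = marginal_posteriors(tree, codes, ctx, p_branch)
    return post.argmax(axis=2).astype(np.int8)


def joint_reconstruction(tree: PhyloTree, codes: np.ndarray, model_or_ctx,
                         p_branch: np.ndarray | None = None) -> np.ndarray:
    """Jointly most probable state assignment (max-product with traceback)."""
    ctx = (model_or_ctx if isinstance(model_or_ctx, ModelContext)
           else model_context(model_or_ctx))
    if p_branch is None:
        p_branch = branch_matrices(tree, ctx.q)
    n_cols = codes.shape[1]
    best: list = [None] * tree.n_nodes
    back: list = [None] * tree.n_nodes
    for node in tree.postorder:
        if tree.is_leaf(node):
            m = LEAF_PARTIAL_TABLE[codes[node]].copy()
        else:
            m = np.ones((n_cols, 5))
            for child in tree.children[node]:
                # cand[m, i, q] = P(q|i) * best_child(q)
                cand = p_branch[child][None, :, :] * best[child][:, None, :]
                back[child] = cand.argmax(axis=2).astype(np.int8)
                m = m * cand.max(axis=2)
            scale = np.maximum(m.max(axis=1), 1e-300)
            m = m / scale[:, None]
        best[node] = m
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int8)
    states[0] = (best[0] * ctx.root_weights).argmax(axis=1)
    for node in tree.preorder:
        for child in tree.children[node]:
            states[child] = np.take_along_axis(
                back[child], states[node][:, None], axis=1)[:, 0]
    return states


def subtree_reconstruction(tree: PhyloTree, codes: np.ndarray, model_or_ctx,
                           p_branch: np.ndarray | None = None) -> np.ndarray:
    """States with maximal subtree (upward) conditional likelihood per node,
    ignoring the context above the node.

    This is the reading of picking states "by likelihood value" during the
    upward recursion.  Unlike the marginal posterior it lets ancestral gaps
    propagate upward whenever a gap state explains the subtree best locally —
    which is what makes gap-as-fifth-character models infer spurious
    insertions on deletion-biased data.
    """
    ctx = (model_or_ctx if isinstance(model_or_ctx, ModelContext)
           else model_context(model_or_ctx))
    if p_branch is None:
        p_branch = branch_matrices(tree, ctx.q)
    _, _, partials, _ = upward_pass(tree, codes, p_branch, keep_all=True)
    return np.stack([p.argmax(axis=1) for p in partials]).astype(np.int8)


def branch_label(tree: PhyloTree, child: int) -> str:
    return tree.labels[child] if tree.is_leaf(child) else f"node{child}"


def count_indel_events(aset: AlignmentSet, model,
                       method: str = "marginal") -> EventCounts:
    """Count insertion/deletion sites over all branches, columns and
    families from per-node most-likely states."""
    recon = {"marginal": marginal_reconstruction,
             "joint": joint_reconstruction,
             "subtree": subtree_reconstruction}.get(method)
    if recon is None:
        raise ValueError(f"unknown reconstruction method {method!r}")
    ctx = model_context(model)
    counts = EventCounts()
    for aln, tree in aset:
        codes = leaf_code_matrix(tree, aln, ctx.gap_as_missing)
        p_branch = branch_matrices(tree, ctx.q)
        states = recon(tree, codes, ctx, p_branch)
        for child in range(1, tree.n_nodes):
            parent = tree.parent[child]
            ins = int(np.sum((states[parent] == GAP) & (states[child] != GAP)))
            dels = int(np.sum((states[parent] != GAP) & (states[child] == GAP)))
            counts.add(aln.family_id, branch_label(tree, child), ins, dels)
    if counts.insertions == 0:
        logger.warning("no insertion events inferred; D/I ratio undefined")
    return counts
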