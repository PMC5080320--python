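"""Forward simulator of alignment sets under the gap-extended models.

Columns evolve independently: the ancestral state of each column is a
residue ``a`` with probability ``p * pi_a`` or absent (gap) with probability
``1 - p``, and every branch applies the model's finite-time conditional
matrix.  All-gap columns are unobservable in real alignments and are dropped
before emission (counts kept in the truth record).

An optional geometric indel-tract mode extends each sampled indel event over
neighbouring columns.  That input violates the per-column independence the
models assume and exists only to reproduce the rate inflation caused by long
indel tracts; it is never the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ALPHABET, GAP, Alignment, AlignmentSet, PhyloTree
from .likelihood import branch_matrices, model_context
from .models import IndelModel

__all__ = ["SimConfig", "TruthRecord", "simulate_family", "make_benchmark_set",
           "balanced_tree", "random_tree"]


# ---------------------------------------------------------------------------
# trees for benchmarks
# ---------------------------------------------------------------------------

def balanced_tree(n_taxa: int, branch_length: float) -> PhyloTree:
    """Balanced-as-possible binary tree with equal branch lengths and leaves
    labeled t1..tn."""
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    parent = [-1]
    lengths = [0.0]
    labels: list = [None]
    counter = iter(range(1, n_taxa + 1))

    def build(node: int, n: int) -> None:
        if n == 1:
            labels[node] = f"t{next(counter)}"
            return
        for size in (n - n // 2, n // 2):
            parent.append(node)
            lengths.append(branch_length)
            labels.append(None)
            build(len(parent) - 1, size)

    build(0, n_taxa)
    # preorder builds children after parents but out of index order; reorder
    order = _preorder_indices(parent)
    return _reindex(parent, lengths, labels, order)


def random_tree(n_taxa: int, rng: np.random.Generator,
                mean_branch: float = 0.1) -> PhyloTree:
    """Random topology by sequential attachment with exponential branch
    lengths (a cheap stand-in for a birth process)."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    parent = [-1, 0, 0]
    lengths = [0.0] + list(rng.exponential(mean_branch, 2))
    labels: list = [None, "t1", "t2"]
    leaves = [1, 2]
    for i in range(3, n_taxa + 1):
        target = leaves[rng.integers(len(leaves))]
        # split the target leaf into an internal node with two leaf children
        new_internal = target
        labels_target = labels[target]
        labels[new_internal] = None
        for lab in (labels_target, f"t{i}"):
            parent.append(new_internal)
            lengths.append(float(rng.exponential(mean_branch)))
            labels.append(lab)
        leaves.remove(target)
        leaves.extend([len(parent) - 2, len(parent) - 1])
    order = _preorder_indices(parent)
    return _reindex(parent, lengths, labels, order)


def _preorder_indices(parent: list) -> list:
    children: dict[int, list] = {}
    for i, p in enumerate(parent):
        children.setdefault(p, []).append(i)
    order = []
    stack = [0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children.get(node, [])))
    return order


def _reindex(parent, lengths, labels, order) -> PhyloTree:
    pos = {old: new for new, old in enumerate(order)}
    new_parent = [-1 if parent[o] == -1 else pos[parent[o]] for o in order]
    return PhyloTree(np.array(new_parent),
                     np.array([lengths[o] for o in order]),
                     [labels[o] for o in order])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Complete per-column state history of one simulated family."""

    family_id: str
    tree_newick: str
    params: dict
    node_states: np.ndarray  # (n_nodes, n_cols) after all-gap dropping
    n_dropped_allgap: int
    seed: int | None = None

    def branch_events(self, tree: PhyloTree) -> dict:
        """True per-branch (insertion, deletion, substitution) site counts."""
        out = {}
        s = self.node_states
        for child in range(1, tree.n_nodes):
            par = tree.parent[child]
            ins = int(np.sum((s[par] == GAP) & (s[child] != GAP)))
            dels = int(np.sum((s[par] != GAP) & (s[child] == GAP)))
            subs = int(np.sum((s[par] != GAP) & (s[child] != GAP)
                              & (s[par] != s[child])))
            out[child] = (ins, dels, subs)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_id": self.family_id,
            "tree": self.tree_newick,
            "params": self.params,
            "n_dropped_allgap": self.n_dropped_allgap,
            "seed": self.seed,
            "node_states": ["".join(ALPHABET[c] for c in row)
                            for row in self.node_states],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        lut = {ch: i for i, ch in enumerate(ALPHABET)}
        states = np.array([[lut[ch] for ch in row] for row in d["node_states"]],
                          dtype=np.int8)
        return cls(d["family_id"], d["tree"], d["params"], states,
                   d["n_dropped_allgap"], d.get("seed"))


def _draw_categorical(rng, cum: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """One draw per column from the categorical rows ``cum[rows[i]]``."""
    u = rng.random(rows.shape[0])
    return (u[:, None] > cum[rows]).sum(axis=1).astype(np.int8)


def simulate_family(tree: PhyloTree, model: IndelModel, n_columns: int,
                    seed, family_id: str = "fam0",
                    tract_mean: float | None = None,
                    keep_allgap: bool = False) -> tuple[Alignment, TruthRecord]:
    """Simulate one family; returns the emitted alignment and full truth."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ctx = model_context(model)
    p_branch = branch_matrices(tree, ctx.q)
    states = np.empty((tree.n_nodes, n_columns), dtype=np.int8)
    root_cum = ctx.root_weights.cumsum()
    u = rng.random(n_columns)
    states[0] = (u[:, None] > root_cum[None, :]).sum(axis=1)
    for node in range(1, tree.n_nodes):
        cum = p_branch[node].cumsum(axis=1)
        states[node] = _draw_categorical(rng, cum, states[tree.parent[node]])
        if tract_mean is not None and tract_mean > 1.0:
            _extend_tracts(states, tree, node, rng, tract_mean, model)
    leaf_ids = tree.leaves
    leaf_states = states[leaf_ids]
    keep = ~np.all(leaf_states == GAP, axis=0)
    n_dropped = int((~keep).sum())
    if keep_allgap:
        keep = np.ones(n_columns, dtype=bool)
        n_dropped = 0
    states = states[:, keep]
    aln = Alignment(family_id, [tree.labels[i] for i in leaf_ids],
                    states[leaf_ids], n_dropped)
    params = {"lambda": model.lam, "mu": model.mu, "alpha": model.f84.alpha,
              "beta": model.f84.beta, "p": model.p,
              "pi": [float(x) for x in model.f84.pi],
              "tract_mean": tract_mean}
    truth = TruthRecord(family_id, tree.newick(), params, states, n_dropped,
                        seed if isinstance(seed, int) else None)
    return aln, truth


def _extend_tracts(states, tree, node, rng, tract_mean, model) -> None:
    """Model-violating tract mode: each fresh indel event on this branch is
    extended rightwards with geometric length (mean ``tract_mean``)."""
    par = states[tree.parent[node]]
    child = states[node]
    n_cols = states.shape[1]
    new_del = np.flatnonzero((par != GAP) & (child == GAP))
    new_ins = np.flatnonzero((par == GAP) & (child != GAP))
    pi_cum = model.f84.pi.cumsum()
    for starts, is_del in ((new_del, True), (new_ins, False)):
        if starts.size == 0:
            continue
        extra = rng.geometric(1.0 / tract_mean, starts.size) - 1
        for c, e in zip(starts, extra):
            stop = min(c + 1 + e, n_cols)
            if is_del:
                states[node, c + 1:stop] = GAP
            else:
                k = stop - (c + 1)
                if k > 0:
                    u = rng.random(k)
                    states[node, c + 1:stop] = (
                        u[:, None] > pi_cum[None, :]).sum(axis=1)


# ---------------------------------------------------------------------------
# benchmark bundles
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    model: IndelModel
    n_families: int
    n_columns: int
    seed: int
    tree: PhyloTree | None = None
    n_taxa: int = 10
    branch_length: float = 0.1
    tract_mean: float | None = None
    shared_tree: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def make_benchmark_set(config: SimConfig, out_dir: str | Path | None = None
                       ) -> tuple[AlignmentSet, list[TruthRecord]]:
    """Deterministic multi-family benchmark; optionally writes
    FASTA + Newick + truth JSON per family."""
    master = np.random.SeedSequence(config.seed)
    family_seeds = master.spawn(config.n_families + 1)
    tree_rng = np.random.default_rng(family_seeds[-1])
    base_tree = config.tree or balanced_tree(config.n_taxa, config.branch_length)
    families = []
    truths = []
    for i in range(config.n_families):
        tree = (base_tree if config.shared_tree
                else random_tree(config.n_taxa, tree_rng, config.branch_length))
        rng = np.random.default_rng(family_seeds[i])
        aln, truth = simulate_family(tree, config.model, config.n_columns,
                                     rng, family_id=f"fam{i:04d}",
                                     tract_mean=config.tract_mean)
        families.append((aln, tree))
        truths.append(truth)
    aset = AlignmentSet(families)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (aln, tree), truth in zip(aset, truths):
            aln.to_fasta(out / f"{aln.family_id}.fa")
            (out / f"{aln.family_id}.nwk").write_text(tree.newick() + "\n")
            truth.to_json(out / f"{aln.family_id}.truth.json")
    return aset, truths
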