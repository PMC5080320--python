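"""Pruning over the gap-extended alphabet with the ancestral-length prior.

The recursion treats the gap as an observed fifth state: a leaf gap
contributes an indicator on the gap state (not missing data), and inner-node
partials sum over residues *and* the gap, so recurrent insertions in one
column are allowed.  Each column likelihood carries a root prior of
``p * pi_a`` for an ancestral residue and ``1 - p`` for no ancestral residue
(the geometric length convention ``P(L = l) = (1 - p) p^l``).

Dataset likelihoods come in two modes: ``site_test`` is the plain sum of
column log-likelihoods (what the per-site LRTs use); ``fit`` additionally
adds one geometric termination term ``log(1 - p)`` per alignment and
conditions every column on being observable (not all-gap at the leaves),
which marginalizes ancestral residues that left no trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GAP, UNKNOWN, Alignment, AlignmentSet, PhyloTree
from .models import (F84Params, HKYGParams, IndelModel, build_f84_rate_matrix,
                     build_f84e_rate_matrix, build_hkyg_rate_matrix,
                     conditional_matrix)

logger = logging.getLogger("indelphase")

#: leaf partial vectors by symbol code (A, C, G, T, gap, unknown)
LEAF_PARTIAL_TABLE = np.array([
    [1., 0., 0., 0., 0.],
    [0., 1., 0., 0., 0.],
    [0., 0., 1., 0., 0.],
    [0., 0., 0., 1., 0.],
    [0., 0., 0., 0., 1.],
    [1., 1., 1., 1., 0.],  # unknown residue: never a gap
])

_SCALE_FLOOR = 1e-300


def leaf_partials(symbol) -> np.ndarray:
    """5-vector of conditional likelihoods for one observed leaf symbol."""
    if isinstance(symbol, str):
        from .io import SYMBOL_CODES
        code = SYMBOL_CODES.get(symbol.upper())
        if code is None:
            raise ValueError(f"unmapped symbol {symbol!r}")
    else:
        code = int(symbol)
        if not 0 <= code <= UNKNOWN:
            raise ValueError(f"unmapped symbol code {code}")
    return LEAF_PARTIAL_TABLE[code].copy()


@dataclass
class ModelContext:
    """Everything the engine needs: generator, root weights, and whether
    leaf gaps are treated as missing data (4-state F84 mode)."""

    q: np.ndarray
    root_weights: np.ndarray
    gap_as_missing: bool
    model: object


def model_context(model) -> ModelContext:
    if isinstance(model, IndelModel):
        w = np.empty(5)
        w[:4] = model.p * model.f84.pi
        w[GAP] = 1.0 - model.p
        return ModelContext(build_f84e_rate_matrix(model), w, False, model)
    if isinstance(model, HKYGParams):
        return ModelContext(build_hkyg_rate_matrix(model), model.pi5.copy(),
                            False, model)
    if isinstance(model, F84Params):
        q = np.zeros((5, 5))
        q[:4, :4] = build_f84_rate_matrix(model)
        w = np.concatenate([model.pi, [0.0]])
        return ModelContext(q, w, True, model)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def leaf_code_matrix(tree: PhyloTree, aln: Alignment,
                     gap_as_missing: bool = False) -> np.ndarray:
    """(n_nodes, n_cols) int8 matrix of leaf symbol codes in tree node order;
    internal-node rows are filled with the unknown code and unused."""
    by_name = {n: i for i, n in enumerate(aln.names)}
    codes = np.full((tree.n_nodes, aln.n_cols), UNKNOWN, dtype=np.int8)
    for node in tree.leaves:
        label = tree.labels[node]
        if label not in by_name:
            raise ValueError(
                f"{aln.family_id}: tree leaf {label!r} missing from alignment")
        codes[node] = aln.data[by_name[label]]
    if gap_as_missing:
        codes = np.where(codes == GAP, UNKNOWN, codes)
    return codes


def branch_matrices(tree: PhyloTree, q: np.ndarray) -> np.ndarray:
    """(n_nodes, 5, 5) stack of exp(Q t_i) for the branch above each node
    (identity at the root); repeated branch lengths share one exponential."""
    out = np.empty((tree.n_nodes, 5, 5))
    cache: dict[float, np.ndarray] = {}
    out[0] = np.eye(5)
    for i in range(1, tree.n_nodes):
        t = float(tree.lengths[i])
        if t not in cache:
            cache[t] = conditional_matrix(q, t)
        out[i] = cache[t]
    return out


def _child_message(partial: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Message to the parent: m(i) = sum_q partial(q) P(q|i,t).

    ``p`` may be one (5, 5) matrix shared by all columns or a per-column
    (n_cols, 5, 5) stack.
    """
    if p.ndim == 2:
        return partial @ p.T
    return np.einsum("mq,miq->mi", partial, p)


def _row_max(a: np.ndarray) -> np.ndarray:
    # a.max(axis=1) is surprisingly slow for a short trailing axis
    m = np.maximum(a[:, 0], a[:, 1])
    for i in range(2, a.shape[1]):
        m = np.maximum(m, a[:, i])
    return m


def upward_pass(tree: PhyloTree, codes: np.ndarray, p_branch: np.ndarray,
                keep_all: bool = False, leaf_parts: list | None = None):
    """Pruning pass over all columns at once.

    Returns ``(root_partial, logscale)`` — and, with ``keep_all``, the per-node
    partial and message arrays needed by the downward (marginal) pass.
    Partials are rescaled (log factors accumulated in ``logscale``) whenever
    underflow threatens, so results match unscaled arithmetic exactly.
    ``leaf_parts`` may supply precomputed leaf partial arrays keyed by node.
    """
    n_cols = codes.shape[1]
    partials: list = [None] * tree.n_nodes
    messages: list = [None] * tree.n_nodes
    logscale = np.zeros(n_cols)
    for node in tree.postorder:
        if tree.is_leaf(node):
            if leaf_parts is not None and leaf_parts[node] is not None:
                part = leaf_parts[node]
            else:
                part = LEAF_PARTIAL_TABLE[codes[node]]
        else:
            part = None
            for child in tree.children[node]:
                msg = _child_message(partials[child], p_branch[child])
                part = msg if part is None else part * msg
                if keep_all:
                    messages[child] = msg
                elif not tree.is_leaf(child):
                    partials[child] = None  # free memory
            scale = _row_max(part)
            if scale.min() < 1e-150:
                scale = np.maximum(scale, _SCALE_FLOOR)
                part = part / scale[:, None]
                logscale += np.log(scale)
        partials[node] = part
    if keep_all:
        return partials[0], logscale, partials, messages
    return partials[0], logscale


def column_loglik(root_partials: np.ndarray, logscale, ctx: ModelContext):
    """Per-column log-likelihood from root partials and the root prior."""
    lik = root_partials @ ctx.root_weights
    with np.errstate(divide="ignore"):
        out = np.log(lik) + logscale
    if np.any(lik == 0.0):
        logger.warning("column with zero likelihood (-inf log-likelihood)")
    return out


def family_column_logliks(tree: PhyloTree, codes: np.ndarray,
                          ctx: ModelContext,
                          p_branch: np.ndarray | None = None) -> np.ndarray:
    if p_branch is None:
        p_branch = branch_matrices(tree, ctx.q)
    root, logscale = upward_pass(tree, codes, p_branch)
    return column_loglik(root, logscale, ctx)


def invisible_probability(tree: PhyloTree, ctx: ModelContext,
                          p_branch: np.ndarray | None = None) -> float:
    """Probability of the unobservable all-gap leaf pattern under the model."""
    if p_branch is None:
        p_branch = branch_matrices(tree, ctx.q)
    codes = np.full((tree.n_nodes, 1), GAP, dtype=np.int8)
    if ctx.gap_as_missing:
        return 0.0
    ll = family_column_logliks(tree, codes, ctx, p_branch)
    return float(np.exp(ll[0]))


def dataset_loglik(aset: AlignmentSet, model, mode: str = "fit") -> float:
    """Total log-likelihood of a multi-family dataset.

    ``site_test`` sums column log-likelihoods; ``fit`` adds the geometric
    termination term log(1-p) per alignment and conditions every column on
    observability (divides by 1 - P(all-gap leaves)).
    """
    if mode not in ("fit", "site_test"):
        raise ValueError(f"unknown mode {mode!r}")
    if not len(aset):
        raise ValueError("empty alignment set")
    ctx = model_context(model)
    total = 0.0
    for aln, tree in aset:
        p_branch = branch_matrices(tree, ctx.q)
        codes = leaf_code_matrix(tree, aln, ctx.gap_as_missing)
        total += float(family_column_logliks(tree, codes, ctx, p_branch).sum())
        if mode == "fit" and isinstance(model, IndelModel):
            p_inv = invisible_probability(tree, ctx, p_branch)
            total += np.log1p(-model.p)
            total -= aln.n_cols * np.log1p(-p_inv)
    return total
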