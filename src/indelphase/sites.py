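"""Per-column likelihood-ratio tests for substitution-rate and indel-rate
scaling, signed scores, multiple-testing helpers and overlap reports.

Two tests are run per column against globally fitted null models:

* ``subst`` — F84 vs F84 with a free branch-length scale ``rho`` (the
  classic conservation/acceleration test; gaps are missing data);
* ``indel`` — the relaxed gap-extended model vs the same model with a free
  scale ``rho_indel`` multiplying the deletion rate, and, weighted by the
  global deletion/insertion length ratio, the insertion rate.

Because of the D/I weighting the alternative family does not pass exactly
through the null point, so the LRT statistic is clamped at zero and the test
is conservative.  p-values use the upper tail of chi-square with 1 d.f.

The scale is optimized per column on a shared log grid followed by a
vectorized golden-section refinement of the promising columns (all columns
sharing one tree are evaluated together, with batched spectral
decompositions of the per-column generators).
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
from scipy.stats import chi2

from .io import GAP, Alignment, PhyloTree, SiteScore
from .likelihood import (ModelContext, branch_matrices, column_loglik,
                         leaf_code_matrix, model_context, upward_pass)
from .models import (F84Params, IndelModel, ScaleContext, apply_indel_scaling,
                     build_f84_rate_matrix, conditional_matrix,
                     reversible_spectral, spectral_transition)

logger = logging.getLogger("indelphase")

_SCORE_CAP = 308.0

#: log10 search bounds for the per-column scale parameters
INDEL_RHO_BOUNDS = (-6.0, 4.0)
SUBST_RHO_BOUNDS = (-4.0, 2.0)


# ---------------------------------------------------------------------------
# scores and thresholds
# ---------------------------------------------------------------------------

def score_from_pvalue(p: float, scale_estimate: float,
                      phast_sign: bool = False) -> float:
    """Signed log10 p-value: positive for acceleration (scale > 1), negative
    for conservation (scale < 1); ``phast_sign`` flips the convention."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p == 0.0:
        logger.warning("p-value underflow; score capped at %g", _SCORE_CAP)
        mag = _SCORE_CAP
    else:
        mag = min(-math.log10(p), _SCORE_CAP)
    if scale_estimate == 1.0 or mag == 0.0:
        return 0.0
    sign = 1.0 if scale_estimate > 1.0 else -1.0
    if phast_sign:
        sign = -sign
    return sign * mag


def bonferroni_alpha(family_wise_alpha: float, total_sites: int) -> float:
    if total_sites < 1:
        raise ValueError("total_sites must be >= 1")
    return family_wise_alpha / total_sites


def overlap_table(subst_scores, indel_scores, alpha: float) -> dict:
    """2x2 partition of the common site universe by per-test significance."""
    sub = {(s.family_id, s.column): s.pvalue < alpha for s in subst_scores}
    ind = {(s.family_id, s.column): s.pvalue < alpha for s in indel_scores}
    if set(sub) != set(ind):
        raise ValueError("subst and indel score tables cover different sites")
    out = {"both": 0, "indel_only": 0, "subst_only": 0, "neither": 0}
    for key, s_sig in sub.items():
        i_sig = ind[key]
        if s_sig and i_sig:
            out["both"] += 1
        elif i_sig:
            out["indel_only"] += 1
        elif s_sig:
            out["subst_only"] += 1
        else:
            out["neither"] += 1
    return out


def normalize_family_scores(scores, bound: float = 50.0):
    """Linearly rescale scores per family so the largest |score| maps to
    ``bound``; zero stays zero and all-zero families are unchanged."""
    if bound <= 0:
        raise ValueError("bound must be > 0")
    max_abs: dict[str, float] = {}
    for s in scores:
        max_abs[s.family_id] = max(max_abs.get(s.family_id, 0.0), abs(s.score))
    out = []
    for s in scores:
        m = max_abs[s.family_id]
        factor = bound / m if m > 0 else 1.0
        out.append(replace(s, score=s.score * factor))
    return out


def summarize_scores(scores, family_wise_alpha: float = 0.05) -> dict:
    """Significant-site counts at the raw and Bonferroni-corrected levels."""
    by_test: dict[str, list] = {}
    for s in scores:
        by_test.setdefault(s.test, []).append(s)
    summary: dict = {"alpha": family_wise_alpha, "tests": {}}
    for test, rows in by_test.items():
        total = len(rows)
        bonf = bonferroni_alpha(family_wise_alpha, total)
        summary["tests"][test] = {
            "total_sites": total,
            "significant_raw": sum(s.pvalue < family_wise_alpha for s in rows),
            "bonferroni_alpha": bonf,
            "significant_bonferroni": sum(s.pvalue < bonf for s in rows),
        }
    return summary


# ---------------------------------------------------------------------------
# alternative-model evaluators
# ---------------------------------------------------------------------------

def _f84e_stationary_batch(lam: np.ndarray, mu: np.ndarray,
                           pi: np.ndarray) -> np.ndarray:
    total = lam + mu
    gap = np.where(total > 0, mu / np.maximum(total, 1e-300), 0.0)
    out = np.empty(lam.shape + (5,))
    out[..., :4] = (1.0 - gap)[..., None] * pi
    out[..., GAP] = gap
    return out


class _IndelAlternative:
    """Evaluates per-column log-likelihoods of the indel-scaled model."""

    def __init__(self, tree: PhyloTree, codes: np.ndarray, model: IndelModel,
                 di_ratio: float, ctx: ModelContext):
        self.tree = tree
        self.codes = codes
        self.model = model
        self.di = di_ratio
        self.root_w = ctx.root_weights

    def at_shared_rho(self, rho: float) -> np.ndarray:
        alt = apply_indel_scaling(self.model, ScaleContext(rho, self.di))
        ctx = model_context(alt)
        root, scale = upward_pass(self.tree, self.codes,
                                  branch_matrices(self.tree, ctx.q))
        return column_loglik(root, scale, ctx)

    def at_column_rho(self, log10_rho: np.ndarray,
                      subset: np.ndarray) -> np.ndarray:
        rho = 10.0 ** log10_rho
        lam = rho * self.di * self.model.lam
        mu = rho * self.model.mu
        m = len(rho)
        q4 = build_f84_rate_matrix(self.model.f84)
        q = np.zeros((m, 5, 5))
        q[:, :4, :4] = q4
        q[:, :4, GAP] = mu[:, None]
        q[:, GAP, :4] = lam[:, None] * self.model.f84.pi
        idx = np.arange(5)
        q[:, idx, idx] = 0.0
        q[:, idx, idx] = -q.sum(axis=2)
        pis = _f84e_stationary_batch(lam, mu, self.model.f84.pi)
        codes = self.codes[:, subset]
        if np.min(pis) < 1e-12:
            return self._expm_path(q, codes)
        w, v, d = reversible_spectral(q, pis)
        p_list: list = [None] * self.tree.n_nodes
        for node in range(1, self.tree.n_nodes):
            p_list[node] = spectral_transition(w, v, d,
                                               float(self.tree.lengths[node]))
        root, scale = upward_pass(self.tree, codes, p_list)
        ll = np.log(np.maximum(root @ self.root_w, 1e-300)) + scale
        return ll

    def _expm_path(self, q: np.ndarray, codes: np.ndarray) -> np.ndarray:
        from scipy.linalg import expm
        p_list: list = [None] * self.tree.n_nodes
        for node in range(1, self.tree.n_nodes):
            t = float(self.tree.lengths[node])
            p_list[node] = np.stack([expm(qi * t) for qi in q])
        root, scale = upward_pass(self.tree, codes, p_list)
        return np.log(np.maximum(root @ self.root_w, 1e-300)) + scale


class _SubstAlternative:
    """Per-column log-likelihoods of F84 with scaled branch lengths."""

    def __init__(self, tree: PhyloTree, codes: np.ndarray, model: F84Params,
                 ctx: ModelContext):
        self.tree = tree
        self.codes = codes  # gaps already mapped to unknown
        self.model = model
        self.root_w = ctx.root_weights
        self.q5 = ctx.q
        self._spec = reversible_spectral(build_f84_rate_matrix(model),
                                         model.pi)

    def at_shared_rho(self, rho: float) -> np.ndarray:
        scaled = self.tree.scale_lengths(rho)
        root, scale = upward_pass(self.tree, self.codes,
                                  branch_matrices(scaled, self.q5))
        with np.errstate(divide="ignore"):
            return np.log(root @ self.root_w) + scale

    def at_column_rho(self, log10_rho: np.ndarray,
                      subset: np.ndarray) -> np.ndarray:
        rho = 10.0 ** log10_rho
        w, v, d = self._spec
        codes = self.codes[:, subset]
        p_list: list = [None] * self.tree.n_nodes
        for node in range(1, self.tree.n_nodes):
            t4 = spectral_transition(w, v, d, rho * float(self.tree.lengths[node]))
            p5 = np.zeros((len(rho), 5, 5))
            p5[:, :4, :4] = t4
            p5[:, GAP, GAP] = 1.0
            p_list[node] = p5
        root, scale = upward_pass(self.tree, codes, p_list)
        return np.log(np.maximum(root @ self.root_w, 1e-300)) + scale


# ---------------------------------------------------------------------------
# the optimizer: shared grid + vectorized golden-section refinement
# ---------------------------------------------------------------------------

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_batch(fun, lo: np.ndarray, hi: np.ndarray, iters: int = 28):
    """Vectorized golden-section maximization over per-column brackets.

    ``fun`` maps a vector of log10-scale values to per-column log-likelihoods.
    Returns (argmax, max value).
    """
    a, b = lo.copy(), hi.copy()
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(iters):
        move_right = fd > fc
        a = np.where(move_right, c, a)
        b = np.where(move_right, b, d)
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc, fd = fun(c), fun(d)
    x = 0.5 * (a + b)
    return x, fun(x)


def _optimize_scale(alternative, null_ll: np.ndarray, bounds: tuple,
                    grid_size: int, refine_lrt: float, refine_iters: int):
    """Shared-grid stage then golden refinement; returns per-column
    (log10 scale, alternative log-likelihood)."""
    n_cols = null_ll.shape[0]
    grid = np.linspace(bounds[0], bounds[1], grid_size)
    table = np.empty((grid_size, n_cols))
    for g, x in enumerate(grid):
        table[g] = alternative.at_shared_rho(10.0 ** x)
    k = table.argmax(axis=0)
    best_x = grid[k]
    best_ll = table[k, np.arange(n_cols)]

    # parabolic vertex through the three bracketing grid points improves the
    # scale estimate of columns that are not golden-refined
    interior = (k > 0) & (k < grid_size - 1)
    if interior.any():
        i = np.flatnonzero(interior)
        y0 = table[k[i] - 1, i]
        y1 = table[k[i], i]
        y2 = table[k[i] + 1, i]
        denom = y0 - 2.0 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-300,
                         0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        h = grid[1] - grid[0]
        best_x[i] = grid[k[i]] + np.clip(shift, -1.0, 1.0) * h

    refine = 2.0 * (best_ll - null_ll) > refine_lrt
    refine &= interior
    if refine.any():
        sel = np.flatnonzero(refine)
        lo = grid[np.maximum(k[sel] - 1, 0)]
        hi = grid[np.minimum(k[sel] + 1, grid_size - 1)]
        x_hat, ll_hat = _golden_batch(
            lambda x: alternative.at_column_rho(x, sel), lo, hi, refine_iters)
        improved = ll_hat >= best_ll[sel]
        best_x[sel] = np.where(improved, x_hat, best_x[sel])
        best_ll[sel] = np.maximum(ll_hat, best_ll[sel])
    return best_x, best_ll


def _make_scores(family_id, null_ll, log10_scale, alt_ll, test,
                 phast_sign=False, columns=None):
    lrt = np.maximum(2.0 * (alt_ll - null_ll), 0.0)
    pvals = chi2.sf(lrt, df=1)
    alt_clamped = np.maximum(alt_ll, null_ll)
    if columns is None:
        columns = range(1, len(null_ll) + 1)
    out = []
    for i, col in enumerate(columns):
        scale = float(10.0 ** log10_scale[i])
        p = float(pvals[i])
        out.append(SiteScore(family_id, int(col), test, float(null_ll[i]),
                             float(alt_clamped[i]), scale, p,
                             score_from_pvalue(p, scale, phast_sign)))
    return out


# ---------------------------------------------------------------------------
# public test entry points
# ---------------------------------------------------------------------------

def indel_scores_for_family(tree: PhyloTree, aln_or_codes, model: IndelModel,
                            di_ratio: float, family_id: str = "",
                            grid_size: int = 41, refine_lrt: float = 2.0,
                            refine_iters: int = 28,
                            phast_sign: bool = False) -> list[SiteScore]:
    """Indel-rate LRT (indelP) for every column of one family."""
    ctx = model_context(model)
    codes = _as_codes(tree, aln_or_codes, ctx)
    root, scale = upward_pass(tree, codes, branch_matrices(tree, ctx.q))
    null_ll = column_loglik(root, scale, ctx)
    alt = _IndelAlternative(tree, codes, model, di_ratio, ctx)
    x, ll = _optimize_scale(alt, null_ll, INDEL_RHO_BOUNDS, grid_size,
                            refine_lrt, refine_iters)
    fam = family_id or _family_of(aln_or_codes)
    return _make_scores(fam, null_ll, x, ll, "indel", phast_sign)


def subst_scores_for_family(tree: PhyloTree, aln_or_codes, model: F84Params,
                            family_id: str = "", grid_size: int = 33,
                            refine_lrt: float = 2.0, refine_iters: int = 28,
                            phast_sign: bool = False) -> list[SiteScore]:
    """Substitution-rate LRT (phyloP analogue) for every column."""
    ctx = model_context(model)
    codes = _as_codes(tree, aln_or_codes, ctx)
    root, scale = upward_pass(tree, codes, branch_matrices(tree, ctx.q))
    null_ll = column_loglik(root, scale, ctx)
    alt = _SubstAlternative(tree, codes, model, ctx)
    x, ll = _optimize_scale(alt, null_ll, SUBST_RHO_BOUNDS, grid_size,
                            refine_lrt, refine_iters)
    fam = family_id or _family_of(aln_or_codes)
    return _make_scores(fam, null_ll, x, ll, "subst", phast_sign)


def _family_of(aln_or_codes) -> str:
    return aln_or_codes.family_id if isinstance(aln_or_codes, Alignment) else ""


def _as_codes(tree: PhyloTree, aln_or_codes, ctx: ModelContext) -> np.ndarray:
    if isinstance(aln_or_codes, Alignment):
        return leaf_code_matrix(tree, aln_or_codes, ctx.gap_as_missing)
    codes = np.asarray(aln_or_codes, dtype=np.int8)
    if ctx.gap_as_missing:
        from .io import UNKNOWN
        codes = np.where(codes == GAP, UNKNOWN, codes)
    return codes


def _column_codes(tree: PhyloTree, column) -> np.ndarray:
    """Build a one-column (n_nodes, 1) code matrix from a leaf-name mapping
    or a vector ordered like ``tree.leaves``."""
    from .io import SYMBOL_CODES, UNKNOWN
    codes = np.full((tree.n_nodes, 1), UNKNOWN, dtype=np.int8)
    if isinstance(column, dict):
        for node in tree.leaves:
            sym = column[tree.labels[node]]
            codes[node, 0] = SYMBOL_CODES[sym.upper()] if isinstance(sym, str) else int(sym)
    else:
        column = list(column)
        for node, sym in zip(tree.leaves, column):
            codes[node, 0] = SYMBOL_CODES[sym.upper()] if isinstance(sym, str) else int(sym)
    return codes


def site_lrt_indel(tree: PhyloTree, column, null_indel_model: IndelModel,
                   di_ratio: float | None, family_id: str = "",
                   column_index: int = 1, **kwargs) -> SiteScore:
    """Indel-rate LRT for a single column (leaf-name dict or leaf-order
    vector of symbols).  A missing D/I ratio falls back to 1 with a warning."""
    if di_ratio is None:
        logger.warning("D/I ratio undefined; falling back to 1")
        di_ratio = 1.0
    codes = _column_codes(tree, column)
    score = indel_scores_for_family(tree, codes, null_indel_model, di_ratio,
                                    family_id, **kwargs)[0]
    return replace(score, family_id=family_id, column=column_index)


def site_lrt_subst(tree: PhyloTree, column, null_f84_model: F84Params,
                   family_id: str = "", column_index: int = 1,
                   **kwargs) -> SiteScore:
    """Substitution-rate LRT for a single column."""
    codes = _column_codes(tree, column)
    score = subst_scores_for_family(tree, codes, null_f84_model,
                                    family_id, **kwargs)[0]
    return replace(score, family_id=family_id, column=column_index)
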