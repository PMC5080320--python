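"""Rate matrices and finite-time transition probabilities for the
gap-extended substitution models.

Three generators are provided over the state order (A, C, G, T, -):

* F84 — classic 4-state substitution model with a transition-specific rate
  component ``alpha`` and a general component ``beta``;
* HKY+G — HKY85 on the residues with the gap as a fifth character exchanged
  at rate ``sigma`` weighted by the stationary frequencies;
* F84e-relaxed — F84 residue block plus a per-site deletion rate ``mu``
  (residue -> gap) and insertion rate ``lambda`` (gap -> residue j at
  ``lambda * pi_j``), with a geometric ancestral-length parameter ``p``.

All generators are reversible; finite-time probabilities come from the
matrix exponential.  The residue/gap lumping of the F84e generator is the
exact two-state chain with rates mu and lambda, which gives the analytic
gap-survival identity P(-|-,t) = 1 - xi(t) used as this module's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

from .io import GAP

#: transition partners under the purine/pyrimidine grouping (A<->G, C<->T)
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True
_PURINE = np.array([True, False, True, False])


@dataclass(frozen=True)
class F84Params:
    alpha: float
    beta: float
    pi: np.ndarray  # residue frequencies (A, C, G, T)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=np.float64))
        if self.pi.shape != (4,) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be a 4-simplex")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


@dataclass(frozen=True)
class IndelModel:
    """F84e-relaxed parameters: indel rates on top of an F84 residue block."""

    lam: float      # per-site insertion rate
    mu: float       # per-site deletion rate
    f84: F84Params
    p: float        # geometric ancestral-length parameter, 0 < p < 1

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("lambda and mu must be >= 0")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")


@dataclass(frozen=True)
class HKYGParams:
    kappa: float
    sigma: float
    pi5: np.ndarray  # frequencies over (A, C, G, T, -)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi5", np.asarray(self.pi5, dtype=np.float64))
        if self.pi5.shape != (5,) or abs(self.pi5.sum() - 1.0) > 1e-9:
            raise ValueError("pi5 must be a 5-simplex")
        if self.kappa < 0 or self.sigma < 0:
            raise ValueError("kappa and sigma must be >= 0")


@dataclass(frozen=True)
class ScaleContext:
    """Per-site indel scaling: ``mu`` is multiplied by ``rho_indel`` and
    ``lambda`` by ``rho_indel * di_ratio`` (deletion/insertion length ratio)."""

    rho_indel: float
    di_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rho_indel) and np.isfinite(self.di_ratio)):
            raise ValueError("scaling context must be finite")
        if self.rho_indel < 0 or self.di_ratio <= 0:
            raise ValueError("rho_indel must be >= 0 and di_ratio > 0")


def _validate_generator(q: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    off = q - np.diag(np.diag(q))
    if np.any(off < -tol):
        raise ValueError("negative off-diagonal rate")
    if np.any(np.abs(q.sum(axis=1)) > tol):
        raise ValueError("generator rows do not sum to zero")
    return q


def build_f84_rate_matrix(params: F84Params) -> np.ndarray:
    """4x4 F84 generator: q_ij = beta*pi_j (+ alpha*pi_j/pi_group(j) for
    transitions); pi is stationary and detailed balance holds."""
    pi = params.pi
    if np.any(pi <= 0):
        raise ValueError("F84 requires strictly positive frequencies")
    group = np.where(_PURINE, pi[_PURINE].sum(), pi[~_PURINE].sum())
    q = params.beta * np.tile(pi, (4, 1))
    q += np.where(_TRANSITION, params.alpha * pi / group, 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return _validate_generator(q)


def build_hkyg_rate_matrix(params: HKYGParams) -> np.ndarray:
    """5x5 gap-as-fifth-character HKY generator.

    Residues follow HKY85 with frequencies renormalized over the residue
    block; residue -> gap at sigma*pi_gap and gap -> residue j at sigma*pi_j,
    so the full pi5 vector is stationary.
    """
    pi5 = params.pi5
    pi_gap = pi5[GAP]
    if pi_gap == 0 and params.sigma > 0:
        raise ValueError("pi_gap = 0 with sigma > 0")
    pr = pi5[:4] / pi5[:4].sum()
    q = np.zeros((5, 5))
    q[:4, :4] = np.tile(pr, (4, 1)) * np.where(_TRANSITION, params.kappa, 1.0)
    q[:4, GAP] = params.sigma * pi_gap
    q[GAP, :4] = params.sigma * pi5[:4]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return _validate_generator(q)


def build_f84e_rate_matrix(model: IndelModel) -> np.ndarray:
    """5x5 relaxed gap-extended F84 generator: F84 residue block, every
    residue deleted at rate mu, the gap reinserted as residue j at
    lambda*pi_j."""
    q = np.zeros((5, 5))
    q[:4, :4] = build_f84_rate_matrix(model.f84)
    q[:4, GAP] = model.mu
    q[GAP, :4] = model.lam * model.f84.pi
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return _validate_generator(q)


def conditional_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """P = exp(Q t); rows sum to one, entries clipped of exponential-method
    noise below zero."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p = expm(np.asarray(q, dtype=np.float64) * t)
    p = np.clip(p, 0.0, None)
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-10):
        raise ValueError("conditional matrix rows do not sum to one")
    return p


def xi(lam: float, mu: float, t: float) -> float:
    """Gap -> residue probability of the lumped two-state chain,
    lambda/(lambda+mu) * (1 - exp(-(lambda+mu) t)); 0 when both rates are 0."""
    if lam < 0 or mu < 0 or t < 0:
        raise ValueError("rates and time must be >= 0")
    total = lam + mu
    if total == 0:
        return 0.0
    return lam / total * -np.expm1(-total * t)


def apply_indel_scaling(model: IndelModel, ctx: ScaleContext) -> IndelModel:
    """Scale mu by rho_indel and lambda by rho_indel * di_ratio; the
    substitution block and the length prior are untouched."""
    return replace(model,
                   lam=ctx.rho_indel * ctx.di_ratio * model.lam,
                   mu=ctx.rho_indel * model.mu)


# ---------------------------------------------------------------------------
# stationary distributions and spectral transition probabilities
# ---------------------------------------------------------------------------

def stationary_f84e(model: IndelModel) -> np.ndarray:
    """Stationary distribution of the F84e-relaxed generator: the gap holds
    mu/(lambda+mu), residues share the rest in proportion pi."""
    total = model.lam + model.mu
    gap = model.mu / total if total > 0 else 0.0
    out = np.empty(5)
    out[:4] = (1.0 - gap) * model.f84.pi
    out[GAP] = gap
    return out


def reversible_spectral(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible generator via its symmetrization.

    Returns ``(w, v, d)`` with ``exp(Qt) = diag(1/d) V exp(w t) V^T diag(d)``
    where ``d = sqrt(pi)``.  ``pi`` must be strictly positive.
    """
    d = np.sqrt(np.asarray(pi, dtype=np.float64))
    s = q * (d[..., :, None] / d[..., None, :])
    s = 0.5 * (s + s.swapaxes(-1, -2))
    w, v = np.linalg.eigh(s)
    return w, v, d


def spectral_transition(w, v, d, t) -> np.ndarray:
    """Transition matrix at time(s) ``t`` from :func:`reversible_spectral`
    factors; broadcasts over leading axes of the factors and of ``t``."""
    t = np.asarray(t, dtype=np.float64)
    e = np.exp(w * t[..., None])
    core = np.einsum("...ik,...k,...jk->...ij", v, e, v)
    p = core * (d[..., None, :] / d[..., :, None])
    return np.clip(p, 0.0, None)
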