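import numpy as np
import pytest
from scipy.linalg import expm

from conftest import random_f84, random_indel_model
from oracles import series_expm, two_state_gap_prob

from indelphase.io import GAP
from indelphase.models import (F84Params, HKYGParams, IndelModel, ScaleContext,
                               apply_indel_scaling, build_f84_rate_matrix,
                               build_f84e_rate_matrix, build_hkyg_rate_matrix,
                               conditional_matrix, reversible_spectral,
                               spectral_transition, stationary_f84e, xi)


def left_stationary(q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(q.T)
    i = np.argmin(np.abs(w))
    pi = np.real(v[:, i])
    return pi / pi.sum()


class TestF84Matrix:
    def test_alpha_zero_uniform_pi_is_jukes_cantor(self):
        q = build_f84_rate_matrix(F84Params(0.0, 1.0, np.full(4, 0.25)))
        off = q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_paper_parameters_are_stationary(self, paper_f84):
        q = build_f84_rate_matrix(paper_f84)
        assert np.allclose(paper_f84.pi @ q, 0.0, atol=1e-12)

    def test_detailed_balance_random_draws(self, rng):
        for _ in range(100):
            f = random_f84(rng)
            q = build_f84_rate_matrix(f)
            flux = f.pi[:, None] * q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rows_sum_to_zero_and_nonneg_offdiag(self, rng):
        q = build_f84_rate_matrix(random_f84(rng))
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(q[~np.eye(4, dtype=bool)] >= 0)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            build_f84_rate_matrix(F84Params(0.5, 0.5,
                                            np.array([0.5, 0.5, 0.0, 0.0])))


class TestHKYGMatrix:
    pi5 = np.array([0.2522, 0.2578, 0.2609, 0.2191, 0.0099])

    def setup_method(self):
        self.pi5 = self.pi5 / self.pi5.sum()

    def test_sigma_zero_decouples_gap(self):
        q = build_hkyg_rate_matrix(HKYGParams(2.0, 0.0, self.pi5))
        assert np.allclose(q[GAP], 0.0)
        assert np.allclose(q[:4, GAP], 0.0)

    def test_stationary_distribution_is_pi5(self):
        q = build_hkyg_rate_matrix(HKYGParams(2.0, 0.7, self.pi5))
        assert np.allclose(left_stationary(q), self.pi5, atol=1e-10)

    def test_insertion_deletion_rate_asymmetry(self):
        # with the published frequencies the gap->A rate exceeds A->gap by
        # pi_A / pi_gap, the two-orders-of-magnitude asymmetry criticized
        # for gap-as-fifth-character models
        q = build_hkyg_rate_matrix(HKYGParams(2.0, 0.7, self.pi5))
        ratio = q[GAP, 0] / q[0, GAP]
        assert ratio == pytest.approx(self.pi5[0] / self.pi5[GAP], rel=1e-12)
        assert 25.0 < ratio < 26.0

    def test_zero_gap_frequency_with_sigma_rejected(self):
        pi = np.array([0.25, 0.25, 0.25, 0.25, 0.0])
        with pytest.raises(ValueError):
            build_hkyg_rate_matrix(HKYGParams(2.0, 0.5, pi))


class TestF84ERelaxedMatrix:
    def test_zero_indel_rates_embed_f84(self, paper_f84):
        m = IndelModel(0.0, 0.0, paper_f84, 0.998)
        q = build_f84e_rate_matrix(m)
        assert np.allclose(q[:4, :4], build_f84_rate_matrix(paper_f84))
        assert np.allclose(q[GAP], 0.0)
        assert np.allclose(q[:4, GAP], 0.0)

    def test_lumping_gives_two_state_chain(self, paper_indel_model):
        q = build_f84e_rate_matrix(paper_indel_model)
        # residue -> gap rate is mu for every residue; total gap -> residue
        # rate is lambda (sum of lambda * pi_j)
        assert np.allclose(q[:4, GAP], paper_indel_model.mu)
        assert q[GAP, :4].sum() == pytest.approx(paper_indel_model.lam)

    def test_stationary_gap_frequency(self, paper_indel_model):
        q = build_f84e_rate_matrix(paper_indel_model)
        st = left_stationary(q)
        m = paper_indel_model
        assert st[GAP] == pytest.approx(m.mu / (m.lam + m.mu), abs=1e-12)
        assert st[GAP] == pytest.approx(0.8787, abs=5e-5)

    def test_rows_sum_to_zero(self, rng):
        for _ in range(20):
            q = build_f84e_rate_matrix(random_indel_model(rng))
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)


class TestConditionalMatrix:
    def test_t_zero_is_identity(self, paper_indel_model):
        q = build_f84e_rate_matrix(paper_indel_model)
        assert np.allclose(conditional_matrix(q, 0.0), np.eye(5))

    def test_negative_t_rejected(self, paper_indel_model):
        q = build_f84e_rate_matrix(paper_indel_model)
        with pytest.raises(ValueError):
            conditional_matrix(q, -0.1)

    def test_gap_survival_identity(self, rng):
        # P(-|-,t) = 1 - xi(t): the lumped chain solved in closed form
        for _ in range(200):
            m = random_indel_model(rng)
            t = float(rng.uniform(0.0, 3.0))
            p = conditional_matrix(build_f84e_rate_matrix(m), t)
            assert p[GAP, GAP] == pytest.approx(1.0 - xi(m.lam, m.mu, t),
                                                abs=1e-10)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(20):
            m = random_indel_model(rng)
            q = build_f84e_rate_matrix(m)
            t1, t2 = rng.uniform(0.0, 2.0, 2)
            assert np.allclose(conditional_matrix(q, t1) @ conditional_matrix(q, t2),
                               conditional_matrix(q, t1 + t2), atol=1e-9)

    def test_matches_truncated_series(self, rng):
        for _ in range(30):
            m = random_indel_model(rng)
            q = build_f84e_rate_matrix(m)
            t = float(rng.uniform(0.0, 1.0))
            if np.abs(q * t).sum() > 5.0:
                continue
            assert np.allclose(conditional_matrix(q, t), series_expm(q, t),
                               atol=1e-9)

    def test_rows_stochastic(self, rng):
        for _ in range(30):
            q = build_f84e_rate_matrix(random_indel_model(rng))
            p = conditional_matrix(q, float(rng.uniform(0, 5)))
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert np.all((p >= 0) & (p <= 1))


class TestXi:
    def test_t_zero(self):
        assert xi(0.3, 0.5, 0.0) == 0.0

    def test_lambda_zero(self):
        assert xi(0.0, 0.5, 7.0) == 0.0

    def test_both_rates_zero(self):
        assert xi(0.0, 0.0, 2.0) == 0.0

    def test_long_time_limit(self, paper_indel_model):
        m = paper_indel_model
        limit = m.lam / (m.lam + m.mu)
        assert xi(m.lam, m.mu, 1e4) == pytest.approx(limit, abs=1e-12)
        p = conditional_matrix(build_f84e_rate_matrix(m), 1e4)
        assert p[GAP, :4].sum() == pytest.approx(limit, abs=1e-9)

    def test_residue_to_gap_closed_form(self, rng):
        for _ in range(50):
            m = random_indel_model(rng)
            t = float(rng.uniform(0, 4))
            p = conditional_matrix(build_f84e_rate_matrix(m), t)
            from_res, from_gap = two_state_gap_prob(m.lam, m.mu, t)
            assert p[0, GAP] == pytest.approx(from_res, abs=1e-10)
            assert p[GAP, GAP] == pytest.approx(from_gap, abs=1e-10)


class TestIndelScaling:
    def test_rho_zero_removes_indels(self, paper_indel_model):
        m = apply_indel_scaling(paper_indel_model, ScaleContext(0.0, 2.0))
        assert m.lam == 0.0 and m.mu == 0.0

    def test_unit_di_doubles_both(self, paper_indel_model):
        m = apply_indel_scaling(paper_indel_model, ScaleContext(2.0, 1.0))
        assert m.lam == pytest.approx(2 * paper_indel_model.lam)
        assert m.mu == pytest.approx(2 * paper_indel_model.mu)

    def test_published_di_ratio_weighting(self, paper_indel_model):
        # D/I from the published totals: 26577 deletions / 4506 insertions
        di = 26577 / 4506
        assert di == pytest.approx(5.8981, abs=1e-4)
        m = apply_indel_scaling(paper_indel_model, ScaleContext(1.5, di))
        assert m.lam == pytest.approx(1.5 * di * paper_indel_model.lam)
        assert m.mu == pytest.approx(1.5 * paper_indel_model.mu)

    def test_scaling_is_multiplicative(self, paper_indel_model, rng):
        for _ in range(20):
            r1, r2 = rng.uniform(0.1, 5.0, 2)
            di = float(rng.uniform(0.5, 8.0))
            a = apply_indel_scaling(
                apply_indel_scaling(paper_indel_model, ScaleContext(r1, di)),
                ScaleContext(r2, 1.0))
            b = apply_indel_scaling(paper_indel_model, ScaleContext(r1 * r2, di))
            assert a.lam == pytest.approx(b.lam, rel=1e-12)
            assert a.mu == pytest.approx(b.mu, rel=1e-12)


class TestSpectral:
    def test_spectral_matches_expm(self, rng):
        for _ in range(30):
            m = random_indel_model(rng)
            if m.lam < 1e-3 or m.mu < 1e-3:
                continue
            q = build_f84e_rate_matrix(m)
            pi = stationary_f84e(m)
            w, v, d = reversible_spectral(q, pi)
            t = float(rng.uniform(0, 3))
            assert np.allclose(spectral_transition(w, v, d, t), expm(q * t),
                               atol=1e-9)
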