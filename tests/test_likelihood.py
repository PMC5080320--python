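import itertools

import numpy as np
import pytest

from conftest import random_indel_model
from oracles import enum_column_likelihood

from indelphase.io import (GAP, UNKNOWN, Alignment, AlignmentSet, PhyloTree,
                           read_newick)
from indelphase.likelihood import (branch_matrices, column_loglik,
                                   dataset_loglik, family_column_logliks,
                                   invisible_probability, leaf_code_matrix,
                                   leaf_partials, model_context, upward_pass)
from indelphase.models import F84Params, IndelModel, build_f84_rate_matrix
from scipy.linalg import expm


def codes_for(tree, mapping):
    codes = np.full((tree.n_nodes, 1), UNKNOWN, dtype=np.int8)
    for node in tree.leaves:
        codes[node, 0] = mapping[tree.labels[node]]
    return codes


def enum_loglik(tree, mapping, model):
    ctx = model_context(model)
    p_branch = [None] + [expm(ctx.q * tree.lengths[i])
                         for i in range(1, tree.n_nodes)]
    leaf_codes = {n: mapping[tree.labels[n]] for n in tree.leaves}
    return np.log(enum_column_likelihood(tree, leaf_codes, p_branch,
                                         ctx.root_weights))


class TestLeafPartials:
    def test_residue_indicator(self):
        assert np.array_equal(leaf_partials("A"), [1, 0, 0, 0, 0])
        assert np.array_equal(leaf_partials("T"), [0, 0, 0, 1, 0])

    def test_gap_is_observed_state(self):
        # the defining departure from missing-data treatment
        assert np.array_equal(leaf_partials("-"), [0, 0, 0, 0, 1])

    def test_unknown_excludes_gap(self):
        assert np.array_equal(leaf_partials("N"), [1, 1, 1, 1, 0])
        assert np.array_equal(leaf_partials("R"), [1, 1, 1, 1, 0])

    def test_unmapped_symbol_raises(self):
        with pytest.raises(ValueError):
            leaf_partials("!")


class TestPruneColumn:
    def test_zero_branch_cherry_concentrates_on_observed(self):
        tree = read_newick("(A:0.0,B:0.0);")
        m = random_indel_model(np.random.default_rng(1))
        ctx = model_context(m)
        codes = codes_for(tree, {"A": 0, "B": 0})
        root, scale = upward_pass(tree, codes, branch_matrices(tree, ctx.q))
        assert np.allclose(root[0], [1, 0, 0, 0, 0])

    def test_three_leaf_matches_enumeration(self, three_leaf, rng):
        for _ in range(25):
            m = random_indel_model(rng)
            mapping = {lab: int(rng.integers(0, 6))
                       for lab in three_leaf.leaf_labels}
            if all(v == GAP for v in mapping.values()):
                continue
            got = family_column_logliks(three_leaf,
                                        codes_for(three_leaf, mapping),
                                        model_context(m))[0]
            assert got == pytest.approx(enum_loglik(three_leaf, mapping, m),
                                        abs=1e-12)

    def test_all_gap_column_allows_recurrent_insertion(self, four_leaf):
        # with every leaf deleted, both a gap ancestor and a residue ancestor
        # (erased by deletions) must carry positive partial likelihood
        m = IndelModel(0.05, 0.3, F84Params(0.5, 0.5, np.full(4, 0.25)), 0.99)
        ctx = model_context(m)
        codes = codes_for(four_leaf, {lab: GAP for lab in "ABCD"})
        root, scale = upward_pass(four_leaf, codes,
                                  branch_matrices(four_leaf, ctx.q))
        assert root[0, GAP] > 0
        assert np.all(root[0, :4] > 0)
        mapping = {lab: GAP for lab in "ABCD"}
        assert column_loglik(root, scale, ctx)[0] == pytest.approx(
            enum_loglik(four_leaf, mapping, m), abs=1e-12)


class TestColumnLoglik:
    def test_single_leaf_tree_gives_length_prior_times_pi(self, paper_indel_model):
        tree = read_newick("(A:0.0);")
        ctx = model_context(paper_indel_model)
        ll = family_column_logliks(tree, codes_for(tree, {"A": 0}), ctx)[0]
        expected = np.log(paper_indel_model.p * paper_indel_model.f84.pi[0])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_gapless_indel_free_reduces_to_f84_plus_log_p(self, three_leaf,
                                                          paper_f84):
        m = IndelModel(0.0, 0.0, paper_f84, 0.9)
        ctx5 = model_context(m)
        ctx4 = model_context(paper_f84)
        for mapping in ({"A": 0, "B": 2, "C": 1}, {"A": 3, "B": 3, "C": 3}):
            codes = codes_for(three_leaf, mapping)
            ll5 = family_column_logliks(three_leaf, codes, ctx5)[0]
            ll4 = family_column_logliks(three_leaf, codes, ctx4)[0]
            assert ll5 == pytest.approx(ll4 + np.log(m.p), abs=1e-12)

    def test_pattern_probabilities_sum_to_one(self, rng):
        tree = read_newick("(A:0.23,B:0.41);")
        m = random_indel_model(rng)
        ctx = model_context(m)
        total = 0.0
        for pat in itertools.product(range(5), repeat=2):
            codes = codes_for(tree, {"A": pat[0], "B": pat[1]})
            total += np.exp(family_column_logliks(tree, codes, ctx)[0])
        assert total == pytest.approx(1.0, abs=1e-10)


class TestDatasetLoglik:
    def make_set(self, tree, rows, names=("A", "B", "C")):
        aln = Alignment("fam", list(names), np.array(rows, dtype=np.int8))
        return AlignmentSet([(aln, tree)])

    def test_single_column_site_test_equals_column_loglik(self, three_leaf,
                                                          paper_indel_model):
        aset = self.make_set(three_leaf, [[0], [2], [1]])
        got = dataset_loglik(aset, paper_indel_model, "site_test")
        ctx = model_context(paper_indel_model)
        codes = codes_for(three_leaf, {"A": 0, "B": 2, "C": 1})
        assert got == pytest.approx(
            float(family_column_logliks(three_leaf, codes, ctx)[0]), abs=1e-12)

    def test_invisible_pattern_with_no_indel_process(self, cherry, paper_f84):
        # lambda = mu = 0: only a gap ancestor yields all-gap leaves, so
        # P(invisible) = 1 - p and the fit-mode correction is -n log p
        m = IndelModel(0.0, 0.0, paper_f84, 0.97)
        ctx = model_context(m)
        p_inv = invisible_probability(cherry, ctx)
        assert p_inv == pytest.approx(1.0 - m.p, abs=1e-12)
        total = 0.0
        for pat in itertools.product(range(5), repeat=2):
            codes = codes_for(cherry, {"A": pat[0], "B": pat[1]})
            lik = np.exp(family_column_logliks(cherry, codes, ctx)[0])
            if pat != (GAP, GAP):
                total += lik
        assert total == pytest.approx(1.0 - p_inv, abs=1e-12)

    def test_fit_mode_differs_by_stated_terms(self, three_leaf,
                                              paper_indel_model):
        aset = self.make_set(three_leaf, [[0, 1, GAP], [0, 1, 1], [2, 1, 1]])
        plain = dataset_loglik(aset, paper_indel_model, "site_test")
        fit = dataset_loglik(aset, paper_indel_model, "fit")
        ctx = model_context(paper_indel_model)
        p_inv = invisible_probability(three_leaf, ctx)
        expected = plain + np.log1p(-paper_indel_model.p) - 3 * np.log1p(-p_inv)
        assert fit == pytest.approx(expected, abs=1e-10)

    def test_empty_set_rejected(self, paper_indel_model):
        with pytest.raises(ValueError):
            dataset_loglik(AlignmentSet([]), paper_indel_model)


class TestEngineInvariants:
    def test_leaf_order_permutation_invariance(self, rng):
        t1 = read_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")
        t2 = read_newick("((D:0.1,C:0.15):0.08,(B:0.2,A:0.1):0.05);")
        m = random_indel_model(rng)
        ctx = model_context(m)
        for _ in range(10):
            mapping = {lab: int(rng.integers(0, 5)) for lab in "ABCD"}
            if all(v == GAP for v in mapping.values()):
                continue
            l1 = family_column_logliks(t1, codes_for(t1, mapping), ctx)[0]
            l2 = family_column_logliks(t2, codes_for(t2, mapping), ctx)[0]
            assert l1 == pytest.approx(l2, abs=1e-12)

    def test_pulley_principle_in_substitution_limit(self, rng, paper_f84):
        # with lambda = mu = 0 and the reversible residue block, sliding the
        # root along the central branch leaves the likelihood unchanged
        t1 = read_newick("((A:0.1,B:0.2):0.0,(C:0.3,D:0.4):0.1);")
        t2 = read_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.0);")
        m = IndelModel(0.0, 0.0, paper_f84, 0.99)
        ctx = model_context(m)
        for _ in range(10):
            mapping = {lab: int(rng.integers(0, 4)) for lab in "ABCD"}
            l1 = family_column_logliks(t1, codes_for(t1, mapping), ctx)[0]
            l2 = family_column_logliks(t2, codes_for(t2, mapping), ctx)[0]
            assert l1 == pytest.approx(l2, abs=1e-12)

    def test_adding_gaps_never_helps_under_small_indel_rates(self, three_leaf,
                                                             paper_f84):
        m = IndelModel(1e-6, 1e-6, paper_f84, 0.998)
        ctx = model_context(m)
        base = {"A": 0, "B": 0, "C": 0}
        ll_base = family_column_logliks(three_leaf, codes_for(three_leaf, base),
                                        ctx)[0]
        for leaf in "ABC":
            gapped = dict(base, **{leaf: GAP})
            ll_gap = family_column_logliks(three_leaf,
                                           codes_for(three_leaf, gapped), ctx)[0]
            assert ll_gap < ll_base

    def test_unknown_equals_residue_marginalization(self, three_leaf, rng):
        # 'N' must equal the sum of the four residue-pattern likelihoods
        m = random_indel_model(rng)
        ctx = model_context(m)
        mapping = {"A": 0, "B": UNKNOWN, "C": 2}
        got = np.exp(family_column_logliks(
            three_leaf, codes_for(three_leaf, mapping), ctx)[0])
        total = sum(np.exp(family_column_logliks(
            three_leaf, codes_for(three_leaf, dict(mapping, B=b)), ctx)[0])
            for b in range(4))
        assert got == pytest.approx(total, rel=1e-12)
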