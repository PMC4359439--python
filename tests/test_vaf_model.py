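import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from clonephy.genome_model import CNV, MATERNAL, PATERNAL, SSM, UNKNOWN
from clonephy.tssb import TreeState, phi_from_eta
from clonephy.vaf_model import (
    ConstraintError,
    DegenerateLocusError,
    LocusCounts,
    PhyloRelation,
    accumulate_locus_counts,
    case1_infeasible,
    classify_relation,
    expected_vaf_case1,
    expected_vaf_case2or3,
    infer_phi_case3,
    reference_read_probability,
    ssm_log_likelihood,
)


class TestClosedForms:
    def test_case1_worked_example_deletion(self):
        # homozygous deletion of the SSM locus in half the cells
        assert expected_vaf_case1(0.75, 0.5, C=0, Cm=0) == pytest.approx(0.25)

    def test_case1_neutral_maternal_copy_gives_half_phi(self):
        assert expected_vaf_case1(0.6, 0.3, C=2, Cm=1) == pytest.approx(0.30)

    def test_case1_hand_evaluated(self):
        got = expected_vaf_case1(0.5, 0.2, C=3, Cm=2)
        assert got == pytest.approx((0.4 + 0.3) / (1.6 + 0.6))

    def test_case1_requires_nesting(self):
        with pytest.raises(ConstraintError):
            expected_vaf_case1(0.2, 0.5, C=1, Cm=0)

    def test_case23_inverts_printed_example(self):
        # the printed discrimination example: phi_s=0.56 maps back to VAF 0.1
        assert expected_vaf_case2or3(0.56, 0.4, C=11) == pytest.approx(0.1)

    def test_case23_no_cnv_cells_reduces_to_half(self):
        assert expected_vaf_case2or3(0.8, 0.0, C=5) == pytest.approx(0.4)

    def test_case23_hand_evaluated(self):
        assert expected_vaf_case2or3(0.2, 0.5, C=1) == pytest.approx(0.2 / 1.5)

    def test_infer_phi_case3_printed_value(self):
        assert infer_phi_case3(0.1, 0.4, C=11) == pytest.approx(0.56)

    def test_infer_phi_case3_zero_and_hand_value(self):
        assert infer_phi_case3(0.0, 0.3, C=4) == 0.0
        assert infer_phi_case3(0.25, 0.5, C=1) == pytest.approx(0.375)

    def test_case1_infeasibility_examples(self):
        assert case1_infeasible(0.1, 0.4, C=11, Cm=10) is True
        assert case1_infeasible(0.9, 0.4, C=11, Cm=1) is False  # Cm=1: rhs 0
        assert case1_infeasible(0.5, 0.1, C=4, Cm=3) is False   # 1.1 vs 0.2

    @given(x=st.floats(0, 1), phi_c=st.floats(0.01, 1), Cm=st.integers(0, 10),
           Cp=st.integers(0, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_infeasibility_iff_negative_phi_s(self, x, phi_c, Cm, Cp):
        # solving Case 1 for phi_s: phi_s = x*denom - (Cm-1)*phi_c
        C = Cm + Cp
        phi_s = x * (2 * (1 - phi_c) + C * phi_c) - (Cm - 1) * phi_c
        assert case1_infeasible(x, phi_c, C, Cm) == (phi_s < 0)


def _chain_tree(etas):
    tree = TreeState(n_samples=1)
    parent = tree.root
    tree.root.eta[0] = etas[0]
    for e in etas[1:]:
        node = tree._new_node(parent)
        node.eta[0] = e
        parent.children.append(node)
        parent = node
    return tree


class TestWorkedExampleAccumulation:
    def test_deleted_ssm_vaf(self, worked_example_tree):
        tree, (a, b, c), deletion = worked_example_tree
        counts = accumulate_locus_counts(
            tree, b, {"cnv1": c}, {"cnv1": deletion}, tree.eta_map(0))
        assert counts.Nr == pytest.approx(0.75)
        assert counts.Nv == pytest.approx(0.25)
        assert 1 - reference_read_probability(counts, 0.0) == pytest.approx(0.25)

    def test_diploid_ssm_at_b(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        counts = accumulate_locus_counts(tree, b, {}, {}, tree.eta_map(0))
        # B and C both carry the SSM: Nr = 2*0.25 + 0.25 + 0.5, Nv = 0.25 + 0.5
        assert (counts.Nr, counts.Nv) == (pytest.approx(1.25), pytest.approx(0.75))
        assert 1 - reference_read_probability(counts, 0.0) == pytest.approx(0.375)

    def test_diploid_ssm_at_c(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        counts = accumulate_locus_counts(tree, c, {}, {}, tree.eta_map(0))
        assert 1 - reference_read_probability(counts, 0.0) == pytest.approx(0.25)

    def test_ssm_after_homozygous_deletion_is_impossible(self, worked_example_tree):
        tree, (a, b, c), deletion = worked_example_tree
        with pytest.raises(ConstraintError):
            accumulate_locus_counts(tree, c, {"cnv1": c}, {"cnv1": deletion},
                                    tree.eta_map(0))

    def test_everywhere_deleted_locus_degenerate(self):
        tree = _chain_tree([0.0, 1.0])
        root, child = tree.nodes()
        deletion = CNV(id="d", chrom="1", start=0, end=10, C=0, Cm=0, Cp=0, phi=[1.0])
        ssm_node = child
        with pytest.raises((DegenerateLocusError, ConstraintError)):
            accumulate_locus_counts(tree, ssm_node, {"d": root}, {"d": deletion},
                                    tree.eta_map(0))


class TestClassifyRelation:
    def test_worked_example_is_ssm_then_cnv(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        rel, gov = classify_relation(tree, b, c, {"cnv1": c})
        assert rel is PhyloRelation.SSM_THEN_CNV and gov == "cnv1"

    def test_no_cnv_no_ssm(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        rel, gov = classify_relation(tree, b, a, {"cnv1": c})
        assert rel is PhyloRelation.NO_SSM_NO_CNV and gov is None

    def test_same_node_counts_as_cnv_then_ssm(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        rel, _ = classify_relation(tree, c, c, {"cnv1": c})
        assert rel is PhyloRelation.CNV_THEN_SSM

    def test_nearest_of_stacked_cnvs_governs(self, rng):
        # random chains with two CNVs on the root path: the nearer governs
        for _ in range(50):
            k = int(rng.integers(4, 8))
            tree = _chain_tree(list(np.ones(k) / k))
            nodes = tree.nodes()
            hi, lo = sorted(rng.choice(range(1, k), size=2, replace=False))
            pop = nodes[-1]
            cnv_nodes = {"far": nodes[hi], "near": nodes[lo]}
            _, gov = classify_relation(tree, nodes[1], pop, cnv_nodes)
            # brute-force ascent
            expect = None
            u = pop
            while u is not None:
                hits = [cid for cid, n in cnv_nodes.items() if n is u]
                if hits:
                    expect = hits[0]
                    break
                u = u.parent
            assert gov == expect


def _case_oracle(relation, phi_s, phi_c, cnv, phase=MATERNAL):
    Cm = cnv.Cm if phase == MATERNAL else cnv.Cp
    if relation == "case1":
        return expected_vaf_case1(phi_s, phi_c, cnv.C, Cm)
    return expected_vaf_case2or3(phi_s, phi_c, cnv.C)


class TestOracleEquivalence:
    """The five-case accumulation must reproduce the closed forms for any
    single-CNV configuration, at epsilon = 0, to 1e-12."""

    def _random_config(self, rng):
        kind = rng.choice(["case1", "case2", "case3"])
        Cm = int(rng.integers(0, 5))
        Cp = int(rng.integers(0, 4))
        if kind == "case2" and Cm + Cp < 1:
            Cm = 1
        cnv = CNV(id="c", chrom="1", start=0, end=10, C=Cm + Cp, Cm=Cm, Cp=Cp,
                  phi=[0.0])
        if kind == "case1":
            # chain: root -> s -> (spacer) -> c ; phi_s >= phi_c > 0
            etas = rng.dirichlet(np.ones(4))
            tree = _chain_tree(etas)
            nodes = tree.nodes()
            ssm_node, cnv_node = nodes[1], nodes[3]
        elif kind == "case2":
            etas = rng.dirichlet(np.ones(4))
            tree = _chain_tree(etas)
            nodes = tree.nodes()
            ssm_node, cnv_node = nodes[3], nodes[1]
        else:
            # branching: root with two children
            tree = TreeState(n_samples=1)
            e = rng.dirichlet(np.ones(3))
            tree.root.eta[0] = e[0]
            kids = []
            for i in (1, 2):
                node = tree._new_node(tree.root)
                node.eta[0] = e[i]
                tree.root.children.append(node)
                kids.append(node)
            ssm_node, cnv_node = kids
        return kind, tree, ssm_node, cnv_node, cnv

    def test_thousand_random_single_cnv_configs(self):
        rng = np.random.default_rng(20240917)
        checked = 0
        while checked < 1000:
            kind, tree, ssm_node, cnv_node, cnv = self._random_config(rng)
            eta = tree.eta_map(0)
            phi = phi_from_eta(tree, 0)
            phi_s, phi_c = phi[ssm_node], phi[cnv_node]
            if phi_c <= 0 or phi_s <= 0:
                continue
            try:
                counts = accumulate_locus_counts(
                    tree, ssm_node, {"c": cnv_node}, {"c": cnv}, eta, phase=MATERNAL)
                got = 1 - reference_read_probability(counts, 0.0)
            except (ConstraintError, DegenerateLocusError):
                # only possible when no copy survives anywhere; skip
                assert cnv.C < 1
                continue
            expect = _case_oracle(kind, phi_s, phi_c, cnv)
            assert got == pytest.approx(expect, abs=1e-12), (kind, cnv.C, cnv.Cm)
            checked += 1
        assert checked == 1000


class TestReferenceReadProbability:
    def test_worked_example_complement(self):
        assert reference_read_probability(LocusCounts(0.75, 0.25), 0.0) == 0.75

    def test_no_variant_copies_gives_one_minus_eps(self):
        assert reference_read_probability(LocusCounts(2.0, 0.0), 0.01) == pytest.approx(0.99)

    def test_symmetric_counts(self):
        assert reference_read_probability(LocusCounts(1.0, 1.0), 0.01) == 0.5

    def test_zeta_bounded_and_monotone_in_nv(self):
        eps = 0.01
        prev = None
        for nv in np.linspace(0, 5, 20):
            z = reference_read_probability(LocusCounts(1.0, nv), eps)
            assert eps <= z <= 1 - eps
            if prev is not None:
                assert z <= prev + 1e-15
            prev = z


class TestSSMLogLikelihood:
    def test_certain_outcome_has_zero_loglik(self, worked_example_tree):
        tree, (a, b, c), _ = worked_example_tree
        ssm = SSM(id="s", a=[50], d=[50], mu_r=1.0, mu_v=1.0, epsilon=0.0)
        ll = ssm_log_likelihood(ssm, tree, b, {}, {}, [tree.eta_map(0)])
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_no_cnv_reduces_to_binomial_mixture(self):
        # success probability (1-phi)*mu_r + phi*mu_v with phi = 0.5
        tree = _chain_tree([0.5, 0.5])
        child = tree.nodes()[1]
        ssm = SSM(id="s", a=[30], d=[40], mu_r=1.0, mu_v=0.5, epsilon=0.0)
        ll = ssm_log_likelihood(ssm, tree, child, {}, {}, [tree.eta_map(0)])
        assert ll == pytest.approx(binom.logpmf(30, 40, 0.75))

    def test_eq1_reduction_on_phi_grid(self):
        # all-diploid accumulation equals (1-phi)*mu_r + phi*mu_v, mu_r=1-eps
        eps = 0.013
        for phi in np.linspace(0.05, 0.95, 10):
            tree = _chain_tree([1 - phi, phi])
            child = tree.nodes()[1]
            ssm = SSM(id="s", a=[7], d=[20], mu_r=1 - eps, mu_v=0.5, epsilon=eps)
            cnv = CNV(id="c", chrom="1", start=0, end=10, C=2, Cm=1, Cp=1, phi=[phi])
            with_cnv = ssm_log_likelihood(
                ssm, tree, child, {"c": child}, {"c": cnv}, [tree.eta_map(0)])
            p = (1 - phi) * (1 - eps) + phi * 0.5
            assert with_cnv == pytest.approx(binom.logpmf(7, 20, p), abs=1e-9)

    def test_unphased_case5_averages_the_two_phased_likelihoods(self):
        tree = _chain_tree([0.2, 0.5, 0.3])
        _, b, c = tree.nodes()
        cnv = CNV(id="c", chrom="1", start=0, end=10, C=3, Cm=2, Cp=1, phi=[0.3])
        eta = [tree.eta_map(0)]
        lls = {}
        for phase in (MATERNAL, PATERNAL):
            ssm = SSM(id="s", a=[28], d=[60], mu_r=1.0, epsilon=0.0, phase=phase)
            lls[phase] = ssm_log_likelihood(ssm, tree, b, {"c": c}, {"c": cnv}, eta)
        unphased = SSM(id="s", a=[28], d=[60], mu_r=1.0, epsilon=0.0, phase=UNKNOWN)
        got = ssm_log_likelihood(unphased, tree, b, {"c": c}, {"c": cnv}, eta)
        expect = math.log(0.5 * math.exp(lls[MATERNAL]) + 0.5 * math.exp(lls[PATERNAL]))
        assert got == pytest.approx(expect, abs=1e-10)
        assert lls[MATERNAL] != pytest.approx(lls[PATERNAL])
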