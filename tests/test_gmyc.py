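import math

import numpy as np
import pytest

from delimscale.gmyc import (
    classify_lineages,
    fit_gmyc,
    interval_table,
    mixed_loglik,
    moran_lambda,
    null_loglik,
)
from delimscale.trees import node_ages, read_newick

TOY3 = "((a:0.01,b:0.01):0.04,c:0.05);"
TOY5 = "((a:0.01,b:0.01):0.09,((c:0.02,d:0.02):0.03,e:0.05):0.05);"


def brute_loglik(newick, T, lambda_z, p_z, lambda_coal, p_c):
    """Independent evaluation of the mixed waiting-time likelihood.

    Works directly from tip sets and node ages: lineages are tracked as
    sets of tip labels, clusters are identified from first principles, and
    the interval sum is accumulated in a plain loop.
    """
    tree = read_newick(newick)
    ages = node_ages(tree)
    nodes = [(ages[n], frozenset(l.taxon.label for l in n.leaf_iter()))
             for n in tree.preorder_node_iter() if not n.is_leaf()]
    nodes.sort(key=lambda t: t[0])
    tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())

    # crossing lineages at T: maximal subtrees with age <= T
    def subtree_sets():
        out = []
        all_nodes = [(ages[n], frozenset(l.taxon.label for l in n.leaf_iter()), n)
                     for n in tree.preorder_node_iter()]
        for age, s, n in all_nodes:
            parent = n.parent_node
            ok = age <= T if not n.is_leaf() else True
            if n.is_leaf():
                age = 0.0
            if age <= T and (parent is None or ages[parent] > T):
                out.append(s)
        return out

    groups = subtree_sets()
    clusters = [g for g in groups if len(g) >= 2]

    def rate_at(t):
        # counts of lineages alive just above time t (t inside an interval)
        alive = [s for a, s in nodes if a >= t]  # ancestors not yet reached
        n_alive = 1 + sum(1 for a, _ in nodes if a > t)  # not used; recompute
        # lineage = every edge crossing t: tips with all ancestors older
        lineages = []
        for tip in tips:
            anc_ages = [a for a, s in nodes if tip in s]
            # the lineage containing this tip at time t is the youngest
            # ancestor set with age >= t... build lineage sets instead:
        # build lineage sets: start from tips, merge nodes with age < t
        lin = [frozenset([x]) for x in sorted(tips)]
        for a, s in nodes:
            if a < t:
                merged = [l for l in lin if l <= s]
                lin = [l for l in lin if not (l <= s)]
                lin.append(frozenset().union(*merged))
        total = 0.0
        if t > T:
            nz = len(lin)
            if nz > 0:
                total += lambda_z * nz**p_z
        else:
            for cl in clusters:
                k = sum(1 for l in lin if l <= cl)
                if k >= 2:
                    total += lambda_coal * (k * (k - 1)) ** p_c
            n_singleton = sum(1 for l in lin if not any(l <= cl for cl in clusters))
            if n_singleton > 0:
                total += lambda_z * n_singleton**p_z
        return total

    boundaries = sorted({0.0, *[a for a, _ in nodes]})
    if 0.0 < T < boundaries[-1]:
        boundaries = sorted(set(boundaries) | {T})
    logL = 0.0
    for lo, hi in zip(boundaries, boundaries[1:]):
        mid = (lo + hi) / 2.0
        b = rate_at(mid)
        logL -= b * (hi - lo)
        if any(abs(a - hi) < 1e-15 for a, _ in nodes):  # event closes interval
            if b <= 0:
                return -math.inf
            logL += math.log(b)
    return logL


class TestMixedLoglikOracle:
    def test_three_tip_pure_yule_hand_value(self):
        tree = read_newick(TOY3)
        # T=0: two intervals with 3 and 2 lineages; lambda_z=1, p_z=1
        expected = math.log(3) + math.log(2) - (3 * 0.01 + 2 * 0.04)
        assert mixed_loglik(tree, 0.0, 1.0, 1.0, 5.0, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "newick,T,params",
        [
            (TOY3, 0.0, (1.0, 1.0, 5.0, 1.0)),
            (TOY3, 0.03, (2.0, 1.5, 40.0, 0.8)),
            (TOY5, 0.03, (3.0, 1.2, 25.0, 0.9)),
            (TOY5, 0.015, (1.5, 2.0, 60.0, 1.1)),
            (TOY5, 0.5, (1.0, 1.0, 8.0, 1.0)),
        ],
    )
    def test_agrees_with_independent_evaluation(self, newick, T, params):
        tree = read_newick(newick)
        got = mixed_loglik(tree, T, *params)
        expected = brute_loglik(newick, T, *params)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_scaling_identity(self):
        # logL(c*ages, lambda/c) = logL - n_events*log(c)
        c = 2.0
        t1 = read_newick(TOY5)
        t2 = read_newick(
            "((a:0.02,b:0.02):0.18,((c:0.04,d:0.04):0.06,e:0.1):0.1);"
        )
        lz, pz, lc, pc = 3.0, 1.2, 25.0, 0.9
        l1 = mixed_loglik(t1, 0.03, lz, pz, lc, pc)
        l2 = mixed_loglik(t2, 0.06, lz / c, pz, lc / c, pc)
        n_events = 4
        assert l2 == pytest.approx(l1 - n_events * math.log(c), abs=1e-8)

    def test_nesting_whole_tree_cluster_equals_null(self):
        tree = read_newick(TOY5)
        assert mixed_loglik(tree, 1.0, 9.9, 3.3, 12.0, 0.7) == pytest.approx(
            null_loglik(tree, 12.0, 0.7), abs=1e-12
        )


class TestClassifyLineages:
    def test_threshold_above_root_single_entity(self):
        clusters, singles, part = classify_lineages(read_newick(TOY5), 1.0)
        assert len(clusters) == 1 and not singles
        assert len(set(part.values())) == 1

    def test_threshold_below_all_nodes_all_singletons(self):
        clusters, singles, part = classify_lineages(read_newick(TOY5), 0.001)
        assert not clusters and len(singles) == 5
        assert len(set(part.values())) == 5

    def test_two_cherries(self):
        tree = read_newick("((a:0.01,b:0.01):0.09,(c:0.01,d:0.01):0.09);")
        clusters, singles, part = classify_lineages(tree, 0.05)
        assert clusters == [["a", "b"], ["c", "d"]]
        assert not singles

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError):
            classify_lineages(read_newick("((a:1,b:1):1,c:5);"), 0.5)


class TestMoranLambda:
    def test_two_tip_closed_form(self):
        assert moran_lambda(read_newick("(a:0.03,b:0.03);")) == pytest.approx(
            1 / (2 * 0.03)
        )

    def test_halving_waiting_times_doubles_lambda(self):
        lam1 = moran_lambda(read_newick(TOY5))
        half = read_newick(
            "((a:0.005,b:0.005):0.045,((c:0.01,d:0.01):0.015,e:0.025):0.025);"
        )
        assert moran_lambda(half) == pytest.approx(2 * lam1)

    def test_near_zero_interval_inflates(self):
        # waiting intervals: x (3 lineages) then 1e-4 (2 lineages);
        # lambda = 2 / (6x + 2e-4) explodes as x -> 0
        def tree_with_first_interval(x):
            top = x + 1e-4
            return read_newick(f"((a:{x},b:{x}):1e-4,c:{top});")

        lam_small = moran_lambda(tree_with_first_interval(1e-3))
        lam_tiny = moran_lambda(tree_with_first_interval(1e-12))
        assert lam_tiny / lam_small >= 10


def five_species_tree():
    """Deep stems (age ~0.02-0.04), shallow crowns (age 0.001)."""
    c = "({0}1:0.001,{0}2:0.001)"
    crowns = [c.format(s) for s in "vwxyz"]
    return read_newick(
        f"(({crowns[0]}:0.019,{crowns[1]}:0.019):0.02,"
        f"(({crowns[2]}:0.024,{crowns[3]}:0.024):0.01,{crowns[4]}:0.034):0.005);"
    )


class TestFitGmyc:
    def test_recovers_planted_five_species(self):
        fit = fit_gmyc(five_species_tree())
        assert fit.n_entities == 5
        assert fit.n_clusters == 5
        assert 0.001 < fit.threshold < 0.02

    def test_mixed_at_least_null(self):
        fit = fit_gmyc(five_species_tree())
        assert fit.logL_mixed >= fit.logL_null - 1e-6
        assert fit.lr >= 0

    def test_entities_non_increasing_in_threshold(self):
        tree = five_species_tree()
        ages = sorted(
            {round(a, 12) for n, a in node_ages(tree).items() if not n.is_leaf()}
        )
        grid = [ages[0] / 2] + [
            (a + b) / 2 for a, b in zip(ages, ages[1:])
        ] + [ages[-1] * 1.5]
        counts = [len(set(classify_lineages(tree, T)[2].values())) for T in grid]
        assert counts == sorted(counts, reverse=True)

    def test_lambda_coal_is_at_a_local_maximum(self):
        fit = fit_gmyc(five_species_tree())
        base = mixed_loglik(
            five_species_tree(),
            fit.threshold,
            fit.lambda_z,
            fit.p_z,
            fit.lambda_coal,
            fit.p_c,
        )
        for f in (0.9, 0.95, 1.05, 1.1):
            perturbed = mixed_loglik(
                five_species_tree(),
                fit.threshold,
                fit.lambda_z,
                fit.p_z,
                fit.lambda_coal * f,
                fit.p_c,
            )
            assert perturbed <= base + 1e-6

    def test_zero_branch_warning(self):
        tree = read_newick(
            "((a:0.0,b:0.0):0.02,(c:0.01,d:0.01):0.01);"
        )
        fit = fit_gmyc(tree)
        assert any("near-zero" in w for w in fit.warnings)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            fit_gmyc(read_newick("(a:0.1,b:0.1);"))


class TestIntervalTable:
    def test_waiting_times_sum_to_root_age(self):
        tree = read_newick(TOY5)
        for T in (0.0, 0.015, 0.03, 0.2):
            tab = interval_table(tree, T)
            assert tab.x.sum() == pytest.approx(0.10, abs=1e-12)
            assert tab.n_events == 4
            assert np.all(tab.x >= 0)
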