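"""Brownian-motion ancestral state reconstruction and its oracles."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pytest
from scipy import optimize

from skimrepeats.ancestral import PhyloTree, branch_deltas, ml_ancestral_bm


SIX_TIP_NEWICK = (
    "((A:1.2,B:0.8):0.6,((C:0.5,D:1.1):0.9,(E:0.7,F:1.4):0.4):0.3):0.0;"
)
SIX_TIP_VALUES = {"A": 10.0, "B": 14.0, "C": 7.5, "D": 9.0, "E": 21.0, "F": 16.5}


def _bm_neg_loglik(tree: dendropy.Tree, states: dict, sigma2: float) -> float:
    """Joint BM log-likelihood with explicit ancestral states."""
    ll = 0.0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        b = node.edge.length
        diff = states[id(node)] - states[id(parent)]
        ll += -0.5 * (np.log(2 * np.pi * sigma2 * b) + diff**2 / (sigma2 * b))
    return -ll


class TestClosedForm:
    def test_constant_tips_give_constant_nodes(self):
        phylo = PhyloTree.from_newick(
            SIX_TIP_NEWICK, {k: 5.0 for k in SIX_TIP_VALUES}
        )
        res = ml_ancestral_bm(phylo)
        for v in res.node_estimates.values():
            assert v == pytest.approx(5.0)
        assert res.sigma_squared == pytest.approx(0.0, abs=1e-18)

    def test_two_tip_symmetric_root_is_mean(self):
        phylo = PhyloTree.from_newick("(A:1.0,B:1.0);", {"A": 2.0, "B": 6.0})
        res = ml_ancestral_bm(phylo)
        assert res.node_estimates[res.root_id] == pytest.approx(4.0)

    def test_tip_estimates_equal_observations(self):
        phylo = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
        res = ml_ancestral_bm(phylo)
        for tip, value in SIX_TIP_VALUES.items():
            assert res.node_estimates[tip] == value

    def test_matches_numerical_likelihood_maximisation(self):
        """Internal-node estimates maximize the joint BM likelihood
        (scipy optimizer oracle, 1e-6 relative agreement)."""
        phylo = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
        res = ml_ancestral_bm(phylo)
        tree = phylo.tree
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        tips = {id(n): SIX_TIP_VALUES[n.taxon.label] for n in tree.leaf_node_iter()}

        def neg(params):
            states = dict(tips)
            states.update({id(n): p for n, p in zip(internal, params)})
            return _bm_neg_loglik(tree, states, max(res.sigma_squared, 1e-9))

        x0 = np.full(len(internal), np.mean(list(SIX_TIP_VALUES.values())))
        opt = optimize.minimize(neg, x0, method="Nelder-Mead", tol=1e-12)
        # map optimizer states back through the same labeling walk
        counter = {"n": 0}
        from skimrepeats.ancestral import _node_label

        labels = {}
        for node in tree.preorder_node_iter():
            labels[id(node)] = _node_label(node, counter)
        for node, opt_val in zip(internal, opt.x):
            mine = res.node_estimates[labels[id(node)]]
            assert mine == pytest.approx(opt_val, rel=1e-6, abs=1e-6)

    def test_branch_rescaling_invariance(self):
        phylo1 = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
        scaled = SIX_TIP_NEWICK
        for a, b in (("1.2", "12.0"), ("0.8", "8.0"), ("0.6", "6.0"),
                     ("0.5", "5.0"), ("1.1", "11.0"), ("0.9", "9.0"),
                     ("0.7", "7.0"), ("1.4", "14.0"), ("0.4", "4.0"),
                     ("0.3", "3.0")):
            scaled = scaled.replace(f":{a}", f":{b}")
        phylo2 = PhyloTree.from_newick(scaled, SIX_TIP_VALUES)
        r1, r2 = ml_ancestral_bm(phylo1), ml_ancestral_bm(phylo2)
        for k in r1.node_estimates:
            assert r1.node_estimates[k] == pytest.approx(r2.node_estimates[k])

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="branch length"):
            PhyloTree.from_newick("(A:1.0,B:0.0);", {"A": 1, "B": 2})
        with pytest.raises(ValueError, match="tip values"):
            PhyloTree.from_newick("(A:1.0,B:1.0);", {"A": 1})


class TestBranchDeltas:
    def test_signed_deltas(self):
        phylo = PhyloTree.from_newick("(A:1.0,B:1.0);", {"A": 4680.0, "B": 2480.0})
        res = ml_ancestral_bm(phylo)
        deltas = branch_deltas(res, res.root_id)
        root = res.node_estimates[res.root_id]
        assert deltas["A"] == pytest.approx(4680 - root)
        assert deltas["B"] == pytest.approx(2480 - root)

    def test_zero_delta_when_tip_equals_reference(self):
        phylo = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
        res = ml_ancestral_bm(phylo)
        res.node_estimates["fixed"] = 10.0
        assert branch_deltas(res, "fixed")["A"] == 0.0

    def test_unknown_reference(self):
        phylo = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
        res = ml_ancestral_bm(phylo)
        with pytest.raises(KeyError):
            branch_deltas(res, "nope")


def _simulate_bm(tree: dendropy.Tree, root_value: float, sigma2: float, rng):
    states = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            states[id(node)] = root_value
        else:
            b = node.edge.length
            states[id(node)] = states[id(parent)] + rng.normal(0, np.sqrt(sigma2 * b))
    return {n.taxon.label: states[id(n)] for n in tree.leaf_node_iter()}


TWELVE_TIP_NEWICK = (
    "(((T1:0.4,T2:0.6):0.5,(T3:0.8,T4:0.3):0.7):0.4,"
    "((T5:0.5,T6:0.5):0.6,((T7:0.4,T8:0.9):0.3,"
    "((T9:0.6,T10:0.4):0.5,(T11:0.7,T12:0.8):0.2):0.3):0.4):0.5);"
)


def test_root_recovery_over_replicates():
    """Mean root estimate over 200 BM replicates sits within 2 SE of
    the generating root value."""
    true_root, sigma2 = 3000.0, 40000.0
    rng = np.random.default_rng(77)
    estimates = []
    base = dendropy.Tree.get(data=TWELVE_TIP_NEWICK, schema="newick",
                             preserve_underscores=True)
    for _ in range(200):
        tips = _simulate_bm(base, true_root, sigma2, rng)
        phylo = PhyloTree.from_newick(TWELVE_TIP_NEWICK, tips)
        res = ml_ancestral_bm(phylo)
        estimates.append(res.node_estimates[res.root_id])
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - true_root) <= 2 * se


def test_matches_r_ape_ace_reference(tmp_path):
    """Cross-check against the independent R implementation (ape::ace,
    ML under BM) on the six-tip tree."""
    script = tmp_path / "ace.R"
    script.write_text(textwrap.dedent(f"""
        library(ape)
        tree <- read.tree(text="{SIX_TIP_NEWICK}")
        x <- c(A=10.0, B=14.0, C=7.5, D=9.0, E=21.0, F=16.5)
        fit <- ace(x[tree$tip.label], tree, type="continuous", method="REML")
        fit2 <- ace(x[tree$tip.label], tree, type="continuous", method="ML")
        cat(fit2$ace, sep="\\n")
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        timeout=300,
    )
    assert out.returncode == 0, out.stderr
    r_states = [float(v) for v in out.stdout.split()]
    phylo = PhyloTree.from_newick(SIX_TIP_NEWICK, SIX_TIP_VALUES)
    res = ml_ancestral_bm(phylo)
    mine = [res.node_estimates[f"node{i}"] for i in range(1, len(r_states) + 1)]
    assert mine == pytest.approx(r_states, rel=1e-4)
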