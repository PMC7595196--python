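"""Tree handling, time calibration, phylogenetic signal and ancestral states."""

import numpy as np
import pandas as pd
import pytest

from dmta import (Specimen, StratRange, TimeTree, TreeParseError,
                  ancestral_states, blomberg_k, correlate_scores_with_age,
                  graft_taxon, pagel_lambda, phylo_texture_space, prune_tree,
                  read_tree, select_largest_per_taxon, simulate_tree_and_traits,
                  time_calibrate_equal, tree_vcv, write_tree)

# ---------------------------------------------------------------------------
# Fixture tree with reference values computed with an independent
# comparative-methods implementation (R phytools 2.5: phylosig, fastAnc)
# and frozen here.
# ---------------------------------------------------------------------------
FIXTURE_NEWICK = (
    "(((T11:7.52855796187753,T12:7.52855796187753):3.5234392187467876,"
    "T1:11.05199718062432):14.710336469580966,((T3:21.35006719766823,"
    "(T5:3.5984248960644494,T6:3.5984248960644494):17.751642301603784)"
    ":3.391513969768794,((T4:21.772023555549456,((T9:3.5155363961459694,"
    "T8:3.5155363961459694):16.61428733981285,(T2:11.47842097493278,"
    "T10:11.47842097493278):8.651402761026041):1.642199819590639)"
    ":2.6527315936592166,T7:24.424755149208675):0.31682601822834916)"
    ":1.0207524827682586):6.021728478971499;")
FIXTURE_TRAITS = {
    "T11": 6.0439179987008105, "T12": 1.2833099566071016,
    "T1": -0.8594429251972578, "T3": 0.25733123012375964,
    "T5": 0.1589284230114658, "T6": 6.634880931859387,
    "T4": -0.11618620509996325, "T9": 3.4688400515686006,
    "T8": 1.5431579467198737, "T2": 1.9089709910989603,
    "T10": -3.3628617457128733, "T7": -8.071403836643766,
}
PHYTOOLS_K = 0.5514609206
PHYTOOLS_LAMBDA_LOGL = -32.9668099838   # logL at phytools' boundary estimate
PHYTOOLS_ASR = {
    # node (by '|'-joined descendant tip set): (estimate, variance)
    "T8|T9": (2.27466268, 2.049543),
    "T5|T6": (3.11782085, 2.108709),
    "T11|T12": (2.50853545, 3.508547),
    "|".join(sorted(["T1", "T10", "T11", "T12", "T2", "T3", "T4", "T5", "T6",
                     "T7", "T8", "T9"])): (-0.04278459, 5.517620),
}


class TestNewick:
    def test_basic_parse(self):
        t = read_tree("((A,B),C);")
        assert len(t.leaf_nodes()) == 3
        assert sum(1 for _ in t.preorder_internal_node_iter()) == 2

    def test_roundtrip_with_lengths(self):
        t = read_tree(FIXTURE_NEWICK)
        back = read_tree(write_tree(t))
        la, Ca = tree_vcv(t)
        lb, Cb = tree_vcv(back)
        assert la == lb
        np.testing.assert_allclose(Ca, Cb, atol=1e-9)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeParseError, match="duplicate"):
            read_tree("((A,A),C);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeParseError):
            read_tree("((A,B,C);")


class TestEqualCalibration:
    def test_strat_range_invariant(self):
        StratRange("ok", 150.0, 140.0)
        with pytest.raises(ValueError, match="FAD >= LAD"):
            StratRange("bad", 140.0, 150.0)

    def test_two_tip_hand_example(self):
        # FADs 150 and 140, extension 10: root 160, branches 10 and 20
        tt = time_calibrate_equal(read_tree("(A,B);"),
                                  {"A": (150, 145), "B": (140, 130)},
                                  root_extension=10)
        assert tt.root_age == pytest.approx(160.0)
        bl = {lf.taxon.label: lf.edge.length for lf in tt.tree.leaf_node_iter()}
        assert bl["A"] == pytest.approx(10.0)
        assert bl["B"] == pytest.approx(20.0)

    def test_three_tip_redistribution_by_hand(self):
        # initial ages: (A,B) node at B's FAD 110, root at 130 + 5 = 135.
        # B's branch starts at zero; the span root -> (A,B) -> B (25 Myr)
        # is split equally, moving the (A,B) node to 122.5
        tt = time_calibrate_equal(read_tree("((A,B),C);"),
                                  {"A": (100, 90), "B": (110, 100), "C": (130, 120)},
                                  root_extension=5)
        ages = {tuple(sorted(l.taxon.label for l in nd.leaf_iter())): nd.age
                for nd in tt.tree.preorder_internal_node_iter()}
        assert ages[("A", "B", "C")] == pytest.approx(135.0)
        assert ages[("A", "B")] == pytest.approx(122.5)
        bl = {lf.taxon.label: lf.edge.length for lf in tt.tree.leaf_node_iter()}
        assert bl == pytest.approx({"A": 22.5, "B": 12.5, "C": 5.0})

    def test_ladder_with_identical_fads(self):
        # all FADs equal: every internal branch must become positive and the
        # root-to-tip span must stay equal to the extension
        top = read_tree("((((A,B),C),D),E);")
        ranges = {t: (100.0, 95.0) for t in "ABCDE"}
        tt = time_calibrate_equal(top, ranges, root_extension=8)
        tt.validate()
        assert tt.root_age == pytest.approx(108.0)
        for nd in tt.tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length > 0
        for lf in tt.tree.leaf_node_iter():
            assert lf.age == pytest.approx(100.0)  # tips pinned at FAD

    def test_tip_depth_equals_root_age_minus_fad(self):
        ranges = {"A": (150, 140), "B": (120, 100), "C": (90, 80), "D": (85, 70)}
        tt = time_calibrate_equal(read_tree("((A,B),(C,D));"), ranges, 2.0)
        labels, C = tree_vcv(tt)
        for lab, d in zip(labels, np.diag(C)):
            assert d == pytest.approx(tt.root_age - ranges[lab][0])

    def test_zero_extension_with_basal_chain_raises(self):
        top = read_tree("((A,B),C);")
        ranges = {t: (100.0, 90.0) for t in "ABC"}
        with pytest.raises(ValueError, match="root_extension"):
            time_calibrate_equal(top, ranges, root_extension=0.0)


class TestPruneGraft:
    def test_prune_hand_example(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        out = prune_tree(t, ["A", "C"])
        s = write_tree(out).replace(" ", "")
        assert s in ("(A:2.0,C:2.0);", "(C:2.0,A:2.0);")

    def test_prune_preserves_patristic_distances(self):
        tt, traits, _ = simulate_tree_and_traits(12, seed=8)
        keep = tt.tip_labels()[:6]
        la, Ca = tree_vcv(tt)
        pruned = prune_tree(tt, keep)
        lb, Cb = tree_vcv(pruned)
        ia = [la.index(l) for l in lb]
        da = np.add.outer(np.diag(Ca), np.diag(Ca)) - 2 * Ca  # patristic
        db = np.add.outer(np.diag(Cb), np.diag(Cb)) - 2 * Cb
        np.testing.assert_allclose(db, da[np.ix_(ia, ia)], atol=1e-9)

    def test_prune_all_tips_is_identity(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        out = prune_tree(t, ["A", "B", "C"])
        _, Ca = tree_vcv(t)
        _, Cb = tree_vcv(out)
        np.testing.assert_allclose(Ca, Cb)

    def test_prune_unknown_taxon_named(self):
        with pytest.raises(ValueError, match="Z"):
            prune_tree(read_tree("((A,B),C);"), ["A", "Z"])

    def test_prune_too_small_keep_set(self):
        with pytest.raises(ValueError, match="at least 2"):
            prune_tree(read_tree("((A,B),C);"), ["A"])

    def test_graft_sister_to_tip(self):
        t = graft_taxon(read_tree("((A,B),C);"), "X", "B")
        labels = sorted(l.taxon.label for l in t.leaf_node_iter())
        assert labels == ["A", "B", "C", "X"]
        # X sister to B: their MRCA excludes A
        key = {tuple(sorted(l.taxon.label for l in nd.leaf_iter()))
               for nd in t.preorder_internal_node_iter()}
        assert ("B", "X") in key

    def test_graft_onto_clade(self):
        t = graft_taxon(read_tree("((A,B),C);"), "X", ["A", "B"],
                        attach_type="clade")
        key = {tuple(sorted(l.taxon.label for l in nd.leaf_iter()))
               for nd in t.preorder_internal_node_iter()}
        assert ("A", "B", "X") in key and ("A", "B") in key

    def test_graft_missing_attachment(self):
        with pytest.raises(ValueError, match="'Q'"):
            graft_taxon(read_tree("((A,B),C);"), "X", "Q")


class TestSelectLargest:
    def test_max_jaw_wins(self):
        sps = [Specimen(f"s{i}", "Rhamphorhynchus", jaw_length_cm=j)
               for i, j in enumerate([10.2, 19.7, 6.1])]
        out = select_largest_per_taxon(sps)
        assert [s.specimen_id for s in out] == ["s1"]

    def test_singleton_passes_through(self):
        sps = [Specimen("only", "Dimorphodon")]
        assert select_largest_per_taxon(sps) == sps

    def test_tie_breaks_lexicographically_with_warning(self):
        sps = [Specimen("b2", "T", jaw_length_cm=12.0),
               Specimen("a1", "T", jaw_length_cm=12.0)]
        with pytest.warns(UserWarning, match="tie"):
            out = select_largest_per_taxon(sps)
        assert out[0].specimen_id == "a1"

    def test_taxon_without_jaws_raises(self):
        sps = [Specimen("x", "T"), Specimen("y", "T")]
        with pytest.raises(ValueError, match="jaw length"):
            select_largest_per_taxon(sps)


class TestBlombergK:
    def test_matches_reference_implementation(self):
        t = read_tree(FIXTURE_NEWICK)
        res = blomberg_k(t, FIXTURE_TRAITS, n_perm=999, seed=1)
        assert res.estimate == pytest.approx(PHYTOOLS_K, abs=1e-8)

    def test_permutation_p_is_seed_reproducible(self):
        t = read_tree(FIXTURE_NEWICK)
        p1 = blomberg_k(t, FIXTURE_TRAITS, n_perm=199, seed=42).p
        p2 = blomberg_k(t, FIXTURE_TRAITS, n_perm=199, seed=42).p
        assert p1 == p2

    def test_shuffling_destroys_signal(self):
        # K of the BM trait exceeds K of tip-shuffled traits almost always
        wins = 0
        for s in range(40):
            tt, tr, _ = simulate_tree_and_traits(25, seed=80_000 + s)
            k_bm = blomberg_k(tt, tr, n_perm=0).estimate
            rng = np.random.default_rng(s)
            labels = list(tr)
            shuffled = dict(zip(labels, rng.permutation([tr[l] for l in labels])))
            k_sh = blomberg_k(tt, shuffled, n_perm=0).estimate
            wins += k_sh < k_bm
        assert wins >= 38  # >= 95% of replicates

    def test_star_tree_rejected(self):
        t = read_tree("(A:1,B:1,C:1,D:1);")
        with pytest.raises(ValueError, match="star"):
            blomberg_k(t, {"A": 1, "B": 2, "C": 3, "D": 4}, n_perm=0)

    def test_constant_trait_rejected(self):
        t = read_tree(FIXTURE_NEWICK)
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(t, {k: 1.0 for k in FIXTURE_TRAITS}, n_perm=0)


class TestPagelLambda:
    def test_matches_reference_loglik(self):
        t = read_tree(FIXTURE_NEWICK)
        res = pagel_lambda(t, FIXTURE_TRAITS)
        # boundary case: phytools stops at λ=1e-4, we reach the 0 boundary;
        # the profile log-likelihoods must agree
        assert res.estimate == pytest.approx(0.0, abs=1e-3)
        assert res.detail["loglik"] == pytest.approx(PHYTOOLS_LAMBDA_LOGL, abs=2e-4)

    def test_lambda_zero_limit_is_independent_normals(self):
        # λ = 0: covariance reduces to its diagonal; likelihood must match
        # the closed-form independent-normals likelihood
        t = read_tree(FIXTURE_NEWICK)
        from dmta.phylo import _lambda_loglik, tree_vcv as vcv
        labels, C = vcv(t)
        x = np.array([FIXTURE_TRAITS[l] for l in labels])
        ll0 = _lambda_loglik(0.0, C.copy(), x)
        v = np.diag(C)
        w = 1.0 / v
        mu = (w * x).sum() / w.sum()
        s2 = ((x - mu) ** 2 / v).sum() / len(x)
        ll_ref = -0.5 * (len(x) * np.log(2 * np.pi * s2)
                         + np.log(v).sum() + len(x))
        assert ll0 == pytest.approx(ll_ref, abs=1e-9)

    def test_lambda_one_transform_is_identity(self):
        tt, tr, _ = simulate_tree_and_traits(15, seed=21)
        from dmta.phylo import _lambda_loglik
        labels, C = tree_vcv(tt)
        x = np.array([tr[l] for l in labels])
        assert _lambda_loglik(1.0, C.copy(), x) == pytest.approx(
            _lambda_loglik(1.0 - 1e-12, C.copy(), x), abs=1e-6)


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        t = read_tree("(A:1,B:1);")
        rec = ancestral_states(t, {"A": 1.0, "B": 3.0})
        assert rec.root_estimate == pytest.approx(2.0)

    def test_three_tip_gls_oracle(self):
        # independent explicit GLS solve, coded from the normal equations
        t = read_tree("((A:1,B:1):1,C:2);")
        vals = {"A": 0.0, "B": 2.0, "C": 4.0}
        rec = ancestral_states(t, vals)
        labels, C = tree_vcv(t)
        x = np.array([vals[l] for l in labels])
        Ci = np.linalg.inv(C)
        one = np.ones(3)
        mu = (one @ Ci @ x) / (one @ Ci @ one)
        # internal node (A,B): shared path with A and B = 1, with C = 0
        cv = np.array([1.0 if l in ("A", "B") else 0.0 for l in labels])
        est_ref = mu + cv @ Ci @ (x - mu)
        got = rec.nodes.loc["A|B", "estimate"]
        assert got == pytest.approx(est_ref, abs=1e-10)
        assert rec.root_estimate == pytest.approx(mu, abs=1e-10)

    def test_matches_reference_implementation(self):
        t = read_tree(FIXTURE_NEWICK)
        rec = ancestral_states(t, FIXTURE_TRAITS)
        for key, (est, var) in PHYTOOLS_ASR.items():
            row = rec.nodes.loc[key]
            assert row["estimate"] == pytest.approx(est, abs=1e-6)
            assert row["variance"] == pytest.approx(var, abs=1e-5)
            assert row["ci_low"] == pytest.approx(est - 1.96 * np.sqrt(var), abs=1e-4)

    def test_constant_trait_reconstructs_constant(self):
        t = read_tree(FIXTURE_NEWICK)
        rec = ancestral_states(t, {k: 2.5 for k in FIXTURE_TRAITS})
        np.testing.assert_allclose(rec.nodes["estimate"], 2.5, atol=1e-9)

    def test_affine_equivariance_and_tip_order_invariance(self):
        tt, tr, _ = simulate_tree_and_traits(10, seed=31)
        rec1 = ancestral_states(tt, tr)
        shifted = {k: 3.0 * v - 7.0 for k, v in tr.items()}
        rec2 = ancestral_states(tt, shifted)
        np.testing.assert_allclose(rec2.nodes["estimate"],
                                   3.0 * rec1.nodes["estimate"] - 7.0, atol=1e-8)
        reordered = dict(reversed(list(tr.items())))
        rec3 = ancestral_states(tt, reordered)
        np.testing.assert_allclose(rec3.nodes["estimate"],
                                   rec1.nodes["estimate"], atol=1e-10)

    def test_root_within_tip_range(self):
        tt, tr, _ = simulate_tree_and_traits(15, seed=41)
        rec = ancestral_states(tt, tr)
        assert min(tr.values()) <= rec.root_estimate <= max(tr.values())


class TestPhyloTextureSpace:
    def test_two_tip_root_at_midpoint(self):
        t = read_tree("(A:1,B:1);")
        scores = pd.DataFrame({"PC1": [0.0, 2.0], "PC2": [1.0, 3.0]},
                              index=["A", "B"])
        nodes, edges = phylo_texture_space(t, scores)
        root = nodes.loc["A|B"]
        assert root["PC1"] == pytest.approx(1.0)
        assert root["PC2"] == pytest.approx(2.0)
        assert len(edges) == 2

    def test_nodes_equal_per_axis_ancestral_states(self):
        tt, tr, _ = simulate_tree_and_traits(8, seed=51)
        tr2 = {k: -0.5 * v for k, v in tr.items()}
        scores = pd.DataFrame({"PC1": pd.Series(tr), "PC2": pd.Series(tr2)})
        nodes, _ = phylo_texture_space(tt, scores)
        rec = ancestral_states(tt, tr)
        for key, est in rec.nodes["estimate"].items():
            assert nodes.loc[key, "PC1"] == pytest.approx(est, abs=1e-12)

    def test_collinear_scores_stay_collinear(self):
        tt, tr, _ = simulate_tree_and_traits(8, seed=61)
        scores = pd.DataFrame({"PC1": pd.Series(tr),
                               "PC2": 2.0 * pd.Series(tr) + 1.0})
        nodes, _ = phylo_texture_space(tt, scores)
        np.testing.assert_allclose(nodes["PC2"], 2.0 * nodes["PC1"] + 1.0, atol=1e-8)


class TestScoreAgeCorrelation:
    def test_monotone_with_age(self):
        ranges = {"A": (150, 140), "B": (120, 100), "C": (90, 80), "D": (85, 70)}
        tt = time_calibrate_equal(read_tree("((A,B),(C,D));"), ranges, 2.0)
        # score increasing with time from root = decreasing with FAD
        scores = {"A": 0.1, "B": 0.5, "C": 0.8, "D": 0.9}
        res = correlate_scores_with_age(tt, scores)
        assert res["rs"] == pytest.approx(1.0)

    def test_ultrametric_flagged_undefined(self):
        tt, tr, _ = simulate_tree_and_traits(6, seed=71)
        res = correlate_scores_with_age(tt, tr)
        assert res["undefined"]
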