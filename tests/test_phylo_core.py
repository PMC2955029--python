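"""Likelihood engine checks: brute-force oracles, closed forms, invariances."""

import itertools

import numpy as np
import pytest

from cophylointron.formats_io import AMBIGUITY, MultipleAlignment, SequenceRecord
from cophylointron.phylo_core import (DistanceMatrix, PhyloTree, SubstModel,
                                      TreeLikelihood, bootstrap_columns,
                                      jc_distance_matrix, log_likelihood,
                                      ml_search, nj_tree, patristic,
                                      robinson_foulds)
from cophylointron.phylo_core.search import enumerate_topologies
from cophylointron.synthetic_data import simulate_alignment


def brute_force_site_lnl(tree, aln, model):
    """Sum over all internal-state assignments — oracle for <= 5 taxa.

    Transition probabilities come from scipy's matrix exponential, so the
    oracle shares no code with the engine's eigendecomposition path.
    """
    from scipy.linalg import expm
    rates, weights = model.category_rates()
    Q = model.q_matrix()

    def P(t, r):
        return expm(Q * t * r)

    def mask(c):
        return np.array([1.0 if s in AMBIGUITY[c] else 0.0 for s in "ACGT"])

    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    out = []
    for col in range(aln.n_cols):
        masks = {r.id: mask(r.seq[col]) for r in aln.records}
        tot = 0.0
        for r_, w in zip(rates, weights):
            s = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                assign = {id(n): x for n, x in zip(internals, states)}
                term = model.freqs[assign[id(tree.root)]]
                for n in tree.postorder():
                    if n.parent is None:
                        continue
                    px = assign[id(n.parent)]
                    if n.is_leaf:
                        term *= P(n.length, r_)[px] @ masks[n.label]
                    else:
                        term *= P(n.length, r_)[px, assign[id(n)]]
                s += term
            tot += w * s
        out.append(np.log(tot))
    return np.array(out)


class TestPruning:
    def test_matches_brute_force_gtr_gi(self, four_taxon_tree, small_alignment,
                                        gtr_gi_model):
        mine = log_likelihood(four_taxon_tree, small_alignment,
                              gtr_gi_model).values
        oracle = brute_force_site_lnl(four_taxon_tree, small_alignment,
                                      gtr_gi_model)
        assert np.max(np.abs(mine - oracle)) < 1e-10

    def test_two_taxon_jc_closed_form(self):
        # P(same) = 1/4 + 3/4 e^{-4t/3}; lnL = sum over sites of log(pi * P)
        t = 0.3
        tree = PhyloTree.from_newick(f"(a:{t / 2},b:{t / 2});")
        aln = MultipleAlignment([SequenceRecord("a", "ACGTAC"),
                                 SequenceRecord("b", "ACGTAT")])
        same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        diff = 0.25 * (0.25 * (1 - np.exp(-4 * t / 3)))
        expected = 5 * np.log(same) + np.log(diff)
        total = log_likelihood(tree, aln, SubstModel(family="JC")).total
        assert total == pytest.approx(expected, abs=1e-10)

    def test_rerooting_leaves_site_lnl_unchanged(self, small_alignment,
                                                 gtr_gi_model):
        t1 = PhyloTree.from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);")
        t2 = PhyloTree.from_newick("(a:0.1,b:0.2,(c:0.3,d:0.05):0.15);")
        l1 = log_likelihood(t1, small_alignment, gtr_gi_model).values
        l2 = log_likelihood(t2, small_alignment, gtr_gi_model).values
        assert np.allclose(l1, l2, atol=1e-10)

    def test_gtr_gi_reduces_to_plain_gtr(self, four_taxon_tree,
                                         small_alignment):
        plain = SubstModel(family="GTR", rates=[1.2, 3, 0.8, 1.1, 4, 1],
                           freqs=[0.3, 0.2, 0.2, 0.3])
        degenerate = SubstModel(family="GTR", rates=[1.2, 3, 0.8, 1.1, 4, 1],
                                freqs=[0.3, 0.2, 0.2, 0.3], alpha=1.0,
                                p_inv=0.0, n_cat=1)
        l1 = log_likelihood(four_taxon_tree, small_alignment, plain).values
        l2 = log_likelihood(four_taxon_tree, small_alignment, degenerate).values
        assert np.allclose(l1, l2, atol=1e-12)

    def test_taxon_mismatch_reported(self, four_taxon_tree, gtr_gi_model):
        bad = MultipleAlignment([SequenceRecord(x, "ACGT")
                                 for x in ("a", "b", "c", "zzz")])
        with pytest.raises(ValueError, match="zzz"):
            log_likelihood(four_taxon_tree, bad, gtr_gi_model)

    def test_unimodal_around_optimized_branch(self, five_taxon_sim):
        tree, aln = five_taxon_sim
        model = SubstModel(family="JC")
        tl = TreeLikelihood(tree.copy(), aln, model)
        best = tl.optimize_branch_lengths(max_rounds=4)
        branch = tl.tree.leaves()[0]
        t_opt = branch.length
        for delta in (0.5, 2.0):
            for t in (t_opt * delta, t_opt / delta if t_opt > 1e-6 else 0.01):
                branch.length = t
                tl._P.clear()
                assert tl.log_likelihood() <= best + 1e-6


class TestOptimize:
    def test_fixed_point_from_truth(self, five_taxon_sim):
        tree, aln = five_taxon_sim
        tl = TreeLikelihood(tree.copy(), aln, SubstModel(family="JC"))
        before = tl.log_likelihood()
        after = tl.optimize()
        assert after >= before - 1e-9
        # starting at (near) the generating parameters, little room to move
        assert after - before < 5.0

    def test_branch_length_recovery(self):
        true = PhyloTree.from_newick(
            "((a:0.1,b:0.15):0.08,(c:0.12,d:0.2):0.06,e:0.3);")
        aln = simulate_alignment(true, SubstModel(family="JC"), 5000, seed=3)
        tl = TreeLikelihood(true.copy(), aln, SubstModel(family="JC"))
        tl.optimize()
        est = {l.label: l.length for l in tl.tree.leaves()}
        for leaf in true.leaves():
            assert est[leaf.label] == pytest.approx(leaf.length, rel=0.15)

    def test_alpha_ordering_recovered(self):
        tree = PhyloTree.from_newick(
            "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,e:0.3);")
        fits = []
        for alpha, seed in ((0.5, 5), (5.0, 6)):
            gen = SubstModel(family="JC", alpha=alpha)
            aln = simulate_alignment(tree, gen, 3000, seed=seed)
            tl = TreeLikelihood(tree.copy(), aln,
                                SubstModel(family="JC", alpha=1.0))
            tl.optimize()
            fits.append(tl.model.alpha)
        assert fits[0] < fits[1]


class TestNeighborJoining:
    def test_consistency_on_additive_matrix(self, five_taxon_sim):
        tree, _ = five_taxon_sim
        d = patristic(tree)
        recovered = nj_tree(d)
        assert robinson_foulds(recovered, tree) == 0
        assert np.allclose(patristic(recovered).reorder(d.labels).values,
                           d.values, atol=1e-9)

    def test_three_taxa_three_point_formulas(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = nj_tree(d)
        lengths = {l.label: l.length for l in t.leaves()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_matches_dendropy_nj(self):
        rng = np.random.default_rng(4)
        tree = PhyloTree.from_newick(
            "(((a:0.1,b:0.2):0.05,c:0.3):0.07,(d:0.15,e:0.1):0.12,f:0.2);")
        aln = simulate_alignment(tree, SubstModel(family="JC"), 2000, rng)
        d = jc_distance_matrix(aln)
        mine = nj_tree(d)
        import dendropy
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(d), delimiter=",")
        theirs = pdm.nj_tree()
        theirs_mine = PhyloTree.from_newick(
            theirs.as_string(schema="newick").replace("[&U]", "").strip())
        assert robinson_foulds(mine, theirs_mine) == 0

    def test_too_few_taxa(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(d)


def _pdm_csv(d):
    import io
    buf = io.StringIO()
    buf.write("," + ",".join(d.labels) + "\n")
    for i, lab in enumerate(d.labels):
        buf.write(lab + "," + ",".join(f"{x:.10f}" for x in d.values[i]) + "\n")
    buf.seek(0)
    return buf


class TestSearch:
    def test_equals_exhaustive_at_five_taxa(self, five_taxon_sim):
        tree, aln = five_taxon_sim
        model = SubstModel(family="JC")
        res = ml_search(aln, model, moves=("nni",))
        tops = enumerate_topologies(sorted(aln.ids))
        assert len(tops) == 15
        best = max(
            TreeLikelihood(t, aln, model).optimize_branch_lengths(max_rounds=5)
            for t in tops)
        assert res.lnl == pytest.approx(best, abs=1e-4)
        assert robinson_foulds(res.tree, tree) == 0

    def test_recovers_eight_taxon_tree(self):
        true = PhyloTree.from_newick(
            "(((a:0.1,b:0.12):0.06,(c:0.09,d:0.14):0.05):0.04,"
            "((e:0.11,f:0.1):0.07,g:0.2):0.03,h:0.25);")
        aln = simulate_alignment(true, SubstModel(family="JC"), 5000, seed=8)
        res = ml_search(aln, SubstModel(family="JC"), moves=("nni",))
        assert robinson_foulds(res.tree, true) == 0

    def test_identical_sequences_return_nj_start(self):
        aln = MultipleAlignment([SequenceRecord(x, "ACGTACGTAA")
                                 for x in "abcde"])
        start = nj_tree(jc_distance_matrix(aln))
        res = ml_search(aln, SubstModel(family="JC"), moves=("nni",))
        assert robinson_foulds(res.tree, start) == 0

    def test_spr_moves_also_reach_optimum(self, five_taxon_sim):
        tree, aln = five_taxon_sim
        res_nni = ml_search(aln, SubstModel(family="JC"), moves=("nni",))
        res_spr = ml_search(aln, SubstModel(family="JC"), moves=("nni", "spr"))
        assert res_spr.lnl >= res_nni.lnl - 1e-4


class TestPatristic:
    def test_two_leaves(self):
        t = PhyloTree.from_newick("(a:1,b:2);")
        assert patristic(t).get("a", "b") == pytest.approx(3.0)

    def test_ultrametric_root_to_leaf_equal(self, rng):
        from cophylointron.synthetic_data import simulate_host_tree
        t = simulate_host_tree(10, 1.0, rng)
        d = patristic(t)
        # in an ultrametric tree every pair of cherries has equal depth:
        # max distance to any other leaf is the same for all leaves
        ecc = d.values.max(axis=1)
        assert np.allclose(ecc, ecc[0], atol=1e-9)

    def test_matches_path_enumeration(self, rng):
        from cophylointron.synthetic_data import simulate_host_tree
        t = simulate_host_tree(10, 1.0, rng)
        d = patristic(t)

        def path_length(tree, x, y):
            # brute force: ancestors of each leaf
            nodes = {l.label: l for l in tree.leaves()}
            def anc(n):
                out = []
                while n is not None:
                    out.append(n)
                    n = n.parent
                return out
            ax, ay = anc(nodes[x]), anc(nodes[y])
            common = next(n for n in ax if n in ay)
            dist = 0.0
            for chain in (ax, ay):
                for n in chain:
                    if n is common:
                        break
                    dist += n.length
            return dist

        for x, y in [("h1", "h5"), ("h2", "h9"), ("h3", "h4")]:
            assert d.get(x, y) == pytest.approx(path_length(t, x, y), abs=1e-9)

    def test_missing_branch_length_errors(self):
        from cophylointron.phylo_core.tree import TreeError
        t = PhyloTree.from_newick("(a:1,(b,c:1):1);")
        with pytest.raises(TreeError):
            patristic(t)


class TestBootstrap:
    def test_seed_reproducibility(self, small_alignment):
        b1 = bootstrap_columns(small_alignment, 42)
        b2 = bootstrap_columns(small_alignment, 42)
        assert b1.records == b2.records
        assert bootstrap_columns(small_alignment, 43).records != b1.records

    def test_columns_are_subset_of_original(self, small_alignment):
        boot = bootstrap_columns(small_alignment, 7)
        original = {small_alignment.column(j)
                    for j in range(1, small_alignment.n_cols + 1)}
        for j in range(1, boot.n_cols + 1):
            assert boot.column(j) in original

    def test_column_usage_law_of_large_numbers(self):
        # 10 distinguishable columns: two rows jointly identify the column
        cols = ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT", "GA", "GC"]
        aln = MultipleAlignment([
            SequenceRecord("r1", "".join(c[0] for c in cols)),
            SequenceRecord("r2", "".join(c[1] for c in cols)),
        ])
        n_rep = 10_000
        rng = np.random.default_rng(0)
        usage = dict.fromkeys(cols, 0)
        for _ in range(n_rep):
            boot = bootstrap_columns(aln, rng)
            for j in range(1, boot.n_cols + 1):
                usage[boot.column(j)] += 1
        # each column drawn Binomial(10 * n_rep, 1/10): mean n_rep
        se = np.sqrt(10 * n_rep * 0.1 * 0.9)
        for c in cols:
            assert abs(usage[c] - n_rep) < 3 * se


@pytest.mark.skipif(__import__("shutil").which("Rscript") is None,
                    reason="R not available for the phangorn cross-check")
@pytest.mark.parametrize("alpha,k", [(None, 1), (0.6, 4)])
def test_likelihood_matches_phangorn(tmp_path, alpha, k):
    """GTR (+Γ with category-mean rates) log-likelihood equals phangorn's."""
    import subprocess
    from cophylointron.formats_io import write_fasta
    from cophylointron.phylo_core import log_likelihood
    tree = PhyloTree.from_newick(
        "((a:0.11,b:0.23):0.14,(c:0.31,d:0.07):0.09,e:0.18);")
    model = SubstModel(family="GTR", rates=[1.3, 2.8, 0.7, 1.2, 4.1, 1.0],
                       freqs=[0.31, 0.19, 0.22, 0.28], alpha=alpha,
                       gamma_method="mean")
    aln = simulate_alignment(tree, model, 200, seed=6)
    mine = log_likelihood(tree, aln, model).total
    write_fasta(aln.records, tmp_path / "a.fasta")
    (tmp_path / "t.nwk").write_text(tree.to_newick() + "\n")
    shape = f", shape={alpha}" if alpha else ""
    script = f'''
    suppressMessages(library(phangorn))
    aln <- read.phyDat("{tmp_path}/a.fasta", format="fasta")
    tr <- read.tree("{tmp_path}/t.nwk")
    fit <- pml(tr, aln, bf=c(0.31,0.19,0.22,0.28),
               Q=c(1.3,2.8,0.7,1.2,4.1,1.0), k={k}{shape})
    cat(sprintf("%.10f", fit$logLik), "\\n")'''
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=120)
    assert mine == pytest.approx(float(out.stdout.strip()), abs=1e-6)
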