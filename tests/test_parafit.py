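"""PCoA embeddings, ParaFit statistics, permutation inference.

ape (R) provides the independent oracle for the global statistic and the
per-link decomposition on one instance; the exhaustive-permutation oracle
checks the Monte-Carlo p-values.
"""

import itertools
import shutil
import subprocess
import tempfile

import numpy as np
import pytest

from cophylointron.parafit import (AssociationMatrix, PcoaResult, pcoa,
                                   parafit_global, parafit_link1,
                                   parafit_test, _fourth_corner)
from cophylointron.phylo_core import patristic
from cophylointron.phylo_core.tree import DistanceMatrix
from cophylointron.synthetic_data import (simulate_cophylogeny,
                                          simulate_host_tree)


class TestPcoa:
    def test_planar_points_reproduced(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 2.5]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("abcd"), D), "lingoes")
        rec = np.sqrt(((res.coordinates[:, None] -
                        res.coordinates[None]) ** 2).sum(-1))
        assert np.abs(rec - D).max() < 1e-10
        assert res.correction_constant == 0.0

    def test_non_euclidean_triangle_corrected(self):
        d = DistanceMatrix(list("xyz"),
                           np.array([[0, 1, 1], [1, 0, 3], [1, 3, 0]], float))
        res_none = pcoa(d, "none")
        assert res_none.eigenvalues.min() < -1e-6
        res_lin = pcoa(d, "lingoes")
        assert res_lin.correction_constant == pytest.approx(5 / 6, abs=1e-9)
        assert res_lin.eigenvalues.min() > -1e-8 * res_lin.eigenvalues.max()

    def test_sqrt_patristic_needs_no_correction(self):
        t = simulate_host_tree(10, 1.0, 3)
        d = patristic(t)
        res = pcoa(DistanceMatrix(d.labels, np.sqrt(d.values)), "lingoes")
        assert res.correction_constant == 0.0

    def test_raw_patristic_correction_recorded(self):
        t = simulate_host_tree(10, 1.0, 3)
        res = pcoa(patristic(t), "lingoes")
        tol = 1e-8 * res.eigenvalues.max()
        assert res.eigenvalues.min() >= -tol or res.correction_constant > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def _random_instance(rng, n=6):
    t1 = simulate_host_tree(n, 1.0, rng)
    t2 = simulate_host_tree(n, 1.0, rng)
    hp = pcoa(patristic(t1))
    pp = pcoa(patristic(t2).reorder(patristic(t1).labels))
    labels = hp.labels
    A = AssociationMatrix(labels, labels, np.eye(n, dtype=int))
    return hp, pp, A


class TestStatistics:
    def test_zero_association_zero_statistic(self):
        rng = np.random.default_rng(0)
        hp, pp, A = _random_instance(rng)
        A0 = AssociationMatrix(A.hosts, A.parasites,
                               np.zeros_like(A.values))
        res = parafit_global(hp, pp, A0, n_perm=9, seed=1)
        assert res.global_stat == 0.0

    def test_single_link_equals_global(self):
        rng = np.random.default_rng(1)
        hp, pp, A = _random_instance(rng)
        single = np.zeros_like(A.values)
        single[2, 4] = 1
        A1 = AssociationMatrix(A.hosts, A.parasites, single)
        res = parafit_global(hp, pp, A1, n_perm=99, seed=2, test_links=True)
        assert len(res.link_stats) == 1
        assert res.link_stats[0] == pytest.approx(res.global_stat, abs=1e-12)

    def test_link_decomposition_identity(self):
        # with D = B' A C and D_k the single-link fourth corner,
        # link1_k = |D|^2 - |D - D_k|^2 = 2 <D, D_k> - |D_k|^2
        rng = np.random.default_rng(2)
        for _ in range(5):
            hp, pp, A = _random_instance(rng)
            res = parafit_global(hp, pp, A, n_perm=0, seed=0, test_links=True)
            B, C = hp.coordinates, pp.coordinates
            D = B.T @ A.values.astype(float) @ C
            for stat, (hi, pi) in zip(res.link_stats, A.links):
                Dk = np.outer(B[hi], C[pi])
                expected = 2 * np.sum(D * Dk) - np.sum(Dk * Dk)
                assert stat == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_reordering_and_rotation(self):
        rng = np.random.default_rng(3)
        hp, pp, A = _random_instance(rng)
        base = _fourth_corner(hp.coordinates, A.values.astype(float),
                              pp.coordinates)
        # orthogonal rotation of either coordinate set
        k = hp.coordinates.shape[1]
        Q, _ = np.linalg.qr(rng.normal(size=(k, k)))
        rotated = _fourth_corner(hp.coordinates @ Q,
                                 A.values.astype(float), pp.coordinates)
        assert rotated == pytest.approx(base, rel=1e-9)
        # simultaneous host reorder
        perm = rng.permutation(len(A.hosts))
        reordered = _fourth_corner(hp.coordinates[perm],
                                   A.values[perm].astype(float),
                                   pp.coordinates)
        assert reordered == pytest.approx(base, rel=1e-9)

    def test_each_link_bounded_by_global(self):
        rng = np.random.default_rng(4)
        hp, pp, A = _random_instance(rng, 8)
        res = parafit_global(hp, pp, A, n_perm=0, seed=0, test_links=True)
        for s in res.link_stats:
            assert s <= res.global_stat + 1e-9

    def test_absent_link_rejected(self):
        rng = np.random.default_rng(5)
        hp, pp, A = _random_instance(rng)
        with pytest.raises(ValueError):
            parafit_link1(hp, pp, A, ("h1", "nope"), n_perm=9)


class TestPermutationInference:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        hp, pp, A = _random_instance(rng)
        r1 = parafit_global(hp, pp, A, n_perm=199, seed=11, test_links=True)
        r2 = parafit_global(hp, pp, A, n_perm=199, seed=11, test_links=True)
        assert r1.global_p == r2.global_p and r1.link_ps == r2.link_ps

    def test_monte_carlo_matches_exhaustive_permutations(self):
        # 5 hosts: a parasite column permutation has 5! images but the global
        # statistic only depends on which host each parasite lands on; an
        # identity association lets us enumerate the exact null exactly.
        rng = np.random.default_rng(7)
        n = 5
        t1 = simulate_host_tree(n, 1.0, rng)
        t2 = simulate_host_tree(n, 1.0, rng)
        labels = patristic(t1).labels
        hp = pcoa(patristic(t1))
        pp = pcoa(patristic(t2).reorder(labels))
        A = AssociationMatrix(labels, labels, np.eye(n, dtype=int))
        Af = A.values.astype(float)
        observed = _fourth_corner(hp.coordinates, Af, pp.coordinates)
        # exact null: each parasite's host drawn independently & uniformly
        stats = []
        for assign in itertools.product(range(n), repeat=n):
            P = np.zeros((n, n))
            for j, i in enumerate(assign):
                P[i, j] = 1.0
            stats.append(_fourth_corner(hp.coordinates, P, pp.coordinates))
        exact_p = (1 + sum(s >= observed - 1e-12 for s in stats)) / (1 + len(stats))
        mc = parafit_global(hp, pp, A, n_perm=1999, seed=13)
        se = np.sqrt(exact_p * (1 - exact_p) / 1999)
        assert abs(mc.global_p - exact_p) < 4 * se + 2e-3

    def test_identical_trees_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 40
        for i in range(n_sim):
            t = simulate_host_tree(12, 1.0, rng)
            links = [(h, h) for h in t.leaf_labels()]
            res = parafit_test(patristic(t), patristic(t), links,
                               n_perm=199, seed=100 + i)
            hits += res.global_p <= 0.05
        assert hits / n_sim >= 0.9

    def test_drop_taxa_sensitivity_rerun(self):
        rng = np.random.default_rng(9)
        t = simulate_host_tree(8, 1.0, rng)
        links = [(h, h) for h in t.leaf_labels()]
        full = parafit_test(patristic(t), patristic(t), links, n_perm=49,
                            seed=1)
        dropped = parafit_test(patristic(t), patristic(t), links, n_perm=49,
                               seed=1, drop_taxa=t.leaf_labels()[:3])
        assert len(dropped.links) == len(full.links) - 3


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the ape cross-check")
def test_global_and_link_statistics_match_ape():
    """ape::parafit on the same matrices must give identical statistics."""
    rng = np.random.default_rng(42)
    h = simulate_host_tree(10, 1.0, rng)
    sc = simulate_cophylogeny(h, 0.0, 0.25, rng)
    taxa = sorted({p for _, p in sc.links})
    hd = patristic(sc.host_tree.restrict(set(taxa))).reorder(taxa)
    pd_ = patristic(sc.parasite_tree).reorder(taxa)
    mine = parafit_test(hd, pd_, sc.links, n_perm=99, seed=7)
    with tempfile.TemporaryDirectory() as td:
        np.savetxt(f"{td}/hd.csv", hd.values, delimiter=",")
        np.savetxt(f"{td}/pd.csv", pd_.values, delimiter=",")
        A = AssociationMatrix.from_links(sc.links, taxa, taxa)
        np.savetxt(f"{td}/hp.csv", A.values, delimiter=",", fmt="%d")
        script = f'''
        library(ape)
        hd <- as.matrix(read.csv("{td}/hd.csv", header=FALSE))
        pd <- as.matrix(read.csv("{td}/pd.csv", header=FALSE))
        hp <- as.matrix(read.csv("{td}/hp.csv", header=FALSE))
        res <- parafit(hd, pd, hp, nperm=0, test.links=TRUE,
                       correction="lingoes", silent=TRUE)
        cat(sprintf("%.12g", res$ParaFitGlobal), "\\n")
        cat(sprintf("%.12g", res$link.table[, "F1.stat"]), sep="\\n")
        '''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        lines = [l for l in out.stdout.split() if l.strip()]
    ape_global = float(lines[0])
    ape_links = [float(x) for x in lines[1:]]
    assert mine.global_stat == pytest.approx(ape_global, rel=1e-9)
    assert mine.link_stats == pytest.approx(ape_links, rel=1e-9)
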