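"""MPD/MMPD, the independent-swap null, and NRI/NTI standardization."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phylofdp import (
    Phylogeny,
    habitat_pool_ses,
    independent_swap,
    mmpd,
    mpd,
    ses_structure,
)
from phylofdp.structure import _has_checkerboard, ses_frame

FIVE_TIP = "((s0:1,s1:1):2,((s2:1.5,s3:1.5):1,s4:2.5):0.5);"


class TestMetrics:
    def test_two_species_assemblage(self, balanced4):
        D = balanced4.cophenetic_matrix()
        assert mpd([0, 2], D) == pytest.approx(D[0, 2])
        assert mmpd([0, 2], D) == pytest.approx(D[0, 2])

    def test_four_species_toy_hand_means(self, balanced4):
        # distances on ((A:1,B:1):2,(C:2,D:2):1): AB=2, CD=4, cross=6
        D = balanced4.cophenetic_matrix()
        members = [0, 1, 2, 3]
        hand_mpd = (2 + 4 + 6 * 4) / 6
        hand_mmpd = (2 + 2 + 4 + 4) / 4
        assert mpd(members, D) == pytest.approx(hand_mpd, abs=1e-12)
        assert mmpd(members, D) == pytest.approx(hand_mmpd, abs=1e-12)

    def test_mmpd_never_exceeds_mpd(self, yule64):
        D = yule64.cophenetic_matrix()
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 30)
            members = rng.choice(64, size=k, replace=False)
            assert mmpd(members, D) <= mpd(members, D) + 1e-12

    def test_richness_below_two_rejected(self, balanced4):
        D = balanced4.cophenetic_matrix()
        with pytest.raises(ValueError):
            mpd([1], D)


class TestIndependentSwap:
    def test_margins_always_preserved(self):
        rng = np.random.default_rng(4)
        P = (rng.random((12, 9)) < 0.4).astype(int)
        out = independent_swap(P, n_burnin=500, n_thin=100, seed=1, n_samples=20)
        for S in out:
            assert (S.sum(axis=0) == P.sum(axis=0)).all()
            assert (S.sum(axis=1) == P.sum(axis=1)).all()

    def test_nested_matrix_returned_unchanged_with_warning(self):
        P = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        with pytest.warns(UserWarning, match="checkerboard"):
            out = independent_swap(P, n_burnin=100, n_thin=10, seed=0)
        assert (out[0] == P).all()

    def test_chain_visits_fixed_margin_matrices_uniformly(self):
        """4x4, all margins 2: exhaustive enumeration gives the support;
        long-run visit frequencies must be uniform (chi-square, a=0.01)."""
        P0 = np.array(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8
        )
        support = set()
        for bits in itertools.product((0, 1), repeat=16):
            M = np.array(bits, dtype=np.int8).reshape(4, 4)
            if (M.sum(axis=0) == 2).all() and (M.sum(axis=1) == 2).all():
                support.add(M.tobytes())
        samples = independent_swap(
            P0, n_burnin=2000, n_thin=41, seed=8, n_samples=5000
        )
        counts = {}
        for S in samples:
            key = np.ascontiguousarray(S, dtype=np.int8).tobytes()
            counts[key] = counts.get(key, 0) + 1
        # every sampled state must be in the enumerated support
        assert set(counts) <= support
        observed = [counts.get(k, 0) for k in support]
        assert sum(observed) == 5000
        _, p = scipy.stats.chisquare(observed)
        assert p > 0.01


class TestSES:
    def test_swap_sampled_nri_matches_exhaustive_enumeration(self):
        """6 quadrats x 5 species: exact null by enumerating every binary
        matrix with the observed margins, swap-sampled NRI within 0.1."""
        tree = Phylogeny.from_newick(FIVE_TIP)
        D = tree.cophenetic_matrix()
        P = np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 0, 1, 1, 0],
                [0, 1, 0, 1, 0],
                [0, 0, 1, 0, 1],
                [1, 1, 0, 1, 0],
                [0, 0, 1, 0, 1],
            ],
            dtype=np.int8,
        )
        row_sums = P.sum(axis=1)
        col_sums = P.sum(axis=0)

        def row_mpd(cols):
            idx = list(cols)
            k = len(idx)
            sub = D[np.ix_(idx, idx)]
            return sub.sum() / (k * (k - 1))

        # exhaustive enumeration with column-capacity pruning
        per_row_values: list[list[float]] = [[] for _ in range(6)]
        choices = [list(itertools.combinations(range(5), r)) for r in row_sums]

        def recurse(r, caps, picked):
            if r == 6:
                if all(c == 0 for c in caps):
                    for i, cols in enumerate(picked):
                        per_row_values[i].append(row_mpd(cols))
                return
            for cols in choices[r]:
                if all(caps[c] > 0 for c in cols):
                    caps2 = list(caps)
                    for c in cols:
                        caps2[c] -= 1
                    recurse(r + 1, caps2, picked + [cols])

        recurse(0, list(col_sums), [])
        obs = [row_mpd(np.flatnonzero(P[i])) for i in range(6)]
        exact_nri = [
            -(obs[i] - np.mean(per_row_values[i])) / np.std(per_row_values[i], ddof=1)
            for i in range(6)
        ]
        res = ses_structure(
            pd.DataFrame(P, columns=tree.taxa),
            tree,
            n_null=999,
            seed=3,
            n_burnin=3000,
            n_thin=60,
        )
        for i, r in enumerate(res):
            assert r.nri == pytest.approx(exact_nri[i], abs=0.1)

    def test_sister_pair_quadrat_is_clustered(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        P = np.array(
            [
                [1, 1, 0, 0, 0],  # the two closest sisters only
                [1, 0, 1, 0, 1],
                [0, 1, 0, 1, 1],
                [1, 0, 1, 1, 0],
                [0, 1, 1, 0, 1],
            ]
        )
        res = ses_structure(pd.DataFrame(P, columns=tree.taxa), tree, n_null=499, seed=0,
                            n_burnin=2000, n_thin=50)
        assert res[0].nri > 0
        assert res[0].nti > 0

    def test_invariant_to_row_and_column_order(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        rng = np.random.default_rng(9)
        P = (rng.random((8, 5)) < 0.5).astype(int)
        P[P.sum(axis=1) < 2, :2] = 1
        df = pd.DataFrame(P, columns=tree.taxa)
        res = ses_structure(df, tree, n_null=199, seed=5, n_burnin=1000, n_thin=40)
        perm_cols = list(np.array(tree.taxa)[[3, 1, 4, 0, 2]])
        res_c = ses_structure(df[perm_cols], tree, n_null=199, seed=5,
                              n_burnin=1000, n_thin=40)
        for a, b in zip(res, res_c):
            assert a.richness == b.richness
            assert a.mpd_obs == pytest.approx(b.mpd_obs)
            assert a.mmpd_obs == pytest.approx(b.mmpd_obs)

    def test_low_richness_assemblages_flagged(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        P = np.array([[1, 0, 0, 0, 0], [1, 1, 1, 0, 0], [0, 1, 1, 1, 0]])
        res = ses_structure(pd.DataFrame(P, columns=tree.taxa), tree, n_null=99,
                            seed=0, n_burnin=500, n_thin=20)
        assert res[0].degenerate and np.isnan(res[0].nri)
        assert not res[1].degenerate

    def test_species_missing_from_tree_dropped_with_warning(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        P = pd.DataFrame(
            np.ones((3, 6), dtype=int),
            columns=list(tree.taxa) + ["ghost"],
        )
        with pytest.warns(UserWarning):
            ses_structure(P, tree, n_null=9, seed=0, n_burnin=10, n_thin=5)

    def test_matches_picante_observed_metrics(self):
        """Observed MPD/MNTD per assemblage agree with R picante."""
        import subprocess

        tree_txt = "((A:1,B:1):2,(C:2,D:2):1);"
        script = (
            'suppressMessages(library(picante));'
            f'tree <- read.tree(text="{tree_txt}");'
            "D <- cophenetic(tree);"
            "comm <- matrix(c(1,1,1,0, 1,0,1,1), nrow=2, byrow=TRUE);"
            'colnames(comm) <- c("A","B","C","D");'
            'cat(sprintf("%.10f %.10f %.10f %.10f", mpd(comm,D)[1], mpd(comm,D)[2],'
            " mntd(comm,D)[1], mntd(comm,D)[2]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        r_mpd1, r_mpd2, r_mntd1, r_mntd2 = map(float, out.stdout.split())
        tree = Phylogeny.from_newick(tree_txt)
        D = tree.cophenetic_matrix()
        assert mpd([0, 1, 2], D) == pytest.approx(r_mpd1, abs=1e-9)
        assert mpd([0, 2, 3], D) == pytest.approx(r_mpd2, abs=1e-9)
        assert mmpd([0, 1, 2], D) == pytest.approx(r_mntd1, abs=1e-9)
        assert mmpd([0, 2, 3], D) == pytest.approx(r_mntd2, abs=1e-9)


class TestHabitatPool:
    def test_full_pool_lists_are_degenerate(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        lists = {h: list(tree.taxa) for h in ("V", "LS", "HG", "RT", "HS")}
        with pytest.warns(UserWarning, match="checkerboard"):
            res = habitat_pool_ses(lists, list(tree.taxa), tree, n_null=49,
                                   n_burnin=100, n_thin=10)
        for r in res:
            assert r.degenerate
            assert r.nri == 0.0 and r.nti == 0.0

    def test_clade_pure_lists_are_clustered(self):
        tree = Phylogeny.from_newick(
            "(((a1:1,a2:1):1,a3:2):2,((b1:1,b2:1):1,b3:2):2);"
        )
        lists = {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}
        res = habitat_pool_ses(lists, list(tree.taxa), tree, n_null=299, seed=2,
                               n_burnin=1000, n_thin=30)
        for r in res:
            assert r.nri > 0

    def test_species_outside_pool_rejected(self):
        tree = Phylogeny.from_newick(FIVE_TIP)
        with pytest.raises(ValueError, match="outside the pool"):
            habitat_pool_ses({"V": ["zz"]}, list(tree.taxa), tree)


def test_checkerboard_detector():
    assert _has_checkerboard(np.array([[1, 0], [0, 1]]))
    assert not _has_checkerboard(np.array([[1, 1], [1, 0]]))
    assert not _has_checkerboard(np.ones((3, 3), dtype=int))
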