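"""Torus-translation association tests against brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phylofdp import (
    HabitatMap,
    build_community_matrix,
    summarize_associations,
    torus_null_maps,
    torus_test,
)
from phylofdp.association import AssociationResult
from phylofdp.community import CommunityMatrix, StemMap


def _stem_map(points, plot_x=100.0, plot_y=80.0):
    df = pd.DataFrame(
        {
            "stem_id": range(len(points)),
            "x_m": [p[0] for p in points],
            "y_m": [p[1] for p in points],
            "species": [p[2] for p in points],
        }
    )
    return StemMap(df, plot_x_m=plot_x, plot_y_m=plot_y)


class TestCommunityMatrix:
    def test_single_stem_lands_in_its_quadrat(self):
        cm = build_community_matrix(_stem_map([(0.0, 0.0, "a")]), 20.0)
        assert cm.counts[0, 0, 0] == 1
        assert cm.total_stems() == 1

    def test_out_of_bounds_stem_errors(self):
        with pytest.raises(ValueError, match="outside"):
            build_community_matrix(_stem_map([(100.0, 0.0, "a")]), 20.0)

    def test_toy_map_matches_per_stem_oracle(self):
        pts = [
            (1.0, 1.0, "a"),
            (19.9, 19.9, "a"),
            (20.0, 0.0, "b"),
            (55.0, 41.0, "b"),
            (99.9, 79.9, "c"),
            (0.0, 60.0, "a"),
            (40.0, 40.0, "c"),
        ]
        cm = build_community_matrix(_stem_map(pts), 20.0)
        oracle = np.zeros((4, 5, 3), dtype=int)
        idx = {"a": 0, "b": 1, "c": 2}
        for x, y, s in pts:
            oracle[int(y // 20), int(x // 20), idx[s]] += 1
        assert (cm.counts == oracle).all()
        assert cm.total_stems() == len(pts)


class TestNullMaps:
    def test_enumeration_size_and_composition(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["V", "LS", "HG"], size=(4, 5))
        hm = HabitatMap(labels=labels, quadrat_m=20.0)
        maps = torus_null_maps(hm)
        assert len(maps) == 4 * 4 * 5
        base = {h: (labels == h).sum() for h in ("V", "LS", "HG")}
        for m in maps:
            assert {h: (m == h).sum() for h in base} == base
        assert (maps[0] == labels).all()  # original included first

    def test_single_habitat_all_identical(self):
        hm = HabitatMap(labels=np.full((3, 3), "V"), quadrat_m=20.0)
        maps = torus_null_maps(hm)
        assert all((m == "V").all() for m in maps)


class TestTorusTest:
    def test_uniform_map_everything_ns(self):
        hm = HabitatMap(labels=np.full((2, 3), "LS"), quadrat_m=20.0)
        counts = np.zeros((2, 3, 1), dtype=int)
        counts[0, 0, 0] = 30
        cm = CommunityMatrix(counts, ["a"], 20.0)
        res = torus_test(cm, hm, min_stems=20)
        ls = [r for r in res if r.habitat == "LS"][0]
        assert ls.verdict == "ns"
        assert ls.p_positive == 1.0 and ls.p_negative == 1.0

    def test_strip_p_values_equal_exhaustive_enumeration(self):
        """1x5 strip; habitat A on quadrats {0,1}; species in quadrat 0 only.

        The brute-force oracle enumerates the translations of all four
        variants of the 1-row map by hand (list slicing, no package code)
        and recomputes both tail probabilities from first principles.
        """
        row = ["V", "V", "LS", "LS", "LS"]
        hm = HabitatMap(labels=np.array([row]), quadrat_m=20.0)
        counts = np.zeros((1, 5, 1), dtype=int)
        counts[0, 0, 0] = 25
        cm = CommunityMatrix(counts, ["a"], 20.0)
        res = torus_test(cm, hm, min_stems=20)

        stems = [25, 0, 0, 0, 0]
        variants = [row, row[::-1], row[::-1], row]  # 180deg, mirror, mirror-rot
        null_v = []
        for var in variants:
            for shift in range(5):
                shifted = var[-shift:] + var[:-shift] if shift else list(var)
                null_v.append(sum(s for s, h in zip(stems, shifted) if h == "V"))
        obs_v = null_v[0]
        exp_p_pos = sum(v >= obs_v for v in null_v) / len(null_v)
        exp_p_neg = sum(v <= obs_v for v in null_v) / len(null_v)
        got = [r for r in res if r.habitat == "V"][0]
        assert got.observed == 25
        assert got.p_positive == pytest.approx(exp_p_pos)
        assert got.p_negative == pytest.approx(exp_p_neg)

    def test_translating_both_layers_leaves_p_unchanged(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["V", "LS", "HG"], size=(6, 8))
        hm = HabitatMap(labels=labels, quadrat_m=20.0)
        counts = rng.poisson(2.0, size=(6, 8, 3))
        cm = CommunityMatrix(counts, ["a", "b", "c"], 20.0)
        res = torus_test(cm, hm, min_stems=10)
        hm2 = HabitatMap(labels=np.roll(labels, (2, 3), axis=(0, 1)), quadrat_m=20.0)
        cm2 = CommunityMatrix(np.roll(counts, (2, 3), axis=(0, 1)), ["a", "b", "c"], 20.0)
        res2 = torus_test(cm2, hm2, min_stems=10)
        for r, r2 in zip(res, res2):
            assert (r.species, r.habitat) == (r2.species, r2.habitat)
            assert r.p_positive == pytest.approx(r2.p_positive)
            assert r.p_negative == pytest.approx(r2.p_negative)

    def test_eligibility_is_strictly_greater(self):
        hm = HabitatMap(labels=np.full((1, 2), "V"), quadrat_m=20.0)
        counts = np.zeros((1, 2, 2), dtype=int)
        counts[0, 0, 0] = 20  # exactly 20: not eligible
        counts[0, 0, 1] = 21
        cm = CommunityMatrix(counts, ["a", "b"], 20.0)
        res = torus_test(cm, hm, min_stems=20)
        assert {r.species for r in res} == {"b"}

    def test_no_eligible_species_warns_empty(self):
        hm = HabitatMap(labels=np.full((1, 2), "V"), quadrat_m=20.0)
        cm = CommunityMatrix(np.ones((1, 2, 1), dtype=int), ["a"], 20.0)
        with pytest.warns(UserWarning):
            assert torus_test(cm, hm, min_stems=20) == []

    def test_type_one_error_calibrated_under_uniform_placement(self):
        """Each tail rejects ~ alpha/2 for unclustered, unfiltered species."""
        rng = np.random.default_rng(42)
        n_rows, n_cols, n_sp = 10, 10, 500
        labels = rng.choice(["V", "LS", "HG", "RT", "HS"], size=(n_rows, n_cols))
        hm = HabitatMap(labels=labels, quadrat_m=20.0)
        counts = rng.multinomial(60, np.full(100, 0.01), size=n_sp)  # (sp, Q)
        cm = CommunityMatrix(
            counts.T.reshape(n_rows, n_cols, n_sp),
            [f"s{i}" for i in range(n_sp)],
            20.0,
        )
        res = torus_test(cm, hm, min_stems=20, alpha=0.05)
        v_tests = [r for r in res if r.habitat == "V"]
        assert len(v_tests) == n_sp
        pos = sum(r.verdict == "+" for r in v_tests)
        neg = sum(r.verdict == "-" for r in v_tests)
        lo, hi = scipy.stats.binom.ppf([0.005, 0.995], n_sp, 0.025)
        assert lo <= pos <= hi
        assert lo <= neg <= hi


class TestSummaries:
    def test_empty_input_all_zero(self):
        tab = summarize_associations([])
        assert (tab["n_positive"] == 0).all() and (tab["n_negative"] == 0).all()
        assert tab.attrs["fraction_significant"] == 0.0

    def test_toy_counts(self):
        mk = lambda sp, hab, v: AssociationResult(sp, hab, 0, 10, 0.5, 0.5, v)
        res = [
            mk("a", "V", "+"),
            mk("a", "HS", "+"),
            mk("b", "V", "-"),
            mk("c", "V", "ns"),
            mk("c", "HS", "ns"),
            mk("d", "RT", "ns"),
        ]
        tab = summarize_associations(res).set_index("habitat")
        assert tab.loc["Total", "n_positive"] == 2
        assert tab.loc["Total", "n_negative"] == 1
        assert tab.attrs["n_species_any"] == 2  # a and b
        assert tab.attrs["fraction_significant"] == pytest.approx(3 / 6)
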