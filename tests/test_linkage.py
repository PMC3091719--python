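"""Two-point estimation, map functions, recoding, screening, grouping."""

import math

import numpy as np
import pandas as pd
import pytest

from ssrbinmap.io_formats import GenotypeTable
from ssrbinmap.linkage import (
    group_markers, haldane_d, haldane_r, kosambi_d, kosambi_r,
    recode_to_parental, screen_framework, two_point, two_point_matrix,
)
from ssrbinmap.pedigree_sim import SimConfig, simulate_fullsib

from oracles import lod_grid_max


class TestTwoPoint:
    def test_closed_form_example(self):
        m1 = [0] * 100
        m2 = [1] * 10 + [0] * 90
        pair = two_point(m1, m2)
        want = 100 * math.log10(2) + 10 * math.log10(0.1) + 90 * math.log10(0.9)
        assert pair.r_hat == pytest.approx(0.10)
        assert pair.lod == pytest.approx(want, abs=1e-9)
        assert pair.lod == pytest.approx(15.9848, abs=1e-3)

    def test_free_recombination_has_zero_lod(self):
        pair = two_point([0, 1] * 50, [0] * 100)
        assert pair.r_hat == 0.5 and pair.lod == 0.0

    def test_orientation_invariance(self, rng):
        a = rng.integers(0, 2, size=120).astype(float)
        b = rng.integers(0, 2, size=120).astype(float)
        p1 = two_point(a, b)
        p2 = two_point(a, 1.0 - b)
        assert (p1.r_hat, p1.lod) == (p2.r_hat, p2.lod)

    def test_undefined_pair_flagged(self):
        pair = two_point([np.nan, 0.0], [1.0, np.nan])
        assert pair.n_informative == 0 and not pair.defined

    def test_lod_maximised_at_r_hat(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            r_count = int(rng.integers(1, n // 2))
            r = r_count / n
            closed = (n * math.log10(2) + r_count * math.log10(r)
                      + (n - r_count) * math.log10(1 - r))
            assert lod_grid_max(n, r_count) <= closed + 1e-9

    def test_matrix_agrees_with_scalar(self, rng):
        a = rng.integers(0, 2, size=(5, 60)).astype(float)
        a[rng.random(a.shape) < 0.1] = np.nan
        r, lod, n = two_point_matrix(a, a)
        for i in range(5):
            for j in range(5):
                p = two_point(a[i], a[j])
                assert n[i, j] == p.n_informative
                assert r[i, j] == pytest.approx(p.r_hat, nan_ok=True)
                assert lod[i, j] == pytest.approx(p.lod, nan_ok=True, abs=1e-9)


class TestMapFunctions:
    def test_kosambi_closed_form(self):
        assert kosambi_d(0.0) == 0.0
        assert kosambi_d(0.1) == pytest.approx(25 * math.log(1.5), abs=1e-12)
        assert kosambi_d(0.1) == pytest.approx(10.137, abs=1e-3)

    def test_round_trips_to_1e12(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert kosambi_r(kosambi_d(r)) == pytest.approx(r, abs=1e-12)
            assert haldane_r(haldane_d(r)) == pytest.approx(r, abs=1e-12)

    def test_kosambi_below_haldane(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert kosambi_d(r) < haldane_d(r)
        assert kosambi_d(0.0) == haldane_d(0.0) == 0.0

    @pytest.mark.parametrize("fn", [kosambi_d, haldane_d])
    def test_rejects_r_at_or_above_half(self, fn):
        with pytest.raises(ValueError):
            fn(0.5)


class TestRecode:
    def _table(self):
        calls = pd.DataFrame(
            {
                "i1": ["lm", "nn", "ac", "hk"],
                "i2": ["ll", "np", "bc", "hh"],
                "i3": ["--", "np", "ad", "kk"],
            },
            index=["f1", "m1", "x1", "h1"],
        )
        seg = pd.Series(["lmxll", "nnxnp", "abxcd", "hkxhk"], index=calls.index)
        phase = pd.Series(["coupling"] * 4, index=calls.index)
        return GenotypeTable(calls=calls, seg_type=seg, phase=phase)

    def test_testcross_markers_split_by_parent(self):
        rec = recode_to_parental(self._table())
        f1 = rec.female.loc["f1"].tolist()
        assert f1[:2] == [1.0, 0.0] and np.isnan(f1[2])  # "--" stays missing
        assert "f1" not in rec.male.index
        assert list(rec.male.loc["m1"]) == [0.0, 1.0, 1.0]
        assert "m1" not in rec.female.index

    def test_outcross_marker_feeds_both_parents(self):
        rec = recode_to_parental(self._table())
        # calls ac, bc, ad -> female a/b = 0,1,0 ; male c/d = 0,0,1
        assert list(rec.female.loc["x1"]) == [0.0, 1.0, 0.0]
        assert list(rec.male.loc["x1"]) == [0.0, 0.0, 1.0]

    def test_intercross_marker_excluded_with_reason(self):
        rec = recode_to_parental(self._table())
        assert "h1" not in rec.female.index and "h1" not in rec.male.index
        assert "h1" in rec.excluded and "1:2:1" in rec.excluded["h1"]

    def test_repulsion_phase_flips_coding(self):
        table = self._table()
        table.phase.loc["f1"] = "repulsion"
        rec = recode_to_parental(table)
        assert list(rec.female.loc["f1"])[:2] == [0.0, 1.0]


class TestScreenAndGroup:
    def _table_with_missing(self, rng, n_markers=20, n_inds=30):
        missing = rng.random((n_markers, n_inds)) < rng.uniform(0, 0.8, (1, n_inds))
        calls = np.where(missing, "--",
                         np.where(rng.random((n_markers, n_inds)) < 0.5, "lm", "ll"))
        frame = pd.DataFrame(calls, index=[f"m{i}" for i in range(n_markers)],
                             columns=[f"i{j}" for j in range(n_inds)])
        seg = pd.Series("lmxll", index=frame.index)
        return GenotypeTable(calls=frame, seg_type=seg)

    def test_individuals_dropped_at_strict_threshold(self):
        calls = pd.DataFrame(
            {"a": ["lm", "ll"], "b": ["--", "lm"], "c": ["--", "--"]},
            index=["m1", "m2"],
        )
        table = GenotypeTable(calls=calls, seg_type=pd.Series("lmxll", index=calls.index))
        kept, _ = screen_framework(table, max_missing_individual=0.5)
        assert kept == ["a"]  # b sits exactly at 50% and is dropped

    def test_screen_matches_brute_force(self, rng):
        table = self._table_with_missing(rng)
        kept, _ = screen_framework(table, 0.5)
        frac = (table.calls == "--").mean(axis=0)
        assert kept == [i for i in table.individual_ids if frac[i] < 0.5]

    def test_all_dropped_raises(self):
        calls = pd.DataFrame({"a": ["--"]}, index=["m1"])
        table = GenotypeTable(calls=calls, seg_type=pd.Series("lmxll", index=["m1"]))
        with pytest.raises(ValueError):
            screen_framework(table, 0.5)

    def test_simulated_data_recovers_twelve_groups(self):
        # LOD 4: orientation-minimised two-point estimates make the
        # false-linkage tail two-sided, so LOD 3 occasionally bridges two
        # chromosomes among ~2,000 unlinked pairs at n = 278
        table, truth = simulate_fullsib(SimConfig(seed=11))
        rec = recode_to_parental(table)
        groups = group_markers(rec.female, lod_threshold=4.0)
        assert len(groups) == 12
        assert sum(len(g) for g in groups) == len(rec.female.index)
        # components match the true linkage groups
        lg_of = truth.marker_info["lg"]
        for comp in groups:
            assert lg_of.loc[comp].nunique() == 1

    def test_infinite_threshold_gives_singletons(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (6, 40)).astype(float),
                           index=[f"m{i}" for i in range(6)])
        groups = group_markers(mat, lod_threshold=math.inf)
        assert all(len(g) == 1 for g in groups)

    def test_duplicated_marker_always_groups_together(self, rng):
        row = rng.integers(0, 2, 50).astype(float)
        mat = pd.DataFrame([row, row], index=["m1", "m1b"])
        groups = group_markers(mat, lod_threshold=3.0)
        assert ["m1", "m1b"] in groups
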