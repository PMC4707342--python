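"""Quantile normalisation, ANOVA/BH funnel and marker filters."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from myomics.design import GroupDesign, InvalidSpecError
from myomics.expression import (
    DeSelection,
    anova_bh,
    count_de_vs_reference,
    dedup_by_symbol,
    fold_change_filter,
    quantile_normalize,
    select_specific_markers,
)


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        """Columns {1,3} and {3,5}: per-rank means are 2 and 4."""
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [3.0, 5.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.0, 4.0]
        assert out["b"].tolist() == [2.0, 4.0]

    def test_permuted_columns_become_identical_multisets(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 50)
        m = pd.DataFrame({
            "a": base,
            "b": rng.permutation(base),
            "c": rng.permutation(base),
        })
        out = quantile_normalize(m)
        for col in out.columns:
            np.testing.assert_allclose(np.sort(out[col]), np.sort(base), atol=1e-12)

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 2.0], "b": [5.0, 1.0, 2.0]})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_rank_order_preserved_and_ties_stay_tied(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 7.0, 3.0], "b": [2.0, 8.0, 4.0, 4.0]})
        out = quantile_normalize(m)
        assert out.at[0, "a"] == out.at[1, "a"]  # tie preserved
        assert out.at[2, "b"] == out.at[3, "b"]
        assert (np.argsort(out["a"]) == np.argsort(m["a"], kind="stable")).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


def _matrix(design, values):
    return pd.DataFrame(values, columns=design.sample_ids)


class TestAnovaBh:
    def test_identical_groups_not_selected(self, tissue_design):
        m = _matrix(tissue_design, np.ones((5, 9)) * 7.0)
        assert anova_bh(m, tissue_design) == []

    def test_f_statistic_matches_hand_formula(self, tissue_design):
        """Three groups of three: F = between mean square / within mean square."""
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]])
        m = _matrix(tissue_design, vals)
        sel = anova_bh(m, tissue_design, alpha=1.1)
        groups = [vals[0, :3], vals[0, 3:6], vals[0, 6:]]
        grand = vals.mean()
        ssb = sum(3 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 6)
        assert sel[0].f_stat == pytest.approx(f_hand, abs=1e-12)
        assert sel[0].p == pytest.approx(scipy.stats.f.sf(f_hand, 2, 6), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_f_oneway_on_random_matrices(self, seed, full_design):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        m = _matrix(full_design, rng.normal(8, 1, size=(n, 12)))
        sel = anova_bh(m, full_design, alpha=1.1)
        cols = [full_design.members(g) for g in full_design.groups]
        for s, (_, row) in zip(sel, m.iterrows()):
            f, p = scipy.stats.f_oneway(*[row[c].to_numpy() for c in cols])
            assert s.f_stat == pytest.approx(f, rel=1e-9)
            assert s.p == pytest.approx(p, rel=1e-9)
        ps = np.array([s.p for s in sel])
        np.testing.assert_allclose(
            [s.q for s in sel], multipletests(ps, method="fdr_bh")[1], rtol=1e-12
        )

    def test_bh_step_up_hand_example(self):
        """p = {.01,.02,.03,.04}, m=4: step-up gives q = .04 everywhere, all < .05."""
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert (q < 0.05).all()

    def test_degenerate_probe_gets_p_one(self, tissue_design):
        m = _matrix(tissue_design, np.full((1, 9), 3.0))
        sel = anova_bh(m, tissue_design, alpha=1.1)
        assert sel[0].p == 1.0
        assert sel[0].f_stat == 0.0

    def test_requires_two_samples_per_group(self):
        d = GroupDesign([("a", "NM"), ("b", "LM"), ("c", "LM")])
        with pytest.raises(ValueError):
            anova_bh(pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"]), d)


class TestFoldChangeFilter:
    def _sel(self, pid="p1"):
        return [DeSelection(pid, 10.0, 0.001, 0.01)]

    def _means(self, lms, nm, lm):
        return pd.DataFrame({"LMS": [lms], "NM": [nm], "LM": [lm]}, index=["p1"])

    def test_fc_above_threshold_kept(self):
        out = fold_change_filter(self._sel(), self._means(25.0, 10.0, 10.0))
        assert len(out) == 1
        assert out[0].fold_changes["LMS_vs_NM"] == pytest.approx(2.5)

    def test_fc_exactly_two_dropped(self):
        out = fold_change_filter(self._sel(), self._means(20.0, 10.0, 20.0))
        assert out == []  # both contrasts exactly at the strict boundary

    def test_downregulation_kept(self):
        out = fold_change_filter(self._sel(), self._means(10.0, 10.0, 4.0))
        assert len(out) == 1
        assert out[0].fold_changes["LM_vs_NM"] == pytest.approx(0.4)

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            fold_change_filter(self._sel(), self._means(0.0, 10.0, 10.0))


class TestDedupBySymbol:
    def test_two_probes_same_symbol_one_survivor(self):
        sels = [
            DeSelection("p1", 1, 0.1, 0.1, {"LMS_vs_NM": 4.0}),
            DeSelection("p2", 1, 0.1, 0.1, {"LMS_vs_NM": 2.5}),
        ]
        ann = pd.Series({"p1": "GENE1", "p2": "GENE1"})
        out = dedup_by_symbol(sels, ann)
        assert [s.probe_id for s in out] == ["p1"]  # larger |log2 FC| wins

    def test_probe_without_symbol_removed(self):
        sels = [DeSelection("p1", 1, 0.1, 0.1), DeSelection("p2", 1, 0.1, 0.1)]
        ann = pd.Series({"p1": "", "p2": "GENE2"})
        assert [s.probe_id for s in dedup_by_symbol(sels, ann)] == ["p2"]

    def test_tie_breaks_to_lexicographic_probe_id(self):
        sels = [
            DeSelection("p9", 1, 0.1, 0.1, {"LMS_vs_NM": 3.0}),
            DeSelection("p2", 1, 0.1, 0.1, {"LMS_vs_NM": 3.0}),
        ]
        ann = pd.Series({"p9": "G", "p2": "G"})
        assert [s.probe_id for s in dedup_by_symbol(sels, ann)] == ["p2"]


class TestSelectSpecificMarkers:
    def _data(self, tissue_design, lms=9.0, nm=4.0, lm=4.0,
              lms_flag="present", nm_flag="absent", lm_flag="absent"):
        cols = tissue_design.sample_ids
        vals, flags = [], []
        for s in cols:
            g = tissue_design.group_of(s)
            vals.append({"NM": nm, "LM": lm, "LMS": lms}[g])
            flags.append({"NM": nm_flag, "LM": lm_flag, "LMS": lms_flag}[g])
        m = pd.DataFrame([vals], columns=cols, index=["p1"])
        f = pd.DataFrame([flags], columns=cols, index=["p1"])
        return m, f

    def test_lms_specific(self, tissue_design):
        m, f = self._data(tissue_design)
        out = select_specific_markers(m, f, tissue_design)
        assert out["LMS"] == ["p1"]
        assert all(v == [] for k, v in out.items() if k != "LMS")

    def test_nm_lm_pair_specific(self, tissue_design):
        m, f = self._data(tissue_design, lms=4.0, nm=9.0, lm=9.0,
                          lms_flag="absent", nm_flag="present", lm_flag="present")
        out = select_specific_markers(m, f, tissue_design)
        assert out["NM/LM"] == ["p1"]

    def test_ubiquitous_probe_not_selected(self, tissue_design):
        m, f = self._data(tissue_design, lms=9.0, nm=9.0, lm=9.0,
                          lms_flag="present", nm_flag="present", lm_flag="present")
        out = select_specific_markers(m, f, tissue_design)
        assert all(v == [] for v in out.values())

    def test_intensity_exactly_six_is_outside(self, tissue_design):
        """Intensity exactly at the threshold counts as low (strict '>')."""
        m, f = self._data(tissue_design, lms=6.0, nm=4.0, lm=4.0)
        out = select_specific_markers(m, f, tissue_design, intensity_t=6.0)
        assert out["LMS"] == []


class TestCountDeVsReference:
    def test_identical_sample_zero_counts(self, tissue_design):
        m = pd.DataFrame(
            np.ones((10, 9)) * 5.0, columns=tissue_design.sample_ids
        )
        out = count_de_vs_reference(m, tissue_design)
        assert (out["n_up"] == 0).all()
        assert (out["n_down"] == 0).all()

    def test_shared_planted_set_full_overlap(self, tissue_design):
        m = pd.DataFrame(np.ones((20, 9)) * 5.0, columns=tissue_design.sample_ids)
        for s in tissue_design.members("LMS"):
            m.loc[m.index[:10], s] = 25.0  # same 10 probes up in all LMS
        out = count_de_vs_reference(m, tissue_design)
        lms = out[out["group"] == "LMS"]
        assert (lms["n_up"] == 10).all()
        assert (lms["common_up_fraction"] == 1.0).all()

    def test_disjoint_sets_zero_overlap(self, tissue_design):
        m = pd.DataFrame(np.ones((30, 9)) * 5.0, columns=tissue_design.sample_ids)
        for i, s in enumerate(tissue_design.members("LMS")):
            m.loc[m.index[10 * i : 10 * (i + 1)], s] = 25.0
        out = count_de_vs_reference(m, tissue_design)
        lms = out[out["group"] == "LMS"]
        assert (lms["common_up_fraction"] == 0.0).all()

    def test_empty_reference_rejected(self, tissue_design):
        m = pd.DataFrame(np.ones((2, 9)), columns=tissue_design.sample_ids)
        with pytest.raises(InvalidSpecError):
            count_de_vs_reference(m, tissue_design, reference_group="CELL")
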