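"""Beta computation, QC, delta-beta classification, tabulation and markers."""

import numpy as np
import pandas as pd
import pytest

from myomics.design import GroupDesign
from myomics.methylation import (
    DmCall,
    bin_regions,
    compute_beta,
    geneset_overlap,
    global_stats,
    group_delta_beta,
    promoter_refine,
    qc_filter,
    regions_to_bed,
    select_methylation_markers,
    tabulate_by_feature,
)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [
            (0.0, 0.0, 0.0),
            (900.0, 0.0, 0.9),  # 900/(900+0+100)
            (300.0, 300.0, 300.0 / 700.0),
        ],
    )
    def test_formula(self, m, u, expected):
        assert compute_beta(m, u) == pytest.approx(expected, abs=1e-12)

    def test_always_below_one(self):
        assert compute_beta(1e9, 0.0) < 1.0

    def test_vectorized(self):
        out = compute_beta(np.array([0.0, 900.0]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(out, [0.0, 0.9])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1.0, 5.0)


def _beta(design, values):
    return pd.DataFrame(values, columns=design.sample_ids)


class TestQcFilter:
    def test_clean_matrix_unchanged(self, tissue_design):
        beta = _beta(tissue_design, np.full((4, 9), 0.5))
        detp = _beta(tissue_design, np.full((4, 9), 0.01))
        out = qc_filter(beta, detp)
        pd.testing.assert_frame_equal(out, beta)

    def test_single_failing_sample_drops_probe(self, tissue_design):
        beta = _beta(tissue_design, np.full((4, 9), 0.5))
        detp = _beta(tissue_design, np.full((4, 9), 0.01))
        detp.iat[2, 5] = 0.06
        out = qc_filter(beta, detp)
        assert len(out) == 3
        assert 2 not in out.index

    def test_blank_beta_drops_probe(self, tissue_design):
        beta = _beta(tissue_design, np.full((3, 9), 0.5))
        beta.iat[1, 0] = np.nan
        detp = _beta(tissue_design, np.full((3, 9), 0.01))
        out = qc_filter(beta, detp)
        assert list(out.index) == [0, 2]

    def test_boundary_p_kept(self, tissue_design):
        """Detection P exactly 0.05 passes (exclusion is for P > 0.05)."""
        beta = _beta(tissue_design, np.full((1, 9), 0.5))
        detp = _beta(tissue_design, np.full((1, 9), 0.05))
        assert len(qc_filter(beta, detp)) == 1


class TestGroupDeltaBeta:
    def test_identical_groups_all_none(self, tissue_design):
        beta = _beta(tissue_design, np.full((5, 9), 0.4))
        calls = group_delta_beta(beta, tissue_design, "LMS", "NM")
        assert all(c.status == "none" and c.delta_beta == 0.0 for c in calls)

    def test_hand_example(self, tissue_design):
        row = {s: 0.8 for s in tissue_design.members("LMS")}
        row.update({s: 0.5 for s in tissue_design.members("NM")})
        row.update({s: 0.5 for s in tissue_design.members("LM")})
        beta = pd.DataFrame([row])[tissue_design.sample_ids]
        (call,) = group_delta_beta(beta, tissue_design, "LMS", "NM")
        assert call.delta_beta == pytest.approx(0.3)
        assert call.status == "hyper"

    @pytest.mark.parametrize("delta,status", [(0.2, "none"), (-0.2, "none"),
                                              (0.2000001, "hyper"), (-0.2000001, "hypo")])
    def test_strict_boundary(self, tissue_design, delta, status):
        row = {s: 0.5 + delta for s in tissue_design.members("LMS")}
        row.update({s: 0.5 for s in tissue_design.members("NM")})
        row.update({s: 0.5 for s in tissue_design.members("LM")})
        beta = pd.DataFrame([row])[tissue_design.sample_ids]
        (call,) = group_delta_beta(beta, tissue_design, "LMS", "NM")
        assert call.status == status

    def test_order_invariance(self, tissue_design):
        rng = np.random.default_rng(1)
        beta = _beta(tissue_design, rng.uniform(0, 1, (30, 9)))
        calls = group_delta_beta(beta, tissue_design, "LMS", "NM")
        shuffled = beta.sample(frac=1.0, random_state=5)
        calls2 = group_delta_beta(shuffled, tissue_design, "LMS", "NM")
        assert {c.probe_id: c.delta_beta for c in calls} == {
            c.probe_id: c.delta_beta for c in calls2
        }


class TestTabulateByFeature:
    def test_planted_counts_and_partition(self, small_manifest):
        probes = list(small_manifest.index)
        tss200 = list(small_manifest.index[small_manifest["feature_group"] == "TSS200"])[:10]
        calls = [
            DmCall(p, 0.4 if p in tss200 else 0.0, "hyper" if p in tss200 else "none")
            for p in probes
        ]
        table = tabulate_by_feature(calls, small_manifest)
        feat = table[table["axis"] == "feature_group"].set_index("category")
        assert feat.at["TSS200", "n_hyper"] == 10
        assert feat["n_hyper"].sum() == 10
        # partition invariant: feature rows sum to the analysed probe total
        assert feat["n_probes"].sum() == len(probes)
        cgi = table[table["axis"] == "cgi_relation"]
        assert cgi["n_probes"].sum() == len(probes)

    def test_unknown_probe_rejected(self, small_manifest):
        with pytest.raises(KeyError):
            tabulate_by_feature([DmCall("not_a_probe", 0.5, "hyper")], small_manifest)


def _manifest(rows):
    return pd.DataFrame(rows).set_index("probe_id")


class TestBinRegions:
    def _mani(self):
        return _manifest([
            {"probe_id": "p1", "chrom": "1", "pos": 100, "gene": "X",
             "feature_group": "TSS200", "cgi_relation": "island"},
            {"probe_id": "p2", "chrom": "1", "pos": 180, "gene": "X",
             "feature_group": "TSS200", "cgi_relation": "island"},
            {"probe_id": "p3", "chrom": "1", "pos": 900, "gene": "X",
             "feature_group": "Body", "cgi_relation": "open_sea"},
        ])

    def test_two_probes_one_region(self):
        calls = [DmCall("p1", 0.4, "hyper"), DmCall("p2", 0.3, "hyper")]
        regions = bin_regions(calls, self._mani(), "hyper")
        assert len(regions) == 1
        r = regions[0]
        assert (r.gene, r.feature_group, r.n_probes) == ("X", "TSS200", 2)
        assert (r.start, r.end) == (100, 180)

    def test_single_probe_no_region(self):
        regions = bin_regions([DmCall("p1", 0.4, "hyper")], self._mani(), "hyper")
        assert regions == []

    def test_lone_body_probe_not_merged_across_features(self):
        calls = [DmCall(p, 0.4, "hyper") for p in ("p1", "p2", "p3")]
        regions = bin_regions(calls, self._mani(), "hyper")
        assert len(regions) == 1
        assert regions[0].feature_group == "TSS200"

    def test_bed_export_zero_based_half_open(self):
        calls = [DmCall("p1", 0.4, "hyper"), DmCall("p2", 0.3, "hyper")]
        bed = regions_to_bed(bin_regions(calls, self._mani(), "hyper"))
        assert bed.iloc[0]["start"] == 99
        assert bed.iloc[0]["end"] == 180
        assert bed.iloc[0]["name"] == "X|TSS200|hyper"


class TestMethylationMarkers:
    def _beta(self, design, lms, lm, nm=0.5):
        row = {}
        for g, vals in (("LMS", lms), ("LM", lm)):
            for s, v in zip(design.members(g), vals):
                row[s] = v
        for s in design.members("NM"):
            row[s] = nm
        return pd.DataFrame([row])[design.sample_ids].set_axis(["p1"])

    def test_clear_separation_selected(self, tissue_design):
        beta = self._beta(tissue_design, [0.7, 0.8, 0.9], [0.05, 0.02, 0.09])
        out = select_methylation_markers(beta, tissue_design)
        assert list(out.index) == ["p1"]
        assert out.at["p1", "direction"] == "hyper_in_a"

    def test_one_sample_below_hi_rejected(self, tissue_design):
        beta = self._beta(tissue_design, [0.7, 0.8, 0.55], [0.05, 0.02, 0.09])
        assert select_methylation_markers(beta, tissue_design).empty

    def test_boundary_values_excluded(self, tissue_design):
        beta = self._beta(tissue_design, [0.6, 0.8, 0.9], [0.05, 0.02, 0.09])
        assert select_methylation_markers(beta, tissue_design).empty

    def test_reverse_direction(self, tissue_design):
        beta = self._beta(tissue_design, [0.05, 0.02, 0.09], [0.7, 0.8, 0.9])
        out = select_methylation_markers(beta, tissue_design)
        assert out.at["p1", "direction"] == "hyper_in_b"

    def test_promoter_refine_requires_two_promoter_probes(self):
        mani = _manifest([
            {"probe_id": "p1", "chrom": "1", "pos": 100, "gene": "NPAS4",
             "feature_group": "TSS200", "cgi_relation": "island"},
            {"probe_id": "p2", "chrom": "1", "pos": 300, "gene": "NPAS4",
             "feature_group": "TSS1500", "cgi_relation": "island"},
            {"probe_id": "p3", "chrom": "2", "pos": 100, "gene": "OTHER",
             "feature_group": "Body", "cgi_relation": "open_sea"},
            {"probe_id": "p4", "chrom": "2", "pos": 400, "gene": "SOLO",
             "feature_group": "TSS200", "cgi_relation": "island"},
        ])
        markers = pd.DataFrame(
            {"direction": ["hyper_in_a"] * 4}, index=["p1", "p2", "p3", "p4"]
        )
        assert promoter_refine(markers, mani) == ["NPAS4"]


class TestGenesetOverlap:
    def test_disjoint(self):
        assert geneset_overlap({"A"}, {"B", "C"}) == (0, 0.0)

    def test_reference_subset(self):
        count, frac = geneset_overlap({"A", "B", "C"}, {"A", "B"})
        assert (count, frac) == (2, 1.0)

    def test_polycomb_scale_arithmetic(self):
        """197 hits of a 1,893-gene reference -> 10.4%."""
        ref = {f"g{i}" for i in range(1893)}
        dm = {f"g{i}" for i in range(197)} | {f"x{i}" for i in range(500)}
        count, frac = geneset_overlap(dm, ref)
        assert count == 197
        assert frac == pytest.approx(0.104, abs=5e-4)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            geneset_overlap({"A"}, set())


class TestGlobalStats:
    def test_constant_matrix(self, tissue_design):
        beta = _beta(tissue_design, np.full((10, 9), 0.5))
        out = global_stats(beta, tissue_design)
        assert (out["median"] == 0.5).all()

    def test_empty_matrix_rejected(self, tissue_design):
        with pytest.raises(ValueError):
            global_stats(pd.DataFrame(columns=tissue_design.sample_ids), tissue_design)
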