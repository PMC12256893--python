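"""1D sequence distances, windows and enrichment around CysLysTyr sites."""

import numpy as np
import pandas as pd
import pytest

from cpdaa.proximity1d import (
    detected_fractions,
    direct_overlap_enrichment,
    distance_comparison,
    enumerate_sites,
    linear_distances,
    nearest_distance,
    variant_level_enrichment,
    window_burden,
    window_enrichment,
)
from cpdaa.sequence_io import ProteinRecord
from cpdaa.variants import classify_variants


def make_variants(rows):
    base = {"accession": "P1", "ref_aa": "A", "alt_aa": "V",
            "ref_codon": "GCT", "alt_codon": "GTT",
            "clinical_label": "none", "allele_frequency": float("nan")}
    df = pd.DataFrame([{**base, **r} for r in rows])
    classified, _ = classify_variants(df)
    return classified


class TestEnumerateSites:
    def test_small_sequence(self):
        prots = [ProteinRecord("P1", "G1", "CAKY")]
        cpdaa = pd.DataFrame({"accession": ["P1"], "position": [1],
                              "residue_type": ["C"]})
        sites = enumerate_sites(prots, cpdaa)
        assert list(zip(sites["position"], sites["residue_type"])) == \
            [(1, "C"), (3, "K"), (4, "Y")]
        fr = detected_fractions(sites).set_index("residue_type")
        assert fr.loc["C", "fraction_detected"] == 1.0
        assert fr.loc["K", "fraction_detected"] == 0.0


class TestLinearDistances:
    def test_pairs_and_overlap(self):
        prots = [ProteinRecord("P1", "G1", "A" * 59 + "K" + "A" * 10)]
        cpdaa = pd.DataFrame({"accession": ["P1"], "position": [60],
                              "residue_type": ["K"]})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants([{"position": 63, "clinical_label": "pathogenic"},
                           {"position": 60, "clinical_label": "pathogenic",
                            "alt_aa": "W"}])
        pairs = linear_distances(sites, v)
        assert set(pairs["distance"]) == {0, 3}
        assert pairs.loc[pairs["distance"] == 0, "overlap"].all()


class TestNearestDistance:
    def test_overlap_excluded(self):
        anchors = pd.DataFrame({"accession": ["P1"], "position": [10]})
        targets = pd.DataFrame({"accession": ["P1", "P1"], "position": [10, 14]})
        nd = nearest_distance(anchors, targets, exclude_overlap=True)
        assert nd["nearest_distance"].iloc[0] == 4

    def test_only_overlap_skipped(self):
        anchors = pd.DataFrame({"accession": ["P1"], "position": [10]})
        targets = pd.DataFrame({"accession": ["P1"], "position": [10]})
        nd = nearest_distance(anchors, targets, exclude_overlap=True)
        assert nd.empty

    def test_two_sided_minimum(self):
        anchors = pd.DataFrame({"accession": ["P1"], "position": [10]})
        targets = pd.DataFrame({"accession": ["P1", "P1"], "position": [3, 12]})
        nd = nearest_distance(anchors, targets)
        assert nd["nearest_distance"].iloc[0] == 2

    def test_never_zero_with_exclusion(self):
        rng = np.random.default_rng(0)
        anchors = pd.DataFrame({"accession": "P1",
                                "position": rng.integers(1, 100, 30)})
        targets = pd.DataFrame({"accession": "P1",
                                "position": rng.integers(1, 100, 50)})
        nd = nearest_distance(anchors, targets, exclude_overlap=True)
        assert (nd["nearest_distance"] > 0).all()


class TestWindowBurden:
    def setup_method(self):
        seq = "A" * 59 + "K" + "A" * 40
        self.prots = [ProteinRecord("P1", "G1", seq)]
        self.cpdaa = pd.DataFrame({"accession": ["P1"], "position": [60],
                                   "residue_type": ["K"]})
        self.sites = enumerate_sites(self.prots, self.cpdaa)

    def test_half_width_counts(self):
        v = make_variants([
            {"position": 58, "clinical_label": "pathogenic"},
            {"position": 66, "clinical_label": "pathogenic"},
            {"position": 60, "clinical_label": "pathogenic", "alt_aa": "W"},
        ])
        b6 = window_burden(self.sites, v, half_width=6)
        assert b6["count_pathogenic"].iloc[0] == 2  # overlap at 60 excluded
        b3 = window_burden(self.sites, v, half_width=3)
        assert b3["count_pathogenic"].iloc[0] == 1

    def test_monotone_in_half_width(self):
        rng = np.random.default_rng(1)
        v = make_variants([
            {"position": int(p), "clinical_label": "pathogenic",
             "alt_aa": "VWY"[i % 3]}
            for i, p in enumerate(rng.integers(1, 100, 40))
        ])
        counts = {}
        for hw in (3, 6, 15):
            counts[hw] = window_burden(self.sites, v, half_width=hw)["count_pathogenic"]
        assert (counts[3] <= counts[6]).all() and (counts[6] <= counts[15]).all()

    def test_unique_allele_unit(self):
        # same position, two alt alleles -> 2; duplicate rows of one allele -> 1
        v = make_variants([
            {"position": 58, "clinical_label": "pathogenic", "alt_aa": "V"},
            {"position": 58, "clinical_label": "pathogenic", "alt_aa": "W"},
        ])
        b = window_burden(self.sites, v, half_width=6)
        assert b["count_pathogenic"].iloc[0] == 2


class TestWindowEnrichment:
    def test_arithmetic_example(self):
        # 10 detected windows (4 containing), 40 undetected (4 containing)
        burdens = pd.DataFrame({
            "accession": "P1",
            "position": range(1, 51),
            "residue_type": "C",
            "detected": [True] * 10 + [False] * 40,
            "contains_pathogenic": [True] * 4 + [False] * 6 + [True] * 4 + [False] * 36,
        })
        res = window_enrichment(burdens, "pathogenic", by_type=False)
        assert res[0].table.tolist() == [[4, 6], [4, 36]]
        assert res[0].odds_ratio == pytest.approx(6.0)

    def test_equal_rates_or_one(self):
        burdens = pd.DataFrame({
            "accession": "P1", "position": range(1, 41), "residue_type": "C",
            "detected": [True] * 20 + [False] * 20,
            "contains_pathogenic": ([True] * 5 + [False] * 15) * 2,
        })
        res = window_enrichment(burdens, "pathogenic", by_type=False)
        assert res[0].odds_ratio == pytest.approx(1.0)


class TestDirectOverlap:
    def test_arithmetic_example(self):
        seq = "C" * 10
        prots = [ProteinRecord("P1", "G1", seq)]
        cpdaa = pd.DataFrame({"accession": "P1", "position": [1, 2],
                              "residue_type": "C"})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants([
            {"position": 1, "ref_aa": "C", "clinical_label": "pathogenic"},
            {"position": 5, "ref_aa": "C", "clinical_label": "pathogenic"},
        ])
        res = direct_overlap_enrichment(sites, v, "pathogenic", by_type=False)
        assert res[0].table.tolist() == [[1, 1], [1, 7]]
        assert res[0].odds_ratio == pytest.approx(7.0)

    def test_no_variants_undefined(self):
        prots = [ProteinRecord("P1", "G1", "CCCC")]
        cpdaa = pd.DataFrame({"accession": ["P1"], "position": [1],
                              "residue_type": ["C"]})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants([{"position": 2, "allele_frequency": 0.2}])
        res = direct_overlap_enrichment(sites, v, "pathogenic", by_type=False)
        assert res[0].undefined


class TestDistanceComparison:
    def test_exact_p_small_sample(self):
        # detected nearest {1,2,3} vs undetected {10,11,12}: exact p = 0.1
        seq_parts = []
        # build a protein where 3 detected sites sit 1,2,3 away from variants
        # and 3 undetected sit 10,11,12 away
        seq = list("A" * 200)
        det_sites = [20, 50, 80]
        undet_sites = [110, 140, 170]
        var_offsets = [1, 2, 3]
        for s in det_sites + undet_sites:
            seq[s - 1] = "C"
        prots = [ProteinRecord("P1", "G1", "".join(seq))]
        cpdaa = pd.DataFrame({"accession": "P1", "position": det_sites,
                              "residue_type": "C"})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants(
            [{"position": s + o, "clinical_label": "pathogenic"}
             for s, o in zip(det_sites, [1, 2, 3])]
            + [{"position": s + o, "clinical_label": "pathogenic"}
               for s, o in zip(undet_sites, [10, 11, 12])]
        )
        out = distance_comparison(sites, v, "pathogenic")
        row = out[out["group"] == "C"].iloc[0]
        assert row["median_detected"] < row["median_undetected"]
        assert row["p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_balanced_distributions_p_one(self):
        # detected nearest distances {2, 9}, undetected {4, 7}: the rank
        # statistic sits exactly at its null mean, exact two-sided p = 1
        seq = list("A" * 100)
        for s in (20, 40, 60, 80):
            seq[s - 1] = "C"
        prots = [ProteinRecord("P1", "G1", "".join(seq))]
        cpdaa = pd.DataFrame({"accession": "P1", "position": [20, 40],
                              "residue_type": "C"})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants([{"position": p, "clinical_label": "pathogenic"}
                           for p in (22, 49, 64, 87)])
        out = distance_comparison(sites, v, "pathogenic")
        row = out[out["group"] == "C"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)


class TestVariantLevelEnrichment:
    def test_zone_flags(self):
        seq = list("A" * 100)
        seq[49] = "K"  # detected site at 50
        prots = [ProteinRecord("P1", "G1", "".join(seq))]
        cpdaa = pd.DataFrame({"accession": ["P1"], "position": [50],
                              "residue_type": ["K"]})
        sites = enumerate_sites(prots, cpdaa)
        v = make_variants([
            {"position": 52, "clinical_label": "pathogenic"},   # near
            {"position": 80, "clinical_label": "pathogenic"},   # far
            {"position": 56, "allele_frequency": 0.2},          # near bg
            {"position": 10, "allele_frequency": 0.2},          # far bg
            {"position": 90, "allele_frequency": 0.2},          # far bg
        ])
        res = variant_level_enrichment(sites, v)
        assert res.table.tolist() == [[1, 1], [1, 2]]
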