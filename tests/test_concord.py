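"""Region annotation, overlaps, concordance table, marker panels."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from hcmomics import concord
from hcmomics.concord import (
    acetylome_direction_by_gene,
    annotate_regions,
    build_concordance_table,
    candidate_table_as_concordance,
    count_plasma_detectable,
    intersect_ranked_de,
    load_candidate_table,
    marker_panel_summary,
    overlap_proteome,
)


def regions_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2fc", "padj"])


def tss_df(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestAnnotateRegions:
    def test_distance_to_upstream_tss(self):
        regions = regions_df([("chr1", 1000, 1200, 1.0, 0.01)])
        tss = tss_df([("geneA", "chr1", 900, "+")])
        out = annotate_regions(regions, tss, window=5000)
        assert len(out) == 1
        assert out.iloc[0]["gene"] == "geneA"
        assert out.iloc[0]["distance"] == 100
        assert out.iloc[0]["nearest"]

    def test_window_boundary_inclusive(self):
        regions = regions_df([("chr1", 10_000, 10_500, 1.0, 0.01)])
        tss = tss_df([("at_boundary", "chr1", 5_000, "+"),
                      ("just_outside", "chr1", 4_999, "+")])
        out = annotate_regions(regions, tss, window=5000)
        assert list(out["gene"]) == ["at_boundary"]

    def test_tss_inside_region_distance_zero(self):
        regions = regions_df([("chr1", 100, 300, -1.0, 0.01)])
        tss = tss_df([("inside", "chr1", 100, "+"), ("last", "chr1", 299, "-")])
        out = annotate_regions(regions, tss, window=5000)
        assert (out["distance"] == 0).all() and len(out) == 2

    def test_nearest_tie_breaks_by_gene_id(self):
        regions = regions_df([("chr1", 1000, 1100, 1.0, 0.01)])
        tss = tss_df([("b_gene", "chr1", 900, "+"), ("a_gene", "chr1", 1199, "-")])
        out = annotate_regions(regions, tss, window=5000)
        nearest = out[out["nearest"]]
        assert list(nearest["gene"]) == ["a_gene"]

    def test_mixed_chromosome_naming_rejected(self):
        regions = regions_df([("chr1", 100, 200, 1.0, 0.01)])
        tss = tss_df([("g", "1", 150, "+")])
        with pytest.raises(ValueError, match="chromosome"):
            annotate_regions(regions, tss, window=5000)

    def test_matches_bruteforce_all_pairs(self):
        from hcmomics.studies import annotation_bruteforce_oracle

        res = annotation_bruteforce_oracle(n_regions=200, n_tss=50, seed=4)
        assert all(v == 1 for v in res.values())

    def test_translation_invariance(self, rng):
        starts = rng.integers(0, 100_000, size=30)
        regions = regions_df([("chrZ", int(s), int(s + 500), 1.0, 0.01)
                              for s in starts])
        tss = tss_df([("g%d" % i, "chrZ", int(p), "+")
                      for i, p in enumerate(rng.integers(0, 100_000, size=10))])
        base = annotate_regions(regions, tss, window=5000)
        shift = 7_777
        regions2 = regions.assign(start=regions["start"] + shift,
                                  end=regions["end"] + shift)
        tss2 = tss.assign(tss=tss["tss"] + shift)
        moved = annotate_regions(regions2, tss2, window=5000)
        assert list(moved["gene"]) == list(base["gene"])
        assert list(moved["distance"]) == list(base["distance"])
        assert list(moved["nearest"]) == list(base["nearest"])

    def test_malformed_region_rejected(self):
        regions = regions_df([("chr1", 500, 200, 1.0, 0.01)])
        with pytest.raises(ValueError, match="start"):
            annotate_regions(regions, tss_df([("g", "chr1", 100, "+")]), 5000)


def ranked_of(features):
    return pd.DataFrame({"feature": features,
                         "loading": np.linspace(1, 0.5, len(features)),
                         "rank": np.arange(1, len(features) + 1)})


def de_of(up=(), down=(), null=()):
    rows = []
    for f in up:
        rows.append({"feature": f, "log2fc": 1.0, "padj": 0.001})
    for f in down:
        rows.append({"feature": f, "log2fc": -1.0, "padj": 0.001})
    for f in null:
        rows.append({"feature": f, "log2fc": 0.1, "padj": 0.5})
    return pd.DataFrame(rows)


class TestIntersectRankedDe:
    def test_direction_split(self):
        inter = intersect_ranked_de(ranked_of(["A", "B", "C"]),
                                    de_of(up=["A", "D"], down=["C"]))
        assert list(inter["up"]["feature"]) == ["A"]
        assert list(inter["down"]["feature"]) == ["C"]

    def test_empty_ranked_list(self):
        inter = intersect_ranked_de(ranked_of([]), de_of(up=["A"]))
        assert inter["up"].empty and inter["down"].empty

    def test_duplicate_de_ids_rejected(self):
        de = de_of(up=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            intersect_ranked_de(ranked_of(["A"]), de)

    def test_monotone_in_ranked_list(self):
        """Enlarging the ranked list never shrinks the outputs."""
        de = de_of(up=["A", "B", "E"], down=["C"], null=["D"])
        small = intersect_ranked_de(ranked_of(["A", "C"]), de)
        big = intersect_ranked_de(ranked_of(["A", "C", "B", "D", "E"]), de)
        assert set(small["up"]["feature"]) <= set(big["up"]["feature"])
        assert set(small["down"]["feature"]) <= set(big["down"]["feature"])


class TestOverlapProteome:
    def test_concordant_retained_discordant_flagged(self):
        up = ranked_of(["A", "B"]).assign(log2fc=[1.0, 1.2], padj=0.01)
        down = ranked_of(["C"]).assign(log2fc=[-1.0], padj=0.01)
        proteome = pd.DataFrame({
            "feature": ["A", "B", "C"],
            "log2fc": [1.0, -1.0, -0.5],
            "padj": [0.001, 0.001, 0.001],
        })
        out = overlap_proteome(up, down, proteome)
        assert list(out["up"]["feature"]) == ["A"]
        assert list(out["down"]["feature"]) == ["C"]
        assert list(out["discordant"]["feature"]) == ["B"]

    def test_non_significant_protein_dropped(self):
        up = ranked_of(["A"]).assign(log2fc=[1.0], padj=0.01)
        proteome = pd.DataFrame({"feature": ["A"], "log2fc": [1.0], "padj": [0.5]})
        out = overlap_proteome(up, ranked_of([]).assign(log2fc=[], padj=[]), proteome)
        assert out["up"].empty

    def test_atp2a2_candidate_row_retained_as_down(self):
        """The curated ATP2A2 row (RNA -1.4668, protein -0.3540) stays down."""
        table = load_candidate_table()
        row = table[table["symbol"] == "ATP2A2"].iloc[0]
        down = pd.DataFrame({"feature": ["ATP2A2"], "rank": [row["o2pls_rank"]],
                             "loading": [0.1], "log2fc": [row["rna_log2fc"]],
                             "padj": [0.001]})
        proteome = pd.DataFrame({"feature": ["ATP2A2"],
                                 "log2fc": [row["protein_log2fc"]],
                                 "padj": [0.001]})
        out = overlap_proteome(down.iloc[0:0], down, proteome)
        assert list(out["down"]["feature"]) == ["ATP2A2"]
        assert out["down"].iloc[0]["protein_log2fc"] == pytest.approx(-0.353968239)


class TestConcordanceTable:
    def _lists(self):
        up = pd.DataFrame({"feature": ["NPPA"], "rank": [13], "loading": [0.3],
                           "log2fc": [1.549472808], "padj": [1e-6],
                           "protein_log2fc": [0.747781872], "protein_padj": [1e-4]})
        down = up.iloc[0:0]
        return up, down

    def test_nppa_style_row_fully_concordant_at_50kb(self):
        up, down = self._lists()
        table = build_concordance_table(
            up, down, {50_000: {"NPPA": 1}},
            plasma={"NPPA": "detected"},
            external_cm={"NPPA": 0.542363796})
        row = table.iloc[0]
        assert row["o2pls_rank"] == 13
        assert row["acetylome_match_50kb"] == "yes"
        assert bool(row["fully_concordant_50kb"])
        assert row["plasma_detectable"] == "detected"

    def test_no_region_in_window_not_fully_concordant(self):
        up, down = self._lists()
        table = build_concordance_table(up, down, {50_000: {}})
        row = table.iloc[0]
        assert row["acetylome_match_50kb"] == "no"
        assert not bool(row["fully_concordant_50kb"])
        assert row["plasma_detectable"] == "no_data"

    def test_opposite_direction_region_no_match(self):
        up, down = self._lists()
        table = build_concordance_table(up, down, {5_000: {"NPPA": -1}})
        assert table.iloc[0]["acetylome_match_5kb"] == "no"

    def test_flag_matrix_matches_bruteforce(self, rng):
        """Random planted patterns vs a row-by-row re-evaluation."""
        genes = [f"g{i}" for i in range(30)]
        signs = rng.choice([1, -1], size=30)
        up = pd.DataFrame({
            "feature": [g for g, s in zip(genes, signs) if s > 0],
            "rank": np.arange(1, int((signs > 0).sum()) + 1),
            "log2fc": 1.0, "padj": 0.001, "protein_log2fc": 0.5,
            "protein_padj": 0.001})
        down = pd.DataFrame({
            "feature": [g for g, s in zip(genes, signs) if s < 0],
            "rank": np.arange(1, int((signs < 0).sum()) + 1),
            "log2fc": -1.0, "padj": 0.001, "protein_log2fc": -0.5,
            "protein_padj": 0.001})
        acet = {g: int(rng.choice([1, -1, 2])) for g in genes if rng.random() < 0.7}
        table = build_concordance_table(up, down, {5000: acet, 50_000: acet})
        for _, row in table.iterrows():
            s = 1 if row["rna_direction"] == "up" else -1
            expect = acet.get(row["gene"])
            expect_match = expect is not None and (expect == 2 or expect == s)
            assert (row["acetylome_match_5kb"] == "yes") == expect_match
            assert bool(row["fully_concordant_5kb"]) == expect_match

    def test_subset_chain(self):
        """fully concordant rows form a subset of the table's genes."""
        up, down = self._lists()
        table = build_concordance_table(up, down, {50_000: {"NPPA": 1}})
        fully = set(table[table["fully_concordant_50kb"]]["gene"])
        assert fully <= set(table["gene"])


class TestPlasmaCount:
    def test_counts_detected_rows(self):
        rows = pd.DataFrame({"plasma_detectable":
                             ["detected", "not_detected", "no_data", "detected"]})
        assert count_plasma_detectable(rows) == 2

    def test_all_no_data_is_zero(self):
        rows = pd.DataFrame({"plasma_detectable": ["no_data"] * 5})
        assert count_plasma_detectable(rows) == 0

    def test_random_flags_equal_indicator_sum(self, rng):
        flags = rng.choice(["detected", "not_detected", "no_data"], size=200)
        rows = pd.DataFrame({"plasma_detectable": flags})
        assert count_plasma_detectable(rows) == int((flags == "detected").sum())


class TestCandidateTableFixture:
    def test_shape_and_direction_counts(self):
        table = load_candidate_table()
        assert len(table) == 53
        assert (table["rna_log2fc"] > 0).sum() == 36
        assert (table["rna_log2fc"] < 0).sum() == 17
        # every curated candidate is RNA/protein sign-concordant
        assert (np.sign(table["rna_log2fc"])
                == np.sign(table["protein_log2fc"])).all()

    def test_fully_concordant_50kb_superset_of_5kb_claim(self):
        """The 50 kb fully-concordant, plasma-detected set contains the five
        genes called out as concordant at 5 kb (ASPN, FMOD, MCAM, NPPA up;
        AASS down)."""
        conc = candidate_table_as_concordance()
        detected = conc[(conc["fully_concordant_50kb"])
                        & (conc["plasma_detectable"] == "detected")]
        assert {"ASPN", "FMOD", "MCAM", "NPPA", "AASS"} <= set(detected["gene"])


class TestMarkerPanels:
    def make_matrix(self, rng, markers, n_samples=8):
        return pd.DataFrame(rng.normal(5, 1, size=(n_samples, len(markers))),
                            index=[f"S{i}" for i in range(n_samples)],
                            columns=markers)

    def test_identical_panels_f_near_zero(self, rng):
        mat = self.make_matrix(rng, ["a", "b", "c"])
        panels = {"cardiomyocyte": ["a", "b", "c"], "other": ["a", "b", "c"]}
        out = marker_panel_summary(mat, panels)
        row = out["panels"].set_index("panel").loc["other"]
        assert row["anova_F"] == pytest.approx(0.0, abs=1e-12)
        assert row["anova_p"] == pytest.approx(1.0)

    def test_f_matches_textbook_formula(self):
        """Marker means {1,2,3} vs {4,5,6}: F = MSB/MSW = 13.5, p from F(1,4)."""
        mat = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], (4, 1)),
            index=[f"S{i}" for i in range(4)],
            columns=["m1", "m2", "m3", "n1", "n2", "n3"])
        panels = {"cardiomyocyte": ["m1", "m2", "m3"], "fibroblast": ["n1", "n2", "n3"]}
        out = marker_panel_summary(mat, panels)
        row = out["panels"].set_index("panel").loc["fibroblast"]
        assert row["anova_F"] == pytest.approx(13.5)
        assert row["anova_p"] == pytest.approx(float(f_dist.sf(13.5, 1, 4)))

    def test_absent_marker_excluded_with_warning(self, rng):
        mat = self.make_matrix(rng, ["a", "b", "c", "d"])
        panels = {"cardiomyocyte": ["a", "b"], "tcell": ["c", "d", "GHOST"]}
        with pytest.warns(UserWarning, match="GHOST"):
            out = marker_panel_summary(mat, panels)
        row = out["panels"].set_index("panel").loc["tcell"]
        assert row["n_markers"] == 2 and row["n_missing"] == 1

    def test_small_panel_gets_no_f(self, rng):
        mat = self.make_matrix(rng, ["a", "b", "c"])
        panels = {"cardiomyocyte": ["a", "b"], "mono": ["c"]}
        out = marker_panel_summary(mat, panels)
        row = out["panels"].set_index("panel").loc["mono"]
        assert np.isnan(row["anova_F"])

    def test_group_means_reported(self, rng):
        mat = self.make_matrix(rng, ["a", "b"], n_samples=6)
        panels = {"cardiomyocyte": ["a", "b"]}
        out = marker_panel_summary(mat, panels,
                                   groups=["case"] * 3 + ["control"] * 3)
        assert {"mean_case", "mean_control"} <= set(out["markers"].columns)


class TestAcetylomeDirection:
    def test_disjunctive_and_strict_modes(self):
        ann = pd.DataFrame({
            "gene": ["g1", "g1", "g2", "g3"],
            "log2fc": [1.0, -1.0, 2.0, -0.5],
        })
        loose = acetylome_direction_by_gene(ann)
        strict = acetylome_direction_by_gene(ann, strict=True)
        assert loose == {"g1": 2, "g2": 1, "g3": -1}
        assert strict == {"g1": 0, "g2": 1, "g3": -1}
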