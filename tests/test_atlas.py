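"""Atlas merging, filtering and signature-CpG selection."""

import numpy as np
import pandas as pd
import pytest

from cfmeth.atlas import (
    MethylationAtlas,
    SelectionConfig,
    add_neighbors,
    add_pairwise_specific,
    build_signature,
    filter_and_pool,
    make_signature,
    merge_atlases,
    select_most_differential,
    select_top_scaled,
)


def atlas_of(data: dict, probes: list[str]) -> MethylationAtlas:
    return MethylationAtlas(pd.DataFrame(data, index=pd.Index(probes, name="probe_id")))


class TestMerge:
    def test_inner_join_keeps_shared_probes(self):
        base = atlas_of({"A": [0.1, 0.2]}, ["p1", "p2"])
        ext = atlas_of({"B": [0.3, 0.4]}, ["p2", "p3"])
        merged = merge_atlases(base, ext)
        assert list(merged.probe_ids) == ["p2"]
        assert merged.cell_types == ["A", "B"]

    def test_duplicate_cell_type_label_rejected(self):
        base = atlas_of({"A": [0.1, 0.2]}, ["p1", "p2"])
        with pytest.raises(ValueError, match="duplicate"):
            merge_atlases(base, atlas_of({"A": [0.1, 0.2]}, ["p1", "p2"]))

    def test_outer_join_introduces_missing_values(self):
        base = atlas_of({"A": [0.1, 0.2, 0.3, 0.4, 0.5], "B": [0.5] * 5},
                        ["p1", "p2", "p3", "p4", "p5"])
        ext = atlas_of({"C": [0.9, 0.8, 0.7]}, ["p2", "p3", "p4"])
        merged = merge_atlases(base, ext, join="outer")
        assert merged.beta.shape == (5, 3)
        assert merged.beta.loc[["p1", "p5"], "C"].isna().all()
        assert merged.beta.loc[["p2", "p3", "p4"], "C"].notna().all()


class TestFilterAndPool:
    def test_constant_low_variance_and_missing_rows_removed(self):
        atlas = atlas_of(
            {"A": [0.5, 0.1, 0.2], "B": [0.5, np.nan, 0.8]}, ["c0", "c1", "c2"]
        )
        pooled = filter_and_pool(atlas)
        assert list(pooled.probe_ids) == ["c2"]  # c0 constant, c1 has NA

    def test_replicates_pooled_by_mean(self):
        atlas = atlas_of({"A_rep1": [0.2, 0.9], "A_rep2": [0.4, 0.1]}, ["p1", "p2"])
        pooled = filter_and_pool(atlas, tissue_map={"A_rep1": "A", "A_rep2": "A"})
        assert pooled.cell_types == ["A"]
        assert pooled.beta.loc["p1", "A"] == pytest.approx(0.3)

    def test_empty_result_reports_diagnostics(self):
        atlas = atlas_of({"A": [0.5], "B": [0.5]}, ["p1"])
        with pytest.raises(ValueError, match="no probes survive"):
            filter_and_pool(atlas)


class TestTopScaled:
    def test_one_hot_atlas_selects_unique_probes(self):
        atlas = atlas_of(
            {"A": [1.0, 0.0, 0.0], "B": [0.0, 1.0, 0.0], "C": [0.0, 0.0, 1.0]},
            ["pa", "pb", "pc"],
        )
        sel = select_top_scaled(atlas, k=1)
        assert sel[("hyper", "A")] == ["pa"]
        assert sel[("hyper", "B")] == ["pb"]
        assert sel[("hyper", "C")] == ["pc"]

    def test_exclusion_list_forces_second_type_to_next_rank(self):
        # after row scaling p1 is the joint best probe of A and B; A (processed
        # first) claims it, so B falls back to its next-ranked probe p3
        atlas = atlas_of(
            {"A": [0.45, 0.4, 0.2], "B": [0.45, 0.2, 0.4], "C": [0.1, 0.4, 0.4]},
            ["p1", "p2", "p3"],
        )
        sel = select_top_scaled(atlas, k=1)
        assert sel[("hyper", "A")] == ["p1"]
        assert sel[("hyper", "B")] == ["p3"]

    def test_toy_matrix_matches_brute_force_ranking(self, toy_atlas):
        # row-scaled col A: p1 .8, p2 .5, p3 .1, p4 .8 -> A takes p1, p4 (tie by ID)
        # col B then: p3 .9, p2 .5 -> B takes p3, p2
        sel = select_top_scaled(toy_atlas, k=2)
        assert sel[("hyper", "A")] == ["p1", "p4"]
        assert sel[("hyper", "B")] == ["p3", "p2"]

    def test_row_scaling_invariance(self, toy_atlas):
        sel = select_top_scaled(toy_atlas, k=2)
        # multiplying a row by a positive constant leaves the scaled rows unchanged
        scaled = toy_atlas.beta.mul(pd.Series([0.5, 1.0, 0.25, 1.0], index=toy_atlas.beta.index), axis=0)
        sel2 = select_top_scaled(MethylationAtlas(scaled), k=2)
        assert sel == sel2

    def test_hyper_hypo_sets_pairwise_disjoint(self, marker_atlas):
        atlas, _ = marker_atlas
        sel = select_top_scaled(atlas, k=20)
        all_sets = list(sel.values())
        for i, s in enumerate(all_sets):
            for t in all_sets[i + 1 :]:
                assert not set(s) & set(t)

    def test_short_supply_warns_and_returns_available(self):
        atlas = atlas_of({"A": [1.0, 0.0], "B": [0.0, 1.0]}, ["p1", "p2"])
        with pytest.warns(UserWarning, match="only"):
            sel = select_top_scaled(atlas, k=5)
        assert sel[("hyper", "A")] == ["p1", "p2"]
        assert sel[("hyper", "B")] == []


class TestMostDifferential:
    def test_extreme_probe_ranks_first(self):
        atlas = atlas_of(
            {"A": [1.0, 0.6], "B": [0.0, 0.4], "C": [0.0, 0.5]}, ["hit", "soft"]
        )
        sel = select_most_differential(atlas, k=2)
        assert sel["A"][0] == "hit"

    def test_pooled_score_orders_by_separation(self):
        # |0.9-0.1|/sd(0.1,0.1) >> |0.6-0.45|/sd(0.4,0.5)
        atlas = atlas_of(
            {"t1": [0.9, 0.6], "t2": [0.1, 0.4], "t3": [0.1, 0.5]}, ["sharp", "fuzzy"]
        )
        sel = select_most_differential(atlas, k=2)
        assert sel["t1"] == ["sharp", "fuzzy"]

    def test_constant_rows_warn_but_stay_deterministic(self):
        atlas = atlas_of({"A": [0.5, 0.5], "B": [0.5, 0.5]}, ["p2", "p1"])
        with pytest.warns(UserWarning, match="no differential signal"):
            sel = select_most_differential(atlas, k=1)
        assert sel["A"] == ["p1"]  # tie broken by probe ID

    def test_replicated_columns_use_anova(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(20)]
        data = {f"A_rep{j}": rng.uniform(0.4, 0.6, 20) for j in (1, 2)}
        data |= {f"B_rep{j}": rng.uniform(0.4, 0.6, 20) for j in (1, 2)}
        # plant a clean A-vs-rest difference on p0
        for j in (1, 2):
            data[f"A_rep{j}"][0] = 0.95
            data[f"B_rep{j}"][0] = 0.05
        atlas = atlas_of(data, probes)
        tissue_map = {c: c.split("_")[0] for c in atlas.beta.columns}
        sel = select_most_differential(atlas, k=3, tissue_map=tissue_map)
        assert sel["A"][0] == "p0"


class TestNeighborsAndPairwise:
    def test_neighbor_window_boundary(self, toy_atlas):
        out = add_neighbors({"p1"}, toy_atlas, window=50)
        assert "p2" in out  # chr1:1049, 49 bp away
        assert "p3" not in out  # chr1:1051, 51 bp away
        assert "p4" not in out  # other chromosome

    def test_no_coordinates_warns_and_passes_through(self):
        atlas = atlas_of({"A": [0.5, 0.1]}, ["p1", "p2"])
        with pytest.warns(UserWarning, match="no coordinates"):
            assert add_neighbors({"p1"}, atlas, 50) == {"p1"}

    def test_pairwise_picks_largest_gap_and_skips_selected(self):
        atlas = atlas_of({"A": [0.9, 0.6], "B": [0.1, 0.4]}, ["big", "small"])
        assert add_pairwise_specific(atlas, set()) == {"big"}
        assert add_pairwise_specific(atlas, {"big"}) == {"big", "small"}

    def test_three_types_give_at_most_three_additions(self):
        rng = np.random.default_rng(0)
        atlas = atlas_of(
            {t: rng.uniform(0, 1, 10) for t in "ABC"}, [f"p{i}" for i in range(10)]
        )
        added = add_pairwise_specific(atlas, set(), k_pair=1)
        assert 1 <= len(added) <= 3


class TestBuildSignature:
    def test_union_is_deduplicated_and_sorted(self, toy_atlas):
        sig = build_signature(toy_atlas, {"hyper_topk": ["p1"], "differential": ["p1", "p3"]})
        assert list(sig.probe_ids) == ["p1", "p3"]

    def test_provenance_precedence(self, toy_atlas):
        sig = build_signature(
            toy_atlas, {"pairwise": ["p1"], "hypo_topk": ["p1"], "neighbor": ["p2"]}
        )
        assert sig.provenance["p1"] == "hypo_topk"
        assert sig.provenance["p2"] == "neighbor"

    def test_empty_selection_rejected(self, toy_atlas):
        with pytest.raises(ValueError, match="empty selection"):
            build_signature(toy_atlas, {})

    def test_signature_recovers_planted_markers(self, marker_atlas):
        atlas, truth = marker_atlas
        cfg = SelectionConfig(k_top=15, k_diff=15, neighbor_window=50)
        sig = make_signature(atlas, cfg)
        planted = set(truth["probe_id"])
        recovered = planted & set(sig.probe_ids)
        assert len(recovered) / len(planted) >= 0.95
        assert set(sig.cell_types) == set(atlas.cell_types)

    def test_signature_build_is_deterministic(self, marker_atlas):
        atlas, _ = marker_atlas
        cfg = SelectionConfig(k_top=10, k_diff=10)
        a = make_signature(atlas, cfg)
        b = make_signature(atlas, cfg)
        pd.testing.assert_frame_equal(a.beta, b.beta)
        pd.testing.assert_series_equal(a.provenance, b.provenance)
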