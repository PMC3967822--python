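"""Node summaries, separation accuracy, %GC categories, diagnostics, borders."""

import numpy as np
import pandas as pd
import pytest

from genomesig import (
    AnalysisError,
    build_degenerate_index,
    diagnostic_map,
    gc_categories,
    separation_accuracy,
    subset_highlight,
    summarize_nodes,
    territory_borders,
)
from genomesig.analysis import MapSummary

from conftest import make_som, taxa_frame


@pytest.fixture(scope="module")
def idx1():
    return build_degenerate_index(1)


def assignment_frame(entries):
    """entries: iterable of (genome_id, start, i, j)."""
    df = pd.DataFrame(entries, columns=["genome_id", "start", "i", "j"])
    df["distance"] = 0.0
    return df


@pytest.fixture
def three_node_summary(idx1):
    """3x1 map holding {X:4}, {Y:3}, {X:2, Y:1} fragments by family."""
    som = make_som(np.full((3, 1, 2), 0.5))
    taxa = taxa_frame(
        [("gx", "sx", "", "X", "G"), ("gy", "sy", "", "Y", "G")]
    )
    entries = (
        [("gx", 100 * t, 0, 0) for t in range(4)]
        + [("gy", 100 * t, 1, 0) for t in range(3)]
        + [("gx", 1000 + 100 * t, 2, 0) for t in range(2)]
        + [("gy", 1000, 2, 0)]
    )
    return summarize_nodes(assignment_frame(entries), taxa, "family", som, idx1)


class TestSummarizeNodes:
    def test_color_classes_by_definition(self, three_node_summary):
        s = three_node_summary
        assert s.color_class[0, 0] == "mono"
        assert s.color_class[1, 0] == "mono"
        assert s.color_class[2, 0] == "multi"
        assert (s.color_class == "multi").sum() == 1

    def test_uniform_weight_gives_50_percent_gc(self, three_node_summary):
        np.testing.assert_allclose(three_node_summary.gc_percent, 50.0)

    def test_empty_nodes_marked_empty(self, idx1):
        som = make_som(np.full((2, 2, 2), 0.5))
        taxa = taxa_frame([("g", "s", "", "F", "G")])
        summary = summarize_nodes(
            assignment_frame([("g", 0, 0, 0)]), taxa, "family", som, idx1
        )
        assert summary.color_class[0, 0] == "mono"
        assert (summary.color_class == "empty").sum() == 3

    def test_missing_label_names_fragment(self, idx1):
        som = make_som(np.full((2, 1, 2), 0.5))
        taxa = taxa_frame([("g", "s", "", "", "")])
        with pytest.raises(AnalysisError, match="g:0"):
            summarize_nodes(
                assignment_frame([("g", 0, 0, 0)]), taxa, "family", som, idx1
            )


class TestSeparationAccuracy:
    def test_hand_counted_example(self, three_node_summary):
        # 7 of 10 fragments sit in mono nodes
        assert separation_accuracy(three_node_summary) == pytest.approx(70.0)

    def test_all_mono_is_100(self, idx1):
        som = make_som(np.full((2, 1, 2), 0.5))
        taxa = taxa_frame([("g", "s", "", "F", "G")])
        summary = summarize_nodes(
            assignment_frame([("g", 0, 0, 0), ("g", 100, 1, 0)]),
            taxa, "family", som, idx1,
        )
        assert separation_accuracy(summary) == 100.0

    def test_single_mixed_node_is_0(self, idx1):
        som = make_som(np.full((2, 1, 2), 0.5))
        taxa = taxa_frame([("a", "", "", "F1", ""), ("b", "", "", "F2", "")])
        summary = summarize_nodes(
            assignment_frame([("a", 0, 0, 0), ("b", 0, 0, 0)]),
            taxa, "family", som, idx1,
        )
        assert separation_accuracy(summary) == 0.0

    def test_purity_mode_counts_majority_fragments(self, three_node_summary):
        # mono nodes contribute 7, the {X:2, Y:1} node contributes its 2-strong
        # majority
        assert separation_accuracy(three_node_summary, mode="purity") == pytest.approx(
            90.0
        )

    def test_invariant_under_family_relabeling(self, idx1):
        som = make_som(np.full((3, 1, 2), 0.5))
        entries = [("a", 0, 0, 0), ("a", 1, 1, 0), ("b", 0, 1, 0), ("b", 1, 2, 0)]
        taxa1 = taxa_frame([("a", "", "", "F1", ""), ("b", "", "", "F2", "")])
        taxa2 = taxa_frame([("a", "", "", "Zeta", ""), ("b", "", "", "Eta", "")])
        acc1 = separation_accuracy(
            summarize_nodes(assignment_frame(entries), taxa1, "family", som, idx1)
        )
        acc2 = separation_accuracy(
            summarize_nodes(assignment_frame(entries), taxa2, "family", som, idx1)
        )
        assert acc1 == acc2

    def test_splitting_labels_cannot_raise_accuracy(self, idx1):
        # species refine families: a mono-family node may become multi-species,
        # so family accuracy >= species accuracy on the same assignment
        som = make_som(np.full((2, 1, 2), 0.5))
        taxa = taxa_frame(
            [("a", "s1", "", "F", ""), ("b", "s2", "", "F", ""), ("c", "s3", "", "H", "")]
        )
        entries = [("a", 0, 0, 0), ("b", 0, 0, 0), ("c", 0, 1, 0)]
        fam = separation_accuracy(
            summarize_nodes(assignment_frame(entries), taxa, "family", som, idx1)
        )
        spc = separation_accuracy(
            summarize_nodes(assignment_frame(entries), taxa, "species", som, idx1)
        )
        assert fam >= spc

    def test_empty_assignment_rejected(self, idx1):
        som = make_som(np.full((2, 1, 2), 0.5))
        summary = summarize_nodes(
            assignment_frame([]), taxa_frame([("g", "", "", "F", "")]),
            "family", som, idx1,
        )
        with pytest.raises(AnalysisError, match="no assigned"):
            separation_accuracy(summary)


class TestGcCategories:
    def _summary(self, gc_values):
        n = len(gc_values)
        counts = np.ones((n, 1), dtype=np.int64)
        color = np.full((n, 1), "mono", dtype=object)
        hists = {(i, 0): {"F": 1} for i in range(n)}
        return MapSummary("family", counts, color, np.array(gc_values)[:, None], hists)

    def test_90_nodes_give_nine_blocks_of_ten(self, rng):
        cats = gc_categories(self._summary(rng.uniform(20, 60, 90)), 9)
        sizes = [(cats == c).sum() for c in range(1, 10)]
        assert sizes == [10] * 9

    def test_91_nodes_put_the_extra_in_the_last_block(self, rng):
        cats = gc_categories(self._summary(rng.uniform(20, 60, 91)), 9)
        sizes = [(cats == c).sum() for c in range(1, 10)]
        assert sizes == [10] * 8 + [11]

    def test_category_nondecreasing_in_gc_rank(self, rng):
        gc = rng.uniform(20, 60, 45)
        cats = gc_categories(self._summary(gc), 9).ravel()
        order = np.argsort(gc, kind="stable")
        assert (np.diff(cats[order]) >= 0).all()

    def test_partitions_nonempty_nodes_exactly_once(self, rng):
        summary = self._summary(rng.uniform(20, 60, 40))
        summary.counts[3, 0] = 0  # one empty node
        cats = gc_categories(summary, 9)
        assert cats[3, 0] == 0
        assert (cats[summary.counts > 0] > 0).all()

    def test_fewer_nodes_than_categories_rejected(self, rng):
        with pytest.raises(AnalysisError, match="non-empty"):
            gc_categories(self._summary(rng.uniform(20, 60, 5)), 9)


class TestDiagnosticMap:
    def test_ratio_grid_from_node_weights(self, idx1):
        # k=1: column 1 is the C/G set; a node with GC-rich weights is
        # "overrepresented" only through its own composition, so ratio == 1
        som = make_som(np.array([[[0.7, 0.3]], [[0.2, 0.8]]]))
        diag = diagnostic_map(som, idx1, "C")
        np.testing.assert_allclose(diag.ratio_grid, 1.0)

    def test_depleted_column_reads_below_one(self, idx4, rng):
        from genomesig import count_fragment
        from conftest import random_dna

        seq = random_dna(rng, 20_000)
        freq = count_fragment(seq, idx4)
        col = idx4.lookup("ACGT")
        freq2 = freq.copy()
        freq2[col] *= 0.2
        freq2 /= freq2.sum()
        som = make_som(np.stack([freq, freq2])[:, None, :])
        diag = diagnostic_map(som, idx4, "ACGT")
        assert diag.ratio_grid[1, 0] < 0.5 * diag.ratio_grid[0, 0]

    def test_negative_weights_are_clamped_with_warning(self, idx1):
        som = make_som(np.array([[[1.1, -0.1]]]))
        with pytest.warns(UserWarning, match="clamping"):
            diag = diagnostic_map(som, idx1, "A")
        assert np.isfinite(diag.ratio_grid).all()

    def test_color_classes_follow_breaks(self, idx1):
        som = make_som(np.array([[[0.7, 0.3]], [[0.2, 0.8]]]))
        diag = diagnostic_map(som, idx1, "C", color_breaks=(0.99, 1.01))
        assert set(diag.color_grid.ravel()) == {"white"}


class TestHighlightAndBorders:
    def test_highlight_definition(self, three_node_summary):
        flags = subset_highlight(three_node_summary, {"X"})
        assert flags[0, 0] and not flags[1, 0] and not flags[2, 0]

    def test_all_labels_highlights_every_nonempty_node(self, three_node_summary):
        flags = subset_highlight(three_node_summary, {"X", "Y"})
        assert flags.sum() == 3

    def test_empty_target_highlights_nothing(self, three_node_summary):
        assert subset_highlight(three_node_summary, set()).sum() == 0

    def _grid(self, layout, labels):
        I, J = len(layout), len(layout[0])
        counts = np.zeros((I, J), dtype=np.int64)
        color = np.full((I, J), "empty", dtype=object)
        hists = {}
        for i in range(I):
            for j in range(J):
                lab = layout[i][j]
                if lab != ".":
                    counts[i, j] = 1
                    color[i, j] = "mono"
                    hists[(i, j)] = {labels[lab]: 1}
        return MapSummary("family", counts, color, np.full((I, J), 50.0), hists)

    def test_empty_node_between_two_territories_is_a_border(self):
        s = self._grid(["X.Y"], {"X": "fx", "Y": "fy"})
        assert territory_borders(s) == {(0, 1)}

    def test_empty_node_beside_one_territory_is_not(self):
        s = self._grid(["X.."], {"X": "fx"})
        assert territory_borders(s) == set()

    def test_full_mono_map_has_no_borders(self):
        s = self._grid(["XX", "XX"], {"X": "fx"})
        assert territory_borders(s) == set()
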