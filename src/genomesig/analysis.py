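"""Analyses of a trained map: node coloring, separation accuracy, %GC
structure, diagnostic oligonucleotides, and taxon-subset highlighting.

Terminology follows the field's map figures: a node is *mono* ("colored")
when every fragment it captured carries the same taxon label at the chosen
rank, *multi* ("black") when labels mix, and *empty* ("white") when no
fragment mapped to it.  Separation accuracy is the percentage of fragments
sitting in mono nodes.  Each node's %GC is read off its weight vector via the
strand-symmetric mononucleotide profile, and a k-mer's observed/expected
ratio per node (frequency divided by the mononucleotide expectation) exposes
the oligonucleotides diagnostic for territory formation independently of GC.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kmers
from .kmers import DegenerateIndex
from .som import BatchSOM

__all__ = [
    "AnalysisError",
    "MapSummary",
    "DiagnosticMap",
    "summarize_nodes",
    "separation_accuracy",
    "gc_categories",
    "diagnostic_map",
    "subset_highlight",
    "territory_borders",
]

DEFAULT_COLOR_BREAKS = (0.78, 1.28)  # blue below, red above; presentation only


class AnalysisError(ValueError):
    """Raised for missing labels, empty maps, or invalid category requests."""


@dataclass
class MapSummary:
    """Per-node summaries of an assignment at one taxonomic rank.

    counts, gc_percent are (I, J) arrays; color_class holds 'empty', 'mono'
    or 'multi'; histograms maps (i, j) -> {label: count} for non-empty nodes.
    """

    rank: str
    counts: np.ndarray
    color_class: np.ndarray
    gc_percent: np.ndarray
    histograms: dict[tuple[int, int], dict[str, int]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_fragments(self) -> int:
        return int(self.counts.sum())

    def top_label(self, i: int, j: int) -> str:
        hist = self.histograms.get((i, j))
        if not hist:
            return ""
        return max(sorted(hist), key=lambda lab: hist[lab])

    def to_frame(self, n_categories: int | None = 9) -> pd.DataFrame:
        I, J = self.shape
        cats = None
        if n_categories is not None:
            try:
                cats = gc_categories(self, n_categories)
            except AnalysisError:
                cats = None
        rows = []
        for i in range(I):
            for j in range(J):
                rows.append(
                    {
                        "i": i,
                        "j": j,
                        "count": int(self.counts[i, j]),
                        "color_class": self.color_class[i, j],
                        "top_label": self.top_label(i, j),
                        "gc_percent": self.gc_percent[i, j],
                        "gc_category": int(cats[i, j]) if cats is not None else -1,
                    }
                )
        return pd.DataFrame(rows)


def _node_frequency(weight: np.ndarray, index: DegenerateIndex) -> np.ndarray:
    """Weight vector as a frequency vector; clamp small training drift."""
    w = np.asarray(weight, dtype=np.float64)
    if (w < 0).any():
        warnings.warn(
            "node weight vector has negative entries after training; "
            "clamping to 0 and renormalizing",
            stacklevel=3,
        )
        w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise AnalysisError("node weight vector has no positive mass")
    return w / total


def summarize_nodes(
    assignment: pd.DataFrame,
    labels,
    rank: str,
    som: BatchSOM,
    index: DegenerateIndex,
) -> MapSummary:
    """Histogram, color class, and %GC for every node of the map.

    labels is a taxon table (DataFrame indexed by or containing genome_id)
    giving each fragment's label at ``rank``; %GC comes from the node weight
    vector's mononucleotide profile.
    """
    from .ingest import read_taxon_table

    taxa = read_taxon_table(labels)
    if rank not in taxa.columns:
        raise AnalysisError(f"rank {rank!r} not present in the taxon table")
    I, J, _ = som.weights_.shape
    counts = np.zeros((I, J), dtype=np.int64)
    hists: dict[tuple[int, int], Counter] = {}
    label_of = taxa[rank].to_dict()
    for row in assignment.itertuples(index=False):
        gid = str(row.genome_id)
        if gid not in label_of or label_of[gid] == "":
            raise AnalysisError(
                f"fragment {gid}:{row.start} has no label at rank {rank!r}"
            )
        key = (int(row.i), int(row.j))
        counts[key] += 1
        hists.setdefault(key, Counter())[label_of[gid]] += 1

    color = np.full((I, J), "empty", dtype=object)
    for key, hist in hists.items():
        color[key] = "mono" if len(hist) == 1 else "multi"

    gc = np.zeros((I, J))
    for i in range(I):
        for j in range(J):
            freq = _node_frequency(som.weights_[i, j], index)
            gc[i, j] = 100.0 * float(freq @ index.gc_counts) / index.k
    return MapSummary(rank, counts, color, gc, {k: dict(v) for k, v in hists.items()})


def separation_accuracy(summary: MapSummary, mode: str = "strict") -> float:
    """Percentage of fragments separated by taxon at the summary's rank.

    strict (default): only fragments in mono nodes count as separated; every
    fragment (including those in multi nodes) is in the denominator.
    purity: fragments matching their node's majority label count as separated.
    """
    total = summary.n_fragments
    if total == 0:
        raise AnalysisError("no assigned fragments: accuracy undefined")
    if mode == "strict":
        good = sum(
            sum(h.values())
            for key, h in summary.histograms.items()
            if summary.color_class[key] == "mono"
        )
    elif mode == "purity":
        good = sum(max(h.values()) for h in summary.histograms.values())
    else:
        raise AnalysisError(f"unknown accuracy mode {mode!r}")
    return 100.0 * good / total


def gc_categories(summary: MapSummary, n_categories: int = 9) -> np.ndarray:
    """Cut non-empty nodes into GC-ranked blocks of near-equal node count.

    Nodes are ranked by gc_percent (ties broken by (i, j) order) and split
    into ``n_categories`` contiguous blocks whose sizes differ by at most one
    (larger blocks last).  Returns an (I, J) array of 1-based categories,
    with 0 marking empty nodes.
    """
    I, J = summary.shape
    nonempty = [(i, j) for i in range(I) for j in range(J) if summary.counts[i, j] > 0]
    n = len(nonempty)
    if n < n_categories:
        raise AnalysisError(
            f"only {n} non-empty nodes for {n_categories} GC categories"
        )
    order = sorted(nonempty, key=lambda ij: (summary.gc_percent[ij], ij[0], ij[1]))
    base, extra = divmod(n, n_categories)
    sizes = [base] * (n_categories - extra) + [base + 1] * extra
    out = np.zeros((I, J), dtype=np.int64)
    pos = 0
    for cat, size in enumerate(sizes, start=1):
        for ij in order[pos : pos + size]:
            out[ij] = cat
        pos += size
    return out


@dataclass
class DiagnosticMap:
    """Observed/expected ratio of one degenerate set across the map."""

    column: int
    canonical: str
    ratio_grid: np.ndarray
    color_breaks: tuple[float, float]

    @property
    def color_grid(self) -> np.ndarray:
        lo, hi = self.color_breaks
        grid = np.full(self.ratio_grid.shape, "white", dtype=object)
        grid[self.ratio_grid < lo] = "blue"
        grid[self.ratio_grid > hi] = "red"
        return grid


def diagnostic_map(
    som: BatchSOM,
    index: DegenerateIndex,
    column: int | str,
    color_breaks: tuple[float, float] = DEFAULT_COLOR_BREAKS,
) -> DiagnosticMap:
    """Per-node observed/expected ratio of one oligonucleotide pair-set.

    Each node's set frequency (from the weight vector) is divided by the
    frequency expected from that node's own mononucleotide composition, so
    over/underrepresentation is read independently of the node's %GC:
    ratio > 1 overrepresented ("red"), < 1 underrepresented ("blue").
    """
    if isinstance(column, str):
        column = index.lookup(column)
    if not 0 <= column < index.n_columns:
        raise AnalysisError(f"column {column} out of range [0, {index.n_columns})")
    I, J, _ = som.weights_.shape
    grid = np.zeros((I, J))
    for i in range(I):
        for j in range(J):
            freq = _node_frequency(som.weights_[i, j], index)
            grid[i, j] = kmers.observed_expected_ratio(freq, index, column)
    return DiagnosticMap(column, index.canonical[column], grid, tuple(color_breaks))


def subset_highlight(summary: MapSummary, target_labels) -> np.ndarray:
    """Boolean (I, J) grid: True iff a node is non-empty and *all* its
    fragments carry a target label at the summary's rank."""
    targets = set(target_labels)
    I, J = summary.shape
    out = np.zeros((I, J), dtype=bool)
    for key, hist in summary.histograms.items():
        out[key] = set(hist) <= targets
    return out


def territory_borders(summary: MapSummary) -> set[tuple[int, int]]:
    """Empty nodes whose 8-neighborhood touches >= 2 distinct mono territories."""
    I, J = summary.shape
    borders = set()
    for i in range(I):
        for j in range(J):
            if summary.color_class[i, j] != "empty":
                continue
            labels = set()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < I and 0 <= nj < J and summary.color_class[ni, nj] == "mono":
                        labels.add(next(iter(summary.histograms[(ni, nj)])))
            if len(labels) >= 2:
                borders.add((i, j))
    return borders
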