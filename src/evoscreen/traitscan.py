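"""Sequence-to-ecology scan: dendrograms from alignments and trait
tables, cophenetic correlation between them, and sliding-window
detection of alignment regions whose clustering tracks ecology more
closely than phylogeny ("trend ties").

Conventional choices, each explicit: Gower distance for mixed trait
tables, uncorrected p-distance for sequences, UPGMA (average linkage)
for dendrograms, Pearson correlation of cophenetic distance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Protocol, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io import SequenceRecord, TraitTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "TreeDistances",
    "trait_distance_matrix",
    "alignment_distance_matrix",
    "upgma",
    "cophenetic_correlation",
    "window_scan",
    "detect_trend_ties",
    "TieRegion",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix; NaN marks a missing pair.

    ``support`` counts the observations (traits or columns) behind each
    cell, for missing-data awareness.
    """

    labels: list[str]
    values: np.ndarray
    support: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, equal_nan=False):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sup = self.support[np.ix_(idx, idx)] if self.support is not None else None
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], sup)


class CopheneticSource(Protocol):
    """Anything exposing leaf labels and pairwise tree distances."""

    @property
    def leaf_labels(self) -> list[str]: ...

    def cophenetic(self, a: str, b: str) -> float: ...


@dataclass
class Dendrogram:
    """Rooted ultrametric tree from UPGMA.

    ``linkage`` is the scipy linkage matrix over ``labels`` (sorted
    lexicographically for determinism); merge heights are half the
    linkage distances, so two leaves merging at cophenetic distance d
    sit under a node of height d/2.
    """

    labels: list[str]
    linkage: np.ndarray
    _coph: np.ndarray = field(repr=False)

    @property
    def leaf_labels(self) -> list[str]:
        return self.labels

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cophenetic(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self._coph[i, j])


@dataclass
class TreeDistances:
    """Adapter presenting a dendropy tree's patristic distances as a
    cophenetic source (for phylogenetic reference trees)."""

    tree: dendropy.Tree
    _labels: list[str] = field(init=False, repr=False)
    _dist: dict[tuple[str, str], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = list(self.tree.taxon_namespace)
        self._labels = sorted(t.label for t in taxa)
        by_label = {t.label: t for t in taxa}
        self._dist = {}
        for a, b in combinations(self._labels, 2):
            d = pdm.patristic_distance(by_label[a], by_label[b])
            self._dist[(a, b)] = self._dist[(b, a)] = float(d)

    @property
    def leaf_labels(self) -> list[str]:
        return self._labels

    def cophenetic(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self._dist[(a, b)]


# ---------------------------------------------------------------------------
# distances


def trait_distance_matrix(table: TraitTable, species: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Gower distance over a mixed numeric/categorical trait table.

    Numeric traits contribute range-normalised absolute differences,
    categorical traits 0/1 mismatches; each pair averages over the
    traits non-missing in both species.  A numeric trait with zero
    range carries no information and is skipped.  A pair sharing no
    trait gets NaN (and will be rejected by UPGMA downstream).
    """
    frame = table.data if species is None else table.data.loc[list(species)]
    labels = list(frame.index)
    n = len(labels)
    parts = []  # (per-pair distance matrix, availability mask)
    for col in frame.columns:
        series = frame[col]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            avail = ~np.isnan(vals)
            rng = np.nanmax(vals) - np.nanmin(vals) if avail.any() else 0.0
            if rng == 0 or not np.isfinite(rng):
                continue
            diff = np.abs(vals[:, None] - vals[None, :]) / rng
        else:
            vals = series.to_numpy(dtype=object)
            avail = pd.notna(series).to_numpy()
            diff = (vals[:, None] != vals[None, :]).astype(float)
        mask = avail[:, None] & avail[None, :]
        parts.append((np.where(mask, diff, 0.0), mask.astype(float)))
    if not parts:
        raise ValueError("trait table has no informative traits")
    num = np.sum([p[0] for p in parts], axis=0)
    den = np.sum([p[1] for p in parts], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels, dist, support=den.astype(int))


def alignment_distance_matrix(
    alignment: Sequence[SequenceRecord], columns: Optional[Sequence[int]] = None
) -> DistanceMatrix:
    """Uncorrected p-distance over a column subset (0-based indices).

    Mismatches / columns where both rows are non-gap; a pair with zero
    comparable columns gets NaN.
    """
    if len(alignment) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    length = len(alignment[0].residues)
    if any(len(r.residues) != length for r in alignment):
        raise ValueError("alignment rows have unequal length")
    cols = list(range(length)) if columns is None else list(columns)
    if not cols:
        raise ValueError("empty column subset")
    if max(cols) >= length:
        raise ValueError("column subset exceeds alignment length")
    labels = [r.id for r in alignment]
    chars = np.array([[r.residues[c] for c in cols] for r in alignment])
    nongap = chars != "-"
    n = len(labels)
    dist = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        both = nongap[i] & nongap[j]
        m = int(both.sum())
        support[i, j] = support[j, i] = m
        if m == 0:
            dist[i, j] = dist[j, i] = np.nan
        else:
            p = np.mean(chars[i][both] != chars[j][both])
            dist[i, j] = dist[j, i] = p
    return DistanceMatrix(labels, dist, support=support)


# ---------------------------------------------------------------------------
# clustering and correlation


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) dendrogram.

    Labels are sorted lexicographically before clustering, so the
    result is invariant to input label order and ties break
    deterministically.  Missing cells are an error: apply pairwise
    deletion (drop species) upstream.
    """
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 labels")
    if not dm.complete:
        raise ValueError(
            "distance matrix has missing cells; drop species (pairwise deletion) "
            "before UPGMA"
        )
    order = sorted(range(len(dm.labels)), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    condensed = squareform(values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    coph = squareform(hierarchy.cophenet(linkage))
    return Dendrogram(labels=labels, linkage=linkage, _coph=coph)


def cophenetic_correlation(x: CopheneticSource, y: CopheneticSource) -> Optional[float]:
    """Pearson correlation of cophenetic distances over shared leaves.

    Returns None (missing) with fewer than 3 shared leaves or when
    either distance vector has zero variance.
    """
    shared = sorted(set(x.leaf_labels) & set(y.leaf_labels))
    if len(shared) < 3:
        return None
    vx = np.array([x.cophenetic(a, b) for a, b in combinations(shared, 2)])
    vy = np.array([y.cophenetic(a, b) for a, b in combinations(shared, 2)])
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        return None
    return float(pearsonr(vx, vy).statistic)


# ---------------------------------------------------------------------------
# window scan


def _drop_incomplete_species(dm: DistanceMatrix) -> DistanceMatrix:
    """Greedy pairwise deletion: remove the species with most missing
    pairs until the matrix is complete."""
    current = dm
    while not current.complete and len(current.labels) > 0:
        nan_counts = np.isnan(current.values).sum(axis=0)
        worst = int(np.argmax(nan_counts))
        keep = [l for i, l in enumerate(current.labels) if i != worst]
        current = current.subset(keep)
    return current


def window_scan(
    alignment: Sequence[SequenceRecord],
    trait_table: TraitTable,
    phylo_tree: dendropy.Tree,
    window: int = 2,
    step: int = 1,
) -> pd.DataFrame:
    """Slide a window over the alignment and correlate each window's
    UPGMA dendrogram against the ecological and phylogenetic references.

    Returns one record per window: ``start`` (1-based column), ``width``,
    ``n_species`` actually usable in that window, ``r_eco`` and
    ``r_phylo`` (NaN when undefined).  Species are harmonised to the
    intersection of alignment, trait table and tree; windowed pairs with
    no comparable columns trigger per-window species dropping.
    """
    length = len(alignment[0].residues)
    if window > length:
        raise ValueError(f"window {window} exceeds alignment length {length}")
    aln_species = {r.id for r in alignment}
    tree_species = {t.label for t in phylo_tree.taxon_namespace}
    shared = sorted(aln_species & set(trait_table.species) & tree_species)
    if len(shared) < 3:
        raise ValueError("fewer than 3 species shared by alignment, traits and tree")
    records = {r.id: r for r in alignment}
    aln = [records[s] for s in shared]

    trait_dm = trait_distance_matrix(table=trait_table, species=shared)
    trait_dm = _drop_incomplete_species(trait_dm)
    eco_dendro = upgma(trait_dm) if len(trait_dm.labels) >= 2 else None
    phylo_ref = TreeDistances(phylo_tree)

    rows = []
    for start0 in range(0, length - window + 1, step):
        cols = list(range(start0, start0 + window))
        dm = alignment_distance_matrix(aln, cols)
        dm = _drop_incomplete_species(dm)
        r_eco = r_phylo = np.nan
        n_species = len(dm.labels)
        if n_species >= 3:
            dendro = upgma(dm)
            if eco_dendro is not None:
                r = cophenetic_correlation(dendro, eco_dendro)
                r_eco = np.nan if r is None else r
            r = cophenetic_correlation(dendro, phylo_ref)
            r_phylo = np.nan if r is None else r
        rows.append(
            {
                "start": start0 + 1,
                "width": window,
                "n_species": n_species,
                "r_eco": r_eco,
                "r_phylo": r_phylo,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TieRegion:
    """Maximal run of consecutive trend-tie windows (1-based inclusive)."""

    start: int
    end: int
    n_windows: int


def detect_trend_ties(track: pd.DataFrame, min_r: float = 0.5) -> list[TieRegion]:
    """Mark windows where the ecological signal ties or beats phylogeny.

    A window is a tie iff r_eco is defined, r_eco >= min_r, and
    r_eco >= r_phylo (an undefined r_phylo does not block a tie).
    Consecutive tie windows merge into regions spanning from the first
    window's start to the last window's end column.
    """
    if track.empty:
        raise ValueError("empty window track")
    ties = []
    for _, row in track.iterrows():
        r_eco, r_phylo = row["r_eco"], row["r_phylo"]
        is_tie = (
            not np.isnan(r_eco)
            and r_eco >= min_r
            and (np.isnan(r_phylo) or r_eco >= r_phylo)
        )
        ties.append(is_tie)
    regions: list[TieRegion] = []
    run: Optional[TieRegion] = None
    for idx, is_tie in enumerate(ties):
        if is_tie:
            pos = int(track["start"].iloc[idx])
            width = int(track["width"].iloc[idx])
            if run is None:
                run = TieRegion(start=pos, end=pos + width - 1, n_windows=1)
            else:
                run.end = pos + width - 1
                run.n_windows += 1
        elif run is not None:
            regions.append(run)
            run = None
    if run is not None:
        regions.append(run)
    return regions
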