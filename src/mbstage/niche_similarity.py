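"""Spatial niche-composition similarity and temporal alignment.

The procedure: label each Visium spot with the cell type the deconvolution
estimates to be most abundant there, count the unordered cell-type pairs of
neighboring spots, normalize those counts into a composition ("pair
profile"), compute Euclidean distances between samples' profiles, invert
and rescale the distances to a [0, 1] similarity, and stage each organoid
at the similarity-weighted average of the tissue gestational timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from ._exceptions import DegenerateInputError, GeometryError, ParameterError, ValidationError
from .io_core import SampleMeta, SpotGrid, TISSUE

logger = logging.getLogger("mbstage.niche_similarity")

UNASSIGNED = "unassigned"


@dataclass
class AbundanceMatrix:
    """Spot x cell-type nonnegative abundances from an external deconvolution."""

    spots: list[str]
    types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spots), len(self.types)):
            raise ValidationError("abundance shape mismatch")
        if len(self.types) < 2:
            raise ValidationError("need >= 2 cell types")
        if np.any(self.values < 0):
            raise ValidationError("abundances must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, barcode_col: str = "barcode") -> "AbundanceMatrix":
        types = [c for c in df.columns if c != barcode_col]
        return cls(spots=list(df[barcode_col]), types=types, values=df[types].to_numpy())


@dataclass
class SpotLabeling:
    spots: list[str]
    labels: list[str]
    tie_flags: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"barcode": self.spots, "label": self.labels, "tie": self.tie_flags})


@dataclass
class PairProfile:
    """Normalized frequencies over unordered cell-type pairs of neighboring spots.

    ``pair_counts`` is a symmetric K x K integer matrix (diagonal = same-type
    adjacencies); ``freq`` is the flattened upper triangle (with diagonal),
    normalized to sum 1 over the retained edges, or all-zero when there are
    no edges.
    """

    types: list[str]
    pair_counts: np.ndarray
    n_edges: int = field(init=False)
    freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        k = len(self.types)
        if self.pair_counts.shape != (k, k):
            raise ValidationError("pair_counts must be K x K")
        if not np.array_equal(self.pair_counts, self.pair_counts.T):
            raise ValidationError("pair_counts must be symmetric")
        iu = np.triu_indices(k)
        upper = self.pair_counts[iu]
        self.n_edges = int(upper.sum())
        self.freq = upper / self.n_edges if self.n_edges > 0 else np.zeros(len(upper), dtype=float)

    def pair_basis(self) -> list[tuple[str, str]]:
        k = len(self.types)
        iu = np.triu_indices(k)
        return [(self.types[i], self.types[j]) for i, j in zip(*iu)]

    def as_frame(self) -> pd.DataFrame:
        basis = self.pair_basis()
        iu = np.triu_indices(len(self.types))
        return pd.DataFrame(
            {
                "type_a": [a for a, _ in basis],
                "type_b": [b for _, b in basis],
                "count": self.pair_counts[iu],
                "freq": self.freq,
            }
        )


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    S: np.ndarray
    D: np.ndarray

    def sim(self, a: str, b: str) -> float:
        return float(self.S[self.sample_ids.index(a), self.sample_ids.index(b)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class TemporalAlignment:
    query: str
    timepoints: list[float]
    weights: np.ndarray
    estimated_timepoint: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timepoint": self.timepoints, "weight": self.weights})


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def label_spots(ab: AbundanceMatrix, tie_rule: str = "first") -> SpotLabeling:
    """Label each spot with its most abundant type (argmax over types).

    Ties are broken by the declared type order (``tie_rule='first'``) and
    flagged; spots whose abundances are all zero are labeled ``unassigned``
    and later excluded from pair counting.
    """
    if tie_rule != "first":
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    labels, ties = [], np.zeros(len(ab.spots), dtype=bool)
    n_unassigned = 0
    for i, row in enumerate(ab.values):
        best = row.max()
        if best == 0:
            labels.append(UNASSIGNED)
            ties[i] = True
            n_unassigned += 1
            continue
        winners = np.flatnonzero(row == best)
        labels.append(ab.types[winners[0]])
        ties[i] = len(winners) > 1
    if n_unassigned:
        logger.warning("label_spots: %d spots with all-zero abundances left unassigned", n_unassigned)
    return SpotLabeling(spots=list(ab.spots), labels=labels, tie_flags=ties)


def build_adjacency(grid: SpotGrid, scale_tolerance: float = 1.05) -> SpotGrid:
    """Connect spots whose center distance is within ``scale_tolerance`` times
    the minimum pairwise center distance (the lattice pitch)."""
    if grid.n_spots < 2:
        grid.adjacency = set()
        return grid
    coords = grid.phys_coords
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    pitch = float(dists[:, 1].min())
    if pitch == 0:
        raise GeometryError("coincident spot coordinates: lattice pitch is zero")
    pairs = tree.query_pairs(r=pitch * scale_tolerance)
    grid.adjacency = {
        tuple(sorted((grid.spots[i], grid.spots[j]))) for i, j in pairs
    }
    return grid


def count_neighbor_pairs(
    grid: SpotGrid, labeling: SpotLabeling, types: list[str] | None = None
) -> PairProfile:
    """Count unordered label pairs over adjacency edges.

    Each edge contributes one count to the pair of its endpoint labels;
    edges touching an ``unassigned`` spot are excluded from both numerator
    and denominator. Diagonal (same-type) pairs are kept. ``types`` fixes
    the profile basis explicitly (defaults to first-appearance label order).
    """
    if grid.adjacency is None:
        raise ValidationError("adjacency not built")
    label_of = dict(zip(labeling.spots, labeling.labels))
    missing = [s for s in grid.spots if s not in label_of]
    if missing:
        raise ValidationError(f"labeling does not cover spots, e.g. {missing[0]!r}")
    if types is None:
        types = [t for t in dict.fromkeys(labeling.labels) if t != UNASSIGNED]
    tidx = {t: i for i, t in enumerate(types)}
    k = len(types)
    counts = np.zeros((k, k), dtype=int)
    excluded = 0
    for a, b in grid.adjacency:
        la, lb = label_of[a], label_of[b]
        if la == UNASSIGNED or lb == UNASSIGNED:
            excluded += 1
            continue
        i, j = tidx[la], tidx[lb]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    if excluded:
        logger.info("count_neighbor_pairs: %d edges excluded (unassigned endpoint)", excluded)
    profile = PairProfile(types=types, pair_counts=counts)
    if profile.n_edges == 0:
        logger.warning("count_neighbor_pairs: no retained edges; all-zero profile")
    return profile


def align_profiles(profiles: list[PairProfile]) -> tuple[list[str], np.ndarray]:
    """Embed profiles into the union type basis (stable first-appearance order).

    Returns the union type list and a (n_samples, K(K+1)/2) frequency matrix;
    pairs absent from a sample are zero.
    """
    union: list[str] = []
    for p in profiles:
        for t in p.types:
            if t not in union:
                union.append(t)
    k = len(union)
    iu = np.triu_indices(k)
    out = np.zeros((len(profiles), len(iu[0])))
    for n, p in enumerate(profiles):
        counts = np.zeros((k, k))
        idx = np.array([union.index(t) for t in p.types], dtype=int)
        counts[np.ix_(idx, idx)] = p.pair_counts
        upper = counts[iu]
        total = upper.sum()
        if total > 0:
            out[n] = upper / total
    return union, out


def sample_similarity(profiles: list[PairProfile], sample_ids: list[str]) -> SimilarityMatrix:
    """Euclidean distances between pair-profile compositions, inverted and
    rescaled so the most dissimilar pair of samples scores exactly 0 and
    identical samples score 1."""
    if len(profiles) < 2:
        raise ParameterError("need >= 2 samples")
    if len(profiles) != len(sample_ids):
        raise ValidationError("profiles and sample ids must align")
    _, freqs = align_profiles(profiles)
    D = squareform(pdist(freqs, metric="euclidean"))
    dmax = D.max()
    if dmax == 0:
        logger.warning("sample_similarity: all profiles identical; S = 1 everywhere")
        S = np.ones_like(D)
    else:
        S = 1.0 - D / dmax
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(sample_ids=list(sample_ids), S=S, D=D)


def temporal_alignment(
    sim: SimilarityMatrix, query: str, tissue_metas: list[SampleMeta]
) -> TemporalAlignment:
    """Stage a query sample at the similarity-weighted mean tissue timepoint.

    Replicates of one timepoint are averaged at the similarity level; the
    per-timepoint mean similarities, normalized to sum 1, are the weights.
    """
    metas = [m for m in tissue_metas if m.kind == TISSUE]
    if any(m.sample_id == query for m in metas):
        raise ParameterError("query must not be a tissue sample")
    by_tp: dict[float, list[str]] = {}
    for m in metas:
        by_tp.setdefault(m.timepoint_value, []).append(m.sample_id)
    if len(by_tp) < 2:
        raise ParameterError("need >= 2 tissue timepoints")
    timepoints = sorted(by_tp)
    sims = np.array([np.mean([sim.sim(query, sid) for sid in by_tp[t]]) for t in timepoints])
    total = sims.sum()
    if total <= 0:
        raise DegenerateInputError(
            f"all similarities of {query!r} to tissue timepoints are zero; alignment undefined"
        )
    weights = sims / total
    est = float(np.dot(weights, timepoints))
    return TemporalAlignment(query=query, timepoints=timepoints, weights=weights, estimated_timepoint=est)
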